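"""Readers and writers for the plain-text formats at the package boundary.

Internal coordinates are 1-based inclusive everywhere; bedGraph and BED are
0-based half-open on disk, and the conversion happens here and only here.
Writers accept an optional seed which is recorded as a header comment so a
simulated fixture documents its own provenance.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import InputError
from .cage import TagTable
from .variants import PileupColumn

_BASE_COLS = ["A", "C", "G", "T"]


def _header(seed: int | None) -> str:
    return f"# seed={seed}\n" if seed is not None else ""


# ---------------------------------------------------------------- bedGraph

def write_bedgraph(depth: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a binned depth/ratio profile (columns chrom, start, end and one
    value column named depth or value) as bedGraph (0-based half-open)."""
    value_col = "depth" if "depth" in depth.columns else "value"
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write('track type=bedGraph name="promdel"\n')
        for row in depth.itertuples():
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{getattr(row, value_col)}\n")


def read_bedgraph(path: str | Path, value_col: str = "depth") -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start) + 1, int(end), float(value)))
    if not rows:
        raise InputError(f"no data lines in {path}")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", value_col])
    if (df[value_col] % 1 == 0).all():
        df[value_col] = df[value_col].astype(int)
    return df


# ------------------------------------------------------------- pileup TSV

def write_pileup_tsv(columns: list[PileupColumn], path: str | Path, seed: int | None = None) -> None:
    """Pileup TSV: chrom, pos, ref, A, C, G, T, then any indel alleles as
    extra columns named by the allele string."""
    extra = sorted({al for c in columns for al in c.counts if al not in _BASE_COLS})
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write("\t".join(["chrom", "pos", "ref"] + _BASE_COLS + extra) + "\n")
        for col in columns:
            counts = [str(col.counts.get(b, 0)) for b in _BASE_COLS + extra]
            fh.write("\t".join([col.chrom, str(col.pos), col.ref_base] + counts) + "\n")


def read_pileup_tsv(path: str | Path) -> list[PileupColumn]:
    df = pd.read_csv(path, sep="\t", comment="#")
    allele_cols = [c for c in df.columns if c not in ("chrom", "pos", "ref")]
    return [
        PileupColumn(
            chrom=rec["chrom"],
            pos=int(rec["pos"]),
            ref_base=rec["ref"],
            counts={al: int(rec[al]) for al in allele_cols},
        )
        for rec in df.to_dict("records")
    ]


# ----------------------------------------------------------------- tag BED

def write_tags_bed(table: TagTable, path: str | Path, seed: int | None = None) -> None:
    """CAGE tags as BED6 with the tag count in the score field; the library's
    total mapped tags are recorded in a header comment."""
    with open(path, "w") as fh:
        fh.write(_header(seed))
        fh.write(f"# sample={table.sample_id} total_mapped={table.total_mapped}\n")
        for row in table.records.itertuples():
            fh.write(
                f"{row.chrom}\t{row.pos - 1}\t{row.pos}\ttag\t{row.count}\t{row.strand}\n"
            )


def read_tags_bed(path: str | Path) -> TagTable:
    sample_id, total_mapped = "", None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    if tok.startswith("sample="):
                        sample_id = tok.split("=", 1)[1]
                    elif tok.startswith("total_mapped="):
                        total_mapped = int(tok.split("=", 1)[1])
                continue
            if not line or line.startswith(("track", "browser")):
                continue
            chrom, start, _end, _name, score, strand = line.split("\t")
            rows.append((chrom, int(start) + 1, strand, int(score)))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
    df = df.sort_values(["chrom", "strand", "pos"], kind="stable").reset_index(drop=True)
    if total_mapped is None:
        total_mapped = int(df["count"].sum())
    return TagTable(sample_id=sample_id, records=df, total_mapped=total_mapped)


# ----------------------------------------------------------- promoter BED

def read_promoters_bed(path: str | Path) -> pd.DataFrame:
    """Named, strand-annotated promoter windows from BED6; returns 1-based
    inclusive columns name, chrom, start, end, strand."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise InputError("promoter BED needs 6 columns incl. name and strand")
            chrom, start, end, name, _score, strand = fields[:6]
            rows.append((name, chrom, int(start) + 1, int(end), strand))
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "strand"])


def write_promoters_bed(promoters: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in promoters.itertuples():
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.name}\t0\t{row.strand}\n")


# -------------------------------------------------------------------- FASTA

def write_fasta(records: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------- VCF output

def write_vcf(calls, path: str | Path) -> None:
    """Minimal VCF for scored variant calls (called sites only), with the
    posterior score and triage class in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SCORE,Number=1,Type=Float,Description="Pr(variant fraction >= theta)">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Pathogenicity triage class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            if not c.called:
                continue
            info = f"SCORE={c.score:.6g}"
            if c.classification:
                info += f";CLASS={c.classification}"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")
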