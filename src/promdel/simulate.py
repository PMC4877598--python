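"""Seeded simulators for every input the pipeline consumes.

The generators emulate the data regimes of a whole-genome-sequencing FAP case
study: ~30x binned read depth with a heterozygous ~10 kb promoter deletion,
pileup columns with sequencing error and heterozygous SNPs, deep-cDNA
allele-specific read counts with a skewed mutant fraction, and CAGE tag
libraries with two APC promoter peaks of very unequal strength, the major one
(promoter 1B) halved in the "patient" sample.

All draws come from ``numpy.random.default_rng`` seeded from the config, so
identical seeds reproduce byte-identical outputs. Coordinates are 1-based
inclusive throughout.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import ConfigError
from .ase import AlleleCounts
from .cage import TagTable
from .variants import PileupColumn

_BASES = np.array(["A", "C", "G", "T"])
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Default promoter windows on a synthetic contig pair. APC sits on the minus
#: strand; the two promoters are ~30 kb apart as in the real locus. These are
#: fixture coordinates, not genome annotations.
DEFAULT_PROMOTER_WINDOWS: dict[str, tuple[str, int, int, str]] = {
    "APC-1B": ("sim5", 40_001, 40_200, "-"),
    "APC-1A": ("sim5", 70_001, 70_200, "-"),
    "ACTB": ("sim7", 5_001, 5_200, "+"),
}

#: Expected CAGE tags per promoter in a healthy-control library of ten million
#: mapped tags: ~30 TPM for APC-1B, ~0.7 TPM for APC-1A (a ~44-fold gap) and
#: ~2,500 TPM for ACTB, the scale the blood CAGE runs show.
DEFAULT_PROMOTER_RATES: dict[str, float] = {
    "APC-1B": 300.0,
    "APC-1A": 7.0,
    "ACTB": 25_000.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the case-study conditions: a 50 kb region binned at
    250 bp with mean diploid depth 30 reads/bin, a heterozygous 10 kb deletion
    covering bins 81-120, per-base error rate 0.5%, heterozygous SNPs at
    balanced allelic depth, 28,437 deep-cDNA reads with mutant fraction 0.112,
    and the CAGE promoter rates above in a 10^7-tag library.
    """

    seed: int = 0
    region_length_bp: int = 50_000
    bin_size_bp: int = 250
    mean_depth: float = 30.0
    deletion_interval: tuple[int, int] | None = (20_001, 30_000)
    error_rate: float = 0.005
    het_sites: tuple[tuple[int, str, str], ...] = (
        (5_000, "G", "A"),
        (12_500, "C", "T"),
        (35_000, "T", "C"),
        (45_000, "A", "G"),
    )
    #: which allele of a het site lies on the deleted haplotype when the site
    #: falls inside the deletion ("ref" or "alt"); the survivor is the other.
    deletion_linked_allele: str = "alt"
    ase_fraction: float = 0.112
    cdna_total_reads: int = 28_437
    promoter_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROMOTER_RATES)
    )
    promoter_windows: dict[str, tuple[str, int, int, str]] = field(
        default_factory=lambda: dict(DEFAULT_PROMOTER_WINDOWS)
    )
    background_rate: float = 20.0
    #: sd (bp) of the rounded-normal scatter of tag 5' ends around the
    #: promoter-window centre; CAGE TSS peaks concentrate most tags on a few
    #: dominant start positions, so the default is sharp.
    peak_sd: float = 1.0
    library_size: int = 10_000_000
    chrom: str = "sim5"

    def validate(self) -> None:
        if self.region_length_bp <= 0 or self.bin_size_bp <= 0:
            raise ConfigError("region_length_bp and bin_size_bp must be positive")
        if self.mean_depth < 0:
            raise ConfigError("mean_depth must be non-negative")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ConfigError("error_rate must lie in [0, 0.05]")
        if not (0.0 <= self.ase_fraction <= 1.0):
            raise ConfigError("ase_fraction must lie in [0, 1]")
        if self.cdna_total_reads < 0 or self.library_size < 0:
            raise ConfigError("counts must be non-negative")
        if self.deletion_interval is not None:
            s, e = self.deletion_interval
            if not (1 <= s <= e <= self.region_length_bp):
                raise ConfigError(
                    f"deletion_interval {self.deletion_interval} must lie within "
                    f"[1, {self.region_length_bp}] with start <= end"
                )
        pos = [p for p, _, _ in self.het_sites]
        if len(pos) != len(set(pos)):
            raise ConfigError("het_sites positions must be unique")
        for p, ref, alt in self.het_sites:
            if not (1 <= p <= self.region_length_bp):
                raise ConfigError(f"het site {p} outside region")
            if ref not in _BASE_INDEX or alt not in _BASE_INDEX or ref == alt:
                raise ConfigError(f"bad het site alleles {ref}/{alt}")
        if self.deletion_linked_allele not in ("ref", "alt"):
            raise ConfigError("deletion_linked_allele must be 'ref' or 'alt'")
        for r in self.promoter_rates.values():
            if r < 0:
                raise ConfigError("promoter rates must be non-negative")
        for name in self.promoter_rates:
            if name not in self.promoter_windows:
                raise ConfigError(f"no promoter window configured for {name!r}")


def with_deletion_halved_1b(config: SimConfig) -> SimConfig:
    """Patient-condition variant of *config*: APC-1B CAGE rate halved."""
    rates = dict(config.promoter_rates)
    if "APC-1B" in rates:
        rates["APC-1B"] = rates["APC-1B"] / 2.0
    return replace(config, promoter_rates=rates)


def _rng(config_seed: int, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, purpose)."""
    return np.random.default_rng([config_seed, zlib.crc32(stream.encode())])


def _copy_number(positions: np.ndarray, interval: tuple[int, int] | None) -> np.ndarray:
    cn = np.full(positions.shape, 2, dtype=np.int64)
    if interval is not None:
        s, e = interval
        cn[(positions >= s) & (positions <= e)] = 1
    return cn


def simulate_depth(config: SimConfig) -> pd.DataFrame:
    """Binned read depth over the region: one Poisson draw per bin with mean
    ``mean_depth * copy_number / 2``, copy number 1 inside the deletion.

    A bin is assigned copy number 1 when its midpoint falls inside the
    deletion interval. Returns a frame with 1-based inclusive ``start``/``end``
    and integer ``depth``; the last bin is truncated at the region end.
    """
    config.validate()
    rng = _rng(config.seed, "depth")
    starts = np.arange(1, config.region_length_bp + 1, config.bin_size_bp)
    ends = np.minimum(starts + config.bin_size_bp - 1, config.region_length_bp)
    mid = (starts + ends) // 2
    cn = _copy_number(mid, config.deletion_interval)
    lam = config.mean_depth * cn / 2.0
    depth = rng.poisson(lam)
    return pd.DataFrame(
        {"chrom": config.chrom, "start": starts, "end": ends, "depth": depth}
    )


def simulate_pileup(config: SimConfig) -> list[PileupColumn]:
    """Per-position pileup columns across the region.

    Depth per position is Poisson with the copy-adjusted mean. At ordinary
    positions each read reports the reference base unless it errs (probability
    ``error_rate``, uniformly to one of the three other bases). At
    heterozygous sites reads first pick an allele (Binomial(depth, 1/2)), then
    err. A het site falling inside the heterozygous deletion keeps only the
    allele not linked to the deleted haplotype, so its pre-error allele
    fraction is forced to 0 or 1.
    """
    config.validate()
    rng = _rng(config.seed, "pileup")
    n = config.region_length_bp
    positions = np.arange(1, n + 1)
    ref_idx = rng.integers(0, 4, size=n)
    het = {p: (ref, alt) for p, ref, alt in config.het_sites}
    for p, (ref, _alt) in het.items():
        ref_idx[p - 1] = _BASE_INDEX[ref]

    cn = _copy_number(positions, config.deletion_interval)
    depth = rng.poisson(config.mean_depth * cn / 2.0)

    counts = np.zeros((n, 4), dtype=np.int64)
    # errors at non-variant positions, vectorised
    n_err = rng.binomial(depth, config.error_rate)
    err_split = rng.multinomial(n_err, [1 / 3] * 3)  # per-position 3-way split
    counts[np.arange(n), ref_idx] = depth - n_err
    # scatter error counts over the three non-reference bases in base order
    other = np.argsort(ref_idx[:, None] == np.arange(4)[None, :], axis=1, kind="stable")[:, :3]
    other.sort(axis=1)
    np.put_along_axis(counts, other, np.take_along_axis(counts, other, 1) + err_split, 1)

    # redo het sites exactly: allele draw, then per-allele errors
    for p, (ref, alt) in het.items():
        i = p - 1
        d = int(depth[i])
        col = np.zeros(4, dtype=np.int64)
        ri, ai = _BASE_INDEX[ref], _BASE_INDEX[alt]
        if cn[i] == 1:  # hemizygous: only the retained allele remains
            retained = ri if config.deletion_linked_allele == "alt" else ai
            allele_counts = {retained: d}
        else:
            a = int(rng.binomial(d, 0.5))
            allele_counts = {ai: a, ri: d - a}
        for src, k in allele_counts.items():
            errs = int(rng.binomial(k, config.error_rate))
            col[src] += k - errs
            targets = [b for b in range(4) if b != src]
            col[targets] += rng.multinomial(errs, [1 / 3] * 3)
        counts[i] = col

    cols = []
    for i in range(n):
        cols.append(
            PileupColumn(
                chrom=config.chrom,
                pos=i + 1,
                ref_base=str(_BASES[ref_idx[i]]),
                counts={str(b): int(c) for b, c in zip(_BASES, counts[i])},
            )
        )
    return cols


def simulate_ase_counts(
    n: int,
    pi: float,
    seed: int,
    site: str = "rs2229992",
    mutant_allele: str = "T",
    wild_allele: str = "C",
) -> AlleleCounts:
    """Deep-cDNA allele counts at one heterozygous coding SNP: mutant reads
    are Binomial(n, pi), wild reads the remainder."""
    if n < 0:
        raise ConfigError("total reads must be non-negative")
    if not (0.0 <= pi <= 1.0):
        raise ConfigError("pi must lie in [0, 1]")
    rng = np.random.default_rng([seed, zlib.crc32(b"ase")])
    mutant = int(rng.binomial(n, pi))
    return AlleleCounts(
        site=site,
        allele_a=mutant_allele,
        count_a=mutant,
        allele_b=wild_allele,
        count_b=n - mutant,
        mutant_allele=mutant_allele,
    )


def simulate_cage(config: SimConfig, sample_id: str = "control") -> TagTable:
    """One CAGE library: per-promoter tag totals are Poisson(rate), tag 5'
    positions concentrate near the promoter-window centre (rounded normal,
    sd = ``peak_sd`` bp, clipped to the window) on the window's strand. Background
    tags (Poisson(background_rate) per chromosome) scatter uniformly over the
    window span +/- 20 kb on random strands, the sparse unannotated
    transcription a deep library shows at this locus scale. ``total_mapped`` is the configured
    library size, standing for all genome-wide mapped tags."""
    config.validate()
    rng = _rng(config.seed, f"cage:{sample_id}")
    rows: list[tuple[str, int, str]] = []
    for name in sorted(config.promoter_rates):
        rate = config.promoter_rates[name]
        chrom, start, end, strand = config.promoter_windows[name]
        total = rng.poisson(rate)
        if total == 0:
            continue
        centre = (start + end) / 2.0
        pos = np.rint(rng.normal(centre, config.peak_sd, size=total)).astype(np.int64)
        pos = np.clip(pos, start, end)
        rows.extend((chrom, int(p), strand) for p in pos)

    if config.background_rate > 0:
        by_chrom: dict[str, tuple[int, int]] = {}
        for chrom, start, end, _ in config.promoter_windows.values():
            lo, hi = by_chrom.get(chrom, (start, end))
            by_chrom[chrom] = (min(lo, start), max(hi, end))
        for chrom in sorted(by_chrom):
            lo, hi = by_chrom[chrom]
            k = rng.poisson(config.background_rate)
            pos = rng.integers(max(1, lo - 20_000), hi + 20_000, size=k, endpoint=True)
            strands = rng.choice(["+", "-"], size=k)
            rows.extend((chrom, int(p), str(s)) for p, s in zip(pos, strands))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    if df.empty:
        df = pd.DataFrame({"chrom": [], "pos": [], "strand": [], "count": []})
        df = df.astype({"pos": np.int64, "count": np.int64})
    else:
        df = (
            df.groupby(["chrom", "strand", "pos"], as_index=False)
            .size()
            .rename(columns={"size": "count"})
            .sort_values(["chrom", "strand", "pos"], kind="stable")
            .reset_index(drop=True)[["chrom", "pos", "strand", "count"]]
        )
    total_tags = int(df["count"].sum()) if len(df) else 0
    return TagTable(
        sample_id=sample_id,
        records=df,
        total_mapped=max(config.library_size, total_tags),
    )
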