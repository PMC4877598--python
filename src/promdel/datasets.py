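"""Small packaged tables used by the worked examples and tests.

``load_variant_table`` carries the 15 coding variants found in the polyposis
genes of the index case, with their consequence annotations and
database status; the population allele-frequency column holds representative
dbSNP-scale values for the triage rules (only the two uncharacterized
nonsynonymous rows are sensitive to it). ``load_promoter_tpm`` and
``load_wnt_target_tpm`` carry the measured blood CAGE promoter activities
(TPM) of the patient and two healthy controls; activities below the 0.1 TPM
reporting floor appear as NaN with the matching ``*_below_floor`` flag set.
``load_promoter_windows`` returns the synthetic promoter windows matching the
CAGE simulator's default coordinates.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_promoters_bed


def _path(name: str):
    return resources.files("promdel.data").joinpath(name)


def load_variant_table() -> pd.DataFrame:
    """Coding variants in the five polyposis-associated genes screened in the
    index case (gene, consequence, db_status, af_dbsnp)."""
    with resources.as_file(_path("polyposis_gene_variants.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def _load_tpm(name: str, key: str) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    out = df[[key]].copy()
    for col in df.columns[1:]:
        floor = df[col].str.startswith("<")
        out[col] = pd.to_numeric(df[col].where(~floor), errors="coerce")
        out[col + "_below_floor"] = floor
    return out


def load_promoter_tpm() -> pd.DataFrame:
    """Blood CAGE promoter activities (TPM) for APC-1B, APC-1A and ACTB in
    the patient and two healthy controls."""
    return _load_tpm("blood_promoter_tpm.tsv", "promoter")


def load_wnt_target_tpm() -> pd.DataFrame:
    """Blood CAGE activities (TPM) of canonical Wnt target genes in the same
    three samples."""
    return _load_tpm("wnt_target_tpm.tsv", "gene")


def load_promoter_windows() -> pd.DataFrame:
    """Synthetic promoter windows (1-based inclusive) matching the CAGE
    simulator's default coordinates."""
    with resources.as_file(_path("promoters.bed")) as p:
        return read_promoters_bed(p)
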