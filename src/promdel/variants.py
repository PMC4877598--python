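"""Bayesian variant scoring on pileup columns and pathogenicity triage.

The caller scores each candidate site by updating a non-informative beta
prior with the observed allele counts: with ``alt`` of ``depth`` reads
supporting the alternate allele, the variant fraction X has posterior
Beta(a0 + alt, b0 + depth - alt), and the site's score is the posterior
probability Pr(X >= theta) that at least a fraction theta (default 5%) of the
DNA carries the variant. Sites whose score exceeds 0.9 (strictly) at adequate
depth are called.

Triage of called variants follows the polyposis-gene screening rules: a
database-annotated status wins outright; otherwise an uncharacterized
nonsynonymous variant is non-pathologic when its maximum population allele
frequency exceeds the gene-specific cutoff (0.01 for APC/BMPR1A/STK11, 0.05
for MUTYH/NTHL1), is a VUS when it does not, and synonymous uncharacterized
variants are non-pathologic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from ._util import InputError

NON_PATHOLOGIC = "non-pathologic"
VUS = "VUS"
CANDIDATE_PATHOLOGIC = "candidate-pathologic"

#: Beta prior shapes by name. "uniform" is the default reading of a
#: non-informative prior; Jeffreys is available for sensitivity checks.
PRIORS: dict[str, tuple[float, float]] = {
    "uniform": (1.0, 1.0),
    "jeffreys": (0.5, 0.5),
}


@dataclass(frozen=True)
class PileupColumn:
    """One reference position: reference base and per-allele read counts.

    ``counts`` maps allele strings to non-negative read counts; keys beyond
    the four bases (e.g. ``"+AG"``, ``"-T"``) represent short insertions and
    deletions, which are scored by the same rule as SNVs.
    """

    chrom: str
    pos: int
    ref_base: str
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"position must be >= 1, got {self.pos}")
        if any(c < 0 for c in self.counts.values()):
            raise InputError("read counts must be non-negative")


@dataclass(frozen=True)
class CallerConfig:
    """Scoring parameters: prior shapes, variant-fraction threshold theta,
    the strict call threshold on the score, and a depth floor (with a uniform
    prior a zero-depth site already scores 0.95, so calling requires data)."""

    prior_a: float = 1.0
    prior_b: float = 1.0
    theta: float = 0.05
    call_threshold: float = 0.9
    min_depth: int = 8

    @classmethod
    def from_prior_name(cls, name: str, **kw) -> "CallerConfig":
        a, b = PRIORS[name]
        return cls(prior_a=a, prior_b=b, **kw)

    def __post_init__(self) -> None:
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise InputError("prior shapes must be positive")
        if not (0.0 < self.theta < 1.0):
            raise InputError("theta must lie in (0, 1)")


@dataclass
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    score: float
    called: bool
    gene: str | None = None
    consequence: str | None = None
    max_population_af: float | None = None
    db_status: str | None = None
    classification: str | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GeneThresholds:
    """Per-gene population-AF cutoffs used in triage (strict '>')."""

    cutoffs: dict[str, float] = field(
        default_factory=lambda: {
            "APC": 0.01,
            "BMPR1A": 0.01,
            "STK11": 0.01,
            "MUTYH": 0.05,
            "NTHL1": 0.05,
        }
    )
    default_cutoff: float = 0.01

    def cutoff_for(self, gene: str | None) -> float:
        if gene is None:
            return self.default_cutoff
        return self.cutoffs.get(gene, self.default_cutoff)

    def __post_init__(self) -> None:
        for g, c in self.cutoffs.items():
            if not (0.0 < c < 1.0):
                raise InputError(f"cutoff for {g} must lie in (0,1)")


def beta_posterior(
    alt_count: int, depth: int, prior_a: float = 1.0, prior_b: float = 1.0
) -> tuple[float, float]:
    """Conjugate update of a Beta(prior_a, prior_b) prior on the variant
    fraction with ``alt_count`` supporting reads out of ``depth``."""
    if prior_a <= 0 or prior_b <= 0:
        raise InputError("prior shapes must be positive")
    if alt_count < 0 or depth < 0 or alt_count > depth:
        raise InputError(f"need 0 <= alt_count <= depth, got {alt_count}/{depth}")
    return (prior_a + alt_count, prior_b + depth - alt_count)


def variant_score(posterior: tuple[float, float], theta: float = 0.05) -> float:
    """Pr(X >= theta) for X ~ Beta(a, b): the regularized incomplete beta
    survival function. Accepts array-valued shapes for bulk scoring."""
    a, b = posterior
    if np.any(np.asarray(theta) <= 0) or np.any(np.asarray(theta) >= 1):
        raise InputError("theta must lie in (0, 1)")
    res = 1.0 - special.betainc(a, b, theta)
    return float(res) if np.isscalar(a) else res


def _best_alt(column: PileupColumn) -> tuple[str, int] | None:
    alts = [(al, c) for al, c in column.counts.items() if al != column.ref_base and c > 0]
    if not alts:
        return None
    # highest count wins; ties broken by lexicographic allele order
    return min(alts, key=lambda t: (-t[1], t[0]))


def call_variants(
    columns: list[PileupColumn], config: CallerConfig | None = None
) -> list[VariantCall]:
    """Score every column's strongest non-reference allele and call it when
    the score strictly exceeds the threshold at depth >= min_depth.

    Columns must be sorted by (chrom, pos). At most one call per position is
    emitted (the max-count alternate allele).
    """
    config = config or CallerConfig()
    keys = [(c.chrom, c.pos) for c in columns]
    if keys != sorted(keys):
        raise InputError("pileup columns must be sorted by (chrom, pos)")

    picked = [(c, _best_alt(c)) for c in columns]
    picked = [(c, ba) for c, ba in picked if ba is not None]
    if not picked:
        return []
    alt_counts = np.array([ba[1] for _, ba in picked], dtype=float)
    depths = np.array([c.depth for c, _ in picked], dtype=float)
    scores = variant_score(
        (config.prior_a + alt_counts, config.prior_b + depths - alt_counts),
        config.theta,
    )
    calls = []
    for (col, (alt, cnt)), score in zip(picked, np.atleast_1d(scores)):
        called = (score > config.call_threshold) and (col.depth >= config.min_depth)
        calls.append(
            VariantCall(
                chrom=col.chrom,
                pos=col.pos,
                ref=col.ref_base,
                alt=alt,
                alt_count=cnt,
                depth=col.depth,
                score=float(score),
                called=bool(called),
            )
        )
    return calls


def classify_variant(
    consequence: str,
    db_status: str | None,
    max_population_af: float | None,
    gene: str | None,
    thresholds: GeneThresholds | None = None,
) -> tuple[str, tuple[str, ...]]:
    """Triage one variant; returns ``(classification, flags)``.

    Database knowledge is decisive: an annotated non-pathologic variant stays
    non-pathologic, an annotated pathologic one becomes candidate-pathologic.
    Uncharacterized variants fall through to the frequency rule (strict '>'
    against the gene's cutoff); a nonsynonymous variant with no AF available
    is conservatively a VUS, flagged ``no-AF``.
    """
    thresholds = thresholds or GeneThresholds()
    if db_status == "non-pathologic":
        return NON_PATHOLOGIC, ()
    if db_status == "pathologic":
        return CANDIDATE_PATHOLOGIC, ()
    if consequence == "nonsynonymous":
        if max_population_af is None:
            return VUS, ("no-AF",)
        if max_population_af > thresholds.cutoff_for(gene):
            return NON_PATHOLOGIC, ()
        return VUS, ()
    # synonymous (or other non-coding consequence) without database evidence
    return NON_PATHOLOGIC, ()


def classify_table(
    table: pd.DataFrame, thresholds: GeneThresholds | None = None
) -> pd.DataFrame:
    """Classify every row of an annotation table with columns ``gene``,
    ``consequence``, ``db_status`` and one or more ``af_*`` population
    frequency columns (the maximum across them is used; all-missing = no AF).
    Returns a copy with ``max_population_af``, ``classification``, ``flags``.
    """
    af_cols = [c for c in table.columns if c.startswith("af_")]
    out = table.copy()
    max_af = out[af_cols].max(axis=1, skipna=True) if af_cols else pd.Series(
        np.nan, index=out.index
    )
    out["max_population_af"] = max_af
    results = [
        classify_variant(
            row.consequence,
            None if pd.isna(row.db_status) else row.db_status,
            None if pd.isna(af) else float(af),
            row.gene,
            thresholds,
        )
        for row, af in zip(out.itertuples(), max_af)
    ]
    out["classification"] = [r[0] for r in results]
    out["flags"] = [",".join(r[1]) for r in results]
    return out
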