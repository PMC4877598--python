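"""CAGE tag clustering, TPM normalization and promoter-activity comparison.

CAGE sequences the 5' ends of capped transcripts, so the per-position tag
counts profile transcription-start usage directly. Tags are normalized to
tags-per-million (TPM) by the library's total mapped tags, grouped into
strand-aware single-linkage clusters, and clusters below 0.1 TPM per base of
width are discarded (strict <). Promoter activity is the summed TPM of
same-strand clusters overlapping a named promoter window; activities under
0.1 TPM are reported as a "<0.1" floor rather than a number, the convention
of the expression tables this package reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import InputError, round_half_away

#: Activities below this TPM are reported as a floor ("<0.1"), never as 0.
TPM_FLOOR = 0.1


class BelowFloorError(ValueError):
    """A ratio was requested against an activity below the reporting floor."""


def _below(value: float, floor: float) -> bool:
    """Strictly below *floor*, with a relative guard so a value that equals
    the floor in exact arithmetic (e.g. one 0.1-TPM tag per base) is not
    dropped by float rounding. NaN (an activity recorded only as "<floor")
    counts as below."""
    if math.isnan(value):
        return True
    return value < floor and not math.isclose(value, floor, rel_tol=1e-9)


@dataclass
class TagTable:
    """One CAGE library: per-position 5'-end tag counts plus the library's
    total mapped tags (>= the tags in the table; genome-wide mapping basis)."""

    sample_id: str
    records: pd.DataFrame  # columns chrom, pos (1-based), strand, count
    total_mapped: int

    def __post_init__(self) -> None:
        req = {"chrom", "pos", "strand", "count"}
        if not req.issubset(self.records.columns):
            raise InputError(f"tag table needs columns {sorted(req)}")
        if len(self.records) and (self.records["count"] < 1).any():
            raise InputError("tag counts must be >= 1")
        if self.total_mapped < int(self.records["count"].sum() if len(self.records) else 0):
            raise InputError("total_mapped cannot be below the tags in the table")


@dataclass
class TagCluster:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    tag_count: int
    tpm: float
    peak_pos: int  # member position with the highest count (leftmost on ties)

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def density(self) -> float:
        return self.tpm / self.width


@dataclass
class PromoterActivity:
    sample_id: str
    promoter: str
    tpm: float
    below_floor: bool

    def render(self) -> str:
        return f"<{TPM_FLOOR}" if self.below_floor else f"{self.tpm:.2f}"


def normalize_tpm(count: float, total_mapped: int) -> float:
    """Tags-per-million: count / total_mapped * 1e6."""
    if total_mapped <= 0:
        raise InputError("total_mapped must be positive")
    if count < 0:
        raise InputError("count must be non-negative")
    return count / total_mapped * 1e6


def cluster_tags(
    table: TagTable, max_gap: int = 20, min_density: float = TPM_FLOOR
) -> list[TagCluster]:
    """Single-linkage, strand-aware tag clustering.

    Consecutive tag positions on the same chrom/strand join one cluster while
    the gap between neighbours is <= ``max_gap`` bp; clusters whose TPM per
    base of width is strictly below ``min_density`` are omitted (set
    ``min_density=0`` to keep everything). Records must be sorted by
    (chrom, strand, pos).
    """
    df = table.records
    clusters: list[TagCluster] = []
    if df.empty:
        return clusters
    key = df[["chrom", "strand", "pos"]].apply(tuple, axis=1).tolist()
    if key != sorted(key):
        raise InputError("tag records must be sorted by (chrom, strand, pos)")

    chrom = df["chrom"].to_numpy()
    strand = df["strand"].to_numpy()
    pos = df["pos"].to_numpy()
    cnt = df["count"].to_numpy()
    new = np.ones(len(df), dtype=bool)
    same = (chrom[1:] == chrom[:-1]) & (strand[1:] == strand[:-1])
    new[1:] = ~(same & (pos[1:] - pos[:-1] <= max_gap))
    group = np.cumsum(new) - 1

    for g in range(group[-1] + 1):
        sel = group == g
        p, c = pos[sel], cnt[sel]
        total = int(c.sum())
        cluster = TagCluster(
            chrom=str(chrom[sel][0]),
            start=int(p.min()),
            end=int(p.max()),
            strand=str(strand[sel][0]),
            tag_count=total,
            tpm=normalize_tpm(total, table.total_mapped),
            peak_pos=int(p[np.argmax(c)]),
        )
        if _below(cluster.density, min_density):
            continue
        clusters.append(cluster)
    return clusters


def _overlaps(cluster: TagCluster, row) -> bool:
    return (
        cluster.chrom == row.chrom
        and cluster.strand == row.strand
        and cluster.start <= row.end
        and cluster.end >= row.start
    )


def promoter_activity(
    clusters: list[TagCluster],
    promoters: pd.DataFrame,
    sample_id: str = "",
) -> list[PromoterActivity]:
    """Per-promoter activity: summed TPM of same-strand clusters overlapping
    each named window.

    ``promoters`` needs columns name, chrom, start, end, strand (1-based
    inclusive). When promoter windows overlap each other, each cluster is
    credited only to the window containing its peak position (first window in
    table order on further ties) so no tag is double counted.
    """
    req = {"name", "chrom", "start", "end", "strand"}
    if not req.issubset(promoters.columns):
        raise InputError(f"promoter table needs columns {sorted(req)}")

    rows = list(promoters.itertuples())
    windows_overlap = any(
        a.chrom == b.chrom
        and a.strand == b.strand
        and a.start <= b.end
        and b.start <= a.end
        for i, a in enumerate(rows)
        for b in rows[i + 1 :]
    )

    tpm = {row.name: 0.0 for row in rows}
    for cl in clusters:
        hits = [row for row in rows if _overlaps(cl, row)]
        if not hits:
            continue
        if windows_overlap and len(hits) > 1:
            containing = [r for r in hits if r.start <= cl.peak_pos <= r.end]
            hits = containing[:1] if containing else hits[:1]
        for row in hits:
            tpm[row.name] += cl.tpm

    return [
        PromoterActivity(
            sample_id=sample_id,
            promoter=row.name,
            tpm=tpm[row.name],
            below_floor=_below(tpm[row.name], TPM_FLOOR),
        )
        for row in rows
    ]


def promoter_fold(numerator_tpm: float, denominator_tpm: float) -> float:
    """Fold difference between two promoter activities in the same sample,
    rounded half-away-from-zero to 1 decimal (30.28 vs 0.68 -> 44.5).

    A denominator below the reporting floor has no meaningful magnitude, so
    the fold is undefined and signalled rather than returned.
    """
    if _below(denominator_tpm, TPM_FLOOR):
        raise BelowFloorError(
            f"denominator activity {denominator_tpm} is below the {TPM_FLOOR} "
            "TPM reporting floor; fold undefined"
        )
    return round_half_away(numerator_tpm / denominator_tpm, 1)


def sample_ratio(patient_tpm: float, control_tpm: float) -> int:
    """Patient-to-control activity of one promoter as an integer percent
    (11.70 vs 30.28 -> 39; 11.70 vs 26.18 -> 45)."""
    if control_tpm <= 0:
        raise InputError("control activity must be positive")
    if patient_tpm < 0:
        raise InputError("activities must be non-negative")
    return int(round_half_away(100.0 * patient_tpm / control_tpm, 0))


def compare_samples(
    activities: list[PromoterActivity],
    patient: str,
    controls: list[str],
    promoter: str = "APC-1B",
    reference_promoter: str = "APC-1A",
) -> pd.DataFrame:
    """Headline comparisons across samples: per control, the within-sample
    fold of ``promoter`` over ``reference_promoter`` (NaN when the reference
    sits below the floor) and the patient/control percent ratio of
    ``promoter``."""
    by = {(a.sample_id, a.promoter): a for a in activities}

    def get(sample: str, prom: str) -> PromoterActivity:
        try:
            return by[(sample, prom)]
        except KeyError:
            raise InputError(f"no activity for {prom!r} in sample {sample!r}") from None

    rows = []
    for ctrl in controls:
        num, den = get(ctrl, promoter), get(ctrl, reference_promoter)
        try:
            fold = promoter_fold(num.tpm, den.tpm)
        except BelowFloorError:
            fold = float("nan")
        rows.append(
            {
                "control": ctrl,
                "promoter": promoter,
                "fold_vs_" + reference_promoter.replace("-", "_"): fold,
                "reference_below_floor": den.below_floor,
                "patient_pct_of_control": sample_ratio(
                    get(patient, promoter).tpm, num.tpm
                ),
            }
        )
    return pd.DataFrame(rows)
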