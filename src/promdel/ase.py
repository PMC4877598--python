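"""Allele-specific expression from deep cDNA read counts at one heterozygous
coding SNP.

In a carrier of a heterozygous promoter deletion, transcripts from the
deleted allele are depleted, so reads over a transcribed heterozygous SNP are
skewed away from 50/50. With 3,191 mutant-allele vs 25,246 wild-allele reads
the mutant transcripts make up 11.2% of the total and are reduced 87%
relative to the wild-type allele; ``ase_test`` adds an exact binomial
confidence interval and a two-sided test against allelic balance.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binomtest

from ._util import InputError, round_half_away


@dataclass(frozen=True)
class AlleleCounts:
    """Read counts for the two alleles of one heterozygous site; ``linkage``
    (which allele rides the mutant haplotype) is declared by the caller, not
    inferred."""

    site: str
    allele_a: str
    count_a: int
    allele_b: str
    count_b: int
    mutant_allele: str

    def __post_init__(self) -> None:
        if self.count_a < 0 or self.count_b < 0:
            raise InputError("allele counts must be non-negative")
        if self.mutant_allele not in (self.allele_a, self.allele_b):
            raise InputError(
                f"mutant allele {self.mutant_allele!r} is neither "
                f"{self.allele_a!r} nor {self.allele_b!r}"
            )

    @property
    def total(self) -> int:
        return self.count_a + self.count_b

    @property
    def mutant_count(self) -> int:
        return self.count_a if self.mutant_allele == self.allele_a else self.count_b

    @property
    def wild_count(self) -> int:
        return self.total - self.mutant_count


@dataclass(frozen=True)
class ASEResult:
    site: str
    mutant_fraction: float
    mutant_percent: float  # rounded to 1 decimal, half away from zero
    ci_low: float
    ci_high: float
    reduction_vs_wild: int  # percent, rounded to nearest integer
    balanced_p: float
    alpha: float


def ase_fraction(mutant_reads: int, wild_reads: int) -> float:
    """Mutant share of the transcript pool: mutant / (mutant + wild)."""
    if mutant_reads < 0 or wild_reads < 0:
        raise InputError("read counts must be non-negative")
    total = mutant_reads + wild_reads
    if total == 0:
        raise InputError("cannot form an allele fraction from zero reads")
    return mutant_reads / total


def ase_percent(mutant_reads: int, wild_reads: int) -> float:
    """``ase_fraction`` as a percent, rounded half-away-from-zero to 1
    decimal (3,191/28,437 reads -> 11.2)."""
    return round_half_away(100.0 * ase_fraction(mutant_reads, wild_reads), 1)


def allele_reduction(mutant_reads: int, wild_reads: int) -> int:
    """Percent reduction of mutant relative to wild expression,
    100 * (1 - mutant/wild), rounded to the nearest integer
    (3,191 vs 25,246 -> 87)."""
    if mutant_reads < 0:
        raise InputError("read counts must be non-negative")
    if wild_reads <= 0:
        raise InputError("reduction undefined without wild-allele reads")
    return int(round_half_away(100.0 * (1.0 - mutant_reads / wild_reads), 0))


def ase_test(counts: AlleleCounts, alpha: float = 0.05) -> ASEResult:
    """Quantify allelic skew with an exact (Clopper-Pearson) CI on the mutant
    fraction and a two-sided exact binomial test against 0.5."""
    if not (0.0 < alpha < 1.0):
        raise InputError("alpha must lie in (0, 1)")
    if counts.total == 0:
        raise InputError("cannot test ASE with zero total reads")
    k, n = counts.mutant_count, counts.total
    test = binomtest(k, n, 0.5)
    ci = test.proportion_ci(confidence_level=1.0 - alpha, method="exact")
    return ASEResult(
        site=counts.site,
        mutant_fraction=k / n,
        mutant_percent=round_half_away(100.0 * k / n, 1),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        reduction_vs_wild=allele_reduction(k, counts.wild_count)
        if counts.wild_count > 0
        else 100,
        balanced_p=float(test.pvalue),
        alpha=alpha,
    )
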