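"""Percent identity of breakpoint-flanking sequences.

Deletions created by non-allelic homologous recombination (classically
between Alu elements) leave highly similar sequence on either side of the
breakpoints. This module extracts fixed windows immediately flanking a
deletion, aligns them globally (Needleman-Wunsch; match +1, mismatch -1,
gap -2 by default) and reports percent identity over alignment columns, with
gaps counting against identity and N-containing columns excluded from both
numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align.substitution_matrices import Array as SubstitutionArray

from ._util import InputError, round_half_away

_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class FlankPair:
    """The two windows flanking a deletion, on the reference strand."""

    seq_left: str
    seq_right: str
    window: int = 200
    padded: bool = False  # True when a flank was N-padded to reach the window


@dataclass(frozen=True)
class IdentityResult:
    percent_identity: float  # rounded to 1 decimal
    matches: int
    columns: int  # alignment columns counted (N columns excluded)
    score: float
    aligned_left: str
    aligned_right: str

    @property
    def alignment_text(self) -> str:
        marks = "".join(
            "|" if a == b and a != "-" else " "
            for a, b in zip(self.aligned_left, self.aligned_right)
        )
        return f"{self.aligned_left}\n{marks}\n{self.aligned_right}"


def _check(seq: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise InputError(f"{label} sequence is empty")
    bad = set(seq) - set(_ALPHABET)
    if bad:
        raise InputError(f"{label} contains invalid characters {sorted(bad)}")
    return seq


def extract_flanks(reference: str, del_start: int, del_end: int, window: int = 200) -> FlankPair:
    """Windows of ``window`` bp immediately left of ``del_start`` and right of
    ``del_end`` (1-based inclusive deletion coordinates within *reference*).
    Flanks that run off the sequence are N-padded and flagged."""
    reference = _check(reference, "reference")
    if not (1 <= del_start <= del_end <= len(reference)):
        raise InputError("deletion interval must lie within the reference")
    left = reference[max(0, del_start - 1 - window) : del_start - 1]
    right = reference[del_end : del_end + window]
    padded = len(left) < window or len(right) < window
    left = "N" * (window - len(left)) + left
    right = right + "N" * (window - len(right))
    return FlankPair(seq_left=left, seq_right=right, window=window, padded=padded)


def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    matrix = SubstitutionArray(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if "N" in (a, b):
                matrix[a, b] = 0.0
            else:
                matrix[a, b] = match if a == b else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def flank_identity(
    pair: FlankPair,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> IdentityResult:
    """Globally align the two flanks and report percent identity.

    Identity = 100 * matches / alignment columns, rounded half-away-from-zero
    to 1 decimal. Gap columns stay in the denominator (conservative); columns
    where either row is N are excluded from both counts.
    """
    left = _check(pair.seq_left, "left flank")
    right = _check(pair.seq_right, "right flank")
    aligner = _aligner(match, mismatch, gap)
    alignment = aligner.align(left, right)[0]
    row_l, row_r = alignment[0], alignment[1]
    matches = columns = 0
    for a, b in zip(row_l, row_r):
        if a == "N" or b == "N":
            continue
        columns += 1
        if a == b and a != "-":
            matches += 1
    if columns == 0:
        raise InputError("no alignable (non-N) columns between the flanks")
    return IdentityResult(
        percent_identity=round_half_away(100.0 * matches / columns, 1),
        matches=matches,
        columns=columns,
        score=float(alignment.score),
        aligned_left=str(row_l),
        aligned_right=str(row_r),
    )


def null_identity(
    length: int = 200, n_pairs: int = 50, seed: int = 0, **scoring
) -> np.ndarray:
    """Percent identities of unrelated random sequence pairs of the given
    length: the background level against which flank homology is judged."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_pairs):
        a = "".join(rng.choice(list("ACGT"), size=length))
        b = "".join(rng.choice(list("ACGT"), size=length))
        out.append(
            flank_identity(FlankPair(a, b, window=length), **scoring).percent_identity
        )
    return np.array(out)
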