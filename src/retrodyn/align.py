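"""Pairwise alignment wrappers with fixed, deterministic scoring.

Nucleotide alignments (LTR vs LTR, flank vs flank) use match +1 / mismatch -1
with affine gaps (open -5, extend -1). Protein alignments use BLOSUM62 with
open -11 / extend -1. Both are global; the first optimal alignment returned
by the dynamic program is taken, which is deterministic for fixed inputs.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@lru_cache(maxsize=None)
def _nuc_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


@lru_cache(maxsize=None)
def _prot_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


@dataclass(frozen=True)
class AlignmentStats:
    """Column tallies of one global pairwise alignment."""

    columns: int            # total alignment columns, gaps included
    matches: int
    mismatches: int
    gap_columns: int
    transitions: int
    transversions: int

    @property
    def ungapped_columns(self) -> int:
        return self.matches + self.mismatches

    @property
    def identity_pct(self) -> float:
        """Percent identity over all alignment columns (gaps count against)."""
        if self.columns == 0:
            return 0.0
        return 100.0 * self.matches / self.columns


def align_nuc(a: str, b: str):
    """Global nucleotide alignment; returns a Bio.Align.Alignment."""
    return _nuc_aligner().align(a.upper(), b.upper())[0]


def align_prot(a: str, b: str):
    return _prot_aligner().align(a, b)[0]


def alignment_stats(alignment) -> AlignmentStats:
    sa, sb = alignment[0], alignment[1]
    matches = mismatches = gaps = ts = tv = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            gaps += 1
        elif x == y:
            matches += 1
        else:
            mismatches += 1
            if (x in PURINES) == (y in PURINES):
                ts += 1
            else:
                tv += 1
    return AlignmentStats(len(sa), matches, mismatches, gaps, ts, tv)


def pairwise_nuc_stats(a: str, b: str) -> AlignmentStats:
    return alignment_stats(align_nuc(a, b))


def prot_identity_distance(a: str, b: str) -> float:
    """1 - (identical fraction over aligned non-gap columns), global protein."""
    st = alignment_stats(align_prot(a, b))
    if st.ungapped_columns == 0:
        return 1.0
    return 1.0 - st.matches / st.ungapped_columns
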