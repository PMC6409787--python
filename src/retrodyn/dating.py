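"""Insertion-time estimation from LTR-LTR divergence.

At insertion the two LTRs of an element are identical; they then accumulate
substitutions independently at the neutral rate. Under a molecular clock the
insertion time is

    T = k / (2 r)

with k the divergence between the element's two LTRs and r the per-site,
per-year substitution rate (default 4.72e-9, a standard plant nuclear rate).
Divergence is computed from a global LTR-LTR alignment with gap columns
excluded, under a selectable distance model: raw p-distance, the Jukes-Cantor
one-parameter correction (JC69) or the Kimura two-parameter correction (K2P,
the default — the conventional choice for LTR dating, correcting for both
multiple hits and transition/transversion bias).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .align import AlignmentStats, align_nuc, alignment_stats

MODELS = ("p-distance", "JC69", "K2P")


class SaturationError(ValueError):
    """Divergence too large for the correction formula (log of <= 0)."""


@dataclass(frozen=True)
class ClockConfig:
    rate: float = 4.72e-9          # substitutions / site / year
    model: str = "K2P"

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("substitution rate must be > 0")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")


@dataclass(frozen=True)
class AgeEstimate:
    element_id: str
    aligned_columns: int   # ungapped columns used
    k: float               # model divergence
    t_years: float

    @property
    def t_my(self) -> float:
        return self.t_years / 1e6


def align_ltrs(ltr5: str, ltr3: str):
    """Global alignment of the two LTRs under the package's fixed scoring."""
    if not ltr5 or not ltr3:
        raise ValueError("both LTR sequences must be non-empty")
    return align_nuc(ltr5, ltr3)


def divergence(alignment, model: str = "K2P", label: str = "") -> float:
    """Model divergence k from a pairwise alignment; gap columns excluded."""
    st = alignment if isinstance(alignment, AlignmentStats) \
        else alignment_stats(alignment)
    n = st.ungapped_columns
    if n < 50:
        warnings.warn(
            f"only {n} ungapped columns{' for ' + label if label else ''}; "
            "divergence estimate is low-confidence",
            stacklevel=2,
        )
    if n == 0:
        raise ValueError("alignment has no ungapped columns")
    p = st.mismatches / n
    if model == "p-distance":
        return p
    if model == "JC69":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise SaturationError(
                f"JC69 saturated (p = {p:.3f}){_of(label)}")
        return -0.75 * math.log(arg)
    if model == "K2P":
        P = st.transitions / n
        Q = st.transversions / n
        a1 = 1.0 - 2.0 * P - Q
        a2 = 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            raise SaturationError(
                f"K2P saturated (P = {P:.3f}, Q = {Q:.3f}){_of(label)}")
        return -0.5 * math.log(a1 * math.sqrt(a2))
    raise ValueError(f"unknown model {model!r}")


def _of(label: str) -> str:
    return f" for element {label}" if label else ""


def insertion_time(k: float, clock: ClockConfig | None = None) -> float:
    """T = k / (2 r), in years."""
    if k < 0:
        raise ValueError("divergence k must be >= 0")
    clock = clock or ClockConfig()
    return k / (2.0 * clock.rate)


def date_ltr_pair(
    ltr5: str, ltr3: str, clock: ClockConfig | None = None,
    element_id: str = "",
) -> AgeEstimate:
    """Convenience: align, estimate divergence, convert to years."""
    clock = clock or ClockConfig()
    st = alignment_stats(align_ltrs(ltr5, ltr3))
    k = divergence(st, clock.model, element_id)
    return AgeEstimate(element_id, st.ungapped_columns, k, insertion_time(k, clock))


def date_elements(candidates, genome: dict[str, str],
                  clock: ClockConfig | None = None) -> list[AgeEstimate]:
    """Date a list of structurally detected elements from their LTR pairs."""
    clock = clock or ClockConfig()
    out = []
    for c in candidates:
        seq = genome[c.contig]
        out.append(
            date_ltr_pair(
                seq[c.ltr5_start : c.ltr5_end],
                seq[c.ltr3_start : c.ltr3_end],
                clock,
                c.id,
            )
        )
    return out


@dataclass(frozen=True)
class AgeHistogram:
    bin_width_years: float
    counts: np.ndarray          # per left-closed, right-open bin from 0
    mean_my: float
    max_my: float
    frac_le_10my: float
    frac_first_bin: float


def age_histogram(
    estimates: list[AgeEstimate], bin_width: float = 2e6
) -> AgeHistogram:
    """Bin insertion ages into left-closed right-open windows from 0."""
    if not estimates:
        raise ValueError("no age estimates to bin")
    years = np.array([e.t_years for e in estimates])
    n_bins = max(1, int(np.floor(years.max() / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((years // bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return AgeHistogram(
        bin_width_years=bin_width,
        counts=counts,
        mean_my=float(years.mean() / 1e6),
        max_my=float(years.max() / 1e6),
        frac_le_10my=float(np.mean(years <= 1e7)),
        frac_first_bin=float(counts[0] / len(years)),
    )
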