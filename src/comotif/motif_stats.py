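"""Information content, Gini scoring, candidate filtering and core trimming.

A genuine co-binding pattern concentrates information content (IC) in a few
contiguous flank positions.  Candidates are therefore scored by total IC and
by the Gini coefficient of the per-position IC vector, and the surviving
candidates are trimmed to the window holding the locally enriched IC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .nmf import ComponentPFM

logger = logging.getLogger(__name__)


def column_ic(column: np.ndarray) -> float:
    """IC of one PFM column in bits: 2 + sum_b f_b log2 f_b, no pseudocount."""
    column = np.asarray(column, dtype=float)
    total = column.sum()
    if total <= 0:
        raise ValueError("all-zero PFM column has no defined IC")
    f = column / total
    nz = f[f > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


def ic_vector(counts: np.ndarray) -> np.ndarray:
    """Per-column IC of a 4 x w count matrix."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("PFM contains an all-zero column")
    f = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    return 2.0 + terms.sum(axis=0)


def gini_coefficient(values: Sequence[float]) -> float:
    """Gini inequality index of a non-negative vector.

    Equals sum_ij |x_i - x_j| / (2 m^2 mean); 0 for constant vectors,
    approaches 1 when all mass sits in one entry.  All-zero input returns 0
    by convention.
    """
    x = np.sort(np.asarray(values, dtype=float))
    m = x.size
    if m < 2:
        raise ValueError("Gini needs at least two values")
    if np.any(x < 0):
        raise ValueError("Gini is defined for non-negative values")
    total = x.sum()
    if total == 0:
        return 0.0
    # sorted-form identity of the mean-absolute-difference definition
    i = np.arange(1, m + 1)
    return float(np.sum((2 * i - m - 1) * x) / (m * total))


@dataclass
class MotifCandidate:
    """A scored full-flank candidate PFM."""

    pfm: ComponentPFM
    ic: np.ndarray
    total_ic: float
    gini: float
    kept: bool = True
    reject_reason: str = ""

    @property
    def label(self) -> str:
        return self.pfm.label


@dataclass
class CoreMotif:
    """The trimmed motif window inside the flank."""

    counts: np.ndarray  # (4, core_width)
    flank_offset: int  # 0-based start of the window within the flank
    core_width: int
    side: str
    parent: MotifCandidate

    @property
    def n(self) -> int:
        return self.parent.pfm.n


def evaluate_candidate(pfm: ComponentPFM) -> MotifCandidate:
    """Compute the IC vector, total IC and Gini score of a candidate."""
    ic = ic_vector(pfm.counts)
    return MotifCandidate(
        pfm=pfm,
        ic=ic,
        total_ic=float(ic.sum()),
        gini=gini_coefficient(ic),
    )


def filter_candidates(
    candidates: Iterable[MotifCandidate],
    ic_min: float = 2.0,
    gini_min: float = 0.5,
) -> tuple[list[MotifCandidate], list[MotifCandidate]]:
    """Keep candidates with total IC >= ic_min and Gini >= gini_min.

    Both thresholds are inclusive.  Returns (kept, rejected); each rejected
    candidate carries its reason.
    """
    kept, rejected = [], []
    for cand in candidates:
        if cand.total_ic < ic_min:
            cand.kept = False
            cand.reject_reason = f"low IC ({cand.total_ic:.3f} < {ic_min})"
            rejected.append(cand)
        elif cand.gini < gini_min:
            cand.kept = False
            cand.reject_reason = f"low Gini ({cand.gini:.3f} < {gini_min})"
            rejected.append(cand)
        else:
            cand.kept = True
            kept.append(cand)
    return kept, rejected


def write_rejection_log(rejected: Iterable[MotifCandidate], path) -> None:
    with open(path, "w") as handle:
        handle.write("candidate\ttotal_ic\tgini\treason\n")
        for cand in rejected:
            handle.write(f"{cand.label}\t{cand.total_ic:.4f}\t{cand.gini:.4f}\t{cand.reject_reason}\n")


def _best_window(ic: np.ndarray, half: float) -> tuple[int, int]:
    """Smallest window whose IC sum >= half; ties: max IC sum, then leftmost.

    Returns (start, width).
    """
    n = ic.size
    for w in range(1, n + 1):
        # direct per-window summation: a cumulative-sum shortcut breaks exact
        # leftmost tie-breaking on constant vectors through rounding noise
        sums = np.array([ic[s:s + w].sum() for s in range(n - w + 1)])
        best = float(sums.max())
        if best >= half - 1e-12:
            start = int(np.argmax(sums))  # leftmost maximum
            return start, w
    return 0, n


def trim_to_core(candidate: MotifCandidate) -> CoreMotif:
    """Trim a kept candidate to its locally IC-enriched window.

    Finds the smallest contiguous window containing at least half of the
    total flank IC (ties broken by maximal IC sum, then leftmost), then
    expands it by floor(width/2) positions on each side, clipped to the
    flank.
    """
    if candidate.total_ic <= 0:
        raise ValueError("cannot trim a candidate with zero IC")
    ic = candidate.ic
    n = ic.size
    start, w = _best_window(ic, 0.5 * candidate.total_ic)
    pad = w // 2
    lo = max(0, start - pad)
    hi = min(n, start + w + pad)
    return CoreMotif(
        counts=candidate.pfm.counts[:, lo:hi].copy(),
        flank_offset=lo,
        core_width=hi - lo,
        side=candidate.pfm.side,
        parent=candidate,
    )
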