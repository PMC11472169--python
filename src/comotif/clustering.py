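"""Motif comparison, clustering and archetype construction.

The discovery stage finds the same underlying motif many times (several k
values, both sides, several datasets).  Redundant core motifs are grouped by
average-linkage agglomeration on a Pearson column-correlation similarity that
scans every overlapping offset and both orientations, and each cluster is
summarized by an archetypal motif: the mean of the aligned member count
matrices with low-IC edges removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._rng import STAGE_PERMTEST, stage_rng
from .motif_stats import CoreMotif, ic_vector

logger = logging.getLogger(__name__)

EDGE_IC_MIN = 0.1  # archetype edge positions below this IC are trimmed


def revcomp_pfm(counts: np.ndarray) -> np.ndarray:
    """Reverse complement of a count matrix (rows A,C,G,T)."""
    return np.asarray(counts)[::-1, ::-1].copy()


def _freqs(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    totals = np.where(totals > 0, totals, 1.0)
    return counts / totals


@dataclass
class SimilarityResult:
    score: float  # best Pearson correlation over offsets/orientations
    normalized_score: float  # score * overlap / max(width_a, width_b)
    offset: int  # position of b's first column in a's coordinates
    orientation: str  # "forward" | "reverse-complement"


def _pearson_batch(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of X (B, L) against y (L,); 0 if degenerate."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = Xc @ yc
    den = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def _score_offsets(
    a_freq: np.ndarray, b_freqs: np.ndarray, min_overlap: int
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Best (score, normalized) per candidate in a batch, plus the offsets scanned.

    ``b_freqs``: (B, 4, wb) batch of frequency matrices compared against
    ``a_freq`` (4, wa), one orientation.
    Returns (scores (B, n_offsets), normalized (B, n_offsets), offsets).
    """
    wa, wb = a_freq.shape[1], b_freqs.shape[2]
    wmax = max(wa, wb)
    B = b_freqs.shape[0]
    offsets = [
        off for off in range(-(wb - min_overlap), wa - min_overlap + 1)
        if min(wa, off + wb) - max(0, off) >= min_overlap
    ]
    scores = np.full((B, len(offsets)), -1.0)
    normalized = np.full((B, len(offsets)), -1.0)
    for j, off in enumerate(offsets):
        a_lo, a_hi = max(0, off), min(wa, off + wb)
        b_lo = a_lo - off
        b_hi = a_hi - off
        ov = a_hi - a_lo
        y = a_freq[:, a_lo:a_hi].reshape(-1)
        X = b_freqs[:, :, b_lo:b_hi].reshape(B, -1)
        r = _pearson_batch(X, y)
        scores[:, j] = r
        normalized[:, j] = r * ov / wmax
    return scores, normalized, offsets


def motif_similarity(a: np.ndarray, b: np.ndarray, min_overlap: int = 3) -> SimilarityResult:
    """Best column-frequency Pearson correlation between two count matrices.

    Scans all offsets with at least ``min_overlap`` overlapping columns (or
    the full smaller width when narrower than that) and both orientations of
    ``b``.  The normalized score scales by overlap / max(width).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    minov = min(min_overlap, a.shape[1], b.shape[1])
    a_freq = _freqs(a)
    best: Optional[SimilarityResult] = None
    for orientation, mat in (("forward", b), ("reverse-complement", revcomp_pfm(b))):
        b_freq = _freqs(mat)[None]
        scores, normalized, offsets = _score_offsets(a_freq, b_freq, minov)
        j = int(np.argmax(scores[0]))
        cand = SimilarityResult(
            score=float(scores[0, j]),
            normalized_score=float(normalized[0, j]),
            offset=offsets[j],
            orientation=orientation,
        )
        if best is None or cand.score > best.score:
            best = cand
    assert best is not None
    return best


def _best_normalized_batch(cands: np.ndarray, target: np.ndarray, min_overlap: int = 3) -> np.ndarray:
    """Best normalized similarity of each candidate in a batch vs target."""
    minov = min(min_overlap, cands.shape[2], target.shape[1])
    t_freq = _freqs(target)
    out = np.full(cands.shape[0], -1.0)
    for mat in (cands, cands[:, ::-1, ::-1]):
        _, normalized, _ = _score_offsets(t_freq, _freqs_batch(mat), minov)
        out = np.maximum(out, normalized.max(axis=1))
    return out


def _freqs_batch(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals = np.where(totals > 0, totals, 1.0)
    return counts / totals


def similarity_pvalue(
    candidate: np.ndarray,
    target: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the similarity of two motifs.

    The null shuffles the candidate's columns, destroying positional
    structure while preserving column composition; p uses the add-one
    estimator, so p >= 1/(n_perm+1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    candidate = np.asarray(candidate, dtype=float)
    target = np.asarray(target, dtype=float)
    observed = _best_normalized_batch(candidate[None], target)[0]
    rng = stage_rng(seed, STAGE_PERMTEST)
    w = candidate.shape[1]
    perms = np.stack([candidate[:, rng.permutation(w)] for _ in range(n_perm)])
    null = _best_normalized_batch(perms, target)
    return float((1 + int(np.sum(null >= observed - 1e-12))) / (n_perm + 1))


@dataclass
class AlignedMotif:
    core: CoreMotif
    offset_to_seed: int
    orientation: str  # relative to the cluster seed


@dataclass
class Cluster:
    seed: CoreMotif
    members: list[AlignedMotif] = field(default_factory=list)


@dataclass
class Archetype:
    """Cluster-level summary motif: mean of aligned member counts, edge-trimmed."""

    counts: np.ndarray
    members: list[AlignedMotif]
    trimmed_range: tuple[int, int]  # kept [start, end) in the untrimmed seed frame

    @property
    def width(self) -> int:
        return self.counts.shape[1]


def _pair_similarity(a: CoreMotif, b: CoreMotif) -> tuple[float, float]:
    sim = motif_similarity(a.counts, b.counts)
    return sim.score, sim.normalized_score


def cluster_motifs(
    cores: Sequence[CoreMotif],
    cor_min: float = 0.6,
    ncor_min: float = 0.4,
) -> list[Cluster]:
    """Average-linkage agglomeration of core motifs.

    Merging continues while the best cluster pair has average correlation
    >= cor_min and average normalized correlation >= ncor_min.  Members are
    stored aligned (offset, orientation) to the cluster seed: the widest
    member, ties broken by highest total IC.
    """
    m = len(cores)
    if m == 0:
        return []
    cor = np.eye(m)
    ncor = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            c, nc = _pair_similarity(cores[i], cores[j])
            cor[i, j] = cor[j, i] = c
            ncor[i, j] = ncor[j, i] = nc

    groups: list[list[int]] = [[i] for i in range(m)]
    while len(groups) > 1:
        best_pair = None
        best_key = None
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                pairs = [(i, j) for i in groups[gi] for j in groups[gj]]
                avg_cor = float(np.mean([cor[i, j] for i, j in pairs]))
                avg_ncor = float(np.mean([ncor[i, j] for i, j in pairs]))
                if avg_cor >= cor_min and avg_ncor >= ncor_min:
                    key = (avg_ncor, avg_cor, -gi, -gj)
                    if best_key is None or key > best_key:
                        best_key = key
                        best_pair = (gi, gj)
        if best_pair is None:
            break
        gi, gj = best_pair
        groups[gi] = groups[gi] + groups[gj]
        del groups[gj]

    clusters: list[Cluster] = []
    for group in groups:
        members = [cores[i] for i in group]
        seed = max(
            members,
            key=lambda c: (c.core_width, float(ic_vector(c.counts).sum())),
        )
        cluster = Cluster(seed=seed)
        for core in members:
            if core is seed:
                cluster.members.append(AlignedMotif(core, 0, "forward"))
            else:
                sim = motif_similarity(seed.counts, core.counts)
                cluster.members.append(AlignedMotif(core, sim.offset, sim.orientation))
        clusters.append(cluster)
    return clusters


def build_archetype(cluster: Cluster, edge_ic_min: float = EDGE_IC_MIN) -> Archetype:
    """Mean of aligned member counts, then strip low-IC edge positions.

    Positions are averaged over the members covering them; successive edge
    positions with IC below ``edge_ic_min`` are discarded from both ends.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    spans = []
    for am in cluster.members:
        w = am.core.core_width
        spans.append((am.offset_to_seed, am.offset_to_seed + w))
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    width = hi - lo
    total = np.zeros((4, width))
    cover = np.zeros(width)
    for am, (s, e) in zip(cluster.members, spans):
        counts = am.core.counts
        if am.orientation == "reverse-complement":
            counts = revcomp_pfm(counts)
        total[:, s - lo:e - lo] += counts
        cover[s - lo:e - lo] += 1
    mean = total / np.where(cover > 0, cover, 1.0)

    ic = ic_vector(mean)
    start, end = 0, width
    while start < end and ic[start] < edge_ic_min:
        start += 1
    while end > start and ic[end - 1] < edge_ic_min:
        end -= 1
    if start == end:  # fully uninformative: keep the single highest-IC column
        start = int(np.argmax(ic))
        end = start + 1
    return Archetype(
        counts=mean[:, start:end].copy(),
        members=list(cluster.members),
        trimmed_range=(start + lo, end + lo),
    )


def summarize_anchor_sequences(anchor_seqs: Sequence[str]) -> np.ndarray:
    """PFM of the anchor sequences attached to one co-binding motif.

    Same counting convention as component PFMs: ambiguous bases add 0.25 to
    every row.
    """
    if not anchor_seqs:
        raise ValueError("no anchor sequences to summarize")
    length = len(anchor_seqs[0])
    if any(len(s) != length for s in anchor_seqs):
        raise ValueError("anchor sequences must share one length")
    counts = np.zeros((4, length))
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq in anchor_seqs:
        for p, base in enumerate(seq.upper()):
            i = index.get(base)
            if i is None:
                counts[:, p] += 0.25
            else:
                counts[i, p] += 1.0
    return counts
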