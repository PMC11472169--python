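"""Pattern discovery by non-negative matrix factorization.

Each one-hot flank matrix is factorized at several component numbers ``k``;
a basis row is a recurring flank pattern and each sequence is assigned to the
component with its maximal coefficient (argmax clustering of the coefficient
matrix).  Per component, a full-flank positional frequency matrix (PFM) is
built from the assigned sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from ._rng import STAGE_NMF, stage_seed
from .anchors import AnchorRecord
from .encoding import BASES, FlankMatrix

logger = logging.getLogger(__name__)

# solver settings: squared Frobenius objective, NNDSVD init with seeded random
# perturbation of zeros, coordinate-descent updates
_NMF_KWARGS = dict(init="nndsvdar", solver="cd", beta_loss="frobenius",
                   max_iter=200, tol=1e-4)


@dataclass
class NMFResult:
    k: int
    coefficients: np.ndarray  # (num_sequences, k)
    basis: np.ndarray  # (k, 4n)
    side: str
    seed: int
    reconstruction_error: float
    row_ids: list[str] = field(default_factory=list)


@dataclass
class ComponentPFM:
    """Full-flank PFM of one NMF component, with provenance."""

    counts: np.ndarray  # (4, n), rows A,C,G,T
    assigned_ids: list[str]
    side: str
    k: int
    component_index: int
    dataset: str = ""

    @property
    def n(self) -> int:
        return self.counts.shape[1]

    @property
    def label(self) -> str:
        ds = f"{self.dataset}:" if self.dataset else ""
        return f"{ds}{self.side}:k{self.k}:c{self.component_index}"


def run_nmf(matrix: FlankMatrix, k: int, seed: int) -> NMFResult:
    """Factorize one flank matrix at a fixed number of components.

    Deterministic given (matrix, k, seed).  Non-convergence within the
    iteration cap is logged, not raised.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.num_sequences:
        raise ValueError(f"k={k} exceeds number of sequences {matrix.num_sequences}")
    X = matrix.values.astype(np.float64)
    if not X.any():
        # degenerate all-zero input: exact zero factorization
        return NMFResult(
            k=k,
            coefficients=np.zeros((matrix.num_sequences, k)),
            basis=np.zeros((k, X.shape[1])),
            side=matrix.side,
            seed=seed,
            reconstruction_error=0.0,
            row_ids=list(matrix.row_ids),
        )
    model = NMF(n_components=k, random_state=seed, **_NMF_KWARGS)
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            W = model.fit_transform(X)
        except ConvergenceWarning:
            logger.debug("NMF (side=%s, k=%d) hit the iteration cap", matrix.side, k)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = NMF(n_components=k, random_state=seed, **_NMF_KWARGS)
                W = model.fit_transform(X)
    return NMFResult(
        k=k,
        coefficients=W,
        basis=model.components_,
        side=matrix.side,
        seed=seed,
        reconstruction_error=float(model.reconstruction_err_),
        row_ids=list(matrix.row_ids),
    )


def assign_sequences(result: NMFResult) -> dict[str, int]:
    """Assign each sequence to its maximal-coefficient component.

    Ties go to the lowest component index (0-based); rows whose maximal
    coefficient is zero are unassigned and absent from the returned map.
    """
    W = result.coefficients
    best = np.argmax(W, axis=1)  # first occurrence on ties
    assigned: dict[str, int] = {}
    for row_id, comp, row in zip(result.row_ids, best, W):
        if row[comp] > 0:
            assigned[row_id] = int(comp)
    return assigned


def build_component_pfm(
    records: Sequence[AnchorRecord],
    assignment: dict[str, int],
    component_index: int,
    side: str,
    k: int = 0,
    dataset: str = "",
) -> Optional[ComponentPFM]:
    """Count bases of the assigned sequences at each flank position.

    Ambiguous bases contribute 0.25 to each of the four rows, keeping column
    sums equal to the number of assigned sequences.  Returns ``None`` (with a
    log entry) when no sequence is assigned to the component.
    """
    ids = [rid for rid, comp in assignment.items() if comp == component_index]
    if not ids:
        logger.debug("component %d (%s, k=%d) is empty; dropped", component_index, side, k)
        return None
    wanted = set(ids)
    base_index = {b: i for i, b in enumerate(BASES)}
    counts: Optional[np.ndarray] = None
    kept_ids = []
    for rec in records:
        if rec.id not in wanted:
            continue
        flank = rec.upstream if side == "upstream" else rec.downstream
        if counts is None:
            counts = np.zeros((4, len(flank)))
        for p, base in enumerate(flank):
            i = base_index.get(base)
            if i is None:
                counts[:, p] += 0.25
            else:
                counts[i, p] += 1.0
        kept_ids.append(rec.id)
    assert counts is not None
    return ComponentPFM(counts, kept_ids, side, k, component_index, dataset)


def discover_candidates(
    upstream: FlankMatrix,
    downstream: FlankMatrix,
    records: Sequence[AnchorRecord],
    k_range: tuple[int, int] = (3, 6),
    seed: int = 0,
    dataset: str = "",
) -> list[ComponentPFM]:
    """Run the factorization over both sides and all k, and collect PFMs.

    Yields one candidate per (side, k, component) with a non-empty
    assignment — at most ``2 * sum(k_range)`` candidates.
    """
    k_lo, k_hi = k_range
    candidates: list[ComponentPFM] = []
    for side_idx, matrix in enumerate((upstream, downstream)):
        for k in range(k_lo, k_hi + 1):
            result = run_nmf(matrix, k, stage_seed(seed, STAGE_NMF, side_idx, k))
            assignment = assign_sequences(result)
            for comp in range(k):
                pfm = build_component_pfm(
                    records, assignment, comp, matrix.side, k=k, dataset=dataset
                )
                if pfm is not None:
                    candidates.append(pfm)
    return candidates
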