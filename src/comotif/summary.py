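"""Spacing/orientation summaries of discovered co-binding patterns.

The biological readout is a grammar: which motif co-occurs with the anchor,
on which side, at what fixed spacing and in which orientation, and in what
fraction of the input sequences.  This module derives those quantities from
clustered archetypes and writes the machine-readable summary (TSV + motif
files + BED of co-bound anchors + optional heatmap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .anchors import AnchorRecord, GenomicInterval
from .clustering import EDGE_IC_MIN, Archetype
from .motif_io import write_jaspar, write_meme_minimal
from .motif_stats import CoreMotif, ic_vector

logger = logging.getLogger(__name__)


def spacing_of(core: CoreMotif) -> tuple[str, int]:
    """Nucleotides between the anchor edge and the raw core window edge."""
    n = core.n
    if core.side == "upstream":
        return "upstream", n - (core.flank_offset + core.core_width)
    return "downstream", core.flank_offset


def effective_span(core: CoreMotif, edge_ic_min: float = EDGE_IC_MIN) -> tuple[int, int]:
    """Informative extent of a core motif, as (flank_offset, width).

    The half-IC window that seeds the core can sit anywhere inside a wider
    informative block, and the subsequent doubling pads it with near-uniform
    background columns.  To read off spacing, the core window is first grown
    over adjacent full-flank positions whose IC is at least ``edge_ic_min``
    and then stripped of edge positions below it, so the span tracks the
    contiguous run of informative columns containing the core.
    """
    ic = core.parent.ic
    n = ic.size
    lo, hi = core.flank_offset, core.flank_offset + core.core_width
    while lo > 0 and ic[lo - 1] >= edge_ic_min:
        lo -= 1
    while hi < n and ic[hi] >= edge_ic_min:
        hi += 1
    while lo < hi and ic[lo] < edge_ic_min:
        lo += 1
    while hi > lo and ic[hi - 1] < edge_ic_min:
        hi -= 1
    if lo == hi:  # nothing above the cutoff: fall back to the IC peak
        lo = core.flank_offset + int(np.argmax(ic_vector(core.counts)))
        hi = lo + 1
    return lo, hi - lo


def effective_spacing(core: CoreMotif, edge_ic_min: float = EDGE_IC_MIN) -> tuple[str, int]:
    """Spacing measured to the low-IC-trimmed edge of the core."""
    offset, width = effective_span(core, edge_ic_min)
    if core.side == "upstream":
        return "upstream", core.n - (offset + width)
    return "downstream", offset


@dataclass
class CoBindingPattern:
    """One co-binding event: an archetype at a fixed side/spacing/orientation."""

    archetype: Archetype
    archetype_id: str
    dataset: str
    side: str
    spacing: int
    orientation: str
    prevalence: float
    cobound_ids: list[str]
    n_datasets: int = 1


def build_patterns(
    archetypes: Sequence[Archetype],
    dataset_sizes: dict[str, int],
    edge_ic_min: float = EDGE_IC_MIN,
) -> list[CoBindingPattern]:
    """Group archetype members into per-(dataset, side, spacing, orientation) rows.

    A sequence assigned to the same pattern through several k values counts
    once (union of assigned ids); a motif found at two spacings yields two
    rows, as on a spacing heatmap.
    """
    patterns: list[CoBindingPattern] = []
    for a_idx, arch in enumerate(archetypes):
        arch_id = f"archetype_{a_idx + 1}"
        groups: dict[tuple[str, str, int, str], set[str]] = {}
        for member in arch.members:
            core = member.core
            side, spacing = effective_spacing(core, edge_ic_min)
            key = (core.parent.pfm.dataset, side, spacing, member.orientation)
            groups.setdefault(key, set()).update(core.parent.pfm.assigned_ids)
        # cross-dataset support per (side, spacing, orientation)
        support: dict[tuple[str, int, str], set[str]] = {}
        for (dataset, side, spacing, orientation) in groups:
            support.setdefault((side, spacing, orientation), set()).add(dataset)
        for (dataset, side, spacing, orientation), ids in sorted(groups.items()):
            size = dataset_sizes.get(dataset, 0)
            prevalence = len(ids) / size if size else 0.0
            patterns.append(
                CoBindingPattern(
                    archetype=arch,
                    archetype_id=arch_id,
                    dataset=dataset,
                    side=side,
                    spacing=spacing,
                    orientation=orientation,
                    prevalence=prevalence,
                    cobound_ids=sorted(ids),
                    n_datasets=len(support[(side, spacing, orientation)]),
                )
            )
    return patterns


def prevalence_of(pattern: CoBindingPattern, dataset_size: int) -> float:
    """Fraction of a dataset's sequences carrying the pattern."""
    if dataset_size <= 0:
        raise ValueError("dataset size must be positive")
    return len(set(pattern.cobound_ids)) / dataset_size


def patterns_to_frame(patterns: Sequence[CoBindingPattern]) -> pd.DataFrame:
    rows = [
        {
            "dataset": p.dataset,
            "anchor_id": f"{p.dataset or 'anchors'}_anchor",
            "side": p.side,
            "spacing": p.spacing,
            "orientation": p.orientation,
            "archetype_id": p.archetype_id,
            "n_datasets": p.n_datasets,
            "prevalence": round(p.prevalence, 6),
        }
        for p in patterns
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "dataset", "anchor_id", "side", "spacing", "orientation",
            "archetype_id", "n_datasets", "prevalence",
        ],
    )


def write_summary(
    patterns: Sequence[CoBindingPattern],
    out_dir: Union[str, Path],
    records_by_dataset: Optional[dict[str, Sequence[AnchorRecord]]] = None,
    heatmap: bool = False,
) -> dict[str, Path]:
    """Write the summary TSV, archetype motif files, co-bound BED and heatmap."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    tsv = out_dir / "cobinding_summary.tsv"
    patterns_to_frame(patterns).to_csv(tsv, sep="\t", index=False)
    written["summary"] = tsv

    motif_counts = {}
    for p in patterns:
        motif_counts.setdefault(p.archetype_id, p.archetype.counts)
    jaspar = out_dir / "archetypes.jaspar"
    meme = out_dir / "archetypes.meme"
    write_jaspar(motif_counts, jaspar)
    write_meme_minimal(motif_counts, meme)
    written["jaspar"] = jaspar
    written["meme"] = meme

    bed = out_dir / "cobound_anchors.bed"
    with open(bed, "w") as handle:
        if records_by_dataset:
            seen = set()
            for p in patterns:
                records = {r.id: r for r in records_by_dataset.get(p.dataset, [])}
                for rid in p.cobound_ids:
                    rec = records.get(rid)
                    if rec is None or not isinstance(rec.source, GenomicInterval):
                        continue
                    iv = rec.source
                    key = (iv.chrom, iv.start, iv.end, iv.strand, p.archetype_id)
                    if key in seen:
                        continue
                    seen.add(key)
                    handle.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                        f"{rid};{p.archetype_id}\t0\t{iv.strand}\n"
                    )
    written["bed"] = bed

    if heatmap and patterns:
        written["heatmap"] = _write_heatmap(patterns, out_dir / "cobinding_heatmap.png")
    return written


def _write_heatmap(patterns: Sequence[CoBindingPattern], path: Path) -> Path:
    """Spacing-vs-pattern heatmap: tile color = datasets, label = prevalence."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = patterns_to_frame(patterns)
    frame["signed_spacing"] = np.where(
        frame["side"] == "upstream", -frame["spacing"] - 1, frame["spacing"]
    )
    pivot = frame.pivot_table(
        index="archetype_id", columns="signed_spacing",
        values="n_datasets", aggfunc="max",
    )
    prev = frame.pivot_table(
        index="archetype_id", columns="signed_spacing",
        values="prevalence", aggfunc="max",
    )
    fig, ax = plt.subplots(figsize=(max(4, pivot.shape[1]), max(2, 0.6 * pivot.shape[0])))
    im = ax.imshow(pivot.to_numpy(dtype=float), aspect="auto", cmap="Reds")
    ax.set_xticks(range(pivot.shape[1]), labels=[str(c) for c in pivot.columns])
    ax.set_yticks(range(pivot.shape[0]), labels=list(pivot.index))
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            v = prev.to_numpy()[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=8)
    ax.set_xlabel("spacing to anchor (negative = upstream)")
    fig.colorbar(im, ax=ax, label="datasets")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
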