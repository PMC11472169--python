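"""Reading and writing motif count matrices (JASPAR PFM and MEME minimal)."""

from __future__ import annotations

from io import StringIO
from pathlib import Path
from typing import Union

import numpy as np
from Bio import motifs as bio_motifs

from .encoding import BASES


def _to_counts(motif) -> np.ndarray:
    return np.array([motif.counts[b] for b in BASES], dtype=float)


def read_jaspar(path: Union[str, Path]) -> dict[str, np.ndarray]:
    """Read JASPAR-format PFMs into {identifier: 4 x w count matrix}."""
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, "jaspar")
    out = {}
    for motif in parsed:
        key = motif.matrix_id or motif.name
        out[key] = _to_counts(motif)
    return out


def write_jaspar(motif_counts: dict[str, np.ndarray], path: Union[str, Path]) -> None:
    """Write {identifier: 4 x w counts} in JASPAR PFM format."""
    with open(path, "w") as handle:
        for name, counts in motif_counts.items():
            counts = np.asarray(counts, dtype=float)
            handle.write(f">{name}\n")
            for b, row in zip(BASES, counts):
                vals = " ".join(f"{v:.2f}".rstrip("0").rstrip(".") for v in row)
                handle.write(f"{b} [ {vals} ]\n")


def read_meme_minimal(path: Union[str, Path]) -> dict[str, np.ndarray]:
    """Read MEME minimal-format motifs into {name: 4 x w frequency matrix}."""
    with open(path) as handle:
        record = bio_motifs.parse(handle, "minimal")
    return {m.name: _to_counts(m) for m in record}


def write_meme_minimal(motif_counts: dict[str, np.ndarray], path: Union[str, Path]) -> None:
    """Write motifs in MEME minimal format (letter-probability matrices)."""
    with open(path, "w") as handle:
        handle.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        handle.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for name, counts in motif_counts.items():
            counts = np.asarray(counts, dtype=float)
            totals = counts.sum(axis=0)
            freqs = counts / np.where(totals > 0, totals, 1.0)
            nsites = int(round(totals.max())) if totals.size else 0
            handle.write(f"MOTIF {name}\n")
            handle.write(
                f"letter-probability matrix: alength= 4 w= {counts.shape[1]} "
                f"nsites= {max(nsites, 1)} E= 0\n"
            )
            for col in freqs.T:
                handle.write(" " + "  ".join(f"{v:.6f}" for v in col) + "\n")
            handle.write("\n")
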