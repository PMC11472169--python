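"""One-hot encoding of flank sequences.

Each nucleotide becomes a 4-bit block in A,C,G,T order (A=1000, C=0100,
G=0010, T=0001); any character outside {A,C,G,T} is ambiguous and encodes as
1111.  A flank set becomes a (num_sequences x 4n) binary matrix, one matrix
per side, which is the input to the factorization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

BASES = "ACGT"

_ENCODE_LUT = np.ones((256, 4), dtype=np.uint8)  # default: ambiguous -> 1111
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = 0
    _ENCODE_LUT[ord(_b), _i] = 1


@dataclass
class FlankMatrix:
    """One-hot matrix for one side (upstream or downstream) of an anchor set."""

    values: np.ndarray  # (num_sequences, 4n) uint8
    side: str  # "upstream" | "downstream"
    row_ids: list[str]
    n: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_ids), 4 * self.n):
            raise ValueError("FlankMatrix shape inconsistent with row_ids / n")

    @property
    def num_sequences(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Dense TSV dump (debugging aid)."""
        with open(path, "w") as handle:
            for rid, row in zip(self.row_ids, self.values):
                handle.write(rid + "\t" + "".join(map(str, row.tolist())) + "\n")


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a flat 4-bit-per-base vector."""
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[codes].reshape(-1)


def decode_row(row: np.ndarray, n: int) -> str:
    """Inverse of :func:`one_hot_encode`; 1111 blocks decode to ``N``."""
    row = np.asarray(row, dtype=np.uint8)
    if row.shape != (4 * n,):
        raise ValueError(f"row length {row.size} != 4*{n}")
    blocks = row.reshape(n, 4)
    sums = blocks.sum(axis=1)
    out = []
    for block, s in zip(blocks, sums):
        if s == 4:
            out.append("N")
        elif s == 1:
            out.append(BASES[int(np.argmax(block))])
        else:
            raise ValueError(f"block {block.tolist()} is neither one-hot nor 1111")
    return "".join(out)


def build_flank_matrices(records) -> tuple[FlankMatrix, FlankMatrix]:
    """Encode the upstream and downstream flanks of an anchor set.

    Rows follow the input record order; both matrices share row ids.
    """
    if not records:
        raise ValueError("no records to encode")
    n = records[0].n
    for rec in records:
        if rec.n != n or len(rec.downstream) != n:
            raise ValueError(f"record {rec.id}: inconsistent flank length")
    row_ids = [rec.id for rec in records]
    up = np.stack([one_hot_encode(rec.upstream) for rec in records])
    down = np.stack([one_hot_encode(rec.downstream) for rec in records])
    return (
        FlankMatrix(up, "upstream", row_ids, n),
        FlankMatrix(down, "downstream", row_ids, n),
    )
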