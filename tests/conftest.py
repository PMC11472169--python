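"""Shared fixtures and small object factories for the test suite."""

import numpy as np
import pytest

from comotif.anchors import AnchorRecord
from comotif.clustering import AlignedMotif, Archetype
from comotif.motif_stats import CoreMotif, MotifCandidate, ic_vector
from comotif.nmf import ComponentPFM

BASES = "ACGT"


def random_dna(length, rng):
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def make_pfm(counts, side="downstream", assigned_ids=None, k=3, comp=0, dataset=""):
    counts = np.asarray(counts, dtype=float)
    if assigned_ids is None:
        assigned_ids = [f"s{i}" for i in range(int(round(counts[:, 0].sum())))]
    return ComponentPFM(counts, list(assigned_ids), side, k, comp, dataset)


def make_candidate(counts=None, ic=None, side="downstream", assigned_ids=None, dataset=""):
    """MotifCandidate with counts, optionally overriding the IC vector."""
    if counts is None:
        assert ic is not None
        # uniform counts placeholder; the given IC vector drives trimming
        counts = np.full((4, len(ic)), 5.0)
    pfm = make_pfm(counts, side=side, assigned_ids=assigned_ids, dataset=dataset)
    if ic is None:
        ic = ic_vector(pfm.counts)
    ic = np.asarray(ic, dtype=float)
    from comotif.motif_stats import gini_coefficient

    return MotifCandidate(
        pfm=pfm, ic=ic, total_ic=float(ic.sum()),
        gini=gini_coefficient(ic) if ic.size >= 2 else 0.0,
    )


def make_core(counts, flank_offset=0, side="downstream", n=30, assigned_ids=None, dataset=""):
    """A CoreMotif embedded in a full-flank parent candidate.

    The parent's flank PFM places the core counts at ``flank_offset`` and
    near-uniform background elsewhere, so parent IC is consistent.
    """
    counts = np.asarray(counts, dtype=float)
    w = counts.shape[1]
    assert flank_offset + w <= n
    nseq = counts.sum(axis=0).max()
    full = np.full((4, n), nseq / 4.0)
    full[:, flank_offset:flank_offset + w] = counts
    cand = make_candidate(full, side=side, assigned_ids=assigned_ids, dataset=dataset)
    return CoreMotif(
        counts=counts.copy(), flank_offset=flank_offset, core_width=w,
        side=side, parent=cand,
    )


def make_archetype(counts, assigned_ids, side="downstream", flank_offset=6, n=30, dataset=""):
    core = make_core(counts, flank_offset=flank_offset, side=side, n=n,
                     assigned_ids=assigned_ids, dataset=dataset)
    return Archetype(
        counts=np.asarray(counts, dtype=float),
        members=[AlignedMotif(core, 0, "forward")],
        trimmed_range=(0, counts.shape[1]),
    )


@pytest.fixture
def toy_genome(tmp_path):
    """A deterministic 200-nt single-chromosome genome FASTA."""
    rng = np.random.default_rng(42)
    seq = random_dna(200, rng)
    path = tmp_path / "genome.fa"
    path.write_text(f">chr1\n{seq}\n")
    return path, seq


@pytest.fixture
def small_records():
    """Twelve 10-nt-anchor records with 30-nt flanks."""
    rng = np.random.default_rng(7)
    return [
        AnchorRecord(f"r{i}", random_dna(10, rng), random_dna(30, rng), random_dna(30, rng))
        for i in range(12)
    ]
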