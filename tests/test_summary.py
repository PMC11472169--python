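"""Spacing conventions, prevalence accounting and summary outputs."""

import numpy as np
import pandas as pd
import pytest

from comotif.anchors import AnchorRecord, GenomicInterval
from comotif.summary import (
    build_patterns,
    effective_spacing,
    prevalence_of,
    spacing_of,
    write_summary,
)
from comotif.synthetic import pfm_from_consensus

from conftest import make_archetype, make_core


class TestSpacing:
    def test_downstream_adjacent(self):
        core = make_core(pfm_from_consensus("TGACGT"), flank_offset=0, side="downstream")
        assert spacing_of(core) == ("downstream", 0)

    def test_upstream_adjacent(self):
        core = make_core(pfm_from_consensus("TGACGT"), flank_offset=24, side="upstream", n=30)
        assert spacing_of(core) == ("upstream", 0)

    def test_downstream_interior(self):
        core = make_core(pfm_from_consensus("TGACGT"), flank_offset=4, side="downstream", n=30)
        assert spacing_of(core) == ("downstream", 4)

    def test_effective_spacing_strips_expansion_padding(self):
        """Low-IC columns padded around the informative block do not shift spacing."""
        m = pfm_from_consensus("TGACGTCA")
        padded = np.hstack([np.full((4, 2), 25.0), m, np.full((4, 2), 25.0)])
        core = make_core(padded, flank_offset=4, side="downstream", n=30)
        assert effective_spacing(core) == ("downstream", 6)
        core_up = make_core(padded, flank_offset=4, side="upstream", n=30)
        # informative block occupies [6, 14): upstream spacing = 30 - 14
        assert effective_spacing(core_up) == ("upstream", 16)

    def test_effective_spacing_grows_to_block_edge(self):
        """A core window that under-covers the block still reports the block edge."""
        m = pfm_from_consensus("TGACGTCA")
        core = make_core(m, flank_offset=6, side="downstream", n=30)
        # pretend trimming only caught the right half of the block
        core.flank_offset, core.core_width, core.counts = 10, 4, core.counts[:, 4:]
        assert effective_spacing(core) == ("downstream", 6)


class TestPatterns:
    def test_prevalence_ratio_and_union(self):
        ids = [f"seq{i}" for i in range(80)]
        arch = make_archetype(pfm_from_consensus("TGACGTCA"), ids, dataset="d1")
        patterns = build_patterns([arch], {"d1": 800})
        assert len(patterns) == 1
        assert patterns[0].prevalence == pytest.approx(0.10)
        assert prevalence_of(patterns[0], 800) == pytest.approx(0.10)

    def test_same_sequence_counted_once_across_k(self):
        m = pfm_from_consensus("TGACGTCA")
        ids = [f"seq{i}" for i in range(50)]
        c1 = make_core(m, flank_offset=6, assigned_ids=ids, dataset="d1")
        c2 = make_core(m, flank_offset=6, assigned_ids=ids[:30], dataset="d1")
        from comotif.clustering import build_archetype, cluster_motifs

        (cluster,) = cluster_motifs([c1, c2])
        arch = build_archetype(cluster)
        (pattern,) = build_patterns([arch], {"d1": 100})
        assert pattern.prevalence == pytest.approx(0.5)  # union, not sum

    def test_distinct_spacings_make_distinct_rows(self):
        m = pfm_from_consensus("TGACGTCA")
        c1 = make_core(m, flank_offset=2, assigned_ids=["a"], dataset="d1")
        c2 = make_core(m, flank_offset=9, assigned_ids=["b"], dataset="d1")
        from comotif.clustering import build_archetype, cluster_motifs

        (cluster,) = cluster_motifs([c1, c2])
        arch = build_archetype(cluster)
        patterns = build_patterns([arch], {"d1": 10})
        assert sorted(p.spacing for p in patterns) == [2, 9]
        assert {p.archetype_id for p in patterns} == {"archetype_1"}

    def test_cross_dataset_support_count(self):
        m = pfm_from_consensus("TGACGTCA")
        cores = [
            make_core(m, flank_offset=6, assigned_ids=[f"{d}_x"], dataset=d)
            for d in ("d1", "d2", "d3")
        ]
        from comotif.clustering import build_archetype, cluster_motifs

        (cluster,) = cluster_motifs(cores)
        arch = build_archetype(cluster)
        patterns = build_patterns([arch], {"d1": 10, "d2": 10, "d3": 10})
        assert len(patterns) == 3
        assert all(p.n_datasets == 3 for p in patterns)

    def test_prevalence_requires_positive_size(self):
        arch = make_archetype(pfm_from_consensus("TGACGTCA"), ["a"], dataset="d1")
        (pattern,) = build_patterns([arch], {"d1": 10})
        with pytest.raises(ValueError):
            prevalence_of(pattern, 0)


class TestWriteSummary:
    def _one_pattern(self):
        ids = [f"seq{i}" for i in range(8)]
        arch = make_archetype(pfm_from_consensus("TGACGTCA"), ids, dataset="d1")
        return build_patterns([arch], {"d1": 80})

    def test_golden_single_row(self, tmp_path):
        patterns = self._one_pattern()
        written = write_summary(patterns, tmp_path)
        frame = pd.read_csv(written["summary"], sep="\t")
        assert list(frame.columns) == [
            "dataset", "anchor_id", "side", "spacing", "orientation",
            "archetype_id", "n_datasets", "prevalence",
        ]
        row = frame.iloc[0]
        assert (
            row["dataset"], row["side"], row["spacing"],
            row["orientation"], row["archetype_id"], row["n_datasets"],
        ) == ("d1", "downstream", 6, "forward", "archetype_1", 1)
        assert row["prevalence"] == pytest.approx(0.1)
        assert written["jaspar"].exists() and written["meme"].exists()

    def test_empty_patterns_write_header_only(self, tmp_path):
        written = write_summary([], tmp_path)
        lines = written["summary"].read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("dataset\t")

    def test_cobound_bed_subset_of_input(self, tmp_path):
        patterns = self._one_pattern()
        records = [
            AnchorRecord(
                f"seq{i}", "A" * 10, "C" * 30, "G" * 30,
                source=GenomicInterval("chr1", 1000 + 50 * i, 1010 + 50 * i, "+", f"seq{i}"),
            )
            for i in range(80)
        ]
        written = write_summary(patterns, tmp_path, records_by_dataset={"d1": records})
        bed_rows = written["bed"].read_text().splitlines()
        assert len(bed_rows) == 8
        input_spans = {(r.source.chrom, r.source.start, r.source.end) for r in records}
        for line in bed_rows:
            chrom, start, end = line.split("\t")[:3]
            assert (chrom, int(start), int(end)) in input_spans

    def test_motif_files_roundtrip(self, tmp_path):
        from comotif.motif_io import read_jaspar, read_meme_minimal

        patterns = self._one_pattern()
        written = write_summary(patterns, tmp_path)
        jaspar = read_jaspar(written["jaspar"])
        assert "archetype_1" in jaspar
        assert np.allclose(jaspar["archetype_1"], patterns[0].archetype.counts, atol=0.01)
        meme = read_meme_minimal(written["meme"])
        freqs = meme["archetype_1"] / meme["archetype_1"].sum(axis=0)
        src = patterns[0].archetype.counts / patterns[0].archetype.counts.sum(axis=0)
        assert np.allclose(freqs, src, atol=1e-4)
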