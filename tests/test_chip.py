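"""Coverage enrichment: RPKM, density ratios, metagene, promoter windows."""

import math
import warnings

import numpy as np
import pytest

from rvbtools import (
    CoverageTrack,
    GeneAnnotation,
    GeneratorConfig,
    class_compare,
    gen_genome_coverage,
    metagene,
    normalized_density,
    promoter_enrichment,
    rpkm,
)


def uniform_track(value=5.0, n_bins=2000, bin_size=10, chroms=("chr1",), total=None):
    counts = {c: np.full(n_bins, value) for c in chroms}
    return CoverageTrack.from_arrays(counts, bin_size, total)


class TestRpkm:
    def test_definitional_arithmetic(self):
        # 100 reads spread over a 1 kb interval, library of 1e6 -> RPKM 100
        track = CoverageTrack({"chr1": np.full(100, 1.0)}, 10, 1e6)
        assert abs(rpkm(track, ("chr1", 0, 1000)) - 100.0) < 1e-9

    def test_empty_window_is_zero(self):
        track = CoverageTrack({"chr1": np.zeros(100)}, 10, 1e6)
        assert rpkm(track, ("chr1", 200, 400)) == 0.0

    def test_depth_scale_invariance(self):
        t1 = CoverageTrack({"chr1": np.arange(100.0)}, 10, 1e6)
        t2 = CoverageTrack({"chr1": np.arange(100.0) * 3}, 10, 3e6)
        iv = ("chr1", 150, 750)
        assert abs(rpkm(t1, iv) - rpkm(t2, iv)) < 1e-9

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="total_mapped_reads"):
            CoverageTrack({"chr1": np.zeros(10)}, 10, 0.0)

    def test_clipped_interval_warns(self):
        track = CoverageTrack({"chr1": np.full(10, 2.0)}, 10, 1e4)
        with pytest.warns(UserWarning, match="clipped"):
            rpkm(track, ("chr1", -50, 50))

    def test_fractional_bin_overlap(self):
        track = CoverageTrack({"chr1": np.array([10.0, 20.0])}, 10, 1e6)
        count, clipped = track.window_count("chr1", 5, 15)
        assert count == 10.0 / 2 + 20.0 / 2
        assert not clipped


class TestNormalizedDensity:
    def test_identical_tracks_ratio_one(self):
        chip = uniform_track(7.0)
        inp = uniform_track(7.0)
        assert abs(normalized_density(chip, inp, ("chr1", 0, 5000)) - 1.0) < 1e-12

    def test_library_size_invariance(self):
        chip = uniform_track(8.0)
        inp1 = uniform_track(4.0)
        inp2 = CoverageTrack(
            {c: a * 5 for c, a in inp1.counts.items()}, inp1.bin_size,
            inp1.total_mapped_reads * 5,
        )
        iv = ("chr1", 100, 900)
        assert abs(
            normalized_density(chip, inp1, iv) - normalized_density(chip, inp2, iv)
        ) < 1e-12

    def test_zero_input_window_finite(self):
        chip = uniform_track(5.0)
        inp = CoverageTrack({"chr1": np.zeros(2000)}, 10, chip.total_mapped_reads)
        val = normalized_density(chip, inp, ("chr1", 0, 100), pseudocount=0.5)
        assert math.isfinite(val) and val > 1

    def test_pseudocount_limit_converges_to_raw_ratio(self):
        chip = uniform_track(6.0, total=1e6)
        inp = uniform_track(2.0, total=1e6)
        iv = ("chr1", 0, 1000)
        raw = rpkm(chip, iv) / rpkm(inp, iv)
        vals = [normalized_density(chip, inp, iv, pc) for pc in (10.0, 1.0, 1e-4)]
        assert abs(vals[-1] - raw) < 1e-3
        assert abs(vals[0] - raw) > abs(vals[-1] - raw)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            normalized_density(
                uniform_track(bin_size=10), uniform_track(bin_size=20), ("chr1", 0, 100)
            )


def mirror_genome(track: CoverageTrack) -> CoverageTrack:
    return CoverageTrack(
        {c: a[::-1].copy() for c, a in track.counts.items()},
        track.bin_size,
        track.total_mapped_reads,
    )


class TestMetagene:
    def test_uniform_coverage_gives_flat_profile(self):
        tracks = {"target": uniform_track(5.0), "control": uniform_track(5.0)}
        genes = [GeneAnnotation("g1", "chr1", 5000, 8000, "+")]
        prof = metagene(tracks, genes, body_bins=20)
        assert prof.matrix.shape == (1, 50 + 20 + 50)
        assert np.allclose(prof.matrix, 1.0)

    def test_strand_flip_invariance(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(10, 2000).astype(float)
        target = CoverageTrack({"chr1": counts}, 10, counts.sum())
        control = uniform_track(10.0, total=counts.sum())
        L = 2000 * 10
        plus = [GeneAnnotation("g", "chr1", 5000, 8000, "+")]
        minus = [GeneAnnotation("g", "chr1", L - 8000, L - 5000, "-")]
        p1 = metagene({"target": target, "control": control}, plus, body_bins=30)
        p2 = metagene(
            {"target": mirror_genome(target), "control": mirror_genome(control)},
            minus, body_bins=30,
        )
        assert np.allclose(p1.matrix, p2.matrix)

    def test_promoter_peak_located_upstream(self):
        cfg = GeneratorConfig(seed=21, noise_cv=0.05)
        genes, tracks = gen_genome_coverage(cfg, {"class_II": 8.0})
        class2 = [g for g in genes if g.class_label == "class_II"]
        prof = metagene(
            {"target": tracks["target"], "control": tracks["control"]},
            class2, body_bins=50,
        )
        mean = prof.matrix.mean(axis=0)
        peak_bin = int(np.argmax(mean))
        assert peak_bin < prof.n_upstream  # peak in the -500..TSS segment
        peak_log2 = np.log2(mean[: prof.n_upstream].mean())
        assert abs(peak_log2 - 3.0) < 0.4

    def test_short_genes_excluded_with_warning(self):
        tracks = {"target": uniform_track(), "control": uniform_track()}
        genes = [
            GeneAnnotation("tiny", "chr1", 5000, 5050, "+"),
            GeneAnnotation("ok", "chr1", 9000, 12000, "+"),
        ]
        with pytest.warns(UserWarning, match="tiny"):
            prof = metagene(tracks, genes, body_bins=100)
        assert prof.gene_ids == ["ok"]

    def test_all_filtered_out_errors(self):
        tracks = {"target": uniform_track(), "control": uniform_track()}
        genes = [GeneAnnotation("tiny", "chr1", 5000, 5050, "+")]
        with pytest.raises(ValueError, match="filtered"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metagene(tracks, genes, body_bins=100)


class TestPromoterEnrichment:
    def test_equal_tracks_zero_log_ratio(self):
        t = uniform_track(4.0)
        genes = [
            GeneAnnotation("a", "chr1", 3000, 6000, "+"),
            GeneAnnotation("b", "chr1", 9000, 12000, "-"),
        ]
        enr = promoter_enrichment(t, t, genes, pseudocount=0.0)
        assert all(abs(e.log2_ratio) < 1e-12 for e in enr)

    def test_class_truth_recovered_at_depth(self):
        cfg = GeneratorConfig(seed=33, noise_cv=0.05, depth=1_000_000)
        genes, tracks = gen_genome_coverage(cfg, {"class_II": 4.0})
        enr = promoter_enrichment(tracks["target"], tracks["control"], genes)
        vals = [e.log2_ratio for e in enr if e.class_label == "class_II"]
        assert abs(np.mean(vals) - 2.0) < 0.1

    def test_library_depth_invariance(self):
        cfg = GeneratorConfig(seed=40, noise_cv=0.05)
        genes, tracks = gen_genome_coverage(cfg, {"class_II": 4.0})
        control = tracks["control"]
        scaled = CoverageTrack(
            {c: a * 7 for c, a in control.counts.items()},
            control.bin_size, control.total_mapped_reads * 7,
        )
        e1 = promoter_enrichment(tracks["target"], control, genes)
        e2 = promoter_enrichment(tracks["target"], scaled, genes)
        assert np.allclose(
            [e.log2_ratio for e in e1], [e.log2_ratio for e in e2]
        )

    def test_chromosome_start_window_clipped_and_flagged(self):
        t = uniform_track(4.0)
        genes = [GeneAnnotation("edge", "chr1", 100, 2000, "+")]
        enr = promoter_enrichment(t, t, genes)
        assert enr[0].clipped


class TestClassCompare:
    @staticmethod
    def enrich(values, label):
        from rvbtools.chip import WindowEnrichment

        return [WindowEnrichment(f"{label}{i}", v, label) for i, v in enumerate(values)]

    def test_identical_distributions_null(self):
        vals = [0.1, 0.4, -0.2, 0.3]
        res = class_compare(
            self.enrich(vals, "class_I") + self.enrich(vals, "class_II"),
            "class_II", "class_I",
        )
        assert abs(res.difference) < 1e-12
        assert res.p_value > 0.99

    def test_separated_classes_strongly_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(2.0, 0.5, 50)
        b = rng.normal(0.0, 0.5, 50)
        res = class_compare(
            self.enrich(a, "class_II") + self.enrich(b, "class_I"),
            "class_II", "class_I",
        )
        assert res.p_value < 1e-10
        assert abs(res.difference - 2.0) < 0.2
        # Welch t recomputed from first principles
        va, vb = a.var(ddof=1) / 50, b.var(ddof=1) / 50
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        assert abs(res.t_statistic - t_hand) < 1e-9

    def test_single_gene_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            class_compare(
                self.enrich([1.0], "class_II") + self.enrich([0.0, 0.1], "class_I"),
                "class_II", "class_I",
            )

    def test_ecdf_coordinates(self):
        res = class_compare(
            self.enrich([3.0, 1.0, 2.0], "class_II")
            + self.enrich([0.0, 0.5], "class_I"),
            "class_II", "class_I",
        )
        x, y = res.ecdf_a
        assert x.tolist() == [1.0, 2.0, 3.0]
        assert y.tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])
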