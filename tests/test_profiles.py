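"""Anchored profiles, metaprofiles, AUC normalization, redistribution."""

import numpy as np
import pytest

from pausekit.annotation import GeneRecord
from pausekit.coverage import CoverageTrack
from pausekit.profiles import (
    AnchoredProfile,
    MetaProfile,
    anchored_profile,
    meta_profile,
    metagene_scaled,
    redistribution,
)
from conftest import oracle_window_density


def flat_track(value=1.0, size=20_000):
    return CoverageTrack({"chr1": np.full(size, value)})


class TestAnchoredProfile:
    def test_flat_track_flat_bins(self):
        gene = GeneRecord("g", "chr1", 5000, 12_000, "+")
        prof = anchored_profile(flat_track(3.0), gene, "TSS", (-2000, 5000), 50)
        assert (prof.bins == 3.0).all()
        assert len(prof.bins) == 140

    def test_signal_confined_to_one_bin(self):
        data = np.zeros(20_000)
        gene = GeneRecord("g", "chr1", 5000, 12_000, "+")
        # bin 3 of span (-2000, 5000) at 50 bp covers offsets [-1850, -1800)
        data[5000 - 1850 : 5000 - 1800] = 1.0
        prof = anchored_profile(CoverageTrack({"chr1": data}), gene, "TSS", (-2000, 5000), 50)
        assert prof.bins[3] == 1.0
        assert prof.bins.sum() == 1.0

    def test_bins_match_oracle_recount(self, small_track):
        track, _ = small_track
        gene = GeneRecord("m", "chr1", 200, 1700, "-")
        prof = anchored_profile(track, gene, "TSS", (-100, 400), 25)
        depth = track.data["chr1"]
        for b, val in enumerate(prof.bins):
            lo = -100 + 25 * b
            assert val == pytest.approx(oracle_window_density(depth, gene, lo, lo + 25))

    def test_tts_anchor(self):
        data = np.zeros(20_000)
        gene = GeneRecord("g", "chr1", 5000, 12_000, "+")
        data[11_999] = 7.0  # the TTS base itself
        prof = anchored_profile(CoverageTrack({"chr1": data}), gene, "TTS", (-50, 50), 50)
        assert prof.bins[1] == pytest.approx(7.0 / 50)

    def test_span_must_divide(self):
        gene = GeneRecord("g", "chr1", 5000, 12_000, "+")
        with pytest.raises(ValueError, match="multiple"):
            anchored_profile(flat_track(), gene, "TSS", (-100, 105), 50)


class TestMetaProfile:
    def _profiles(self, values):
        return [
            AnchoredProfile(f"g{i}", "TSS", np.full(10, v), 50, (0, 500))
            for i, v in enumerate(values)
        ]

    def test_mean_of_flat_profiles(self):
        meta = meta_profile(self._profiles([2.0, 4.0]), stat="mean")
        assert (meta.bins == 3.0).all()
        assert meta.n_genes == 2

    def test_auc_integral_is_one(self):
        rng = np.random.default_rng(0)
        profs = [
            AnchoredProfile(f"g{i}", "TSS", rng.uniform(0.1, 5, 10), 50, (0, 500))
            for i in range(5)
        ]
        meta = meta_profile(profs, normalize="AUC")
        assert meta.integral() == pytest.approx(1.0, abs=1e-9)

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        mats = [rng.exponential(1.0, 10) for _ in range(3)]
        profs = [AnchoredProfile(f"g{i}", "TSS", m, 50, (0, 500)) for i, m in enumerate(mats)]
        meta = meta_profile(profs, stat="median")
        stacked = np.vstack(mats)
        oracle = np.array([sorted(stacked[:, j])[1] for j in range(10)])
        np.testing.assert_allclose(meta.bins, oracle)

    def test_mixed_spans_rejected(self):
        a = AnchoredProfile("a", "TSS", np.ones(10), 50, (0, 500))
        b = AnchoredProfile("b", "TSS", np.ones(10), 50, (-250, 250))
        with pytest.raises(ValueError, match="mix"):
            meta_profile([a, b])

    def test_all_zero_auc_rejected(self):
        profs = self._profiles([0.0])
        with pytest.raises(ValueError, match="non-positive"):
            meta_profile(profs, normalize="AUC")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            meta_profile([])

    def test_mean_is_linear(self):
        p1, p2 = self._profiles([2.0, 4.0])
        m12 = meta_profile([p1, p2]).bins
        m1 = meta_profile([p1]).bins
        m2 = meta_profile([p2]).bins
        np.testing.assert_allclose(m12, (m1 + m2) / 2)


class TestRedistribution:
    def _meta(self, bins, norm="AUC"):
        return MetaProfile(np.asarray(bins, float), 3, 50, (0, 500), normalization=norm)

    def test_identical_inputs_zero(self):
        a = self._meta(np.linspace(1, 2, 10))
        assert (redistribution(a, a).bins == 0).all()

    def test_auc_difference_integrates_to_zero(self):
        rng = np.random.default_rng(2)
        mk = lambda: meta_profile(
            [AnchoredProfile("g", "TSS", rng.uniform(0.5, 2, 10), 50, (0, 500))],
            normalize="AUC",
        )
        diff = redistribution(mk(), mk())
        assert diff.integral() == pytest.approx(0.0, abs=1e-9)

    def test_normalization_mismatch_rejected(self):
        with pytest.raises(ValueError, match="normalization"):
            redistribution(self._meta(np.ones(10)), self._meta(np.ones(10), norm="none"))

    def test_release_gives_negative_pause_positive_downstream(self):
        """A pause-release simulation must show the repositioning sign pattern."""
        from pausekit import simulate as sim
        from pausekit.profiles import anchored_profile as ap

        catalog, sizes = sim.simulate_catalog(12, (6000, 12_000), 6000, seed=5)
        model = sim.OccupancyModel()
        mock = sim.ConditionSpec(label="mock")
        uv = sim.ConditionSpec(label="uv", release_fraction=0.5, release_zone=2000)
        from pausekit.coverage import normalize_per_10M, pileup

        metas = {}
        for cond in (mock, uv):
            frags = sim.simulate_chip_library(catalog, model, cond, 100_000, sizes, seed=7)
            track = normalize_per_10M(pileup(frags, sizes), frags.mapped_count)
            profs = [ap(track, g, "TSS", (-2000, 5000), 50) for g in catalog]
            metas[cond.label] = meta_profile(profs, normalize="AUC", label=cond.label)
        diff = redistribution(metas["uv"], metas["mock"])
        offsets = diff.offsets
        pause_bin = np.argmin(np.abs(offsets))
        assert diff.bins[pause_bin] < 0
        downstream = (offsets >= 300) & (offsets < 1500)
        assert diff.bins[downstream].mean() > 0


class TestMetageneScaled:
    def test_flat_track_flat_profile(self):
        gene = GeneRecord("g", "chr1", 5000, 12_000, "+")
        prof = metagene_scaled(flat_track(2.0), gene, flank=1000, body_bins=20)
        assert np.allclose(prof.bins, 2.0)

    def test_length_invariance_of_fractional_shape(self):
        """Two genes with the same fractional-coordinate shape scale identically."""
        size = 60_000
        data = np.zeros(size)
        g1 = GeneRecord("g1", "chr1", 5000, 15_000, "+")
        g2 = GeneRecord("g2", "chr1", 25_000, 45_000, "+")
        # signal over the first half of each body
        data[5000:10_000] = 1.0
        data[25_000:35_000] = 1.0
        track = CoverageTrack({"chr1": data})
        p1 = metagene_scaled(track, g1, flank=1000, body_bins=10)
        p2 = metagene_scaled(track, g2, flank=1000, body_bins=10)
        n_flank = 1000 // 50
        np.testing.assert_allclose(
            p1.bins[n_flank : n_flank + 10], p2.bins[n_flank : n_flank + 10]
        )

    def test_matches_fractional_recount_oracle(self, small_track):
        track, _ = small_track
        gene = GeneRecord("g", "chr1", 300, 1303, "+")  # length 1003, not divisible
        body_bins = 7
        prof = metagene_scaled(track, gene, flank=100, body_bins=body_bins, flank_bin_size=50)
        depth = track.data["chr1"]
        body = depth[300:1303]
        edges = np.linspace(0, 1003, body_bins + 1)
        for b in range(body_bins):
            acc = 0.0
            for i in range(len(body)):
                overlap = max(0.0, min(i + 1, edges[b + 1]) - max(i, edges[b]))
                acc += overlap * body[i]
            expected = acc / (edges[b + 1] - edges[b])
            assert prof.bins[2 + b] == pytest.approx(expected)

    def test_too_short_gene_rejected(self):
        gene = GeneRecord("g", "chr1", 100, 150, "+")
        with pytest.raises(ValueError, match="shorter"):
            metagene_scaled(flat_track(), gene, flank=0, body_bins=100)
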