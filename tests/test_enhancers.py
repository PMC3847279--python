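import numpy as np
import pandas as pd
import pytest

from epicoord import enhancers as en
from tests.conftest import make_track


def flat_tracks(n_bins=2000, level=10, seed=0, bump=None):
    rng = np.random.default_rng(seed)
    mark = rng.poisson(level, n_bins)
    ctrl = rng.poisson(level, n_bins)
    if bump is not None:
        for b, h in bump:
            mark[b] += h
    return (make_track({"chr1": mark}, mark="H3K4me1"),
            make_track({"chr1": ctrl}, mark="panH3"))


class TestCallIslands:
    def test_flat_background_yields_nothing(self):
        m, c = flat_tracks()
        assert en.call_islands(m, c) == []

    def test_nearby_runs_merge_within_gap(self):
        # two elevated runs 400 bp (2 bins) apart merge into one island
        bump = [(100, 60), (101, 60), (104, 60), (105, 60)]
        m, c = flat_tracks(bump=bump)
        islands = en.call_islands(m, c, gap=600)
        assert len(islands) == 1
        assert islands[0].start_bin == 100 and islands[0].end_bin == 106

    def test_runs_beyond_gap_stay_separate(self):
        bump = [(100, 60), (101, 60), (110, 60), (111, 60)]
        m, c = flat_tracks(bump=bump)
        islands = en.call_islands(m, c, gap=600)
        assert len(islands) == 2

    def test_empty_control_falls_back_with_warning(self, caplog):
        counts = np.full(2000, 10)
        counts[50:52] += 80
        m = make_track({"chr1": counts}, mark="H3K4me1")
        zero = make_track({"chr1": np.zeros(2000, dtype=int)}, mark="panH3")
        with caplog.at_level("WARNING"):
            islands = en.call_islands(m, zero)
        assert len(islands) == 1
        assert "control" in caplog.text

    def test_planted_peak_recovered_with_anchor(self, small_study):
        """Each planted differential enhancer has an island containing its
        planted apex bin, whose anchor is (close to) the apex."""
        tracks, truth = small_study["tracks"], small_study["truth"]
        m = tracks[("H3K27ac", "mesenchymal")]
        c = tracks[("panH3", "mesenchymal")]
        islands = en.call_islands(m, c)
        gains = [e for e in truth.enhancers if e["direction"] == "gain"]
        assert gains
        for e in gains:
            hit = [i for i in islands
                   if i.chrom == e["chrom"] and i.overlaps_bin(e["anchor_bin"])]
            assert len(hit) == 1
            # the anchor stays within the peak support, so the resulting
            # 11-bin locus always covers the planted apex
            anchor = en.select_anchor(hit[0], m)
            assert abs(anchor.bin - e["anchor_bin"]) <= 5


class TestAnchors:
    def test_unique_max(self):
        t = make_track({"chr1": np.array([0, 2, 9, 4, 0])})
        a = en.select_anchor(en.Island("chr1", 1, 4), t)
        assert a.bin == 2

    def test_tie_breaks_leftmost(self):
        t = make_track({"chr1": np.array([0, 5, 5, 1, 0])})
        a = en.select_anchor(en.Island("chr1", 1, 4), t)
        assert a.bin == 1

    @pytest.mark.parametrize("anchor_bin,kept", [
        (10, False),   # inside the K4me3 island
        (12, True),    # 1 bin outside (half-open)
    ])
    def test_h3k4me3_filter(self, anchor_bin, kept):
        anchors = [en.Anchor("chr1", anchor_bin, "H3K4me1")]
        islands = [en.Island("chr1", 9, 12)]
        out = en.filter_h3k4me3(anchors, islands)
        assert (len(out) == 1) is kept

    def test_empty_k4me3_set_is_identity(self):
        anchors = [en.Anchor("chr1", 5, "H3K4me1")]
        assert en.filter_h3k4me3(anchors, []) == anchors


class TestCollapse:
    def test_k4me1_near_k27ac_collapses_to_k27ac(self):
        k4 = [en.Anchor("chr1", 102, "H3K4me1")]   # 400 bp from the K27ac site
        k27 = [en.Anchor("chr1", 100, "H3K27ac")]
        loci = en.collapse_anchors(k4, k27)
        assert len(loci) == 1
        assert loci[0].source_mark == "H3K27ac"

    def test_distant_anchors_both_kept(self):
        k4 = [en.Anchor("chr1", 130, "H3K4me1")]   # 5.6 kb away
        k27 = [en.Anchor("chr1", 102, "H3K27ac")]
        loci = en.collapse_anchors(k4, k27)
        assert len(loci) == 2

    def test_every_locus_is_2200_bp(self):
        k4 = [en.Anchor("chr1", b, "H3K4me1") for b in (50, 90, 130)]
        k27 = [en.Anchor("chr1", 200, "H3K27ac")]
        for loc in en.collapse_anchors(k4, k27):
            assert loc.end - loc.start == 2200
            s, e = loc.bin_range
            assert e - s == 11

    def test_edge_anchor_dropped(self):
        loci = en.collapse_anchors([en.Anchor("chr1", 2, "H3K4me1")], [],
                                   chrom_sizes={"chr1": 100_000})
        assert loci == []


class TestEnhancerMarks:
    def test_fixed_set_returns_the_six_marks(self):
        assert en.identify_enhancer_marks([], {}) == list(
            en.ENHANCER_ASSOCIATED_MARKS)

    def test_correlated_mark_selected_noise_mark_excluded(self):
        rng = np.random.default_rng(0)
        n_loci, n_bins = 200, 4000
        base = np.zeros(n_bins)
        loci = []
        for i in range(n_loci):
            b = 8 + i * (n_bins // n_loci)
            base[b - 5:b + 6] = rng.normal(0, 5)
            loci.append(en.EnhancerLocus(f"e{i}", "chr1", b, "H3K27ac",
                                         b * 200 - 1000, b * 200 + 1200))
        tracks = {
            "H3K4me1": make_track({"chr1": base.copy()}, kind="SDE"),
            "H3K27ac": make_track({"chr1": base.copy()}, kind="SDE"),
            "twin": make_track({"chr1": base + rng.normal(0, 0.5, n_bins)},
                               kind="SDE"),
            "noise": make_track({"chr1": rng.normal(0, 5, n_bins)},
                                kind="SDE"),
        }
        out = en.identify_enhancer_marks(loci, tracks, r_min=0.5,
                                         fixed_set=False)
        assert "twin" in out and "noise" not in out

    def test_too_few_loci_rejected(self):
        with pytest.raises(ValueError):
            en.identify_enhancer_marks([], {}, fixed_set=False)


class TestExtremeNull:
    def test_recovers_gaussian_parameters(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.3, 0.05, 4000)
        nm = en.fit_extreme_null(x)
        assert nm.mu_hat == pytest.approx(0.3, abs=0.01)
        assert nm.sigma_hat == pytest.approx(x.std(), rel=0.15)

    def test_two_point_tail_formula(self):
        """With exactly two points a and b below the mode at distances
        da, db, the printed formula gives sqrt(da^2 + db^2)."""
        bulk = np.full(500, 0.5) + np.random.default_rng(0).normal(0, 1e-3, 500)
        x = np.concatenate([bulk, [0.4, 0.35]])
        nm = en.fit_extreme_null(x, bandwidth=0.005)
        da, db = nm.mu_hat - 0.4, nm.mu_hat - 0.35
        tail_below = x[x <= nm.mu_hat]
        expected = np.sqrt(np.sum((tail_below - nm.mu_hat) ** 2)
                           / (len(tail_below) - 1))
        assert nm.sigma_hat == pytest.approx(expected)
        assert nm.sigma_hat >= np.sqrt((da**2 + db**2) / (len(tail_below) - 1))

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            en.fit_extreme_null(np.full(100, 0.5))


class TestFilterDifferential:
    def _loci(self, mags):
        return [en.EnhancerLocus(f"e{i}", "chr1", 100 + 20 * i, "H3K27ac",
                                 0, 2200, max_magnitude=m)
                for i, m in enumerate(mags)]

    def test_at_mode_is_filtered_at_boundary_retained(self):
        nm = en.NullModel(mu_hat=0.5, sigma_hat=0.1, bandwidth=0.025, n_tail=50)
        boundary = 0.5 + 1.6449 * 0.1   # normal 95% point to 4 decimals
        loci = self._loci([0.5, boundary, boundary + 0.05])
        kept = en.filter_differential(loci, nm, alpha=0.05)
        ids = {l.locus_id for l in kept}
        assert "e0" not in ids           # p = 0.5 at the mode
        assert "e1" in ids               # boundary p = alpha kept
        assert "e2" in ids
        assert all(l.status == "differential" for l in kept)

    def test_gaussian_null_population_retained_at_alpha(self):
        rng = np.random.default_rng(3)
        mags = rng.normal(0.4, 0.06, 10_000)
        loci = self._loci(mags)
        nm = en.fit_extreme_null(mags)
        kept = en.filter_differential(loci, nm, alpha=0.05)
        frac = len(kept) / len(loci)
        assert abs(frac - 0.05) <= 0.02

    def test_unset_magnitude_rejected(self):
        nm = en.NullModel(0.5, 0.1, 0.025, 10)
        with pytest.raises(ValueError):
            en.filter_differential(self._loci([None]), nm)


class TestAssignToGenes:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                           "txStart", "txEnd"])

    def test_enhancer_between_two_tss_assigned_to_both(self):
        genes = self._genes([("g1", "chr1", "+", 10_000, 15_000),
                             ("g2", "chr1", "+", 30_000, 35_000)])
        loci = [en.EnhancerLocus("e", "chr1", 90, "H3K27ac", 17_900, 20_100)]
        out = en.assign_to_genes(loci, genes)
        assert sorted(out[0].genes) == ["g1", "g2"]

    def test_one_megabase_cap(self):
        genes = self._genes([("g1", "chr1", "+", 10_000, 15_000)])
        far = 10_000 + 2_000_000
        loci = [en.EnhancerLocus("e", "chr1", far // 200, "H3K27ac",
                                 far, far + 2200)]
        out = en.assign_to_genes(loci, genes)
        assert out[0].genes == []

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        n_genes, cap = 50, 1_000_000
        tss = np.sort(rng.choice(5_000_000, n_genes, replace=False))
        genes = self._genes([(f"g{i}", "chr1", "+", int(t), int(t) + 2000)
                             for i, t in enumerate(tss)])
        loci = [en.EnhancerLocus(f"e{i}", "chr1", int(p) // 200, "H3K27ac",
                                 int(p), int(p) + 2200)
                for i, p in enumerate(rng.choice(5_000_000, 80))]
        out = en.assign_to_genes(loci, genes, cap=cap)
        for loc in out:
            expected = []
            for i, t in enumerate(tss):
                left = max(t - cap, tss[i - 1] if i > 0 else t - cap, 0)
                right = min(t + cap, tss[i + 1] if i + 1 < len(tss) else t + cap)
                if left < loc.end and loc.start < right:
                    expected.append(f"g{i}")
            assert sorted(loc.genes) == sorted(expected)
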