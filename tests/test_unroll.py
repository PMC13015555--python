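"""Spiral fitting, digital unrolling, and composition analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mucosa import simulate as sim
from mucosa import unroll as ur


@pytest.fixture(scope="module")
def fitted(small_roll):
    _, cells, _ = small_roll
    sub = cells[cells["sample_id"] == "control_0"]
    spiral = ur.fit_spiral(sub)
    return sub, spiral, ur.unroll(sub, spiral)


class TestFitSpiral:
    def test_noiseless_exact_recovery(self):
        theta = np.linspace(0.0, 6 * np.pi, 4000)
        r = 200 + 80 * theta
        pts = pd.DataFrame({"x": r * np.cos(theta), "y": r * np.sin(theta)})
        spiral = ur.fit_spiral(pts, anchor_cluster=None)
        # a is gauge-dependent (theta origin is arbitrary up to whole turns)
        a_gauge = spiral.a - spiral.b * 2 * np.pi * round(
            (spiral.a - 200) / (2 * np.pi * spiral.b)
        )
        assert spiral.b == pytest.approx(80.0, rel=0.01)
        assert a_gauge == pytest.approx(200.0, rel=0.01)

    def test_jittered_roll_recovery(self, small_roll, fitted):
        spec, _, _ = small_roll
        _, spiral, _ = fitted
        assert spiral.b == pytest.approx(spec.b, rel=0.05)
        assert spiral.luminal_sign == spec.luminal_sign

    def test_circle_errors(self):
        phi = np.linspace(0, 2 * np.pi, 1500, endpoint=False)
        pts = pd.DataFrame({"x": 500 * np.cos(phi), "y": 500 * np.sin(phi)})
        with pytest.raises(ValueError, match="circle"):
            ur.fit_spiral(pts, anchor_cluster=None)

    def test_partial_turn_errors(self):
        theta = np.linspace(0.0, 4.0, 1500)
        r = 300 + 100 * theta
        pts = pd.DataFrame({"x": r * np.cos(theta), "y": r * np.sin(theta)})
        with pytest.raises(ValueError):
            ur.fit_spiral(pts, anchor_cluster=None)

    def test_clockwise_roll_recovered(self):
        theta = np.linspace(1.0, 6 * np.pi, 4000)
        r = 300 + 90 * theta
        rng = np.random.default_rng(1)
        rr = r + rng.normal(0, 30, size=r.size)
        pts = pd.DataFrame({"x": rr * np.cos(-theta), "y": rr * np.sin(-theta)})
        spiral = ur.fit_spiral(pts, anchor_cluster=None)
        assert spiral.chirality == -1
        assert spiral.b == pytest.approx(90.0, rel=0.05)


class TestArcLength:
    def test_numeric_matches_closed_form(self, fitted):
        _, spiral, _ = fitted
        theta, numeric = spiral.arc_length_grid()
        exact = ur.archimedean_arc_length(spiral.a, spiral.b, theta)
        exact = exact - exact[0]
        assert np.max(np.abs(numeric - exact)) <= 1e-3 * exact[-1]

    def test_adjacent_turns_separated_by_one_turn_arc(self, fitted):
        _, spiral, _ = fitted
        t0 = spiral.theta_range[0] + 0.5
        length = ur.archimedean_arc_length(spiral.a, spiral.b,
                                           np.array([t0, t0 + 2 * np.pi]))
        one_turn = length[1] - length[0]
        # analytic arc of one full turn at the local radius
        approx = 2 * np.pi * spiral.radius(t0 + np.pi)
        assert one_turn == pytest.approx(approx, rel=0.01)


class TestUnroll:
    def test_recovers_truth(self, small_roll, fitted):
        _, _, truth = small_roll
        sub, _, unrolled = fitted
        tr = truth.loc[sub["cell_id"]]
        rho = stats.spearmanr(unrolled["s"], tr["s"].to_numpy()).statistic
        derr = np.abs(unrolled["d"].to_numpy() - tr["d"].to_numpy())
        assert rho > 0.99
        assert np.quantile(derr, 0.95) < 0.1

    def test_centerline_cell_maps_to_mid_depth(self, fitted):
        _, spiral, _ = fitted
        t = 0.5 * sum(spiral.theta_range)
        r = spiral.radius(t)
        cells = pd.DataFrame(
            {
                "cell_id": ["c0"],
                "x": [spiral.center[0] + r * np.cos(spiral.chirality * t)],
                "y": [spiral.center[1] + r * np.sin(spiral.chirality * t)],
            }
        )
        out = ur.unroll(cells, spiral)
        assert out["d"].iloc[0] == pytest.approx(0.5, abs=1e-6)

    def test_zero_jitter_exact_inverse(self):
        """With the generating spiral supplied directly, unrolling inverts
        the roll to the precision of the arc-length quadrature."""
        spec = sim.SpatialSimSpec(
            seed=1, jitter_r=0.0, jitter_theta=0.0,
            colon_length=24000.0, cells_per_mm=200.0, n_samples_per_genotype=1,
        )
        cells, truth = sim.simulate_swiss_roll(spec)
        sub = cells[cells["sample_id"] == "control_0"]
        t1 = sim._theta_end(spec)
        true_spiral = ur.SpiralModel(
            center=(0.0, 0.0), a=spec.a, b=spec.b,
            theta_range=(spec.theta0, t1),
            ht_theta=np.array([spec.theta0, t1]),
            ht_values=np.full(2, spec.half_thickness),
        )
        out = ur.unroll(sub, true_spiral)
        tr = truth.loc[sub["cell_id"]]
        assert np.abs(out["s"].to_numpy() - tr["s"].to_numpy()).max() < 1e-6
        assert np.abs(out["d"].to_numpy() - tr["d"].to_numpy()).max() < 1e-9

    def test_deterministic(self, fitted):
        sub, spiral, unrolled = fitted
        again = ur.unroll(sub, spiral)
        pd.testing.assert_frame_equal(unrolled, again)


class TestRegions:
    def test_boundary_convention(self):
        regions = ur.assign_regions([0.0, 1 / 3, 0.5, 2 / 3, 1.0])
        assert list(regions) == ["proximal", "mid", "mid", "distal", "distal"]

    def test_uniform_split_near_equal(self):
        s = (np.arange(999) + 0.5) / 999
        regions = ur.assign_regions(s)
        counts = pd.Series(regions).value_counts()
        assert (np.abs(counts - 333) <= 1).all()

    def test_bad_boundaries(self):
        with pytest.raises(ValueError):
            ur.assign_regions([0.5], boundaries=(0.8, 0.2))


class TestComposition:
    def test_frequencies_sum_to_one(self, unrolled_roll):
        prof = ur.composition_profile(unrolled_roll, n_bins=4)
        sums = prof.groupby(["genotype", "bin"])["frequency"].sum().dropna()
        np.testing.assert_allclose(sums, 1.0)

    def test_mid_restricted_cluster_confined(self, unrolled_roll):
        prof = ur.composition_profile(unrolled_roll, n_bins=3)
        target = prof[prof["cluster"] == "canonical_gc_mid"]
        mid = target[target["bin"] == 1]
        outer = target[target["bin"] != 1]
        assert (mid["frequency"] > 0).all()
        assert (outer["frequency"].fillna(0.0) < 0.01).all()

    def test_refinement_conservation(self, unrolled_roll):
        """Merging adjacent fine bins reproduces coarse frequencies."""
        fine = ur.composition_profile(unrolled_roll, n_bins=6)
        coarse = ur.composition_profile(unrolled_roll, n_bins=3)
        merged = (
            fine.assign(cbin=fine["bin"] // 2)
            .groupby(["genotype", "cbin", "cluster"])["count"]
            .sum()
            .reset_index()
        )
        totals = merged.groupby(["genotype", "cbin"])["count"].transform("sum")
        merged["frequency"] = merged["count"] / totals
        joined = coarse.merge(
            merged,
            left_on=["genotype", "bin", "cluster"],
            right_on=["genotype", "cbin", "cluster"],
        )
        np.testing.assert_allclose(joined["frequency_x"], joined["frequency_y"])

    def test_unknown_cluster_errors(self, unrolled_roll):
        with pytest.raises(ValueError, match="unknown"):
            ur.composition_profile(unrolled_roll, cluster_vocab=["enterocyte"])

    def test_single_cluster_frequency_one(self, unrolled_roll):
        solo = unrolled_roll.assign(cluster="only")
        prof = ur.composition_profile(solo, n_bins=3)
        np.testing.assert_allclose(prof["frequency"].dropna(), 1.0)


class TestCompare:
    def test_identical_composition_zero(self, unrolled_roll):
        ctrl = unrolled_roll[unrolled_roll["genotype"] == "control"]
        fake = pd.concat(
            [ctrl, ctrl.assign(genotype="knockout")], ignore_index=True
        )
        out = ur.compare_composition(fake, n_bins=3, seed=0, n_boot=100)
        np.testing.assert_allclose(out["log2_ratio"], 0.0, atol=1e-12)

    def test_antisymmetric_under_genotype_swap(self, unrolled_roll):
        fwd = ur.compare_composition(
            unrolled_roll, n_bins=3, genotypes=("control", "knockout"), seed=0,
            n_boot=50,
        )
        rev = ur.compare_composition(
            unrolled_roll, n_bins=3, genotypes=("knockout", "control"), seed=0,
            n_boot=50,
        )
        np.testing.assert_allclose(
            fwd["log2_ratio"], -rev["log2_ratio"], atol=1e-12
        )

    def test_planted_expansion_detected(self, unrolled_roll):
        out = ur.compare_composition(unrolled_roll, n_bins=3, seed=3)
        row = out[(out["bin"] == 1) & (out["cluster"] == "canonical_gc_mid")].iloc[0]
        assert row["ci_low"] <= 1.0 <= row["ci_high"]
        assert row["ci_low"] > 0.0

    def test_seeded_bootstrap_reproducible(self, unrolled_roll):
        a = ur.compare_composition(unrolled_roll, n_bins=3, seed=9, n_boot=200)
        b = ur.compare_composition(unrolled_roll, n_bins=3, seed=9, n_boot=200)
        pd.testing.assert_frame_equal(a, b)


class TestCryptPosition:
    def test_planted_ordering(self, small_roll, unrolled_roll):
        spec, _, _ = small_roll
        med = ur.median_crypt_position(unrolled_roll)
        # generator layout: smooth muscle near the base, intercrypt at the
        # luminal surface
        assert med["smooth_muscle"] < med["proliferating_gc"] < med["intercrypt_gc"]
        lo, hi = spec.layout["intercrypt_gc"][2:4]
        assert med["intercrypt_gc"] == pytest.approx((lo + hi) / 2, abs=0.08)

    def test_single_cell_cluster(self, unrolled_roll):
        one = unrolled_roll.head(1).assign(cluster="solo")
        assert ur.median_crypt_position(one, "solo") == one["d"].iloc[0]

    def test_empty_cluster_errors(self, unrolled_roll):
        with pytest.raises(ValueError):
            ur.median_crypt_position(unrolled_roll, "no_such_cluster")


@pytest.fixture(scope="module")
def counts_roll():
    spec = sim.SpatialSimSpec(
        seed=6, colon_length=24000.0, cells_per_mm=300.0,
        n_samples_per_genotype=1, with_counts=True,
    )
    cells, truth, counts = sim.simulate_swiss_roll(spec)
    sub = cells[cells["sample_id"] == "control_0"]
    unrolled = ur.unroll(sub, ur.fit_spiral(sub))
    return unrolled, counts


class TestExpressionMap:
    def test_mid_restricted_gene_confined(self, counts_roll):
        unrolled, counts = counts_roll
        grid, n = ur.expression_map(unrolled, counts, "Retnlb", 6, 4)
        col_means = np.nansum(grid * n, axis=0) / np.maximum(n.sum(axis=0), 1)
        # Retnlb marks the planted mid-colon cluster: outer thirds carry
        # only the background leak rate
        mid = col_means[2:4].mean()
        outer = np.concatenate([col_means[:2], col_means[4:]]).mean()
        assert mid > 5 * outer

    def test_all_zero_gene(self, counts_roll):
        unrolled, counts = counts_roll
        zero = counts.assign(Null=0)
        grid, n = ur.expression_map(unrolled, zero, "Null", 5, 5)
        assert np.nansum(grid) == 0.0

    def test_order_invariance(self, counts_roll):
        unrolled, counts = counts_roll
        g1, _ = ur.expression_map(unrolled, counts, "Muc2", 5, 5)
        shuffled = unrolled.sample(frac=1, random_state=0)
        g2, _ = ur.expression_map(shuffled, counts, "Muc2", 5, 5)
        np.testing.assert_allclose(g1, g2, equal_nan=True)

    def test_unknown_gene_errors(self, counts_roll):
        unrolled, counts = counts_roll
        with pytest.raises(KeyError):
            ur.expression_map(unrolled, counts, "NOPE")
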