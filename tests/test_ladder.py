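"""Competition DNA-ladder selectivity analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sahdna.ladder import (
    LadderTitration,
    analyze_ladder,
    c50,
    compare_constructs,
    kdapp_per_fragment,
    normalize_free_dna,
    selectivity_slope,
)
from sahdna.simulate import NoiseModel, simulate_hill_ladder, simulate_lattice_ladder


def make_ladder(conc, fragments, free, construct="t"):
    return LadderTitration(np.asarray(conc, float), tuple(fragments), np.asarray(free, float), construct)


class TestNormalizeFreeDna:
    def test_zero_protein_lane_is_one(self):
        ld = make_ladder([0, 10], (20, 30), [[120, 80], [30, 40]])
        curves = normalize_free_dna(ld)
        assert curves.iloc[0].tolist() == [1.0, 1.0]
        assert curves.loc[10, 20] == pytest.approx(0.25)

    def test_flat_curve_stays_one(self):
        ld = make_ladder([0, 10, 100], (20,), [[50], [50], [50]])
        assert np.allclose(normalize_free_dna(ld).to_numpy(), 1.0)

    def test_noise_not_clamped(self):
        ld = make_ladder([0, 10], (20,), [[100], [110]])
        assert normalize_free_dna(ld).loc[10, 20] == pytest.approx(1.1)

    def test_zero_reference_names_fragment(self):
        ld = make_ladder([0, 10], (20, 30), [[100, 0], [50, 0]])
        with pytest.raises(ValueError, match="30 bp"):
            normalize_free_dna(ld)


class TestKdappAndC50:
    def test_hill_depletion_self_consistency(self, conc_grid):
        """Depletion following the isotherm with K_D = 100, h = 1 refits to 100."""
        ld = simulate_hill_ladder(conc_grid, {40: 100.0}, hill_h=1.0)
        res = kdapp_per_fragment(normalize_free_dna(ld))
        assert not res[0].censored
        assert res[0].kdapp_nM == pytest.approx(100.0, rel=1e-4)
        # with h = 1 and Bmax = 1, C50 coincides with K_Dapp
        assert res[0].c50_nM == pytest.approx(res[0].kdapp_nM, rel=1e-4)

    def test_flat_curve_censored(self, conc_grid):
        ld = simulate_hill_ladder(conc_grid, {10: np.inf, 40: 100.0})
        res = {r.fragment_bp: r for r in kdapp_per_fragment(normalize_free_dna(ld))}
        assert res[10].censored and np.isnan(res[10].kdapp_nM)
        assert not res[40].censored

    def test_lattice_ordering_matches_enumeration(self, conc_grid):
        """K_Dapp ordering by length matches the generator's effective
        affinity ordering (from the exact free-DNA probabilities)."""
        ld = simulate_lattice_ladder(conc_grid, (20, 30, 40, 50), footprint_bp=20,
                                     K_assoc_per_nM=0.01, omega=2.0)
        res = kdapp_per_fragment(normalize_free_dna(ld))
        kdapps = [r.kdapp_nM for r in res]
        # exact P(free=0.5) crossing per fragment from the generator itself
        from oracles import enumerate_occupancy

        crossings = []
        for L in (20, 30, 40, 50):
            grid = np.geomspace(0.1, 5000, 400)
            p0 = np.array([enumerate_occupancy(L, 20, 2.0, 0.01, c)[0] for c in grid])
            crossings.append(grid[np.argmin(np.abs(p0 - 0.5))])
        assert np.all(np.argsort(kdapps) == np.argsort(crossings))

    def test_c50_closed_form_inversion(self, conc_grid):
        """C50 for h=2, Bmax=0.8: normalized free 0.5 at K_D sqrt(0.5/0.3)."""
        ld = simulate_hill_ladder(conc_grid, {40: 100.0}, hill_h=2.0, bmax=0.8)
        series = c50(normalize_free_dna(ld), method="fit")
        assert series[40] == pytest.approx(100.0 * np.sqrt(0.5 / 0.3), rel=1e-3)

    def test_c50_interpolation_and_censoring(self):
        ld = make_ladder([0, 10, 100], (20, 30), [[100, 100], [80, 95], [20, 90]])
        series = c50(normalize_free_dna(ld), method="interpolate")
        assert 10 < series[20] < 100
        assert np.isnan(series[30])

    def test_c50_nonmonotone_needs_fit(self):
        ld = make_ladder([0, 10, 100], (20,), [[100], [40], [60]])
        with pytest.raises(ValueError, match="fit"):
            c50(normalize_free_dna(ld), method="interpolate")


class TestSelectivitySlope:
    def test_direct_arithmetic(self):
        from sahdna.ladder import FragmentResult

        res = [
            FragmentResult(40, 200.0, 1.0, 1.0, 1.0, 200.0, False, 0.9),
            FragmentResult(50, 150.0, 1.0, 1.0, 1.0, 150.0, False, 0.9),
        ]
        assert selectivity_slope(res) == pytest.approx(-5.0)

    def test_threshold_null_is_zero(self):
        from sahdna.ladder import FragmentResult

        res = [
            FragmentResult(40, 200.0, 1.0, 1.0, 1.0, 200.0, False, 0.9),
            FragmentResult(50, 200.0, 1.0, 1.0, 1.0, 200.0, False, 0.9),
        ]
        assert selectivity_slope(res) == 0.0

    def test_censored_undefined(self):
        from sahdna.ladder import FragmentResult

        res = [
            FragmentResult(40, np.nan, np.nan, np.nan, np.nan, np.nan, True, 0.05),
            FragmentResult(50, 150.0, 1.0, 1.0, 1.0, 150.0, False, 0.9),
        ]
        with pytest.raises(ValueError, match="censored"):
            selectivity_slope(res)

    def test_replicate_summary(self, conc_grid):
        ladders = [
            simulate_hill_ladder(conc_grid, {40: 200.0, 50: 150.0}, noise=NoiseModel(cv=0.02), seed=s)
            for s in range(3)
        ]
        result = analyze_ladder(ladders)
        assert result.slope_40_50 == pytest.approx(-5.0, abs=1.5)
        assert result.slope_sd > 0


class TestEqualAffinityNull:
    def test_no_spurious_selectivity(self, conc_grid):
        """Equal-affinity fragments give equal K_Dapp; the 40->50 slope is ~0."""
        ladders = [
            simulate_hill_ladder(conc_grid, {f: 200.0 for f in (20, 30, 40, 50)},
                                 noise=NoiseModel(cv=0.03), seed=s)
            for s in range(4)
        ]
        result = analyze_ladder(ladders)
        kds = [f.kdapp_nM for f in result.fragments]
        assert np.ptp(kds) / np.mean(kds) < 0.15
        assert abs(result.slope_40_50) < 3.0  # nM/bp, MC error on K_D = 200

    def test_short_fragment_always_censored(self, conc_grid):
        """A 10 bp fragment cannot host a 20 bp-footprint ligand: always flat."""
        for seed in range(5):
            ld = simulate_lattice_ladder(conc_grid, noise=NoiseModel(cv=0.05), seed=seed)
            res = {r.fragment_bp: r for r in kdapp_per_fragment(normalize_free_dna(ld))}
            assert res[10].censored


class TestCompareConstructs:
    def test_identical_groups(self):
        out = compare_constructs({"WT": [1.0, 2.0, 3.0], "mut": [1.0, 2.0, 3.0]})
        assert out["F"] == 0.0 and out["p"] == 1.0

    def test_textbook_anova(self):
        """Two groups {1,2,3} vs {4,5,6}: hand-computed F = 13.5, p ~ 0.0213."""
        out = compare_constructs({"WT": [1, 2, 3], "mut": [4, 5, 6]})
        assert out["F"] == pytest.approx(13.5)
        assert out["p"] == pytest.approx(stats.f.sf(13.5, 1, 4), rel=1e-9)
        assert "mut" in out["contrasts"]

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, (3, 6))
        pvals = []
        for shift in (0.5, 2.0, 6.0):
            groups = {"a": base[0], "b": base[1], "c": base[2] + shift}
            pvals.append(compare_constructs(groups)["p"])
        assert pvals[0] > pvals[1] > pvals[2]

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            compare_constructs({"WT": [1.0, 2.0], "mut": [3.0]})

    def test_tukey_table_available(self):
        out = compare_constructs({"WT": [1, 2, 3], "a": [4, 5, 6], "b": [1, 2, 2]}, tukey=True)
        assert out["tukey"] is not None


def test_long_frame_round_trip(conc_grid):
    ld = simulate_lattice_ladder(conc_grid, seed=2, noise=NoiseModel(cv=0.02))
    rows = []
    for i, conc in enumerate(ld.conc_nM):
        for j, frag in enumerate(ld.fragment_bp):
            rows.append({"construct": "t", "replicate": 0, "protein_conc_nM": conc,
                         "fragment_bp": frag, "free_intensity": ld.free_intensity[i, j]})
    back = LadderTitration.from_long_frame(pd.DataFrame(rows))
    assert len(back) == 1
    assert np.allclose(back[0].free_intensity, ld.free_intensity)
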