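"""Finite-lattice binding simulator and the other synthetic-data generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import enumerate_lattice, enumerate_occupancy
from sahdna.binding import TitrationSeries, fit_hill, fraction_bound, hill_curve
from sahdna.sequences import helical_face_bias, predict_ion_pairs
from sahdna.simulate import (
    LatticeConfig,
    NoiseModel,
    generate_helix,
    generate_sah_sequence,
    lattice_contact_coefficients,
    lattice_partition,
    render_emsa,
    simulate_titration,
)

ENUM_GRID = [
    (10, 20), (19, 20), (20, 20), (30, 20), (40, 20), (50, 20), (60, 20),
    (50, 25), (60, 25), (25, 10), (40, 10), (60, 10), (15, 5), (25, 5), (30, 5),
]
OMEGAS = (0.1, 1.0, 10.0)


class TestLatticeCoefficients:
    def test_single_ligand_placement_count(self):
        """k = 1 on L = 50, m = 20: L - m + 1 = 31 placements."""
        c = lattice_contact_coefficients(50, 20, 1.0)
        assert c[1] == 31

    def test_two_ligand_count_matches_binomial(self):
        """k = 2, omega = 1: C(L - km + k, k) = C(12, 2) = 66."""
        c = lattice_contact_coefficients(50, 20, 1.0)
        assert c[2] == 66

    @pytest.mark.parametrize("L,m", ENUM_GRID)
    @pytest.mark.parametrize("omega", OMEGAS)
    def test_recursion_equals_enumeration(self, L, m, omega):
        """Transfer recursion = exhaustive placement enumeration, all k."""
        fast = lattice_contact_coefficients(L, m, omega)
        slow = enumerate_lattice(L, m, omega)
        for k in range(L // m + 1):
            assert fast[k] == pytest.approx(slow.get(k, 0.0), rel=1e-12)

    def test_too_short_lattice(self):
        c = lattice_contact_coefficients(19, 20, 1.0)
        assert c.tolist() == [1.0]


class TestLatticePartition:
    def test_probabilities_sum_to_one(self):
        cfg = LatticeConfig(50, 20, 0.05, 5.0)
        dist = lattice_partition(cfg, np.geomspace(1e-3, 1e6, 30))
        assert np.allclose(dist.prob.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_enumeration_probabilities(self):
        for omega in OMEGAS:
            cfg = LatticeConfig(40, 15, 0.02, omega)
            for conc in (1.0, 50.0, 2000.0):
                fast = lattice_partition(cfg, conc).prob[0]
                slow = enumerate_occupancy(40, 15, omega, 0.02, conc)
                assert np.allclose(fast, slow, atol=1e-12)

    def test_inert_short_fragment(self):
        """L < footprint: k = 0 with probability 1 at any concentration."""
        cfg = LatticeConfig(10, 20, 0.05, 1.0)
        dist = lattice_partition(cfg, [0.0, 10.0, 1e5])
        assert np.allclose(dist.prob, 1.0)  # single column, all ones
        assert dist.k_max == 0

    def test_extreme_concentration_no_overflow(self):
        cfg = LatticeConfig(60, 10, 1.0, 100.0)
        dist = lattice_partition(cfg, 1e30)
        assert np.isfinite(dist.prob).all()
        assert dist.prob[0, -1] == pytest.approx(1.0)  # saturated lattice

    @settings(derandomize=True, max_examples=25)
    @given(
        L=st.integers(5, 60),
        m=st.integers(5, 25),
        omega=st.sampled_from([0.2, 1.0, 5.0]),
        k_assoc=st.floats(1e-3, 1.0),
    )
    def test_mean_occupancy_monotone(self, L, m, omega, k_assoc):
        cfg = LatticeConfig(L, m, k_assoc, omega)
        dist = lattice_partition(cfg, np.geomspace(0.1, 1e4, 25))
        occ = dist.mean_occupancy
        assert np.all(np.diff(occ) >= -1e-12)

    def test_single_site_limit_is_hill_h1(self):
        """m = L (one site): occupancy follows the h = 1 isotherm exactly."""
        cfg = LatticeConfig(30, 30, 0.05, 7.0)  # omega irrelevant at k_max = 1
        conc = np.geomspace(0.1, 1e4, 40)
        bound = 1.0 - lattice_partition(cfg, conc).p_free
        expected = hill_curve(conc, 1.0 / 0.05, 1.0, 1.0)
        assert np.allclose(bound, expected, atol=1e-12)


class TestSimulateTitration:
    def test_trace_dna_limit(self):
        """1 nM DNA in the 37-760 nM protein range: depletion correction
        shifts occupancy probabilities by under 1 %."""
        cfg = LatticeConfig(40, 20, 0.02, 2.0)
        conc = np.array([37.0, 100.0, 300.0, 760.0])
        no_dep = simulate_titration(cfg, conc, dna_conc_nM=1.0, deplete_ligand=False)
        dep = simulate_titration(cfg, conc, dna_conc_nM=1.0, deplete_ligand=True)
        assert np.max(np.abs(dep.prob - no_dep.prob)) < 0.01

    def test_zero_ligand_all_free(self):
        cfg = LatticeConfig(40, 20, 0.05, 1.0)
        dist = simulate_titration(cfg, [0.0], deplete_ligand=True)
        assert dist.prob[0, 0] == 1.0

    def test_high_cooperativity_steepens_hill_fit(self):
        """Strong contact cooperativity on a 2-site lattice gives h > 1."""
        conc = np.concatenate([[0.0], np.geomspace(1.0, 5e3, 14)])
        fits = {}
        for omega in (1.0, 1000.0):
            cfg = LatticeConfig(40, 20, 0.005, omega)
            frac = 1.0 - lattice_partition(cfg, conc).p_free
            fits[omega] = fit_hill(TitrationSeries(conc, np.clip(frac, 0, 1.05)))
        assert fits[1000.0].hill_h > 1.4
        assert fits[1000.0].hill_h > fits[1.0].hill_h + 0.3

    def test_occupancy_jump_with_cooperativity(self):
        """omega >> 1 on L = 40, m = 20: occupancy jumps from 0 to 2 ligands."""
        cfg = LatticeConfig(40, 20, 0.002, 500.0)
        dist = lattice_partition(cfg, np.geomspace(1.0, 1e4, 50))
        p1 = dist.prob[:, 1]
        assert p1.max() < 0.35  # singly bound species suppressed throughout


class TestRenderEmsa:
    def test_zero_noise_proportional(self):
        cfg = LatticeConfig(40, 20, 0.02, 1.0)
        dist = lattice_partition(cfg, [0.0, 50.0, 500.0])
        lanes = render_emsa(dist, NoiseModel(cv=0.0), dna_amount=1000.0)
        for lane, p in zip(lanes, dist.prob):
            assert np.allclose(lane.band_intensities, p * 1000.0)

    def test_band_count_scales_with_length(self):
        """At saturation an 80 bp fragment shows 4 complexes, a 40 bp shows 2."""
        for L, k_exp in ((80, 4), (40, 2)):
            cfg = LatticeConfig(L, 20, 1.0, 1.0)
            dist = lattice_partition(cfg, [1e6])
            lane = render_emsa(dist, NoiseModel(cv=0.0))[0]
            bands = np.asarray(lane.band_intensities)
            assert len(bands) == k_exp + 1
            assert np.argmax(bands) == k_exp

    def test_determinism(self):
        cfg = LatticeConfig(40, 20, 0.02, 1.0)
        dist = lattice_partition(cfg, [0.0, 50.0])
        a = render_emsa(dist, NoiseModel(cv=0.1), seed=5)
        b = render_emsa(dist, NoiseModel(cv=0.1), seed=5)
        assert all(np.allclose(x.band_intensities, y.band_intensities) for x, y in zip(a, b))

    def test_round_trip_recovery(self):
        """Render at effective K_D = 50 nM, refit: within 10 % at CV = 5 %."""
        conc = np.concatenate([[0.0], np.geomspace(2.0, 2e3, 11)])
        cfg = LatticeConfig(25, 25, 1.0 / 50.0, 1.0)  # single site, K_D = 50
        dist = lattice_partition(cfg, conc)
        kds = []
        for seed in range(40):
            lanes = render_emsa(dist, NoiseModel(cv=0.05), seed=seed)
            series = fraction_bound(lanes, mode="bound-over-total")
            kds.append(fit_hill(TitrationSeries(series.conc_nM, np.clip(series.fraction, 0, 1.05))).kd_nM)
        assert np.median(kds) == pytest.approx(50.0, rel=0.10)


class TestGenerateHelix:
    def test_straight_end_to_end_closed_form(self):
        h = generate_helix(86)
        assert np.linalg.norm(h.ca_coords[-1] - h.ca_coords[0]) == pytest.approx(85 * 1.5, abs=0.2)

    def test_infinite_curvature_radius_equals_straight(self):
        a = generate_helix(40)
        b = generate_helix(40, curvature_radius_A=np.inf)
        assert np.allclose(a.ca_coords, b.ca_coords)

    def test_consecutive_ca_distance_realistic(self):
        h = generate_helix(50)
        d = np.linalg.norm(np.diff(h.ca_coords, axis=0), axis=1)
        assert np.all((d > 3.5) & (d < 4.2))  # ~3.8 A for an alpha-helix


class TestGenerateSahSequence:
    def test_full_density_all_participate(self):
        for length in (7, 16, 90):
            s = generate_sah_sequence(length, ion_pair_density=1.0, seed=1)
            net = predict_ion_pairs(s)
            assert all(net.participation[p] for p in s.positions)

    def test_no_bias_no_face(self):
        s = generate_sah_sequence(90, ion_pair_density=0.0, basic_stripe_bias=0.0, seed=2)
        rep = helical_face_bias(s)
        assert rep.max_basic_sector[1] == 0.0

    def test_stripe_bias_creates_face(self):
        s = generate_sah_sequence(90, ion_pair_density=0.0, basic_stripe_bias=1.0, seed=3)
        rep = helical_face_bias(s, sector_width_deg=120)
        assert rep.max_basic_sector[1] >= 10

    def test_seeded_determinism(self):
        a = generate_sah_sequence(60, 0.5, 0.4, seed=11)
        b = generate_sah_sequence(60, 0.5, 0.4, seed=11)
        assert a.residues == b.residues
        c = generate_sah_sequence(60, 0.5, 0.4, seed=12)
        assert a.residues != c.residues
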