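"""Synthetic-data generators mirroring the study designs the package analyses.

The binding generator is a finite one-dimensional lattice: a DNA fragment of
L base pairs is a lattice of L sites, each protein monomer occludes a
footprint of m contiguous sites (default 20 bp), ligands may not overlap,
and two ligands in direct contact gain a nearest-neighbour cooperativity
factor omega.  A configuration with k ligands and c abutting pairs has
statistical weight (K_assoc [P])^k omega^c; the occupancy distribution comes
from the exact partition function, evaluated by an O(L k_max) recursion.
This reproduces the qualitative structure of the EMSA data: a ladder of
shifted bands whose count scales with fragment length (k_max = floor(L/m)),
an inert fragment shorter than one footprint, and sigmoidal (Hill h > 1)
titration curves when omega > 1.

Also provided: an EMSA lane renderer with multiplicative/additive noise, a
per-fragment independent Hill-depletion ladder (the equal-affinity null), CD
spectrum and thermal-melt simulators, ideal/curved alpha-helix Cα coordinate
generators, and SAH-patterned sequence generation.  Every stochastic
generator takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .binding import GelLane, hill_curve
from .cd import CDSpectrum, MeltCurve, mre_scale, two_state_melt
from .geometry import HelixModel
from .ladder import LadderTitration
from .sequences import ProteinSequence

__all__ = [
    "LatticeConfig",
    "OccupancyDistribution",
    "NoiseModel",
    "lattice_contact_coefficients",
    "lattice_partition",
    "simulate_titration",
    "render_emsa",
    "simulate_lattice_ladder",
    "simulate_hill_ladder",
    "simulate_cd",
    "simulate_melt",
    "generate_helix",
    "generate_sah_sequence",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Finite-lattice cooperative binding parameters.

    K_assoc is the intrinsic association constant per site placement
    (nM^-1); omega >= 0 is the contact cooperativity (1 = independent
    binding).
    """

    L_bp: int
    footprint_bp: int = 20
    K_assoc_per_nM: float = 0.02
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.L_bp < 1 or self.footprint_bp < 1:
            raise ValueError("lattice length and footprint must be >= 1")
        if self.K_assoc_per_nM <= 0:
            raise ValueError("K_assoc must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")

    @property
    def k_max(self) -> int:
        return self.L_bp // self.footprint_bp


@dataclass
class OccupancyDistribution:
    """P(k ligands bound) per concentration; rows sum to 1."""

    conc_nM: np.ndarray
    prob: np.ndarray  # (n_conc, k_max + 1)
    config: LatticeConfig

    @property
    def k_max(self) -> int:
        return self.prob.shape[1] - 1

    @property
    def mean_occupancy(self) -> np.ndarray:
        return self.prob @ np.arange(self.prob.shape[1])

    @property
    def p_free(self) -> np.ndarray:
        return self.prob[:, 0]


def lattice_contact_coefficients(L: int, m: int, omega: float) -> np.ndarray:
    """Occupancy-resolved partition-function coefficients c_k(omega).

    c_k = sum over all placements of k non-overlapping footprint-m ligands on
    an L-site lattice of omega^(number of abutting pairs), so the partition
    function is Z([P]) = sum_k c_k (K [P])^k.  Evaluated by a two-state
    recursion over lattice prefixes: ``e[i]`` counts configurations of the
    first i sites with site i uncovered, ``a[i]`` those where a ligand ends
    exactly at site i (each resolved by ligand count k).

    At omega = 1, c_k equals the binomial placement count C(L - k m + k, k).
    """
    k_max = L // m
    e = np.zeros((L + 1, k_max + 1))
    a = np.zeros((L + 1, k_max + 1))
    e[0, 0] = 1.0
    for i in range(1, L + 1):
        e[i] = e[i - 1] + a[i - 1]
        if i >= m:
            prev_e = e[i - m]
            prev_a = a[i - m]
            a[i, 1:] = prev_e[:-1] + omega * prev_a[:-1]
    return e[L] + a[L]


def lattice_partition(config: LatticeConfig, free_ligand_nM: float | np.ndarray) -> OccupancyDistribution:
    """Exact occupancy distribution at given free-ligand concentration(s).

    Probabilities are combined in log space (log c_k + k log K[P]) so that
    extreme concentrations or cooperativities cannot overflow.
    """
    conc = np.atleast_1d(np.asarray(free_ligand_nM, float))
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    c_k = lattice_contact_coefficients(config.L_bp, config.footprint_bp, config.omega)
    k = np.arange(config.k_max + 1)
    with np.errstate(divide="ignore"):
        log_ck = np.where(c_k > 0, np.log(np.where(c_k > 0, c_k, 1.0)), -np.inf)
        x = config.K_assoc_per_nM * conc
        log_x = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), -np.inf)
    with np.errstate(invalid="ignore"):
        log_w = log_ck[None, :] + k[None, :] * log_x[:, None]
    log_w[:, 0] = log_ck[0]  # k=0 term is always 1 config, weight 1
    log_w = np.nan_to_num(log_w, nan=-np.inf)  # 0 * log(0) terms: zero weight
    log_z = logsumexp(log_w, axis=1)
    prob = np.exp(log_w - log_z[:, None])
    return OccupancyDistribution(conc, prob, config)


def simulate_titration(
    config: LatticeConfig,
    total_ligand_nM: Sequence[float],
    dna_conc_nM: float = 1.0,
    deplete_ligand: bool = False,
) -> OccupancyDistribution:
    """Occupancy distributions across a protein titration.

    With ``deplete_ligand`` the free-ligand concentration at each point is
    solved from mass balance, free + [DNA] * mean_occupancy(free) = total, by
    root bracketing; otherwise free = total (the trace-DNA regime of a 1-3 nM
    probe titrated with tens-to-hundreds nM protein).
    """
    total = np.asarray(total_ligand_nM, float)
    if not deplete_ligand:
        return lattice_partition(config, total)

    free = np.empty_like(total)
    for i, tot in enumerate(total):
        if tot == 0:
            free[i] = 0.0
            continue

        def balance(f: float) -> float:
            occ = lattice_partition(config, f).mean_occupancy[0]
            return f + dna_conc_nM * occ - tot

        lo, hi = 0.0, float(tot)
        if balance(lo) > 0 or balance(hi) < 0:
            raise ValueError("mass-balance root not bracketed")
        free[i] = brentq(balance, lo, hi, xtol=1e-12 * max(tot, 1.0))
    dist = lattice_partition(config, free)
    return OccupancyDistribution(total, dist.prob, config)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise for rendered gel lanes.

    ``cv`` is the multiplicative lane noise (lognormal, coefficient of
    variation); background is additive Gaussian (clipped at 0); intensities
    saturate at ``ceiling`` when finite.
    """

    cv: float = 0.05
    background_mean: float = 0.0
    background_sd: float = 0.0
    ceiling: float = np.inf

    def __post_init__(self) -> None:
        if self.cv < 0 or self.background_sd < 0:
            raise ValueError("cv and background_sd must be >= 0")

    def apply(self, intensity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(intensity, float).copy()
        if self.cv > 0:
            sigma = np.sqrt(np.log1p(self.cv**2))
            out = out * rng.lognormal(-0.5 * sigma**2, sigma, out.shape)
        if self.background_mean or self.background_sd:
            out = out + np.clip(
                rng.normal(self.background_mean, self.background_sd, out.shape), 0.0, None
            )
        return np.clip(out, 0.0, self.ceiling)


def render_emsa(
    distribution: OccupancyDistribution,
    noise: NoiseModel = NoiseModel(cv=0.0),
    seed: int = 0,
    dna_amount: float = 1000.0,
) -> list[GelLane]:
    """Render an occupancy titration as gel lanes.

    Band k's intensity is proportional to P(k bound) times the DNA amount;
    band 0 is the free DNA.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    lanes = []
    for i, conc in enumerate(distribution.conc_nM):
        clean = distribution.prob[i] * dna_amount
        bands = noise.apply(clean, rng)
        lanes.append(GelLane(float(conc), bands.tolist(), background=0.0, lane_id=f"lane{i}"))
    return lanes


def simulate_lattice_ladder(
    conc_nM: Sequence[float],
    fragment_bp: Sequence[int] = (10, 20, 30, 40, 50),
    footprint_bp: int = 20,
    K_assoc_per_nM: float = 0.02,
    omega: float = 1.0,
    noise: NoiseModel = NoiseModel(cv=0.0),
    seed: int = 0,
    construct: str = "sim",
    dna_amount: float = 1000.0,
) -> LadderTitration:
    """Multi-fragment competition titration from the lattice generator.

    Each fragment is simulated in the trace-DNA regime (each at ~1 nM, as in
    the competition assay, so free protein is not measurably depleted and the
    fragments' curves are independent).  The rendered observable is each
    fragment's free-DNA band, i.e. P(0 bound) x DNA amount plus noise.
    A fragment shorter than one footprint never binds and stays flat.
    """
    conc = np.asarray(conc_nM, float)
    if conc[0] != 0:
        raise ValueError("concentration grid must start at 0 (zero-protein lane)")
    rng = np.random.default_rng(seed)
    free = np.empty((len(conc), len(fragment_bp)))
    for j, L in enumerate(fragment_bp):
        cfg = LatticeConfig(L_bp=int(L), footprint_bp=footprint_bp,
                            K_assoc_per_nM=K_assoc_per_nM, omega=omega)
        p0 = lattice_partition(cfg, conc).p_free
        free[:, j] = noise.apply(p0 * dna_amount, rng)
    free[0] = np.maximum(free[0], 1e-9)  # zero-protein lane must carry signal
    return LadderTitration(conc, tuple(int(b) for b in fragment_bp), free, construct)


def simulate_hill_ladder(
    conc_nM: Sequence[float],
    kd_by_fragment: dict[int, float],
    hill_h: float = 1.0,
    bmax: float = 1.0,
    noise: NoiseModel = NoiseModel(cv=0.0),
    seed: int = 0,
    construct: str = "sim-hill",
    dna_amount: float = 1000.0,
) -> LadderTitration:
    """Equal-footing null generator: each fragment's free-DNA depletion
    follows an independent Hill isotherm with the given per-fragment K_D.

    With identical K_D for every fragment this is the no-selectivity null
    against which the ladder analysis is validated.  A fragment with
    K_D = inf never depletes (censored analog).
    """
    conc = np.asarray(conc_nM, float)
    if conc[0] != 0:
        raise ValueError("concentration grid must start at 0 (zero-protein lane)")
    rng = np.random.default_rng(seed)
    frags = tuple(sorted(kd_by_fragment))
    free = np.empty((len(conc), len(frags)))
    for j, frag in enumerate(frags):
        kd = kd_by_fragment[frag]
        bound = np.zeros_like(conc) if not np.isfinite(kd) else hill_curve(conc, kd, hill_h, bmax)
        free[:, j] = noise.apply((1.0 - bound) * dna_amount, rng)
    free[0] = np.maximum(free[0], 1e-9)
    return LadderTitration(conc, frags, free, construct)


# --- CD simulators ---------------------------------------------------------

def _gauss(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / width) ** 2)


def _helix_basis(wl: np.ndarray) -> np.ndarray:
    """Alpha-helix MRE basis: positive ~193 nm band, negative 208/222 bands,
    normalized so the 222 nm value is exactly -39000 deg cm^2 dmol^-1."""
    shape = 0.9 * _gauss(wl, 193.0, 5.5) - 1.0 * _gauss(wl, 208.5, 6.0) - 1.0 * _gauss(wl, 222.0, 7.5)
    ref = 0.9 * _gauss(np.array([222.0]), 193.0, 5.5) - _gauss(np.array([222.0]), 208.5, 6.0) - 1.0
    return shape * (-39000.0 / ref[0])


def _coil_basis(wl: np.ndarray) -> np.ndarray:
    """Random-coil MRE basis: deep negative ~198 nm band, weak signal at
    222 nm pinned to the -3000 coil reference."""
    shape = -1.0 * _gauss(wl, 198.0, 6.5) - 0.04 * _gauss(wl, 222.0, 10.0)
    ref = -1.0 * _gauss(np.array([222.0]), 198.0, 6.5) - 0.04
    return shape * (-3000.0 / ref[0])


def simulate_cd(
    helix_fraction: float,
    n_residues: int = 91,
    mw_g_mol: float = 11000.0,
    path_cm: float = 0.1,
    conc_g_L: float = 0.1,
    wavelength_nm: np.ndarray | None = None,
    noise_mdeg_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> CDSpectrum:
    """Synthetic CD spectrum of a helix/coil mixture, in millidegrees.

    The underlying MRE is ``f * helix_basis + (1 - f) * coil_basis`` (the two
    bases hit the -39000 / -3000 references at 222 nm exactly, so the 222 nm
    two-point helicity estimate round-trips the input fraction); it is
    converted to observed millidegrees with the sample's own MRE factor.
    """
    if not 0.0 <= helix_fraction <= 1.0:
        raise ValueError("helix_fraction must lie in [0, 1]")
    wl = np.arange(190.0, 251.0) if wavelength_nm is None else np.asarray(wavelength_nm, float)
    mre_true = helix_fraction * _helix_basis(wl) + (1.0 - helix_fraction) * _coil_basis(wl)
    m0 = mre_true / mre_scale(mw_g_mol, n_residues, path_cm, conc_g_L)
    if noise_mdeg_sd > 0:
        m0 = m0 + np.random.default_rng(seed).normal(0.0, noise_mdeg_sd, m0.shape)
    return CDSpectrum(wl, m0, mw_g_mol, n_residues, path_cm, conc_g_L, label)


def simulate_melt(
    tm_C: float,
    dH_kJ_mol: float = 250.0,
    native_baseline: tuple[float, float] = (-20000.0, 30.0),   # (intercept, slope)
    denatured_baseline: tuple[float, float] = (-4000.0, 10.0),
    temperature_C: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> MeltCurve:
    """Two-state thermal melt at 222 nm with linear baselines plus noise."""
    t = np.arange(20.0, 90.5, 1.0) if temperature_C is None else np.asarray(temperature_C, float)
    y = two_state_melt(t, tm_C, dH_kJ_mol,
                       native_baseline[0], native_baseline[1],
                       denatured_baseline[0], denatured_baseline[1])
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, y.shape)
    return MeltCurve(t, y, label)


# --- structural generators -------------------------------------------------

def generate_helix(
    n_residues: int,
    rise_per_residue_A: float = 1.5,
    twist_deg: float = 100.0,
    radius_A: float = 2.3,
    curvature_radius_A: float | None = None,
    chain_id: str = "A",
    first_residue: int = 1,
) -> HelixModel:
    """Cα coordinates of an ideal (or uniformly curved) alpha-helix.

    The helical path has the given per-residue rise, twist and Cα radius; if
    ``curvature_radius_A`` is finite the helix axis is bent onto a circle of
    that radius (in the x-z plane), giving a uniform axis curvature of
    1/curvature_radius.  Deterministic.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    i = np.arange(n_residues)
    theta = np.radians(i * twist_deg)
    s = i * rise_per_residue_A
    if curvature_radius_A is None or not np.isfinite(curvature_radius_A):
        axis = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
        normal = np.tile([1.0, 0.0, 0.0], (n_residues, 1))
        binormal = np.tile([0.0, 1.0, 0.0], (n_residues, 1))
    else:
        R = float(curvature_radius_A)
        phi = s / R
        axis = np.column_stack([R * (1.0 - np.cos(phi)), np.zeros_like(phi), R * np.sin(phi)])
        normal = np.column_stack([np.cos(phi), np.zeros_like(phi), -np.sin(phi)])
        binormal = np.tile([0.0, 1.0, 0.0], (n_residues, 1))
    ca = axis + radius_A * (np.cos(theta)[:, None] * normal + np.sin(theta)[:, None] * binormal)
    return HelixModel(chain_id, i + first_residue, ca, source="generated")


# --- sequence generator ----------------------------------------------------

_CHARGED_BLOCK = "EEEEKKKK"  # every residue of this block has an i+/-3 or 4 partner
_NEUTRAL_RESIDUES = "AQLSTNG"


def generate_sah_sequence(
    length: int,
    ion_pair_density: float = 1.0,
    basic_stripe_bias: float = 0.0,
    seed: int = 0,
    stripe_centre_deg: float = 0.0,
    twist_deg: float = 100.0,
    id: str = "sah-sim",
    numbering_offset: int = 1,
) -> ProteinSequence:
    """SAH-patterned synthetic sequence.

    The sequence is built from 8-residue blocks: with probability
    ``ion_pair_density`` a block carries the canonical E4K4 charge pattern
    (every residue of which participates in an i,i+3/i,i+4 opposite-charge
    pair), otherwise it is neutral.  ``basic_stripe_bias`` in [0, 1] converts
    neutral residues whose helical-wheel angle falls within +/-60 degrees of
    ``stripe_centre_deg`` to lysine with that probability, emulating the
    basic stripe on one helical face.  Deterministic given the seed.
    """
    if length < 7:
        raise ValueError("length must be >= 7")
    if not 0.0 <= ion_pair_density <= 1.0 or not 0.0 <= basic_stripe_bias <= 1.0:
        raise ValueError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    residues = []
    pos = 0
    while pos < length:
        block_len = min(8, length - pos)
        if rng.random() < ion_pair_density:
            residues.extend(_CHARGED_BLOCK[:block_len])
        else:
            residues.extend(rng.choice(list(_NEUTRAL_RESIDUES), size=block_len).tolist())
        pos += block_len
    if basic_stripe_bias > 0:
        for idx in range(length):
            if residues[idx] in _NEUTRAL_RESIDUES:
                ang = (idx * twist_deg - stripe_centre_deg) % 360.0
                on_face = ang <= 60.0 or ang >= 300.0
                if on_face and rng.random() < basic_stripe_bias:
                    residues[idx] = "K"
    return ProteinSequence(id, "".join(residues), numbering_offset)
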