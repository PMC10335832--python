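# Methods

`sahdna` analyses the experiments by which a single alpha-helix (SAH)
DNA-binding domain — such as the KER region of the CAF-1 histone-chaperone
large subunit — is characterized quantitatively: electrophoretic mobility
shift assay (EMSA) titrations, multi-fragment competition ladders,
circular-dichroism (CD) spectra and thermal melts, helix geometry from
crystallographic coordinates, and the charge patterning of the sequence
itself. This note records the models, the parameters that matter, and the
design decisions taken where the analysis was genuinely open.

## Cooperative binding isotherm (`sahdna.binding`)

Fraction bound f as a function of protein concentration P is modelled with
the Hill isotherm

    f(P) = Bmax · P^h / (K_D^h + P^h),

with dissociation constant K_D (nM), Hill coefficient h and amplitude Bmax.
Fits are nonlinear least squares (Levenberg–Marquardt via lmfit) with
box bounds K_D ∈ [1e-3, 1e6] nM, h ∈ [0.2, 10], Bmax ∈ [0, 1.2] — wide
enough to be non-informative, tight enough to exclude numerically
pathological excursions. Initial guesses come from the data (K_D at the
half-maximum crossing, h = 1, Bmax at the maximum observed fraction); on a
failed convergence the fit restarts up to five times from seeded log-normal
perturbations of the guesses. Asymptotic standard errors are taken from the
Jacobian at the optimum. Unweighted by default; inverse-variance weighting
is available when replicate SDs exist. A nested h = 1 refit is exposed for
AIC comparison (`compare_noncooperative`); on low-noise data the AIC
difference is only meaningful relative to the 2-unit parameter penalty.

Fraction bound from lane intensities supports two conventions, because
densitometry practice varies: *bound-over-total* (sum of shifted bands over
total lane signal — the default for single-fragment gels, since it uses all
band information and is invariant to uniform lane rescaling) and
*free-depletion* (1 − free/free-at-zero, the natural choice when only the
free band is reliably quantifiable). Background is a single scalar per lane,
subtracted and clamped at zero. Replicate aggregation requires identical
concentration grids (relative tolerance 1e-6) and reports sample SD
(ddof = 1); a single replicate reports SD as missing rather than zero.

## Competition-ladder selectivity (`sahdna.ladder`)

In the competition assay, equimolar Cy5-labelled DNA fragments (default 10,
20, 30, 40, 50 bp, each ~1 nM) are titrated together with protein and each
fragment's free-DNA band is quantified. Free signal is normalized to the
zero-protein lane (values above 1 from noise are deliberately not clamped),
depletion (1 − normalized free) is fitted per fragment with the isotherm
above to give an apparent dissociation constant K_Dapp, and C50 — the
concentration of 50 % free-DNA depletion — is obtained by inverting the
fitted curve (a monotone linear interpolation of the raw curve is a
fallback). With h = 1 and Bmax = 1, C50 and K_Dapp coincide.

Fragments that never deplete carry no affinity information and are reported
right-censored rather than fitted. The censoring statistic is the mean
depletion over the three highest protein concentrations compared with a
20 % threshold (configurable): true depletion is monotone in protein, so a
tail mean retains sensitivity while being robust to single-lane noise
excursions that a pointwise maximum would turn into spurious fits on inert
fragments.

Length selectivity is summarized as the slope (K_Dapp(50 bp) −
K_Dapp(40 bp))/10 in nM/bp — negative when the longer fragment is bound
more tightly; zero is the "threshold-effect" null. Per-replicate slopes
feed a one-way ANOVA across constructs (scipy), with per-construct t
contrasts against a reference (wild type) and optional Tukey HSD
(statsmodels). No multiplicity correction is applied to contrasts by
default. Each fragment's depletion curve is treated as an independent
binding reaction; no explicit free-protein competition linkage is modelled
across fragments (in the trace-DNA regime the coupling is below 1 %, as the
simulator's mass-balance mode verifies).

## CD processing (`sahdna.cd`)

Observed ellipticity m⁰ (millidegrees) converts to mean residue ellipticity

    MRE = m⁰ · MW / ((n − 1) · 10 · L · C)

with molecular weight MW (g/mol), n residues, path length L (cm) and
concentration C (g/L). Fractional helicity uses the 222 nm two-point
method, (MRE₂₂₂ − θ_u)/(θ_h − θ_u) with coil and full-helix references
θ_u = −3000 and θ_h = −39000 deg·cm²·dmol⁻¹; values outside [0, 1] are
reported as-is with a flag (they diagnose concentration or reference error)
rather than clipped. DNA-signal subtraction is pointwise on identical
wavelength grids, or on the overlap after linear interpolation when
requested; the protein sample's metadata is retained.

Thermal denaturation at 222 nm is fitted with a two-state van't Hoff model
with linear folded/unfolded baselines,

    y(T) = (b_n(T) + b_d(T)·K(T)) / (1 + K(T)),
    K(T) = exp(−ΔH/R · (1/T − 1/T_m)),

temperatures in kelvin internally, interfaces in °C, ΔH in kJ/mol. The
functional form is the standard minimal model for a cooperative two-state
transition; the classification against "non-cooperative" fraying (the
behaviour expected of an isolated SAH, which lacks tertiary structure) is
by model comparison: the transition is called non-cooperative when a plain
linear model wins on AIC, when the fitted ΔH falls below a 40 kJ/mol floor,
when the fitted T_m leaves the measured range, or when the fitted baseline
separation at T_m is under 5 % of the signal span (a guard against
degenerate fits in which the two-state model imitates a line with
coinciding baselines). Melting-point shifts between paired curves use
fitted T_m by default, with a model-free half-transition midpoint reading
available.

## Helix geometry (`sahdna.geometry`)

The local helix axis is built from sliding windows of four consecutive Cα
atoms: second differences of the Cα trace point at the axis, the cross
product of successive second differences gives the local axis direction
(sign following the chain), and the angle between successive second
differences is the local twist. A local construction was chosen over global
cylinder fitting because the helices of interest are visibly curved, and a
global fit would smear the bend into the residuals. Chain breaks split the
axis into segments.

Reported measures: end-to-end length (first-to-last Cα distance); axis arc
length (polyline length of the axis points, extended to the projections of
the terminal Cα onto the end directions — so a straight helix's arc equals
its axial span); number of turns, defined as residue count × mean per-step
twist / 360° (an ideal 3.6-residue/turn helix of n residues reports n/3.6
turns); and a per-residue curvature profile. Axis arc ≥ end-to-end holds up
to a 0.5 % tolerance that absorbs the terminal chord offset (bounded by
twice the 2.3 Å helix radius). Curvature is the angle between local axis
directions after smoothing them with a 4-window (≈ one helical turn) moving
average — the raw per-window direction wobbles with helical phase, and the
turn-length smoothing removes that bias (uniform-bend recovery is then
accurate to ~0.5 %). The curved region is the longest contiguous run above
a threshold, default 1.5°/residue.

Superposition uses the Kabsch SVD solution (reflections excluded) over the
models' common author-numbered residues; pairwise RMSD matrices are
symmetric with zero diagonal by construction. PDB/mmCIF reading is through
gemmi, keeping the first alternate location per residue.

## Sequence charge patterning (`sahdna.sequences`)

Charges: K/R = +1, D/E = −1, others 0. Histidine is neutral by default
(the binding and CD experiments are buffered near pH 7.4) with a
configurable partial charge for analyses that count His as basic. Terminal
charges are ignored. The sliding-window net charge (default window 7,
assigned to the window's centre residue, reported in author numbering)
rejects even windows rather than guessing an assignment convention.
Candidate stabilizing ion pairs are all (i, i+3) and (i, i+4) position
pairs with opposite nonzero charge — the spacings that place side chains on
the same helical face one turn apart; a residue may participate in several
pairs. Helical-face bias places residue r at wheel angle (r−1)·100° mod 360
(ideal 3.6 residues/turn; configurable), partitions the wheel into fixed
sectors (default 60°, must divide 360) whose charges sum to the total
sequence charge, and locates the maximally basic sector by sliding a
sector of the same width over the residue angles (ties broken toward the
smallest start angle).

## Synthetic-data generators (`sahdna.simulate`)

The binding generator is a finite lattice: a fragment of L bp is a lattice
of L sites; each protein monomer occludes m = 20 contiguous sites (the
~20 bp site size typical of the domain class); ligands cannot overlap; two
ligands in direct contact gain a nearest-neighbour cooperativity factor ω
(the minimal standard contact-cooperativity choice). A configuration with k
ligands and c abutting pairs has weight (K·P)^k ω^c. The occupancy-resolved
partition function is computed by an exact two-state prefix recursion in
O(L·k_max) and combined with concentration terms in log space, so extreme
concentrations or cooperativities cannot overflow; the recursion is
validated against explicit placement enumeration. The study's
phenomenology emerges rather than being painted in: a ladder of
floor(L/20) + 1 bands, an inert 10 bp fragment, steepened (h > 1) titration
curves when ω > 1, and length-dependent free-band depletion.

Titration simulation defaults to the trace-DNA regime (free ≈ total
protein, as with a 1–3 nM probe against tens-to-hundreds nM protein); a
mass-balance mode solves free ligand by root bracketing when depletion
matters. The lane renderer maps P(k bound) to band intensities with
multiplicative log-normal lane noise (default CV 5 %, typical of gel
densitometry), optional additive background and a saturation ceiling; all
noise is seeded and deterministic. A second ladder generator draws each
fragment's depletion from an independent Hill isotherm — the equal-affinity
null used to show the analysis invents no selectivity.

CD spectra are simulated as f·helix-basis + (1−f)·coil-basis over
190–250 nm, with smooth Gaussian-band bases pinned exactly to the −39000 /
−3000 references at 222 nm (so the two-point helicity estimate round-trips
f by construction) and converted to millidegrees through the inverse MRE
relation for the sample's own metadata. Melts come from the same two-state
model the fitter uses, with defaults (ΔH = 250 kJ/mol, sloped baselines
spanning ≈ 16000 deg·cm²·dmol⁻¹) shaped like a mid-sized helical domain's
unfolding. Helix coordinates use rise 1.5 Å/residue, twist 100°, Cα radius
2.3 Å, with optional uniform bending of the axis onto a circle. SAH-like
sequences are assembled from 8-residue blocks (E₄K₄ charged blocks, in
which every residue has an i±3/i±4 opposite-charge partner, versus neutral
blocks) at a configurable density, with an optional basic stripe written
onto one helical face.

What the generators do *not* emulate: gel-migration physics and band
overlap, image segmentation, fluorophore photophysics, instrument drift and
scan averaging in CD, non-two-state (intermediate-populated) unfolding, and
overlap-exclusion binding with non-integer site size (McGhee–von Hippel
style). Passing tests therefore demonstrate correctness of the analysis
chain under the stated statistical structure of the data, not robustness to
every artefact of real gels and spectra.

## Problem sizes and tolerances

The validation suite and the acceptance script use: 200 seeded noisy
titrations per (K_D, h) grid point (σ = 0.03, 12 concentrations; median
K_D recovered within 5 %, h within 10 %; noiseless recovery to 1e-6
relative); enumeration cross-checks on lattices up to L = 60, m ∈ {5...25},
ω ∈ {0.1, 1, 10} with probability normalization to 1e-12; six-replicate
equal-affinity ladders for the null slope and ten seeds for sub-footprint
censoring; 200 melt fits at 3 %-of-span noise (median |T_m| error under
0.5 °C) and ten paired-curve shifts (+10 °C offset recovered to ±0.3 °C);
and closed-form geometry on an 86-residue ideal helix (end-to-end
85 × 1.5 = 127.5 Å, 86/3.6 ≈ 23.9 turns) with a rotation-grid superposition
oracle agreeing within 0.05 Å. These sizes make the whole suite run in
well under a minute while keeping Monte-Carlo error far below each
tolerance.

## Known limitations

- K_Dapp from competition ladders is an operational, per-fragment quantity;
  it folds competition into the apparent constant rather than modelling it.
- The Hill isotherm is phenomenological; the lattice generator is the
  mechanistic stand-in, and the two agree only in the regimes tested
  (single-site limit exactly; multi-site effectively).
- Fractional helicity by the 222 nm two-point method inherits the
  uncertainty of the coil/helix reference values; it is a comparative, not
  absolute, measure.
- Helix curvature below ~0.05°/residue is not reliably distinguishable from
  numerical noise of the axis construction.
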