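"""DNA-length selectivity analysis of multi-fragment competition EMSAs.

A Cy5-labelled DNA ladder (by default 10/20/30/40/50 bp fragments, each at
equimolar concentration) is titrated with protein; the free-DNA band of each
fragment is quantified per lane.  Free-band signal is normalized to the
zero-protein lane, depletion curves (fraction bound = 1 - normalized free)
are fitted with the cooperative isotherm to give a per-fragment apparent
dissociation constant K_Dapp and the concentration of 50 % depletion (C50),
and length selectivity is summarized as the 40->50 bp slope of K_Dapp.
Constructs are compared by one-way ANOVA on replicate slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binding import HillBindingModel, TitrationSeries

__all__ = [
    "LadderTitration",
    "FragmentResult",
    "SelectivityResult",
    "normalize_free_dna",
    "kdapp_per_fragment",
    "c50",
    "selectivity_slope",
    "compare_constructs",
    "analyze_ladder",
]

DEFAULT_FRAGMENTS = (10, 20, 30, 40, 50)


@dataclass
class LadderTitration:
    """Free-DNA intensities for every fragment at every protein concentration.

    ``free_intensity`` is a (n_concentrations, n_fragments) array aligned with
    ``conc_nM`` and ``fragment_bp``; the first concentration must be 0
    (zero-protein lane).
    """

    conc_nM: np.ndarray
    fragment_bp: tuple[int, ...]
    free_intensity: np.ndarray
    construct: str = ""
    replicate: int | str = 0

    def __post_init__(self) -> None:
        self.conc_nM = np.asarray(self.conc_nM, float)
        self.free_intensity = np.asarray(self.free_intensity, float)
        if self.free_intensity.shape != (len(self.conc_nM), len(self.fragment_bp)):
            raise ValueError("free_intensity must be (n_conc, n_fragments)")
        if np.any(self.free_intensity < 0):
            raise ValueError("intensities must be >= 0")
        if self.conc_nM[0] != 0:
            raise ValueError("first lane must be the zero-protein lane")

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> list["LadderTitration"]:
        """Build titrations from a long table (construct, replicate,
        protein_conc_nM, fragment_bp, free_intensity)."""
        out = []
        for (construct, rep), g in df.groupby(["construct", "replicate"], sort=True):
            wide = g.pivot_table(index="protein_conc_nM", columns="fragment_bp", values="free_intensity")
            out.append(
                cls(
                    conc_nM=wide.index.to_numpy(),
                    fragment_bp=tuple(int(c) for c in wide.columns),
                    free_intensity=wide.to_numpy(),
                    construct=str(construct),
                    replicate=rep,
                )
            )
        return out


def normalize_free_dna(ladder: LadderTitration) -> pd.DataFrame:
    """Free-DNA signal normalized to the zero-protein lane, per fragment.

    Values may exceed 1 from noise; they are deliberately not clamped.
    """
    zero = ladder.free_intensity[0]
    for frag, z in zip(ladder.fragment_bp, zero):
        if z <= 0:
            raise ValueError(f"zero-protein intensity is 0 for the {frag} bp fragment")
    norm = ladder.free_intensity / zero
    return pd.DataFrame(norm, index=pd.Index(ladder.conc_nM, name="protein_conc_nM"),
                        columns=pd.Index(ladder.fragment_bp, name="fragment_bp"))


@dataclass
class FragmentResult:
    fragment_bp: int
    kdapp_nM: float  # NaN when censored
    kdapp_se: float
    hill_h: float
    bmax: float
    c50_nM: float  # NaN when censored
    censored: bool
    max_depletion: float
    fit: object | None = field(default=None, repr=False)


def kdapp_per_fragment(
    curves: pd.DataFrame,
    censor_depletion: float = 0.2,
    fix_bmax: float | None = None,
    seed: int = 0,
) -> list[FragmentResult]:
    """Fit the cooperative isotherm to each fragment's depletion curve.

    Fragments whose free signal never drops by at least ``censor_depletion``
    (default 20 %) are reported as right-censored (K_Dapp beyond the tested
    range) rather than fitted — flat curves carry no affinity information.
    Because true depletion is monotone in protein, the censoring statistic is
    the mean depletion over the three highest concentrations, which is robust
    to single-lane noise excursions on inert fragments.
    """
    conc = curves.index.to_numpy(float)
    results = []
    for frag in curves.columns:
        norm = curves[frag].to_numpy(float)
        frac = 1.0 - norm
        frac[conc == 0] = 0.0
        max_dep = float(np.nanmax(frac))
        order = np.argsort(conc)
        tail_dep = float(np.nanmean(frac[order][-3:]))
        if tail_dep < censor_depletion:
            results.append(FragmentResult(int(frag), np.nan, np.nan, np.nan, np.nan, np.nan, True, max_dep))
            continue
        series = TitrationSeries(conc, np.clip(frac, 0.0, 1.05), label=f"{frag} bp")
        try:
            res = HillBindingModel(series, fix_bmax=fix_bmax).fit(seed=seed)
        except ValueError as err:
            raise ValueError(f"fit failed for the {frag} bp fragment: {err}") from err
        c50_val = res.half_saturation_conc(0.5)
        results.append(
            FragmentResult(int(frag), res.kd_nM, res.kd_se, res.hill_h, res.bmax, c50_val, False, max_dep, fit=res)
        )
    return results


def c50(curves: pd.DataFrame, method: str = "fit", **fit_kwargs) -> pd.Series:
    """Protein concentration at which normalized free DNA reaches 0.5.

    ``method='fit'`` inverts the fitted isotherm (smoother on noisy tails);
    ``method='interpolate'`` linearly interpolates the raw monotone curve.
    Censored (never-reached) fragments report NaN.
    """
    if method == "fit":
        return pd.Series(
            {r.fragment_bp: r.c50_nM for r in kdapp_per_fragment(curves, **fit_kwargs)},
            name="c50_nM",
        )
    if method != "interpolate":
        raise ValueError("method must be 'fit' or 'interpolate'")
    conc = curves.index.to_numpy(float)
    out = {}
    for frag in curves.columns:
        y = curves[frag].to_numpy(float)
        if np.any(np.diff(y) > 1e-9):
            raise ValueError(
                f"non-monotone raw curve for the {frag} bp fragment; use method='fit'"
            )
        if y.min() > 0.5:
            out[int(frag)] = np.nan
            continue
        idx = int(np.argmax(y <= 0.5))
        x0, x1, y0, y1 = conc[idx - 1], conc[idx], y[idx - 1], y[idx]
        out[int(frag)] = float(x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0)) if y1 != y0 else float(x1)
    return pd.Series(out, name="c50_nM")


def selectivity_slope(results: list[FragmentResult], lo: int = 40, hi: int = 50) -> float:
    """(K_Dapp(hi) - K_Dapp(lo)) / (hi - lo), nM per bp.

    Negative when the longer fragment is bound more tightly.  Raises when
    either fragment is censored (slope undefined).
    """
    by_len = {r.fragment_bp: r for r in results}
    for length in (lo, hi):
        if length not in by_len:
            raise ValueError(f"no result for the {length} bp fragment")
        if by_len[length].censored:
            raise ValueError(f"K_Dapp censored at {length} bp; slope undefined")
    return float((by_len[hi].kdapp_nM - by_len[lo].kdapp_nM) / (hi - lo))


@dataclass
class SelectivityResult:
    """Per-fragment affinities and the 40->50 bp selectivity summary."""

    construct: str
    fragments: list[FragmentResult]
    replicate_slopes: np.ndarray  # one slope per replicate (may be empty)

    @property
    def slope_40_50(self) -> float:
        return float(np.mean(self.replicate_slopes)) if len(self.replicate_slopes) else np.nan

    @property
    def slope_sd(self) -> float:
        return float(np.std(self.replicate_slopes, ddof=1)) if len(self.replicate_slopes) > 1 else np.nan

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "fragment_bp": r.fragment_bp,
                    "kdapp_nM": r.kdapp_nM,
                    "kdapp_se": r.kdapp_se,
                    "hill_h": r.hill_h,
                    "c50_nM": r.c50_nM,
                    "censored": r.censored,
                }
                for r in self.fragments
            ]
        )
        df.attrs["construct"] = self.construct
        df.attrs["slope_40_50_nM_per_bp"] = self.slope_40_50
        df.attrs["slope_sd"] = self.slope_sd
        return df


def analyze_ladder(
    ladders: list[LadderTitration],
    censor_depletion: float = 0.2,
    fix_bmax: float | None = None,
    seed: int = 0,
) -> SelectivityResult:
    """Full per-construct analysis of replicate ladder titrations.

    Per-replicate fits give the replicate slopes; the reported per-fragment
    K_Dapp values come from fitting the replicate-averaged curves.
    """
    if not ladders:
        raise ValueError("no ladder titrations supplied")
    constructs = {ld.construct for ld in ladders}
    if len(constructs) > 1:
        raise ValueError(f"mixed constructs in one analysis: {sorted(constructs)}")
    slopes = []
    norm_curves = []
    for ld in ladders:
        curves = normalize_free_dna(ld)
        norm_curves.append(curves)
        try:
            res = kdapp_per_fragment(curves, censor_depletion, fix_bmax, seed=seed)
            slopes.append(selectivity_slope(res))
        except ValueError:
            pass  # censored replicate: no slope
    mean_curves = sum(norm_curves) / len(norm_curves)
    fragments = kdapp_per_fragment(mean_curves, censor_depletion, fix_bmax, seed=seed)
    return SelectivityResult(ladders[0].construct, fragments, np.array(slopes))


def compare_constructs(
    slopes_by_construct: dict[str, np.ndarray],
    reference: str | None = None,
    tukey: bool = False,
) -> dict:
    """One-way ANOVA across constructs' replicate selectivity slopes.

    Returns the omnibus F and p, per-construct two-sample t contrasts against
    the reference (default: first construct, e.g. wild type), and optionally a
    Tukey HSD table.
    """
    if len(slopes_by_construct) < 2:
        raise ValueError("need at least 2 constructs")
    groups = {k: np.asarray(v, float) for k, v in slopes_by_construct.items()}
    for name, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"construct {name!r} has fewer than 2 replicates")
    names = list(groups)
    values = [groups[n] for n in names]
    means = [g.mean() for g in values]
    if np.ptp(means) == 0:
        # no between-group variation at all -> F = 0 by definition
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*values)
        f_stat, p_val = float(f_stat), float(p_val)
    reference = reference or names[0]
    contrasts = {}
    for name in names:
        if name == reference:
            continue
        t, p = stats.ttest_ind(groups[name], groups[reference])
        contrasts[name] = {"t": float(t), "p": float(p)}
    out = {"F": f_stat, "p": p_val, "reference": reference, "contrasts": contrasts}
    if tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        data = np.concatenate(values)
        labels = np.concatenate([[n] * len(groups[n]) for n in names])
        out["tukey"] = pairwise_tukeyhsd(data, labels)
    return out
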