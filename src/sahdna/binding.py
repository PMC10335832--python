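"""Cooperative protein-DNA binding analysis of EMSA titrations.

Band intensities from an electrophoretic mobility shift assay are converted
to fraction bound per lane, replicates are aggregated, and the cooperative
binding isotherm

    fraction bound = Bmax * [P]^h / (K_D^h + [P]^h)

is fitted by nonlinear least squares to estimate the dissociation constant
K_D (nM), the Hill coefficient h, and the binding amplitude Bmax.

The fitting surface follows the Model/Results convention: build a
:class:`HillBindingModel` from a :class:`TitrationSeries` (or a DataFrame),
call :meth:`~HillBindingModel.fit`, and read estimates, standard errors and
diagnostics off the returned :class:`HillBindingResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "GelLane",
    "TitrationSeries",
    "HillBindingModel",
    "HillBindingResults",
    "hill_curve",
    "fraction_bound",
    "aggregate_replicates",
    "fit_hill",
]

KD_BOUNDS = (1e-3, 1e6)  # nM
H_BOUNDS = (0.2, 10.0)
BMAX_BOUNDS = (0.0, 1.2)


def hill_curve(conc: np.ndarray, kd: float, h: float, bmax: float = 1.0) -> np.ndarray:
    """Cooperative binding isotherm; monotone non-decreasing in conc."""
    conc = np.asarray(conc, dtype=float)
    out = np.zeros_like(conc)
    pos = conc > 0
    # compute in ratio form for numerical range safety
    r = (conc[pos] / kd) ** h
    out[pos] = bmax * r / (1.0 + r)
    return out


@dataclass
class GelLane:
    """One EMSA lane: free-DNA band followed by the shifted-complex bands."""

    protein_conc_nM: float
    band_intensities: Sequence[float]  # index 0 = free DNA, 1..k = complexes
    background: float = 0.0
    lane_id: str = ""

    def __post_init__(self) -> None:
        if self.protein_conc_nM < 0:
            raise ValueError("protein concentration must be >= 0")
        if len(self.band_intensities) < 1:
            raise ValueError("lane needs at least the free-DNA band")

    def corrected(self) -> np.ndarray:
        """Background-subtracted band intensities, clamped at zero."""
        return np.clip(np.asarray(self.band_intensities, float) - self.background, 0.0, None)


@dataclass
class TitrationSeries:
    """(protein concentration, fraction bound) points, possibly replicated."""

    conc_nM: np.ndarray
    fraction: np.ndarray
    label: str = ""
    dna_length_bp: int | None = None
    dna_conc_nM: float | None = None
    sd: np.ndarray | None = None  # per-point SD when aggregated
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.conc_nM = np.asarray(self.conc_nM, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.conc_nM.shape != self.fraction.shape:
            raise ValueError("conc and fraction must have matching shapes")

    def to_frame(self) -> pd.DataFrame:
        d = {"protein_conc_nM": self.conc_nM, "fraction_bound": self.fraction}
        if self.sd is not None:
            d["sd"] = self.sd
        return pd.DataFrame(d)


def fraction_bound(
    lanes: Sequence[GelLane],
    mode: Literal["bound-over-total", "free-depletion"] = "bound-over-total",
    **series_kwargs,
) -> TitrationSeries:
    """Convert a set of gel lanes to a fraction-bound titration.

    ``bound-over-total``: fraction = sum(shifted) / (free + sum(shifted)) per
    lane, after background subtraction.  ``free-depletion``: fraction =
    1 - free / free_at_zero_protein.  The zero-protein lane yields fraction 0
    in both modes.
    """
    if not lanes:
        raise ValueError("no lanes supplied")
    lanes = sorted(lanes, key=lambda ln: ln.protein_conc_nM)
    zero = [ln for ln in lanes if ln.protein_conc_nM == 0]
    if mode == "free-depletion" and not zero:
        raise ValueError("free-depletion mode requires a zero-protein lane")

    conc, frac = [], []
    free_at_zero = zero[0].corrected()[0] if zero else None
    for ln in lanes:
        bands = ln.corrected()
        total = bands.sum()
        if total <= 0:
            raise ValueError(f"empty lane (zero total signal): {ln.lane_id!r}")
        if ln.protein_conc_nM == 0:
            f = 0.0
        elif mode == "bound-over-total":
            f = bands[1:].sum() / total
        elif mode == "free-depletion":
            if free_at_zero <= 0:
                raise ValueError("zero-protein free band has no signal")
            f = 1.0 - bands[0] / free_at_zero
        else:
            raise ValueError(f"unknown mode {mode!r}")
        conc.append(ln.protein_conc_nM)
        frac.append(f)
    return TitrationSeries(np.array(conc), np.array(frac), **series_kwargs)


def aggregate_replicates(series_list: Sequence[TitrationSeries], rtol: float = 1e-6) -> TitrationSeries:
    """Mean +/- sample SD per concentration across replicate titrations.

    Replicates must share the concentration grid (relative tolerance
    ``rtol``).  With a single replicate the SD is reported as missing (NaN),
    not zero.
    """
    if not series_list:
        raise ValueError("no replicates supplied")
    ref = series_list[0].conc_nM
    for s in series_list[1:]:
        if s.conc_nM.shape != ref.shape or not np.allclose(s.conc_nM, ref, rtol=rtol):
            bad = s.conc_nM[~np.isclose(s.conc_nM, ref, rtol=rtol)] if s.conc_nM.shape == ref.shape else s.conc_nM
            raise ValueError(f"replicate concentration grids differ at: {np.asarray(bad)}")
    stack = np.vstack([s.fraction for s in series_list])
    n = len(series_list)
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.full(ref.shape, np.nan)
    first = series_list[0]
    return TitrationSeries(
        ref.copy(),
        stack.mean(axis=0),
        label=first.label,
        dna_length_bp=first.dna_length_bp,
        dna_conc_nM=first.dna_conc_nM,
        sd=sd,
        n_replicates=n,
    )


class HillBindingModel:
    """Cooperative binding isotherm fitted to a fraction-bound titration.

    Parameters
    ----------
    series
        The titration to fit.  Needs at least 4 distinct nonzero
        concentrations; fractions must lie in [0, 1.05].
    fix_bmax
        Fix the amplitude at this value instead of estimating it.
    fix_h
        Fix the Hill coefficient (e.g. 1.0 for the non-cooperative nested
        model).
    weights
        ``None`` (unweighted), or "sd" to use inverse-variance weights from
        the series' replicate SDs.
    """

    def __init__(
        self,
        series: TitrationSeries,
        fix_bmax: float | None = None,
        fix_h: float | None = None,
        weights: str | None = None,
    ):
        mask = series.conc_nM > 0
        if len(np.unique(series.conc_nM[mask])) < 4:
            raise ValueError("need at least 4 distinct nonzero concentrations")
        if np.any(series.fraction < -1e-9) or np.any(series.fraction > 1.05 + 1e-9):
            raise ValueError("fractions must lie in [0, 1.05]")
        if np.all(series.fraction[mask] <= 0):
            raise ValueError("no binding detected (all fractions zero)")
        self.series = series
        self.fix_bmax = fix_bmax
        self.fix_h = fix_h
        self._weights = None
        if weights == "sd":
            if series.sd is None or np.any(~np.isfinite(series.sd)) or np.any(series.sd <= 0):
                raise ValueError("inverse-variance weighting needs positive SDs")
            self._weights = 1.0 / series.sd

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, conc_col="protein_conc_nM", frac_col="fraction_bound", **kw):
        return cls(TitrationSeries(df[conc_col].to_numpy(), df[frac_col].to_numpy()), **kw)

    def _initial_guesses(self) -> dict[str, float]:
        c, f = self.series.conc_nM, self.series.fraction
        bmax0 = max(float(f.max()), 0.05)
        half = bmax0 / 2.0
        above = np.nonzero(f >= half)[0]
        kd0 = float(c[above[0]]) if len(above) and c[above[0]] > 0 else float(np.median(c[c > 0]))
        return {"kd": kd0, "h": 1.0, "bmax": bmax0}

    def _make_params(self, guesses: dict[str, float]) -> lmfit.Parameters:
        p = lmfit.Parameters()
        p.add("kd", value=np.clip(guesses["kd"], *KD_BOUNDS), min=KD_BOUNDS[0], max=KD_BOUNDS[1])
        if self.fix_h is None:
            p.add("h", value=guesses["h"], min=H_BOUNDS[0], max=H_BOUNDS[1])
        else:
            p.add("h", value=self.fix_h, vary=False)
        if self.fix_bmax is None:
            p.add("bmax", value=np.clip(guesses["bmax"], 0.05, BMAX_BOUNDS[1]), min=BMAX_BOUNDS[0], max=BMAX_BOUNDS[1])
        else:
            p.add("bmax", value=self.fix_bmax, vary=False)
        return p

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        model = hill_curve(self.series.conc_nM, params["kd"].value, params["h"].value, params["bmax"].value)
        res = model - self.series.fraction
        if self._weights is not None:
            res = res * self._weights
        return res

    def fit(self, n_restarts: int = 5, seed: int = 0) -> "HillBindingResults":
        """Least-squares fit with seeded multi-start on poor convergence."""
        guesses = self._initial_guesses()
        best = lmfit.minimize(self._residual, self._make_params(guesses), method="leastsq")
        rng = np.random.default_rng(seed)
        if not best.success:
            for _ in range(n_restarts):
                g = dict(guesses)
                g["kd"] = guesses["kd"] * float(np.exp(rng.normal(0, 1.5)))
                g["h"] = float(np.clip(guesses["h"] * np.exp(rng.normal(0, 0.5)), *H_BOUNDS))
                out = lmfit.minimize(self._residual, self._make_params(g), method="leastsq")
                if out.success and (not best.success or out.chisqr < best.chisqr):
                    best = out
                if best.success:
                    break
        return HillBindingResults(self, best)


@dataclass
class HillBindingResults:
    """Estimates, uncertainties and diagnostics from a Hill-isotherm fit."""

    model: HillBindingModel
    minimizer_result: lmfit.minimizer.MinimizerResult = field(repr=False)

    @property
    def kd_nM(self) -> float:
        return float(self.minimizer_result.params["kd"].value)

    @property
    def hill_h(self) -> float:
        return float(self.minimizer_result.params["h"].value)

    @property
    def bmax(self) -> float:
        return float(self.minimizer_result.params["bmax"].value)

    def _stderr(self, name: str) -> float:
        err = self.minimizer_result.params[name].stderr
        return float(err) if err is not None else np.nan

    @property
    def kd_se(self) -> float:
        return self._stderr("kd")

    @property
    def hill_se(self) -> float:
        return self._stderr("h")

    @property
    def bmax_se(self) -> float:
        return self._stderr("bmax")

    @property
    def rss(self) -> float:
        return float(np.sum((hill_curve(self.model.series.conc_nM, self.kd_nM, self.hill_h, self.bmax) - self.model.series.fraction) ** 2))

    @property
    def converged(self) -> bool:
        return bool(self.minimizer_result.success)

    @property
    def aic(self) -> float:
        return float(self.minimizer_result.aic)

    def predict(self, conc_nM: np.ndarray) -> np.ndarray:
        return hill_curve(np.asarray(conc_nM, float), self.kd_nM, self.hill_h, self.bmax)

    def half_saturation_conc(self, level: float = 0.5) -> float:
        """Concentration where fraction bound reaches ``level`` (absolute).

        Inverts the fitted isotherm; returns NaN (censored) when the fitted
        amplitude never reaches ``level``.
        """
        if self.bmax <= level:
            return np.nan
        return float(self.kd_nM * (level / (self.bmax - level)) ** (1.0 / self.hill_h))

    def compare_noncooperative(self) -> float:
        """AIC(h free) - AIC(h=1): negative favours the cooperative model."""
        nested = HillBindingModel(self.model.series, fix_bmax=self.model.fix_bmax, fix_h=1.0).fit()
        return self.aic - nested.aic

    def summary(self) -> pd.DataFrame:
        rows = [
            ("kd_nM", self.kd_nM, self.kd_se),
            ("hill_h", self.hill_h, self.hill_se),
            ("bmax", self.bmax, self.bmax_se),
        ]
        df = pd.DataFrame(rows, columns=["parameter", "estimate", "stderr"])
        df.attrs["rss"] = self.rss
        df.attrs["converged"] = self.converged
        df.attrs["label"] = self.model.series.label
        return df

    def plot(self, ax=None):
        """Quick-look plot of data and fitted isotherm."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        ax.errorbar(s.conc_nM, s.fraction, yerr=s.sd, fmt="o", label=s.label or "data")
        pos = s.conc_nM[s.conc_nM > 0]
        grid = np.geomspace(pos.min() / 3, pos.max() * 3, 200)
        ax.plot(grid, self.predict(grid), "-", label=f"fit: Kd={self.kd_nM:.3g} nM, h={self.hill_h:.2f}")
        ax.set_xscale("log")
        ax.set_xlabel("[protein] (nM)")
        ax.set_ylabel("fraction bound")
        ax.legend()
        return ax


def fit_hill(
    series: TitrationSeries,
    fix_bmax: float | None = None,
    weights: str | None = None,
    seed: int = 0,
) -> HillBindingResults:
    """Convenience wrapper: fit the cooperative isotherm to a titration."""
    return HillBindingModel(series, fix_bmax=fix_bmax, weights=weights).fit(seed=seed)
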