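"""Circular-dichroism processing for alpha-helical proteins.

Observed ellipticity in millidegrees is converted to mean residue ellipticity

    MRE(lambda) = m0(lambda) * MW / ((n - 1) * 10 * L * C)

(MW in g/mol, n residues, path length L in cm, concentration C in g/L) and
helix content is estimated by the 222 nm two-point method,

    fractional helicity = (MRE_222 - theta_u) / (theta_h - theta_u),

with coil and full-helix references theta_u = -3000 and
theta_h = -39000 deg cm^2 dmol^-1.  Thermal denaturation at 222 nm is fitted
with a two-state van't Hoff model with linear folded/unfolded baselines and
classified against a no-transition linear alternative, which separates
cooperative (tertiary-stabilized) unfolding from the gradual fraying typical
of an isolated single alpha-helix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import lmfit
import numpy as np
import pandas as pd

R_GAS = 8.314462618e-3  # kJ mol^-1 K^-1
C_TO_K = 273.15

__all__ = [
    "CDSpectrum",
    "HelicityReference",
    "MeltCurve",
    "ThermalMeltModel",
    "MeltFitResults",
    "mre",
    "fractional_helicity",
    "subtract_dna_signal",
    "fit_melt",
    "melt_shift",
    "average_scans",
]


@dataclass
class CDSpectrum:
    """Raw CD spectrum: observed ellipticity (millidegrees) vs wavelength."""

    wavelength_nm: np.ndarray
    millidegrees: np.ndarray
    mw_g_mol: float | None = None
    n_residues: int | None = None
    path_cm: float | None = None
    conc_g_L: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, float)
        self.millidegrees = np.asarray(self.millidegrees, float)
        if self.wavelength_nm.shape != self.millidegrees.shape:
            raise ValueError("wavelength and signal grids must match")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def _require_meta(self) -> None:
        for name in ("mw_g_mol", "n_residues", "path_cm", "conc_g_L"):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValueError(f"sample metadata {name} must be set and positive")
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2 (MRE divides by n - 1)")

    def at(self, wavelength: float) -> float:
        """Signal at a wavelength, linearly interpolated."""
        lo, hi = self.wavelength_nm[0], self.wavelength_nm[-1]
        if not lo <= wavelength <= hi:
            raise ValueError(f"{wavelength} nm outside the measured range [{lo}, {hi}]")
        return float(np.interp(wavelength, self.wavelength_nm, self.millidegrees))


@dataclass(frozen=True)
class HelicityReference:
    """222 nm MRE references for 0 % and 100 % helix."""

    theta_u: float = -3000.0
    theta_h: float = -39000.0

    def __post_init__(self) -> None:
        if not self.theta_h < self.theta_u < 0:
            raise ValueError("require theta_h < theta_u < 0")


def mre(spectrum: CDSpectrum) -> pd.Series:
    """Mean residue ellipticity (deg cm^2 dmol^-1) per wavelength."""
    spectrum._require_meta()
    scale = spectrum.mw_g_mol / (
        (spectrum.n_residues - 1) * 10.0 * spectrum.path_cm * spectrum.conc_g_L
    )
    return pd.Series(
        spectrum.millidegrees * scale,
        index=pd.Index(spectrum.wavelength_nm, name="wavelength_nm"),
        name="mre",
    )


def mre_scale(mw_g_mol: float, n_residues: int, path_cm: float, conc_g_L: float) -> float:
    """Millidegree -> MRE conversion factor for a sample."""
    return mw_g_mol / ((n_residues - 1) * 10.0 * path_cm * conc_g_L)


def fractional_helicity(
    mre222: float, ref: HelicityReference = HelicityReference()
) -> tuple[float, bool]:
    """Helix fraction from the 222 nm MRE; (value, out_of_range flag).

    Values outside [0, 1] are reported as-is with the flag set — they signal
    reference mismatch or concentration error rather than being silently
    clipped.
    """
    if ref.theta_h == ref.theta_u:
        raise ValueError("degenerate helicity reference")
    f = (mre222 - ref.theta_u) / (ref.theta_h - ref.theta_u)
    return float(f), not (0.0 <= f <= 1.0)


def subtract_dna_signal(
    complex_spec: CDSpectrum,
    dna_spec: CDSpectrum,
    interpolate: bool = False,
) -> CDSpectrum:
    """Remove the DNA contribution from a protein-DNA complex spectrum.

    Grids must match exactly unless ``interpolate`` is set, in which case the
    DNA spectrum is linearly interpolated onto the overlapping part of the
    complex grid.  The protein sample's metadata is retained.
    """
    wl_c, wl_d = complex_spec.wavelength_nm, dna_spec.wavelength_nm
    if not interpolate:
        if wl_c.shape != wl_d.shape or not np.array_equal(wl_c, wl_d):
            raise ValueError("wavelength grids differ; pass interpolate=True")
        wl, m0 = wl_c, complex_spec.millidegrees - dna_spec.millidegrees
    else:
        lo, hi = max(wl_c[0], wl_d[0]), min(wl_c[-1], wl_d[-1])
        if lo > hi:
            raise ValueError("wavelength ranges do not overlap")
        keep = (wl_c >= lo) & (wl_c <= hi)
        wl = wl_c[keep]
        dna_on_grid = np.interp(wl, wl_d, dna_spec.millidegrees)
        m0 = complex_spec.millidegrees[keep] - dna_on_grid
    return CDSpectrum(
        wl, m0,
        mw_g_mol=complex_spec.mw_g_mol, n_residues=complex_spec.n_residues,
        path_cm=complex_spec.path_cm, conc_g_L=complex_spec.conc_g_L,
        label=f"{complex_spec.label} - DNA",
    )


def average_scans(spectra: list[CDSpectrum]) -> CDSpectrum:
    """Average repeated scans of the same sample (identical grids)."""
    ref = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.wavelength_nm, ref.wavelength_nm):
            raise ValueError("scan wavelength grids differ")
    m0 = np.mean([s.millidegrees for s in spectra], axis=0)
    return CDSpectrum(ref.wavelength_nm.copy(), m0, ref.mw_g_mol, ref.n_residues,
                      ref.path_cm, ref.conc_g_L, ref.label)


@dataclass
class MeltCurve:
    """Thermal denaturation monitored at 222 nm: MRE vs temperature (C)."""

    temperature_C: np.ndarray
    mre222: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature_C = np.asarray(self.temperature_C, float)
        self.mre222 = np.asarray(self.mre222, float)
        if self.temperature_C.shape != self.mre222.shape:
            raise ValueError("temperature and signal grids must match")
        if np.any(np.diff(self.temperature_C) <= 0):
            raise ValueError("temperatures must be strictly increasing")


def two_state_melt(
    temp_C: np.ndarray,
    tm_C: float,
    dH_kJ_mol: float,
    bn_int: float,
    bn_slope: float,
    bd_int: float,
    bd_slope: float,
) -> np.ndarray:
    """Two-state van't Hoff melt with linear native/denatured baselines.

    K(T) = exp(-dH/R * (1/T - 1/Tm)) (T in kelvin) is the unfolding constant;
    the signal is the population-weighted average of the two baselines.
    """
    T = np.asarray(temp_C, float) + C_TO_K
    Tm = tm_C + C_TO_K
    K = np.exp(-dH_kJ_mol / R_GAS * (1.0 / T - 1.0 / Tm))
    native = bn_int + bn_slope * np.asarray(temp_C, float)
    denat = bd_int + bd_slope * np.asarray(temp_C, float)
    return (native + denat * K) / (1.0 + K)


class ThermalMeltModel:
    """Two-state thermal unfolding fitted to a 222 nm melt curve.

    Fits the van't Hoff two-state model and a no-transition linear
    alternative; the results object classifies the transition as
    ``two_state`` or ``non_cooperative`` (linear model preferred by AIC, or
    fitted dH below ``dh_floor_kJ_mol``).
    """

    def __init__(self, curve: MeltCurve, dh_floor_kJ_mol: float = 40.0):
        if len(curve.temperature_C) < 8:
            raise ValueError("need at least 8 temperatures spanning the transition")
        self.curve = curve
        self.dh_floor = dh_floor_kJ_mol

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, temp_col="temperature_C", sig_col="mre222", **kw):
        return cls(MeltCurve(df[temp_col].to_numpy(), df[sig_col].to_numpy()), **kw)

    def _params(self) -> lmfit.Parameters:
        t, y = self.curve.temperature_C, self.curve.mre222
        k = max(3, len(t) // 5)
        bn = np.polyfit(t[:k], y[:k], 1)
        bd = np.polyfit(t[-k:], y[-k:], 1)
        mid = 0.5 * (np.median(y[:k]) + np.median(y[-k:]))
        tm0 = float(t[np.argmin(np.abs(y - mid))])
        tm0 = float(np.clip(tm0, t[0] + 1.0, t[-1] - 1.0))
        p = lmfit.Parameters()
        p.add("tm_C", value=tm0, min=t[0] - 5.0, max=t[-1] + 5.0)
        p.add("dH_kJ_mol", value=200.0, min=1.0, max=2000.0)
        p.add("bn_int", value=float(bn[1]))
        p.add("bn_slope", value=float(bn[0]))
        p.add("bd_int", value=float(bd[1]))
        p.add("bd_slope", value=float(bd[0]))
        return p

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        v = params.valuesdict()
        return two_state_melt(self.curve.temperature_C, v["tm_C"], v["dH_kJ_mol"],
                              v["bn_int"], v["bn_slope"], v["bd_int"], v["bd_slope"]) - self.curve.mre222

    def fit(self) -> "MeltFitResults":
        two_state = lmfit.minimize(self._residual, self._params(), method="leastsq")
        t, y = self.curve.temperature_C, self.curve.mre222
        lin = np.polyfit(t, y, 1)
        lin_rss = float(np.sum((np.polyval(lin, t) - y) ** 2))
        n = len(t)
        # AIC = n log(RSS/n) + 2k, same convention for both candidates
        lin_aic = n * np.log(max(lin_rss, 1e-300) / n) + 2 * 2
        ts_rss = float(np.sum(self._residual(two_state.params) ** 2))
        ts_aic = n * np.log(max(ts_rss, 1e-300) / n) + 2 * 6
        return MeltFitResults(self, two_state, lin, float(ts_aic), float(lin_aic))


@dataclass
class MeltFitResults:
    model: ThermalMeltModel
    minimizer_result: lmfit.minimizer.MinimizerResult = field(repr=False)
    linear_coef: np.ndarray = field(repr=False)
    aic_two_state: float = np.nan
    aic_linear: float = np.nan

    @property
    def tm_C(self) -> float:
        return float(self.minimizer_result.params["tm_C"].value)

    @property
    def tm_se(self) -> float:
        err = self.minimizer_result.params["tm_C"].stderr
        return float(err) if err is not None else np.nan

    @property
    def vanthoff_dH(self) -> float:
        """Fitted van't Hoff unfolding enthalpy, kJ/mol."""
        return float(self.minimizer_result.params["dH_kJ_mol"].value)

    @property
    def baselines(self) -> dict:
        v = self.minimizer_result.params.valuesdict()
        return {
            "native": (v["bn_slope"], v["bn_int"]),
            "denatured": (v["bd_slope"], v["bd_int"]),
        }

    @property
    def delta_aic(self) -> float:
        """AIC(two-state) - AIC(linear); negative favours two-state."""
        return self.aic_two_state - self.aic_linear

    @property
    def converged(self) -> bool:
        return bool(self.minimizer_result.success)

    @property
    def transition_amplitude(self) -> float:
        """Baseline separation at Tm — the size of the fitted unfolding step."""
        v = self.minimizer_result.params.valuesdict()
        native = v["bn_int"] + v["bn_slope"] * self.tm_C
        denat = v["bd_int"] + v["bd_slope"] * self.tm_C
        return float(abs(denat - native))

    @property
    def model_class(self) -> Literal["two_state", "non_cooperative", "undetermined"]:
        if not self.converged:
            return "undetermined"
        if self.delta_aic >= 0 or self.vanthoff_dH < self.model.dh_floor:
            return "non_cooperative"
        t = self.model.curve.temperature_C
        if not t[0] <= self.tm_C <= t[-1]:
            return "non_cooperative"
        span = float(np.ptp(self.model.curve.mre222))
        if span == 0 or self.transition_amplitude < 0.05 * span:
            # coinciding baselines: the "transition" carries no signal
            return "non_cooperative"
        return "two_state"

    def predict(self, temp_C: np.ndarray) -> np.ndarray:
        v = self.minimizer_result.params.valuesdict()
        return two_state_melt(np.asarray(temp_C, float), v["tm_C"], v["dH_kJ_mol"],
                              v["bn_int"], v["bn_slope"], v["bd_int"], v["bd_slope"])

    def midpoint_tm(self) -> float:
        """Model-free midpoint: temperature where the signal crosses halfway
        between its initial and final plateaus (linear interpolation)."""
        t, y = self.model.curve.temperature_C, self.model.curve.mre222
        mid = 0.5 * (y[0] + y[-1])
        s = np.sign(y - mid)
        cross = np.nonzero(np.diff(s))[0]
        if len(cross) == 0:
            return np.nan
        i = cross[0]
        return float(np.interp(0.0, [y[i] - mid, y[i + 1] - mid], [t[i], t[i + 1]])
                     if y[i + 1] != y[i] else t[i])

    def summary(self) -> pd.DataFrame:
        rows = [
            ("tm_C", self.tm_C, self.tm_se),
            ("vanthoff_dH_kJ_mol", self.vanthoff_dH, self._stderr("dH_kJ_mol")),
        ]
        df = pd.DataFrame(rows, columns=["parameter", "estimate", "stderr"])
        df.attrs["model_class"] = self.model_class
        df.attrs["delta_aic"] = self.delta_aic
        return df

    def _stderr(self, name: str) -> float:
        err = self.minimizer_result.params[name].stderr
        return float(err) if err is not None else np.nan

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.temperature_C, c.mre222, "o", label=c.label or "data")
        grid = np.linspace(c.temperature_C[0], c.temperature_C[-1], 300)
        ax.plot(grid, self.predict(grid), "-", label=f"fit: Tm={self.tm_C:.1f} C ({self.model_class})")
        ax.set_xlabel("temperature (C)")
        ax.set_ylabel("MRE at 222 nm")
        ax.legend()
        return ax


def fit_melt(curve: MeltCurve, dh_floor_kJ_mol: float = 40.0) -> MeltFitResults:
    """Convenience wrapper: fit the two-state melt model to a curve."""
    return ThermalMeltModel(curve, dh_floor_kJ_mol).fit()


def melt_shift(reference: MeltCurve | MeltFitResults, perturbed: MeltCurve | MeltFitResults,
               method: str = "fit") -> float:
    """Melting-temperature shift (perturbed - reference), degrees C.

    ``method='fit'`` uses fitted two-state Tm values; ``'midpoint'`` uses the
    model-free half-transition reading.
    """
    def _result(x):
        return x if isinstance(x, MeltFitResults) else fit_melt(x)

    a, b = _result(reference), _result(perturbed)
    if method == "fit":
        return b.tm_C - a.tm_C
    if method == "midpoint":
        return b.midpoint_tm() - a.midpoint_tm()
    raise ValueError("method must be 'fit' or 'midpoint'")
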