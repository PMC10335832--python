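"""Delimited-text input/output for the command-line pipeline.

All tabular interchange is plain delimited text with headers.  Gel-lane
tables are wide (lane_id, protein_conc_nM, background, free, complex1..K,
ragged K via blanks); ladder tables are long (construct, replicate,
protein_conc_nM, fragment_bp, free_intensity); CD files are two columns
(wavelength_nm or temperature_C, millidegrees) preceded by ``# key = value``
metadata lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binding import GelLane
from .cd import CDSpectrum, MeltCurve
from .ladder import LadderTitration

FLOAT_FMT = "%.6g"


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def read_lanes(path: str | Path) -> list[GelLane]:
    """Read a wide gel-lane table into GelLane objects."""
    df = _read_table(path)
    required = {"lane_id", "protein_conc_nM", "background", "free"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lane table missing columns: {sorted(missing)}")
    complex_cols = sorted(
        (c for c in df.columns if c.startswith("complex")),
        key=lambda c: int(c.removeprefix("complex")),
    )
    lanes = []
    for _, row in df.iterrows():
        bands = [float(row["free"])]
        for c in complex_cols:
            v = row[c]
            if pd.notna(v):
                bands.append(float(v))
        lanes.append(
            GelLane(float(row["protein_conc_nM"]), bands, float(row["background"]), str(row["lane_id"]))
        )
    return lanes


def write_lanes(lanes: list[GelLane], path: str | Path) -> None:
    k_max = max(len(ln.band_intensities) for ln in lanes) - 1
    rows = []
    for ln in lanes:
        row = {
            "lane_id": ln.lane_id,
            "protein_conc_nM": ln.protein_conc_nM,
            "background": ln.background,
            "free": ln.band_intensities[0],
        }
        for k in range(1, k_max + 1):
            row[f"complex{k}"] = ln.band_intensities[k] if k < len(ln.band_intensities) else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_ladder_long(path: str | Path) -> list[LadderTitration]:
    """Read a long-format ladder table into per-(construct, replicate) titrations."""
    df = _read_table(path)
    required = {"construct", "replicate", "protein_conc_nM", "fragment_bp", "free_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ladder table missing columns: {sorted(missing)}")
    return LadderTitration.from_long_frame(df)


def write_ladder_long(ladders: list[LadderTitration], path: str | Path) -> None:
    rows = []
    for ld in ladders:
        for i, conc in enumerate(ld.conc_nM):
            for j, frag in enumerate(ld.fragment_bp):
                rows.append(
                    {
                        "construct": ld.construct,
                        "replicate": ld.replicate,
                        "protein_conc_nM": conc,
                        "fragment_bp": frag,
                        "free_intensity": ld.free_intensity[i, j],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


_META_KEYS = {"mw_g_mol", "n_residues", "path_cm", "conc_g_L", "label"}


def _read_two_column(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key = key.strip()
                if key in _META_KEYS:
                    meta[key] = value.strip() if key == "label" else float(value)
        elif line.strip():
            data_lines.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(data_lines)), sep=None, engine="python")
    if df.shape[1] != 2:
        raise ValueError("expected a two-column data block")
    if "n_residues" in meta:
        meta["n_residues"] = int(meta["n_residues"])
    return df, meta


def read_cd_spectrum(path: str | Path) -> CDSpectrum:
    df, meta = _read_two_column(path)
    return CDSpectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), **meta)


def write_cd_spectrum(spec: CDSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in ("mw_g_mol", "n_residues", "path_cm", "conc_g_L"):
            v = getattr(spec, key)
            if v is not None:
                fh.write(f"# {key} = {v}\n")
        if spec.label:
            fh.write(f"# label = {spec.label}\n")
        pd.DataFrame({"wavelength_nm": spec.wavelength_nm, "millidegrees": spec.millidegrees}).to_csv(
            fh, index=False, float_format=FLOAT_FMT
        )


def read_melt_curve(path: str | Path) -> MeltCurve:
    df, meta = _read_two_column(path)
    return MeltCurve(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), label=meta.get("label", ""))


def write_melt_curve(curve: MeltCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        if curve.label:
            fh.write(f"# label = {curve.label}\n")
        pd.DataFrame({"temperature_C": curve.temperature_C, "mre222": curve.mre222}).to_csv(
            fh, index=False, float_format=FLOAT_FMT
        )
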