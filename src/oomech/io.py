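"""Standard-format I/O: CSV tables, TIFF/PNG frame stacks, JSON sidecars.

Cohort tables and pressure traces travel as CSV with the documented
headers; frame stacks as multi-page TIFF (or a directory of zero-padded
PNG frames) plus a JSON sidecar carrying the pixel scale, frame rate and
any ground truth.  The cohort CSV schema is this package's own — the
study's outcome workbook schema is not published, so the columns here
are the ones the generator documents.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

from .tracking import FrameStack
from .simulate import PressureTrace

COHORT_COLUMNS = ["patient_id", "clinic_id", "oocyte_id", "arm", "patient_age",
                  "mii_count", "fertilized", "day3_grade_a", "blastocyst",
                  "usable_blastocyst"]

__all__ = ["write_cohort", "read_cohort", "write_pressure", "read_pressure",
           "write_stack", "read_stack", "write_fits", "read_fits",
           "write_curves", "read_curves", "read_ratings"]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    for c in ("fertilized", "day3_grade_a", "blastocyst", "usable_blastocyst"):
        if df[c].dtype == object:
            df[c] = df[c].str.lower().map({"yes": True, "no": False})
        df[c] = df[c].astype(bool)
    return df


def write_pressure(trace: PressureTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "pressure_psi": trace.pressures}).to_csv(
        path, index=False)
    meta = Path(path).with_suffix(".json")
    meta.write_text(json.dumps({"balance_pressure_psi": trace.balance_pressure}))


def read_pressure(path, balance: float | None = None) -> PressureTrace:
    df = pd.read_csv(path)
    if balance is None:
        meta = Path(path).with_suffix(".json")
        balance = (json.loads(meta.read_text())["balance_pressure_psi"]
                   if meta.exists() else 0.0)
    return PressureTrace(times=df["time_s"].to_numpy(),
                         pressures=df["pressure_psi"].to_numpy(),
                         balance_pressure=balance)


def _sidecar(stack: FrameStack, extra: dict | None) -> dict:
    meta = {"frame_rate": stack.frame_rate, "um_per_px": stack.um_per_px,
            "n_frames": len(stack)}
    if extra:
        meta.update({k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in extra.items()})
    return meta


def write_stack(stack: FrameStack, path, truth: dict | None = None) -> None:
    """Multi-page TIFF if ``path`` ends in .tif/.tiff, else a directory
    of zero-padded PNG frames; JSON sidecar either way."""
    path = Path(path)
    frames8 = (np.clip(stack.frames, 0, 1) * 255).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, frames8)
        side = path.with_suffix(path.suffix + ".json")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, f in enumerate(frames8):
            iio.imwrite(path / f"frame_{i:05d}.png", f)
        side = path / "stack.json"
    side.write_text(json.dumps(_sidecar(stack, truth), indent=1))


def read_stack(path) -> tuple[FrameStack, dict]:
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(f"no frame_*.png files in {path}")
        frames = np.stack([iio.imread(f) for f in files]).astype(np.float32) / 255.0
        side = path / "stack.json"
    else:
        frames = tifffile.imread(path).astype(np.float32) / 255.0
        side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    stack = FrameStack(frames=frames, frame_rate=meta.get("frame_rate", 70.0),
                       um_per_px=meta.get("um_per_px"))
    return stack, meta


FIT_COLUMNS = ["oocyte_id", "k0", "k1", "eta0", "eta1", "tau", "sse",
               "converged", "F0"]


def write_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, index=False)


def read_fits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "converged" in df.columns and df["converged"].dtype == object:
        df["converged"] = df["converged"].astype(str).str.lower().isin(
            ("true", "yes", "1"))
    return df


def write_curves(curves: dict, path) -> None:
    """Long-format CSV of many depth curves: oocyte_id, time_s, depth_um."""
    rows = [pd.DataFrame({"oocyte_id": oid, "time_s": c.times, "depth_um": c.depths})
            for oid, c in curves.items()]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_curves(path) -> dict:
    from .tracking import AspirationCurve
    df = pd.read_csv(path)
    out = {}
    for oid, g in df.groupby("oocyte_id", sort=False):
        out[oid] = AspirationCurve(times=g["time_s"].to_numpy(),
                                   depths=g["depth_um"].to_numpy())
    return out


def read_ratings(path) -> pd.DataFrame:
    """Subjects x raters categorical ratings; first column is the subject id."""
    return pd.read_csv(path, index_col=0)
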