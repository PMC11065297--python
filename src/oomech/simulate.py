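"""Synthetic aspiration experiments with known ground truth.

Everything the downstream modules consume can be generated here under a
fixed seed: creep curves drawn from the modified Zener model with
additive measurement noise, rendered micropipette-aspiration frame
stacks matching the measurement geometry (~110 um oocyte, 50 um
inner-diameter pipette, 70 fps, 0.5 s analysis window, -0.1 p.s.i.
suction), constant-suction pressure traces, and patient-structured
cohorts whose usable-blastocyst label depends on the mechanical
parameters with a controllable effect size while fertilization is, by
default, independent of mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from .model import ZenerParams, ForceSpec, zener_depth
from .tracking import FrameStack, AspirationCurve

__all__ = [
    "SimulationConfig",
    "PressureTrace",
    "RenderGeometry",
    "generate_curve",
    "generate_pressure_trace",
    "render_frame_stack",
    "generate_cohort",
    "draw_params",
]

#: log-space medians of the mechanical parameters (SI); chosen so that
#: simulated curves span roughly 5-20 um over the 0.5 s window at the
#: default -0.1 p.s.i. suction through a 50 um pipette, with the creep
#: time constant (60 ms) well inside the window so the exponential
#: transient is resolved and the viscous drift is separable.
DEFAULT_PARAM_MEDIANS = {"k0": 0.08, "k1": 0.08, "eta0": 0.0024, "eta1": 0.25}
DEFAULT_PARAM_LOG_SD = 0.25


@dataclass(frozen=True)
class PressureTrace:
    """Instrument-convention pressure log: suction is negative p.s.i."""

    times: np.ndarray
    pressures: np.ndarray
    balance_pressure: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pressures, dtype=float)
        if t.size == 0 or t.shape != p.shape:
            raise ValueError("times and pressures must be non-empty and matched")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if not np.any(p < self.balance_pressure):
            raise ValueError("trace contains no suction below balance pressure")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pressures", p)

    def mean_suction_magnitude(self, t0: float, t1: float) -> float:
        """Mean suction magnitude (p.s.i.) over the clip window [t0, t1]."""
        sel = (self.times >= t0) & (self.times <= t1)
        if not sel.any():
            raise ValueError("no pressure samples inside the window")
        below = self.pressures[sel] - self.balance_pressure
        return float(-below[below < 0].mean()) if (below < 0).any() else 0.0


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort generator."""

    seed: int = 0
    n_patients: int = 68
    oocytes_per_patient: tuple[int, int] = (11, 25)  # inclusive range
    frame_rate: float = 70.0
    window: float = 0.5
    suction_psi: float = 0.1          # magnitude
    pipette_inner_diameter_um: float = 50.0
    noise_sd_um: float = 0.2
    class_effect: float = 1.5         # multiplicative usable-vs-unusable shift
    usable_fraction: float = 0.40
    fert_rate: float = 0.77
    day3_grade_a_rate: float = 0.45
    nonusable_blast_rate: float = 0.25
    measured_fraction: float = 0.5
    clinic_b_fraction: float = 22 / 68  # blastocyst-culture site share
    video_exclude_rate: float = 6 / 215
    age_range: tuple[float, float] = (21.0, 45.0)
    fert_depends_on_mechanics: bool = False
    param_medians: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_MEDIANS))
    param_log_sd: float = DEFAULT_PARAM_LOG_SD

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if isinstance(self.oocytes_per_patient, int):
            self.oocytes_per_patient = (self.oocytes_per_patient,
                                        self.oocytes_per_patient)
        if self.oocytes_per_patient[0] < 1:
            raise ValueError("oocytes_per_patient must be >= 1")
        for name in ("usable_fraction", "fert_rate", "day3_grade_a_rate",
                     "nonusable_blast_rate", "measured_fraction",
                     "clinic_b_fraction", "video_exclude_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd_um < 0:
            raise ValueError("noise_sd_um must be >= 0")
        if self.frame_rate <= 0 or self.window <= 0:
            raise ValueError("frame_rate and window must be > 0")

    @property
    def force_newtons(self) -> float:
        return ForceSpec(self.suction_psi, self.pipette_inner_diameter_um).F0


def generate_curve(params: ZenerParams, force: float, frame_rate: float = 70.0,
                   window: float = 0.5, noise_sd: float = 0.2,
                   seed: int = 0) -> AspirationCurve:
    """Sample the forward model on the frame grid and add tracking noise.

    Times run t = k/frame_rate for k = 0 .. floor(window*frame_rate); the
    t=0 sample is the instantaneous elastic jump F0/(k0+k1).  Noise is
    i.i.d. Gaussian on depth with standard deviation ``noise_sd`` (um),
    emulating sub-pixel tracking error.
    """
    if window <= 0 or frame_rate <= 0:
        raise ValueError("window and frame_rate must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = int(math.floor(window * frame_rate)) + 1
    times = np.arange(n) / frame_rate
    depths = zener_depth(times, params, force)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        depths = depths + rng.normal(0.0, noise_sd, size=n)
    return AspirationCurve(times=times, depths=depths)


def generate_pressure_trace(suction_psi: float = 0.1, balance: float = 0.0,
                            duration: float = 2.0, rate_hz: float = 70.0,
                            onset: float = 0.2) -> PressureTrace:
    """Constant-suction pressure log: balance before onset, then a step
    to ``balance - suction_psi`` held for the rest of the trace."""
    times = np.arange(int(duration * rate_hz) + 1) / rate_hz
    pressures = np.full_like(times, balance)
    pressures[times >= onset] = balance - suction_psi
    return PressureTrace(times=times, pressures=pressures, balance_pressure=balance)


@dataclass(frozen=True)
class RenderGeometry:
    """Pixel-space layout of the rendered aspiration scene."""

    image_shape: tuple[int, int] = (256, 420)
    um_per_px: float = 0.5
    oocyte_radius_um: float = 55.0
    zona_thickness_um: float = 15.0
    pipette_inner_diameter_um: float = 50.0
    wall_thickness_px: int = 4
    background: float = 0.12
    cytoplasm: float = 0.45
    zona: float = 0.92
    wall: float = 0.85


def render_frame_stack(curve: AspirationCurve, geometry: RenderGeometry | None = None,
                       n_pre_frames: int = 5, noise_sd: float = 0.02,
                       seed: int = 0):
    """Render a synthetic aspiration video for a depth curve.

    Each frame shows the oocyte body, its bright zona annulus, the
    horizontal pipette walls, and an aspirated tongue whose tip sits at
    the resting zona thickness plus the curve's depth for that frame
    (rounded to the nearest pixel).  ``n_pre_frames`` static frames at
    the resting position precede motion onset.

    Returns
    -------
    (stack, truth) where ``truth`` holds the per-frame tip positions in
    pixels from the tip plane, the onset index, and the pixel geometry.
    """
    geom = geometry or RenderGeometry()
    H, W = geom.image_shape
    scale = geom.um_per_px
    if scale <= 0:
        raise ValueError("um_per_px must be > 0")
    R_px = geom.oocyte_radius_um / scale
    zona_px = geom.zona_thickness_um / scale
    lumen_px = geom.pipette_inner_diameter_um / scale
    cy = H // 2
    tip_col = int(round(W - max(W // 8, 4) - 2 - (geom.zona_thickness_um +
                        float(np.max(curve.depths)) + 5.0) / scale))
    if tip_col - 2 * R_px < 0:
        raise ValueError("frame too small for the oocyte at this scale")
    cx = tip_col - R_px

    rest_px = int(round(zona_px))
    tips = np.concatenate([
        np.full(n_pre_frames, rest_px, dtype=int),
        np.round((geom.zona_thickness_um + np.asarray(curve.depths)) / scale).astype(int),
    ])
    max_run = W - max(W // 8, 4) - 2 - tip_col
    if tips.max() > max_run:
        raise ValueError("aspiration depth exceeds the rendered pipette length")

    yy, xx = np.mgrid[0:H, 0:W]
    rr = np.hypot(yy - cy, xx - cx)
    base = np.full((H, W), geom.background, dtype=np.float32)
    base[rr <= R_px] = geom.cytoplasm
    base[(rr <= R_px) & (rr >= R_px - zona_px)] = geom.zona
    half = int(round(lumen_px / 2))
    wt = geom.wall_thickness_px
    base[cy - half - wt:cy - half, tip_col:] = geom.wall   # upper wall
    base[cy + half:cy + half + wt, tip_col:] = geom.wall   # lower wall
    base[cy - half:cy + half, tip_col:] = geom.background  # lumen interior (2*half px)

    rng = np.random.default_rng(seed)
    frames = np.empty((tips.size, H, W), dtype=np.float32)
    tongue_rows = slice(cy - half + 3, cy + half - 3)
    for i, tip in enumerate(tips):
        f = base.copy()
        if tip > 0:
            f[tongue_rows, tip_col:tip_col + tip] = geom.zona
        if noise_sd > 0:
            f += rng.normal(0.0, noise_sd, size=f.shape).astype(np.float32)
        frames[i] = np.clip(f, 0.0, 1.0)

    stack = FrameStack(frames=frames, frame_rate=float(1.0 /
                       (curve.times[1] - curve.times[0])) if curve.times.size > 1
                       else 70.0, um_per_px=scale)
    truth = {
        "tip_positions_px": tips,
        "onset_index": n_pre_frames,
        "tip_col": tip_col,
        "lumen_px": 2 * half,
        "rest_px": rest_px,
        "um_per_px": scale,
    }
    return stack, truth


def draw_params(rng: np.random.Generator, usable: np.ndarray,
                medians: dict, log_sd: float, class_effect: float) -> pd.DataFrame:
    """Log-normal mechanical parameters with class-dependent location:
    usable oocytes have every parameter median multiplied by
    ``class_effect`` (stiffer and more viscous), unusable ones sit at the
    base medians.  ``class_effect = 1`` gives identical distributions."""
    n = usable.size
    shift = np.where(usable, math.log(class_effect), 0.0)
    cols = {}
    for name in ("k0", "k1", "eta0", "eta1"):
        mu = math.log(medians[name]) + shift
        cols[name] = np.exp(rng.normal(mu, log_sd, size=n))
    return pd.DataFrame(cols)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Patient-structured synthetic cohort mirroring a split-cohort
    aspiration safety study.

    One row per oocyte with columns: patient_id, clinic_id, oocyte_id,
    arm (measured/control), patient_age, mii_count, fertilized,
    day3_grade_a, blastocyst, usable_blastocyst, excluded (poor video
    quality, measured arm only) and, for measured oocytes, the
    ground-truth mechanical parameters true_k0 .. true_tau.

    The generative chain: a latent quality bit Q ~ Bernoulli(usable_fraction)
    drives both the mechanical parameters (via ``class_effect``) and
    blastocyst usability; fertilization is independent of Q by default;
    ``usable = fertilized & Q``; ``blastocyst = usable or
    (fertilized & Bernoulli(nonusable_blast_rate))`` so the label
    hierarchy usable => blastocyst => fertilized always holds.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.oocytes_per_patient
    n_oo = rng.integers(lo, hi + 1, size=cfg.n_patients)
    ages = rng.uniform(*cfg.age_range, size=cfg.n_patients)
    n_clinic_b = int(round(cfg.clinic_b_fraction * cfg.n_patients))
    clinic = np.array(["B"] * n_clinic_b + ["A"] * (cfg.n_patients - n_clinic_b))
    rng.shuffle(clinic)

    rows = []
    for p in range(cfg.n_patients):
        n = int(n_oo[p])
        rows.append(pd.DataFrame({
            "patient_id": f"P{p:03d}",
            "clinic_id": clinic[p],
            "oocyte_id": [f"P{p:03d}-O{i:02d}" for i in range(n)],
            "patient_age": round(float(ages[p]), 1),
            "mii_count": n,
        }))
    df = pd.concat(rows, ignore_index=True)
    n_total = len(df)

    # split-cohort arm assignment within each patient
    arm = np.empty(n_total, dtype=object)
    for pid, idx in df.groupby("patient_id").indices.items():
        idx = np.asarray(idx)
        k = int(round(cfg.measured_fraction * idx.size))
        chosen = rng.choice(idx, size=k, replace=False)
        arm[idx] = "control"
        arm[chosen] = "measured"
    df["arm"] = arm

    quality = rng.random(n_total) < cfg.usable_fraction
    if cfg.fert_depends_on_mechanics:
        p_fert = np.where(quality, min(1.0, cfg.fert_rate * 1.2), cfg.fert_rate * 0.8)
        fert = rng.random(n_total) < p_fert
    else:
        fert = rng.random(n_total) < cfg.fert_rate
    day3 = fert & (rng.random(n_total) < cfg.day3_grade_a_rate)
    usable = fert & quality
    blast = usable | (fert & (rng.random(n_total) < cfg.nonusable_blast_rate))

    df["fertilized"] = fert
    df["day3_grade_a"] = day3
    df["blastocyst"] = blast
    df["usable_blastocyst"] = usable

    measured = (df["arm"] == "measured").to_numpy()
    params = draw_params(rng, quality, cfg.param_medians, cfg.param_log_sd,
                         cfg.class_effect)
    for name in ("k0", "k1", "eta0", "eta1"):
        col = np.full(n_total, np.nan)
        col[measured] = params.loc[measured, name]
        df[f"true_{name}"] = col
    df["true_tau"] = df["true_eta0"] * (df["true_k0"] + df["true_k1"]) / (
        df["true_k0"] * df["true_k1"])
    df["excluded"] = measured & (rng.random(n_total) < cfg.video_exclude_rate)
    return df
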