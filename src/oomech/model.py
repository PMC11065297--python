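"""Modified Zener (standard linear solid + series dashpot) creep model.

A micropipette applies a constant suction force ``F0`` to the zona
pellucida and the aspirated tongue advances into the lumen.  The lumped
viscoelastic circuit used here has two springs (``k0``, ``k1``, N/m) and
two dashpots (``eta0``, ``eta1``, N·s/m); its creep response is an
instantaneous elastic jump, an exponential approach with time constant

    tau = eta0 * (k0 + k1) / (k0 * k1)

and a linear viscous drift:

    d(t) = (F0 / k1) * (1 - (k0 / (k0 + k1)) * exp(-t / tau)) + F0 * t / eta1

so that d(0) = F0 / (k0 + k1).  All mechanics are kept in SI internally;
depths are exposed in micrometers, matching how aspiration depths are
measured from video.

The model is fitted to a measured depth-vs-time curve by minimising the
sum of squared errors (SSE, um^2) with a quasi-Newton (BFGS) descent in
log-parameter space, which enforces positivity by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np
from scipy.optimize import minimize

PASCALS_PER_PSI = 6894.757
METERS_PER_MICROMETER = 1e-6
M_TO_UM = 1e6

# box constraints on each SI parameter during fitting
PARAM_LOWER = 1e-6
PARAM_UPPER = 1e3

__all__ = [
    "ForceSpec",
    "ZenerParams",
    "applied_force",
    "creep_time_constant",
    "zener_depth",
    "fit_zener",
    "FitDegenerateError",
]


class FitDegenerateError(ValueError):
    """Raised when a curve carries no deformation signal to fit."""


@dataclass(frozen=True)
class ForceSpec:
    """Suction force specification for a constant-pressure aspiration.

    Parameters
    ----------
    suction_magnitude : float
        Magnitude of the applied suction in p.s.i. (the instrument logs
        suction as negative pressure; the magnitude enters the force).
    inner_diameter_um : float
        Inner diameter of the micropipette in micrometers.
    """

    suction_magnitude: float
    inner_diameter_um: float

    def __post_init__(self) -> None:
        if self.suction_magnitude <= 0:
            raise ValueError("suction magnitude must be > 0 (p.s.i.)")
        if self.inner_diameter_um <= 0:
            raise ValueError("pipette inner diameter must be > 0 (um)")

    @property
    def F0(self) -> float:
        """Applied force in newtons: pressure times lumen cross-section."""
        radius_m = 0.5 * self.inner_diameter_um * METERS_PER_MICROMETER
        return self.suction_magnitude * PASCALS_PER_PSI * math.pi * radius_m**2


def applied_force(spec: ForceSpec) -> float:
    """Suction force F0 (newtons) produced by the pressure inside the lumen."""
    return spec.F0


def creep_time_constant(k0: float, k1: float, eta0: float) -> float:
    """Creep time constant tau = eta0*(k0+k1)/(k0*k1), seconds."""
    if k0 <= 0 or k1 <= 0 or eta0 <= 0:
        raise ValueError("k0, k1 and eta0 must all be > 0")
    return eta0 * (k0 + k1) / (k0 * k1)


@dataclass
class ZenerParams:
    """Mechanical parameters of the modified Zener model (SI units).

    ``k0``/``k1`` are the spring stiffnesses (N/m, solid-like behaviour:
    the instantaneous elongation), ``eta0``/``eta1`` the dashpot
    viscosities (N·s/m, liquid-like behaviour).  ``tau`` (s) is derived,
    never free.  ``sse`` (um^2) and ``converged`` are fit diagnostics.
    """

    k0: float
    k1: float
    eta0: float
    eta1: float
    sse: float = 0.0
    converged: bool = True
    n_iter: int = 0
    F0: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "eta0", "eta1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def tau(self) -> float:
        return creep_time_constant(self.k0, self.k1, self.eta0)

    def as_array(self) -> np.ndarray:
        return np.array([self.k0, self.k1, self.eta0, self.eta1])

    def as_dict(self) -> dict:
        return {
            "k0": self.k0,
            "k1": self.k1,
            "eta0": self.eta0,
            "eta1": self.eta1,
            "tau": self.tau,
            "sse": self.sse,
            "converged": self.converged,
            "F0": self.F0,
        }


def zener_depth(t, params: ZenerParams, F0: float):
    """Aspiration depth d(t) in micrometers under constant force F0 (N).

    d(t) = (F0/k1)(1 - (k0/(k0+k1)) e^{-t/tau}) + F0 t / eta1, converted
    from meters to micrometers.  Accepts scalar or array ``t`` (seconds,
    >= 0).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    k0, k1, eta0, eta1 = params.k0, params.k1, params.eta0, params.eta1
    tau = params.tau
    depth_m = (F0 / k1) * (1.0 - (k0 / (k0 + k1)) * np.exp(-t / tau)) + F0 * t / eta1
    out = depth_m * M_TO_UM
    return float(out) if out.ndim == 0 else out


def _sse(log_params: np.ndarray, times: np.ndarray, depths_um: np.ndarray, F0: float) -> float:
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        k0, k1, eta0, eta1 = np.exp(log_params)
        tau = eta0 * (k0 + k1) / (k0 * k1)
        model_um = ((F0 / k1) * (1.0 - (k0 / (k0 + k1)) * np.exp(-times / tau))
                    + F0 * times / eta1) * M_TO_UM
        r = model_um - depths_um
        out = float(r @ r)
    return out if math.isfinite(out) else 1e12  # reject runaway line-search steps


def _initial_guess(times: np.ndarray, depths_um: np.ndarray, F0: float,
                   window: float) -> np.ndarray:
    """Heuristic start: split the observed jump equally over the springs,
    put tau at a third of the window, and read eta1 off the tail slope."""
    d0_m = max(depths_um[0], 1e-3) * METERS_PER_MICROMETER
    k_sum = F0 / d0_m
    k0 = k1 = 0.5 * k_sum
    tau0 = max(window / 3.0, 1e-3)
    eta0 = tau0 * k0 * k1 / (k0 + k1)
    tail = slice(max(len(times) - 5, 0), None)
    if len(times) >= 3 and times[tail][-1] > times[tail][0]:
        slope_m = np.polyfit(times[tail], depths_um[tail] * METERS_PER_MICROMETER, 1)[0]
    else:
        slope_m = 0.0
    eta1 = F0 / slope_m if slope_m > 0 else 10.0 * eta0
    x0 = np.array([k0, k1, eta0, eta1])
    return np.log(np.clip(x0, PARAM_LOWER, PARAM_UPPER))


def fit_zener(curve, F0: float, init: ZenerParams | None = None,
              bounds: tuple[float, float] = (PARAM_LOWER, PARAM_UPPER),
              max_iter: int = 500, gtol: float = 1e-8) -> ZenerParams:
    """Fit the modified Zener model to an aspiration curve by SSE minimisation.

    Parameters
    ----------
    curve : AspirationCurve or (times, depths) pair
        Times in seconds (>= 5 samples), depths in micrometers.
    F0 : float
        Applied suction force in newtons (fixed, never fitted: scaling F0
        together with all four parameters leaves d(t) unchanged, so F0
        must be pinned for the parameters to be identifiable).
    init : ZenerParams, optional
        Starting point; by default a heuristic built from the observed
        instantaneous jump and tail slope.

    Returns
    -------
    ZenerParams with derived tau, final SSE (um^2) and a convergence flag.
    The returned SSE never exceeds the SSE at the initialisation.
    """
    if hasattr(curve, "times"):
        times = np.asarray(curve.times, dtype=float)
        depths = np.asarray(curve.depths, dtype=float)
    else:
        times, depths = (np.asarray(a, dtype=float) for a in curve)
    if times.shape != depths.shape or times.size < 5:
        raise ValueError("curve needs >= 5 matched (time, depth) samples")
    if F0 <= 0:
        raise ValueError("F0 must be > 0")
    if np.ptp(depths) < 1e-9 and abs(depths[0]) < 1e-9:
        raise FitDegenerateError("flat zero curve: no deformation to fit")

    lo, hi = bounds
    if init is not None:
        x0 = np.log(np.clip(init.as_array(), lo, hi))
    else:
        window = times[-1] - times[0] if times[-1] > times[0] else 0.5
        x0 = _initial_guess(times, depths, F0, window)

    sse0 = _sse(x0, times, depths, F0)
    res = minimize(_sse, x0, args=(times, depths, F0), method="BFGS",
                   options={"gtol": gtol, "maxiter": max_iter})
    # one polish pass helps BFGS escape finite-difference stalls
    res2 = minimize(_sse, res.x, args=(times, depths, F0), method="BFGS",
                    options={"gtol": gtol, "maxiter": max_iter})
    best = min((res, res2), key=lambda r: r.fun)
    x = np.clip(best.x, math.log(lo), math.log(hi))
    sse = _sse(x, times, depths, F0)
    if sse > sse0:  # never return worse than the start
        x, sse, success = x0, sse0, False
    else:
        # BFGS with finite-difference gradients routinely exits with a
        # precision-loss status at the optimum; a small gradient norm is
        # the meaningful convergence signal there
        gnorm = float(np.linalg.norm(best.jac)) if best.jac is not None else np.inf
        success = bool(res.success or res2.success or gnorm <= 1e-3 * (1.0 + sse))
    k0, k1, eta0, eta1 = np.exp(x)
    return ZenerParams(k0=k0, k1=k1, eta0=eta0, eta1=eta1, sse=sse,
                       converged=success, n_iter=int(res.nit + res2.nit), F0=F0)
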