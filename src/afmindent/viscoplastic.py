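"""Force-relaxation (Prony) analysis and Herschel-Bulkley parameter extraction.

During the constant-height hold the force relaxes as a two-exponential Prony
series ``F(t) = B0 + B1 exp(-t/tau1) + B2 exp(-t/tau2)``.  Dividing by the
contact area turns the force coefficients into hardness coefficients
``C_i = B_i / (pi a^2)``, giving the instantaneous hardness ``H0 = sum C_i``
and the long-term hardness ``Hinf = C0``.  Treating the relaxation as a
conversion of elastic into plastic strain at constant total strain yields a
plastic strain-rate series; pairing it with the mean stress
``sigma(t) = H(t) / psi`` produces a flow curve to which the Herschel-Bulkley
model ``sigma = sigma_Y + k rate**j`` is fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from afmindent.config import CalibrationConfig
from afmindent.core_io import IndentationCurve
from afmindent.exceptions import DataError, ParameterError

__all__ = [
    "PronyFit",
    "RelaxationResult",
    "HBResult",
    "fit_prony",
    "hardness_relaxation",
    "plastic_strain_rate",
    "stress_series",
    "fit_herschel_bulkley",
    "relaxation_to_hb",
    "analyze_relaxation",
]

#: multi-start relaxation-time initial guesses, seconds
PRONY_TAU_STARTS = ((0.05, 1.0), (0.1, 2.0), (0.5, 3.0))


@dataclass
class PronyFit:
    """Two-exponential Prony fit of a force-relaxation segment."""

    b0: float
    b1: float
    b2: float
    tau1: float
    tau2: float
    r_squared: float
    flags: list = field(default_factory=list)


@dataclass
class RelaxationResult:
    """Per-curve relaxation analysis: force and hardness coefficients."""

    curve_id: str
    b0: float
    b1: float
    b2: float
    tau1: float
    tau2: float
    c0: float
    c1: float
    c2: float
    h0: float  # Pa, instantaneous hardness
    h_inf: float  # Pa, long-term hardness
    r_squared: float
    a: float  # m, contact radius used
    flags: list = field(default_factory=list)


@dataclass
class HBResult:
    """Herschel-Bulkley viscoplastic parameters from one flow curve."""

    sigma_y: float  # Pa
    k: float  # Pa s^j
    j: float
    r_squared: float
    e_used: float | None = None  # Pa
    rate_min: float = np.nan  # 1/s
    rate_max: float = np.nan


def _prony_model(t, b0, b1, b2, tau1, tau2):
    return b0 + b1 * np.exp(-t / tau1) + b2 * np.exp(-t / tau2)


def fit_prony(time: np.ndarray, force: np.ndarray) -> PronyFit:
    """Fit ``F(t) = B0 + B1 e^{-t/tau1} + B2 e^{-t/tau2}`` to a hold segment.

    Time is restarted at the hold onset.  For each relaxation-time start the
    linear coefficients are solved by non-negative least squares, then all
    five parameters are refined with bounds ``B_i >= 0``, ``tau_i > 0``; the
    best residual wins and the times are returned ordered ``tau1 < tau2``.
    Terms with a relaxation time outside ``(dt/2, 5 dwell)`` are flagged
    unidentifiable.  A non-relaxing segment yields the degenerate
    ``B1 = B2 = 0`` fit with a warning rather than an error.
    """
    t = np.asarray(time, dtype=float)
    F = np.asarray(force, dtype=float)
    if t.size < 6:
        raise DataError(f"hold segment has {t.size} samples; need >= 6")
    t = t - t[0]
    dt = float(np.median(np.diff(t)))
    dwell = float(t[-1])
    if dwell < 5 * dt:
        raise DataError("hold duration shorter than 5 sampling intervals")

    F_span = float(np.abs(F).max()) or 1.0
    decay_slope = np.polyfit(t, F, 1)[0]
    if decay_slope * dwell >= -1e-9 * F_span:
        warnings.warn("no relaxation detected; returning degenerate Prony fit", stacklevel=2)
        b0 = float(np.mean(F))
        return PronyFit(b0, 0.0, 0.0, 0.1, 2.0, 0.0, flags=["degenerate"])

    F_scale = float(np.abs(F).max()) or 1.0
    Fn = F / F_scale
    best = None
    for tau1, tau2 in PRONY_TAU_STARTS:
        X = np.column_stack([np.ones_like(t), np.exp(-t / tau1), np.exp(-t / tau2)])
        b_init, _ = nnls(X, Fn)

        def resid(p):
            return _prony_model(t, *p) - Fn

        sol = least_squares(
            resid,
            x0=[max(b_init[0], 1e-9), max(b_init[1], 1e-9), max(b_init[2], 1e-9),
                tau1, tau2],
            bounds=([0, 0, 0, 1e-6, 1e-6], [np.inf] * 5),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            method="trf",
        )
        if best is None or sol.cost < best.cost:
            best = sol

    b0, b1, b2, tau1, tau2 = map(float, best.x)
    b0, b1, b2 = b0 * F_scale, b1 * F_scale, b2 * F_scale
    best_fun = best.fun * F_scale
    if tau1 > tau2:
        b1, b2, tau1, tau2 = b2, b1, tau2, tau1
    flags = []
    for name, tau, b in (("tau1", tau1, b1), ("tau2", tau2, b2)):
        if b > 0 and not (dt / 2 < tau < 5 * dwell):
            flags.append(f"{name}_unidentifiable")
    ss_res = float(np.sum(best_fun**2))
    ss_tot = float(np.sum((F - F.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PronyFit(b0, b1, b2, tau1, tau2, r2, flags=flags)


def hardness_relaxation(
    b0: float, b1: float, b2: float, a: float
) -> tuple[float, float, float, float, float]:
    """Convert force coefficients to hardness: ``C_i = B_i / (pi a^2)``.

    Returns ``(C0, C1, C2, H0, Hinf)`` with ``H0 = C0 + C1 + C2`` and
    ``Hinf = C0``.
    """
    if a <= 0:
        raise ParameterError("contact radius must be positive")
    area = np.pi * a**2
    c0, c1, c2 = b0 / area, b1 / area, b2 / area
    return c0, c1, c2, c0 + c1 + c2, c0


def plastic_strain_rate(c1: float, c2: float, tau1: float, tau2: float, E: float, t):
    """Uniaxial plastic strain rate during the hold.

    ``rate(t) = (3/E) (C1/tau1 e^{-t/tau1} + C2/tau2 e^{-t/tau2})`` — the
    elastic strain released by the relaxing mean stress (constraint factor 3)
    converted to plastic strain at constant total strain.
    """
    if E <= 0:
        raise ParameterError("E must be positive")
    t = np.asarray(t, dtype=float)
    rate = (3.0 / E) * (
        c1 / tau1 * np.exp(-t / tau1) + c2 / tau2 * np.exp(-t / tau2)
    )
    return float(rate) if rate.ndim == 0 else rate


def stress_series(c0: float, c1: float, c2: float, tau1: float, tau2: float, psi: float, t):
    """Uniaxial stress during the hold, ``sigma(t) = H(t) / psi``."""
    if psi <= 0:
        raise ParameterError("psi must be positive")
    t = np.asarray(t, dtype=float)
    sigma = (c0 + c1 * np.exp(-t / tau1) + c2 * np.exp(-t / tau2)) / psi
    return float(sigma) if sigma.ndim == 0 else sigma


def fit_herschel_bulkley(
    sigma: np.ndarray,
    rate: np.ndarray,
    j_fixed: float | None = None,
    sigma_y0: float | None = None,
) -> HBResult:
    """Fit ``sigma = sigma_Y + k rate**j`` to a flow curve.

    Bounded fit with ``sigma_Y >= 0``, ``k >= 0`` and ``j in (0.05, 1]``.
    ``j_fixed=1`` restricts to the Bingham form (closed-form linear
    regression).  Requires >= 20 points and at least one decade of strain
    rate (warns below 1.5 decades).
    """
    sigma = np.asarray(sigma, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if sigma.shape != rate.shape:
        raise ParameterError("sigma and rate must have matching shapes")
    ok = rate > 0
    sigma, rate = sigma[ok], rate[ok]
    if sigma.size < 20:
        raise ParameterError(f"need >= 20 (sigma, rate) pairs, have {sigma.size}")
    decades = float(np.log10(rate.max() / rate.min()))
    if decades < 1.0:
        raise ParameterError("insufficient rate coverage — extend dwell")
    if decades < 1.5:
        warnings.warn(f"rate range spans only {decades:.2f} decades (< 1.5)", stacklevel=2)

    if j_fixed is not None and abs(j_fixed - 1.0) < 1e-12:
        k, sy = np.polyfit(rate, sigma, 1)
        pred = sy + k * rate
        ss_res = float(np.sum((pred - sigma) ** 2))
        ss_tot = float(np.sum((sigma - sigma.mean()) ** 2))
        return HBResult(
            sigma_y=float(sy), k=float(k), j=1.0,
            r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
            rate_min=float(rate.min()), rate_max=float(rate.max()),
        )

    j0 = 0.3 if j_fixed is None else j_fixed
    sy0 = sigma_y0 if sigma_y0 is not None else max(0.9 * float(sigma.min()), 0.0)
    denom = rate.max() ** j0 - rate.min() ** j0
    k0 = max((float(sigma.max()) - float(sigma.min())) / denom, 1e-12) if denom > 0 else 1.0

    if j_fixed is not None:
        def resid(p):
            return p[0] + p[1] * rate**j_fixed - sigma

        sol = least_squares(resid, x0=[sy0, k0], bounds=([0, 0], [np.inf, np.inf]))
        sy, k, j = float(sol.x[0]), float(sol.x[1]), float(j_fixed)
    else:
        def resid(p):
            return p[0] + p[1] * rate ** p[2] - sigma

        sol = least_squares(
            resid,
            x0=[sy0, k0, j0],
            bounds=([0.0, 0.0, 0.05], [np.inf, np.inf, 1.0]),
            method="trf",
        )
        sy, k, j = map(float, sol.x)
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((sigma - sigma.mean()) ** 2))
    return HBResult(
        sigma_y=sy,
        k=k,
        j=j,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        rate_min=float(rate.min()),
        rate_max=float(rate.max()),
    )


def relaxation_to_hb(
    relax: RelaxationResult,
    E: float,
    psi: float = 3.0,
    dwell: float | None = None,
    dt: float | None = None,
    n_samples: int = 60,
) -> HBResult:
    """Build the flow curve implied by a relaxation fit and fit HB to it.

    Samples log-spaced times over ``(2 dt, dwell)`` (avoiding hold-onset
    transients), evaluates ``sigma(t)`` and the plastic strain rate on the
    same grid, and fits the Herschel-Bulkley model.
    """
    dwell = dwell if dwell is not None else 4.0
    dt = dt if dt is not None else dwell / 500.0
    t = np.geomspace(2.0 * dt, dwell, n_samples)
    sigma = stress_series(relax.c0, relax.c1, relax.c2, relax.tau1, relax.tau2, psi, t)
    rate = plastic_strain_rate(relax.c1, relax.c2, relax.tau1, relax.tau2, E, t)
    hb = fit_herschel_bulkley(sigma, rate, sigma_y0=relax.c0 / psi)
    hb.e_used = E
    return hb


def analyze_relaxation(
    curve: IndentationCurve,
    a: float,
    E: float,
    config: CalibrationConfig | None = None,
) -> tuple[RelaxationResult, HBResult | None]:
    """Prony + Herschel-Bulkley analysis of one curve's hold segment.

    ``a`` and ``E`` come from the same curve's unloading analysis.  The HB
    fit is only attempted when the Prony fit is accepted
    (R^2 >= ``config.hb_min_prony_r2`` and a genuinely relaxing signal).
    """
    config = config or CalibrationConfig()
    t, F = curve.pause()
    if "short_pause" in curve.flags:
        raise DataError(f"curve {curve.curve_id!r}: pause shorter than 90% of nominal dwell")
    prony = fit_prony(t, F)
    c0, c1, c2, h0, h_inf = hardness_relaxation(prony.b0, prony.b1, prony.b2, a)
    relax = RelaxationResult(
        curve_id=curve.curve_id,
        b0=prony.b0,
        b1=prony.b1,
        b2=prony.b2,
        tau1=prony.tau1,
        tau2=prony.tau2,
        c0=c0,
        c1=c1,
        c2=c2,
        h0=h0,
        h_inf=h_inf,
        r_squared=prony.r_squared,
        a=a,
        flags=list(prony.flags),
    )
    hb = None
    if (
        prony.r_squared >= config.hb_min_prony_r2
        and "degenerate" not in prony.flags
        and prony.b1 + prony.b2 > 0
    ):
        dt = float(np.median(np.diff(t))) if t.size > 1 else None
        dwell = float(t[-1] - t[0]) if t.size > 1 else None
        hb = relaxation_to_hb(relax, E, psi=config.psi, dwell=dwell, dt=dt)
    return relax, hb
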