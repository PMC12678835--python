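"""Per-curve elastoplastic analysis of unloading data.

The unloading branch of an elastoplastic indentation is purely elastic, so
the initial unloading stiffness together with the calibrated tip geometry
yields the Young's modulus ``E = (sqrt(pi)/2)(1 - nu^2) S0 / sqrt(A_max)``,
while the peak force over the contact area gives the hardness
``H = F_max / A_max`` and, through the constraint factor, a static yield
stress ``sigma_Y = H / psi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from afmindent.calibration import TipProfile, evaluate_tip
from afmindent.config import CalibrationConfig
from afmindent.core_io import IndentationCurve
from afmindent.exceptions import DataError, ParameterError

__all__ = [
    "UnloadingResult",
    "fit_unloading",
    "sink_in_depth",
    "contact_depth",
    "youngs_modulus",
    "hardness",
    "analyze_unloading",
]


@dataclass
class UnloadingResult:
    """Elastoplastic quantities extracted from one curve."""

    curve_id: str
    c_e: float  # N/m^2, quadratic unloading coefficient
    h_f: float  # m, residual depth
    s0: float  # N/m, initial unloading stiffness
    f_max: float  # N
    h_max: float  # m
    h_s: float  # m, sink-in depth
    h_c: float  # m, contact depth
    h_e: float  # m, elastic recovery h_max - h_f
    a: float  # m, contact radius at h_c
    area_max: float  # m^2
    E: float  # Pa
    H: float  # Pa
    sigma_bar: float  # Pa, mean contact stress (= H)
    sigma_y_static: float  # Pa, H / psi
    r_squared: float
    flags: list = field(default_factory=list)


def _quadratic_unloading_force(v: np.ndarray, c_e: float, k_c: float) -> np.ndarray:
    """Force at piezo coordinate ``v = (z - z0) - h_f``, closed form.

    Solving ``F = C_e (v - F/k_c)^2`` for F (physical root):
    ``F = [1 + 2 C_e v / k_c - sqrt(1 + 4 C_e v / k_c)] k_c^2 / (2 C_e)``.
    Reduces to ``C_e v^2`` as ``k_c -> inf``.
    """
    v = np.clip(v, 0.0, None)
    x = c_e * v / k_c
    return (1.0 + 2.0 * x - np.sqrt(1.0 + 4.0 * x)) * k_c**2 / (2.0 * c_e)


def fit_unloading(
    depth: np.ndarray,
    force: np.ndarray,
    fit_fraction: float = 0.8,
    depth_window: bool = False,
    k_c: float | None = None,
) -> tuple[float, float, float, float]:
    """Fit ``F = C_e (h - h_f)^2`` to the upper part of the unloading branch.

    The fit window keeps samples with ``F >= (1 - fit_fraction) F_max`` (or,
    with ``depth_window=True``, ``h >= h_f_est + (1 - fit_fraction) range``).
    A linear regression of ``sqrt(F)`` on ``h`` provides the exact solution
    for clean data and the starting point for a bounded refinement.

    When the spring constant ``k_c`` is given, the refinement is carried out
    in the noise-free piezo coordinate ``u = h + F/k_c``: the measured depth
    carries deflection noise anti-correlated with the force noise, which
    would otherwise bias the stiffness of contacts much stiffer than the
    cantilever.

    Returns ``(C_e, h_f, S0, r_squared)`` with
    ``S0 = 2 C_e (h_max - h_f)``.
    """
    if not 0 < fit_fraction <= 1:
        raise ParameterError("fit_fraction must lie in (0, 1]")
    h = np.asarray(depth, dtype=float)
    F = np.asarray(force, dtype=float)
    pos = F > 0
    h, F = h[pos], F[pos]
    if h.size < 10:
        raise DataError(f"only {h.size} positive-force unloading samples; need >= 10")
    f_max = float(F.max())
    h_max = float(h.max())
    if depth_window:
        h_lo = h.min() + (1.0 - fit_fraction) * (h.max() - h.min())
        win = h >= h_lo
    else:
        win = F >= (1.0 - fit_fraction) * f_max
    if win.sum() < 10:
        raise DataError(f"only {int(win.sum())} samples in the unloading fit window; need >= 10")
    # normalised coordinates: makes the fit independent of the caller's force
    # and length units (bit-level, up to rounding) and well-conditioned
    h_scale = h_max
    F_scale = f_max
    hw = h[win] / h_scale
    Fw = F[win] / F_scale
    kcn = k_c * h_scale / F_scale if k_c else None

    slope, intercept = np.polyfit(hw, np.sqrt(Fw), 1)
    if slope <= 0:
        raise DataError("unloading force not decreasing with decreasing depth")
    c_e0 = slope**2
    h_f0 = float(np.clip(-intercept / slope, 0.0, 1.0 - 1e-9))

    if kcn:
        uw = hw + Fw / kcn

        def resid(p):
            return _quadratic_unloading_force(uw - p[1], p[0], kcn) - Fw

    else:

        def resid(p):
            return p[0] * (hw - p[1]) ** 2 - Fw

    sol = least_squares(
        resid,
        x0=[c_e0, h_f0],
        bounds=([1e-30, 0.0], [np.inf, 1.0 - 1e-12]),
        x_scale=[max(c_e0, 1e-30), 1.0],
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        method="trf",
    )
    c_en, h_fn = map(float, sol.x)
    if h_fn >= 1.0:
        raise DataError("no residual depth: fitted h_f >= h_max")
    h_max_n = 1.0
    if kcn:
        # depth at peak from the fit, free of single-sample deflection noise
        u_max = float(uw.max())
        f_peak_n = float(_quadratic_unloading_force(np.array([u_max - h_fn]), c_en, kcn)[0])
        h_max_n = u_max - f_peak_n / kcn
    s0_n = 2.0 * c_en * (h_max_n - h_fn)
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((Fw - Fw.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    c_e = c_en * F_scale / h_scale**2
    h_f = h_fn * h_scale
    s0 = s0_n * F_scale / h_scale
    return c_e, h_f, s0, r2


def sink_in_depth(f_max: float, s0: float, phi: float = 0.73) -> float:
    """Elastic surface deflection at the contact perimeter, ``h_s = phi F_max / S0``."""
    if s0 <= 0:
        raise ParameterError("S0 must be positive")
    if phi < 0:
        raise ParameterError("phi must be non-negative")
    return phi * f_max / s0


def contact_depth(h_max: float, h_s: float) -> float:
    """``h_c = h_max - h_s``; errors when the sink-in exceeds the total depth."""
    if h_s > h_max:
        raise DataError("sink-in exceeds depth (degenerate unloading fit)")
    return h_max - h_s


def youngs_modulus(s0: float, area_max: float, nu: float) -> float:
    """``E = (sqrt(pi)/2) (1 - nu^2) S0 / sqrt(A_max)``.

    With ``A_max = pi a^2`` this is equivalent to ``E = (1 - nu^2) S0 / (2a)``.
    """
    if area_max <= 0:
        raise ParameterError("contact area must be positive")
    if not 0 <= nu < 0.5 + 1e-12:
        raise ParameterError("nu must lie in [0, 0.5]")
    return 0.5 * np.sqrt(np.pi) * (1.0 - nu**2) * s0 / np.sqrt(area_max)


def hardness(f_max: float, area_max: float, psi: float = 3.0) -> tuple[float, float]:
    """Hardness ``H = F_max / A_max`` and static yield stress ``H / psi``."""
    if area_max <= 0:
        raise ParameterError("contact area must be positive")
    if psi <= 0:
        raise ParameterError("psi must be positive")
    H = f_max / area_max
    return H, H / psi


def analyze_unloading(
    curve: IndentationCurve,
    tip: TipProfile,
    config: CalibrationConfig | None = None,
) -> UnloadingResult:
    """Full elastoplastic analysis of one indentation curve."""
    config = config or CalibrationConfig()
    h_ret, f_ret = curve.unloading(include_adhesive=False)
    if f_ret.size == 0:
        raise DataError(f"curve {curve.curve_id!r}: empty unloading segment")
    n_adhesive = int(np.count_nonzero(curve.adhesive))

    k_c = curve.metadata.get("spring_constant")
    c_e, h_f, s0, r2 = fit_unloading(
        h_ret, f_ret, config.unloading_fit_fraction, k_c=k_c
    )
    # unloading-start state from the smoothed fit rather than single noisy
    # samples
    if k_c:
        u_max = float((h_ret + f_ret / k_c)[f_ret > 0].max())
        f_unload = float(_quadratic_unloading_force(np.array([u_max - h_f]), c_e, k_c)[0])
        h_unload = u_max - f_unload / k_c
    else:
        h_unload = float(h_ret[f_ret > 0].max())
        f_unload = float(c_e * (h_unload - h_f) ** 2)

    # the contact geometry is set at the force peak (end of loading): during a
    # constant-height hold the depth creeps on while the contact radius stays
    # put, so h_max/F_max are taken at maximum force, as in the unloading
    # analysis convention
    app = curve.seg_mask("approach")
    if np.count_nonzero(app) >= 10:
        h_app, f_app = curve.depth[app], curve.force[app]
        if k_c:
            # evaluate at the trigger via a short local fit in the noise-free
            # piezo coordinate, so single-sample noise does not leak into the
            # peak state
            u_app = (h_app + f_app / k_c)[-10:]
            coef = np.polyfit(u_app, f_app[-10:], 1)
            f_peak = float(np.polyval(coef, u_app[-1]))
            h_peak = float(u_app[-1] - f_peak / k_c)
        else:
            f_peak = float(f_app[-1])
            h_peak = float(h_app[-1])
    else:
        f_peak, h_peak = f_unload, h_unload
    f_peak = max(f_peak, f_unload)
    h_max = h_peak
    f_max = f_peak

    h_s = sink_in_depth(f_max, s0, config.phi)
    h_c = contact_depth(h_max, h_s)

    flags: list[str] = list(curve.flags)
    if n_adhesive:
        flags.append("adhesive_excluded")
    if h_c <= 0:
        flags.append("zero_contact_depth")
        h_c = max(h_c, 0.0)
    a = float(evaluate_tip(tip, h_c, warn_extrapolation=False))
    if tip.extrapolated(h_c):
        flags.append("tip_extrapolated")
    area = np.pi * a**2
    E = youngs_modulus(s0, area, config.nu_sample)
    H, sigma_y = hardness(f_peak, area, config.psi)

    thickness = curve.metadata.get("thickness")
    if thickness and float(curve.depth.max()) > config.thickness_fraction_limit * thickness:
        flags.append("depth_exceeds_thickness_limit")

    return UnloadingResult(
        curve_id=curve.curve_id,
        c_e=c_e,
        h_f=h_f,
        s0=s0,
        f_max=f_max,
        h_max=h_max,
        h_s=h_s,
        h_c=h_c,
        h_e=h_unload - h_f,
        a=a,
        area_max=area,
        E=E,
        H=H,
        sigma_bar=H,
        sigma_y_static=sigma_y,
        r_squared=r2,
        flags=flags,
    )
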