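"""Effective indenter geometry from loading curves on an elastic reference.

For a rigid axisymmetric indenter on a linear-elastic half-space the contact
stiffness is ``S = dF/dh = 2 E* a``, so a smoothed, averaged loading curve on
a reference of known plane-strain modulus yields the contact radius as a
function of depth.  Describing the local tip shape as a power law
``h_c = c * a**n`` links the load index ``m`` of ``F ~ h**m`` to the profile
index via ``n = 1/(m - 1)`` and gives the depth scaling
``h = kappa(n) * h_c`` with ``kappa = sqrt(pi) * Gamma((n+2)/2) / Gamma((n+1)/2)``.
Combining both produces the tip radius function ``a(h_c)``, summarised as a
polynomial over its reliable range plus a power-law cap near the apex.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from afmindent.config import CalibrationConfig
from afmindent.core_io import IndentationCurve
from afmindent.exceptions import DataError, GeometryError, ParameterError
from afmindent.units import c_si_to_um

__all__ = [
    "TipProfile",
    "ElasticCalibrationResult",
    "PolyLoad",
    "average_loading_curves",
    "smooth_load_curve",
    "contact_radius_profile",
    "load_index_profile",
    "load_index_windowed",
    "profile_index",
    "load_index_from_profile_index",
    "depth_scaling_kappa",
    "contact_depth_map",
    "fit_tip_profile",
    "evaluate_tip",
    "calibrate_tip",
]


# ---------------------------------------------------------------------------
# scalar relations
# ---------------------------------------------------------------------------


def profile_index(m):
    """Profile index ``n = 1 / (m - 1)`` from the load index ``m``.

    Undefined at or below linear loading (``m <= 1``).
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 1.0):
        raise ParameterError("profile index undefined at/below linear loading (m <= 1)")
    n = 1.0 / (m - 1.0)
    return float(n) if n.ndim == 0 else n


def load_index_from_profile_index(n):
    """Inverse of :func:`profile_index`: ``m = 1 + 1/n``."""
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0.0):
        raise ParameterError("profile index must be positive")
    m = 1.0 + 1.0 / n
    return float(m) if m.ndim == 0 else m


def depth_scaling_kappa(n):
    """Depth scaling ``kappa = sqrt(pi) * Gamma((n+2)/2) / Gamma((n+1)/2)``.

    ``h = kappa * h_c`` for a power-law indenter profile of index ``n``;
    ``kappa(2) = 2`` (paraboloid) and ``kappa(1) = pi/2`` (cone).
    """
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0.0):
        raise ParameterError("profile index must be positive")
    k = np.sqrt(np.pi) * np.exp(gammaln((n + 2.0) / 2.0) - gammaln((n + 1.0) / 2.0))
    return float(k) if k.ndim == 0 else k


def contact_depth_map(h, n):
    """Pointwise ``h_c = h / kappa(n)`` using the local profile index."""
    h = np.asarray(h, dtype=float)
    hc = h / depth_scaling_kappa(n)
    return float(hc) if hc.ndim == 0 else hc


def contact_radius_profile(S, e_star):
    """Contact radius ``a = S / (2 E*)`` from the stiffness profile."""
    if e_star <= 0:
        raise ParameterError("e_star must be positive")
    S = np.asarray(S, dtype=float)
    a = S / (2.0 * e_star)
    return float(a) if a.ndim == 0 else a


# ---------------------------------------------------------------------------
# loading-curve smoothing
# ---------------------------------------------------------------------------


def average_loading_curves(
    curves: list[IndentationCurve] | list[tuple[np.ndarray, np.ndarray]],
    depth_grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pointwise mean loading force on a common depth grid.

    Curves whose maximum depth is below 50% of the grid maximum are excluded
    with a warning; at least 3 curves must survive.  Returns
    ``(mean_force, sd_force, n_used)``.
    """
    depth_grid = np.asarray(depth_grid, dtype=float)
    stacks = []
    excluded = 0
    for curve in curves:
        if isinstance(curve, IndentationCurve):
            h, F = curve.loading()
        else:
            h, F = curve
        h = np.asarray(h, float)
        F = np.asarray(F, float)
        if h.size == 0 or h.max() < 0.5 * depth_grid.max():
            excluded += 1
            continue
        order = np.argsort(h)
        stacks.append(np.interp(depth_grid, h[order], F[order]))
    if excluded:
        warnings.warn(f"{excluded} curve(s) excluded: max depth < 50% of grid", stacklevel=2)
    if len(stacks) < 3:
        raise DataError(
            f"need >= 3 usable curves covering the depth grid, have {len(stacks)}"
        )
    arr = np.vstack(stacks)
    return arr.mean(axis=0), arr.std(axis=0, ddof=0), len(stacks)


@dataclass
class PolyLoad:
    """Zero-intercept polynomial fit of a loading curve, SI coefficients.

    ``force(h) = sum_k coeffs[k-1] * h**k`` for ``k = 1..order``.
    """

    coeffs: np.ndarray  # ascending powers 1..order
    order: int
    residual_sd: float
    h_max: float

    def force(self, h):
        h = np.asarray(h, dtype=float)
        out = np.zeros_like(h)
        for k, c in enumerate(self.coeffs, start=1):
            out = out + c * h**k
        return out

    def stiffness(self, h):
        h = np.asarray(h, dtype=float)
        out = np.zeros_like(h)
        for k, c in enumerate(self.coeffs, start=1):
            out = out + k * c * h ** (k - 1)
        return out

    def load_index(self, h):
        """Local log-log slope ``m(h) = h F'(h) / F(h)``."""
        h = np.asarray(h, dtype=float)
        F = self.force(h)
        if np.any(F <= 0):
            raise DataError("smoothed force non-positive at evaluation points")
        return h * self.stiffness(h) / F


def smooth_load_curve(
    depth: np.ndarray,
    force: np.ndarray,
    order: int = 6,
    relative_weight: bool = True,
    weight_floor_fraction: float = 0.05,
) -> PolyLoad:
    """Fit ``F(h) = p1 h + ... + p_order h**order`` (zero intercept enforced).

    The fit runs in scaled units for conditioning.  With
    ``relative_weight=True`` residuals are weighted by ``1/max(F, floor)`` so
    the shallow-depth part of the curve — which controls the near-apex tip
    geometry — is fitted in relative rather than absolute terms.
    """
    if order < 2:
        raise ParameterError("smoothing order must be >= 2 (order 1 cannot represent curvature)")
    h = np.asarray(depth, dtype=float)
    F = np.asarray(force, dtype=float)
    pos = h > 0
    h, F = h[pos], F[pos]
    if h.size <= order + 2:
        raise DataError("too few samples for the requested smoothing order")
    h_scale = float(h.max())
    F_scale = float(np.abs(F).max())
    hs = h / h_scale
    Fs = F / F_scale
    X = np.column_stack([hs**k for k in range(1, order + 1)])
    if relative_weight:
        w = 1.0 / np.maximum(np.abs(Fs), weight_floor_fraction)
    else:
        w = np.ones_like(Fs)
    Xw = X * w[:, None]
    cond = np.linalg.cond(Xw)
    if cond > 1e12:
        raise ParameterError(
            f"polynomial fit ill-conditioned (cond={cond:.2g}); rescale data to nm/nN"
        )
    beta, *_ = np.linalg.lstsq(Xw, Fs * w, rcond=None)
    resid = (X @ beta - Fs) * F_scale
    coeffs = beta * F_scale / h_scale ** np.arange(1, order + 1)
    return PolyLoad(
        coeffs=coeffs,
        order=order,
        residual_sd=float(np.std(resid, ddof=min(order, resid.size - 1))),
        h_max=float(h.max()),
    )


def load_index_profile(poly: PolyLoad, h) -> np.ndarray:
    """Local load index ``m(h)`` from a smoothed loading polynomial."""
    return poly.load_index(h)


def load_index_windowed(depth, force, centers, window_factor: float = 0.3) -> np.ndarray:
    """Windowed log-log power-law alternative to :func:`load_index_profile`.

    For each center depth, regress ``ln F`` on ``ln h`` over
    ``[h*(1-w), h*(1+w)]``.  Offered for cross-checking the polynomial route.
    """
    h = np.asarray(depth, float)
    F = np.asarray(force, float)
    out = np.full(len(np.atleast_1d(centers)), np.nan)
    for i, hc in enumerate(np.atleast_1d(centers)):
        sel = (h >= hc * (1 - window_factor)) & (h <= hc * (1 + window_factor)) & (F > 0) & (h > 0)
        if sel.sum() >= 5:
            slope, _ = np.polyfit(np.log(h[sel]), np.log(F[sel]), 1)
            out[i] = slope
    return out


# ---------------------------------------------------------------------------
# tip profile
# ---------------------------------------------------------------------------


@dataclass
class TipProfile:
    """Effective axisymmetric indenter geometry.

    A degree-``len(poly_coeffs)-1`` polynomial ``a(h_c)`` (SI, ascending
    powers from ``d0``) over ``[h_c_min, h_c_max]`` plus a power-law cap
    ``a = (h_c / cap_c)**(1/cap_n)`` used below ``cap_limit``.
    """

    poly_coeffs: np.ndarray
    cap_c: float
    cap_n: float
    cap_limit: float
    h_c_min: float
    h_c_max: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.poly_coeffs = np.asarray(self.poly_coeffs, dtype=float)
        if self.cap_n <= 0 or self.cap_c <= 0:
            raise GeometryError("cap parameters must be positive")

    def _poly(self, h_c):
        out = np.zeros_like(h_c)
        for k, d in enumerate(self.poly_coeffs):
            out = out + d * h_c**k
        return out

    def radius(self, h_c, warn_extrapolation: bool = True):
        """Contact radius a(h_c); see :func:`evaluate_tip`."""
        h_c = np.asarray(h_c, dtype=float)
        scalar = h_c.ndim == 0
        h_c = np.atleast_1d(h_c)
        if np.any(h_c < 0):
            raise ParameterError("h_c must be >= 0")
        a = np.empty_like(h_c)
        cap = h_c < self.cap_limit
        a[cap] = (h_c[cap] / self.cap_c) ** (1.0 / self.cap_n)
        a[~cap] = self._poly(h_c[~cap])
        if warn_extrapolation and np.any(h_c > self.h_c_max):
            warnings.warn(
                f"tip evaluated beyond calibrated range (h_c_max={self.h_c_max:.3g} m)",
                stacklevel=2,
            )
        return float(a[0]) if scalar else a

    def extrapolated(self, h_c):
        """Boolean mask: evaluation outside the calibrated validity range."""
        h_c = np.asarray(h_c, dtype=float)
        out = h_c > self.h_c_max
        return bool(out) if out.ndim == 0 else out

    @classmethod
    def from_power_law(cls, c: float, n: float, h_c_max: float = 1.0) -> "TipProfile":
        """Pure power-law tip ``h_c = c a**n`` (cap everywhere); for testing."""
        return cls(
            poly_coeffs=np.zeros(7),
            cap_c=c,
            cap_n=n,
            cap_limit=np.inf,
            h_c_min=0.0,
            h_c_max=h_c_max,
        )

    @classmethod
    def from_polynomial(
        cls, coeffs, h_c_min: float, h_c_max: float, cap_limit: float = 0.0
    ) -> "TipProfile":
        """Polynomial tip with a cap spliced on at ``cap_limit`` (0 disables)."""
        coeffs = np.asarray(coeffs, dtype=float)
        if cap_limit > 0:
            a_s = float(np.polyval(coeffs[::-1], cap_limit))
            da = float(np.polyval(np.polyder(coeffs[::-1]), cap_limit))
            if a_s <= 0 or da <= 0:
                raise GeometryError("polynomial not increasing at splice point")
            n_cap = a_s / (cap_limit * da)
            c_cap = cap_limit / a_s**n_cap
        else:
            n_cap, c_cap, cap_limit = 1.0, 1.0, 0.0
        return cls(
            poly_coeffs=coeffs,
            cap_c=c_cap,
            cap_n=n_cap,
            cap_limit=cap_limit,
            h_c_min=h_c_min,
            h_c_max=h_c_max,
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "poly_coeffs_si": list(map(float, self.poly_coeffs)),
            "cap_c_si": float(self.cap_c),
            "cap_n": float(self.cap_n),
            "cap_c_um_convention": (
                None if not np.isfinite(self.cap_c) else c_si_to_um(self.cap_c, self.cap_n)
            ),
            "cap_limit_m": float(self.cap_limit),
            "h_c_min_m": float(self.h_c_min),
            "h_c_max_m": float(self.h_c_max),
            "diagnostics": {
                k: (float(v) if np.isscalar(v) else v) for k, v in self.diagnostics.items()
            },
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TipProfile":
        d = json.loads(Path(path).read_text())
        return cls(
            poly_coeffs=np.asarray(d["poly_coeffs_si"], dtype=float),
            cap_c=d["cap_c_si"],
            cap_n=d["cap_n"],
            cap_limit=d["cap_limit_m"],
            h_c_min=d["h_c_min_m"],
            h_c_max=d["h_c_max_m"],
            diagnostics=d.get("diagnostics", {}),
        )


def evaluate_tip(tip: TipProfile, h_c, warn_extrapolation: bool = True):
    """Contact radius ``a`` at contact depth ``h_c``.

    The power-law cap applies below the splice point and the polynomial
    above; evaluation beyond ``h_c_max`` returns the extrapolated value with
    a warning.
    """
    return tip.radius(h_c, warn_extrapolation=warn_extrapolation)


def power_law_cap(
    depth: np.ndarray,
    force: np.ndarray,
    e_star: float,
    window: float,
    offset_bound: float = 0.0,
    delta_bound: float = 2e-9,
) -> tuple[float, float]:
    """Near-apex power-law tip parameters from the initial contact region.

    Fits ``F = b (h - delta)**m`` over ``0 < h <= window``: the free depth
    offset ``delta`` absorbs residual contact-point error, to which the
    power-law exponent is extremely sensitive at shallow depth.  The load
    coefficient is then inverted via
    ``b = 2 E* n/(n+1) (kappa c)**(-1/n)`` with ``n = 1/(m-1)``.
    Exact for a pure power-law tip.

    ``delta_bound`` limits the depth offset to the scale of residual
    contact-detection error (an unbounded offset trades against the exponent
    under noise).  ``offset_bound > 0`` adds a force-offset parameter bounded
    by that value (newtons); at 0 the force offset is fixed to zero.
    """
    from scipy.optimize import least_squares

    h = np.asarray(depth, dtype=float)
    F = np.asarray(force, dtype=float)
    # drop the shallowest slice: interpolation error and noise dominate there
    sel = (h > 0.05 * window) & (h <= window) & (F > 0)
    if sel.sum() < 8:
        raise DataError("too few samples in the cap fit window")
    hs, Fs = h[sel], F[sel]
    F_scale = float(Fs.max())
    m0, ln_b0 = np.polyfit(np.log(hs), np.log(Fs), 1)
    m0 = float(np.clip(m0, 1.01, 4.99))
    h_lo = float(hs.min())

    d_hi = min(delta_bound, 0.9 * h_lo)
    d_scale = max(min(delta_bound, h_lo), 1e-10)
    tol = dict(xtol=1e-15, ftol=1e-15, gtol=1e-15, method="trf")
    if offset_bound > 0:

        def resid4(p):
            ln_b, m, delta, eps = p
            return (np.exp(ln_b + m * np.log(hs - delta)) + eps - Fs) / F_scale

        sol = least_squares(
            resid4,
            x0=[ln_b0, m0, 0.0, 0.0],
            bounds=(
                [-np.inf, 1.0 + 1e-6, -delta_bound, -offset_bound],
                [np.inf, 5.0, d_hi, offset_bound],
            ),
            x_scale=[1.0, 0.1, d_scale, offset_bound],
            **tol,
        )
    else:

        def resid3(p):
            ln_b, m, delta = p
            return (np.exp(ln_b + m * np.log(hs - delta)) - Fs) / F_scale

        sol = least_squares(
            resid3,
            x0=[ln_b0, m0, 0.0],
            bounds=([-np.inf, 1.0 + 1e-6, -delta_bound], [np.inf, 5.0, d_hi]),
            x_scale=[1.0, 0.1, d_scale],
            **tol,
        )
    ln_b, m = float(sol.x[0]), float(sol.x[1])
    if not 1.0 < m < 5.0:
        raise DataError(f"cap load index {m:.3f} outside (1, 5)")
    b = float(np.exp(ln_b))
    n = profile_index(m)
    c = (2.0 * e_star * n / (b * (n + 1.0))) ** n / depth_scaling_kappa(n)
    return float(c), float(n)


def fit_tip_profile(
    a: np.ndarray,
    h_c: np.ndarray,
    config: CalibrationConfig | None = None,
    cap: tuple[float, float] | None = None,
) -> TipProfile:
    """Fit the tip radius function from (contact depth, contact radius) points.

    A degree-``config.tip_poly_degree`` polynomial is fitted over
    ``config.h_c_fit_range`` (in nm-scaled coordinates for conditioning).
    The power-law cap used below ``config.h_c_cap_limit`` is, in order of
    preference: the explicit ``cap=(c, n)`` pair (e.g. from
    :func:`power_law_cap`), a log-log fit anchored on the points below the
    cap limit, or the polynomial's value and local exponent at the splice
    point.
    """
    config = config or CalibrationConfig()
    a = np.asarray(a, dtype=float)
    h_c = np.asarray(h_c, dtype=float)
    if a.shape != h_c.shape:
        raise ParameterError("a and h_c must have matching shapes")
    lo, hi = config.h_c_fit_range
    sel = (h_c >= lo) & (h_c <= hi) & (a > 0)
    if sel.sum() < 20:
        raise DataError(
            f"only {int(sel.sum())} (h_c, a) points inside the fit range; need >= 20"
        )
    # the polynomial is only trusted where there are points: the splice to the
    # power-law cap moves up when the shallow region was unrecoverable
    splice = max(config.h_c_cap_limit, float(h_c[sel].min()))
    lo_valid = min(splice, lo)
    hi = min(hi, float(h_c[sel].max()))  # do not claim validity beyond the data
    if splice > config.h_c_cap_limit:
        warnings.warn(
            f"no contact-radius points below {splice:.3g} m; cap region extended",
            stacklevel=2,
        )

    # fit in nm coordinates; if the polynomial comes out non-monotone (noisy
    # stiffness at depth), shrink the fit range from the top and retry
    coeffs = None
    for _ in range(5):
        sel = (h_c >= lo) & (h_c <= hi) & (a > 0)
        if sel.sum() < 20:
            break
        x = h_c[sel] / 1e-9
        y = a[sel] / 1e-9
        series = np.polynomial.Polynomial.fit(x, y, deg=config.tip_poly_degree).convert()
        coeffs_nm = series.coef
        if coeffs_nm.size < config.tip_poly_degree + 1:
            coeffs_nm = np.pad(coeffs_nm, (0, config.tip_poly_degree + 1 - coeffs_nm.size))
        # back to SI: a[m] = sum d_k h_c[m]**k
        trial = coeffs_nm * 1e-9 / (1e-9) ** np.arange(coeffs_nm.size)
        dense = np.linspace(splice, hi, 1000)
        a_dense = np.polyval(trial[::-1], dense)
        if np.all(np.diff(a_dense) > 0) and np.all(a_dense > 0):
            coeffs = trial
            break
        hi *= 0.85
        warnings.warn(
            f"fitted a(h_c) non-monotone; shrinking fit range to {hi:.3g} m", stacklevel=2
        )
    if coeffs is None:
        raise GeometryError(
            "fitted a(h_c) not positive and increasing over the validity range; "
            "reduce the fit range"
        )

    cap_pts = (h_c > 0) & (h_c < splice) & (a > 0)
    if cap is not None:
        c_cap, n_cap = cap
        if c_cap <= 0 or n_cap <= 0:
            raise GeometryError("cap parameters must be positive")
    elif cap_pts.sum() >= 5:
        # anchor the cap on the near-apex points: ln h_c = ln c + n ln a
        n_cap, ln_c = np.polyfit(np.log(a[cap_pts]), np.log(h_c[cap_pts]), 1)
        if n_cap <= 0:
            raise GeometryError("cap fit produced non-increasing profile")
        c_cap = float(np.exp(ln_c))
    else:
        a_s = float(np.polyval(coeffs[::-1], splice))
        da = float(np.polyval(np.polyder(coeffs[::-1]), splice))
        if a_s <= 0 or da <= 0:
            raise GeometryError("polynomial not increasing at the cap splice point")
        n_cap = a_s / (splice * da)
        c_cap = splice / a_s**n_cap

    a_cap_splice = (splice / c_cap) ** (1.0 / n_cap)
    a_poly_splice = float(np.polyval(coeffs[::-1], splice))
    mismatch = abs(a_cap_splice - a_poly_splice) / a_poly_splice
    if mismatch > 0.05:
        warnings.warn(
            f"cap/polynomial splice mismatch {mismatch:.1%} exceeds 5%", stacklevel=2
        )

    resid = np.polyval(coeffs[::-1], h_c[sel]) - a[sel]
    return TipProfile(
        poly_coeffs=coeffs,
        cap_c=c_cap,
        cap_n=float(n_cap),
        cap_limit=splice,
        h_c_min=lo_valid,
        h_c_max=hi,
        diagnostics={
            "residual_sd_m": float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0,
            "n_points": int(sel.sum()),
            "n_cap_points": int(cap_pts.sum()),
            "splice_mismatch": float(mismatch),
        },
    )


# ---------------------------------------------------------------------------
# full calibration chain
# ---------------------------------------------------------------------------


@dataclass
class ElasticCalibrationResult:
    """Intermediate and final products of the tip calibration chain."""

    depth: np.ndarray
    force_mean: np.ndarray
    force_sd: np.ndarray
    n_curves: int
    poly: PolyLoad
    stiffness: np.ndarray
    contact_radius: np.ndarray
    load_index: np.ndarray
    profile_index: np.ndarray
    kappa: np.ndarray
    contact_depth: np.ndarray
    tip: TipProfile


def calibrate_tip(
    curves,
    config: CalibrationConfig | None = None,
    n_grid: int = 800,
) -> ElasticCalibrationResult:
    """Run the full calibration chain on reference loading curves.

    average -> polynomial smoothing -> stiffness -> contact radius (S/2E*)
    -> local load index -> profile index -> kappa -> contact depth -> tip fit.
    """
    config = config or CalibrationConfig()
    h_maxes = []
    for c in curves:
        h, _ = c.loading() if isinstance(c, IndentationCurve) else c
        if len(h):
            h_maxes.append(np.max(h))
    if not h_maxes:
        raise DataError("no loading data in supplied curves")
    grid = np.linspace(0.0, float(np.median(h_maxes)), n_grid + 1)[1:]
    F_mean, F_sd, n_used = average_loading_curves(curves, grid)
    poly = smooth_load_curve(grid, F_mean, order=config.smoothing_order)

    # evaluate away from the very apex where the polynomial ratio degenerates
    h_eval = grid[grid >= 0.005 * grid.max()]
    S = poly.stiffness(h_eval)
    Fhat = poly.force(h_eval)
    ok = (S > 0) & (Fhat > 0)
    m = np.full(h_eval.shape, np.nan)
    m[ok] = h_eval[ok] * S[ok] / Fhat[ok]
    in_band = ok & (m > 1.0 + 1e-6) & (m < 3.0)
    if not np.all(in_band[ok]):
        warnings.warn(
            f"{int(np.count_nonzero(ok) - np.count_nonzero(in_band))} depth points "
            "with load index outside (1, 3) excluded",
            stacklevel=2,
        )
    h_eval = h_eval[in_band]
    S = S[in_band]
    m = m[in_band]
    a = contact_radius_profile(S, config.e_star_ref)
    n = profile_index(m)
    kappa = depth_scaling_kappa(n)
    h_c = h_eval / kappa
    # cap fitted on the full averaged curve: the free-offset power-law fit is
    # exact for power-law tips and, for general tips, still anchors the
    # near-apex region far more stably than the noise-dominated shallow data
    try:
        cap = power_law_cap(grid, F_mean, config.e_star_ref, float(grid.max()))
    except DataError:
        cap = None  # fall back to the point-anchored cap
    tip = fit_tip_profile(a, h_c, config, cap=cap)
    return ElasticCalibrationResult(
        depth=h_eval,
        force_mean=poly.force(h_eval),
        force_sd=np.interp(h_eval, grid, F_sd),
        n_curves=n_used,
        poly=poly,
        stiffness=S,
        contact_radius=a,
        load_index=m,
        profile_index=n,
        kappa=kappa,
        contact_depth=h_c,
        tip=tip,
    )
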