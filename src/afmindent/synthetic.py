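"""Forward simulator for force curves.

Generates (a) linear-elastic loading/unloading curves on a reference material
for a known axisymmetric tip, (b) elastoplastic cell curves with hysteresis
and residual depth, (c) two-exponential force relaxation during the hold, and
(d) full grid datasets (participants x cells x curves) written in the core_io
TSV dialect with a ground-truth sidecar, so every downstream analysis stage
is testable without instrument data.

The elastoplastic loading branch is the minimal model consistent with the
analysis equations: fully yielded contact ``F = pi a^2 H`` with elastic
sink-in ``h = h_c + phi F / S`` where ``S = 2 E* a``; unloading follows the
quadratic ``F = C_e (h - h_f)^2`` whose initial slope is the elastic
stiffness ``S0 = 2 E* a_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from afmindent.calibration import depth_scaling_kappa
from afmindent.core_io import ForceCurve, IndentationCurve, write_force_curve
from afmindent.exceptions import GeometryError, ParameterError

__all__ = [
    "MaterialTruth",
    "IndenterTruth",
    "power_law_elastic_force",
    "sneddon_elastic_curve",
    "elastic_reference_curve",
    "elastoplastic_state",
    "elastoplastic_curve",
    "relaxation_curve",
    "derive_hb_truth",
    "generate_dataset",
    "DEFAULT_TIP_TRUTH",
    "DEFAULT_PARTICIPANTS",
]


# ---------------------------------------------------------------------------
# ground-truth descriptions
# ---------------------------------------------------------------------------


@dataclass
class MaterialTruth:
    """Ground-truth constitutive parameters for one simulated material."""

    behaviour: str  # elastic | elastoplastic | viscoplastic
    E: float  # Pa
    nu: float = 0.4
    H: float | None = None  # Pa, elastoplastic hardness
    C0: float = 0.0  # Pa, Prony hardness coefficients
    C1: float = 0.0
    C2: float = 0.0
    tau1: float = 0.1  # s
    tau2: float = 2.0

    def __post_init__(self) -> None:
        if self.behaviour not in ("elastic", "elastoplastic", "viscoplastic"):
            raise ParameterError(f"unknown behaviour {self.behaviour!r}")
        if self.E <= 0:
            raise ParameterError("E must be positive")
        if min(self.C0, self.C1, self.C2) < 0:
            raise ParameterError("Prony coefficients must be non-negative")
        if self.behaviour == "viscoplastic" and not self.tau1 < self.tau2:
            raise ParameterError("tau1 < tau2 required")

    @property
    def e_star(self) -> float:
        return self.E / (1.0 - self.nu**2)

    @property
    def hardness0(self) -> float:
        """Hardness at the end of loading (instantaneous hardness)."""
        if self.behaviour == "viscoplastic":
            return self.C0 + self.C1 + self.C2
        if self.H is None:
            raise ParameterError("H required for elastoplastic behaviour")
        return self.H


@dataclass
class IndenterTruth:
    """True indenter geometry used by the simulator.

    ``kind`` is one of ``power_law`` (``h_c = c a**n``), ``paraboloid``
    (radius ``R``) or ``polynomial`` (``a = d0 + d1 h_c + ...``).
    """

    kind: str
    c: float | None = None
    n: float | None = None
    R: float | None = None
    coeffs: np.ndarray | None = None
    truncation_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "power_law":
            if not (self.c and self.c > 0 and self.n and self.n > 0):
                raise ParameterError("power_law tip needs c > 0 and n > 0")
        elif self.kind == "paraboloid":
            if not (self.R and self.R > 0):
                raise ParameterError("paraboloid tip needs R > 0")
            self.c, self.n = 1.0 / (2.0 * self.R), 2.0
        elif self.kind == "polynomial":
            self.coeffs = np.asarray(self.coeffs, dtype=float)
            if self.coeffs is None or self.coeffs.size == 0:
                raise ParameterError("polynomial tip needs coefficients")
        else:
            raise ParameterError(f"unknown tip kind {self.kind!r}")

    def contact_radius(self, h_c):
        """a(h_c)."""
        h_c = np.asarray(h_c, dtype=float)
        if self.kind in ("power_law", "paraboloid"):
            a = (h_c / self.c) ** (1.0 / self.n)
        else:
            a = np.polyval(self.coeffs[::-1], h_c)
        return a

    def contact_depth(self, a):
        """h_c(a), inverting the polynomial numerically where needed."""
        a_arr = np.atleast_1d(np.asarray(a, dtype=float))
        if self.kind in ("power_law", "paraboloid"):
            out = self.c * a_arr**self.n
        else:
            out = np.empty_like(a_arr)
            hi = 1.0
            for i, ai in enumerate(a_arr):
                if ai <= self.coeffs[0]:
                    out[i] = 0.0
                    continue
                out[i] = brentq(lambda x: np.polyval(self.coeffs[::-1], x) - ai, 0.0, hi)
        return float(out[0]) if np.isscalar(a) or np.ndim(a) == 0 else out

    def check_increasing(self, h_c_max: float) -> None:
        grid = np.linspace(h_c_max / 2000.0, h_c_max, 2000)
        a = self.contact_radius(grid)
        if np.any(np.diff(a) <= 0) or np.any(a <= 0):
            raise GeometryError("indenter profile a(h_c) must be positive and increasing")


#: blunted-cone default, comparable in scale to a worn sharp AFM tip
DEFAULT_TIP_TRUTH = IndenterTruth(kind="polynomial", coeffs=np.array([20e-9, 0.55]))


# ---------------------------------------------------------------------------
# elastic forward models
# ---------------------------------------------------------------------------


def power_law_elastic_force(e_star: float, c: float, n: float, h):
    """Elastic force for a rigid power-law indenter ``h_c = c a**n``.

    ``F = [2 E* n / (n+1)] (kappa c)**(-1/n) h**((n+1)/n)``; reduces to the
    Hertz expression ``F = (4/3) E* sqrt(R) h**1.5`` at ``n=2, c=1/(2R)``.
    """
    if e_star <= 0 or c <= 0 or n <= 0:
        raise ParameterError("e_star, c and n must be positive")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ParameterError("h must be >= 0")
    kap = depth_scaling_kappa(n)
    F = 2.0 * e_star * n / (n + 1.0) * (kap * c) ** (-1.0 / n) * h ** ((n + 1.0) / n)
    return float(F) if F.ndim == 0 else F


def _elastic_loading_table(
    profile: IndenterTruth, e_star: float, h_max: float, n_fine: int = 4000
) -> tuple[np.ndarray, np.ndarray]:
    """Fine parametric (h, F) loading table for an arbitrary increasing profile.

    Integrates ``dF = 2 E* a dh`` with the local-exponent mapping
    ``h = kappa(n_loc) h_c``, ``n_loc = d ln h_c / d ln a``.
    """
    if profile.kind in ("power_law", "paraboloid"):
        h = np.linspace(0.0, h_max, n_fine)
        return h, power_law_elastic_force(e_star, profile.c, profile.n, h)
    # generous h_c upper bound: h >= h_c always (kappa > 1)
    h_c = np.geomspace(h_max * 1e-6, h_max, n_fine)
    a = profile.contact_radius(h_c)
    if np.any(np.diff(a) <= 0) or np.any(a <= 0):
        raise GeometryError("indenter profile a(h_c) must be positive and increasing")
    dln_a = np.gradient(np.log(a), np.log(h_c))
    n_loc = 1.0 / np.clip(dln_a, 1e-12, None)
    h = depth_scaling_kappa(n_loc) * h_c
    F = cumulative_trapezoid(2.0 * e_star * a, h, initial=0.0)
    h = np.concatenate([[0.0], h])
    F = np.concatenate([[0.0], F])
    return h, F


def sneddon_elastic_curve(
    profile: IndenterTruth,
    e_star: float,
    h_max: float,
    n_points: int = 500,
    speed: float = 0.5e-6,
) -> IndentationCurve:
    """Noiseless elastic loading/unloading indentation curve for a known tip."""
    if n_points < 16:
        raise ParameterError("n_points too small (need >= 16)")
    if h_max <= 0 or e_star <= 0:
        raise ParameterError("h_max and e_star must be positive")
    h_fine, F_fine = _elastic_loading_table(profile, e_star, h_max)
    h = np.linspace(0.0, h_max, n_points)
    F = np.interp(h, h_fine, F_fine)
    depth = np.concatenate([h, h[::-1]])
    force = np.concatenate([F, F[::-1]])
    segment = np.array(["approach"] * n_points + ["retract"] * n_points, dtype=object)
    time = np.arange(depth.size) * (h_max / max(n_points - 1, 1)) / speed
    return IndentationCurve(
        curve_id="elastic",
        time=time,
        depth=depth,
        force=force,
        segment=segment,
        z0=0.0,
        f0=0.0,
        adhesive=np.zeros(depth.size, dtype=bool),
        metadata={"e_star": e_star},
    )


# ---------------------------------------------------------------------------
# raw-curve assembly helpers
# ---------------------------------------------------------------------------


def _assemble_raw_curve(
    curve_id: str,
    z0: float,
    k_c: float,
    load_h: np.ndarray,
    load_F: np.ndarray,
    unload_h: np.ndarray,
    unload_F: np.ndarray,
    pause_t: np.ndarray | None,
    pause_F: np.ndarray | None,
    speed: float,
    baseline: float,
    sample_dz: float,
    noise_sd: float,
    rng: np.random.Generator | None,
    metadata: dict,
) -> ForceCurve:
    """Build a raw (time, piezo height, force) curve from branch tables.

    Piezo height maps to depth via ``z = z0 + h + F/k_c``; approach and
    retract are sampled uniformly in z (constant piezo speed), the pause is
    sampled on its own time grid at constant height.
    """
    z_load = z0 + load_h + load_F / k_c
    z_top = z_load[-1]
    z_app = np.arange(z0 - baseline, z_top + 0.5 * sample_dz, sample_dz)
    F_app = np.where(z_app < z0, 0.0, np.interp(z_app, z_load, load_F))
    t_app = (z_app - z_app[0]) / speed

    t_cursor = t_app[-1]
    segments = [("approach", t_app, z_app, F_app)]

    if pause_t is not None and pause_t.size:
        dt = pause_t[1] - pause_t[0] if pause_t.size > 1 else 1e-3
        t_pause = t_cursor + dt + pause_t
        segments.append(("pause", t_pause, np.full(pause_t.size, z_top), pause_F))
        t_cursor = t_pause[-1]

    z_unl = z0 + unload_h + unload_F / k_c  # decreasing branch (h from h_max down)
    z_ret = np.arange(z_top, z0 - baseline, -sample_dz)
    F_ret = np.where(
        z_ret >= z_unl.min(),
        np.interp(z_ret, z_unl[::-1], unload_F[::-1]),
        0.0,
    )
    t_ret = t_cursor + (z_top - z_ret) / speed
    segments.append(("retract", t_ret, z_ret, F_ret))

    seg_labels = np.concatenate([np.full(s[1].size, s[0], dtype=object) for s in segments])
    time = np.concatenate([s[1] for s in segments])
    height = np.concatenate([s[2] for s in segments])
    force = np.concatenate([s[3] for s in segments])
    if noise_sd > 0:
        if rng is None:
            raise ParameterError("rng required when noise_sd > 0")
        force = force + rng.normal(0.0, noise_sd, force.size)
    return ForceCurve(
        curve_id=curve_id,
        time=time,
        height=height,
        signal=force,
        segment=seg_labels,
        signal_unit="N",
        metadata=metadata,
    )


def elastic_reference_curve(
    profile: IndenterTruth,
    e_star: float,
    f_max: float,
    k_c: float = 28.5,
    speed: float = 0.5e-6,
    z0: float = 0.0,
    baseline: float = 100e-9,
    sample_dz: float = 0.1e-9,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    curve_id: str = "ref",
    metadata: dict | None = None,
) -> ForceCurve:
    """Raw elastic force curve on the reference material up to ``f_max``.

    Sampled finely (0.1 nm piezo steps, matching multi-kHz acquisition at
    sub-um/s approach speeds): the tip calibration averages many shallow,
    low-force samples and needs the data volume.
    """
    # bracket h_max by doubling until the force table passes f_max
    h_try = 100e-9
    for _ in range(40):
        h_fine, F_fine = _elastic_loading_table(profile, e_star, h_try)
        if F_fine[-1] >= f_max:
            break
        h_try *= 1.6
    else:  # pragma: no cover
        raise ParameterError("could not reach f_max with this profile")
    h_max = float(np.interp(f_max, F_fine, h_fine))
    sel = h_fine <= h_max
    load_h = np.concatenate([h_fine[sel], [h_max]])
    load_F = np.concatenate([F_fine[sel], [f_max]])
    meta = {
        "spring_constant": k_c,
        "sensitivity": 20e-9,
        "setpoint": f_max,
        "speed": speed,
        **(metadata or {}),
    }
    return _assemble_raw_curve(
        curve_id, z0, k_c, load_h, load_F, load_h[::-1], load_F[::-1],
        None, None, speed, baseline, sample_dz, noise_sd, rng, meta,
    )


# ---------------------------------------------------------------------------
# elastoplastic / viscoplastic forward model
# ---------------------------------------------------------------------------


def elastoplastic_state(
    truth: MaterialTruth, profile: IndenterTruth, f_max: float, phi: float = 0.73
) -> dict:
    """Deterministic end-of-loading state implied by the forward model.

    Returns a dict with ``a`` (contact radius at peak), ``h_c``, ``h_s``,
    ``h_max``, ``S0``, ``h_f``, ``C_e`` and ``H``.
    """
    if f_max <= 0:
        raise ParameterError("f_max must be positive")
    H = truth.hardness0
    if H >= truth.E:
        raise ParameterError("H >= E is nonphysical for this contact model")
    a_max = float(np.sqrt(f_max / (np.pi * H)))
    h_c = float(profile.contact_depth(a_max))
    S0 = 2.0 * truth.e_star * a_max
    h_s = phi * f_max / S0
    h_max = h_c + h_s
    h_f = h_max - 2.0 * f_max / S0
    return {
        "a": a_max,
        "h_c": h_c,
        "h_s": float(h_s),
        "h_max": float(h_max),
        "S0": float(S0),
        "h_f": float(h_f),
        "C_e": float(S0**2 / (4.0 * f_max)),
        "H": float(H),
    }


def elastoplastic_curve(
    truth: MaterialTruth,
    profile: IndenterTruth,
    f_max: float,
    speed: float = 0.5e-6,
    k_c: float = 28.5,
    phi: float = 0.73,
    dwell: float = 0.0,
    pause_dt: float = 0.008,
    z0: float = 0.0,
    baseline: float = 100e-9,
    sample_dz: float = 1e-9,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    curve_id: str = "cell",
    metadata: dict | None = None,
) -> ForceCurve:
    """Raw loading-pause-unloading curve for an elastoplastic/viscoplastic cell.

    Loading: fully yielded contact ``F = pi a^2 H0`` with elastic sink-in.
    Pause: ``F(t) = pi a_max^2 H(t)`` with the Prony hardness (constant for
    purely elastoplastic truth).  Unloading: ``F = C_e (h - h_f)^2`` from the
    post-pause force with initial slope ``S0 = 2 E* a_max``.
    """
    H0 = truth.hardness0
    if H0 >= truth.E:
        raise ParameterError("H >= E is nonphysical for this contact model")
    a_max = np.sqrt(f_max / (np.pi * H0))
    a = np.linspace(0.0, a_max, 800)[1:]
    h_c = profile.contact_depth(a)
    F = np.pi * a**2 * H0
    S = 2.0 * truth.e_star * a
    h_s = phi * F / S
    load_h = np.concatenate([[0.0], h_c + h_s])
    load_F = np.concatenate([[0.0], F])
    if np.any(np.diff(load_h) <= 0):
        raise GeometryError("loading depth not monotone; profile invalid")
    h_max = float(load_h[-1])

    if dwell > 0 and truth.behaviour == "viscoplastic":
        pause_t = np.arange(0.0, dwell + 0.5 * pause_dt, pause_dt)
        _, pause_F = relaxation_curve(truth, a_max, dwell, pause_dt)
        F_end = float(pause_F[-1])
    elif dwell > 0:
        pause_t = np.arange(0.0, dwell + 0.5 * pause_dt, pause_dt)
        pause_F = np.full(pause_t.size, f_max)
        F_end = f_max
    else:
        pause_t = pause_F = None
        F_end = f_max

    S0 = 2.0 * truth.e_star * a_max
    # during the constant-height hold the sample creeps: depth grows by the
    # released cantilever deflection, so unloading starts from h_start
    h_start = h_max + (f_max - F_end) / k_c
    h_f = h_start - 2.0 * F_end / S0
    if h_f < 0:
        raise ParameterError("unloading would overshoot the origin (h_f < 0); lower H/E contrast")
    C_e = S0**2 / (4.0 * F_end)
    unload_h = np.linspace(h_start, h_f, 600)
    unload_F = C_e * (unload_h - h_f) ** 2

    meta = {
        "spring_constant": k_c,
        "sensitivity": 20e-9,
        "setpoint": f_max,
        "speed": speed,
        "dwell": dwell,
        "thickness": 1e-6,
        **(metadata or {}),
    }
    return _assemble_raw_curve(
        curve_id, z0, k_c, load_h, load_F, unload_h, unload_F,
        pause_t, pause_F, speed, baseline, sample_dz, noise_sd, rng, meta,
    )


def relaxation_curve(
    truth: MaterialTruth, a: float, dwell: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pause-segment force series ``F(t) = pi a^2 H(t)`` on a uniform grid."""
    if dwell <= 0 or dt <= 0:
        raise ParameterError("dwell and dt must be positive")
    if min(truth.C0, truth.C1, truth.C2) < 0:
        raise ParameterError("Prony coefficients must be non-negative")
    for tau in (truth.tau1, truth.tau2):
        if not dt < tau < 10.0 * dwell:
            warnings.warn(
                f"relaxation time {tau} s outside identifiable window "
                f"({dt}, {10 * dwell}) s",
                stacklevel=2,
            )
    t = np.arange(0.0, dwell + 0.5 * dt, dt)
    H = truth.C0 + truth.C1 * np.exp(-t / truth.tau1) + truth.C2 * np.exp(-t / truth.tau2)
    return t, np.pi * a**2 * H


def derive_hb_truth(
    truth: MaterialTruth,
    psi: float = 3.0,
    dwell: float = 4.0,
    dt: float = 1e-3,
    n_samples: int = 400,
) -> dict:
    """Herschel-Bulkley ground truth implied by a Prony truth.

    Evaluates the stress and plastic strain-rate series on a fine log-spaced
    grid and fits ``sigma = sigma_Y + k rate**j`` — the same transformation
    the analysis applies, computed from exact series rather than fitted
    relaxation curves.
    """
    from afmindent.viscoplastic import fit_herschel_bulkley, plastic_strain_rate, stress_series

    t = np.geomspace(2 * dt, dwell, n_samples)
    sigma = stress_series(truth.C0, truth.C1, truth.C2, truth.tau1, truth.tau2, psi, t)
    rate = plastic_strain_rate(truth.C1, truth.C2, truth.tau1, truth.tau2, truth.E, t)
    hb = fit_herschel_bulkley(sigma, rate, sigma_y0=truth.C0 / psi)
    return {"sigma_Y": hb.sigma_y, "k": hb.k, "j": hb.j}


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

#: participant-level median parameters used by the default simulation
DEFAULT_PARTICIPANTS = (
    {"E": 1.18e9, "C0": 151e6, "C1": 30e6, "C2": 17e6, "tau1": 0.12, "tau2": 1.99},
    {"E": 0.42e9, "C0": 76e6, "C1": 33e6, "C2": 18e6, "tau1": 0.16, "tau2": 2.11},
    {"E": 1.10e9, "C0": 92e6, "C1": 43e6, "C2": 24e6, "tau1": 0.14, "tau2": 2.40},
)


def generate_dataset(
    out_dir: str | Path,
    seed: int,
    participants: int = 3,
    cells_per_participant: int = 5,
    grid_shape: tuple[int, int] = (8, 8),
    setpoint: float = 2e-6,
    speed: float = 0.5e-6,
    dwell: float = 4.0,
    noise_sd: float = 0.0,
    tip: IndenterTruth = DEFAULT_TIP_TRUTH,
    cell_spread: float = 0.12,
    curve_spread: float = 0.06,
    include_reference: bool = True,
    reference_curves: int = 64,
    reference_setpoint: float = 250e-9,
    pause_dt: float = 0.008,
) -> Path:
    """Write a synthetic dataset and return the cell-manifest path.

    Layout under ``out_dir``: ``curves/*.tsv`` + ``manifest.csv`` +
    ``truth.csv`` for the cells, and (optionally) ``reference/*.tsv`` +
    ``reference_manifest.csv`` for elastic calibration curves on the
    reference material.  Deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    curves_dir = out_dir / "curves"
    curves_dir.mkdir(parents=True, exist_ok=True)

    grid_x, grid_y = grid_shape
    region = 5e-6
    manifest_rows = []
    truth_rows = []
    for p in range(participants):
        base = DEFAULT_PARTICIPANTS[p % len(DEFAULT_PARTICIPANTS)]
        for cell in range(cells_per_participant):
            cell_factor = float(np.exp(rng.normal(0.0, cell_spread)))
            for iy in range(grid_y):
                for ix in range(grid_x):
                    curve_factor = float(np.exp(rng.normal(0.0, curve_spread)))
                    scale = cell_factor * curve_factor
                    truth = MaterialTruth(
                        behaviour="viscoplastic",
                        E=base["E"] * scale,
                        nu=0.4,
                        C0=base["C0"] * scale,
                        C1=base["C1"] * scale,
                        C2=base["C2"] * scale,
                        tau1=base["tau1"] * float(np.exp(rng.normal(0.0, 0.05))),
                        tau2=base["tau2"] * float(np.exp(rng.normal(0.0, 0.05))),
                    )
                    curve_id = f"P{p + 1}_C{cell + 1}_x{ix}_y{iy}"
                    pos_x = ix * region / max(grid_x - 1, 1)
                    pos_y = iy * region / max(grid_y - 1, 1)
                    curve = elastoplastic_curve(
                        truth,
                        tip,
                        f_max=setpoint,
                        speed=speed,
                        dwell=dwell,
                        pause_dt=pause_dt,
                        noise_sd=noise_sd,
                        rng=rng,
                        curve_id=curve_id,
                        metadata={"position_x": pos_x, "position_y": pos_y},
                    )
                    fname = f"{curve_id}.tsv"
                    write_force_curve(curve, curves_dir / fname)
                    manifest_rows.append(
                        {
                            "curve_file": f"curves/{fname}",
                            "curve_id": curve_id,
                            "participant": p + 1,
                            "cell": cell + 1,
                            "grid_x": ix,
                            "grid_y": iy,
                        }
                    )
                    a_peak = float(np.sqrt(setpoint / (np.pi * truth.hardness0)))
                    truth_rows.append(
                        {
                            "curve_id": curve_id,
                            "E": truth.E,
                            "H": truth.hardness0,
                            "C0": truth.C0,
                            "C1": truth.C1,
                            "C2": truth.C2,
                            "tau1": truth.tau1,
                            "tau2": truth.tau2,
                            "a": a_peak,
                        }
                    )

    import pandas as pd

    manifest = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False, float_format="%.10g")

    if include_reference:
        ref_dir = out_dir / "reference"
        ref_dir.mkdir(exist_ok=True)
        ref_rows = []
        for i in range(reference_curves):
            curve_id = f"REF_{i:03d}"
            curve = elastic_reference_curve(
                tip,
                e_star=3.79e6,
                f_max=reference_setpoint,
                speed=speed,
                noise_sd=noise_sd * reference_setpoint / setpoint if noise_sd else 0.0,
                rng=rng,
                curve_id=curve_id,
            )
            write_force_curve(curve, ref_dir / f"{curve_id}.tsv")
            ref_rows.append({"curve_file": f"reference/{curve_id}.tsv", "curve_id": curve_id})
        pd.DataFrame(ref_rows).to_csv(out_dir / "reference_manifest.csv", index=False)

    return manifest
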