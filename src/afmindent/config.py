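"""Calibration / analysis configuration.

Holds the handful of material and model constants the whole pipeline depends
on: the plane-strain modulus of the elastic reference used for tip
calibration, Poisson ratios, the geometric sink-in factor ``phi``, the plastic
constraint factor ``psi``, and the fitting windows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from afmindent.exceptions import ParameterError


@dataclass
class CalibrationConfig:
    """Constants and fit windows shared across the pipeline.

    Parameters
    ----------
    e_star_ref : float
        Plane-strain modulus of the elastic reference material, Pa.
    nu_ref : float
        Poisson's ratio of the reference (0.5 for an incompressible
        elastomer).
    nu_sample : float
        Poisson's ratio assumed for the cells.
    phi : float
        Geometric factor of the sink-in depth ``h_s = phi * F_max / S0``.
    psi : float
        Plastic constraint factor relating hardness to uniaxial yield
        stress, ``H = psi * sigma_Y``.
    unloading_fit_fraction : float
        Fraction of the unloading force range included in the stiffness
        fit (force window ``F >= (1 - fraction) * F_max``).
    h_c_fit_range : tuple of float
        Contact-depth range (m) over which the tip polynomial is fitted.
    h_c_cap_limit : float
        Contact depth (m) below which the power-law cap replaces the
        polynomial.
    smoothing_order : int
        Order of the zero-intercept polynomial used to smooth averaged
        loading curves.
    tip_poly_degree : int
        Degree of the contact-radius polynomial ``a(h_c)``.
    hb_min_prony_r2 : float
        Minimum Prony-fit R^2 for a curve to enter the Herschel-Bulkley
        analysis.
    nominal_dwell : float
        Nominal pause duration, s; pauses shorter than 90% of it are
        excluded from relaxation analysis.
    """

    e_star_ref: float = 3.79e6
    nu_ref: float = 0.5
    nu_sample: float = 0.4
    phi: float = 0.73
    psi: float = 3.0
    unloading_fit_fraction: float = 0.8
    h_c_fit_range: tuple[float, float] = (10e-9, 200e-9)
    h_c_cap_limit: float = 5e-9
    smoothing_order: int = 6
    tip_poly_degree: int = 6
    hb_min_prony_r2: float = 0.95
    nominal_dwell: float = 4.0
    thickness_fraction_limit: float = 0.1

    def __post_init__(self) -> None:
        if self.e_star_ref <= 0:
            raise ParameterError("e_star_ref must be positive")
        for name in ("nu_ref", "nu_sample"):
            nu = getattr(self, name)
            if not 0.0 <= nu <= 0.5:
                raise ParameterError(f"{name} must lie in [0, 0.5], got {nu}")
        if self.phi <= 0:
            raise ParameterError("phi must be positive")
        if self.psi <= 0:
            raise ParameterError("psi must be positive")
        if not 0.0 < self.unloading_fit_fraction <= 1.0:
            raise ParameterError("unloading_fit_fraction must lie in (0, 1]")
        lo, hi = self.h_c_fit_range
        if not 0 < lo < hi:
            raise ParameterError("h_c_fit_range must satisfy 0 < lo < hi")
        if self.h_c_cap_limit <= 0:
            raise ParameterError("h_c_cap_limit must be positive")
        if self.smoothing_order < 2:
            raise ParameterError("smoothing_order must be >= 2")
        if self.tip_poly_degree < 1:
            raise ParameterError("tip_poly_degree must be >= 1")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["h_c_fit_range"] = list(d["h_c_fit_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "h_c_fit_range" in kwargs:
            kwargs["h_c_fit_range"] = tuple(kwargs["h_c_fit_range"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Stable hash of the configuration, recorded in output provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
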