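"""Force-curve data model, text I/O, signal conversion and contact detection.

A force curve is the raw record of one indentation event: time, piezo height
and cantilever signal (volts or newtons) split into approach / pause / retract
segments.  The on-disk dialect is a TSV with a ``# key: value`` metadata
header; a manifest CSV maps curve files to (participant, cell, grid x, grid y).

Sign conventions: compression is positive force, and piezo height increases
toward the sample, so the approach segment has increasing ``height``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from afmindent.exceptions import ContactError, DataError, FormatError, ParameterError

SEGMENTS = ("approach", "pause", "retract")

#: header key -> (metadata key, scale to SI)
_HEADER_KEYS = {
    "spring_constant_N_per_m": ("spring_constant", 1.0),
    "sensitivity_nm_per_V": ("sensitivity", 1e-9),
    "setpoint_N": ("setpoint", 1.0),
    "speed_m_per_s": ("speed", 1.0),
    "dwell_s": ("dwell", 1.0),
    "position_x_m": ("position_x", 1.0),
    "position_y_m": ("position_y", 1.0),
    "thickness_m": ("thickness", 1.0),
}
_META_TO_HEADER = {v[0]: (k, v[1]) for k, v in _HEADER_KEYS.items()}


def _validate_segments(time: np.ndarray, segment: np.ndarray, curve_id: str) -> None:
    seen = set(segment.tolist())
    unknown = seen - set(SEGMENTS)
    if unknown:
        raise FormatError(f"curve {curve_id!r}: unknown segment labels {sorted(unknown)}")
    for name in SEGMENTS:
        mask = segment == name
        if mask.sum() >= 2 and not np.all(np.diff(time[mask]) > 0):
            raise DataError(f"curve {curve_id!r}: time not strictly increasing in {name} segment")
    # segments must be contiguous blocks in approach->pause->retract order
    order = [SEGMENTS.index(s) for s in segment]
    if np.any(np.diff(order) < 0):
        raise DataError(f"curve {curve_id!r}: segments out of order or interleaved")


@dataclass
class ForceCurve:
    """One raw indentation event.

    ``signal`` is cantilever deflection in volts (``signal_unit='V'``) or
    force in newtons (``signal_unit='N'``).
    """

    curve_id: str
    time: np.ndarray
    height: np.ndarray
    signal: np.ndarray
    segment: np.ndarray
    signal_unit: str = "N"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        n = self.time.size
        if not (self.height.size == self.signal.size == self.segment.size == n):
            raise FormatError(f"curve {self.curve_id!r}: column lengths differ")
        if self.signal_unit not in ("V", "N"):
            raise ParameterError(f"signal_unit must be 'V' or 'N', got {self.signal_unit!r}")
        _validate_segments(self.time, self.segment, self.curve_id)

    # -- accessors ---------------------------------------------------------

    def seg_mask(self, name: str) -> np.ndarray:
        if name not in SEGMENTS:
            raise ParameterError(f"unknown segment {name!r}")
        return self.segment == name

    def seg(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (time, height, signal) views of one segment."""
        m = self.seg_mask(name)
        return self.time[m], self.height[m], self.signal[m]

    @property
    def force(self) -> np.ndarray:
        if self.signal_unit != "N":
            raise ParameterError(
                f"curve {self.curve_id!r} holds volts; run convert_raw_signal first"
            )
        return self.signal

    @property
    def needs_conversion(self) -> bool:
        """True when the signal is in volts and must be converted to force."""
        return self.signal_unit == "V"

    @property
    def can_convert(self) -> bool:
        return ("sensitivity" in self.metadata) and ("spring_constant" in self.metadata)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def write_force_curve(curve: ForceCurve, path: str | Path) -> Path:
    """Write one curve in the TSV dialect (12 significant digits)."""
    path = Path(path)
    lines = [f"# curve_id: {curve.curve_id}"]
    for meta_key, (header_key, scale) in _META_TO_HEADER.items():
        if meta_key in curve.metadata:
            lines.append(f"# {header_key}: {curve.metadata[meta_key] / scale:.12g}")
    signal_col = "deflection_V" if curve.signal_unit == "V" else "force_N"
    lines.append("\t".join(["time_s", "height_m", signal_col, "segment"]))
    for t, z, x, s in zip(curve.time, curve.height, curve.signal, curve.segment):
        lines.append(f"{t:.12e}\t{z:.12e}\t{x:.12e}\t{s}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_force_curve(path: str | Path) -> ForceCurve:
    """Read one curve from the TSV dialect.

    Raises :class:`FormatError` when mandatory columns are missing and
    :class:`DataError` (naming the curve) for non-monotone time.  A missing
    segment (e.g. a truncated file without a retract block) is tolerated with
    a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    header: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line[1:].partition(":")
                    header[key.strip()] = value.strip()
            elif line.strip():
                body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no data rows")
    columns = body_lines[0].rstrip("\n").split("\t")
    if "time_s" not in columns or "height_m" not in columns:
        raise FormatError(f"{path}: mandatory columns time_s/height_m missing")
    if "force_N" in columns:
        signal_col, unit = "force_N", "N"
    elif "deflection_V" in columns:
        signal_col, unit = "deflection_V", "V"
    else:
        raise FormatError(f"{path}: needs a force_N or deflection_V column")
    if "segment" not in columns:
        raise FormatError(f"{path}: mandatory column segment missing")
    df = pd.read_csv(
        io.StringIO("".join(body_lines)),
        sep="\t",
        dtype={"time_s": float, "height_m": float, signal_col: float, "segment": str},
    )
    curve_id = header.get("curve_id", path.stem)
    metadata: dict = {}
    for header_key, (meta_key, scale) in _HEADER_KEYS.items():
        if header_key in header:
            metadata[meta_key] = float(header[header_key]) * scale
    if unit == "V" and not {"sensitivity", "spring_constant"} <= metadata.keys():
        warnings.warn(
            f"curve {curve_id!r}: deflection in volts but sensitivity/spring constant "
            "missing from header; conversion will need explicit values",
            stacklevel=2,
        )
    missing = [s for s in SEGMENTS if s not in set(df["segment"])]
    if missing:
        warnings.warn(f"curve {curve_id!r}: empty segment(s) {missing}", stacklevel=2)
    return ForceCurve(
        curve_id=curve_id,
        time=df["time_s"].to_numpy(),
        height=df["height_m"].to_numpy(),
        signal=df[signal_col].to_numpy(),
        segment=df["segment"].to_numpy(dtype=object),
        signal_unit=unit,
        metadata=metadata,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV; ``curve_file`` paths are resolved against its folder."""
    path = Path(path)
    df = pd.read_csv(path)
    if "curve_file" not in df.columns:
        raise FormatError(f"{path}: manifest needs a curve_file column")
    df["curve_path"] = [str(path.parent / p) for p in df["curve_file"]]
    return df


def read_force_curves(path: str | Path, dialect: str = "tsv") -> list[ForceCurve]:
    """Read a collection of curves.

    ``path`` may be a single curve TSV, a manifest CSV, or a directory of
    ``*.tsv`` curve files.
    """
    if dialect != "tsv":
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if path.is_dir():
        return [read_force_curve(p) for p in sorted(path.glob("*.tsv"))]
    if path.suffix == ".csv":
        manifest = read_manifest(path)
        return [read_force_curve(p) for p in manifest["curve_path"]]
    return [read_force_curve(path)]


# ---------------------------------------------------------------------------
# signal conversion
# ---------------------------------------------------------------------------


def convert_raw_signal(curve: ForceCurve, sensitivity: float, k_c: float) -> ForceCurve:
    """Convert a volts curve to force units.

    ``d[m] = sensitivity * volts`` and ``F = k_c * d``.  The original volt
    trace is retained in ``metadata['raw_deflection_V']``.

    Parameters
    ----------
    sensitivity : float
        Deflection sensitivity in m/V.
    k_c : float
        Cantilever spring constant in N/m.
    """
    if curve.signal_unit != "V":
        raise ParameterError(f"curve {curve.curve_id!r} is already in force units")
    if sensitivity <= 0:
        raise ParameterError(f"sensitivity must be positive, got {sensitivity}")
    if k_c <= 0:
        raise ParameterError(f"spring constant must be positive, got {k_c}")
    force = k_c * sensitivity * curve.signal
    metadata = dict(curve.metadata)
    metadata["raw_deflection_V"] = curve.signal.copy()
    metadata["sensitivity"] = sensitivity
    metadata["spring_constant"] = k_c
    return replace(curve, signal=force, signal_unit="N", metadata=metadata)


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------


def detect_contact_point(
    curve: ForceCurve,
    noise_sd: float | str = "auto",
    baseline_fraction: float = 0.4,
    threshold_multiplier: float = 5.0,
    force_floor: float = 1e-11,
    refine_window: float = 20e-9,
    deep_refine: bool = False,
) -> tuple[float, float]:
    """Locate the surface position ``z0`` and force baseline ``F0``.

    A straight line is fitted to the first ``baseline_fraction`` of the
    approach segment (removing virtual-deflection tilt); contact is the first
    sample whose baseline-corrected force exceeds
    ``max(threshold_multiplier * noise_sd, force_floor)``, refined by
    back-extrapolating a power-law fit of the first ``refine_window`` of
    contact to zero force.

    With ``deep_refine=True`` the contact position is additionally refined by
    a free-exponent power-law fit of the high-force part of the approach
    (force above 10% of its maximum) with the contact position free.  On a
    compliant sample indented with a stiff cantilever the near-contact signal
    sits below the noise floor, so only the deep, high signal-to-noise region
    can locate the surface without bias; this is the recommended mode for
    reference-material calibration curves.

    Returns
    -------
    (z0, F0) : tuple of float
        Surface height (m) and baseline force (N) at ``z0``.
    """
    _, z, F = curve.seg("approach")
    if curve.signal_unit != "N":
        raise ParameterError("convert the curve to force units before contact detection")

    if z.size < 20:
        raise DataError(f"curve {curve.curve_id!r}: approach segment too short")

    def _sustained_crossing(signal: np.ndarray, threshold: float) -> int | None:
        # require the crossing to be sustained so single noise spikes do not count
        for i in np.flatnonzero(signal > threshold):
            j = min(i + 5, signal.size)
            if np.count_nonzero(signal[i:j] > 0.5 * threshold) >= min(4, j - i):
                return int(i)
        return None

    # pass 1 (coarse): robust level/scatter from an initial window, plus a
    # small fraction of the full force range so a window that swallows part
    # of the contact region still brackets the contact sample from above
    n0 = max(10, int(baseline_fraction * z.size / 2))
    level = float(np.median(F[:n0]))
    scatter = 1.4826 * float(np.median(np.abs(F[:n0] - np.median(F[:n0]))))
    coarse_thr = max(
        threshold_multiplier * scatter, force_floor, 0.01 * (float(F.max()) - level)
    )
    idx_coarse = _sustained_crossing(F - level, coarse_thr)
    if idx_coarse is None:
        raise ContactError(f"curve {curve.curve_id!r}: no contact found")

    # pass 2 (refined): straight-line baseline on the pre-contact region only.
    # Walk back from the coarse crossing to the last *sustained* quiet run
    # (single samples dip below threshold well inside contact when noisy).
    quiet = (F - level)[:idx_coarse] <= max(2.0 * scatter, force_floor)
    run_len = 8
    n_base = idx_coarse
    if quiet.size >= run_len:
        runs = np.convolve(quiet.astype(int), np.ones(run_len, dtype=int), mode="valid")
        full = np.flatnonzero(runs == run_len)
        n_base = int(full[-1]) + run_len if full.size else idx_coarse
    n_base -= 2
    if n_base < 10:
        raise DataError(
            f"curve {curve.curve_id!r}: baseline region has {max(n_base, 0)} samples (< 10)"
        )
    base_coef = np.polyfit(z[:n_base], F[:n_base], 1)
    F_corr = F - np.polyval(base_coef, z)
    if noise_sd == "auto":
        noise_sd = float(np.std(F_corr[:n_base], ddof=2))
    threshold = max(threshold_multiplier * float(noise_sd), force_floor)
    idx = _sustained_crossing(F_corr, threshold)
    if idx is None:
        raise ContactError(f"curve {curve.curve_id!r}: no contact found")

    z0 = float(z[idx])
    # refine: power-law back-extrapolation of the early contact region to
    # F = 0.  With noise the 5-sigma crossing can sit well inside contact, so
    # the contact position may move back as far as the end of the baseline.
    # fit in tip-displacement coordinates (z - F/k_c) when the spring constant
    # is known: the material law is a power law in depth, not piezo height
    k_c = curve.metadata.get("spring_constant")
    x = z - F_corr / k_c if k_c else z
    sel = (z >= z0) & (z <= z0 + refine_window)
    if np.count_nonzero(sel) >= 8:
        zs, Fs = x[sel], F_corr[sel]
        w = float(zs[-1] - zs[0]) or refine_window
        u = (zs - z0) / w
        g = Fs / float(Fs.max())
        spacing = float(np.median(np.diff(zs))) / w if zs.size > 1 else 0.1
        u_floor = (float(z[max(n_base - 1, 0)]) - z0) / w  # end of baseline

        def model(uu, u0, amp, p):
            out = np.zeros_like(uu)
            inside = uu > u0
            out[inside] = amp * (uu[inside] - u0) ** p
            return out

        try:
            popt, _ = curve_fit(
                model,
                u,
                g,
                p0=[-0.5 * spacing, 1.0, 1.5],
                bounds=([min(u_floor, -spacing), 0.0, 1.0], [0.5 * spacing, np.inf, 3.0]),
                maxfev=5000,
            )
            z0 = float(z0 + popt[0] * w)
        except RuntimeError:  # pragma: no cover - keep the threshold crossing
            pass

    if deep_refine:
        from scipy.optimize import least_squares

        deep = F_corr > 0.1 * float(F_corr.max())
        if np.count_nonzero(deep) >= 30:
            zs, Fs = x[deep], F_corr[deep]
            F_scale = float(Fs.max())

            def resid(p):
                ln_b, m, z_c = p
                return (
                    np.exp(ln_b + m * np.log(np.clip(zs - z_c, 1e-12, None))) - Fs
                ) / F_scale

            m0 = 1.5
            ln_b0 = float(np.log(F_scale) - m0 * np.log(max(zs.max() - z0, 1e-12)))
            sol = least_squares(
                resid,
                x0=[ln_b0, m0, z0 - 5e-9],
                bounds=([-np.inf, 1.0, z0 - 200e-9], [np.inf, 3.0, float(zs.min()) - 1e-10]),
                x_scale=[1.0, 0.1, 1e-9],
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                method="trf",
            )
            if sol.success:
                z0_deep = float(sol.x[2])
                # sanity check: extrapolating the deep power law back to the
                # locally detected contact must not predict measurable force
                # where the data show baseline (a blunt apex fools the deep
                # fit into a spuriously early origin)
                ln_b_f, m_f, _ = sol.x
                gap = z0 - z0_deep
                pred_at_local = (
                    np.exp(ln_b_f + m_f * np.log(gap)) if gap > 0 else 0.0
                )
                if pred_at_local <= 2.0 * threshold:
                    z0 = z0_deep
                    # the quiet-run endpoint can drift into early contact;
                    # with a trustworthy z0 refit the baseline below it
                    clean = z < z0 - 8.0 * float(np.median(np.diff(z[:50])))
                    if np.count_nonzero(clean) >= 10:
                        base_coef = np.polyfit(z[clean], F[clean], 1)

    F0 = float(np.polyval(base_coef, z0))
    return z0, F0


# ---------------------------------------------------------------------------
# indentation curve
# ---------------------------------------------------------------------------


@dataclass
class IndentationCurve:
    """Baseline-subtracted force vs indentation depth for one event.

    ``depth = (z - z0) - d`` with ``d = F / k_c`` the cantilever deflection in
    metres: the tip displacement is the piezo travel minus the cantilever
    deflection.  Retract samples with negative force are retained but flagged
    ``adhesive`` and excluded from property fits.
    """

    curve_id: str
    time: np.ndarray
    depth: np.ndarray
    force: np.ndarray
    segment: np.ndarray
    z0: float
    f0: float
    adhesive: np.ndarray
    metadata: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def seg_mask(self, name: str) -> np.ndarray:
        return self.segment == name

    def loading(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.seg_mask("approach")
        return self.depth[m], self.force[m]

    def pause(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.seg_mask("pause")
        return self.time[m], self.force[m]

    def unloading(self, include_adhesive: bool = False) -> tuple[np.ndarray, np.ndarray]:
        m = self.seg_mask("retract")
        if not include_adhesive:
            m = m & ~self.adhesive
        return self.depth[m], self.force[m]


def to_indentation(
    curve: ForceCurve,
    z0: float,
    f0: float,
    nominal_dwell: float | None = None,
) -> IndentationCurve:
    """Convert a force-unit curve with a known contact point to depth/force.

    Pre-contact approach samples (``z < z0``) are dropped; retract samples
    with ``F < 0`` are flagged adhesive.  If the pause lasts less than 90% of
    the nominal dwell a ``short_pause`` flag is set.
    """
    F_all = curve.force - f0
    if not (curve.height.min() <= z0 <= curve.height.max()):
        raise ParameterError(f"curve {curve.curve_id!r}: z0 outside curve height range")
    k_c = curve.metadata.get("spring_constant")
    if k_c is None or k_c <= 0:
        raise ParameterError(
            f"curve {curve.curve_id!r}: positive spring_constant metadata required"
        )
    d = F_all / k_c
    h = (curve.height - z0) - d
    keep = ~(curve.seg_mask("approach") & (curve.height < z0))
    time = curve.time[keep]
    h = h[keep]
    F = F_all[keep]
    segment = curve.segment[keep]
    adhesive = (F < 0) & (segment == "retract")

    flags: list[str] = []
    dwell = nominal_dwell or curve.metadata.get("dwell")
    pause_mask = segment == "pause"
    if dwell and pause_mask.sum() >= 2:
        span = time[pause_mask].max() - time[pause_mask].min()
        if span < 0.9 * dwell:
            flags.append("short_pause")
    elif dwell and pause_mask.sum() < 2:
        flags.append("short_pause")

    return IndentationCurve(
        curve_id=curve.curve_id,
        time=time,
        depth=h,
        force=F,
        segment=segment,
        z0=z0,
        f0=f0,
        adhesive=adhesive,
        metadata=dict(curve.metadata),
        flags=flags,
    )
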