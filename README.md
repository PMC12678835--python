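# afmindent

AFM nanoindentation analysis for stiff biological samples probed with sharp
tips. The package implements the full workflow:

1. **Tip calibration** — derive an effective axisymmetric indenter geometry
   `a(h_c)` from loading curves on a linear-elastic reference of known
   plane-strain modulus, via the contact-stiffness relation `S = 2 E* a`,
   local load-index analysis (`n = 1/(m-1)`,
   `kappa = sqrt(pi) Gamma((n+2)/2) / Gamma((n+1)/2)`), a best-fit polynomial
   over the reliable contact-depth range and a power-law cap
   (`h_c = c a**n`) near the apex.
2. **Elastoplastic analysis** — per-curve quadratic fit to the upper part of
   the unloading branch, initial unloading stiffness `S0`, sink-in depth
   `h_s = phi F_max / S0`, contact depth, Young's modulus
   `E = (sqrt(pi)/2)(1 - nu^2) S0 / sqrt(A_max)`, hardness `H = F_max / A_max`
   and static yield stress `H / psi`.
3. **Viscoplastic analysis** — two-exponential Prony fit of the
   constant-height force relaxation, hardness relaxation coefficients
   (`C_i = B_i / (pi a^2)`, instantaneous `H0` and long-term `Hinf`), plastic
   strain-rate series and Herschel-Bulkley fit
   `sigma = sigma_Y + k rate**j`.
4. **Synthetic data** — a forward simulator (elastic reference curves,
   elastoplastic cell curves with hysteresis and residual depth,
   two-exponential relaxation holds, full participant/cell/grid datasets with
   ground-truth sidecars) so every stage is testable without instrument data.

## Command-line interface

```bash
# generate a synthetic dataset (curves + manifest + ground truth + reference)
afmindent simulate --out dataset --seed 1

# calibrate the effective tip from the reference curves
afmindent calibrate-tip --curves dataset/reference_manifest.csv --out tip.json

# per-curve elastoplastic and relaxation analyses
afmindent analyze-indent --curves dataset/manifest.csv --tip tip.json --out indent.csv
afmindent analyze-relax --curves dataset/manifest.csv --indent-results indent.csv --out visco.csv

# or everything at once, with summaries, rejection log and provenance
afmindent run-all --curves dataset/manifest.csv --reference dataset/reference_manifest.csv --out results
afmindent report --results results --out report
```

Configuration (reference modulus, Poisson ratios, `phi`, `psi`, fit windows)
lives in a YAML file passed with `--config`; defaults are in
`afmindent.config.CalibrationConfig`.

## File formats

Force curves are TSV files with a `# key: value` metadata header and columns
`time_s  height_m  force_N|deflection_V  segment` (segments: approach /
pause / retract). A manifest CSV maps curve files to (participant, cell,
grid x, grid y). Tip profiles are JSON. All analysis outputs are CSV.

## Notes and limitations

- Units are SI internally (m, N, Pa, s).
- Contact-point detection combines a robust baseline fit, a sustained
  threshold crossing and power-law back-extrapolation; an optional
  deep-region refinement (`deep_refine=True`, used for reference-material
  calibration) locates the surface from the high signal-to-noise part of the
  curve and is validated against the measured baseline before being accepted.
- A blunt (truncated) tip apex on a compliant reference produces initial
  contact forces below any realistic noise floor; in that regime the contact
  point, and hence the near-apex cap of the calibrated tip, carries an
  irreducible uncertainty of tens of nanometres. The calibration then
  extends the power-law cap region upward and flags it.
- Samples much stiffer than the cantilever (`S0 >> k_c`) have intrinsically
  amplified stiffness errors; results at such points are computed but should
  be interpreted with care.
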