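# Methods

This note documents the models implemented in `ciuscreen`, the assumptions
behind the synthetic-data generators, the numerical choices, and what the
package's tests do and do not demonstrate about real instrument data.

## CIU conformer model

An arrival-time distribution (ATD) of the selected charge state is modelled
as the sum of two Gaussians with a **shared width**:

    y(t) = a_c · N(t; μ_c, σ) + a_e · N(t; μ_e, σ)

* μ_c, μ_e — compact and extended conformer drift times. Defaults 5.5 ms and
  7.6 ms, each constrained to ±0.3 ms around its expected value during
  fitting. The window is wide enough for calibration drift on a
  travelling-wave mobility cell, narrow enough to keep the two components
  identifiable.
* σ — shared component width (ms). The equal-width constraint makes the
  area ratio equal the apex-height ratio and keeps the five-parameter fit
  identifiable on a 200-bin trace.
* The screening statistic is `unfold% = 100 · a_e/a_c` (extended area as a
  percent of the compact base peak). It can exceed 100% when the extended
  conformer dominates. Extended components below 0.1% of the compact area
  are reported as exactly zero (detection floor), never as small negative
  values.

Fitting is trust-region least squares (`scipy.optimize.curve_fit`) with
non-negativity bounds on the amplitudes. Initial amplitudes are read off a
5-point quadratic Savitzky–Golay smoothing of the trace at the expected
centers; the fit itself runs on the raw intensities. Non-convergence raises
an error carrying the initial residual RMS.

The statistic is defined on the fitted areas relative to the compact base
peak rather than relative to the total ion current; with two components of
equal width the two definitions differ only by a monotone transform, and
the base-peak form is the one the calibrated class statistics are stated
in.

The analysis charge state is always the lowest observed (11+ here), the
most native-like ion population.

## Classification rule

Calibration is data, not code: a JSON-serialisable table of per-(voltage,
class) mean, sd and observed range of unfold%. The built-in FGFR1 table is

| V | type I mean (sd) [range] | type II mean (sd) [range] |
|---|---|---|
| 21 | 27.6 (3.9) [22, 35] | 48.9 (4.4) [40, ∞) |
| 24 | 44.2 (5.6) [30, 50] | 76.7 (11.6) [64, 95] |

The per-voltage call is nearest class mean; the overall call requires all
calibrated voltages to agree, otherwise `ambiguous` — a first-class outcome
suited to screening triage, not an error. The decision boundary (the
midpoint of the two class means: 38.25% at 21 V, 60.45% at 24 V) lies
outside both calibrated ranges at both voltages, so every score inside a
calibrated range is assigned its own class. Confidence is reported as the
distance to the boundary in units of the assigned class's sd. No explicit
numeric boundary is part of the calibration; the nearest-mean rule is this
package's formalisation of "clearly separated" class statistics. Users can
recalibrate for other kinases by supplying their own table.

## Affinity models

**ITC (one-site).** Cumulative heat after injection i:

    Q_i = (n·Mt_i·ΔH·V0/2)·[1 + r + K − sqrt((1 + r + K)² − 4r)],
    r = Xt/(n·Mt),  K = Kd/(n·Mt)

with the displaced-volume dilution d = ΣdV/V0:

    Mt = M0(1 − d/2)/(1 + d/2),   Xt = X0·d/(1 + d/2)

and the observed injection heat ΔQ_i = Q_i + (dV_i/V0)(Q_i + Q_{i−1})/2 −
Q_{i−1}. Heats are in μcal with ΔH in kcal/mol. A negative discriminant
(numerical) is clamped to zero with a warning. The default design is 19 ×
2 μL injections of 200 μM titrant into 20 μM protein in a 200 μL cell —
the cell volume and injection count are instrument-typical values recorded
in the design config. Fits outside the Wiseman window (c = n·Mt/Kd outside
[1, 1000]) carry a reliability warning. The test suite checks this model
against a brute-force oracle that solves the binding quadratic for [PL]
directly at every injection (agreement to 1e-6 relative).

**SPR (1:1 steady state).** Req = Rmax·C/(Kd + C), fitted over (Kd, Rmax).
A fitted Kd above the top injected concentration triggers an
unsaturated-design warning. The default dose series is 9 concentrations
spanning a 256-fold range in 2-fold dilutions, each in triplicate.

**MST (Hill n = 1).** Fnorm(C) = F_unbound + (F_bound − F_unbound)·C/(Kd +
C), fitted over all three parameters; fraction bound is (Fnorm −
F_unbound)/(F_bound − F_unbound). No ligand-depletion correction: with 60 nM
protein and μM-range Kd the free-ligand approximation is exact to well
under a percent; a warning fires when protein concentration exceeds Kd/10.

All Kd values are fitted on a log10 scale (well-conditioned from pM to mM
and positive by construction); the reported standard error is delta-method
transformed. Initial Kd comes from the half-saturation point of the
response; stoichiometry starts at 1; window bounds start at the data
extremes.

## Synthetic-data model

The generators emulate the study conditions the pipeline is designed for:

* **Native spectrum** — a 36 kDa protein presenting charges 11+–13+ under a
  Gaussian envelope (envelope sd: half the charge span), apo peak for charge
  z at (M + z·m_p)/z and a 1:1 holo peak shifted by the ligand mass, with
  holo:apo heights equal to bound_fraction/(1 − bound_fraction). Peaks are
  Gaussian with sd 1 Th on a 0.05 Th grid; m_p = 1.00728 Da (average-mass
  convention). Default solution conditions for the bound fraction follow
  the 2 μM protein / 8 μM ligand incubation, via the exact binding
  quadratic.
* **ATD** — the two-conformer model above with σ = 0.35 ms on a 0–14 ms,
  0.07 ms (200-bin) grid; the compact apex is normalised to 100 counts.
* **CIU panel** — ten inhibitors (7 type I, 3 type II), voltages 21 and
  24 V, 3 replicates. Each inhibitor draws one latent stability score
  u ~ N(0,1) shared across voltages (a single stability scale drives CIU,
  guaranteeing monotone fingerprints); the per-voltage truth is
  mean + u·sd clipped to the calibrated class range, with the open 21 V
  type II range capped at 60%. Replicates differ only by trace noise — the
  split between inter-inhibitor variation (latent score) and
  inter-replicate variation (noise) is an assumption, since only pooled
  class statistics are calibrated. Given the class parameters, the 24 V
  truth exceeds the 21 V truth for every latent score, so simulated
  fingerprints are always monotone in voltage.
* **Ligand stripping** — bound fraction decays logistically with trap
  voltage, b(V) = b0/(1 + exp((V − v50)/s)), defaults v50 = 20 V, s = 3 V.
* **Titrations** — the closed-form assay models above plus additive noise.
* **Noise** — additive Gaussian, truncated at zero intensity for traces.
  Defaults: 1% of base peak (spectra), 2% of base peak (ATDs), 0.1 μcal
  (ITC), 2% of Rmax (SPR), 1% of the Fnorm span (MST).
* Panel Kd values for compound D (36 nM), Ponatinib (8 nM), JK-P3 (25 μM)
  and Linifanib (37 μM) are the reported affinities; the remaining six and
  the non-commercial ligand masses are synthetic placeholders within the
  reported nM–μM span.

Every generator is bit-reproducible under its seed; the panel generator
derives one child seed per (inhibitor, voltage, replicate).

**What the generators do not emulate:** isotope structure, salt adducts,
charge-state-dependent unfolding, multimodal or drifting baselines,
heteroscedastic detector noise, SPR kinetics (equilibrium responses only),
ITC baseline drift and peak-integration error. Passing tests therefore
demonstrate that the analysis correctly inverts data with the assumed
statistical structure — two Gaussian conformers, additive noise, calibrated
truncated-normal class truth — not that it is robust to every artefact of
real travelling-wave IMS data.

## Numerical choices

* Peak picking requires both height and prominence above the relative
  threshold (default 5% of base peak), so noise riding on a broad profile
  peak is not split into spurious peaks; centroids are intensity-weighted
  means over the FWHM region, heights are 3-point parabolic apexes.
* Charge assignment solves z from the neutral-mass consistency of peak
  pairs, accepts |z_real − round(z)| ≤ 0.2, groups peaks into series of ≥2
  consecutive charges within a 5 Da neutral-mass window, greedily by
  support; leftover peaks are returned as unassigned, never dropped.
* Bound-fraction quantitation uses peak heights (not areas), matching how
  relative species intensity is read off native spectra.
* The screening pipeline statistic (grand means near 27.6/48.9/44.2/76.7%)
  carries a small truncation shift (≲0.5%) from clipping the truth model to
  the class ranges; the acceptance tolerances include it.

## Problem sizes

The statistical recovery checks use 200 simulated panels (12 000 ATD fits,
~1 minute single-core) — enough to pin the grand class means to ±0.3% — and
100 noisy titrations for the ITC bias check. The acceptance script uses the
same 200-panel design.

## Known limitations

* The two-conformer model cannot represent intermediate unfolding states;
  traces with three or more populations will bias the statistic.
* Calibration transfers to other kinases only after recalibration; the
  built-in table is FGFR1-specific.
* No CCS calibration is provided — drift times are used as-is.
* Ambiguous calls are reported, not resolved; resolving them needs more
  voltages or orthogonal data.
* The mzML reader is a convenience adapter; the pipeline's native formats
  are the CSV dialects documented in `ciuscreen.io`.
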