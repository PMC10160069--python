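# Methods

This note documents the models, parameter choices and numerical decisions
behind `buscarb`, and what the synthetic-data tests do and do not
demonstrate about real observations.

## Secular-trend normalization

Surface-ocean pCO2 observations are shifted to a common reference year
(default 2020) with a piecewise-linear trend: 1.5 µatm yr⁻¹ for whole
years before 1992 and 1.9 µatm yr⁻¹ from 1992 onward. The boundary is
interpreted so that an observation in year y < 1992 accrues
`1.5·(1992−y) + 1.9·(ref−1992)` µatm. Both rates and the boundary are
module constants (`buscarb.gridding`), deliberately visible rather than
configurable — they define the reference climatology.

## Ordinary kriging and error propagation

The sample variogram uses the classical Matheron estimator on great-circle
separations (haversine); surveys above 4000 points are deterministically
subsampled before the O(n²) pair sweep. Three isotropic models —
spherical, exponential, gaussian — are fitted by weighted least squares
with weights `n_pairs/lag²` (short lags dominate, as they should for
interpolation); the family with the lowest weighted residual wins. All
families are parameterized by their *practical* range (the distance where
the semivariance levels off), so the autocorrelation length used for
degrees-of-freedom thinning can be read directly from the fitted model for
any family. A fit that fails to converge falls back to an exponential
model with moment-based parameters and is flagged.

Prediction is ordinary kriging with the unbiasedness constraint (Lagrange
multiplier), per cell using the nearest observations (cap 40) within a
great-circle arc of 0.5°; cells with fewer than 5 neighbours stay
unpredicted. Exact duplicate locations are averaged beforehand (counted)
to keep the system nonsingular; negative round-off variances are clamped
to zero and counted. The kriging system is solved densely per cell —
neighbourhoods are small, so exactness beats cleverness.

Aggregate uncertainty of a gridded region is `SE = √(Σσᵢ²)/√N_eff`,
applied literally as printed in the source analysis (note it does *not*
reduce to σ/√N for uniform σ; the dimensional interpretation belongs to
the original authors). `N_eff` is a greedy thinning: scanning cells in
row-major order, a cell counts iff it is farther than the autocorrelation
range from every cell already counted (floor 1). When a degenerate fit
yields so long a range that `N_eff < 0.05·N`, the uncorrected `N` is used
and flagged.

## Upwelling-zone delineation

Records are binned by distance to coast (10 km bins; sample s.d. defined
only where n ≥ 2). The offshore boundary is the outer edge of the first
bin such that this bin *and every subsequent bin with a defined s.d.* lie
below the ±30 µatm threshold — the only reading of "persistently" that is
deterministic and order-independent; a trailing data-free bin does not
break persistence. If no bin qualifies, the outermost edge is returned
with a not-converged flag. Areas use 111.0 km per degree of latitude
exactly, which uniquely reproduces the documented subsystem areas
(10°·111.0·340 km = 377,400 km²; 8°·111.0·200 km = 177,600 km²).

## Air–sea flux

`F = K0·k·ΔpCO2` with K0 from Weiss (1974) (mol kg⁻¹ atm⁻¹, converted to
volumetric with ρ = 1025 kg m⁻³), k in cm h⁻¹ converted with 8760 h yr⁻¹,
ΔpCO2 in atm; positive flux is outgassing. The Schmidt number is the
Wanninkhof (2014) quartic (Sc(20 °C) = 668). Six k parameterizations are
data entries with citations: KW14 (0.251u²), KW92 (0.31u², short-term
winds), Wanninkhof–McGillis (0.0283u³), Nightingale (0.333u + 0.222u²),
McGillis (3.3 + 0.026u³), Ho (0.266u²); all scale by (Sc/660)^−1/2.
Region totals use the *region-average* mode by default (K0, Sc, k at the
zone-mean SST/SSS/wind applied to the zone-mean ΔpCO2, then × area ×
12.011 g mol⁻¹), matching the reference procedure; a cell-wise mode is
provided because wind–pCO2 covariance can matter. Seasonal estimates use
season-specific kriged grids for all four inputs, hence season-specific
K0 and Sc. The spread metric across parameterizations is
(max−min)/min·100 on flux magnitudes.

## Carbonate system

The solver works on the total hydrogen-ion scale at 0 dbar with Mehrbach
constants as refit by Dickson & Millero (1987) (converted from the
seawater scale with Dickson 1990 bisulfate and Dickson & Riley 1979
fluoride), Dickson (1990) borate, Millero (1995) water, Uppström (1974)
total boron. Total alkalinity is carbonate + borate + water − free-H −
bisulfate − HF; phosphate and silicate alkalinity are neglected,
consistent with a surface application in which TA itself comes from a
salinity regression. pH is found by safeguarded bisection on [4, 11] to
1e-8 (the residual is monotone in [H⁺], so bracketing is robust); states
with no root in that bracket raise by default or yield NaN in per-cell
grid work. Round trips (TA,DIC)→pCO2→DIC are stable to well below
0.1 µatm; the solver's thermal sensitivity ∂ln pCO2/∂T lies in
0.03–0.05 °C⁻¹ over the relevant range, bracketing the empirical
0.0423 °C⁻¹. fCO2 inputs convert to pCO2 with the virial correction
(~0.35% at 20 °C), switchable off.

Biological drawdown in the source-water validation removes 106/16 mol DIC
and releases 1 mol TA per mol nitrate assimilated (proton consumption
during NO3⁻ uptake; the exact TA stoichiometry is not documented in the
reference analysis, so it is exposed as `ta_per_no3`). Uncertainties
propagate by first-order central finite differences from the source-water
standard errors. The non-thermal reconstruction solves, per cell:
TA(S) → DIC(TA, pCO2, SST, SSS) → pCO2(TA, DIC, T_source, S_source).

No externally validated carbonate package is bundled; the test suite
cross-checks the solver against an independently transcribed,
polynomial-root-based reference (`tests/synthetic_co2sys_reference.py`, a
synthetic stand-in, labelled as such) to < 0.1 µatm over a 625-state grid,
and the constants against published total-scale pK values.

## Preformed nutrients and production

AOU = O2_sat(θ,S) − O2 with Garcia & Gordon (1992) saturation (Benson–
Krause coefficients). Regenerated pools use the fixed oxidation ratios
16/138 (N) and 1/138 (P); preformed = total − regenerated, with negative
values retained and flagged (clipping would bias means). Water masses are
classified by vertical distance in θ to the SACW (θ = 8.56S − 289.08) and
ESACW (θ = 9.44S − 319.03) mixing lines, nearest line within 1.0 °C
(tolerance configurable; the source defines only the lines).

Production converts preformed nitrate in the upwelling flux with Redfield
106:16 and 12.011 g mol⁻¹ over 3.1536e7 s yr⁻¹. One Sverdrup is taken as
1e9 kg s⁻¹ (ρ = 1000 kg m⁻³): this choice uniquely reproduces the
documented 14.5 and 7.5 Tg C yr⁻¹ from the documented inputs (ρ = 1025
would give 14.9); the density is exposed in configuration. The
preformed fraction is mean(N_pref)/mean(N) with first-order SE
propagation, computed from nitrate (production is nitrate-based).

## Synthetic data: what it emulates, and what it does not

The survey generator produces cross-shelf transects over a schematic
meridional coastline with (i) a deterministic mean field
`pCO2(d) = 380 + 420·exp(−d/80 km)` µatm — nearshore enrichment from
freshly upwelled carbon-rich water, decaying offshore through degassing
and biological uptake; (ii) a zero-mean Gaussian random field with an
exponential variogram (sill 3600 µatm², practical range 0.5° ≈ 55 km,
matching coastal autocorrelation scales) whose variance decays offshore
with the mean anomaly, so the ±30 µatm boundary rule has a closed-form
crossing at `L·ln(sill/θ²)`; (iii) a seasonal sinusoid (±15 µatm, peaking
in austral winter). 36 tracks × 100 points are the default: 36 tracks
cycle the calendar exactly three times, so the seasonal term is balanced
in annual aggregates, and 3600 points keep every stage at desk scale
(seconds, one CPU). The random field is realized exactly by Cholesky
factorization of the covariance at the track points — no FFT-grid
artifacts, at the cost of O(n³) limited to a few thousand points.

The bottle generator is the exact forward model of the decomposition:
θ–S on the f·SACW + (1−f)·ESACW mixture line, AOU saturating with depth,
nutrients = preformed truth + oxidation ratio × AOU, plus Gaussian noise
(negative draws clipped and counted). Noise-free bottles therefore
round-trip the decomposition to machine precision; that is a correctness
check of the arithmetic, not evidence about real water masses.

Not emulated: mesoscale filaments and event-scale upwelling, wind–pCO2
covariance, alongshore structure, real SSS gradients, denitrification
(N*), or variable stoichiometry. Passing synthetic tests demonstrates the
pipeline's internal consistency and statistical calibration under its own
assumptions — not the fidelity of those assumptions to the real BUS.

## End-to-end closure check

The full synthetic run compares the area-integrated annual flux (both
subsystems combined, KW14, region-average mode, evaluated over the
*detected* zones) against the closed-form flux of the noise-free mean
field over the same zones. Using the basin total averages out the two
leading fluctuation terms of a single realization — the zone-mean of the
correlated noise field (~5 µatm) and the squared zone-mean wind wobble —
either of which can reach several percent per subsystem. Observed
closure error is typically 3–6%, within the 15% band the design targets.

## Known limitations

- The kriging neighbourhood cap (40) trades exactness for speed; with the
  0.5° radius and 0.1° cells the truncation error is far below the
  kriging σ, but pathological clustering could widen it.
- Variogram fitting on trended fields (the cross-shelf pCO2 decline is
  left in, as in the reference procedure) inflates fitted ranges; this is
  intentional — predictions use local neighbourhoods and are insensitive
  to it, but the N_eff correction inherits the long range, which is why
  the 5% fallback to N exists.
- The TA–salinity regression is fitted on synthetic bottles whose TA–S
  relation is linear by construction; with real data its validity window
  (`margin`, default ±1 salinity unit) matters and predictions outside it
  are NaN by design.
- `effective_n` depends on the cell scan order (row-major by
  construction), as any greedy thinning does.
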