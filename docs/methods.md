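# Methods

## The decay-chain model

Deadenylation is modeled as a unidirectional first-order Markov chain over
tail lengths. With x_i(t) the abundance of RNA carrying a tail of length i
and λ_i its removal rate (min⁻¹),

    dx_i/dt = λ_{i+1} x_{i+1} − λ_i x_i .

Two assumptions are load-bearing: (1) first-order Markov structure — the
flux into length i comes only from length i+1 (no endonucleolytic
shortcuts, no re-adenylation); (2) time-independent rates — λ_i does not
drift over the reaction (enzyme stays active, substrate is not depleted in
a rate-relevant way). The tailless body is absorbing, so total abundance
is conserved; this conservation is checked by `mass_balance` and enforced
to integrator tolerance in tests.

Coordinates: results are reported against tail position p counted from
the 3' end of the original tail. Gel species s = 1..N+1 (intact substrate
to bare body) relate to tail length L by s = N+1−L, and the removal event
s → s+1 hydrolyses the residue at p = s. All public interfaces use p/s;
the tail-length form above is internal.

Because the system is linear with constant coefficients, two solvers are
provided: LSODA (stiff-capable, default for the public simulation API,
rtol 1e-8 / atol 1e-10 — rates span about two orders of magnitude across
stalled positions) and an exact matrix-exponential propagator used inside
fitting loops (~100× fewer integrator internals per residual evaluation;
the two agree to ≤1e-7 in tests). For pairwise-distinct rates the Bateman
closed form serves as an independent analytic oracle; it cancels
catastrophically when rates nearly coincide, so its use is restricted to
well-separated chains and the equal-rate limit is checked against the
truncated Poisson form instead.

## Densitometry

The algorithmic contract starts at the 1D lane profile (pixel rows summed
across the lane width); image parsing is a thin adapter. Band separators
are profile minima of a lightly smoothed profile (moving mean, width 3),
ranked by the discrete second difference there: for overlapping bands the
curvature peaks exactly at the inter-band valley, for fully resolved bands
the minimum (plateau midpoint) decides alone. Exact score ties are broken
toward the most even segment widths, reflecting the near-uniform
single-nucleotide spacing of the ladder. Manual boundary curation on real
gels is replaced by a reproducible override map (boundary index → row).
Band intensity is the segment **maximum**, not the integral — integration
is more common, but the maximum is the quantity this pipeline is built
around, and with equal band widths the two differ only by a common factor
that normalization removes.

Unity-based normalization divides the whole assay matrix by its global
maximum; this is the fitting target. Column-wise normalization (each time
point scaled to max 1) is for heatmap display only and is never fed to the
fit.

## Rate estimation

The residual is the element-wise difference between the unity-normalized
observed matrix and the identically normalized simulation started from the
intact substrate, flattened over species × time; all cells are weighted
equally. Minimization uses MINPACK Levenberg–Marquardt
(`scipy.optimize.least_squares(method="lm")`). Positivity is enforced by
fitting θ = log λ (default); a box-constrained trust-region option
(`mode="box"`) fits λ directly. θ is clipped to ±16 inside the objective
so extreme LM probe steps cannot overflow the propagator.

Initialization matters on heavily stalled data: the uniform start
λ = N/t_max can converge to a distant local minimum. The default start is
therefore read off the data: on a decay chain, species s is maximally
populated roughly when the reaction front passes it, so successive
peak-time differences approximate removal times 1/λ (zero gaps floored at
a quarter of the median positive gap). If the resulting fit's RMS
residual exceeds 2% of the unity scale, uniform fallback starts (1×, ½×,
2× of N/t_max) are tried and the best solution kept.

**Standard errors.** All variants share the Gauss–Newton curvature JᵀJ at
the estimate. The default, `se_method="relative"`, models the per-cell
variance as s²·pred² (constant relative error — the natural model for
fluorescent densitometry, whose noise is multiplicative) inside a
sandwich; s² is estimated from cells with prediction > 0.01. The
classical homoscedastic formula σ̂²·diag((JᵀJ)⁻¹) is available but
understates uncertainty at positions constrained by bright bands (its
pooled σ̂ is dominated by near-empty cells); HC2/HC3 residual-based
sandwiches are offered for data with unknown noise structure. Under the
generator's conditions the relative-error SEs cover the truth at 2 SE for
97–100% of informative positions and sit within a factor of 3 of the
empirical replicate spread. In log mode, covariances map to rate units by
the delta method. Positions the reaction never exercises (see below) get
NaN SEs with a warning, as do numerically singular curvature directions.

**Informative positions.** λ_p is flagged identifiable only if both the
species it drains (s = p) and the species it feeds (s = p+1) reach ≥ 2% of
the matrix maximum at some time point. Estimates outside this mask are
returned but should not be interpreted.

**Truncation.** For reactions that do not complete, species beyond a cut
index T are aggregated into species T, which the companion model treats
as absorbing; only λ_1..λ_{T−1} are estimated and column totals are
preserved exactly. T is read as a species index by default; a
tail-position interpretation is available via `truncate_coordinate`
(identical for matrices that start at the intact species, distinct
otherwise). Fits of the slow-complex preset with T = 16 vs 17 agree on
λ_1..λ_11 to well under 2%.

**Holdout validation.** `holdout_validate` refits with chosen time points
withheld and reports the out-of-sample prediction error and the rate
distance to the full-data fit, excluding (with a warning) positions that
lose their signal in the reduced fit.

## Stalling effect

z_p = 1/λ_p is the single-event reaction time. For a non-A residue at
tail position r, relative positions are z(i) = z_{r+i}; the stalled
window is i ∈ {−2, −1, 0}. The no-stalling baseline assumes the gradual
tail-length-dependent slowdown is proportional between the mixed-tail
experiment and its matched pure-poly(A) control:

    b = (z(a₁) − z(a₂)) / (z_A(a₁) − z_A(a₂)),
    ε(i) = b · (z_A(a₁) − z_A(i)),   z_∅(i) = z(a₁) − ε(i),

with calibration anchors (a₁, a₂) = (−3, +2) by default — any positions
outside the stalled window with reliable estimates work; the anchors are
configurable. A perfectly flat control is handled as the limit ε ≡ 0
(b is then undefined and reported NaN); any other vanishing denominator
is an error directing the user to different anchors. The effect size

    ζ = Σ_{i∈{−2,−1,0}} z(i)/z_∅(i) − 2

equals 1 exactly when the mixed profile is the affinely rescaled control
(the −2 constant encodes that baseline equivalence at two of the three
positions, per the no-stalling formulation; it is asserted, not
re-derived here). ζ is invariant to common rescaling of both profiles.
For the second residue of a two-residue substrate the control positions
are taken at the same absolute tail positions, anchors shifting with r;
each residue is assessed separately.

Uncertainty on ζ is reported as the s.e.m. across replicate fits
(sd/√n, ddof 1); a first-order delta-method propagation from the per-rate
SEs is available as a diagnostic only.

**Effective tail length.** A designed mixed tail of length L with non-A
composition counts c_res and equivalences ζ_res behaves like a pure
poly(A) of length (L − Σc) + Σ c_res·ζ_res. Interactions between non-As
closer than 3 nt are not modeled (warned when positions are supplied);
ζ < 1 triggers a warning as biologically unexpected.

## Synthetic data generator

The generator emulates the study design, not any particular measured
values: a 7-mer body (UCUACAU) with a 20-nt tail; mixed variants with one
residue type at tail positions 7 and 14; nine time points at 2, 4, 6, 8,
12, 16, 24, 32, 48 min; all mass initially in the intact substrate.

*Baseline rate profile*: λ rises linearly from 0.6×peak at position 1 to
the peak (2.0 min⁻¹) at position 4, then decays exponentially (length
constant 8 nt) toward a floor of 0.5 min⁻¹ — a speed-up over the first
few removals followed by gradual deceleration, scaled per complex variant
(wild-type ×1.0 completes within 48 min; CAF1-only ×0.6; CCR4-only ×0.2,
deliberately incomplete at 48 min to exercise truncation).

*Stall factors*: per residue type, multiplicative rate reductions at
(−2, −1, 0). The tables are fixed so each preset's analytic ζ sits at the
adenosine-equivalent scale characteristic of its complex variant
(wild-type G/U/C ≈ 5.6/7.8/10.8; CAF1-only ≈ 6.6/7.5/9.5; CCR4-only
G ≈ 6 with pyrimidines ≈ 18–22) and the qualitative position patterns
hold: guanosine under the wild-type complex stalls mostly at −1,
CAF1 stalls early (−2/−1), CCR4 shows weak −2 stalling for guanosine but
is strongly inhibited by pyrimidines at −1/0. Because the generated mixed
profile is exactly the shared baseline times the factors, the baseline
construction recovers the control and ζ reduces analytically to
Σ 1/f_i − 2 (`analytic_zeta`), giving every end-to-end test an exact
ground truth.

*Noise*: per-cell multiplicative lognormal, x → x·exp(σZ),
median-unbiased, σ = 2% by default — gel densitometry is positive-valued
and heteroscedastic. Real gels additionally carry structured background,
lane-to-lane loading variation, band-shape distortion and marker
misalignment, none of which are modeled; passing recovery tests therefore
demonstrates correctness of the estimator under the stated noise model,
not robustness to every gel artifact.

*Lane rendering*: each species becomes a Gaussian band (area ∝ abundance)
at uniform ladder spacing, plus a marker lane with standards at the
intact, one-nucleotide and tailless rows; this inverts the densitometry
pipeline up to discretization and underlies the round-trip tests
(relative intensities recovered within 5% at ≥4σ band separation).

## Numerical and design choices

- Normalization inside the residual is applied to both observed and
  predicted matrices identically, so the arbitrary fluorescence scale is
  not a free parameter and estimates are invariant to rescaling the raw
  input.
- Degenerate inputs fail loudly: all-zero matrices, non-increasing time
  grids, negative rates/abundances, flat lane profiles, too few separator
  candidates (the deficit is named), out-of-range truncation indices,
  holdouts that leave fewer than two time points.
- Problem sizes in the test suite (20-seed Monte-Carlo at σ = 2%, one
  mixed substrate per complex variant with matched controls, 100 random
  oracle chains with N ≤ 25) were chosen to give stable statistics at
  interactive runtimes; all randomness is seeded.
- The two catalytic subunits are characterized only through separate
  preset variants; no claim is made that their effects add, and no
  enzyme-binding or processivity sub-steps are modeled.

## Known limitations

- Rates are identifiable only where the reaction front actually passes
  during the observation window; for slow complexes the truncated model
  is required and later positions remain unconstrained.
- The stalling construction assumes the proportional-slowdown hypothesis
  between experiments; violations bias b and hence ζ.
- Closely spaced non-A residues (< 3 nt apart) overlap their stall
  windows; neither the generator presets nor the effective-length
  arithmetic models that interaction.
- The equal-weight residual treats every matrix cell as equally reliable;
  masking of known-bad bands is not implemented.
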