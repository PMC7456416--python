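# Methods

## Spectral model and units

A CD spectrum is a pair (wavelength grid in nm, intensities in kMRE =
1000 deg·cm²·dmol⁻¹).  kMRE is the single internal unit; readers never
auto-convert (a `--mre` flag divides by 1000 on load for files in plain
MRE).  Silent unit conversions are exactly the class of scale bug this
package exists to quantify, so the conversion is explicit or absent.

All deviation measures are sums over *shared measured wavelengths*:
`align_grids` restricts two spectra to the exact intersection of their
grids (absolute tolerance 1e-6 nm) and never invents values.  Linear
interpolation exists but only as an explicit opt-in.  The default
synthetic grid is 175–269 nm at 1 nm (95 points) — a typical
synchrotron-radiation CD range; it is configurable and recorded in every
output header.

## Prediction and scaling

A predicted spectrum is the composition-weighted sum of basis spectra.
Comparison metrics are the RMSD in kMRE and the NRMSD (RMSD divided by the
RMS of the measured intensities).  The RMSD responds linearly and
type-independently to injected spectral errors; the NRMSD does not,
because the error also changes its normalization term — superlinear for
under-scaled spectra, sublinear for over-scaled or contaminated ones.
That non-linearity is why only RMSD feeds the prediction-based validation
schemes.

Scaling convention, fixed once and loudly: the **measured** spectrum
carries the concentration error, so the factor `α` multiplies the measured
spectrum, `α = ⟨pred, meas⟩/⟨meas, meas⟩`, and the scaling error is
`|α−1|/α`.  The inverse convention silently inverts that formula.
Ensemble scaling averages the per-prediction factors with equal weights;
non-positive factors (anti-correlated predictions) have no concentration
interpretation and are excluded with a logged warning.

## Deconvolution

The objective is the RMSD between the spectrum and the coefficient-weighted
basis combination, minimized by a multistart adaptive Nelder–Mead simplex
search.  The simplex uses the Gao–Han dimension-dependent parameters
(reflection 1, expansion 1 + 2/n, contraction 0.75 − 1/(2n), shrink
1 − 1/n), as provided by scipy's adaptive Nelder–Mead; the multistart
scheme, constraint handling and acceptance logic are this package's own.

Constraint handling:

* **D1** — the unit sum is exact by construction: the search runs in an
  (n−1)-dimensional reparameterization with the last coefficient defined
  as one minus the rest.  Non-negativity (D1 and D2) is a quadratic
  exterior penalty with weight 1e3 · RMS(spectrum).  If the accepted
  optimum still violates non-negativity beyond 1e-5, the penalty is
  doubled and the whole start schedule re-run (up to three doublings).
  The 1e-5 slack is the inherent resolution of an exterior penalty at this
  weight (residual violation ≈ gradient / 2·weight).
* **D2** — non-negative only; the fitted scale of the measured spectrum is
  1/(sum of clamped coefficients).
* **D3** — unconstrained; kept on the same simplex code path so the three
  regimes differ only in their declared constraints.

Defaults: 500 starts for D1, 200 for D2/D3; convergence when the simplex
spread falls below 1e-6 in both objective and coefficients; 2000-iteration
cap per start, with capped searches counted as non-converged (a result
with `n_converged = 0` is returned flagged, not hidden — constrained
searches genuinely fail to converge sometimes, and that behaviour is part
of what the benchmark measures).  Start coefficients: D1 uniform on the
probability simplex (Dirichlet(1)); D2 a simplex draw times a factor
uniform in [0.5, 2] so starts probe plausible scaling errors; D3
additionally flips signs with probability 0.1.  Per-start RNG streams are
derived from (seed, start index), so enlarging `n_starts` extends the
schedule without reshuffling earlier starts, which makes the best-fit RMSD
non-increasing in `n_starts`.  Ties in the best-fit selection go to the
earliest start, for reproducibility.

Post-processing (all regimes): negative coefficients clamped to zero, the
remainder renormalized to unit sum; the implied measured-spectrum scale is
1/(sum of clamped coefficients).  D1 reports scale 1 — it never rescales.

## Synthetic benchmark

The correct model is 30% helix / 40% strand / 30% other; the correct
spectrum is its prediction with the fixture basis.  The 21 candidate
models swap fixed amounts between class pairs, so each true deviation
`ΔSS_j` (half the L1 distance) equals the swapped amount; the table values
are nevertheless recomputed, never stored blindly.

The 21 spectra inject errors as `1/α · (correct + w · contamination)`,
with eight scaling-only recipes (1/α ∈ {0.3, 0.7, 0.8, 0.9, 1.1, 1.2,
1.3, 1.5}), eight contamination-only recipes (w ∈ {±0.1, ±0.3, ±0.5,
±1.0}), and four combined recipes ((1.3, 0.2), (0.8, −0.3), (0.7, 1.0),
(1.1, −1.0)).  The contamination is rescaled to the same RMS intensity as
the correct signal *before* weighting.  "Average intensity" is read as RMS
intensity deliberately: only under RMS normalization does the injected
deviation of a contamination-only spectrum equal |w| exactly for **any**
contamination shape (expand `RMS(c + w·n)/RMS(c)` with `RMS(n) = RMS(c)`),
which is what makes that column of the benchmark reproducible without any
particular residual signal.  The combined recipes' deviations depend on
the correct–contamination cosine and are recomputed from the realized
spectra via the full quadratic form
`(1/α − 1)² + (w/α)² + 2·(1/α)(1/α − 1)·w·cos`.

The fixture basis is a seeded sum of Gaussian bands per class with
canonical far-UV shapes (helix: strong positive ≈193 nm, double negative
≈208/222 nm; strand: positive ≈196 nm, negative ≈218 nm; disordered:
deep negative ≈198 nm) and small seeded jitter; draws must be full rank
with condition number < 1e3.  The contamination fixture is a seeded sum of
3–5 signed Gaussian bands, regenerated if nearly parallel to the correct
signal (|cos| > 0.95).  A measured non-SS residual spectrum can replace
the synthetic contamination through the same entry point; it is RMS-
rescaled on the way in.

What the generator does *not* emulate: instrument noise, baseline drift,
wavelength-dependent error correlation, and the specific band shapes of
any published basis set.  Benchmark results therefore demonstrate the
behaviour of the *methods* under controlled error injection, not the
numeric accuracy of any particular real basis set.

## Validation schemes and scoring

V1 and V2 deconvolve the raw spectrum (D1, D2) and report the composition
distance to the proposed model.  V3 first rescales the measured spectrum
to the proposed model's *prediction*, then uses D1 — when the model is
wrong the rescaling target is wrong too; that bias is a property of the
scheme being studied and is deliberately not corrected.  V4/V5 rescale
the measured spectrum against the model's prediction and convert the
remaining RMSD to an SS error through a sensitivity slope `m_f` (kMRE per
unit deviation); presets 15.6 (experimental calibration) and 30.7
(synthetic-population calibration) kMRE.

Per spectrum, the validation error is the mean of (estimated − true)
deviation over the 20 wrong models; the ranking score counts wrong models
whose estimated error is *lower than or equal to* the correct model's
(ties count against the method).  Expected behaviours, all covered by
tests: with rescaling (V2/V4/V5) the error profile over scaling-only
spectra is flat and the rank stays 0; without it (V1) the error grows with
the scaling error; with a perfect estimator both scores are identically
zero.

Calibration fits the slope of RMSD on true deviation **through the
origin** (a correct model against an ideal spectrum has zero RMSD, so no
intercept is admitted) and reports the Pearson correlation as a
diagnostic.  The synthetic reference population draws compositions uniform
on the simplex, scaling factors Normal(0.87, 0.25) truncated to α > 0.2
(the truncation shifts the population mean by ≈0.003 and the SD by
≈0.004 — below sampling noise at the sizes used), and contamination
weights half-Normal with the scale set so the population median is 0.2,
with random sign and a fresh seeded contamination shape per protein.
These defaults describe a typical high-quality SR-CD reference set: mean
scaling factor below one (adsorption losses), about half the spectra with
non-SS contributions under 20%.

## Reference-set analysis

Per protein: the ensemble α from all basis-set predictions; the spectrum
rescaled by α; per basis set a deconvolution, the composition deviation,
the non-SS contribution (relative residual between the *fitted* raw
combination and the rescaled spectrum) and the noise-to-signal ratio
(prediction residual over the estimated-signal RMS); then plain averages
over basis sets.  Using the fitted raw combination — not the renormalized
composition's prediction — is what makes the residual isolate the non-SS
part.  Two consequences, both intended: the measure *underestimates* true
contamination (the fit absorbs whatever part of it lies in the basis
span), and the ensemble α is biased when contamination correlates with the
SS signal.  Proteins whose every scaling factor is non-positive are
skipped with a logged reason, never silently.

Population summaries are sample moments, or for non-negative error
magnitudes a maximum-likelihood Normal truncated at zero (Nelder–Mead on
the negative log-likelihood, initialized at the sample moments).

## Numerical choices and limitations

* Grid equality tolerance 1e-6 nm; file round-trips use `%.17g` and are
  lossless.
* Basis linear independence: smallest singular value above 1e-10 of the
  largest; rank-deficiency reports name the most collinear column pair.
* Degenerate deconvolutions (all coefficients non-positive after
  clamping) raise rather than return a fabricated composition.
* Problem sizes in the shipped tests and the acceptance script (start
  counts 40–200 where the search space is the well-conditioned 3-class
  fixture, populations of 500–10⁴) were chosen as the smallest sizes at
  which the checked statistics are stable; the library defaults remain
  500/200 starts.
* The multistart search is a global heuristic: on ill-conditioned or
  many-class bases the usual Nelder–Mead caveats apply, and `n_converged`
  should be inspected.
* Real-data accuracy claims require real basis sets and residuals; the
  package loads them through the same file formats but ships none.
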