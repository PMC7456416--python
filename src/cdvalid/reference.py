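"""Error characterization of a CD reference set.

Given measured spectra paired with reference SS compositions, this module
estimates, per protein:

* the ensemble scaling factor ``alpha`` (average of the optimal factors
  against each basis set's prediction) and the implied scaling error
  ``|alpha - 1| / alpha``;
* the SS deviation between the reference composition and the composition
  estimated by deconvolving the rescaled spectrum (averaged over basis
  sets);
* the non-SS contribution: the relative residual between the back-
  calculated SS signal and the rescaled measured spectrum;
* the noise-to-signal ratio: the total prediction residual relative to the
  estimated SS signal.

Population summaries are plain or zero-truncated Gaussian fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .deconvolution import deconvolve
from .errors import CalibrationError, ScalingDomainError
from .prediction import ensemble_scale, predict_spectrum
from .spectra import BasisSet, CDSpectrum, SSComposition, align_grids
from .synthetic import ss_deviation

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceErrorRecord:
    """Per-protein error estimates, averaged over basis sets."""

    protein_id: str
    alpha: float
    scaling_error: float
    ss_deviation: float
    nonss_contribution: float
    noise_to_signal: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ScalingDomainError("alpha must be positive")
        for name in ("scaling_error", "ss_deviation",
                     "nonss_contribution", "noise_to_signal"):
            if getattr(self, name) < 0:
                raise ScalingDomainError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DistributionSummary:
    """Gaussian summary of an error population, optionally truncated at 0."""

    mean: float
    sd: float
    truncated: bool
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n < 1:
            raise CalibrationError("invalid distribution summary")


def nonss_contribution(estimated_signal: CDSpectrum, measured: CDSpectrum,
                       alpha: float) -> float:
    """Relative non-SS residual:
    ``RMS(estimated - alpha * measured) / RMS(alpha * measured)``."""
    if alpha <= 0:
        raise ScalingDomainError(f"alpha must be positive, got {alpha}")
    estimated_signal, measured = align_grids(estimated_signal, measured)
    ref = alpha * measured.intensities
    denom = np.sum(ref ** 2)
    if denom == 0.0:
        raise ScalingDomainError("rescaled measured spectrum has zero norm")
    num = np.sum((estimated_signal.intensities - ref) ** 2)
    return float(np.sqrt(num / denom))


def noise_to_signal(predicted: CDSpectrum, measured: CDSpectrum,
                    estimated_signal: CDSpectrum) -> float:
    """Total prediction residual relative to the estimated SS signal:
    ``RMS(predicted - measured) / RMS(estimated)``."""
    predicted, measured = align_grids(predicted, measured)
    est, _ = align_grids(estimated_signal, predicted)
    denom = np.sum(est.intensities ** 2)
    if denom == 0.0:
        raise ScalingDomainError("estimated signal has zero norm")
    num = np.sum((predicted.intensities - measured.intensities) ** 2)
    return float(np.sqrt(num / denom))


def analyze_reference_set(entries: Sequence[tuple],
                          basis_sets: Sequence[BasisSet],
                          deconv_options: dict | None = None,
                          deconv_mode: str = "D1",
                          ) -> list[ReferenceErrorRecord]:
    """Run the full error-estimation pipeline over a reference set.

    ``entries`` pairs each measured :class:`CDSpectrum` with its reference
    :class:`SSComposition`.  Per protein: the ensemble scaling factor is
    formed from the predictions of all basis sets, the spectrum rescaled by
    it, and the deconvolution-based error measures computed per basis set
    and averaged.  Failing proteins are logged and skipped, never silently
    dropped.
    """
    if not entries:
        raise CalibrationError("empty reference set")
    opts = dict(deconv_options or {})
    records = []
    n_failed = 0
    for idx, (measured, ref_comp) in enumerate(entries):
        pid = measured.label or f"protein{idx}"
        try:
            predictions = [predict_spectrum(ref_comp, b) for b in basis_sets]
            scale = ensemble_scale(measured, predictions)
            rescaled = measured.scaled(scale.alpha)
            dss, d0, dtot = [], [], []
            for b, predicted in zip(basis_sets, predictions):
                result = deconvolve(rescaled, b, mode=deconv_mode, **opts)
                est_comp = result.composition
                # back-calculated SS signal: the *fitted* combination (raw
                # coefficients), so the residual against the rescaled
                # spectrum isolates the non-SS part rather than mixing in
                # the renormalization of the composition
                raw = SSComposition(b.class_labels,
                                    result.raw_coefficients, raw=True)
                est_signal = predict_spectrum(raw, b)
                dss.append(ss_deviation(est_comp, ref_comp))
                d0.append(nonss_contribution(est_signal, measured, scale.alpha))
                dtot.append(noise_to_signal(predicted, rescaled, est_signal))
            records.append(
                ReferenceErrorRecord(
                    protein_id=pid,
                    alpha=scale.alpha,
                    scaling_error=scale.scaling_error,
                    ss_deviation=float(np.mean(dss)),
                    nonss_contribution=float(np.mean(d0)),
                    noise_to_signal=float(np.mean(dtot)),
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-protein isolation
            n_failed += 1
            log.warning("skipping %s: %s", pid, exc)
    if n_failed:
        log.warning("analyze_reference_set: %d of %d proteins skipped",
                    n_failed, len(entries))
    return records


def fit_distribution(values: Sequence[float],
                     truncated: bool = False) -> DistributionSummary:
    """Summarize an error population by a Gaussian.

    Untruncated: sample mean and SD.  Truncated: maximum-likelihood
    parameters of a Normal truncated to positive values (the form expected
    for magnitudes of random deviations), found by Nelder–Mead on the
    negative log-likelihood.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise CalibrationError("need >= 2 values")
    mean, sd = float(np.mean(arr)), float(np.std(arr, ddof=1))
    if sd == 0.0:
        log.warning("fit_distribution: all values identical")
        return DistributionSummary(mean, 0.0, truncated, int(arr.size))
    if not truncated:
        return DistributionSummary(mean, sd, False, int(arr.size))
    if np.any(arr < 0):
        raise CalibrationError("truncated fit requires non-negative values")

    def nll(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        z = (arr - mu) / sigma
        # normalization over the positive half-line
        log_z = np.log(stats.norm.sf(-mu / sigma))
        return float(np.sum(0.5 * z ** 2 + log_sigma + log_z))

    res = optimize.minimize(nll, x0=[mean, np.log(sd)], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-8,
                                     "maxiter": 2000})
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    return DistributionSummary(mu, sigma, True, int(arr.size))
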