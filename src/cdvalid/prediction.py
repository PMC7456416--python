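"""CD-spectrum prediction from secondary-structure compositions, spectral
deviation measures (RMSD / NRMSD), and intensity scaling factors.

Convention used throughout: the *measured* spectrum is the one that carries
the concentration-normalization error, so the scaling factor ``alpha``
multiplies the measured spectrum to best match a prediction.  The inverse
convention would silently invert the scaling-error formula
``|alpha - 1| / alpha``, so it is fixed here once and documented loudly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EstimationError, ScalingDomainError
from .spectra import BasisSet, CDSpectrum, SSComposition, align_grids, rms_intensity

log = logging.getLogger(__name__)


def predict_spectrum(comp: SSComposition, basis: BasisSet,
                     label: str | None = None) -> CDSpectrum:
    """Predict a CD spectrum as the composition-weighted sum of basis spectra.

    Labels are matched by name, order-insensitively.  The result lives on
    the basis grid.
    """
    comp = comp.reordered(basis.class_labels)
    intensities = basis.matrix() @ comp.fractions
    if label is None:
        label = f"pred[{basis.name}]"
    return CDSpectrum(basis.wavelengths, intensities, label)


def rmsd(a: CDSpectrum, b: CDSpectrum) -> float:
    """Root-mean-square deviation between two spectra (kMRE), on the
    intersection of their grids."""
    a, b = align_grids(a, b)
    return float(np.sqrt(np.mean((a.intensities - b.intensities) ** 2)))


def nrmsd(pred: CDSpectrum, measured: CDSpectrum) -> float:
    """RMSD divided by the RMS of the measured intensities (dimensionless).

    A relative deviation measure; unlike plain RMSD it responds non-linearly
    to scaling errors because they also change the normalization term.
    """
    pred, measured = align_grids(pred, measured)
    denom = rms_intensity(measured)
    if denom == 0.0:
        raise ScalingDomainError("measured spectrum has zero RMS intensity")
    return rmsd(pred, measured) / denom


def optimal_scale(measured: CDSpectrum, predicted: CDSpectrum) -> float:
    """Scaling factor alpha minimizing RMSD(predicted, alpha * measured).

    Closed form: alpha = <pred, meas> / <meas, meas>.  May be <= 0 for
    anti-correlated spectra; callers decide whether that is admissible.
    """
    measured, predicted = align_grids(measured, predicted)
    denom = float(np.dot(measured.intensities, measured.intensities))
    if denom == 0.0:
        raise ScalingDomainError("measured spectrum has zero norm")
    return float(np.dot(predicted.intensities, measured.intensities) / denom)


def scaling_error(alpha: float) -> float:
    """Scaling error |alpha - 1| / alpha of a spectrum corrected by alpha."""
    if alpha <= 0:
        raise ScalingDomainError(f"scaling factor must be positive, got {alpha}")
    return abs(alpha - 1.0) / alpha


@dataclass(frozen=True)
class ScalingEstimate:
    """Ensemble scaling factor for a measured spectrum.

    ``alpha`` is the arithmetic mean of the per-prediction factors that were
    retained; non-positive factors (anti-correlated predictions, which have
    no concentration interpretation) are excluded with a logged warning and
    counted in ``n_excluded``.
    """

    alpha: float
    per_prediction_alphas: tuple
    scaling_error: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ScalingDomainError(f"ensemble alpha must be positive, got {self.alpha}")
        if self.per_prediction_alphas:
            mean = float(np.mean(self.per_prediction_alphas))
            if abs(mean - self.alpha) > 1e-9 * max(1.0, abs(mean)):
                raise EstimationError("alpha is not the mean of its factors")


def ensemble_scale(measured: CDSpectrum,
                   predictions: Sequence[CDSpectrum]) -> ScalingEstimate:
    """Average the per-prediction optimal scaling factors into one alpha.

    Each prediction contributes equally (no fit-quality weighting, no
    trimming).  Raises :class:`EstimationError` if every factor is
    non-positive.
    """
    if not predictions:
        raise EstimationError("ensemble_scale needs at least one prediction")
    factors = [optimal_scale(measured, p) for p in predictions]
    kept = [f for f in factors if f > 0]
    n_excluded = len(factors) - len(kept)
    if n_excluded:
        log.warning(
            "excluded %d non-positive scaling factor(s) from ensemble for %r",
            n_excluded, measured.label,
        )
    if not kept:
        raise EstimationError(
            f"all {len(factors)} scaling factors non-positive for {measured.label!r}"
        )
    alpha = float(np.mean(kept))
    return ScalingEstimate(
        alpha=alpha,
        per_prediction_alphas=tuple(kept),
        scaling_error=scaling_error(alpha),
        n_excluded=n_excluded,
    )
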