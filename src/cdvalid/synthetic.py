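"""Synthetic ground-truth benchmark for CD-based model validation.

The benchmark consists of

* 21 secondary-structure *models* spanning the helix/strand/coil space
  around a correct composition of 30% helix, 40% strand, 30% other, each
  with an exactly known deviation from the correct model, and
* 21 synthetic *spectra* derived from the correct CD signal by injecting a
  multiplicative scaling error (factor ``1/alpha``), an additive non-SS
  contamination of weight ``w``, or both, each with an exactly known
  spectral deviation.

Because the contamination signal is rescaled to the same RMS intensity as
the correct spectrum before weighting, the injected spectral deviation of a
pure-contamination spectrum is exactly ``|w|`` *regardless of the
contamination shape* — which is what makes the contamination series of the
benchmark reproducible with any seeded stand-in signal.  The four combined
scaling+contamination spectra have deviations that do depend on the
correct–contamination overlap and are therefore recomputed, not tabulated.

Real basis spectra are loadable through :mod:`cdvalid.spectra`; this module
also provides a seeded synthetic three-class basis with canonical far-UV
band shapes for self-contained benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, LabelMappingError, ScalingDomainError
from .prediction import predict_spectrum
from .spectra import (
    DEFAULT_GRID,
    BasisSet,
    CDSpectrum,
    SSComposition,
    align_grids,
    rms_intensity,
)

#: canonical class labels of the three-class benchmark
SS_LABELS = ("alpha-helix", "beta-strand", "other")

#: the correct model: 30% helix, 40% strand, 30% other
CORRECT_COMPOSITION = (0.3, 0.4, 0.3)

# name -> (helix, strand, other); the 20 perturbed models swap fractions
# between pairs of classes (AB: helix<->strand, BC: strand<->other,
# AC: helix<->other), so each row's deviation from the correct model is the
# swapped amount itself.
MODEL_TABLE = (
    ("Correct", (0.30, 0.40, 0.30)),
    ("AB+30", (0.00, 0.70, 0.30)),
    ("AB+20", (0.10, 0.60, 0.30)),
    ("AB+10", (0.20, 0.50, 0.30)),
    ("AB-10", (0.40, 0.30, 0.30)),
    ("AB-20", (0.50, 0.20, 0.30)),
    ("AB-30", (0.60, 0.10, 0.30)),
    ("AB-40", (0.70, 0.00, 0.30)),
    ("BC+36", (0.30, 0.04, 0.66)),
    ("BC+26", (0.30, 0.14, 0.56)),
    ("BC+16", (0.30, 0.24, 0.46)),
    ("BC+6", (0.30, 0.34, 0.36)),
    ("BC-6", (0.30, 0.46, 0.24)),
    ("BC-16", (0.30, 0.56, 0.14)),
    ("BC-26", (0.30, 0.66, 0.04)),
    ("AC+23", (0.07, 0.40, 0.53)),
    ("AC+13", (0.17, 0.40, 0.43)),
    ("AC+3", (0.27, 0.40, 0.33)),
    ("AC-3", (0.33, 0.40, 0.27)),
    ("AC-13", (0.43, 0.40, 0.17)),
    ("AC-23", (0.53, 0.40, 0.07)),
)

# name -> (1/alpha, w); S rows inject scaling only, C rows contamination
# only, CS rows both (contamination weighted first, then scaled).
SPECTRUM_TABLE = (
    ("Correct", 1.0, 0.0),
    ("S+10", 1.1, 0.0),
    ("S+20", 1.2, 0.0),
    ("S+30", 1.3, 0.0),
    ("S+50", 1.5, 0.0),
    ("S-10", 0.9, 0.0),
    ("S-20", 0.8, 0.0),
    ("S-30", 0.7, 0.0),
    ("S-70", 0.3, 0.0),
    ("C+10", 1.0, 0.1),
    ("C+30", 1.0, 0.3),
    ("C+50", 1.0, 0.5),
    ("C+100", 1.0, 1.0),
    ("C-100", 1.0, -1.0),
    ("C-50", 1.0, -0.5),
    ("C-30", 1.0, -0.3),
    ("C-10", 1.0, -0.1),
    ("CS-1", 1.3, 0.2),
    ("CS-2", 0.8, -0.3),
    ("CS-3", 0.7, 1.0),
    ("CS-4", 1.1, -1.0),
)


@dataclass(frozen=True)
class SyntheticModel:
    """One candidate SS composition with its exact deviation from truth."""

    model_id: int
    name: str
    composition: SSComposition
    true_ss_deviation: float


@dataclass(frozen=True)
class SyntheticSpectrumSpec:
    """One synthetic spectrum: its error-injection recipe and realization.

    ``inv_alpha`` is the multiplicative factor 1/alpha applied to the
    combined signal; ``w`` the signed contamination weight;
    ``true_cd_deviation`` the realized deviation from the correct spectrum
    as a fraction of the correct-signal RMS (recomputed, never tabulated).
    """

    spectrum_id: int
    name: str
    inv_alpha: float
    w: float
    spectrum: CDSpectrum
    true_cd_deviation: float

    def __post_init__(self) -> None:
        if self.inv_alpha <= 0:
            raise ScalingDomainError(f"1/alpha must be positive, got {self.inv_alpha}")


def ss_deviation(est: SSComposition, ref: SSComposition) -> float:
    """Half the L1 distance between two normalized compositions, in [0, 1].

    This is the fraction of residues that would have to change class to
    turn one composition into the other.
    """
    est = est.reordered(ref.class_labels)
    if est.raw or ref.raw:
        raise LabelMappingError("ss_deviation requires normalized compositions")
    return float(np.sum(np.abs(est.fractions - ref.fractions)) / 2.0)


def spectrum_error(synthetic: CDSpectrum, correct: CDSpectrum) -> float:
    """Deviation of a spectrum from the correct one, as a fraction of the
    correct-signal RMS: ``RMS(synthetic - correct) / RMS(correct)``."""
    synthetic, correct = align_grids(synthetic, correct)
    denom = np.sum(correct.intensities ** 2)
    if denom == 0.0:
        raise ScalingDomainError("correct spectrum has zero RMS")
    num = np.sum((synthetic.intensities - correct.intensities) ** 2)
    return float(np.sqrt(num / denom))


def correct_model() -> SSComposition:
    return SSComposition(SS_LABELS, np.asarray(CORRECT_COMPOSITION))


def make_model_grid() -> list[SyntheticModel]:
    """The 21 benchmark SS models; the correct model sits at index 0 and
    every deviation is recomputed from the compositions."""
    ref = correct_model()
    models = []
    for j, (name, fractions) in enumerate(MODEL_TABLE):
        comp = SSComposition(SS_LABELS, np.asarray(fractions))
        models.append(
            SyntheticModel(
                model_id=j,
                name=name,
                composition=comp,
                true_ss_deviation=ss_deviation(comp, ref),
            )
        )
    return models


# ---------------------------------------------------------------------------
# fixture basis and contamination signals


def _gaussian_bands(wavelengths: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(wavelengths, dtype=float)
    for center, width, amplitude in bands:
        out += amplitude * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return out

# canonical far-UV band parameters (center nm, width nm, amplitude kMRE):
# helix shows the strong positive pi-pi* band near 193 nm and the double
# negative at 208/222 nm; strand a weaker positive near 196 and negative
# near 218; disordered/other a deep negative near 198 nm.
_CANONICAL_BANDS = {
    "alpha-helix": ((193.0, 6.5, 65.0), (208.0, 6.0, -22.0), (222.0, 7.5, -26.0)),
    "beta-strand": ((196.0, 7.0, 28.0), (218.0, 8.0, -14.0)),
    "other": ((198.0, 7.0, -35.0), (222.0, 9.0, 2.5)),
}

#: maximum allowed condition number for a generated fixture basis
FIXTURE_COND_MAX = 1e3


def make_fixture_basis(n_classes: int = 3, seed: int = 0,
                       wavelengths: np.ndarray | None = None) -> BasisSet:
    """Seeded synthetic basis set built from sums of Gaussian bands.

    The default three-class set mimics canonical helix / strand / coil
    far-UV shapes with a small seeded jitter on band positions and
    amplitudes; for ``n_classes > 3`` additional classes get random band
    mixtures.  The generated matrix is guaranteed full rank with condition
    number below 1e3 (regenerated with a perturbed seed when the draw
    fails; error after 10 attempts).
    """
    if n_classes < 2:
        raise ConfigurationError("need >= 2 classes")
    wl = DEFAULT_GRID if wavelengths is None else np.asarray(wavelengths, float)
    for attempt in range(10):
        rng = np.random.default_rng([int(seed), attempt, 0xBA515])
        labels = []
        columns = []
        for i in range(n_classes):
            if i < 3:
                label = SS_LABELS[i]
                bands = [
                    (c + rng.uniform(-0.5, 0.5), s * (1 + rng.uniform(-0.05, 0.05)),
                     a * (1 + rng.uniform(-0.05, 0.05)))
                    for c, s, a in _CANONICAL_BANDS[label]
                ]
            else:
                label = f"class{i + 1}"
                bands = [
                    (rng.uniform(180, 250), rng.uniform(5, 12), rng.uniform(-40, 40))
                    for _ in range(rng.integers(2, 4))
                ]
            labels.append(label)
            columns.append(_gaussian_bands(wl, bands))
        m = np.column_stack(columns)
        sv = np.linalg.svd(m, compute_uv=False)
        if sv[-1] > 0 and sv[0] / sv[-1] < FIXTURE_COND_MAX:
            spectra = tuple(
                CDSpectrum(wl, col, label=lab) for lab, col in zip(labels, columns)
            )
            return BasisSet(tuple(labels), spectra, name=f"fixture{n_classes}-s{seed}")
    raise ConfigurationError(
        f"could not generate a well-conditioned {n_classes}-class basis "
        f"from seed {seed} in 10 attempts"
    )


#: maximum allowed |cosine| between contamination and correct spectrum
CONTAMINATION_COS_MAX = 0.95


def make_contamination(correct: CDSpectrum, seed: int = 0) -> CDSpectrum:
    """Seeded smooth non-SS contamination signal on the grid of ``correct``.

    A sum of 3–5 Gaussian bands with signed amplitudes, rescaled so its RMS
    intensity equals that of the correct spectrum exactly.  Draws nearly
    parallel to the correct spectrum (|cosine| > 0.95) are regenerated;
    error after 10 attempts.
    """
    target_rms = rms_intensity(correct)
    if target_rms == 0.0:
        raise ScalingDomainError("correct spectrum has zero RMS")
    wl = correct.wavelengths
    for attempt in range(10):
        rng = np.random.default_rng([int(seed), attempt, 0xC0477])
        n_bands = int(rng.integers(3, 6))
        bands = [
            (rng.uniform(180, 260), rng.uniform(5, 15), rng.uniform(-1, 1))
            for _ in range(n_bands)
        ]
        signal = _gaussian_bands(wl, bands)
        rms = np.sqrt(np.mean(signal ** 2))
        if rms == 0.0:
            continue
        signal = signal * (target_rms / rms)
        cos = float(
            np.dot(signal, correct.intensities)
            / (np.linalg.norm(signal) * np.linalg.norm(correct.intensities))
        )
        if abs(cos) <= CONTAMINATION_COS_MAX:
            return CDSpectrum(wl, signal, label=f"contamination-s{seed}")
    raise ConfigurationError(
        f"could not generate contamination from seed {seed} in 10 attempts"
    )


def compose_spectrum(correct: CDSpectrum, contamination: CDSpectrum,
                     w: float, inv_alpha: float,
                     label: str | None = None) -> CDSpectrum:
    """Inject errors into the correct spectrum:
    ``inv_alpha * (correct + w * contamination)`` point-wise.

    ``contamination`` must already be RMS-normalized to the correct
    spectrum (as :func:`make_contamination` guarantees); this is re-checked
    so the injected contamination deviation is exactly ``|w|``.
    """
    if inv_alpha <= 0:
        raise ScalingDomainError(f"1/alpha must be positive, got {inv_alpha}")
    if not correct.same_grid(contamination):
        correct, contamination = align_grids(correct, contamination)
    rms_c = rms_intensity(correct)
    rms_n = rms_intensity(contamination)
    if abs(rms_n - rms_c) > 1e-6 * max(rms_c, 1.0):
        raise ConfigurationError(
            f"contamination RMS {rms_n:.6g} != correct RMS {rms_c:.6g}; "
            "rescale it first (make_contamination does)"
        )
    values = inv_alpha * (correct.intensities + w * contamination.intensities)
    if label is None:
        label = f"synthetic(w={w:g},1/a={inv_alpha:g})"
    return CDSpectrum(correct.wavelengths, values, label)


def make_spectrum_grid(correct: CDSpectrum,
                       contamination: CDSpectrum) -> list[SyntheticSpectrumSpec]:
    """The 21 benchmark spectra: the correct one, eight scaling-only (S±),
    eight contamination-only (C±), and four combined (CS) recipes, each with
    its deviation recomputed from the realized spectrum."""
    specs = []
    for k, (name, inv_alpha, w) in enumerate(SPECTRUM_TABLE):
        spectrum = compose_spectrum(correct, contamination, w, inv_alpha, label=name)
        specs.append(
            SyntheticSpectrumSpec(
                spectrum_id=k,
                name=name,
                inv_alpha=inv_alpha,
                w=w,
                spectrum=spectrum,
                true_cd_deviation=spectrum_error(spectrum, correct),
            )
        )
    return specs


def make_correct_spectrum(basis: BasisSet) -> CDSpectrum:
    """The correct CD signal: the correct model predicted with ``basis``."""
    comp = correct_model().reordered(basis.class_labels)
    spectrum = predict_spectrum(comp, basis, label="Correct")
    return spectrum


def build_benchmark(seed: int = 0, basis: BasisSet | None = None,
                    contamination: CDSpectrum | None = None):
    """Assemble the complete benchmark.

    Returns ``(models, spectra, basis, contamination, correct)`` where the
    basis and contamination default to the seeded fixtures.  A measured
    non-SS residual spectrum can be passed in place of the synthetic
    contamination; it is RMS-rescaled to the correct signal first.
    """
    if basis is None:
        basis = make_fixture_basis(seed=seed)
    correct = make_correct_spectrum(basis)
    if contamination is None:
        contamination = make_contamination(correct, seed=seed)
    else:
        contamination, correct_a = align_grids(contamination, correct)
        scale = rms_intensity(correct_a) / rms_intensity(contamination)
        contamination = contamination.scaled(scale)
        correct = correct_a
    models = make_model_grid()
    spectra = make_spectrum_grid(correct, contamination)
    return models, spectra, basis, contamination, correct


def benchmark_manifest(seed: int, models, spectra, basis, contamination) -> dict:
    """JSON-serializable record of every recipe and recomputed truth."""
    return {
        "seed": int(seed),
        "basis": basis.name,
        "grid": {
            "start_nm": float(basis.wavelengths[0]),
            "stop_nm": float(basis.wavelengths[-1]),
            "n_points": int(basis.wavelengths.size),
        },
        "contamination": contamination.label,
        "models": [
            {
                "j": m.model_id,
                "name": m.name,
                "composition": m.composition.as_dict(),
                "true_ss_deviation": m.true_ss_deviation,
            }
            for m in models
        ],
        "spectra": [
            {
                "k": s.spectrum_id,
                "name": s.name,
                "inv_alpha": s.inv_alpha,
                "w": s.w,
                "true_cd_deviation": s.true_cd_deviation,
            }
            for s in spectra
        ],
    }
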