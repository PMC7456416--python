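"""Secondary-structure estimation by constrained spectrum deconvolution.

A measured CD spectrum is approximated by a linear combination of basis
spectra; the combination coefficients estimate the fractions of residues in
each secondary-structure class.  The objective is the RMSD (kMRE) between
the spectrum and the combination, minimized by a multistart adaptive
Nelder–Mead simplex search (Gao–Han dimension-dependent reflection /
expansion / contraction / shrink parameters, as provided by
``scipy.optimize.minimize(..., method="Nelder-Mead", options={"adaptive": True})``).

Three constraint regimes are supported:

``D1``
    Coefficients non-negative and summing to one — they *are* residue
    fractions.  The unit sum is enforced exactly by searching in an
    (n-1)-dimensional reparameterization (the last coefficient is one minus
    the sum of the others); non-negativity by a quadratic exterior penalty.
    500 starts by default.
``D2``
    Non-negative only.  Dropping the unit sum lets the fit absorb an
    intensity-scaling error of the measured spectrum: the implied scaling
    factor is 1 / (sum of fitted coefficients).  200 starts by default.
``D3``
    Unconstrained linear fit (still found by the same simplex machinery so
    all three regimes share one code path).  Also scale-free, but free to
    over-fit additive non-SS contamination with negative coefficients.
    200 starts by default.

After the best (lowest-RMSD) accepted search, negative coefficients are
clamped to zero and the remainder renormalized to unit sum, yielding a
plausible composition for every regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import DegenerateFitError, SpectrumInputError
from .spectra import BasisSet, CDSpectrum, SSComposition, align_grids, rms_intensity

MODES = ("D1", "D2", "D3")

#: default number of random simplex starts per regime
DEFAULT_STARTS = {"D1": 500, "D2": 200, "D3": 200}

#: simplex convergence tolerance (objective spread and coefficient spread)
DEFAULT_TOL = 1e-6

#: iteration cap per start; searches hitting it count as non-converged
MAX_ITER = 2000

#: exterior-penalty weight, in units of the spectrum RMS
PENALTY_RMS_FACTOR = 1e3

#: feasibility slack when checking the accepted optimum; the exterior
#: penalty leaves a residual violation of order (objective gradient) /
#: (2 * penalty weight), which is ~1e-5 at the default weight
CONSTRAINT_TOL = 1e-5


@dataclass(frozen=True)
class DeconvolutionResult:
    """Outcome of a multistart deconvolution.

    ``raw_coefficients`` come from the best accepted search and may be
    negative (D3) or sum away from one (D2/D3); ``composition`` is the
    post-processed normalized estimate.  ``fitted_scale`` is the implied
    scaling factor of the measured spectrum (1 for D1).  ``fit_rmsd`` is the
    kMRE deviation of the raw best fit.
    """

    mode: str
    raw_coefficients: np.ndarray
    composition: SSComposition
    fitted_scale: float
    fit_rmsd: float
    n_searches: int
    n_converged: int
    seed: int

    @property
    def converged(self) -> bool:
        return self.n_converged > 0

    def __post_init__(self) -> None:
        if self.fit_rmsd < 0 or self.n_converged > self.n_searches:
            raise SpectrumInputError("inconsistent deconvolution bookkeeping")


def postprocess_coefficients(raw, class_labels=None):
    """Clamp negative coefficients to zero and renormalize to unit sum.

    Returns ``(composition, fitted_scale)`` where ``fitted_scale`` is
    1 / (sum of clamped coefficients) — the factor by which the measured
    spectrum would have to be multiplied to match a unit-sum composition.

    Raises :class:`DegenerateFitError` when no coefficient is positive.
    """
    raw = np.asarray(raw, dtype=float)
    if class_labels is None:
        class_labels = tuple(f"class{i + 1}" for i in range(raw.size))
    clamped = np.maximum(raw, 0.0)
    total = clamped.sum()
    if total <= 0.0:
        raise DegenerateFitError(
            f"all coefficients non-positive after clamping: {raw.tolist()}"
        )
    comp = SSComposition(tuple(class_labels), clamped / total)
    return comp, 1.0 / total


def random_start(mode: str, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    """Random starting coefficients for one simplex search.

    D1 draws uniformly from the probability simplex (Dirichlet(1)); D2
    rescales a simplex draw by a factor uniform in [0.5, 2] so starts probe
    plausible scaling errors; D3 additionally flips each coefficient's sign
    with probability 0.1.
    """
    if mode not in MODES:
        raise SpectrumInputError(f"unknown deconvolution mode {mode!r}")
    if n_classes < 2:
        raise SpectrumInputError("need >= 2 classes")
    point = rng.dirichlet(np.ones(n_classes))
    if mode == "D1":
        return point
    point = point * rng.uniform(0.5, 2.0)
    if mode == "D3":
        flips = rng.random(n_classes) < 0.1
        point = np.where(flips, -point, point)
    return point


def _start_rng(seed: int, start_index: int) -> np.random.Generator:
    # counter scheme: stream i depends only on (seed, i), so raising
    # n_starts extends the schedule without reshuffling earlier starts
    return np.random.default_rng([int(seed), int(start_index)])


def _make_objective(mode: str, B: np.ndarray, y: np.ndarray, penalty: float):
    n = B.shape[1]

    if mode == "D1":
        def objective(x):
            c = np.empty(n)
            c[:-1] = x
            c[-1] = 1.0 - x.sum()
            r = B @ c - y
            f = np.sqrt(np.mean(r * r))
            neg = np.minimum(c, 0.0)
            return f + penalty * np.dot(neg, neg)

        def expand(x):
            return np.append(x, 1.0 - np.sum(x))

        return objective, expand

    if mode == "D2":
        def objective(c):
            r = B @ c - y
            f = np.sqrt(np.mean(r * r))
            neg = np.minimum(c, 0.0)
            return f + penalty * np.dot(neg, neg)
    else:  # D3: unconstrained
        def objective(c):
            r = B @ c - y
            return np.sqrt(np.mean(r * r))

    return objective, lambda c: np.asarray(c, float)


def deconvolve(spectrum: CDSpectrum, basis: BasisSet, mode: str = "D1",
               n_starts: int | None = None, seed: int = 0,
               tol: float = DEFAULT_TOL, max_iter: int = MAX_ITER,
               ) -> DeconvolutionResult:
    """Estimate an SS composition from a CD spectrum by multistart search.

    Parameters
    ----------
    spectrum, basis
        Must share an alignable wavelength grid.
    mode
        Constraint regime, one of ``D1``, ``D2``, ``D3`` (see module docs).
    n_starts
        Number of random starts (defaults: D1 500, D2/D3 200).
    seed
        Master seed; per-start streams are derived by a counter scheme so
        results for start *i* do not depend on ``n_starts``.
    tol
        Simplex convergence tolerance on both the objective spread and the
        coefficient spread.
    max_iter
        Iteration cap per start; capped searches count as non-converged.
        The search with the lowest objective is accepted even if no start
        formally converged (``n_converged == 0`` flags that case).
    """
    if mode not in MODES:
        raise SpectrumInputError(f"unknown deconvolution mode {mode!r}")
    if n_starts is None:
        n_starts = DEFAULT_STARTS[mode]
    if n_starts < 1:
        raise SpectrumInputError("n_starts must be >= 1")

    aligned_s, _ = align_grids(spectrum, basis.spectra[0])
    sub_basis = BasisSet(
        basis.class_labels,
        tuple(align_grids(spectrum, s)[1] for s in basis.spectra),
        name=basis.name,
    )
    B = sub_basis.matrix()
    y = aligned_s.intensities
    n = B.shape[1]

    penalty = PENALTY_RMS_FACTOR * max(rms_intensity(aligned_s), 1e-12)
    for _attempt in range(4):
        objective, expand = _make_objective(mode, B, y, penalty)
        best_val = np.inf
        best_c = None
        n_converged = 0
        for i in range(n_starts):
            start = random_start(mode, n, _start_rng(seed, i))
            x0 = start[:-1] if mode == "D1" else start
            res = minimize(
                objective, x0, method="Nelder-Mead",
                options={"adaptive": True, "xatol": tol, "fatol": tol,
                         "maxiter": max_iter, "maxfev": 10 * max_iter},
            )
            if res.status == 0:
                n_converged += 1
            if res.fun < best_val:
                best_val = res.fun
                best_c = expand(res.x)
        # feasibility check at the accepted optimum; if the penalty was too
        # soft, double it and redo the whole schedule
        if mode == "D3" or best_c.min() >= -CONSTRAINT_TOL:
            break
        penalty *= 2.0

    raw = np.asarray(best_c, dtype=float)
    fit_rmsd = float(np.sqrt(np.mean((B @ raw - y) ** 2)))
    composition, fitted_scale = postprocess_coefficients(raw, basis.class_labels)
    if mode == "D1":
        fitted_scale = 1.0  # D1 never rescales the measured spectrum
    return DeconvolutionResult(
        mode=mode,
        raw_coefficients=raw,
        composition=composition,
        fitted_scale=fitted_scale,
        fit_rmsd=fit_rmsd,
        n_searches=n_starts,
        n_converged=n_converged,
        seed=int(seed),
    )
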