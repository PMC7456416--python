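"""Spectral data model, file I/O and grid algebra.

The universal intensity unit is kMRE (1000 deg cm^2 dmol^-1, i.e. thousand
mean-residue-ellipticity units).  Readers never auto-convert: a single
internal unit avoids silent scale bugs, which are precisely the error class
this package is built to quantify.  Wavelengths are in nm.

Spectrum files are two-column whitespace-delimited text (wavelength,
intensity) with ``#`` comment lines; basis-set files carry a header row of
class labels followed by a wavelength column and one intensity column per
secondary-structure class.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    GridMismatchError,
    LabelMappingError,
    RankDeficiencyError,
    SpectrumInputError,
    SpectrumParseError,
)

#: Absolute tolerance (nm) below which two grid points are the same point.
GRID_ATOL = 1e-6

#: Default synthetic wavelength grid: 175-269 nm at 1 nm (95 points), a
#: typical synchrotron-radiation CD range.  Configurable everywhere it is
#: used; recorded in every output header.
DEFAULT_GRID = np.arange(175.0, 270.0, 1.0)


@dataclass(frozen=True)
class CDSpectrum:
    """A circular-dichroism spectrum on a strictly increasing nm grid.

    Parameters
    ----------
    wavelengths : array-like
        Strictly increasing wavelength grid in nm, length >= 2.
    intensities : array-like
        One intensity in kMRE per wavelength; finite, possibly negative.
    label : str
        Free-text identifier.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise SpectrumInputError(
                f"wavelengths and intensities must be 1-D of equal length, "
                f"got {wl.shape} and {it.shape}"
            )
        if wl.size < 2:
            raise SpectrumInputError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(it)):
            raise SpectrumInputError("non-finite value in spectrum")
        if np.any(np.diff(wl) <= GRID_ATOL):
            if np.any(np.abs(np.diff(np.sort(wl))) <= GRID_ATOL):
                raise SpectrumInputError("duplicate wavelength in spectrum")
            raise SpectrumInputError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        self.wavelengths.setflags(write=False)
        self.intensities.setflags(write=False)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def with_intensities(self, values: np.ndarray, label: str | None = None) -> "CDSpectrum":
        """Same grid, new intensities (and optionally a new label)."""
        return CDSpectrum(self.wavelengths, np.asarray(values, float),
                          self.label if label is None else label)

    def scaled(self, factor: float, label: str | None = None) -> "CDSpectrum":
        """Spectrum multiplied point-wise by ``factor``."""
        return self.with_intensities(factor * self.intensities, label)

    def same_grid(self, other: "CDSpectrum") -> bool:
        return len(self) == len(other) and bool(
            np.all(np.abs(self.wavelengths - other.wavelengths) <= GRID_ATOL)
        )


@dataclass(frozen=True)
class SSComposition:
    """Labelled per-class secondary-structure fractions.

    Raw deconvolution coefficients may be negative or sum away from one;
    such vectors carry ``raw=True``.  A normalized composition has
    non-negative fractions summing to 1 within 1e-9.
    """

    class_labels: tuple
    fractions: np.ndarray
    raw: bool = False

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.class_labels)
        fr = np.asarray(self.fractions, dtype=float)
        if fr.ndim != 1 or fr.size != len(labels):
            raise LabelMappingError(
                f"{fr.size} fractions for {len(labels)} labels"
            )
        if len(set(labels)) != len(labels):
            raise LabelMappingError(f"duplicate class labels: {labels}")
        if not np.all(np.isfinite(fr)):
            raise SpectrumInputError("non-finite fraction")
        if not self.raw:
            if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
                raise SpectrumInputError(
                    "normalized composition must be non-negative and sum to 1 "
                    f"(got sum {fr.sum():.3g}); pass raw=True for raw coefficients"
                )
        object.__setattr__(self, "class_labels", labels)
        object.__setattr__(self, "fractions", fr)
        self.fractions.setflags(write=False)

    def __len__(self) -> int:
        return len(self.class_labels)

    def reordered(self, labels: Sequence[str]) -> "SSComposition":
        """Fractions permuted into the order of ``labels`` (matched by name)."""
        missing = [l for l in labels if l not in self.class_labels]
        extra = [l for l in self.class_labels if l not in labels]
        if missing or extra:
            raise LabelMappingError(
                f"cannot map labels: missing {missing}, unmatched {extra}"
            )
        idx = [self.class_labels.index(l) for l in labels]
        return SSComposition(tuple(labels), self.fractions[idx], raw=self.raw)

    def as_dict(self) -> dict:
        return dict(zip(self.class_labels, self.fractions.tolist()))


@dataclass(frozen=True)
class BasisSet:
    """An ordered set of per-class basis spectra on one shared grid."""

    class_labels: tuple
    spectra: tuple
    name: str = ""

    #: relative singular-value floor for the linear-independence check
    RANK_RTOL = 1e-10

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.class_labels)
        spectra = tuple(self.spectra)
        if len(labels) < 2:
            raise SpectrumInputError("a basis set needs >= 2 classes")
        if len(set(labels)) != len(labels):
            raise LabelMappingError(f"duplicate class labels: {labels}")
        if len(spectra) != len(labels):
            raise LabelMappingError(
                f"{len(spectra)} spectra for {len(labels)} labels"
            )
        first = spectra[0]
        for s in spectra[1:]:
            if not first.same_grid(s):
                raise GridMismatchError(
                    f"basis spectra of {self.name!r} are not on one grid"
                )
        object.__setattr__(self, "class_labels", labels)
        object.__setattr__(self, "spectra", spectra)
        self._check_rank()

    def _check_rank(self) -> None:
        m = self.matrix()
        sv = np.linalg.svd(m, compute_uv=False)
        if sv[-1] <= self.RANK_RTOL * sv[0]:
            # name the most collinear pair to make the report actionable
            unit = m / np.linalg.norm(m, axis=0)
            cos = np.abs(unit.T @ unit)
            np.fill_diagonal(cos, 0.0)
            i, j = np.unravel_index(np.argmax(cos), cos.shape)
            raise RankDeficiencyError(
                f"basis {self.name!r} is rank deficient; most collinear pair: "
                f"{self.class_labels[i]!r} and {self.class_labels[j]!r} "
                f"(|cos| = {cos[i, j]:.6f})"
            )

    def __len__(self) -> int:
        return len(self.class_labels)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def matrix(self) -> np.ndarray:
        """Grid-by-class intensity matrix (one column per SS class)."""
        return np.column_stack([s.intensities for s in self.spectra])

    def condition_number(self) -> float:
        sv = np.linalg.svd(self.matrix(), compute_uv=False)
        return float(sv[0] / sv[-1])


# ---------------------------------------------------------------------------
# file I/O


def _parse_two_columns(lines: Iterable[str], source: str) -> tuple[np.ndarray, np.ndarray]:
    wl, it = [], []
    for lineno, line in enumerate(lines, start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        parts = text.split()
        if len(parts) != 2:
            raise SpectrumParseError(
                f"{source}: line {lineno}: expected 2 columns, got {len(parts)}"
            )
        try:
            wl.append(float(parts[0]))
            it.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(
                f"{source}: line {lineno}: non-numeric value ({exc})"
            ) from None
    return np.asarray(wl), np.asarray(it)


def read_spectrum(path: str | os.PathLike, label: str | None = None,
                  mre: bool = False) -> CDSpectrum:
    """Read a two-column (wavelength nm, intensity kMRE) text spectrum.

    Lines starting with ``#`` are ignored; rows may appear in any wavelength
    order and are sorted ascending.  ``mre=True`` divides intensities by 1000
    on load, for files recorded in plain MRE units.
    """
    path = Path(path)
    with open(path) as fh:
        wl, it = _parse_two_columns(fh, str(path))
    if wl.size < 2:
        raise SpectrumInputError(f"{path}: fewer than 2 data rows")
    order = np.argsort(wl)
    wl, it = wl[order], it[order]
    if np.any(np.diff(wl) <= GRID_ATOL):
        raise SpectrumInputError(f"{path}: duplicate wavelength")
    if mre:
        it = it / 1000.0
    return CDSpectrum(wl, it, label if label is not None else path.stem)


def write_spectrum(spectrum: CDSpectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column text with a labelled header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# label: {spectrum.label}\n")
        fh.write("# columns: wavelength_nm intensity_kMRE\n")
        fh.write(f"# grid: {spectrum.wavelengths[0]:g}..{spectrum.wavelengths[-1]:g} nm, "
                 f"{len(spectrum)} points\n")
        for w, y in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{w:.17g} {y:.17g}\n")


def read_basis_set(path: str | os.PathLike, name: str | None = None) -> BasisSet:
    """Read a basis set: header row of class labels, then wavelength + one
    intensity column per class."""
    path = Path(path)
    labels: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if labels is None:
                labels = parts
                continue
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric value"
                ) from None
            if len(rows[-1]) != len(rows[0]):
                raise SpectrumParseError(
                    f"{path}: line {lineno}: ragged row "
                    f"({len(rows[-1])} columns, expected {len(rows[0])})"
                )
    if labels is None or not rows:
        raise SpectrumParseError(f"{path}: no header or no data rows")
    data = np.asarray(rows)
    ncls = data.shape[1] - 1
    if len(labels) == ncls + 1:
        labels = labels[1:]  # header included a wavelength-column name
    if len(labels) != ncls:
        raise SpectrumParseError(
            f"{path}: {len(labels)} header labels for {ncls} intensity columns"
        )
    order = np.argsort(data[:, 0])
    data = data[order]
    wl = data[:, 0]
    spectra = tuple(
        CDSpectrum(wl, data[:, i + 1], label=labels[i]) for i in range(ncls)
    )
    return BasisSet(tuple(labels), spectra,
                    name=name if name is not None else path.stem)


def write_basis_set(basis: BasisSet, path: str | os.PathLike) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# basis set: {basis.name}\n")
        fh.write("# columns: wavelength_nm then one kMRE column per class\n")
        fh.write("wavelength " + " ".join(basis.class_labels) + "\n")
        m = basis.matrix()
        for i, w in enumerate(basis.wavelengths):
            fh.write(f"{w:.17g} " + " ".join(f"{v:.17g}" for v in m[i]) + "\n")


def read_composition(path: str | os.PathLike) -> SSComposition:
    """Read a labelled composition file: one ``label fraction`` pair per line."""
    path = Path(path)
    labels, fracs = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 'label fraction'"
                )
            labels.append(parts[0])
            try:
                fracs.append(float(parts[1]))
            except ValueError:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric fraction"
                ) from None
    if not labels:
        raise SpectrumParseError(f"{path}: empty composition file")
    return SSComposition(tuple(labels), np.asarray(fracs))


def write_composition(comp: SSComposition, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: class_label fraction\n")
        for label, frac in zip(comp.class_labels, comp.fractions):
            fh.write(f"{label} {frac:.17g}\n")


# ---------------------------------------------------------------------------
# grid algebra


def align_grids(a: CDSpectrum, b: CDSpectrum,
                interpolate: bool = False) -> tuple[CDSpectrum, CDSpectrum]:
    """Restrict two spectra to a common wavelength grid.

    By default both are restricted to the exact intersection of their grids
    (absolute tolerance 1e-6 nm); points present in only one input are
    dropped and no values are invented.  With ``interpolate=True``, ``b`` is
    linearly interpolated onto the part of ``a``'s grid inside ``b``'s range
    instead — an explicit opt-in, since all deviation measures here are sums
    over shared measured wavelengths.
    """
    if a.same_grid(b):
        return a, b
    if interpolate:
        lo = max(a.wavelengths[0], b.wavelengths[0])
        hi = min(a.wavelengths[-1], b.wavelengths[-1])
        keep = (a.wavelengths >= lo - GRID_ATOL) & (a.wavelengths <= hi + GRID_ATOL)
        if keep.sum() < 2:
            raise GridMismatchError(
                f"grids of {a.label!r} and {b.label!r} overlap in < 2 points"
            )
        wl = a.wavelengths[keep]
        return (
            CDSpectrum(wl, a.intensities[keep], a.label),
            CDSpectrum(wl, np.interp(wl, b.wavelengths, b.intensities), b.label),
        )
    # sorted two-pointer intersection with tolerance
    ia, ib = 0, 0
    keep_a, keep_b = [], []
    while ia < len(a) and ib < len(b):
        d = a.wavelengths[ia] - b.wavelengths[ib]
        if abs(d) <= GRID_ATOL:
            keep_a.append(ia)
            keep_b.append(ib)
            ia += 1
            ib += 1
        elif d < 0:
            ia += 1
        else:
            ib += 1
    if len(keep_a) < 2:
        raise GridMismatchError(
            f"grids of {a.label!r} and {b.label!r} intersect in "
            f"{len(keep_a)} point(s); >= 2 required"
        )
    return (
        CDSpectrum(a.wavelengths[keep_a], a.intensities[keep_a], a.label),
        CDSpectrum(b.wavelengths[keep_b], b.intensities[keep_b], b.label),
    )


def rms_intensity(spectrum: CDSpectrum) -> float:
    """Root-mean-square intensity over the grid, in kMRE."""
    return float(np.sqrt(np.mean(spectrum.intensities ** 2)))
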