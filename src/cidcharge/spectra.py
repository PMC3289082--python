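"""In-memory containers for centroided MS/MS spectra.

A spectrum is stored as parallel numpy arrays of m/z (Thomson) and
intensity (arbitrary abundance units), sorted strictly ascending in m/z.
Peaks sharing an identical m/z are merged by summing their intensities and
zero-intensity peaks are dropped — the pair-enumeration predicates that
drive the charge-state features assume distinct m/z values and non-trivial
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Peak:
    """A single centroided peak: m/z in Thomson, non-negative intensity."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


def _canonicalize(mz, intensity):
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape or mz.ndim != 1:
        raise ValueError("mz and intensity must be 1-D arrays of equal length")
    if np.any(mz <= 0):
        raise ValueError("all peak m/z values must be positive")
    if np.any(intensity < 0):
        raise ValueError("all peak intensities must be non-negative")
    keep = intensity > 0
    mz, intensity = mz[keep], intensity[keep]
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    # merge exact m/z duplicates by summing intensity
    if mz.size > 1 and np.any(np.diff(mz) == 0):
        uniq, inverse = np.unique(mz, return_inverse=True)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, intensity)
        mz, intensity = uniq, summed
    return mz, intensity


@dataclass
class Spectrum:
    """One MS/MS scan: precursor m/z plus a canonical peak list.

    Parameters
    ----------
    spectrum_id : str
        Opaque identifier, unique within a collection.
    precursor_mz : float
        m/z of the precursor (parent) ion, Thomson.
    mz, intensity : array-like
        Peak arrays; canonicalized on construction (sorted, deduplicated,
        zero intensities dropped).
    true_charge : int or None
        Known precursor charge (2 or 3), used only for evaluation.
    """

    spectrum_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    true_charge: int | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if self.true_charge is not None and self.true_charge not in (2, 3):
            raise ValueError(f"true_charge must be 2 or 3, got {self.true_charge}")
        self.mz, self.intensity = _canonicalize(self.mz, self.intensity)

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]


@dataclass
class SpectrumCollection:
    """An ordered set of spectra with unique identifiers."""

    spectra: list[Spectrum] = field(default_factory=list)
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        ids = [s.spectrum_id for s in self.spectra]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate spectrum_id(s) in collection: {dupes}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, idx: int) -> Spectrum:
        return self.spectra[idx]

    @property
    def true_charges(self) -> np.ndarray:
        """Array of known charges; raises if any spectrum is unlabeled."""
        charges = [s.true_charge for s in self.spectra]
        if any(c is None for c in charges):
            raise ValueError("collection contains unlabeled spectra")
        return np.asarray(charges, dtype=int)
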