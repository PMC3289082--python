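"""Synthetic ion-trap CID spectra of tryptic +2/+3 peptides.

The generator emulates the statistical structure the charge-state features
exploit, with full ground-truth bookkeeping so every downstream stage can
be tested against known answers:

* tryptic sequences ending in K/R; +3 peptides carry exactly one extra
  internal basic residue (K, R or H) on top of the C-terminal one,
  reflecting the proton-retention picture in which a +z precursor needs
  z - 1 basic side chains plus the N-terminal amine;
* each backbone bond fragments independently into a complementary b/y
  pair with probability ``fragmentation_efficiency``; +2 precursors emit
  (+1, +1) pairs, +3 precursors emit (+1, +2) with probability
  ``plus12_fraction_for_3`` and (+1, +1) otherwise. The +2 always goes to
  the y ion: it carries the C-terminal K/R and (for most bonds) the
  internal basic residue, hence retains two protons;
* y-side intensities are lognormal with a median
  ``y_over_b_intensity_ratio`` times the b-side median;
* Gaussian m/z jitter and Poisson-many uniform noise peaks in
  (50, 2*mp).

It does not attempt mobile-proton fragmentation chemistry, isotope
envelopes or correlated instrument noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .constants import MassConstants, DEFAULT_CONSTANTS, CANONICAL_RESIDUES
from .spectra import Spectrum, SpectrumCollection

_NONBASIC = tuple(aa for aa in CANONICAL_RESIDUES if aa not in "KRH")
_TRYPTIC_TERMINI = ("K", "R")
_INTERNAL_BASIC = ("K", "R", "H")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic dataset.

    Defaults describe a mid-quality ion-trap run: 70% of bonds yield a
    detectable pair, y ions twice as intense as b ions at the median,
    0.15 Da centroiding jitter, and ten uniform noise peaks per spectrum.
    """

    n_spectra: int = 1000
    frac_plus3: float = 0.5
    peptide_length_range: tuple[int, int] = (8, 20)
    fragmentation_efficiency: float = 0.7
    plus12_fraction_for_3: float = 0.7
    y_over_b_intensity_ratio: float = 2.0
    noise_peaks_per_spectrum: float = 10.0
    mz_jitter_sd: float = 0.15
    intensity_cv: float = 0.3
    seed: int = 0
    constants: MassConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be positive")
        for name in ("frac_plus3", "fragmentation_efficiency", "plus12_fraction_for_3"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.peptide_length_range
        if not 2 <= lo <= hi:
            raise ValueError("peptide_length_range must satisfy 2 <= lo <= hi")
        if self.noise_peaks_per_spectrum < 0 or self.mz_jitter_sd < 0 or self.intensity_cv < 0:
            raise ValueError("noise, jitter and intensity CV must be non-negative")


@dataclass(frozen=True)
class EmittedIon:
    """One fragment ion actually placed in a synthetic spectrum."""

    bond_index: int            # cleavage after residue `bond_index` (1-based)
    terminal: Literal["N", "C"]
    charge: int                # 1 or 2
    mz_theoretical: float
    mz_observed: float         # after jitter
    intensity: float


@dataclass
class GroundTruth:
    """Provenance of every peak in one synthetic spectrum."""

    sequence: str
    charge: int
    ions: list[EmittedIon] = field(default_factory=list)
    noise_mz: list[float] = field(default_factory=list)
    #: aligned with the canonical (sorted) peak list: index into `ions`, or -1 for noise
    peak_origins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def _lognormal(rng: np.random.Generator, median: float, cv: float) -> float:
    if cv == 0:
        return median
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(median * math.exp(rng.normal(0.0, sigma)))


def generate_peptide(params: SimParams, rng: np.random.Generator, charge: int) -> str:
    """A random tryptic sequence for the given precursor charge.

    Every peptide ends in K or R; +2 peptides have no other basic residue,
    +3 peptides exactly one extra internal K, R or H.
    """
    if charge not in (2, 3):
        raise ValueError("charge must be 2 or 3")
    lo, hi = params.peptide_length_range
    length = int(rng.integers(lo, hi + 1))
    internal = [str(rng.choice(_NONBASIC)) for _ in range(length - 1)]
    if charge == 3:
        pos = int(rng.integers(length - 1))
        internal[pos] = str(rng.choice(_INTERNAL_BASIC))
    return "".join(internal) + str(rng.choice(_TRYPTIC_TERMINI))


def generate_spectrum(
    sequence: str,
    charge: int,
    params: SimParams,
    rng: np.random.Generator,
    spectrum_id: str = "synthetic",
) -> tuple[Spectrum, GroundTruth]:
    """Simulate one CID spectrum of ``sequence`` at the given charge."""
    if charge not in (2, 3):
        raise ValueError("charge must be 2 or 3")
    constants = params.constants
    proton = constants.proton
    mass = constants.peptide_mass(sequence)
    mp = (mass + charge * proton) / charge

    residue = np.array([constants.residue_masses[aa] for aa in sequence])
    prefix = np.cumsum(residue)
    ions: list[EmittedIon] = []
    for bond in range(1, len(sequence)):
        if rng.random() >= params.fragmentation_efficiency:
            continue
        b1 = prefix[bond - 1] + proton
        y1 = (prefix[-1] - prefix[bond - 1]) + constants.h2o + proton
        b_charge = y_charge = 1
        if charge == 3 and rng.random() < params.plus12_fraction_for_3:
            y_charge = 2  # y side holds the basic residues, so it keeps both protons
        for terminal, singly, frag_charge, median in (
            ("N", b1, b_charge, 1.0),
            ("C", y1, y_charge, params.y_over_b_intensity_ratio),
        ):
            theo = singly if frag_charge == 1 else (singly + proton) / 2.0
            observed = theo + rng.normal(0.0, params.mz_jitter_sd) if params.mz_jitter_sd else theo
            ions.append(
                EmittedIon(
                    bond_index=bond,
                    terminal=terminal,
                    charge=frag_charge,
                    mz_theoretical=theo,
                    mz_observed=observed,
                    intensity=_lognormal(rng, median, params.intensity_cv),
                )
            )
    n_noise = int(rng.poisson(params.noise_peaks_per_spectrum))
    noise_mz = rng.uniform(50.0, 2.0 * mp, size=n_noise)
    noise_intensity = np.array([_lognormal(rng, 1.0, params.intensity_cv) for _ in range(n_noise)])

    mz = np.concatenate([[ion.mz_observed for ion in ions], noise_mz])
    intensity = np.concatenate([[ion.intensity for ion in ions], noise_intensity])
    origins = np.concatenate(
        [np.arange(len(ions)), np.full(n_noise, -1, dtype=int)]
    ).astype(int)
    order = np.argsort(mz, kind="stable")
    spectrum = Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=mp,
        mz=mz[order],
        intensity=intensity[order],
        true_charge=charge,
    )
    truth = GroundTruth(
        sequence=sequence,
        charge=charge,
        ions=ions,
        noise_mz=list(map(float, noise_mz)),
        peak_origins=origins[order],
    )
    return spectrum, truth


def generate_dataset(params: SimParams) -> tuple[SpectrumCollection, list[GroundTruth]]:
    """A labeled collection of ``n_spectra`` synthetic spectra.

    Class sizes are deterministic — ``round(n * frac_plus3)`` spectra are
    +3 — and the whole dataset is reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n3 = int(round(params.n_spectra * params.frac_plus3))
    charges = [2] * (params.n_spectra - n3) + [3] * n3
    spectra: list[Spectrum] = []
    truths: list[GroundTruth] = []
    for i, charge in enumerate(charges):
        sequence = generate_peptide(params, rng, charge)
        spectrum, truth = generate_spectrum(
            sequence, charge, params, rng, spectrum_id=f"syn-{i:05d}"
        )
        spectra.append(spectrum)
        truths.append(truth)
    collection = SpectrumCollection(spectra=spectra, source_path=f"<simulated seed={params.seed}>")
    return collection, truths


def write_ground_truth(truths: list[GroundTruth], collection: SpectrumCollection, path) -> None:
    """TSV sidecar: spectrum_id, peptide sequence, true charge, ion count."""
    import pandas as pd

    rows = [
        {
            "spectrum_id": s.spectrum_id,
            "sequence": t.sequence,
            "true_charge": t.charge,
            "n_fragment_ions": len(t.ions),
            "n_noise_peaks": len(t.noise_mz),
        }
        for s, t in zip(collection, truths)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
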