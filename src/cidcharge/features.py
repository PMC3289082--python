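"""The four per-spectrum charge-state features and the scaled feature matrix.

Each feature summarizes one physical asymmetry between MS/MS spectra of
doubly and triply charged tryptic peptides:

* ``delta_cp`` — count of (+1, +1) complementary pairs minus count of
  (+1, +2) pairs. +2 precursors fragment into two +1 ions at a bond, +3
  precursors often into one +1 and one +2 ion, so this is larger for +2.
* ``delta_rcp`` — intensity-ratio analogue of ``delta_cp``: the b/y
  intensity ratio over (+1, +1) pairs (offset by +0.5 for the known y > b
  intensity asymmetry) minus the (+2 member)/(+1 member) ratio over
  (+1, +2) pairs. Larger for +2.
* ``i_dc`` — summed intensity of +2-consistent peaks in the m/z region
  [mp, 1.5*mp], which only +3 precursors can populate with +2 fragments.
  Larger for +3.
* ``n_bs`` — pseudo-count of basic sites: peak pairs whose m/z difference
  matches a K/R/H residue mass (directly or through one neutral loss),
  divided by the theoretical repeat number ``nt``. +3 peptides carry an
  extra basic residue, so this is larger for +3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .constants import MassConstants, DEFAULT_CONSTANTS
from .fragments import (
    RELATION_KINDS,
    Tolerance,
    basic_site_pair_mask,
    doubly_charged_flags,
    pair_relation_masks,
)
from .spectra import Spectrum, SpectrumCollection

FEATURE_NAMES = ("delta_cp", "delta_rcp", "i_dc", "n_bs")

#: Expected per-class mean direction: ">" means larger for +2 than for +3.
EXPECTED_DIRECTIONS = {"delta_cp": ">", "delta_rcp": ">", "i_dc": "<", "n_bs": "<"}

#: Feature subset of the best-performing classifier (basic-site count excluded).
DEFAULT_FEATURE_SUBSET = ("delta_cp", "delta_rcp", "i_dc")


@dataclass(frozen=True)
class FeatureParams:
    """Knobs shared by all feature computations.

    ``nt`` is the theoretical repeat number dividing the basic-site
    pseudo-count; 1 leaves the raw pseudo-count. ``ratio_mode`` selects
    the aggregation for ``delta_rcp``: ``"set_sum"`` sums intensities over
    the member peak sets before taking ratios (robust to zero
    denominators), ``"pair_mean"`` averages per-pair intensity ratios.
    """

    constants: MassConstants = DEFAULT_CONSTANTS
    tolerance: Tolerance = Tolerance()
    losses_enabled: bool = True
    nt: float = 1.0
    ratio_mode: Literal["set_sum", "pair_mean"] = "set_sum"

    def __post_init__(self) -> None:
        if self.nt < 1:
            raise ValueError("theoretical repeat number nt must be >= 1")
        if self.ratio_mode not in ("set_sum", "pair_mean"):
            raise ValueError(f"unknown ratio_mode {self.ratio_mode!r}")


DEFAULT_PARAMS = FeatureParams()


def _complementary_pair_sets(spectrum: Spectrum, params: FeatureParams):
    """Distinct (+1,+1) pairs and oriented (+1,+2) pairs, either hypothesis.

    Returns ``(cp1, cp2)``: ``cp1`` is a list of (i, j) pairs matching the
    (+1, +1) relation under z=2 or z=3; ``cp2`` a list of (plus2_index,
    plus1_index) orientations matching a (+1, +2) relation. Each pair /
    orientation appears once however many relation variants it satisfies.
    """
    if len(spectrum) < 2:
        return [], []
    ii, jj, masks = pair_relation_masks(
        spectrum, params.constants, params.tolerance, params.losses_enabled
    )
    cp1_mask = masks[("CP11", 2)] | masks[("CP11", 3)]
    low2_mask = masks[("CP12_LOW2", 2)] | masks[("CP12_LOW2", 3)]
    high2_mask = masks[("CP12_HIGH2", 2)] | masks[("CP12_HIGH2", 3)]
    cp1 = list(zip(ii[cp1_mask].tolist(), jj[cp1_mask].tolist()))
    cp2 = list(zip(ii[low2_mask].tolist(), jj[low2_mask].tolist()))
    cp2 += [(j, i) for i, j in zip(ii[high2_mask].tolist(), jj[high2_mask].tolist())]
    return cp1, sorted(set(cp2))


def delta_cp(spectrum: Spectrum, params: FeatureParams = DEFAULT_PARAMS) -> float:
    """|CP1| - |CP2|: complementary (+1,+1) pairs minus (+1,+2) pairs."""
    cp1, cp2 = _complementary_pair_sets(spectrum, params)
    cp2_pairs = {tuple(sorted(p)) for p in cp2}
    return float(len(set(cp1)) - len(cp2_pairs))


def delta_rcp(spectrum: Spectrum, params: FeatureParams = DEFAULT_PARAMS) -> float:
    """Intensity-ratio difference between (+1,+1) and (+1,+2) pair sets.

    The +0.5 offset compensates the y-over-b intensity asymmetry and is
    applied only when (+1, +1) pairs exist; with neither pair set present
    the feature is 0.
    """
    cp1, cp2 = _complementary_pair_sets(spectrum, params)
    intensity = spectrum.intensity
    term1 = term2 = 0.0
    if cp1:
        if params.ratio_mode == "set_sum":
            low = intensity[sorted({i for i, _ in cp1})].sum()
            high = intensity[sorted({j for _, j in cp1})].sum()
            ratio = low / high if high > 0 else 0.0
        else:
            ratios = [intensity[i] / intensity[j] for i, j in cp1 if intensity[j] > 0]
            ratio = float(np.mean(ratios)) if ratios else 0.0
        term1 = ratio + 0.5
    if cp2:
        if params.ratio_mode == "set_sum":
            plus2 = intensity[sorted({p for p, _ in cp2})].sum()
            plus1 = intensity[sorted({q for _, q in cp2})].sum()
            term2 = plus2 / plus1 if plus1 > 0 else 0.0
        else:
            ratios = [intensity[p] / intensity[q] for p, q in cp2 if intensity[q] > 0]
            term2 = float(np.mean(ratios)) if ratios else 0.0
    return float(term1 - term2)


def i_dc(spectrum: Spectrum, params: FeatureParams = DEFAULT_PARAMS) -> float:
    """Summed intensity of +2-consistent peaks with m/z in [mp, 1.5*mp]."""
    if len(spectrum) == 0:
        return 0.0
    flags = doubly_charged_flags(spectrum, params.constants, params.tolerance)
    mp = spectrum.precursor_mz
    in_region = (spectrum.mz >= mp) & (spectrum.mz <= 1.5 * mp)
    return float(spectrum.intensity[flags & in_region].sum())


def n_bs(spectrum: Spectrum, params: FeatureParams = DEFAULT_PARAMS) -> float:
    """Basic-site pseudo-count over the theoretical repeat number.

    Counts unordered peak pairs whose m/z difference matches a K, R or H
    residue mass within tolerance — directly or with one neutral loss on
    either member — each pair at most once, then divides by ``nt``.
    """
    if len(spectrum) < 2:
        return 0.0
    _, _, mask = basic_site_pair_mask(
        spectrum, params.constants, params.tolerance, params.losses_enabled
    )
    return float(mask.sum()) / params.nt


_FEATURE_FUNCS = {"delta_cp": delta_cp, "delta_rcp": delta_rcp, "i_dc": i_dc, "n_bs": n_bs}


def feature_vector(spectrum: Spectrum, params: FeatureParams = DEFAULT_PARAMS) -> dict[str, float]:
    """All four raw features for one spectrum."""
    return {name: _FEATURE_FUNCS[name](spectrum, params) for name in FEATURE_NAMES}


def compute_features(
    collection: SpectrumCollection, params: FeatureParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Raw feature table: one row per spectrum, indexed by spectrum_id."""
    rows = [feature_vector(s, params) for s in collection]
    frame = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    frame.insert(0, "spectrum_id", [s.spectrum_id for s in collection])
    return frame.set_index("spectrum_id")


@dataclass
class FeatureMatrix:
    """Column-scaled feature matrix ready for mixture fitting.

    Each retained column is the raw feature divided by its sample standard
    deviation (optionally after mean-centering), so scaled columns have
    unit variance. ``scale_factors`` and ``offsets`` allow exact recovery
    of the raw values.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    scale_factors: np.ndarray
    offsets: np.ndarray
    spectrum_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_spectra(self) -> int:
        return int(self.values.shape[0])

    def to_raw(self) -> np.ndarray:
        """Invert the scaling: raw = scaled * sd + offset."""
        return self.values * self.scale_factors[None, :] + self.offsets[None, :]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]


def build_feature_matrix(
    raw: pd.DataFrame,
    feature_subset: Sequence[str] = DEFAULT_FEATURE_SUBSET,
    center: bool = False,
) -> FeatureMatrix:
    """Scale selected raw feature columns to unit sample variance.

    ``raw`` is the output of :func:`compute_features` (or any DataFrame
    with the feature columns). A constant column cannot be scaled and is
    reported as an error naming the feature.
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 spectra to scale features")
    subset = tuple(feature_subset)
    if not subset:
        raise ValueError("feature subset must be non-empty")
    unknown = [f for f in subset if f not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature name(s): {unknown}")
    data = raw.loc[:, list(subset)].to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite feature values")
    sds = data.std(axis=0, ddof=1)
    for name, sd in zip(subset, sds):
        if sd == 0:
            raise ValueError(f"feature {name!r} is constant; cannot scale to unit variance")
    offsets = data.mean(axis=0) if center else np.zeros(len(subset))
    scaled = (data - offsets[None, :]) / sds[None, :]
    return FeatureMatrix(
        values=scaled,
        feature_names=subset,
        scale_factors=sds,
        offsets=offsets,
        spectrum_ids=tuple(raw.index.astype(str)),
    )
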