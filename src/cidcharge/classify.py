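"""Mapping mixture components to charge labels and per-spectrum calls.

The mixture fit is unsupervised, so its two components are unlabeled. The
assignment rule votes with the known physical direction of each feature
(complementary-pair features larger for +2; doubly-charged-region
intensity and basic-site count larger for +3): for every feature in the
model, the component whose mean sits on the +2 side earns a vote, and the
majority labels the components. Ties break on the intensity-ratio feature
``delta_rcp``, the most discriminant of the four.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import EXPECTED_DIRECTIONS, FeatureMatrix
from .gmm import FitResult
from .spectra import SpectrumCollection


@dataclass(frozen=True)
class ChargePrediction:
    """Posterior probability of +3 and the thresholded charge call."""

    spectrum_id: str
    posterior_plus3: float
    predicted_charge: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior_plus3 <= 1.0:
            raise ValueError("posterior_plus3 must lie in [0, 1]")
        if self.predicted_charge not in (2, 3):
            raise ValueError("predicted_charge must be 2 or 3")


@dataclass(frozen=True)
class LabelMap:
    """Which mixture component is +2 and which +3, with the votes cast."""

    component_for_plus2: int
    component_for_plus3: int
    votes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if {self.component_for_plus2, self.component_for_plus3} != {0, 1}:
            raise ValueError("label map must assign components 0 and 1 to distinct charges")


def assign_labels(fit: FitResult, feature_names: tuple[str, ...] | None = None) -> LabelMap:
    """Label the two components of a fit as +2 and +3 by feature direction.

    For each feature, the vote records which component (0 or 1) looks like
    +2 under that feature's expected direction. The majority component is
    labeled +2; a tied vote is decided by ``delta_rcp`` when present, else
    by the first feature in the model.
    """
    if fit.params.n_components != 2:
        raise ValueError("label assignment requires a 2-component fit")
    names = tuple(feature_names) if feature_names is not None else fit.feature_names
    if len(names) != fit.params.n_dims:
        raise ValueError("feature names must match the model dimension")
    votes: dict[str, int] = {}
    for d, name in enumerate(names):
        direction = EXPECTED_DIRECTIONS.get(name)
        if direction is None:
            raise ValueError(f"unknown feature {name!r}")
        mean0, mean1 = fit.params.means[0, d], fit.params.means[1, d]
        looks_plus2 = 0 if (mean0 > mean1) == (direction == ">") else 1
        votes[name] = looks_plus2
    tally = sum(votes.values())  # number of votes for component 1 as +2
    if tally * 2 == len(votes):
        tiebreak = "delta_rcp" if "delta_rcp" in votes else names[0]
        plus2 = votes[tiebreak]
    else:
        plus2 = 1 if tally * 2 > len(votes) else 0
    return LabelMap(component_for_plus2=plus2, component_for_plus3=1 - plus2, votes=votes)


def predict(
    collection: SpectrumCollection,
    matrix: FeatureMatrix,
    fit: FitResult,
    label_map: LabelMap,
    threshold: float = 0.5,
) -> list[ChargePrediction]:
    """Per-spectrum charge calls from the fitted responsibilities.

    The posterior of +3 is the responsibility of the +3-labeled component;
    the call is +3 strictly above the threshold, +2 at or below it.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    n = len(collection)
    if matrix.n_spectra != n or fit.responsibilities.shape[0] != n:
        raise ValueError(
            f"misaligned inputs: {n} spectra, {matrix.n_spectra} feature rows, "
            f"{fit.responsibilities.shape[0]} responsibility rows"
        )
    posterior = fit.responsibilities[:, label_map.component_for_plus3]
    posterior = np.clip(posterior, 0.0, 1.0)
    return [
        ChargePrediction(
            spectrum_id=s.spectrum_id,
            posterior_plus3=float(p),
            predicted_charge=3 if p > threshold else 2,
        )
        for s, p in zip(collection, posterior)
    ]
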