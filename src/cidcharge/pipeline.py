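"""End-to-end charge assignment: features → scaling → EM fit → labels."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .classify import ChargePrediction, LabelMap, assign_labels, predict
from .features import (
    DEFAULT_FEATURE_SUBSET,
    DEFAULT_PARAMS,
    FeatureMatrix,
    FeatureParams,
    build_feature_matrix,
    compute_features,
)
from .gmm import FitResult, fit
from .spectra import SpectrumCollection


@dataclass
class PipelineResult:
    """Everything the unsupervised pipeline produced for one collection."""

    raw_features: pd.DataFrame
    matrix: FeatureMatrix
    fit: FitResult
    label_map: LabelMap
    predictions: list[ChargePrediction]

    def prediction_rows(self) -> list[dict]:
        """Rows for :func:`cidcharge.io.write_predictions` (raw features)."""
        rows = []
        for pred in self.predictions:
            raw = self.raw_features.loc[pred.spectrum_id]
            rows.append(
                {
                    "spectrum_id": pred.spectrum_id,
                    "delta_cp": float(raw["delta_cp"]),
                    "delta_rcp": float(raw["delta_rcp"]),
                    "i_dc": float(raw["i_dc"]),
                    "n_bs": float(raw["n_bs"]),
                    "posterior_plus3": pred.posterior_plus3,
                    "predicted_charge": pred.predicted_charge,
                }
            )
        return rows

    @property
    def posterior_plus3(self):
        import numpy as np

        return np.array([p.posterior_plus3 for p in self.predictions])

    @property
    def predicted_charges(self):
        import numpy as np

        return np.array([p.predicted_charge for p in self.predictions])


def assign_charges(
    collection: SpectrumCollection,
    feature_subset: Sequence[str] = DEFAULT_FEATURE_SUBSET,
    feature_params: FeatureParams = DEFAULT_PARAMS,
    center: bool = False,
    seed: int | None = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol_ll: float = 1e-8,
    threshold: float = 0.5,
) -> PipelineResult:
    """Run the full unsupervised charge-state pipeline on a collection.

    Computes the four raw features, scales the selected subset to unit
    variance, fits a 2-component spherical Gaussian mixture by EM, labels
    the components by feature direction and thresholds the +3 posterior.
    """
    raw = compute_features(collection, feature_params)
    matrix = build_feature_matrix(raw, feature_subset, center=center)
    result = fit(
        matrix.values,
        k=2,
        seed=seed,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol_ll=tol_ll,
        feature_names=matrix.feature_names,
    )
    label_map = assign_labels(result)
    predictions = predict(collection, matrix, result, label_map, threshold=threshold)
    return PipelineResult(
        raw_features=raw,
        matrix=matrix,
        fit=result,
        label_map=label_map,
        predictions=predictions,
    )
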