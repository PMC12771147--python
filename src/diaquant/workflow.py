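"""End-to-end quantification: chamber image -> signals -> calibration -> unknowns.

Glue over the imaging and calibration modules for the single-image workflow:
one photograph carries the analytical blank, the calibration standards and
the unknown samples; the standards calibrate a PLS1 model on the
blank-referenced signals and the unknowns are predicted from the same image.

Feature spaces:

* ``"reflectance"`` — the three blank-referenced channel ratios as-is;
* ``"absorbance"`` — their ``-log10`` transform, linear in concentration
  under Beer-Lambert attenuation (the default for quantification);
* ``"reflectance+means"`` — reflectances augmented with raw channel means
  (p = 6).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import imaging
from .calibration import PLSCalibration, PLSCalibrationResults

__all__ = ["feature_matrix", "calibrate_signals", "quantify_image"]

_REFL = ["refl_r", "refl_g", "refl_b"]
_MEANS = ["mean_r", "mean_g", "mean_b"]


def feature_matrix(signals: pd.DataFrame, features: str = "absorbance") -> np.ndarray:
    """Feature matrix for calibration from a signals table."""
    refl = signals[_REFL].to_numpy(dtype=float)
    if features == "reflectance":
        return refl
    if features == "absorbance":
        if np.any(refl <= 0):
            raise ValueError("non-positive reflectance; absorbance undefined")
        return -np.log10(refl)
    if features == "reflectance+means":
        return np.column_stack([refl, signals[_MEANS].to_numpy(dtype=float)])
    raise ValueError(f"unknown feature space {features!r}")


def calibrate_signals(
    signals: pd.DataFrame,
    levels: Mapping[str, float],
    features: str = "absorbance",
    n_components: int | None = None,
) -> PLSCalibrationResults:
    """Fit a PLS1 calibration on the rows of *signals* listed in *levels*.

    *levels* maps standard labels to concentrations (mg/mL); rows are matched
    by the ``label`` column.
    """
    cal = signals[signals["label"].isin(levels)].copy()
    missing = set(levels) - set(cal["label"])
    if missing:
        raise ValueError(f"standards missing from signals: {sorted(missing)}")
    y = cal["label"].map(levels).to_numpy(dtype=float)
    X = feature_matrix(cal, features)
    return PLSCalibration(X, y, n_components=n_components).fit()


def quantify_image(
    image: np.ndarray,
    rois: Sequence[imaging.ROISpec],
    levels: Mapping[str, float],
    blank_label: str = "blank",
    features: str = "absorbance",
    n_components: int | None = None,
) -> tuple[pd.DataFrame, PLSCalibrationResults]:
    """Quantify every non-standard ROI of a single chamber image.

    Returns the prediction table (label, predicted concentration, a
    below-blank flag for negative predictions) and the fitted calibration.
    """
    signals = imaging.signals_table(image, rois, blank_label=blank_label)
    results = calibrate_signals(signals, levels, features=features, n_components=n_components)
    unknowns = signals[
        ~signals["label"].isin(levels) & (signals["label"] != blank_label)
    ].copy()
    preds = results.predict(feature_matrix(unknowns, features))
    table = pd.DataFrame(
        {
            "label": unknowns["label"].to_numpy(),
            "predicted_mg_per_ml": preds,
            "below_blank": preds < 0,
        }
    )
    return table, results
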