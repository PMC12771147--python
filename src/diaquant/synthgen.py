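"""Synthetic cuvette-grid scenes and tabular fixtures with known ground truth.

The generator emulates the closed-chamber photograph the imaging pipeline
consumes: a grid of cuvettes (default 3x3, the nine-cuvette chamber layout)
holding a blank, the six-level analytical curve of a red azo dye and unknown
samples.  The dye absorbs most strongly near 504 nm, so the green channel is
attenuated hardest; concentration maps to colour through per-channel
Beer-Lambert attenuation of the blank intensity,

    mean_ch(c) = blank_ch * 10^(-k_ch * path_scale * c),

with apparent absorptivities k_g > k_b > k_r.  Pixel noise is additive
Gaussian per pixel and channel, then clipped to [0, 255] and rounded to
8 bits.  All randomness flows through an explicit seed; renders are
deterministic.

The module also ships the printed method-comparison summary table (ten candy
samples measured by both methods) as a packaged CSV, and a replicate
generator for feeding recovery/precision computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .comparison import SampleMeasurement
from .imaging import DEFAULT_ROI_EDGE, ROISpec

__all__ = [
    "CALIBRATION_LEVELS",
    "DyeColorModel",
    "SceneSpec",
    "render_scene",
    "default_calibration_scene",
    "scene_rois",
    "table3_fixture",
    "replicate_generator",
]

#: the six-level analytical curve, mg/mL
CALIBRATION_LEVELS = (2.00e-4, 5.00e-4, 1.00e-3, 5.00e-3, 1.00e-2, 2.00e-2)


@dataclass(frozen=True)
class DyeColorModel:
    """Concentration-to-colour map for a red dye in a white-lit chamber.

    ``absorptivity_k`` are apparent per-channel absorptivities in mL/mg; the
    defaults give a green-dominated attenuation (k_g > k_b > k_r) spanning
    roughly one decade of green transmittance over the calibration range.
    They are free synthesis parameters, not measured dye properties.
    """

    blank_rgb: tuple[float, float, float] = (245.0, 243.0, 240.0)
    absorptivity_k: tuple[float, float, float] = (4.0, 60.0, 25.0)
    path_scale: float = 1.0

    def transmittance(self, conc: float) -> np.ndarray:
        """Per-channel transmittance ``10^(-k c)``; 1 at zero concentration."""
        k = np.asarray(self.absorptivity_k, dtype=float)
        return 10.0 ** (-k * self.path_scale * conc)

    def mean_rgb(self, conc: float) -> np.ndarray:
        """Noise-free channel means of a cuvette at concentration *conc*."""
        return np.asarray(self.blank_rgb, dtype=float) * self.transmittance(conc)


@dataclass(frozen=True)
class SceneSpec:
    """Layout and acquisition conditions of one synthetic chamber image.

    ``assignments`` maps cuvette label to concentration (mg/mL) in row-major
    grid order.  ``noise_sd`` is the per-pixel Gaussian noise in channel
    units; 2.0 emulates a quiet consumer sensor in a closed chamber.
    """

    assignments: Mapping[str, float]
    grid: tuple[int, int] = (3, 3)
    cell_px: int = 100
    roi_edge: int = DEFAULT_ROI_EDGE
    noise_sd: float = 2.0
    seed: int = 0
    background_rgb: tuple[float, float, float] = (40.0, 40.0, 40.0)

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if len(self.assignments) > rows * cols:
            raise ValueError(
                f"{len(self.assignments)} cuvettes do not fit a {rows}x{cols} grid"
            )
        if self.roi_edge > self.cell_px:
            raise ValueError("ROI edge larger than the grid cell")


def scene_rois(spec: SceneSpec) -> list[ROISpec]:
    """ROI layout matching :func:`render_scene`: one ROI centred per cuvette."""
    rois = []
    for i, label in enumerate(spec.assignments):
        r, c = divmod(i, spec.grid[1])
        offset = (spec.cell_px - spec.roi_edge) // 2
        rois.append(
            ROISpec(
                label=label,
                row0=r * spec.cell_px + offset,
                col0=c * spec.cell_px + offset,
                edge=spec.roi_edge,
            )
        )
    return rois


def render_scene(
    spec: SceneSpec, model: DyeColorModel = DyeColorModel()
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the chamber image and return it with its ground-truth table.

    Each cuvette paints its whole grid cell with the Beer-Lambert colour of
    its concentration; Gaussian pixel noise is added to the float image, then
    clipped to [0, 255] and rounded to uint8.  The ground truth lists label,
    concentration and the noise-free mean RGB of each cuvette.
    """
    rows, cols = spec.grid
    h, w = rows * spec.cell_px, cols * spec.cell_px
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(spec.background_rgb, dtype=float)
    truth_rows = []
    for i, (label, conc) in enumerate(spec.assignments.items()):
        if conc < 0:
            raise ValueError(f"cuvette {label!r}: negative concentration")
        r, c = divmod(i, cols)
        rgb = model.mean_rgb(conc)
        img[r * spec.cell_px : (r + 1) * spec.cell_px,
            c * spec.cell_px : (c + 1) * spec.cell_px] = rgb
        truth_rows.append(
            {
                "label": label,
                "concentration": conc,
                "true_r": rgb[0],
                "true_g": rgb[1],
                "true_b": rgb[2],
            }
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, pd.DataFrame(truth_rows)


def default_calibration_scene(
    unknowns: Mapping[str, float] | None = None,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> SceneSpec:
    """The standard analysis scene: blank + six standards + two unknowns.

    The nine cuvettes of a 3x3 chamber hold the analytical blank, the six
    calibration levels in increasing order and two unknown samples (defaults
    inside the calibration range).
    """
    if unknowns is None:
        unknowns = {"unk_1": 2.50e-3, "unk_2": 7.50e-3}
    assignments: dict[str, float] = {"blank": 0.0}
    for i, level in enumerate(CALIBRATION_LEVELS, start=1):
        assignments[f"std_{i}"] = level
    assignments.update(unknowns)
    return SceneSpec(assignments=assignments, noise_sd=noise_sd, seed=seed)


def table3_fixture() -> tuple[list[SampleMeasurement], list[SampleMeasurement]]:
    """The ten-candy-sample comparison summary (printed means/SDs, n = 3).

    Returns the UV-vis (reference) and image-method measurement lists,
    samples A1..A10, loaded from the packaged CSV.
    """
    with resources.files("diaquant.data").joinpath(
        "table3_method_comparison.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    ref = [
        SampleMeasurement(row.sample_id, row.uvvis_mean, row.uvvis_sd, int(row.n))
        for row in df.itertuples()
    ]
    alt = [
        SampleMeasurement(row.sample_id, row.dia_mean, row.dia_sd, int(row.n))
        for row in df.itertuples()
    ]
    return ref, alt


def replicate_generator(true_mean: float, cv_pct: float, n: int, seed: int) -> np.ndarray:
    """Gaussian replicates with the given mean and coefficient of variation.

    Deterministic under *seed*; ``cv_pct = 0`` returns *n* copies of the
    mean.
    """
    if cv_pct < 0:
        raise ValueError("cv_pct must be non-negative")
    if n < 2:
        raise ValueError("need at least two replicates")
    if cv_pct == 0.0:
        return np.full(n, float(true_mean))
    rng = np.random.default_rng(seed)
    return rng.normal(true_mean, abs(true_mean) * cv_pct / 100.0, size=n)
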