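"""ROI-based colour-signal extraction from 8-bit RGB images.

The analytical medium is an ordinary 8-bit RGB photograph of cuvettes taken
inside a closed imaging chamber.  A fixed square region of interest (ROI) is
placed over each cuvette; per-channel pixel statistics of that window are the
raw analytical response, and referencing each channel mean to the blank
cuvette's mean gives a dimensionless reflectance triple that plays the role
absorbance plays in spectrophotometry.

Conventions (fixed so ROI placement is reproducible):

* pixel coordinates are 0-based ``(row, col)`` with the origin at the top-left;
* an ROI covers the half-open window ``[row0, row0+edge) x [col0, col0+edge)``;
* images are used in their stored 8-bit sRGB values — no gamma linearisation
  or white-balance correction is applied, since a closed chamber already
  controls the illumination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "DEFAULT_ROI_EDGE",
    "ImageFormatError",
    "ROIBoundsError",
    "DegenerateBlankError",
    "ROISpec",
    "ColorSignal",
    "load_image",
    "extract_roi",
    "roi_histogram",
    "channel_means",
    "reflectance_signal",
    "effective_absorbance",
    "grid_layout",
    "load_layout",
    "signals_table",
]

#: edge length, in pixels, of the square ROI placed over each cuvette
DEFAULT_ROI_EDGE = 45


class ImageFormatError(ValueError):
    """Raised for images that are not 8-bit, 3-channel RGB after alpha drop."""


class ROIBoundsError(ValueError):
    """Raised when an ROI window does not fit inside the image."""


class DegenerateBlankError(ValueError):
    """Raised when a blank channel mean is zero and cannot reference a ratio."""


@dataclass(frozen=True)
class ROISpec:
    """Square region of interest over one cuvette.

    Parameters
    ----------
    label
        Free-text identifier, e.g. ``"blank"``, ``"std_1"`` or ``"sample_A7"``.
    row0, col0
        Top-left corner of the window (0-based pixel indices).
    edge
        Side length in pixels; the window is ``edge x edge``.
    """

    label: str
    row0: int
    col0: int
    edge: int = DEFAULT_ROI_EDGE

    def __post_init__(self) -> None:
        if self.edge < 1:
            raise ValueError(f"ROI {self.label!r}: edge must be >= 1, got {self.edge}")
        if self.row0 < 0 or self.col0 < 0:
            raise ROIBoundsError(
                f"ROI {self.label!r}: negative origin ({self.row0}, {self.col0})"
            )


@dataclass(frozen=True)
class ColorSignal:
    """Per-ROI channel means, optionally with blank-referenced reflectance.

    Means are real-valued in [0, 255].  Reflectance fields are ``None`` until
    :func:`reflectance_signal` references the signal against a blank; the
    blank referenced against itself is exactly (1, 1, 1).
    """

    label: str
    mean_r: float
    mean_g: float
    mean_b: float
    refl_r: float | None = None
    refl_g: float | None = None
    refl_b: float | None = None

    @property
    def means(self) -> tuple[float, float, float]:
        return (self.mean_r, self.mean_g, self.mean_b)

    @property
    def reflectance(self) -> tuple[float, float, float]:
        if self.refl_r is None:
            raise ValueError(f"signal {self.label!r} has not been blank-referenced")
        return (self.refl_r, self.refl_g, self.refl_b)  # type: ignore[return-value]


def load_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit RGB image as a ``(H, W, 3)`` uint8 array.

    PNG, JPEG and TIFF are accepted.  An alpha channel is dropped (not
    composited).  Sixteen-bit and grayscale images are rejected with
    :class:`ImageFormatError`.
    """
    path = Path(path)
    with Image.open(path) as im:
        mode = im.mode
        if mode in ("I", "I;16", "I;16B", "I;16L", "I;16N", "F"):
            raise ImageFormatError(f"{path.name}: not an 8-bit image (mode {mode!r})")
        if mode == "P":
            im = im.convert("RGBA" if "transparency" in im.info else "RGB")
            mode = im.mode
        arr = np.asarray(im)
    if mode == "RGBA":
        arr = arr[:, :, :3]
    elif mode != "RGB":
        raise ImageFormatError(
            f"{path.name}: expected 3-channel RGB, got mode {mode!r}"
        )
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"{path.name}: unexpected shape {arr.shape}")
    return np.ascontiguousarray(arr, dtype=np.uint8)


def extract_roi(image: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Return the ``edge x edge x 3`` patch under *roi*.

    Raises :class:`ROIBoundsError` (naming the ROI label) if the window does
    not fit inside the image.
    """
    h, w = image.shape[:2]
    if roi.row0 + roi.edge > h or roi.col0 + roi.edge > w:
        raise ROIBoundsError(
            f"ROI {roi.label!r} at ({roi.row0}, {roi.col0}) edge {roi.edge} "
            f"exceeds image bounds ({h}, {w})"
        )
    return image[roi.row0 : roi.row0 + roi.edge, roi.col0 : roi.col0 + roi.edge]


def roi_histogram(patch: np.ndarray) -> np.ndarray:
    """Per-channel intensity histogram of a patch.

    Returns a ``(3, 256)`` integer matrix; row ``c`` bins channel ``c`` over
    values 0..255, so each row sums to the patch pixel count.
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("empty patch")
    counts = np.empty((3, 256), dtype=np.int64)
    for c in range(3):
        counts[c] = np.bincount(patch[:, :, c].ravel(), minlength=256)
    return counts


def channel_means(patch: np.ndarray, label: str = "") -> ColorSignal:
    """Arithmetic mean of each channel over the patch."""
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("empty patch")
    m = patch.reshape(-1, 3).mean(axis=0)
    return ColorSignal(label=label, mean_r=float(m[0]), mean_g=float(m[1]), mean_b=float(m[2]))


def reflectance_signal(sample: ColorSignal, blank: ColorSignal) -> ColorSignal:
    """Blank-referenced reflectance: per channel, sample mean / blank mean.

    Values may exceed 1 when the sample is brighter than the blank.  A blank
    channel mean of zero raises :class:`DegenerateBlankError`.
    """
    if min(blank.means) <= 0.0:
        raise DegenerateBlankError(
            f"blank {blank.label!r} has a non-positive channel mean {blank.means}"
        )
    return replace(
        sample,
        refl_r=sample.mean_r / blank.mean_r,
        refl_g=sample.mean_g / blank.mean_g,
        refl_b=sample.mean_b / blank.mean_b,
    )


def effective_absorbance(signal: ColorSignal) -> tuple[float, float, float]:
    """Effective absorbance per channel, ``-log10(reflectance)``.

    An optional transform of the reflectance triple; linear in concentration
    whenever the colour response follows Beer–Lambert attenuation.
    """
    r = signal.reflectance
    if min(r) <= 0.0:
        raise ValueError(f"signal {signal.label!r} has non-positive reflectance {r}")
    return tuple(-np.log10(r))  # type: ignore[return-value]


def grid_layout(
    image_shape: tuple[int, int],
    labels: Sequence[str],
    rows: int = 3,
    cols: int = 3,
    edge: int = DEFAULT_ROI_EDGE,
) -> list[ROISpec]:
    """ROIs centred on a ``rows x cols`` grid of cells covering the image.

    Convenience for the nine-cuvette chamber layout: the image is divided into
    equal cells and one ROI is centred in each, in row-major order, one per
    label.  Cells beyond ``len(labels)`` are left empty.
    """
    h, w = image_shape[:2]
    if len(labels) > rows * cols:
        raise ValueError(f"{len(labels)} labels for a {rows}x{cols} grid")
    ch, cw = h // rows, w // cols
    if edge > ch or edge > cw:
        raise ROIBoundsError(f"edge {edge} does not fit a {ch}x{cw} grid cell")
    rois = []
    for i, label in enumerate(labels):
        r, c = divmod(i, cols)
        rois.append(
            ROISpec(
                label=label,
                row0=r * ch + (ch - edge) // 2,
                col0=c * cw + (cw - edge) // 2,
                edge=edge,
            )
        )
    return rois


def load_layout(path: str | Path) -> list[ROISpec]:
    """Read an ROI layout from a JSON or YAML file.

    The file holds a list (or a mapping with a ``rois`` list) of entries with
    keys ``label``, ``row0``, ``col0`` and optional ``edge`` (default 45).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if isinstance(data, dict):
        data = data["rois"]
    return [
        ROISpec(
            label=str(entry["label"]),
            row0=int(entry["row0"]),
            col0=int(entry["col0"]),
            edge=int(entry.get("edge", DEFAULT_ROI_EDGE)),
        )
        for entry in data
    ]


def signals_table(
    image: np.ndarray,
    rois: Sequence[ROISpec],
    blank_label: str = "blank",
) -> pd.DataFrame:
    """Extract all ROI signals from one image as a tidy table.

    Returns a DataFrame with columns ``label, mean_r, mean_g, mean_b,
    refl_r, refl_g, refl_b``; reflectance columns are referenced to the ROI
    whose label equals *blank_label* and are NaN if no blank ROI is present.
    """
    signals = [channel_means(extract_roi(image, roi), label=roi.label) for roi in rois]
    blank = next((s for s in signals if s.label == blank_label), None)
    if blank is not None:
        signals = [reflectance_signal(s, blank) for s in signals]
    return pd.DataFrame(
        {
            "label": [s.label for s in signals],
            "mean_r": [s.mean_r for s in signals],
            "mean_g": [s.mean_g for s in signals],
            "mean_b": [s.mean_b for s in signals],
            "refl_r": [s.refl_r if s.refl_r is not None else np.nan for s in signals],
            "refl_g": [s.refl_g if s.refl_g is not None else np.nan for s in signals],
            "refl_b": [s.refl_b if s.refl_b is not None else np.nan for s in signals],
        }
    )
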