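"""Histological composition from labelled section masks.

Two stains are modelled as two label masks of the same clot: an MSB-like
mask (RBC vs fibrin/other vs white blood cells) and a CD42b-like mask
(platelet vs rest). Content of a component is its pixel area as a
percentage of the clot cross-section (all non-background pixels of that
mask). The normalized composition expresses the RBC and platelet areas as
percentages of the combined MSB clot area and CD42b platelet area; the
remainder is "other" (fibrin plus white blood cells). Where two slices per
clot are available their results are averaged field-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np

__all__ = [
    "BACKGROUND",
    "RBC",
    "PLATELET",
    "FIBRIN_OTHER",
    "WBC",
    "LabelMask",
    "CompositionResult",
    "content_percent",
    "normalized_composition",
    "average_slices",
    "quantify_pair",
    "load_label_mask",
    "save_label_mask",
]

# integer class codes for label masks
BACKGROUND = 0
RBC = 1
PLATELET = 2
FIBRIN_OTHER = 3
WBC = 4


@dataclass(frozen=True)
class LabelMask:
    """2-D integer class grid; ``pixel_size`` in um/pixel."""

    labels: np.ndarray
    pixel_size: float = 0.23

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def clot_area(self) -> int:
        """Clot cross-section in pixels (non-background)."""
        return int(np.count_nonzero(np.asarray(self.labels) != BACKGROUND))

    def class_area(self, component: int) -> int:
        return int(np.count_nonzero(np.asarray(self.labels) == component))


@dataclass(frozen=True)
class CompositionResult:
    """Content and normalized composition of one clot slice, all in %."""

    rbc_content: float
    platelet_content: float
    normalized_rbc: float
    normalized_platelet: float
    normalized_other: float


def content_percent(mask: LabelMask, component: int) -> float:
    """Component area as % of the clot cross-sectional area."""
    clot = mask.clot_area
    if clot == 0:
        raise ValueError("mask has an empty clot region (all background)")
    return 100.0 * mask.class_area(component) / clot


def normalized_composition(
    msb_clot_area: float, rbc_area: float, platelet_area: float
) -> Tuple[float, float, float]:
    """Normalized (RBC, platelet, other) percentages.

    The denominator is the combined MSB clot area and CD42b platelet area
    (the platelet stain is a separate section, so its area is added to the
    MSB section's clot area rather than contained in it).
    """
    denom = msb_clot_area + platelet_area
    if denom <= 0:
        raise ValueError("combined MSB clot + CD42b platelet area must be > 0")
    n_rbc = 100.0 * rbc_area / denom
    n_plt = 100.0 * platelet_area / denom
    return (n_rbc, n_plt, 100.0 - n_rbc - n_plt)


def average_slices(results: Sequence[CompositionResult]) -> CompositionResult:
    """Field-wise mean of one or two slice results (single slice passes through)."""
    if not 1 <= len(results) <= 2:
        raise ValueError("expected one or two slice results")
    if len(results) == 1:
        return results[0]
    return CompositionResult(
        **{
            f.name: float(np.mean([getattr(r, f.name) for r in results]))
            for f in fields(CompositionResult)
        }
    )


def quantify_pair(msb: LabelMask, cd42b: LabelMask) -> CompositionResult:
    """Quantify one clot slice from its MSB-like and CD42b-like masks."""
    rbc_pct = content_percent(msb, RBC)
    plt_pct = content_percent(cd42b, PLATELET)
    n_rbc, n_plt, n_other = normalized_composition(
        msb_clot_area=msb.clot_area,
        rbc_area=msb.class_area(RBC),
        platelet_area=cd42b.class_area(PLATELET),
    )
    return CompositionResult(
        rbc_content=rbc_pct,
        platelet_content=plt_pct,
        normalized_rbc=n_rbc,
        normalized_platelet=n_plt,
        normalized_other=n_other,
    )


def load_label_mask(path: Union[str, Path], pixel_size: float = 0.23) -> LabelMask:
    """Read an integer-class TIFF label mask."""
    import tifffile

    labels = np.asarray(tifffile.imread(str(path)))
    return LabelMask(labels=labels.astype(np.uint8), pixel_size=pixel_size)


def save_label_mask(mask: LabelMask, path: Union[str, Path]) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(mask.labels, dtype=np.uint8))
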