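"""Tubular-vs-round classification and the normalized tubulation index.

A segmented lysosome counts as *tubular* when it is simultaneously
non-circular (circularity < 0.5), elongated by its ellipse of inertia
(eccentricity > 0.9) and has a major/minor axis ratio above 4.  The stated
axis-ratio criterion is a length-to-width ratio: a literal width/length ratio
of an elongated particle is below 1 and could never exceed 4, so the ratio is
computed major over minor (configurable).

The tubulation index rescales a tubule density linearly between the mean
densities of knockout (index 0) and wild-type (index 1) reference cells
measured in the same experiment, clamped to [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import RegionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ShapeThresholds",
    "ShapeVerdict",
    "TubulationIndex",
    "classify_tubular",
    "classify_regions",
    "tubule_density",
    "tubulation_index",
    "experiment_summary",
]


@dataclass(frozen=True)
class ShapeThresholds:
    """Cutoffs of the tubular-shape rule (defaults 0.5 / 0.9 / 4)."""

    circularity_max: float = 0.5
    eccentricity_min: float = 0.9
    axis_ratio_min: float = 4.0


@dataclass(frozen=True)
class ShapeVerdict:
    """Classification of one particle with the criteria it was judged on."""

    label: int
    frame: int
    tubular: bool
    circularity: float
    eccentricity: float
    axis_ratio: float


@dataclass(frozen=True)
class TubulationIndex:
    """Tubule density rescaled between knockout (0) and wild-type (1) means."""

    tubules_per_um2: float
    index: float
    wt_mean: float
    ko_mean: float
    condition_id: str = ""


def classify_tubular(
    record: RegionRecord, thresholds: ShapeThresholds = ShapeThresholds()
) -> ShapeVerdict:
    """Apply the three-way tubular shape rule to one particle.

    A zero minor axis (degenerate one-pixel-wide line) gives an infinite
    axis ratio; the decision is still defined.
    """
    if record.minor_axis_um == 0:
        ratio = math.inf
    else:
        ratio = record.major_axis_um / record.minor_axis_um
    tubular = (
        record.circularity < thresholds.circularity_max
        and record.eccentricity > thresholds.eccentricity_min
        and ratio > thresholds.axis_ratio_min
    )
    return ShapeVerdict(
        label=record.label,
        frame=record.frame,
        tubular=tubular,
        circularity=record.circularity,
        eccentricity=record.eccentricity,
        axis_ratio=ratio,
    )


def classify_regions(
    records: list[RegionRecord], thresholds: ShapeThresholds = ShapeThresholds()
) -> list[ShapeVerdict]:
    return [classify_tubular(r, thresholds) for r in records]


def tubule_density(verdicts, cell_area_um2: float) -> float:
    """Tubular lysosomes per μm² of cell area."""
    if cell_area_um2 <= 0:
        raise ValueError("cell_area_um2 must be > 0")
    return sum(1 for v in verdicts if v.tubular) / cell_area_um2


def tubulation_index(
    density: float, wt_mean: float, ko_mean: float, condition_id: str = ""
) -> TubulationIndex:
    """Rescale a density between same-experiment KO (0) and WT (1) means."""
    if wt_mean == ko_mean:
        raise ValueError(
            "tubulation index undefined: wild-type and knockout reference "
            "means are equal"
        )
    if not wt_mean > ko_mean >= 0:
        raise ValueError("expected wt_mean > ko_mean >= 0")
    raw = (density - ko_mean) / (wt_mean - ko_mean)
    return TubulationIndex(
        tubules_per_um2=density,
        index=float(np.clip(raw, 0.0, 1.0)),
        wt_mean=wt_mean,
        ko_mean=ko_mean,
        condition_id=condition_id,
    )


def experiment_summary(values, experiment_ids) -> pd.Series:
    """Mean per independent experiment (superplot-style summarization).

    Downstream statistics consume these per-experiment means, never the
    pooled per-cell values.  Experiments contributing no values are excluded
    with a warning.
    """
    df = pd.DataFrame({"value": values, "experiment": experiment_ids})
    if df.empty:
        raise ValueError("experiment_summary needs at least one experiment")
    empty = df["value"].isna().groupby(df["experiment"]).all()
    for exp in empty[empty].index:
        logger.warning("experiment %r has no values; excluded", exp)
    means = df.dropna(subset=["value"]).groupby("experiment")["value"].mean()
    return means
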