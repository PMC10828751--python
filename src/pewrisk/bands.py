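"""Scoring bands for the six-component hemodialysis PEW risk score.

Each component is worth 0-3 points. Continuous components are banded with
half-open intervals that partition the whole positive axis; boundaries are
assigned to the less-severe side for BMI and albumin (a value exactly at a
"better" cut keeps the better score) and to the lower band for ferritin
(exactly 700 ug/L scores 0). Dialysis vintage reads the printed brackets
literally: the 3-4 year band is closed at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

FUNCTIONAL_LEVELS = (
    "normal",
    "occasional_difficulty",
    "dependent_difficulty",
    "bed_chair_bound",
)

COMORBIDITIES = ("DM", "HTN", "IHD", "CVD")

DEFAULT_THRESHOLD = 6


@dataclass(frozen=True)
class ScoreBands:
    """Band edges for the continuous components and the category maps.

    ``bmi_cuts`` and ``albumin_cuts`` are ascending edges (c1, c2, c3) with
    score 3 below c1, 2 in [c1, c2), 1 in [c2, c3) and 0 at or above c3.
    ``ferritin_cuts`` are ascending edges with score 0 at or below the first
    cut, then 1, 2 and 3 above the last. ``vintage_cuts`` (v1, v2, v3) give
    score 0 below v1, 1 in [v1, v2), 2 in [v2, v3] (closed above) and 3
    beyond v3.
    """

    bmi_cuts: tuple[float, float, float] = (16.0, 18.0, 20.0)
    albumin_cuts: tuple[float, float, float] = (28.0, 32.0, 35.0)
    ferritin_cuts: tuple[float, float, float] = (700.0, 800.0, 1000.0)
    vintage_cuts: tuple[float, float, float] = (1.0, 3.0, 4.0)
    functional_points: Mapping[str, int] = field(
        default_factory=lambda: {lvl: i for i, lvl in enumerate(FUNCTIONAL_LEVELS)}
    )
    # comorbidity count -> points; counts above the largest key score 3,
    # counts below the smallest score 0
    comorbidity_points: Mapping[int, int] = field(
        default_factory=lambda: {1: 0, 2: 1, 3: 2, 4: 3}
    )

    def __post_init__(self) -> None:
        for name in ("bmi_cuts", "albumin_cuts", "ferritin_cuts", "vintage_cuts"):
            cuts = getattr(self, name)
            if len(cuts) != 3 or list(cuts) != sorted(cuts):
                raise ValueError(f"{name} must be three ascending edges, got {cuts!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["functional_points"] = dict(self.functional_points)
        d["comorbidity_points"] = {int(k): int(v) for k, v in self.comorbidity_points.items()}
        return d


DEFAULT_BANDS = ScoreBands()


def load_config(path: str | Path) -> dict:
    """Read a YAML scoring config: band edges, threshold, aggregation policy.

    Missing keys fall back to the defaults, so a config file may override
    just the threshold, or a single component's edges.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    band_kwargs = {}
    for key in ("bmi_cuts", "albumin_cuts", "ferritin_cuts", "vintage_cuts"):
        if key in raw:
            band_kwargs[key] = tuple(float(x) for x in raw[key])
    if "functional_points" in raw:
        band_kwargs["functional_points"] = {str(k): int(v) for k, v in raw["functional_points"].items()}
    if "comorbidity_points" in raw:
        band_kwargs["comorbidity_points"] = {int(k): int(v) for k, v in raw["comorbidity_points"].items()}
    return {
        "bands": ScoreBands(**band_kwargs),
        "threshold": int(raw.get("threshold", DEFAULT_THRESHOLD)),
        "aggregation": str(raw.get("aggregation", "maximum")),
        "haldane_anscombe": bool(raw.get("haldane_anscombe", False)),
        "yates": bool(raw.get("yates", False)),
    }


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0
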