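"""Directional gait variable scores (GVS), gait profile score (GPS), and
movement-analysis-profile (MAP) group summaries.

A classic GVS is the RMS difference over the gait cycle between one
kinematic curve and the TD reference mean for that variable.  Here the four
variables whose deviation direction carries distinct clinical meaning - the
sagittal hip, knee and ankle angles and the foot progression angle - are
split into two one-sided scores each (e.g. knee *flexion* when the patient
is more flexed than reference vs. knee *extension* when more extended),
giving 13 scores from 9 variables.

The one-sided scores are RMS values of the clipped deviation over all 51
samples (samples on the other side contribute zeros).  This convention makes
the split exact: for each split variable,

    flexion_score**2 + extension_score**2 == full-cycle RMS**2.

The GPS is the RMS average of all 13 directional scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import GaitCycle, ReferenceProfile, KINEMATIC_VARIABLES

#: Variables whose full-cycle RMS is used unsplit.
UNSPLIT_VARIABLES: tuple[str, ...] = (
    "pelvic_tilt",
    "pelvic_obliquity",
    "pelvic_rotation",
    "hip_abdadd",
    "hip_rotation",
)

#: Split variables mapped to (positive-side score, negative-side score).
#: Positive deviation = more flexion / dorsiflexion / inward progression
#: than the reference, under the sign convention fixed in :mod:`somgait.io`.
SPLIT_VARIABLES: dict[str, tuple[str, str]] = {
    "hip_flexion": ("hip_flexion", "hip_extension"),
    "knee_flexion": ("knee_flexion", "knee_extension"),
    "ankle_dorsiflexion": ("ankle_dorsiflexion", "ankle_plantarflexion"),
    "foot_progression": ("foot_progression_in", "foot_progression_out"),
}

#: The 13 directional score names, in canonical (reporting) order.
GVS_NAMES: tuple[str, ...] = (
    "pelvic_tilt",
    "pelvic_obliquity",
    "pelvic_rotation",
    "hip_flexion",
    "hip_extension",
    "hip_abdadd",
    "hip_rotation",
    "knee_flexion",
    "knee_extension",
    "ankle_dorsiflexion",
    "ankle_plantarflexion",
    "foot_progression_in",
    "foot_progression_out",
)


@dataclass
class GVSVector:
    """The 13 directional gait variable scores of one limb (degrees, >= 0)."""

    limb_id: str
    condition: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.scores) != set(GVS_NAMES):
            raise ValueError(
                f"limb {self.limb_id}: expected exactly the 13 directional scores"
            )
        for name, v in self.scores.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"limb {self.limb_id}, score {name}: invalid value {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.scores[n] for n in GVS_NAMES], dtype=float)


@dataclass
class GPSValue:
    """Gait profile score: RMS average of a limb's 13 GVSs."""

    limb_id: str
    condition: str
    gps: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.gps) or self.gps < 0:
            raise ValueError(f"limb {self.limb_id}: invalid GPS {self.gps}")


def signed_deviation(cycle: GaitCycle, ref: ReferenceProfile) -> dict[str, np.ndarray]:
    """Per-variable signed deviation curve cycle - reference mean (degrees)."""
    if set(cycle.curves) != set(ref.mean_curves):
        raise ValueError("cycle and reference cover different variables")
    return {v: cycle.curves[v] - ref.mean_curves[v] for v in KINEMATIC_VARIABLES}


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def compute_gvs(cycle: GaitCycle, ref: ReferenceProfile) -> GVSVector:
    """The 13 directional GVSs of one limb against the TD reference."""
    dev = signed_deviation(cycle, ref)
    scores: dict[str, float] = {}
    for v in UNSPLIT_VARIABLES:
        scores[v] = _rms(dev[v])
    for v, (pos_name, neg_name) in SPLIT_VARIABLES.items():
        d = dev[v]
        scores[pos_name] = _rms(np.clip(d, 0.0, None))
        scores[neg_name] = _rms(np.clip(-d, 0.0, None))
    return GVSVector(limb_id=cycle.limb_id, condition=cycle.condition, scores=scores)


def compute_gps(gvs: GVSVector) -> GPSValue:
    """GPS = sqrt(mean of the 13 squared directional scores)."""
    arr = gvs.as_array()
    return GPSValue(
        limb_id=gvs.limb_id,
        condition=gvs.condition,
        gps=float(np.sqrt(np.mean(arr**2))),
    )


def gvs_matrix(vectors: Iterable[GVSVector]) -> np.ndarray:
    """Stack GVS vectors into an (n, 13) array in canonical score order."""
    return np.stack([v.as_array() for v in vectors])


def map_table(gvs_by_group: Mapping[str, Iterable[GVSVector]]) -> pd.DataFrame:
    """Movement analysis profile: per-group mean of each of the 13 GVSs.

    Returns a DataFrame with one row per score (canonical order) and one
    column per group, i.e. the bar heights of a MAP chart.
    """
    columns = {}
    for group, vectors in gvs_by_group.items():
        vectors = list(vectors)
        if not vectors:
            raise ValueError(f"group {group!r} is empty")
        columns[group] = gvs_matrix(vectors).mean(axis=0)
    return pd.DataFrame(columns, index=list(GVS_NAMES))


def gvs_table(vectors: Iterable[GVSVector]) -> pd.DataFrame:
    """One row per limb-condition: the 13 scores plus the GPS, in degrees."""
    rows = []
    for v in vectors:
        row = {"limb_id": v.limb_id, "condition": v.condition}
        row.update({n: round(v.scores[n], 4) for n in GVS_NAMES})
        row["gps"] = round(compute_gps(v).gps, 4)
        rows.append(row)
    return pd.DataFrame(rows, columns=["limb_id", "condition", *GVS_NAMES, "gps"])
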