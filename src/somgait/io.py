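"""Reading, validating and writing time-normalized gait-cycle kinematics.

A gait cycle is described by 9 joint-angle curves, each time-normalized to
51 samples covering 0-100% of the cycle at 2% steps (0% = ipsilateral foot
strike).  Angles are in degrees under the standard clinical convention:
flexion, dorsiflexion, adduction, internal rotation, anterior pelvic tilt
and inward (internal) foot progression are positive.

The on-disk format is a long CSV dialect: one row per (limb, condition,
variable) with metadata columns followed by 51 value columns ``t000``,
``t002``, ... ``t100``.  Laboratories exporting from C3D-based pipelines are
expected to time-normalize and average their strides upstream and write this
dialect; this package never reads C3D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The 9 kinematic variables of a lower-limb gait cycle, in canonical order.
KINEMATIC_VARIABLES: tuple[str, ...] = (
    "pelvic_tilt",
    "pelvic_obliquity",
    "pelvic_rotation",
    "hip_flexion",
    "hip_abdadd",
    "hip_rotation",
    "knee_flexion",
    "ankle_dorsiflexion",
    "foot_progression",
)

#: Number of samples per time-normalized curve (0-100% every 2%).
N_SAMPLES: int = 51

#: The percent grid the curves live on.
GRID_PERCENT: np.ndarray = np.linspace(0.0, 100.0, N_SAMPLES)

SIDES = frozenset({"left", "right"})
COHORTS = frozenset({"TD", "CP"})
CONDITIONS = frozenset({"barefoot", "orthosis"})
ORTHOSIS_TYPES = frozenset(
    {"none", "GRAFO", "PLS", "solid", "hinged", "SMO", "sport", "other"}
)

#: Sentinel limb_id used when serializing a reference profile row set.
REFERENCE_LIMB_ID = "=TD_REFERENCE="

_VALUE_COLUMNS = tuple(f"t{p:03d}" for p in range(0, 101, 2))
_META_COLUMNS = (
    "limb_id",
    "subject_id",
    "side",
    "cohort",
    "condition",
    "orthosis_type",
    "variable",
)


class GaitValidationError(ValueError):
    """Raised when gait-cycle data violate the format contract."""


@dataclass
class GaitCycle:
    """One limb x condition: 9 joint-angle curves of 51 samples each.

    Parameters
    ----------
    limb_id, subject_id:
        Opaque identifiers; ``limb_id`` is unique per limb within a cohort.
    side:
        ``"left"`` or ``"right"``.
    cohort:
        ``"TD"`` (typically developing) or ``"CP"`` (cerebral palsy).
    condition:
        ``"barefoot"`` or ``"orthosis"``.
    orthosis_type:
        The prescribed orthosis design; ``"none"`` unless ``condition`` is
        ``"orthosis"``.
    curves:
        Mapping from each kinematic variable to a float array of 51 degrees.
    """

    limb_id: str
    subject_id: str
    side: str
    cohort: str
    condition: str
    orthosis_type: str
    curves: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise GaitValidationError(f"invalid side {self.side!r} for limb {self.limb_id}")
        if self.cohort not in COHORTS:
            raise GaitValidationError(f"invalid cohort {self.cohort!r} for limb {self.limb_id}")
        if self.condition not in CONDITIONS:
            raise GaitValidationError(
                f"invalid condition {self.condition!r} for limb {self.limb_id}"
            )
        if self.orthosis_type not in ORTHOSIS_TYPES:
            raise GaitValidationError(
                f"invalid orthosis_type {self.orthosis_type!r} for limb {self.limb_id}"
            )
        if self.condition == "orthosis" and self.orthosis_type == "none":
            raise GaitValidationError(
                f"limb {self.limb_id}: condition=orthosis requires an orthosis_type"
            )
        if self.cohort == "TD" and self.condition != "barefoot":
            raise GaitValidationError(
                f"limb {self.limb_id}: TD limbs are measured barefoot only"
            )
        missing = set(KINEMATIC_VARIABLES) - set(self.curves)
        extra = set(self.curves) - set(KINEMATIC_VARIABLES)
        if missing:
            raise GaitValidationError(
                f"limb {self.limb_id} ({self.condition}): missing variables {sorted(missing)}"
            )
        if extra:
            raise GaitValidationError(
                f"limb {self.limb_id} ({self.condition}): unknown variables {sorted(extra)}"
            )
        for name in KINEMATIC_VARIABLES:
            arr = np.asarray(self.curves[name], dtype=float)
            if arr.shape != (N_SAMPLES,):
                raise GaitValidationError(
                    f"limb {self.limb_id}, variable {name}: expected 51 samples, "
                    f"got {arr.size}"
                )
            if not np.all(np.isfinite(arr)):
                raise GaitValidationError(
                    f"limb {self.limb_id}, variable {name}: non-finite angle value"
                )
            self.curves[name] = arr

    @property
    def key(self) -> tuple[str, str]:
        return (self.limb_id, self.condition)

    def as_matrix(self) -> np.ndarray:
        """Curves stacked as a (9, 51) array in canonical variable order."""
        return np.stack([self.curves[v] for v in KINEMATIC_VARIABLES])


@dataclass
class ReferenceProfile:
    """Pointwise mean (and SD) typically-developing gait curves.

    The mean curves are the comparison baseline for every gait variable
    score; the SDs are informational only.
    """

    mean_curves: dict[str, np.ndarray]
    sd_curves: dict[str, np.ndarray]
    n_limbs: int

    def __post_init__(self) -> None:
        if self.n_limbs < 1:
            raise GaitValidationError("reference profile needs at least one TD limb")
        for store in (self.mean_curves, self.sd_curves):
            if set(store) != set(KINEMATIC_VARIABLES):
                raise GaitValidationError("reference profile must cover all 9 variables")
            for name, arr in store.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (N_SAMPLES,):
                    raise GaitValidationError(
                        f"reference {name}: expected 51 samples, got {arr.size}"
                    )
                store[name] = arr
        for name, arr in self.sd_curves.items():
            if np.any(arr < 0):
                raise GaitValidationError(f"reference {name}: negative SD")


def resample_cycle(samples: Sequence[tuple[float, float]]) -> np.ndarray:
    """Linearly interpolate (percent, degrees) pairs onto the 0,2,...,100 grid.

    Percents must be strictly increasing and span [0, 100]; no extrapolation
    is performed.
    """
    pts = np.asarray(samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (percent, value) pairs")
    percent, value = pts[:, 0], pts[:, 1]
    if np.any(np.diff(percent) <= 0):
        raise ValueError("percent values must be strictly increasing")
    if percent[0] > 0.0 or percent[-1] < 100.0:
        raise ValueError(
            f"samples span [{percent[0]}, {percent[-1]}] but must cover [0, 100]; "
            "no extrapolation is performed"
        )
    return np.interp(GRID_PERCENT, percent, value)


def build_reference(td_cycles: Iterable[GaitCycle]) -> ReferenceProfile:
    """Pointwise mean and population SD over TD limbs, per variable and sample."""
    cycles = list(td_cycles)
    if not cycles:
        raise GaitValidationError("cannot build a reference from an empty TD set")
    for c in cycles:
        if c.cohort != "TD":
            raise GaitValidationError(
                f"limb {c.limb_id} has cohort {c.cohort!r}; reference input must be TD"
            )
    stacked = np.stack([c.as_matrix() for c in cycles])  # (n, 9, 51)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=0)
    return ReferenceProfile(
        mean_curves={v: mean[i] for i, v in enumerate(KINEMATIC_VARIABLES)},
        sd_curves={v: sd[i] for i, v in enumerate(KINEMATIC_VARIABLES)},
        n_limbs=len(cycles),
    )


def _cycles_to_frame(cycles: Iterable[GaitCycle]) -> pd.DataFrame:
    rows = []
    for c in cycles:
        for v in KINEMATIC_VARIABLES:
            row = {
                "limb_id": c.limb_id,
                "subject_id": c.subject_id,
                "side": c.side,
                "cohort": c.cohort,
                "condition": c.condition,
                "orthosis_type": c.orthosis_type,
            }
            row["variable"] = v
            row.update(dict(zip(_VALUE_COLUMNS, c.curves[v])))
            rows.append(row)
    return pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(_VALUE_COLUMNS))


def write_gait_table(cycles: Iterable[GaitCycle], path: str | Path) -> None:
    """Write gait cycles in the long CSV dialect (full float precision)."""
    frame = _cycles_to_frame(cycles)
    frame.to_csv(path, index=False, float_format="%.17g")


def write_reference(ref: ReferenceProfile, path: str | Path) -> None:
    """Serialize a reference profile using the same dialect.

    Mean curves carry the sentinel limb_id with condition "barefoot"; SDs are
    stored as a second block with subject_id "sd".
    """
    rows = []
    for kind, store in (("mean", ref.mean_curves), ("sd", ref.sd_curves)):
        for v in KINEMATIC_VARIABLES:
            row = {
                "limb_id": REFERENCE_LIMB_ID,
                "subject_id": kind,
                "side": "left",
                "cohort": "TD",
                "condition": "barefoot",
                "orthosis_type": "none",
                "variable": v,
            }
            row.update(dict(zip(_VALUE_COLUMNS, store[v])))
            rows.append(row)
    frame = pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(_VALUE_COLUMNS))
    frame.to_csv(path, index=False, float_format="%.17g")


def read_reference(path: str | Path) -> ReferenceProfile:
    """Read a reference profile written by :func:`write_reference`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    mean_rows = frame[frame["subject_id"] == "mean"]
    sd_rows = frame[frame["subject_id"] == "sd"]
    mean_curves = {
        r["variable"]: np.asarray([r[c] for c in _VALUE_COLUMNS], dtype=float)
        for _, r in mean_rows.iterrows()
    }
    sd_curves = {
        r["variable"]: np.asarray([r[c] for c in _VALUE_COLUMNS], dtype=float)
        for _, r in sd_rows.iterrows()
    }
    return ReferenceProfile(mean_curves=mean_curves, sd_curves=sd_curves, n_limbs=1)


def read_gait_table(path: str | Path) -> list[GaitCycle]:
    """Read gait cycles from the long CSV dialect, enforcing all invariants.

    Returns one :class:`GaitCycle` per (limb_id, condition), preserving the
    file's row order.  Rows with the reference sentinel limb_id are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={c: str for c in _META_COLUMNS},
                        float_precision="round_trip")
    missing_cols = [c for c in list(_META_COLUMNS) + list(_VALUE_COLUMNS) if c not in frame.columns]
    if missing_cols:
        raise GaitValidationError(f"{path.name}: missing columns {missing_cols}")

    groups: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for idx, row in frame.iterrows():
        if row["limb_id"] == REFERENCE_LIMB_ID:
            continue
        key = (row["limb_id"], row["condition"])
        values = row[list(_VALUE_COLUMNS)].to_numpy()
        try:
            curve = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise GaitValidationError(
                f"{path.name} row {idx}: non-numeric angle value ({exc})"
            ) from None
        if key not in groups:
            groups[key] = {
                "meta": {c: row[c] for c in _META_COLUMNS if c != "variable"},
                "curves": {},
            }
            order.append(key)
        if row["variable"] in groups[key]["curves"]:
            raise GaitValidationError(
                f"{path.name} row {idx}: duplicate variable {row['variable']!r} "
                f"for limb {key[0]} condition {key[1]}"
            )
        groups[key]["curves"][row["variable"]] = curve

    cycles = []
    for key in order:
        g = groups[key]
        m = g["meta"]
        cycles.append(
            GaitCycle(
                limb_id=m["limb_id"],
                subject_id=m["subject_id"],
                side=m["side"],
                cohort=m["cohort"],
                condition=m["condition"],
                orthosis_type=m["orthosis_type"],
                curves=g["curves"],
            )
        )
    return cycles
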