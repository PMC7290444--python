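"""Orthosis outcome evaluation through gait profile score differences.

For each limb measured both barefoot and with its prescribed orthosis,

    dGPS = GPS_barefoot - GPS_orthosis,

so a positive difference means the orthosis moved the gait pattern toward
the typically developing reference.  Improvement is strict (dGPS > 0), and
a separate flag marks limbs whose improvement reaches the minimal
clinically important difference for the GPS, 1.6 points.  Outcomes are
aggregated per (gait-pattern cluster, orthosis design) as the number of
limbs, the share improved, the mean dGPS over all limbs, and the mean dGPS
over improved limbs only; cells with no improved limbs report the latter as
missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Minimal clinically important difference for the GPS, in points (degrees).
MCID_GPS: float = 1.6

#: Display categories of the prescription crosstab, in fixed column order.
CROSSTAB_COLUMNS: tuple[str, ...] = (
    "No Orthosis",
    "GRAFO",
    "PLS AFO",
    "Solid/Rigid AFO",
    "Hinged AFO",
    "Others",
)

#: Raw orthosis_type -> crosstab display category (dynamic designs collapse
#: into "Others"; full types remain on the records).
_TYPE_TO_CATEGORY = {
    "none": "No Orthosis",
    "GRAFO": "GRAFO",
    "PLS": "PLS AFO",
    "solid": "Solid/Rigid AFO",
    "hinged": "Hinged AFO",
    "SMO": "Others",
    "sport": "Others",
    "other": "Others",
}


def clinical_example_crosstab() -> pd.DataFrame:
    """Prescription counts from a published clinical CP cohort (196 limbs).

    One row per gait-pattern group, one column per orthosis category, no
    margins; pass through :func:`add_margins` for totals.  Useful as a
    realistic worked example of the crosstab arithmetic: 196 limbs in
    total, of which 139 carried an orthosis prescription.
    """
    counts = [
        [23, 1, 23, 0, 2, 0],
        [8, 2, 14, 0, 0, 0],
        [13, 5, 25, 8, 1, 4],
        [11, 1, 17, 6, 3, 1],
        [2, 0, 18, 7, 1, 0],
    ]
    return pd.DataFrame(
        counts,
        index=[f"Group {i}" for i in range(1, 6)],
        columns=list(CROSSTAB_COLUMNS),
    )


@dataclass
class OutcomeRecord:
    """Per-limb orthosis outcome: paired GPS values and derived flags."""

    limb_id: str
    cluster: int
    orthosis_type: str
    gps_barefoot: float
    gps_orthosis: float
    delta_gps: float
    improved: bool
    mcid_met: bool


def delta_gps(limb_id: str, cluster: int, orthosis_type: str,
              gps_barefoot: float, gps_orthosis: float,
              mcid: float = MCID_GPS) -> OutcomeRecord:
    """Build an outcome record from a barefoot/orthosis GPS pair.

    dGPS = barefoot - orthosis; improvement requires dGPS strictly positive
    (a zero difference is not an improvement); the MCID flag is inclusive
    (dGPS >= mcid).
    """
    d = float(gps_barefoot) - float(gps_orthosis)
    return OutcomeRecord(
        limb_id=limb_id,
        cluster=cluster,
        orthosis_type=orthosis_type,
        gps_barefoot=float(gps_barefoot),
        gps_orthosis=float(gps_orthosis),
        delta_gps=d,
        improved=d > 0.0,
        mcid_met=d >= mcid,
    )


def outcome_table(records: Iterable[OutcomeRecord]) -> pd.DataFrame:
    """Aggregate outcomes per (cluster, orthosis category).

    Columns: n_limbs, n_improved, percent_improved, average_delta_gps,
    average_positive_delta_gps (NaN when no limb in the cell improved).
    Only limbs with a measured orthosis condition enter any denominator.
    """
    rows = []
    records = list(records)
    for r in records:
        if r.cluster is None:
            raise ValueError(f"record {r.limb_id} has no cluster label")
    keyed: dict[tuple[int, str], list[OutcomeRecord]] = {}
    for r in records:
        cat = _TYPE_TO_CATEGORY[r.orthosis_type]
        keyed.setdefault((r.cluster, cat), []).append(r)
    for (cluster, cat) in sorted(keyed, key=lambda k: (k[0], CROSSTAB_COLUMNS.index(k[1]))):
        cell = keyed[(cluster, cat)]
        deltas = np.array([r.delta_gps for r in cell])
        pos = deltas[deltas > 0]
        rows.append(
            {
                "cluster": cluster,
                "orthosis": cat,
                "n_limbs": len(cell),
                "n_improved": int((deltas > 0).sum()),
                "percent_improved": 100.0 * float((deltas > 0).mean()),
                "average_delta_gps": float(deltas.mean()),
                "average_positive_delta_gps": float(pos.mean()) if pos.size else np.nan,
                "n_mcid": int(sum(r.mcid_met for r in cell)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "orthosis",
            "n_limbs",
            "n_improved",
            "percent_improved",
            "average_delta_gps",
            "average_positive_delta_gps",
            "n_mcid",
        ],
    )


def add_margins(table: pd.DataFrame) -> pd.DataFrame:
    """Append row/column totals to a counts crosstab ("Total" row/column)."""
    out = table.copy()
    out["Total"] = out.sum(axis=1)
    out.loc["Total"] = out.sum(axis=0)
    return out


def prescription_crosstab(limb_types: Mapping[str, str],
                          limb_clusters: Mapping[str, int]) -> pd.DataFrame:
    """Cluster x orthosis-category count table with margins.

    ``limb_types`` maps every CP limb (orthosis-prescribed or not) to its
    raw orthosis type; ``limb_clusters`` gives the cluster label per limb.
    Limbs without a prescription count under "No Orthosis".
    """
    clusters = sorted(set(limb_clusters.values())) if limb_clusters else []
    table = pd.DataFrame(
        0, index=[f"Group {c}" for c in clusters], columns=list(CROSSTAB_COLUMNS)
    )
    for limb, otype in limb_types.items():
        if limb not in limb_clusters:
            raise ValueError(f"limb {limb} has no cluster label")
        cat = _TYPE_TO_CATEGORY[otype]
        table.loc[f"Group {limb_clusters[limb]}", cat] += 1
    return add_margins(table)
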