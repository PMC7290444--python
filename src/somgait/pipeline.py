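"""End-to-end orchestration: cohort in, classified gait patterns out.

Stage order: build TD reference -> directional GVS per limb -> z-score
normalization -> batch SOM training -> cluster-count sensitivity analysis
-> k-means over the codebook -> limb assignment -> group statistics ->
orthosis outcome tables.  All artifacts of a run are written into a single
output directory (written to a temporary directory first and moved into
place on success, so a failed run never leaves partial artifacts), together
with the effective configuration and a run log carrying the seed and a
configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .scores import compute_gvs, compute_gps, gvs_matrix, gvs_table, map_table
from .som import SOMTrainConfig, normalize_features, train_som, hit_map
from .clustering import cluster_som, assign_limbs, select_k, canonicalize_labels
from .stats import stats_report
from .outcomes import MCID_GPS, delta_gps, outcome_table, prescription_crosstab
from .simulate import CohortConfig, generate_cohort

SCHEMA_VERSION = "somgait-1"


@dataclass
class PipelineConfig:
    """Validated, fully serializable run configuration."""

    input_csv: str | None = None  # None -> simulate the default cohort
    outdir: str = "somgait_run"
    seed: int = 0
    som: SOMTrainConfig = field(default_factory=SOMTrainConfig)
    k_min: int = 2
    k_max: int = 10
    k_fixed: int | None = None  # skip the sensitivity analysis if set
    n_init: int = 10
    mcid: float = MCID_GPS
    write_plots: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.som, dict):
            self.som = SOMTrainConfig(**self.som)
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        if self.mcid < 0:
            raise ValueError("MCID threshold must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_csv(frame: pd.DataFrame, path: Path, schema: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}/{schema}\n")
        frame.to_csv(fh, index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a result summary dict.

    Artifacts written: gait.csv + truth.csv (when simulating), reference.csv,
    gvs.csv, som_model.json, select_k.csv, assignments.csv, hit_map.csv,
    map_table.csv, stats_report.json, outcome_table.csv, crosstab.csv,
    config.yaml, run.log.
    """
    outdir = Path(config.outdir)
    outdir.parent.mkdir(parents=True, exist_ok=True)
    tmpdir = Path(tempfile.mkdtemp(prefix=".somgait-", dir=outdir.parent))
    log_lines = [f"seed={config.seed}", f"config_hash={config.config_hash()}"]
    try:
        result = _run_stages(config, tmpdir, log_lines)
        (tmpdir / "run.log").write_text("\n".join(log_lines) + "\n")
        (tmpdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
        if outdir.exists():
            shutil.rmtree(outdir)
        tmpdir.replace(outdir)
        result["outdir"] = str(outdir)
    except Exception:
        shutil.rmtree(tmpdir, ignore_errors=True)
        raise
    return result


def _run_stages(config: PipelineConfig, outdir: Path, log: list[str]) -> dict:
    # --- input -----------------------------------------------------------
    if config.input_csv is None:
        log.append("stage=simulate: generating default synthetic cohort")
        cycles, truth = generate_cohort(CohortConfig(seed=config.seed))
        gio.write_gait_table(cycles, outdir / "gait.csv")
        _write_csv(truth, outdir / "truth.csv", "truth")
    else:
        log.append(f"stage=read: {config.input_csv}")
        cycles = gio.read_gait_table(config.input_csv)
        truth = None
    barefoot = [c for c in cycles if c.condition == "barefoot"]
    with_orthosis = {c.limb_id: c for c in cycles if c.condition == "orthosis"}

    # --- reference and scores -------------------------------------------
    td = [c for c in barefoot if c.cohort == "TD"]
    if not td:
        raise ValueError("stage=reference: input contains no TD limbs")
    ref = gio.build_reference(td)
    gio.write_reference(ref, outdir / "reference.csv")
    log.append(f"stage=reference: n_limbs={ref.n_limbs}")

    gvs = [compute_gvs(c, ref) for c in barefoot]
    gvs_orth = {c.limb_id: compute_gvs(c, ref) for c in with_orthosis.values()}
    _write_csv(gvs_table(gvs + list(gvs_orth.values())), outdir / "gvs.csv", "gvs")
    log.append(f"stage=gvs: n_limbs={len(gvs)}")

    # --- SOM -------------------------------------------------------------
    matrix = gvs_matrix(gvs)
    z, params = normalize_features(matrix)
    som_config = SOMTrainConfig(**{**asdict(config.som), "seed": config.seed})
    model = train_som(z, som_config, norm_params=params)
    model.to_json(outdir / "som_model.json")
    log.append(f"stage=som: qe_final={model.qe_history[-1]:.6f}")

    # --- cluster number and assignment ----------------------------------
    if config.k_fixed is not None:
        chosen_k, diagnostics = config.k_fixed, []
    else:
        chosen_k, diagnostics = select_k(
            model, range(config.k_min, config.k_max + 1),
            seed=config.seed, n_init=config.n_init,
        )
        _write_csv(pd.DataFrame(diagnostics), outdir / "select_k.csv", "select_k")
    log.append(f"stage=select_k: k={chosen_k}")

    clusters, label_grid = cluster_som(model, chosen_k, seed=config.seed,
                                       n_init=config.n_init)
    assignment = assign_limbs(model, clusters, gvs)
    td_ids = {c.limb_id for c in td}
    relabel = canonicalize_labels(
        {limb: lab for limb, (_, lab) in assignment.items()}, td_ids, chosen_k
    )
    assignment = {limb: (u, relabel[lab]) for limb, (u, lab) in assignment.items()}

    rows = model.config.grid_rows
    assign_frame = pd.DataFrame(
        [
            {
                "limb_id": limb,
                "unit_row": u // model.config.grid_cols,
                "unit_col": u % model.config.grid_cols,
                "cluster": lab,
            }
            for limb, (u, lab) in assignment.items()
        ]
    )
    _write_csv(assign_frame, outdir / "assignments.csv", "assignments")
    hits = hit_map(model, model.normalize(matrix))
    _write_csv(pd.DataFrame(hits), outdir / "hit_map.csv", "hit_map")

    # --- group statistics ------------------------------------------------
    by_group: dict[str, list] = {}
    for v in gvs:
        label = assignment[v.limb_id][1]
        by_group.setdefault(f"Group {label}", []).append(v)
    by_group = dict(sorted(by_group.items()))
    _write_csv(map_table(by_group), outdir / "map_table.csv", "map_table", index=True)
    report = stats_report(by_group)
    (outdir / "stats_report.json").write_text(json.dumps(report, indent=1))
    log.append(f"stage=stats: n_groups={len(by_group)}")

    # --- orthosis outcomes ----------------------------------------------
    cp_barefoot = [c for c in barefoot if c.cohort == "CP"]
    records = []
    gps_by_limb = {}
    for c in barefoot:
        limb_gvs = next(v for v in gvs if v.limb_id == c.limb_id)
        gps_by_limb[c.limb_id] = compute_gps(limb_gvs).gps
    for c in cp_barefoot:
        if c.limb_id in with_orthosis:
            gps_o = compute_gps(gvs_orth[c.limb_id]).gps
            records.append(
                delta_gps(
                    c.limb_id,
                    assignment[c.limb_id][1],
                    with_orthosis[c.limb_id].orthosis_type,
                    gps_by_limb[c.limb_id],
                    gps_o,
                    mcid=config.mcid,
                )
            )
    outcomes = outcome_table(records)
    _write_csv(outcomes, outdir / "outcome_table.csv", "outcome_table")
    crosstab = prescription_crosstab(
        {c.limb_id: c.orthosis_type for c in cp_barefoot},
        {c.limb_id: assignment[c.limb_id][1] for c in cp_barefoot},
    )
    _write_csv(crosstab, outdir / "crosstab.csv", "crosstab", index=True)
    log.append(
        f"stage=outcomes: n_orthosis_limbs={len(records)} "
        f"n_cp_limbs={len(cp_barefoot)}"
    )

    if config.write_plots:
        _render_plots(outdir, hits, label_grid, by_group)

    n_improved = sum(r.improved for r in records)
    return {
        "outdir": str(outdir),
        "n_limbs": len(barefoot),
        "n_td_limbs": len(td),
        "n_cp_limbs": len(cp_barefoot),
        "chosen_k": chosen_k,
        "k_diagnostics": diagnostics,
        "assignment": assignment,
        "n_orthosis_limbs": len(records),
        "n_improved": n_improved,
        "percent_improved": 100.0 * n_improved / len(records) if records else float("nan"),
        "records": records,
        "reference_n_limbs": ref.n_limbs,
    }


def _render_plots(outdir: Path, hits: np.ndarray, label_grid: np.ndarray,
                  by_group: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].imshow(hits, cmap="Greys")
    axes[0].set_title("BMU hit map")
    axes[1].imshow(label_grid, cmap="tab10")
    axes[1].set_title("codebook clusters")
    fig.savefig(outdir / "som_maps.png", dpi=100)
    plt.close(fig)

    mt = map_table(by_group)
    ax = mt.plot.bar(figsize=(12, 4))
    ax.set_ylabel("mean GVS (deg)")
    ax.figure.tight_layout()
    ax.figure.savefig(outdir / "map_profiles.png", dpi=100)
    plt.close(ax.figure)
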