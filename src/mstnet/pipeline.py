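"""End-to-end orchestration: simulate/load -> PLI -> trees -> aggregation -> stats.

Everything is driven by a single :class:`PipelineConfig`; outputs are plain
CSV files plus a manifest with content hashes and a run log, so a run with the
same configuration and seed reproduces byte-identical tables and each stage's
output can be re-loaded independently.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .aggregate import average_mst, hub_table, overlap_graph, write_overlap_csv
from .connectivity import (
    BANDS,
    ConnectivityMatrix,
    condition_matrix,
    get_band,
    mean_pli,
    trial_connectivity,
    write_matrix_csv,
)
from .stats import analyze_metric_table
from .synthetic import GroupSimConfig, SyntheticStudy, generate_group, write_truth_csv
from .tree import METRIC_NAMES, max_spanning_tree, tree_metrics, write_tree_csv
from .trial_io import CONDITIONS, Study, exclude_subjects, read_study, write_study

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "metric_table_from_study",
    "mpli_table_from_study",
    "condition_matrices",
    "subject_condition_trees",
]

AGGREGATION_MODES = ("matrix-average", "trial-metric-average")


@dataclass
class PipelineConfig:
    """Everything one run needs; validated before any computation starts."""

    out_dir: str
    simulation: GroupSimConfig | None = None
    input_dir: str | None = None
    input_format: str = "native"
    bands: tuple[str, ...] = ("gamma",)
    aggregation: str = "matrix-average"
    distance_convention: str = "weighted"
    fdr_family: str = "per-metric"
    edge_trim: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("specify exactly one of simulation or input_dir")
        if self.aggregation not in AGGREGATION_MODES:
            raise ValueError(f"aggregation must be one of {AGGREGATION_MODES}")
        if self.distance_convention not in ("weighted", "hop"):
            raise ValueError("distance_convention must be 'weighted' or 'hop'")
        if self.fdr_family not in ("per-metric", "per-band"):
            raise ValueError("fdr_family must be 'per-metric' or 'per-band'")
        fs = self.simulation.fs if self.simulation is not None else 128.0
        for b in self.bands:
            band = get_band(b)
            if band.hi >= fs / 2:
                raise ValueError(
                    f"band {band.name} upper edge {band.hi} Hz at/above the "
                    f"Nyquist frequency ({fs / 2} Hz)"
                )

    def to_yaml(self) -> str:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = asdict(self.simulation)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        if d.get("simulation") is not None:
            d["simulation"] = GroupSimConfig(**d["simulation"])
        if d.get("bands") is not None:
            d["bands"] = tuple(d["bands"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Stage helpers (usable directly, without the full pipeline)
# ---------------------------------------------------------------------------

def condition_matrices(
    study: Study, bands: Sequence[str], edge_trim: float = 0.5
) -> dict[tuple[str, str, str], ConnectivityMatrix]:
    """One averaged PLI matrix per (subject, condition, band).

    Per-trial matrices are averaged element-wise within each condition.
    """
    out: dict[tuple[str, str, str], ConnectivityMatrix] = {}
    for subj in study.subjects:
        per_band_trials: dict[tuple[str, str], list[ConnectivityMatrix]] = {}
        for trial, cond in zip(subj.trials, subj.conditions):
            if cond not in CONDITIONS:
                continue
            for band in bands:
                m = trial_connectivity(trial, band, edge_trim=edge_trim)
                per_band_trials.setdefault((cond, band), []).append(m)
        for (cond, band), mats in per_band_trials.items():
            avg = condition_matrix(mats)
            avg.condition = cond
            out[(subj.subject_id, cond, band)] = avg
    return out


def subject_condition_trees(
    matrices: dict[tuple[str, str, str], ConnectivityMatrix],
):
    """Maximum-PLI spanning tree per (subject, condition, band) matrix."""
    return {key: max_spanning_tree(m) for key, m in matrices.items()}


def mpli_table_from_study(
    study: Study, bands: Sequence[str], edge_trim: float = 0.5
) -> pd.DataFrame:
    """Long-format table of the MPLI only (no trees built).

    Much cheaper than :func:`metric_table_from_study`; used when only the
    mean connectivity strength is analyzed, e.g. in large replicate runs.
    """
    rows = []
    for (sid, cond, band), m in condition_matrices(study, bands, edge_trim).items():
        rows.append(
            {
                "subject_id": sid,
                "condition": cond,
                "band": band,
                "metric": "mpli",
                "value": mean_pli(m),
            }
        )
    return pd.DataFrame(rows, columns=["subject_id", "condition", "band", "metric", "value"])


def metric_table_from_study(
    study: Study,
    bands: Sequence[str],
    aggregation: str = "matrix-average",
    distance_convention: str = "weighted",
    edge_trim: float = 0.5,
) -> tuple[pd.DataFrame, dict, dict]:
    """Long-format metric table plus the per-cell trees and averaged matrices.

    ``aggregation='matrix-average'`` (default): average the per-trial PLI
    matrices within each subject x condition, then build one tree and one set
    of metrics per cell. ``'trial-metric-average'``: build a tree and metrics
    per trial and average the metric values within the cell; the reported
    tree for the cell is the one from the averaged matrix (used only for the
    cross-subject aggregation stage).
    """
    if aggregation not in AGGREGATION_MODES:
        raise ValueError(f"aggregation must be one of {AGGREGATION_MODES}")
    rows: list[dict] = []
    trees: dict[tuple[str, str, str], object] = {}
    matrices: dict[tuple[str, str, str], ConnectivityMatrix] = {}
    for subj in study.subjects:
        per_cell: dict[tuple[str, str], list[ConnectivityMatrix]] = {}
        for trial, cond in zip(subj.trials, subj.conditions):
            if cond not in CONDITIONS:
                continue
            for band in bands:
                m = trial_connectivity(trial, band, edge_trim=edge_trim)
                per_cell.setdefault((cond, band), []).append(m)
        for (cond, band), mats in per_cell.items():
            avg = condition_matrix(mats)
            avg.condition = cond
            matrices[(subj.subject_id, cond, band)] = avg
            cell_tree = max_spanning_tree(avg)
            trees[(subj.subject_id, cond, band)] = cell_tree
            if aggregation == "matrix-average":
                tm = tree_metrics(
                    cell_tree, mpli=mean_pli(avg), distance_convention=distance_convention
                )
                values = tm.as_dict()
            else:
                per_trial = [
                    tree_metrics(
                        max_spanning_tree(m),
                        mpli=mean_pli(m),
                        distance_convention=distance_convention,
                    ).as_dict()
                    for m in mats
                ]
                values = {
                    name: float(np.mean([d[name] for d in per_trial]))
                    for name in METRIC_NAMES
                }
            for name in METRIC_NAMES:
                v = values[name]
                rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "condition": cond,
                        "band": band,
                        "metric": name,
                        "value": np.nan if v is None else float(v),
                    }
                )
    table = pd.DataFrame(
        rows, columns=["subject_id", "condition", "band", "metric", "value"]
    )
    return table, trees, matrices


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute every stage and return the artifact manifest (also written).

    Output layout under ``config.out_dir``::

        config.yaml                          the run configuration, verbatim
        study/                               native container (simulated runs)
        matrices/<subj>_<cond>_<band>.csv    averaged PLI matrices
        trees/<subj>_<cond>_<band>.csv       per-subject spanning trees
        metrics.csv                          long-format metric table
        average_mst/<cond>_<band>.csv        cross-subject average trees
        hubs/<cond>_<band>.csv               hub tables
        stats_anova.csv / stats_contrasts.csv / stats_summary.csv
        exclusions.csv                       excluded subjects and reasons
        manifest.csv                         file list with sha256 hashes
        run.log                              stage timings, versions, seed
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"mstnet {_pkg_version}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed {config.seed}",
    ]
    (out / "config.yaml").write_text(config.to_yaml())
    config_hash = hashlib.sha256(config.to_yaml().encode()).hexdigest()
    log_lines.append(f"config sha256 {config_hash}")

    t0 = time.time()
    if config.simulation is not None:
        sim = (
            config.simulation
            if config.simulation.seed == config.seed
            else GroupSimConfig(**{**asdict(config.simulation), "seed": config.seed})
        )
        synth = generate_group(sim)
        study = synth.study
        study_dir = out / "study"
        write_study(study, study_dir)
        write_truth_csv(synth, study_dir / "ground_truth.csv")
        log_lines.append(f"simulated {len(study.subjects)} subjects")
    else:
        study = read_study(config.input_dir, format_tag=config.input_format)
        log_lines.append(
            f"loaded {len(study.subjects)} subjects from {config.input_dir}"
        )

    study, exclusion_log = exclude_subjects(study)
    exclusion_log.to_csv(out / "exclusions.csv", index=False)
    log_lines.append(
        f"retained {len(study.subjects)} subjects, excluded {len(exclusion_log)}"
    )
    log_lines.append(f"input stage: {time.time() - t0:.1f} s")

    t0 = time.time()
    table, trees, matrices = metric_table_from_study(
        study,
        bands=config.bands,
        aggregation=config.aggregation,
        distance_convention=config.distance_convention,
        edge_trim=config.edge_trim,
    )
    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for (sid, cond, band), m in sorted(matrices.items()):
        write_matrix_csv(m, mat_dir / f"{sid}_{cond}_{band}.csv")
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    for (sid, cond, band), t in sorted(trees.items()):
        write_tree_csv(t, tree_dir / f"{sid}_{cond}_{band}.csv")
    table.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
    log_lines.append(f"connectivity+trees stage: {time.time() - t0:.1f} s")

    t0 = time.time()
    avg_dir = out / "average_mst"
    hub_dir = out / "hubs"
    avg_dir.mkdir(exist_ok=True)
    hub_dir.mkdir(exist_ok=True)
    node_order = None
    for band in config.bands:
        for cond in CONDITIONS:
            cell_trees = [
                t for (sid, c, b), t in sorted(trees.items())
                if c == cond and b == band
            ]
            if not cell_trees:
                continue
            if node_order is None:
                node_order = list(cell_trees[0].nodes)
            ov = overlap_graph(cell_trees)
            write_overlap_csv(ov, avg_dir / f"overlap_{cond}_{band}.csv")
            avg = average_mst(ov, node_order=node_order)
            write_tree_csv(avg, avg_dir / f"{cond}_{band}.csv", weight_column="count")
            hub_table(avg).to_csv(hub_dir / f"{cond}_{band}.csv", index=False)
    log_lines.append(f"aggregation stage: {time.time() - t0:.1f} s")

    t0 = time.time()
    results = analyze_metric_table(table, fdr_family=config.fdr_family)
    results["anova"].to_csv(out / "stats_anova.csv", index=False, float_format="%.10g")
    results["contrasts"].to_csv(
        out / "stats_contrasts.csv", index=False, float_format="%.10g"
    )
    results["summary"].to_csv(
        out / "stats_summary.csv", index=False, float_format="%.10g"
    )
    log_lines.append(f"stats stage: {time.time() - t0:.1f} s")

    files = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name not in ("manifest.csv", "run.log")
    )
    manifest = pd.DataFrame(
        {
            "path": [str(p.relative_to(out)) for p in files],
            "sha256": [_sha256(p) for p in files],
        }
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
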