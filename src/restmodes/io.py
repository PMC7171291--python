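"""TSV/JSON file formats shared by the pipeline stages and the CLI.

Time series travel as header-less numeric TSV matrices (volumes x ROIs)
with a JSON sidecar carrying acquisition metadata; partitions, window
labelings and summary tables are TSVs with headers; models and reports
are JSON. All writers are deterministic given identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .communities import Partition
from .exceptions import InvalidParameterError
from .states import SequenceCounts, StateLabeling, WindowState
from .synthetic import SyntheticCohort
from .timeseries import RoiTimeSeries

SIDECAR_FIELDS = ("tr", "run_id", "encoding_tag", "subject_id")


def read_timeseries(path) -> RoiTimeSeries:
    """Read a volumes x ROIs TSV plus its ``.json`` sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise InvalidParameterError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("tr", "run_id"):
        if key not in meta:
            raise InvalidParameterError(f"sidecar {sidecar} lacks required key {key!r}")
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if width is None:
                width = len(fields)
            elif len(fields) != width:
                raise InvalidParameterError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(fields)} fields, expected {width})"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise InvalidParameterError(
                    f"{path}: non-numeric cell at line {lineno}: {exc}"
                ) from None
    if not rows:
        raise InvalidParameterError(f"{path} is empty")
    return RoiTimeSeries(
        data=np.asarray(rows), tr=float(meta["tr"]), run_id=str(meta["run_id"]),
        encoding_tag=str(meta.get("encoding_tag", "")),
        subject_id=str(meta.get("subject_id", "")),
    )


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, ts.data, delimiter="\t", fmt="%.17g")
    meta = {k: getattr(ts, k) for k in SIDECAR_FIELDS}
    path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True, indent=2))


def read_partition(path) -> Partition:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("roi_index")
    return Partition(labels=df["community"].to_numpy())


def write_partition(partition: Partition, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"roi_index": np.arange(partition.n_nodes), "community": partition.labels}
    ).to_csv(path, sep="\t", index=False)


def write_labeling(labeling: StateLabeling, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in labeling.states:
        row = {"run": s.run_id, "window": s.window_index, "mode": s.label}
        row.update({f"ami_{m}": v for m, v in zip(labeling.modes, s.profile)})
        row["tie"] = int(s.tie)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labeling(path) -> StateLabeling:
    df = pd.read_csv(path, sep="\t")
    modes = tuple(c[len("ami_"):] for c in df.columns if c.startswith("ami_"))
    states = tuple(
        WindowState(
            run_id=str(r["run"]), window_index=int(r["window"]), label=str(r["mode"]),
            profile=tuple(float(r[f"ami_{m}"]) for m in modes), tie=bool(r["tie"]),
        )
        for _, r in df.iterrows()
    )
    return StateLabeling(modes=modes, states=states)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Partition):
        return obj.labels.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return {c: obj[c].to_dict() for c in obj.columns}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), sort_keys=True, indent=2) + "\n")


def sequence_counts_table(per_subject: dict) -> pd.DataFrame:
    """Mean +/- SD of the 12 ordered-pair switch counts across subjects."""
    subjects = list(per_subject.keys())
    pairs = sorted({pair for sc in per_subject.values() for pair in sc.counts})
    data = np.array(
        [[per_subject[s].counts[pair] for pair in pairs] for s in subjects], dtype=float
    )
    return pd.DataFrame(
        {
            "from_mode": [a for a, _ in pairs],
            "to_mode": [b for _, b in pairs],
            "mean": data.mean(axis=0),
            "sd": data.std(axis=0, ddof=1) if len(subjects) > 1 else 0.0,
        }
    )


def state_counts_table(per_subject: dict, modes) -> pd.DataFrame:
    """Mean +/- SD of per-mode window counts across subjects."""
    subjects = list(per_subject.keys())
    data = np.array([[per_subject[s][m] for m in modes] for s in subjects], dtype=float)
    return pd.DataFrame(
        {
            "mode": list(modes),
            "mean": data.mean(axis=0),
            "sd": data.std(axis=0, ddof=1) if len(subjects) > 1 else 0.0,
        }
    )


def write_results(results: dict, outdir) -> list:
    """Write a stage-results mapping to ``outdir``; returns the paths written.

    DataFrames become TSVs, Partitions partition TSVs, StateLabelings
    labeling TSVs, everything else JSON. Keys name the files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, value in results.items():
        if isinstance(value, pd.DataFrame):
            path = outdir / f"{key}.tsv"
            value.to_csv(path, sep="\t", index=True)
        elif isinstance(value, Partition):
            path = outdir / f"{key}.tsv"
            write_partition(value, path)
        elif isinstance(value, StateLabeling):
            path = outdir / f"{key}.tsv"
            write_labeling(value, path)
        else:
            path = outdir / f"{key}.json"
            write_json(value, path)
        written.append(path)
    return written


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write a cohort's runs, behavior and ground truth; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": list(cohort.subjects), "seed": cohort.seed, "runs": {}}
    for sid in cohort.subjects:
        entries = []
        for mode, ts in cohort.task_runs.get(sid, {}).items():
            rel = f"{sid}/task-{mode}.tsv"
            write_timeseries(ts, outdir / rel)
            entries.append(rel)
        for ts in cohort.rest_runs.get(sid, []):
            rel = f"{sid}/{ts.run_id}.tsv"
            write_timeseries(ts, outdir / rel)
            entries.append(rel)
        manifest["runs"][sid] = entries
    cohort.behavior.to_csv(outdir / "behavior.tsv", sep="\t", index=True)
    gt = cohort.ground_truth
    write_json(
        {
            "templates": {m: gt.templates.partitions[m] for m in gt.templates.modes},
            "window_labels": gt.window_labels,
            "true_transition_counts": {
                s: {f"{a}->{b}": c for (a, b), c in d.items()}
                for s, d in gt.true_transition_counts.items()
            },
            "beta": gt.beta,
            "behavior_loadings": gt.behavior_loadings,
            "planted_feature": gt.planted_feature,
        },
        outdir / "ground_truth.json",
    )
    gt.features.to_csv(outdir / "features_ground_truth.tsv", sep="\t", index=True)
    manifest["behavior"] = "behavior.tsv"
    manifest["ground_truth"] = "ground_truth.json"
    manifest_path = outdir / "manifest.json"
    write_json(manifest, manifest_path)
    return manifest_path
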