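"""End-to-end orchestration: simulate -> prep -> communities -> states -> CCA.

The pipeline mirrors the full analysis chain on a synthetic cohort:
task-mode templates are estimated from the task runs (per-subject Louvain
ensembles, then group consensus per resolution), rest runs are windowed
and every window's consensus partition is classified against the
templates, state and switch counts and stable-core similarity indices are
derived (averaged over resolutions), their reliability is quantified with
ICC(2,1) across resolutions, and a cross-validated CCA links the neural
indices to behavior. Because the cohort is synthetic, every stage is also
scored against the planted ground truth.

Every random draw flows from the single configured seed through spawned
`numpy.random.SeedSequence` streams; two runs with the same configuration
produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io as rio
from .behavior import cca_crossval, fold_summary
from .communities import (
    ConsensusParams,
    ModularityParams,
    ensemble_consensus,
    group_consensus,
)
from .exceptions import DegenerateDataError, InvalidParameterError, RankDeficientError
from .reliability import icc_2_1
from .states import (
    adjusted_mutual_information,
    average_over_gammas,
    classify_windows,
    core_similarity,
    count_states,
    count_transitions,
)
from .synthetic import CohortConfig, SyntheticCohort, simulate_cohort
from .timeseries import plan_windows, static_connectivity, window_connectivity


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic pipeline run.

    ``task_n_init``/``task_reps`` control the Louvain ensembles behind the
    task templates; ``window_n_init``/``window_reps`` the (much more
    numerous) per-window ensembles. Defaults are desk-scale; the study-scale
    settings (100 restarts, 100 consensus reps) are available by raising
    them.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    gammas: tuple = (0.95, 1.00, 1.05)
    task_n_init: int = 24
    task_reps: int = 24
    window_n_init: int = 10
    window_reps: int = 10
    tau: float = 0.0
    cv_folds: int = 5
    n_perm: int = 9999
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self):
        for name in ("task_n_init", "task_reps", "window_n_init",
                     "window_reps", "cv_folds", "n_perm", "n_boot"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be positive")
        if self.cohort.n_subjects < 2:
            raise InvalidParameterError("cohort must contain at least 2 subjects")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _mean_sd(values) -> dict:
    arr = np.asarray(list(values), dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sd": sd}


def estimate_task_templates(cohort: SyntheticCohort, config: RunConfig,
                            seed_seq: np.random.SeedSequence):
    """Per-subject task partitions and per-γ group templates."""
    modes = cohort.ground_truth.templates.modes
    cons = ConsensusParams(tau=config.tau, reps=config.task_reps)
    subj_parts: dict = {}
    subject_seqs = seed_seq.spawn(len(cohort.subjects) + 1)
    for sid, sseq in zip(cohort.subjects, subject_seqs):
        subj_parts[sid] = {}
        for m, mseq in zip(modes, sseq.spawn(len(modes))):
            W = static_connectivity([cohort.task_runs[sid][m]])
            params = ModularityParams(
                gammas=config.gammas, n_init=config.task_n_init, seed=_seed_int(mseq)
            )
            subj_parts[sid][m] = ensemble_consensus(W, params, cons, level="subject")
    group_seq = subject_seqs[-1]
    templates: dict = {g: {} for g in config.gammas}
    for m, mseq in zip(modes, group_seq.spawn(len(modes))):
        for g, gseq in zip(config.gammas, mseq.spawn(len(config.gammas))):
            templates[g][m] = group_consensus(
                [subj_parts[sid][m][g] for sid in cohort.subjects],
                cons, seed=_seed_int(gseq), gamma_tag=g,
            )
    return subj_parts, templates


def analyze_rest(cohort: SyntheticCohort, templates: dict, config: RunConfig,
                 seed_seq: np.random.SeedSequence):
    """Window partitions, state labelings, counts and core similarity per subject."""
    modes = cohort.ground_truth.templates.modes
    cons = ConsensusParams(tau=config.tau, reps=config.window_reps)
    cfg = cohort.config
    out: dict = {}
    for sid, sseq in zip(cohort.subjects, seed_seq.spawn(len(cohort.subjects))):
        runs = cohort.rest_runs[sid]
        plan = plan_windows(
            {ts.run_id: ts.n_volumes for ts in runs}, cfg.window_len, cfg.hop
        )
        mats, run_ids = [], []
        for ts in runs:
            for mat in window_connectivity(ts, plan):
                mats.append(mat)
                run_ids.append(ts.run_id)
        children = sseq.spawn(len(mats) + 1)
        win_parts = {g: [] for g in config.gammas}
        for mat, wseq in zip(mats, children):
            params = ModularityParams(
                gammas=config.gammas, n_init=config.window_n_init, seed=_seed_int(wseq)
            )
            per_gamma = ensemble_consensus(mat, params, cons, level="window")
            for g in config.gammas:
                win_parts[g].append(per_gamma[g])
        core_seq = children[-1]
        per_gamma_results = {}
        for g, gseq in zip(config.gammas, core_seq.spawn(len(config.gammas))):
            labeling = classify_windows(win_parts[g], templates[g], run_ids=run_ids)
            core = group_consensus(
                win_parts[g], cons, seed=_seed_int(gseq), gamma_tag=g
            ) if len(win_parts[g]) > 1 else win_parts[g][0]
            per_gamma_results[g] = {
                "labeling": labeling,
                "states": count_states(labeling),
                "transitions": count_transitions(labeling),
                "core": core,
                "similarity": core_similarity(core, templates[g]),
            }
        out[sid] = {
            "plan": plan,
            "run_ids": run_ids,
            "per_gamma": per_gamma_results,
        }
    return out


def _gamma_averaged_features(rest_results: dict, modes, gammas) -> pd.DataFrame:
    rows = {}
    for sid, res in rest_results.items():
        row = {}
        for m in modes:
            row[f"sim_{m}"] = average_over_gammas(
                {g: res["per_gamma"][g]["similarity"].values[m] for g in gammas}
            )
        row["n_ps"] = average_over_gammas(
            {g: res["per_gamma"][g]["transitions"].counts[("perceptual", "semantic")]
             for g in gammas}
        )
        row["n_sp"] = average_over_gammas(
            {g: res["per_gamma"][g]["transitions"].counts[("semantic", "perceptual")]
             for g in gammas}
        )
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def _reliability_block(rest_results: dict, modes, gammas) -> dict:
    """ICC(2,1) of each index across the resolution-parameter settings."""
    subjects = list(rest_results.keys())
    tables = {}
    for m in modes:
        tables[f"sim_{m}"] = [
            [rest_results[s]["per_gamma"][g]["similarity"].values[m] for g in gammas]
            for s in subjects
        ]
    for key, pair in (("n_ps", ("perceptual", "semantic")),
                      ("n_sp", ("semantic", "perceptual"))):
        tables[key] = [
            [rest_results[s]["per_gamma"][g]["transitions"].counts[pair] for g in gammas]
            for s in subjects
        ]
    iccs = {}
    for key, table in tables.items():
        try:
            res = icc_2_1(np.asarray(table, dtype=float))
            iccs[key] = {"icc": res.icc, "fair_to_good": res.fair_to_good}
        except DegenerateDataError:
            iccs[key] = None
    return iccs


def _recovery_block(cohort: SyntheticCohort, templates: dict,
                    rest_results: dict, features: pd.DataFrame) -> dict:
    gt = cohort.ground_truth
    modes = gt.templates.modes
    gammas = list(templates.keys())
    template_ami = {
        m: float(np.mean([
            adjusted_mutual_information(templates[g][m], gt.templates.partitions[m])
            for g in gammas
        ]))
        for m in modes
    }
    acc_num = acc_den = 0
    for sid, res in rest_results.items():
        true_flat = [
            lab for rid in gt.window_labels[sid] for lab in gt.window_labels[sid][rid]
        ]
        for g in gammas:
            est = res["per_gamma"][g]["labeling"].labels
            acc_num += sum(e == t for e, t in zip(est, true_flat))
            acc_den += len(true_flat)
    true_ps = np.array(
        [gt.true_transition_counts[s][("perceptual", "semantic")] for s in cohort.subjects],
        dtype=float,
    )
    est_ps = features.loc[list(cohort.subjects), "n_ps"].to_numpy()
    if np.ptp(true_ps) > 0 and np.ptp(est_ps) > 0:
        rho = float(stats.spearmanr(true_ps, est_ps).statistic)
    else:
        rho = float("nan")
    sim_dwell = {}
    for m in modes:
        frac = gt.dwell_window_fractions.loc[list(cohort.subjects), m].to_numpy()
        sim = features.loc[list(cohort.subjects), f"sim_{m}"].to_numpy()
        if np.ptp(frac) > 0 and np.ptp(sim) > 0:
            sim_dwell[m] = float(np.corrcoef(frac, sim)[0, 1])
        else:
            sim_dwell[m] = float("nan")
    return {
        "template_ami": template_ami,
        "window_label_accuracy": acc_num / acc_den if acc_den else float("nan"),
        "transition_count_spearman": rho,
        "sim_dwell_correlation": sim_dwell,
    }


def run_pipeline(config: RunConfig | None = None, outdir=None) -> dict:
    """Execute the full synthetic pipeline; optionally write results to disk.

    Returns a JSON-serializable report with the tabulated summary
    statistics (state counts, switch counts, similarity indices, ICCs,
    cross-validated CCA r and permutation p) plus recovery scores against
    the planted ground truth.
    """
    config = config or RunConfig()
    ss = np.random.SeedSequence(config.seed)
    s_cohort, s_task, s_rest, s_cca = ss.spawn(4)
    cohort = simulate_cohort(
        dataclasses.replace(config.cohort, seed=_seed_int(s_cohort))
    )
    modes = cohort.ground_truth.templates.modes

    subj_parts, templates = estimate_task_templates(cohort, config, s_task)
    rest_results = analyze_rest(cohort, templates, config, s_rest)
    features = _gamma_averaged_features(rest_results, modes, config.gammas)

    gamma_ref = config.gammas[len(config.gammas) // 2]
    state_counts = {
        sid: rest_results[sid]["per_gamma"][gamma_ref]["states"]
        for sid in cohort.subjects
    }
    seq_counts = {
        sid: rest_results[sid]["per_gamma"][gamma_ref]["transitions"]
        for sid in cohort.subjects
    }
    max_possible = seq_counts[cohort.subjects[0]].max_possible_switches

    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": len(cohort.subjects),
        "n_windows_per_subject": rest_results[cohort.subjects[0]]["plan"].n_windows,
        "max_possible_switches": int(max_possible),
        "state_counts": {
            m: _mean_sd(state_counts[s][m] for s in cohort.subjects) for m in modes
        },
        "switch_counts": {
            f"{a}->{b}": _mean_sd(
                seq_counts[s].counts[(a, b)] for s in cohort.subjects
            )
            for a in modes for b in modes if a != b
        },
        "similarity": {
            m: _mean_sd(features[f"sim_{m}"]) for m in modes
        },
        "reliability": _reliability_block(rest_results, modes, config.gammas),
        "recovery": _recovery_block(cohort, templates, rest_results, features),
    }

    # brain-behavior CCA on the estimated indices; estimated similarity
    # columns can degenerate at small n, so prune until full rank
    X = features.loc[list(cohort.subjects)]
    keep = [c for c in X.columns if X[c].std(ddof=1) > 0]
    Y = cohort.behavior.loc[list(cohort.subjects)]
    n = len(X)
    cv = None
    while keep and n > len(keep) + Y.shape[1] + config.cv_folds:
        try:
            cv = cca_crossval(
                X[keep], Y, k_folds=config.cv_folds, seed=_seed_int(s_cca),
                n_perm=config.n_perm,
            )
            break
        except (RankDeficientError, DegenerateDataError) as exc:
            if not exc.columns:
                break
            keep = [c for c in keep if c not in exc.columns]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropped degenerate feature columns: {dropped}", stacklevel=2)
    if cv is not None:
        report["cca"] = {
            "pooled_r": cv.r,
            "permutation_p": cv.p,
            "median_brain_weights": fold_summary(cv, "x_weights")["median"].to_dict(),
            "median_behavior_weights": fold_summary(cv, "y_weights")["median"].to_dict(),
            "median_brain_loadings": fold_summary(cv, "x_loadings")["median"].to_dict(),
            "median_behavior_loadings": fold_summary(cv, "y_loadings")["median"].to_dict(),
        }
    else:
        report["cca"] = None

    if outdir is not None:
        results = {
            "report": report,
            "features": features,
            "state_counts_table": rio.state_counts_table(state_counts, modes),
            "switch_counts_table": rio.sequence_counts_table(seq_counts),
        }
        for g in config.gammas:
            for m in modes:
                results[f"template_{m}_gamma{g}"] = templates[g][m]
        for sid in cohort.subjects:
            results[f"labeling_{sid}"] = rest_results[sid]["per_gamma"][gamma_ref]["labeling"]
        rio.write_results(results, outdir)
    return report
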