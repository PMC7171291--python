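"""Classify rest windows against task-mode templates and count sequences.

Every rest window's consensus partition is compared to the four task
templates with chance-corrected AMI; the best match labels the window.
Ordered label changes between consecutive windows of the same run are
the task-state sequences (e.g. perceptual -> semantic).
"""

import restmodes as rm

cfg = rm.CohortConfig(n_subjects=2, overlap=0.0, rho=0.6, dwells_per_run=12, seed=9)
cohort = rm.simulate_cohort(cfg)
templates = cohort.ground_truth.templates.partitions

sid = cohort.subjects[0]
(ts,) = cohort.rest_runs[sid]
plan = rm.plan_windows({ts.run_id: ts.n_volumes}, cfg.window_len, cfg.hop)
parts = [
    rm.ensemble_consensus(
        mat, rm.ModularityParams(gammas=(1.0,), n_init=10, seed=i),
        rm.ConsensusParams(reps=10),
    )[1.0]
    for i, mat in enumerate(rm.window_connectivity(ts, plan))
]
labeling = rm.classify_windows(parts, templates, run_ids=[ts.run_id] * len(parts))
truth = cohort.ground_truth.window_labels[sid][ts.run_id]

print(f"{sid}: {plan.n_windows} rest windows")
print("estimated:", labeling.labels)
print("truth:    ", truth)
acc = sum(e == t for e, t in zip(labeling.labels, truth)) / len(truth)
print(f"window-label accuracy: {acc:.2f}")

counts = rm.count_states(labeling)
seq = rm.count_transitions(labeling)
print("\nwindows per mode:", counts)
print("perceptual->semantic sequences:", seq.counts[("perceptual", "semantic")],
      f"(of at most {seq.max_possible_switches} switches)")
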