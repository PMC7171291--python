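"""Synthetic cohorts with planted task modes, rest dynamics and behavior.

The generator emulates the structure of a multi-subject task/rest fMRI
study at the ROI level: four task conditions each induce a distinct
community structure ("mode template") over the ROIs; rest runs alternate
among those structures with subject-specific dwell propensities; and a
behavioral variable carries a planted canonical correlation with a
neural summary feature (fewer perceptual-to-semantic sequences plus a
rest-core-similarity composite). Every planted quantity is recorded in a
:class:`GroundTruth` object so downstream stages can be scored.

Signal model per dwell: ``x(t, i) = sqrt(rho) g(t, c_i) + sqrt(1-rho)
eps(t, i)`` with ``g`` (one factor per community) and ``eps`` independent
standard Gaussians, giving expected within-community correlation ``rho``
and zero between communities. An optional AR(1) coefficient adds temporal
autocorrelation while preserving unit marginal variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .communities import Partition
from .exceptions import InvalidParameterError
from .states import DEFAULT_MODES
from .timeseries import RoiTimeSeries

PS_PAIR = ("perceptual", "semantic")


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# mode templates


@dataclass(frozen=True)
class ModeTemplates:
    """One planted community partition per task mode."""

    modes: tuple
    partitions: dict  # mode -> Partition
    overlap: float

    @property
    def n_rois(self) -> int:
        return next(iter(self.partitions.values())).n_nodes


def _balanced_labels(n: int, k: int) -> np.ndarray:
    """Community sizes as balanced as divisibility allows, labels 1..k."""
    sizes = [n // k + (1 if j < n % k else 0) for j in range(k)]
    return np.repeat(np.arange(1, k + 1), sizes)


def make_mode_partitions(n_rois: int, k_per_mode=4, overlap: float = 0.5,
                         seed: int = 0, modes=DEFAULT_MODES) -> ModeTemplates:
    """Generate one balanced partition per task mode with controlled overlap.

    ``overlap`` is the fraction of ROIs whose assignment is shared across
    modes: 1 makes all templates identical, 0 draws them independently.
    The non-shared ROIs have their labels reshuffled independently per
    mode, so community sizes stay balanced in every template.
    """
    if isinstance(k_per_mode, int):
        k_per_mode = {m: k_per_mode for m in modes}
    if not (0 <= overlap <= 1):
        raise InvalidParameterError("overlap must lie in [0, 1]")
    for m, k in k_per_mode.items():
        if k < 2:
            raise InvalidParameterError(f"mode {m!r}: need at least 2 communities")
        if k > n_rois:
            raise InvalidParameterError(
                f"mode {m!r}: K={k} exceeds n_rois={n_rois}"
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_rois)  # shared ROI ordering aligns the templates
    n_shared = int(round(overlap * n_rois))
    free = order[n_shared:]
    partitions = {}
    for m in modes:
        base = np.empty(n_rois, dtype=int)
        base[order] = _balanced_labels(n_rois, k_per_mode[m])
        labels = base.copy()
        labels[free] = base[rng.permutation(free)]
        partitions[m] = Partition(labels=labels, level="group", gamma="planted")
    return ModeTemplates(modes=tuple(modes), partitions=partitions, overlap=overlap)


# ---------------------------------------------------------------------------
# time-series simulation


def _ar1(x: np.ndarray, ar: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1)-filter columns of white noise, keeping unit marginal variance."""
    if ar == 0.0:
        return x
    out = np.empty_like(x)
    out[0] = x[0]
    scale = np.sqrt(1.0 - ar**2)
    for t in range(1, x.shape[0]):
        out[t] = ar * out[t - 1] + scale * x[t]
    return out


def _block_signal(labels: np.ndarray, n_volumes: int, rho: float,
                  rng: np.random.Generator, ar: float) -> np.ndarray:
    k = int(labels.max())
    g = _ar1(rng.standard_normal((n_volumes, k)), ar, rng)
    eps = _ar1(rng.standard_normal((n_volumes, labels.size)), ar, rng)
    return np.sqrt(rho) * g[:, labels - 1] + np.sqrt(1.0 - rho) * eps


def simulate_task_timeseries(partition: Partition, n_volumes: int, rho: float,
                             tr: float, seed: int = 0, ar: float = 0.0,
                             subject_id: str = "", run_id: str = "task",
                             encoding_tag: str = "") -> RoiTimeSeries:
    """Latent-factor time series with planted community structure.

    Expected within-community Pearson correlation is ``rho``; expected
    between-community correlation is 0. Deterministic given ``seed``.
    """
    if not (0.0 <= rho <= 1.0):
        raise InvalidParameterError("rho must lie in [0, 1]")
    if n_volumes < 2:
        raise InvalidParameterError("n_volumes must be >= 2")
    rng = np.random.default_rng(seed)
    data = _block_signal(partition.labels, n_volumes, rho, rng, ar)
    return RoiTimeSeries(data=data, tr=tr, run_id=run_id,
                         subject_id=subject_id, encoding_tag=encoding_tag)


# ---------------------------------------------------------------------------
# rest runs with planted state schedules


@dataclass(frozen=True)
class StateSchedule:
    """Ordered (mode, dwell length in volumes) pairs for one rest run."""

    dwells: tuple  # of (mode_name, n_volumes)

    def __post_init__(self):
        if not self.dwells:
            raise InvalidParameterError("schedule needs at least one dwell")
        if any(length < 1 for _, length in self.dwells):
            raise InvalidParameterError("every dwell must last at least 1 volume")

    @property
    def run_length(self) -> int:
        return sum(length for _, length in self.dwells)

    def volume_modes(self) -> list:
        """Mode occupying each volume, plus the dwell index of each volume."""
        modes, dwell_idx = [], []
        for d, (mode, length) in enumerate(self.dwells):
            modes.extend([mode] * length)
            dwell_idx.extend([d] * length)
        return modes, dwell_idx


def true_window_labels(schedule: StateSchedule, window_len: int, hop: int) -> list:
    """Majority-rule ground-truth mode per window; ties go to the earlier dwell."""
    modes, dwell_idx = schedule.volume_modes()
    L = schedule.run_length
    labels = []
    for start in range(0, L - window_len + 1, hop):
        win_modes = modes[start:start + window_len]
        win_dwells = dwell_idx[start:start + window_len]
        tally: dict = {}
        first_dwell: dict = {}
        for m, d in zip(win_modes, win_dwells):
            tally[m] = tally.get(m, 0) + 1
            first_dwell.setdefault(m, d)
        top = max(tally.values())
        tied = [m for m, c in tally.items() if c == top]
        labels.append(min(tied, key=lambda m: first_dwell[m]))
    return labels


def simulate_rest_run(templates: ModeTemplates, schedule: StateSchedule,
                      rho: float, tr: float, window_len: int, hop: int,
                      seed: int = 0, ar: float = 0.0, n_volumes: int | None = None,
                      subject_id: str = "", run_id: str = "rest",
                      encoding_tag: str = ""):
    """Rest run alternating among mode templates, with true window labels.

    Within each dwell the signal follows :func:`simulate_task_timeseries`
    under that mode's partition. Returns ``(RoiTimeSeries, labels)`` where
    ``labels[w]`` is the mode occupying the majority of window ``w``'s
    volumes (ties resolved toward the earlier dwell).
    """
    if not (0.0 <= rho <= 1.0):
        raise InvalidParameterError("rho must lie in [0, 1]")
    for mode, _ in schedule.dwells:
        if mode not in templates.partitions:
            raise InvalidParameterError(f"schedule references unknown mode {mode!r}")
    if n_volumes is not None and schedule.run_length != n_volumes:
        raise InvalidParameterError(
            f"schedule dwell lengths sum to {schedule.run_length}, "
            f"but the run requests {n_volumes} volumes"
        )
    rng = np.random.default_rng(seed)
    pieces = [
        _block_signal(templates.partitions[mode].labels, length, rho, rng, ar)
        for mode, length in schedule.dwells
    ]
    ts = RoiTimeSeries(data=np.vstack(pieces), tr=tr, run_id=run_id,
                       subject_id=subject_id, encoding_tag=encoding_tag)
    return ts, true_window_labels(schedule, window_len, hop)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for a synthetic cohort.

    Defaults describe a desk-scale cohort: 60 ROIs, 4 balanced communities
    per mode with half the ROIs shared across modes, within-community
    coupling rho = 0.6, rest runs of 12 window-length dwells, and a planted
    brain-behavior canonical correlation beta = 0.5.
    """

    n_subjects: int = 20
    n_rois: int = 60
    k_per_mode: int = 4
    overlap: float = 0.5
    rho: float = 0.6
    beta: float = 0.5
    tr: float = 2.0
    task_volumes: int = 300
    n_rest_runs: int = 1
    dwells_per_run: int = 12
    dwell_volumes: int | None = None  # default: one window length
    window_len: int = 15
    hop: int = 15
    ar: float = 0.0
    sim_noise_sd: float = 0.5  # measurement noise on the similarity indices
    pref_alpha: float = 1.0  # Dirichlet concentration of subject mode preferences
    ps_boost_sd: float = 0.8  # subject spread of the perceptual->semantic propensity
    seed: int = 0

    @classmethod
    def hcp_like(cls, **kw) -> "CohortConfig":
        """Acquisition geometry of the 4-run, TR 0.72 s dataset (window 41, hop 3)."""
        base = dict(tr=0.72, window_len=41, hop=3, n_rest_runs=4,
                    dwells_per_run=8, dwell_volumes=150)
        base.update(kw)
        return cls(**base)

    @classmethod
    def sam_like(cls, **kw) -> "CohortConfig":
        """Single-run TR 2 s geometry: window 15 volumes (30 s), hop 1 TR."""
        base = dict(tr=2.0, window_len=15, hop=1, n_rest_runs=1,
                    dwells_per_run=12, dwell_volumes=15)
        base.update(kw)
        return cls(**base)


@dataclass(frozen=True)
class GroundTruth:
    """Everything that was planted, for scoring recovery downstream."""

    templates: ModeTemplates
    schedules: dict  # subject -> list[StateSchedule]
    window_labels: dict  # subject -> run_id -> list of true mode labels
    true_transition_counts: dict  # subject -> (from, to) -> int
    dwell_window_fractions: pd.DataFrame  # subjects x modes
    features: pd.DataFrame  # subjects x brain features (sim_* + n_ps + n_sp)
    planted_feature: pd.Series  # standardized neural composite driving behavior
    beta: float
    behavior_loadings: dict


@dataclass(frozen=True)
class SyntheticCohort:
    subjects: tuple
    task_runs: dict  # subject -> mode -> RoiTimeSeries
    rest_runs: dict  # subject -> list[RoiTimeSeries]
    behavior: pd.DataFrame
    ground_truth: GroundTruth
    config: CohortConfig
    seed: int

    @property
    def n_rois(self) -> int:
        return self.ground_truth.templates.n_rois


def _subject_schedule(modes, n_dwells: int, dwell_len: int, pref: np.ndarray,
                      ps_boost: float, rng: np.random.Generator) -> StateSchedule:
    """Markov dwell sequence with subject-specific mode preferences."""
    modes = list(modes)
    seq = [modes[rng.choice(len(modes), p=pref / pref.sum())]]
    for _ in range(n_dwells - 1):
        cur = seq[-1]
        w = np.array([0.0 if m == cur else pref[j] for j, m in enumerate(modes)])
        if cur == PS_PAIR[0]:
            w[modes.index(PS_PAIR[1])] *= ps_boost
        seq.append(modes[rng.choice(len(modes), p=w / w.sum())])
    return StateSchedule(dwells=tuple((m, dwell_len) for m in seq))


def simulate_cohort(config: CohortConfig | None = None,
                    generate_timeseries: bool = True) -> SyntheticCohort:
    """Generate a full multi-subject cohort with planted ground truth.

    Each subject gets one task run per mode, ``n_rest_runs`` rest runs
    whose dwell sequences follow subject-specific transition propensities,
    and behavioral scores in which the "visual_em" column carries the
    planted correlation ``beta`` with the standardized neural composite
    ``z(-z(n_ps) + z(sim_math))`` (fewer perceptual-to-semantic sequences,
    greater rest-math-architecture similarity). ``generate_timeseries=False``
    skips the signal matrices but still populates ground truth, features
    and behavior, which are fully determined by the schedules.
    """
    config = config or CohortConfig()
    if config.n_subjects < 2:
        raise InvalidParameterError("need at least 2 subjects")
    if not (0.0 <= config.beta <= 1.0):
        raise InvalidParameterError("beta must lie in [0, 1]")
    dwell_len = config.dwell_volumes or config.window_len
    if dwell_len < config.window_len:
        raise InvalidParameterError("dwell length must be at least one window length")
    ss = np.random.SeedSequence(config.seed)
    tmpl_ss, behav_ss, *subj_ss = ss.spawn(2 + config.n_subjects)
    templates = make_mode_partitions(
        config.n_rois, config.k_per_mode, config.overlap,
        seed=tmpl_ss.generate_state(1)[0] % (2**31 - 1),
    )
    modes = templates.modes
    subjects = tuple(f"sub-{i + 1:03d}" for i in range(config.n_subjects))

    task_runs: dict = {}
    rest_runs: dict = {}
    schedules: dict = {}
    window_labels: dict = {}
    trans_counts: dict = {}
    frac_rows = []
    for sid, sseq in zip(subjects, subj_ss):
        rng = np.random.default_rng(sseq)
        pref = rng.dirichlet(np.full(len(modes), config.pref_alpha))
        ps_boost = float(rng.lognormal(0.0, config.ps_boost_sd))
        schedules[sid] = []
        window_labels[sid] = {}
        counts = {(a, b): 0 for a in modes for b in modes if a != b}
        rest_runs[sid] = []
        for r in range(config.n_rest_runs):
            sched = _subject_schedule(
                modes, config.dwells_per_run, dwell_len, pref, ps_boost, rng
            )
            schedules[sid].append(sched)
            run_id = f"rest-{r + 1}"
            labels = true_window_labels(sched, config.window_len, config.hop)
            window_labels[sid][run_id] = labels
            for a, b in zip(labels[:-1], labels[1:]):
                if a != b:
                    counts[(a, b)] += 1
            if generate_timeseries:
                ts, _ = simulate_rest_run(
                    templates, sched, config.rho, config.tr,
                    config.window_len, config.hop,
                    seed=int(rng.integers(2**31 - 1)), ar=config.ar,
                    subject_id=sid, run_id=run_id,
                )
                rest_runs[sid].append(ts)
        trans_counts[sid] = counts
        all_labels = [lab for labs in window_labels[sid].values() for lab in labs]
        total = max(len(all_labels), 1)
        frac_rows.append([sum(lab == m for lab in all_labels) / total for m in modes])
        task_runs[sid] = {}
        if generate_timeseries:
            for m in modes:
                task_runs[sid][m] = simulate_task_timeseries(
                    templates.partitions[m], config.task_volumes, config.rho,
                    config.tr, seed=int(rng.integers(2**31 - 1)), ar=config.ar,
                    subject_id=sid, run_id=f"task-{m}",
                )

    fractions = pd.DataFrame(frac_rows, index=list(subjects), columns=list(modes))

    # ground-truth brain feature table: noisy similarity proxies + true counts
    brng = np.random.default_rng(behav_ss)
    features = pd.DataFrame(index=list(subjects))
    for m in modes:
        features[f"sim_{m}"] = (
            _zscore(fractions[m].to_numpy())
            + config.sim_noise_sd * brng.standard_normal(config.n_subjects)
        )
    features["n_ps"] = [trans_counts[s][PS_PAIR] for s in subjects]
    features["n_sp"] = [trans_counts[s][(PS_PAIR[1], PS_PAIR[0])] for s in subjects]

    planted = _zscore(
        -_zscore(features["n_ps"].to_numpy())
        + _zscore(features["sim_math"].to_numpy())
    )
    noise = brng.standard_normal(config.n_subjects)
    y1 = config.beta * planted + np.sqrt(1.0 - config.beta**2) * noise
    behavior = pd.DataFrame(
        {
            "age": brng.standard_normal(config.n_subjects),
            "verbal_em": brng.standard_normal(config.n_subjects),
            "visual_em": _zscore(y1) if config.beta < 1.0 else planted,
        },
        index=list(subjects),
    )

    ground_truth = GroundTruth(
        templates=templates, schedules=schedules, window_labels=window_labels,
        true_transition_counts=trans_counts, dwell_window_fractions=fractions,
        features=features, planted_feature=pd.Series(planted, index=list(subjects)),
        beta=config.beta,
        behavior_loadings={"visual_em": config.beta, "age": 0.0, "verbal_em": 0.0},
    )
    return SyntheticCohort(
        subjects=subjects, task_runs=task_runs, rest_runs=rest_runs,
        behavior=behavior, ground_truth=ground_truth, config=config,
        seed=config.seed,
    )


def ground_truth_features(cohort: SyntheticCohort):
    """The planted brain-feature and behavior tables, ready for CCA."""
    return cohort.ground_truth.features.copy(), cohort.behavior.copy()
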