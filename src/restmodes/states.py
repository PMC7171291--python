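"""Task-mode expression during rest: AMI classification and sequence counting.

Each rest window's community partition is compared against the group task
templates with the adjusted mutual information (AMI, corrected for chance
under the permutation model); the window is labeled with the best-matching
task mode. State counts, ordered mode-pair transition counts (within runs
only), stable-core similarity profiles and the leave-one-subject-out
template validation all build on that classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .communities import ConsensusParams, Partition, consensus_partition, group_consensus
from .exceptions import InvalidParameterError

#: canonical mode order used for deterministic tie-breaking
DEFAULT_MODES = ("perceptual", "semantic", "math", "motor")


# ---------------------------------------------------------------------------
# adjusted mutual information


def _contingency(u: np.ndarray, v: np.ndarray):
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    r, c = ui.max() + 1, vi.max() + 1
    table = np.zeros((r, c), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return table


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log(p)))


def expected_mutual_information(table: np.ndarray) -> float:
    """Exact E[I(U,V)] under the permutation (hypergeometric) null model.

    For fixed marginals ``a_i``, ``b_j`` the count ``n_ij`` is
    hypergeometric; the expectation sums the mutual-information kernel over
    its support, with log-factorials via ``gammaln`` for stability.
    """
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    n = int(table.sum())
    gln = gammaln
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term = (nij / n) * np.log(n * nij / (ai * bj))
            logp = (
                gln(ai + 1) + gln(bj + 1) + gln(n - ai + 1) + gln(n - bj + 1)
                - gln(n + 1) - gln(nij + 1) - gln(ai - nij + 1)
                - gln(bj - nij + 1) - gln(n - ai - bj + nij + 1)
            )
            emi += float(np.sum(term * np.exp(logp)))
    return emi


def adjusted_mutual_information(U, V) -> float:
    """Chance-corrected partition similarity, max-normalized.

    ``AMI = (I − E[I]) / (max(H(U), H(V)) − E[I])`` with ``E[I]`` exact under
    the permutation model. Equals 1 iff the partitions are identical up to
    relabeling; 0 in expectation for independent partitions. Two trivial
    (single-community) partitions give 1; exactly one trivial gives 0.
    """
    u = U.labels if isinstance(U, Partition) else np.asarray(U)
    v = V.labels if isinstance(V, Partition) else np.asarray(V)
    if u.size != v.size:
        raise InvalidParameterError("partitions must have equal length")
    table = _contingency(u, v)
    n = int(table.sum())
    a, b = table.sum(axis=1), table.sum(axis=0)
    hu, hv = _entropy(a, n), _entropy(b, n)
    if hu == 0.0 and hv == 0.0:
        return 1.0
    if hu == 0.0 or hv == 0.0:
        return 0.0
    nz = table[table > 0]
    mi = float(np.sum((nz / n) * np.log(nz * n / np.outer(a, b)[table > 0])))
    emi = expected_mutual_information(table)
    denom = max(hu, hv) - emi
    if abs(denom) < 1e-15:
        same = np.array_equal(
            Partition(labels=u).labels, Partition(labels=v).labels
        )
        return 1.0 if same else 0.0
    return (mi - emi) / denom


# ---------------------------------------------------------------------------
# window classification


@dataclass(frozen=True)
class WindowState:
    """Classification of one rest window."""

    run_id: str
    window_index: int
    label: str
    profile: tuple  # AMI against each mode template, in mode order
    tie: bool


@dataclass(frozen=True)
class StateLabeling:
    """Best-matching task mode per rest window, with run boundaries preserved."""

    modes: tuple
    states: tuple  # of WindowState, in presentation order

    @property
    def labels(self) -> list:
        return [s.label for s in self.states]

    @property
    def run_ids(self) -> list:
        seen = []
        for s in self.states:
            if s.run_id not in seen:
                seen.append(s.run_id)
        return seen

    def run_labels(self, run_id) -> list:
        return [s.label for s in self.states if s.run_id == run_id]


def classify_windows(window_partitions, templates, run_ids=None) -> StateLabeling:
    """Label each window with the task mode whose template it best matches.

    Parameters
    ----------
    window_partitions:
        Ordered per-window :class:`Partition` objects (one rest window each).
    templates:
        Mapping mode name -> template :class:`Partition`; insertion order is
        the canonical mode order used to break exact AMI ties (flagged).
    run_ids:
        Optional per-window run identifiers (defaults to a single run).
    """
    if not templates:
        raise InvalidParameterError("template map must not be empty")
    modes = tuple(templates.keys())
    parts = list(window_partitions)
    if run_ids is None:
        run_ids = ["run-1"] * len(parts)
    if len(run_ids) != len(parts):
        raise InvalidParameterError("run_ids must match window_partitions in length")
    states = []
    counters: dict = {}
    for rid, part in zip(run_ids, parts):
        profile = np.array(
            [adjusted_mutual_information(part, templates[m]) for m in modes]
        )
        best = int(np.argmax(profile))  # ties fall to the earlier-listed mode
        tie = bool(np.sum(profile == profile[best]) > 1)
        idx = counters.get(rid, 0)
        counters[rid] = idx + 1
        states.append(
            WindowState(run_id=rid, window_index=idx, label=modes[best],
                        profile=tuple(float(x) for x in profile), tie=tie)
        )
    return StateLabeling(modes=modes, states=tuple(states))


# ---------------------------------------------------------------------------
# counting


def count_states(labeling: StateLabeling) -> dict:
    """Windows spent in each task mode; counts sum to the total window count."""
    counts = {m: 0 for m in labeling.modes}
    for s in labeling.states:
        counts[s.label] += 1
    return counts


@dataclass(frozen=True)
class SequenceCounts:
    """Ordered mode-pair switch counts over consecutive within-run windows."""

    counts: dict  # (from_mode, to_mode) -> int, all ordered pairs with from != to
    n_windows: dict  # mode -> window count
    max_possible_switches: int

    def total_switches(self) -> int:
        return sum(self.counts.values())


def count_transitions(labeling: StateLabeling) -> SequenceCounts:
    """Count ordered mode-pair switches; pairs never straddle a run boundary.

    Consecutive same-mode windows are not switches, so the total switch
    count is at most ``Σ_runs (windows_in_run − 1)``.
    """
    modes = labeling.modes
    counts = {(a, b): 0 for a in modes for b in modes if a != b}
    max_possible = 0
    for rid in labeling.run_ids:
        labels = labeling.run_labels(rid)
        max_possible += max(len(labels) - 1, 0)
        for prev, nxt in zip(labels[:-1], labels[1:]):
            if prev != nxt:
                counts[(prev, nxt)] += 1
    return SequenceCounts(
        counts=counts, n_windows=count_states(labeling),
        max_possible_switches=max_possible,
    )


# ---------------------------------------------------------------------------
# similarity profiles and averaging


@dataclass(frozen=True)
class SimilarityProfile:
    """AMI between a subject's stable rest core and each group task template."""

    values: dict  # mode -> AMI
    gamma: object = None


def core_similarity(rest_core: Partition, templates) -> SimilarityProfile:
    """Similarity of the stable rest core to every task-mode template."""
    values = {
        m: adjusted_mutual_information(rest_core, t) for m, t in templates.items()
    }
    return SimilarityProfile(values=values, gamma=rest_core.gamma)


def average_over_gammas(per_gamma: dict) -> float:
    """Arithmetic mean of homologous indices across resolution values."""
    if not per_gamma:
        raise InvalidParameterError("need at least one gamma entry")
    return float(np.mean(list(per_gamma.values())))


# ---------------------------------------------------------------------------
# leave-one-subject-out template validation


def loso_validate(subject_block_partitions: dict,
                  cons: ConsensusParams | None = None, seed: int = 0):
    """Leave-one-subject-out validation of the AMI-based mode classifier.

    ``subject_block_partitions`` maps subject -> mode -> list of block-level
    partitions. For each left-out subject, mode templates are rebuilt from
    the remaining subjects (block consensus per subject, then group
    consensus), and every left-out block is classified by maximum AMI.

    Returns ``(accuracy, ppv, confusion)`` where ``confusion[true][pred]``
    counts blocks and PPV is per-mode precision averaged over modes that
    received at least one prediction.
    """
    subjects = list(subject_block_partitions.keys())
    if len(subjects) < 2:
        raise InvalidParameterError("need at least 2 subjects")
    modes = list(subject_block_partitions[subjects[0]].keys())
    if len(modes) < 2:
        raise InvalidParameterError("need at least 2 task modes")
    cons = cons or ConsensusParams()
    rng = np.random.default_rng(seed)

    # per-subject per-mode consensus over blocks, computed once
    subj_mode = {}
    for s in subjects:
        subj_mode[s] = {}
        for m in modes:
            blocks = subject_block_partitions[s][m]
            if len(blocks) == 1:
                subj_mode[s][m] = blocks[0]
            else:
                subj_mode[s][m] = consensus_partition(
                    blocks, cons, seed=int(rng.integers(2**31 - 1))
                )

    confusion = {t: {p: 0 for p in modes} for t in modes}
    n_correct = n_total = 0
    for s in subjects:
        rest = [r for r in subjects if r != s]
        templates = {}
        for m in modes:
            templates[m] = group_consensus(
                [subj_mode[r][m] for r in rest], cons,
                seed=int(rng.integers(2**31 - 1)),
            )
        for m in modes:
            for block in subject_block_partitions[s][m]:
                profile = np.array(
                    [adjusted_mutual_information(block, templates[t]) for t in modes]
                )
                pred = modes[int(np.argmax(profile))]
                confusion[m][pred] += 1
                n_correct += pred == m
                n_total += 1

    accuracy = n_correct / n_total
    precisions = []
    for p in modes:
        n_pred = sum(confusion[t][p] for t in modes)
        if n_pred == 0:
            warnings.warn(
                f"mode {p!r} never predicted; excluded from the PPV average",
                stacklevel=2,
            )
            continue
        precisions.append(confusion[p][p] / n_pred)
    ppv = float(np.mean(precisions)) if precisions else float("nan")
    return float(accuracy), ppv, confusion
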