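"""Signed-network community detection and consensus partitions.

The modularity objective is the signed variant that puts a premium on
positive couplings: with ``w+``/``w-`` the positive and negative parts of
the connectivity matrix, ``s±_i = Σ_j w±_ij``, ``v± = Σ_ij w±_ij`` and
null terms ``e±_ij = s±_i s±_j / v±``,

    Q = (1/v+) Σ_ij (w+_ij − γ e+_ij) δ(c_i,c_j)
        − (1/(v+ + v−)) Σ_ij (w−_ij − γ e−_ij) δ(c_i,c_j)

(terms with ``v± = 0`` are dropped). γ is the spatial resolution
parameter: larger γ inflates the null term and fragments the partition.
Louvain is run many times per γ and the runs are combined with the
Lancichinetti–Fortunato agreement-matrix consensus scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConsensusError, InvalidParameterError
from .timeseries import ConnectivityMatrix

_GAIN_TOL = 1e-12


def _canonical_labels(labels) -> np.ndarray:
    """Relabel communities 1..K contiguously by first appearance."""
    labels = np.asarray(labels)
    mapping: dict = {}
    out = np.empty(labels.shape[0], dtype=np.int64)
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(lab, len(mapping) + 1)
    return out


@dataclass(frozen=True)
class Partition:
    """Assignment of ROIs to communities.

    ``labels`` are stored contiguously renumbered 1..K by first appearance,
    so two partitions are identical up to relabeling iff their stored labels
    are equal. ``level`` records what the partition describes (a window, a
    subject consensus, or a group template); ``gamma`` the resolution it was
    obtained at (or ``"averaged"``).
    """

    labels: np.ndarray
    level: str = "window"
    gamma: object = None

    def __post_init__(self):
        labels = _canonical_labels(self.labels)
        if labels.size < 1:
            raise InvalidParameterError("partition must cover at least one node")
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())

    def same_as(self, other: "Partition") -> bool:
        return self.labels.size == other.labels.size and bool(
            np.all(self.labels == other.labels)
        )


@dataclass(frozen=True)
class ModularityParams:
    """Louvain ensemble settings: resolutions, restarts, signed variant."""

    gammas: tuple = (0.95, 1.00, 1.05)
    n_init: int = 100
    variant: str = "negative_asym"
    seed: int = 0

    def __post_init__(self):
        if any(g <= 0 for g in self.gammas):
            raise InvalidParameterError("all gammas must be > 0")
        if self.n_init < 1:
            raise InvalidParameterError("n_init must be >= 1")
        if self.variant not in ("negative_asym", "negative_sym"):
            raise InvalidParameterError("variant must be 'negative_asym' or 'negative_sym'")


@dataclass(frozen=True)
class ConsensusParams:
    """Agreement-matrix consensus settings (threshold tau, re-clustering reps)."""

    tau: float = 0.0
    reps: int = 100
    max_iter: int = 50

    def __post_init__(self):
        if not (0 <= self.tau < 1):
            raise InvalidParameterError("tau must lie in [0, 1)")
        if self.reps < 1:
            raise InvalidParameterError("reps must be >= 1")


def _as_matrix(W) -> np.ndarray:
    if isinstance(W, ConnectivityMatrix):
        return W.values
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvalidParameterError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise InvalidParameterError("W must be symmetric")
    return W


def modularity_matrix(W, gamma: float = 1.0, variant: str = "negative_asym") -> np.ndarray:
    """Matrix ``B`` such that ``Q = Σ_ij B_ij δ(c_i, c_j)``."""
    W = _as_matrix(W)
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    sp, sn = Wp.sum(axis=1), Wn.sum(axis=1)
    vp, vn = sp.sum(), sn.sum()
    B = np.zeros_like(W)
    if vp > 0:
        B += (Wp - gamma * np.outer(sp, sp) / vp) / vp
    if vn > 0:
        scale = vn if variant == "negative_sym" else vp + vn
        B -= (Wn - gamma * np.outer(sn, sn) / vn) / scale
    return B


def signed_modularity(W, partition: Partition, gamma: float = 1.0,
                      variant: str = "negative_asym") -> float:
    """Signed modularity Q of ``partition`` on ``W`` at resolution ``gamma``."""
    B = modularity_matrix(W, gamma, variant)
    labels = partition.labels
    if labels.size != B.shape[0]:
        raise InvalidParameterError("partition length does not match W")
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def _local_move_phase(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Louvain level: greedy node moves on modularity matrix B."""
    n = B.shape[0]
    Bz = B.copy()
    np.fill_diagonal(Bz, 0.0)
    comm = np.arange(n)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            # coupling of node i to each community (excluding itself)
            conn = np.bincount(comm, weights=Bz[i], minlength=n)
            best = int(np.argmax(conn))  # first best community wins
            if conn[best] - conn[comm[i]] > _GAIN_TOL:
                comm[i] = best
                improved = True
    return _canonical_labels(comm) - 1


def _generalized_louvain(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Two-phase Louvain on an arbitrary symmetric modularity matrix."""
    n = B.shape[0]
    node_comm = np.arange(n)  # original node -> current top-level community
    level_B = B
    while True:
        labels = _local_move_phase(level_B, rng)
        k = int(labels.max()) + 1
        if k == level_B.shape[0]:
            break  # no merges at this level: done
        node_comm = labels[node_comm]
        # aggregate: block sums of B over the new communities
        one_hot = np.zeros((level_B.shape[0], k))
        one_hot[np.arange(level_B.shape[0]), labels] = 1.0
        level_B = one_hot.T @ level_B @ one_hot
        if k == 1:
            break
    return node_comm


def louvain_once(W, gamma: float = 1.0, seed: int = 0,
                 variant: str = "negative_asym", level: str = "window") -> Partition:
    """A single seeded Louvain optimization of the signed modularity.

    Node sweep order is randomized by ``seed``; the run is deterministic
    given the seed. Starting from singletons with strictly improving moves
    guarantees the returned Q is at least the all-singletons Q.
    """
    B = modularity_matrix(W, gamma, variant)
    rng = np.random.default_rng(seed)
    labels = _generalized_louvain(B, rng)
    return Partition(labels=labels, level=level, gamma=gamma)


def agreement_matrix(partitions) -> np.ndarray:
    """Entry (i, j): fraction of partitions placing i and j together; zero diagonal."""
    partitions = list(partitions)
    if not partitions:
        raise InvalidParameterError("need at least one partition")
    n = partitions[0].n_nodes
    A = np.zeros((n, n))
    for p in partitions:
        if p.n_nodes != n:
            raise InvalidParameterError("partitions must have equal length")
        A += p.labels[:, None] == p.labels[None, :]
    A /= len(partitions)
    np.fill_diagonal(A, 0.0)
    return A


def consensus_partition(partitions, params: ConsensusParams | None = None,
                        seed: int = 0, level: str = "subject",
                        gamma_tag=None) -> Partition:
    """Lancichinetti–Fortunato consensus over an ensemble of partitions.

    The agreement matrix is thresholded at ``tau`` (entries <= tau zeroed),
    re-clustered ``reps`` times with Louvain at γ = 1, and the procedure
    iterates on the agreement of those runs until all ``reps`` partitions
    coincide. Raises :class:`ConsensusError` carrying the last agreement
    matrix if the fixed point is not reached within ``max_iter`` rounds.
    """
    params = params or ConsensusParams()
    parts = [p if isinstance(p, Partition) else Partition(labels=p) for p in partitions]
    if not parts:
        raise InvalidParameterError("need at least one partition")
    if len(parts) == 1:
        return Partition(labels=parts[0].labels, level=level, gamma=gamma_tag)
    rng = np.random.default_rng(seed)
    A = None
    for _ in range(params.max_iter):
        A = agreement_matrix(parts)
        A = np.where(A > params.tau, A, 0.0)
        if A.max() == 0.0:
            warnings.warn(
                "agreement matrix is all-zero after thresholding; "
                "returning singleton communities",
                stacklevel=2,
            )
            return Partition(labels=np.arange(A.shape[0]), level=level, gamma=gamma_tag)
        seeds = rng.integers(0, 2**31 - 1, size=params.reps)
        parts = [louvain_once(A, gamma=1.0, seed=int(s)) for s in seeds]
        first = parts[0]
        if all(p.same_as(first) for p in parts[1:]):
            return Partition(labels=first.labels, level=level, gamma=gamma_tag)
    raise ConsensusError(
        f"consensus did not converge within {params.max_iter} iterations",
        agreement=A,
    )


def ensemble_consensus(W, params: ModularityParams | None = None,
                       cons: ConsensusParams | None = None,
                       level: str = "subject") -> dict:
    """Per-γ Louvain ensembles reduced to one consensus partition each.

    For every resolution in ``params.gammas``, ``params.n_init`` seeded
    Louvain runs are combined by :func:`consensus_partition`. Resolutions
    are processed independently and never pooled before consensus.
    """
    params = params or ModularityParams()
    cons = cons or ConsensusParams()
    ss = np.random.SeedSequence(params.seed)
    out = {}
    for gamma, child in zip(params.gammas, ss.spawn(len(params.gammas))):
        init_seeds = child.generate_state(params.n_init + 1)
        runs = [
            louvain_once(W, gamma=gamma, seed=int(s % (2**31 - 1)), variant=params.variant)
            for s in init_seeds[:-1]
        ]
        out[gamma] = consensus_partition(
            runs, cons, seed=int(init_seeds[-1] % (2**31 - 1)),
            level=level, gamma_tag=gamma,
        )
    return out


def group_consensus(subject_partitions, cons: ConsensusParams | None = None,
                    seed: int = 0, gamma_tag=None) -> Partition:
    """Consensus across subjects (task templates) or across a subject's windows."""
    parts = list(subject_partitions)
    if len(parts) < 2:
        raise InvalidParameterError("group consensus needs at least 2 partitions")
    return consensus_partition(parts, cons, seed=seed, level="group", gamma_tag=gamma_tag)
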