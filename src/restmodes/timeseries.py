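"""ROI time-series preparation and sliding-window connectivity.

Covers the per-run preprocessing applied before community detection:
confound regression, band-pass filtering, task-regressor construction,
sliding-window planning, and (Hann-weighted) Pearson/Fisher-z
connectivity estimation.

Conventions used throughout the package: volumes are 0-based and windows
are half-open ``[start, end)``; connectivity matrices are symmetric,
zero-diagonal Fisher-z couplings with ``r`` clipped at ``|r| = 0.999999``
before ``atanh``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, signal

from .exceptions import DegenerateDataError, InvalidParameterError, RankDeficientError

#: clip bound applied to correlations before the Fisher transform
R_CLIP = 0.999999


@dataclass(frozen=True)
class RoiTimeSeries:
    """One run of one subject: a volumes x ROIs signal matrix plus metadata.

    Parameters
    ----------
    data:
        2-D float array, shape ``(n_volumes, n_rois)``, arbitrary BOLD-like units.
    tr:
        Repetition time in seconds.
    run_id:
        Run identifier, unique within a subject.
    encoding_tag:
        Free label for the phase-encoding direction (e.g. ``"LR"``/``"RL"``).
    subject_id:
        Subject identifier.
    """

    data: np.ndarray
    tr: float
    run_id: str = "run-1"
    encoding_tag: str = ""
    subject_id: str = ""

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise InvalidParameterError("time series must be a 2-D volumes x ROIs matrix")
        if data.shape[0] < 2:
            raise InvalidParameterError("time series needs at least 2 volumes")
        if not np.all(np.isfinite(data)):
            raise InvalidParameterError("time series contains non-finite values")
        if self.tr <= 0:
            raise InvalidParameterError("tr must be positive (seconds)")
        object.__setattr__(self, "data", data)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowPlan:
    """Sliding-window layout over one or more runs.

    ``windows`` is an ordered list of ``(run_id, start, end)`` with half-open
    ``[start, end)`` volume spans; every window lies entirely within one run,
    so windows never mix runs (and hence never mix phase-encoding directions).
    """

    window_len: int
    hop: int
    windows: tuple = ()
    weighting: str = "hann"

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def windows_in_run(self, run_id) -> list:
        return [w for w in self.windows if w[0] == run_id]

    @property
    def run_ids(self) -> list:
        seen = []
        for rid, _, _ in self.windows:
            if rid not in seen:
                seen.append(rid)
        return seen

    def max_possible_switches(self) -> int:
        """Sum over runs of (windows in run - 1): consecutive within-run pairs."""
        return sum(
            max(len(self.windows_in_run(rid)) - 1, 0) for rid in self.run_ids
        )


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ROI x ROI Fisher-z coupling with zero diagonal."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidParameterError("connectivity must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-10):
            raise InvalidParameterError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("connectivity matrix must be finite")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


# ---------------------------------------------------------------------------
# confound regression


def regress_confounds(ts: RoiTimeSeries, confounds: np.ndarray | None) -> RoiTimeSeries:
    """Remove nuisance signals from every ROI by linear regression.

    The design matrix is ``[intercept, linear trend, confounds]``; the
    returned series holds the least-squares residuals, orthogonal to every
    regressor column. Raises :class:`RankDeficientError` naming the
    offending columns when the design is rank deficient.
    """
    t = ts.n_volumes
    trend = np.linspace(-1.0, 1.0, t)
    cols = ["intercept", "trend"]
    design = [np.ones(t), trend]
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] == 1 and confounds.shape[1] == t:
            confounds = confounds.T
        if confounds.shape[0] != t:
            raise InvalidParameterError(
                f"confounds have {confounds.shape[0]} rows but the run has {t} volumes"
            )
        for j in range(confounds.shape[1]):
            design.append(confounds[:, j])
            cols.append(f"confound_{j}")
    X = np.column_stack(design)
    # pivoted QR exposes which columns are linearly dependent
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [cols[j] for j in piv[rank:]]
        raise RankDeficientError(
            f"rank-deficient confound design; dependent columns: {bad}", columns=bad
        )
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return replace(ts, data=resid)


# ---------------------------------------------------------------------------
# task regressors


def build_task_regressors(
    onsets, durations, tr: float, n_volumes: int, oversample: int = 16
) -> np.ndarray:
    """HRF-convolved boxcar regressor and its first temporal derivative.

    The boxcar over the task blocks is convolved with the canonical
    double-gamma HRF (peak 6 s, undershoot 16 s) on a grid oversampled
    ``oversample`` times relative to TR, then sampled at volume times.
    Column 2 is the first finite difference of column 1 (leading zero).

    Returns an ``(n_volumes, 2)`` array.
    """
    from nilearn.glm.first_level.hemodynamic_models import spm_hrf

    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if onsets.shape != durations.shape:
        raise InvalidParameterError("onsets and durations must have the same length")
    run_end = n_volumes * tr
    if onsets.size and np.any(onsets < 0):
        raise InvalidParameterError("block onsets must be non-negative")
    if onsets.size and np.any(onsets + durations > run_end + 1e-9):
        raise InvalidParameterError(
            "a task block extends past the end of the run "
            f"(run length {run_end:.2f} s)"
        )
    out = np.zeros((n_volumes, 2))
    if onsets.size == 0:
        return out
    dt = tr / oversample
    grid_len = int(np.ceil(run_end / dt)) + 1
    box = np.zeros(grid_len)
    times = np.arange(grid_len) * dt
    for on, dur in zip(onsets, durations):
        box[(times >= on) & (times < on + dur)] = 1.0
    hrf = spm_hrf(tr, oversampling=oversample)
    conv = np.convolve(box, hrf)[:grid_len]
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    out[:, 0] = conv[vol_idx]
    out[1:, 1] = np.diff(out[:, 0])
    return out


# ---------------------------------------------------------------------------
# band-pass filter


def bandpass_filter(ts: RoiTimeSeries, f_lo: float = 0.008, f_hi: float = 0.09) -> RoiTimeSeries:
    """Linear detrend followed by a zero-phase frequency-domain band-pass.

    Frequencies strictly inside ``(f_lo, f_hi)`` Hz are retained; the mask is
    applied to the real FFT, so the filter introduces no temporal shift.
    """
    nyq = 1.0 / (2.0 * ts.tr)
    if not (0 <= f_lo < f_hi):
        raise InvalidParameterError("need 0 <= f_lo < f_hi")
    if f_hi >= nyq:
        raise InvalidParameterError(
            f"f_hi={f_hi} Hz is not below the Nyquist frequency {nyq:.4f} Hz"
        )
    x = signal.detrend(ts.data, axis=0, type="linear")
    freqs = np.fft.rfftfreq(ts.n_volumes, d=ts.tr)
    mask = (freqs > f_lo) & (freqs < f_hi)
    spec = np.fft.rfft(x, axis=0)
    spec[~mask, :] = 0.0
    filtered = np.fft.irfft(spec, n=ts.n_volumes, axis=0)
    return replace(ts, data=filtered)


def despike(ts: RoiTimeSeries, window: int = 7, threshold: float = 5.0) -> RoiTimeSeries:
    """Median-filter-based spike attenuation (optional, off the main path).

    Samples deviating from a running median by more than ``threshold``
    robust SDs are replaced by the running median.
    """
    med = signal.medfilt(ts.data, kernel_size=(window, 1))
    dev = ts.data - med
    mad = np.median(np.abs(dev), axis=0, keepdims=True)
    sd = 1.4826 * np.maximum(mad, 1e-12)
    out = np.where(np.abs(dev) > threshold * sd, med, ts.data)
    return replace(ts, data=out)


# ---------------------------------------------------------------------------
# window planning and connectivity


def plan_windows(
    run_lengths: dict, window_len: int, hop: int, weighting: str = "hann"
) -> WindowPlan:
    """Lay out sliding windows independently within each run.

    Per run of length ``L``, windows start at ``0, hop, 2*hop, ...`` while
    ``start + window_len <= L``. Runs shorter than ``window_len`` contribute
    no windows and trigger a warning.
    """
    if window_len < 2:
        raise InvalidParameterError("window_len must be >= 2 volumes")
    if hop < 1:
        raise InvalidParameterError("hop must be >= 1 volume")
    if weighting not in ("hann", "uniform"):
        raise InvalidParameterError("weighting must be 'hann' or 'uniform'")
    windows = []
    for run_id, length in run_lengths.items():
        if length < window_len:
            warnings.warn(
                f"run {run_id!r} ({length} volumes) is shorter than the "
                f"window ({window_len} volumes); no windows planned",
                stacklevel=2,
            )
            continue
        for start in range(0, length - window_len + 1, hop):
            windows.append((run_id, start, start + window_len))
    return WindowPlan(window_len=window_len, hop=hop, windows=tuple(windows), weighting=weighting)


def _window_weights(window_len: int, weighting: str) -> np.ndarray:
    if weighting == "hann":
        w = np.hanning(window_len)
    else:
        w = np.ones(window_len)
    return w / w.sum()


def _weighted_corr(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix; weights sum to 1."""
    mu = w @ x
    xc = x - mu
    cov = (xc * w[:, None]).T @ xc
    var = np.diag(cov).copy()
    # relative threshold: rounding in the weighted mean leaves ~eps^2 variance
    # in genuinely constant columns
    vmax = var.max()
    zero = var <= (vmax * 1e-12 if vmax > 0 else np.inf)
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} ROI(s) with zero weighted variance in a window; "
            "their correlations are set to 0",
            stacklevel=3,
        )
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    r = cov / denom
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    return r


def window_connectivity(ts: RoiTimeSeries, plan: WindowPlan) -> list:
    """Weighted Pearson/Fisher-z connectivity for every window of ``ts``'s run.

    Hann weighting emphasises the central volumes of each window, reducing
    the leakage of autocorrelated signal between adjacent windows.
    """
    mats = []
    w = _window_weights(plan.window_len, plan.weighting)
    for run_id, start, end in plan.windows:
        if run_id != ts.run_id:
            continue
        if end > ts.n_volumes:
            raise InvalidParameterError(
                f"window [{start}, {end}) exceeds run {ts.run_id!r} "
                f"({ts.n_volumes} volumes)"
            )
        r = _weighted_corr(ts.data[start:end], w)
        z = _fisher_z(r)
        np.fill_diagonal(z, 0.0)
        mats.append(
            ConnectivityMatrix(values=z, provenance=f"{ts.run_id}:w{start:05d}")
        )
    return mats


def static_connectivity(runs) -> ConnectivityMatrix:
    """Fisher-z Pearson connectivity over concatenated, per-run standardized runs."""
    if isinstance(runs, RoiTimeSeries):
        runs = [runs]
    if not runs:
        raise InvalidParameterError("need at least one run")
    n_rois = runs[0].n_rois
    pieces = []
    for run in runs:
        if run.n_rois != n_rois:
            raise InvalidParameterError("all runs must share n_rois")
        x = run.data
        sd = x.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        pieces.append((x - x.mean(axis=0)) / sd)
    cat = np.vstack(pieces)
    if cat.shape[0] < 2:
        raise DegenerateDataError("cannot correlate a single volume")
    r = np.corrcoef(cat, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    z = _fisher_z(r)
    np.fill_diagonal(z, 0.0)
    label = "+".join(run.run_id for run in runs)
    return ConnectivityMatrix(values=z, provenance=f"static:{label}")
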