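"""Brain-behavior inference: cross-validated CCA with permutation tests.

Canonical correlation analysis pairs linear combinations (variates) of a
brain feature set (task-rest similarity indices and sequence counts) and a
behavioral set (age and memory scores) so that the variate correlation is
maximal. Out-of-sample validity is assessed by k-fold cross-validation:
discovery CCAs are fit on the training folds, test subjects are projected
with the training weights (standardized with training parameters), the
predicted variates are pooled across folds, and the pooled correlation is
evaluated with a permutation test. Bootstrap CIs screen which brain
variables contribute reliably, and a zeroed-weight projection transfers
the model to a second cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import norm

from .exceptions import DegenerateDataError, InvalidParameterError, RankDeficientError


def _as_frame(X, prefix: str, require_variance: bool = True) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        df = pd.DataFrame(X, columns=[f"{prefix}{j}" for j in range(X.shape[1])])
    if df.isna().any().any():
        raise InvalidParameterError("feature table contains missing values")
    if require_variance:
        sd = df.std(axis=0, ddof=1)
        bad = list(df.columns[(sd == 0) | ~np.isfinite(sd)])
        if bad:
            raise DegenerateDataError(
                f"zero-variance feature columns: {bad}", columns=bad
            )
    return df


def _check_rank(Z: np.ndarray, names) -> None:
    _, R, piv = linalg.qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Z.shape) * np.finfo(float).eps * 100
    rank = int(np.sum(diag > tol))
    if rank < Z.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficientError(
            f"collinear feature columns: {bad}", columns=bad
        )


def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    vals = np.maximum(vals, 1e-12)
    return vecs @ np.diag(vals**-0.5) @ vecs.T


@dataclass(frozen=True)
class CcaModel:
    """Fitted canonical correlation model with training standardization."""

    x_names: tuple
    y_names: tuple
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    x_weights: np.ndarray  # p x m canonical weights (standardized space)
    y_weights: np.ndarray  # q x m
    correlations: np.ndarray  # m, non-increasing in [0, 1]
    x_loadings: np.ndarray  # p x m correlations of raw X columns with X variates
    y_loadings: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.correlations.size

    def transform(self, X, Y=None):
        """Project new data with the training weights and standardization."""
        Xf = _as_frame(X, "x", require_variance=False)[list(self.x_names)]
        u = ((Xf.to_numpy() - self.x_mean) / self.x_sd) @ self.x_weights
        if Y is None:
            return u
        Yf = _as_frame(Y, "y", require_variance=False)[list(self.y_names)]
        v = ((Yf.to_numpy() - self.y_mean) / self.y_sd) @ self.y_weights
        return u, v


def cca_fit(X, Y) -> CcaModel:
    """Canonical correlation analysis via the correlation-matrix SVD.

    Columns are standardized; directions come from the SVD of
    ``Sxx^{-1/2} Sxy Syy^{-1/2}``, so the canonical correlations are the
    singular values (non-increasing, clipped to [0, 1]). The sign of each
    mode is anchored so the weight of the first behavioral variable is
    non-negative. Loadings are Pearson correlations between the raw
    variables and their variates.
    """
    Xf = _as_frame(X, "x")
    Yf = _as_frame(Y, "y")
    if len(Xf) != len(Yf):
        raise InvalidParameterError("X and Y must describe the same subjects")
    n, p = Xf.shape
    q = Yf.shape[1]
    if n <= p + q:
        raise InvalidParameterError(
            f"need more subjects ({n}) than total variables ({p + q})"
        )
    x_mean, x_sd = Xf.mean().to_numpy(), Xf.std(ddof=1).to_numpy()
    y_mean, y_sd = Yf.mean().to_numpy(), Yf.std(ddof=1).to_numpy()
    Zx = (Xf.to_numpy() - x_mean) / x_sd
    Zy = (Yf.to_numpy() - y_mean) / y_sd
    _check_rank(Zx, list(Xf.columns))
    _check_rank(Zy, list(Yf.columns))
    Sxx = Zx.T @ Zx / (n - 1)
    Syy = Zy.T @ Zy / (n - 1)
    Sxy = Zx.T @ Zy / (n - 1)
    Wx, Wy = _inv_sqrt(Sxx), _inv_sqrt(Syy)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    m = min(p, q)
    A = Wx @ U[:, :m]
    B = Wy @ Vt.T[:, :m]
    corr = np.clip(s[:m], 0.0, 1.0)
    # sign anchor: first behavioral variable's weight non-negative per mode
    for k in range(m):
        if B[0, k] < 0:
            A[:, k] *= -1.0
            B[:, k] *= -1.0
    u_var = Zx @ A
    v_var = Zy @ B
    x_load = _col_corr(Xf.to_numpy(), u_var)
    y_load = _col_corr(Yf.to_numpy(), v_var)
    return CcaModel(
        x_names=tuple(Xf.columns), y_names=tuple(Yf.columns),
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        x_weights=A, y_weights=B, correlations=corr,
        x_loadings=x_load, y_loadings=y_load,
    )


def _col_corr(M: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Correlations between every column of M and every column of V."""
    Mc = M - M.mean(axis=0)
    Vc = V - V.mean(axis=0)
    denom = np.outer(
        np.sqrt((Mc**2).sum(axis=0)), np.sqrt((Vc**2).sum(axis=0))
    )
    denom[denom == 0] = 1.0
    return (Mc.T @ Vc) / denom


@dataclass(frozen=True)
class CvResult:
    """Pooled test-fold CCA predictions and their correlation."""

    fold_assignments: np.ndarray  # subject -> fold index
    pooled_u: np.ndarray  # predicted brain variate, one entry per subject
    pooled_v: np.ndarray  # predicted behavioral variate
    r: float
    p: float | None
    fold_models: tuple  # discovery CcaModel per fold
    mode: int = 0


def _make_folds(n: int, k_folds: int, fold_sizes, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    if fold_sizes is not None:
        if sum(fold_sizes) != n:
            raise InvalidParameterError("fold sizes must sum to the number of subjects")
        sizes = list(fold_sizes)
    else:
        base, extra = divmod(n, k_folds)
        sizes = [base + (1 if f < extra else 0) for f in range(k_folds)]
    if any(s < 2 for s in sizes):
        raise InvalidParameterError("every fold needs at least 2 subjects")
    start = 0
    for f, size in enumerate(sizes):
        assign[perm[start:start + size]] = f
        start += size
    return assign


def _std_train(A: np.ndarray):
    mean = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (A - mean) / sd, mean, sd


def _cca_direction(Zx: np.ndarray, Zy: np.ndarray, mode: int):
    """First-anchor canonical weight pair for one mode (lean path)."""
    n = Zx.shape[0]
    Wx = _inv_sqrt(Zx.T @ Zx / (n - 1))
    Wy = _inv_sqrt(Zy.T @ Zy / (n - 1))
    U, _, Vt = np.linalg.svd(Wx @ (Zx.T @ Zy / (n - 1)) @ Wy)
    a = Wx @ U[:, mode]
    b = Wy @ Vt[mode]
    if b[0] < 0:
        a, b = -a, -b
    return a, b


def _cv_pooled_r(Xv: np.ndarray, Yv: np.ndarray, assign: np.ndarray,
                 mode: int) -> float:
    """Pooled test-fold variate correlation for one (possibly permuted) Y."""
    n = Xv.shape[0]
    Zx_all, _, _ = _std_train(Xv)
    Zy_all, _, _ = _std_train(Yv)
    a_ref, _ = _cca_direction(Zx_all, Zy_all, mode)
    pooled_u = np.empty(n)
    pooled_v = np.empty(n)
    for f in range(assign.max() + 1):
        test = assign == f
        Zx_tr, mx, sx = _std_train(Xv[~test])
        Zy_tr, my, sy = _std_train(Yv[~test])
        a, b = _cca_direction(Zx_tr, Zy_tr, mode)
        s = 1.0 if a @ a_ref >= 0 else -1.0
        pooled_u[test] = ((Xv[test] - mx) / sx) @ a * s
        pooled_v[test] = ((Yv[test] - my) / sy) @ b * s
    return float(np.corrcoef(pooled_u, pooled_v)[0, 1])


def cca_crossval(X, Y, k_folds: int = 10, fold_sizes=None, seed: int = 0,
                 n_perm: int = 0, mode: int = 0) -> CvResult:
    """k-fold cross-validated CCA with pooled test-fold predictions.

    Each discovery model is sign-aligned to a full-sample reference model
    (joint flip of the brain and behavior weights, which leaves the model
    equivalent) so that predictions pooled across folds share a common
    orientation. ``r`` is the Pearson correlation of the pooled predicted
    brain and behavioral variates.

    If ``n_perm > 0``, the permutation p-value re-runs the *entire*
    cross-validation on behavior tables with permuted subject rows:
    because fold models share training subjects, fold-wise test
    correlations are positively dependent, and permuting only the pooled
    variates understates the null variance (anti-conservative). Permuting
    subjects upstream of the whole procedure restores exchangeability.
    """
    Xf = _as_frame(X, "x")
    Yf = _as_frame(Y, "y")
    n = len(Xf)
    if k_folds < 2 and fold_sizes is None:
        raise InvalidParameterError("k_folds must be >= 2")
    rng = np.random.default_rng(seed)
    assign = _make_folds(n, k_folds, fold_sizes, rng)
    reference = cca_fit(Xf, Yf)
    pooled_u = np.empty(n)
    pooled_v = np.empty(n)
    models = []
    for f in range(assign.max() + 1):
        test = assign == f
        model = cca_fit(Xf.loc[~test], Yf.loc[~test])
        model = _align_signs(model, reference)
        u, v = model.transform(Xf.loc[test], Yf.loc[test])
        pooled_u[test] = u[:, mode]
        pooled_v[test] = v[:, mode]
        models.append(model)
    r = float(np.corrcoef(pooled_u, pooled_v)[0, 1])
    p = None
    if n_perm > 0:
        Xv = Xf.to_numpy()
        Yv = Yf.to_numpy()
        n_exceed = 0
        for _ in range(n_perm):
            r_perm = _cv_pooled_r(Xv, Yv[rng.permutation(n)], assign, mode)
            n_exceed += abs(r_perm) >= abs(r)
        p = (1 + n_exceed) / (n_perm + 1)
    return CvResult(
        fold_assignments=assign, pooled_u=pooled_u, pooled_v=pooled_v,
        r=r, p=p, fold_models=tuple(models), mode=mode,
    )


def _align_signs(model: CcaModel, reference: CcaModel) -> CcaModel:
    """Jointly flip (brain, behavior) weights to match a reference orientation."""
    A = model.x_weights.copy()
    B = model.y_weights.copy()
    xl = model.x_loadings.copy()
    yl = model.y_loadings.copy()
    m = min(model.n_modes, reference.n_modes)
    for k in range(m):
        if A[:, k] @ reference.x_weights[:, k] < 0:
            A[:, k] *= -1.0
            B[:, k] *= -1.0
            xl[:, k] *= -1.0
            yl[:, k] *= -1.0
    return CcaModel(
        x_names=model.x_names, y_names=model.y_names,
        x_mean=model.x_mean, x_sd=model.x_sd,
        y_mean=model.y_mean, y_sd=model.y_sd,
        x_weights=A, y_weights=B, correlations=model.correlations,
        x_loadings=xl, y_loadings=yl,
    )


def fold_summary(cv: CvResult, which: str = "x_weights", mode: int = 0) -> pd.DataFrame:
    """Median plus min/max of weights or loadings across discovery folds."""
    names = cv.fold_models[0].x_names if which.startswith("x") else cv.fold_models[0].y_names
    vals = np.stack([getattr(m, which)[:, mode] for m in cv.fold_models])
    return pd.DataFrame(
        {
            "median": np.median(vals, axis=0),
            "min": vals.min(axis=0),
            "max": vals.max(axis=0),
        },
        index=list(names),
    )


# ---------------------------------------------------------------------------
# permutation inference


def perm_test_correlation(a, b, n_perm: int = 100_000, seed: int = 0,
                          chunk: int = 2000) -> float:
    """Two-sided permutation p-value for the Pearson correlation of a and b.

    ``b`` is permuted, ``a`` held fixed; ``p = (1 + #{|r_perm| >= |r_obs|})
    / (n_perm + 1)``, so the smallest attainable p is ``1/(n_perm+1)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("a and b must be equal-length vectors")
    if a.size < 3:
        raise InvalidParameterError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateDataError("cannot permute a constant vector")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.sqrt((ac**2).sum())
    nb = np.sqrt((bc**2).sum())
    r_obs = float(ac @ bc / (na * nb))
    rng = np.random.default_rng(seed)
    n_exceed = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        P = rng.permuted(np.broadcast_to(bc, (m, bc.size)).copy(), axis=1)
        r_perm = (P @ ac) / (na * nb)
        n_exceed += int(np.sum(np.abs(r_perm) >= abs(r_obs)))
        done += m
    return (1 + n_exceed) / (n_perm + 1)


def residualize_variate(v, confounds) -> np.ndarray:
    """Least-squares residual of a subject-indexed vector on (intercept, confounds)."""
    v = np.asarray(v, dtype=float)
    if confounds is None:
        return v - v.mean()
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] == 1 and C.shape[1] == v.size:
        C = C.T
    if C.shape[0] != v.size:
        raise InvalidParameterError("confound rows must match the vector length")
    X = np.column_stack([np.ones(v.size), C])
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    if np.sum(diag > tol) < X.shape[1]:
        bad = [int(j) - 1 for j in piv[np.sum(diag > tol):]]
        raise RankDeficientError(
            f"rank-deficient confound matrix; dependent columns: {bad}", columns=bad
        )
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_corr_perm(x, y, covariates=None, n_perm: int = 100_000,
                      seed: int = 0):
    """Partial correlation of x and y given covariates, with permutation p.

    Both vectors are residualized on the covariates (plus intercept); the
    residual vectors are then correlated and one of them permuted as in
    :func:`perm_test_correlation`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] == 1 and C.shape[1] == x.size:
            C = C.T
        if x.size <= C.shape[1] + 2:
            raise InvalidParameterError("too few observations for the covariate count")
    rx = residualize_variate(x, covariates)
    ry = residualize_variate(y, covariates)
    # a variable fully explained by the covariates leaves only rounding dust
    for res, orig in ((rx, x), (ry, y)):
        if res.std() <= 1e-10 * max(orig.std(), 1.0):
            warnings.warn(
                "a variable is fully explained by the covariates; "
                "partial correlation set to 0",
                stacklevel=2,
            )
            return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    p = perm_test_correlation(rx, ry, n_perm=n_perm, seed=seed)
    return r, p


# ---------------------------------------------------------------------------
# bootstrap contributor screening


@dataclass(frozen=True)
class BootstrapCi:
    names: tuple
    coef: np.ndarray  # full-sample regression coefficients (per predictor)
    ci_low: np.ndarray
    ci_high: np.ndarray
    reliable: np.ndarray  # CI excludes 0
    n_redrawn: int
    method: str


def _batched_ols(X1: np.ndarray, y: np.ndarray, W: np.ndarray, min_eig_tol: float):
    """OLS coefficients for case-weight matrices W (n_boot x n); NaN rows if degenerate."""
    G = np.einsum("bn,np,nq->bpq", W, X1, X1, optimize=True)
    c = (W * y) @ X1
    eig_ok = np.linalg.eigvalsh(G)[:, 0] > min_eig_tol
    out = np.full((W.shape[0], X1.shape[1]), np.nan)
    if eig_ok.any():
        out[eig_ok] = np.linalg.solve(G[eig_ok], c[eig_ok][:, :, None])[:, :, 0]
    return out, eig_ok


def bootstrap_regression_ci(X, y, n_boot: int = 100_000, alpha: float = 0.05,
                            seed: int = 0, method: str = "bca",
                            chunk: int = 5000) -> BootstrapCi:
    """Case-resampling bootstrap CIs for multiple-regression coefficients.

    ``X`` and ``y`` are expected standardized. BCa intervals by default
    (``method="percentile"`` for simple percentile bounds). Rank-deficient
    resamples are redrawn; their number is recorded on the result.
    A predictor is flagged reliable when its CI excludes zero.
    """
    Xf = _as_frame(X, "x")
    y = np.asarray(y, dtype=float)
    n, p = Xf.shape
    if y.shape != (n,):
        raise InvalidParameterError("y must be a vector matching X's rows")
    if n <= p + 1:
        raise InvalidParameterError("need more observations than predictors")
    if method not in ("bca", "percentile"):
        raise InvalidParameterError("method must be 'bca' or 'percentile'")
    X1 = np.column_stack([np.ones(n), Xf.to_numpy()])
    G_full = X1.T @ X1
    min_eig_tol = np.linalg.eigvalsh(G_full)[0] * 1e-8
    beta_hat = np.linalg.solve(G_full, X1.T @ y)[1:]

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, p))
    done = 0
    n_redrawn = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        W = rng.multinomial(n, np.full(n, 1.0 / n), size=m).astype(float)
        coefs, ok = _batched_ols(X1, y, W, min_eig_tol)
        n_redrawn += int((~ok).sum())
        good = coefs[ok][:, 1:]
        take = min(good.shape[0], n_boot - done)
        boot[done:done + take] = good[:take]
        done += take
    if n_redrawn:
        warnings.warn(f"redrew {n_redrawn} rank-deficient bootstrap resamples", stacklevel=2)

    if method == "percentile":
        lo = np.quantile(boot, alpha / 2, axis=0)
        hi = np.quantile(boot, 1 - alpha / 2, axis=0)
    else:
        lo, hi = _bca_interval(boot, beta_hat, X1, y, alpha)
    reliable = (lo > 0) | (hi < 0)
    return BootstrapCi(
        names=tuple(Xf.columns), coef=beta_hat, ci_low=lo, ci_high=hi,
        reliable=reliable, n_redrawn=n_redrawn, method=method,
    )


def _bca_interval(boot: np.ndarray, beta_hat: np.ndarray, X1: np.ndarray,
                  y: np.ndarray, alpha: float):
    """Bias-corrected and accelerated percentile bounds per coefficient."""
    n_boot, p = boot.shape
    n = X1.shape[0]
    prop = (boot < beta_hat).mean(axis=0)
    prop = np.clip(prop, 1.0 / (n_boot + 1), n_boot / (n_boot + 1))
    z0 = norm.ppf(prop)
    # jackknife acceleration: leave-one-out coefficients via weight matrices
    W = np.ones((n, n)) - np.eye(n)
    jack, _ = _batched_ols(X1, y, W, min_eig_tol=0.0)
    jack = jack[:, 1:]
    jm = jack.mean(axis=0)
    num = ((jm - jack) ** 3).sum(axis=0)
    den = 6.0 * (((jm - jack) ** 2).sum(axis=0)) ** 1.5
    a = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    lo = np.empty(p)
    hi = np.empty(p)
    for j in range(p):
        a1 = norm.cdf(z0[j] + (z0[j] + z_lo) / (1 - a[j] * (z0[j] + z_lo)))
        a2 = norm.cdf(z0[j] + (z0[j] + z_hi) / (1 - a[j] * (z0[j] + z_hi)))
        lo[j] = np.quantile(boot[:, j], a1)
        hi[j] = np.quantile(boot[:, j], a2)
    return lo, hi


# ---------------------------------------------------------------------------
# transfer to a second cohort


def transfer_projection(features, model: CcaModel, zero_names=(),
                        confounds=None, mode: int = 0) -> np.ndarray:
    """Project a new cohort with zeroed-out weights, then residualize.

    The new cohort's features are standardized with their *own* means/SDs,
    projected with the model's brain weights after setting the weights of
    ``zero_names`` to zero; the score is then residualized on the zeroed
    variables themselves plus any supplied confounds, so those variables
    are covaried out rather than contributing to the variate.
    """
    Xf = _as_frame(features, "x")
    missing = [nm for nm in model.x_names if nm not in Xf.columns]
    if missing:
        raise InvalidParameterError(f"features missing model variables: {missing}")
    Xf = Xf[list(model.x_names)]
    unknown = [nm for nm in zero_names if nm not in model.x_names]
    if unknown:
        raise InvalidParameterError(f"unknown variables in zero_names: {unknown}")
    Z = (Xf.to_numpy() - Xf.mean().to_numpy()) / Xf.std(ddof=1).to_numpy()
    w = model.x_weights[:, mode].copy()
    zero_idx = [model.x_names.index(nm) for nm in zero_names]
    w[zero_idx] = 0.0
    score = Z @ w
    resid_cols = [Z[:, j] for j in zero_idx]
    if confounds is not None:
        C = np.atleast_2d(np.asarray(confounds, dtype=float))
        if C.shape[0] == 1 and C.shape[1] == score.size:
            C = C.T
        resid_cols.extend(C[:, j] for j in range(C.shape[1]))
    if resid_cols:
        score = residualize_variate(score, np.column_stack(resid_cols))
    return score
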