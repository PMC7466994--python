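"""Population-level association testing on pooled allele frequencies.

Trait values here are population adjusted means, and 'genotypes' are
alternative-allele frequencies, so a marker test is a regression of the
population mean on the frequency column.  Four model specifications are
supported: naive OLS, structure covariates (cluster dummies), a kinship
mixed model y = Xb + u + e with u ~ N(0, sigma_g^2 G), and structure +
kinship.  The mixed model is fitted by REML through a single spectral
decomposition; per-marker tests reuse the null variance components (the
P3D shortcut) unless exact per-marker REML is requested.

Multiple testing uses Benjamini-Hochberg q-values with the study-standard
10% threshold; utilities cover per-marker variance explained with and
without kinship, redundancy pruning at a correlation threshold, and the
forward-stepwise multi-marker model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from poolgp.dataio import AlleleFrequencyMatrix
from poolgp.grm import KinshipMatrix

_DELTA_GRID = np.logspace(-5, 5, 100)


@dataclass
class NullModelFit:
    """REML fit of y = Xb + u + e with u ~ N(0, sigma_g^2 G).

    Caches the spectral decomposition of G so per-marker GLS tests and
    whitening reuse it.
    """

    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    reml_loglik: float
    eigvals: np.ndarray = field(repr=False)  # of G
    eigvecs: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)  # fixed-effect design used in the fit

    def whitening(self) -> np.ndarray:
        """W with W H W' = I for H = sigma_g2 G + sigma_e2 I."""
        w = self.sigma_g2 * np.clip(self.eigvals, 0.0, None) + self.sigma_e2
        return (self.eigvecs / np.sqrt(w)).T


def _restricted_loglik(delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    nq = xi.size
    denom = xi + delta
    s = float((eta2 / denom).sum())
    return 0.5 * (nq * np.log(nq / (2 * np.pi)) - nq - nq * np.log(s) - np.log(denom).sum())


def fit_null_mm(
    y: np.ndarray,
    G: KinshipMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
) -> NullModelFit:
    """Single-variance-component REML via spectral decomposition.

    Profiles the restricted likelihood over delta = sigma_e2/sigma_g2 on a
    100-point log grid spanning 1e-5..1e5, then refines with bounded
    golden-section/Brent search to 1e-6 relative precision.  *covariates*
    (if given) are appended to an intercept column.
    """
    y = np.asarray(y, dtype=float).ravel()
    Gm = G.G if isinstance(G, KinshipMatrix) else np.asarray(G, dtype=float)
    n = y.size
    if Gm.shape != (n, n):
        raise ValueError(f"G shape {Gm.shape} incompatible with n={n}")
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([X, C])
    q = np.linalg.matrix_rank(X)
    if n - q < 2:
        raise ValueError("not enough residual degrees of freedom for REML")

    lam_full, U_full = np.linalg.eigh(0.5 * (Gm + Gm.T))
    scale = max(1.0, float(np.abs(lam_full).max()))
    if lam_full.min() < -1e-6 * scale:
        raise ValueError(f"G not PSD (min eigenvalue {lam_full.min():.3e})")

    # restricted spectrum: eigen of S G S on the complement of col(X)
    Q, _ = np.linalg.qr(X)
    S = np.eye(n) - Q[:, :q] @ Q[:, :q].T
    SGS = S @ Gm @ S
    xi_all, V = np.linalg.eigh(0.5 * (SGS + SGS.T))
    order = np.argsort(xi_all)[::-1]
    keep = order[: n - q]
    xi = np.clip(xi_all[keep], 0.0, None)
    # project y off col(X) first: when G is rank-deficient the null space of
    # S G S mixes col(X) with null(G), and the kept zero-eigenvalue basis
    # vectors would otherwise pick up fixed-effect signal
    eta = V[:, keep].T @ (S @ y)
    eta2 = eta**2

    if float(eta2.sum()) <= 1e-300:
        # y lies in col(X): no residual variance to partition
        return NullModelFit(0.0, 0.0, np.inf, 0.0, lam_full, U_full, X)

    ll = np.array([_restricted_loglik(d, xi, eta2) for d in _DELTA_GRID])
    best = int(np.argmax(ll))
    lo = _DELTA_GRID[max(best - 1, 0)]
    hi = _DELTA_GRID[min(best + 1, _DELTA_GRID.size - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_restricted_loglik(float(np.exp(t)), xi, eta2),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    if _restricted_loglik(delta, xi, eta2) < ll[best]:
        delta = float(_DELTA_GRID[best])
    sigma_g2 = float((eta2 / (xi + delta)).sum()) / (n - q)
    sigma_e2 = delta * sigma_g2
    return NullModelFit(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        reml_loglik=float(_restricted_loglik(delta, xi, eta2)),
        eigvals=lam_full,
        eigvecs=U_full,
        X=X,
    )


@dataclass
class GwasResult:
    """Per-marker association results under one model specification."""

    table: pd.DataFrame  # marker, scaffold, pos_bp, beta, se, p, q, r2_ols, r2_kinship, flagged
    model: str
    sigma_g2: float
    sigma_e2: float
    delta: float

    def __post_init__(self) -> None:
        pq = self.table[["p", "q"]].to_numpy()
        if np.nanmin(pq) < -1e-12 or np.nanmax(pq) > 1 + 1e-12:
            raise ValueError("p/q outside [0, 1]")


@dataclass
class StepwiseModel:
    """Forward-selected multi-marker regression."""

    markers: list[str]
    coefficients: pd.Series  # intercept + per-marker
    r2: float
    r2_path: list[float]

    def __post_init__(self) -> None:
        if any(b > a + 1e-12 for a, b in zip(self.r2_path[1:], self.r2_path)):
            raise ValueError("R^2 must be non-decreasing along the selection path")


def _structure_dummies(clusters) -> np.ndarray:
    """One-hot dummies for cluster labels, reference level dropped."""
    s = pd.Series(list(clusters)).astype(str)
    return pd.get_dummies(s, drop_first=True, dtype=float).to_numpy()


def run_gwas(
    y: np.ndarray | pd.Series,
    freqs: AlleleFrequencyMatrix,
    model: str = "kinship",
    G: KinshipMatrix | None = None,
    clusters=None,
    p3d: bool = True,
) -> GwasResult:
    """Per-marker association tests under one of four model specifications.

    naive / structure: OLS with an intercept (plus cluster dummies), two-
    sided t-test.  kinship / structure+kinship: GLS with
    H = sigma_g2 G + sigma_e2 I fixed at the null REML estimates (P3D);
    with ``p3d=False`` the variance components are re-estimated by REML for
    every marker.  Constant markers are flagged with beta 0 and p 1.
    """
    if model not in ("naive", "structure", "kinship", "structure+kinship"):
        raise ValueError(f"unknown model {model!r}")
    if "kinship" in model and G is None:
        raise ValueError("kinship models need a relationship matrix G")
    if "structure" in model and clusters is None:
        raise ValueError("structure models need cluster labels")
    yv = np.asarray(y, dtype=float).ravel()
    n, p = freqs.n_pops, freqs.n_markers
    if yv.size != n:
        raise ValueError("y length does not match populations")
    M = freqs.values
    if np.isnan(M).any():
        raise ValueError("impute missing frequencies before GWAS")

    covar = _structure_dummies(clusters) if "structure" in model else None
    sigma_g2 = sigma_e2 = 0.0
    delta = np.inf
    null_fit = None
    if "kinship" in model:
        null_fit = fit_null_mm(yv, G, covariates=covar)
        sigma_g2, sigma_e2, delta = null_fit.sigma_g2, null_fit.sigma_e2, null_fit.delta

    if null_fit is not None and sigma_g2 > 0:
        W = null_fit.whitening()
        yw, Mw = W @ yv, W @ M
        X0w = W @ null_fit.X
    else:
        yw, Mw = yv.copy(), M.copy()
        X0w = np.ones((n, 1)) if covar is None else np.hstack([np.ones((n, 1)), covar])

    if not p3d and null_fit is not None:
        beta, se, pvals, flagged = _exact_scan(yv, M, G, covar)
    else:
        beta, se, pvals, flagged = _gls_scan(yw, Mw, X0w)

    qvals = qvalues(pvals)
    r2_ols = _r2_ols_all(yv, M)
    r2_kin = _r2_partial_all(yw, Mw, X0w)

    table = pd.DataFrame(
        {
            "marker": freqs.marker_ids,
            "scaffold": freqs.marker_map["scaffold"].to_numpy(),
            "pos_bp": freqs.marker_map["pos_bp"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": pvals,
            "q": qvals,
            "r2_ols": r2_ols,
            "r2_kinship": r2_kin,
            "flagged": flagged,
        }
    )
    return GwasResult(table=table, model=model, sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta)


def _residualize(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, A, rcond=None)
    return A - X @ coef


def _gls_scan(yw, Mw, X0w):
    """Vectorized per-marker test on (already whitened) data."""
    n = yw.size
    q = np.linalg.matrix_rank(X0w)
    ry = _residualize(yw, X0w)
    RM = _residualize(Mw, X0w)
    sxx = (RM**2).sum(axis=0)
    sxy = RM.T @ ry
    ryy = float(ry @ ry)
    df = n - q - 1
    tol = 1e-12 * max(1.0, float(sxx.max(initial=0.0)))
    flagged = sxx <= tol
    safe = np.where(flagged, 1.0, sxx)
    beta = np.where(flagged, 0.0, sxy / safe)
    rss = np.clip(ryy - beta * sxy, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / safe)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.where(flagged | ~np.isfinite(pvals), np.where(flagged, 1.0, 0.0), pvals)
    se = np.where(flagged, np.nan, se)
    return beta, se, pvals, flagged


def _exact_scan(yv, M, G, covar):
    """Per-marker REML refit (slow; validation of the P3D shortcut)."""
    n, p = M.shape
    beta = np.zeros(p)
    se = np.full(p, np.nan)
    pvals = np.ones(p)
    flagged = np.zeros(p, dtype=bool)
    for j in range(p):
        xj = M[:, j]
        if np.ptp(xj) == 0.0:
            flagged[j] = True
            continue
        cov_j = xj[:, None] if covar is None else np.hstack([covar, xj[:, None]])
        fit = fit_null_mm(yv, G, covariates=cov_j)
        W = fit.whitening() if fit.sigma_g2 > 0 else np.eye(n)
        X0w = W @ (np.ones((n, 1)) if covar is None else np.hstack([np.ones((n, 1)), covar]))
        b, s, pv, fl = _gls_scan(W @ yv, (W @ xj)[:, None], X0w)
        beta[j], se[j], pvals[j], flagged[j] = b[0], s[0], pv[0], fl[0]
    return beta, se, pvals, flagged


def _r2_ols_all(y, M):
    yc = y - y.mean()
    Mc = M - M.mean(axis=0)
    sy = float(yc @ yc)
    sxx = (Mc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (Mc.T @ yc) ** 2 / (sxx * sy)
    return np.where(sxx <= 1e-12 * max(1.0, float(sxx.max(initial=0.0))), 0.0, r2)


def _r2_partial_all(yw, Mw, X0w):
    """Partial R^2 of each marker given the (whitened) base design."""
    ry = _residualize(yw, X0w)
    RM = _residualize(Mw, X0w)
    ryy = float(ry @ ry)
    sxx = (RM**2).sum(axis=0)
    sxy = RM.T @ ry
    tol = 1e-12 * max(1.0, float(sxx.max(initial=0.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy**2 / (sxx * ryy)
    return np.where((sxx <= tol) | (ryy <= 0), 0.0, np.clip(r2, 0.0, 1.0))


def qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant(result: GwasResult, q_max: float = 0.10) -> list[str]:
    """Markers with q strictly below *q_max*, ordered by ascending p."""
    tab = result.table[result.table["q"] < q_max]
    return tab.sort_values(["p", "marker"], kind="mergesort")["marker"].tolist()


def variance_explained(
    y: np.ndarray,
    x_j: np.ndarray,
    G: KinshipMatrix | None = None,
    null_fit: NullModelFit | None = None,
) -> tuple[float, float]:
    """Trait variance explained by one marker, without and with kinship.

    R2_ols is the squared Pearson correlation of y with the frequency
    column.  R2_kinship is the partial R^2 of the marker after whitening
    both by H^{-1/2} from the null mixed model (variance components fixed
    at their null estimates) — the structure-corrected analogue.
    """
    yv = np.asarray(y, dtype=float).ravel()
    xv = np.asarray(x_j, dtype=float).ravel()
    if np.ptp(xv) == 0.0:
        return 0.0, 0.0
    r2_ols = float(np.corrcoef(yv, xv)[0, 1] ** 2)
    if G is None and null_fit is None:
        return r2_ols, r2_ols
    if null_fit is None:
        null_fit = fit_null_mm(yv, G)
    if null_fit.sigma_g2 > 0:
        W = null_fit.whitening()
        yw, xw, X0w = W @ yv, W @ xv, W @ np.ones((yv.size, 1))
    else:
        yw, xw, X0w = yv, xv, np.ones((yv.size, 1))
    r2_kin = float(_r2_partial_all(yw, xw[:, None], X0w)[0])
    return r2_ols, r2_kin


def prune_by_correlation(
    markers: list[str], freqs: AlleleFrequencyMatrix, r_threshold: float
) -> tuple[int, list[str]]:
    """Markers unlinked to every other listed marker at threshold t.

    A marker is 'unlinked at t' iff the maximum absolute Pearson
    correlation of its frequency column with each other listed marker's
    column is strictly below t.  Returns (count, subset).
    """
    if not markers:
        raise ValueError("need at least one marker")
    if len(markers) == 1:
        return 1, list(markers)
    sub = freqs.subset_markers(list(markers))
    C = np.corrcoef(sub.values.T)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 0.0)
    unlinked = np.abs(C).max(axis=1) < r_threshold
    chosen = [m for m, u in zip(markers, unlinked) if u]
    return len(chosen), chosen


def stepwise_model(
    y: np.ndarray,
    significant_markers: list[str],
    freqs: AlleleFrequencyMatrix,
) -> StepwiseModel:
    """Forward stepwise multiple regression over significant markers.

    Candidates are visited in the given order (most significant first); a
    marker enters iff it lowers the AIC of the multiple regression.  The
    candidate list is truncated to n - 2 markers to keep residual degrees
    of freedom.
    """
    if not significant_markers:
        raise ValueError("need at least one significant marker")
    yv = np.asarray(y, dtype=float).ravel()
    n = yv.size
    candidates = list(significant_markers)[: max(n - 2, 1)]
    sub = freqs.subset_markers(candidates)
    cols = {m: sub.values[:, k] for k, m in enumerate(candidates)}

    def fit_aic(X: np.ndarray) -> tuple[float, np.ndarray, float]:
        coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ coef
        rss = float(resid @ resid)
        k = X.shape[1]
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
        tss = float(((yv - yv.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        return aic, coef, r2

    selected: list[str] = []
    X = np.ones((n, 1))
    aic_cur, coef, r2 = fit_aic(X)
    r2_path: list[float] = []
    for m in candidates:
        X_try = np.hstack([X, cols[m][:, None]])
        aic_try, coef_try, r2_try = fit_aic(X_try)
        if aic_try < aic_cur - 1e-10:
            X, aic_cur, coef, r2 = X_try, aic_try, coef_try, r2_try
            selected.append(m)
            r2_path.append(r2)
    if not selected:
        # even alone the best marker defines the model
        m = candidates[0]
        X = np.hstack([np.ones((n, 1)), cols[m][:, None]])
        _, coef, r2 = fit_aic(X)
        selected, r2_path = [m], [r2]
    names = ["intercept"] + selected
    return StepwiseModel(
        markers=selected,
        coefficients=pd.Series(coef, index=names),
        r2=float(r2),
        r2_path=r2_path,
    )
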