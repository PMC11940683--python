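"""Statistical layer: classical tests, varimax PCA, exact 1-D clustering,
and repeated-measures ANOVA with covariates.

The repeated-measures machinery follows the multivariate approach: the
within-subject factor (phase, k levels) is transformed into k-1 orthonormal
difference contrasts which are regressed on the between-subject design
(intercept, effect-coded factors with their interactions, mean-centered
covariates).  Each model term is tested multivariately with Pillai's trace
``V = tr(H (H + E)^{-1})`` and its standard F approximation, and
univariately with the averaged F whose degrees of freedom are shrunk by the
Greenhouse-Geisser epsilon ``(tr S)^2 / ((k-1) tr S^2)`` computed from the
contrast-transformed residual covariance ``S``.  Between-subject effects are
tested on the subject means.  Estimated marginal means are evaluated at the
covariate means with balanced (unweighted) factor weights, and pairwise
phase contrasts are Bonferroni-adjusted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateClusterError,
    InvalidParameterError,
    TooShortError,
)
from .series import PHASES

__all__ = [
    "TTestResult",
    "Chi2Result",
    "PCAResult",
    "ClusterResult",
    "ContrastResult",
    "RMAnovaResult",
    "paired_t_test",
    "chi2_independence",
    "pearson_corr_matrix",
    "pca_varimax",
    "kmeans_binary",
    "rm_anova",
    "adjusted_pairwise_contrasts",
    "pillai_trace_test",
]


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    infinite: bool = False  # zero variance of differences with nonzero mean


def paired_t_test(x, y) -> TTestResult:
    """Classical paired t test on the differences x - y (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be 1-D with equal length")
    n = x.size
    if n < 3:
        raise TooShortError("paired t test needs n >= 3")
    d = x - y
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0, mean_diff=0.0)
        return TTestResult(
            t=float(np.inf) * np.sign(md), df=df, p=0.0, mean_diff=md, infinite=True
        )
    t = md / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p), mean_diff=md)


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float
    exact: bool = False


def chi2_independence(table, exact: bool = True) -> Chi2Result:
    """Pearson chi-square for a 2x2 contingency table (no continuity correction).

    ``exact=True`` computes the p value by full enumeration of tables with
    the observed margins (hypergeometric weights, for N <= 200), summing the
    probability of all tables whose Pearson statistic is at least the
    observed one; otherwise the chi-square(1) tail is used.
    """
    T = np.asarray(table, dtype=float)
    if T.shape != (2, 2):
        raise InvalidParameterError("table must be 2x2")
    if np.any(T < 0) or np.any(T != np.round(T)):
        raise InvalidParameterError("counts must be non-negative integers")
    rows = T.sum(axis=1)
    cols = T.sum(axis=0)
    N = T.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise InvalidParameterError("zero margin")

    def pearson(a: float) -> float:
        t = np.array([[a, rows[0] - a], [cols[0] - a, N - rows[0] - cols[0] + a]])
        E = np.outer(rows, cols) / N
        return float(np.sum((t - E) ** 2 / E))

    chi2 = pearson(T[0, 0])
    if exact and N <= 200:
        amin = int(max(0, rows[0] + cols[0] - N))
        amax = int(min(rows[0], cols[0]))
        p = 0.0
        for a in range(amin, amax + 1):
            if pearson(a) >= chi2 - 1e-12:
                p += sps.hypergeom.pmf(a, int(N), int(rows[0]), int(cols[0]))
        return Chi2Result(chi2=chi2, df=1, p=float(min(p, 1.0)), exact=True)
    return Chi2Result(chi2=chi2, df=1, p=float(sps.chi2.sf(chi2, 1)), exact=False)


def pearson_corr_matrix(data: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p (t transform, n-2 df).

    Zero-variance columns yield NaN cells (flagged undefined) rather than
    raising.
    """
    cols = list(data.columns)
    n = len(data)
    if n < 4:
        raise TooShortError("correlation needs n >= 4")
    X = data.to_numpy(dtype=float)
    r = np.full((len(cols), len(cols)), np.nan)
    p = np.full_like(r, np.nan)
    sd = X.std(axis=0, ddof=1)
    for i, j in itertools.combinations_with_replacement(range(len(cols)), 2):
        if sd[i] == 0 or sd[j] == 0:
            continue
        if i == j:
            r[i, i], p[i, i] = 1.0, 0.0
            continue
        rij = float(np.corrcoef(X[:, i], X[:, j])[0, 1])
        rij = max(min(rij, 1.0), -1.0)
        if abs(rij) == 1.0:
            pij = 0.0
        else:
            t = rij * np.sqrt((n - 2) / (1.0 - rij**2))
            pij = float(2.0 * sps.t.sf(abs(t), n - 2))
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


# ---------------------------------------------------------------------------
# PCA with varimax rotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray  # all, descending
    loadings_unrotated: np.ndarray  # variables x retained
    loadings_rotated: np.ndarray
    var_prop_unrotated: np.ndarray  # retained eigenvalues / n_vars
    var_prop_rotated: np.ndarray  # rotated SS loadings / n_vars
    n_retained: int
    variables: tuple[str, ...]

    @property
    def cumulative_pct(self) -> float:
        """Cumulative percent variance of the retained components."""
        return 100.0 * float(np.sum(self.var_prop_unrotated))


def _varimax(L: np.ndarray, max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Orthogonal varimax rotation (raw criterion) of a loading matrix."""
    p, k = L.shape
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        B = L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(B)
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1.0 + tol):
            break
        d_old = d
    return L @ R


def pca_varimax(
    means: pd.DataFrame, retain_gt: float = 1.0, n_components: int | None = None
) -> PCAResult:
    """PCA on the correlation matrix with varimax/Kaiser rotation.

    ``means`` is observations x variables (communicator-level judgment
    means).  Components with eigenvalue strictly greater than ``retain_gt``
    are retained (``n_components`` overrides the rule with a fixed count),
    rotated by varimax after Kaiser row normalization (rows scaled to unit
    communality before rotating, rescaled after).
    """
    if means.shape[1] < 2:
        raise InvalidParameterError("need >= 2 variables")
    if means.shape[0] < 3:
        raise InvalidParameterError("need >= 3 observations")
    if means.shape[0] < means.shape[1]:
        warnings.warn("fewer observations than variables: correlation is rank-deficient")
    X = means.to_numpy(dtype=float)
    corr = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    if n_components is not None:
        if not 1 <= n_components <= means.shape[1]:
            raise InvalidParameterError("n_components out of range")
        k = int(n_components)
    else:
        k = max(int(np.sum(eigval > retain_gt)), 1)
    L = eigvec[:, :k] * np.sqrt(eigval[:k])
    # sign convention: dominant loading of each component positive
    for j in range(k):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]

    if k > 1:
        h = np.sqrt(np.sum(L**2, axis=1))
        h = np.where(h > 0, h, 1.0)
        Lr = _varimax(L / h[:, None]) * h[:, None]
        # order rotated components by explained variance, keep dominant-positive
        ss = (Lr**2).sum(axis=0)
        Lr = Lr[:, np.argsort(ss)[::-1]]
        for j in range(k):
            if Lr[np.argmax(np.abs(Lr[:, j])), j] < 0:
                Lr[:, j] = -Lr[:, j]
    else:
        Lr = L.copy()

    nvar = means.shape[1]
    return PCAResult(
        eigenvalues=eigval,
        loadings_unrotated=L,
        loadings_rotated=Lr,
        var_prop_unrotated=eigval[:k] / nvar,
        var_prop_rotated=(Lr**2).sum(axis=0) / nvar,
        n_retained=k,
        variables=tuple(map(str, means.columns)),
    )


# ---------------------------------------------------------------------------
# Exact 1-D binary K-means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray  # "high"/"low" per input value
    center_high: float
    center_low: float
    size_high: int
    size_low: int
    f_stat: float
    df: tuple[int, int]
    p: float


def kmeans_binary(values) -> ClusterResult:
    """Exact two-cluster solution in 1-D via the optimal sorted split.

    Minimizes within-cluster sum of squares over all n-1 ordered splits,
    which contains the global K-means optimum in one dimension.  The
    separation F statistic uses (1, n-2) degrees of freedom.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise InvalidParameterError("need a 1-D array with n >= 2")
    if np.unique(v).size < 2:
        raise DegenerateClusterError("all values identical: no binary split exists")
    order = np.argsort(v, kind="stable")
    s = v[order]
    n = s.size
    csum = np.cumsum(s)
    csq = np.cumsum(s**2)
    best_j, best_w = 1, np.inf
    for j in range(1, n):  # low cluster = s[:j]
        w_lo = csq[j - 1] - csum[j - 1] ** 2 / j
        w_hi = (csq[-1] - csq[j - 1]) - (csum[-1] - csum[j - 1]) ** 2 / (n - j)
        w = w_lo + w_hi
        if w < best_w - 1e-15:
            best_w, best_j = w, j
    j = best_j
    c_lo = float(csum[j - 1] / j)
    c_hi = float((csum[-1] - csum[j - 1]) / (n - j))
    labels = np.empty(n, dtype=object)
    labels[order[:j]] = "low"
    labels[order[j:]] = "high"
    grand = csum[-1] / n
    ss_between = j * (c_lo - grand) ** 2 + (n - j) * (c_hi - grand) ** 2
    df = (1, n - 2)
    if best_w <= 0:
        f = float(np.inf)
        p = 0.0
    else:
        f = float(ss_between / 1.0 / (best_w / df[1]))
        p = float(sps.f.sf(f, *df))
    return ClusterResult(
        labels=labels,
        center_high=c_hi,
        center_low=c_lo,
        size_high=n - j,
        size_low=j,
        f_stat=f,
        df=df,
        p=p,
    )


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (multivariate + GG-corrected univariate)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    """One tested effect, mirroring an ANOVA summary row."""

    effect: str
    test: str  # "multivariate" | "within" | "between"
    F: float
    df1: float
    df2: float
    p: float
    eta_p2: float
    pillai: float | None = None
    gg_epsilon: float | None = None
    md: float | None = None
    se: float | None = None


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal difference (Helmert) contrasts."""
    M = np.zeros((k, k - 1))
    for j in range(k - 1):
        M[: j + 1, j] = 1.0
        M[j + 1, j] = -(j + 1.0)
        M[:, j] /= np.linalg.norm(M[:, j])
    return M


def pillai_trace_test(H: np.ndarray, E: np.ndarray, q: int, df_e: int):
    """Pillai's trace and its F approximation for hypothesis/error SSCP.

    ``q`` is the hypothesis df (rank of L), ``df_e`` the error df; the
    number of response variables is inferred from H.
    """
    p = H.shape[0]
    V = float(np.trace(H @ np.linalg.pinv(H + E)))
    V = max(V, 0.0)
    s = min(p, q)
    m = (abs(p - q) - 1.0) / 2.0
    nn = (df_e - p - 1.0) / 2.0
    df1 = s * (2.0 * m + s + 1.0)
    df2 = s * (2.0 * nn + s + 1.0)
    denom = s - V
    F = (df2 / df1) * (V / denom) if denom > 1e-12 else float(np.inf)
    pval = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return V, float(F), float(df1), float(df2), pval, V / s


def _effect_code(levels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (effect) coding; last sorted level is the reference."""
    cats = sorted(levels.unique())
    if len(cats) < 2:
        raise InvalidParameterError(f"factor has a single level: {cats}")
    cols = []
    names = []
    for c in cats[:-1]:
        x = np.where(levels == c, 1.0, 0.0) - np.where(levels == cats[-1], 1.0, 0.0)
        cols.append(x)
        names.append(str(c))
    return np.column_stack(cols), names


@dataclass
class RMAnovaResult:
    """Fitted repeated-measures model with its test table."""

    results: list[ContrastResult]
    dv: str
    phase_order: tuple[str, ...]
    subjects: pd.Index
    Y: np.ndarray  # n x k wide responses
    X: np.ndarray  # between design
    term_columns: dict[str, list[int]]
    df_error: int
    covariate_means: dict[str, float]
    gg_epsilon: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": r.effect,
                    "test": r.test,
                    "F": r.F,
                    "df1": r.df1,
                    "df2": r.df2,
                    "p": r.p,
                    "eta_p2": r.eta_p2,
                    "md": r.md,
                    "se": r.se,
                }
                for r in self.results
            ]
        )


def _build_design(
    meta: pd.DataFrame,
    between: tuple[str, ...],
    covariates: tuple[str, ...],
    factor_interactions: bool = True,
) -> tuple[np.ndarray, dict[str, list[int]], dict[str, float]]:
    n = len(meta)
    cols: list[np.ndarray] = [np.ones(n)]
    term_columns: dict[str, list[int]] = {"intercept": [0]}
    factor_codes: dict[str, np.ndarray] = {}
    next_col = 1
    for f in between:
        code, _ = _effect_code(meta[f])
        factor_codes[f] = code
        term_columns[f] = list(range(next_col, next_col + code.shape[1]))
        cols.append(code)
        next_col += code.shape[1]
    # full factorial: all interactions among between factors
    for r in range(2, (len(between) + 1) if factor_interactions else 2):
        for combo in itertools.combinations(between, r):
            inter = factor_codes[combo[0]]
            for f in combo[1:]:
                inter = np.einsum("ij,ik->ijk", inter, factor_codes[f]).reshape(n, -1)
            name = ":".join(combo)
            term_columns[name] = list(range(next_col, next_col + inter.shape[1]))
            cols.append(inter)
            next_col += inter.shape[1]
    cov_means: dict[str, float] = {}
    for c in covariates:
        x = meta[c].to_numpy(dtype=float)
        cov_means[c] = float(np.mean(x))
        cols.append((x - cov_means[c])[:, None])
        term_columns[c] = [next_col]
        next_col += 1
    X = np.hstack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name an aliased term: prefer interactions/covariates over main terms
        for term, idx in reversed(list(term_columns.items())):
            if term == "intercept":
                continue
            sub = X[:, [i for i in range(X.shape[1]) if i not in idx]]
            if np.linalg.matrix_rank(sub) == rank:
                raise InvalidParameterError(f"singular design: term {term!r} is aliased")
        raise InvalidParameterError("singular between-subject design")
    return X, term_columns, cov_means


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    within: str = "phase",
    between: tuple[str, ...] = (),
    covariates: tuple[str, ...] = (),
    phase_order: tuple[str, ...] = PHASES,
    factor_interactions: bool = True,
) -> RMAnovaResult:
    """Repeated-measures ANOVA of ``dv`` across the within factor.

    ``data`` is tidy (one row per subject x phase) and must carry the
    between factors and covariates (constant within subject).  Subjects with
    incomplete phase data are dropped.  Tests reported per term: Pillai's
    trace multivariate, GG-corrected univariate (within), and the
    between-subjects F on subject means.
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="first")
    missing = [p for p in phase_order if p not in wide.columns]
    if missing:
        raise InvalidParameterError(f"within levels absent from data: {missing}")
    wide = wide[list(phase_order)].dropna()
    if len(wide) < 3:
        raise TooShortError("need >= 3 complete subjects")
    meta = (
        data.drop_duplicates(subset=subject)
        .set_index(subject)
        .loc[wide.index, list(between) + list(covariates)]
        if (between or covariates)
        else pd.DataFrame(index=wide.index)
    )
    X, term_columns, cov_means = _build_design(
        meta, tuple(between), tuple(covariates), factor_interactions
    )
    n, k = wide.shape
    Y = wide.to_numpy(dtype=float)
    M = _orthonormal_contrasts(k)
    U = Y @ M
    # snap numerically-zero contrast scores (dv constant within subject) to 0
    y_scale = float(np.sqrt(np.trace(Y.T @ Y))) or 1.0
    if float(np.sqrt(np.trace(U.T @ U))) < 1e-12 * y_scale:
        U = np.zeros_like(U)

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ X.T @ U
    resid = U - X @ B
    E = resid.T @ resid
    df_e = n - X.shape[1]
    if df_e < 1:
        raise InvalidParameterError("no residual degrees of freedom")

    # Greenhouse-Geisser epsilon from the contrast-transformed covariance
    S = E / df_e
    tr_s2 = float(np.trace(S @ S))
    eps = float(np.trace(S) ** 2 / ((k - 1) * tr_s2)) if tr_s2 > 0 else 1.0

    results: list[ContrastResult] = []
    for term, idx in term_columns.items():
        L = np.zeros((len(idx), X.shape[1]))
        for r, c in enumerate(idx):
            L[r, c] = 1.0
        q = len(idx)
        LB = L @ B
        H = LB.T @ np.linalg.inv(L @ XtX_inv @ L.T) @ LB
        effect = within if term == "intercept" else f"{within}:{term}"
        V, F, df1, df2, pval, eta_mv = pillai_trace_test(H, E, q, df_e)
        results.append(
            ContrastResult(
                effect=effect,
                test="multivariate",
                F=F,
                df1=df1,
                df2=df2,
                p=pval,
                eta_p2=eta_mv,
                pillai=V,
            )
        )
        # averaged (univariate) within-subject test with GG correction
        ssh, sse = float(np.trace(H)), float(np.trace(E))
        df1u, df2u = q * (k - 1.0), df_e * (k - 1.0)
        if sse > 0:
            Fu = (ssh / df1u) / (sse / df2u)
        else:
            Fu = 0.0 if ssh == 0 else float(np.inf)
        pu = float(sps.f.sf(Fu, df1u * eps, df2u * eps))
        results.append(
            ContrastResult(
                effect=effect,
                test="within",
                F=Fu,
                df1=df1u,
                df2=df2u,
                p=pu,
                eta_p2=ssh / (ssh + sse) if ssh + sse > 0 else 0.0,
                gg_epsilon=eps,
            )
        )

    # between-subject tests on subject means
    ybar = Y.mean(axis=1)
    b = XtX_inv @ X.T @ ybar
    res_b = ybar - X @ b
    sse_b = float(res_b @ res_b)
    for term, idx in term_columns.items():
        if term == "intercept":
            continue
        L = np.zeros((len(idx), X.shape[1]))
        for r, c in enumerate(idx):
            L[r, c] = 1.0
        q = len(idx)
        Lb = L @ b
        ssh = float(Lb.T @ np.linalg.inv(L @ XtX_inv @ L.T) @ Lb)
        F = (ssh / q) / (sse_b / df_e) if sse_b > 0 else float(np.inf)
        pval = float(sps.f.sf(F, q, df_e))
        results.append(
            ContrastResult(
                effect=term,
                test="between",
                F=F,
                df1=float(q),
                df2=float(df_e),
                p=pval,
                eta_p2=ssh / (ssh + sse_b) if ssh + sse_b > 0 else 0.0,
            )
        )

    return RMAnovaResult(
        results=results,
        dv=dv,
        phase_order=tuple(phase_order),
        subjects=wide.index,
        Y=Y,
        X=X,
        term_columns=term_columns,
        df_error=df_e,
        covariate_means=cov_means,
        gg_epsilon=eps,
    )


def adjusted_pairwise_contrasts(
    model: RMAnovaResult, effect: str = "phase", adjust: str = "bonferroni"
) -> tuple[pd.Series, pd.DataFrame]:
    """Estimated marginal means and pairwise within-factor contrasts.

    EMMs are the model intercepts of each phase column regressed on the
    between design: with effect-coded factors and centered covariates this
    evaluates each phase at the covariate means with balanced factor
    weights.  Pairwise mean differences come from the same regression on the
    difference scores, so each MD equals the difference of the two adjusted
    means exactly; p values are Bonferroni-multiplied.
    """
    if effect != "phase" and effect not in model.term_columns:
        raise InvalidParameterError(f"effect {effect!r} not in the fitted model")
    X = model.X
    XtX_inv = np.linalg.inv(X.T @ X)
    hat = XtX_inv @ X.T
    df_e = model.df_error

    emm = {}
    for j, phase in enumerate(model.phase_order):
        emm[phase] = float((hat @ model.Y[:, j])[0])
    emm_s = pd.Series(emm, name="emmean")

    pairs = list(itertools.combinations(range(len(model.phase_order)), 2))
    n_tests = len(pairs)
    rows = []
    for i, j in pairs:
        d = model.Y[:, i] - model.Y[:, j]
        beta = hat @ d
        resid = d - X @ beta
        sigma2 = float(resid @ resid) / df_e
        se = float(np.sqrt(sigma2 * XtX_inv[0, 0]))
        md = float(beta[0])
        if se > 0:
            t = md / se
            p = 2.0 * sps.t.sf(abs(t), df_e)
        else:
            t, p = (0.0, 1.0) if md == 0 else (float(np.inf), 0.0)
        p_adj = min(1.0, p * n_tests) if adjust == "bonferroni" else p
        rows.append(
            {
                "a": model.phase_order[i],
                "b": model.phase_order[j],
                "md": md,
                "se": se,
                "t": t,
                "df": df_e,
                "p_adj": float(p_adj),
            }
        )
    return emm_s, pd.DataFrame(rows)
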