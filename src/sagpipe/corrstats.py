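"""Correlation-matrix statistics for co-expression cluster testing.

Given a candidate gene module (for instance the members of a complex
sense-antisense architecture), the questions asked here are:

1. Is the module's correlation matrix R significantly different from the
   identity, i.e. do the genes co-express at all?  Tested with Bartlett's
   sphericity statistic ``T = -(N - 1 - (2p+5)/6) * ln|R|``, compared both
   against its asymptotic chi-square(p(p-1)/2) distribution and against an
   empirical null built by drawing windows of *p* consecutive genes (in
   genomic order) from a large expression pool — the bootstrap Bartlett
   test.  The empirical null matters because physically neighbouring genes
   share chromatin domains and are not independent, so the analytic null
   is optimistic for a "does this local cluster stand out" question.

2. Is the module's correlation structure different from that of its
   genomic neighbours, or between tumour grades?  Tested with Box's M on
   per-group standardized data (so covariance equals correlation), with
   the chi-square approximation; matrices of unequal dimension are
   compared by averaging over all order-preserving sub-signatures of the
   larger group.

Pearson is used on large cohorts after a Kolmogorov-Smirnov/Lilliefors
normality screen; Kendall's tau-b on small samples (e.g. cell-line panels).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .datamodel import ClinicalTable, ExpressionMatrix

__all__ = [
    "CorrMatrixResult",
    "NormalityReport",
    "BartlettResult",
    "BoxMResult",
    "pearson_matrix",
    "kendall_matrix",
    "normality_screen",
    "bartlett_statistic",
    "bootstrap_bartlett",
    "BartlettClusterTest",
    "box_m",
    "box_m_unequal",
    "grade_stratified_matrices",
]

DEFAULT_ALPHA = 0.01  # correlation-level significance used throughout
DEFAULT_B = 5000      # bootstrap draws for the empirical Bartlett null


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

@dataclass
class CorrMatrixResult:
    """A gene-by-gene correlation matrix with a significance mask."""

    gene_order: list
    R: pd.DataFrame
    method: str
    n_samples: int
    alpha: float
    p_values: pd.DataFrame
    sig_mask: pd.DataFrame

    def masked(self) -> pd.DataFrame:
        """Matrix with non-significant off-diagonal entries blanked (NaN)."""
        out = self.R.where(self.sig_mask)
        np.fill_diagonal(out.values, 1.0)
        return out

    def significant_offdiag_fraction(self) -> float:
        mask = self.sig_mask.to_numpy()
        p = mask.shape[0]
        off = ~np.eye(p, dtype=bool)
        return float(mask[off].mean()) if p > 1 else float("nan")

    def summary(self) -> str:
        lines = [
            f"{self.method} correlation matrix, p={len(self.gene_order)}, "
            f"n={self.n_samples}, alpha={self.alpha:g}",
            self.masked().round(3).to_string(),
        ]
        return "\n".join(lines)


def _extract(expr: ExpressionMatrix, probes) -> tuple[np.ndarray, list]:
    probes = list(probes) if probes is not None else expr.probe_ids
    sub = expr.subset(probes)
    X = sub.values.T  # samples x probes
    for j, p in enumerate(probes):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant probe {p!r}: correlation undefined")
    return X, probes


def pearson_matrix(
    expr: ExpressionMatrix, probes=None, alpha: float = DEFAULT_ALPHA
) -> CorrMatrixResult:
    """Pearson product-moment correlations among probes, with a two-sided
    t-test significance mask at level ``alpha``."""
    X, probes = _extract(expr, probes)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for Pearson correlation")
    R = np.corrcoef(X, rowvar=False)
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - R * R))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(pvals, 0.0)
    return _wrap_corr(R, pvals, probes, "pearson", n, alpha)


def kendall_matrix(
    expr: ExpressionMatrix, probes=None, alpha: float = DEFAULT_ALPHA
) -> CorrMatrixResult:
    """Kendall tau-b correlations (tie-corrected) with significance mask."""
    X, probes = _extract(expr, probes)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for Kendall correlation")
    p = len(probes)
    R = np.eye(p)
    pvals = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            tau, pv = stats.kendalltau(X[:, i], X[:, j])
            R[i, j] = R[j, i] = tau
            pvals[i, j] = pvals[j, i] = pv
    return _wrap_corr(R, pvals, probes, "kendall", n, alpha)


def _wrap_corr(R, pvals, probes, method, n, alpha) -> CorrMatrixResult:
    Rdf = pd.DataFrame(R, index=probes, columns=probes)
    pdf = pd.DataFrame(pvals, index=probes, columns=probes)
    sig = pdf < alpha
    np.fill_diagonal(sig.values, True)
    return CorrMatrixResult(
        gene_order=list(probes), R=Rdf, method=method, n_samples=n,
        alpha=alpha, p_values=pdf, sig_mask=sig,
    )


# ---------------------------------------------------------------------------
# normality screen
# ---------------------------------------------------------------------------

@dataclass
class NormalityReport:
    """Per-probe Kolmogorov-Smirnov/Lilliefors normality screen."""

    table: pd.DataFrame  # columns: statistic, p_value, passes
    alpha: float

    @property
    def all_pass(self) -> bool:
        return bool(self.table["passes"].all())

    def summary(self) -> str:
        return (
            f"Lilliefors normality screen at alpha={self.alpha:g} "
            f"({int(self.table['passes'].sum())}/{len(self.table)} pass)\n"
            + self.table.to_string()
        )


def normality_screen(
    expr: ExpressionMatrix, probes=None, alpha: float = DEFAULT_ALPHA
) -> NormalityReport:
    """Kolmogorov-Smirnov test for normality with Lilliefors-corrected P
    values (mean and variance estimated from the data), per probe."""
    X, probes = _extract(expr, probes)
    if X.shape[0] < 5:
        raise ValueError("need at least 5 samples per probe for the screen")
    rows = []
    for j, probe in enumerate(probes):
        stat, pval = lilliefors(X[:, j], dist="norm", pvalmethod="table")
        rows.append((probe, stat, pval, pval > alpha))
    table = pd.DataFrame(
        rows, columns=["probe", "statistic", "p_value", "passes"]
    ).set_index("probe")
    return NormalityReport(table=table, alpha=alpha)


# ---------------------------------------------------------------------------
# Bartlett sphericity: analytic and bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BartlettResult:
    """Bartlett sphericity test of a correlation matrix, with optional
    genomic-window bootstrap null."""

    T: float
    df: int
    p_analytic: float
    N: int
    p: int
    p_boot: float | None = None
    B: int | None = None
    n_redraws: int = 0
    boot_stats: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Bartlett test of sphericity (H0: R = I)",
            f"  T = {self.T:.4f}  df = {self.df}  N = {self.N}  p = {self.p}",
            f"  analytic P (chi-square upper tail) = {self.p_analytic:.3e}",
        ]
        if self.p_boot is not None:
            lines.append(
                f"  bootstrap P ({self.B} neighbouring-gene draws) = "
                f"{self.p_boot:.4g}"
            )
        return "\n".join(lines)


def bartlett_statistic(R: np.ndarray, N: int) -> tuple[float, int, float]:
    """Bartlett sphericity statistic for a correlation matrix.

    ``T = -(N - 1 - (2p + 5) / 6) * ln|R|`` is asymptotically
    chi-square with ``p(p-1)/2`` degrees of freedom under H0: R = I.

    Returns ``(T, df, p_analytic)``; raises on a singular or invalid R.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular or non-positive-definite correlation matrix")
    T = -(N - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    p_analytic = float(stats.chi2.sf(T, df))
    return float(T), df, p_analytic


def bootstrap_bartlett(
    target_probes,
    expr_pool: ExpressionMatrix,
    B: int = DEFAULT_B,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> BartlettResult:
    """Bartlett test of a target module against a neighbouring-gene null.

    The target statistic T is computed on the Pearson correlation matrix of
    ``target_probes``.  The null distribution is built by drawing ``B``
    windows of p consecutive probes from ``expr_pool`` — whose row order is
    taken to be genomic order — excluding windows that intersect the
    target probes, and computing the statistic on each.  The bootstrap P
    value is the fraction of null statistics at least as large as T
    (resolution 1/B).  Singular draws are redrawn, up to ``10 * B``
    attempts in total.
    """
    target_probes = list(target_probes)
    p = len(target_probes)
    if p < 2:
        raise ValueError("need at least 2 target probes")
    pool = expr_pool.data
    n_pool, N = pool.shape
    missing = [pr for pr in target_probes if pr not in pool.index]
    if missing:
        raise KeyError(f"target probes not present in the pool: {missing}")
    target_idx = {pool.index.get_loc(pr) for pr in target_probes}
    starts = [
        s for s in range(n_pool - p + 1)
        if not any(s <= t < s + p for t in target_idx)
    ]
    if len(starts) < 2:
        raise ValueError("expression pool too small for bootstrap windows")

    R = np.corrcoef(expr_pool.subset(target_probes).values)
    T, df, p_analytic = bartlett_statistic(R, N)

    rng = np.random.default_rng(seed)
    X = pool.to_numpy()
    boot = np.empty(B)
    attempts = 0
    got = 0
    redraws = 0
    max_attempts = 10 * B
    while got < B:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"exceeded {max_attempts} bootstrap attempts "
                f"({redraws} singular redraws)"
            )
        s = starts[rng.integers(len(starts))]
        attempts += 1
        Rb = np.corrcoef(X[s:s + p])
        sign, logdet = np.linalg.slogdet(Rb)
        if sign <= 0 or not np.isfinite(logdet):
            redraws += 1
            continue
        boot[got] = -(N - 1 - (2 * p + 5) / 6.0) * logdet
        got += 1
    p_boot = float(np.mean(boot >= T))
    return BartlettResult(
        T=T, df=df, p_analytic=p_analytic, N=N, p=p,
        p_boot=p_boot, B=B, n_redraws=redraws, boot_stats=boot,
    )


class BartlettClusterTest:
    """Model-style wrapper: does a gene set form a co-expression cluster?

    Parameters
    ----------
    expr_pool : ExpressionMatrix
        Full expression matrix in genomic row order (serves as both the
        source of the target data and the bootstrap pool).
    target_probes : sequence
        Probes of the candidate module.

    ``fit()`` returns a :class:`BartlettResult` with both the analytic
    chi-square P value and the genomic-window bootstrap P value.
    """

    def __init__(self, expr_pool: ExpressionMatrix, target_probes):
        self.expr_pool = expr_pool
        self.target_probes = list(target_probes)

    def fit(self, B: int = DEFAULT_B, seed: int | None = None) -> BartlettResult:
        return bootstrap_bartlett(
            self.target_probes, self.expr_pool, B=B, seed=seed
        )


# ---------------------------------------------------------------------------
# Box's M
# ---------------------------------------------------------------------------

@dataclass
class BoxMResult:
    """Box's M test for equality of two covariance/correlation structures."""

    M: float
    chi2: float
    df: int
    p_chi2: float
    v1: int
    v2: int
    dim: int
    n_subcomparisons: int = 1
    p_averaged: float | None = None
    sub_p_values: list | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Box's M test (H0: equal correlation structure)",
            f"  M = {self.M:.4f}  chi2 = {self.chi2:.4f}  df = {self.df}  "
            f"P = {self.p_chi2:.3e}",
            f"  group dof v1 = {self.v1}, v2 = {self.v2}, dimension = {self.dim}",
        ]
        if self.n_subcomparisons > 1:
            lines.append(
                f"  averaged over {self.n_subcomparisons} sub-signatures: "
                f"mean P = {self.p_averaged:.3e}"
            )
        return "\n".join(lines)


def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant variable: covariance singular")
    return (X - X.mean(axis=0)) / sd


def box_m(data_1: np.ndarray, data_2: np.ndarray, standardize: bool = True) -> BoxMResult:
    """Box's M comparison of two groups' covariance matrices.

    Both groups are column-standardized first (mean 0, variance 1) so the
    compared covariance matrices equal the groups' correlation matrices —
    the hypotheses here concern correlation structure, while the M
    statistic itself is defined through variance-covariance determinants:

        M = (v1 + v2) ln|S_pool| - v1 ln|S1| - v2 ln|S2|,
        S_pool = (v1 S1 + v2 S2) / (v1 + v2),  v_i = n_i - 1.

    Significance from Box's chi-square approximation (scale factor
    ``1 - c1``, df ``q(q+1)/2`` for two groups).
    """
    X1 = np.asarray(data_1, dtype=float)
    X2 = np.asarray(data_2, dtype=float)
    if X1.ndim != 2 or X2.ndim != 2 or X1.shape[1] != X2.shape[1]:
        raise ValueError("both groups must be 2-D with equal column count")
    q = X1.shape[1]
    n1, n2 = X1.shape[0], X2.shape[0]
    if n1 <= q or n2 <= q:
        raise ValueError("each group needs more samples than variables")
    if standardize:
        X1, X2 = _standardize(X1), _standardize(X2)
    v1, v2 = n1 - 1, n2 - 1
    S1 = np.cov(X1, rowvar=False)
    S2 = np.cov(X2, rowvar=False)
    S_pool = (v1 * S1 + v2 * S2) / (v1 + v2)
    dets = []
    for S in (S1, S2, S_pool):
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0 or not np.isfinite(logdet):
            raise ValueError("singular covariance matrix in Box's M")
        dets.append(logdet)
    ld1, ld2, ldp = dets
    M = (v1 + v2) * ldp - v1 * ld1 - v2 * ld2
    M = max(M, 0.0)
    # Box's chi-square approximation, k = 2 groups
    c1 = (
        (1.0 / v1 + 1.0 / v2 - 1.0 / (v1 + v2))
        * (2 * q * q + 3 * q - 1)
        / (6.0 * (q + 1))
    )
    chi2_stat = M * (1.0 - c1)
    df = q * (q + 1) // 2
    p = float(stats.chi2.sf(chi2_stat, df))
    return BoxMResult(
        M=float(M), chi2=float(chi2_stat), df=df, p_chi2=p,
        v1=v1, v2=v2, dim=q,
    )


def box_m_unequal(
    data_module: np.ndarray, data_neighbours: np.ndarray,
    standardize: bool = True,
) -> BoxMResult:
    """Box's M between groups measured on unequal numbers of variables.

    The module has p variables, the neighbour group q >= p.  Every
    order-preserving choice of p of the q neighbour variables (C(q, p)
    sub-signatures) is compared with the module by :func:`box_m`, and the
    P values are averaged arithmetically.  The returned statistic fields
    (M, chi2, p_chi2) are those of the first sub-comparison; use
    ``p_averaged`` for inference.
    """
    Xm = np.asarray(data_module, dtype=float)
    Xn = np.asarray(data_neighbours, dtype=float)
    p = Xm.shape[1]
    q = Xn.shape[1]
    if q < p:
        raise ValueError("neighbour group must have at least as many variables")
    results = []
    for cols in itertools.combinations(range(q), p):
        results.append(box_m(Xm, Xn[:, list(cols)], standardize=standardize))
    sub_p = [r.p_chi2 for r in results]
    first = results[0]
    return BoxMResult(
        M=first.M, chi2=first.chi2, df=first.df, p_chi2=first.p_chi2,
        v1=first.v1, v2=first.v2, dim=p,
        n_subcomparisons=len(results),
        p_averaged=float(np.mean(sub_p)),
        sub_p_values=sub_p,
    )


# ---------------------------------------------------------------------------
# grade stratification
# ---------------------------------------------------------------------------

def grade_stratified_matrices(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    probes=None,
    method: str = "pearson",
    alpha: float = DEFAULT_ALPHA,
    min_extra: int = 2,
) -> dict:
    """One correlation matrix per tumour grade plus the pooled total group.

    Strata with fewer than ``p + min_extra`` samples are skipped with a
    warning entry (value ``None``).  The pooled matrix is keyed
    ``"Total group"``.
    """
    import warnings

    probes = list(probes) if probes is not None else expr.probe_ids
    corr = pearson_matrix if method == "pearson" else kendall_matrix
    shared = [s for s in expr.sample_ids if s in clinical.data.index]
    if not shared:
        raise ValueError("expression and clinical tables share no samples")
    expr = expr.subset_samples(shared)
    clinical = clinical.subset(shared)
    out: dict = {}
    p = len(probes)
    for grade, grp in clinical.data.groupby("grade", sort=True, observed=True):
        samples = list(grp.index)
        if len(samples) < p + min_extra:
            warnings.warn(
                f"grade {grade!r}: only {len(samples)} samples for p={p}; skipped"
            )
            out[str(grade)] = None
            continue
        out[str(grade)] = corr(expr.subset_samples(samples), probes, alpha)
    out["Total group"] = corr(expr, probes, alpha)
    return out
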