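"""Data-driven grouping (DDg) survival analysis for genes and gene pairs.

One-dimensional DDg dichotomizes patients on a single gene's log-intensity
at the cut-off ``c`` that maximizes the separation of the two Kaplan-Meier
curves, measured by the two-sample log-rank statistic; the resulting
low/high-risk grouping is then fitted with a univariate Cox proportional
hazards model and judged by the Wald P value of the group coefficient.

Two-dimensional DDg takes a gene pair (i, j) with their individual 1D
cut-offs, splits the expression plane into quadrants

    A: y_i <  c_i and y_j <  c_j      B: y_i >= c_i and y_j <  c_j
    C: y_i <  c_i and y_j >= c_j      D: y_i >= c_i and y_j >= c_j

and evaluates the seven non-trivial two-group designs over {A, B, C, D}:
five "synergistic" partitions ({A}, {B}, {C}, {D}, {A,D} against the rest)
and two "independent" ones ({A,C} vs {B,D} and {A,B} vs {C,D}) which
reproduce the single-gene splits.  The best design is the one with the
smallest Cox Wald P.  A pair is flagged *synergistic* when its best P is
more than ten times smaller than both individual gene P values.

The Cox model is fitted by Newton iteration on the binary-covariate
partial likelihood with the Breslow convention for tied event times.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ClinicalTable, ExpressionMatrix

__all__ = [
    "CutoffResult",
    "CoxFitResult",
    "DesignPartition",
    "PairSurvivalResult",
    "FdrResult",
    "logrank_scan",
    "find_cutoff_1d",
    "cox_fit_binary",
    "enumerate_designs",
    "pair_survival_2d",
    "fdr_bh",
    "screen_genes_and_pairs",
    "intersect_pair_screens",
    "DataDrivenGrouping",
    "PairedDataDrivenGrouping",
]

QUADRANTS = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class CutoffResult:
    """Optimal 1D expression cut-off and the grouping it induces."""

    probe_id: str
    cutoff: float
    group_labels: np.ndarray  # 1 = high (y >= cutoff), aligned with samples
    separation_stat: float    # two-sample log-rank chi-square
    n_low: int
    n_high: int
    events_low: int
    events_high: int
    n_candidates: int = 0
    # realized range of the low-group fraction over admissible candidates
    # (needed by the maximally-selected-statistic correction)
    eps_low: float = 0.1
    eps_high: float = 0.9


@dataclass
class CoxFitResult:
    """Univariate Cox fit of a binary grouping (Breslow ties)."""

    beta: float
    se_beta: float
    wald_z: float
    wald_p: float
    loglik_at_beta: float
    n: int
    n_events: int
    n_iter: int = 0

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.beta))

    def summary(self) -> str:
        return (
            f"Cox PH (binary group, Breslow): beta = {self.beta:.4f} "
            f"(HR = {self.hazard_ratio:.3f}), se = {self.se_beta:.4f}, "
            f"z = {self.wald_z:.3f}, Wald P = {self.wald_p:.3e}, "
            f"n = {self.n}, events = {self.n_events}"
        )


@dataclass(frozen=True)
class DesignPartition:
    """One of the seven two-group designs over quadrants A-D."""

    design_id: int
    side_one: frozenset
    kind: str  # "synergistic" | "independent"

    @property
    def side_two(self) -> frozenset:
        return frozenset(QUADRANTS) - self.side_one

    def label(self) -> str:
        one = "".join(sorted(self.side_one))
        two = "".join(sorted(self.side_two))
        return f"{{{one}}}|{{{two}}}"


@dataclass
class PairSurvivalResult:
    """2D DDg outcome for one gene pair."""

    probe_i: str
    probe_j: str
    cutoff_i: float
    cutoff_j: float
    best_design: DesignPartition
    cox: CoxFitResult
    p_pair: float
    p_i: float
    p_j: float
    synergy: bool
    design_p_values: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"2D DDg pair ({self.probe_i}, {self.probe_j}): best design "
            f"{self.best_design.design_id} {self.best_design.label()} "
            f"({self.best_design.kind}), pair P = {self.p_pair:.3e}, "
            f"individual P = ({self.p_i:.3e}, {self.p_j:.3e}), "
            f"synergy = {self.synergy}"
        )


@dataclass
class FdrResult:
    """Benjamini-Hochberg step-up FDR correction outcome."""

    raw_p: np.ndarray
    significant: np.ndarray
    threshold: float  # largest raw P called significant (0 if none)
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


# ---------------------------------------------------------------------------
# log-rank machinery
# ---------------------------------------------------------------------------

def _time_order(time: np.ndarray, event: np.ndarray):
    """Sort by time ascending; return order, block starts of distinct times
    and per-block event counts."""
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    block_starts = np.flatnonzero(np.r_[True, np.diff(t_sorted) != 0])
    return order, t_sorted, block_starts


def logrank_scan(
    groups: np.ndarray, time: np.ndarray, event: np.ndarray
) -> np.ndarray:
    """Two-sample log-rank chi-square for many candidate groupings at once.

    ``groups`` is (n_candidates, K) boolean/0-1 (1 = group "high"); returns
    the chi-square statistic per candidate.  Candidates with zero log-rank
    variance (e.g. a degenerate grouping) get statistic 0.
    """
    groups = np.atleast_2d(np.asarray(groups, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    order, _t, block_starts = _time_order(time, event)
    Z = groups[:, order]                     # candidates x samples (by time)
    e_sorted = event[order]
    K = len(time)
    # suffix sums: group-1 members still at risk entering each index
    S1 = np.cumsum(Z[:, ::-1], axis=1)[:, ::-1]
    d_block = np.add.reduceat(e_sorted, block_starts)          # events per time
    d1_block = np.add.reduceat(Z * e_sorted, block_starts, axis=1)
    keep = d_block > 0
    bs = block_starts[keep]
    dj = d_block[keep]
    d1j = d1_block[:, keep]
    nj = (K - bs).astype(float)
    n1j = S1[:, bs]
    frac = n1j / nj
    O1 = d1j.sum(axis=1)
    E1 = (dj * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vterm = dj * frac * (1.0 - frac) * (nj - dj) / np.maximum(nj - 1.0, 1.0)
    vterm = np.where(nj > 1, vterm, 0.0)
    V = vterm.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, (O1 - E1) ** 2 / V, 0.0)
    return chi2


def _align(clinical: ClinicalTable, sample_ids) -> ClinicalTable:
    return clinical.subset(list(sample_ids))


def find_cutoff_1d(
    expr_row: np.ndarray,
    clinical: ClinicalTable,
    min_frac: float = 0.10,
    min_events: int = 3,
    probe_id: str = "",
) -> CutoffResult:
    """Optimal dichotomizing cut-off for one gene's expression.

    Candidate cut-offs are the midpoints between consecutive distinct
    expression values.  A candidate is admissible when each side keeps at
    least ``min_frac`` of the patients and at least ``min_events`` events.
    Among admissible candidates the two-sample log-rank statistic is
    maximized; exact ties are broken toward the cut-off closest to the
    median expression.  Raises ``ValueError`` when no candidate is
    admissible (e.g. constant expression).
    """
    y = np.asarray(expr_row, dtype=float)
    time = clinical.dfs_time
    event = clinical.dfs_event
    K = len(y)
    if K != len(time):
        raise ValueError("expression row and clinical table lengths differ")
    distinct = np.unique(y)
    if distinct.size < 2:
        raise ValueError(f"probe {probe_id or '<row>'}: constant expression, "
                         "no admissible cut-off")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    high = y[None, :] >= candidates[:, None]        # candidates x K
    n_high = high.sum(axis=1)
    n_low = K - n_high
    ev_high = (high * event[None, :]).sum(axis=1)
    ev_low = event.sum() - ev_high
    min_n = max(int(np.ceil(min_frac * K)), 1)
    admissible = (
        (n_high >= min_n) & (n_low >= min_n)
        & (ev_high >= min_events) & (ev_low >= min_events)
    )
    if not admissible.any():
        raise ValueError(
            f"probe {probe_id or '<row>'}: no admissible cut-off "
            f"(min {min_n} patients and {min_events} events per side)"
        )
    cand = candidates[admissible]
    chi2 = logrank_scan(high[admissible], time, event)
    best = chi2.max()
    tied = np.flatnonzero(chi2 >= best - 1e-12 * max(best, 1.0))
    med = np.median(y)
    pick = tied[np.argmin(np.abs(cand[tied] - med))]
    c = float(cand[pick])
    labels = (y >= c).astype(int)
    frac_low = n_low[admissible] / K
    return CutoffResult(
        probe_id=probe_id,
        cutoff=c,
        group_labels=labels,
        separation_stat=float(chi2[pick]),
        n_low=int((labels == 0).sum()),
        n_high=int((labels == 1).sum()),
        events_low=int(event[labels == 0].sum()),
        events_high=int(event[labels == 1].sum()),
        n_candidates=int(admissible.sum()),
        eps_low=float(frac_low.min()),
        eps_high=float(frac_low.max()),
    )


def maxstat_corrected_p(chi2_max: float, eps_low: float, eps_high: float) -> float:
    """Selection-bias-corrected P value for a maximally selected log-rank
    statistic.

    Scanning the cut-off inflates the nominal P of the best split: the
    statistic is the supremum of an (approximate) standardized Brownian
    bridge over the candidate quantile range.  This applies the improved
    Bonferroni bound of Miller & Siegmund for that supremum,

        P(M >= b) ~ 4 phi(b)/b
                    + phi(b) (b - 1/b) log[ e2 (1-e1) / (e1 (1-e2)) ],

    with ``b = sqrt(chi2_max)`` and ``(e1, e2)`` the realized range of the
    low-group fraction over admissible cut-offs.  The result is clipped to
    [pointwise two-sided P, 1]; a degenerate scan range collapses to the
    pointwise P.
    """
    if not 0 < eps_low <= eps_high < 1:
        raise ValueError("quantile bounds must satisfy 0 < e1 <= e2 < 1")
    b = math.sqrt(max(chi2_max, 0.0))
    pointwise = float(2.0 * stats.norm.sf(b))
    if b < 1e-8:
        return 1.0
    if eps_low == eps_high:
        return pointwise
    phi = stats.norm.pdf(b)
    span = math.log((eps_high * (1 - eps_low)) / (eps_low * (1 - eps_high)))
    approx = 4.0 * phi / b + phi * (b - 1.0 / b) * span
    return float(min(1.0, max(approx, pointwise)))


# ---------------------------------------------------------------------------
# Cox partial likelihood for a binary covariate (Breslow ties)
# ---------------------------------------------------------------------------

def _cox_sufficient(x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Per-distinct-event-time sufficient statistics (d, s, n1, n0)."""
    order = np.argsort(time, kind="stable")
    t_s, x_s, e_s = time[order], x[order].astype(float), event[order].astype(float)
    block_starts = np.flatnonzero(np.r_[True, np.diff(t_s) != 0])
    K = len(t_s)
    suffix_x = np.cumsum(x_s[::-1])[::-1]
    d = np.add.reduceat(e_s, block_starts)
    s = np.add.reduceat(x_s * e_s, block_starts)
    n_at_risk = (K - block_starts).astype(float)
    n1 = suffix_x[block_starts]
    keep = d > 0
    return d[keep], s[keep], n1[keep], n_at_risk[keep] - n1[keep]


def cox_loglik_binary(
    beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow partial log-likelihood of a binary covariate at ``beta``."""
    d, s, n1, n0 = _cox_sufficient(
        np.asarray(x, float), np.asarray(time, float), np.asarray(event, float)
    )
    eb = np.exp(beta)
    return float(np.sum(beta * s - d * np.log(n0 + n1 * eb)))


class CoxConvergenceError(RuntimeError):
    pass


def cox_fit_binary(
    groups: np.ndarray, clinical: ClinicalTable, max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxFitResult:
    """Fit the univariate Cox model for a binary grouping by Newton iteration.

    ``groups`` holds 0/1 labels aligned with the clinical table.  The
    partial likelihood uses the Breslow convention for tied event times;
    the Wald P value is the two-sided normal tail of beta / se(beta).
    Raises if either group has no event or the likelihood is monotone
    (group perfectly separates the events).
    """
    x = np.asarray(groups, dtype=float)
    if not np.isin(x, [0, 1]).all():
        raise ValueError("groups must be binary 0/1")
    time = clinical.dfs_time
    event = clinical.dfs_event
    if len(x) != len(time):
        raise ValueError("groups and clinical table lengths differ")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events at all: Cox model undefined")
    for g in (0, 1):
        if event[x == g].sum() == 0:
            raise ValueError(f"group {g} has no events; Wald test undefined")
    d, s, n1, n0 = _cox_sufficient(x, time.astype(float), event.astype(float))
    beta = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        eb = np.exp(beta)
        denom = n0 + n1 * eb
        mu = n1 * eb / denom
        grad = float(np.sum(s - d * mu))
        hess = float(-np.sum(d * mu * (1.0 - mu)))
        if hess >= -1e-300:
            raise CoxConvergenceError(
                f"degenerate information at beta={beta:.3f}"
            )
        step = -grad / hess
        step = float(np.clip(step, -2.0, 2.0))  # damp early overshoot
        beta += step
        if abs(beta) > 30:
            raise CoxConvergenceError(
                "monotone partial likelihood: a group separates the events "
                f"(beta diverging, iteration {it})"
            )
        if abs(step) < tol:
            break
    else:
        raise CoxConvergenceError(f"Newton did not converge in {max_iter} steps")
    eb = np.exp(beta)
    denom = n0 + n1 * eb
    mu = n1 * eb / denom
    info = float(np.sum(d * mu * (1.0 - mu)))
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    loglik = float(np.sum(beta * s - d * np.log(denom)))
    return CoxFitResult(
        beta=float(beta), se_beta=float(se), wald_z=float(z), wald_p=p,
        loglik_at_beta=loglik, n=len(x), n_events=n_events, n_iter=it,
    )


# ---------------------------------------------------------------------------
# 2D designs
# ---------------------------------------------------------------------------

def enumerate_designs() -> list[DesignPartition]:
    """The seven two-group designs over quadrants {A, B, C, D}.

    Designs 1-5 are synergistic (one quadrant, or the A+D diagonal,
    against the rest); designs 6 and 7 are independent: {A,C}|{B,D}
    reproduces the split by gene i alone and {A,B}|{C,D} the split by
    gene j alone.
    """
    synergistic = [
        frozenset("A"), frozenset("B"), frozenset("C"), frozenset("D"),
        frozenset("AD"),
    ]
    independent = [frozenset("AC"), frozenset("AB")]
    designs = [
        DesignPartition(i + 1, side, "synergistic")
        for i, side in enumerate(synergistic)
    ] + [
        DesignPartition(i + 6, side, "independent")
        for i, side in enumerate(independent)
    ]
    return designs


def assign_quadrants(
    y_i: np.ndarray, y_j: np.ndarray, c_i: float, c_j: float
) -> np.ndarray:
    """Quadrant label per patient from the two cut-offs."""
    hi_i = np.asarray(y_i) >= c_i
    hi_j = np.asarray(y_j) >= c_j
    labels = np.empty(len(hi_i), dtype="<U1")
    labels[~hi_i & ~hi_j] = "A"
    labels[hi_i & ~hi_j] = "B"
    labels[~hi_i & hi_j] = "C"
    labels[hi_i & hi_j] = "D"
    return labels


def pair_survival_2d(
    expr_i: np.ndarray,
    expr_j: np.ndarray,
    clinical: ClinicalTable,
    cutoff_i: float,
    cutoff_j: float,
    min_frac: float = 0.10,
    min_events: int = 3,
    probe_i: str = "i",
    probe_j: str = "j",
    synergy_factor: float = 10.0,
) -> PairSurvivalResult:
    """Evaluate the seven quadrant designs for one gene pair.

    The individual 1D cut-offs are reused, not re-optimized.  Each design
    whose two sides meet the size and event minima is Cox-fitted; the best
    design is the admissible one with the smallest Wald P.  ``p_i`` and
    ``p_j`` are the single-gene Wald Ps at the same cut-offs; the synergy
    flag requires the pair P to beat both by more than ``synergy_factor``.
    """
    y_i = np.asarray(expr_i, float)
    y_j = np.asarray(expr_j, float)
    K = len(y_i)
    quadrant = assign_quadrants(y_i, y_j, cutoff_i, cutoff_j)
    event = clinical.dfs_event
    min_n = max(int(np.ceil(min_frac * K)), 1)
    results: dict[int, tuple[DesignPartition, CoxFitResult]] = {}
    design_p: dict[int, float] = {}
    for design in enumerate_designs():
        side = np.isin(quadrant, sorted(design.side_one)).astype(int)
        n1 = int(side.sum())
        if n1 < min_n or K - n1 < min_n:
            continue
        if event[side == 1].sum() < min_events or event[side == 0].sum() < min_events:
            continue
        try:
            fit = cox_fit_binary(side, clinical)
        except (ValueError, CoxConvergenceError):
            continue
        results[design.design_id] = (design, fit)
        design_p[design.design_id] = fit.wald_p
    if not results:
        raise ValueError(
            f"pair ({probe_i}, {probe_j}): no admissible design"
        )

    def _single_p(side_one: frozenset) -> float:
        side = np.isin(quadrant, sorted(side_one)).astype(int)
        try:
            return cox_fit_binary(side, clinical).wald_p
        except (ValueError, CoxConvergenceError):
            return float("nan")

    p_i = design_p.get(6, _single_p(frozenset("AC")))
    p_j = design_p.get(7, _single_p(frozenset("AB")))
    best_id = min(design_p, key=design_p.get)
    best_design, best_fit = results[best_id]
    p_pair = design_p[best_id]
    synergy = bool(
        np.isfinite(p_i) and np.isfinite(p_j) and p_pair > 0
        and p_i / p_pair > synergy_factor and p_j / p_pair > synergy_factor
    )
    return PairSurvivalResult(
        probe_i=probe_i, probe_j=probe_j,
        cutoff_i=float(cutoff_i), cutoff_j=float(cutoff_j),
        best_design=best_design, cox=best_fit, p_pair=float(p_pair),
        p_i=float(p_i), p_j=float(p_j), synergy=synergy,
        design_p_values=design_p,
    )


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_bh(raw_p, alpha: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up FDR correction.

    The classic BH procedure remains valid under positive dependence
    (PRDS), which is the situation for positively co-expressed gene sets.
    Reports the data-dependent threshold: the largest raw P value still
    called significant (0.0 when nothing is).
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return FdrResult(p, np.zeros(0, bool), 0.0, alpha)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    reject, _adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return FdrResult(raw_p=p, significant=reject, threshold=threshold,
                     alpha=alpha)


# ---------------------------------------------------------------------------
# screening workflow
# ---------------------------------------------------------------------------

def screen_genes_and_pairs(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    module_probes,
    neighbour_probes=(),
    alpha: float = 0.05,
    min_frac: float = 0.10,
    min_events: int = 3,
    run_pairs: bool = True,
    correct_selection_bias: bool = False,
) -> dict:
    """Full survival screen: 1D DDg per probe, 2D DDg per probe pair, BH
    FDR within each family, plus synergy flags.

    Returns a dict with ``genes`` and ``pairs`` DataFrames (shaped like the
    per-cohort report tables: probe, group, cut-off, Cox beta, Wald P, FDR
    call; pair rows add the design and synergy flag) and the two
    :class:`FdrResult` objects.

    By default the FDR screen uses the raw Wald P of the optimized
    grouping, which is optimistically biased by the cut-off search (the
    historical convention for this analysis).  With
    ``correct_selection_bias=True`` the per-gene screening P is instead
    the maximally-selected-statistic corrected P
    (:func:`maxstat_corrected_p`), which restores screen-level error
    control under the null; the Cox Wald P is still reported per gene.
    """
    module_probes = list(module_probes)
    neighbour_probes = list(neighbour_probes)
    probes = module_probes + neighbour_probes
    clinical = clinical.subset(expr.sample_ids)
    cutoffs: dict[str, CutoffResult] = {}
    rows = []
    for probe in probes:
        group = "module" if probe in module_probes else "neighbour"
        y = expr.row(probe)
        try:
            cut = find_cutoff_1d(y, clinical, min_frac, min_events, probe_id=probe)
            fit = cox_fit_binary(cut.group_labels, clinical)
            cutoffs[probe] = cut
            p_screen = (
                maxstat_corrected_p(cut.separation_stat, cut.eps_low,
                                    cut.eps_high)
                if correct_selection_bias else fit.wald_p
            )
            rows.append((probe, group, cut.cutoff, fit.beta, fit.wald_p,
                         p_screen))
        except (ValueError, CoxConvergenceError):
            rows.append((probe, group, np.nan, np.nan, np.nan, np.nan))
    genes = pd.DataFrame(
        rows, columns=["probe", "group", "cutoff", "beta", "wald_p",
                       "p_screen"]
    )
    ok = genes["p_screen"].notna()
    fdr_genes = fdr_bh(genes.loc[ok, "p_screen"].to_numpy(), alpha=alpha)
    genes["fdr_significant"] = False
    genes.loc[ok, "fdr_significant"] = fdr_genes.significant

    pairs = pd.DataFrame(
        columns=["probe_i", "probe_j", "design", "design_kind",
                 "p_i", "p_j", "p_pair", "synergy"]
    )
    fdr_pairs = FdrResult(np.zeros(0), np.zeros(0, bool), 0.0, alpha)
    if run_pairs:
        prows = []
        pool = [p for p in probes if p in cutoffs]
        for pi, pj in itertools.combinations(pool, 2):
            try:
                res = pair_survival_2d(
                    expr.row(pi), expr.row(pj), clinical,
                    cutoffs[pi].cutoff, cutoffs[pj].cutoff,
                    min_frac, min_events, probe_i=pi, probe_j=pj,
                )
            except ValueError:
                continue
            prows.append((
                pi, pj, res.best_design.design_id, res.best_design.kind,
                res.p_i, res.p_j, res.p_pair, res.synergy,
            ))
        if prows:
            pairs = pd.DataFrame(prows, columns=pairs.columns)
            fdr_pairs = fdr_bh(pairs["p_pair"].to_numpy(), alpha=alpha)
            pairs["fdr_significant"] = fdr_pairs.significant
    if "fdr_significant" not in pairs.columns:
        pairs["fdr_significant"] = pd.Series(dtype=bool)
    return {
        "genes": genes,
        "pairs": pairs,
        "fdr_genes": fdr_genes,
        "fdr_pairs": fdr_pairs,
        "cutoffs": cutoffs,
    }


def intersect_pair_screens(pairs_a: pd.DataFrame, pairs_b: pd.DataFrame) -> pd.DataFrame:
    """Keep the significant gene pairs common to two cohorts' screens."""
    def keys(df):
        sig = df[df["fdr_significant"]]
        return {frozenset((r.probe_i, r.probe_j)) for r in sig.itertuples()}
    common = keys(pairs_a) & keys(pairs_b)
    mask = [
        frozenset((r.probe_i, r.probe_j)) in common
        for r in pairs_a.itertuples()
    ]
    return pairs_a[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# model-style front ends
# ---------------------------------------------------------------------------

class DataDrivenGrouping:
    """1D DDg as a fittable model: one gene's expression against survival.

    Examples
    --------
    >>> model = DataDrivenGrouping(expr.row("g1"), clinical, probe_id="g1")
    >>> res = model.fit()
    >>> print(res.summary())                          # doctest: +SKIP
    """

    def __init__(self, expr_row, clinical: ClinicalTable, probe_id: str = ""):
        self.y = np.asarray(expr_row, dtype=float)
        self.clinical = clinical
        self.probe_id = probe_id

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix, probe_id,
                        clinical: ClinicalTable):
        clin = clinical.subset(expr.sample_ids)
        return cls(expr.row(probe_id), clin, probe_id=str(probe_id))

    def fit(self, min_frac: float = 0.10, min_events: int = 3) -> "DDg1DResults":
        cut = find_cutoff_1d(self.y, self.clinical, min_frac, min_events,
                             probe_id=self.probe_id)
        cox = cox_fit_binary(cut.group_labels, self.clinical)
        return DDg1DResults(model=self, cutoff=cut, cox=cox)


@dataclass
class DDg1DResults:
    model: DataDrivenGrouping
    cutoff: CutoffResult
    cox: CoxFitResult

    @property
    def wald_p(self) -> float:
        return self.cox.wald_p

    def kaplan_meier_coordinates(self) -> dict:
        """Step-function coordinates of the two KM curves (for plotting)."""
        from lifelines import KaplanMeierFitter
        out = {}
        clin = self.model.clinical
        for g, name in ((0, "low"), (1, "high")):
            mask = self.cutoff.group_labels == g
            kmf = KaplanMeierFitter()
            kmf.fit(clin.dfs_time[mask], clin.dfs_event[mask])
            sf = kmf.survival_function_
            out[name] = pd.DataFrame(
                {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
            )
        return out

    def summary(self) -> str:
        c = self.cutoff
        return (
            f"1D data-driven grouping for probe {c.probe_id or '<row>'}\n"
            f"  cut-off = {c.cutoff:.4f} (log-rank chi2 = "
            f"{c.separation_stat:.3f}, {c.n_candidates} admissible candidates)\n"
            f"  groups: low n={c.n_low} ({c.events_low} events), "
            f"high n={c.n_high} ({c.events_high} events)\n  "
            + self.cox.summary()
        )


class PairedDataDrivenGrouping:
    """2D DDg as a fittable model for a gene pair.

    Reuses the genes' individual 1D cut-offs (fitting them first when not
    supplied), evaluates the seven quadrant designs and keeps the one with
    the smallest Cox Wald P.
    """

    def __init__(self, expr_i, expr_j, clinical: ClinicalTable,
                 probe_i: str = "i", probe_j: str = "j"):
        self.y_i = np.asarray(expr_i, dtype=float)
        self.y_j = np.asarray(expr_j, dtype=float)
        self.clinical = clinical
        self.probe_i = probe_i
        self.probe_j = probe_j

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix, probe_i, probe_j,
                        clinical: ClinicalTable):
        clin = clinical.subset(expr.sample_ids)
        return cls(expr.row(probe_i), expr.row(probe_j), clin,
                   probe_i=str(probe_i), probe_j=str(probe_j))

    def fit(self, cutoff_i: float | None = None, cutoff_j: float | None = None,
            min_frac: float = 0.10, min_events: int = 3) -> PairSurvivalResult:
        if cutoff_i is None:
            cutoff_i = find_cutoff_1d(self.y_i, self.clinical, min_frac,
                                      min_events, probe_id=self.probe_i).cutoff
        if cutoff_j is None:
            cutoff_j = find_cutoff_1d(self.y_j, self.clinical, min_frac,
                                      min_events, probe_id=self.probe_j).cutoff
        return pair_survival_2d(
            self.y_i, self.y_j, self.clinical, cutoff_i, cutoff_j,
            min_frac, min_events, probe_i=self.probe_i, probe_j=self.probe_j,
        )
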