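"""Synthetic cohort generator with the structure the analysis assumes.

Every stage of the pipeline is testable without any download because this
module emits the exact inputs the analysis consumes — an expression
matrix in genomic row order, a clinical table with disease-free survival
and grade labels, strand-aware gene models of a sense-antisense locus,
and a copy-number track — together with a *truth record* describing what
was planted (module membership, latent co-expression factor, true risk
groups, amplification factor), which the recovery tests in the other
modules consume.

The planted structure emulates a small sense-antisense gene module:

* a 5-gene module drawn from an equicorrelated multivariate normal
  (correlation ``rho``, optionally per tumour grade so the cluster
  tightens with grade), embedded among independent neighbour genes and a
  large pool of independent "genomic background" probes used by the
  bootstrap Bartlett null;
* a genomic layout with two convergent overlapping gene pairs (one
  overlap exactly 376 bp) chained through shared bidirectional promoter
  gaps into one five-gene architecture, flanked by non-overlapping
  neighbours within 80-170 kb;
* exponential survival times whose hazard depends on the dichotomized
  module factor, with independent uniform censoring calibrated to a
  target censoring fraction;
* a copy-number track whose markers share one latent amplification
  factor, calibrated so the Kendall correlation with module expression
  hits a target tau.

Default cohort sizes are 251 and 159 samples, mirroring typical breast
cancer microarray cohorts; the copy-number panel defaults to 38 samples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import (
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotationSet,
    GeneRecord,
    normalize_mean_scale,
    write_clinical,
    write_expression,
    write_gene_models_bed,
)
from .copynumber import CopyNumberTrack, write_copy_number

__all__ = [
    "SimulationConfig",
    "gen_expression",
    "gen_gene_models",
    "gen_survival",
    "gen_copy_number",
    "gen_cohort_bundle",
    "write_bundle",
]

DEFAULT_GRADES = ("G1", "G1-like", "G3-like", "G3")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``rho`` is the module's equicorrelation (requires
    ``rho > -1/(p-1)`` for positive definiteness); ``rho_by_grade``
    optionally overrides it per grade.  ``hazard_ratio`` applies to the
    high-risk half of the dichotomized module factor; ``tau_target`` is
    the desired Kendall correlation between module expression and the
    copy-number track (0 disables the amplification component).
    """

    n_samples: int = 251
    module_size: int = 5
    n_neighbours: int = 6
    pool_size: int = 2000
    rho: float = 0.6
    rho_by_grade: dict | None = None
    grades: tuple = DEFAULT_GRADES
    baseline_hazard: float = 0.02
    hazard_ratio: float = 2.5
    censoring_rate: float = 0.3
    cn_samples: int = 38
    tau_target: float = 0.0
    n_markers: int = 4
    marker_noise_sd: float = 0.0
    log_base: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        p = self.module_size
        rhos = [self.rho] + list((self.rho_by_grade or {}).values())
        for r in rhos:
            if not (-1.0 / (p - 1) < r < 1.0):
                raise ValueError(
                    f"rho={r} does not give a positive-definite "
                    f"equicorrelation matrix for p={p}"
                )
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if not 0.0 <= self.tau_target < 1.0:
            raise ValueError("tau_target must be in [0, 1)")


def driver_hr_for_gene_hr(gene_hr: float, rho: float) -> float:
    """Driver-level hazard ratio that makes each module gene's median
    split exhibit a target hazard ratio.

    The simulated hazard attaches to the dichotomized latent module
    factor; an individual gene correlates with the factor at
    ``r = sqrt(rho)``, so its median split agrees with the risk split
    with probability ``a = 1/2 + arcsin(r)/pi`` (bivariate-normal
    quadrant probability) and its observable hazard ratio is the
    two-group mixture ``(aH + 1 - a) / ((1 - a)H + a)``.  This inverts
    that mixture for ``H``; it requires ``gene_hr < a / (1 - a)``.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1) for a shared-factor module")
    a = 0.5 + math.asin(math.sqrt(rho)) / math.pi
    if gene_hr >= a / (1 - a):
        raise ValueError(
            f"gene-level hazard ratio {gene_hr} unreachable at rho={rho}"
        )
    return (gene_hr * a - (1 - a)) / (a - gene_hr * (1 - a))


def _amp_weight(tau_target: float) -> float:
    """Pearson loading on the amplification factor that yields a Kendall
    correlation of ``tau_target`` between expression and copy number
    (bivariate-normal relation tau = (2/pi) arcsin(r))."""
    return math.sin(math.pi * tau_target / 2.0)


def _module_draw(rng, n: int, p: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Draw n samples of a p-variate equicorrelated normal; returns
    (samples x p matrix, latent factor) — the factor is NaN for rho < 0."""
    if rho >= 0:
        f = rng.standard_normal(n)
        z = rng.standard_normal((n, p))
        return math.sqrt(rho) * f[:, None] + math.sqrt(1 - rho) * z, f
    sigma = np.full((p, p), rho)
    np.fill_diagonal(sigma, 1.0)
    L = np.linalg.cholesky(sigma)
    x = rng.standard_normal((n, p)) @ L.T
    return x, np.full(n, np.nan)


def gen_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, dict]:
    """Generate the expression matrix and its truth record.

    Row order is genomic: first half of the background pool, the upstream
    neighbours, the module block, the downstream neighbours, then the
    rest of the pool — so windows of consecutive rows behave like windows
    of physically neighbouring genes.  The grand mean is scaled to
    log(500) in the configured base.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, p, q = config.n_samples, config.module_size, config.n_neighbours
    grades = np.array(
        [config.grades[i % len(config.grades)] for i in range(n)], dtype=object
    )
    rng.shuffle(grades)

    module = np.empty((n, p))
    factor = np.empty(n)
    # sorted for cross-process determinism (set order is hash-randomized)
    for g in sorted(set(grades)):
        rho_g = (config.rho_by_grade or {}).get(g, config.rho)
        mask = grades == g
        module[mask], factor[mask] = _module_draw(rng, int(mask.sum()), p, rho_g)

    amp = rng.standard_normal(n)
    w = _amp_weight(config.tau_target)
    if w > 0:
        # dosage component: expression rises with log2 copy number, the
        # co-expression part shrinks so each gene keeps unit variance
        module = math.sqrt(1 - w * w) * module + w * amp[:, None]

    neighbours = rng.standard_normal((n, q))
    pool = rng.standard_normal((n, config.pool_size))

    module_ids = [f"MOD{i+1}" for i in range(p)]
    neigh_ids = [f"NB{i+1}" for i in range(q)]
    pool_ids = [f"POOL{i+1:05d}" for i in range(config.pool_size)]
    q_up = q // 2
    half = config.pool_size // 2
    row_ids = (
        pool_ids[:half] + neigh_ids[:q_up] + module_ids
        + neigh_ids[q_up:] + pool_ids[half:]
    )
    blocks = np.hstack([
        pool[:, :half], neighbours[:, :q_up], module,
        neighbours[:, q_up:], pool[:, half:],
    ]).T  # probes x samples
    sample_ids = [f"S{i+1:04d}" for i in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(blocks, index=row_ids, columns=sample_ids),
        log_base=config.log_base,
    )
    expr = normalize_mean_scale(expr)
    truth = {
        "seed": config.seed,
        "module_probes": module_ids,
        "neighbour_probes": neigh_ids,
        "pool_probes": pool_ids,
        "rho": config.rho,
        "rho_by_grade": config.rho_by_grade,
        "amp_weight": w,
        "grades": grades.tolist(),
        "factor": factor.tolist(),
        "amp": amp.tolist(),
        "sample_ids": sample_ids,
    }
    return expr, truth


def gen_gene_models(config: SimulationConfig) -> GeneAnnotationSet:
    """Synthetic sense-antisense locus matching the module layout.

    Five module genes on one chromosome form two convergent overlapping
    pairs (MOD1/MOD2 and MOD3/MOD4; the latter overlap is exactly 376 bp)
    chained by two bidirectional-promoter gaps (MOD2-MOD3 and MOD4-MOD5,
    both under 1 kb), flanked by non-overlapping neighbour genes within
    80 kb upstream and 170 kb downstream, plus one far gene beyond
    200 kb that no default window should pick up.
    """
    chrom = "chr17s"
    module = [
        GeneRecord("MOD1", chrom, 200_000, 210_000, "+", ("MOD1",)),
        GeneRecord("MOD2", chrom, 209_500, 218_000, "-", ("MOD2",)),
        GeneRecord("MOD3", chrom, 218_800, 228_000, "+", ("MOD3",)),
        GeneRecord("MOD4", chrom, 227_624, 236_000, "-", ("MOD4",)),
        GeneRecord("MOD5", chrom, 236_600, 242_000, "+", ("MOD5",)),
    ]
    span_start, span_end = 200_000, 242_000
    q = config.n_neighbours
    q_up = q // 2
    q_down = q - q_up
    neighbours = []
    # upstream (centromeric) within 80 kb of the span start
    for i in range(q_up):
        gap = 80_000 - i * (70_000 // max(q_up, 1))
        end = span_start - gap
        neighbours.append(
            GeneRecord(f"NB{i+1}", chrom, end - 5_000, end,
                       "+" if i % 2 == 0 else "-", (f"NB{i+1}",))
        )
    # downstream (telomeric) within 170 kb of the span end
    for i in range(q_down):
        gap = 20_000 + i * (150_000 // max(q_down, 1))
        start = span_end + gap
        neighbours.append(
            GeneRecord(f"NB{q_up+i+1}", chrom, start, start + 5_000,
                       "-" if i % 2 == 0 else "+", (f"NB{q_up+i+1}",))
        )
    far = [GeneRecord("FAR1", chrom, span_end + 250_000,
                      span_end + 255_000, "+", ("FAR1",))]
    records = sorted(module + neighbours + far, key=lambda r: r.start)
    return GeneAnnotationSet(records)


def _calibrate_uniform_censoring(hazards: np.ndarray, target: float) -> float:
    """Upper bound U of Uniform(0, U) censoring giving the target expected
    censoring fraction for exponential event times with the given hazards."""

    def frac_censored(U: float) -> float:
        hU = hazards * U
        return float(np.mean((1.0 - np.exp(-hU)) / hU))

    lo, hi = 1e-9, 1.0
    while frac_censored(hi) > target and hi < 1e12:
        hi *= 2.0
    return brentq(lambda U: frac_censored(U) - target, lo, hi, xtol=1e-10)


def gen_survival(
    labels: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    hazard_ratios: dict | None = None,
    grades: np.ndarray | None = None,
    sample_ids=None,
) -> ClinicalTable:
    """Exponential survival with per-label hazard and uniform censoring.

    ``labels`` may be binary (0 = baseline hazard, 1 = baseline x
    ``config.hazard_ratio``) or arbitrary keys into ``hazard_ratios``
    (label -> hazard ratio).  Censoring times are Uniform(0, U) with U
    calibrated so the expected censoring fraction equals
    ``config.censoring_rate``; a rate of 0 means no censoring at all.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    labels = np.asarray(labels)
    n = len(labels)
    if hazard_ratios is None:
        hr = np.where(labels.astype(float) > 0, config.hazard_ratio, 1.0)
    else:
        bad = sorted({l for l in labels.tolist() if l not in hazard_ratios})
        if bad:
            raise ValueError(f"labels without a hazard ratio: {bad}")
        hr = np.array([hazard_ratios[l] for l in labels.tolist()], dtype=float)
    if np.any(hr <= 0):
        raise ValueError("hazard ratios must be positive")
    hazards = config.baseline_hazard * hr
    t_event = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        U = _calibrate_uniform_censoring(hazards, config.censoring_rate)
        t_cens = rng.uniform(0.0, U, size=n)
        dfs_time = np.minimum(t_event, t_cens)
        dfs_event = (t_event <= t_cens).astype(int)
    else:
        dfs_time = t_event
        dfs_event = np.ones(n, dtype=int)
    if sample_ids is None:
        sample_ids = [f"S{i+1:04d}" for i in range(n)]
    if grades is None:
        grades = np.array(
            [config.grades[i % len(config.grades)] for i in range(n)],
            dtype=object,
        )
    df = pd.DataFrame(
        {"dfs_time": dfs_time, "dfs_event": dfs_event, "grade": grades},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ClinicalTable(df)


def gen_copy_number(
    truth: dict, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CopyNumberTrack:
    """Copy-number track driven by the recorded amplification factor.

    Every marker inside the amplified window carries the same value
    ``2 * 2**(w * amp)`` (per sample), where ``w`` is the loading the
    expression generator used — so log2(copy number) matches the dosage
    component of module expression exactly and copy-number normalization
    can remove it.  Optional marker noise perturbs each marker
    independently.  With ``tau_target = 0`` the track is flat (diploid)
    plus noise and carries no association.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    amp = np.asarray(truth["amp"], dtype=float)
    w = float(truth.get("amp_weight", 0.0))
    sample_ids = truth["sample_ids"][: len(amp)]
    base = 2.0 * np.exp(w * math.log(2.0) * amp)
    rows = {}
    positions = np.linspace(205_000, 240_000, config.n_markers).astype(int)
    for m in range(config.n_markers):
        values = base.copy()
        if config.marker_noise_sd > 0:
            values = values * np.exp(
                rng.normal(0.0, config.marker_noise_sd, size=len(values))
            )
        rows[f"rs{9000000 + m}"] = values
    df = pd.DataFrame(rows, index=sample_ids).T
    df.insert(0, "chrom", "chr17s")
    df.insert(1, "position", positions)
    df.index.name = "marker_id"
    return CopyNumberTrack(df)


def gen_cohort_bundle(config: SimulationConfig) -> dict:
    """One complete synthetic cohort: expression, clinical, gene models,
    copy number (when ``tau_target > 0``) and the truth record.

    Survival risk groups come from dichotomizing the module's latent
    factor at its median, so the true 1D cut-off of every module gene
    sits at its 50th percentile; neighbour and pool genes carry no
    survival signal.  With ``hazard_ratio = 1`` the cohort is a global
    null.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    expr, truth = gen_expression(config, rng)
    factor = np.asarray(truth["factor"], dtype=float)
    amp = np.asarray(truth["amp"], dtype=float)
    w = truth["amp_weight"]
    # risk driver = the common module signal each sample actually carries
    driver = factor if w == 0 else (
        math.sqrt(1 - w * w) * factor + w * amp
    )
    if np.isnan(driver).any():
        driver = np.zeros(len(factor))
    high = (driver >= np.median(driver)).astype(int)
    clinical = gen_survival(
        high, config, rng,
        grades=np.asarray(truth["grades"], dtype=object),
        sample_ids=truth["sample_ids"],
    )
    truth["risk_group"] = high.tolist()
    truth["driver"] = driver.tolist()
    cn = gen_copy_number(truth, config, rng) if config.tau_target > 0 else None
    genes = gen_gene_models(config) if config.module_size == 5 else None
    return {
        "expression": expr,
        "clinical": clinical,
        "gene_models": genes,
        "copy_number": cn,
        "truth": truth,
        "config": config,
    }


def write_bundle(bundle: dict, outdir) -> dict:
    """Write a generated bundle to TSV/BED files plus a truth JSON sidecar.

    Returns the mapping of logical names to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_expression(bundle["expression"], outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    write_clinical(bundle["clinical"], outdir / "clinical.tsv")
    paths["clinical"] = str(outdir / "clinical.tsv")
    if bundle.get("gene_models") is not None:
        write_gene_models_bed(bundle["gene_models"], outdir / "genes.bed")
        paths["gene_models"] = str(outdir / "genes.bed")
    if bundle.get("copy_number") is not None:
        write_copy_number(bundle["copy_number"], outdir / "copy_number.tsv")
        paths["copy_number"] = str(outdir / "copy_number.tsv")
    sidecar = dict(bundle["truth"])
    sidecar["config"] = asdict(bundle["config"])
    sidecar["config"]["grades"] = list(sidecar["config"]["grades"])
    with open(outdir / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    paths["truth"] = str(outdir / "truth.json")
    return paths
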