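"""End-to-end orchestration: from input files to the report tables.

The pipeline runs the five-step workflow the package exists for:

1. detect sense-antisense pairs and chain them into architectures;
2. build grade-stratified correlation matrices for the candidate module
   and its genomic neighbours (Pearson on large cohorts that pass the
   normality screen, Kendall otherwise);
3. test the module's cluster significance with the bootstrap Bartlett
   procedure, against a neighbouring-gene null drawn from the whole
   expression pool;
4. compare module vs neighbour and grade vs grade correlation structure
   with Box's M;
5. screen genes and gene pairs for survival significance with 1D/2D
   data-driven grouping, BH FDR correction and the x10 synergy rule;
   optionally correlate expression with DNA copy number and re-test the
   module on copy-number-normalized expression.

Every table is written as TSV with a run-metadata header (seed, package
version, config hash) so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .architecture import chain_csagas, detect_sagps, neighbour_window, promoter_edges
from .copynumber import (
    cn_expression_correlation,
    normalize_expression_by_cn,
    read_copy_number,
)
from .corrstats import (
    bootstrap_bartlett,
    box_m_unequal,
    box_m,
    grade_stratified_matrices,
    kendall_matrix,
    normality_screen,
    pearson_matrix,
)
from .datamodel import read_clinical, read_expression, read_gene_models
from .survival import screen_genes_and_pairs

logger = logging.getLogger("sagpipe")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and settings of one pipeline run (YAML/JSON serializable)."""

    expression: str = ""
    clinical: str = ""
    gene_models: str = ""
    copy_number: str | None = None
    module_probes: list = field(default_factory=list)   # empty = auto-detect
    neighbour_probes: list = field(default_factory=list)
    alpha_corr: float = 0.01
    alpha_survival: float = 0.05
    bootstrap_draws: int = 5000
    min_group_frac: float = 0.10
    min_events: int = 3
    promoter_gap: int = 1000
    use_promoter_edges: bool = True
    neighbour_window_bp: int = 200_000
    pearson_min_samples: int = 50
    seed: int = 0
    outdir: str = "sagpipe_out"

    def validate(self) -> None:
        for attr in ("expression", "clinical"):
            path = getattr(self, attr)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{attr} file not found: {path!r}")
        if self.gene_models and not Path(self.gene_models).exists():
            raise FileNotFoundError(f"gene_models file not found: {self.gene_models!r}")
        if self.copy_number and not Path(self.copy_number).exists():
            raise FileNotFoundError(f"copy_number file not found: {self.copy_number!r}")
        for a in (self.alpha_corr, self.alpha_survival):
            if not 0 < a < 1:
                raise ValueError(f"alpha {a} outside (0, 1)")
        if self.bootstrap_draws < 100:
            raise ValueError("bootstrap_draws must be at least 100")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset covers JSON
        return cls(**data)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)

    def hash(self) -> str:
        # outdir does not affect any computed number, so two runs that
        # differ only in output location share a hash
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sagpipe {__version__}\n")
        fh.write(f"# seed={config.seed} config_hash={config.hash()}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _choose_method(expr, probes, alpha, min_samples) -> str:
    n = len(expr.sample_ids)
    if n < min_samples:
        logger.info("n=%d < %d: using Kendall tau-b", n, min_samples)
        return "kendall"
    report = normality_screen(expr, probes, alpha=alpha)
    if not report.all_pass:
        failed = report.table.index[~report.table["passes"]].tolist()
        logger.info("normality screen failed for %s: using Kendall", failed)
        return "kendall"
    return "pearson"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory results and writes
    one TSV per stage under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}

    def stage(name):
        logger.info("stage: %s", name)

    # ---- 1. inputs -----------------------------------------------------
    stage("read inputs")
    expr = read_expression(config.expression)
    clinical = read_clinical(config.clinical)
    shared = [s for s in expr.sample_ids if s in clinical.sample_ids]
    expr = expr.subset_samples(shared)
    clinical = clinical.subset(shared)

    # ---- 2. architecture ----------------------------------------------
    module_probes = list(config.module_probes)
    neighbour_probes = list(config.neighbour_probes)
    if config.gene_models:
        stage("architecture detection")
        genes = read_gene_models(config.gene_models)
        pairs = detect_sagps(genes)
        extra = (
            promoter_edges(genes, config.promoter_gap)
            if config.use_promoter_edges else []
        )
        csagas = chain_csagas(pairs, genes, extra_edges=extra)
        pair_table = pd.DataFrame(
            [(p.gene_a, p.gene_b, p.orientation, p.overlap_len,
              p.chrom, p.overlap_start, p.overlap_end) for p in pairs + extra],
            columns=["gene_a", "gene_b", "orientation", "overlap_len",
                     "chrom", "overlap_start", "overlap_end"],
        )
        _write_table(pair_table, outdir / "sag_pairs.tsv", config)
        comp_table = pd.DataFrame(
            [(c.component_id, len(c), ",".join(c.member_genes))
             for c in csagas],
            columns=["component_id", "n_genes", "member_genes"],
        )
        _write_table(comp_table, outdir / "csagas.tsv", config)
        results["sag_pairs"] = pairs
        results["csagas"] = csagas
        if not module_probes and csagas:
            focal = max(csagas, key=len)
            module_probes = [
                pr for g in focal.member_genes
                for pr in ((genes[g].probe_ids or (g,)) if g in genes else (g,))
                if pr in expr.data.index
            ]
            window = neighbour_window(focal, genes, config.neighbour_window_bp)
            neighbour_probes = [
                pr for g in window.all_genes
                for pr in (genes[g].probe_ids or (g,))
                if pr in expr.data.index
            ]
            logger.info(
                "auto-detected module %s with neighbours %s",
                module_probes, neighbour_probes,
            )
    if not module_probes:
        raise ValueError("no module probes: supply module_probes or gene models")

    # ---- 3. correlation matrices per grade -----------------------------
    stage("correlation matrices")
    method = _choose_method(expr, module_probes, config.alpha_corr,
                            config.pearson_min_samples)
    results["corr_method"] = method
    by_grade = grade_stratified_matrices(
        expr, clinical, module_probes, method=method, alpha=config.alpha_corr
    )
    results["module_matrices"] = by_grade
    long_rows = []
    for grade, res in by_grade.items():
        if res is None:
            continue
        for a in res.gene_order:
            for b in res.gene_order:
                long_rows.append(
                    (grade, a, b, res.R.loc[a, b], res.p_values.loc[a, b],
                     bool(res.sig_mask.loc[a, b]))
                )
    _write_table(
        pd.DataFrame(long_rows, columns=["grade", "probe_a", "probe_b",
                                         "r", "p", "significant"]),
        outdir / "correlation_matrices.tsv", config,
    )

    # ---- 4. bootstrap Bartlett -----------------------------------------
    stage("bootstrap Bartlett")
    bart_rows = []
    targets = {"SFGM": module_probes}
    if neighbour_probes:
        targets["NG"] = neighbour_probes
    rng = np.random.default_rng(config.seed)
    results["bartlett"] = {}
    for name, probes in targets.items():
        res = bootstrap_bartlett(
            probes, expr, B=config.bootstrap_draws,
            seed=int(rng.integers(2**31)),
        )
        results["bartlett"][name] = res
        bart_rows.append((name, res.p, res.N, res.T, res.df,
                          res.p_analytic, res.p_boot, res.B))
    _write_table(
        pd.DataFrame(bart_rows, columns=["gene_set", "p_dim", "n_samples",
                                         "T", "df", "p_analytic", "p_boot",
                                         "B"]),
        outdir / "bartlett.tsv", config,
    )

    # ---- 5. Box M -------------------------------------------------------
    stage("Box M comparisons")
    boxm_rows = []
    Xm = expr.subset(module_probes).values.T
    if neighbour_probes:
        Xn = expr.subset(neighbour_probes).values.T
        res = (box_m_unequal(Xm, Xn) if Xn.shape[1] > Xm.shape[1]
               else box_m(Xm, Xn))
        results["box_m_module_vs_neighbours"] = res
        boxm_rows.append(("SFGM/NG", "Total group", res.M, res.p_chi2,
                          res.n_subcomparisons,
                          res.p_averaged if res.p_averaged is not None
                          else res.p_chi2))
    grade_groups = {
        g: list(grp.index)
        for g, grp in clinical.data.groupby("grade", observed=True)
        if len(grp) > len(module_probes) + 2
    }
    names = sorted(grade_groups)
    results["box_m_grade_pairs"] = {}
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            Xa = expr.subset(module_probes).subset_samples(grade_groups[ga]).values.T
            Xb = expr.subset(module_probes).subset_samples(grade_groups[gb]).values.T
            try:
                res = box_m(Xa, Xb)
            except ValueError as exc:
                logger.warning("Box M %s vs %s failed: %s", ga, gb, exc)
                continue
            results["box_m_grade_pairs"][(ga, gb)] = res
            boxm_rows.append((f"SFGM {ga} vs {gb}", "grade pair", res.M,
                              res.p_chi2, 1, res.p_chi2))
    _write_table(
        pd.DataFrame(boxm_rows, columns=["comparison", "stratum", "M",
                                         "p_chi2", "n_subcomparisons",
                                         "p_averaged"]),
        outdir / "box_m.tsv", config,
    )

    # ---- 6. survival screens -------------------------------------------
    stage("1D/2D data-driven grouping")
    screen = screen_genes_and_pairs(
        expr, clinical, module_probes, neighbour_probes,
        alpha=config.alpha_survival, min_frac=config.min_group_frac,
        min_events=config.min_events,
    )
    results["screen"] = screen
    _write_table(screen["genes"], outdir / "survival_genes.tsv", config)
    _write_table(screen["pairs"], outdir / "survival_pairs.tsv", config)

    # ---- 7. copy number -------------------------------------------------
    if config.copy_number:
        stage("copy-number correlation")
        cn = read_copy_number(config.copy_number).deduplicated()
        corr = cn_expression_correlation(
            cn, expr, module_probes + neighbour_probes,
            alpha=config.alpha_corr,
        )
        results["cn_correlation"] = corr
        _write_table(corr["masked"], outdir / "cn_correlation.tsv",
                     config, index=True)
        marker = cn.marker_ids[0]
        norm_expr = normalize_expression_by_cn(expr, cn, marker)
        corr_fun = kendall_matrix if method == "kendall" else pearson_matrix
        before = corr_fun(expr, module_probes, alpha=config.alpha_corr)
        after = corr_fun(norm_expr, module_probes, alpha=config.alpha_corr)
        results["cn_normalized_module"] = {"before": before, "after": after}
        _write_table(after.masked(), outdir / "module_corr_cn_normalized.tsv",
                     config, index=True)

    logger.info("pipeline complete: %s", outdir)
    return results
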