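"""DNA copy-number association with expression and dosage normalization.

Recurrent amplification of a genomic segment raises the DNA dosage of
every gene inside it, which can drive their mRNA levels jointly and hence
manufacture a co-expression cluster without any shared regulation.  Two
tools address this:

* Kendall tau-b correlation between per-marker copy-number values and
  per-probe expression across the shared samples (rank-based, suitable for
  small panels such as cell-line collections), with a significance mask;
* copy-number normalization: dividing linear-scale expression by the
  copy number per sample and returning to the log scale, so that a purely
  dosage-driven correlation pattern collapses while regulation-driven
  correlation survives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix

__all__ = [
    "CopyNumberTrack",
    "read_copy_number",
    "write_copy_number",
    "cn_expression_correlation",
    "normalize_expression_by_cn",
]


class CopyNumberTrack:
    """Per-marker, per-sample estimated DNA copy numbers.

    ``data`` is a DataFrame indexed by marker id with columns
    ``chrom``, ``position`` then one column per sample.  Copy-number
    values must be strictly positive; positions must be sorted within
    each chromosome.
    """

    META = ("chrom", "position")

    def __init__(self, data: pd.DataFrame):
        for col in self.META:
            if col not in data.columns:
                raise ValueError(f"copy-number table missing column {col!r}")
        data = data.copy()
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated marker id(s): {dups}")
        values = data.drop(columns=list(self.META)).astype(float)
        if (values.to_numpy() <= 0).any() or not np.isfinite(values.to_numpy()).all():
            raise ValueError("copy-number values must be finite and positive")
        for _chrom, grp in data.groupby("chrom", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(
                    f"marker positions not sorted within chromosome {_chrom!r}"
                )
        self.data = data
        self._values = values

    @property
    def marker_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self._values.columns)

    def values_for(self, marker_id) -> pd.Series:
        return self._values.loc[marker_id]

    @property
    def values(self) -> pd.DataFrame:
        """Markers x samples copy-number values (no metadata columns)."""
        return self._values

    def deduplicated(self) -> "CopyNumberTrack":
        """Drop markers whose per-sample values duplicate an earlier marker.

        SNP markers inside one amplified segment often carry identical
        copy-number estimates; keeping them all would just repeat the same
        column in every downstream table.  Emits a warning naming the
        dropped markers.
        """
        seen: dict[tuple, str] = {}
        keep, dropped = [], []
        for m in self.marker_ids:
            key = tuple(self._values.loc[m].to_numpy())
            if key in seen:
                dropped.append((m, seen[key]))
            else:
                seen[key] = m
                keep.append(m)
        if dropped:
            warnings.warn(
                "dropping markers with values identical to an earlier marker: "
                + ", ".join(f"{m} (= {ref})" for m, ref in dropped)
            )
        return CopyNumberTrack(self.data.loc[keep])

    def __len__(self) -> int:
        return len(self.data)


def read_copy_number(path) -> CopyNumberTrack:
    """Read a copy-number TSV: marker_id, chrom, position, then samples."""
    df = pd.read_csv(path, sep="\t", index_col="marker_id")
    return CopyNumberTrack(df)


def write_copy_number(cn: CopyNumberTrack, path) -> None:
    df = cn.data.copy()
    df.index.name = "marker_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def cn_expression_correlation(
    cn: CopyNumberTrack,
    expr: ExpressionMatrix,
    probes=None,
    alpha: float = 0.01,
    markers=None,
) -> dict:
    """Kendall tau-b between each (probe, marker) pair across shared samples.

    Returns a dict with ``tau`` (probes x markers DataFrame), ``p_values``,
    ``sig_mask`` and ``masked`` — the report-style view where only
    correlations significant at ``alpha`` are shown (others NaN).
    Requires at least 8 shared samples.
    """
    probes = list(probes) if probes is not None else expr.probe_ids
    markers = list(markers) if markers is not None else cn.marker_ids
    shared = [s for s in expr.sample_ids if s in cn.sample_ids]
    if len(shared) < 8:
        raise ValueError(
            f"only {len(shared)} shared samples between expression and "
            "copy number; need at least 8"
        )
    E = expr.subset(probes).subset_samples(shared).values
    C = cn.values[shared].loc[markers].to_numpy()
    tau = np.zeros((len(probes), len(markers)))
    pvals = np.ones_like(tau)
    for i in range(len(probes)):
        for j in range(len(markers)):
            t, p = stats.kendalltau(E[i], C[j])
            tau[i, j] = t
            pvals[i, j] = p
    tau_df = pd.DataFrame(tau, index=probes, columns=markers)
    p_df = pd.DataFrame(pvals, index=probes, columns=markers)
    sig = p_df < alpha
    return {
        "tau": tau_df,
        "p_values": p_df,
        "sig_mask": sig,
        "masked": tau_df.where(sig),
        "n_samples": len(shared),
        "alpha": alpha,
    }


def normalize_expression_by_cn(
    expr: ExpressionMatrix, cn: CopyNumberTrack, marker
) -> ExpressionMatrix:
    """Per-sample ratio of linear-scale expression to copy number, re-logged.

    The log-scale values are exponentiated to the linear scale, divided by
    the sample's copy number at ``marker``, and log-transformed again in
    the matrix's own base; equivalently ``y - log_b(cn)`` on the log scale.
    A uniform copy number of 1 therefore leaves the matrix unchanged and a
    uniform 2 shifts it by ``-log_b(2)``.
    """
    cn_values = cn.values_for(marker)
    missing = [s for s in expr.sample_ids if s not in cn_values.index]
    if missing:
        raise ValueError(f"copy-number marker {marker!r} lacks samples: {missing}")
    c = cn_values.loc[expr.sample_ids].to_numpy(dtype=float)
    if np.any(c <= 0):
        raise ValueError("copy-number values must be strictly positive")
    shifted = expr.values - np.log(c)[None, :] / math.log(expr.log_base)
    out = pd.DataFrame(shifted, index=expr.data.index, columns=expr.data.columns)
    return ExpressionMatrix(out, expr.log_base)
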