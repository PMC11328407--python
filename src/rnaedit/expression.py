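"""Gene expression support: TPM normalisation and a simple group test.

TPM (transcripts per million): per sample, each gene's count is divided by
its length in bases to a rate, and rates are scaled to sum to one million.
Differential expression across groups is a one-way Gaussian test on
log2(TPM+1) — the likelihood-ratio test of a group-means model against an
intercept-only model, which is equivalent to the ANOVA F test — with
Benjamini-Hochberg adjustment across genes. This deliberately lightweight
test exists to support the editing/expression correlation analyses, not to
replace a count-based differential-expression framework.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .design import StudyDesign
from .dre import bh_adjust


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM matrix from a gene x sample count table and gene lengths (bases).

    A zero-depth sample yields an all-NaN column (with a warning) rather
    than a division error.
    """
    if not counts.index.equals(lengths.index):
        lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every gene needs a length")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"zero-depth samples: {list(totals.index[zero])}")
        totals = totals.replace(0, np.nan)
    return rate.div(totals, axis=1) * 1e6


def read_gene_counts(path) -> tuple[pd.DataFrame, pd.Series]:
    """Gene-count TSV (gene_id, length, one column per sample)."""
    frame = pd.read_csv(path, sep="\t")
    if "gene_id" not in frame.columns or "length" not in frame.columns:
        raise ValueError("gene-count table needs gene_id and length columns")
    frame = frame.set_index("gene_id")
    lengths = frame.pop("length").astype(float)
    return frame.astype(float), lengths


def de_glm(tpm_table: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Per-gene one-way group test on log2(TPM+1), BH-adjusted.

    Constant genes get p = 1. Returns gene, p, fdr and per-group mean
    log-expression columns.
    """
    groups = design.groups
    group_samples = {
        g: [s for s in design.samples_in_group(g) if s in tpm_table.columns]
        for g in groups
    }
    usable = [g for g in groups if len(group_samples[g]) >= 2]
    if len(usable) < 2:
        raise ValueError("need >=2 groups with >=2 samples each")
    log_expr = np.log2(tpm_table + 1.0)
    pvals = np.ones(len(log_expr))
    means = {g: np.full(len(log_expr), np.nan) for g in groups}
    arrays = {g: log_expr[group_samples[g]].to_numpy() for g in usable}
    for i in range(len(log_expr)):
        vals = [arrays[g][i] for g in usable]
        for g in groups:
            if group_samples[g]:
                means[g][i] = float(np.mean(log_expr[group_samples[g]].iloc[i]))
        flat = np.concatenate(vals)
        if np.all(flat == flat[0]):
            pvals[i] = 1.0
            continue
        if all(np.var(v) == 0 for v in vals):
            # between-group signal with zero residual variance: F -> inf
            pvals[i] = 0.0
            continue
        _, p = stats.f_oneway(*vals)
        pvals[i] = p if not np.isnan(p) else 1.0
    out = pd.DataFrame({"gene_id": log_expr.index, "p": pvals})
    out["fdr"] = bh_adjust(out["p"])
    for g in groups:
        out[f"mean_log2_{g}"] = means[g]
    return out
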