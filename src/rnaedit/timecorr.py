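"""Spearman correlation analyses over the LPS time course.

Three kinds of records are produced, all from the same tie-corrected
Spearman machinery (two-sided p from the t-approximation on n-2 df):

* ``time``       — per-site editing level vs minutes post-treatment (the
                   PBS control contributes time 0);
* ``cis_expression`` — per (site, host gene): editing level vs the gene's
                   TPM, sample by sample;
* ``enzyme_expression`` — per editing enzyme (Adar-like / Adarb1-like):
                   per-sample mean editing level vs the enzyme's TPM.

Correlations default to per-sample values (n = groups x replicates); a
group-means mode is available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .design import StudyDesign
from .filtering import event_levels

LOW_N = 6  # below this many pairs the p-value is flagged as unstable


@dataclass(frozen=True)
class CorrelationRecord:
    key: tuple  # site key, (site, gene), or (gene,) for enzymes
    kind: str  # time | cis_expression | enzyme_expression
    r: float
    p: float
    n: int
    flagged: bool = False  # p < alpha for the analysis that produced it
    low_n: bool = False


def spearman(
    x: Iterable[float],
    y: Iterable[float],
    method: str = "t",
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Tie-corrected Spearman (r, p, n) after pairwise missing removal.

    ``method='t'`` uses the t-approximation with n-2 df; ``'permutation'``
    returns a +1-smoothed two-sided permutation p (full-shuffle sampling,
    seeded), useful at the small n of these designs. Constant input after
    missing removal, or fewer than 3 pairs, yields (nan, nan, n).
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("length mismatch")
    mask = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[mask], ya[mask]
    n = len(xa)
    if n < 3:
        return math.nan, math.nan, n
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return math.nan, math.nan, n
    r, p = stats.spearmanr(xa, ya)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        obs = abs(r)
        hits = 0
        for _ in range(n_perm):
            rp, _ = stats.spearmanr(xa, rng.permutation(ya))
            if abs(rp) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return float(r), float(p), n


def time_dependent_sites(
    events: pd.DataFrame,
    design: StudyDesign,
    alpha: float = 0.05,
    use_group_means: bool = False,
) -> list[CorrelationRecord]:
    """Per-site Spearman of editing level against time post-treatment."""
    levels = event_levels(events)
    records: list[CorrelationRecord] = []
    if use_group_means:
        xs = [float(design.time_of_group(g)) for g in design.groups]
    else:
        samples = [s for s in design.sample_ids if s in levels.columns]
        xs = [float(design.time_of(s)) for s in samples]
    for key in levels.index:
        if use_group_means:
            ys = []
            for g in design.groups:
                gs = [s for s in design.samples_in_group(g) if s in levels.columns]
                ys.append(float(levels.loc[key, gs].mean()))
        else:
            ys = levels.loc[key, samples].tolist()
        r, p, n = spearman(xs, ys)
        if math.isnan(r):
            continue
        records.append(
            CorrelationRecord(
                key=key, kind="time", r=r, p=p, n=n,
                flagged=bool(p < alpha), low_n=n < LOW_N,
            )
        )
    return records


def cis_expression_correlation(
    events: pd.DataFrame,
    tpm: pd.DataFrame,
    gene_map: dict[tuple, str],
    alpha: float = 0.05,
) -> list[CorrelationRecord]:
    """Spearman of per-sample editing level vs host-gene TPM, per site.

    ``gene_map`` maps site keys (chrom, pos, strand) to gene ids; sites
    whose gene is absent from the TPM matrix are skipped.
    """
    levels = event_levels(events)
    samples = [s for s in levels.columns if s in tpm.columns]
    records: list[CorrelationRecord] = []
    for key in levels.index:
        gene = gene_map.get(key)
        if gene is None or gene not in tpm.index:
            continue
        r, p, n = spearman(levels.loc[key, samples], tpm.loc[gene, samples])
        if math.isnan(r):
            continue
        records.append(
            CorrelationRecord(
                key=(key, gene), kind="cis_expression", r=r, p=p, n=n,
                flagged=bool(p < alpha), low_n=n < LOW_N,
            )
        )
    return records


def enzyme_correlation(
    per_sample_mean_editing: pd.Series,
    tpm: pd.DataFrame,
    enzyme_genes: Iterable[str] = ("Adar", "Adarb1"),
    alpha: float = 0.05,
) -> list[CorrelationRecord]:
    """Spearman of per-sample mean editing vs editing-enzyme expression."""
    records: list[CorrelationRecord] = []
    for gene in enzyme_genes:
        if gene not in tpm.index:
            continue
        samples = [s for s in per_sample_mean_editing.index if s in tpm.columns]
        r, p, n = spearman(
            per_sample_mean_editing[samples], tpm.loc[gene, samples]
        )
        if math.isnan(r):
            continue
        records.append(
            CorrelationRecord(
                key=(gene,), kind="enzyme_expression", r=r, p=p, n=n,
                flagged=bool(p < alpha), low_n=n < LOW_N,
            )
        )
    return records


def records_to_frame(records: Iterable[CorrelationRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        if rec.kind == "time":
            chrom, pos, strand = rec.key
            site, gene = f"{chrom}:{pos}:{strand}", None
        elif rec.kind == "cis_expression":
            (chrom, pos, strand), gene = rec.key
            site = f"{chrom}:{pos}:{strand}"
        else:
            site, gene = None, rec.key[0]
        rows.append(
            {
                "site": site, "gene": gene, "kind": rec.kind,
                "r": rec.r, "p": rec.p, "n": rec.n,
                "flagged": rec.flagged, "low_n": rec.low_n,
            }
        )
    return pd.DataFrame(
        rows, columns=["site", "gene", "kind", "r", "p", "n", "flagged", "low_n"]
    )


def top_k_by_abs_r(records: Iterable[CorrelationRecord], k: int = 25) -> pd.DataFrame:
    """Top-k correlation table sorted by |r| (descending), ties by key."""
    frame = records_to_frame(records)
    frame["abs_r"] = frame["r"].abs()
    frame = frame.sort_values(
        ["abs_r", "site", "gene"], ascending=[False, True, True], na_position="last"
    ).drop(columns="abs_r")
    return frame.head(k).reset_index(drop=True)
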