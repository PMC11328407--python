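"""Differential RNA editing (DRE) across treatment groups.

The decision rule is a dual criterion per site:

1. a binomial GLM (logit link) of per-sample (edited, unedited) read counts
   on the group factor, tested against the intercept-only null with a
   likelihood-ratio test (chi-square with k-1 df) — the "empirical GLM p";
2. GLM FDR < threshold OR Fisher FDR < threshold, where the Fisher p comes
   from an exact R x 2 test on group-pooled reference/alternative counts,
   computed only for sites passing gate (1), and both FDRs are
   Benjamini-Hochberg adjustments. By default the Fisher adjustment uses
   multiplicity over all GLM-tested sites (selection by gate 1 is part of
   the procedure); a subset-only family is available but degenerates — on
   pooled counts Fisher and the GLM LRT are nearly the same test, so every
   selected Fisher p is small and subset-BH waves the whole subset through.

A site is differentially edited iff gate (1) and gate (2) both hold. Tukey
HSD on per-sample levels is emitted as a descriptive post-hoc and never
gates the decision.

With a single categorical predictor the binomial GLM has closed-form
maximum-likelihood fits (the group-pooled proportions), so the LRT deviance
difference is computed directly from the pooled counts; a unit test checks
the statistic against iteratively fitted GLMs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .design import StudyDesign
from .filtering import SITE_KEYS, event_counts, event_levels


@dataclass(frozen=True)
class DREConfig:
    glm_p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    missense_diff_threshold: float = 0.05  # on the proportion scale
    family: str = "binomial"
    empirical_p_mode: str = "lrt"  # or "permutation"
    fisher_bh_family: str = "all_tested"  # or "subset"
    n_perm: int = 1000
    fisher_enum_budget: int = 200_000  # max tables enumerated exactly
    fisher_n_mc: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.glm_p_threshold, self.fdr_threshold, self.missense_diff_threshold):
            if not (0 < t < 1):
                raise ValueError("thresholds must be in (0, 1)")
        if self.empirical_p_mode not in ("lrt", "permutation"):
            raise ValueError("empirical_p_mode must be 'lrt' or 'permutation'")
        if self.fisher_bh_family not in ("all_tested", "subset"):
            raise ValueError("fisher_bh_family must be 'all_tested' or 'subset'")


@dataclass
class SiteCountsByGroup:
    """Per-group allele counts for one site.

    ``alt``/``ref`` hold one integer array per group (covered samples only);
    pooled totals are their sums.
    """

    groups: list[str]
    alt: list[np.ndarray]
    ref: list[np.ndarray]

    @property
    def pooled_alt(self) -> np.ndarray:
        return np.array([a.sum() for a in self.alt], dtype=float)

    @property
    def pooled_ref(self) -> np.ndarray:
        return np.array([r.sum() for r in self.ref], dtype=float)

    def covered_groups(self, min_samples: int = 1):
        return [
            i
            for i in range(len(self.groups))
            if len(self.alt[i]) >= min_samples and (self.alt[i] + self.ref[i]).sum() > 0
        ]


def _binom_loglik(alt: np.ndarray, ref: np.ndarray, p: np.ndarray) -> float:
    # kernel only; constants cancel in the LRT
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.where(alt > 0, alt * np.log(p), 0.0)
        lr = np.where(ref > 0, ref * np.log1p(-p), 0.0)
    return float(np.sum(la) + np.sum(lr))


def glm_lrt_statistic(pooled_alt: np.ndarray, pooled_ref: np.ndarray) -> float:
    """Deviance difference of group model vs intercept-only binomial GLM."""
    alt = np.asarray(pooled_alt, dtype=float)
    ref = np.asarray(pooled_ref, dtype=float)
    tot = alt + ref
    p_group = np.divide(alt, tot, out=np.zeros_like(alt), where=tot > 0)
    p_null = alt.sum() / tot.sum()
    stat = 2.0 * (_binom_loglik(alt, ref, p_group) - _binom_loglik(alt, ref, np.full_like(alt, p_null)))
    return max(stat, 0.0)


def glm_lrt_test(
    site: SiteCountsByGroup,
    config: DREConfig | None = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float, bool]:
    """(p, LRT statistic, separation_adjusted) for one site.

    Requires >=2 groups with >=2 covered samples each; returns NaNs
    otherwise. Complete separation (a group entirely edited or entirely
    unedited) is guarded by adding 0.5 to every group's pooled ref and alt
    count (Haldane-Anscombe style), reported via the returned flag. In
    permutation mode the empirical p is the +1-smoothed tail proportion of
    the statistic under group-label shuffles of the per-sample count pairs.
    """
    config = config or DREConfig()
    idx = [
        i for i in range(len(site.groups))
        if len(site.alt[i]) >= 2 and (site.alt[i] + site.ref[i]).sum() > 0
    ]
    if len(idx) < 2:
        return math.nan, math.nan, False
    alt = site.pooled_alt[idx]
    ref = site.pooled_ref[idx]
    adjusted = bool(np.any(alt == 0) or np.any(ref == 0))
    if adjusted:
        alt = alt + 0.5
        ref = ref + 0.5
    stat = glm_lrt_statistic(alt, ref)
    df = len(idx) - 1
    if config.empirical_p_mode == "lrt":
        p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
        return p, stat, adjusted
    # permutation mode: shuffle sample->group labels, keep group sizes
    rng = rng or np.random.default_rng(config.seed)
    alt_s = np.concatenate([site.alt[i] for i in idx]).astype(float)
    ref_s = np.concatenate([site.ref[i] for i in idx]).astype(float)
    sizes = [len(site.alt[i]) for i in idx]
    bounds = np.cumsum([0] + sizes)
    exceed = 0
    n = len(alt_s)
    for _ in range(config.n_perm):
        perm = rng.permutation(n)
        pa = np.array([alt_s[perm[bounds[j]:bounds[j + 1]]].sum() for j in range(len(sizes))])
        pr = np.array([ref_s[perm[bounds[j]:bounds[j + 1]]].sum() for j in range(len(sizes))])
        if adjusted:
            pa, pr = pa + 0.5, pr + 0.5
        if glm_lrt_statistic(pa, pr) >= stat - 1e-12:
            exceed += 1
    p = (exceed + 1) / (config.n_perm + 1)
    return float(p), stat, adjusted


# ---- exact R x 2 Fisher test ------------------------------------------------

_REL_TOL = 1e-7


def _table_count_bound(rows: np.ndarray, c1: int) -> float:
    return float(np.prod([min(int(r), c1) + 1 for r in rows]))


def fisher_rx2_test(
    table: Sequence[Sequence[int]] | np.ndarray,
    enum_budget: int = 200_000,
    n_mc: int = 20_000,
    rng: Optional[np.random.Generator] = None,
    return_total: bool = False,
) -> tuple[float, str] | tuple[float, str, float]:
    """Two-sided exact Fisher test for an R x 2 table; (p, method).

    p is the total probability, under fixed margins, of tables whose point
    probability is <= the observed one (within 1e-7 relative tolerance).
    Exact recursive enumeration is used while the number of candidate tables
    stays under ``enum_budget``; beyond that a seeded Monte-Carlo sample of
    margin-fixed tables (multivariate hypergeometric) is used and the method
    string says so. With ``return_total`` the summed point probability over
    all enumerated tables is also returned (1 for the exact branch, NaN
    otherwise) as a self-consistency diagnostic.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("expected an R x 2 table")
    if (t < 0).any():
        raise ValueError("negative cell")
    t = t[t.sum(axis=1) > 0]
    if t.shape[0] < 2:
        return (1.0, "degenerate", math.nan) if return_total else (1.0, "degenerate")
    rows = t.sum(axis=1)
    c1 = int(t[:, 0].sum())
    c2 = int(t[:, 1].sum())
    if c1 == 0 or c2 == 0:
        warnings.warn("degenerate table: one allele column is all zero; p = 1")
        return (1.0, "degenerate", math.nan) if return_total else (1.0, "degenerate")
    n = int(rows.sum())

    def log_prob(a: np.ndarray) -> float:
        # product of per-row binomials over the hypergeometric normaliser
        return float(
            np.sum(gammaln(rows + 1) - gammaln(a + 1) - gammaln(rows - a + 1))
            + gammaln(c1 + 1) + gammaln(c2 + 1) - gammaln(n + 1)
        )

    obs_lp = log_prob(t[:, 0].astype(np.float64))
    cutoff = obs_lp + math.log1p(_REL_TOL)

    if _table_count_bound(rows, c1) <= enum_budget:
        k = len(rows)
        lg_rows = gammaln(rows + 1)
        norm = gammaln(c1 + 1) + gammaln(c2 + 1) - gammaln(n + 1)
        suffix = np.concatenate([np.cumsum(rows[::-1])[::-1][1:], [0]])
        total = 0.0
        p_sum = 0.0

        def descend(i: int, rem: int, lp: float) -> None:
            nonlocal total, p_sum
            if i == k - 1:
                if 0 <= rem <= rows[-1]:
                    lp_f = lp + lg_rows[-1] - gammaln(rem + 1) - gammaln(rows[-1] - rem + 1) + norm
                    pr = math.exp(lp_f)
                    total += pr
                    if lp_f <= cutoff:
                        p_sum += pr
                return
            lo = max(0, rem - int(suffix[i]))
            hi = min(int(rows[i]), rem)
            for a in range(lo, hi + 1):
                descend(i + 1, rem - a, lp + lg_rows[i] - gammaln(a + 1) - gammaln(rows[i] - a + 1))

        descend(0, c1, 0.0)
        # total sums to 1 by construction; min() guards fp overshoot
        p = min(p_sum / total, 1.0)
        return (p, "exact", total) if return_total else (p, "exact")

    rng = rng or np.random.default_rng(0)
    draws = rng.multivariate_hypergeometric(rows.astype(np.int64), c1, size=n_mc)
    lps = (
        np.sum(gammaln(rows + 1) - gammaln(draws + 1) - gammaln(rows - draws + 1), axis=1)
        + gammaln(c1 + 1) + gammaln(c2 + 1) - gammaln(n + 1)
    )
    p = (1 + int(np.sum(lps <= cutoff))) / (n_mc + 1)
    return (float(p), "monte_carlo", math.nan) if return_total else (float(p), "monte_carlo")


def bh_adjust(p_values: Sequence[float] | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through.

    Input order is preserved; adjusted values are capped at 1 and made
    monotone in rank, per the standard step-up recipe.
    """
    from statsmodels.stats.multitest import multipletests

    arr = np.asarray(p_values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if mask.sum() == 0:
        return out
    vals = arr[mask]
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def tukey_hsd(
    levels_by_group: dict[str, np.ndarray]
) -> tuple[dict[tuple[str, str], float], bool]:
    """All-pairs Tukey HSD p-values from per-group editing levels.

    Returns (pair -> p, degenerate_flag). When every group has zero
    within-group variance the studentized range is undefined; the limit
    convention assigns p = 0 to pairs with unequal means and p = 1 to equal
    ones, and the flag is set.
    """
    names = sorted(levels_by_group)
    samples = [np.asarray(levels_by_group[g], dtype=float) for g in names]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >=2 groups with >=2 samples each")
    if any(np.isnan(s).any() for s in samples):
        raise ValueError("missing levels; drop them before the post-hoc")
    sse = sum(((s - s.mean()) ** 2).sum() for s in samples)
    out: dict[tuple[str, str], float] = {}
    if sse == 0:
        for a, b in itertools.combinations(range(len(names)), 2):
            equal = samples[a].mean() == samples[b].mean()
            out[(names[a], names[b])] = 1.0 if equal else 0.0
        return out, True
    res = stats.tukey_hsd(*samples)
    for a, b in itertools.combinations(range(len(names)), 2):
        out[(names[a], names[b])] = float(res.pvalue[a, b])
    return out, False


def decide_dre(
    glm_p: float,
    glm_fdr: float,
    fisher_fdr: Optional[float],
    config: DREConfig | None = None,
) -> bool:
    """The dual decision: GLM p below threshold AND either FDR below it."""
    config = config or DREConfig()
    if glm_p is None or math.isnan(glm_p):
        return False
    gate1 = glm_p < config.glm_p_threshold
    fdr_ok = (not math.isnan(glm_fdr) and glm_fdr < config.fdr_threshold) or (
        fisher_fdr is not None
        and not math.isnan(fisher_fdr)
        and fisher_fdr < config.fdr_threshold
    )
    return bool(gate1 and fdr_ok)


def flag_missense_diff(
    is_dre: bool,
    category: Optional[str],
    max_intergroup_diff: float,
    config: DREConfig | None = None,
) -> bool:
    """Missense DRE with more than 5% spread between group mean levels."""
    config = config or DREConfig()
    return bool(
        is_dre
        and category == "missense"
        and max_intergroup_diff > config.missense_diff_threshold
    )


def site_counts_by_group(
    events: pd.DataFrame, design: StudyDesign
) -> dict[tuple, SiteCountsByGroup]:
    """Assemble per-site, per-group count arrays from a wide events table."""
    alt = event_counts(events, "alt")
    ref = event_counts(events, "ref")
    groups = design.groups
    group_samples = {
        g: [s for s in design.samples_in_group(g) if s in alt.columns] for g in groups
    }
    out = {}
    for key in alt.index:
        a_row, r_row = alt.loc[key], ref.loc[key]
        site_alt, site_ref = [], []
        for g in groups:
            gs = [s for s in group_samples[g] if not pd.isna(a_row[s])]
            site_alt.append(a_row[gs].to_numpy(dtype=float))
            site_ref.append(r_row[gs].to_numpy(dtype=float))
        out[key] = SiteCountsByGroup(groups=list(groups), alt=site_alt, ref=site_ref)
    return out


def run_differential_editing(
    events: pd.DataFrame,
    design: StudyDesign,
    config: DREConfig | None = None,
    annotations: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Full per-site DRE analysis over a high-confidence events table.

    Returns one row per site: glm_p, glm_fdr, fisher_p/fisher_fdr (gate-1
    subset only), is_dre, per-group mean levels, max intergroup difference,
    Tukey pair p-values, and the missense >5%-spread flag when annotations
    are supplied.
    """
    config = config or DREConfig()
    rng = np.random.default_rng(config.seed)
    counts = site_counts_by_group(events, design)
    levels = event_levels(events)
    keys = list(counts)

    rows = []
    for key in keys:
        p, stat, adjusted = glm_lrt_test(counts[key], config, rng)
        rows.append({"site": key, "glm_p": p, "glm_stat": stat, "separation_adjusted": adjusted})
    res = pd.DataFrame(rows)
    res["glm_fdr"] = bh_adjust(res["glm_p"])

    # Fisher only for gate-1 sites; BH within that subset
    fisher_p = np.full(len(res), np.nan)
    gate1 = res["glm_p"] < config.glm_p_threshold
    for i in np.flatnonzero(gate1.to_numpy()):
        site = counts[keys[i]]
        idx = site.covered_groups()
        table = np.column_stack([site.pooled_ref[idx], site.pooled_alt[idx]])
        fisher_p[i], _ = fisher_rx2_test(
            table, enum_budget=config.fisher_enum_budget, n_mc=config.fisher_n_mc, rng=rng
        )
    res["fisher_p"] = fisher_p
    if config.fisher_bh_family == "all_tested":
        # selection by gate 1 is part of the procedure: adjust with
        # multiplicity over every GLM-tested site (untested Fisher p -> 1)
        padded = np.where(
            np.isnan(fisher_p) & res["glm_p"].notna().to_numpy(), 1.0, fisher_p
        )
        res["fisher_fdr"] = np.where(np.isnan(fisher_p), np.nan, bh_adjust(padded))
    else:  # BH within the gate-1 subset only
        res["fisher_fdr"] = bh_adjust(res["fisher_p"])

    group_means, max_diffs, tukey_cols = [], [], []
    pair_names = [
        f"tukey_{a}_vs_{b}" for a, b in itertools.combinations(sorted(design.groups), 2)
    ]
    for key in keys:
        lv = levels.loc[key]
        means = {}
        by_group = {}
        for g in design.groups:
            gs = [s for s in design.samples_in_group(g) if s in lv.index]
            vals = lv[gs].dropna().to_numpy(dtype=float)
            by_group[g] = vals
            means[g] = float(vals.mean()) if len(vals) else np.nan
        group_means.append(means)
        finite = [v for v in means.values() if not math.isnan(v)]
        max_diffs.append(max(finite) - min(finite) if len(finite) >= 2 else np.nan)
        try:
            pairs, _ = tukey_hsd({g: v for g, v in by_group.items() if len(v) >= 2})
            tukey_cols.append(
                {f"tukey_{a}_vs_{b}": p for (a, b), p in pairs.items()}
            )
        except ValueError:
            tukey_cols.append({})
    for g in design.groups:
        res[f"mean_{g}"] = [m.get(g, np.nan) for m in group_means]
    res["max_intergroup_diff"] = max_diffs
    for name in pair_names:
        res[name] = [t.get(name, np.nan) for t in tukey_cols]

    res["is_dre"] = [
        decide_dre(r.glm_p, r.glm_fdr, r.fisher_fdr, config) for r in res.itertuples()
    ]

    res[SITE_KEYS] = pd.DataFrame(res["site"].tolist(), index=res.index)
    res = res.drop(columns=["site"])
    if annotations is not None:
        res = res.merge(
            annotations[SITE_KEYS + ["category", "gene_id", "hgvs_c", "hgvs_p"]],
            on=SITE_KEYS,
            how="left",
        )
        res["missense_flag"] = [
            flag_missense_diff(r.is_dre, r.category, r.max_intergroup_diff, config)
            for r in res.itertuples()
        ]
    front = SITE_KEYS + [c for c in res.columns if c not in SITE_KEYS]
    return res[front]


def manhattan_table(dre: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (chrom, pos, -log10 p) table from a DRE result frame."""
    out = dre[SITE_KEYS + ["glm_p"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["glm_p"])
    return out
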