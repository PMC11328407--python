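"""High-confidence editing events: retention, activity summaries, overlaps.

A candidate site graduates to a high-confidence editing event when its
editing level is >= 1% in at least two samples, or when it is a known
editing site (REDIportal-style list) — the rescue clause. Rescued sites
still need a passing call in at least one sample, so zero-evidence known
sites never enter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .design import StudyDesign

SITE_KEYS = ["chrom", "pos", "strand"]


def read_known_sites(path) -> pd.DataFrame:
    """Known-site TSV: chrom, pos (1-based), ref, alt (or 'A-to-I'), strand."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos"} - set(frame.columns)
    if missing:
        raise ValueError(f"known-site table missing columns: {sorted(missing)}")
    return frame


def known_site_set(known: Optional[pd.DataFrame]) -> set[tuple[str, int]]:
    if known is None or len(known) == 0:
        return set()
    return {(str(c), int(p)) for c, p in zip(known["chrom"], known["pos"])}


def retain_high_confidence(
    calls: pd.DataFrame,
    known: Optional[pd.DataFrame] = None,
    min_level: float = 0.01,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Aggregate A-to-I typed calls into high-confidence events.

    Parameters
    ----------
    calls:
        Long call table (one row per site x sample) with columns chrom, pos,
        strand, sample_id, ref_count, alt_count, level, is_a_to_i, passes.
    known:
        Optional known-site table; membership rescues sites observed passing
        in fewer than ``min_samples`` samples.

    Returns a wide events table keyed by (chrom, pos, strand) with
    ``level_<sample>``, ``ref_<sample>``, ``alt_<sample>`` and
    ``detected_<sample>`` columns plus ``is_known``.
    """
    atoi = calls[calls["is_a_to_i"] == True]  # noqa: E712 (NaN-safe mask)
    if len(atoi) == 0:
        return pd.DataFrame(columns=SITE_KEYS + ["is_known"])
    known_set = known_site_set(known)

    passing = atoi[atoi["passes"]]
    strong = passing[passing["level"] >= min_level]
    by_site_strong = strong.groupby(SITE_KEYS)["sample_id"].nunique()
    multi_sample = set(by_site_strong[by_site_strong >= min_samples].index)

    by_site_pass = passing.groupby(SITE_KEYS)["sample_id"].nunique()
    has_pass = set(by_site_pass[by_site_pass >= 1].index)
    rescued = {
        key for key in has_pass if (key[0], key[1]) in known_set
    }

    keep = multi_sample | rescued
    if not keep:
        return pd.DataFrame(columns=SITE_KEYS + ["is_known"])

    sub = atoi.set_index(SITE_KEYS)
    sub = sub[sub.index.isin(keep)].reset_index()

    level = sub.pivot_table(index=SITE_KEYS, columns="sample_id", values="level")
    ref = sub.pivot_table(index=SITE_KEYS, columns="sample_id", values="ref_count")
    alt = sub.pivot_table(index=SITE_KEYS, columns="sample_id", values="alt_count")
    det = sub.pivot_table(
        index=SITE_KEYS, columns="sample_id", values="passes", aggfunc="any"
    )

    out = pd.concat(
        {
            "level": level,
            "ref": ref,
            "alt": alt,
            "detected": det,
        },
        axis=1,
    )
    out.columns = [f"{kind}_{sample}" for kind, sample in out.columns]
    out = out.reset_index()
    out["is_known"] = [
        (str(c), int(p)) in known_set for c, p in zip(out["chrom"], out["pos"])
    ]
    return out.sort_values(SITE_KEYS).reset_index(drop=True)


def event_levels(events: pd.DataFrame) -> pd.DataFrame:
    """Site x sample editing-level matrix from a wide events table."""
    cols = [c for c in events.columns if c.startswith("level_")]
    mat = events.set_index(
        pd.MultiIndex.from_frame(events[SITE_KEYS])
    )[cols]
    mat.columns = [c[len("level_"):] for c in cols]
    return mat


def event_counts(events: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Site x sample ref or alt count matrix (kind in {'ref','alt'})."""
    cols = [c for c in events.columns if c.startswith(f"{kind}_")]
    mat = events.set_index(pd.MultiIndex.from_frame(events[SITE_KEYS]))[cols]
    mat.columns = [c[len(kind) + 1:] for c in cols]
    return mat


def event_detected(events: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in events.columns if c.startswith("detected_")]
    mat = events.set_index(pd.MultiIndex.from_frame(events[SITE_KEYS]))[cols]
    mat.columns = [c[len("detected_"):] for c in cols]
    return mat.fillna(False).astype(bool)


@dataclass(frozen=True)
class ActivitySummary:
    per_sample_mean: pd.Series  # mean level over sites called in the sample
    per_group_mean: pd.Series  # mean of sample means within each group
    per_group_pooled_mean: pd.Series  # mean over all site x sample values
    per_group_event_count: pd.Series  # sites detected in >=1 sample of group


def summarize_activity(events: pd.DataFrame, design: StudyDesign) -> ActivitySummary:
    """Per-sample and per-group average editing level and event counts.

    The default group mean averages sites within a sample first, then
    samples within the group; the pooled alternative (all site x sample
    values of a group at once) is also reported.
    """
    if len(events) == 0:
        raise ValueError("no events to summarize")
    levels = event_levels(events)
    detected = event_detected(events)
    samples = [s for s in design.sample_ids if s in levels.columns]
    levels = levels[samples]
    per_sample = levels.mean(axis=0, skipna=True)
    group_mean, pooled, counts = {}, {}, {}
    for g in design.groups:
        gs = [s for s in design.samples_in_group(g) if s in levels.columns]
        if not gs or levels[gs].notna().sum().sum() == 0:
            warnings.warn(f"group {g!r} has no non-missing editing levels")
            group_mean[g] = np.nan
            pooled[g] = np.nan
            counts[g] = 0
            continue
        group_mean[g] = per_sample[gs].mean()
        pooled[g] = levels[gs].stack().mean()
        gdet = [s for s in gs if s in detected.columns]
        counts[g] = int(detected[gdet].any(axis=1).sum()) if gdet else 0
    return ActivitySummary(
        per_sample_mean=per_sample,
        per_group_mean=pd.Series(group_mean, name="mean_editing_level"),
        per_group_pooled_mean=pd.Series(pooled, name="pooled_mean_editing_level"),
        per_group_event_count=pd.Series(counts, name="n_events"),
    )


def venn_regions(named_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts of a Venn diagram over named sets.

    Keys are sorted tuples of the set names whose exclusive intersection the
    count belongs to; regions sum to the size of the union.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(named_sets)
    regions: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(
                *(named_sets[n] for n in names if n not in combo), set()
            ) if len(combo) < len(names) else set()
            regions[combo] = len(inside - outside)
    return regions


@dataclass(frozen=True)
class GroupPresence:
    presence: pd.DataFrame  # site x group boolean
    shared_fraction: float  # events present in all groups / total events
    regions: dict[tuple[str, ...], int]


def group_presence(events: pd.DataFrame, design: StudyDesign) -> GroupPresence:
    """Which groups each event is detected in, plus Venn region counts."""
    if len(events) == 0:
        raise ValueError("no events")
    detected = event_detected(events)
    presence = pd.DataFrame(index=detected.index)
    for g in design.groups:
        gs = [s for s in design.samples_in_group(g) if s in detected.columns]
        presence[g] = detected[gs].any(axis=1) if gs else False
    shared = float(presence.all(axis=1).mean())
    named = {
        g: set(presence.index[presence[g]].tolist()) for g in design.groups
    }
    return GroupPresence(
        presence=presence, shared_fraction=shared, regions=venn_regions(named)
    )
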