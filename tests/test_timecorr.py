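"""Spearman machinery and the time / cis / enzyme correlation analyses."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from rnaedit.calling import calls_to_frame, records_from_table, screen_records, type_calls
from rnaedit.annotate import TranscriptIndex
from rnaedit.design import lps_design
from rnaedit.expression import tpm
from rnaedit.filtering import retain_high_confidence
from rnaedit.simulate import SimulationConfig, generate_dataset
from rnaedit.timecorr import (
    cis_expression_correlation,
    enzyme_correlation,
    spearman,
    time_dependent_sites,
    top_k_by_abs_r,
)


def rank_formula_spearman(x, y):
    """Independent oracle: Pearson correlation of average ranks."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearman:
    def test_perfect_monotone(self):
        r, p, n = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_constant_vector_missing(self):
        r, p, _ = spearman([1, 2, 3, 4], [5, 5, 5, 5])
        assert math.isnan(r) and math.isnan(p)

    def test_fewer_than_three_pairs_missing(self):
        r, p, n = spearman([1, 2], [3, 4])
        assert math.isnan(r) and n == 2

    def test_pairwise_missing_removal(self):
        r, _, n = spearman([1, 2, np.nan, 4, 5], [1, np.nan, 3, 4, 5])
        assert n == 3 and r == pytest.approx(1.0)

    def test_tied_fixtures_match_rank_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            x = rng.integers(0, 4, 12).astype(float)  # heavy ties
            y = rng.integers(0, 5, 12).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            r, _, _ = spearman(x, y)
            assert r == pytest.approx(rank_formula_spearman(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 15)
        y = rng.uniform(0, 1, 15)
        r0, p0, _ = spearman(x, y)
        r1, p1, _ = spearman(np.exp(3 * x), y**3 + 2)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 1, 12)
        y = rng.uniform(0, 1, 12)
        r0, p0, _ = spearman(x, y)
        r1, p1, _ = spearman(x, -y)
        assert r1 == pytest.approx(-r0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_permutation_p_close_to_t_approx(self):
        rng = np.random.default_rng(14)
        x = np.arange(12.0)
        y = x + rng.normal(0, 4, 12)
        _, p_t, _ = spearman(x, y)
        _, p_perm, _ = spearman(x, y, method="permutation", n_perm=4000, seed=2)
        assert p_perm == pytest.approx(p_t, abs=0.05)


def _events_from_levels(levels: pd.DataFrame) -> pd.DataFrame:
    out = levels.copy()
    out.columns = [f"level_{c}" for c in levels.columns]
    out = out.reset_index()
    return out


class TestTimeDependentSites:
    def test_linear_trend_site_flagged(self, design4x3):
        """A site rising linearly in time at depth 500 is flagged with a
        strong positive correlation."""
        rng = np.random.default_rng(1)
        samples = design4x3.sample_ids
        levels = {
            s: rng.binomial(500, 0.1 + 0.0005 * design4x3.time_of(s)) / 500
            for s in samples
        }
        frame = pd.DataFrame([{"chrom": "chr1", "pos": 1, "strand": "+", **{
            f"level_{s}": v for s, v in levels.items()}}])
        (rec,) = time_dependent_sites(frame, design4x3)
        # the early time points (0/15/30 min) differ by less than binomial
        # noise at depth 500, so r saturates well below 1 even here
        assert rec.flagged and rec.r > 0.7 and rec.p < 0.01

    def test_too_few_samples_gives_no_record(self, design4x3):
        row = {"chrom": "chr1", "pos": 1, "strand": "+"}
        for i, s in enumerate(design4x3.sample_ids):
            row[f"level_{s}"] = 0.1 + 0.01 * i if i < 2 else np.nan
        assert time_dependent_sites(pd.DataFrame([row]), design4x3) == []

    def test_negating_levels_negates_r_preserves_p(self, design4x3):
        rng = np.random.default_rng(2)
        row = {"chrom": "chr1", "pos": 1, "strand": "+"}
        neg = dict(row)
        for s in design4x3.sample_ids:
            v = 0.1 + 0.001 * design4x3.time_of(s) + rng.normal(0, 0.02)
            row[f"level_{s}"] = v
            neg[f"level_{s}"] = 1 - v
        (a,) = time_dependent_sites(pd.DataFrame([row]), design4x3)
        (b,) = time_dependent_sites(pd.DataFrame([neg]), design4x3)
        assert b.r == pytest.approx(-a.r, abs=1e-12)
        assert b.p == pytest.approx(a.p, abs=1e-12)

    def test_null_sites_calibrated(self, design4x3):
        """Truth-null sites are flagged at close to the nominal rate."""
        rng = np.random.default_rng(33)
        n = 800
        rows = []
        for i in range(n):
            row = {"chrom": "chr1", "pos": i + 1, "strand": "+"}
            for s in design4x3.sample_ids:
                depth = max(int(rng.negative_binomial(5, 5 / 55)), 1)
                row[f"level_{s}"] = rng.binomial(depth, 0.1) / depth
            rows.append(row)
        recs = time_dependent_sites(pd.DataFrame(rows), design4x3)
        frac = np.mean([r.flagged for r in recs])
        assert 0.02 <= frac <= 0.09


@pytest.fixture(scope="module")
def cis_dataset():
    config = SimulationConfig(
        n_sites=120, seed=19, frac_dre=0.0, frac_time_trend=0.3, frac_cis=0.2,
        depth_nb_params=(100.0, 5.0),
    )
    return generate_dataset(config)


class TestCisAndEnzyme:
    def _events_and_tpm(self, dataset):
        index = TranscriptIndex(dataset.transcripts)
        calls = calls_to_frame(
            type_calls(screen_records(records_from_table(dataset.allele_counts)), index.strand_at)
        )
        events = retain_high_confidence(calls, dataset.known_sites)
        counts = dataset.gene_counts.set_index("gene_id")
        lengths = counts.pop("length").astype(float)
        return events, tpm(counts, lengths)

    def test_cis_sites_positive_and_significant(self, cis_dataset):
        dataset, truth = cis_dataset
        events, tpm_table = self._events_and_tpm(dataset)
        gene_map = {
            (r.chrom, r.pos, r.strand): r.gene_id for r in truth.itertuples()
        }
        recs = cis_expression_correlation(events, tpm_table, gene_map)
        by_site = {rec.key[0]: rec for rec in recs}
        cis_truth = truth[truth.is_cis]
        found = [
            by_site[(r.chrom, r.pos, r.strand)]
            for r in cis_truth.itertuples()
            if (r.chrom, r.pos, r.strand) in by_site
        ]
        assert len(found) >= 0.8 * len(cis_truth)
        # per-sample NB expression noise keeps individual p-values modest;
        # the systematic signature is positivity plus enrichment of small p
        assert np.mean([rec.r > 0 for rec in found]) >= 0.95
        cis_sig = np.mean([rec.p < 0.05 for rec in found])
        null_keys = {
            (r.chrom, r.pos, r.strand)
            for r in truth[~truth.is_cis & ~truth.is_time_trend].itertuples()
        }
        null_sig = np.mean([rec.p < 0.05 for rec in recs if rec.key[0] in null_keys])
        assert cis_sig > 3 * max(null_sig, 0.05)
        best = max(found, key=lambda rec: rec.r)
        assert best.r > 0.7 and best.p < 0.01

    def test_permuting_expression_attenuates_r(self, cis_dataset):
        dataset, truth = cis_dataset
        events, tpm_table = self._events_and_tpm(dataset)
        gene_map = {(r.chrom, r.pos, r.strand): r.gene_id for r in truth.itertuples()}
        recs = cis_expression_correlation(events, tpm_table, gene_map)
        cis_keys = {
            (r.chrom, r.pos, r.strand) for r in truth[truth.is_cis].itertuples()
        }
        base = np.mean([abs(r.r) for r in recs if r.key[0] in cis_keys])
        rng = np.random.default_rng(3)
        perm_means = []
        for _ in range(20):
            shuffled = tpm_table.copy()
            shuffled.columns = rng.permutation(tpm_table.columns)
            precs = cis_expression_correlation(events, shuffled, gene_map)
            perm_means.append(
                np.mean([abs(r.r) for r in precs if r.key[0] in cis_keys])
            )
        assert np.mean(perm_means) < base

    def test_missing_gene_skipped(self, design4x3):
        frame = _events_from_levels(
            pd.DataFrame(
                {s: [0.1 + 0.01 * i for i in range(1)] for s in design4x3.sample_ids},
                index=pd.MultiIndex.from_tuples(
                    [("chr1", 1, "+")], names=["chrom", "pos", "strand"]
                ),
            )
        )
        tpm_table = pd.DataFrame(
            {s: [1.0] for s in design4x3.sample_ids}, index=["other_gene"]
        )
        assert cis_expression_correlation(
            frame, tpm_table, {("chr1", 1, "+"): "absent"}
        ) == []

    def test_enzyme_tracking_construction(self):
        """When global editing is built to follow the ADAR2-like enzyme,
        that enzyme correlates more strongly than the flat ADAR1-like one."""
        config = SimulationConfig(
            n_sites=300, seed=23, frac_dre=0.0, frac_time_trend=0.6, frac_cis=0.0,
            effect_size=0.2, depth_nb_params=(100.0, 5.0), trend_positive_frac=1.0,
        )
        dataset, truth = generate_dataset(config)
        events, tpm_table = self._events_and_tpm(dataset)
        from rnaedit.filtering import summarize_activity

        activity = summarize_activity(events, dataset.design)
        recs = enzyme_correlation(activity.per_sample_mean, tpm_table)
        by_gene = {r.key[0]: r for r in recs}
        assert abs(by_gene["Adarb1"].r) > abs(by_gene["Adar"].r)
        assert by_gene["Adarb1"].r > 0

    def test_identical_enzyme_trajectories_identical_records(self, design4x3):
        mean_editing = pd.Series(
            np.linspace(0.1, 0.3, 12), index=design4x3.sample_ids
        )
        expr = pd.DataFrame(
            [np.linspace(10, 40, 12)] * 2,
            index=["Adar", "Adarb1"],
            columns=design4x3.sample_ids,
        )
        a, b = enzyme_correlation(mean_editing, expr)
        assert (a.r, a.p, a.n) == (b.r, b.p, b.n)

    def test_low_n_flagged(self):
        mean_editing = pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"])
        expr = pd.DataFrame(
            {"a": [1.0], "b": [2.0], "c": [3.0]}, index=["Adar"]
        )
        (rec,) = enzyme_correlation(mean_editing, expr)
        assert rec.low_n and not math.isnan(rec.p)


def test_top_k_sorted_by_abs_r(design4x3):
    rng = np.random.default_rng(30)
    rows = []
    for i in range(40):
        row = {"chrom": "chr1", "pos": i + 1, "strand": "+"}
        slope = rng.uniform(-0.002, 0.002)
        for s in design4x3.sample_ids:
            row[f"level_{s}"] = 0.2 + slope * design4x3.time_of(s) + rng.normal(0, 0.01)
        rows.append(row)
    recs = time_dependent_sites(pd.DataFrame(rows), design4x3)
    top = top_k_by_abs_r(recs, k=25)
    assert len(top) == 25
    assert (top["r"].abs().diff().dropna() <= 1e-12).all()
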