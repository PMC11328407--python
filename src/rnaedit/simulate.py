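"""Synthetic LPS time-course data with known ground truth.

Generates every input the analysis consumes — per-site per-sample allele
counts, a gene-count matrix with lengths, transcript models with CDS
sequences, a known-site list and the study design — plus a truth table, so
each downstream stage can be tested by recovery against known answers.

The generative model mirrors the study structure: four time-point groups
(PBS control at 0 min) with three replicates each; per-site baseline
editing levels drawn from a beta distribution; negative-binomial sequencing
depth; binomial edited-read counts given depth and level. Designated site
blocks carry a group effect (differential editing), a monotone-in-time
effect (saturating in log-time, mimicking a fast LPS response), or a
cis-regulatory link in which the host gene's expression rises with the
site's group-mean editing. An ADAR2-like enzyme gene's expression tracks
the per-sample mean editing level while an ADAR1-like gene stays flat.
Decoy sites carry non-A-to-G mismatches and must be removed by A-to-I
typing, never by luck.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotate import TranscriptModel, write_cds_fasta, write_transcript_table
from .calling import complement
from .design import StudyDesign, lps_design

_NON_STOP_CODONS = sorted(
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA")
)
# (codon, edited offset) pairs whose A>G edit is missense / synonymous
_MISSENSE_CODONS = [("AGC", 1), ("AAA", 1), ("CAA", 2), ("CAT", 2), ("AAG", 2), ("TAC", 2)]
_SYNONYMOUS_CODONS = [(c, 3) for c in ("GCA", "CCA", "GGA", "ACA", "GTA", "CTA", "TCA", "CGA")]
_NON_AG_PAIRS = [
    (r, a) for r in "ACGT" for a in "ACGT" if r != a and (r, a) != ("A", "G")
]

DEFAULT_CATEGORY_MIX = {
    "3UTR": 0.40,
    "missense": 0.15,
    "intronic": 0.20,
    "lincRNA": 0.10,
    "synonymous": 0.05,
    "5UTR": 0.10,
}

# transcript-space layout of simulated protein-coding genes (bases)
_UTR5, _CDS_LEN, _UTR3 = 100, 300, 300
_EXON1_LEN, _INTRON_LEN = 200, 400
_GENE_SPACING = 5_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults encode a cerebral-vessels-like design: 4 groups (PBS, then 15,
    30 and 240 minutes post-LPS) x 3 replicates; baseline editing levels
    Beta(2, 18) (mean 10%, the scale typical of bulk editing screens);
    depth negative-binomial with mean 50 and dispersion 5; additive group
    effects of 0.15 on the proportion scale.
    """

    n_groups: int = 4
    n_replicates: int = 3
    group_times_min: tuple[int, ...] = (0, 15, 30, 240)
    n_sites: int = 500
    frac_dre: float = 0.10
    frac_time_trend: float = 0.10
    frac_cis: float = 0.05
    baseline_beta_params: tuple[float, float] = (2.0, 18.0)
    effect_size: float = 0.15
    depth_nb_params: tuple[float, float] = (50.0, 5.0)
    decoy_mismatch_frac: float = 0.10
    trend_positive_frac: float = 0.70  # most time-trends rise post-LPS
    category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    known_site_frac: float = 0.30
    minus_strand_frac: float = 0.30
    tissue: str = "cerebral_vessels"
    clip_tolerance: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 10:
            raise ValueError("n_sites must be >= 10")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if len(self.group_times_min) != self.n_groups:
            raise ValueError("group_times_min must have n_groups entries")
        if list(self.group_times_min) != sorted(set(self.group_times_min)):
            raise ValueError("group_times_min must be strictly increasing")
        for name in ("frac_dre", "frac_time_trend", "frac_cis", "decoy_mismatch_frac",
                     "known_site_frac", "minus_strand_frac", "trend_positive_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        if self.frac_cis > self.frac_time_trend:
            raise ValueError(
                "frac_cis must not exceed frac_time_trend (cis sites need a "
                "non-constant editing trajectory to track)"
            )
        a, b = self.baseline_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("beta parameters must be positive")
        if not (0 <= self.effect_size < 1):
            raise ValueError("effect_size must be in [0, 1)")
        # an effect that cannot fit inside [0,1] in either direction is
        # unusable no matter the baseline draw
        if self.effect_size > 1 - 2 * self.clip_tolerance:
            raise ValueError("effect_size pushes levels outside [0, 1]")

    @property
    def group_labels(self) -> list[str]:
        return ["PBS" if t == 0 else f"LPS_{t}min" for t in self.group_times_min]


@dataclass
class SimulatedDataset:
    allele_counts: pd.DataFrame
    gene_counts: pd.DataFrame  # gene_id, length, one column per sample
    transcripts: list[TranscriptModel]
    cds_sequences: dict[str, str]
    known_sites: pd.DataFrame
    design: StudyDesign
    config: SimulationConfig


def _transcript_range_to_intervals(exons, strand, t_lo, t_hi):
    """Genomic intervals covered by a transcript-coordinate range."""
    ivals = []
    acc = 0
    oriented = exons if strand == "+" else tuple(reversed(exons))
    for gs, ge in oriented:
        length = ge - gs + 1
        lo, hi = max(t_lo, acc + 1), min(t_hi, acc + length)
        if lo <= hi:
            if strand == "+":
                ivals.append((gs + (lo - acc - 1), gs + (hi - acc - 1)))
            else:
                ivals.append((ge - (hi - acc - 1), ge - (lo - acc - 1)))
        acc += length
    return tuple(sorted(ivals))


def _make_gene(
    idx: int, category: str, strand: str, rng: np.random.Generator
) -> tuple[TranscriptModel, Optional[str], int]:
    """Build one gene hosting one site; returns (model, cds_seq, site_pos)."""
    start = 1 + idx * _GENE_SPACING
    gene_id = f"gene{idx:05d}"
    tid = f"tx{idx:05d}"
    if category == "lincRNA":
        exons = ((start, start + _UTR5 + _CDS_LEN + _UTR3 - 1),)
        model = TranscriptModel(gene_id, tid, "chr1", strand, exons, (), "lincRNA")
        tpos = int(rng.integers(1, model.exonic_length + 1))
        return model, None, model.transcript_to_genomic(tpos)

    exon1 = (start, start + _EXON1_LEN - 1)
    exon2_start = exon1[1] + _INTRON_LEN + 1
    exon2 = (exon2_start, exon2_start + (_UTR5 + _CDS_LEN + _UTR3 - _EXON1_LEN) - 1)
    exons = (exon1, exon2)
    cds = _transcript_range_to_intervals(exons, strand, _UTR5 + 1, _UTR5 + _CDS_LEN)
    model = TranscriptModel(gene_id, tid, "chr1", strand, exons, cds, "protein_coding")

    codons = ["ATG"] + [
        _NON_STOP_CODONS[i]
        for i in rng.integers(0, len(_NON_STOP_CODONS), _CDS_LEN // 3 - 2)
    ] + ["TAA"]
    if category in ("missense", "synonymous"):
        pool = _MISSENSE_CODONS if category == "missense" else _SYNONYMOUS_CODONS
        codon, offset = pool[int(rng.integers(0, len(pool)))]
        codon_index = int(rng.integers(2, _CDS_LEN // 3))  # keep ATG and stop
        codons[codon_index - 1] = codon
        cds_pos = 3 * (codon_index - 1) + offset
        site = model.cds_to_genomic(cds_pos)
    elif category == "5UTR":
        tpos = int(rng.integers(1, _UTR5 + 1))
        site = model.transcript_to_genomic(tpos)
    elif category in ("3UTR", "decoy"):
        tpos = int(rng.integers(_UTR5 + _CDS_LEN + 1, _UTR5 + _CDS_LEN + _UTR3 + 1))
        site = model.transcript_to_genomic(tpos)
    elif category == "intronic":
        site = int(rng.integers(exon1[1] + 5, exon2[0] - 5))
    else:
        raise ValueError(f"unknown category {category!r}")
    return model, "".join(codons), site


def generate_dataset(config: SimulationConfig) -> tuple[SimulatedDataset, pd.DataFrame]:
    """Generate a dataset and its truth table; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    design = lps_design(config.group_times_min, config.n_replicates, config.tissue)
    groups = config.group_labels
    times = np.asarray(config.group_times_min, dtype=float)
    samples = design.sample_ids
    sample_group_idx = np.array(
        [groups.index(design.group_of(s)) for s in samples]
    )

    n_sites = config.n_sites
    n_decoy = int(round(config.decoy_mismatch_frac * n_sites))
    n_edit = n_sites - n_decoy
    n_dre = int(round(config.frac_dre * n_sites))
    n_trend = int(round(config.frac_time_trend * n_sites))
    n_cis = int(round(config.frac_cis * n_sites))
    if n_dre + n_trend > n_edit:
        raise ValueError("frac_dre + frac_time_trend exceed the non-decoy fraction")

    # flags over editing sites: [0:n_dre] DRE, [n_dre:n_dre+n_trend] trend,
    # first n_cis of the trend block also cis
    is_dre = np.zeros(n_sites, bool)
    is_trend = np.zeros(n_sites, bool)
    is_cis = np.zeros(n_sites, bool)
    is_decoy = np.zeros(n_sites, bool)
    is_dre[:n_dre] = True
    is_trend[n_dre : n_dre + n_trend] = True
    is_cis[n_dre : n_dre + n_cis] = True
    is_decoy[n_edit:] = True

    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    categories = [cats[i] for i in rng.choice(len(cats), size=n_sites, p=probs)]

    a, b = config.baseline_beta_params
    baseline = rng.beta(a, b, size=n_sites)
    trend_f = np.log1p(times) / np.log1p(times.max())  # saturating response

    true_levels = np.tile(baseline[:, None], (1, len(groups)))
    trend_sign = np.zeros(n_sites, dtype=int)
    amp = config.effect_size
    for i in range(n_sites):
        if is_dre[i]:
            g = int(rng.integers(0, len(groups)))
            direction = 1.0 if baseline[i] + amp <= 1 - config.clip_tolerance else -1.0
            true_levels[i, g] = baseline[i] + direction * amp
        elif is_trend[i]:
            sign = 1 if rng.random() < config.trend_positive_frac else -1
            if baseline[i] + sign * amp > 1 - config.clip_tolerance or (
                baseline[i] + sign * amp < config.clip_tolerance and sign < 0
            ):
                sign = -sign
            trend_sign[i] = sign
            true_levels[i] = baseline[i] + sign * amp * trend_f
    if (true_levels < -config.clip_tolerance).any() or (
        true_levels > 1 + config.clip_tolerance
    ).any():
        raise ValueError("effect_size pushes true levels outside [0, 1]")
    true_levels = np.clip(true_levels, 0.0, 1.0)

    # genes, models, site positions
    models: list[TranscriptModel] = []
    cds_sequences: dict[str, str] = {}
    positions = np.zeros(n_sites, dtype=int)
    strands: list[str] = []
    ref_bases: list[str] = []
    alt_bases: list[str] = []
    for i in range(n_sites):
        if is_decoy[i]:
            ref, alt = _NON_AG_PAIRS[int(rng.integers(0, len(_NON_AG_PAIRS)))]
            # a T>C decoy on a minus-strand gene would masquerade as A-to-I
            strand = "+" if (ref, alt) == ("T", "C") else (
                "-" if rng.random() < config.minus_strand_frac else "+"
            )
            model, seq, pos = _make_gene(i, "decoy", strand, rng)
            categories[i] = model.region_of(pos).replace("CDS", "missense")
        else:
            strand = "-" if rng.random() < config.minus_strand_frac else "+"
            model, seq, pos = _make_gene(i, categories[i], strand, rng)
            ref, alt = ("A", "G") if strand == "+" else ("T", "C")
        models.append(model)
        if seq is not None:
            cds_sequences[model.transcript_id] = seq
        positions[i] = pos
        strands.append(strand)
        ref_bases.append(ref)
        alt_bases.append(alt)

    # allele counts: depth ~ NB(mean, dispersion), alt ~ Binom(depth, level)
    m, disp = config.depth_nb_params
    depth = rng.negative_binomial(disp, disp / (disp + m), size=(n_sites, len(samples)))
    level_per_sample = true_levels[:, sample_group_idx]
    alt_counts = rng.binomial(depth, level_per_sample)
    ref_counts = depth - alt_counts

    allele_rows = {
        "chrom": np.repeat(["chr1"], n_sites * len(samples)),
        "pos": np.repeat(positions, len(samples)),
        "ref": np.repeat(ref_bases, len(samples)),
        "alt": np.repeat(alt_bases, len(samples)),
        "sample_id": np.tile(samples, n_sites),
        "ref_count": ref_counts.ravel(),
        "alt_count": alt_counts.ravel(),
        "other_count": np.zeros(n_sites * len(samples), dtype=int),
    }
    allele_counts = pd.DataFrame(allele_rows)

    # gene expression: constant mean per gene; cis genes track group-mean
    # editing; ADAR2-like enzyme tracks the per-sample mean editing level
    base_expr = rng.lognormal(mean=5.0, sigma=0.8, size=n_sites)
    expr_mean = np.tile(base_expr[:, None], (1, len(samples)))
    for i in np.flatnonzero(is_cis):
        expr_mean[i] = base_expr[i] * (0.2 + 8.0 * level_per_sample[i])
    editing_mean_s = true_levels[~is_decoy][:, sample_group_idx].mean(axis=0)
    adar_mean = np.full(len(samples), 400.0)
    adarb1_mean = 300.0 * (0.2 + 4.0 * editing_mean_s)
    expr_disp = np.full((n_sites, 1), 10.0)
    # enzymes modelled as deeply covered, low-dispersion genes
    expr_mean = np.vstack([expr_mean, adar_mean, adarb1_mean])
    expr_disp = np.vstack([expr_disp, [[30.0]], [[30.0]]])
    expr_counts = rng.negative_binomial(
        expr_disp, expr_disp / (expr_disp + expr_mean)
    )
    gene_ids = [mdl.gene_id for mdl in models] + ["Adar", "Adarb1"]
    lengths = [mdl.exonic_length for mdl in models] + [2000, 2000]
    gene_counts = pd.DataFrame(expr_counts, columns=samples)
    gene_counts.insert(0, "length", lengths)
    gene_counts.insert(0, "gene_id", gene_ids)

    # known-site list: a configurable subset of true editing sites
    edit_idx = np.flatnonzero(~is_decoy)
    n_known = int(round(config.known_site_frac * len(edit_idx)))
    known_idx = rng.choice(edit_idx, size=n_known, replace=False)
    known_idx = np.sort(known_idx)
    known_sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_known,
            "pos": positions[known_idx],
            "ref": [ref_bases[i] for i in known_idx],
            "alt": [alt_bases[i] for i in known_idx],
            "strand": [strands[i] for i in known_idx],
        }
    )

    truth = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": positions,
            "strand": strands,
            "gene_id": [mdl.gene_id for mdl in models],
            "category": categories,
            "is_decoy": is_decoy,
            "is_dre": is_dre,
            "is_time_trend": is_trend,
            "trend_sign": trend_sign,
            "is_cis": is_cis,
        }
    )
    for gi, g in enumerate(groups):
        truth[f"level_{g}"] = true_levels[:, gi]

    dataset = SimulatedDataset(
        allele_counts=allele_counts,
        gene_counts=gene_counts,
        transcripts=models,
        cds_sequences=cds_sequences,
        known_sites=known_sites,
        design=design,
        config=config,
    )
    return dataset, truth


FILE_NAMES = {
    "allele_counts": "allele_counts.tsv",
    "gene_counts": "gene_counts.tsv",
    "transcripts": "transcripts.tsv",
    "cds_fasta": "cds.fasta",
    "known_sites": "known_sites.tsv",
    "design": "design.tsv",
    "truth": "truth.tsv",
}


def write_dataset(
    dataset: SimulatedDataset, truth: pd.DataFrame, out_dir, force: bool = False
) -> dict[str, Path]:
    """Write all dataset files to a directory; refuses to overwrite.

    Returns the mapping of logical names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in FILE_NAMES.items()}
    if not force:
        existing = [str(p) for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite without force=True: {existing}"
            )
    dataset.allele_counts.to_csv(paths["allele_counts"], sep="\t", index=False)
    dataset.gene_counts.to_csv(paths["gene_counts"], sep="\t", index=False)
    write_transcript_table(dataset.transcripts, paths["transcripts"])
    write_cds_fasta(dataset.cds_sequences, paths["cds_fasta"])
    dataset.known_sites.to_csv(paths["known_sites"], sep="\t", index=False)
    dataset.design.write_tsv(paths["design"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
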