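"""End-to-end pipeline: simulate/load -> call -> filter -> annotate -> DRE
-> time/cis correlation -> report, with a JSON run manifest.

Each stage writes one or more TSV outputs into the run directory and the
manifest records the configuration snapshot, seed, package versions,
per-stage row counts and a sha256 checksum of every output file, so two
runs with the same seed can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    TranscriptIndex,
    annotate_events,
    read_cds_fasta,
    read_gtf,
    read_transcript_table,
)
from .calling import CallingThresholds, calls_to_frame, records_from_table, screen_records, type_calls
from .design import StudyDesign
from .dre import DREConfig, manhattan_table, run_differential_editing
from .expression import de_glm, read_gene_counts, tpm
from .filtering import (
    SITE_KEYS,
    event_levels,
    group_presence,
    read_known_sites,
    retain_high_confidence,
    summarize_activity,
)
from .report import category_distribution, pca_on_dre
from .simulate import SimulationConfig, generate_dataset, write_dataset
from .timecorr import (
    cis_expression_correlation,
    enzyme_correlation,
    records_to_frame,
    time_dependent_sites,
    top_k_by_abs_r,
)

logger = logging.getLogger("rnaedit")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path) -> Path:
    frame.to_csv(path, sep="\t", index=False)
    return path


def run_pipeline(config: dict | str | Path, out_dir: Optional[str] = None, force: bool = False) -> dict:
    """Run all stages from a config mapping or YAML path; returns manifest.

    The config needs either a ``simulate`` block (SimulationConfig fields)
    or an ``inputs`` block with paths for allele_counts, transcripts,
    cds_fasta, known_sites, design and gene_counts. A stage failure aborts
    with a :class:`PipelineError` naming the stage.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config.get("out_dir", "rnaedit_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    outputs: dict[str, Path] = {}
    counts: dict[str, int] = {}

    # ---- stage: simulate / load inputs ------------------------------------
    stage = "simulate"
    try:
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"] or {})
            sim_kwargs.setdefault("seed", seed)
            for key in ("group_times_min", "depth_nb_params", "baseline_beta_params"):
                if key in sim_kwargs:
                    sim_kwargs[key] = tuple(sim_kwargs[key])
            sim_config = SimulationConfig(**sim_kwargs)
            dataset, truth = generate_dataset(sim_config)
            data_dir = out / "data"
            paths = write_dataset(dataset, truth, data_dir, force=True)
            outputs.update({f"data_{k}": p for k, p in paths.items()})
            allele = dataset.allele_counts
            models = dataset.transcripts
            cds_seqs = dataset.cds_sequences
            known = dataset.known_sites
            design = dataset.design
            gene_counts = dataset.gene_counts.set_index("gene_id")
            lengths = gene_counts.pop("length").astype(float)
        elif "inputs" in config:
            paths = config["inputs"]
            missing = {"allele_counts", "transcripts", "design", "gene_counts"} - set(paths)
            if missing:
                raise ValueError(f"inputs block missing keys: {sorted(missing)}")
            allele = pd.read_csv(paths["allele_counts"], sep="\t")
            tpath = str(paths["transcripts"])
            models = read_gtf(tpath) if tpath.endswith((".gtf", ".gtf.gz")) else read_transcript_table(tpath)
            cds_seqs = read_cds_fasta(paths["cds_fasta"]) if "cds_fasta" in paths else {}
            known = read_known_sites(paths["known_sites"]) if "known_sites" in paths else None
            design = StudyDesign.read_tsv(paths["design"])
            gene_counts, lengths = read_gene_counts(paths["gene_counts"])
        else:
            raise ValueError("config needs a 'simulate' or an 'inputs' block")
        counts["allele_rows"] = len(allele)
        logger.info("stage %s: %d allele-count rows", stage, len(allele))
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    index = TranscriptIndex(models)

    # ---- stage: call --------------------------------------------------------
    stage = "call"
    try:
        thresholds = CallingThresholds(**(config.get("thresholds") or {}))
        records = records_from_table(allele)
        screened = screen_records(records, thresholds)
        typed = type_calls(screened, index.strand_at)
        calls = calls_to_frame(typed)
        outputs["calls"] = _write(calls, out / "calls.tsv")
        counts["calls"] = int(calls["passes"].sum())
        counts["calls_a_to_i"] = int((calls["is_a_to_i"] == True).sum())  # noqa: E712
        logger.info("stage call: %d passing, %d A-to-I typed", counts["calls"], counts["calls_a_to_i"])
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: filter ------------------------------------------------------
    stage = "filter"
    try:
        events = retain_high_confidence(calls, known)
        if len(events) == 0:
            raise ValueError("no high-confidence events retained")
        outputs["events"] = _write(events, out / "events.tsv")
        counts["events"] = len(events)
        activity = summarize_activity(events, design)
        summary = pd.DataFrame(
            {
                "group": activity.per_group_mean.index,
                "mean_editing_level": activity.per_group_mean.to_numpy(),
                "pooled_mean_editing_level": activity.per_group_pooled_mean.to_numpy(),
                "n_events": activity.per_group_event_count.to_numpy(),
            }
        )
        outputs["group_summary"] = _write(summary, out / "group_summary.tsv")
        presence = group_presence(events, design)
        venn = pd.DataFrame(
            {
                "region": ["&".join(k) for k in presence.regions],
                "count": list(presence.regions.values()),
            }
        )
        venn["shared_fraction"] = presence.shared_fraction
        outputs["venn"] = _write(venn, out / "venn_groups.tsv")
        logger.info("stage filter: %d events, shared fraction %.3f",
                    len(events), presence.shared_fraction)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: annotate ----------------------------------------------------
    stage = "annotate"
    try:
        annotated = annotate_events(events[SITE_KEYS], index, cds_seqs)
        outputs["annotated"] = _write(annotated, out / "annotated_sites.tsv")
        counts["annotated"] = len(annotated)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: dre ---------------------------------------------------------
    stage = "dre"
    try:
        dre_kwargs = dict(config.get("dre") or {})
        dre_kwargs.setdefault("seed", seed)
        dre_config = DREConfig(**dre_kwargs)
        dre = run_differential_editing(events, design, dre_config, annotations=annotated)
        outputs["dre"] = _write(dre, out / "dre.tsv")
        outputs["manhattan"] = _write(manhattan_table(dre), out / "manhattan.tsv")
        counts["dre_sites_tested"] = int(dre["glm_p"].notna().sum())
        counts["dre_significant"] = int(dre["is_dre"].sum())
        logger.info("stage dre: %d significant of %d tested",
                    counts["dre_significant"], counts["dre_sites_tested"])
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: timecorr ----------------------------------------------------
    stage = "timecorr"
    try:
        alpha = float(config.get("alpha", 0.05))
        tpm_table = tpm(gene_counts, lengths)
        outputs["tpm"] = _write(
            tpm_table.reset_index().rename(columns={"index": "gene_id"}), out / "tpm.tsv"
        )
        de = de_glm(tpm_table, design)
        outputs["de"] = _write(de, out / "differential_expression.tsv")
        time_recs = time_dependent_sites(events, design, alpha=alpha)
        gene_map = {
            (r.chrom, r.pos, r.strand): r.gene_id
            for r in annotated.itertuples()
            if r.gene_id is not None
        }
        cis_recs = cis_expression_correlation(events, tpm_table, gene_map, alpha=alpha)
        activity = summarize_activity(events, design)
        enzymes = config.get("enzyme_genes", ["Adar", "Adarb1"])
        enz_recs = enzyme_correlation(activity.per_sample_mean, tpm_table, enzymes, alpha=alpha)
        corr = records_to_frame(time_recs + cis_recs + enz_recs)
        outputs["correlations"] = _write(corr, out / "correlations.tsv")
        outputs["top_time"] = _write(top_k_by_abs_r(time_recs, k=25), out / "top25_time.tsv")
        counts["time_dependent"] = int(sum(r.flagged for r in time_recs))
        counts["cis_records"] = len(cis_recs)
        logger.info("stage timecorr: %d time-dependent sites", counts["time_dependent"])
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: report ------------------------------------------------------
    stage = "report"
    try:
        merged = annotated.merge(dre[SITE_KEYS + ["is_dre"]], on=SITE_KEYS)
        cat_all = category_distribution(merged)
        cat = pd.DataFrame({"category": cat_all.index, "proportion_all": cat_all.to_numpy()})
        if merged["is_dre"].any():
            cat_dre = category_distribution(merged, dre_only=True)
            cat["proportion_dre"] = [cat_dre.get(c, 0.0) for c in cat["category"]]
        outputs["categories"] = _write(cat, out / "category_distribution.tsv")
        dre_sites = dre[dre["is_dre"]][SITE_KEYS]
        if len(dre_sites) >= 2:
            levels = event_levels(events)
            keys = pd.MultiIndex.from_frame(dre_sites)
            sub = levels[levels.index.isin(keys)]
            try:
                pca = pca_on_dre(sub)
                scores = pca.scores.reset_index().rename(columns={"index": "sample_id"})
                outputs["pca_scores"] = _write(scores, out / "pca_scores.tsv")
                var = pd.DataFrame(
                    {
                        "component": [f"PC{i + 1}" for i in range(len(pca.variance_fraction))],
                        "variance_fraction": pca.variance_fraction,
                    }
                )
                outputs["pca_variance"] = _write(var, out / "pca_variance.tsv")
            except ValueError as exc:
                logger.warning("PCA skipped: %s", exc)
        else:
            logger.warning("PCA skipped: fewer than 2 differentially edited sites")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "package_version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": seed,
        "config": _jsonable(config),
        "stage_counts": counts,
        "outputs": {
            name: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
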