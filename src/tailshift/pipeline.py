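"""End-to-end orchestration: inputs (or simulation) -> APA, PAL, m6A, DE
and integration outputs in a reproducible run directory.

A run is driven by :class:`RunConfig` (YAML-serializable).  Comparisons
default to all ordered stage pairs in stage order, the earlier stage acting
as control.  Analysis outputs (TSV, BED, JSON summary) are byte-identical
across reruns with the same config and inputs; run.log carries timestamps
and is excluded from that guarantee.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import GeneModel, load_annotation, load_modcalls, load_reads
from .apa import apa_analysis, clusters_to_bed, global_mean_red, results_to_frame
from .errors import ConfigurationError, PipelineError
from .m6a import (m6a_diff_all, metagene_profile, longest_cds_transcript,
                  gene_m6a_rates, site_region_table, stage_m6a_rate_distribution)
from .pal import pal_diff_all, summarize_pal
from .quant import (correlation_analysis, de_standin, group_compare,
                    modified_transcripts, quantify_tpm, transcript_lengths)
from .synthetic import SimulationConfig, generate_fixture

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML unchanged."""

    output_dir: str = "tailshift_run"
    seed: int = 0
    # inputs: either file paths ...
    annotation_path: str | None = None
    reads_path: str | None = None
    modcalls_path: str | None = None
    # ... or a simulation
    simulate: SimulationConfig | None = None
    # (control, treatment) stage pairs; None -> all ordered pairs
    comparisons: list[tuple[str, str]] | None = None
    # thresholds
    cluster_window: int = 24
    pas_min_count: int = 5
    pas_min_count_per_condition: int = 5
    pseudocount: float = 1.0
    apa_threshold: float = 0.3
    apa_threshold_mode: str = "log2"
    pal_min_n: int = 10
    metagene_bins: int = 10
    m6a_min_ratio: float = 0.1
    m6a_min_coverage: int = 10
    span_slack: int = 1000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        if self.comparisons is not None:
            d["comparisons"] = [list(p) for p in self.comparisons]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        if d.get("comparisons") is not None:
            d["comparisons"] = [tuple(p) for p in d["comparisons"]]
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))


def default_demo_config(seed: int = 1, output_dir: str = "tailshift_demo",
                        n_genes: int = 50) -> RunConfig:
    """A small simulated run (50 genes by default) used by docs and tests."""
    return RunConfig(output_dir=output_dir, seed=seed,
                     simulate=SimulationConfig(seed=seed, n_genes=n_genes,
                                               reads_per_gene_mean=60.0))


# ---------------------------------------------------------------------------

def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in sorted(x.items())}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return None
        return round(float(x), nd)
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def load_inputs(cfg: RunConfig, outdir: Path | None = None):
    """Resolve inputs: parse the given files or simulate (and export)."""
    if cfg.simulate is not None:
        sim = dataclasses.replace(cfg.simulate)
        genes, reads, modcalls, truth = generate_fixture(
            sim, outdir / "fixture" if outdir is not None else None)
        return genes, reads, modcalls, truth
    if not (cfg.annotation_path and cfg.reads_path and cfg.modcalls_path):
        raise ConfigurationError(
            "provide annotation/reads/modcalls paths or a simulate block")
    genes = load_annotation(cfg.annotation_path)
    report = load_reads(Path(cfg.reads_path).read_text(), genes,
                        span_slack=cfg.span_slack)
    modcalls = load_modcalls(Path(cfg.modcalls_path).read_text())
    return genes, report.reads, modcalls, None


def resolve_comparisons(cfg: RunConfig, stages: list[str]
                        ) -> list[tuple[str, str]]:
    if cfg.comparisons is None:
        return list(combinations(stages, 2))
    for a, b in cfg.comparisons:
        for s in (a, b):
            if s not in stages:
                raise ConfigurationError(
                    f"comparison references unknown stage {s!r}; "
                    f"stages present: {stages}")
    return [tuple(p) for p in cfg.comparisons]


def _stage_samples(reads: pd.DataFrame) -> dict[str, list[str]]:
    return {s: sorted(g["sample_id"].unique())
            for s, g in reads.groupby("stage")}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage for every comparison pair; returns the output dir.

    Any stage failure aborts with a stage-named message and leaves an
    INCOMPLETE marker in the output directory.
    """
    if cfg.simulate is not None and cfg.comparisons is not None:
        # fail fast, before any simulation or file parsing
        resolve_comparisons(cfg, list(cfg.simulate.stages))
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tailshift")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    marker = outdir / "INCOMPLETE"
    marker.write_text("run in progress\n")
    cfg_text = cfg.to_yaml()
    (outdir / "config.yaml").write_text(cfg_text)
    # hash the analysis-relevant config: where the run lands is not part of it
    hashed = {k: v for k, v in cfg.to_dict().items() if k != "output_dir"}
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(hashed, sort_keys=True).encode()).hexdigest()[:16]
    logger.info("tailshift %s  seed=%d  config sha256:%s",
                __version__, cfg.seed, cfg_hash)
    try:
        summary = _run_stages(cfg, outdir)
        summary["config_sha256"] = cfg_hash
        summary["seed"] = cfg.seed
        summary["version"] = __version__
        (outdir / "summary.json").write_text(
            json.dumps(_round(summary), sort_keys=True, indent=1) + "\n")
        marker.unlink()
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        marker.write_text(f"pipeline failed: {exc}\n")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def _run_stages(cfg: RunConfig, outdir: Path) -> dict:
    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineError:
            raise
        except ConfigurationError as exc:
            raise PipelineError(f"stage '{name}': {exc}") from exc
        except Exception as exc:
            raise PipelineError(
                f"stage '{name}' failed: {exc}") from exc

    genes, reads, modcalls, truth = stage("inputs", load_inputs, cfg, outdir)
    stages_present = [s for s in
                      (cfg.simulate.stages if cfg.simulate else
                       pd.unique(reads["stage"]))
                      if (reads["stage"] == s).any()]
    pairs = resolve_comparisons(cfg, stages_present)
    samples_of = _stage_samples(reads)

    summary: dict = {"stages": stages_present,
                     "comparisons": [list(p) for p in pairs],
                     "n_reads": int(len(reads)),
                     "n_genes": int(reads["gene_id"].nunique())}

    # stage-level PAL summaries
    pal_sum = stage("pal-summary", summarize_pal, reads, ("stage",))
    _write_tsv(outdir / "pal_summary_by_stage.tsv", pal_sum)
    pal_fl = stage("pal-summary", summarize_pal, reads,
                   ("stage", "full_length"))
    _write_tsv(outdir / "pal_summary_by_stage_fulllength.tsv", pal_fl)
    summary["pal_median_by_stage"] = {
        r["stage"]: r["median"] for _, r in pal_sum.iterrows()}

    # expression
    lengths = transcript_lengths(genes)
    em = stage("tpm", quantify_tpm, reads, lengths)
    _write_tsv(outdir / "tpm.tsv",
               em.tpm.reset_index(names="transcript_id"))

    # m6A stage-level
    rate_dist = stage("m6a-rates", stage_m6a_rate_distribution,
                      modcalls, reads, stages_present)
    _write_tsv(outdir / "m6a_rate_by_stage.tsv", rate_dist)
    summary["m6a_rate_median_by_stage"] = {
        r["stage"]: r["median"] for _, r in rate_dist.iterrows()}

    regions = stage("m6a-regions", site_region_table, modcalls, genes)
    _write_tsv(outdir / "m6a_site_regions.tsv", regions)
    gene_map = {g.gene_id: g for g in genes}

    def site_transcript(entry):
        return longest_cds_transcript(gene_map[entry[3]])

    site_rows = [tuple(r) for r in regions[
        ["site_chrom", "site_pos", "site_strand", "gene_id"]].itertuples(
            index=False)]
    profile = stage("metagene", metagene_profile, site_rows, site_transcript,
                    cfg.metagene_bins)
    prof_df = pd.DataFrame({
        "bin": range(len(profile)),
        "region": [("5UTR", "CDS", "3UTR")[b // cfg.metagene_bins]
                   for b in range(len(profile))],
        "density": profile})
    _write_tsv(outdir / "m6a_metagene_profile.tsv", prof_df)
    summary["metagene_profile_sum"] = float(profile.sum())
    summary["n_m6a_sites"] = int(len(regions))

    # per-comparison analyses
    per_pair: dict[str, dict] = {}
    for ctrl, trt in pairs:
        key = f"{ctrl}_vs_{trt}"
        s1, s2 = samples_of[ctrl], samples_of[trt]
        apa_res = stage("apa", apa_analysis, reads, genes, s1, s2,
                        cfg.cluster_window, cfg.pas_min_count,
                        cfg.pas_min_count_per_condition, cfg.pseudocount,
                        cfg.apa_threshold, cfg.apa_threshold_mode)
        _write_tsv(outdir / f"apa_{key}.tsv", results_to_frame(apa_res))
        (outdir / f"pas_{key}.bed").write_text(clusters_to_bed(apa_res))
        pal_res = stage("pal", pal_diff_all, reads, ctrl, trt, cfg.pal_min_n)
        _write_tsv(outdir / f"pal_{key}.tsv", pal_res)
        m6a_res = stage("m6a", m6a_diff_all, modcalls, reads, s1, s2)
        _write_tsv(outdir / f"m6a_{key}.tsv", m6a_res)
        de_res = stage("de", de_standin, em, s1, s2)
        _write_tsv(outdir / f"de_{key}.tsv", de_res)
        tested = pal_res[pal_res["tested"]] if len(pal_res) else pal_res
        per_pair[key] = {
            "apa_tested": len(apa_res),
            "apa_significant": int(sum(r.significant for r in apa_res)),
            "apa_proximal_up": int(sum(r.shift_class == "proximal_up"
                                       for r in apa_res)),
            "apa_distal_up": int(sum(r.shift_class == "distal_up"
                                     for r in apa_res)),
            "global_mean_red": global_mean_red(apa_res),
            "pal_tested": int(len(tested)),
            "pal_significant": int(tested["significant"].sum())
            if len(tested) else 0,
            "pal_longer": int((tested["direction"] == "longer").sum())
            if len(tested) else 0,
            "pal_shorter": int((tested["direction"] == "shorter").sum())
            if len(tested) else 0,
            "m6a_tested": int(len(m6a_res)),
            "m6a_significant": int(m6a_res["significant"].sum())
            if len(m6a_res) else 0,
            "de_significant": int(de_res["significant"].sum()),
        }
    summary["per_comparison"] = per_pair

    # integration analyses (first vs last stage where a pair is needed)
    summary["integration"] = stage(
        "integration", _integration, cfg, outdir, genes, reads, modcalls,
        em, stages_present, samples_of)
    return summary


def _integration(cfg, outdir, genes, reads, modcalls, em, stages, samples_of
                 ) -> dict:
    out: dict = {}
    first, last = stages[0], stages[-1]
    tx_as = {t.transcript_id: t.as_class
             for g in genes for t in g.transcripts}
    tx_ids = em.tpm.index.to_numpy()
    mean_tpm = em.tpm.mean(axis=1).to_numpy()
    log_tpm = np.log2(mean_tpm + 1.0)
    as_labels = np.array([tx_as.get(t, "none") for t in tx_ids])
    expressed = mean_tpm > 0

    # AS class vs expression
    try:
        gc = group_compare(log_tpm[expressed], as_labels[expressed],
                           grouping="as_class_vs_expression")
        _write_tsv(outdir / "integration_as_vs_expression.tsv", gc.group_stats)
        out["as_vs_expression_anova_p"] = gc.omnibus_p
    except ConfigurationError as exc:
        logger.warning("as_vs_expression skipped: %s", exc)

    # per-transcript median PAL (all stages pooled)
    pal_med = reads.dropna(subset=["polya_len"]).groupby(
        "transcript_id")["polya_len"].median()
    pal_vals = pal_med.reindex(tx_ids).to_numpy()

    # AS class vs PAL
    try:
        gc = group_compare(pal_vals, as_labels, grouping="as_class_vs_pal")
        _write_tsv(outdir / "integration_as_vs_pal.tsv", gc.group_stats)
        out["as_vs_pal_anova_p"] = gc.omnibus_p
    except ConfigurationError as exc:
        logger.warning("as_vs_pal skipped: %s", exc)

    # PAL vs expression (within the first stage)
    sub = reads[(reads["stage"] == first)].dropna(subset=["polya_len"])
    med1 = sub.groupby("transcript_id")["polya_len"].median()
    tpm1 = em.tpm[samples_of[first]].mean(axis=1)
    common = med1.index.intersection(tpm1.index)
    try:
        rho, p = correlation_analysis(
            med1.loc[common].to_numpy(),
            np.log2(tpm1.loc[common].to_numpy() + 1.0))
        out["pal_expression_spearman_rho"] = rho
        out["pal_expression_spearman_p"] = p
    except ConfigurationError as exc:
        logger.warning("pal_expression correlation skipped: %s", exc)

    # m6A ratio vs expression (within the first stage)
    rates1 = gene_m6a_rates(modcalls, reads, samples_of[first])
    gene_tpm = reads[["transcript_id", "gene_id"]].drop_duplicates() \
        .set_index("transcript_id")["gene_id"]
    tpm_by_gene = tpm1.groupby(gene_tpm.reindex(tpm1.index)).sum()
    common_g = rates1.index.intersection(tpm_by_gene.index)
    try:
        rho, p = correlation_analysis(
            rates1.loc[common_g].to_numpy(),
            np.log2(tpm_by_gene.loc[common_g].to_numpy() + 1.0))
        out["m6a_expression_spearman_rho"] = rho
        out["m6a_expression_spearman_p"] = p
    except ConfigurationError as exc:
        logger.warning("m6a_expression correlation skipped: %s", exc)

    # m6A-modified vs unmodified transcripts: PAL comparison
    mod_tx = modified_transcripts(modcalls, reads,
                                  sorted(reads["sample_id"].unique()),
                                  cfg.m6a_min_ratio, cfg.m6a_min_coverage)
    status = np.array(["modified" if t in mod_tx else "unmodified"
                       for t in pal_med.index])
    try:
        gc = group_compare(pal_med.to_numpy(), status,
                           grouping="m6a_status_vs_pal")
        _write_tsv(outdir / "integration_m6a_vs_pal.tsv", gc.group_stats)
        out["m6a_vs_pal_t_p"] = gc.omnibus_p
        med = {r["group"]: r["median"] for _, r in gc.group_stats.iterrows()}
        out["m6a_modified_pal_median"] = med.get("modified")
        out["m6a_unmodified_pal_median"] = med.get("unmodified")
    except ConfigurationError as exc:
        logger.warning("m6a_vs_pal skipped: %s", exc)

    # APA shift class (first vs last stage) vs gene m6A ratio
    apa_res = apa_analysis(reads, genes, samples_of[first], samples_of[last],
                           cfg.cluster_window, cfg.pas_min_count,
                           cfg.pas_min_count_per_condition, cfg.pseudocount,
                           cfg.apa_threshold, cfg.apa_threshold_mode)
    shift = {r.gene_id: r.shift_class for r in apa_res}
    rates_all = gene_m6a_rates(modcalls, reads,
                               sorted(reads["sample_id"].unique()))
    gids = [g for g in rates_all.index if g in shift]
    try:
        gc = group_compare(rates_all.loc[gids].to_numpy(),
                           np.array([shift[g] for g in gids]),
                           grouping="apa_shift_vs_m6a_ratio")
        _write_tsv(outdir / "integration_apa_vs_m6a.tsv", gc.group_stats)
        out["apa_vs_m6a_anova_p"] = gc.omnibus_p
    except ConfigurationError as exc:
        logger.warning("apa_vs_m6a skipped: %s", exc)
    return out
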