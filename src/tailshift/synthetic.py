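"""Seeded per-read feature simulator with planted, recorded effects.

The generator emulates the per-read feature tables a nanopore direct-RNA
run of developing peanut pods would yield after upstream processing:

* four developmental stages (AerPeg, SubPeg, ExpPod1, ExpPod2) with three
  replicates each and negative-binomial per-gene read counts;
* stage-specific poly(A)-tail-length (PAL) distributions — gamma, with the
  scale solved so the distribution median hits the stage target
  (84.38 / 79.91 / 81.6 / 86.59 nt by default);
* exactly two poly(A) sites per gene in the final exon, reads choosing the
  proximal site with a stage-dependent weight; a planted subset of genes
  has its proximal odds multiplied in the two late stages (the
  distal-to-proximal developmental shift);
* per-site m6A modification calls at Beta-distributed stoichiometries with
  mean 0.5; a planted subset of sites gains ``m6a_planted_delta`` in the
  late stages;
* a planted subset of transcripts whose PAL median changes by
  ``pal_planted_fold`` (direction alternating) in the late stages, and a
  planted subset of genes whose expression changes ``de_planted_fold``-fold.

Every planted effect is recorded in :class:`GroundTruth`, so downstream
statistics can be scored for sensitivity and false-positive rate.  The same
seed and config always produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .annotation import (GeneModel, TranscriptModel, genes_to_gff3,
                         READS_COLUMNS, MODCALLS_COLUMNS)
from .errors import ConfigurationError, ValidationError

FIXTURE_SCHEMA = "tailshift-fixture v1"

DEFAULT_STAGES = ("AerPeg", "SubPeg", "ExpPod1", "ExpPod2")
#: Stage PAL medians (nt) — the study's reported per-stage medians.
DEFAULT_PAL_MEDIANS = {"AerPeg": 84.38, "SubPeg": 79.91,
                       "ExpPod1": 81.6, "ExpPod2": 86.59}
#: Transcript AS-class frequencies (exon skipping dominant, MX rare).
DEFAULT_AS_PROBS = {"none": 0.30, "SE": 0.25, "RI": 0.12, "A3": 0.10,
                    "A5": 0.10, "AF": 0.06, "AL": 0.05, "MX": 0.02}
#: m6A site placement across transcript regions (CDS-dominant, 3'UTR next).
DEFAULT_M6A_REGION_WEIGHTS = {"5UTR": 0.05, "CDS": 0.74, "3UTR": 0.21}


@dataclass
class SimulationConfig:
    """All knobs of the simulator; defaults are the emulated study conditions."""

    seed: int = 0
    n_genes: int = 200
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 3
    reads_per_gene_mean: float = 200.0          # per gene per sample
    nb_dispersion: float = 20.0                 # NB size parameter r
    pal_median_by_stage: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAL_MEDIANS))
    pal_shape: float = 4.0                      # gamma shape (right-skewed)
    pas_pair_distance_nt: int = 200
    proximal_weight_by_stage: dict[str, float] = field(
        default_factory=lambda: {s: 0.45 for s in DEFAULT_STAGES})
    apa_planted_fraction: float = 0.10
    apa_planted_odds_multiplier: float = 3.0
    apa_shift_direction: str = "proximal"       # direction of the planted shift
    m6a_sites_per_gene_mean: float = 2.0
    m6a_ratio_alpha: float = 8.0                # Beta(8,8): mean 0.5
    m6a_ratio_beta: float = 8.0
    m6a_planted_fraction: float = 0.15
    m6a_planted_delta: float = 0.30
    m6a_region_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_M6A_REGION_WEIGHTS))
    pal_planted_fraction: float = 0.10
    pal_planted_fold: float = 1.8
    de_planted_fraction: float = 0.05
    de_planted_fold: float = 4.0
    as_class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AS_PROBS))
    pas_positional_noise_sd: float = 5.0
    full_length_prob: float = 0.6
    partial_coverage_prob: float = 0.5          # non-full-length read covers a site
    pal_missing_prob: float = 0.03
    expr_log_sd: float = 0.2                    # per-gene lognormal expression spread
    pal_gene_log_sd: float = 0.03               # per-gene PAL multiplier spread
    pal_expression_rho: float = -0.6            # rank link of gene PAL to expression
    n_effect_stages: int = 2                    # planted effects act on the last k stages

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.replicates_per_stage < 1:
            raise ConfigurationError("replicates_per_stage must be >= 1")
        if self.reads_per_gene_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("read-count parameters must be positive")
        if self.pal_shape <= 0:
            raise ConfigurationError("pal_shape must be positive")
        if self.pas_pair_distance_nt <= 0:
            raise ConfigurationError("pas_pair_distance_nt must be positive")
        if self.pas_positional_noise_sd < 0:
            raise ConfigurationError("pas_positional_noise_sd must be >= 0")
        if self.apa_shift_direction not in ("proximal", "distal"):
            raise ConfigurationError("apa_shift_direction: 'proximal' or 'distal'")
        if self.apa_planted_odds_multiplier <= 0:
            raise ConfigurationError("apa_planted_odds_multiplier must be > 0")
        if self.pal_planted_fold <= 1:
            raise ConfigurationError("pal_planted_fold must be > 1")
        for s in self.stages:
            if s not in self.pal_median_by_stage:
                raise ConfigurationError(f"no PAL median for stage {s}")
            if self.pal_median_by_stage[s] <= 0:
                raise ConfigurationError("PAL medians must be > 0")
            w = self.proximal_weight_by_stage.get(s)
            if w is None or not 0.0 <= w <= 1.0:
                raise ConfigurationError(
                    f"proximal weight for stage {s} must be in [0,1]")
        for name, probs in (("as_class_probs", self.as_class_probs),
                            ("m6a_region_weights", self.m6a_region_weights)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1")
        for name, val in (
                ("apa_planted_fraction", self.apa_planted_fraction),
                ("m6a_planted_fraction", self.m6a_planted_fraction),
                ("pal_planted_fraction", self.pal_planted_fraction),
                ("de_planted_fraction", self.de_planted_fraction),
                ("m6a_planted_delta", self.m6a_planted_delta),
                ("full_length_prob", self.full_length_prob),
                ("partial_coverage_prob", self.partial_coverage_prob),
                ("pal_missing_prob", self.pal_missing_prob)):
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1]")

    @property
    def late_stages(self) -> tuple[str, ...]:
        return tuple(self.stages[-self.n_effect_stages:])

    @property
    def sample_ids(self) -> list[str]:
        return [f"{s}_r{i + 1}" for s in self.stages
                for i in range(self.replicates_per_stage)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Every planted effect, keyed by the ids used in the generated tables."""

    apa_shift_genes: dict[str, str]                # gene_id -> shift direction
    pal_diff_transcripts: dict[str, dict]          # transcript_id -> {fold, direction}
    m6a_diff_sites: dict[str, float]               # "chrom:pos:strand" -> planted delta
    de_diff_genes: dict[str, float]                # gene_id -> expression fold (late/early)
    proximal_weight_by_stage: dict[str, float]
    pal_median_by_transcript: dict[str, dict[str, float]]  # tid -> stage -> true median
    site_base_rates: dict[str, float]              # every site's drawn Beta rate
    pas_positions: dict[str, dict[str, int]]       # gene_id -> {proximal, distal}

    def to_json(self) -> str:
        d = {"schema": FIXTURE_SCHEMA, **dataclasses.asdict(self)}
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d.pop("schema", None)
        return cls(**d)


def site_key(chrom: str, pos: int, strand: str) -> str:
    return f"{chrom}:{pos}:{strand}"


def gamma_scale_for_median(median: float, shape: float) -> float:
    """Scale of a gamma(shape) whose distribution median equals ``median``."""
    return median / scipy.stats.gamma.median(shape)


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

_N_CHROMS = 4
_GENE_GAP = 2000


def generate_annotation(config: SimulationConfig
                        ) -> tuple[list[GeneModel], str]:
    """Generate ``n_genes`` three-exon gene models and their GFF3 document.

    Each transcript has a 5' UTR, a CDS split over three exons, and a 3' UTR
    inside the final exon long enough for two poly(A) sites separated by
    ``pas_pair_distance_nt`` plus noise margin.  Strands alternate.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    classes = sorted(config.as_class_probs)
    class_p = np.array([config.as_class_probs[c] for c in classes])
    cursors = {f"chr{i + 1}": 1000 for i in range(_N_CHROMS)}
    genes: list[GeneModel] = []
    for gi in range(config.n_genes):
        gene_id = f"gene{gi + 1:04d}"
        chrom = f"chr{gi % _N_CHROMS + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        utr5 = 150 + int(rng.integers(0, 101))
        cds_len = 3 * int(rng.integers(150, 401))
        utr3 = 130 + config.pas_pair_distance_nt + 250 + int(rng.integers(0, 201))
        total = utr5 + cds_len + utr3
        # two introns inside the CDS; the final exon holds the whole 3' UTR
        i1 = utr5 + cds_len // 3
        i2 = utr5 + (2 * cds_len) // 3
        intron1 = 200 + int(rng.integers(0, 301))
        intron2 = 200 + int(rng.integers(0, 301))
        start = cursors[chrom]
        # exon layout in transcription order, as plus-strand offsets
        seg_bounds = [(0, i1 - 1), (i1, i2 - 1), (i2, total - 1)]
        offsets = [0, intron1, intron1 + intron2]
        plus_exons = [(start + s + off, start + e + off)
                      for (s, e), off in zip(seg_bounds, offsets)]
        span_len = total + intron1 + intron2
        cds_t = (utr5, utr5 + cds_len - 1)  # transcript-coordinate CDS
        if strand == "+":
            exons = plus_exons
            cds = (_plus_map(plus_exons, start, cds_t[0]),
                   _plus_map(plus_exons, start, cds_t[1]))
        else:
            # mirror the plus layout inside the gene span
            hi = start + span_len - 1
            exons = sorted((start + hi - e, start + hi - s) for s, e in plus_exons)
            cds = tuple(sorted((start + hi - _plus_map(plus_exons, start, cds_t[0]),
                                start + hi - _plus_map(plus_exons, start, cds_t[1]))))
        as_class = classes[int(rng.choice(len(classes), p=class_p))]
        t = TranscriptModel(
            transcript_id=f"{gene_id}.1", chrom=chrom, strand=strand,
            exons=tuple(exons), cds=cds, as_class=as_class)
        genes.append(GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                               transcripts=(t,)))
        cursors[chrom] = start + span_len + _GENE_GAP
    return genes, genes_to_gff3(genes)


def _plus_map(plus_exons, start, t_off):
    """Map a transcript offset to a genomic position on the plus layout."""
    for (s, e) in plus_exons:
        ln = e - s + 1
        if t_off < ln:
            return s + t_off
        t_off -= ln
    raise AssertionError("offset beyond transcript")


# ---------------------------------------------------------------------------
# Read / modification simulation
# ---------------------------------------------------------------------------

def simulate_reads(config: SimulationConfig, genes: list[GeneModel]
                   ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the per-read feature and modification-call tables.

    Returns ``(reads, modcalls, truth)``; rerunning with the same config and
    gene set reproduces the tables exactly.
    """
    config.validate()
    if not genes:
        raise ConfigurationError("empty gene set")
    rng = np.random.default_rng([config.seed, 202])
    stages = list(config.stages)
    n_rep = config.replicates_per_stage
    late = set(config.late_stages)
    stage_w = np.array([config.proximal_weight_by_stage[s] for s in stages])
    stage_med = np.array([config.pal_median_by_stage[s] for s in stages])
    stage_is_late = np.array([s in late for s in stages])
    gamma_med1 = scipy.stats.gamma.median(config.pal_shape)

    n_genes = len(genes)
    # per-gene expression factor, with gene-level PAL multiplier rank-linked
    # (negatively, by default) to expression
    z_expr = rng.standard_normal(n_genes)
    rho = config.pal_expression_rho
    z_pal = rho * z_expr + np.sqrt(max(0.0, 1 - rho * rho)) * \
        rng.standard_normal(n_genes)
    expr_factor = np.exp(config.expr_log_sd * z_expr)
    pal_factor = np.exp(config.pal_gene_log_sd * z_pal)

    apa_planted = rng.random(n_genes) < config.apa_planted_fraction
    pal_planted = rng.random(n_genes) < config.pal_planted_fraction
    pal_dir = np.where(rng.random(n_genes) < 0.5, 1, -1)  # longer / shorter
    de_planted = rng.random(n_genes) < config.de_planted_fraction
    de_dir = np.where(rng.random(n_genes) < 0.5, 1, -1)

    truth = GroundTruth(
        apa_shift_genes={}, pal_diff_transcripts={}, m6a_diff_sites={},
        de_diff_genes={},
        proximal_weight_by_stage=dict(config.proximal_weight_by_stage),
        pal_median_by_transcript={}, site_base_rates={}, pas_positions={})

    read_chunks: list[pd.DataFrame] = []
    mod_chunks: list[pd.DataFrame] = []
    read_counter = 0

    for gi, gene in enumerate(genes):
        t = gene.apa_reference_transcript
        stop = t.stop_codon_pos
        sgn = 1 if gene.strand == "+" else -1
        # proximal / distal PAS positions inside the 3' UTR
        u = int(rng.integers(60, 121))
        ppos = stop + sgn * u
        dpos = stop + sgn * (u + config.pas_pair_distance_nt)
        truth.pas_positions[gene.gene_id] = {"proximal": int(ppos),
                                             "distal": int(dpos)}

        if apa_planted[gi]:
            truth.apa_shift_genes[gene.gene_id] = config.apa_shift_direction
        de_fold = 1.0
        if de_planted[gi]:
            de_fold = config.de_planted_fold ** de_dir[gi]
            truth.de_diff_genes[gene.gene_id] = float(de_fold)
        if pal_planted[gi]:
            truth.pal_diff_transcripts[t.transcript_id] = {
                "fold": config.pal_planted_fold,
                "direction": "longer" if pal_dir[gi] > 0 else "shorter"}
        truth.pal_median_by_transcript[t.transcript_id] = {
            s: round(float(stage_med[si] * pal_factor[gi] *
                           (config.pal_planted_fold ** pal_dir[gi]
                            if pal_planted[gi] and stage_is_late[si] else 1.0)), 4)
            for si, s in enumerate(stages)}

        # m6A sites on this gene
        n_sites = int(rng.poisson(config.m6a_sites_per_gene_mean))
        sites = _draw_sites(rng, config, t, n_sites)
        site_rates = rng.beta(config.m6a_ratio_alpha, config.m6a_ratio_beta,
                              size=len(sites))
        site_planted = rng.random(len(sites)) < config.m6a_planted_fraction
        for (pos, _), rate, planted in zip(sites, site_rates, site_planted):
            key = site_key(gene.chrom, pos, gene.strand)
            truth.site_base_rates[key] = round(float(rate), 6)
            if planted:
                truth.m6a_diff_sites[key] = config.m6a_planted_delta

        # reads: negative binomial count per sample
        mu = config.reads_per_gene_mean * expr_factor[gi]
        r0 = config.nb_dispersion
        counts = np.empty(len(stages) * n_rep, dtype=np.int64)
        for si in range(len(stages)):
            m = mu * (de_fold if stage_is_late[si] else 1.0)
            p = r0 / (r0 + m)
            counts[si * n_rep:(si + 1) * n_rep] = rng.negative_binomial(
                r0, p, size=n_rep)
        n_total = int(counts.sum())
        if n_total == 0:
            continue
        sample_idx = np.repeat(np.arange(len(counts)), counts)
        stage_idx = sample_idx // n_rep

        # PAS choice: stage weight, planted genes get odds multiplied late
        w = stage_w[stage_idx].copy()
        if apa_planted[gi]:
            mult = config.apa_planted_odds_multiplier
            if config.apa_shift_direction == "distal":
                mult = 1.0 / mult
            odds = w / (1.0 - w) * mult
            w_eff = odds / (1.0 + odds)
            w = np.where(stage_is_late[stage_idx], w_eff, w)
        use_prox = rng.random(n_total) < w
        noise = np.rint(rng.normal(0.0, config.pas_positional_noise_sd,
                                   n_total)).astype(np.int64)
        pos3 = np.where(use_prox, ppos, dpos) + noise

        # PAL: gamma scaled to the per-read target median
        target = stage_med[stage_idx] * pal_factor[gi]
        if pal_planted[gi]:
            target = target * np.where(
                stage_is_late[stage_idx],
                config.pal_planted_fold ** pal_dir[gi], 1.0)
        pal = rng.gamma(config.pal_shape, 1.0, n_total) * (target / gamma_med1)
        pal = np.round(pal, 2)
        missing = rng.random(n_total) < config.pal_missing_prob
        pal[missing] = np.nan

        full_len = rng.random(n_total) < config.full_length_prob
        read_ids = np.array([f"r{read_counter + k:07d}" for k in range(n_total)])
        read_counter += n_total
        samples = np.array(config.sample_ids)[sample_idx]
        read_chunks.append(pd.DataFrame({
            "read_id": read_ids,
            "sample_id": samples,
            "stage": np.array(stages)[stage_idx],
            "gene_id": gene.gene_id,
            "transcript_id": t.transcript_id,
            "strand": gene.strand,
            "three_prime_pos": pos3,
            "polya_len": pal,
            "full_length": full_len.astype(np.int64),
            "as_class": t.as_class,
        }))

        # modification calls: one per covering read per site
        for (pos, _), rate, planted in zip(sites, site_rates, site_planted):
            covered = full_len | (rng.random(n_total) < config.partial_coverage_prob)
            n_cov = int(covered.sum())
            if n_cov == 0:
                continue
            r_eff = np.full(n_cov, rate)
            if planted:
                r_eff = np.where(stage_is_late[stage_idx[covered]],
                                 min(rate + config.m6a_planted_delta, 0.99),
                                 rate)
            modified = (rng.random(n_cov) < r_eff).astype(np.int64)
            mod_chunks.append(pd.DataFrame({
                "read_id": read_ids[covered],
                "gene_id": gene.gene_id,
                "site_chrom": gene.chrom,
                "site_pos": pos,
                "site_strand": gene.strand,
                "modified": modified,
            }))

    reads = pd.concat(read_chunks, ignore_index=True) if read_chunks else \
        pd.DataFrame(columns=READS_COLUMNS)
    modcalls = pd.concat(mod_chunks, ignore_index=True) if mod_chunks else \
        pd.DataFrame(columns=MODCALLS_COLUMNS)
    return reads, modcalls, truth


def _draw_sites(rng, config: SimulationConfig, t: TranscriptModel,
                n_sites: int) -> list[tuple[int, str]]:
    """Draw distinct genomic m6A site positions within the transcript."""
    regions = sorted(config.m6a_region_weights)
    probs = np.array([config.m6a_region_weights[r] for r in regions])
    bounds = {"5UTR": (0, t.utr5_len),
              "CDS": (t.utr5_len, t.utr5_len + t.cds_len),
              "3UTR": (t.utr5_len + t.cds_len, t.exonic_length)}
    out: set[int] = set()
    for _ in range(n_sites):
        region = regions[int(rng.choice(len(regions), p=probs))]
        lo, hi = bounds[region]
        if hi <= lo:
            continue
        off = int(rng.integers(lo, hi))
        out.add(t.transcript_to_genomic(off))
    return [(pos, "site") for pos in sorted(out)]


# ---------------------------------------------------------------------------
# Fixture export / import
# ---------------------------------------------------------------------------

def export_fixture(reads: pd.DataFrame, modcalls: pd.DataFrame,
                   gff3_text: str, truth: GroundTruth, outdir: str | Path
                   ) -> dict[str, Path]:
    """Write reads.tsv, modcalls.tsv, annotation.gff3 and truth.json.

    Each TSV starts with a schema-version header line; numeric formatting is
    fixed so identical inputs produce identical bytes.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {outdir}: {exc}") from exc
    paths = {
        "reads": outdir / "reads.tsv",
        "modcalls": outdir / "modcalls.tsv",
        "annotation": outdir / "annotation.gff3",
        "truth": outdir / "truth.json",
    }
    _write_tsv(paths["reads"], reads, float_format="%.2f")
    _write_tsv(paths["modcalls"], modcalls)
    paths["annotation"].write_text(gff3_text)
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths


def _write_tsv(path: Path, df: pd.DataFrame, float_format=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {FIXTURE_SCHEMA}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format,
                  na_rep="")


def generate_fixture(config: SimulationConfig, outdir: str | Path | None = None):
    """Convenience: annotation + reads + modcalls (+ optional export).

    Returns ``(genes, reads, modcalls, truth)``.
    """
    genes, gff3_text = generate_annotation(config)
    reads, modcalls, truth = simulate_reads(config, genes)
    for planted in truth.apa_shift_genes:
        if planted not in {g.gene_id for g in genes}:
            raise ValidationError(f"planted gene {planted} missing from annotation")
    if outdir is not None:
        export_fixture(reads, modcalls, gff3_text, truth, outdir)
    return genes, reads, modcalls, truth
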