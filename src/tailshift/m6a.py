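"""Per-site m6A stoichiometry, region assignment, metagene profiles and
differential-methylation calls.

The m6A ratio of a site is modified reads / (modified + unmodified reads).
Between two conditions, the difference ``delta`` is the difference of mean
per-replicate ratios, while the p-value comes from a two-sided Fisher exact
test on the pooled 2x2 table (point-probability two-sidedness).  A site is
differential when |delta| > 0.1 and p < 0.05.  Metagene profiles scale each
of 5' UTR, CDS and 3' UTR to a fixed number of bins and histogram the sites'
fractional positions; the profile is normalized to sum 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .annotation import GeneModel, TranscriptModel
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

DELTA_CUTOFF = 0.1
P_CUTOFF = 0.05
REGIONS = ("5UTR", "CDS", "3UTR")


@dataclass
class M6aSiteCounts:
    """Modified / unmodified read counts for one site in one condition."""

    site: tuple[str, int, str]
    gene_id: str
    n_mod: int
    n_unmod: int
    per_replicate: dict[str, tuple[int, int]]

    @property
    def n_total(self) -> int:
        return self.n_mod + self.n_unmod

    @property
    def testable(self) -> bool:
        return self.n_total > 0

    @property
    def ratio(self) -> float:
        if not self.testable:
            raise ValidationError(
                f"site {self.site}: ratio undefined with zero coverage")
        return self.n_mod / self.n_total

    @property
    def mean_replicate_ratio(self) -> float:
        ratios = [m / (m + u) for m, u in self.per_replicate.values()
                  if m + u > 0]
        if not ratios:
            raise ValidationError(
                f"site {self.site}: no covered replicate")
        return float(np.mean(ratios))


@dataclass
class M6aDiffResult:
    site: tuple[str, int, str]
    gene_id: str
    ratio_1: float
    ratio_2: float
    delta: float
    p_value: float
    significant: bool


def aggregate_site_counts(modcalls: pd.DataFrame, reads: pd.DataFrame,
                          samples: list[str]
                          ) -> dict[tuple[str, int, str], M6aSiteCounts]:
    """Pool modification calls per site over ``samples`` (one condition).

    ``reads`` supplies the read -> sample mapping.  Pooled and per-replicate
    counts are both retained; sites with zero coverage in the condition are
    returned untestable (they appear only if seen in other rows).
    """
    dup = modcalls.duplicated(
        subset=["read_id", "site_chrom", "site_pos", "site_strand"])
    if dup.any():
        raise ValidationError("a read contributes two calls at one site")
    merged = modcalls.merge(reads[["read_id", "sample_id"]], on="read_id",
                            how="inner")
    merged = merged[merged["sample_id"].isin(samples)]
    out: dict[tuple[str, int, str], M6aSiteCounts] = {}
    grouped = merged.groupby(
        ["site_chrom", "site_pos", "site_strand", "gene_id", "sample_id"],
        sort=True)["modified"].agg(["sum", "count"])
    for (chrom, pos, strand, gene_id, sample), row in grouped.iterrows():
        key = (chrom, int(pos), strand)
        n_mod, n_tot = int(row["sum"]), int(row["count"])
        sc = out.get(key)
        if sc is None:
            sc = M6aSiteCounts(site=key, gene_id=gene_id, n_mod=0, n_unmod=0,
                               per_replicate={})
            out[key] = sc
        sc.n_mod += n_mod
        sc.n_unmod += n_tot - n_mod
        sc.per_replicate[sample] = (n_mod, n_tot - n_mod)
    return out


def assign_region(site_pos: int, transcript: TranscriptModel) -> str:
    """Strand-aware region of a site: 5UTR, CDS (termini inclusive) or 3UTR.

    Returns ``unassigned`` when the site is intronic/outside the exons.
    """
    if transcript.cds is None:
        return "unassigned"
    if transcript.genomic_to_transcript(site_pos) is None:
        return "unassigned"
    cs, ce = transcript.cds
    if cs <= site_pos <= ce:
        return "CDS"
    before = site_pos < cs
    if transcript.strand == "+":
        return "5UTR" if before else "3UTR"
    return "3UTR" if before else "5UTR"


def metagene_profile(site_positions: list[tuple[str, int, str]] | list[int],
                     transcript_of_site, bins_per_region: int = 10
                     ) -> np.ndarray:
    """Site density over the scaled 5'UTR | CDS | 3'UTR axis.

    ``transcript_of_site`` maps each site entry to its TranscriptModel (a
    callable or a dict).  Sites outside exons or in zero-length regions are
    skipped and reported; an all-empty input yields an explicit empty
    (all-zero) profile.  Non-empty profiles sum to 1.
    """
    if bins_per_region < 1:
        raise ConfigurationError("bins_per_region must be >= 1")
    lookup = transcript_of_site if callable(transcript_of_site) else \
        transcript_of_site.__getitem__
    profile = np.zeros(3 * bins_per_region)
    skipped = 0
    for entry in site_positions:
        pos = entry[1] if isinstance(entry, tuple) else entry
        t = lookup(entry)
        region = assign_region(pos, t)
        if region == "unassigned":
            skipped += 1
            continue
        toff = t.genomic_to_transcript(pos)
        bounds = {"5UTR": (0, t.utr5_len),
                  "CDS": (t.utr5_len, t.utr5_len + t.cds_len),
                  "3UTR": (t.utr5_len + t.cds_len, t.exonic_length)}
        lo, hi = bounds[region]
        if hi <= lo:
            skipped += 1
            continue
        frac = (toff - lo) / (hi - lo)
        b = min(int(frac * bins_per_region), bins_per_region - 1)
        profile[REGIONS.index(region) * bins_per_region + b] += 1
    if skipped:
        logger.warning("metagene: %d sites unassignable, skipped", skipped)
    total = profile.sum()
    if total > 0:
        profile /= total
    else:
        logger.warning("metagene: no assignable sites; empty profile")
    return profile


def fisher_exact_two_sided(n_mod_1: int, n_unmod_1: int,
                           n_mod_2: int, n_unmod_2: int) -> float:
    """Two-sided Fisher exact p on a 2x2 table (point-probability method:
    all tables with fixed margins whose probability does not exceed the
    observed table's are summed)."""
    _, p = scipy.stats.fisher_exact(
        [[n_mod_1, n_unmod_1], [n_mod_2, n_unmod_2]],
        alternative="two-sided")
    return float(p)


def m6a_diff_test(counts_1: M6aSiteCounts, counts_2: M6aSiteCounts
                  ) -> M6aDiffResult:
    """Differential m6A between two conditions at one site.

    Fisher exact (two-sided, point-probability) on the pooled 2x2 table;
    delta is the difference of mean per-replicate ratios.
    """
    if not (counts_1.testable and counts_2.testable):
        raise ValidationError(
            f"site {counts_1.site}: untestable (zero coverage in a condition)")
    p = fisher_exact_two_sided(counts_1.n_mod, counts_1.n_unmod,
                               counts_2.n_mod, counts_2.n_unmod)
    r1 = counts_1.mean_replicate_ratio
    r2 = counts_2.mean_replicate_ratio
    delta = r2 - r1
    sig = bool(abs(delta) > DELTA_CUTOFF and p < P_CUTOFF)
    return M6aDiffResult(site=counts_1.site, gene_id=counts_1.gene_id,
                         ratio_1=r1, ratio_2=r2, delta=delta,
                         p_value=float(p), significant=sig)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def m6a_diff_all(modcalls: pd.DataFrame, reads: pd.DataFrame,
                 cond1_samples: list[str], cond2_samples: list[str],
                 fdr: bool = False) -> pd.DataFrame:
    """Differential m6A for every site testable in both conditions.

    Raw p-values decide significance by default; with ``fdr=True`` a
    ``q_value`` column is added and takes the p-value's place in the
    significance rule.
    """
    c1 = aggregate_site_counts(modcalls, reads, cond1_samples)
    c2 = aggregate_site_counts(modcalls, reads, cond2_samples)
    rows = []
    for key in sorted(set(c1) & set(c2)):
        if not (c1[key].testable and c2[key].testable):
            continue
        r = m6a_diff_test(c1[key], c2[key])
        rows.append({"site_chrom": key[0], "site_pos": key[1],
                     "site_strand": key[2], "gene_id": r.gene_id,
                     "ratio_1": r.ratio_1, "ratio_2": r.ratio_2,
                     "delta": r.delta, "p_value": r.p_value,
                     "significant": r.significant})
    out = pd.DataFrame(rows, columns=[
        "site_chrom", "site_pos", "site_strand", "gene_id", "ratio_1",
        "ratio_2", "delta", "p_value", "significant"])
    if fdr and len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out["significant"] = (out["q_value"] < P_CUTOFF) & \
            (out["delta"].abs() > DELTA_CUTOFF)
    return out


def gene_m6a_rates(modcalls: pd.DataFrame, reads: pd.DataFrame,
                   samples: list[str]) -> pd.Series:
    """Per-gene mean of per-site m6A ratios within one condition."""
    counts = aggregate_site_counts(modcalls, reads, samples)
    per_gene: dict[str, list[float]] = {}
    for sc in counts.values():
        if sc.testable:
            per_gene.setdefault(sc.gene_id, []).append(sc.ratio)
    return pd.Series({g: float(np.mean(v)) for g, v in sorted(per_gene.items())},
                     dtype=float)


def stage_m6a_rate_distribution(modcalls: pd.DataFrame, reads: pd.DataFrame,
                                stages: list[str]) -> pd.DataFrame:
    """Per-stage summary (median, quartiles, n) of per-gene mean m6A ratios."""
    rows = []
    for stage in stages:
        samples = sorted(reads.loc[reads["stage"] == stage, "sample_id"]
                         .unique())
        rates = gene_m6a_rates(modcalls, reads, samples)
        if rates.empty:
            logger.warning("stage %s has no testable genes; omitted", stage)
            continue
        q1, med, q3 = np.percentile(rates.to_numpy(), [25, 50, 75])
        rows.append((stage, len(rates), med, q1, q3))
    return pd.DataFrame(rows, columns=["stage", "n_genes", "median", "q1", "q3"])


def longest_cds_transcript(gene: GeneModel) -> TranscriptModel | None:
    """Region-assignment frame for multi-isoform genes: longest CDS."""
    coding = [t for t in gene.transcripts if t.cds is not None]
    if not coding:
        return None
    return max(coding, key=lambda t: (t.cds_len, t.transcript_id))


def site_region_table(modcalls: pd.DataFrame, genes: list[GeneModel]
                      ) -> pd.DataFrame:
    """Unique sites with their assigned transcript region."""
    gene_map = {g.gene_id: g for g in genes}
    sites = modcalls[["site_chrom", "site_pos", "site_strand", "gene_id"]] \
        .drop_duplicates().sort_values(
            ["site_chrom", "site_pos", "site_strand"]).reset_index(drop=True)
    regions = []
    for _, row in sites.iterrows():
        gene = gene_map.get(row["gene_id"])
        t = longest_cds_transcript(gene) if gene is not None else None
        regions.append(assign_region(int(row["site_pos"]), t)
                       if t is not None else "unassigned")
    sites["region"] = regions
    return sites
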