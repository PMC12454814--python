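"""Poly(A)-site clustering and alternative-polyadenylation statistics.

Read 3'-end positions are clustered per gene by single linkage over the
sorted positions (adjacent gap <= window merges, window inclusive).  Among
clusters in the final exon, the two most abundant become the proximal
(pPAS) and distal (dPAS) sites by their distance from the stop codon in
transcription direction.  For a condition pair the usage-shift statistic is

    D = | log2((DPAS1 + c) / (DPAS2 + c)) - log2((PPAS1 + c) / (PPAS2 + c)) |

with pseudocount c, significant when D exceeds the ">30%" threshold (three
interpretations selectable; default: D > 0.3).  Per-condition RED scores
are log2(dPAS/pPAS) usage ratios; delta RED = RED_2 - RED_1 is negative
when condition 2 shifts proximally (global 3' UTR shortening).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptModel
from .errors import ConfigurationError, ValidationError

#: how the "more than 30%" significance rule is read (see apa_d_statistic)
APA_THRESHOLD_MODES = ("log2", "fold", "usage")


@dataclass
class PasCluster:
    """A clustered poly(A) site with per-sample read counts."""

    gene_id: str
    chrom: str
    strand: str
    mode_pos: int
    span: tuple[int, int]
    counts: dict[str, int]
    in_final_exon: bool = False

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def condition_count(self, samples: list[str]) -> int:
        return sum(self.counts.get(s, 0) for s in samples)


@dataclass
class ApaGeneResult:
    """Per-gene APA contrast between two conditions."""

    gene_id: str
    ppas: PasCluster
    dpas: PasCluster
    ppas1: int
    dpas1: int
    ppas2: int
    dpas2: int
    d_statistic: float
    significant: bool
    red_1: float
    red_2: float
    delta_red: float
    shift_class: str


def _txn_distance(pos: int, stop: int | None, strand: str) -> float:
    """Distance from the stop codon along the transcription direction."""
    if stop is None:
        return float(pos)
    d = (pos - stop) if strand == "+" else (stop - pos)
    return abs(d)


def cluster_pas(endpoints: list[tuple[int, str]], window: int, *,
                gene_id: str = "", chrom: str = "", strand: str = "+",
                stop_codon_pos: int | None = None) -> list[PasCluster]:
    """Single-linkage clustering of read 3' ends.

    ``endpoints`` is a list of (position, sample_id).  Sorted positions are
    split wherever the gap between neighbours exceeds ``window`` (a gap equal
    to the window still merges).  The representative ``mode_pos`` is the most
    frequent position; ties go to the position most proximal to the stop
    codon in transcription direction (smallest position when no stop given).
    """
    if window < 0:
        raise ConfigurationError("clustering window must be >= 0")
    if not endpoints:
        return []
    pts = sorted(endpoints)
    clusters: list[PasCluster] = []
    block: list[tuple[int, str]] = [pts[0]]
    for p in pts[1:]:
        if p[0] - block[-1][0] <= window:
            block.append(p)
        else:
            clusters.append(_make_cluster(block, gene_id, chrom, strand,
                                          stop_codon_pos))
            block = [p]
    clusters.append(_make_cluster(block, gene_id, chrom, strand, stop_codon_pos))
    return clusters


def _make_cluster(block, gene_id, chrom, strand, stop) -> PasCluster:
    positions = [p for p, _ in block]
    freq = Counter(positions)
    top = max(freq.values())
    candidates = [p for p, n in freq.items() if n == top]
    mode = min(candidates, key=lambda p: (_txn_distance(p, stop, strand), p))
    counts: dict[str, int] = {}
    for _, sample in block:
        counts[sample] = counts.get(sample, 0) + 1
    return PasCluster(gene_id=gene_id, chrom=chrom, strand=strand,
                      mode_pos=mode, span=(min(positions), max(positions)),
                      counts=counts)


def annotate_final_exon(clusters: list[PasCluster],
                        transcript: TranscriptModel) -> None:
    fs, fe = transcript.final_exon
    for c in clusters:
        c.in_final_exon = fs <= c.mode_pos <= fe


def select_pas_pair(clusters: list[PasCluster], transcript: TranscriptModel,
                    min_count: int = 5
                    ) -> tuple[PasCluster, PasCluster] | None:
    """Pick the two most abundant final-exon clusters as (pPAS, dPAS).

    Returns None when fewer than two final-exon clusters reach ``min_count``
    total reads.  Count ties break deterministically by proximity to the
    stop codon; the nearer of the chosen pair is always the pPAS.
    """
    stop = transcript.stop_codon_pos
    strand = transcript.strand
    eligible = [c for c in clusters
                if c.in_final_exon and c.total_count >= min_count]
    if len(eligible) < 2:
        return None
    eligible.sort(key=lambda c: (-c.total_count,
                                 _txn_distance(c.mode_pos, stop, strand),
                                 c.mode_pos))
    a, b = eligible[0], eligible[1]
    if _txn_distance(a.mode_pos, stop, strand) <= \
            _txn_distance(b.mode_pos, stop, strand):
        return a, b
    return b, a


def apa_d_statistic(ppas1: int, dpas1: int, ppas2: int, dpas2: int,
                    pseudocount: float = 1.0, threshold: float = 0.3,
                    mode: str = "log2") -> tuple[float, bool]:
    """The usage-shift statistic D and its significance call.

    ``mode`` selects the reading of "difference in relative abundance of
    more than 30%": ``log2`` -> D > threshold (default 0.3); ``fold`` ->
    D > log2(1 + threshold), i.e. a >1.3-fold odds change; ``usage`` ->
    the distal usage fraction changes by more than ``threshold`` (30
    percentage points).  D itself is identical in all modes.
    """
    for v in (ppas1, dpas1, ppas2, dpas2):
        if v < 0:
            raise ValidationError("PAS counts must be non-negative")
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    if mode not in APA_THRESHOLD_MODES:
        raise ConfigurationError(f"unknown APA threshold mode {mode!r}")
    c = pseudocount
    d = abs(math.log2((dpas1 + c) / (dpas2 + c)) -
            math.log2((ppas1 + c) / (ppas2 + c)))
    if mode == "log2":
        significant = d > threshold
    elif mode == "fold":
        significant = d > math.log2(1.0 + threshold)
    else:
        u1 = (dpas1 + c) / (dpas1 + ppas1 + 2 * c)
        u2 = (dpas2 + c) / (dpas2 + ppas2 + 2 * c)
        significant = abs(u2 - u1) > threshold
    return d, significant


def red_score(dpas: int, ppas: int, pseudocount: float = 1.0) -> float:
    """Per-condition RED: log2 of distal over proximal usage."""
    c = pseudocount
    return math.log2((dpas + c) / (ppas + c))


def classify_apa_shift(significant: bool, delta_red: float) -> str:
    if significant and delta_red < 0:
        return "proximal_up"
    if significant and delta_red > 0:
        return "distal_up"
    return "unchanged"


def apa_gene_result(gene_id: str, ppas: PasCluster, dpas: PasCluster,
                    cond1_samples: list[str], cond2_samples: list[str],
                    pseudocount: float = 1.0, threshold: float = 0.3,
                    mode: str = "log2") -> ApaGeneResult:
    p1 = ppas.condition_count(cond1_samples)
    d1 = dpas.condition_count(cond1_samples)
    p2 = ppas.condition_count(cond2_samples)
    d2 = dpas.condition_count(cond2_samples)
    d_stat, sig = apa_d_statistic(p1, d1, p2, d2, pseudocount, threshold, mode)
    r1 = red_score(d1, p1, pseudocount)
    r2 = red_score(d2, p2, pseudocount)
    delta = r2 - r1
    return ApaGeneResult(
        gene_id=gene_id, ppas=ppas, dpas=dpas,
        ppas1=p1, dpas1=d1, ppas2=p2, dpas2=d2,
        d_statistic=d_stat, significant=sig,
        red_1=r1, red_2=r2, delta_red=delta,
        shift_class=classify_apa_shift(sig, delta))


def apa_analysis(reads: pd.DataFrame, genes: list[GeneModel],
                 cond1_samples: list[str], cond2_samples: list[str],
                 window: int = 24, min_count: int = 5,
                 min_count_per_condition: int = 5,
                 pseudocount: float = 1.0, threshold: float = 0.3,
                 mode: str = "log2") -> list[ApaGeneResult]:
    """Cluster 3' ends and contrast pPAS/dPAS usage for every testable gene.

    A gene is testable when it has a final-exon PAS pair and both sites
    carry at least ``min_count_per_condition`` reads in each condition.
    The final exon is taken from the transcript with the most-3' stop codon.
    """
    wanted = set(cond1_samples) | set(cond2_samples)
    sub = reads[reads["sample_id"].isin(wanted)]
    results: list[ApaGeneResult] = []
    by_gene = dict(tuple(sub.groupby("gene_id", sort=True)))
    for gene in genes:
        rows = by_gene.get(gene.gene_id)
        if rows is None or rows.empty:
            continue
        t = gene.apa_reference_transcript
        endpoints = list(zip(rows["three_prime_pos"].tolist(),
                             rows["sample_id"].tolist()))
        clusters = cluster_pas(
            endpoints, window, gene_id=gene.gene_id, chrom=gene.chrom,
            strand=gene.strand, stop_codon_pos=t.stop_codon_pos)
        annotate_final_exon(clusters, t)
        pair = select_pas_pair(clusters, t, min_count=min_count)
        if pair is None:
            continue
        ppas, dpas = pair
        ok = all(cl.condition_count(cs) >= min_count_per_condition
                 for cl in (ppas, dpas)
                 for cs in (cond1_samples, cond2_samples))
        if not ok:
            continue
        results.append(apa_gene_result(
            gene.gene_id, ppas, dpas, cond1_samples, cond2_samples,
            pseudocount, threshold, mode))
    return results


def global_mean_red(results: list[ApaGeneResult]) -> float | None:
    """Mean delta RED over testable genes; None for an empty set."""
    if not results:
        return None
    return float(np.mean([r.delta_red for r in results]))


def results_to_frame(results: list[ApaGeneResult]) -> pd.DataFrame:
    cols = ["gene_id", "chrom", "strand", "ppas_pos", "dpas_pos",
            "ppas1", "dpas1", "ppas2", "dpas2", "d_statistic",
            "significant", "red_1", "red_2", "delta_red", "shift_class"]
    rows = [[r.gene_id, r.ppas.chrom, r.ppas.strand, r.ppas.mode_pos,
             r.dpas.mode_pos, r.ppas1, r.dpas1, r.ppas2, r.dpas2,
             r.d_statistic, r.significant, r.red_1, r.red_2, r.delta_red,
             r.shift_class] for r in results]
    return pd.DataFrame(rows, columns=cols)


def clusters_to_bed(results: list[ApaGeneResult]) -> str:
    """pPAS/dPAS clusters as BED6 (0-based half-open)."""
    lines = []
    for r in results:
        for cl, label in ((r.ppas, "proximal"), (r.dpas, "distal")):
            lines.append("\t".join([
                cl.chrom, str(cl.span[0] - 1), str(cl.span[1]),
                f"{r.gene_id}:{label}", str(cl.total_count), cl.strand]))
    return "\n".join(lines) + ("\n" if lines else "")
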