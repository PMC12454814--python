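"""Expression quantification (TPM), a declared differential-expression
stand-in, and the stratified integration statistics.

TPM divides each transcript's read count by its spliced length in kilobases
and scales each sample so the values sum to one million.  The DE stand-in
applies the study-style thresholds (p < 0.05 and |log2 fold change| > 1) to
a Welch t test on log2(TPM + 1) across replicates — deliberately simpler
than a count-model estimator, and labelled as a stand-in in its outputs.
Group comparisons use one-way ANOVA plus all pairwise Welch t tests (the
two-group case is exactly the unpaired Welch t test); correlations are
Spearman rank correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .annotation import GeneModel
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

DE_P_CUTOFF = 0.05
DE_LFC_CUTOFF = 1.0
DE_METHOD_LABEL = "welch-t-log2tpm-standin"


@dataclass
class ExpressionMatrix:
    """Counts and TPM, transcripts x samples."""

    counts: pd.DataFrame
    tpm: pd.DataFrame
    lengths: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class GroupComparisonResult:
    grouping: str
    group_stats: pd.DataFrame         # group, n, median, q1, q3
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame            # group_a, group_b, t, p
    dropped_groups: list[str] = field(default_factory=list)


def transcript_lengths(genes: list[GeneModel]) -> pd.Series:
    return pd.Series({t.transcript_id: t.exonic_length
                      for g in genes for t in g.transcripts}, dtype=float)


def quantify_tpm(reads: pd.DataFrame, lengths: pd.Series,
                 samples: list[str] | None = None) -> ExpressionMatrix:
    """Per-transcript read counts and TPM per sample.

    All annotated transcripts appear (zero-filled); an all-zero sample gets
    all-zero TPM with a warning rather than a division error.
    """
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValidationError(f"zero/negative transcript lengths: {bad[:5]}")
    if samples is None:
        samples = sorted(reads["sample_id"].unique())
    counts = (reads.groupby(["transcript_id", "sample_id"]).size()
              .unstack(fill_value=0)
              .reindex(index=lengths.index, columns=samples, fill_value=0))
    rate = counts.div(lengths / 1000.0, axis=0)
    tot = rate.sum(axis=0)
    zero = tot == 0
    if zero.any():
        logger.warning("samples with zero reads: %s",
                       list(tot.index[zero]))
        tot = tot.replace(0, np.nan)
    tpm = rate.div(tot, axis=1).mul(1e6).fillna(0.0)
    return ExpressionMatrix(counts=counts, tpm=tpm, lengths=lengths)


def de_standin(matrix: ExpressionMatrix, cond1_samples: list[str],
               cond2_samples: list[str]) -> pd.DataFrame:
    """Study-style DE thresholds on a Welch t over log2(TPM + 1).

    log2_fc = log2((mean TPM_2 + 1) / (mean TPM_1 + 1)); significant when
    p < 0.05 and |log2_fc| > 1.  Requires >= 2 replicates per condition.
    """
    if len(cond1_samples) < 2 or len(cond2_samples) < 2:
        raise ConfigurationError(
            "de_standin requires >= 2 replicates per condition")
    t1 = matrix.tpm[cond1_samples].to_numpy()
    t2 = matrix.tpm[cond2_samples].to_numpy()
    lfc = np.log2((t2.mean(axis=1) + 1.0) / (t1.mean(axis=1) + 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = scipy.stats.ttest_ind(
            np.log2(t2 + 1.0), np.log2(t1 + 1.0), axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both: no evidence
    sig = (p < DE_P_CUTOFF) & (np.abs(lfc) > DE_LFC_CUTOFF)
    return pd.DataFrame({
        "transcript_id": matrix.tpm.index,
        "log2_fc": lfc,
        "t_statistic": stat,
        "p_value": p,
        "significant": sig,
        "method": DE_METHOD_LABEL,
    }).reset_index(drop=True)


def group_compare(values, labels, grouping: str = "",
                  min_group_size: int = 3) -> GroupComparisonResult:
    """One-way ANOVA omnibus + all pairwise Welch t tests across groups.

    Groups below ``min_group_size`` are dropped with a warning; with two
    groups the omnibus IS the unpaired Welch t test.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    groups: dict[str, np.ndarray] = {
        str(lb): values[labels == lb] for lb in pd.unique(labels)}
    dropped = [lb for lb, v in groups.items() if len(v) < min_group_size]
    for lb in dropped:
        logger.warning("group %r below %d items; dropped", lb, min_group_size)
        del groups[lb]
    if len(groups) < 2:
        raise ConfigurationError("fewer than two usable groups")
    names = sorted(groups)
    stats_rows = []
    for lb in names:
        v = groups[lb]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        stats_rows.append((lb, len(v), med, q1, q3))
    pair_rows = []
    for a, b in combinations(names, 2):
        t, p = scipy.stats.ttest_ind(groups[a], groups[b], equal_var=False)
        pair_rows.append((a, b, float(t), float(p)))
    pairwise = pd.DataFrame(pair_rows, columns=["group_a", "group_b", "t", "p"])
    if len(names) == 2:
        omni_stat, omni_p = pairwise.loc[0, "t"], pairwise.loc[0, "p"]
    else:
        omni_stat, omni_p = scipy.stats.f_oneway(*(groups[lb] for lb in names))
    return GroupComparisonResult(
        grouping=grouping,
        group_stats=pd.DataFrame(
            stats_rows, columns=["group", "n", "median", "q1", "q3"]),
        omnibus_statistic=float(omni_stat), omnibus_p=float(omni_p),
        pairwise=pairwise, dropped_groups=dropped)


def correlation_analysis(x, y, min_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation; (nan, nan) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < min_n:
        raise ConfigurationError(
            f"correlation needs >= {min_n} paired observations, got {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input: correlation undefined")
        return float("nan"), float("nan")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def modified_transcripts(modcalls: pd.DataFrame, reads: pd.DataFrame,
                         samples: list[str], min_ratio: float = 0.1,
                         min_coverage: int = 10) -> set[str]:
    """Transcripts counted as m6A-modified for stratified comparisons.

    A transcript qualifies when its gene has >= 1 site with m6A ratio >=
    ``min_ratio`` at >= ``min_coverage`` covering reads.
    """
    from .m6a import aggregate_site_counts
    counts = aggregate_site_counts(modcalls, reads, samples)
    mod_genes = {sc.gene_id for sc in counts.values()
                 if sc.n_total >= min_coverage and sc.testable
                 and sc.ratio >= min_ratio}
    sub = reads[reads["gene_id"].isin(mod_genes)]
    return set(sub["transcript_id"].unique())
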