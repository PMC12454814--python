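"""Gene/transcript data model and input parsing.

Coordinates are 1-based inclusive throughout, matching GFF3; BED export
converts to 0-based half-open at the boundary.  A transcript's 3' landmarks
(stop-codon position, final exon, 3' UTR) are derived strand-aware: the
stop-codon position is the annotated CDS 3' terminus (stop codon inside the
CDS, the common GFF3 convention), the final exon is the rightmost exon on
'+' and the leftmost on '-', and the 3' UTR is the part of the final exon
downstream of the stop codon in transcription direction.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

#: Transcript-level alternative-splicing class labels accepted in input.
AS_CLASSES = ("AF", "AL", "A3", "A5", "SE", "MX", "RI", "none")

READS_COLUMNS = [
    "read_id", "sample_id", "stage", "gene_id", "transcript_id", "strand",
    "three_prime_pos", "polya_len", "full_length", "as_class",
]
MODCALLS_COLUMNS = [
    "read_id", "gene_id", "site_chrom", "site_pos", "site_strand", "modified",
]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sorted exons, optional CDS, an AS-class label.

    ``cds`` is the genomic interval from the first to the last CDS base
    (it may span introns); both termini must fall inside exons.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: Interval | None = None
    as_class: str = "none"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s > e:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon ({s},{e}) inverted")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons")
            prev_end = e
        if self.cds is not None:
            cs, ce = int(self.cds[0]), int(self.cds[1])
            object.__setattr__(self, "cds", (cs, ce))
            if cs > ce:
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS ({cs},{ce}) inverted")
            if not (self._in_exons(cs) and self._in_exons(ce)):
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS ({cs},{ce}) "
                    "outside the exon union")
        if self.as_class not in AS_CLASSES:
            raise ValidationError(
                f"transcript {self.transcript_id}: unknown AS class "
                f"{self.as_class!r}")

    def _in_exons(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    # -- strand-aware 3' landmarks ------------------------------------

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def stop_codon_pos(self) -> int | None:
        """Genomic position of the CDS 3' terminus (stop codon included)."""
        if self.cds is None:
            return None
        return self.cds[1] if self.strand == "+" else self.cds[0]

    @property
    def final_exon(self) -> Interval:
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def utr3(self) -> Interval | None:
        """3' UTR within the final exon, or None when the CDS reaches the end."""
        stop = self.stop_codon_pos
        if stop is None:
            return None
        fs, fe = self.final_exon
        if self.strand == "+":
            return (stop + 1, fe) if stop < fe else None
        return (fs, stop - 1) if stop > fs else None

    # -- spliced-coordinate mapping ------------------------------------

    def genomic_to_transcript(self, pos: int) -> int | None:
        """0-based offset from the transcript 5' end, or None if intronic."""
        off = 0
        plus_off = None
        for s, e in self.exons:
            if s <= pos <= e:
                plus_off = off + (pos - s)
                break
            off += e - s + 1
        if plus_off is None:
            return None
        if self.strand == "+":
            return plus_off
        return self.exonic_length - 1 - plus_off

    def transcript_to_genomic(self, offset: int) -> int:
        if not 0 <= offset < self.exonic_length:
            raise ValidationError(
                f"transcript {self.transcript_id}: offset {offset} outside "
                f"[0,{self.exonic_length})")
        plus_off = offset if self.strand == "+" else self.exonic_length - 1 - offset
        for s, e in self.exons:
            ln = e - s + 1
            if plus_off < ln:
                return s + plus_off
            plus_off -= ln
        raise AssertionError("unreachable")

    @property
    def utr5_len(self) -> int:
        """Spliced length of the 5' UTR (0 when no CDS)."""
        if self.cds is None:
            return 0
        start = self.cds[0] if self.strand == "+" else self.cds[1]
        t = self.genomic_to_transcript(start)
        if t is None:
            raise ValidationError(
                f"transcript {self.transcript_id}: CDS start not exonic")
        return t

    @property
    def cds_len(self) -> int:
        """Spliced CDS length (stop codon included)."""
        if self.cds is None:
            return 0
        a = self.genomic_to_transcript(self.cds[0])
        b = self.genomic_to_transcript(self.cds[1])
        if a is None or b is None:
            raise ValidationError(
                f"transcript {self.transcript_id}: CDS terminus not exonic")
        return abs(a - b) + 1

    @property
    def utr3_len(self) -> int:
        if self.cds is None:
            return 0
        return self.exonic_length - self.utr5_len - self.cds_len


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts on one chromosome and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id}: no transcripts")
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValidationError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} on a "
                    "different chrom/strand")

    @property
    def span(self) -> Interval:
        return (min(t.span[0] for t in self.transcripts),
                max(t.span[1] for t in self.transcripts))

    @property
    def apa_reference_transcript(self) -> TranscriptModel:
        """Transcript whose stop codon is most 3' — the gene-level APA frame."""
        coding = [t for t in self.transcripts if t.cds is not None]
        pool = coding or list(self.transcripts)
        if self.strand == "+":
            return max(pool, key=lambda t: (t.stop_codon_pos or -1, t.transcript_id))
        return min(pool, key=lambda t: (t.stop_codon_pos or 2**62, t.transcript_id))


@dataclass
class ReadRecord:
    """One sequenced molecule's per-read features (row of reads.tsv)."""

    read_id: str
    sample_id: str
    stage: str
    gene_id: str
    transcript_id: str
    strand: str
    three_prime_pos: int
    polya_len: float | None
    full_length: bool
    as_class: str = "none"


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def genes_to_gff3(genes: list[GeneModel], source: str = "tailshift") -> str:
    """Serialize gene models as a GFF3 document (1-based inclusive)."""
    out = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
        gs, ge = g.span
        out.append("\t".join([
            g.chrom, source, "gene", str(gs), str(ge), ".", g.strand, ".",
            f"ID={g.gene_id}"]))
        for t in g.transcripts:
            ts, te = t.span
            out.append("\t".join([
                g.chrom, source, "mRNA", str(ts), str(te), ".", g.strand, ".",
                f"ID={t.transcript_id};Parent={g.gene_id};as_class={t.as_class}"]))
            for i, (s, e) in enumerate(t.exons, 1):
                out.append("\t".join([
                    g.chrom, source, "exon", str(s), str(e), ".", g.strand, ".",
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"]))
            if t.cds is not None:
                segs = _cds_segments(t)
                phases = _cds_phases(t, segs)
                for i, ((s, e), ph) in enumerate(zip(segs, phases), 1):
                    out.append("\t".join([
                        g.chrom, source, "CDS", str(s), str(e), ".", g.strand,
                        str(ph), f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}"]))
    return "\n".join(out) + "\n"


def _cds_segments(t: TranscriptModel) -> list[Interval]:
    cs, ce = t.cds
    segs = []
    for s, e in t.exons:
        lo, hi = max(s, cs), min(e, ce)
        if lo <= hi:
            segs.append((lo, hi))
    return segs


def _cds_phases(t: TranscriptModel, segs: list[Interval]) -> list[int]:
    ordered = segs if t.strand == "+" else list(reversed(segs))
    phases, cum = [], 0
    for s, e in ordered:
        phases.append((3 - cum % 3) % 3)
        cum += e - s + 1
    return phases if t.strand == "+" else list(reversed(phases))


def load_annotation(source: str) -> list[GeneModel]:
    """Parse a GFF3 document (path or text) into gene models.

    Raises :class:`ValidationError` naming the offending transcript when a
    CDS lies outside its exons or a feature lacks its parent.
    """
    from_string = "\n" in source or source.lstrip().startswith("##gff")
    db = gffutils.create_db(
        source, dbfn=":memory:", from_string=from_string,
        merge_strategy="create_unique", keep_order=True)
    known_mrna_parents = {g.id for g in db.features_of_type("gene")}
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = []
        for m in db.children(g, featuretype="mRNA", order_by="start"):
            exons = tuple(
                (f.start, f.end)
                for f in db.children(m, featuretype="exon", order_by="start"))
            if not exons:
                raise ValidationError(f"transcript {m.id}: no exon children")
            cds_feats = list(db.children(m, featuretype="CDS", order_by="start"))
            cds = None
            if cds_feats:
                cds = (min(f.start for f in cds_feats),
                       max(f.end for f in cds_feats))
            as_class = m.attributes.get("as_class", ["none"])[0]
            transcripts.append(TranscriptModel(
                transcript_id=m.id, chrom=g.seqid, strand=g.strand,
                exons=exons, cds=cds, as_class=as_class))
        genes.append(GeneModel(
            gene_id=g.id, chrom=g.seqid, strand=g.strand,
            transcripts=tuple(transcripts)))
    # orphan mRNAs (parent gene missing) are a structural error
    for m in db.features_of_type("mRNA"):
        parents = m.attributes.get("Parent", [])
        if not parents or parents[0] not in known_mrna_parents:
            raise ValidationError(f"transcript {m.id}: missing parent gene link")
    return genes


# ---------------------------------------------------------------------------
# Per-read tables
# ---------------------------------------------------------------------------

@dataclass
class ReadLoadReport:
    """Parsed reads plus a validation summary (the plain-text log)."""

    reads: pd.DataFrame
    n_input: int
    n_dropped_unknown_transcript: int
    n_flagged_outside_span: int
    messages: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"reads parsed: {self.n_input}",
            f"dropped (unknown transcript): {self.n_dropped_unknown_transcript}",
            f"flagged (3' end outside gene span + slack): {self.n_flagged_outside_span}",
        ]
        return "\n".join(lines + self.messages)


def _read_tsv(source: str, required: list[str]) -> pd.DataFrame:
    buf = io.StringIO(source) if "\n" in source else source
    df = pd.read_csv(buf, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"input table missing columns: {missing}")
    return df


def _coerce_numeric(df: pd.DataFrame, col: str, kind: str,
                    allow_missing: bool = False) -> pd.Series:
    raw = df[col].str.strip()
    empty = raw == ""
    vals = pd.to_numeric(raw.where(~empty), errors="coerce")
    bad = vals.isna() & ~empty
    if not allow_missing:
        bad |= empty
    if bad.any():
        # +2: 1-based line numbers plus the header line (comment lines were
        # stripped before pandas saw the file, so numbers are approximate
        # when a '#' header is present).
        lines = (df.index[bad] + 2).tolist()
        raise ValidationError(
            f"malformed {kind} field '{col}' at lines {lines[:20]}"
            + (" ..." if len(lines) > 20 else ""))
    if kind == "int":
        return vals.fillna(0).astype(np.int64).where(~empty)
    return vals


def load_reads(source: str, genes: list[GeneModel],
               span_slack: int = 1000) -> ReadLoadReport:
    """Load reads.tsv, dropping rows with unknown transcript ids.

    Missing poly(A) lengths stay missing (NaN), never 0.  Reads whose 3' end
    falls outside the assigned gene span by more than ``span_slack`` nt are
    flagged in the ``outside_span`` column but kept.
    """
    df = _read_tsv(source, READS_COLUMNS)
    n_input = len(df)
    pos = _coerce_numeric(df, "three_prime_pos", "int")
    pal = _coerce_numeric(df, "polya_len", "float", allow_missing=True)
    fl = _coerce_numeric(df, "full_length", "int")
    df = df.assign(three_prime_pos=pos.astype(np.int64),
                   polya_len=pal.astype(float),
                   full_length=fl.astype(np.int64).astype(bool))
    if (df["polya_len"].dropna() < 0).any():
        raise ValidationError("negative polya_len values present")

    known = {t.transcript_id for g in genes for t in g.transcripts}
    keep = df["transcript_id"].isin(known)
    n_dropped = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)

    spans = {g.gene_id: g.span for g in genes}
    lo = df["gene_id"].map(lambda g: spans.get(g, (0, 0))[0])
    hi = df["gene_id"].map(lambda g: spans.get(g, (0, 0))[1])
    outside = (df["three_prime_pos"] < lo - span_slack) | \
              (df["three_prime_pos"] > hi + span_slack)
    df["outside_span"] = outside
    report = ReadLoadReport(
        reads=df, n_input=n_input,
        n_dropped_unknown_transcript=n_dropped,
        n_flagged_outside_span=int(outside.sum()))
    if n_dropped:
        report.messages.append(
            f"{n_dropped} rows referenced transcripts absent from the annotation")
    logger.info(report.summary())
    return report


def load_modcalls(source: str) -> pd.DataFrame:
    """Load modcalls.tsv; a read contributing two calls at one site is an error."""
    df = _read_tsv(source, MODCALLS_COLUMNS)
    pos = _coerce_numeric(df, "site_pos", "int")
    mod = _coerce_numeric(df, "modified", "int")
    df = df.assign(site_pos=pos.astype(np.int64),
                   modified=mod.astype(np.int64))
    if not df["modified"].isin([0, 1]).all():
        raise ValidationError("modified column must be 0/1")
    dup = df.duplicated(
        subset=["read_id", "site_chrom", "site_pos", "site_strand"])
    if dup.any():
        raise ValidationError(
            f"{int(dup.sum())} duplicate (read, site) modification calls")
    return df
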