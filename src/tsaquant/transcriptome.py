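"""Transcript models, expression quantification and transcript-level filters.

Internal genomic coordinates are 0-based half-open; GTF I/O (see
:mod:`tsaquant.io`) converts to and from the 1-based inclusive convention.
Expression is carried as FPKM in a transcript x sample matrix with one
tumor and one matched normal sample per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from tsaquant.errors import ValidationError

BIOTYPES = ("coding", "lncRNA", "novel")

#: Novel-transcript spliced-length bounds (nt, both inclusive).  The upper
#: bound is the length of the longest annotated tumor lncRNA (KCNQ1OT1).
NOVEL_MIN_LENGTH = 300
NOVEL_MAX_LENGTH = 91666


@dataclass
class TranscriptRecord:
    """A transcript: the unit of expression, specificity and ORF calling.

    Parameters
    ----------
    transcript_id : str
        Unique identifier.
    biotype : {"coding", "lncRNA", "novel"}
    chrom : str
    strand : {"+", "-", "unknown"}
    exons : list of (start, end)
        Genomic exon intervals, 0-based half-open, sorted, non-overlapping.
    sequence : str, optional
        Spliced transcript sequence (5'->3'); length must equal the summed
        exon length when present.
    cds : (start, end), optional
        Annotated coding sequence in transcript coordinates (0-based
        half-open, stop codon included); coding transcripts only.
    """

    transcript_id: str
    biotype: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    sequence: str | None = None
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.transcript_id}: biotype {self.biotype!r} not in {BIOTYPES}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValidationError(
                    f"{self.transcript_id}: bad exon interval ({start}, {end})"
                )
            if start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if self.sequence is not None and len(self.sequence) != self.spliced_length:
            raise ValidationError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"spliced length {self.spliced_length}"
            )
        if self.cds is not None:
            start, end = self.cds
            if not (0 <= start < end <= self.spliced_length):
                raise ValidationError(f"{self.transcript_id}: CDS out of bounds")
            if (end - start) % 3 != 0:
                raise ValidationError(
                    f"{self.transcript_id}: CDS length {end - start} not divisible by 3"
                )

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def genomic_span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def with_strand(self, strand: str) -> "TranscriptRecord":
        return replace(self, strand=strand)


@dataclass
class CohortCutoffs:
    """Expression cutoffs for a cohort.

    ``expr_cutoff`` gates "expressed" (strict >); ``tumor_hi`` / ``normal_lo``
    gate the matched tumor-specificity call (strict > and strict <);
    ``panel_max_median`` gates the healthy-panel filter (median <= value
    passes).  The default 1 / 1 / 0.1 set is used by most cohorts; a
    2 / 2 / 0.2 variant fits cohorts with overall higher noncoding
    expression.
    """

    expr_cutoff: float = 1.0
    tumor_hi: float = 1.0
    normal_lo: float = 0.1
    panel_max_median: float = 0.5

    def __post_init__(self) -> None:
        for name in ("expr_cutoff", "tumor_hi", "normal_lo", "panel_max_median"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.normal_lo < self.tumor_hi:
            raise ValidationError("normal_lo must be < tumor_hi")


@dataclass
class ExpressionMatrix:
    """FPKM values (transcript x sample) plus per-sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``patient_id``,
    ``tissue`` ("tumor" | "normal") and ``cohort_id``; every patient must
    contribute exactly one tumor and one normal sample.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("FPKM values must be non-negative")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        counts = self.sample_meta.groupby(["patient_id", "tissue"]).size()
        per_patient = counts.unstack(fill_value=0)
        for tissue in ("tumor", "normal"):
            if tissue not in per_patient.columns or (per_patient[tissue] != 1).any():
                raise ValidationError(
                    "every patient needs exactly one tumor and one normal sample"
                )

    @property
    def patients(self) -> list[str]:
        return sorted(self.sample_meta["patient_id"].unique())

    def sample_of(self, patient_id: str, tissue: str) -> str:
        meta = self.sample_meta
        hits = meta.index[
            (meta["patient_id"] == patient_id) & (meta["tissue"] == tissue)
        ]
        if len(hits) != 1:
            raise KeyError(f"no unique {tissue} sample for patient {patient_id}")
        return hits[0]

    def tumor_samples(self) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["tissue"] == "tumor"])

    def normal_samples(self) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["tissue"] == "normal"])


def counts_to_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """Convert uniquely-mapped read counts to FPKM.

    fpkm = count * 1e9 / (length_nt * library_size).
    """
    lengths = lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValidationError("every transcript needs a positive length")
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValidationError("every sample needs a positive library size")
    return counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)


def filter_expressed(
    matrix: ExpressionMatrix, cutoffs: CohortCutoffs, sample: str
) -> set[str]:
    """Transcripts expressed in ``sample``: FPKM strictly above the cutoff."""
    if sample not in matrix.values.columns:
        raise KeyError(f"unknown sample {sample!r}")
    col = matrix.values[sample]
    return set(col.index[col > cutoffs.expr_cutoff])


def filter_novel_length(
    transcripts: list[TranscriptRecord],
    min_length: int = NOVEL_MIN_LENGTH,
    max_length: int = NOVEL_MAX_LENGTH,
) -> list[TranscriptRecord]:
    """Retain novel transcripts with min <= spliced length <= max (inclusive)."""
    return [t for t in transcripts if min_length <= t.spliced_length <= max_length]


def _overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def impute_strand(
    novel: TranscriptRecord,
    reference_catalog: list[tuple[str, int, int, str, str]],
) -> TranscriptRecord | None:
    """Impute the strand of an unstranded novel transcript from a catalog.

    ``reference_catalog`` rows are (chrom, start, end, strand, ref_id) with
    0-based half-open coordinates.  Any reference overlapping the
    transcript's genomic span by >= 1 bp (on either strand) is a match; the
    strand of the largest-overlap match wins, ties broken by lexicographic
    reference id.  Returns ``None`` (discard) when nothing overlaps.
    """
    if novel.strand != "unknown":
        raise ValidationError(f"{novel.transcript_id}: strand already known")
    span = novel.genomic_span
    best: tuple[int, str, str] | None = None  # (-overlap, ref_id, strand)
    for chrom, start, end, strand, ref_id in reference_catalog:
        if chrom != novel.chrom:
            continue
        ov = _overlap_bp(span, (start, end))
        if ov >= 1:
            key = (-ov, ref_id, strand)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return novel.with_strand(best[2])


def _exonic_overlap(a: TranscriptRecord, b: TranscriptRecord) -> int:
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += _overlap_bp(ea, eb)
    return total


def merge_novel_across_patients(
    per_patient_transcripts: list[TranscriptRecord],
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Merge novel transcripts reconstructed in different patients.

    Single-linkage clustering of transcripts sharing >= 1 bp of exonic
    overlap on the same chromosome and strand.  Returns one representative
    per cluster (the longest member, ties by transcript id) carrying a
    stable ``NOVM`` identifier, plus a membership map from every input
    transcript id to its representative's id.
    """
    for t in per_patient_transcripts:
        if t.strand == "unknown":
            raise ValidationError(f"{t.transcript_id}: unstranded input to merge")

    # Union-find over indices; candidate pairs restricted by (chrom, strand)
    # and sorted genomic spans so the scan is near-linear for sparse input.
    parent = list(range(len(per_patient_transcripts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_key: dict[tuple[str, str], list[int]] = {}
    for i, t in enumerate(per_patient_transcripts):
        by_key.setdefault((t.chrom, t.strand), []).append(i)
    for idxs in by_key.values():
        idxs.sort(key=lambda i: per_patient_transcripts[i].genomic_span)
        for a_pos, i in enumerate(idxs):
            ti = per_patient_transcripts[i]
            for j in idxs[a_pos + 1:]:
                tj = per_patient_transcripts[j]
                if tj.genomic_span[0] >= ti.genomic_span[1]:
                    break
                if _exonic_overlap(ti, tj) >= 1:
                    union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(per_patient_transcripts)):
        clusters.setdefault(find(i), []).append(i)

    def cluster_sort_key(members: list[int]) -> tuple:
        t0 = min(
            (per_patient_transcripts[i] for i in members),
            key=lambda t: (t.chrom, t.genomic_span, t.transcript_id),
        )
        return (t0.chrom, t0.genomic_span, t0.transcript_id)

    representatives: list[TranscriptRecord] = []
    membership: dict[str, str] = {}
    for k, members in enumerate(sorted(clusters.values(), key=cluster_sort_key)):
        rep_src = min(
            (per_patient_transcripts[i] for i in members),
            key=lambda t: (-t.spliced_length, t.transcript_id),
        )
        rep_id = f"NOVM{k + 1:05d}"
        rep = replace(rep_src, transcript_id=rep_id)
        representatives.append(rep)
        for i in members:
            membership[per_patient_transcripts[i].transcript_id] = rep_id
    return representatives, membership
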