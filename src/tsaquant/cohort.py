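"""Cohort-level analyses: frequent candidates, TE/HERV enrichment,
candidate co-expression.

Frequent candidates are transcripts tumor-specific in >= 10% of patients,
highly expressed in at least one tumor (> 5 FPKM) and essentially absent
from normal samples (< 1% prevalence).  Transposable-element overlap is
computed on exonic coordinates requiring >= 1 bp on the same strand, with
overlapping TE copies merged so no base is counted twice; enrichment of
each TE class among tumor-specific transcripts is tested with Fisher's
exact test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tsaquant.errors import ValidationError
from tsaquant.transcriptome import CohortCutoffs, ExpressionMatrix, TranscriptRecord

TE_CLASSES = ("LINE", "SINE", "LTR/HERV", "retrotransposon", "RNA")


@dataclass(frozen=True)
class CandidateTranscript:
    transcript_id: str
    biotype: str
    n_patients_specific: int
    fraction_patients: float
    max_tumor_fpkm: float
    normal_prevalence: float
    herv_overlap_bp: int = 0
    herv_overlap_fraction: float = 0.0
    thymus_expressed: bool = False
    translated_evidence: bool = False


@dataclass
class TEAnnotation:
    """Stranded transposable-element intervals, grouped by class.

    ``intervals`` rows are (chrom, start, end, strand, te_class) with
    0-based half-open coordinates; unknown-strand features are rejected.
    """

    intervals: list[tuple[str, int, int, str, str]]

    def __post_init__(self) -> None:
        for chrom, start, end, strand, te_class in self.intervals:
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"TE feature {chrom}:{start}-{end} has unknown strand; "
                    "only stranded TEs are allowed"
                )
            if not 0 <= start < end:
                raise ValidationError(f"bad TE interval {chrom}:{start}-{end}")

    def by_class(
        self, chrom: str, strand: str
    ) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for c, start, end, s, te_class in self.intervals:
            if c == chrom and s == strand:
                out.setdefault(te_class, []).append((start, end))
        return out


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals so overlapping copies are not double counted."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _intersection_bp(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def te_overlap(
    transcript: TranscriptRecord, te: TEAnnotation
) -> dict[str, dict[str, float]]:
    """Exonic overlap between a transcript and each TE class.

    Same-strand TE copies of a class are merged before intersecting with
    the transcript's exons; returns per class ``{"bp": int, "fraction":
    float}`` with fraction = overlap bp / spliced length.  A transcript
    "overlaps" a class when bp >= 1.
    """
    if transcript.strand not in ("+", "-"):
        raise ValidationError(
            f"{transcript.transcript_id}: TE overlap requires a stranded transcript"
        )
    per_class = te.by_class(transcript.chrom, transcript.strand)
    result: dict[str, dict[str, float]] = {}
    for te_class in TE_CLASSES:
        merged = _merge_intervals(per_class.get(te_class, []))
        bp = _intersection_bp(transcript.exons, merged)
        result[te_class] = {
            "bp": bp,
            "fraction": bp / transcript.spliced_length,
        }
    return result


def herv_enrichment(
    tumor_expressed_set: set[str],
    tumor_specific_set: set[str],
    overlaps: dict[str, bool],
    te_class: str = "LTR/HERV",
    alternative: str = "two-sided",
) -> dict:
    """Fisher's exact test for TE-class enrichment among tumor-specific
    transcripts versus the other tumor-expressed ones.

    ``overlaps`` maps transcript id -> whether it overlaps the class.
    Returns the 2x2 table, odds ratio and p-value.  Empty margins give
    p = 1 with a warning.
    """
    if not tumor_specific_set <= tumor_expressed_set:
        raise ValidationError(
            "tumor_specific_set must be a subset of tumor_expressed_set"
        )
    background = tumor_expressed_set - tumor_specific_set
    a = sum(1 for t in tumor_specific_set if overlaps.get(t, False))
    b = len(tumor_specific_set) - a
    c = sum(1 for t in background if overlaps.get(t, False))
    d = len(background) - c
    table = [[a, b], [c, d]]
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        warnings.warn(
            f"degenerate 2x2 table for {te_class}: {table}; p set to 1",
            stacklevel=2,
        )
        return {"te_class": te_class, "table": table,
                "odds_ratio": float("nan"), "p_value": 1.0}
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return {"te_class": te_class, "table": table,
            "odds_ratio": float(odds), "p_value": float(p)}


def select_candidates(
    sharing: pd.DataFrame,
    matrix: ExpressionMatrix,
    cutoffs: CohortCutoffs,
    biotypes: dict[str, str],
    min_fraction: float = 0.10,
    min_max_fpkm: float = 5.0,
    max_normal_prevalence: float = 0.01,
    herv_overlaps: dict[str, dict[str, float]] | None = None,
    thymus_flags: dict[str, bool] | None = None,
    translated_ids: set[str] | None = None,
) -> list[CandidateTranscript]:
    """Shortlist frequent, highly tumor-specific transcripts.

    Retains transcripts tumor-specific in >= ceil(min_fraction x
    n_patients) patients, with a tumor FPKM > min_max_fpkm in at least one
    patient, and expressed (> expr_cutoff) in < max_normal_prevalence of
    all normal samples.  Output order is by descending patient count, then
    transcript id (invariant to input row order).
    """
    n_patients = len(matrix.patients)
    patient_threshold = math.ceil(min_fraction * n_patients)
    tumor_cols = matrix.values[matrix.tumor_samples()]
    normal_cols = matrix.values[matrix.normal_samples()]
    candidates: list[CandidateTranscript] = []
    for transcript_id, row in sharing.iterrows():
        n_spec = int(row["n_patients_specific"])
        if n_spec < patient_threshold:
            continue
        if transcript_id not in matrix.values.index:
            continue
        max_fpkm = float(tumor_cols.loc[transcript_id].max())
        if not max_fpkm > min_max_fpkm:
            continue
        prevalence = float(
            (normal_cols.loc[transcript_id] > cutoffs.expr_cutoff).mean()
        )
        if not prevalence < max_normal_prevalence:
            continue
        herv = (herv_overlaps or {}).get(transcript_id, {})
        candidates.append(
            CandidateTranscript(
                transcript_id=transcript_id,
                biotype=biotypes.get(transcript_id, "novel"),
                n_patients_specific=n_spec,
                fraction_patients=n_spec / n_patients,
                max_tumor_fpkm=max_fpkm,
                normal_prevalence=prevalence,
                herv_overlap_bp=int(herv.get("bp", 0)),
                herv_overlap_fraction=float(herv.get("fraction", 0.0)),
                thymus_expressed=(thymus_flags or {}).get(transcript_id, False),
                translated_evidence=transcript_id in (translated_ids or set()),
            )
        )
    candidates.sort(key=lambda c: (-c.n_patients_specific, c.transcript_id))
    return candidates


def candidate_correlations(
    candidates: list[CandidateTranscript],
    matrix: ExpressionMatrix,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pairwise Pearson correlation of candidate expression across tumors.

    Returns the correlation matrix over tumor samples and the mean
    off-diagonal correlation per biotype class (pairs within a class).
    Zero-variance transcripts yield missing correlations and are excluded
    from class means with a warning.
    """
    ids = [c.transcript_id for c in candidates]
    expr = matrix.values.loc[ids, matrix.tumor_samples()]
    variances = expr.var(axis=1)
    flat = variances[variances == 0].index.tolist()
    if flat:
        warnings.warn(
            f"zero-variance candidates, correlations undefined: {flat}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = expr.T.corr(method="pearson")
    corr.loc[flat, :] = np.nan
    corr.loc[:, flat] = np.nan
    class_means: dict[str, float] = {}
    by_class: dict[str, list[str]] = {}
    for c in candidates:
        by_class.setdefault(c.biotype, []).append(c.transcript_id)
    for biotype, members in by_class.items():
        if len(members) < 2:
            continue
        sub = corr.loc[members, members].to_numpy()
        off_diag = sub[~np.eye(len(members), dtype=bool)]
        valid = off_diag[~np.isnan(off_diag)]
        class_means[biotype] = float(valid.mean()) if valid.size else float("nan")
    return corr, class_means
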