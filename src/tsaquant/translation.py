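"""Translation calling from P-site resolved ribosome footprint profiles.

Each candidate ORF is scored for the two hallmarks of active translation in
ribosome profiling data: 3-nt periodicity (the fraction of P-sites falling
in the ORF's reading frame) and homogeneity of the signal along the ORF
(normalized Shannon entropy of the per-codon count distribution).  The
transparent score s = f1 * h is thresholded at 0.5 together with a minimum
of five footprints, mirroring the cutoff semantics of periodicity-based
callers used on real data.  Class-level translation is summarized as a
translation index: the length-weighted fraction of candidate ncORF sequence
called translated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from tsaquant.errors import CoordinateError, ValidationError
from tsaquant.orfs import OrfRecord
from tsaquant.transcriptome import CohortCutoffs, ExpressionMatrix, filter_expressed

MIN_READS_DEFAULT = 5
SCORE_CUTOFF_DEFAULT = 0.5


@dataclass
class FootprintProfile:
    """Per-nucleotide P-site counts over a transcript."""

    transcript_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValidationError("footprint counts must be a 1-D array")
        if (self.counts < 0).any():
            raise ValidationError("footprint counts must be non-negative")


@dataclass(frozen=True)
class TranslationCall:
    orf_id: str
    n_reads: int
    inframe_fraction: float
    homogeneity: float
    score: float
    translated: bool


@dataclass(frozen=True)
class TranslationIndex:
    """Length-weighted fraction of candidate ncORF sequence called translated."""

    transcript_class: str
    value: float
    n_orfs_tested: int
    n_orfs_translated: int
    count_fraction: float


def score_orf(
    orf: OrfRecord,
    profile: FootprintProfile,
    min_reads: int = MIN_READS_DEFAULT,
    score_cutoff: float = SCORE_CUTOFF_DEFAULT,
) -> TranslationCall:
    """Score one ORF's footprint signal and call translation.

    f1 is the fraction of ORF P-site counts at positions congruent to the
    ORF start mod 3; h is the Shannon entropy of per-codon totals divided
    by log(n_codons) (1 for an even spread, -> 0 for a single-codon
    pileup).  The call requires n_reads >= min_reads and f1 * h >=
    score_cutoff.  A zero-read ORF scores 0 everywhere.
    """
    if orf.start < 0 or orf.end > len(profile.counts):
        raise CoordinateError(
            f"{orf.orf_id}: ORF [{orf.start}, {orf.end}) outside profile of "
            f"length {len(profile.counts)}"
        )
    window = profile.counts[orf.start:orf.end]
    n_reads = int(window.sum())
    if n_reads == 0:
        return TranslationCall(orf.orf_id, 0, 0.0, 0.0, 0.0, False)
    f1 = float(window[::3].sum()) / n_reads
    codon_totals = window.reshape(-1, 3).sum(axis=1)
    n_codons = len(codon_totals)
    if n_codons <= 1:
        h = 1.0
    else:
        p = codon_totals[codon_totals > 0] / n_reads
        h = float(-(p * np.log(p)).sum() / math.log(n_codons))
    score = f1 * h
    translated = n_reads >= min_reads and score >= score_cutoff
    return TranslationCall(orf.orf_id, n_reads, f1, h, score, translated)


def call_translated(
    catalog: list[OrfRecord],
    profiles: dict[str, FootprintProfile],
    min_reads: int = MIN_READS_DEFAULT,
    score_cutoff: float = SCORE_CUTOFF_DEFAULT,
) -> list[TranslationCall]:
    """Score every ORF in the catalog against its transcript's profile.

    ORFs whose transcript has no profile are skipped with a warning.
    """
    calls: list[TranslationCall] = []
    missing: set[str] = set()
    for orf in catalog:
        profile = profiles.get(orf.transcript_id)
        if profile is None:
            missing.add(orf.transcript_id)
            continue
        calls.append(score_orf(orf, profile, min_reads, score_cutoff))
    if missing:
        warnings.warn(
            f"no footprint profile for {len(missing)} transcript(s); "
            f"their ORFs were skipped: {sorted(missing)[:5]}...",
            stacklevel=2,
        )
    return calls


def deduplicate_translated(
    calls: list[TranslationCall], catalog: list[OrfRecord]
) -> list[OrfRecord]:
    """Reduce translated ORFs to a nonredundant set.

    Among translated ORFs of the same transcript overlapping in the same
    frame, only the longest is kept (ties broken by the most 5' start, then
    by orf id).  Different-frame overlaps are untouched.
    """
    by_id = {orf.orf_id: orf for orf in catalog}
    translated = [by_id[c.orf_id] for c in calls if c.translated]
    translated.sort(key=lambda o: (-o.length_nt, o.start, o.orf_id))
    kept: list[OrfRecord] = []
    for orf in translated:
        if any(
            k.frame == orf.frame and k.overlaps(orf)
            for k in kept
            if k.transcript_id == orf.transcript_id
        ):
            continue
        kept.append(orf)
    kept.sort(key=lambda o: (o.transcript_id, o.start, o.orf_id))
    return kept


def widely_expressed_filter(
    matrix: ExpressionMatrix,
    cutoffs: CohortCutoffs,
    fraction: float = 0.9,
) -> set[str]:
    """Transcripts expressed in at least ``fraction`` of tumor samples.

    The patient-count threshold is ceil(fraction * n_patients); used to
    restrict translation-index estimation to transcripts the profiling
    cohort can actually see.
    """
    tumor_samples = matrix.tumor_samples()
    if not tumor_samples:
        raise ValidationError("matrix has no tumor samples")
    threshold = math.ceil(fraction * len(tumor_samples))
    counts: dict[str, int] = {t: 0 for t in matrix.values.index}
    for sample in tumor_samples:
        for t in filter_expressed(matrix, cutoffs, sample):
            counts[t] += 1
    return {t for t, n in counts.items() if n >= threshold}


def compute_translation_index(
    catalog_class_subset: list[OrfRecord],
    translated_set: set[str],
    transcript_class: str,
) -> TranslationIndex:
    """Length-weighted translated fraction over a class's tested ORFs.

    value = sum of length_nt over translated ORFs / sum over all tested
    ORFs.  The unweighted count fraction is reported alongside.  An empty
    tested set yields 0 with a warning.
    """
    total_nt = sum(o.length_nt for o in catalog_class_subset)
    if total_nt == 0:
        warnings.warn(
            f"translation index for {transcript_class}: no tested ORFs; "
            "reporting 0",
            stacklevel=2,
        )
        return TranslationIndex(transcript_class, 0.0, 0, 0, 0.0)
    translated = [o for o in catalog_class_subset if o.orf_id in translated_set]
    translated_nt = sum(o.length_nt for o in translated)
    return TranslationIndex(
        transcript_class=transcript_class,
        value=translated_nt / total_nt,
        n_orfs_tested=len(catalog_class_subset),
        n_orfs_translated=len(translated),
        count_fraction=len(translated) / len(catalog_class_subset),
    )
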