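"""Per-patient tumor-specificity classification and sharing accounting.

A transcript is tumor-specific in a patient when it clears the matched
tumor/normal cutoffs (> tumor_hi FPKM in the tumor, < normal_lo in the
matched normal) AND is silent across a healthy-tissue panel
(median <= 0.5 in every nonreproductive tissue).  Testis/ovary expression
is recorded but never gates the call — germinal cells do not present HLA —
and the same holds for the thymus flag, which only annotates candidates
for central-tolerance review.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from tsaquant.errors import ValidationError
from tsaquant.transcriptome import CohortCutoffs, ExpressionMatrix

REPRODUCTIVE_TISSUES = frozenset({"testis", "ovary"})


@dataclass(frozen=True)
class PatientCall:
    """Outcome of the tumor-specificity cascade for one patient x transcript."""

    patient_id: str
    transcript_id: str
    tumor_fpkm: float
    normal_fpkm: float
    pass_matched: bool
    pass_panel: bool
    testis_expressed: bool
    thymus_expressed: bool

    @property
    def tumor_specific(self) -> bool:
        # testis/thymus flags are annotations only and never gate the call
        return self.pass_matched and self.pass_panel


@dataclass
class NormalPanel:
    """Median expression per transcript across a healthy-tissue panel.

    ``medians`` is transcript x tissue.  Tissues in ``reproductive`` are
    exempt from gating; units must match whatever threshold the caller
    supplies (the filter itself is unit-agnostic).  Transcripts absent from
    the panel are treated as unexpressed there, with a warning — novel
    transcripts are absent from annotation-based panels by construction.
    """

    medians: pd.DataFrame
    reproductive: frozenset[str] = field(default=REPRODUCTIVE_TISSUES)

    def __post_init__(self) -> None:
        if (self.medians.to_numpy() < 0).any():
            raise ValidationError("panel medians must be non-negative")

    @property
    def nonreproductive_tissues(self) -> list[str]:
        return [c for c in self.medians.columns if c not in self.reproductive]


def call_matched(
    tumor_fpkm: float, normal_fpkm: float, cutoffs: CohortCutoffs
) -> bool:
    """Matched-pair filter: strictly above tumor_hi in tumor, strictly below
    normal_lo in the matched normal."""
    return tumor_fpkm > cutoffs.tumor_hi and normal_fpkm < cutoffs.normal_lo


def call_panel(
    transcript_id: str,
    panel: NormalPanel,
    max_median: float = 0.5,
) -> tuple[bool, bool]:
    """Healthy-panel filter.

    Returns ``(passes, testis_expressed)``: passes iff every
    nonreproductive tissue median is <= max_median; reproductive tissues are
    recorded (testis flag) but never gate.
    """
    if transcript_id not in panel.medians.index:
        warnings.warn(
            f"{transcript_id} absent from normal panel; treated as unexpressed",
            stacklevel=2,
        )
        return True, False
    row = panel.medians.loc[transcript_id]
    passes = bool(
        all(row[t] <= max_median for t in panel.nonreproductive_tissues)
    )
    testis = bool("testis" in panel.medians.columns and row["testis"] > max_median)
    return passes, testis


def thymus_flag(median: float, cutoff: float = 0.5) -> bool:
    """True when the thymic median expression is strictly above the cutoff.

    Annotation only: thymic expression marks potential central tolerance
    but never removes a call.
    """
    if median < 0:
        raise ValidationError("thymus median must be >= 0")
    return median > cutoff


def classify_cohort(
    matrix: ExpressionMatrix,
    panel: NormalPanel,
    cutoffs: CohortCutoffs,
    thymus_medians: pd.Series | None = None,
) -> list[PatientCall]:
    """Run the full specificity cascade for every patient x transcript.

    Only transcripts passing the matched filter are panel-checked (the
    panel outcome of the rest is irrelevant to the call and recorded as
    False/False).  Returns one ``PatientCall`` per (patient, transcript)
    with nonzero tumor expression interest, i.e. all pairs.
    """
    calls: list[PatientCall] = []
    panel_cache: dict[str, tuple[bool, bool]] = {}
    for patient in matrix.patients:
        t_col = matrix.values[matrix.sample_of(patient, "tumor")]
        n_col = matrix.values[matrix.sample_of(patient, "normal")]
        for transcript_id in matrix.values.index:
            tumor_fpkm = float(t_col[transcript_id])
            normal_fpkm = float(n_col[transcript_id])
            pass_matched = call_matched(tumor_fpkm, normal_fpkm, cutoffs)
            if pass_matched:
                if transcript_id not in panel_cache:
                    panel_cache[transcript_id] = call_panel(
                        transcript_id, panel, cutoffs.panel_max_median
                    )
                pass_panel, testis = panel_cache[transcript_id]
            else:
                pass_panel, testis = False, False
            thymus = bool(
                thymus_medians is not None
                and transcript_id in thymus_medians.index
                and thymus_flag(float(thymus_medians[transcript_id]))
            )
            calls.append(
                PatientCall(
                    patient_id=patient,
                    transcript_id=transcript_id,
                    tumor_fpkm=tumor_fpkm,
                    normal_fpkm=normal_fpkm,
                    pass_matched=pass_matched,
                    pass_panel=pass_panel,
                    testis_expressed=testis,
                    thymus_expressed=thymus,
                )
            )
    return calls


def normal_specific_set(
    patient_id: str, matrix: ExpressionMatrix, cutoffs: CohortCutoffs
) -> set[str]:
    """Transcripts specific to the patient's normal tissue: the exact mirror
    of the matched tumor filter under a tumor<->normal swap."""
    t_col = matrix.values[matrix.sample_of(patient_id, "tumor")]
    n_col = matrix.values[matrix.sample_of(patient_id, "normal")]
    return {
        t
        for t in matrix.values.index
        if call_matched(float(n_col[t]), float(t_col[t]), cutoffs)
    }


def specificity_ratio_test(
    tumor_counts: pd.DataFrame,
    normal_counts: pd.DataFrame,
) -> dict:
    """Paired test of noncoding enrichment among tumor-specific transcripts.

    Inputs are patient x class count tables (classes include "coding" and
    at least one of "lncRNA"/"novel") of tumor-specific and normal-specific
    transcripts.  Per patient the noncoding:coding ratio is computed in
    each compartment and the paired Wilcoxon signed-rank test is applied
    across patients.  Patients with a zero coding count in either
    compartment have an undefined ratio and are dropped with a warning.
    """
    if len(tumor_counts) < 2:
        raise ValidationError("paired ratio test needs at least 2 patients")

    def ratios(df: pd.DataFrame) -> pd.Series:
        noncoding_cols = [c for c in df.columns if c != "coding"]
        noncoding = df[noncoding_cols].sum(axis=1)
        coding = df["coding"]
        return noncoding.where(coding > 0) / coding.where(coding > 0)

    r_tumor = ratios(tumor_counts)
    r_normal = ratios(normal_counts.reindex(tumor_counts.index))
    valid = r_tumor.notna() & r_normal.notna()
    if (~valid).any():
        warnings.warn(
            f"{int((~valid).sum())} patient(s) dropped from the ratio test "
            "(zero coding count)",
            stacklevel=2,
        )
    r_tumor, r_normal = r_tumor[valid], r_normal[valid]
    if len(r_tumor) < 2:
        raise ValidationError("fewer than 2 patients with defined ratios")
    diffs = r_tumor - r_normal
    if np.allclose(diffs, 0):
        return {"statistic": float("nan"), "p_value": 1.0, "n_patients": len(diffs)}
    stat, p = stats.wilcoxon(r_tumor, r_normal)
    return {"statistic": float(stat), "p_value": float(p), "n_patients": len(diffs)}


def sharing_table(calls: list[PatientCall]) -> pd.DataFrame:
    """Per-transcript sharing of tumor-specific calls across patients.

    Returns a frame indexed by transcript id with ``n_patients_specific``
    and ``fraction_patients`` (over the union of patients in ``calls``).
    The column sum of counts equals the total number of tumor-specific
    calls (conservation).
    """
    patients = sorted({c.patient_id for c in calls})
    n_patients = len(patients)
    counts: dict[str, int] = {}
    for c in calls:
        if c.tumor_specific:
            counts[c.transcript_id] = counts.get(c.transcript_id, 0) + 1
    if not counts:
        return pd.DataFrame(
            columns=["n_patients_specific", "fraction_patients"]
        ).rename_axis("transcript_id")
    df = pd.DataFrame(
        {"n_patients_specific": pd.Series(counts, dtype=int)}
    ).rename_axis("transcript_id")
    df["fraction_patients"] = df["n_patients_specific"] / n_patients
    return df.sort_index()
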