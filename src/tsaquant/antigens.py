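"""HLA-I strong-binder enumeration and antigen-load modelling.

Candidate antigens are all 9-mer peptides from tumor-specific sources
(canonical CDS products, ncORF microproteins, missense-mutation windows).
A peptide is a strong binder for a patient when its predicted IC50 is
strictly below 50 nM for at least one of the patient's HLA-I alleles.
Strong binders matching any non-tumor-specific protein or ORF product are
discarded (self filter), and ncORF-derived counts are deflated by the
class translation index to obtain the expected antigen load.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

from tsaquant.errors import ValidationError

STRONG_BINDER_IC50_NM = 50.0
SOURCE_CLASSES = ("coding", "lncRNA", "novel", "mutation")
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: predictor signature: (peptide, allele) -> IC50 in nM
Predictor = Callable[[str, str], float]


@dataclass(frozen=True)
class BindingCall:
    peptide: str
    source_class: str
    source_id: str
    patient_id: str
    allele: str
    ic50_nm: float

    @property
    def strong(self) -> bool:
        return self.ic50_nm < STRONG_BINDER_IC50_NM


@dataclass(frozen=True)
class VariantRecord:
    """A somatic single-nucleotide variant at protein resolution."""

    patient_id: str
    gene_id: str
    protein_pos: int  # 1-based residue index
    ref_aa: str
    alt_aa: str
    depth: int
    alt_reads: int
    consequence: str = "missense"

    @property
    def passes_filter(self) -> bool:
        return self.depth > 10 and self.alt_reads >= 3 and self.consequence == "missense"


@dataclass
class AntigenLoad:
    """Per-patient strong-binder counts by source class.

    ``n_corrected`` multiplies the self-filtered ncORF counts by the class
    translation index; coding and mutation counts pass through unchanged.
    """

    patient_id: str
    n_strong_raw: dict[str, int]
    n_strong_selffiltered: dict[str, int]
    n_corrected: dict[str, float]
    translation_index_used: dict[str, float]


def enumerate_9mers(peptide: str, window: int = 9) -> list[str]:
    """All contiguous 9-mer windows of a peptide, order preserved.

    Windows containing X (ambiguous translation) are dropped; peptides
    shorter than the window yield an empty list.
    """
    return [
        peptide[i:i + window]
        for i in range(len(peptide) - window + 1)
        if "X" not in peptide[i:i + window]
    ]


def mutation_windows(
    protein: str, variant: VariantRecord, window: int = 9
) -> list[str]:
    """All mutant 9-mers containing the altered residue.

    The reference residue at ``protein_pos`` must match the record; windows
    identical to the reference sequence (impossible for a true missense)
    are excluded.  An internal position of a long protein yields exactly 9
    windows; termini yield fewer.
    """
    pos0 = variant.protein_pos - 1
    if not (0 <= pos0 < len(protein)):
        raise ValidationError(
            f"{variant.gene_id}: protein position {variant.protein_pos} outside "
            f"protein of length {len(protein)}"
        )
    if protein[pos0] != variant.ref_aa:
        raise ValidationError(
            f"{variant.gene_id}: reference residue mismatch at position "
            f"{variant.protein_pos} ({protein[pos0]} != {variant.ref_aa})"
        )
    mutant = protein[:pos0] + variant.alt_aa + protein[pos0 + 1:]
    out: list[str] = []
    for i in range(max(0, pos0 - window + 1), min(pos0, len(protein) - window) + 1):
        win = mutant[i:i + window]
        if "X" in win or win == protein[i:i + window]:
            continue
        out.append(win)
    return out


def predict_binders(
    peptides: Iterable[tuple[str, str, str]],
    patient_alleles: Mapping[str, list[str]],
    predictor: Predictor,
) -> list[BindingCall]:
    """Predict IC50 for every (peptide, patient, allele) combination.

    ``peptides`` yields (peptide, source_class, source_id) triples; one
    ``BindingCall`` is emitted per patient allele (duplicate allele entries
    are collapsed, so calls are invariant to allele order and multiplicity).
    """
    peptide_list = list(peptides)
    calls: list[BindingCall] = []
    for patient_id in sorted(patient_alleles):
        alleles = sorted(set(patient_alleles[patient_id]))
        for peptide, source_class, source_id in peptide_list:
            if source_class not in SOURCE_CLASSES:
                raise ValidationError(f"unknown source class {source_class!r}")
            for allele in alleles:
                try:
                    ic50 = predictor(peptide, allele)
                except KeyError:
                    raise LookupError(
                        f"no affinity available for ({peptide}, {allele})"
                    )
                calls.append(
                    BindingCall(peptide, source_class, source_id, patient_id,
                                allele, float(ic50))
                )
    return calls


def strong_binder_sets(
    calls: list[BindingCall],
) -> dict[str, dict[str, set[str]]]:
    """Patient-level strong-binder peptide sets, keyed patient -> class.

    A peptide is a patient-level strong binder when it is strong for at
    least one of that patient's alleles.
    """
    out: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for c in calls:
        if c.strong:
            out[c.patient_id][c.source_class].add(c.peptide)
    return {p: dict(d) for p, d in out.items()}


def self_filter(
    strong_sets: dict[str, set[str]], self_9mer_set: set[str]
) -> tuple[dict[str, set[str]], dict[str, float]]:
    """Discard strong binders whose exact sequence occurs in the self set.

    The self set is built from all canonical proteome 9-mers plus 9-mers of
    ORFs on transcripts that are not tumor-specific anywhere in the cohort.
    Returns the filtered per-class sets and the removed fraction per class.
    """
    filtered: dict[str, set[str]] = {}
    removed_fraction: dict[str, float] = {}
    for source_class, peptides in strong_sets.items():
        kept = {p for p in peptides if p not in self_9mer_set}
        filtered[source_class] = kept
        removed_fraction[source_class] = (
            1.0 - len(kept) / len(peptides) if peptides else 0.0
        )
    return filtered, removed_fraction


def antigen_load(
    patient_id: str,
    raw_sets: dict[str, set[str]],
    filtered_sets: dict[str, set[str]],
    translation_indices: Mapping[str, float],
) -> AntigenLoad:
    """Translation-index-corrected antigen load for one patient.

    Counts are unique peptides per class after the self filter; lncRNA and
    novel counts are multiplied by the class translation index, coding and
    mutation counts are untouched.
    """
    n_raw = {c: len(raw_sets.get(c, set())) for c in SOURCE_CLASSES}
    n_filt = {c: len(filtered_sets.get(c, set())) for c in SOURCE_CLASSES}
    indices_used: dict[str, float] = {}
    corrected: dict[str, float] = {}
    for c in SOURCE_CLASSES:
        if c in ("lncRNA", "novel"):
            idx = float(translation_indices.get(c, 1.0))
            if not 0.0 <= idx <= 1.0:
                raise ValidationError(f"translation index for {c} outside [0, 1]")
        else:
            idx = 1.0
        indices_used[c] = idx
        corrected[c] = n_filt[c] * idx
    return AntigenLoad(patient_id, n_raw, n_filt, corrected, indices_used)


def class_contributions(loads: list[AntigenLoad]) -> dict[str, float]:
    """Each class's share of the cohort's summed corrected antigen load."""
    totals = {c: sum(l.n_corrected[c] for l in loads) for c in SOURCE_CLASSES}
    grand = sum(totals.values())
    if grand == 0:
        return {c: 0.0 for c in SOURCE_CLASSES}
    return {c: totals[c] / grand for c in SOURCE_CLASSES}


def shared_private_summary(
    cohort_sets: dict[str, dict[str, set[str]]],
) -> dict[str, dict[str, float]]:
    """Per-class shared vs private fractions of unique strong binders.

    A peptide is shared when it is a patient-level strong binder (exact
    9-mer identity) in >= 2 distinct patients of the cohort; fractions are
    over unique peptides per class and satisfy shared + private = 1.
    """
    summary: dict[str, dict[str, float]] = {}
    for source_class in SOURCE_CLASSES:
        carrier_counts: dict[str, int] = defaultdict(int)
        for per_class in cohort_sets.values():
            for peptide in per_class.get(source_class, set()):
                carrier_counts[peptide] += 1
        n_unique = len(carrier_counts)
        if n_unique == 0:
            summary[source_class] = {
                "n_unique": 0, "shared": 0.0, "private": 0.0
            }
            continue
        n_shared = sum(1 for n in carrier_counts.values() if n >= 2)
        summary[source_class] = {
            "n_unique": n_unique,
            "shared": n_shared / n_unique,
            "private": (n_unique - n_shared) / n_unique,
        }
    return summary


def filter_variants(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep high-confidence missense variants: depth > 10 and >= 3 alt reads."""
    return [r for r in records if r.passes_filter]
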