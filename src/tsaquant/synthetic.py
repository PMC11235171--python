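"""Synthetic cohort generator with full ground-truth labels.

Emulates the data structure of a paired tumor/matched-normal cohort:
class-dependent expression levels (coding > lncRNA > novel), patient-
specific tumor-activation events with a truncated-geometric prevalence so
most events are private but some are widely shared, 3-nt periodic P-site
footprint profiles for translated ORFs (in-frame fraction 0.58 by default)
against sparse uniform noise for untranslated ones, per-patient HLA-I
allele draws, essentially private somatic missense mutations, and
transposable-element intervals with boosted HERV odds on tumor-specific
lncRNAs.  Every emitted record maps to exactly one ground-truth entry and
regeneration from the same seed is byte-identical.

The distributional choices (log-normal expression, geometric prevalence)
are stand-ins with no claim of realism beyond the orderings and rates the
pipeline is designed to detect; all are exposed in :class:`CohortConfig`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from tsaquant import io as tio
from tsaquant.antigens import AA_ALPHABET, VariantRecord, mutation_windows
from tsaquant.cohort import TEAnnotation
from tsaquant.errors import ConfigurationError, CoordinateError, ValidationError
from tsaquant.orfs import (
    STOP_CODONS,
    OrfRecord,
    canonical_cds_orf,
    enumerate_ncorfs,
)
from tsaquant.transcriptome import ExpressionMatrix, TranscriptRecord
from tsaquant.translation import FootprintProfile

HLA_ALLELE_POOL = [
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01", "HLA-A*24:02",
    "HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01", "HLA-B*44:02",
    "HLA-C*03:01", "HLA-C*07:01", "HLA-C*07:02", "HLA-C*12:03",
]

PANEL_TISSUES = ["brain", "heart", "kidney", "liver", "lung", "testis", "ovary"]

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Probabilities live in [0, 1]; counts are >= 1; ``seed`` fixes every
    downstream draw.  ``tumor_specific_rate`` may be a single float or a
    per-class mapping.  ``inframe_read_fraction`` defaults to 0.58, the
    observed average periodicity of 28-nt footprints;
    ``translated_fraction_lncrna`` defaults to 0.116 and
    ``translated_fraction_novel`` to 0.0053, the length-weighted translated
    fractions the pipeline is meant to recover.
    """

    n_patients: int = 12
    n_coding: int = 60
    n_lncrna: int = 60
    n_novel: int = 30
    tumor_specific_rate: float | dict = field(
        default_factory=lambda: {"coding": 0.08, "lncRNA": 0.20, "novel": 0.20}
    )
    prevalence_geom_p: float = 0.35
    translated_fraction_lncrna: float = 0.116
    translated_fraction_novel: float = 0.0053
    inframe_read_fraction: float = 0.58
    mean_depth: float = 300.0
    noise_fraction: float = 0.1
    herv_enrichment_odds: float = 4.0
    herv_background_prob: float = 0.15
    n_alleles_per_patient: int = 6
    mutation_rate: float = 8.0
    mutation_recurrence_rate: float = 0.0
    testis_escape_rate: float = 0.25
    panel_leak_rate: float = 0.1
    strong_binder_rate: float = 0.09
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_coding", "n_lncrna", "n_novel",
                     "n_alleles_per_patient"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("prevalence_geom_p", "translated_fraction_lncrna",
                     "translated_fraction_novel", "inframe_read_fraction",
                     "noise_fraction", "herv_background_prob",
                     "mutation_recurrence_rate", "testis_escape_rate",
                     "panel_leak_rate", "strong_binder_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("mean_depth", "mutation_rate", "herv_enrichment_odds"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_alleles_per_patient > len(HLA_ALLELE_POOL):
            raise ConfigurationError(
                "n_alleles_per_patient exceeds the allele pool size"
            )
        rates = self.rates_by_class()
        for cls, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(
                    f"tumor_specific_rate[{cls}] must be in [0, 1], got {r}"
                )

    def rates_by_class(self) -> dict[str, float]:
        if isinstance(self.tumor_specific_rate, dict):
            out = {"coding": 0.0, "lncRNA": 0.0, "novel": 0.0}
            out.update(self.tumor_specific_rate)
            return out
        r = float(self.tumor_specific_rate)
        return {"coding": r, "lncRNA": r, "novel": r}


@dataclass
class GroundTruth:
    """Labels for every record the generator emits."""

    #: transcript_id -> {"biotype", "herv_overlap"}
    transcripts: dict[str, dict]
    #: transcript_id -> {"carriers": [...], "testis_escape", "panel_pass"}
    tumor_specific: dict[str, dict]
    #: orf_id -> translated flag (all candidate ncORFs on noncoding transcripts)
    translated_orfs: dict[str, bool]
    #: orf_id -> transcript-coordinate span / length for index accounting
    orf_lengths: dict[str, int]
    #: passing somatic missense mutations, patient -> list of dicts
    mutations: dict[str, list[dict]]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)

    def expected_tumor_specific_calls(self) -> set[tuple[str, str]]:
        """The (patient, transcript) pairs the specificity cascade should
        recover: activation events whose transcript passes the panel."""
        out = set()
        for tid, ev in self.tumor_specific.items():
            if ev["panel_pass"]:
                for patient in ev["carriers"]:
                    out.add((patient, tid))
        return out


# ---------------------------------------------------------------------------
# surrogate HLA binding predictor

@lru_cache(maxsize=256)
def _allele_pwm(allele: str) -> tuple[np.ndarray, float, float]:
    rng = np.random.default_rng(zlib.crc32(allele.encode()) & 0x7FFFFFFF)
    w = rng.normal(0.0, 1.0, size=(9, 20))
    mu = float(w.mean(axis=1).sum())
    sigma = float(np.sqrt(w.var(axis=1).sum()))
    return w, mu, sigma


_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def surrogate_affinity(
    peptide: str, allele: str, strong_rate: float = 0.09
) -> float:
    """Deterministic stand-in HLA-I affinity predictor.

    An allele-seeded 9x20 position-weight matrix scores the peptide; the
    standardized score is mapped monotonically through its normal quantile
    to (0, 50000] nM, calibrated so that a ``strong_rate`` fraction of
    uniform-random 9-mers falls below the 50 nM strong-binder threshold.
    """
    return float(surrogate_affinity_batch([peptide], allele, strong_rate)[0])


def surrogate_affinity_batch(
    peptides: list[str], allele: str, strong_rate: float = 0.09
) -> np.ndarray:
    """Vectorized :func:`surrogate_affinity` over many peptides."""
    if not 0.0 < strong_rate < 1.0:
        raise ConfigurationError("strong_rate must be in (0, 1)")
    w, mu, sigma = _allele_pwm(allele)
    idx = np.empty((len(peptides), 9), dtype=np.int64)
    for row, peptide in enumerate(peptides):
        if len(peptide) != 9:
            raise ValidationError(
                f"peptide {peptide!r} has length {len(peptide)}, expected 9"
            )
        try:
            idx[row] = [_AA_INDEX[aa] for aa in peptide]
        except KeyError:
            bad = sorted(set(peptide) - set(AA_ALPHABET))
            raise ValidationError(f"illegal residues {bad} in {peptide!r}")
    scores = w[np.arange(9), idx].sum(axis=1)
    u = norm.sf((scores - mu) / sigma)
    alpha = np.log(50.0 / 50000.0) / np.log(strong_rate)
    return np.maximum(50000.0 * u ** alpha, 1e-3)


def make_surrogate_predictor(strong_rate: float = 0.09):
    """A (peptide, allele) -> IC50 callable bound to one calibration."""

    def predictor(peptide: str, allele: str) -> float:
        return surrogate_affinity(peptide, allele, strong_rate)

    return predictor


# ---------------------------------------------------------------------------
# footprint simulation

def simulate_footprints(
    orf: OrfRecord,
    translated: bool,
    config: CohortConfig,
    rng: np.random.Generator,
    transcript_length: int | None = None,
) -> FootprintProfile:
    """Simulate a P-site profile contribution for one ORF.

    Translated ORFs receive Poisson(mean_depth) footprints, multinomial
    over positions with in-frame probability ``inframe_read_fraction`` and
    codon-level homogeneity; untranslated ORFs receive sparse uniform noise
    (Poisson(mean_depth * noise_fraction), expected in-frame fraction 1/3).
    The returned profile spans the whole transcript with counts only inside
    the ORF.
    """
    length = transcript_length if transcript_length is not None else orf.end
    if orf.start < 0 or orf.end > length:
        raise CoordinateError(
            f"{orf.orf_id}: ORF [{orf.start}, {orf.end}) outside transcript "
            f"of length {length}"
        )
    counts = np.zeros(length, dtype=np.int64)
    orf_len = orf.length_nt
    if translated:
        n = int(rng.poisson(config.mean_depth))
        f1 = config.inframe_read_fraction
        probs = np.empty(orf_len)
        probs[0::3] = f1
        probs[1::3] = (1.0 - f1) / 2.0
        probs[2::3] = (1.0 - f1) / 2.0
        probs /= probs.sum()
    else:
        n = int(rng.poisson(config.mean_depth * config.noise_fraction))
        probs = np.full(orf_len, 1.0 / orf_len)
    if n > 0:
        counts[orf.start:orf.end] = rng.multinomial(n, probs)
    return FootprintProfile(orf.transcript_id, counts)


def _select_translated(
    orfs: list[OrfRecord],
    target_fraction: float,
    rng: np.random.Generator,
) -> set[str]:
    """Length-weighted selection of translated ORFs toward a target fraction.

    ORFs are visited in random order and accepted while the cumulative
    translated length stays below target; ORFs overlapping an already
    selected one (any frame) are skipped so simulated signals do not mix.
    """
    total_nt = sum(o.length_nt for o in orfs)
    if total_nt == 0 or target_fraction <= 0:
        return set()
    target_nt = target_fraction * total_nt
    selected: list[OrfRecord] = []
    cum = 0

    def conflicts(orf: OrfRecord) -> bool:
        return any(
            o.transcript_id == orf.transcript_id and o.overlaps(orf)
            for o in selected
        )

    # pass 1: random order, keeps the selection unbiased w.r.t. position
    for i in rng.permutation(len(orfs)):
        orf = orfs[i]
        if cum + orf.length_nt / 2.0 > target_nt or conflicts(orf):
            continue
        selected.append(orf)
        cum += orf.length_nt
    # pass 2: greedy earliest-end completion toward high target fractions
    chosen = {o.orf_id for o in selected}
    for orf in sorted(orfs, key=lambda o: (o.transcript_id, o.end)):
        if cum + orf.length_nt / 2.0 > target_nt:
            continue
        if orf.orf_id in chosen or conflicts(orf):
            continue
        selected.append(orf)
        chosen.add(orf.orf_id)
        cum += orf.length_nt
    return {o.orf_id for o in selected}


def simulate_translation_benchmark(
    n_orfs: int,
    translated_fraction: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[list[OrfRecord], dict[str, FootprintProfile], dict[str, bool]]:
    """A labelled ORF set with simulated footprint profiles.

    Random lncRNA-like transcripts are generated until ``n_orfs`` candidate
    ORFs have been enumerated; a length-weighted ``translated_fraction`` of
    them is marked translated (overlapping ORFs are never co-selected) and
    per-transcript profiles are simulated.  Returns the catalog, the
    profiles and the per-ORF truth labels — the substrate for caller
    sensitivity/specificity and translation-index recovery checks.
    """
    catalog: list[OrfRecord] = []
    lengths: dict[str, int] = {}
    i = 0
    while len(catalog) < n_orfs:
        i += 1
        tid = f"BM{i:05d}"
        length = int(rng.integers(400, 1200))
        seq = _random_sequence(rng, length, probs=_NC_BASE_PROBS)
        orfs = enumerate_ncorfs(seq, transcript_id=tid)
        catalog.extend(orfs)
        lengths[tid] = length
    catalog = catalog[:n_orfs]
    kept_tids = {o.transcript_id for o in catalog}
    translated_ids = _select_translated(catalog, translated_fraction, rng)
    truth = {o.orf_id: o.orf_id in translated_ids for o in catalog}
    profiles: dict[str, FootprintProfile] = {}
    for tid in sorted(kept_tids):
        counts = np.zeros(lengths[tid], dtype=np.int64)
        for orf in (o for o in catalog if o.transcript_id == tid):
            contrib = simulate_footprints(
                orf, truth[orf.orf_id], config, rng,
                transcript_length=lengths[tid],
            )
            counts += contrib.counts
        profiles[tid] = FootprintProfile(tid, counts)
    return catalog, profiles, truth


# ---------------------------------------------------------------------------
# transcript and sequence generation

_BASES = np.array(list("ACGT"))
#: base composition of noncoding transcript sequence.  Deliberately G-poor:
#: every permitted start codon contains a G while the TAA stop does not, so
#: candidate ORFs are short and rarely overlap across frames — which keeps
#: the labelled translated length fraction controllable over its full range.
_NC_BASE_PROBS = np.array([0.37, 0.27, 0.03, 0.33])


def _random_sequence(
    rng: np.random.Generator, length: int, probs: np.ndarray | None = None
) -> str:
    if probs is None:
        return "".join(_BASES[rng.integers(0, 4, size=length)])
    return "".join(_BASES[rng.choice(4, size=length, p=probs)])


def _make_transcript(
    rng: np.random.Generator,
    transcript_id: str,
    biotype: str,
) -> TranscriptRecord:
    if biotype == "coding":
        n_exons = int(rng.integers(2, 6))
        spliced = int(rng.integers(600, 1500))
    else:
        n_exons = int(rng.integers(1, 4))
        spliced = int(rng.integers(400, 1200))
    cuts = np.sort(rng.choice(np.arange(1, spliced), size=n_exons - 1,
                              replace=False)) if n_exons > 1 else np.array([], int)
    exon_lengths = np.diff(np.concatenate([[0], cuts, [spliced]])).astype(int)
    chrom = f"chr{int(rng.integers(1, 5))}"
    pos = int(rng.integers(0, 5_000_000))
    exons: list[tuple[int, int]] = []
    for ex_len in exon_lengths:
        exons.append((pos, pos + int(ex_len)))
        pos += int(ex_len) + int(rng.integers(100, 5000))
    strand = "+" if rng.random() < 0.5 else "-"
    seq = _random_sequence(
        rng, spliced, probs=None if biotype == "coding" else _NC_BASE_PROBS
    )
    cds = None
    if biotype == "coding":
        n_codons = int(rng.integers(80, min(300, (spliced - 60) // 3)))
        cds_len = 3 * n_codons
        cds_start = int(rng.integers(0, spliced - cds_len + 1))
        body = "".join(
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
        )
        stop = STOP_CODONS[int(rng.integers(0, 3))]
        cds_seq = "ATG" + body + stop
        seq = seq[:cds_start] + cds_seq + seq[cds_start + cds_len:]
        cds = (cds_start, cds_start + cds_len)
    return TranscriptRecord(
        transcript_id=transcript_id, biotype=biotype, chrom=chrom,
        strand=strand, exons=exons, sequence=seq, cds=cds,
    )


# ---------------------------------------------------------------------------
# expression

_CLASS_LOG_MEDIAN = {"coding": 3.0, "lncRNA": 1.4, "novel": 0.8}
_CLASS_LOG_SD = 0.8


def simulate_expression(
    config: CohortConfig,
    ground_truth: GroundTruth,
    rng: np.random.Generator,
    cutoffs=None,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.Series]:
    """Draw per-sample FPKM tables plus panel and thymus medians.

    Non-tumor-specific transcripts are either expressed in both tissues of
    every patient (log-normal around a class-dependent median, floored
    well above the normal cutoff) or silent everywhere, so activation
    events are exactly recoverable through the matched filter.  Carriers
    of a tumor-specific transcript get a tumor value above the tumor
    cutoff and a matched-normal value below the normal cutoff; the panel
    medians stay below threshold except for testis-escape and panel-leak
    transcripts.
    """
    from tsaquant.transcriptome import CohortCutoffs

    cutoffs = cutoffs or CohortCutoffs()
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    tids = sorted(ground_truth.transcripts)
    tumor = pd.DataFrame(0.0, index=tids, columns=[f"{p}_T" for p in patients])
    normal = pd.DataFrame(0.0, index=tids, columns=[f"{p}_N" for p in patients])
    panel = pd.DataFrame(0.0, index=tids, columns=PANEL_TISSUES)
    thymus = pd.Series(0.0, index=tids)

    floor = 3.0 * cutoffs.normal_lo
    for tid in tids:
        info = ground_truth.transcripts[tid]
        ts = ground_truth.tumor_specific.get(tid)
        if ts is not None:
            carriers = set(ts["carriers"])
            for p in patients:
                if p in carriers:
                    tumor.loc[tid, f"{p}_T"] = cutoffs.tumor_hi * (
                        3.0 + float(rng.lognormal(1.0, 0.8))
                    )
                    normal.loc[tid, f"{p}_N"] = float(
                        rng.uniform(0.0, 0.5 * cutoffs.normal_lo)
                    )
                else:
                    tumor.loc[tid, f"{p}_T"] = float(
                        rng.uniform(0.0, 0.5 * cutoffs.normal_lo)
                    )
                    normal.loc[tid, f"{p}_N"] = float(
                        rng.uniform(0.0, 0.5 * cutoffs.normal_lo)
                    )
            base_panel = rng.uniform(0.0, 0.6 * cutoffs.panel_max_median,
                                     size=len(PANEL_TISSUES))
            panel.loc[tid] = base_panel
            if ts["testis_escape"]:
                panel.loc[tid, "testis"] = float(rng.uniform(1.0, 10.0))
            if not ts["panel_pass"]:
                leak_tissue = PANEL_TISSUES[int(rng.integers(0, 5))]
                panel.loc[tid, leak_tissue] = float(rng.uniform(1.0, 5.0))
        else:
            base = float(rng.lognormal(_CLASS_LOG_MEDIAN[info["biotype"]],
                                       _CLASS_LOG_SD))
            if base > cutoffs.expr_cutoff:
                vals_t = np.maximum(
                    base * rng.uniform(0.9, 1.1, size=config.n_patients), floor
                )
                vals_n = np.maximum(
                    base * rng.uniform(0.9, 1.1, size=config.n_patients), floor
                )
                tumor.loc[tid] = vals_t
                normal.loc[tid] = vals_n
                panel.loc[tid] = np.maximum(
                    base * rng.uniform(0.7, 1.3, size=len(PANEL_TISSUES)), floor
                )
            else:
                tumor.loc[tid] = rng.uniform(
                    0.0, 0.5 * cutoffs.normal_lo, size=config.n_patients
                )
                normal.loc[tid] = rng.uniform(
                    0.0, 0.5 * cutoffs.normal_lo, size=config.n_patients
                )
        if rng.random() < 0.05:
            thymus[tid] = float(rng.uniform(0.6, 3.0))

    values = pd.concat([tumor, normal], axis=1)
    meta = pd.DataFrame(
        {
            "patient_id": [c[:-2] for c in values.columns],
            "tissue": ["tumor" if c.endswith("_T") else "normal"
                       for c in values.columns],
            "cohort_id": "SYN1",
        },
        index=values.columns,
    )
    return ExpressionMatrix(values, meta), panel, thymus


# ---------------------------------------------------------------------------
# TE placement

def simulate_te_overlap(
    is_tumor_specific: np.ndarray,
    odds: float,
    background_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli HERV-overlap flags with boosted odds for tumor-specific
    transcripts: p_ts = odds*p / (1 - p + odds*p)."""
    p_bg = background_prob
    p_ts = odds * p_bg / (1.0 - p_bg + odds * p_bg)
    probs = np.where(is_tumor_specific, p_ts, p_bg)
    return rng.random(len(probs)) < probs


def _place_te_intervals(
    transcripts: list[TranscriptRecord],
    herv_flags: dict[str, bool],
    rng: np.random.Generator,
) -> TEAnnotation:
    intervals: list[tuple[str, int, int, str, str]] = []
    for t in transcripts:
        if t.biotype == "coding":
            continue
        exon = t.exons[int(rng.integers(0, len(t.exons)))]
        if herv_flags.get(t.transcript_id, False):
            # same-strand HERV inside one exon
            lo = int(rng.integers(exon[0], max(exon[0] + 1, exon[1] - 50)))
            hi = min(exon[1], lo + int(rng.integers(50, 300)))
            intervals.append((t.chrom, lo, hi, t.strand, "LTR/HERV"))
        elif rng.random() < 0.1:
            # opposite-strand HERV: must NOT count as overlap
            opp = "-" if t.strand == "+" else "+"
            lo = int(rng.integers(exon[0], max(exon[0] + 1, exon[1] - 50)))
            hi = min(exon[1], lo + int(rng.integers(50, 300)))
            intervals.append((t.chrom, lo, hi, opp, "LTR/HERV"))
        if rng.random() < 0.3:
            cls = ("LINE", "SINE", "retrotransposon", "RNA")[int(rng.integers(0, 4))]
            strand = t.strand if rng.random() < 0.5 else ("-" if t.strand == "+" else "+")
            lo = int(rng.integers(exon[0], max(exon[0] + 1, exon[1] - 20)))
            hi = min(exon[1], lo + int(rng.integers(30, 200)))
            intervals.append((t.chrom, lo, hi, strand, cls))
    return TEAnnotation(sorted(intervals))


# ---------------------------------------------------------------------------
# cohort bundle

@dataclass
class CohortBundle:
    """In-memory synthetic cohort plus the paths of the emitted files."""

    config: CohortConfig
    transcripts: list[TranscriptRecord]
    orf_catalog: list[OrfRecord]
    matrix: ExpressionMatrix
    panel_medians: pd.DataFrame
    thymus_medians: pd.Series
    profiles: dict[str, FootprintProfile]
    te: TEAnnotation
    hla: dict[str, list[str]]
    variants: list[VariantRecord]
    ground_truth: GroundTruth
    paths: dict[str, str] = field(default_factory=dict)


def generate_cohort(config: CohortConfig, outdir: str | Path | None = None) -> CohortBundle:
    """Generate a fully labelled synthetic cohort bundle.

    With ``outdir`` set, writes GTF, FASTA, per-sample expression TSVs,
    footprint TSV, panel/thymus TSVs, TE BED, HLA TSV, variant TSV,
    affinity TSV (tumor-specific source peptides x cohort alleles) and the
    ground-truth JSON.  The same seed reproduces the bundle byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]

    # --- transcripts ------------------------------------------------------
    transcripts: list[TranscriptRecord] = []
    for i in range(config.n_coding):
        transcripts.append(_make_transcript(rng, f"COD{i + 1:04d}", "coding"))
    for i in range(config.n_lncrna):
        transcripts.append(_make_transcript(rng, f"LNC{i + 1:04d}", "lncRNA"))
    for i in range(config.n_novel):
        transcripts.append(_make_transcript(rng, f"NOV{i + 1:04d}", "novel"))
    by_id = {t.transcript_id: t for t in transcripts}

    # --- tumor-specific activation events --------------------------------
    rates = config.rates_by_class()
    gt_transcripts: dict[str, dict] = {}
    tumor_specific: dict[str, dict] = {}
    for t in transcripts:
        gt_transcripts[t.transcript_id] = {
            "biotype": t.biotype, "herv_overlap": False
        }
        if rng.random() < rates[t.biotype]:
            k = min(
                config.n_patients,
                int(rng.geometric(config.prevalence_geom_p))
                if config.prevalence_geom_p > 0 else config.n_patients,
            )
            carriers = sorted(
                rng.choice(patients, size=k, replace=False).tolist()
            )
            tumor_specific[t.transcript_id] = {
                "carriers": carriers,
                "testis_escape": bool(rng.random() < config.testis_escape_rate),
                "panel_pass": bool(rng.random() >= config.panel_leak_rate),
            }

    # --- ncORF catalog and translated labels ------------------------------
    orf_catalog: list[OrfRecord] = []
    noncoding_orfs: dict[str, list[OrfRecord]] = {"lncRNA": [], "novel": []}
    for t in transcripts:
        if t.biotype == "coding":
            orf_catalog.append(canonical_cds_orf(t))
        else:
            orfs = enumerate_ncorfs(t.sequence, transcript_id=t.transcript_id)
            orf_catalog.extend(orfs)
            noncoding_orfs[t.biotype].extend(orfs)
    translated_ids = _select_translated(
        noncoding_orfs["lncRNA"], config.translated_fraction_lncrna, rng
    ) | _select_translated(
        noncoding_orfs["novel"], config.translated_fraction_novel, rng
    )
    translated_orfs = {
        o.orf_id: o.orf_id in translated_ids
        for cls in ("lncRNA", "novel") for o in noncoding_orfs[cls]
    }
    orf_lengths = {
        o.orf_id: o.length_nt
        for cls in ("lncRNA", "novel") for o in noncoding_orfs[cls]
    }

    # --- HERV flags -------------------------------------------------------
    lnc = [t for t in transcripts if t.biotype != "coding"]
    ts_flags = np.array([t.transcript_id in tumor_specific for t in lnc])
    herv = simulate_te_overlap(
        ts_flags, config.herv_enrichment_odds, config.herv_background_prob, rng
    )
    herv_flags = {t.transcript_id: bool(f) for t, f in zip(lnc, herv)}
    for tid, flag in herv_flags.items():
        gt_transcripts[tid]["herv_overlap"] = flag
    te = _place_te_intervals(transcripts, herv_flags, rng)

    # --- mutations --------------------------------------------------------
    coding_ids = sorted(t.transcript_id for t in transcripts if t.biotype == "coding")
    proteins = {
        tid: canonical_cds_orf(by_id[tid]).peptide for tid in coding_ids
    }
    recurrent_pool: list[tuple[str, int, str, str]] = []
    if config.mutation_recurrence_rate > 0:
        for _ in range(5):
            gene = coding_ids[int(rng.integers(0, len(coding_ids)))]
            pos = int(rng.integers(1, len(proteins[gene]) + 1))
            ref = proteins[gene][pos - 1]
            alt = _random_alt(rng, ref)
            recurrent_pool.append((gene, pos, ref, alt))
    used: set[tuple[str, int]] = set()
    variants: list[VariantRecord] = []
    gt_mutations: dict[str, list[dict]] = {p: [] for p in patients}
    for patient in patients:
        k = int(rng.poisson(config.mutation_rate))
        for _ in range(k):
            if recurrent_pool and rng.random() < config.mutation_recurrence_rate:
                gene, pos, ref, alt = recurrent_pool[
                    int(rng.integers(0, len(recurrent_pool)))
                ]
            else:
                for _attempt in range(50):
                    gene = coding_ids[int(rng.integers(0, len(coding_ids)))]
                    pos = int(rng.integers(1, len(proteins[gene]) + 1))
                    if (gene, pos) not in used:
                        break
                used.add((gene, pos))
                ref = proteins[gene][pos - 1]
                alt = _random_alt(rng, ref)
            fail_mode = rng.random()
            if fail_mode < 0.05:
                depth, alt_reads, cons = int(rng.integers(1, 11)), 3, "missense"
            elif fail_mode < 0.10:
                depth, alt_reads, cons = 11 + int(rng.poisson(40)), int(rng.integers(0, 3)), "missense"
            elif fail_mode < 0.15:
                depth, alt_reads, cons = 11 + int(rng.poisson(40)), 3 + int(rng.poisson(10)), "synonymous"
            else:
                depth, alt_reads, cons = 11 + int(rng.poisson(40)), 3 + int(rng.poisson(10)), "missense"
            rec = VariantRecord(patient, gene, pos, ref, alt, depth, alt_reads, cons)
            variants.append(rec)
            if rec.passes_filter:
                gt_mutations[patient].append(
                    {"gene_id": gene, "protein_pos": pos, "ref_aa": ref, "alt_aa": alt}
                )

    ground_truth = GroundTruth(
        transcripts=gt_transcripts,
        tumor_specific=tumor_specific,
        translated_orfs=translated_orfs,
        orf_lengths=orf_lengths,
        mutations=gt_mutations,
    )

    # --- expression, panel, thymus ---------------------------------------
    matrix, panel, thymus = simulate_expression(config, ground_truth, rng)

    # --- footprints (noncoding transcripts only) --------------------------
    profiles: dict[str, FootprintProfile] = {}
    for t in transcripts:
        if t.biotype == "coding":
            continue
        counts = np.zeros(t.spliced_length, dtype=np.int64)
        for orf in enumerate_ncorfs(t.sequence, transcript_id=t.transcript_id):
            contrib = simulate_footprints(
                orf, translated_orfs[orf.orf_id], config, rng,
                transcript_length=t.spliced_length,
            )
            counts += contrib.counts
        profiles[t.transcript_id] = FootprintProfile(t.transcript_id, counts)

    # --- HLA --------------------------------------------------------------
    hla = {
        p: sorted(
            rng.choice(HLA_ALLELE_POOL, size=config.n_alleles_per_patient,
                       replace=False).tolist()
        )
        for p in patients
    }

    bundle = CohortBundle(
        config=config, transcripts=transcripts, orf_catalog=orf_catalog,
        matrix=matrix, panel_medians=panel, thymus_medians=thymus,
        profiles=profiles, te=te, hla=hla, variants=variants,
        ground_truth=ground_truth,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _random_alt(rng: np.random.Generator, ref: str) -> str:
    choices = [aa for aa in AA_ALPHABET if aa != ref]
    return choices[int(rng.integers(0, len(choices)))]


def _write_bundle(bundle: CohortBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def register(key: str, name: str) -> Path:
        p = outdir / name
        paths[key] = str(p)
        return p

    tio.write_gtf(bundle.transcripts, register("gtf", "cohort.gtf"))
    tio.write_fasta(
        {t.transcript_id: t.sequence for t in bundle.transcripts},
        register("fasta", "transcripts.fa"),
    )
    expr_dir = outdir / "expression"
    expr_dir.mkdir(exist_ok=True)
    for sample in sorted(bundle.matrix.values.columns):
        p = expr_dir / f"{sample}.tsv"
        tio.write_expression_tsv(bundle.matrix.values[sample], p)
        paths[f"expr:{sample}"] = str(p)
    tio.write_footprints_tsv(bundle.profiles, register("footprints", "footprints.tsv"))
    tio.write_panel_tsv(bundle.panel_medians, register("panel", "panel.tsv"))
    tio.write_panel_tsv(
        bundle.thymus_medians.to_frame("thymus"), register("thymus", "thymus.tsv")
    )
    tio.write_te_bed(bundle.te, register("te", "te.bed"))
    tio.write_hla_tsv(bundle.hla, register("hla", "hla.tsv"))
    tio.write_variants_tsv(bundle.variants, register("variants", "variants.tsv"))

    # affinity table restricted to tumor-specific source peptides
    from tsaquant.antigens import enumerate_9mers

    alleles = sorted({a for al in bundle.hla.values() for a in al})
    peptides: set[str] = set()
    ts_ids = set(bundle.ground_truth.tumor_specific)
    for orf in bundle.orf_catalog:
        if orf.transcript_id in ts_ids:
            peptides.update(enumerate_9mers(orf.peptide))
    proteins = {
        t.transcript_id: canonical_cds_orf(t).peptide
        for t in bundle.transcripts if t.biotype == "coding"
    }
    for patient, muts in bundle.ground_truth.mutations.items():
        for m in muts:
            rec = VariantRecord(patient, m["gene_id"], m["protein_pos"],
                                m["ref_aa"], m["alt_aa"], 100, 10)
            peptides.update(mutation_windows(proteins[m["gene_id"]], rec))
    affinities: dict[tuple[str, str], float] = {}
    pep_list = sorted(peptides)
    for allele in alleles:
        ic50 = surrogate_affinity_batch(
            pep_list, allele, bundle.config.strong_binder_rate
        )
        for pep, v in zip(pep_list, ic50):
            affinities[(pep, allele)] = float(v)
    tio.write_affinity_tsv(affinities, register("affinity", "affinity.tsv"))

    gt_path = register("ground_truth", "ground_truth.json")
    tio.write_json(bundle.ground_truth.to_dict(), gt_path)
    bundle.paths = paths
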