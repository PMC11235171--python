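"""End-to-end orchestration: quantify -> orfs -> translate -> tumorspec ->
antigens -> cohort, with a single config, structured per-filter logging and
a checksummed output manifest.

Each stage reads the bundle files (or the previous stage's outputs), writes
its tables under the output directory and registers them in the manifest;
re-running with the same config and inputs reproduces identical checksums.
A stage failure aborts the run with the stage name attached.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from tsaquant import io as tio
from tsaquant.antigens import (
    SOURCE_CLASSES,
    antigen_load,
    class_contributions,
    enumerate_9mers,
    filter_variants,
    mutation_windows,
    predict_binders,
    self_filter,
    shared_private_summary,
    strong_binder_sets,
)
from tsaquant.cohort import (
    TE_CLASSES,
    candidate_correlations,
    herv_enrichment,
    select_candidates,
    te_overlap,
)
from tsaquant.errors import ConfigurationError, TsaquantError
from tsaquant.orfs import canonical_cds_orf, enumerate_ncorfs
from tsaquant.specificity import NormalPanel, classify_cohort, sharing_table
from tsaquant.synthetic import make_surrogate_predictor
from tsaquant.transcriptome import CohortCutoffs, ExpressionMatrix
from tsaquant.translation import (
    call_translated,
    compute_translation_index,
    deduplicate_translated,
    widely_expressed_filter,
)

logger = logging.getLogger("tsaquant")

STAGES = ("quantify", "orfs", "translate", "tumorspec", "antigens", "cohort")


class PipelineStageError(TsaquantError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs and knobs of one pipeline run.

    ``affinity`` is either the path of a peptide/allele/IC50 TSV or the
    string "surrogate" for the built-in predictor.  Round-trips to YAML.
    """

    gtf: str
    fasta: str
    expr_dir: str
    footprints: str
    panel: str
    thymus: str
    te_bed: str
    hla: str
    variants: str
    outdir: str
    affinity: str = "surrogate"
    cutoffs: CohortCutoffs = field(default_factory=CohortCutoffs)
    stages: tuple[str, ...] = STAGES
    min_reads: int = 5
    score_cutoff: float = 0.5
    widely_expressed_fraction: float = 0.9
    strong_binder_rate: float = 0.09
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cutoffs, dict):
            self.cutoffs = CohortCutoffs(**self.cutoffs)
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log_filter(stage: str, name: str, n_in: int, n_out: int) -> None:
    logger.info("stage=%s filter=%s in=%d out=%d", stage, name, n_in, n_out)


def run_all(config: RunConfig) -> dict:
    """Run the enabled stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    state: dict = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = path

    stage_fns = {
        "quantify": _stage_quantify,
        "orfs": _stage_orfs,
        "translate": _stage_translate,
        "tumorspec": _stage_tumorspec,
        "antigens": _stage_antigens,
        "cohort": _stage_cohort,
    }
    # stages form a linear dependency chain: run everything up to the last
    # enabled stage, but only register enabled stages' outputs
    last = max(STAGES.index(s) for s in config.stages)
    for stage in STAGES[: last + 1]:
        sink = emit if stage in config.stages else (lambda name, path: None)
        try:
            stage_fns[stage](config, state, outdir, sink)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "files": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in sorted(outputs.items())
        },
    }
    tio.write_json(manifest, outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_quantify(config: RunConfig, state: dict, outdir: Path, emit) -> None:
    transcripts = tio.read_gtf(config.gtf)
    tio.attach_sequences(transcripts, tio.read_fasta(config.fasta))
    expr_dir = Path(config.expr_dir)
    columns = {}
    meta_rows = {}
    for path in sorted(expr_dir.glob("*.tsv")):
        sample = path.stem
        columns[sample] = tio.read_expression_tsv(path)
        patient, tissue_code = sample.rsplit("_", 1)
        meta_rows[sample] = {
            "patient_id": patient,
            "tissue": "tumor" if tissue_code == "T" else "normal",
            "cohort_id": "run",
        }
    values = pd.DataFrame(columns).sort_index()
    matrix = ExpressionMatrix(values, pd.DataFrame.from_dict(meta_rows, orient="index"))
    state["transcripts"] = transcripts
    state["matrix"] = matrix
    out = outdir / "fpkm_matrix.tsv"
    values.to_csv(out, sep="\t", index_label="transcript_id", float_format="%.6g")
    emit("fpkm_matrix", out)
    _log_filter("quantify", "loaded", len(values), len(values))


def _stage_orfs(config: RunConfig, state: dict, outdir: Path, emit) -> None:
    transcripts = state["transcripts"]
    catalog = []
    for t in transcripts:
        if t.biotype == "coding":
            catalog.append(canonical_cds_orf(t))
        else:
            catalog.extend(enumerate_ncorfs(t.sequence, transcript_id=t.transcript_id))
    state["catalog"] = catalog
    rows = [
        {
            "orf_id": o.orf_id, "transcript_id": o.transcript_id,
            "start": o.start, "end": o.end, "frame": o.frame,
            "start_codon": o.start_codon, "is_canonical": o.is_canonical,
            "peptide": o.peptide,
        }
        for o in catalog
    ]
    out = outdir / "orf_catalog.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    emit("orf_catalog", out)
    pep_out = outdir / "orf_peptides.fa"
    tio.write_fasta({o.orf_id: o.peptide for o in catalog}, pep_out)
    emit("orf_peptides", pep_out)
    _log_filter("orfs", "enumerated", len(transcripts), len(catalog))


def _stage_translate(config: RunConfig, state: dict, outdir: Path, emit) -> None:
    transcripts = state["transcripts"]
    catalog = state["catalog"]
    matrix = state["matrix"]
    lengths = {
        t.transcript_id: t.spliced_length
        for t in transcripts if t.biotype != "coding"
    }
    profiles = tio.read_footprints_tsv(config.footprints, lengths)
    nc_catalog = [o for o in catalog if not o.is_canonical]
    calls = call_translated(nc_catalog, profiles, config.min_reads, config.score_cutoff)
    translated = deduplicate_translated(calls, nc_catalog)
    _log_filter("translate", "translated", len(calls),
                sum(c.translated for c in calls))

    widely = widely_expressed_filter(
        matrix, config.cutoffs, config.widely_expressed_fraction
    )
    biotypes = {t.transcript_id: t.biotype for t in transcripts}
    translated_ids = {o.orf_id for o in translated}
    indices = {}
    for cls in ("lncRNA", "novel"):
        tested = [
            o for o in nc_catalog
            if biotypes[o.transcript_id] == cls and o.transcript_id in widely
        ]
        indices[cls] = compute_translation_index(tested, translated_ids, cls)
    state["translation_calls"] = calls
    state["translated_orfs"] = translated
    state["translation_indices"] = {c: ti.value for c, ti in indices.items()}

    rows = [
        {
            "orf_id": c.orf_id, "n_reads": c.n_reads,
            "inframe_fraction": round(c.inframe_fraction, 6),
            "homogeneity": round(c.homogeneity, 6),
            "score": round(c.score, 6), "translated": c.translated,
        }
        for c in calls
    ]
    out = outdir / "translation_calls.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    emit("translation_calls", out)
    idx_out = outdir / "translation_index.json"
    tio.write_json(
        {
            cls: {
                "value": ti.value, "n_orfs_tested": ti.n_orfs_tested,
                "n_orfs_translated": ti.n_orfs_translated,
                "count_fraction": ti.count_fraction,
            }
            for cls, ti in indices.items()
        },
        idx_out,
    )
    emit("translation_index", idx_out)


def _stage_tumorspec(config: RunConfig, state: dict, outdir: Path, emit) -> None:
    matrix = state["matrix"]
    panel = NormalPanel(tio.read_panel_tsv(config.panel))
    thymus = tio.read_panel_tsv(config.thymus)["thymus"]
    calls = classify_cohort(matrix, panel, config.cutoffs, thymus)
    state["patient_calls"] = calls
    sharing = sharing_table(calls)
    state["sharing"] = sharing
    _log_filter("tumorspec", "tumor_specific", len(calls),
                sum(c.tumor_specific for c in calls))
    rows = [
        {
            "patient_id": c.patient_id, "transcript_id": c.transcript_id,
            "tumor_fpkm": round(c.tumor_fpkm, 6),
            "normal_fpkm": round(c.normal_fpkm, 6),
            "pass_matched": c.pass_matched, "pass_panel": c.pass_panel,
            "testis_expressed": c.testis_expressed,
            "thymus_expressed": c.thymus_expressed,
            "tumor_specific": c.tumor_specific,
        }
        for c in calls if c.pass_matched
    ]
    out = outdir / "patient_calls.tsv"
    pd.DataFrame(
        rows,
        columns=["patient_id", "transcript_id", "tumor_fpkm", "normal_fpkm",
                 "pass_matched", "pass_panel", "testis_expressed",
                 "thymus_expressed", "tumor_specific"],
    ).to_csv(out, sep="\t", index=False)
    emit("patient_calls", out)
    share_out = outdir / "sharing.tsv"
    sharing.to_csv(share_out, sep="\t", float_format="%.6g")
    emit("sharing", share_out)


def _stage_antigens(config: RunConfig, state: dict, outdir: Path, emit) -> None:
    transcripts = state["transcripts"]
    catalog = state["catalog"]
    matrix = state["matrix"]
    calls = state["patient_calls"]
    indices = state.get("translation_indices", {"lncRNA": 1.0, "novel": 1.0})
    biotypes = {t.transcript_id: t.biotype for t in transcripts}

    hla = tio.read_hla_tsv(config.hla)
    variants = filter_variants(tio.read_variants_tsv(config.variants))
    if config.affinity == "surrogate":
        predictor = make_surrogate_predictor(config.strong_binder_rate)
    else:
        table = tio.read_affinity_tsv(config.affinity)
        predictor = lambda pep, allele: table[(pep, allele)]  # noqa: E731

    ts_by_patient: dict[str, set[str]] = {}
    for c in calls:
        if c.tumor_specific:
            ts_by_patient.setdefault(c.patient_id, set()).add(c.transcript_id)
    cohort_ts = set().union(*ts_by_patient.values()) if ts_by_patient else set()

    orfs_by_transcript: dict[str, list] = {}
    for o in catalog:
        orfs_by_transcript.setdefault(o.transcript_id, []).append(o)
    proteins = {
        t.transcript_id: canonical_cds_orf(t).peptide
        for t in transcripts if t.biotype == "coding"
    }

    # self set: products of transcripts never tumor-specific in the cohort
    self_set: set[str] = set()
    for t in transcripts:
        if t.transcript_id in cohort_ts:
            continue
        for o in orfs_by_transcript.get(t.transcript_id, []):
            self_set.update(enumerate_9mers(o.peptide))
    _log_filter("antigens", "self_set", len(catalog), len(self_set))

    variants_by_patient: dict[str, list] = {}
    for v in variants:
        variants_by_patient.setdefault(v.patient_id, []).append(v)

    raw_by_patient: dict[str, dict[str, set[str]]] = {}
    loads = []
    for patient in matrix.patients:
        triples: list[tuple[str, str, str]] = []
        for tid in sorted(ts_by_patient.get(patient, set())):
            cls = biotypes[tid]
            for o in orfs_by_transcript.get(tid, []):
                for pep in enumerate_9mers(o.peptide):
                    triples.append((pep, cls, o.orf_id))
        tumor_col = matrix.values[matrix.sample_of(patient, "tumor")]
        for v in variants_by_patient.get(patient, []):
            if v.gene_id not in proteins:
                continue
            if float(tumor_col.get(v.gene_id, 0.0)) <= config.cutoffs.expr_cutoff:
                continue  # only mutations in genes expressed in the tumor
            for pep in mutation_windows(proteins[v.gene_id], v):
                triples.append(
                    (pep, "mutation", f"{v.gene_id}:{v.ref_aa}{v.protein_pos}{v.alt_aa}")
                )
        binding = predict_binders(triples, {patient: hla[patient]}, predictor)
        raw_by_patient[patient] = strong_binder_sets(binding).get(patient, {})

    filtered_by_patient = {}
    for patient, raw in raw_by_patient.items():
        filtered, _removed = self_filter(raw, self_set)
        filtered_by_patient[patient] = filtered
        loads.append(antigen_load(patient, raw, filtered, indices))

    contributions = class_contributions(loads)
    summary = shared_private_summary(filtered_by_patient)
    state["antigen_loads"] = loads
    state["shared_private"] = summary

    rows = []
    for load in loads:
        for cls in SOURCE_CLASSES:
            rows.append(
                {
                    "patient_id": load.patient_id, "source_class": cls,
                    "n_strong_raw": load.n_strong_raw[cls],
                    "n_strong_selffiltered": load.n_strong_selffiltered[cls],
                    "n_corrected": round(load.n_corrected[cls], 6),
                    "translation_index_used": load.translation_index_used[cls],
                }
            )
    out = outdir / "antigen_loads.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    emit("antigen_loads", out)
    sp_out = outdir / "shared_private.json"
    tio.write_json(
        {"per_class": summary, "class_contributions": contributions}, sp_out
    )
    emit("shared_private", sp_out)


def _stage_cohort(config: RunConfig, state: dict, outdir: Path, emit) -> None:
    transcripts = state["transcripts"]
    matrix = state["matrix"]
    sharing = state["sharing"]
    calls = state["patient_calls"]
    te = tio.read_te_bed(config.te_bed)
    biotypes = {t.transcript_id: t.biotype for t in transcripts}

    overlaps = {}
    herv_flags = {}
    for t in transcripts:
        if t.biotype == "coding" or t.strand not in ("+", "-"):
            continue
        ov = te_overlap(t, te)
        overlaps[t.transcript_id] = ov["LTR/HERV"]
        herv_flags[t.transcript_id] = ov["LTR/HERV"]["bp"] >= 1

    ts_set = {c.transcript_id for c in calls if c.tumor_specific}
    expressed = {
        t.transcript_id
        for t in transcripts
        if t.biotype != "coding"
        and (matrix.values.loc[t.transcript_id, matrix.tumor_samples()]
             > config.cutoffs.expr_cutoff).any()
    }
    ts_noncoding = ts_set & expressed
    enrichment = herv_enrichment(expressed, ts_noncoding, herv_flags)

    thymus = tio.read_panel_tsv(config.thymus)["thymus"]
    thymus_flags = {tid: bool(m > 0.5) for tid, m in thymus.items()}
    translated_transcripts = {
        o.transcript_id for o in state.get("translated_orfs", [])
    }
    candidates = select_candidates(
        sharing, matrix, config.cutoffs, biotypes,
        herv_overlaps=overlaps, thymus_flags=thymus_flags,
        translated_ids=translated_transcripts,
    )
    state["candidates"] = candidates
    _log_filter("cohort", "candidates", len(sharing), len(candidates))

    rows = [
        {
            "transcript_id": c.transcript_id, "biotype": c.biotype,
            "n_patients_specific": c.n_patients_specific,
            "fraction_patients": round(c.fraction_patients, 6),
            "max_tumor_fpkm": round(c.max_tumor_fpkm, 6),
            "normal_prevalence": round(c.normal_prevalence, 6),
            "herv_overlap_bp": c.herv_overlap_bp,
            "herv_overlap_fraction": round(c.herv_overlap_fraction, 6),
            "thymus_expressed": c.thymus_expressed,
            "translated_evidence": c.translated_evidence,
        }
        for c in candidates
    ]
    out = outdir / "candidates.tsv"
    pd.DataFrame(
        rows,
        columns=["transcript_id", "biotype", "n_patients_specific",
                 "fraction_patients", "max_tumor_fpkm", "normal_prevalence",
                 "herv_overlap_bp", "herv_overlap_fraction",
                 "thymus_expressed", "translated_evidence"],
    ).to_csv(out, sep="\t", index=False)
    emit("candidates", out)

    enr_out = outdir / "herv_enrichment.json"
    tio.write_json(enrichment, enr_out)
    emit("herv_enrichment", enr_out)

    if len(candidates) >= 2:
        corr, class_means = candidate_correlations(candidates, matrix)
        corr_out = outdir / "candidate_correlations.tsv"
        corr.to_csv(corr_out, sep="\t", float_format="%.6g")
        emit("candidate_correlations", corr_out)
        means_out = outdir / "correlation_class_means.json"
        tio.write_json(class_means, means_out)
        emit("correlation_class_means", means_out)
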