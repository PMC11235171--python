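"""File formats used by the pipeline.

GTF is written/read 1-based inclusive (internal coordinates are 0-based
half-open); BED6 stays 0-based half-open.  Tables are plain TSV read and
written through pandas; FASTA goes through Biopython.  All writers emit
records in a deterministic order with fixed float formatting so that a
bundle regenerated from the same seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tsaquant.errors import ParseError, ValidationError
from tsaquant.antigens import VariantRecord
from tsaquant.cohort import TEAnnotation
from tsaquant.transcriptome import TranscriptRecord
from tsaquant.translation import FootprintProfile

_BIOTYPE_TO_GTF = {"coding": "protein_coding", "lncRNA": "lncRNA", "novel": "novel"}
_GTF_TO_BIOTYPE = {v: k for k, v in _BIOTYPE_TO_GTF.items()}


def _fmt(x: float) -> str:
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# transcript-coordinate <-> genomic mapping

def transcript_to_genomic(
    transcript: TranscriptRecord, start: int, end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to genomic blocks (0-based
    half-open), honouring strand (transcript coordinate 0 is the 5' end)."""
    if not 0 <= start < end <= transcript.spliced_length:
        raise ValidationError(
            f"{transcript.transcript_id}: interval [{start}, {end}) outside "
            "transcript"
        )
    exons = transcript.exons
    if transcript.strand == "-":
        exons = exons[::-1]
    blocks: list[tuple[int, int]] = []
    offset = 0
    for ex_start, ex_end in exons:
        ex_len = ex_end - ex_start
        lo = max(start, offset)
        hi = min(end, offset + ex_len)
        if lo < hi:
            if transcript.strand == "-":
                blocks.append((ex_end - (hi - offset), ex_end - (lo - offset)))
            else:
                blocks.append((ex_start + lo - offset, ex_start + hi - offset))
        offset += ex_len
    return sorted(blocks)


def genomic_to_transcript_length(
    transcript: TranscriptRecord, blocks: list[tuple[int, int]]
) -> tuple[int, int]:
    """Invert :func:`transcript_to_genomic` for a contiguous feature: returns
    the (start, end) transcript interval covered by the genomic blocks."""
    positions: list[int] = []
    offset = 0
    exons = transcript.exons if transcript.strand != "-" else transcript.exons[::-1]
    for ex_start, ex_end in exons:
        ex_len = ex_end - ex_start
        for b_start, b_end in blocks:
            lo, hi = max(b_start, ex_start), min(b_end, ex_end)
            if lo < hi:
                if transcript.strand == "-":
                    positions.append(offset + (ex_end - hi))
                    positions.append(offset + (ex_end - lo))
                else:
                    positions.append(offset + (lo - ex_start))
                    positions.append(offset + (hi - ex_start))
        offset += ex_len
    if not positions:
        raise ValidationError("blocks do not touch the transcript")
    return min(positions), max(positions)


# ---------------------------------------------------------------------------
# GTF

def write_gtf(transcripts: list[TranscriptRecord], path: str | Path) -> None:
    lines: list[str] = []
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.genomic_span, t.transcript_id)):
        attrs = (
            f'gene_id "{t.transcript_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_biotype "{_BIOTYPE_TO_GTF[t.biotype]}";'
        )
        span = t.genomic_span
        strand = t.strand if t.strand in ("+", "-") else "."
        lines.append(
            "\t".join([t.chrom, "tsaquant", "transcript", str(span[0] + 1),
                       str(span[1]), ".", strand, ".", attrs])
        )
        for ex_start, ex_end in t.exons:
            lines.append(
                "\t".join([t.chrom, "tsaquant", "exon", str(ex_start + 1),
                           str(ex_end), ".", strand, ".", attrs])
            )
        if t.cds is not None:
            for b_start, b_end in transcript_to_genomic(t, *t.cds):
                lines.append(
                    "\t".join([t.chrom, "tsaquant", "CDS", str(b_start + 1),
                               str(b_end), ".", strand, ".", attrs])
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attributes(field: str, line_number: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise ParseError(f"malformed GTF attribute {chunk!r}", line_number)
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Read transcript/exon/CDS features into transcript records."""
    feats: dict[str, dict] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(
                    f"expected 9 GTF fields, found {len(parts)}", ln
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attr_s = parts
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError:
                raise ParseError(f"non-numeric coordinates {start!r}/{end!r}", ln)
            attrs = _parse_attributes(attr_s, ln)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError("missing transcript_id attribute", ln)
            rec = feats.setdefault(
                tid,
                {"chrom": chrom, "strand": strand,
                 "biotype": _GTF_TO_BIOTYPE.get(attrs.get("gene_biotype", ""), None),
                 "exons": [], "cds_blocks": []},
            )
            if rec["biotype"] is None:
                raise ParseError(
                    f"unknown gene_biotype {attrs.get('gene_biotype')!r}", ln
                )
            if feature == "exon":
                rec["exons"].append((start_i, end_i))
            elif feature == "CDS":
                rec["cds_blocks"].append((start_i, end_i))
    out: list[TranscriptRecord] = []
    for tid, rec in feats.items():
        strand = rec["strand"] if rec["strand"] in ("+", "-") else "unknown"
        t = TranscriptRecord(
            transcript_id=tid,
            biotype=rec["biotype"],
            chrom=rec["chrom"],
            strand=strand,
            exons=sorted(rec["exons"]),
        )
        if rec["cds_blocks"]:
            t.cds = genomic_to_transcript_length(t, sorted(rec["cds_blocks"]))
        out.append(t)
    out.sort(key=lambda t: (t.chrom, t.genomic_span, t.transcript_id))
    ids = [t.transcript_id for t in out]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate transcript_id in GTF")
    return out


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def attach_sequences(
    transcripts: list[TranscriptRecord], sequences: dict[str, str]
) -> None:
    for t in transcripts:
        seq = sequences.get(t.transcript_id)
        if seq is None:
            raise ValidationError(f"{t.transcript_id}: no FASTA sequence")
        if len(seq) != t.spliced_length:
            raise ValidationError(
                f"{t.transcript_id}: FASTA length {len(seq)} != spliced "
                f"length {t.spliced_length}"
            )
        t.sequence = seq


# ---------------------------------------------------------------------------
# TSV tables

def write_expression_tsv(fpkm: pd.Series, path: str | Path) -> None:
    lines = ["transcript_id\tfpkm"]
    for tid in sorted(fpkm.index):
        lines.append(f"{tid}\t{_fmt(float(fpkm[tid]))}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("transcript_id")["fpkm"]


def write_footprints_tsv(
    profiles: dict[str, FootprintProfile], path: str | Path
) -> None:
    """Sparse profile table: one row per nonzero position."""
    lines = ["transcript_id\tposition\tcount"]
    for tid in sorted(profiles):
        counts = profiles[tid].counts
        for pos in counts.nonzero()[0]:
            lines.append(f"{tid}\t{pos}\t{counts[pos]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_footprints_tsv(
    path: str | Path, transcript_lengths: dict[str, int]
) -> dict[str, FootprintProfile]:
    import numpy as np

    df = pd.read_csv(path, sep="\t")
    profiles: dict[str, FootprintProfile] = {
        tid: FootprintProfile(tid, np.zeros(length, dtype=np.int64))
        for tid, length in transcript_lengths.items()
    }
    for tid, sub in df.groupby("transcript_id"):
        if tid not in profiles:
            raise ValidationError(f"footprints for unknown transcript {tid}")
        profiles[tid].counts[sub["position"].to_numpy()] = sub["count"].to_numpy()
    return profiles


def write_panel_tsv(medians: pd.DataFrame, path: str | Path) -> None:
    medians.sort_index().to_csv(path, sep="\t", index_label="transcript_id",
                                float_format="%.6g")


def read_panel_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="transcript_id")


def write_hla_tsv(alleles: dict[str, list[str]], path: str | Path) -> None:
    lines = ["patient_id\tallele"]
    for patient in sorted(alleles):
        for allele in sorted(alleles[patient]):
            lines.append(f"{patient}\t{allele}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_hla_tsv(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return {p: sorted(sub["allele"]) for p, sub in df.groupby("patient_id")}


_VARIANT_COLS = ["patient_id", "gene_id", "protein_pos", "ref_aa", "alt_aa",
                 "depth", "alt_reads", "consequence"]


def write_variants_tsv(records: list[VariantRecord], path: str | Path) -> None:
    lines = ["\t".join(_VARIANT_COLS)]
    for r in sorted(records, key=lambda r: (r.patient_id, r.gene_id, r.protein_pos)):
        lines.append("\t".join(str(getattr(r, c)) for c in _VARIANT_COLS))
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _VARIANT_COLS:
            raise ParseError(f"unexpected variant header {header}", 1)
        for ln, raw in enumerate(fh, start=2):
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(_VARIANT_COLS):
                raise ParseError("wrong number of variant fields", ln)
            try:
                records.append(
                    VariantRecord(
                        patient_id=parts[0], gene_id=parts[1],
                        protein_pos=int(parts[2]), ref_aa=parts[3],
                        alt_aa=parts[4], depth=int(parts[5]),
                        alt_reads=int(parts[6]), consequence=parts[7],
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), ln)
    return records


def write_affinity_tsv(
    affinities: dict[tuple[str, str], float], path: str | Path
) -> None:
    lines = ["peptide\tallele\tic50_nm"]
    for (peptide, allele) in sorted(affinities):
        lines.append(f"{peptide}\t{allele}\t{_fmt(affinities[(peptide, allele)])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_affinity_tsv(path: str | Path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t")
    return {
        (row.peptide, row.allele): float(row.ic50_nm)
        for row in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# BED6

def write_te_bed(te: TEAnnotation, path: str | Path) -> None:
    lines = []
    rows = sorted(te.intervals)
    for i, (chrom, start, end, strand, te_class) in enumerate(rows):
        name = f"{te_class}|TE{i + 1:05d}"
        lines.append(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_te_bed(path: str | Path) -> TEAnnotation:
    intervals: list[tuple[int, int, str, str, str]] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError("BED6 requires 6 fields", ln)
            chrom, start, end, name, _score, strand = parts[:6]
            te_class = name.split("|")[0]
            try:
                intervals.append((chrom, int(start), int(end), strand, te_class))
            except ValueError as exc:
                raise ParseError(str(exc), ln)
    return TEAnnotation(intervals)


# ---------------------------------------------------------------------------
# JSON

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
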