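"""Candidate ORF enumeration and peptide translation.

Noncanonical ORFs (ncORFs) start at ATG or a near-cognate codon (ACG, CTG,
GTG, TTG), end at a stop codon within the transcript, and are at least 30 nt
long (stop included, so every reported ORF encodes at least one 9-mer).
When several same-frame ORFs share a stop codon only the longest — the one
with the most 5' start — is reported.  On protein-coding transcripts only
the annotated CDS is considered.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from tsaquant.errors import AnnotationError, ValidationError
from tsaquant.transcriptome import TranscriptRecord

START_CODONS = ("ATG", "ACG", "CTG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
MIN_ORF_LENGTH_NT = 30

_NT_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class OrfRecord:
    """A candidate ORF in transcript coordinates.

    ``start`` is the first base of the start codon (0-based), ``end`` is
    half-open just past the stop codon; the encoded ``peptide`` excludes the
    stop, so its length is ``(end - start) / 3 - 1``.
    """

    orf_id: str
    transcript_id: str
    start: int
    end: int
    start_codon: str
    peptide: str
    is_canonical: bool = False

    @property
    def frame(self) -> int:
        return self.start % 3

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "OrfRecord") -> bool:
        return (
            self.transcript_id == other.transcript_id
            and self.start < other.end
            and other.start < self.end
        )


def translate_orf(orf_nt_sequence: str, initiator_as_met: bool = True) -> str:
    """Translate an ORF nucleotide sequence (with terminal stop) to peptide.

    The initiator codon is rendered as Met by default, reflecting
    initiator-tRNA behaviour at near-cognate starts; codons containing N
    translate to X.  An internal stop codon is an error.
    """
    seq = orf_nt_sequence.upper()
    if len(seq) % 3 != 0:
        raise ValidationError(f"ORF length {len(seq)} not divisible by 3")
    if seq[-3:] not in STOP_CODONS:
        raise ValidationError("ORF must end with a stop codon")
    aa = str(Seq(seq[:-3]).translate())
    if "*" in aa:
        raise ValidationError("internal stop codon in ORF")
    if initiator_as_met and aa:
        aa = "M" + aa[1:]
    return aa


def enumerate_ncorfs(
    sequence: str,
    min_len_nt: int = MIN_ORF_LENGTH_NT,
    transcript_id: str = "",
    initiator_as_met: bool = True,
) -> list[OrfRecord]:
    """Enumerate candidate ncORFs on a transcript sequence.

    For each (frame, stop codon) pair at most one ORF is reported: the one
    starting at the most 5' candidate start codon with no intervening
    in-frame stop, i.e. the longest of any same-frame overlapping set.
    ORFs without a stop codon inside the transcript are dropped; codons
    containing N never match a start or a stop.  Output is sorted by
    (start, frame).
    """
    seq = sequence.upper()
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise ValidationError(f"illegal nucleotide characters: {sorted(bad)}")

    records: list[OrfRecord] = []
    for frame in range(3):
        first_start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if first_start is not None:
                    length = pos + 3 - first_start
                    if length >= min_len_nt:
                        records.append(
                            _make_record(
                                seq, first_start, pos + 3, transcript_id,
                                initiator_as_met,
                            )
                        )
                    first_start = None
            elif first_start is None and codon in START_CODONS:
                first_start = pos
    records.sort(key=lambda r: (r.start, r.frame))
    return [
        OrfRecord(
            orf_id=f"{transcript_id or 'seq'}:ORF{i + 1:03d}",
            transcript_id=r.transcript_id,
            start=r.start,
            end=r.end,
            start_codon=r.start_codon,
            peptide=r.peptide,
        )
        for i, r in enumerate(records)
    ]


def _make_record(
    seq: str, start: int, end: int, transcript_id: str, initiator_as_met: bool
) -> OrfRecord:
    nt = seq[start:end]
    aa = str(Seq(nt[:-3]).translate())
    if initiator_as_met and aa:
        aa = "M" + aa[1:]
    return OrfRecord(
        orf_id="",
        transcript_id=transcript_id,
        start=start,
        end=end,
        start_codon=seq[start:start + 3],
        peptide=aa,
    )


def canonical_cds_orf(transcript: TranscriptRecord) -> OrfRecord:
    """Return the annotated CDS of a coding transcript as a canonical ORF."""
    if transcript.biotype != "coding":
        raise AnnotationError(
            f"{transcript.transcript_id}: canonical CDS requested on "
            f"{transcript.biotype} transcript"
        )
    if transcript.cds is None:
        raise AnnotationError(f"{transcript.transcript_id}: no CDS annotated")
    if transcript.sequence is None:
        raise AnnotationError(f"{transcript.transcript_id}: sequence not loaded")
    start, end = transcript.cds
    nt = transcript.sequence[start:end].upper()
    try:
        peptide = translate_orf(nt)
    except ValidationError as exc:
        raise AnnotationError(f"{transcript.transcript_id}: invalid CDS: {exc}")
    return OrfRecord(
        orf_id=f"{transcript.transcript_id}:CDS",
        transcript_id=transcript.transcript_id,
        start=start,
        end=end,
        start_codon=nt[:3],
        peptide=peptide,
        is_canonical=True,
    )
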