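"""Candidate peptide database construction from transcripts.

Transcripts are scanned in three forward frames (six-frame optional for
genomic input); within each inter-stop segment the first configured start
codon (AUG/GUG/UUG by default) opens an ORF that must end at an in-frame
stop.  Surviving 8-100 aa translations are deduplicated into a FASTA
database with deterministic, zero-padded identifiers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "Transcript",
    "OrfRecord",
    "OrfConfig",
    "SepEntry",
    "SepDatabase",
    "find_orfs",
    "build_database",
    "database_from_orfs",
    "start_codon_summary",
    "length_summary",
    "read_transcripts",
    "write_database",
    "read_database",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})  # bacterial table 11

_TABLE11 = CodonTable.unambiguous_dna_by_id[11].forward_table

_VALID_NT = set("ACGTN")


@dataclass(frozen=True)
class Transcript:
    """A stranded nucleotide sequence (T convention, ACGTN alphabet)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} is empty")
        for i, ch in enumerate(self.sequence):
            if ch not in _VALID_NT:
                raise ValueError(
                    f"transcript {self.id!r}: invalid nucleotide {ch!r} at offset {i}"
                )


@dataclass(frozen=True)
class OrfRecord:
    """An ORF called on a transcript.

    ``start`` is the 0-based offset of the start codon's first base;
    ``end`` is the 0-based offset of the stop codon's first base (exclusive
    end of the coding region).  The stop codon itself occupies [end, end+3).
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    start_codon: str
    protein: str
    strand: str = "+"


@dataclass(frozen=True)
class OrfConfig:
    start_codons: frozenset[str] = frozenset({"ATG", "GTG", "TTG"})
    min_len: int = 8
    max_len: int = 100
    translate_start_as_met: bool = True
    emit_nested_starts: bool = False

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        for c in self.start_codons:
            if len(c) != 3 or set(c) - set("ACGT"):
                raise ValueError(f"invalid start codon {c!r}")


@dataclass
class SepEntry:
    sep_id: str
    protein: str
    provenance: list[OrfRecord]


@dataclass
class SepDatabase:
    entries: list[SepEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def proteins(self) -> set[str]:
        return {e.protein for e in self.entries}

    def by_id(self, sep_id: str) -> SepEntry:
        for e in self.entries:
            if e.sep_id == sep_id:
                return e
        raise KeyError(sep_id)


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return _TABLE11.get(codon, "X")


def translate(seq: str, initiator_as_met: bool = True) -> str:
    """Table-11 translation of an in-frame coding region (stop excluded)."""
    aas = [_translate_codon(seq[i:i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)]
    if aas and initiator_as_met:
        aas[0] = "M"
    return "".join(aas)


def find_orfs(t: Transcript, cfg: OrfConfig = OrfConfig()) -> list[OrfRecord]:
    """Call ORFs on the forward strand in all three frames.

    Within each inter-stop segment the first configured start codon opens
    the reported ORF; subsequent starts in the same segment are reported
    only when ``cfg.emit_nested_starts``.  ORFs without a downstream
    in-frame stop are not reported.  Codons containing N are never starts
    or stops and translate to X.
    """
    seq = t.sequence
    records: list[OrfRecord] = []
    for frame in range(3):
        open_starts: list[int] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if "N" not in codon and codon in STOP_CODONS:
                for s in open_starts:
                    records.append(_make_orf(t, frame, s, pos, cfg))
                open_starts = []
            elif codon in cfg.start_codons:
                if not open_starts or cfg.emit_nested_starts:
                    open_starts.append(pos)
    return records


def _make_orf(t: Transcript, frame: int, start: int, end: int, cfg: OrfConfig) -> OrfRecord:
    coding = t.sequence[start:end]
    protein = translate(coding, initiator_as_met=cfg.translate_start_as_met)
    return OrfRecord(
        transcript_id=t.id,
        frame=frame,
        start=start,
        end=end,
        start_codon=t.sequence[start:start + 3],
        protein=protein,
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_database(
    transcripts: Iterable[Transcript],
    cfg: OrfConfig = OrfConfig(),
    six_frame: bool = False,
) -> SepDatabase:
    """Call ORFs on every transcript, length-filter, deduplicate and assign ids.

    Exact duplicate proteins are merged into one entry whose provenance
    lists every source ORF.  Identifiers are assigned in lexicographic
    protein order so reruns are diffable.  An empty result is a valid
    (empty) database, not an error.
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("no transcripts supplied")
    orfs: list[OrfRecord] = []
    for t in transcripts:
        orfs.extend(find_orfs(t, cfg))
        if six_frame:
            rc = Transcript(t.id, reverse_complement(t.sequence))
            for o in find_orfs(rc, cfg):
                orfs.append(OrfRecord(o.transcript_id, o.frame, o.start, o.end,
                                      o.start_codon, o.protein, strand="-"))
    return database_from_orfs(orfs, cfg.min_len, cfg.max_len)


def database_from_orfs(orfs: Iterable[OrfRecord], min_len: int = 8, max_len: int = 100) -> SepDatabase:
    """Length-filter, deduplicate and id-assign a set of ORF records.

    Idempotent on protein sets: re-feeding a database's provenance yields
    the same entries.
    """
    by_protein: dict[str, list[OrfRecord]] = {}
    for o in orfs:
        if min_len <= len(o.protein) <= max_len:
            by_protein.setdefault(o.protein, []).append(o)
    entries = []
    for i, protein in enumerate(sorted(by_protein), start=1):
        prov = sorted(set(by_protein[protein]),
                      key=lambda o: (o.transcript_id, o.strand, o.frame, o.start))
        entries.append(SepEntry(f"SEP{i:06d}", protein, prov))
    return SepDatabase(entries)


def start_codon_summary(db: SepDatabase) -> dict[str, float]:
    """Fraction of entries per start codon (first provenance record of each)."""
    counts: dict[str, int] = {}
    for e in db:
        codon = e.provenance[0].start_codon
        counts[codon] = counts.get(codon, 0) + 1
    total = sum(counts.values())
    return {c: counts[c] / total for c in sorted(counts)} if total else {}


def length_summary(db: SepDatabase) -> dict[str, float]:
    """Min/quartiles/max of entry lengths; empty dict for an empty database."""
    if not len(db):
        return {}
    import numpy as np

    lengths = np.array(sorted(len(e.protein) for e in db))
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return {
        "n": int(len(lengths)),
        "min": int(lengths[0]),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": int(lengths[-1]),
    }


# ---------------------------------------------------------------------------
# FASTA / TSV interchange


def read_transcripts(path: str) -> list[Transcript]:
    return [Transcript(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_transcripts(transcripts: Iterable[Transcript], path: str) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i:i + 70] + "\n")


def write_database(db: SepDatabase, fasta_path: str, provenance_path: str | None = None) -> None:
    with open(fasta_path, "w") as fh:
        for e in db:
            p = e.provenance[0]
            fh.write(f">{e.sep_id} tr={p.transcript_id} frame={p.frame} "
                     f"start={p.start} codon={p.start_codon}\n")
            for i in range(0, len(e.protein), 70):
                fh.write(e.protein[i:i + 70] + "\n")
    if provenance_path:
        with open(provenance_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["sep_id", "transcript_id", "strand", "frame", "start", "end", "start_codon"])
            for e in db:
                for o in e.provenance:
                    w.writerow([e.sep_id, o.transcript_id, o.strand, o.frame, o.start, o.end, o.start_codon])


def read_database(fasta_path: str) -> SepDatabase:
    """Read a database FASTA written by :func:`write_database`.

    Provenance is reconstructed from the header fields (first record only).
    """
    entries = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        fields = dict(kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv)
        protein = str(rec.seq)
        prov = OrfRecord(
            transcript_id=fields.get("tr", "?"),
            frame=int(fields.get("frame", 0)),
            start=int(fields.get("start", 0)),
            end=int(fields.get("start", 0)) + 3 * len(protein),
            start_codon=fields.get("codon", "ATG"),
            protein=protein,
        )
        entries.append(SepEntry(rec.id, protein, [prov]))
    return SepDatabase(entries)
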