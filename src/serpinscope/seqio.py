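"""Sequence I/O and open-reading-frame discovery.

FASTA parsing/writing is delegated to Biopython; the six-frame ORF scan and
the translator are explicit reimplementations of the standard procedure so
that every reported ORF is reproducible from the rules stated here.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")
FRAME_ORDER = (1, 2, 3, -1, -2, -3)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})
START_CODON = "ATG"


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class NucleotideRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: illegal nucleotide(s) {sorted(bad)}")


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    description: str = ""
    # provenance of a translated ORF: parent transcript, frame, nt span
    source: Optional[tuple[str, int, int, int]] = None


@dataclass
class Orf:
    transcript_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    start: int  # forward-strand, 0-based half-open (includes stop if present)
    end: int
    protein: ProteinRecord
    partial3: bool = False  # no stop codon before sequence end


def read_fasta(path, alphabet: str = "auto") -> list:
    """Read a FASTA file into nucleotide or protein records (file order).

    ``alphabet`` is ``"nt"``, ``"aa"`` or ``"auto"`` (sniff: a sequence over
    ACGTN only is treated as DNA).  Whitespace is stripped and sequences
    upper-cased.  Malformed headers or illegal residues raise
    :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    records = []
    seen = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    # pre-validate headers so we can report line numbers (SeqIO silently
    # tolerates some malformed input)
    header_lines = {}
    current = None
    for i, line in enumerate(lines, start=1):
        if line.startswith(">"):
            name = line[1:].split(None, 1)[0] if line[1:].strip() else ""
            if not name:
                raise FastaParseError("empty FASTA header", i)
            if name in seen:
                raise FastaParseError(f"duplicate record id {name!r}", i)
            seen.add(name)
            header_lines[name] = i
            current = i
        elif line.strip() and current is None:
            raise FastaParseError("sequence data before first '>' header", i)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        desc = rec.description[len(rec.id):].strip()
        if alphabet == "nt" or (alphabet == "auto" and set(seq) <= DNA_ALPHABET and seq):
            try:
                records.append(NucleotideRecord(rec.id, seq, desc))
            except ValueError as exc:
                raise FastaParseError(str(exc), header_lines.get(rec.id, 0))
        else:
            bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWYX*")
            if bad:
                raise FastaParseError(
                    f"{rec.id}: illegal residue(s) {sorted(bad)}",
                    header_lines.get(rec.id, 0),
                )
            records.append(ProteinRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def translate(nt: str, include_stop: bool = False) -> str:
    """Translate DNA with the standard genetic code (table 1).

    Codons containing N translate to ``X``; a trailing partial codon is
    dropped with a warning; a terminal stop is rendered ``*`` only when
    ``include_stop`` is true (internal stops are always rendered ``*`` so the
    caller can detect them).
    """
    nt = nt.upper()
    bad = set(nt) - DNA_ALPHABET
    if bad:
        raise ValueError(f"illegal nucleotide(s) {sorted(bad)}")
    if len(nt) % 3:
        warnings.warn(
            f"dropping trailing partial codon of {len(nt) % 3} nt", stacklevel=2
        )
        nt = nt[: len(nt) - len(nt) % 3]
    aas = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        aas.append("X" if "N" in codon else CODON_TO_AA[codon])
    prot = "".join(aas)
    if prot.endswith("*") and not include_stop:
        prot = prot[:-1]
    return prot


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def _scan_frame(seq: str, offset: int):
    """Yield maximal (start, end, has_stop) codon spans: the first ATG after
    each stop opens an ORF that runs to the next stop (or sequence end)."""
    n = (len(seq) - offset) // 3
    start = None
    for k in range(n):
        codon = seq[offset + 3 * k : offset + 3 * k + 3]
        aa = "X" if "N" in codon else CODON_TO_AA[codon]
        if aa == "*":
            if start is not None:
                yield start, k + 1, True
                start = None
        elif start is None and codon == START_CODON:
            start = k
    if start is not None:
        yield start, n, False


def find_orfs(
    record: NucleotideRecord, min_codons: int = 100, both_strands: bool = True
) -> list[Orf]:
    """Find every maximal ATG→stop open reading frame of at least
    ``min_codons`` amino acids in the three forward (and optionally three
    reverse) frames.

    ORFs reaching the sequence end without a stop are flagged ``partial3``.
    Reverse-strand coordinates are mapped back to the forward strand.  Output
    is sorted by descending protein length, ties by (frame, start).
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    L = len(record.sequence)
    orfs = []
    for strand in (1, -1):
        if strand == -1 and not both_strands:
            break
        seq = record.sequence if strand == 1 else reverse_complement(record.sequence)
        for offset in range(3):
            frame = strand * (offset + 1)
            for c0, c1, has_stop in _scan_frame(seq, offset):
                nt_start = offset + 3 * c0
                nt_end = offset + 3 * c1
                aa = translate(seq[nt_start:nt_end])
                if len(aa) < min_codons:
                    continue
                if strand == -1:
                    nt_start, nt_end = L - nt_end, L - nt_start
                prot = ProteinRecord(
                    id=f"{record.id}|f{frame:+d}|{nt_start + 1}-{nt_end}",
                    sequence=aa,
                    source=(record.id, frame, nt_start, nt_end),
                )
                orfs.append(
                    Orf(record.id, frame, nt_start, nt_end, prot, partial3=not has_stop)
                )
    orfs.sort(
        key=lambda o: (-len(o.protein.sequence), FRAME_ORDER.index(o.frame), o.start)
    )
    return orfs
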