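"""Serpin candidate screening: signature/motif matching and completeness.

The signature matcher is a small PROSITE-syntax compiler (residues, ``x``,
``[ALLOWED]``, ``{FORBIDDEN}``, ``(n)`` / ``(n,m)`` repeats, ``<`` / ``>``
anchors).  The pattern string itself is data (see
:data:`serpinscope.data.SERPIN_SIGNATURE_PATTERN`), not logic.

Completeness follows the published full-length rule for tick salivary
serpins: initiator methionine, length within a configured window
(default 350–450 aa), a hinge-conforming reactive center loop, and RCL
uniqueness within the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import data
from .seqio import ProteinRecord


class PrositeSyntaxError(ValueError):
    def __init__(self, message: str, offset: int):
        super().__init__(f"offset {offset}: {message}")
        self.offset = offset


@dataclass(frozen=True)
class _Element:
    allowed: Optional[frozenset]  # None = any residue
    negated: bool
    min_rep: int
    max_rep: int


@dataclass
class PrositeMatcher:
    """Compiled PROSITE pattern: a list of per-position residue constraints.

    ``search`` reports, for each feasible start, the greedy (longest) match
    span — one span per start, like an overlapped regex scan.
    """

    pattern: str
    elements: list[_Element]
    anchored_start: bool
    anchored_end: bool

    def _match_from(self, seq: str, pos: int) -> Optional[int]:
        def rec(ei: int, p: int) -> Optional[int]:
            if ei == len(self.elements):
                if self.anchored_end and p != len(seq):
                    return None
                return p
            el = self.elements[ei]
            # count the residues this element can consume at p
            max_take = 0
            while max_take < el.max_rep and p + max_take < len(seq):
                ch = seq[p + max_take]
                if el.allowed is None:
                    ok = True
                elif el.negated:
                    ok = ch not in el.allowed
                else:
                    ok = ch in el.allowed
                if not ok:
                    break
                max_take += 1
            for take in range(max_take, el.min_rep - 1, -1):  # greedy first
                end = rec(ei + 1, p + take)
                if end is not None:
                    return end
            return None

        return rec(0, pos)

    def search(self, protein: str) -> list[tuple[int, int]]:
        """All match spans (0-based half-open), one greedy span per start."""
        starts = [0] if self.anchored_start else range(len(protein) + 1)
        spans = []
        for s in starts:
            e = self._match_from(protein, s)
            if e is not None:
                spans.append((s, e))
        return spans


def compile_prosite(pattern: str) -> PrositeMatcher:
    """Compile a PROSITE-syntax pattern into a position-constraint matcher."""
    text = pattern.strip()
    if text.endswith("."):
        text = text[:-1]
    anchored_start = text.startswith("<")
    if anchored_start:
        text = text[1:]
    anchored_end = text.endswith(">")
    if anchored_end:
        text = text[:-1]
    if not text:
        raise PrositeSyntaxError("empty pattern", 0)
    elements: list[_Element] = []
    pos = 0
    for token in text.split("-"):
        if not token:
            raise PrositeSyntaxError("empty element (stray '-')", pos)
        base, rep = token, None
        if "(" in token:
            if not token.endswith(")"):
                raise PrositeSyntaxError("unterminated repeat", pos + token.index("("))
            base, rep = token[: token.index("(")], token[token.index("(") + 1 : -1]
        if base == "x":
            allowed, negated = None, False
        elif base.startswith("[") and base.endswith("]"):
            allowed, negated = frozenset(base[1:-1]), False
        elif base.startswith("{") and base.endswith("}"):
            allowed, negated = frozenset(base[1:-1]), True
        elif len(base) == 1 and base.isalpha() and base.isupper():
            allowed, negated = frozenset(base), False
        else:
            raise PrositeSyntaxError(f"unrecognised element {base!r}", pos)
        if allowed is not None and not allowed:
            raise PrositeSyntaxError("empty residue class", pos)
        if rep is None:
            lo = hi = 1
        else:
            parts = rep.split(",")
            try:
                nums = [int(p) for p in parts]
            except ValueError:
                raise PrositeSyntaxError(f"bad repeat count {rep!r}", pos)
            if len(nums) == 1:
                lo = hi = nums[0]
            elif len(nums) == 2:
                lo, hi = nums
            else:
                raise PrositeSyntaxError(f"bad repeat {rep!r}", pos)
            if lo < 0 or hi < lo:
                raise PrositeSyntaxError(f"bad repeat range {rep!r}", pos)
        elements.append(_Element(allowed, negated, lo, hi))
        pos += len(token) + 1
    return PrositeMatcher(pattern, elements, anchored_start, anchored_end)


@dataclass
class MotifMatch:
    motif: str
    start: int
    end: int
    mismatch_count: int
    matched: str


def find_motif(
    protein: ProteinRecord | str, motif: str, max_mismatches: int = 0
) -> list[MotifMatch]:
    """All windows within ``max_mismatches`` Hamming distance of ``motif``,
    ranked by (mismatches, start).  ``max_mismatches=0`` is exact search."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    m = len(motif)
    hits = []
    for s in range(len(seq) - m + 1):
        window = seq[s : s + m]
        d = sum(a != b for a, b in zip(window, motif))
        if d <= max_mismatches:
            hits.append(MotifMatch(motif, s, s + m, d, window))
    hits.sort(key=lambda h: (h.mismatch_count, h.start))
    return hits


@dataclass
class ScreenConfig:
    prosite_pattern: str = data.SERPIN_SIGNATURE_PATTERN
    nterm_motif: str = data.NTERM_MOTIF
    nterm_max_mismatches: int = 2  # consensus motif; exact match would drop variants
    full_length_min: int = 350
    full_length_max: int = 450


@dataclass
class CompletenessCall:
    status: str  # "full" | "partial"
    reasons: dict  # criterion name -> bool
    tags: list = field(default_factory=list)

    @property
    def is_full(self) -> bool:
        return self.status == "full"


def classify_completeness(
    protein: ProteinRecord,
    rcl,  # Optional[RCLAnnotation]
    config: ScreenConfig = ScreenConfig(),
    rcl_unique: bool = True,
) -> CompletenessCall:
    """Full-length call: initiator Met, length in range, RCL present and
    unique within the run; anything else is partial, with per-criterion
    reasons.  Sequences lacking an RCL are tagged truncated-C-terminus."""
    reasons = {
        "has_start_met": protein.sequence.startswith("M"),
        "length_in_range": config.full_length_min
        <= len(protein.sequence)
        <= config.full_length_max,
        "has_rcl": rcl is not None,
        "rcl_unique": rcl is not None and rcl_unique,
    }
    tags = [] if rcl is not None else ["truncated C-terminus"]
    status = "full" if all(reasons.values()) else "partial"
    return CompletenessCall(status, reasons, tags)


@dataclass
class SerpinRecord:
    """A screened candidate with its motif evidence and annotations."""

    id: str
    protein: ProteinRecord
    signature_matches: list = field(default_factory=list)
    nterm_matches: list = field(default_factory=list)
    rcl: object = None  # RCLAnnotation
    completeness: Optional[CompletenessCall] = None
    features: object = None
    sexes: str = ""


def screen_proteins(
    proteins: Sequence[ProteinRecord],
    config: ScreenConfig = ScreenConfig(),
    rcl_config=None,
    tpm_sums: Optional[dict] = None,
) -> list[SerpinRecord]:
    """Run the signature/motif screen and the RCL scan over a protein set and
    produce one :class:`SerpinRecord` per input (count-conserving).

    RCL uniqueness is resolved run-wide: identical 21-mer RCLs collapse to a
    single full-length representative — highest summed TPM wins
    (``tpm_sums``: id → summed TPM), ties broken lexicographically by id.
    """
    from . import rcl as rcl_mod

    signature = compile_prosite(config.prosite_pattern)
    rcl_config = rcl_config or rcl_mod.HingePattern.default()
    records = []
    for prot in proteins:
        sig = [
            MotifMatch(config.prosite_pattern, s, e, 0, prot.sequence[s:e])
            for s, e in signature.search(prot.sequence)
        ]
        half = len(prot.sequence) // 2
        nterm = [
            m
            for m in find_motif(prot, config.nterm_motif, config.nterm_max_mismatches)
            if m.start < half
        ]
        ann = rcl_mod.annotate_rcl(prot, rcl_config)
        records.append(SerpinRecord(prot.id, prot, sig, nterm, ann))

    # run-wide RCL dedup
    by_rcl: dict[str, list[SerpinRecord]] = {}
    for rec in records:
        if rec.rcl is not None:
            by_rcl.setdefault(rec.rcl.rcl_seq, []).append(rec)
    unique_ids = set()
    for group in by_rcl.values():
        rep = min(
            group, key=lambda r: (-(tpm_sums or {}).get(r.id, 0.0), r.id)
        )
        unique_ids.add(rep.id)
    for rec in records:
        rec.completeness = classify_completeness(
            rec.protein, rec.rcl, config, rcl_unique=rec.id in unique_ids
        )
    return records
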