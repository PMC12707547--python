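"""Reactive-center-loop annotation.

The RCL is the exposed C-terminal loop of a serpin; its hinge (P17–P9) must
be small-residue rich for inhibitory loop insertion, and the residue at P1 —
17 positions from the hinge start, counting P17 as the first — sets protease
specificity.  The annotated window spans P17→P4′ (21 residues).

Subsite constraints follow the eight-residue hinge consensus
``P17 [E] - P16 [E/K/R] - P15 [G] - P14 [T/S] - P13 [x] - P12..P9 [A/G/S]``
with P17/P15/P14/P12 critical and a mismatch budget over the rest: retained
natural serpins are known to deviate at P16 or P9, so strict matching would
reject real loops.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import data
from ._util import round_half_up
from .seqio import ProteinRecord

RCL_LENGTH = 21
P1_OFFSET = 16  # P1 sits 17 residues into the loop, counting P17 as first


@dataclass(frozen=True)
class Subsite:
    name: str
    allowed: Optional[frozenset]  # None = unconstrained
    critical: bool = False


@dataclass
class HingePattern:
    """Per-position allowed-residue constraints for the hinge consensus."""

    subsites: tuple
    max_noncritical_mismatches: int = 2

    @classmethod
    def default(cls) -> "HingePattern":
        ags = frozenset("AGS")
        return cls(
            subsites=(
                Subsite("P17", frozenset("E"), critical=True),
                Subsite("P16", frozenset("EKR")),
                Subsite("P15", frozenset("G"), critical=True),
                Subsite("P14", frozenset("TS"), critical=True),
                Subsite("P13", None),
                Subsite("P12", ags, critical=True),
                Subsite("P11", ags),
                Subsite("P10", ags),
                Subsite("P9", ags),
            )
        )

    def evaluate(self, window: str) -> Optional[tuple[int, list[str]]]:
        """Score a window starting at P17.  Returns (matched-constraint
        count, mismatched subsite names), or None if a critical subsite or
        the mismatch budget fails."""
        score, mismatched = 0, []
        for i, sub in enumerate(self.subsites):
            if sub.allowed is None:
                continue
            if window[i] in sub.allowed:
                score += 1
            elif sub.critical:
                return None
            else:
                mismatched.append(sub.name)
        if len(mismatched) > self.max_noncritical_mismatches:
            return None
        return score, mismatched


@dataclass
class HingeCandidate:
    start: int  # 0-based protein index of P17
    score: int
    mismatched_subsites: list


@dataclass
class RCLAnnotation:
    hinge_start: int
    rcl_seq: str
    p1_index: int
    p1_residue: str
    p1_class: str
    predicted_target: str
    mismatched_subsites: list = field(default_factory=list)
    score: int = 0


def scan_hinge(
    protein: ProteinRecord | str,
    pattern: Optional[HingePattern] = None,
    window: int = 80,
) -> list[HingeCandidate]:
    """Scan the C-terminal ``window`` residues for hinge-conforming starts.

    A candidate must satisfy every critical subsite, stay within the
    noncritical mismatch budget, and leave at least 21 residues from P17 to
    the sequence end.  Ranked by (score desc, start desc): among equal
    scores the most C-terminal wins, the RCL being the C-terminal-most
    hinge-like element.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    pattern = pattern or HingePattern.default()
    lo = max(0, len(seq) - window)
    out = []
    for s in range(lo, len(seq) - RCL_LENGTH + 1):
        res = pattern.evaluate(seq[s : s + len(pattern.subsites)])
        if res is not None:
            out.append(HingeCandidate(s, res[0], res[1]))
    out.sort(key=lambda c: (-c.score, -c.start))
    return out


def extract_rcl(
    protein: ProteinRecord | str,
    hinge_start: int,
    mismatched_subsites: Sequence[str] = (),
    score: int = 0,
) -> RCLAnnotation:
    """Cut the 21-residue P17→P4′ window at ``hinge_start`` and classify P1."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if hinge_start + RCL_LENGTH > len(seq):
        raise ValueError(
            f"fewer than {RCL_LENGTH} residues remain at {hinge_start}; "
            "sequence is C-terminally truncated"
        )
    rcl_seq = seq[hinge_start : hinge_start + RCL_LENGTH]
    p1 = rcl_seq[P1_OFFSET]
    p1_class, target = classify_p1(p1)
    return RCLAnnotation(
        hinge_start=hinge_start,
        rcl_seq=rcl_seq,
        p1_index=hinge_start + P1_OFFSET,
        p1_residue=p1,
        p1_class=p1_class,
        predicted_target=target,
        mismatched_subsites=list(mismatched_subsites),
        score=score,
    )


def annotate_rcl(
    protein: ProteinRecord | str,
    pattern: Optional[HingePattern] = None,
    window: int = 80,
) -> Optional[RCLAnnotation]:
    """Top-ranked hinge candidate → RCL annotation; None when no hinge is
    found (the caller classifies the sequence as partial)."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if len(seq) < RCL_LENGTH:
        return None
    cands = scan_hinge(seq, pattern, window)
    if not cands:
        return None
    best = cands[0]
    return extract_rcl(seq, best.start, best.mismatched_subsites, best.score)


def classify_p1(residue: str) -> tuple[str, str]:
    """Chemistry class and predicted target protease family for a P1 residue."""
    for cls, members in data.P1_CLASSES.items():
        if residue in members:
            return cls, data.P1_TARGETS[cls]
    raise ValueError(f"non-standard residue {residue!r}")


def p1_summary(annotations: Sequence) -> dict:
    """Class counts/percentages and the distinct-P1-residue count.

    ``annotations`` may be RCLAnnotation objects or bare P1 residue letters.
    Percentages are 100 × count / total, rounded half-up to 2 decimals.
    """
    if len(annotations) == 0:
        raise ValueError("empty annotation list")
    residues = [
        a.p1_residue if isinstance(a, RCLAnnotation) else str(a) for a in annotations
    ]
    classes = [classify_p1(r)[0] for r in residues]
    counts = Counter(classes)
    total = len(residues)
    return {
        "total": total,
        "counts": {cls: counts.get(cls, 0) for cls in data.P1_CLASSES},
        "percentages": {
            cls: round_half_up(100 * counts.get(cls, 0) / total)
            for cls in data.P1_CLASSES
        },
        "distinct_residues": len(set(residues)),
    }


def hinge_conservation_report(
    annotations: Sequence[RCLAnnotation], pattern: Optional[HingePattern] = None
) -> pd.DataFrame:
    """Per-subsite residue frequencies over the aligned 21-mer RCLs.

    ``conserved`` flags unanimity (a single residue across all loops);
    ``pattern_compliance`` is the fraction satisfying the hinge constraint
    at constrained subsites (NaN where unconstrained).
    """
    if not annotations:
        raise ValueError("need at least one annotation")
    pattern = pattern or HingePattern.default()
    constraint = {s.name: s.allowed for s in pattern.subsites}
    rows = []
    n = len(annotations)
    for i, name in enumerate(data.RCL_SUBSITES):
        col = [a.rcl_seq[i] for a in annotations]
        freq = Counter(col)
        allowed = constraint.get(name)
        rows.append(
            {
                "subsite": name,
                "frequencies": {r: c / n for r, c in sorted(freq.items())},
                "conserved": len(freq) == 1,
                "pattern_compliance": (
                    sum(r in allowed for r in col) / n if allowed else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("subsite")


def logo_matrix(annotations: Sequence) -> pd.DataFrame:
    """21 × 20 information-content-weighted frequency matrix (sequence logo).

    Per column, IC = log2(20) − H with H the Shannon entropy (bits) of the
    observed residue frequencies; cell = frequency × IC.  No small-sample
    correction.
    """
    seqs = [a.rcl_seq if isinstance(a, RCLAnnotation) else str(a) for a in annotations]
    if len(seqs) < 2:
        raise ValueError("need at least 2 aligned loops")
    if any(len(s) != RCL_LENGTH for s in seqs):
        raise ValueError("all loops must be 21 residues")
    aa = list(data.AMINO_ACIDS)
    mat = np.zeros((RCL_LENGTH, len(aa)))
    for i in range(RCL_LENGTH):
        col = [s[i] for s in seqs]
        freq = np.array([col.count(a) / len(col) for a in aa])
        nz = freq[freq > 0]
        ic = np.log2(len(aa)) - float(-(nz * np.log2(nz)).sum())
        mat[i] = freq * ic
    return pd.DataFrame(mat, index=data.RCL_SUBSITES, columns=aa)
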