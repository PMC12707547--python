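"""Physicochemical annotations and external-predictor ingestion.

Molecular weights use average (not monoisotopic) residue masses, matching
the convention of the usual web calculators.  N-glycosylation reporting is
the canonical sequon rule N-X-S/T (X ≠ P) — these are *potential sequons*,
the necessary sequence condition, not occupancy predictions.  Signal-peptide
and O-glycosylation calls are not computed here; they are ingested from an
external predictor's TSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from ._util import round_half_up
from .seqio import ProteinRecord

WATER_MASS = 18.01524

# Average residue masses (Da), Expasy/ProtParam convention.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}


def molecular_weight(protein: ProteinRecord | str) -> float:
    """Average-isotopic molecular weight in Da, to 2 decimals.

    Sum of residue masses plus one water; ambiguous (X) or empty sequences
    are rejected.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not seq:
        raise ValueError("empty sequence")
    try:
        mass = sum(RESIDUE_MASS[aa] for aa in seq)
    except KeyError as exc:
        raise ValueError(f"ambiguous or non-standard residue {exc.args[0]!r}")
    return round_half_up(mass + WATER_MASS)


def find_nglyc(protein: ProteinRecord | str) -> list[int]:
    """1-based positions of N in N-X-S/T sequons with X ≠ P."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    return [
        i + 1
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"
    ]


@dataclass
class ExternalAnnotation:
    sp_present: bool
    sp_length: Optional[int] = None
    oglyc_sites: list = field(default_factory=list)


@dataclass
class FeatureAnnotation:
    molecular_weight: float
    nglyc_sites: list
    signal_peptide: Optional[tuple[bool, Optional[int]]] = None
    oglyc_sites: Optional[list] = None


def annotate_features(
    protein: ProteinRecord, external: Optional[dict] = None
) -> FeatureAnnotation:
    ext = (external or {}).get(protein.id)
    return FeatureAnnotation(
        molecular_weight=(
            molecular_weight(protein) if "X" not in protein.sequence else float("nan")
        ),
        nglyc_sites=find_nglyc(protein),
        signal_peptide=(ext.sp_present, ext.sp_length) if ext else None,
        oglyc_sites=list(ext.oglyc_sites) if ext else None,
    )


def ingest_external_annotations(tsv_path) -> dict[str, ExternalAnnotation]:
    """Read external predictor calls: TSV columns
    ``id  sp_present{SP,NSP}  sp_length  oglyc_positions`` (semicolons
    separating positions).  Unknown ids simply stay absent downstream."""
    out: dict[str, ExternalAnnotation] = {}
    with open(Path(tsv_path)) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].lower() in ("id", "#id"):
                continue
            if len(row) != 4:
                raise ValueError(f"line {lineno}: expected 4 columns, got {len(row)}")
            ident, sp, sp_len, oglyc = (c.strip() for c in row)
            if sp not in ("SP", "NSP"):
                raise ValueError(f"line {lineno}: sp_present must be SP or NSP")
            try:
                length = int(sp_len) if sp == "SP" else None
                if sp == "SP" and length is not None and length <= 0:
                    raise ValueError
                sites = sorted(int(p) for p in oglyc.split(";") if p)
            except ValueError:
                raise ValueError(f"line {lineno}: malformed numeric field")
            out[ident] = ExternalAnnotation(sp == "SP", length, sites)
    return out


def write_external_annotations(annotations: dict, tsv_path) -> None:
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for ident in annotations:
            a = annotations[ident]
            w.writerow(
                [
                    ident,
                    "SP" if a.sp_present else "NSP",
                    a.sp_length if a.sp_present and a.sp_length else "",
                    ";".join(str(p) for p in a.oglyc_sites),
                ]
            )
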