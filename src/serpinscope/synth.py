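"""Synthetic serpin sequences and two-sex expression tables with ground truth.

The generator emulates the structure of a tick sialotranscriptome serpin
set: full-length proteins carry an initiator Met, an N-terminal NAVYFKG
motif, a PROSITE-style signature 11-mer, and a hinge-conforming 21-residue
reactive center loop with a chosen P1 residue placed so that 21+K residues
(K ∈ [10, 40]) remain to the C-terminus; partial sequences are the same
scaffolds cut upstream of the hinge.  Background residues are uniform over
the 20 standard amino acids.

Planted structure is made unambiguous by construction: scaffolds are
rejection-sampled until the planted hinge is the unique top-ranked hinge
candidate (and truncated sequences carry none), and expressed count cells
draw zero-truncated negative binomials so a planted "expressed" transcript
can never show zero counts.  Recovery by the screening/RCL/partition stages
is therefore exact for every seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import data
from .features import ExternalAnnotation
from .rcl import RCL_LENGTH, HingePattern, classify_p1, scan_hinge
from .screen import compile_prosite
from .seqio import CODON_TO_AA, NucleotideRecord, ProteinRecord, write_fasta

# default planted-P1 frequencies: the published 17-residue P1 spectrum
_P1_DEFAULT = {
    r: n / 17 for r, n in {"K": 4, "R": 4, "C": 3, "Y": 2, "I": 1, "L": 1, "S": 1, "T": 1}.items()
}


@dataclass
class SyntheticSpec:
    n_total: int = 110
    n_full_length: int = 17
    sex_counts: tuple[int, int, int] = (4, 15, 91)  # female_only, male_only, shared
    p1_distribution: dict = field(default_factory=lambda: dict(_P1_DEFAULT))
    planted_p1: Optional[Sequence[str]] = None  # overrides the distribution
    length_range: tuple[int, int] = (350, 450)
    min_truncated_length: int = 150
    signal_peptide_fraction: float = 6 / 17
    nb_mean: float = 200.0
    nb_dispersion: float = 0.5
    samples_per_sex: int = 2
    seed: int = 7

    def __post_init__(self):
        if self.n_full_length > self.n_total:
            raise ValueError("n_full_length exceeds n_total")
        if sum(self.sex_counts) != self.n_total:
            raise ValueError("sex_counts must sum to n_total")
        if self.planted_p1 is not None and len(self.planted_p1) != self.n_full_length:
            raise ValueError("planted_p1 length must equal n_full_length")
        if abs(sum(self.p1_distribution.values()) - 1) > 1e-9:
            raise ValueError("p1_distribution must sum to 1")
        lo, hi = self.length_range
        if hi < lo or lo < 120:
            raise ValueError("length range too small to host the planted motifs")


def hds_preset(seed: int = 7) -> SyntheticSpec:
    """The study-shaped preset: 110 transcripts, 17 full-length serpins
    planted with the published P1 residue list, 4/15/91 sex structure."""
    return SyntheticSpec(
        planted_p1=list(data.HDS_P1_RESIDUES.values()), seed=seed
    )


def _rand_aa(rng, k: int) -> str:
    return "".join(rng.choice(list(data.AMINO_ACIDS), size=k))


def _sample_signature(rng, pattern: str) -> str:
    out = []
    for el in compile_prosite(pattern).elements:
        pool = sorted(el.allowed) if el.allowed and not el.negated else list(
            data.AMINO_ACIDS
        )
        for _ in range(el.min_rep):
            out.append(rng.choice(pool))
    return "".join(out)


def _build_rcl(rng, p1: str) -> str:
    loop = [
        "E",
        rng.choice(list("EKR")),
        "G",
        rng.choice(list("TS")),
        rng.choice(list(data.AMINO_ACIDS)),
    ]
    loop += [rng.choice(list("AGS")) for _ in range(4)]  # P12..P9
    loop += [rng.choice(list(data.AMINO_ACIDS)) for _ in range(7)]  # P8..P2
    loop.append(p1)
    loop += [rng.choice(list(data.AMINO_ACIDS)) for _ in range(4)]  # P1'..P4'
    return "".join(loop)


def _build_full_length(rng, p1: str, length_range, hinge: HingePattern) -> tuple:
    """A full-length scaffold whose planted hinge is the unique top-ranked
    candidate (rejection-sampled)."""
    lo, hi = length_range
    for _ in range(1000):
        L = int(rng.integers(lo, hi + 1))
        tail = int(rng.integers(10, 41))
        hinge_start = L - RCL_LENGTH - tail
        seq = list("M" + _rand_aa(rng, L - 1))
        nav_pos = int(rng.integers(1, max(2, L // 3 - len(data.NTERM_MOTIF))))
        seq[nav_pos : nav_pos + len(data.NTERM_MOTIF)] = data.NTERM_MOTIF
        sig = _sample_signature(rng, data.SERPIN_SIGNATURE_PATTERN)
        sig_lo = max(L // 3, hinge_start - 60)
        sig_pos = int(rng.integers(sig_lo, hinge_start - len(sig) + 1))
        seq[sig_pos : sig_pos + len(sig)] = sig
        seq[hinge_start : hinge_start + RCL_LENGTH] = _build_rcl(rng, p1)
        s = "".join(seq)
        cands = scan_hinge(s, hinge)
        if cands and cands[0].start == hinge_start:
            return s, hinge_start, nav_pos
    raise RuntimeError("could not build a clean full-length scaffold")


def _build_partial(rng, spec: SyntheticSpec, hinge: HingePattern) -> str:
    """A C-terminally truncated scaffold with no hinge candidate left."""
    for _ in range(1000):
        p1 = rng.choice(list(spec.p1_distribution), p=list(spec.p1_distribution.values()))
        s, hinge_start, _ = _build_full_length(rng, p1, spec.length_range, hinge)
        cut = int(rng.integers(spec.min_truncated_length, hinge_start + 1))
        trunc = s[:cut]
        if not scan_hinge(trunc, hinge):
            return trunc
    raise RuntimeError("could not build a clean truncated scaffold")


_CODON_CHOICES = {}
for codon, aa in CODON_TO_AA.items():
    _CODON_CHOICES.setdefault(aa, []).append(codon)
for aa in _CODON_CHOICES:
    _CODON_CHOICES[aa].sort()


def _back_translate(rng, protein: str) -> str:
    return "".join(rng.choice(_CODON_CHOICES[aa]) for aa in protein) + rng.choice(
        _CODON_CHOICES["*"]
    )


def _make_transcript(rng, ident: str, protein: str) -> NucleotideRecord:
    """Back-translate with flanking UTRs, rejecting UTR draws that create a
    competing >=100-codon ORF (so the planted CDS is the longest ORF)."""
    from .seqio import find_orfs

    cds = _back_translate(rng, protein)
    for _ in range(50):
        nt = list("ACGT")
        utr5 = "".join(rng.choice(nt, size=int(rng.integers(20, 80)))) + "TAA"
        utr3 = "".join(rng.choice(nt, size=int(rng.integers(20, 80))))
        rec = NucleotideRecord(ident, utr5 + cds + utr3)
        orfs = find_orfs(rec, min_codons=min(100, len(protein)), both_strands=True)
        if orfs and orfs[0].protein.sequence == protein:
            return rec
    raise RuntimeError(f"could not place clean UTRs for {ident}")


def _find_sequons(seq: str) -> list[int]:
    return [
        i + 1
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"
    ]


def generate_serpins(
    spec: SyntheticSpec, with_transcripts: bool = True
) -> tuple[list[ProteinRecord], list[NucleotideRecord], pd.DataFrame]:
    """Emit protein records, exact back-translated transcripts and the
    ground-truth table.  Byte-identical output for a given spec."""
    rng = np.random.default_rng(spec.seed)
    hinge = HingePattern.default()
    ids = [f"SYN{i + 1:03d}" for i in range(spec.n_total)]
    full_idx = set(rng.choice(spec.n_total, size=spec.n_full_length, replace=False).tolist())
    # sex categories over all transcripts
    cat = ["F"] * spec.sex_counts[0] + ["M"] * spec.sex_counts[1] + ["FM"] * spec.sex_counts[2]
    sexes = list(rng.permutation(cat))

    if spec.planted_p1 is not None:
        p1_iter = iter(spec.planted_p1)
    proteins, transcripts, rows = [], [], []
    used_rcls = set()
    for i, ident in enumerate(ids):
        if i in full_idx:
            p1 = (
                next(p1_iter)
                if spec.planted_p1 is not None
                else str(rng.choice(list(spec.p1_distribution), p=list(spec.p1_distribution.values())))
            )
            for _ in range(100):
                seq, hinge_start, nav_pos = _build_full_length(
                    rng, p1, spec.length_range, hinge
                )
                rcl_seq = seq[hinge_start : hinge_start + RCL_LENGTH]
                if rcl_seq not in used_rcls:
                    used_rcls.add(rcl_seq)
                    break
            sp = bool(rng.random() < spec.signal_peptide_fraction)
            rows.append(
                {
                    "id": ident,
                    "full_length": True,
                    "length": len(seq),
                    "hinge_start": hinge_start,
                    "rcl_seq": rcl_seq,
                    "p1_residue": p1,
                    "p1_class": classify_p1(p1)[0],
                    "sexes": sexes[i],
                    "sp_present": sp,
                    "sp_length": int(rng.integers(15, 31)) if sp else None,
                    "nglyc_sites": _find_sequons(seq),
                }
            )
        else:
            seq = _build_partial(rng, spec, hinge)
            rows.append(
                {
                    "id": ident,
                    "full_length": False,
                    "length": len(seq),
                    "hinge_start": None,
                    "rcl_seq": None,
                    "p1_residue": None,
                    "p1_class": None,
                    "sexes": sexes[i],
                    "sp_present": False,
                    "sp_length": None,
                    "nglyc_sites": _find_sequons(seq),
                }
            )
        proteins.append(ProteinRecord(ident, seq))
        if with_transcripts:
            transcripts.append(_make_transcript(rng, ident, seq))
    truth = pd.DataFrame(rows).set_index("id")
    return proteins, transcripts, truth


def external_annotations_from_truth(truth: pd.DataFrame, seed: int = 0) -> dict:
    """Emulated external-predictor calls (signal peptide, O-glycosylation)
    consistent with the truth table, for the ingestion pathway."""
    rng = np.random.default_rng(seed)
    out = {}
    for ident, row in truth.iterrows():
        if not row["full_length"]:
            continue
        n_og = int(rng.integers(0, 4))
        sites = sorted(rng.choice(np.arange(30, row["length"]), size=n_og, replace=False).tolist())
        out[ident] = ExternalAnnotation(
            bool(row["sp_present"]),
            int(row["sp_length"]) if row["sp_present"] else None,
            sites,
        )
    return out


def generate_expression(
    spec: SyntheticSpec,
    ids: Optional[Sequence[str]] = None,
    sexes: Optional[Sequence[str]] = None,
    lengths: Optional[Sequence[int]] = None,
):
    """Two-sex counts table plus the true partition.

    Expressed cells draw a zero-truncated negative binomial (var = μ + φμ²);
    non-expressed sexes get exact zeros, so the zero-TPM rule recovers the
    planted partition exactly.
    """
    from .expression import ExpressionTable, SexPartition

    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_total
    if ids is None:
        ids = [f"SYN{i + 1:03d}" for i in range(n)]
    if sexes is None:
        cat = (
            ["F"] * spec.sex_counts[0]
            + ["M"] * spec.sex_counts[1]
            + ["FM"] * spec.sex_counts[2]
        )
        sexes = list(rng.permutation(cat))
    if lengths is None:
        lengths = rng.integers(900, 1500, size=n)
    samples = [f"F{k + 1}" for k in range(spec.samples_per_sex)] + [
        f"M{k + 1}" for k in range(spec.samples_per_sex)
    ]
    sex_map = {s: s[0] for s in samples}
    r = 1.0 / spec.nb_dispersion
    p = r / (r + spec.nb_mean)

    def draw_positive(size):
        x = rng.negative_binomial(r, p, size=size)
        while (x == 0).any():
            z = x == 0
            x[z] = rng.negative_binomial(r, p, size=int(z.sum()))
        return x

    counts = np.zeros((n, len(samples)))
    for j, s in enumerate(samples):
        mask = np.array([sex_map[s] in sx for sx in sexes])
        counts[mask, j] = draw_positive(int(mask.sum()))
    table = ExpressionTable(
        pd.DataFrame(counts, index=list(ids), columns=samples),
        pd.Series(np.asarray(lengths, dtype=float), index=list(ids)),
        sex_map,
    )
    truth = SexPartition(
        female_only=frozenset(i for i, sx in zip(ids, sexes) if sx == "F"),
        male_only=frozenset(i for i, sx in zip(ids, sexes) if sx == "M"),
        shared=frozenset(i for i, sx in zip(ids, sexes) if sx == "FM"),
    )
    return table, truth


def generate_dataset(spec: SyntheticSpec, outdir) -> dict:
    """Full bundle: proteins.fasta, transcripts.fasta, counts.tsv,
    external_annotations.tsv, truth.json."""
    from .features import write_external_annotations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins, transcripts, truth = generate_serpins(spec)
    table, partition = generate_expression(
        spec,
        ids=list(truth.index),
        sexes=list(truth["sexes"]),
        lengths=[3 * (l + 1) for l in truth["length"]],
    )
    write_fasta(proteins, outdir / "proteins.fasta")
    write_fasta(transcripts, outdir / "transcripts.fasta")
    table.write_tsv(outdir / "counts.tsv")
    ext = external_annotations_from_truth(truth, seed=spec.seed + 2)
    write_external_annotations(ext, outdir / "external_annotations.tsv")
    truth_json = {
        "spec": {
            "n_total": spec.n_total,
            "n_full_length": spec.n_full_length,
            "sex_counts": list(spec.sex_counts),
            "seed": spec.seed,
        },
        "records": json.loads(truth.reset_index().to_json(orient="records")),
        "partition": partition.to_dict(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))
    return {
        "proteins": proteins,
        "transcripts": transcripts,
        "truth": truth,
        "expression": table,
        "partition": partition,
        "external": ext,
    }
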