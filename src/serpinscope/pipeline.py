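"""End-to-end pipeline: ORFs → screen → RCL → features → expression →
pairwise comparison and tree, emitting the report bundle.

Outputs (in ``outdir``): ``serpin_table.tsv`` (per-record annotation table),
``summary.json`` (counts, sex partition, P1 class spectrum),
``pairwise_identity.tsv`` / ``pairwise_similarity.tsv`` /
``pairwise_coverage.tsv``, ``tree.nwk`` (NJ, rooted as configured),
``logo_matrix.tsv`` and ``partition.json``.  Every input record appears
exactly once in the final table with a status.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import compare, expression, features, rcl, screen, seqio

log = logging.getLogger("serpinscope")


@dataclass
class PipelineConfig:
    proteins: Optional[str] = None  # protein FASTA (skips the ORF stage)
    transcripts: Optional[str] = None  # nucleotide FASTA
    counts: Optional[str] = None  # expression TSV
    sex_map: dict = field(default_factory=dict)  # sample -> F/M
    external_annotations: Optional[str] = None
    outdir: str = "serpinscope_out"
    min_codons: int = 100
    both_strands: bool = True
    screen: screen.ScreenConfig = field(default_factory=screen.ScreenConfig)
    rcl_window: int = 80
    outgroup: Optional[str] = None  # taxon for outgroup rooting; else midpoint
    align_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sc = raw.pop("screen", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.screen = screen.ScreenConfig(**sc)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    log.addHandler(handler)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    # --- stage 1: input / ORFs ------------------------------------------
    no_orf_ids = []
    if config.proteins:
        proteins = seqio.read_fasta(config.proteins, alphabet="aa")
        log.info("input: %d protein records", len(proteins))
    elif config.transcripts:
        transcripts = seqio.read_fasta(config.transcripts, alphabet="nt")
        proteins = []
        for t in transcripts:
            orfs = seqio.find_orfs(t, config.min_codons, config.both_strands)
            if orfs:
                best = orfs[0].protein
                proteins.append(
                    seqio.ProteinRecord(t.id, best.sequence, source=best.source)
                )
            else:
                no_orf_ids.append(t.id)
        log.info(
            "ORF stage: %d transcripts in, %d ORFs out, %d without ORF",
            len(transcripts), len(proteins), len(no_orf_ids),
        )
    else:
        raise ValueError("config must name a proteins or transcripts FASTA")

    # --- stage 2: expression (optional, feeds the RCL dedup) ------------
    summary: dict = {"n_input": len(proteins) + len(no_orf_ids)}
    tpm_sums, partition, tpm = None, None, None
    if config.counts:
        table = expression.ExpressionTable.read_tsv(config.counts, config.sex_map)
        tpm = expression.compute_tpm(table)
        tpm_sums = tpm.sum(axis=1).to_dict()
        partition = expression.partition_by_sex(tpm, table.sex_map)
        (outdir / "partition.json").write_text(json.dumps(partition.to_dict(), indent=1))
        expression.log2_matrix(tpm).to_csv(outdir / "log2_tpm.tsv", sep="\t")
        summary["sex_partition"] = partition.to_dict()["counts"]
        summary["sex_percentages"] = partition.percentages()
        log.info(
            "expression stage: %d transcripts, %d expressed",
            len(tpm), partition.total_expressed,
        )

    # --- stage 3: screen + RCL ------------------------------------------
    hinge = rcl.HingePattern.default()
    records = screen.screen_proteins(
        proteins, config.screen, rcl_config=hinge, tpm_sums=tpm_sums
    )
    full = [r for r in records if r.completeness.is_full]
    log.info("screen stage: %d records, %d full-length", len(records), len(full))

    # --- stage 4: features ----------------------------------------------
    external = (
        features.ingest_external_annotations(config.external_annotations)
        if config.external_annotations
        else {}
    )
    for r in records:
        r.features = features.annotate_features(r.protein, external)
    sex_lookup = {}
    if partition is not None:
        for i in partition.female_only:
            sex_lookup[i] = "F"
        for i in partition.male_only:
            sex_lookup[i] = "M"
        for i in partition.shared:
            sex_lookup[i] = "M/F"

    _write_serpin_table(records, no_orf_ids, sex_lookup, outdir / "serpin_table.tsv")

    # --- stage 5: P1 spectrum + logo ------------------------------------
    anns = [r.rcl for r in full]
    if anns:
        summary["p1"] = rcl.p1_summary(anns)
        if len(anns) >= 2:
            rcl.logo_matrix(anns).to_csv(outdir / "logo_matrix.tsv", sep="\t")
            rcl.hinge_conservation_report(anns, hinge).to_csv(
                outdir / "hinge_conservation.tsv", sep="\t"
            )
    summary.update(
        n_full=len(full),
        n_partial=sum(1 for r in records if not r.completeness.is_full),
        n_no_orf=len(no_orf_ids),
    )

    # --- stage 6: compare + tree ----------------------------------------
    kw = dict(
        matrix=config.align_matrix,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
    )
    if len(full) >= 2:
        mats = compare.pairwise_report([r.protein for r in full], **kw)
        for name, df in mats.items():
            df.to_csv(outdir / f"pairwise_{name}.tsv", sep="\t")
    if len(full) >= 3:
        dm = compare.distance_matrix([r.protein for r in full], **kw)
        tree = compare.nj_tree(dm)
        rooted = (
            compare.root_outgroup(tree, config.outgroup)
            if config.outgroup
            else compare.root_midpoint(tree)
        )
        compare.write_newick(rooted, outdir / "tree.nwk")
        log.info("tree stage: %d taxa", len(dm.ids))

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return {"summary": summary, "records": records, "partition": partition}


def _write_serpin_table(records, no_orf_ids, sex_lookup, path) -> None:
    """Per-record annotation table in the published table's column layout
    (1-based coordinates in report output)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "id", "status", "expression_sexes", "orf_bp", "length_aa",
                "signal_peptide", "mw_da", "nglyc_sites", "oglyc_sites",
                "p1_residue", "p1_class", "predicted_target", "rcl_seq",
                "reasons",
            ]
        )
        for r in records:
            f, a = r.features, r.rcl
            sp = "—"
            if f and f.signal_peptide is not None:
                sp = f"SP ({f.signal_peptide[1]})" if f.signal_peptide[0] else "NSP"
            orf_bp = ""
            if r.protein.source:
                orf_bp = r.protein.source[3] - r.protein.source[2]
            w.writerow(
                [
                    r.id,
                    r.completeness.status,
                    sex_lookup.get(r.id, ""),
                    orf_bp,
                    len(r.protein.sequence),
                    sp,
                    f.molecular_weight if f else "",
                    ";".join(f"N_{p}" for p in f.nglyc_sites) if f else "",
                    ";".join(str(p) for p in (f.oglyc_sites or [])) if f else "",
                    a.p1_residue if a else "",
                    a.p1_class if a else "",
                    a.predicted_target if a else "",
                    a.rcl_seq if a else "",
                    ";".join(k for k, v in r.completeness.reasons.items() if not v),
                ]
            )
        for ident in no_orf_ids:
            w.writerow([ident, "no_orf"] + [""] * 12)
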