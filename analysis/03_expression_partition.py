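#!/usr/bin/env python
"""Abundance metrics and the zero-TPM sex partition on the simulated
two-sex counts table.

Finding: the zero-TPM presence rule recovers the planted 4/15/91 structure
exactly — 106 transcripts expressed in males vs 95 in females, 13.64%
male-exclusive and 3.64% female-exclusive.
"""

import json
from pathlib import Path

from serpinscope.expression import (
    ExpressionTable,
    compute_tpm,
    log2_matrix,
    partition_by_sex,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "synthetic"
SEX_MAP = {"F1": "F", "F2": "F", "M1": "M", "M2": "M"}

table = ExpressionTable.read_tsv(DATA / "counts.tsv", SEX_MAP)
tpm = compute_tpm(table)
part = partition_by_sex(tpm, SEX_MAP)
log2_matrix(tpm).round(3).to_csv(ROOT / "results" / "03_log2_tpm.tsv", sep="\t")
(ROOT / "results" / "03_partition.json").write_text(
    json.dumps(part.to_dict()["counts"] | part.percentages(), indent=1) + "\n"
)
c = part.to_dict()["counts"]
print(f"male-expressed {c['expressed_in_male']}, female-expressed "
      f"{c['expressed_in_female']}; exclusives {part.percentages()}")
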