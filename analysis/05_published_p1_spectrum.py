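#!/usr/bin/env python
"""Classify the published P1 residues of the 17 full-length H. dromedarii
salivary serpins (HDS12–HDS35).

Finding: 8/17 polar basic (47.06%), 7/17 polar uncharged (41.18%), 2/17
hydrophobic (11.76%); 8 distinct residues.  Basic-P1 serpins are predicted
to target trypsin/thrombin-like (coagulation) proteases, uncharged-P1 ones
elastase/chymotrypsin-like proteases.
"""

import json
from pathlib import Path

from serpinscope import data
from serpinscope.rcl import classify_p1, p1_summary

ROOT = Path(__file__).resolve().parents[1]

rows = {
    ident: {"p1": res, "class": classify_p1(res)[0], "target": classify_p1(res)[1]}
    for ident, res in data.HDS_P1_RESIDUES.items()
}
summary = p1_summary(list(data.HDS_P1_RESIDUES.values()))
out = {"per_serpin": rows, "summary": summary}
(ROOT / "results" / "05_published_p1_summary.json").write_text(
    json.dumps(out, indent=1) + "\n"
)
print(json.dumps(summary, indent=1))
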