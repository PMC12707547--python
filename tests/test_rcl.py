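"""RCL annotation: hinge scan vs brute force, P17→P4′ geometry, the P1
chemistry table, summary percentages and the conservation/logo statistics."""

import numpy as np
import pytest
from scipy.stats import entropy

from serpinscope import data
from serpinscope.rcl import (
    RCL_LENGTH,
    HingePattern,
    RCLAnnotation,
    annotate_rcl,
    classify_p1,
    extract_rcl,
    hinge_conservation_report,
    logo_matrix,
    p1_summary,
    scan_hinge,
)

AA = data.AMINO_ACIDS
HDS_P1 = list(data.HDS_P1_RESIDUES.values())


# ---------------------------------------------------------------- hinge

def test_scan_hinge_conformant_construction():
    seq = "L" * 40 + "EEGTEAAAA" + "WQNDFHI" + "K" + "MPVC" + "LLLL"
    cands = scan_hinge(seq)
    assert cands and cands[0].start == 40 and cands[0].mismatched_subsites == []


def test_scan_hinge_allows_pattern_alternatives():
    # P16 K is allowed ([E/K/R]); P12-P9 drawn from {A,G,S}
    seq = "L" * 40 + "EKGTAASGS" + "WQNDFHI" + "R" + "MPVC" + "LLLL"
    (best, *_) = scan_hinge(seq)
    assert best.start == 40 and best.score == 8


def test_scan_hinge_noncritical_budget_and_critical_veto():
    base = "L" * 40
    tail = "WQNDFHI" + "K" + "MPVC"
    # two noncritical deviations (P16, P9) pass; critical P15 deviation vetoes
    assert scan_hinge(base + "EWGTEAAAW" + tail)
    assert not scan_hinge(base + "EEATEAAAA" + tail)
    # three noncritical deviations exceed the budget
    assert not scan_hinge(base + "EWGTEAWWA" + tail)


def _oracle_scan(seq, window=80):
    pat = HingePattern.default()
    out = []
    lo = max(0, len(seq) - window)
    for s in range(lo, len(seq) - RCL_LENGTH + 1):
        w = seq[s : s + 9]
        ok, score, mm = True, 0, 0
        for i, sub in enumerate(pat.subsites):
            if sub.allowed is None:
                continue
            if w[i] in sub.allowed:
                score += 1
            elif sub.critical:
                ok = False
                break
            else:
                mm += 1
        if ok and mm <= pat.max_noncritical_mismatches:
            out.append((s, score))
    return sorted(out, key=lambda t: (-t[1], -t[0]))


def test_scan_hinge_matches_bruteforce(rng):
    for _ in range(200):
        seq = "".join(rng.choice(list(AA), size=int(rng.integers(21, 120))))
        got = [(c.start, c.score) for c in scan_hinge(seq)]
        assert got == _oracle_scan(seq)


def test_scan_hinge_ignores_upstream_extension(rng):
    """Prepending residues upstream of the scan window changes nothing."""
    seq = "".join(rng.choice(list(AA), size=100))
    ref = [(c.start, c.score) for c in scan_hinge(seq, window=80)]
    ext = "W" * 37 + seq
    got = [(c.start - 37, c.score) for c in scan_hinge(ext, window=80)]
    assert got == ref


# -------------------------------------------------------------- extract

def test_extract_whole_protein_and_arithmetic():
    ann = extract_rcl("E" * 21, 0)
    assert ann.rcl_seq == "E" * 21 and ann.p1_index == 16
    long = "A" * 371
    ann = extract_rcl(long, 350)
    assert (ann.hinge_start, ann.p1_index) == (350, 366)


def test_extract_truncated_raises():
    with pytest.raises(ValueError, match="truncated"):
        extract_rcl("A" * 30, 15)


def test_extraction_recovers_planted_rcl(hds_dataset):
    _, proteins, truth = hds_dataset
    full = truth[truth.full_length]
    for ident, row in full.iterrows():
        prot = next(p for p in proteins if p.id == ident)
        ann = annotate_rcl(prot)
        assert ann is not None
        assert ann.rcl_seq == row["rcl_seq"]
        assert ann.p1_residue == row["p1_residue"]
        assert ann.p1_index - ann.hinge_start == 16
        assert len(ann.rcl_seq) == RCL_LENGTH
        assert classify_p1(ann.p1_residue)[0] == row["p1_class"]


# ------------------------------------------------------------ classify_p1

@pytest.mark.parametrize(
    "residue,cls,target",
    [
        ("K", "polar basic", "Trypsin- or thrombin-like proteases"),
        ("Y", "polar uncharged", "Elastase- or chymotrypsin-like proteases"),
        ("I", "hydrophobic", "Not specified"),
        ("D", "polar acidic", "Not specified"),
    ],
)
def test_classify_p1_examples(residue, cls, target):
    assert classify_p1(residue) == (cls, target)


def test_p1_class_table_total_and_disjoint():
    for aa in AA:
        matches = [c for c, members in data.P1_CLASSES.items() if aa in members]
        assert len(matches) == 1
    with pytest.raises(ValueError):
        classify_p1("X")


# ------------------------------------------------------------ p1_summary

def test_p1_summary_published_residues():
    """The 17 published P1 residues give the reported class spectrum."""
    res = p1_summary(HDS_P1)
    assert res["percentages"]["polar basic"] == 47.06
    assert res["percentages"]["polar uncharged"] == 41.18
    assert res["percentages"]["hydrophobic"] == 11.76
    assert res["distinct_residues"] == 8


def test_p1_summary_single_and_empty():
    res = p1_summary(["K"])
    assert res["percentages"]["polar basic"] == 100.0
    assert res["distinct_residues"] == 1
    with pytest.raises(ValueError):
        p1_summary([])


def test_p1_summary_rounding_drift_bounded(rng):
    for _ in range(200):
        n = int(rng.integers(1, 40))
        res = p1_summary(rng.choice(list(AA), size=n))
        assert abs(sum(res["percentages"].values()) - 100) <= 0.03


# ---------------------------------------------------- conservation / logo

def _ann(seq):
    return RCLAnnotation(0, seq, 16, seq[16], *classify_p1(seq[16]))


def test_conservation_identical_loops():
    loops = [_ann("EEGTEAAAA" + "WQNDFHI" + "K" + "MPVC")] * 17
    rep = hinge_conservation_report(loops)
    assert rep["conserved"].all()


def test_conservation_flags_deviant_subsite():
    a = "EEGTEAAAA" + "WQNDFHI" + "K" + "MPVC"
    b = "EKGTEAAAA" + "WQNDFHI" + "K" + "MPVC"  # deviates at P16 (still allowed)
    rep = hinge_conservation_report([_ann(a), _ann(b)])
    assert not rep.loc["P16", "conserved"]
    assert rep.loc["P16", "pattern_compliance"] == 1.0
    assert rep.loc["P17", "conserved"]


def test_conservation_frequencies_match_column_counts(rng):
    loops = ["".join(rng.choice(list(AA), size=21)) for _ in range(9)]
    rep = hinge_conservation_report([_ann(s) for s in loops])
    for i, name in enumerate(data.RCL_SUBSITES):
        col = [s[i] for s in loops]
        for res, f in rep.loc[name, "frequencies"].items():
            assert f == pytest.approx(col.count(res) / 9)


def test_logo_matrix_extremes():
    conserved = logo_matrix(["A" * 21] * 5)
    assert conserved.loc["P17", "A"] == pytest.approx(np.log2(20))
    uniform = logo_matrix([aa * 21 for aa in AA])
    assert np.allclose(uniform.values, 0.0)


def test_logo_matrix_matches_independent_entropy(rng):
    loops = ["".join(rng.choice(list(AA), size=21)) for _ in range(12)]
    mat = logo_matrix(loops)
    for i in range(21):
        col = [s[i] for s in loops]
        freqs = np.array([col.count(a) / len(col) for a in AA])
        ic = np.log2(20) - entropy(freqs[freqs > 0], base=2)
        assert np.allclose(mat.iloc[i].values, freqs * ic)


def test_logo_matrix_input_validation():
    with pytest.raises(ValueError):
        logo_matrix(["A" * 21])
    with pytest.raises(ValueError):
        logo_matrix(["A" * 21, "A" * 20])
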