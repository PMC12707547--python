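# Methods

## Scope and model

`serpinscope` reimplements, as a tested pipeline, the rule-based procedure
used to catalogue serpins in a two-sex tick sialotranscriptome: ORF
discovery, serpin signature/motif screening, reactive-center-loop (RCL)
annotation with P1-site classification, completeness calls, sex-differential
expression partitioning, pairwise comparison and distance trees. Homology
annotation (BLASTp against protein databases), neural-network predictors
(signal peptides, O-glycosylation — ingested as external calls instead),
maximum-likelihood/JTT phylogenetics and figure rendering are out of scope.

## ORF discovery and translation

Six-frame scan for maximal ATG→stop spans: within each frame, the first ATG
after a stop opens the ORF that runs to the next stop (or to the sequence
end, flagged partial-3′). An ATG start is required because the full-length
rule demands an initiator Met. Default `min_codons=100`: serpins are
~350–450 aa, so 100 suppresses spurious short ORFs without losing
meaningful partials. Internal coordinates are 0-based half-open;
reverse-strand ORFs are mapped to forward-strand coordinates; report output
is 1-based inclusive. Translation uses the standard genetic code (table 1);
any codon containing N renders X; a trailing partial codon is dropped with
a warning.

## Screening

The serpin signature is matched with a PROSITE-syntax compiler (residues,
`x`, `[..]`, `{..}`, `(n)`/`(n,m)`, `<`/`>`); the pattern string itself is
configuration data taken from the PROSITE release, so a newer release
string can be substituted without code changes. The matcher reports one
greedy span per feasible start (overlapped-scan semantics). The N-terminal
consensus motif NAVYFKG is searched with a Hamming tolerance of ≤2
mismatches restricted to the N-terminal half — it is a consensus, and exact
matching would reject natural variants.

Completeness: a sequence is full-length iff it has an initiator Met, length
within [350, 450] (configurable; the published set itself contains a 336-aa
entry flagged by this rule — the discrepancy is surfaced in a warning, not
silently resolved), a hinge-conforming RCL, and an RCL unique within the
run. Identical 21-mer RCLs collapse to one representative — highest summed
TPM, ties broken lexicographically by id — because the source procedure
keeps one sequence per distinct RCL without stating its rule; this
deterministic choice is ours. Sequences without an RCL are tagged
"truncated C-terminus".

## RCL annotation

Hinge constraints (P17 [E], P16 [E/K/R], P15 [G], P14 [T/S], P13 free,
P12–P9 [A/G/S]) are evaluated over the C-terminal 80 residues only: RCLs
sit ~30–50 residues from the terminus, so 80 is safely generous while
keeping N-terminal hinge-like noise out. P17/P15/P14/P12 are critical;
up to 2 mismatches are tolerated at P16/P11/P10/P9, since retained natural
serpins deviate at P16 or P9. Candidates are ranked by (score desc, start
desc): among equal scores the most C-terminal wins, the RCL being the
C-terminal-most hinge-like element. The annotation window is
protein[hinge : hinge+21] (P17→P4′), with P1 at offset 16 — "17 residues
from the hinge start" counting P17 as the first.

P1 classes are a total, disjoint table over the 20 standard residues:
polar basic {K,R,H}, polar uncharged {S,T,C,Y,N,Q}, polar acidic {D,E},
hydrophobic {A,V,I,L,M,F,W,P,G}. G and P are grouped with the hydrophobics
purely for totality — neither occurs at P1 in the published set — and the
choice is visible in `data.P1_CLASSES`. Summary percentages are rounded
half-up to 2 decimals (8/17 → 47.06, 7/17 → 41.18, 2/17 → 11.76).

The logo matrix reports true information content per column,
IC = log2(20) − H (bits), without small-sample correction; a fully
conserved column scores log2(20) ≈ 4.32 bits and is not rescaled to 4.
The conservation report flags a subsite "conserved" on unanimity and
separately reports the fraction of loops satisfying the hinge constraint.

## Features

Molecular weight = Σ average residue masses + 18.01524 Da (one water),
reported to 2 decimals; average rather than monoisotopic masses match the
usual web calculator convention. N-glycosylation reporting is the canonical
sequon N-X-S/T with X ≠ P — a deterministic necessary condition, labelled
"potential sequons" rather than predictions. Signal peptides and
O-glycosylation are ingested from an external predictor TSV
(`id  SP|NSP  sp_length  pos;pos;...`); missing ids simply remain
unannotated.

## Expression

TPM_i = 10⁶·(c_i/l_i)/Σ_j(c_j/l_j); FPKM_i = 10⁹·c_i/(l_i·N);
IsoPct_i = 100·TPM_i/ΣTPM over the gene (identity gene map by default).
Presence is strictly TPM > 0 — no epsilon — and samples within a sex are
OR-combined, mirroring pooled feeding-stage sampling. The heatmap matrix is
log2(TPM + 1); the pseudocount of 1 maps true zeros to 0 and is
configurable.

## Comparison and trees

Pairwise statistics come from optimal affine-gap global alignment
(BLOSUM62, gap open 10, extend 0.5 — conventional defaults, configurable;
the original used a multiple aligner at "standard settings" without stating
parameters). Identity = identical columns / alignment length; similarity =
columns with positive substitution score / alignment length (no universal
definition exists — this convention is stated wherever reported);
coverage = columns aligned in both / shorter input length. Distances are
p-distances (1 − identity/100); JTT maximum-likelihood distances are
deliberately out of scope. Trees are Saitou–Nei neighbor joining with the
Q-criterion; a negative limb estimate is clamped to zero with the deficit
moved to its sibling so the joined pair's distance is conserved; children
are sorted by smallest descendant taxon, making topology independent of
input order. Midpoint rooting bisects the longest tip-to-tip path (the
2-leaf degenerate case is handled explicitly); outgroup rooting splits the
outgroup's pendant edge at half length.

## Synthetic data

The generator emulates the study's data structure, not real serpin
composition: backgrounds are uniform over the 20 standard residues (real
composition is irrelevant to rule recovery and would complicate the truth
guarantees). Full-length scaffolds (uniform length in [350, 450], initiator
M) carry NAVYFKG in the N-terminal third, a signature-conforming 11-mer
upstream of the hinge, and a fully hinge-conforming RCL placed so 21+K
residues remain (K uniform in [10, 40]) with P1 from a configurable
distribution — the default planted spectrum copies the published 17-residue
list (K×4, R×4, C×3, Y×2, I, L, S, T). Partials are the same scaffolds cut
uniformly upstream of the hinge (minimum 150 aa so ORF discovery retains
them). Transcripts are exact back-translations (random synonymous codons,
stop codon, 20–80 nt UTRs with an in-frame stop sealing the 5′ end).

Two guarantees make planted truth unambiguous for every seed, which the
recovery tests rely on: (i) scaffolds are rejection-sampled until the
planted hinge is the unique top-ranked candidate and truncated sequences
retain no hinge match in the scan window; (ii) expressed count cells draw a
zero-truncated negative binomial (mean 200, dispersion 0.5 — over-dispersed,
RNA-seq-like, configurable), non-expressed cells are exact zeros, so the
zero-TPM rule recovers the planted 4/15/91 sex structure exactly. Two
samples per sex emulate pooled stages.

What passing these tests shows: the rules are implemented as specified and
recover structure they are designed to detect. What they do not show:
performance on real transcripts — real serpins have biased composition,
hinge variants beyond the mismatch budget, sequencing artifacts and
isoforms; the published molecular weights and pairwise identities cannot be
reproduced without the unpublished sequences and are not used as test
vectors.

## Problem sizes and determinism

The shipped preset is the study-sized problem (110 sequences, 17
full-length, 4-sample expression table), which runs in seconds; oracle
tests use 50–200 random instances per property and exhaustive enumeration
only where the space is tiny (all codons; alignments of ≤6-mers). All
randomness flows through explicit seeds; identical configuration yields
byte-identical output bundles.

## Known limitations

- The hinge consensus and mismatch budget are tuned to tick serpins;
  non-inhibitory serpins with degenerate hinges will be called partial.
- P1-based target prediction is a coarse heuristic; acidic and hydrophobic
  P1 map to "Not specified".
- The RCL-uniqueness dedup rule (TPM-ranked) is a reconstruction of an
  unstated manual step.
- Six-frame ORF discovery has no coding-likelihood model; on real data it
  reports more candidates than a Markov-model tool would.
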