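"""Reference data for serpin screening and annotation.

Everything here is configurable at run time (config file / function
arguments); this module only provides the defaults.
"""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Serpin signature (PROSITE release pattern PS00284), shipped as data so a
# newer release string can be dropped in via config without touching code.
SERPIN_SIGNATURE_PATTERN = (
    "[LIVMFY]-x-[LIVMFYAC]-[DNQ]-[RKHQS]-[PST]-F-[LIVMFY]-[LIVMFYC]-x-[LIVMFAH]"
)

# Consensus serpin N-terminal motif (the "S3a" helix region).
NTERM_MOTIF = "NAVYFKG"

# P1 residue chemistry classes (Schechter–Berger P1 subsite).  The table is
# total and disjoint over the 20 standard residues; G and P are grouped with
# the hydrophobics so that every residue has a class.
P1_CLASSES = {
    "polar basic": frozenset("KRH"),
    "polar uncharged": frozenset("STCYNQ"),
    "polar acidic": frozenset("DE"),
    "hydrophobic": frozenset("AVILMFWPG"),
}

# Predicted target protease family by P1 chemistry: basic P1 residues point
# at trypsin/thrombin-like proteases (coagulation cascade), uncharged ones at
# elastase/chymotrypsin-like proteases.
P1_TARGETS = {
    "polar basic": "Trypsin- or thrombin-like proteases",
    "polar uncharged": "Elastase- or chymotrypsin-like proteases",
    "polar acidic": "Not specified",
    "hydrophobic": "Not specified",
}

# P1 residues of the 17 full-length H. dromedarii salivary serpins (HDS),
# from the study's published annotation table; used as a worked example and
# as the default planted-P1 list for the synthetic "hds" preset.
HDS_P1_RESIDUES = {
    "HDS12": "K",
    "HDS13": "C",
    "HDS15": "C",
    "HDS17": "K",
    "HDS18": "K",
    "HDS19": "C",
    "HDS20": "R",
    "HDS21": "I",
    "HDS22": "L",
    "HDS26": "S",
    "HDS27": "R",
    "HDS28": "R",
    "HDS30": "Y",
    "HDS31": "Y",
    "HDS32": "T",
    "HDS34": "R",
    "HDS35": "K",
}

# Subsite labels for the 21-residue reactive center loop, P17..P1 then
# P1'..P4' (primed residues are C-terminal of the scissile bond).
RCL_SUBSITES = [f"P{i}" for i in range(17, 0, -1)] + ["P1'", "P2'", "P3'", "P4'"]
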