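"""Reference data for the FcµR Ig-like domain analyses.

The two domain sequences below are the ones used to build the human and mouse
FcµR Ig-like domain homology models (GenBank protein records NP_005440 and
NP_081252).  They are stored exactly as printed, including the embedded
hyphens, which are typesetting artifacts removed by the parser: after
stripping, the human domain is 108 residues and the mouse domain 107,
consistent with the single-residue deletion in the rodent CDR2.

Numbering throughout the package is full-length (1-based from the initiator
methionine of the receptor).  The printed domain fragment starts at residue
17, which is recovered by anchoring the unique ``KVEG`` motif at positions
24-27.
"""

from __future__ import annotations

HUMAN_DOMAIN_RAW = (
    "LRILPEVKVEGELGGSVTIKCPLPEMHVRIYLCREMAGSGTCGTVVSTTNFIKAEYKGRVTLKQYPRK"
    "-NLFLVEVTQLTESDSGVYACGAGMNTDRGKTQKVTLNVHS"
)

MOUSE_DOMAIN_RAW = (
    "LRVLPEVQLNVEWGGSIIIECPLPQLHVRMYLCRQMAKPGICSTVVSN"
    "-TFVKKEYERRVTLTPCLDKKLFLVEMTQLTENDDGIYACGVGMKTDKGKTQKITLNVHN"
)

HUMAN_DOMAIN_ID = "huFcmuR_Ig_domain"
MOUSE_DOMAIN_ID = "moFcmuR_Ig_domain"

#: Anchor used to place the printed fragment in full-length numbering.
ANCHOR_MOTIF = "KVEG"
ANCHOR_POSITION = 24

#: Intra-chain disulfide bridges of the human domain (full-length numbering).
HUMAN_DISULFIDES = ((37, 104), (49, 58))

#: Conserved salt bridge of the Ig-like domain.
HUMAN_SALT_BRIDGE = (75, 98)

#: The eight replacement mutants assayed against wild type, written in the
#: compact from/positions/to notation (``-`` denotes a deletion).
MUTANT_LABELS = (
    "KVEG24-27QLNV",
    "E41Q",
    "M42L",
    "EM41-42QL",
    "N66-",
    "KQYPR79-83TPCLD",
    "Y81C",
    "N109K",
)

#: Predicted melting temperatures (K) for the Ig-like domains, as reported:
#: per-construct mean over five 1 µs heating repeats with its standard
#: deviation, under the two melting criteria.  These come from µs-scale MD
#: and are inputs for the summary-statistic comparisons, not quantities this
#: package recomputes.
TABLE1 = {
    "contacts_q80": {
        "huWT": {"mean": 336.0, "sd": 5.7, "n": 5},
        "24-27": {"mean": 342.0, "sd": 12.2, "n": 5},
        "N66-": {"mean": 330.0, "sd": 11.9, "n": 5},
        "79-83": {"mean": 336.0, "sd": 5.1, "n": 5},
        "N109K": {"mean": 333.0, "sd": 9.6, "n": 5},
        "moWT": {"mean": 327.0, "sd": 5.8, "n": 5},
    },
    "rg_gt_14": {
        "huWT": {"mean": 344.0, "sd": 5.9, "n": 5},
        "24-27": {"mean": 336.0, "sd": 11.5, "n": 5},
        "N66-": {"mean": 342.0, "sd": 8.6, "n": 5},
        "79-83": {"mean": 351.0, "sd": 4.9, "n": 5},
        "N109K": {"mean": 343.0, "sd": 9.0, "n": 5},
        "moWT": {"mean": 329.0, "sd": 8.7, "n": 5},
    },
}

#: Docking-score / affinity anchors quoted for the score-to-logKa relation:
#: the receptor/ligand poses scored 780 and 924, the positive-control pose
#: 1110, and the test-case affinities span Ka = 1e4 .. 1e10 M^-1 with the
#: receptor interaction near 1e6 M^-1.
DOCKING_SCORES = {"chain_C_pose": 780.0, "chain_D_pose": 924.0, "pIgR_control": 1110.0}
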