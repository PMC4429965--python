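"""Published reference data for the AuFaeA disulfide-engineering case study.

AuFaeA is the type A feruloyl esterase (EC 3.1.1.73) from *Aspergillus
usamii*; its thermostabilization by an engineered A126C-N152C disulfide is
the worked example this package reproduces.  The constants below are the
study's printed inputs — the consensus candidate list, the native-bridge and
catalytic-triad annotations, the mutagenesis primers, and the assay
parameters — in the enzyme's own author numbering.
"""

from __future__ import annotations

from .assay_calc import StandardCurve
from .mutagenesis import PrimerPair
from .ssbond_design import CandidatePair, TriadSpec

# native disulfide bridges of the wild-type enzyme
NATIVE_BRIDGES: list[tuple[str, str]] = [
    ("C29", "C258"),
    ("C91", "C94"),
    ("C227", "C234"),
]

# serine-hydrolase catalytic triad and its exclusion radius
TRIAD = TriadSpec(labels=("S133", "H247", "D194"), radius=6.0)

# the 11 residue pairs proposed by both geometric predictors
CONSENSUS_PAIRS: list[tuple[str, str]] = [
    ("C91", "C94"),
    ("C227", "C234"),
    ("D93", "A167"),
    ("C94", "F168"),
    ("W214", "C234"),
    ("H97", "Y100"),
    ("A24", "R66"),
    ("Y80", "P200"),
    ("F176", "Y186"),
    ("Y122", "Y125"),
    ("A126", "N152"),
]

# H97-Y100 is the pair reported within 6 Å of the catalytic triad
TRIAD_PROXIMAL: set[str] = {"H97"}

# the five pairs that survive the rejection rules
KEPT_PAIRS: list[tuple[str, str]] = [
    ("A24", "R66"),
    ("Y80", "P200"),
    ("F176", "Y186"),
    ("Y122", "Y125"),
    ("A126", "N152"),
]


def consensus_candidates() -> list[CandidatePair]:
    """The 11 consensus pairs as label-only :class:`CandidatePair` objects."""
    return [CandidatePair.from_labels(a, b) for a, b in CONSENSUS_PAIRS]


# QuikChange mutagenesis primers (forward, reverse, both 5'→3')
PRIMERS: dict[str, PrimerPair] = {
    "A126C": PrimerPair(name="A126C",
                        forward="ATCCGGACTATTGCCTTACCGTGACA",
                        reverse="TGTCACGGTAAGGCAATAGTCCGGAT"),
    "N152C": PrimerPair(name="N152C",
                        forward="GCGACATATGACTGCGTCCGTCTGTAC",
                        reverse="GTACAGACGGACGCAGTCATATGTCGC"),
    "C29T": PrimerPair(name="C29T",
                       forward="ACGCCGACCTAACTAATATTCCATCGACT",
                       reverse="AGTCGATGGAATATTAGTTAGGTCGGCGT"),
    "C91T": PrimerPair(name="C91T",
                       forward="ACTCTACCTCAAACTAACGATTGCG",
                       reverse="CGCAATCGTTAGTTTGAGGTAGAGT"),
    "C234T": PrimerPair(name="C234T",
                        forward="ACTGGGGATGAAGTACAGACTTGTGAGGCA",
                        reverse="TGCCTCACAAGTCTGTACTTCATCCCCAGT"),
}

PRIMER_SIZES_BP: dict[str, int] = {
    "A126C": 26, "N152C": 27, "C29T": 29, "C91T": 25, "C234T": 30,
}

# Ellman calibration: OD410 = 0.8727·[Cys, mM] + 1.3972
STANDARD_CURVE = StandardCurve(slope=0.8727, intercept=1.3972)

# thiol titration conditions and readings
PROTEIN_MG_PER_ML = 2.0
MW_KDA = 36.0  # apparent molecular weight on SDS-PAGE
OD410_WILD = 1.452
OD410_VARIANT = 1.437
TOTAL_CYS_WILD = 7  # 6 bridge cysteines + the free C235
TOTAL_CYS_VARIANT = 9  # + C126, C152

# Michaelis-Menten parameters (substrate: p-nitrophenyl ferulate)
KM_WILD_MM = 3.62
VMAX_WILD = 225.0  # U/mg
KCAT_WILD = 8093.0  # min^-1
KM_VARIANT_MM = 5.98
VMAX_VARIANT = 356.0
KCAT_VARIANT = 12805.0

# thermal inactivation half-lives (min)
HALF_LIFE_WILD = {50: 50.0, 55: 15.0, 60: 4.0}
HALF_LIFE_VARIANT = {55: 188.0, 60: 40.0}

TEMPERATURE_OPTIMUM_WILD = 45.0  # °C
TEMPERATURE_OPTIMUM_VARIANT = 51.0  # °C
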