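"""In-silico point mutation and QuikChange-style primer design/validation.

Cysteine-pair variants (e.g. A126C-N152C) are built by renaming residues and
stubbing side chains; whole-plasmid mutagenesis primers are fully
complementary forward/reverse oligos carrying the mutant codon near their
center.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from ._geometry import CB_SG_BOND, place_sgamma
from .structure_io import Atom, Residue, Structure

__all__ = [
    "Mutation",
    "PrimerPair",
    "PrimerParams",
    "ValidationReport",
    "mutate_sequence",
    "mutate_structure",
    "reverse_complement",
    "design_quikchange_primers",
    "validate_primer_pair",
]

_DNA_RE = re.compile(r"^[ACGTN]*$")
_BACKBONE = ("N", "CA", "C", "O", "CB")


@dataclass(frozen=True)
class Mutation:
    """A single substitution in author numbering, e.g. A126C."""

    position: int
    wild: str  # 1-letter
    new: str  # 1-letter
    chain: str = "A"

    def __post_init__(self):
        if self.wild == self.new:
            raise ValueError("wild-type and mutant residues are identical")
        for aa in (self.wild, self.new):
            if len(aa) != 1 or not aa.isalpha():
                raise ValueError(f"bad amino-acid code {aa!r}")

    @property
    def label(self) -> str:
        return f"{self.wild}{self.position}{self.new}"

    @classmethod
    def from_label(cls, label: str, chain: str = "A") -> "Mutation":
        m = re.match(r"^([A-Za-z])(\d+)([A-Za-z])$", label.strip())
        if not m:
            raise ValueError(f"cannot parse mutation label {label!r}")
        return cls(position=int(m.group(2)), wild=m.group(1).upper(),
                   new=m.group(3).upper(), chain=chain)


@dataclass
class PrimerPair:
    """A complementary QuikChange primer pair (both strands 5'→3')."""

    name: str
    forward: str
    reverse: str
    codon_start: int | None = None  # 0-based offset of the mutant codon in forward
    tm: float | None = None  # °C

    def __post_init__(self):
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()

    @property
    def length(self) -> int:
        return len(self.forward)


@dataclass
class PrimerParams:
    """Design constraints: length bounds, Tm floor, codon-centering tolerance."""

    min_length: int = 25
    max_length: int = 45
    min_tm: float = 78.0
    center_tolerance: int = 3  # nt


@dataclass
class ValidationReport:
    checks: dict = field(default_factory=dict)  # name -> True/False/None (not run)
    messages: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(v is not False for v in self.checks.values())


# --------------------------------------------------------------------------
# sequence / structure mutation


def mutate_sequence(sequence: str, mutations: Iterable[Mutation]) -> str:
    """Apply substitutions to a 1-based protein sequence.

    Refuses if the observed residue at any position differs from the stated
    wild type — the guard that catches numbering-offset mistakes.
    """
    seq = list(sequence)
    for m in mutations:
        if not (1 <= m.position <= len(seq)):
            raise ValueError(f"{m.label}: position outside sequence of length {len(seq)}")
        observed = seq[m.position - 1].upper()
        if observed != m.wild.upper():
            raise ValueError(
                f"{m.label}: expected {m.wild} at position {m.position}, found {observed}"
            )
        seq[m.position - 1] = m.new.upper()
    return "".join(seq)


_ONE_TO_THREE = {"C": "CYS", "T": "THR"}


def mutate_structure(structure: Structure, mutation: Mutation,
                     place_sg: bool = True,
                     sg_direction: np.ndarray | None = None) -> Structure:
    """Apply a mutation to CYS or THR in a structure (stub side-chain model).

    The residue is renamed, side-chain atoms beyond Cβ are removed, and for a
    cysteine an idealized Sγ is optionally added — by default at the common
    gauche- χ1 rotamer, or along an explicit unit direction from Cβ.
    """
    if mutation.new not in _ONE_TO_THREE:
        raise ValueError(f"only mutations to CYS or THR are supported, got {mutation.new}")
    target = structure.get(mutation.chain, mutation.position)
    if target is None and len(structure.chains()) == 1:
        target = structure.get(structure.chains()[0], mutation.position)
    if target is None:
        raise ValueError(f"residue {mutation.position} (chain {mutation.chain}) not found")
    if target.label[1:] != str(mutation.position) or target.label[0] != mutation.wild:
        raise ValueError(
            f"{mutation.label}: residue at {mutation.position} is {target.label}, "
            f"expected {mutation.wild}{mutation.position}"
        )
    new_residues = []
    for res in structure.residues:
        if res is not target:
            new_residues.append(Residue(chain=res.chain, seqnum=res.seqnum,
                                        icode=res.icode, name=res.name,
                                        atoms=list(res.atoms)))
            continue
        kept = [a for a in res.atoms if a.name in _BACKBONE]
        if res.name != "GLY" and res.atom("CB") is None:
            raise ValueError(f"residue {res.label} lacks the CB atom needed for the stub")
        new_name = _ONE_TO_THREE[mutation.new]
        new_res = Residue(chain=res.chain, seqnum=res.seqnum, icode=res.icode,
                          name=new_name, atoms=kept)
        if new_name == "CYS" and place_sg:
            n, ca, cb = res.atom("N"), res.atom("CA"), res.atom("CB")
            if cb is None:
                raise ValueError(f"residue {res.label}: cannot place SG without CB")
            if sg_direction is not None:
                d = np.asarray(sg_direction, dtype=float)
                d = d / np.linalg.norm(d)
                sg_xyz = cb.coords + CB_SG_BOND * d
            else:
                if n is None or ca is None:
                    raise ValueError(f"residue {res.label}: incomplete backbone")
                sg_xyz = place_sgamma(n.coords, ca.coords, cb.coords)
            new_res.atoms.append(Atom(name="SG", element="S", coords=sg_xyz))
        new_residues.append(new_res)
    return Structure(label=structure.label, residues=new_residues,
                     ssbonds=list(structure.ssbonds))


# --------------------------------------------------------------------------
# primers


def reverse_complement(dna: str) -> str:
    """Reverse complement over the ACGTN alphabet (case-insensitive input)."""
    seq = dna.upper()
    if not _DNA_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-ACGTN characters in DNA sequence: {bad}")
    return str(Seq(seq).reverse_complement())


def primer_tm(primer: str, mismatch_bases: int = 0) -> float:
    """QuikChange-manual melting estimate:
    Tm = 81.5 + 0.41·%GC − 675/N − %mismatch (an external kit convention)."""
    n = len(primer)
    if n == 0:
        raise ValueError("empty primer")
    gc = 100.0 * sum(1 for c in primer if c in "GC") / n
    pct_mismatch = 100.0 * mismatch_bases / n
    return 81.5 + 0.41 * gc - 675.0 / n - pct_mismatch


def design_quikchange_primers(gene: str, codon_number: int, new_codon: str,
                              params: PrimerParams | None = None,
                              name: str = "") -> PrimerPair:
    """Design a complementary primer pair carrying *new_codon* at codon
    *codon_number* (1-based) of *gene*, growing symmetric flanks until the
    length and Tm constraints hold.
    """
    params = params or PrimerParams()
    gene = gene.upper()
    if not _DNA_RE.match(gene):
        raise ValueError("gene sequence must be ACGTN")
    new_codon = new_codon.upper()
    if len(new_codon) != 3 or not _DNA_RE.match(new_codon):
        raise ValueError("mutant codon must be 3 nt of ACGTN")
    start = (codon_number - 1) * 3
    if start < 0 or start + 3 > len(gene):
        raise ValueError(f"codon {codon_number} outside the gene")
    mismatches = sum(1 for a, b in zip(gene[start:start + 3], new_codon) if a != b)
    flank = (params.min_length - 3) // 2
    while True:
        lo, hi = start - flank, start + 3 + flank
        if lo < 0 or hi > len(gene):
            raise ValueError(
                "design failure: flanks reach the gene ends before the length/Tm "
                f"constraints are satisfied (needed flank {flank} nt)"
            )
        forward = gene[lo:start] + new_codon + gene[start + 3:hi]
        tm = primer_tm(forward, mismatch_bases=mismatches)
        if len(forward) >= params.min_length and tm >= params.min_tm:
            break
        if len(forward) >= params.max_length:
            raise ValueError(
                f"design failure: Tm {tm:.1f} °C still below {params.min_tm} °C at "
                f"the maximum length {params.max_length} nt"
            )
        flank += 1
    return PrimerPair(name=name or f"codon{codon_number}", forward=forward,
                      reverse=reverse_complement(forward),
                      codon_start=start - lo, tm=tm)


def _best_anneal(gene: str, primer: str) -> tuple[int, int]:
    """(offset, mismatches) of the best gapless alignment of primer on gene."""
    best = (0, len(primer) + 1)
    for off in range(len(gene) - len(primer) + 1):
        mm = sum(1 for a, b in zip(gene[off:off + len(primer)], primer) if a != b)
        if mm < best[1]:
            best = (off, mm)
    return best


def validate_primer_pair(pair: PrimerPair, mutation_codon: str | None = None,
                         gene: str | None = None,
                         params: PrimerParams | None = None) -> ValidationReport:
    """Check a primer pair: exact reverse-complementarity, mutant-codon
    presence and centering (when the codon span is known), and annealing to
    the gene with only the intended mismatches (when the gene is given).

    Checks that cannot run (no codon span, no gene) are reported as None.
    """
    params = params or PrimerParams()
    report = ValidationReport()
    ok = reverse_complement(pair.forward) == pair.reverse
    report.checks["reverse_complement"] = ok
    if not ok:
        report.messages.append("reverse primer is not the exact reverse complement")

    if pair.codon_start is not None:
        span_ok = 0 <= pair.codon_start and pair.codon_start + 3 <= len(pair.forward)
        codon = pair.forward[pair.codon_start:pair.codon_start + 3] if span_ok else ""
        present = span_ok and (mutation_codon is None or codon == mutation_codon.upper())
        report.checks["mutant_codon_present"] = present
        center = pair.codon_start + 1.5
        centered = abs(center - len(pair.forward) / 2.0) <= params.center_tolerance
        report.checks["codon_centered"] = centered
        if not centered:
            report.messages.append(
                f"mutant codon center offset {abs(center - len(pair.forward) / 2.0):.1f} nt "
                f"exceeds tolerance {params.center_tolerance}"
            )
    else:
        report.checks["mutant_codon_present"] = None
        report.checks["codon_centered"] = None

    if gene is not None:
        gene = gene.upper()
        off, mm = _best_anneal(gene, pair.forward)
        intended = 0
        if pair.codon_start is not None:
            intended = sum(
                1 for a, b in zip(gene[off + pair.codon_start:off + pair.codon_start + 3],
                                  pair.forward[pair.codon_start:pair.codon_start + 3])
                if a != b
            )
        anneal_ok = mm == intended and mm <= 3
        report.checks["anneals_with_intended_mismatch_only"] = anneal_ok
        if not anneal_ok:
            report.messages.append(
                f"best alignment at offset {off} has {mm} mismatches "
                f"({intended} intended)"
            )
    else:
        report.checks["anneals_with_intended_mismatch_only"] = None
    return report
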