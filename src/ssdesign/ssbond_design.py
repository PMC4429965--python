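"""Disulfide-bridge site design: native-bridge detection, candidate
enumeration by two geometric criteria sets, consensus, and rule-based
filtering down to an engineerable short-list.

The two enumerators mirror the workflow of the MODIP and Disulfide-by-Design
class of predictors: one grades residue pairs A-D by nested stereochemical
windows on the Cα–Cα and Cβ–Cβ distances, the other scores pairs inside a
Cβ–Cβ window by distance strain plus an idealized χ3 torsion term.  Pairs
proposed by both, minus pairs that clash with native bridges or sit near the
catalytic triad, are the candidates worth building.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._geometry import dihedral, place_sgamma, virtual_cbeta
from .structure_io import Residue, Structure

__all__ = [
    "ResidueRef",
    "BridgePair",
    "CandidatePair",
    "TriadSpec",
    "FilterDecision",
    "ModipParams",
    "DbdParams",
    "detect_native_bridges",
    "enumerate_candidates_modip",
    "enumerate_candidates_dbd",
    "consensus",
    "filter_candidates",
    "decisions_to_frame",
]

log = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"^(?:(?P<chain>\w+):)?(?P<aa>[A-Za-z])(?P<num>\d+)$")


@dataclass(frozen=True)
class ResidueRef:
    """A residue reference in author numbering with its one-letter label."""

    chain: str
    seqnum: int
    label: str  # e.g. "A126"

    @classmethod
    def from_residue(cls, res: Residue) -> "ResidueRef":
        return cls(chain=res.chain, seqnum=res.seqnum, label=res.label)

    @classmethod
    def from_label(cls, label: str, chain: str = "A") -> "ResidueRef":
        m = _LABEL_RE.match(label.strip())
        if not m:
            raise ValueError(f"cannot parse residue label {label!r}")
        return cls(chain=m.group("chain") or chain,
                   seqnum=int(m.group("num")),
                   label=f"{m.group('aa').upper()}{m.group('num')}")


def _pair_key(r1: ResidueRef, r2: ResidueRef) -> frozenset:
    return frozenset({(r1.chain, r1.seqnum), (r2.chain, r2.seqnum)})


def _ordered(r1: ResidueRef, r2: ResidueRef) -> tuple[ResidueRef, ResidueRef]:
    return (r1, r2) if (r1.chain, r1.seqnum) <= (r2.chain, r2.seqnum) else (r2, r1)


@dataclass(frozen=True)
class BridgePair:
    """A disulfide bridge, native (with Sγ–Sγ distance) or candidate."""

    res1: ResidueRef
    res2: ResidueRef
    kind: str = "native"  # native | candidate
    sg_distance: float | None = None

    def __post_init__(self):
        if (self.res1.chain, self.res1.seqnum) == (self.res2.chain, self.res2.seqnum):
            raise ValueError("a bridge needs two distinct residues")

    @property
    def key(self) -> frozenset:
        return _pair_key(self.res1, self.res2)

    @property
    def label(self) -> str:
        a, b = _ordered(self.res1, self.res2)
        return f"{a.label}-{b.label}"


@dataclass(frozen=True)
class CandidatePair:
    """A residue pair scored for disulfide compatibility by either predictor."""

    res1: ResidueRef
    res2: ResidueRef
    ca_distance: float | None = None
    cb_distance: float | None = None
    modip_grade: str | None = None  # A|B|C|D
    dbd_pass: bool = False
    dbd_score: float | None = None
    chi3_est: float | None = None  # degrees, |chi3| <= 180

    def __post_init__(self):
        for d in (self.ca_distance, self.cb_distance):
            if d is not None and d <= 0:
                raise ValueError("distances must be positive")
        if self.chi3_est is not None and abs(self.chi3_est) > 180:
            raise ValueError("|chi3| must be <= 180 degrees")

    @property
    def key(self) -> frozenset:
        return _pair_key(self.res1, self.res2)

    @property
    def label(self) -> str:
        a, b = _ordered(self.res1, self.res2)
        return f"{a.label}-{b.label}"

    @classmethod
    def from_labels(cls, label1: str, label2: str, chain: str = "A", **kw) -> "CandidatePair":
        r1 = ResidueRef.from_label(label1, chain)
        r2 = ResidueRef.from_label(label2, chain)
        a, b = _ordered(r1, r2)
        return cls(res1=a, res2=b, **kw)


@dataclass
class TriadSpec:
    """The catalytic triad and the exclusion radius around it (Å)."""

    labels: Sequence[str] = ("S133", "H247", "D194")
    radius: float = 6.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("exclusion radius must be positive")


@dataclass(frozen=True)
class FilterDecision:
    """Audit record: why a candidate pair was kept or rejected."""

    pair: CandidatePair
    verdict: str  # kept | rejected
    rule: str  # native_pair | near_native | triad_proximity | none
    distance: float | None = None

    def __post_init__(self):
        if (self.verdict == "kept") != (self.rule == "none"):
            raise ValueError("verdict 'kept' requires rule 'none' and vice versa")


# --------------------------------------------------------------------------
# geometry extraction


def _cbeta(res: Residue) -> np.ndarray:
    cb = res.atom("CB")
    if cb is not None:
        return cb.coords
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if n is None or ca is None or c is None:
        raise ValueError(f"residue {res.label}: no CB and incomplete backbone")
    return virtual_cbeta(n.coords, ca.coords, c.coords)


def _sgamma_est(res: Residue) -> np.ndarray:
    sg = res.atom("SG")
    if sg is not None:
        return sg.coords
    n, ca = res.atom("N"), res.atom("CA")
    cb = _cbeta(res)
    if n is None or ca is None:
        raise ValueError(f"residue {res.label}: incomplete backbone for Sgamma model")
    return place_sgamma(n.coords, ca.coords, cb)


def _sequence_separation(r1: Residue, r2: Residue) -> int:
    if r1.chain != r2.chain:
        return 10**6  # different chains: no covalent-sequence constraint
    return abs(r1.seqnum - r2.seqnum)


# --------------------------------------------------------------------------
# native bridges


def detect_native_bridges(structure: Structure, sg_cutoff: float = 2.3) -> list[BridgePair]:
    """Find native disulfides as CYS pairs with Sγ–Sγ distance ≤ *sg_cutoff*.

    Each cysteine joins at most one bridge; assignment is greedy by shortest
    distance, ties broken by residue order.  Cysteines lacking an Sγ atom are
    skipped with a warning.
    """
    cys: list[Residue] = []
    for res in structure:
        if res.name == "CYS":
            if res.atom("SG") is None:
                log.warning("CYS %s lacks an SG atom; skipped", res.label)
                continue
            cys.append(res)
    pairs = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i].atom("SG").coords - cys[j].atom("SG").coords))
            if d <= sg_cutoff:
                pairs.append((d, i, j))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set[int] = set()
    bridges: list[BridgePair] = []
    for d, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        r1, r2 = _ordered(ResidueRef.from_residue(cys[i]), ResidueRef.from_residue(cys[j]))
        bridges.append(BridgePair(res1=r1, res2=r2, kind="native", sg_distance=d))
    bridges.sort(key=lambda b: (b.res1.chain, b.res1.seqnum, b.res2.chain, b.res2.seqnum))
    return bridges


# --------------------------------------------------------------------------
# candidate enumeration


@dataclass
class ModipParams:
    """Nested stereochemical windows, graded best (A) to loosest (D).

    Each window is ((Cα–Cα min, max), (Cβ–Cβ min, max)) in Å.  Grade A is the
    classical sterically ideal band; B-D widen it progressively.
    """

    windows: dict = field(default_factory=lambda: {
        "A": ((4.4, 6.8), (3.4, 4.6)),
        "B": ((4.0, 7.4), (3.0, 5.1)),
        "C": ((3.6, 8.0), (2.5, 5.5)),
        "D": ((3.2, 9.0), (2.0, 6.2)),
    })
    min_separation: int = 2


@dataclass
class DbdParams:
    """Cβ–Cβ window plus the strain-score weights.

    score = w_dist*(d_CβCβ - 3.85)² + w_chi3*(1 + cos 2χ3)/2 with χ3 estimated
    from idealized Sγ placement; lower is better — zero at the ideal 3.85 Å
    separation and |χ3| = 90° (disulfides cluster near ±87°).
    """

    cb_window: tuple[float, float] = (3.0, 5.1)
    ideal_cb: float = 3.85
    w_dist: float = 1.0
    w_chi3: float = 1.0
    min_separation: int = 2


def _check_structure(structure: Structure) -> None:
    if len(structure) < 4:
        raise ValueError("structure too small for candidate enumeration (< 4 residues)")
    for res in structure:
        if res.atom("CA") is None:
            raise ValueError(f"residue {res.label} lacks a CA atom")


def enumerate_candidates_modip(structure: Structure,
                               params: ModipParams | None = None) -> list[CandidatePair]:
    """Grade all residue pairs A-D by nested (Cα–Cα, Cβ–Cβ) distance windows.

    Pairs outside every window are omitted.  Glycines get a virtual Cβ.
    """
    params = params or ModipParams()
    _check_structure(structure)
    residues = structure.residues
    ca = np.array([r.atom("CA").coords for r in residues])
    cb = np.array([_cbeta(r) for r in residues])
    out: list[CandidatePair] = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            if _sequence_separation(residues[i], residues[j]) < params.min_separation:
                continue
            dca = float(np.linalg.norm(ca[i] - ca[j]))
            dcb = float(np.linalg.norm(cb[i] - cb[j]))
            grade = None
            for g, ((ca_lo, ca_hi), (cb_lo, cb_hi)) in params.windows.items():
                if ca_lo <= dca <= ca_hi and cb_lo <= dcb <= cb_hi:
                    grade = g
                    break
            if grade is None:
                continue
            r1, r2 = _ordered(ResidueRef.from_residue(residues[i]),
                              ResidueRef.from_residue(residues[j]))
            out.append(CandidatePair(res1=r1, res2=r2, ca_distance=dca,
                                     cb_distance=dcb, modip_grade=grade))
    out.sort(key=lambda p: (p.res1.chain, p.res1.seqnum, p.res2.chain, p.res2.seqnum))
    return out


def enumerate_candidates_dbd(structure: Structure,
                             params: DbdParams | None = None) -> list[CandidatePair]:
    """Score residue pairs inside the Cβ–Cβ window by distance + χ3 strain.

    χ3 is the Cβ–Sγ–Sγ–Cβ torsion computed from idealized Sγ placement (χ1 at
    the common gauche- rotamer) on both residues.  Output is sorted ascending
    by score, canonical residue order within each pair.
    """
    params = params or DbdParams()
    _check_structure(structure)
    residues = structure.residues
    cb = np.array([_cbeta(r) for r in residues])
    sg = np.array([_sgamma_est(r) for r in residues])
    lo, hi = params.cb_window
    out: list[CandidatePair] = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            if _sequence_separation(residues[i], residues[j]) < params.min_separation:
                continue
            dcb = float(np.linalg.norm(cb[i] - cb[j]))
            if not (lo <= dcb <= hi):
                continue
            chi3 = dihedral(cb[i], sg[i], sg[j], cb[j])
            score = (params.w_dist * (dcb - params.ideal_cb) ** 2
                     + params.w_chi3 * (1.0 + np.cos(2.0 * np.radians(chi3))) / 2.0)
            dca = None
            if residues[i].atom("CA") is not None and residues[j].atom("CA") is not None:
                dca = float(np.linalg.norm(residues[i].atom("CA").coords
                                           - residues[j].atom("CA").coords))
            r1, r2 = _ordered(ResidueRef.from_residue(residues[i]),
                              ResidueRef.from_residue(residues[j]))
            out.append(CandidatePair(res1=r1, res2=r2, ca_distance=dca, cb_distance=dcb,
                                     dbd_pass=True, dbd_score=float(score),
                                     chi3_est=chi3))
    out.sort(key=lambda p: (p.dbd_score, p.res1.chain, p.res1.seqnum, p.res2.seqnum))
    return out


def consensus(list_a: Iterable[CandidatePair],
              list_b: Iterable[CandidatePair]) -> list[CandidatePair]:
    """Pairs present in both candidate lists (unordered residue match), with
    annotations merged; order deterministic by residue numbering."""
    by_key: dict[frozenset, CandidatePair] = {p.key: p for p in list_a}
    merged: list[CandidatePair] = []
    seen: set[frozenset] = set()
    for q in list_b:
        p = by_key.get(q.key)
        if p is None or q.key in seen:
            continue
        seen.add(q.key)
        merged.append(replace(
            p,
            ca_distance=p.ca_distance if p.ca_distance is not None else q.ca_distance,
            cb_distance=p.cb_distance if p.cb_distance is not None else q.cb_distance,
            modip_grade=p.modip_grade or q.modip_grade,
            dbd_pass=p.dbd_pass or q.dbd_pass,
            dbd_score=p.dbd_score if p.dbd_score is not None else q.dbd_score,
            chi3_est=p.chi3_est if p.chi3_est is not None else q.chi3_est,
        ))
    merged.sort(key=lambda p: (p.res1.chain, p.res1.seqnum, p.res2.chain, p.res2.seqnum))
    return merged


# --------------------------------------------------------------------------
# filtering


def _native_refs(native_bridges: Iterable) -> tuple[set[frozenset], set[tuple[str, int]]]:
    keys: set[frozenset] = set()
    members: set[tuple[str, int]] = set()
    for b in native_bridges:
        if isinstance(b, BridgePair):
            r1, r2 = b.res1, b.res2
        else:  # a pair of labels, e.g. ("C91", "C94")
            r1, r2 = (ResidueRef.from_label(x) for x in b)
        keys.add(_pair_key(r1, r2))
        members.add((r1.chain, r1.seqnum))
        members.add((r2.chain, r2.seqnum))
    return keys, members


def _min_heavy_distance(res_a: Residue, res_b: Residue) -> float:
    xa, xb = res_a.heavy_coords, res_b.heavy_coords
    if len(xa) == 0 or len(xb) == 0:
        return float("inf")
    diff = xa[:, None, :] - xb[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def filter_candidates(pairs: Iterable[CandidatePair],
                      native_bridges: Iterable,
                      triad: TriadSpec | None = None,
                      structure: Structure | None = None,
                      near_native_window: int = 2,
                      triad_proximal: Iterable[str] | None = None,
                      ) -> list[FilterDecision]:
    """Apply the three rejection rules, in order, to each candidate pair.

    1. *native_pair* — the pair IS a native disulfide.
    2. *near_native* — either member is a native-bridge cysteine or sits
       within ±*near_native_window* sequence positions of one (same chain);
       rebuilding next to an existing bridge risks distorting it.
    3. *triad_proximity* — either member lies within the triad exclusion
       radius.  With a *structure*, the minimum heavy-atom distance to any
       triad residue is measured; without one, membership in the
       *triad_proximal* annotation set (residue labels known to be within
       the radius, e.g. from published analysis) is used.

    Survivors get verdict ``kept``, rule ``none``.  The output is a partition
    of the input: one decision per pair, in input order.
    """
    native_keys, native_members = _native_refs(native_bridges)
    proximal = {lbl.strip() for lbl in (triad_proximal or ())}

    triad_residues: list[Residue] = []
    if triad is not None and structure is not None:
        for lbl in triad.labels:
            res = structure.find_label(lbl)
            if res is None:
                raise ValueError(f"triad residue {lbl} not found in structure")
            triad_residues.append(res)

    decisions: list[FilterDecision] = []
    for pair in pairs:
        rule, dist = None, None
        if pair.key in native_keys:
            rule = "native_pair"
        if rule is None:
            for ref in (pair.res1, pair.res2):
                if (ref.chain, ref.seqnum) in native_members:
                    rule = "near_native"
                    break
                for (nchain, nseq) in native_members:
                    if ref.chain == nchain and abs(ref.seqnum - nseq) <= near_native_window:
                        rule = "near_native"
                        break
                if rule:
                    break
        if rule is None and triad is not None:
            if triad_residues:
                dmin = float("inf")
                for ref in (pair.res1, pair.res2):
                    res = structure.get(ref.chain, ref.seqnum)
                    if res is None:
                        raise ValueError(f"candidate residue {ref.label} not in structure")
                    for tres in triad_residues:
                        dmin = min(dmin, _min_heavy_distance(res, tres))
                if dmin <= triad.radius:
                    rule, dist = "triad_proximity", dmin
            elif proximal and (pair.res1.label in proximal or pair.res2.label in proximal
                               or pair.label in proximal):
                rule, dist = "triad_proximity", triad.radius
        if rule is None:
            decisions.append(FilterDecision(pair=pair, verdict="kept", rule="none"))
        else:
            decisions.append(FilterDecision(pair=pair, verdict="rejected",
                                            rule=rule, distance=dist))
    return decisions


def decisions_to_frame(decisions: Sequence[FilterDecision]) -> pd.DataFrame:
    """Tabular (TSV-ready) report of filter decisions."""
    rows = []
    for d in decisions:
        p = d.pair
        rows.append({
            "pair": p.label,
            "modip_grade": p.modip_grade or "",
            "dbd_score": p.dbd_score if p.dbd_score is not None else "",
            "ca_distance_A": p.ca_distance if p.ca_distance is not None else "",
            "cb_distance_A": p.cb_distance if p.cb_distance is not None else "",
            "verdict": d.verdict,
            "rule": d.rule,
            "rule_distance_A": d.distance if d.distance is not None else "",
        })
    return pd.DataFrame(rows)
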