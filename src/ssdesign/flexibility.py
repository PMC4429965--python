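"""Flexibility and rigidity analytics used to rank disulfide candidates.

Candidate bridges are judged by how much they rigidify the protein:
trajectory Cα RMSD after optimal (Kabsch) superposition, the mode of the
post-equilibration RMSD distribution, crystallographic B-factor hotspots, and
a Gaussian network model (GNM) that serves as a desk-scale surrogate for
high-temperature molecular-dynamics comparison — adding the candidate bridge
as an extra contact and measuring the drop in total predicted fluctuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ssbond_design import CandidatePair
from .structure_io import Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "RmsdSeries",
    "RmsdSummary",
    "BfactorProfile",
    "EnmResult",
    "RigidityDelta",
    "kabsch_superpose",
    "rmsd_series",
    "rmsd_mode",
    "bfactor_profile",
    "gnm_fluctuations",
    "compare_rigidity",
    "rank_candidates",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of one point set onto another."""

    rotation: np.ndarray  # 3x3 proper rotation (det = +1)
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RmsdSeries:
    times: np.ndarray  # ps
    values: np.ndarray  # Å
    reference_frame: int = 0
    equilibration_start: int = 0

    @property
    def post_equilibration(self) -> np.ndarray:
        return self.values[self.equilibration_start:]


@dataclass
class RmsdSummary:
    bin_width: float
    edges: np.ndarray
    counts: np.ndarray
    mode_center: float
    mean: float
    tie: bool = False


@dataclass
class BfactorProfile:
    seqnums: np.ndarray
    raw: np.ndarray  # per-residue mean heavy-atom B, Å²
    smoothed: np.ndarray
    window: int
    hotspots: list[tuple[int, int]]  # inclusive author-numbering intervals


@dataclass
class EnmResult:
    cutoff: float
    fluctuations: np.ndarray  # per-residue mean-square fluctuation, relative units
    total: float
    extra_contacts: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class RigidityDelta:
    pair: CandidatePair
    total_without: float
    total_with: float
    per_residue_delta: np.ndarray

    @property
    def delta(self) -> float:
        """Change in total fluctuation on adding the bridge contact (≤ 0)."""
        return self.total_with - self.total_without


# --------------------------------------------------------------------------
# superposition


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of *coords_b* onto *coords_a*.

    SVD-based Kabsch algorithm; a reflection solution is corrected to a
    proper rotation by flipping the smallest singular direction.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):  # rank < 2: collinear or coincident points
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = B0 @ R.T
    rmsd = float(np.sqrt(((fitted - A0) ** 2).sum() / n))
    t = ca - cb @ R.T
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def superposed_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    return kabsch_superpose(coords_a, coords_b).rmsd


# --------------------------------------------------------------------------
# trajectory RMSD


def _equilibration_start(values: np.ndarray, window_frac: float = 0.2,
                         tol: float = 0.05) -> int:
    """First index from which a trailing-window mean stops drifting.

    The mean over a sliding window (fraction *window_frac* of the series) is
    compared with the final window's mean; the earliest index whose window
    mean is within relative tolerance *tol* of the final one is the
    equilibration start.  Heuristic, always reported alongside full-series
    statistics.
    """
    n = len(values)
    w = max(1, int(round(n * window_frac)))
    tail = values[n - w:].mean()
    scale = max(abs(tail), 1e-12)
    for i in range(0, n - w + 1):
        if abs(values[i:i + w].mean() - tail) / scale < tol:
            return i
    return n - w


def rmsd_series(trajectory: Trajectory, reference_frame: int = 0,
                selection: str = "CA") -> RmsdSeries:
    """Per-frame superposed RMSD of the selection (default Cα) vs a reference frame."""
    idx = trajectory.atom_index(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    ref = trajectory.frames[reference_frame][idx]
    values = np.empty(trajectory.n_frames)
    for k in range(trajectory.n_frames):
        frame = trajectory.frames[k][idx]
        if k == reference_frame:
            values[k] = 0.0
        else:
            values[k] = superposed_rmsd(ref, frame)
    eq = _equilibration_start(values)
    return RmsdSeries(times=trajectory.times.copy(), values=values,
                      reference_frame=reference_frame, equilibration_start=eq)


def rmsd_mode(series: RmsdSeries, bin_width: float = 0.05,
              post_equilibration: bool = True) -> RmsdSummary:
    """Histogram the RMSD values on bins aligned to multiples of *bin_width*
    and report the modal bin center (e.g. the [0.45, 0.50) bin → 0.475 Å)."""
    values = series.post_equilibration if post_equilibration else series.values
    if values.size == 0:
        raise ValueError("empty post-equilibration slice; "
                         "re-run with post_equilibration=False for full-series mode")
    lo = np.floor(values.min() / bin_width)
    hi = np.floor(values.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    top = counts.max()
    k = int(np.argmax(counts))  # argmax takes the lowest index on ties
    tie = int((counts == top).sum()) > 1
    center = float((edges[k] + edges[k + 1]) / 2.0)
    return RmsdSummary(bin_width=bin_width, edges=edges, counts=counts,
                       mode_center=center, mean=float(values.mean()), tie=tie)


def series_to_frame(series: RmsdSeries) -> pd.DataFrame:
    return pd.DataFrame({"time_ps": series.times, "rmsd_A": series.values})


# --------------------------------------------------------------------------
# B-factor profile


def bfactor_profile(structure: Structure, window: int = 5,
                    hotspot_quantile: float = 0.8) -> BfactorProfile:
    """Per-residue mean heavy-atom B-factors, smoothed by a centered sliding
    window, with hotspots as maximal runs above the given quantile.

    High-B regions mark mobile segments — classic targets for stabilizing
    mutations.
    """
    seqnums, raw = [], []
    for res in structure:
        bs = [a.bfactor for a in res.atoms if a.element != "H"]
        if bs:
            seqnums.append(res.seqnum)
            raw.append(float(np.mean(bs)))
    raw_arr = np.array(raw)
    if raw_arr.size == 0 or np.allclose(raw_arr, raw_arr[0]):
        raise ValueError("B-factor column is absent or uninformative (all equal)")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd residue count")
    half = window // 2
    smoothed = np.array([
        raw_arr[max(0, i - half):i + half + 1].mean() for i in range(raw_arr.size)
    ])
    threshold = np.quantile(smoothed, hotspot_quantile)
    hotspots: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(smoothed):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            hotspots.append((seqnums[start], seqnums[i - 1]))
            start = None
    if start is not None:
        hotspots.append((seqnums[start], seqnums[-1]))
    return BfactorProfile(seqnums=np.array(seqnums), raw=raw_arr, smoothed=smoothed,
                          window=window, hotspots=hotspots)


# --------------------------------------------------------------------------
# Gaussian network model


def _kirchhoff(ca: np.ndarray, cutoff: float,
               extra_contacts: Iterable[tuple[int, int]] = ()) -> np.ndarray:
    n = ca.shape[0]
    diff = ca[:, None, :] - ca[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    for i, j in extra_contacts:
        if i == j:
            raise ValueError("an extra contact needs two distinct residues")
        contact[i, j] = contact[j, i] = True
    K = -contact.astype(float)
    np.fill_diagonal(K, contact.sum(axis=1))
    return K


def gnm_fluctuations(structure: Structure, cutoff: float = 7.3,
                     extra_contacts: Sequence[tuple[int, int]] = ()) -> EnmResult:
    """Gaussian-network-model mean-square fluctuations from Cα contacts.

    Builds the Kirchhoff (connectivity) matrix at the given cutoff, optionally
    augmented with extra contacts representing a proposed disulfide, and takes
    per-residue fluctuations proportional to the diagonal of its pseudoinverse
    (the single zero mode of a connected network removed).  Units are relative
    (spring constant set to 1); only ratios and differences are meaningful.
    """
    ca = structure.ca_coords()
    if ca.shape[0] < 2:
        raise ValueError("need at least two residues with CA atoms")
    K = _kirchhoff(ca, cutoff, extra_contacts)
    w, V = np.linalg.eigh(K)
    zero = w < 1e-8 * max(w[-1], 1.0)
    if zero.sum() != 1:
        comps = _components(K)
        raise ValueError(
            f"contact network disconnected at cutoff {cutoff} Å: components {comps}"
        )
    inv_w = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, w))
    diag = (V ** 2 * inv_w).sum(axis=1)
    return EnmResult(cutoff=cutoff, fluctuations=diag, total=float(diag.sum()),
                     extra_contacts=list(extra_contacts))


def _components(K: np.ndarray) -> list[list[int]]:
    n = K.shape[0]
    seen: set[int] = set()
    comps = []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], []
        seen.add(s)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(K[u] < 0)[0]:
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        comps.append(sorted(comp))
    return comps


def compare_rigidity(structure: Structure, pair: CandidatePair,
                     cutoff: float = 7.3) -> RigidityDelta:
    """GNM totals with and without the candidate bridge as an extra contact.

    A (more negative) drop in total fluctuation means the bridge rigidifies
    the network more; rigidity correlates with thermostability, so candidates
    are ranked by this drop.
    """
    index = {(r.chain, r.seqnum): k for k, r in enumerate(structure.residues)
             if r.atom("CA") is not None}
    try:
        i = index[(pair.res1.chain, pair.res1.seqnum)]
        j = index[(pair.res2.chain, pair.res2.seqnum)]
    except KeyError as exc:
        raise ValueError(f"pair {pair.label} not resolvable in structure") from exc
    base = gnm_fluctuations(structure, cutoff=cutoff)
    bridged = gnm_fluctuations(structure, cutoff=cutoff, extra_contacts=[(i, j)])
    return RigidityDelta(pair=pair, total_without=base.total, total_with=bridged.total,
                         per_residue_delta=bridged.fluctuations - base.fluctuations)


def rank_candidates(structure: Structure, pairs: Sequence[CandidatePair],
                    cutoff: float = 7.3) -> list[RigidityDelta]:
    """Rank candidate pairs by total-fluctuation decrease (largest drop first);
    ties broken by DbD score (ascending), then label order."""
    deltas = [compare_rigidity(structure, p, cutoff=cutoff) for p in pairs]
    deltas.sort(key=lambda d: (
        d.delta,
        d.pair.dbd_score if d.pair.dbd_score is not None else float("inf"),
        d.pair.label,
    ))
    return deltas
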