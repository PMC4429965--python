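"""Synthetic fixtures for every input class the design pipeline consumes.

Real inputs to this kind of study are a homology model of the target enzyme
and molecular-dynamics trajectories; neither is reproducible at desk scale,
so this module builds idealized stand-ins with *known* ground truth: poly-Ala
backbones at ideal φ/ψ, residue pairs planted at an exact Cβ–Cβ distance,
native-style disulfides with Sγ atoms at bonding distance, thermally
jittered multi-model trajectories with stated noise, and assay tables drawn
from the stated generative models (Michaelis–Menten, first-order decay,
calibration line, Gaussian temperature profile).

All randomness flows through ``numpy.random.default_rng`` (PCG64) with an
explicit seed in every call; there is no global RNG state, and a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from ._geometry import place_atom, unit, virtual_cbeta
from .structure_io import Atom, Residue, Structure, Trajectory

__all__ = [
    "FixtureSpec",
    "TrajectorySpec",
    "make_structure",
    "make_trajectory",
    "make_assay_data",
]

# standard backbone stereochemistry
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_C_N_CA, _ANG_N_CA_C, _ANG_CA_C_N = 121.7, 111.2, 116.2
_OMEGA = 180.0
_HELIX = (-57.0, -47.0)
_STRAND = (-139.0, 135.0)
_SS_BOND = 2.05  # planted native Sγ–Sγ distance, Å
_CB_SG = 1.808


@dataclass
class FixtureSpec:
    """Recipe for a synthetic structure.

    ``planted_pairs`` are (i, j, target Cβ–Cβ Å) in 1-based residue numbers:
    the chain is rigidly re-hinged so the pair sits at exactly the requested
    distance with the Cβ vectors facing each other — a geometrically ideal
    disulfide site.  ``native_bridges`` are (i, j) pairs turned into CYS with
    Sγ atoms placed at 2.05 Å separation.  ``bfactor_hot`` paints elevated
    B-factors on inclusive residue ranges over a flat baseline.
    """

    motif: str = "helix"  # helix | hairpin | dumbbell
    length: int = 30
    planted_pairs: Sequence[tuple[int, int, float]] = ()
    native_bridges: Sequence[tuple[int, int]] = ()
    bfactor_base: float = 20.0
    bfactor_hot: Sequence[tuple[int, int, float]] = ()
    bfactor_noise: float = 0.0
    chain: str = "A"
    seed: int = 0

    def __post_init__(self):
        if self.length < 2 or self.length > 300:
            raise ValueError("fixture length must be in [2, 300]")
        for i, j, d in self.planted_pairs:
            if not (1 <= i <= self.length and 1 <= j <= self.length) or d <= 0:
                raise ValueError(f"planted pair ({i}, {j}, {d}) outside the fixture")
        for i, j in self.native_bridges:
            if not (1 <= i <= self.length and 1 <= j <= self.length) or i == j:
                raise ValueError(f"bad native bridge ({i}, {j})")


@dataclass
class TrajectorySpec:
    """Recipe for a jittered trajectory around a reference structure."""

    frames: int = 100
    jitter_sigma: float = 0.3  # Å, iid per coordinate
    rigid_motion: bool = False  # random rotation+translation per frame
    drift_amplitude: float = 0.0  # Å, decaying mean displacement (equilibration)
    drift_tau: float = 10.0  # frames
    dt_ps: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.frames < 1 or self.jitter_sigma < 0:
            raise ValueError("need frames ≥ 1 and σ ≥ 0")


# --------------------------------------------------------------------------
# backbone construction


def _phi_psi_schedule(motif: str, n: int) -> list[tuple[float, float]]:
    if motif == "helix":
        return [_HELIX] * n
    if motif == "hairpin":
        half = (n - 2) // 2
        turn = [(-60.0, -30.0), (-90.0, 0.0)]
        sched = [_STRAND] * half + turn + [_STRAND] * (n - half - 2)
        return sched[:n]
    if motif == "dumbbell":
        dom = max(2, int(round(n * 0.4)))
        linker = n - 2 * dom
        if linker < 1:
            dom, linker = (n - 1) // 2, n - 2 * ((n - 1) // 2)
        return [_HELIX] * dom + [_STRAND] * linker + [_HELIX] * (n - dom - linker)
    raise ValueError(f"unknown motif {motif!r}")


def _build_backbone(angles: Sequence[tuple[float, float]]) -> list[dict]:
    """N/CA/C/O/CB coordinates for a chain at the given (φ, ψ) schedule."""
    n_res = len(angles)
    residues: list[dict] = []
    # seed the first residue in the xy-plane
    N = np.zeros(3)
    CA = np.array([_N_CA, 0.0, 0.0])
    theta = np.radians(_ANG_N_CA_C)
    C = CA + _CA_C * np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])
    residues.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = angles[i - 1][1]
        phi = angles[i][0]
        N = place_atom(prev["N"], prev["CA"], prev["C"], _C_N, _ANG_CA_C_N, psi_prev)
        CA = place_atom(prev["CA"], prev["C"], N, _N_CA, _ANG_C_N_CA, _OMEGA)
        C = place_atom(prev["C"], N, CA, _CA_C, _ANG_N_CA_C, phi)
        residues.append({"N": N, "CA": CA, "C": C})
    # carbonyl O and Cβ
    for i, res in enumerate(residues):
        if i + 1 < n_res:
            res["O"] = place_atom(residues[i + 1]["N"], res["CA"], res["C"],
                                  _C_O, 120.5, 180.0)
        else:
            psi = angles[i][1]
            res["O"] = place_atom(res["N"], res["CA"], res["C"], _C_O, 120.5, psi + 180.0)
        res["CB"] = virtual_cbeta(res["N"], res["CA"], res["C"])
    return residues


def _rotation_between(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal rotation taking one direction onto another (Rodrigues form)."""
    a, b = unit(v_from), unit(v_to)
    v = np.cross(a, b)
    s2 = float(np.dot(v, v))
    c = float(np.dot(a, b))
    if s2 < 1e-24:
        if c > 0:
            return np.eye(3)
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return Rotation.from_rotvec(np.pi * unit(perp)).as_matrix()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1.0 - c) / s2)


def _plant_pair(coords: list[dict], i: int, j: int, target: float) -> None:
    """Re-hinge the chain so the (i, j) Cβ–Cβ distance is exactly *target*.

    Everything from the split point (midway between i and j) onward is
    rigidly transformed: residue j's Cβ is dropped at the target distance
    along residue i's Cα→Cβ axis, with j's Cβ→Cα direction turned
    perpendicular to that axis — the tilted face-to-face arrangement of real
    disulfides, which leaves the Cα–Cα distance in the sterically ideal band
    (≈5.6 Å at a 3.85 Å Cβ–Cβ separation).
    """
    i0, j0 = i - 1, j - 1
    if i0 > j0:
        i0, j0 = j0, i0
    split = (i0 + j0) // 2 + 1
    if split <= i0 or split > j0:
        raise ValueError(f"cannot hinge the chain between residues {i} and {j}")
    u = unit(coords[i0]["CB"] - coords[i0]["CA"])
    target_cb = coords[i0]["CB"] + target * u
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(u, [0.0, 1.0, 0.0])
    R0 = _rotation_between(coords[j0]["CA"] - coords[j0]["CB"], unit(perp))
    pivot = coords[j0]["CB"].copy()
    # roll about the bridge axis to put the idealized chi3 as close to the
    # disulfide optimum (|chi3| = 87 deg) as the hinge allows
    from ._geometry import dihedral, place_sgamma  # local import avoids a cycle

    def _chi3(R: np.ndarray) -> float:
        n_j = R @ (coords[j0]["N"] - pivot) + target_cb
        ca_j = R @ (coords[j0]["CA"] - pivot) + target_cb
        sg_i = place_sgamma(coords[i0]["N"], coords[i0]["CA"], coords[i0]["CB"])
        sg_j = place_sgamma(n_j, ca_j, target_cb)
        return dihedral(coords[i0]["CB"], sg_i, sg_j, target_cb)

    best_R, best_err = R0, float("inf")
    for gamma in np.arange(0.0, 360.0, 5.0):
        Rg = Rotation.from_rotvec(np.radians(gamma) * u).as_matrix() @ R0
        err = abs(abs(_chi3(Rg)) - 87.0)
        if err < best_err:
            best_R, best_err = Rg, err
    for k in range(split, len(coords)):
        for name in coords[k]:
            coords[k][name] = best_R @ (coords[k][name] - pivot) + target_cb


def _place_native_sg(coords: list[dict], i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
    cb_i, cb_j = coords[i - 1]["CB"], coords[j - 1]["CB"]
    D = float(np.linalg.norm(cb_j - cb_i))
    a = (D - _SS_BOND) / 2.0
    if abs(a) >= _CB_SG:
        raise ValueError(
            f"native bridge ({i}, {j}): Cβ–Cβ distance {D:.2f} Å is outside the "
            "geometrically feasible range for an Sγ–Sγ bond"
        )
    h = float(np.sqrt(_CB_SG ** 2 - a ** 2))
    u = unit(cb_j - cb_i)
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(u, [0.0, 1.0, 0.0])
    p = unit(perp)
    return cb_i + a * u + h * p, cb_j - a * u + h * p


def make_structure(spec: FixtureSpec) -> Structure:
    """Build the synthetic structure described by *spec* (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    coords = _build_backbone(_phi_psi_schedule(spec.motif, spec.length))
    for i, j, d in spec.planted_pairs:
        _plant_pair(coords, i, j, d)
    names = ["ALA"] * spec.length
    sgammas: dict[int, np.ndarray] = {}
    for i, j in spec.native_bridges:
        names[i - 1] = names[j - 1] = "CYS"
        sg_i, sg_j = _place_native_sg(coords, i, j)
        sgammas[i - 1], sgammas[j - 1] = sg_i, sg_j
    bfac = np.full(spec.length, spec.bfactor_base, dtype=float)
    for lo, hi, value in spec.bfactor_hot:
        bfac[lo - 1:hi] = value
    if spec.bfactor_noise > 0:
        bfac = np.maximum(bfac + rng.normal(0.0, spec.bfactor_noise, spec.length), 0.0)
    residues = []
    for k in range(spec.length):
        atoms = [
            Atom("N", "N", coords[k]["N"], bfactor=bfac[k]),
            Atom("CA", "C", coords[k]["CA"], bfactor=bfac[k]),
            Atom("C", "C", coords[k]["C"], bfactor=bfac[k]),
            Atom("O", "O", coords[k]["O"], bfactor=bfac[k]),
            Atom("CB", "C", coords[k]["CB"], bfactor=bfac[k]),
        ]
        if k in sgammas:
            atoms.append(Atom("SG", "S", sgammas[k], bfactor=bfac[k]))
        residues.append(Residue(chain=spec.chain, seqnum=k + 1, icode="",
                                name=names[k], atoms=atoms))
    return Structure(label=f"synthetic-{spec.motif}", residues=residues)


# --------------------------------------------------------------------------
# trajectories


def make_trajectory(structure: Structure, spec: TrajectorySpec) -> Trajectory:
    """Jittered frames around *structure* (frame 0 = the reference itself).

    Frame k ≥ 1 adds iid Gaussian jitter of the stated σ, an optional random
    rigid motion (which superposed RMSD must ignore), and an optional
    internal drift — a fixed random per-atom displacement field whose
    amplitude decays with time constant ``drift_tau`` — emulating the early
    conformational relaxation that equilibration detection must find.
    """
    rng = np.random.default_rng(spec.seed)
    ref = np.array([a.coords for a in structure.atoms])
    n_atoms = ref.shape[0]
    frames = np.empty((spec.frames, n_atoms, 3))
    frames[0] = ref
    drift_field = rng.normal(size=(n_atoms, 3))
    drift_field /= np.linalg.norm(drift_field, axis=1, keepdims=True)
    for k in range(1, spec.frames):
        xyz = ref.copy()
        if spec.drift_amplitude > 0:
            xyz = xyz + spec.drift_amplitude * np.exp(-k / spec.drift_tau) * drift_field
        if spec.jitter_sigma > 0:
            xyz = xyz + rng.normal(0.0, spec.jitter_sigma, size=xyz.shape)
        if spec.rigid_motion:
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(0.0, 5.0, size=3)
            center = xyz.mean(axis=0)
            xyz = (xyz - center) @ R.T + center + t
        frames[k] = xyz
    times = np.arange(spec.frames, dtype=float) * spec.dt_ps
    return Trajectory(topology=structure, frames=frames, times=times)


# --------------------------------------------------------------------------
# assay tables


def make_assay_data(kind: str, params: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Seeded synthetic assay tables from the stated generative models.

    Kinds and their parameters (all optional, sensible defaults):

    - ``mm`` — Michaelis–Menten rates: ``km`` (mM), ``vmax`` (U/mg),
      ``concentrations`` (default 12 geometric levels over 0.5-20 mM),
      ``noise`` (multiplicative Gaussian sd fraction).
      Columns: substrate_mM, rate_U_per_mg.
    - ``decay`` — first-order inactivation A₀·2^(−t/t½): ``half_life`` (min),
      ``times`` (default 0-60 min every 5), ``a0`` (%), ``noise``
      (multiplicative sd fraction).  Columns: time_min, residual_pct.
    - ``standard_curve`` — calibration line m·x+b: ``slope``, ``intercept``,
      ``concentrations`` (default 9 levels over 0-0.4 mM), ``noise``
      (additive OD sd).  Columns: conc_mM, od410.
    - ``temp_profile`` — Gaussian activity bump: ``center`` (°C), ``width``
      (°C), ``temperatures`` (default 43-53 °C every 1), ``noise`` (additive
      % sd).  Columns: temperature_C, activity_pct.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "mm":
        km = float(p.pop("km", 3.62))
        vmax = float(p.pop("vmax", 225.0))
        conc = np.asarray(p.pop("concentrations",
                                np.geomspace(0.5, 20.0, 12)), dtype=float)
        noise = float(p.pop("noise", 0.0))
        _reject_extras(kind, p)
        v = vmax * conc / (km + conc)
        if noise > 0:
            v = v * (1.0 + rng.normal(0.0, noise, size=v.shape))
        return pd.DataFrame({"substrate_mM": conc, "rate_U_per_mg": v})
    if kind == "decay":
        half_life = float(p.pop("half_life", 15.0))
        times = np.asarray(p.pop("times", np.arange(0.0, 65.0, 5.0)), dtype=float)
        a0 = float(p.pop("a0", 100.0))
        noise = float(p.pop("noise", 0.0))
        _reject_extras(kind, p)
        a = a0 * np.power(2.0, -times / half_life)
        if noise > 0:
            a = a * (1.0 + rng.normal(0.0, noise, size=a.shape))
        return pd.DataFrame({"time_min": times, "residual_pct": a})
    if kind == "standard_curve":
        slope = float(p.pop("slope", 0.8727))
        intercept = float(p.pop("intercept", 1.3972))
        conc = np.asarray(p.pop("concentrations", np.linspace(0.0, 0.4, 9)), dtype=float)
        noise = float(p.pop("noise", 0.0))
        _reject_extras(kind, p)
        od = slope * conc + intercept
        if noise > 0:
            od = od + rng.normal(0.0, noise, size=od.shape)
        return pd.DataFrame({"conc_mM": conc, "od410": od})
    if kind == "temp_profile":
        center = float(p.pop("center", 51.0))
        width = float(p.pop("width", 4.0))
        temps = np.asarray(p.pop("temperatures", np.arange(43.0, 54.0, 1.0)), dtype=float)
        noise = float(p.pop("noise", 0.0))
        _reject_extras(kind, p)
        act = 100.0 * np.exp(-0.5 * ((temps - center) / width) ** 2)
        if noise > 0:
            act = np.maximum(act + rng.normal(0.0, noise, size=act.shape), 0.0)
        return pd.DataFrame({"temperature_C": temps, "activity_pct": act})
    raise ValueError(f"unknown assay kind {kind!r}")


def _reject_extras(kind: str, leftovers: dict) -> None:
    if leftovers:
        raise ValueError(f"unknown parameters for kind {kind!r}: {sorted(leftovers)}")
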