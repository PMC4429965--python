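"""Internal-coordinate geometry helpers shared by the design modules.

All lengths in Å, all angles in degrees.  Ideal values follow standard
amino-acid stereochemistry (Engh–Huber-style parameters).
"""

from __future__ import annotations

import numpy as np

CA_CB_BOND = 1.521
CB_SG_BOND = 1.808
CA_CB_SG_ANGLE = 114.0
N_CA_CB_ANGLE = 110.4
C_N_CA_CB_DIHEDRAL = 122.6  # L-configuration
DEFAULT_CHI1 = -60.0  # gauche-, the most common side-chain rotamer


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom d with |c-d| = bond, angle(b,c,d) and torsion(a,b,c,d) given.

    Natural-extension (NeRF) construction.
    """
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    frame = np.column_stack([bc, np.cross(n, bc), n])
    return c + frame @ d_local


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position from backbone N, Cα, C (used for glycine)."""
    return place_atom(c, n, ca, CA_CB_BOND, N_CA_CB_ANGLE, C_N_CA_CB_DIHEDRAL)


def place_sgamma(n: np.ndarray, ca: np.ndarray, cb: np.ndarray,
                 chi1_deg: float = DEFAULT_CHI1) -> np.ndarray:
    """Idealized cysteine Sγ from backbone + Cβ at the given χ1 rotamer."""
    return place_atom(n, ca, cb, CB_SG_BOND, CA_CB_SG_ANGLE, chi1_deg)
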