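"""Backbone geometry: dihedrals, Ramachandran-region labels, secondary
structure from dihedral runs, and the turn-local coordinate frame.

The turn-local frame is the method's central representational device: every
four-residue turn defines a rigid frame from its four Calpha atoms, and
expressing all turns in their own frames superposes the whole dataset without
any pairwise fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_RAMA_BOXES, RamaBox, TurnmapConfig
from .structure_io import Chain, Residue, Structure

__all__ = [
    "GeometryError",
    "ResidueGeometry",
    "FrameTransform",
    "dihedral",
    "bond_angle",
    "backbone_dihedrals",
    "rama_label",
    "assign_ss",
    "turn_frame",
    "apply_frame",
]


class GeometryError(ValueError):
    """Degenerate geometry (coincident/collinear points, undefined frame)."""


def _wrap_angle(x: float) -> float:
    """Wrap to (-180, 180]."""
    w = (x + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees, IUPAC sign convention.

    With b1 = p2-p1, b2 = p3-p2, b3 = p4-p3 and plane normals n1 = b1 x b2,
    n2 = b2 x b3, the angle is atan2((n1 x n2) . b2_hat, n1 . n2); looking
    down p2->p3, a clockwise rotation of p4 relative to p1 is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-10 or np.linalg.norm(b1) < 1e-10 or np.linalg.norm(b3) < 1e-10:
        raise GeometryError("degenerate dihedral: coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("degenerate dihedral: collinear points")
    ang = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2)))
    return _wrap_angle(float(ang))


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise GeometryError("degenerate angle: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class ResidueGeometry:
    phi: Optional[float] = None
    psi: Optional[float] = None
    omega: Optional[float] = None
    rama_code: Optional[str] = None
    ss: str = "C"


def rama_label(
    phi: float,
    psi: float,
    omega: Optional[float] = 180.0,
    boxes: Optional[dict[str, list[RamaBox]]] = None,
) -> str:
    """Ramachandran region label for one residue.

    The default region table is a five-letter alphabet {A, B, L, E, G} of
    half-open phi/psi boxes tiling the full torus; the lowercase variant marks
    a cis peptide bond (|omega| < 90 deg). The table is configurable so a
    published partition can be substituted.
    """
    boxes = boxes if boxes is not None else DEFAULT_RAMA_BOXES
    # normalize to [-180, 180) for half-open box lookup
    p = _wrap_angle(phi)
    s = _wrap_angle(psi)
    p = -180.0 if p == 180.0 else p
    s = -180.0 if s == 180.0 else s
    label = None
    for code, region in boxes.items():
        for (plo, phi_hi, slo, shi) in region:
            if plo <= p < phi_hi and slo <= s < shi:
                label = code
                break
        if label:
            break
    if label is None:  # a custom table may not tile the torus
        label = "G"
    if omega is not None and abs(_wrap_angle(omega)) < 90.0:
        label = label.lower()
    return label


def backbone_dihedrals(
    chain: Chain, config: Optional[TurnmapConfig] = None
) -> list[ResidueGeometry]:
    """Per-residue phi/psi/omega with Ramachandran codes.

    phi_i uses C(i-1),N,CA,C; psi_i uses N,CA,C,N(i+1); omega_i uses
    CA(i-1),C(i-1),N,CA. Angles are absent at termini, across chain breaks
    (peptide C-N distance above the break threshold) and wherever backbone
    atoms are missing.
    """
    cfg = config or TurnmapConfig()
    res = chain.residues
    n = len(res)

    def atom_coord(i: int, name: str):
        if 0 <= i < n:
            a = res[i].atom(name)
            return None if a is None else a.coord
        return None

    def linked(i: int) -> bool:
        """True if residue i is peptide-bonded to residue i+1."""
        c = atom_coord(i, "C")
        nn = atom_coord(i + 1, "N")
        if c is None or nn is None:
            return False
        return float(np.linalg.norm(nn - c)) <= cfg.chain_break_distance

    out = []
    for i in range(n):
        g = ResidueGeometry()
        N, CA, C = atom_coord(i, "N"), atom_coord(i, "CA"), atom_coord(i, "C")
        if i > 0 and linked(i - 1) and all(x is not None for x in (N, CA, C)):
            cprev = atom_coord(i - 1, "C")
            caprev = atom_coord(i - 1, "CA")
            try:
                g.phi = dihedral(cprev, N, CA, C)
                if caprev is not None:
                    g.omega = dihedral(caprev, cprev, N, CA)
            except GeometryError:
                pass
        if i < n - 1 and linked(i) and all(x is not None for x in (N, CA, C)):
            nnext = atom_coord(i + 1, "N")
            try:
                g.psi = dihedral(N, CA, C, nnext)
            except GeometryError:
                pass
        if g.phi is not None and g.psi is not None:
            g.rama_code = rama_label(g.phi, g.psi, g.omega, cfg.rama_boxes)
        out.append(g)
    return out


_H_PHI, _H_PSI = (-100.0, -30.0), (-67.0, -7.0)
_E_PHI = (-170.0, -50.0)


def _fits_helix(g: ResidueGeometry) -> bool:
    if g.phi is None and g.psi is None:
        return False
    ok_phi = g.phi is None or _H_PHI[0] < g.phi < _H_PHI[1]
    ok_psi = g.psi is None or _H_PSI[0] < g.psi < _H_PSI[1]
    return ok_phi and ok_psi


def _fits_strand(g: ResidueGeometry) -> bool:
    if g.phi is None and g.psi is None:
        return False
    ok_phi = g.phi is None or _E_PHI[0] < g.phi < _E_PHI[1]
    ok_psi = g.psi is None or (80.0 < g.psi <= 180.0) or (-180.0 < g.psi <= -170.0)
    return ok_phi and ok_psi


def assign_ss(
    chain: Chain,
    geometries: Optional[Sequence[ResidueGeometry]] = None,
    override: Optional[dict[int, str]] = None,
    config: Optional[TurnmapConfig] = None,
) -> list[str]:
    """Dihedral-run secondary structure: H / E / C.

    H needs a run of >= 4 residues in the helical phi/psi window, E a run of
    >= 3 in the strand window; everything else is coil. Terminal residues with
    one angle undefined join a run if their defined angle fits. ``override``
    maps seq_index -> label and takes precedence (e.g. DSSP output).
    """
    geoms = list(geometries) if geometries is not None else backbone_dihedrals(chain, config)
    n = len(geoms)
    labels = ["C"] * n

    def mark_runs(fits, min_len: int, code: str) -> None:
        i = 0
        while i < n:
            if fits(geoms[i]):
                j = i
                while j < n and fits(geoms[j]):
                    j += 1
                if j - i >= min_len:
                    for k in range(i, j):
                        labels[k] = code
                i = j
            else:
                i += 1

    mark_runs(_fits_strand, 3, "E")
    mark_runs(_fits_helix, 4, "H")  # helix wins where windows overlap
    if override:
        for i, res in enumerate(chain.residues):
            if res.seq_index in override:
                labels[i] = override[res.seq_index]
    return labels


@dataclass
class FrameTransform:
    """Rigid map x -> rotation @ x + translation into turn-local coordinates."""

    rotation: np.ndarray   # 3x3, proper orthonormal
    translation: np.ndarray  # 3-vector

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "FrameTransform":
        rt = self.rotation.T
        return FrameTransform(rotation=rt, translation=-rt @ self.translation)

    @classmethod
    def identity(cls) -> "FrameTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def turn_frame(turn_residues: Sequence[Residue]) -> FrameTransform:
    """Turn-local frame from the four turn Calpha atoms.

    The centroid of the four Calpha maps to the origin; the Calpha1->Calpha4
    direction maps to +x; the component of (midpoint of Calpha2/Calpha3 -
    centroid) orthogonal to x maps to +y; z completes a right-handed triad.
    Chirality is preserved (determinant +1), so a mirror-image turn lands on
    the mirror of its parent's image rather than on the parent itself.
    """
    if len(turn_residues) != 4:
        raise ValueError("turn_frame needs exactly four residues")
    cas = []
    for r in turn_residues:
        a = r.atom("CA")
        if a is None:
            raise GeometryError(f"residue {r.seq_index} lacks CA")
        cas.append(a.coord)
    ca = np.asarray(cas)
    centroid = ca.mean(axis=0)
    x = ca[3] - ca[0]
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise GeometryError("degenerate frame: Calpha1 == Calpha4")
    x = x / nx
    mid = 0.5 * (ca[1] + ca[2])
    v = mid - centroid
    y = v - np.dot(v, x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-8:
        raise GeometryError("degenerate frame: central midpoint on the x-axis")
    y = y / ny
    z = np.cross(x, y)
    rotation = np.vstack([x, y, z])  # rows are the local axes
    translation = -rotation @ centroid
    return FrameTransform(rotation=rotation, translation=translation)


def apply_frame(s: Structure, f: FrameTransform) -> Structure:
    """Return a copy of ``s`` with every atom mapped into the frame."""
    import copy

    out = copy.deepcopy(s)
    for chain in out.chains:
        for res in chain.residues:
            for a in list(res.atoms) + list(res.hydrogens):
                a.coord = f.rotation @ a.coord + f.translation
    return out
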