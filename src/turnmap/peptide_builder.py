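"""Synthetic peptide construction from internal coordinates.

Fragments are built residue by residue with NeRF-style internal->Cartesian
conversion: the backbone from ideal peptide bond lengths/angles and the
requested phi/psi/omega, side chains from the requested chi angles with the
remaining internal coordinates taken from ideal residue geometry (the
chemical component dictionary bundled with biotite). Ensembles drawn from
mixtures of such templates with wrapped-Gaussian dihedral noise provide
planted-truth datasets for every downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .structure_io import Atom, Chain, Residue, Structure, ONE_TO_THREE
from .turn_geometry import GeometryError, dihedral, bond_angle

__all__ = [
    "ResidueSpec",
    "EnsembleSpec",
    "CHI_ATOMS",
    "chi_count",
    "place_atom",
    "build_fragment",
    "measure_chis",
    "generate_ensemble",
]

# Ideal backbone geometry (lengths in Angstrom, angles in degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# Side-chain chi angle definitions: quadruples of atom names, chi1..chi4.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "C": [("N", "CA", "CB", "SG")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "P": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "S": [("N", "CA", "CB", "OG")],
    "T": [("N", "CA", "CB", "OG1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "V": [("N", "CA", "CB", "CG1")],
    "A": [],
    "G": [],
}


def chi_count(aa: str) -> int:
    try:
        return len(CHI_ATOMS[aa])
    except KeyError:
        raise ValueError(f"unknown amino acid {aa!r}") from None


@dataclass
class ResidueSpec:
    """One residue of a fragment template.

    ``chi=None`` takes the ideal-geometry rotamer; an explicit list must have
    exactly the amino acid's chi count. omega is the torsion of the peptide
    bond *preceding* this residue (trans by default; set near 0 for a cis
    bond, as in classical type VIa/VIb turns with cis-proline).
    """

    aa: str
    phi: float = -120.0
    psi: float = 130.0
    omega: float = 180.0
    chi: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if self.aa not in CHI_ATOMS:
            raise ValueError(f"unknown amino acid {self.aa!r}")
        for name in ("phi", "psi", "omega"):
            v = getattr(self, name)
            if not -180.0 < v <= 180.0:
                raise ValueError(f"{name}={v} outside (-180, 180]")
        if self.chi is not None and len(self.chi) != chi_count(self.aa):
            raise ValueError(
                f"{self.aa} takes {chi_count(self.aa)} chi angles, "
                f"got {len(self.chi)}"
            )


def place_atom(a, b, c, bond_length: float, bond_angle_deg: float,
               dihedral_deg: float) -> np.ndarray:
    """NeRF placement: the point d with |d-c| = bond_length,
    angle(b,c,d) = bond_angle and dihedral(a,b,c,d) = dihedral."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    if nbc < 1e-10 or np.linalg.norm(ab) < 1e-10:
        raise GeometryError("degenerate placement: coincident reference points")
    bc_hat = bc / nbc
    n = np.cross(ab, bc_hat)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("degenerate placement: collinear reference points")
    n_hat = n / nn
    m_hat = np.cross(n_hat, bc_hat)
    theta = np.radians(bond_angle_deg)
    chi = np.radians(dihedral_deg)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


# ---------------------------------------------------------------------------
# Side-chain templates from ideal residue geometry.
# Each template entry: (atom_name, element, ref names (a, b, c), bond, angle,
# torsion_kind) with torsion_kind one of ("chi", i), ("offset", i, delta) or
# ("fixed", value).  Atoms sharing a rotatable axis with a chi-defining atom
# are stored as offsets so the whole branch follows the chi.
# ---------------------------------------------------------------------------

_TemplateEntry = tuple[str, str, tuple[str, str, str], float, float, tuple]


@lru_cache(maxsize=None)
def _sidechain_template(aa: str) -> list[_TemplateEntry]:
    from biotite.structure.info import residue as ccd_residue

    arr = ccd_residue(ONE_TO_THREE[aa])
    heavy = arr[(arr.element != "H") & (arr.atom_name != "OXT")]
    names = list(heavy.atom_name)
    coords = {n: heavy.coord[i] for i, n in enumerate(names)}
    bonds: dict[str, set[str]] = {n: set() for n in names}
    all_names = list(arr.atom_name)
    for i, j, _ in arr.bonds.as_array():
        ni, nj = all_names[i], all_names[j]
        if ni in bonds and nj in bonds:
            bonds[ni].add(nj)
            bonds[nj].add(ni)

    # torsion reference parents; N's pseudo-parent C gives CB the (C, N, CA)
    # reference quadruple so that chi1 = (N, CA, CB, X) arises naturally
    parent: dict[str, str] = {"CA": "N", "N": "C"}
    chi_quads = {quad: i + 1 for i, quad in enumerate(CHI_ATOMS[aa])}

    placed = ["N", "CA", "C", "O"]
    order: list[str] = []
    queue = ["CA"]
    while queue:
        cur = queue.pop(0)
        for nb in sorted(bonds.get(cur, ())):
            if nb in placed or nb in order or nb in ("N", "C", "O"):
                continue
            parent[nb] = cur
            order.append(nb)
            queue.append(nb)

    template: list[_TemplateEntry] = []
    axis_first: dict[tuple[str, str], tuple[str, float]] = {}
    for d in order:
        c = parent[d]
        b = parent[c]
        a = parent[b]
        bl = float(np.linalg.norm(coords[d] - coords[c]))
        ang = bond_angle(coords[b], coords[c], coords[d])
        tor = dihedral(coords[a], coords[b], coords[c], coords[d])
        quad = (a, b, c, d)
        axis = (b, c)
        if quad in chi_quads:
            kind: tuple = ("chi", chi_quads[quad])
            axis_first[axis] = (d, tor)
        elif axis in axis_first:
            ref_name, ref_tor = axis_first[axis]
            first = next(t for t in template if t[0] == ref_name)
            if first[5][0] == "chi":
                kind = ("offset", first[5][1], _wrap(tor - ref_tor))
            else:
                kind = ("fixed", tor)
        else:
            kind = ("fixed", tor)
            axis_first[axis] = (d, tor)
        element = str(heavy.element[names.index(d)])
        template.append((d, element, (a, b, c), bl, ang, kind))
    return template


def _wrap(x: float) -> float:
    w = (x + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def build_fragment(specs: Sequence[ResidueSpec], chain_id: str = "A",
                   source_id: str = "SYNTH") -> Structure:
    """Build a contiguous fragment whose measured phi/psi/omega/chi reproduce
    the specs (interior angles to ~1e-3 degree)."""
    if len(specs) == 0:
        raise ValueError("need at least one residue")
    residues: list[Residue] = []
    prev: dict[str, np.ndarray] = {}
    for i, spec in enumerate(specs):
        if i == 0:
            N = np.zeros(3)
            CA = np.array([BOND_N_CA, 0.0, 0.0])
            C = place_atom([0.0, -1.0, 0.0], N, CA, BOND_CA_C, ANGLE_N_CA_C, 0.0)
        else:
            N = place_atom(prev["N"], prev["CA"], prev["C"],
                           BOND_C_N, ANGLE_CA_C_N, specs[i - 1].psi)
            # carbonyl O of the previous residue, anti to this N
            O_prev = place_atom(N, prev["CA"], prev["C"],
                                BOND_C_O, ANGLE_CA_C_O, 180.0)
            residues[-1].atoms.append(Atom("O", "O", O_prev))
            CA = place_atom(prev["CA"], prev["C"], N,
                            BOND_N_CA, ANGLE_C_N_CA, spec.omega)
            C = place_atom(prev["C"], N, CA, BOND_CA_C, ANGLE_N_CA_C, spec.phi)
        res = Residue(aa=spec.aa, seq_index=i + 1)
        res.atoms.extend([Atom("N", "N", N), Atom("CA", "C", CA), Atom("C", "C", C)])
        _build_sidechain(res, spec, {"N": N, "CA": CA, "C": C})
        residues.append(res)
        prev = {"N": N, "CA": CA, "C": C}
    # last carbonyl O from psi of the final residue
    O_last = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_O,
                        ANGLE_CA_C_O, _wrap(specs[-1].psi + 180.0))
    residues[-1].atoms.append(Atom("O", "O", O_last))
    # keep backbone atom order N, CA, C, O, then side chain
    for res in residues:
        key = {"N": 0, "CA": 1, "C": 2, "O": 3}
        res.atoms.sort(key=lambda a: key.get(a.name, 4))
    return Structure(source_id=source_id, chains=[Chain(id=chain_id, residues=residues)])


def _build_sidechain(res: Residue, spec: ResidueSpec,
                     coords: dict[str, np.ndarray]) -> None:
    template = _sidechain_template(spec.aa)
    if not template:
        return
    chis = spec.chi
    chi_assigned: dict[int, float] = {}
    for name, element, (a, b, c), bl, ang, kind in template:
        if kind[0] == "chi":
            idx = kind[1]
            if chis is not None:
                tor = chis[idx - 1]
            else:
                # ideal-geometry rotamer: the CCD torsion for this quadruple
                tor = _ccd_chi_default(spec.aa, idx)
            chi_assigned[idx] = tor
        elif kind[0] == "offset":
            tor = _wrap(chi_assigned[kind[1]] + kind[2])
        else:
            tor = kind[1]
        pos = place_atom(coords[a], coords[b], coords[c], bl, ang, tor)
        coords[name] = pos
        res.atoms.append(Atom(name, element, pos))


@lru_cache(maxsize=None)
def _ccd_chi_default(aa: str, chi_index: int) -> float:
    for name, _el, _refs, _bl, _ang, kind in _sidechain_template(aa):
        if kind[0] == "chi" and kind[1] == chi_index:
            from biotite.structure.info import residue as ccd_residue

            arr = ccd_residue(ONE_TO_THREE[aa])
            crd = {n: arr.coord[i] for i, n in enumerate(arr.atom_name)}
            a, b, c, d = CHI_ATOMS[aa][chi_index - 1]
            return dihedral(crd[a], crd[b], crd[c], crd[d])
    raise ValueError(f"{aa} has no chi{chi_index}")


def measure_chis(res: Residue) -> list[float]:
    """Chi angles measured on built/observed coordinates; absent atoms end
    the list early."""
    out = []
    for quad in CHI_ATOMS[res.aa]:
        atoms = [res.atom(n) for n in quad]
        if any(a is None for a in atoms):
            break
        out.append(dihedral(*(a.coord for a in atoms)))
    return out


@dataclass
class EnsembleSpec:
    """Mixture-of-templates ensemble with wrapped-Gaussian dihedral noise.

    Either ``residue_specs`` (single component) or ``components`` (list of
    templates with ``component_weights``) defines the planted truth. Noise of
    the given circular sd (degrees) is added independently to every phi, psi
    and chi; omega is left exact (peptide bonds stay planar).
    """

    n: int
    residue_specs: Optional[list[ResidueSpec]] = None
    components: Optional[list[list[ResidueSpec]]] = None
    component_weights: Optional[list[float]] = None
    angular_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.components is None:
            if self.residue_specs is None:
                raise ValueError("give residue_specs or components")
            self.components = [self.residue_specs]
        if self.component_weights is None:
            self.component_weights = [1.0 / len(self.components)] * len(self.components)
        w = np.asarray(self.component_weights, dtype=float)
        if len(w) != len(self.components) or not np.isclose(w.sum(), 1.0):
            raise ValueError("component_weights must match components and sum to 1")

    def to_json(self, path: str | Path) -> None:
        def enc(specs):
            return [
                {"aa": r.aa, "phi": r.phi, "psi": r.psi, "omega": r.omega,
                 "chi": r.chi}
                for r in specs
            ]

        payload = {
            "n": self.n,
            "components": [enc(c) for c in self.components],
            "component_weights": self.component_weights,
            "angular_noise_sd": self.angular_noise_sd,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleSpec":
        raw = json.loads(Path(path).read_text())

        def mk(specs):
            return [ResidueSpec(**r) for r in specs]

        comps = raw.get("components")
        return cls(
            n=raw["n"],
            residue_specs=mk(raw["residue_specs"]) if raw.get("residue_specs") else None,
            components=[mk(c) for c in comps] if comps else None,
            component_weights=raw.get("component_weights"),
            angular_noise_sd=raw.get("angular_noise_sd", 0.0),
            seed=raw.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# Named planted-truth scenarios used throughout the test battery.
# ---------------------------------------------------------------------------

def turn_window_template(
    phi2: float, psi2: float, phi3: float, psi3: float,
    sequence: str = "GAADDKSL",
    chis: Optional[dict[int, list[float]]] = None,
    phipsi_overrides: Optional[dict[int, tuple[float, float]]] = None,
) -> list[ResidueSpec]:
    """An 8-residue turn/tail window template: extended tails around a
    four-residue turn whose central dihedrals are given.

    ``chis`` maps window indices (0..7 for positions -2..+2) to explicit
    chi-angle lists for those residues; ``phipsi_overrides`` does the same
    for (phi, psi) pairs outside the two central positions.
    """
    aas = list(sequence)
    phipsi = [(-120.0, 130.0)] * 3 + [(phi2, psi2), (phi3, psi3)] + [(-120.0, 130.0)] * 3
    if phipsi_overrides:
        for i, pair in phipsi_overrides.items():
            phipsi[i] = pair
    chis = chis or {}
    return [
        ResidueSpec(aa, ph, ps, chi=chis.get(i))
        for i, (aa, (ph, ps)) in enumerate(zip(aas, phipsi))
    ]


def classical_mixture_spec(
    types: Sequence[str] = ("I", "II", "I'"),
    n: int = 600,
    angular_noise_sd: float = 10.0,
    seed: int = 0,
) -> EnsembleSpec:
    """Equal-weight mixture of classical turn types (backbone recovery test)."""
    from .turn_detection import CLASSICAL_IDEALS

    comps = []
    for name in types:
        (p2, s2, p3, s3), _cis = CLASSICAL_IDEALS[name]
        comps.append(turn_window_template(p2, s2, p3, s3))
    return EnsembleSpec(n=n, components=comps,
                        angular_noise_sd=angular_noise_sd, seed=seed)


def ser_rotamer_spec(
    n: int = 300,
    angular_noise_sd: float = 8.0,
    seed: int = 0,
    weights: Optional[list[float]] = None,
) -> EnsembleSpec:
    """Type-I turns with a Ser at turn position 4 in three chi1 rotamers.

    In the g+ rotamer (chi1 = +60 deg, Ser phi = -90) the Ser OG donates to
    the backbone O of turn position 1 (2.1 A, 123 deg at the donor) -- the
    familiar serine turn-capping bond; the g- and trans rotamers form no
    such bond. This plants both a three-way side-chain clustering truth and
    a rotamer-specific H-bond whose map frequency should track the
    component weight. Position 4 sits on the turn frame itself, so the
    rotamer geometry stays crisp under backbone noise. The g+ component
    pairs its rotamer with a helical Ser phi (a backbone-dependent rotamer
    preference); the other two components keep the extended default.
    """
    comps = [
        turn_window_template(-60, -30, -90, 0, sequence="GAADDSKL",
                             chis={5: [60.0]},
                             phipsi_overrides={5: (-90.0, 130.0)}),
        turn_window_template(-60, -30, -90, 0, sequence="GAADDSKL",
                             chis={5: [-60.0]}),
        turn_window_template(-60, -30, -90, 0, sequence="GAADDSKL",
                             chis={5: [180.0]}),
    ]
    return EnsembleSpec(n=n, components=comps, component_weights=weights,
                        angular_noise_sd=angular_noise_sd, seed=seed)


def generate_ensemble(spec: EnsembleSpec) -> tuple[list[Structure], list[int]]:
    """Draw ``spec.n`` fragments; returns (structures, component labels).

    Bitwise reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(len(spec.components), size=spec.n, p=spec.component_weights)
    structures = []
    for i, comp in enumerate(labels):
        template = spec.components[comp]
        noisy = []
        for rs in template:
            def jitter(x: float) -> float:
                if spec.angular_noise_sd == 0.0:
                    return x
                return _wrap(x + rng.normal(0.0, spec.angular_noise_sd))

            chi = None
            if chi_count(rs.aa) > 0:
                base = rs.chi if rs.chi is not None else [
                    _ccd_chi_default(rs.aa, k + 1) for k in range(chi_count(rs.aa))
                ]
                chi = [jitter(c) for c in base]
            noisy.append(ResidueSpec(aa=rs.aa, phi=jitter(rs.phi),
                                     psi=jitter(rs.psi), omega=rs.omega, chi=chi))
        structures.append(build_fragment(noisy, source_id=f"SYN{i:05d}"))
    return structures, [int(x) for x in labels]
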