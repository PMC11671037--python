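"""Protein structure I/O and canonicalization.

Reads single-model PDB files into lightweight coordinate containers suitable
for turn geometry work, resolves alternate locations, separates hydrogens,
and applies the dataset screening hooks (allow list + resolution cutoff).
Parsing and writing of the PDB format itself is delegated to gemmi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "StructureError",
    "read_structure",
    "canonicalize_structure",
    "screen_chains",
    "write_pdb",
    "read_allow_list",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine is retained as methionine
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}
ONE_TO_THREE["X"] = "UNK"

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Raised for unparseable, empty or unwritable structures."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise StructureError(f"non-finite coordinate for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    aa: str                       # one-letter code, "X" for unknown standard
    seq_index: int                # author numbering
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)
    hydrogens: list[Atom] = field(default_factory=list)  # side store

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def backbone_complete(self) -> bool:
        names = {a.name for a in self.atoms}
        return all(n in names for n in BACKBONE_ATOMS)

    def heavy_sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    source_id: str
    chains: list[Chain] = field(default_factory=list)
    resolution: Optional[float] = None

    def __iter__(self):
        return iter(self.chains)

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


def _is_hydrogen(element: str, name: str) -> bool:
    el = element.strip().upper()
    if el in ("H", "D"):
        return True
    return el == "" and name.strip().upper().startswith(("H", "D"))


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read the first model of a PDB file.

    HETATM residues are excluded except selenomethionine (kept as Met);
    chain and residue order are preserved as written.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}; only 'pdb' is read")
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    source_id = st.name.strip() or path.stem
    resolution = st.resolution if st.resolution and st.resolution > 0 else None

    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]  # MODEL 1 only

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            aa = THREE_TO_ONE.get(gres.name.upper())
            if aa is None:
                continue  # nonstandard residue: dropped, chain breaks here
            res = Residue(
                aa=aa,
                seq_index=gres.seqid.num,
                insertion_code=(gres.seqid.icode or " ").strip(),
            )
            for ga in gres:
                atom = Atom(
                    name=ga.name,
                    element=ga.element.name if ga.element else "",
                    coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc=(ga.altloc or "").strip(),
                )
                res.atoms.append(atom)
            if res.atoms:
                residues.append(res)
        if residues:
            chains.append(Chain(id=gchain.name, residues=residues))

    if not chains:
        raise StructureError(f"{path}: zero protein residues")
    return Structure(source_id=source_id, chains=chains, resolution=resolution)


def _resolve_altlocs(atoms: Iterable[Atom]) -> list[Atom]:
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = sorted(
            by_name[name],
            # highest occupancy first; ties: altloc "A", then alphabetical
            key=lambda a: (-a.occupancy, a.altloc != "A", a.altloc),
        )
        keep = group[0]
        keep.altloc = ""
        out.append(keep)
    return out


def canonicalize_structure(s: Structure) -> Structure:
    """Resolve altlocs and shelve hydrogens, in place; returns ``s``.

    Idempotent: a canonical structure passes through unchanged.
    """
    for chain in s.chains:
        for res in chain.residues:
            heavy = [a for a in res.atoms if not _is_hydrogen(a.element, a.name)]
            hydro = [a for a in res.atoms if _is_hydrogen(a.element, a.name)]
            res.atoms = _resolve_altlocs(heavy)
            res.hydrogens.extend(_resolve_altlocs(hydro))
    return s


def read_allow_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column plain text: ``PDBID CHAIN`` per line; '#' comments allowed."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"malformed allow-list line: {line!r}")
        pairs.append((fields[0].upper(), fields[1]))
    return pairs


def screen_chains(
    structures: Sequence[Structure],
    allow_list: Optional[Sequence[tuple[str, str]]] = None,
    resolution_max: Optional[float] = None,
) -> list[tuple[Structure, Chain]]:
    """Apply allow-list and resolution screening; order is stable.

    Redundancy screening proper (sequence-identity culling) is expected to be
    done upstream (e.g. a PISCES-style list); here the precomputed list is
    simply applied. Structures without a recorded resolution pass the
    resolution filter (synthetic inputs carry none).
    """
    allowed = None
    if allow_list is not None:
        allowed = {(p.upper(), c) for p, c in allow_list}
    kept: list[tuple[Structure, Chain]] = []
    for s in structures:
        if (
            resolution_max is not None
            and s.resolution is not None
            and s.resolution > resolution_max
        ):
            continue
        for chain in s.chains:
            if allowed is not None and (s.source_id.upper(), chain.id) not in allowed:
                continue
            kept.append((s, chain))
    if not kept:
        warnings.warn("chain screening produced an empty set", stacklevel=2)
    return kept


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a single-model PDB; round-trips names, sequence and coordinates
    to the format's 3-decimal precision."""
    if s.n_residues() == 0:
        raise StructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = s.source_id
    if s.resolution is not None:
        st.resolution = s.resolution
    model = gemmi.Model("1")
    for chain in s.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = ONE_TO_THREE.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(res.seq_index, res.insertion_code or " ")
            for a in list(res.atoms) + list(res.hydrogens):
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element or a.name[:1])
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = a.occupancy
                if a.altloc:
                    ga.altloc = a.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc
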