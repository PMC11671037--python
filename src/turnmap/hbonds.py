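"""Geometric hydrogen-bond detection and per-cluster frequency aggregation.

Detection is heavy-atom only (donor-acceptor distance plus the angle at the
donor measured through its covalent antecedent), because typical X-ray
structures carry no hydrogens. Chemically ambiguous atom pairs (carboxylate
oxygens, guanidinium nitrogens, ring carbons) are collapsed to canonical
names before frequencies are tallied, so a bond that merely flips between
equivalent atom labels counts as the same interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import TurnmapConfig
from .structure_io import Residue, BACKBONE_ATOMS
from .turn_detection import TurnInstance, POSITION_LABELS
from .turn_geometry import bond_angle, GeometryError

__all__ = [
    "HBond",
    "HBondFrequency",
    "detect_hbonds",
    "canonical_pair_key",
    "hbond_frequencies",
    "frequencies_to_table",
]

# Side-chain donor atoms per amino acid, with the covalent antecedent used
# for the angle criterion. Backbone amide N (antecedent CA) donates for all
# residues except proline.
SIDECHAIN_DONORS: dict[str, list[tuple[str, str]]] = {
    "S": [("OG", "CB")],
    "T": [("OG1", "CB")],
    "Y": [("OH", "CZ")],
    "C": [("SG", "CB")],
    "K": [("NZ", "CE")],
    "R": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "N": [("ND2", "CG")],
    "Q": [("NE2", "CD")],
    "H": [("ND1", "CG"), ("NE2", "CD2")],
    "W": [("NE1", "CD1")],
}

SIDECHAIN_ACCEPTORS: dict[str, list[str]] = {
    "D": ["OD1", "OD2"],
    "E": ["OE1", "OE2"],
    "N": ["OD1"],
    "Q": ["OE1"],
    "S": ["OG"],
    "T": ["OG1"],
    "Y": ["OH"],
    "H": ["ND1", "NE2"],
    "M": ["SD"],
    "C": ["SG"],
}

# Chemically equivalent atoms -> canonical representative, per amino acid.
SYMMETRIC_CANONICAL: dict[tuple[str, str], str] = {
    ("D", "OD1"): "OD*", ("D", "OD2"): "OD*",
    ("E", "OE1"): "OE*", ("E", "OE2"): "OE*",
    ("R", "NH1"): "NH*", ("R", "NH2"): "NH*",
    ("F", "CD1"): "CD*", ("F", "CD2"): "CD*",
    ("F", "CE1"): "CE*", ("F", "CE2"): "CE*",
    ("Y", "CD1"): "CD*", ("Y", "CD2"): "CD*",
    ("Y", "CE1"): "CE*", ("Y", "CE2"): "CE*",
}


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, str]        # (position label, atom name)
    acceptor: tuple[str, str]
    category: str                 # "SC/SC" | "SC/BB" | "BB/BB"
    da_distance: float
    angle_at_donor: Optional[float]
    donor_aa: str = "X"
    acceptor_aa: str = "X"


@dataclass(frozen=True)
class HBondFrequency:
    pair_key: tuple[tuple[str, str], tuple[str, str]]
    category: str
    count: int
    fraction: float


def _donors(res: Residue, position: str) -> list[tuple[str, str, Optional[str]]]:
    """(position, atom, antecedent) donor triples for one residue."""
    out = []
    if res.aa != "P" and res.atom("N") is not None:
        out.append((position, "N", "CA"))
    for atom, ante in SIDECHAIN_DONORS.get(res.aa, []):
        if res.atom(atom) is not None:
            out.append((position, atom, ante))
    return out


def _acceptors(res: Residue, position: str) -> list[tuple[str, str]]:
    out = []
    if res.atom("O") is not None:
        out.append((position, "O"))
    for atom in SIDECHAIN_ACCEPTORS.get(res.aa, []):
        if res.atom(atom) is not None:
            out.append((position, atom))
    return out


def detect_hbonds(
    turn: TurnInstance,
    config: Optional[TurnmapConfig] = None,
) -> list[HBond]:
    """All donor-acceptor contacts within the 8-residue turn/tail window.

    A bond is reported when the heavy-atom donor-acceptor distance is within
    the cutoff and the antecedent-donor-acceptor angle is at least the
    minimum (bonds whose donor lacks its antecedent atom pass on distance
    alone). Intra-residue pairs are excluded. Categories follow the atom
    classes: backbone = {N, CA, C, O}, everything else side chain.
    """
    cfg = config or TurnmapConfig()
    window = turn.window_residues()
    donors, acceptors = [], []
    for pos_label, res in zip(POSITION_LABELS, window):
        if res is None:
            continue
        donors.extend((d, res) for d in _donors(res, pos_label))
        acceptors.extend((a, res) for a in _acceptors(res, pos_label))

    bonds = []
    for (dpos, datom, dante), dres in donors:
        d_coord = dres.atom(datom).coord
        ante_atom = dres.atom(dante) if dante else None
        for (apos, aatom), ares in acceptors:
            if ares is dres:
                continue
            a_coord = ares.atom(aatom).coord
            dist = float(np.linalg.norm(a_coord - d_coord))
            if dist > cfg.hbond_distance_max:
                continue
            angle = None
            if ante_atom is not None:
                try:
                    angle = bond_angle(ante_atom.coord, d_coord, a_coord)
                except GeometryError:
                    angle = None
                if angle is not None and angle < cfg.hbond_angle_min:
                    continue
            d_bb = datom in BACKBONE_ATOMS
            a_bb = aatom in BACKBONE_ATOMS
            category = ("BB" if d_bb else "SC") + "/" + ("BB" if a_bb else "SC")
            if category == "SC/BB" or category == "BB/SC":
                category = "SC/BB"  # one canonical mixed category
            bonds.append(
                HBond(
                    donor=(dpos, datom),
                    acceptor=(apos, aatom),
                    category=category,
                    da_distance=dist,
                    angle_at_donor=angle,
                    donor_aa=dres.aa,
                    acceptor_aa=ares.aa,
                )
            )
    return bonds


def canonical_pair_key(hbond: HBond) -> tuple[tuple[str, str], tuple[str, str]]:
    """Canonicalize chemically equivalent atom names in a bond's endpoints.

    Idempotent: already-canonical names map to themselves.
    """
    dpos, datom = hbond.donor
    apos, aatom = hbond.acceptor
    datom = SYMMETRIC_CANONICAL.get((hbond.donor_aa, datom), datom)
    aatom = SYMMETRIC_CANONICAL.get((hbond.acceptor_aa, aatom), aatom)
    return ((dpos, datom), (apos, aatom))


def hbond_frequencies(
    cluster_members: Sequence[TurnInstance],
    threshold: Optional[float] = None,
    config: Optional[TurnmapConfig] = None,
    precomputed: Optional[Sequence[Sequence[HBond]]] = None,
) -> list[HBondFrequency]:
    """Fraction of cluster members exhibiting each canonical H-bond.

    A member counts once per pair key however many bonds realize it. Pairs
    below the display threshold (default 20% of members) are omitted; the
    result is sorted by fraction descending, then key.
    """
    cfg = config or TurnmapConfig()
    if threshold is None:
        threshold = cfg.display_threshold
    n = len(cluster_members)
    if n == 0:
        return []
    counts: dict[tuple, int] = {}
    categories: dict[tuple, str] = {}
    for i, turn in enumerate(cluster_members):
        bonds = precomputed[i] if precomputed is not None else detect_hbonds(turn, cfg)
        seen = set()
        for b in bonds:
            key = canonical_pair_key(b)
            if key in seen:
                continue
            seen.add(key)
            counts[key] = counts.get(key, 0) + 1
            categories.setdefault(key, b.category)
    out = [
        HBondFrequency(pair_key=k, category=categories[k], count=c, fraction=c / n)
        for k, c in counts.items()
        if c / n >= threshold - 1e-12 and c > 0
    ]
    out.sort(key=lambda f: (-f.fraction, f.pair_key))
    return out


def frequencies_to_table(freqs: Sequence[HBondFrequency], cluster: str = "") -> pd.DataFrame:
    rows = [
        {
            "cluster": cluster,
            "pair_key": f"{f.pair_key[0][0]}.{f.pair_key[0][1]}->"
                        f"{f.pair_key[1][0]}.{f.pair_key[1][1]}",
            "category": f.category,
            "count": f.count,
            "fraction": round(f.fraction, 4),
        }
        for f in freqs
    ]
    return pd.DataFrame(rows, columns=["cluster", "pair_key", "category", "count", "fraction"])
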