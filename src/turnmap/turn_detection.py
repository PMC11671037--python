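"""Turn detection and classification.

A four-residue window is a turn when its residues are backbone-complete and
contiguous, the Calpha1-Calpha4 distance is at most 7 A, and the four
residues are not all helical. Turns whose central residues sit inside beta
strands are "strand" turns (groups E2/E3/E2E3); the rest are beta turns.
Each turn carries its two-residue tails, the central dihedral vector
(phi2, psi2, phi3, psi3), a classical type, a Ramachandran type string and
a turn-local frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import TurnmapConfig
from .structure_io import Chain, Residue
from .turn_geometry import (
    FrameTransform,
    GeometryError,
    ResidueGeometry,
    backbone_dihedrals,
    assign_ss,
    turn_frame,
)

__all__ = [
    "TurnInstance",
    "CLASSICAL_IDEALS",
    "detect_turns",
    "classify_classical",
    "classify_strand_group",
    "turns_to_table",
]

# Classical type ideals: (phi2, psi2, phi3, psi3) and whether the central
# peptide bond (omega of position 3) must be cis.
CLASSICAL_IDEALS: dict[str, tuple[tuple[float, float, float, float], bool]] = {
    "I":    ((-60.0, -30.0, -90.0, 0.0), False),
    "I'":   ((60.0, 30.0, 90.0, 0.0), False),
    "II":   ((-60.0, 120.0, 80.0, 0.0), False),
    "II'":  ((60.0, -120.0, -80.0, 0.0), False),
    "VIII": ((-60.0, -30.0, -120.0, 120.0), False),
    "VIa1": ((-60.0, 120.0, -90.0, 0.0), True),
    "VIa2": ((-120.0, 120.0, -60.0, 0.0), True),
    "VIb":  ((-135.0, 135.0, -75.0, 160.0), True),
}

CLASSICAL_TYPES = tuple(CLASSICAL_IDEALS) + ("IV",)

# Map position label -> index into the 8-residue window / sequence8 string.
POSITION_LABELS = ("-2", "-1", "1", "2", "3", "4", "+1", "+2")


@dataclass
class TurnInstance:
    address: tuple[str, str, int]          # (structure id, chain id, seq_index of pos 1)
    residues: list[Residue]                # positions 1-4
    n_tail: list[Residue]                  # up to 2, order (-2, -1)
    c_tail: list[Residue]                  # up to 2, order (+1, +2)
    dihedral_vector: tuple[float, float, float, float]
    sequence8: str
    kind: str                              # "beta" | "strand"
    classical_type: str
    strand_group: Optional[str]            # E2 | E3 | E2E3 | None
    rama_type: str
    frame: FrameTransform
    bb_cluster: Optional[str] = None
    geometries: list[ResidueGeometry] = field(default_factory=list, repr=False)

    def window_residues(self) -> list[Optional[Residue]]:
        """The 8 positions -2..+2; None where a tail residue is absent."""
        n = list(self.n_tail)
        while len(n) < 2:
            n.insert(0, None)
        c = list(self.c_tail)
        while len(c) < 2:
            c.append(None)
        return n + list(self.residues) + c

    def residue_at(self, position: str) -> Optional[Residue]:
        return self.window_residues()[POSITION_LABELS.index(position)]

    @property
    def address_str(self) -> str:
        return f"{self.address[0]}_{self.address[1]}_{self.address[2]}"


def _angdiff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def classify_classical(
    dihedral_vector: Sequence[float],
    omega3: Optional[float] = 180.0,
    config: Optional[TurnmapConfig] = None,
) -> str:
    """Nearest classical ideal within the tolerance windows, else type IV.

    A turn matches an ideal when three of its four central dihedrals lie
    within +/-30 deg of the ideal and the fourth within +/-45 deg, and the
    cis/trans state of the central peptide bond agrees. Among matching
    ideals the angularly nearest wins.
    """
    cfg = config or TurnmapConfig()
    dv = tuple(float(x) for x in dihedral_vector)
    is_cis = omega3 is not None and abs(omega3) < 90.0
    best = None
    for name, (ideal, needs_cis) in CLASSICAL_IDEALS.items():
        if needs_cis != is_cis:
            continue
        devs = sorted(_angdiff(x, y) for x, y in zip(dv, ideal))
        if devs[-1] <= cfg.classical_excursion and devs[-2] <= cfg.classical_tolerance:
            dist = float(np.sqrt(sum(d * d for d in (_angdiff(x, y) for x, y in zip(dv, ideal)))))
            if best is None or dist < best[0]:
                best = (dist, name)
    return best[1] if best else "IV"


def classify_strand_group(ss2: str, ss3: str) -> Optional[str]:
    """E2/E3/E2E3 from the strand membership of the two central residues."""
    if ss2 == "E" and ss3 == "E":
        return "E2E3"
    if ss2 == "E":
        return "E2"
    if ss3 == "E":
        return "E3"
    return None


def _contiguous(geoms: Sequence[ResidueGeometry], i: int, j: int) -> bool:
    """True if residues i..j are peptide-linked (no break): every interior
    junction has psi on the left or phi on the right defined."""
    for k in range(i, j):
        # dihedral absence encodes a break or missing atoms at the junction
        if geoms[k].psi is None and geoms[k + 1].phi is None:
            return False
    return True


def detect_turns(
    chain: Chain,
    ss_labels: Optional[Sequence[str]] = None,
    structure_id: str = "SYNTH",
    config: Optional[TurnmapConfig] = None,
) -> list[TurnInstance]:
    """All four-residue turns in a chain, with tails and classifications.

    Overlapping windows are all reported. Tails are attached only where the
    flanking residues exist, are backbone-complete and are contiguous with
    the turn.
    """
    cfg = config or TurnmapConfig()
    res = chain.residues
    n = len(res)
    if n < 4:
        return []
    geoms = backbone_dihedrals(chain, cfg)
    ss = list(ss_labels) if ss_labels is not None else assign_ss(chain, geoms, config=cfg)

    turns: list[TurnInstance] = []
    for i in range(n - 3):
        quad = res[i:i + 4]
        if not all(r.backbone_complete for r in quad):
            continue
        if not _contiguous(geoms, i, i + 3):
            continue
        ca1, ca4 = quad[0].atom("CA"), quad[3].atom("CA")
        d14 = float(np.linalg.norm(ca4.coord - ca1.coord))
        if d14 > cfg.turn_ca_distance_max:
            continue
        if all(ss[k] == "H" for k in range(i, i + 4)):
            continue
        g2, g3 = geoms[i + 1], geoms[i + 2]
        if None in (g2.phi, g2.psi, g3.phi, g3.psi):
            continue
        dv = (g2.phi, g2.psi, g3.phi, g3.psi)

        def tail(indices: list[int]) -> list[Residue]:
            out = []
            for k in indices:
                if not (0 <= k < n) or not res[k].backbone_complete:
                    break
                lo, hi = (k, i) if k < i else (i + 3, k)
                if not _contiguous(geoms, lo, hi):
                    break
                out.append(res[k])
            return out

        n_tail = list(reversed(tail([i - 1, i - 2])))
        c_tail = tail([i + 4, i + 5])

        seq8 = (
            "".join(r.aa for r in n_tail).rjust(2, "-")
            + "".join(r.aa for r in quad)
            + "".join(r.aa for r in c_tail).ljust(2, "-")
        )
        group = classify_strand_group(ss[i + 1], ss[i + 2])
        kind = "strand" if group else "beta"
        rama_type = (g2.rama_code or "?") + (g3.rama_code or "?")
        try:
            frame = turn_frame(quad)
        except GeometryError:
            continue
        turns.append(
            TurnInstance(
                address=(structure_id, chain.id, quad[0].seq_index),
                residues=list(quad),
                n_tail=n_tail,
                c_tail=c_tail,
                dihedral_vector=dv,
                sequence8=seq8,
                kind=kind,
                classical_type=classify_classical(dv, g3.omega, cfg),
                strand_group=group,
                rama_type=rama_type,
                frame=frame,
                geometries=geoms[max(0, i - 2):i + 6],
            )
        )
    for t in turns:
        assert np.linalg.norm(
            t.residues[3].atom("CA").coord - t.residues[0].atom("CA").coord
        ) <= cfg.turn_ca_distance_max + 1e-9
    return turns


def turns_to_table(turns: Sequence[TurnInstance]) -> pd.DataFrame:
    """Flat per-turn table for TSV export."""
    rows = []
    for t in turns:
        rows.append(
            {
                "address": t.address_str,
                "sequence8": t.sequence8,
                "phi2": round(t.dihedral_vector[0], 3),
                "psi2": round(t.dihedral_vector[1], 3),
                "phi3": round(t.dihedral_vector[2], 3),
                "psi3": round(t.dihedral_vector[3], 3),
                "kind": t.kind,
                "classical_type": t.classical_type,
                "strand_group": t.strand_group or "",
                "rama_type": t.rama_type,
                "bb_cluster": t.bb_cluster or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "address", "sequence8", "phi2", "psi2", "phi3", "psi3",
            "kind", "classical_type", "strand_group", "rama_type", "bb_cluster",
        ],
    )
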