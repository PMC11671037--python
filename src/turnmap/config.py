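"""Run-time configuration for the turn-mapping pipeline.

Every geometric cutoff, clustering control and display rule that the method
uses is collected here so that published alternatives (different Ramachandran
region boundaries, reference backbone medoids, H-bond criteria) can be dropped
in without touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

# Ramachandran region table: label -> list of (phi_lo, phi_hi, psi_lo, psi_hi)
# half-open boxes on [-180, 180).  The default is a five-region alphabet
# {A, B, L, E, G} that tiles the full torus; cis-omega residues get the
# lowercase variant of their label.
RamaBox = tuple[float, float, float, float]

DEFAULT_RAMA_BOXES: dict[str, list[RamaBox]] = {
    "A": [(-180.0, 0.0, -90.0, 50.0)],
    "B": [(-180.0, 0.0, 50.0, 180.0), (-180.0, 0.0, -180.0, -170.0)],
    "L": [(0.0, 180.0, -50.0, 100.0)],
    "E": [(0.0, 180.0, 100.0, 180.0), (0.0, 180.0, -180.0, -50.0)],
    "G": [(-180.0, 0.0, -170.0, -90.0)],
}


@dataclass
class TurnmapConfig:
    """Tunable parameters, with the defaults the pipeline was built around."""

    # -- turn detection -----------------------------------------------------
    turn_ca_distance_max: float = 7.0      # Angstrom, Calpha1-Calpha4
    chain_break_distance: float = 2.5      # Angstrom, peptide C-N
    resolution_max: float = 2.0            # Angstrom, dataset screening

    # -- classical type assignment -----------------------------------------
    classical_tolerance: float = 30.0      # degrees on each dihedral
    classical_excursion: float = 45.0      # one dihedral may stray this far

    # -- hydrogen bonds -----------------------------------------------------
    hbond_distance_max: float = 3.5        # Angstrom, donor-acceptor heavy atom
    hbond_angle_min: float = 90.0          # degrees at the donor
    display_threshold: float = 0.20        # min member fraction shown in maps

    # -- clustering ---------------------------------------------------------
    dbscan_eps: float = 30.0               # degrees, angular metric
    dbscan_min_pts: int = 25               # scaled down for small sets
    silhouette_threshold: float = 0.25     # below this, one cluster
    sc_k_max: int = 8
    tail_k_max: int = 5

    # -- motif statistics ---------------------------------------------------
    min_support: int = 10                  # min motif count per cluster

    # -- tables -------------------------------------------------------------
    rama_boxes: dict[str, list[RamaBox]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_RAMA_BOXES.items()}
    )
    reference_medoids_path: Optional[str] = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TurnmapConfig":
        raw = json.loads(Path(path).read_text())
        if "rama_boxes" in raw:
            raw["rama_boxes"] = {
                k: [tuple(box) for box in v] for k, v in raw["rama_boxes"].items()
            }
        return cls(**raw)


DEFAULT_CONFIG = TurnmapConfig()
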