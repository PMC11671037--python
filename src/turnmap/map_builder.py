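"""Assembly and export of motif maps.

A motif map is the three-level conformational hierarchy for one sequence
motif: backbone clusters ordered by the motif's statistical significance,
side-chain clusters ordered by size, and tail clusters ordered by size,
each represented by its medoid and annotated with H-bond frequencies,
log-odds profiles and member addresses. The map serializes to a versioned
JSON document plus one PDB file per medoid in turn-local coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .config import TurnmapConfig
from .structure_io import Chain, Structure, write_pdb
from .turn_detection import TurnInstance
from .turn_geometry import apply_frame
from .clustering import motif_hierarchy, BBEntryClusters
from .hbonds import hbond_frequencies, HBondFrequency
from .motif_stats import (
    MotifSpec,
    match_motif,
    motif_significance,
    positional_background,
    log_odds_profile,
)

__all__ = ["MotifMap", "build_map", "export_map", "load_map"]

SCHEMA = "turnmap-json/1"


@dataclass
class MotifMap:
    """The serializable map plus (when built in-process) medoid structures."""

    data: dict
    medoid_turns: dict[str, TurnInstance] = field(default_factory=dict, repr=False)

    @property
    def motif_name(self) -> str:
        return self.data["motif"]

    @property
    def bb_entries(self) -> list[dict]:
        return self.data["bb_entries"]

    def __eq__(self, other) -> bool:
        return isinstance(other, MotifMap) and self.data == other.data


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        if math.isinf(obj):
            return 1e308 if obj > 0 else -1e308
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _freqs_json(freqs: Sequence[HBondFrequency]) -> list[dict]:
    return [
        {
            "donor": f"{f.pair_key[0][0]}.{f.pair_key[0][1]}",
            "acceptor": f"{f.pair_key[1][0]}.{f.pair_key[1][1]}",
            "category": f.category,
            "count": f.count,
            "fraction": f.fraction,
        }
        for f in freqs
    ]


def _turn_window_structure(turn: TurnInstance, local: bool = True) -> Structure:
    residues = [r for r in turn.window_residues() if r is not None]
    s = Structure(
        source_id=turn.address[0],
        chains=[Chain(id=turn.address[1] or "A", residues=residues)],
    )
    return apply_frame(s, turn.frame) if local else s


def build_map(
    turns: Sequence[TurnInstance],
    motif: MotifSpec,
    config: Optional[TurnmapConfig] = None,
) -> MotifMap:
    """Build the full motif map over an already BB-labeled turn dataset.

    Backbone entries cover every cluster containing the motif, ordered by
    the motif's significance in the cluster (exact binomial tail against
    the positional background of the whole set); heat is the significance
    score normalized by the best cluster. Entries with fewer matches than
    the minimum support keep their statistics but are not subclustered.
    """
    cfg = config or TurnmapConfig()
    labeled = [t for t in turns if t.bb_cluster is not None]
    background = positional_background(labeled if labeled else list(turns))
    p_bg = 1.0
    for p, aa in motif.constraints:
        p_bg *= background[p][aa]

    matching_idx = [i for i, t in enumerate(labeled) if match_motif(t, motif)]
    data: dict = {
        "schema": SCHEMA,
        "motif": motif.name,
        "n_turns": len(labeled),
        "n_matching": len(matching_idx),
        "display_threshold": cfg.display_threshold,
        "min_support": cfg.min_support,
        "bb_entries": [],
    }
    mm = MotifMap(data=data)
    if not matching_idx:
        data["diagnostic"] = "no turns match the motif"
        return mm
    if p_bg <= 0.0:
        # motif residues never occur in the background; treat as rare
        p_bg = 1.0 / (4.0 * max(1, len(labeled)))

    by_bb: dict[str, list[int]] = {}
    cluster_size: dict[str, int] = {}
    for t in labeled:
        lbl = str(t.bb_cluster)
        cluster_size[lbl] = cluster_size.get(lbl, 0) + 1
    match_set = set(matching_idx)
    for i in matching_idx:
        by_bb.setdefault(str(labeled[i].bb_cluster), []).append(i)

    # significance per BB cluster
    stats = {}
    for lbl, idx in by_bb.items():
        n_trials = sum(
            1
            for i, t in enumerate(labeled)
            if str(t.bb_cluster) == lbl
            and all(t.sequence8[_pos_index(p)] != "-" for p, _ in motif.constraints)
        )
        stats[lbl] = motif_significance(len(idx), max(n_trials, len(idx)), p_bg)
    max_score = max((s.score for s in stats.values() if math.isfinite(s.score)), default=0.0)
    for s in stats.values():
        if max_score > 0 and math.isfinite(s.score):
            s.heat = min(1.0, max(0.0, s.score / max_score))
        else:
            s.heat = 1.0 if not math.isfinite(s.score) else 0.0

    supported = {lbl for lbl, idx in by_bb.items() if len(idx) >= cfg.min_support}
    hierarchy: dict[str, BBEntryClusters] = {}
    hier_turns: list[TurnInstance] = []
    if supported:
        hier_turns = [t for t in labeled if str(t.bb_cluster) in supported]
        hierarchy = motif_hierarchy(hier_turns, motif, cfg.sc_k_max, cfg)

    order = sorted(by_bb, key=lambda l: (stats[l].p_value, -len(by_bb[l]), l))
    for lbl in order:
        st = stats[lbl]
        entry = {
            "bb_label": lbl,
            "cluster_size": cluster_size[lbl],
            "n_obs": st.n_obs,
            "n_expected": st.n_expected,
            "p_value": st.p_value,
            "score": st.score,
            "heat": st.heat,
            "fractional_overrep_pct": st.fractional_overrep,
            "size_fraction": len(by_bb[lbl]) / len(matching_idx),
            "sc_entries": [],
        }
        if lbl in hierarchy:
            h = hierarchy[lbl]
            members = [hier_turns[i] for i in h.members]
            entry["medoid_address"] = hier_turns[h.medoid].address_str
            entry["member_addresses"] = [t.address_str for t in members]
            entry["hbond_frequencies"] = _freqs_json(
                hbond_frequencies(members, cfg.display_threshold, cfg)
            )
            mm.medoid_turns[f"BB_{lbl}"] = hier_turns[h.medoid]
            bb_background = positional_background(
                [t for t in labeled if str(t.bb_cluster) == lbl]
            )
            for sc in h.sc_clusters:
                sc_members = [hier_turns[i] for i in sc.members]
                profile = log_odds_profile(sc_members, bb_background)
                sc_entry = {
                    "label": sc.label,
                    "size": len(sc.members),
                    "size_fraction": len(sc.members) / len(h.members),
                    "medoid_address": hier_turns[sc.medoid].address_str,
                    "member_addresses": [t.address_str for t in sc_members],
                    "hbond_frequencies": _freqs_json(
                        hbond_frequencies(sc_members, cfg.display_threshold, cfg)
                    ),
                    "log_odds_profile": profile,
                    "n_tail_entries": [],
                    "c_tail_entries": [],
                }
                mm.medoid_turns[f"BB_{lbl}_{sc.label}"] = hier_turns[sc.medoid]
                for side, key in (("n_tails", "n_tail_entries"), ("c_tails", "c_tail_entries")):
                    for tg in getattr(sc, side):
                        tg_members = [hier_turns[i] for i in tg.members]
                        tail_entry = {
                            "label": tg.label,
                            "size": len(tg.members),
                            "medoid_address": hier_turns[tg.medoid].address_str,
                            "member_addresses": [t.address_str for t in tg_members],
                            "hbond_frequencies": _freqs_json(
                                hbond_frequencies(tg_members, cfg.display_threshold, cfg)
                            ),
                        }
                        sc_entry[key].append(tail_entry)
                        mm.medoid_turns[
                            f"BB_{lbl}_{sc.label}_{tg.label}"
                        ] = hier_turns[tg.medoid]
                entry["sc_entries"].append(sc_entry)
            if h.warning:
                entry["warning"] = h.warning
        else:
            idx = by_bb[lbl]
            entry["medoid_address"] = labeled[idx[0]].address_str
            entry["member_addresses"] = [labeled[i].address_str for i in idx]
        data["bb_entries"].append(entry)
    return mm


def _pos_index(p: str) -> int:
    from .turn_detection import POSITION_LABELS

    return POSITION_LABELS.index(p)


def export_map(mm: MotifMap, out_dir: str | Path) -> Path:
    """Write map.json, per-medoid PDB files (turn-local coordinates) and the
    unique-sorted PDB-ID list. Deterministic: identical maps produce
    byte-identical JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(_round_floats(mm.data), indent=2, sort_keys=True) + "\n"
    (out / "map.json").write_text(payload)

    medoid_dir = out / "medoids"
    if mm.medoid_turns:
        medoid_dir.mkdir(exist_ok=True)
        for name, turn in sorted(mm.medoid_turns.items()):
            write_pdb(_turn_window_structure(turn, local=True), medoid_dir / f"{name}.pdb")

    ids = sorted(
        {
            addr.split("_")[0]
            for e in mm.data["bb_entries"]
            for addr in e.get("member_addresses", [])
        }
    )
    (out / "pdb_ids.txt").write_text("\n".join(ids) + ("\n" if ids else ""))
    return out / "map.json"


def load_map(path: str | Path) -> MotifMap:
    """Load an exported map.json; lossless for everything the JSON stores."""
    raw = json.loads(Path(path).read_text())
    if raw.get("schema") != SCHEMA:
        raise ValueError(f"unsupported map schema {raw.get('schema')!r}")
    return MotifMap(data=raw)
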