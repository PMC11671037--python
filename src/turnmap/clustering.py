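"""Clustering mathematics for the three-stage conformational hierarchy.

Stage 1 groups turns in Ramachandran space with a wraparound angular metric,
either by assignment to a reference backbone clustering or by a hybrid
DBSCAN -> PAM k-medoids procedure (DBSCAN finds the number of dense groups
and seed medoids, PAM refines, noise is folded into the nearest cluster).
Stage 2 clusters the motif side chains and stage 3 the turn tails, both by
RMS distance in the shared turn-local Euclidean frame -- no re-superposition
is performed anywhere: the common frame IS the alignment.

PAM and DBSCAN are implemented here with fully deterministic tie-breaking
(BUILD ties to the lowest index, first-improvement SWAP in fixed scan order,
DBSCAN labels in first-core-point order) so that identical inputs always
give identical clusterings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .config import TurnmapConfig
from .turn_detection import TurnInstance

__all__ = [
    "NOISE",
    "ClusterResult",
    "angular_distance",
    "angular_distance_matrix",
    "pairwise_rms_matrix",
    "pam_kmedoids",
    "dbscan",
    "choose_k",
    "hybrid_bb_cluster",
    "split_cluster",
    "assign_to_reference",
    "read_reference_medoids",
    "motif_hierarchy",
    "TailGroup",
    "SCCluster",
    "BBEntryClusters",
    "SYMMETRIC_SWAPS",
]

NOISE = -1


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def angular_distance(u: Sequence[float], v: Sequence[float]) -> float:
    """Euclidean distance in angle space with 360-degree wraparound per
    coordinate: sqrt(sum_i min(|u_i-v_i|, 360-|u_i-v_i|)^2)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    d = np.abs(u - v) % 360.0
    d = np.minimum(d, 360.0 - d)
    return float(np.sqrt(np.sum(d * d)))


def angular_distance_matrix(vectors: Sequence[Sequence[float]]) -> np.ndarray:
    x = np.asarray(vectors, dtype=float)
    d = np.abs(x[:, None, :] - x[None, :, :]) % 360.0
    d = np.minimum(d, 360.0 - d)
    return np.sqrt((d * d).sum(axis=2))


def pairwise_rms_matrix(coord_sets: Sequence[np.ndarray]) -> np.ndarray:
    """RMS coordinate distance between equal-shape (m, 3) coordinate sets."""
    x = np.asarray(coord_sets, dtype=float)
    diff = x[:, None, :, :] - x[None, :, :, :]
    return np.sqrt((diff ** 2).sum(axis=(2, 3)) / x.shape[1])


# ---------------------------------------------------------------------------
# PAM k-medoids
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Labels plus per-cluster medoid indices and sizes."""

    labels: list                      # per-item cluster label (NOISE allowed)
    medoid_index: dict = field(default_factory=dict)   # label -> item index
    sizes: dict = field(default_factory=dict)          # label -> member count

    @property
    def n(self) -> int:
        return len(self.labels)

    def members(self, label) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == label]

    def cluster_labels(self) -> list:
        seen = []
        for l in self.labels:
            if l != NOISE and l not in seen:
                seen.append(l)
        return seen


def _pam_cost(D: np.ndarray, medoids: Sequence[int]) -> float:
    return float(D[:, list(medoids)].min(axis=1).sum())


def _assign(D: np.ndarray, medoids: Sequence[int]) -> list[int]:
    """Nearest medoid; ties go to the medoid with the lower item index."""
    med = sorted(medoids)
    sub = D[:, med]
    best = sub.argmin(axis=1)  # argmin takes the first (= lowest index) on ties
    return [med[b] for b in best]


def pam_kmedoids(D: np.ndarray, k: int) -> ClusterResult:
    """Partitioning Around Medoids with deterministic BUILD + SWAP.

    BUILD seeds greedily (each step adds the item giving the largest cost
    reduction; ties to the lowest index); SWAP applies the first improving
    (medoid, non-medoid) exchange in fixed scan order until no exchange
    improves the cost. The total cost is non-increasing throughout.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")

    # BUILD
    row_sums = D.sum(axis=1)
    medoids = [int(row_sums.argmin())]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))

    # SWAP, first improvement in fixed scan order
    cost = _pam_cost(D, medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(len(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = _pam_cost(D, trial)
                if c < cost - 1e-12:
                    assert c <= cost  # monotone by construction
                    medoids, cost = trial, c
                    improved = True
                    break
            if improved:
                break

    assignment = _assign(D, medoids)
    med_sorted = sorted(medoids)
    label_of = {m: i for i, m in enumerate(med_sorted)}
    labels = [label_of[m] for m in assignment]
    sizes = {l: labels.count(l) for l in range(k)}
    return ClusterResult(
        labels=labels,
        medoid_index={label_of[m]: m for m in med_sorted},
        sizes=sizes,
    )


# ---------------------------------------------------------------------------
# DBSCAN on a precomputed matrix
# ---------------------------------------------------------------------------

def dbscan(D: np.ndarray, eps: float, min_pts: int) -> list[int]:
    """Density clustering; returns per-item labels with NOISE = -1.

    Cluster ids follow first-core-point scan order; border points join the
    first cluster that discovers them.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    neighbors = [np.flatnonzero(D[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = [NOISE] * n
    cluster = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        labels[i] = cluster
        queue = list(neighbors[i])
        qi = 0
        while qi < len(queue):
            j = int(queue[qi])
            qi += 1
            if labels[j] == NOISE:
                labels[j] = cluster
                if core[j]:
                    queue.extend(int(x) for x in neighbors[j] if labels[x] == NOISE)
        cluster += 1
    return labels


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def choose_k(
    D: np.ndarray,
    k_max: int,
    silhouette_threshold: float = 0.25,
) -> int:
    """Mean-silhouette selection of the cluster count for PAM.

    Evaluates k in 2..min(k_max, n-1); returns the argmax (smallest k on
    ties), or 1 when even the best silhouette falls below the acceptance
    threshold (the data do not support splitting).
    """
    from sklearn.metrics import silhouette_score

    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2 or float(D.max()) < 1e-9:  # degenerate: identical items
        return 1
    best_k, best_s = 1, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        labels = pam_kmedoids(D, k).labels
        if len(set(labels)) < 2:
            continue
        s = float(silhouette_score(D, labels, metric="precomputed"))
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_s < silhouette_threshold:
        return 1
    return best_k


# ---------------------------------------------------------------------------
# stage 1: backbone clustering
# ---------------------------------------------------------------------------

def hybrid_bb_cluster(
    dihedral_vectors: Sequence[Sequence[float]],
    eps: Optional[float] = None,
    min_pts: Optional[int] = None,
    config: Optional[TurnmapConfig] = None,
) -> ClusterResult:
    """Hybrid DBSCAN / PAM backbone clustering in Ramachandran space.

    DBSCAN under the wraparound angular metric finds the number of dense
    groups and their medoids; PAM SWAP refinement runs on the non-noise
    points from those seeds; finally every noise point is assigned to its
    nearest medoid so that all turns carry a backbone label. With zero core
    points the whole set falls back to a single cluster.
    """
    cfg = config or TurnmapConfig()
    X = np.asarray(dihedral_vectors, dtype=float)
    n = X.shape[0]
    D = angular_distance_matrix(X)
    if eps is None:
        eps = cfg.dbscan_eps
    if min_pts is None:
        min_pts = min(cfg.dbscan_min_pts, max(5, n // 50))

    db = dbscan(D, eps, min_pts)
    cluster_ids = sorted(set(l for l in db if l != NOISE))
    if not cluster_ids:
        med = int(D.sum(axis=1).argmin())
        return ClusterResult(labels=[0] * n, medoid_index={0: med}, sizes={0: n})

    dense = [i for i, l in enumerate(db) if l != NOISE]
    sub = np.ix_(dense, dense)
    Dd = D[sub]
    # seed medoids: per-DBSCAN-cluster medoid, then SWAP refinement
    seeds = []
    for cid in cluster_ids:
        members = [j for j, i in enumerate(dense) if db[i] == cid]
        rows = Dd[np.ix_(members, members)].sum(axis=1)
        seeds.append(members[int(rows.argmin())])
    medoids = sorted(seeds)
    cost = _pam_cost(Dd, medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(len(medoids)):
            for h in range(len(dense)):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = _pam_cost(Dd, trial)
                if c < cost - 1e-12:
                    medoids, cost = trial, c
                    improved = True
                    break
            if improved:
                break
    final_medoids = sorted(dense[m] for m in medoids)
    assignment = _assign(D, final_medoids)  # covers noise points too
    label_of = {m: i for i, m in enumerate(final_medoids)}
    labels = [label_of[m] for m in assignment]
    return ClusterResult(
        labels=labels,
        medoid_index={label_of[m]: m for m in final_medoids},
        sizes={l: labels.count(l) for l in range(len(final_medoids))},
    )


def split_cluster(
    result: ClusterResult,
    D: np.ndarray,
    target_label,
    parts: int,
) -> ClusterResult:
    """Split one cluster into ``parts`` sub-clusters by PAM on its members.

    New labels are ``f"{target_label}_{i}"`` with i = 1..parts ordered by
    sub-cluster size descending (ties: lower medoid index first); other
    clusters are untouched. This implements map-level refinements such as
    subdividing the dominant type-I backbone cluster.
    """
    members = result.members(target_label)
    if len(members) < parts:
        raise ValueError(
            f"cluster {target_label!r} has {len(members)} members < {parts} parts"
        )
    if parts == 1:
        return ClusterResult(
            labels=list(result.labels),
            medoid_index=dict(result.medoid_index),
            sizes=dict(result.sizes),
        )
    D = np.asarray(D, dtype=float)
    sub = pam_kmedoids(D[np.ix_(members, members)], parts)
    order = sorted(
        sub.cluster_labels(),
        key=lambda l: (-sub.sizes[l], members[sub.medoid_index[l]]),
    )
    rename = {old: f"{target_label}_{i + 1}" for i, old in enumerate(order)}
    labels = list(result.labels)
    for local, glob in enumerate(members):
        labels[glob] = rename[sub.labels[local]]
    medoid_index = {l: m for l, m in result.medoid_index.items() if l != target_label}
    sizes = {l: s for l, s in result.sizes.items() if l != target_label}
    for old, new in rename.items():
        medoid_index[new] = members[sub.medoid_index[old]]
        sizes[new] = sub.sizes[old]
    return ClusterResult(labels=labels, medoid_index=medoid_index, sizes=sizes)


def assign_to_reference(
    dihedral_vector: Sequence[float],
    reference_medoids: dict[str, Sequence[float]],
) -> str:
    """Label of the nearest reference medoid (wraparound metric); distance
    ties resolve to the alphabetically first label."""
    if not reference_medoids:
        raise ValueError("empty reference medoid set")
    best = None
    for label in sorted(reference_medoids):
        d = angular_distance(dihedral_vector, reference_medoids[label])
        if best is None or d < best[0] - 1e-12:
            best = (d, label)
    return best[1]


def read_reference_medoids(path: str | Path) -> dict[str, list[float]]:
    """TSV reference medoids: label, phi2, psi2, phi3, psi3[, more angles]."""
    out: dict[str, list[float]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.replace("\t", " ").split()
        if len(fields) < 5:
            raise ValueError(f"malformed medoid line: {line!r}")
        out[fields[0]] = [float(x) for x in fields[1:]]
    if not out:
        raise ValueError(f"no medoids in {path}")
    return out


# ---------------------------------------------------------------------------
# stages 2 and 3: side chains and tails in the turn-local frame
# ---------------------------------------------------------------------------

# Chemically equivalent side-chain atoms swapped together when comparing
# conformations (ring flips / carboxylate and guanidinium exchanges).
SYMMETRIC_SWAPS: dict[str, list[list[tuple[str, str]]]] = {
    "D": [[("OD1", "OD2")]],
    "E": [[("OE1", "OE2")]],
    "R": [[("NH1", "NH2")]],
    "F": [[("CD1", "CD2"), ("CE1", "CE2")]],
    "Y": [[("CD1", "CD2"), ("CE1", "CE2")]],
}

TAIL_BACKBONE = ("N", "CA", "C", "O")


@dataclass
class TailGroup:
    label: str
    members: list[int]            # global turn indices
    medoid: int                   # global turn index


@dataclass
class SCCluster:
    label: str
    members: list[int]
    medoid: int
    n_tails: list[TailGroup] = field(default_factory=list)
    c_tails: list[TailGroup] = field(default_factory=list)


@dataclass
class BBEntryClusters:
    bb_label: str
    members: list[int]
    medoid: int
    sc_clusters: list[SCCluster] = field(default_factory=list)
    warning: Optional[str] = None


def _local_sidechain_coords(turn: TurnInstance, position: str) -> tuple[list[str], np.ndarray]:
    res = turn.residue_at(position)
    if res is None:
        return [], np.zeros((0, 3))
    atoms = [a for a in res.atoms if a.name not in ("N", "CA", "C", "O")]
    atoms.sort(key=lambda a: a.name)
    names = [a.name for a in atoms]
    if not atoms:
        return [], np.zeros((0, 3))
    coords = np.array([turn.frame.rotation @ a.coord + turn.frame.translation for a in atoms])
    return names, coords


def _symmetric_rms(names_x: list[str], x: np.ndarray, names_y: list[str],
                   y: np.ndarray, aa: str) -> float:
    """RMS over name-matched atoms, minimized over chemically equivalent
    swaps within each symmetric group."""
    idx = {n: i for i, n in enumerate(names_x)}
    idy = {n: i for i, n in enumerate(names_y)}
    common = [n for n in names_x if n in idy]
    if not common:
        return 0.0
    swap_atoms = {a for group in SYMMETRIC_SWAPS.get(aa, []) for p in group for a in p}
    base = [n for n in common if n not in swap_atoms]
    total = sum(float(((x[idx[n]] - y[idy[n]]) ** 2).sum()) for n in base)
    count = len(base)
    for group in SYMMETRIC_SWAPS.get(aa, []):
        pairs = [(a, b) for a, b in group if a in idx and b in idx and a in idy and b in idy]
        if not pairs:
            continue
        straight = sum(
            float(((x[idx[a]] - y[idy[a]]) ** 2).sum()) +
            float(((x[idx[b]] - y[idy[b]]) ** 2).sum())
            for a, b in pairs
        )
        flipped = sum(
            float(((x[idx[a]] - y[idy[b]]) ** 2).sum()) +
            float(((x[idx[b]] - y[idy[a]]) ** 2).sum())
            for a, b in pairs
        )
        total += min(straight, flipped)
        count += 2 * len(pairs)
    return float(np.sqrt(total / count)) if count else 0.0


def sc_distance_matrix(turns: Sequence[TurnInstance], positions: Sequence[str]) -> np.ndarray:
    """Pairwise side-chain RMS over the motif positions, in local frames."""
    per_turn = []
    for t in turns:
        entry = []
        for p in positions:
            res = t.residue_at(p)
            aa = res.aa if res is not None else "?"
            names, coords = _local_sidechain_coords(t, p)
            entry.append((aa, names, coords))
        per_turn.append(entry)
    n = len(turns)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num, den = 0.0, 0
            for (aa, nx, cx), (_aa2, ny, cy) in zip(per_turn[i], per_turn[j]):
                if len(nx) == 0 or len(ny) == 0:
                    continue
                r = _symmetric_rms(nx, cx, ny, cy, aa)
                m = len([x for x in nx if x in ny])
                num += r * r * m
                den += m
            D[i, j] = D[j, i] = float(np.sqrt(num / den)) if den else 0.0
    return D


def _tail_coords(turn: TurnInstance, side: str) -> Optional[np.ndarray]:
    tail = turn.n_tail if side == "n" else turn.c_tail
    if not tail:
        return None
    coords = []
    for res in tail:
        for name in TAIL_BACKBONE:
            a = res.atom(name)
            if a is None:
                return None
            coords.append(turn.frame.rotation @ a.coord + turn.frame.translation)
    return np.array(coords)


def _cluster_tails(
    turns: Sequence[TurnInstance],
    member_idx: list[int],
    side: str,
    cfg: TurnmapConfig,
) -> list[TailGroup]:
    """Cluster one tail side of an SC cluster's members.

    Tails are partitioned by length (2, 1, 0 residues); equal-length tails
    are clustered by backbone RMS in the turn-local frame, and members with
    no tail form the designated "absent" group.
    """
    by_len: dict[int, list[int]] = {}
    for gi in member_idx:
        coords = _tail_coords(turns[gi], side)
        length = 0 if coords is None else len(coords) // len(TAIL_BACKBONE)
        by_len.setdefault(length, []).append(gi)

    groups: list[TailGroup] = []
    for length in sorted(by_len, reverse=True):
        members = by_len[length]
        if length == 0:
            groups.append(TailGroup(label="absent", members=members, medoid=min(members)))
            continue
        coords = [_tail_coords(turns[gi], side) for gi in members]
        if len(members) == 1:
            groups.append(TailGroup(label="tmp", members=members, medoid=members[0]))
            continue
        D = pairwise_rms_matrix(coords)
        k = choose_k(D, cfg.tail_k_max, cfg.silhouette_threshold)
        res = pam_kmedoids(D, k)
        for l in res.cluster_labels():
            mem = [members[i] for i in res.members(l)]
            groups.append(TailGroup(label="tmp", members=mem,
                                    medoid=members[res.medoid_index[l]]))
    named = sorted(
        [g for g in groups if g.label != "absent"],
        key=lambda g: (-len(g.members), g.medoid),
    )
    prefix = side.upper()
    for i, g in enumerate(named):
        g.label = f"{prefix}{i + 1}"
    return named + [g for g in groups if g.label == "absent"]


def motif_hierarchy(
    turns: Sequence[TurnInstance],
    motif,
    k_max: Optional[int] = None,
    config: Optional[TurnmapConfig] = None,
    bb_labels: Optional[Sequence] = None,
) -> dict[str, BBEntryClusters]:
    """Stages 2+3 for the turns matching a motif, grouped by backbone cluster.

    Within each backbone cluster the matching turns are clustered by the RMS
    of the motif side chains in the turn-local frame (cluster count by
    silhouette selection), and within each side-chain cluster the N- and
    C-terminal tails are clustered independently the same way. Sizes are
    conserved at every level.
    """
    from .motif_stats import match_motif  # late import to avoid a cycle

    cfg = config or TurnmapConfig()
    k_max = k_max if k_max is not None else cfg.sc_k_max
    positions = [p for p, _aa in motif.constraints]

    labels = list(bb_labels) if bb_labels is not None else [t.bb_cluster for t in turns]
    matching: dict[str, list[int]] = {}
    for i, t in enumerate(turns):
        if labels[i] is None:
            continue
        if match_motif(t, motif):
            matching.setdefault(str(labels[i]), []).append(i)

    out: dict[str, BBEntryClusters] = {}
    for bb_label, member_idx in sorted(matching.items()):
        vecs = [turns[i].dihedral_vector for i in member_idx]
        Dbb = angular_distance_matrix(vecs)
        bb_medoid = member_idx[int(Dbb.sum(axis=1).argmin())]
        entry = BBEntryClusters(bb_label=bb_label, members=member_idx, medoid=bb_medoid)

        sub_turns = [turns[i] for i in member_idx]
        Dsc = sc_distance_matrix(sub_turns, positions)
        if np.allclose(Dsc, 0.0) and any(
            len(_local_sidechain_coords(t, p)[0]) == 0
            for t in sub_turns for p in positions
        ):
            entry.warning = "motif side chain has no heavy atoms (Gly); single SC cluster"
            warnings.warn(entry.warning, stacklevel=2)
            k = 1
        else:
            k = choose_k(Dsc, k_max, cfg.silhouette_threshold) if len(member_idx) > 1 else 1
        res = pam_kmedoids(Dsc, k)
        sc_list = []
        for l in res.cluster_labels():
            mem = [member_idx[i] for i in res.members(l)]
            sc_list.append(SCCluster(label="tmp", members=mem,
                                     medoid=member_idx[res.medoid_index[l]]))
        sc_list.sort(key=lambda c: (-len(c.members), c.medoid))
        for i, c in enumerate(sc_list):
            c.label = f"SC{i + 1}"
            c.n_tails = _cluster_tails(turns, c.members, "n", cfg)
            c.c_tails = _cluster_tails(turns, c.members, "c", cfg)
        entry.sc_clusters = sc_list
        out[bb_label] = entry
    return out
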