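import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turnmap.config import TurnmapConfig
from turnmap.structure_io import Atom, Chain, Residue, Structure
from turnmap.peptide_builder import ResidueSpec, build_fragment
from turnmap.turn_geometry import (
    FrameTransform,
    GeometryError,
    apply_frame,
    assign_ss,
    backbone_dihedrals,
    dihedral,
    rama_label,
    turn_frame,
)
from conftest import random_rigid_motion


def oracle_dihedral(p1, p2, p3, p4):
    """Independent torsion implementation: project the outer bonds onto the
    plane orthogonal to the central bond and take the signed angle."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b = p3 - p2
    b = b / np.linalg.norm(b)
    u = (p1 - p2) - np.dot(p1 - p2, b) * b
    v = (p4 - p3) - np.dot(p4 - p3, b) * b
    # signed angle from u (toward p1) to v (toward p4) about b
    return float(np.degrees(np.arctan2(np.dot(np.cross(u, v), b), np.dot(u, v))))


@pytest.mark.parametrize(
    "pts,expected",
    [
        ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], 0.0),
        ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)], 180.0),
        ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)], 90.0),
        ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, -1)], -90.0),
    ],
)
def test_dihedral_reference_values(pts, expected):
    assert dihedral(*pts) == pytest.approx(expected, abs=1e-9)


def test_dihedral_matches_independent_oracle_on_random_quadruples(rng):
    for _ in range(1000):
        pts = rng.normal(scale=3.0, size=(4, 3))
        try:
            ours = dihedral(*pts)
        except GeometryError:
            continue
        ref = oracle_dihedral(*pts)
        diff = abs(ours - ref) % 360.0
        assert min(diff, 360.0 - diff) < 1e-6


def test_dihedral_degenerate_raises():
    with pytest.raises(GeometryError):
        dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
    with pytest.raises(GeometryError):
        dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


def test_backbone_dihedrals_absent_at_termini_and_breaks(type1_window):
    chain = type1_window.chains[0]
    geoms = backbone_dihedrals(chain)
    assert geoms[0].phi is None and geoms[-1].psi is None
    assert geoms[3].phi == pytest.approx(-60, abs=1e-3)
    assert geoms[3].psi == pytest.approx(-30, abs=1e-3)
    # introduce a 10 A gap after residue 3
    broken = copy.deepcopy(chain)
    for res in broken.residues[4:]:
        for a in res.atoms:
            a.coord = a.coord + np.array([10.0, 0, 0])
    g2 = backbone_dihedrals(broken)
    assert g2[3].psi is None and g2[4].phi is None and g2[4].omega is None


@pytest.mark.parametrize(
    "phi,psi,omega,expected",
    [
        (-60, -30, 180, "A"),
        (-120, 130, 180, "B"),
        (60, 40, 180, "L"),
        (60, 170, 180, "E"),
        (-100, -120, 180, "G"),
        (-75, 150, 0, "b"),  # cis bond lowercases the label
    ],
)
def test_rama_label_regions(phi, psi, omega, expected):
    assert rama_label(phi, psi, omega) == expected


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.floats(-180, 180), st.floats(-180, 180))
def test_rama_label_tiles_the_full_torus(phi, psi):
    lab = rama_label(phi, psi, 180.0)
    assert lab in set("ABLEG")


def _fragment(phipsi, n):
    return build_fragment([ResidueSpec("A", p, s) for p, s in [phipsi] * n])


def test_assign_ss_runs():
    helix = _fragment((-60, -45), 8)
    assert assign_ss(helix.chains[0]) == ["H"] * 8
    strand = _fragment((-120, 130), 6)
    assert assign_ss(strand.chains[0]) == ["E"] * 6
    # alternating angles break every run
    specs = []
    for i in range(8):
        specs.append(ResidueSpec("A", -60 if i % 2 else -120, -45 if i % 2 else 130))
    mixed = build_fragment(specs)
    assert assign_ss(mixed.chains[0]) == ["C"] * 8


def test_assign_ss_override_takes_precedence():
    helix = _fragment((-60, -45), 8)
    labels = assign_ss(helix.chains[0], override={3: "E"})
    assert labels[2] == "E" and labels[0] == "H"  # seq_index 3 is residue #2


def _turn_residues(structure):
    return structure.chains[0].residues[2:6]


def test_turn_frame_normalizes_pose(type1_window):
    f = turn_frame(_turn_residues(type1_window))
    R = f.rotation
    assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
    cas = np.array([r.atom("CA").coord for r in _turn_residues(type1_window)])
    local = cas @ R.T + f.translation
    assert np.allclose(local.mean(axis=0), 0.0, atol=1e-9)
    x = local[3] - local[0]
    assert x[0] > 0 and abs(x[1]) < 1e-9 and abs(x[2]) < 1e-9
    mid = 0.5 * (local[1] + local[2])
    assert mid[1] >= -1e-9  # central midpoint on the +y side


def test_turn_frame_invariant_under_rigid_motion(type1_window, rng):
    base = _turn_residues(type1_window)
    f0 = turn_frame(base)
    ref = np.array([a.coord for r in base for a in r.atoms])
    ref_local = ref @ f0.rotation.T + f0.translation
    worst = 0.0
    for _ in range(100):
        R, t = random_rigid_motion(rng)
        moved = copy.deepcopy(base)
        for r in moved:
            for a in r.atoms:
                a.coord = R @ a.coord + t
        f = turn_frame(moved)
        coords = np.array([a.coord for r in moved for a in r.atoms])
        local = coords @ f.rotation.T + f.translation
        worst = max(worst, float(np.abs(local - ref_local).max()))
    assert worst <= 1e-6


def test_turn_frame_distinguishes_mirror_image(type1_window):
    base = _turn_residues(type1_window)
    f = turn_frame(base)
    mirrored = copy.deepcopy(base)
    for r in mirrored:
        for a in r.atoms:
            a.coord = a.coord * np.array([-1.0, 1.0, 1.0])
    fm = turn_frame(mirrored)
    assert np.linalg.det(fm.rotation) == pytest.approx(1.0, abs=1e-9)
    o = base[1].atom("O").coord
    om = mirrored[1].atom("O").coord
    z = (f.rotation @ o + f.translation)[2]
    zm = (fm.rotation @ om + fm.translation)[2]
    assert z * zm < 0  # reference atom lands on opposite z sides


def test_turn_frame_degenerate_inputs(type1_window):
    res = copy.deepcopy(_turn_residues(type1_window))
    res[3].atom("CA").coord = res[0].atom("CA").coord.copy()
    with pytest.raises(GeometryError):
        turn_frame(res)


def test_apply_frame_rigidity(type1_window, rng):
    f = turn_frame(_turn_residues(type1_window))
    moved = apply_frame(type1_window, f)
    back = apply_frame(moved, f.inverse())
    for co, cb in zip(type1_window.chains[0].residues, back.chains[0].residues):
        for ao, ab in zip(co.atoms, cb.atoms):
            assert np.allclose(ao.coord, ab.coord, atol=1e-9)
    # pairwise distances preserved
    orig = np.array([a.coord for r in type1_window.chains[0].residues for a in r.atoms])
    new = np.array([a.coord for r in moved.chains[0].residues for a in r.atoms])
    do = np.linalg.norm(orig[:, None] - orig[None, :], axis=2)
    dn = np.linalg.norm(new[:, None] - new[None, :], axis=2)
    assert np.abs(do - dn).max() < 1e-9
    ident = apply_frame(type1_window, FrameTransform.identity())
    assert np.allclose(
        ident.chains[0].residues[0].atoms[0].coord,
        type1_window.chains[0].residues[0].atoms[0].coord,
    )


def test_custom_rama_boxes_are_honored():
    cfg = TurnmapConfig()
    cfg.rama_boxes = {"Z": [(-180.0, 180.0, -180.0, 180.0)]}
    assert rama_label(-60, -30, 180, cfg.rama_boxes) == "Z"
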