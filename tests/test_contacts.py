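"""Geometric protein-RNA contact detection: boundary cases, oracle
equivalence, rigid-body invariance, reporting."""

import math

import numpy as np
import pytest

from quadrufold.contacts import (
    AtomRecord,
    ContactCriteria,
    aggregate_replicates,
    backbone_rmsd,
    contact_report,
    detect_hbonds,
    detect_salt_bridges,
    detect_stacking,
    read_frames,
    write_frames,
    PROTEIN_ACCEPTORS,
    PROTEIN_DONORS,
    RNA_ACCEPTORS,
    RNA_DONORS,
    CATIONIC_GROUPS,
    ANIONIC_RNA_ATOMS,
    PROTEIN_RINGS,
    PURINE_RING,
    PYRIMIDINE_RING,
    MAX_DH_BOND,
    _rna_base,
)
from quadrufold.synth import ContactPlan, gen_frames


def atom(name, res_name, res_id, coord, chain="A", element=None):
    el = element or ("H" if name.startswith("H") else name[0])
    return AtomRecord(
        name=name, element=el, res_name=res_name, res_id=res_id,
        chain_id=chain, coord=tuple(float(c) for c in coord),
    )


def ser_donor(res_id=1, og=(0, 0, 0), hg=(0.97, 0, 0)):
    return [atom("OG", "SER", res_id, og), atom("HG", "SER", res_id, hg)]


# ---------------------------------------------------------------------------
# hydrogen bonds

def test_collinear_hbond_detected():
    frame = ser_donor() + [atom("O6", "G", 10, (2.9, 0, 0), chain="B")]
    bonds = detect_hbonds(frame)
    assert len(bonds) == 1
    b = bonds[0]
    assert b.distance == pytest.approx(2.9)
    assert b.angle == pytest.approx(180.0)
    assert b.target == "base"
    assert b.residue_type == "SER"


def test_hbond_distance_beyond_cutoff_rejected():
    frame = ser_donor() + [atom("O6", "G", 10, (3.6, 0, 0), chain="B")]
    assert detect_hbonds(frame) == []


def test_hbond_angle_below_cutoff_rejected():
    # H positioned so the donor-H-acceptor angle is ~101 deg at d = 2.9
    ang = math.radians(60.0)
    hg = (0.97 * math.cos(ang), 0.97 * math.sin(ang), 0)
    frame = ser_donor(hg=hg) + [atom("O6", "G", 10, (2.9, 0, 0), chain="B")]
    assert detect_hbonds(frame) == []


def test_hbond_boundary_values_inclusive():
    # exactly d = 3.5 and angle exactly 120 deg both count
    frame = ser_donor() + [atom("O6", "G", 10, (3.5, 0, 0), chain="B")]
    assert len(detect_hbonds(frame)) == 1
    # place H so that the angle at H is exactly 120 deg
    d, r = 2.9, 0.97
    for theta in np.linspace(0, math.pi / 2, 20001):
        h = (r * math.cos(theta), r * math.sin(theta), 0)
        v1 = np.array([0, 0, 0]) - np.array(h)
        v2 = np.array([d, 0, 0]) - np.array(h)
        a = math.degrees(
            math.acos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        )
        if abs(a - 120.0) < 5e-3:
            frame = ser_donor(hg=h) + [atom("O6", "G", 10, (d, 0, 0), chain="B")]
            assert len(detect_hbonds(frame)) == 1
            break
    else:
        pytest.fail("no 120-degree geometry found")


def test_rna_donor_to_protein_acceptor_direction():
    # guanine N2-H donating to a backbone carbonyl
    frame = [
        atom("N2", "G", 10, (0, 0, 0), chain="B"),
        atom("H21", "G", 10, (1.0, 0, 0), chain="B"),
        atom("O", "SER", 1, (3.0, 0, 0)),
    ]
    bonds = detect_hbonds(frame)
    assert len(bonds) == 1
    assert bonds[0].target == "base"


def test_moiety_classification():
    for name, moiety in [("O6", "base"), ("O2'", "ribose"), ("OP1", "phosphate")]:
        frame = ser_donor() + [atom(name, "G", 10, (2.9, 0, 0), chain="B")]
        assert detect_hbonds(frame)[0].target == moiety


def test_frame_without_hydrogens_rejected():
    frame = [
        atom("OG", "SER", 1, (0, 0, 0)),
        atom("O6", "G", 10, (2.9, 0, 0), chain="B"),
    ]
    with pytest.raises(ValueError, match="hydrogens"):
        detect_hbonds(frame)


# ---------------------------------------------------------------------------
# salt bridges

def test_salt_bridge_within_cutoff():
    frame = [
        atom("NH1", "ARG", 1, (0, 0, 0)),
        atom("OP1", "G", 10, (3.5, 0, 0), chain="B"),
    ]
    assert len(detect_salt_bridges(frame)) == 1


def test_group_minimum_distance_governs():
    frame = [
        atom("NH1", "ARG", 1, (0, 0, 0)),
        atom("NH2", "ARG", 1, (0.3, 0, 0)),
        atom("OP2", "G", 10, (4.2, 0, 0), chain="B"),
    ]
    # NH1 at 4.2, NH2 at 3.9: one bridge (group minimum below cutoff)
    bridges = detect_salt_bridges(frame)
    assert len(bridges) == 1
    assert bridges[0].distance == pytest.approx(3.9)


def test_salt_bridge_boundary_strict():
    frame = [
        atom("NZ", "LYS", 1, (0, 0, 0)),
        atom("OP1", "G", 10, (4.0, 0, 0), chain="B"),
    ]
    assert detect_salt_bridges(frame) == []  # "below 4 A" is strict


# ---------------------------------------------------------------------------
# stacking

def _hexagon(names, center, z, radius=1.39, tilt_deg=0.0):
    out = []
    t = math.radians(tilt_deg)
    for i, n in enumerate(names):
        a = math.radians(60 * i)
        x, y = radius * math.cos(a), radius * math.sin(a)
        yz = (y * math.cos(t), z + y * math.sin(t))
        out.append((n, (center[0] + x, center[1] + yz[0], yz[1])))
    return out


def _tyr_ring(res_id=1, center=(0, 0), z=0.0, tilt_deg=0.0):
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    return [
        atom(n, "TYR", res_id, c)
        for n, c in _hexagon(names, center, z, tilt_deg=tilt_deg)
    ]


def _base_ring(res_id=10, center=(0, 0), z=3.5, tilt_deg=0.0, base="C"):
    return [
        atom(n, base, res_id, c, chain="B")
        for n, c in _hexagon(PYRIMIDINE_RING, center, z, tilt_deg=tilt_deg)
    ]


def test_parallel_rings_stack():
    frame = _tyr_ring() + _base_ring(z=3.5)
    stacks = detect_stacking(frame)
    assert len(stacks) == 1
    assert stacks[0].distance == pytest.approx(3.5)
    assert stacks[0].angle == pytest.approx(0.0, abs=1e-6)


def test_tilted_rings_rejected():
    frame = _tyr_ring() + _base_ring(z=3.5, tilt_deg=45.0)
    assert detect_stacking(frame) == []


def test_distant_rings_rejected():
    frame = _tyr_ring() + _base_ring(z=4.5)
    assert detect_stacking(frame) == []


def test_guanidinium_counts_as_planar_cation():
    arg = [
        atom("CZ", "ARG", 1, (0, 0, 0)),
        atom("NE", "ARG", 1, (1.33, 0, 0)),
        atom("NH1", "ARG", 1, (-0.66, 1.15, 0)),
        atom("NH2", "ARG", 1, (-0.66, -1.15, 0)),
    ]
    frame = arg + _base_ring(z=3.4)
    stacks = detect_stacking(frame)
    assert len(stacks) == 1
    assert stacks[0].protein_res[0] == "ARG"


def test_degenerate_collinear_group_skipped():
    collinear = [
        atom("CG", "TYR", 1, (0, 0, 0)),
        atom("CD1", "TYR", 1, (1, 0, 0)),
        atom("CE1", "TYR", 1, (2, 0, 0)),
    ]
    frame = collinear + _base_ring(z=3.4)
    with pytest.warns(UserWarning, match="degenerate"):
        assert detect_stacking(frame) == []


# ---------------------------------------------------------------------------
# brute-force oracle equivalence

def _oracle_contacts(frame, criteria=ContactCriteria()):
    """All-pairs pure-python re-derivation of the three contact classes."""
    hbonds, bridges, stacks = set(), set(), set()

    def dist(a, b):
        return math.dist(a.coord, b.coord)

    def angle(p1, p2, p3):
        v1 = np.subtract(p1, p2)
        v2 = np.subtract(p3, p2)
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    prot = [a for a in frame if a.is_protein]
    rna = [a for a in frame if a.is_rna]
    hydrogens = [a for a in frame if a.element.upper() == "H"]

    def donors(side, table, key):
        out = []
        for a in side:
            names = table.get(key(a), set())
            if key(a) is not None and a.name in (
                names | (table.get("*", set()) if "*" in table else set())
            ):
                hs = [
                    h for h in hydrogens
                    if h.chain_id == a.chain_id and h.res_id == a.res_id
                    and dist(h, a) <= MAX_DH_BOND
                ]
                if hs:
                    out.append((a, hs))
        return out

    prot_d = donors(prot, PROTEIN_DONORS, lambda a: a.res_name.upper())
    rna_d = donors(rna, RNA_DONORS, lambda a: a.base)
    prot_a = [
        a for a in prot
        if a.name in PROTEIN_ACCEPTORS.get(a.res_name.upper(), set())
        | PROTEIN_ACCEPTORS["*"] and a.element.upper() != "H"
    ]
    rna_a = [
        a for a in rna if a.name in RNA_ACCEPTORS.get(a.base, set())
    ]
    for dlist, alist in ((prot_d, rna_a), (rna_d, prot_a)):
        for d, hs in dlist:
            for acc in alist:
                if dist(d, acc) <= criteria.hbond_distance_max and any(
                    angle(d.coord, h.coord, acc.coord) >= criteria.hbond_angle_min
                    for h in hs
                ):
                    hbonds.add(((d.chain_id, d.res_id, d.name),
                                (acc.chain_id, acc.res_id, acc.name)))

    cat, an = {}, {}
    for a in prot:
        if a.name in CATIONIC_GROUPS.get(a.res_name.upper(), ()):
            cat.setdefault((a.chain_id, a.res_id), []).append(a)
    for a in rna:
        if a.name in ANIONIC_RNA_ATOMS:
            an.setdefault((a.chain_id, a.res_id), []).append(a)
    for ck, cas in cat.items():
        for ak, aas in an.items():
            if min(dist(x, y) for x in cas for y in aas) < criteria.saltbridge_distance_max:
                bridges.add((ck, ak))

    def plane(atoms):
        xyz = np.array([a.coord for a in atoms])
        c = xyz.mean(axis=0)
        _, s, vt = np.linalg.svd(xyz - c)
        return (c, vt[2]) if s[1] >= 1e-6 else (None, None)

    prings, brings = {}, {}
    for a in prot:
        if a.name in PROTEIN_RINGS.get(a.res_name.upper(), ()):
            prings.setdefault((a.chain_id, a.res_id), []).append(a)
    ring_for = {"G": PURINE_RING, "A": PURINE_RING, "C": PYRIMIDINE_RING,
                "U": PYRIMIDINE_RING}
    for a in rna:
        if a.name in ring_for.get(a.base, ()):
            brings.setdefault((a.chain_id, a.res_id), []).append(a)
    for pk, pa in prings.items():
        if len(pa) < 3:
            continue
        pc, pn = plane(pa)
        if pc is None:
            continue
        for bk, ba in brings.items():
            if len(ba) < 3:
                continue
            bc, bn = plane(ba)
            if bc is None:
                continue
            d = float(np.linalg.norm(pc - bc))
            ang = math.degrees(math.acos(min(1.0, abs(float(np.dot(pn, bn))))))
            if d < criteria.stacking_distance_max and ang <= criteria.stacking_angle_max:
                stacks.add((pk, bk))
    return hbonds, bridges, stacks


def test_detection_matches_all_pairs_oracle():
    plan = ContactPlan(
        hbond_base=2, hbond_ribose=1, hbond_phosphate=1,
        salt_bridge=2, stacking=2, decoys=True,
    )
    frames, _ = gen_frames(plan, n_frames=3, jitter_sd=0.05, seed=99)
    for frame in frames:
        o_hb, o_sb, o_st = _oracle_contacts(frame)
        hb = {
            ((b.donor.chain_id, b.donor.res_id, b.donor.name),
             (b.acceptor.chain_id, b.acceptor.res_id, b.acceptor.name))
            for b in detect_hbonds(frame)
        }
        sb = {
            ((c[1], c[2]), (a[1], a[2]))
            for c, a in [(x.cation_res, x.anion_res) for x in detect_salt_bridges(frame)]
        }
        st = {
            ((c[1], c[2]), (a[1], a[2]))
            for c, a in [(x.protein_res, x.base_res) for x in detect_stacking(frame)]
        }
        assert hb == o_hb
        assert sb == o_sb
        assert st == o_st


def test_rigid_body_invariance():
    frames, truth = gen_frames(ContactPlan(), n_frames=1, jitter_sd=0.0, seed=1)
    frame = frames[0]
    theta = 0.7
    rot = np.array([
        [math.cos(theta), -math.sin(theta), 0],
        [math.sin(theta), math.cos(theta), 0],
        [0, 0, 1],
    ])
    shift = np.array([11.0, -3.0, 5.0])
    moved = [
        AtomRecord(
            name=a.name, element=a.element, res_name=a.res_name,
            res_id=a.res_id, chain_id=a.chain_id,
            coord=tuple(rot @ np.array(a.coord) + shift),
        )
        for a in frame
    ]
    b0, b1 = detect_hbonds(frame), detect_hbonds(moved)
    assert len(b0) == len(b1)
    for x, y in zip(b0, b1):
        assert abs(x.distance - y.distance) < 1e-9
        assert abs(x.angle - y.angle) < 1e-7
    assert len(detect_salt_bridges(frame)) == len(detect_salt_bridges(moved))
    assert len(detect_stacking(frame)) == len(detect_stacking(moved))


def test_enlarging_cutoffs_never_removes_contacts():
    frames, _ = gen_frames(ContactPlan(), n_frames=1, seed=4)
    frame = frames[0]
    tight = ContactCriteria()
    loose = ContactCriteria(
        hbond_distance_max=4.5, saltbridge_distance_max=5.0,
        stacking_distance_max=5.0,
    )
    assert len(detect_hbonds(frame, loose)) >= len(detect_hbonds(frame, tight))
    assert len(detect_salt_bridges(frame, loose)) >= len(
        detect_salt_bridges(frame, tight)
    )
    assert len(detect_stacking(frame, loose)) >= len(
        detect_stacking(frame, tight)
    )


# ---------------------------------------------------------------------------
# frame I/O and reporting

def test_multi_model_roundtrip(tmp_path):
    frames, _ = gen_frames(ContactPlan(), n_frames=3, seed=8)
    path = tmp_path / "frames.pdb"
    write_frames(frames, path)
    back = read_frames(path)
    assert len(back) == 3
    assert len(back[0]) == len(frames[0])
    for a, b in zip(frames[0], back[0]):
        assert a.name == b.name
        assert np.allclose(a.coord, b.coord, atol=1e-2)  # PDB precision


def test_single_model_file(tmp_path):
    frames, _ = gen_frames(ContactPlan(), n_frames=1, seed=8)
    path = tmp_path / "one.pdb"
    write_frames(frames, path)
    assert len(read_frames(path)) == 1


def test_truncated_record_errors_with_line_number(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text("MODEL     1\nATOM      1  OG  SER A   1      0.0\n")
    with pytest.raises(ValueError, match="bad.pdb:2"):
        read_frames(path)


def test_contact_report_counts_planted_truth():
    plan = ContactPlan(hbond_base=2, hbond_phosphate=1, salt_bridge=3, stacking=1)
    frames, truth = gen_frames(plan, n_frames=4, seed=21)
    report = contact_report(frames)
    for cls, k in truth.items():
        assert (report.per_frame[cls] == k).all(), cls
    # residue attribution sums match totals
    total_hb = report.per_frame["hbond_base"].sum() + report.per_frame["hbond_backbone"].sum()
    assert sum(v["hbond"] for v in report.by_residue.values()) == total_hb
    assert sum(report.base_hbond_by_residue.values()) == report.per_frame["hbond_base"].sum()


def test_protein_only_frame_counts_zero():
    frame = ser_donor() + [atom("O", "ALA", 2, (5, 5, 5))]
    report = contact_report([frame])
    assert report.per_frame.iloc[0].sum() == 0


def test_replicate_aggregation_mean_sd():
    reports = [
        contact_report(gen_frames(ContactPlan(), n_frames=2, seed=s)[0])
        for s in (1, 2, 3)
    ]
    agg = aggregate_replicates(reports)
    assert agg["salt_bridge"]["mean"] == pytest.approx(1.0)
    assert agg["salt_bridge"]["sd"] == pytest.approx(0.0)


def test_backbone_rmsd_zero_for_identical_frames():
    frames, _ = gen_frames(ContactPlan(), n_frames=1, jitter_sd=0.0, seed=3)
    rmsd = backbone_rmsd([frames[0], frames[0]], atom_names=set())
    assert rmsd == pytest.approx([0.0, 0.0], abs=1e-12)


def test_rna_residue_name_normalization():
    assert _rna_base("G") == "G"
    assert _rna_base("RG") == "G"
    assert _rna_base("G5") == "G"
    assert _rna_base("SER") is None
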