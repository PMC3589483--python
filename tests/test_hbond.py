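"""Hydrogen-bond detection, classification, occupancy and RMSF."""
import math

import numpy as np
import pytest

from oxohb.hbond import (
    BONDI_RADII,
    HBondCriterion,
    backbone_rmsf,
    classify_frame,
    detect_hbonds,
    occupancy,
)
from oxohb.io import Frame, frame_from_atoms
from oxohb.synthetic import _SimpleAtom


def _res(resname, chain, resid, atoms):
    return (resname, chain, resid,
            [_SimpleAtom(n, e, p) for n, e, p in atoms])


def donor_lys(chain, resid, n_pos, h_toward=None):
    n_pos = np.asarray(n_pos, float)
    atoms = [("NZ", "N", n_pos)]
    if h_toward is not None:
        d = np.asarray(h_toward, float) - n_pos
        atoms.append(("HZ1", "H", n_pos + 1.0 * d / np.linalg.norm(d)))
    return _res("LYS", chain, resid, atoms)


def acceptor_sep(chain, resid, o_positions):
    atoms = [("P", "P", np.mean(o_positions, axis=0) + [0, 0, 1.5])]
    for k, p in enumerate(o_positions, 1):
        atoms.append((f"O{k}P", "O", np.asarray(p, float)))
    return _res("SEP", chain, resid, atoms)


class TestDistanceAngleCriterion:
    def test_bond_inside_both_cutoffs(self):
        o = [0.0, 0.0, 0.0]
        frame = frame_from_atoms([
            acceptor_sep("A", 1, [o]),
            donor_lys("A", 2, [2.8, 0.0, 0.0], h_toward=o),
        ])
        bonds = detect_hbonds(frame, HBondCriterion())
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.8)
        assert 180.0 - bonds[0].angle <= 1e-6

    def test_distance_beyond_cutoff(self):
        o = [0.0, 0.0, 0.0]
        frame = frame_from_atoms([
            acceptor_sep("A", 1, [o]),
            donor_lys("A", 2, [3.2, 0.0, 0.0], h_toward=o),
        ])
        assert detect_hbonds(frame, HBondCriterion()) == []

    def test_angle_beyond_cutoff(self):
        # H pointing 90 degrees off the N-O axis
        frame = frame_from_atoms([
            acceptor_sep("A", 1, [[0.0, 0.0, 0.0]]),
            donor_lys("A", 2, [2.8, 0.0, 0.0], h_toward=[2.8, 5.0, 0.0]),
        ])
        assert detect_hbonds(frame, HBondCriterion()) == []

    def test_hydrogen_free_frame_rejected(self):
        frame = frame_from_atoms([
            acceptor_sep("A", 1, [[0.0, 0.0, 0.0]]),
            donor_lys("A", 2, [2.8, 0.0, 0.0]),
        ])
        with pytest.raises(ValueError, match="hydrogens"):
            detect_hbonds(frame, HBondCriterion())


class TestRadiusSumCriterion:
    def test_heavy_atom_contact(self):
        rsum = BONDI_RADII["N"] + BONDI_RADII["O"]   # 3.07
        frame = frame_from_atoms([
            acceptor_sep("A", 1, [[0.0, 0.0, 0.0]]),
            donor_lys("A", 2, [rsum - 0.05, 0.0, 0.0]),
        ])
        crit = HBondCriterion(mode="radius_sum")
        assert len(detect_hbonds(frame, crit)) == 1
        frame2 = frame_from_atoms([
            acceptor_sep("A", 1, [[0.0, 0.0, 0.0]]),
            donor_lys("A", 2, [rsum + 0.05, 0.0, 0.0]),
        ])
        assert detect_hbonds(frame2, crit) == []

    def test_radius_table_must_cover_elements(self):
        with pytest.raises(ValueError, match="radius table"):
            HBondCriterion(mode="radius_sum", radius_table={"N": 1.55})


def _brute_force(frame, crit):
    """Independent all-pairs reimplementation (plain python)."""
    from oxohb.hbond import SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS

    found = set()
    n = len(frame)
    for i in range(n):
        rn, an = frame.resnames[i], frame.names[i]
        is_donor = (rn, an) in SIDECHAIN_DONORS or (
            an == "N" and frame.elements[i] == "N")
        if not is_donor:
            continue
        for j in range(n):
            names = SIDECHAIN_ACCEPTORS.get(frame.resnames[j])
            if not names or frame.names[j] not in names:
                continue
            if (frame.chains[i], frame.resids[i]) == (
                    frame.chains[j], frame.resids[j]):
                continue
            dx = frame.coords[i] - frame.coords[j]
            dist = math.sqrt(float(dx @ dx))
            if crit.mode == "radius_sum":
                if dist < (crit.radius_table[frame.elements[i]]
                           + crit.radius_table[frame.elements[j]]):
                    found.add((i, j))
            else:
                if dist > crit.distance_cutoff:
                    continue
                for h in range(n):
                    if frame.elements[h] != "H":
                        continue
                    if (frame.chains[h], frame.resids[h]) != (
                            frame.chains[i], frame.resids[i]):
                        continue
                    hv = frame.coords[h] - frame.coords[i]
                    if math.sqrt(float(hv @ hv)) > 1.25:
                        continue
                    v1 = frame.coords[i] - frame.coords[h]
                    v2 = frame.coords[j] - frame.coords[h]
                    c = float(v1 @ v2) / (
                        math.sqrt(float(v1 @ v1)) * math.sqrt(float(v2 @ v2)))
                    ang = math.degrees(math.acos(max(-1.0, min(1.0, c))))
                    if 180.0 - ang <= crit.angle_cutoff:
                        found.add((i, j))
                        break
    return found


def _random_frame(rng):
    groups = []
    resid = 1
    for _ in range(rng.integers(2, 5)):
        o = rng.uniform(-4, 4, 3)
        groups.append(acceptor_sep("A", resid, [o]))
        resid += 1
    for _ in range(rng.integers(3, 8)):
        npos = rng.uniform(-5, 5, 3)
        h_toward = rng.uniform(-5, 5, 3)
        groups.append(donor_lys("A", resid, npos, h_toward=h_toward))
        resid += 1
    return frame_from_atoms(groups)


@pytest.mark.parametrize("mode", ["distance_angle", "radius_sum"])
def test_detection_equals_brute_force_oracle(mode):
    rng = np.random.default_rng(20260921)
    crit = HBondCriterion(mode=mode)
    for _ in range(100):
        frame = _random_frame(rng)
        got = {(b.donor_atom.index, b.acceptor_atom.index)
               for b in detect_hbonds(frame, crit)}
        assert got == _brute_force(frame, crit)


def _arg_frame(contacts):
    """Arg donor with explicit N/H positions against a two-oxygen SEP."""
    o1 = np.array([0.0, 1.2, 0.0])
    o2 = np.array([0.0, -1.2, 0.0])
    atoms = []
    for name, hname, o in contacts:
        npos = o + np.array([2.8, 0.0, 0.0])
        atoms.append((name, "N", npos))
        atoms.append((hname, "H", npos - [1.0, 0.0, 0.0]))
    return frame_from_atoms([
        acceptor_sep("A", 1, [o1, o2]),
        _res("ARG", "A", 2, atoms),
    ])


class TestClassification:
    def test_two_nitrogens_two_oxygens_is_bidentate(self):
        frame = _arg_frame([("NH1", "HH11", np.array([0.0, 1.2, 0.0])),
                            ("NH2", "HH21", np.array([0.0, -1.2, 0.0]))])
        fc = classify_frame(frame, ("A", 2), ("A", 1))
        assert fc.label == "bidentate"
        assert len(fc.bonds) == 2

    def test_one_nitrogen_two_oxygens_is_single(self):
        # one NH1 equidistant from both oxygens
        o1 = np.array([0.0, 1.2, 0.0])
        npos = np.array([2.4, 0.0, 0.0])
        frame = frame_from_atoms([
            acceptor_sep("A", 1, [o1, -o1]),
            _res("ARG", "A", 2, [
                ("NH1", "N", npos),
                ("HH11", "H", npos + 0.95 * (o1 - npos) / np.linalg.norm(o1 - npos)),
                ("HH12", "H", npos + 0.95 * (-o1 - npos) / np.linalg.norm(-o1 - npos)),
            ]),
        ])
        fc = classify_frame(frame, ("A", 2), ("A", 1))
        assert len(fc.bonds) == 2
        assert fc.label == "single"

    def test_no_contact_is_none(self):
        frame = _arg_frame([("NH1", "HH11", np.array([8.0, 1.2, 0.0]))])
        assert classify_frame(frame, ("A", 2), ("A", 1)).label == "none"

    def test_missing_residue_raises(self):
        frame = _arg_frame([("NH1", "HH11", np.array([0.0, 1.2, 0.0]))])
        with pytest.raises(ValueError, match="not found"):
            classify_frame(frame, ("B", 9), ("A", 1))

    def test_label_invariant_under_nh1_nh2_swap(self):
        frame = _arg_frame([("NH1", "HH11", np.array([0.0, 1.2, 0.0])),
                            ("NH2", "HH21", np.array([0.0, -1.2, 0.0]))])
        swapped = _arg_frame([("NH2", "HH21", np.array([0.0, 1.2, 0.0])),
                              ("NH1", "HH11", np.array([0.0, -1.2, 0.0]))])
        assert (classify_frame(frame, ("A", 2), ("A", 1)).label
                == classify_frame(swapped, ("A", 2), ("A", 1)).label)


class TestOccupancy:
    def _traj(self, labels):
        frames = []
        for lbl in labels:
            if lbl == "bidentate":
                frames.append(_arg_frame(
                    [("NH1", "HH11", np.array([0.0, 1.2, 0.0])),
                     ("NH2", "HH21", np.array([0.0, -1.2, 0.0]))]))
            elif lbl == "single":
                frames.append(_arg_frame(
                    [("NH1", "HH11", np.array([0.0, 1.2, 0.0]))]))
            else:
                frames.append(_arg_frame(
                    [("NH1", "HH11", np.array([9.0, 1.2, 0.0]))]))
        return frames

    def test_planted_fraction_recovered(self):
        rec = occupancy(self._traj(["single"] * 4 + ["none"] * 6),
                        ("A", 2), ("A", 1))
        assert rec.any_pct == 40.0

    def test_partition_of_percentages(self):
        labels = ["bidentate"] * 2 + ["single"] * 3 + ["none"] * 5
        rec = occupancy(self._traj(labels), ("A", 2), ("A", 1))
        assert (rec.any_pct, rec.single_pct, rec.bidentate_pct) == (
            50.0, 30.0, 20.0)
        assert rec.single_pct + rec.bidentate_pct == rec.any_pct

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            occupancy([], ("A", 2), ("A", 1))


def _backbone_res(chain, resid, base, o_offset=None):
    base = np.asarray(base, float)
    o = base + ([1.2, 1.2, 0.0] if o_offset is None else o_offset)
    return _res("GLY", chain, resid, [
        ("N", "N", base),
        ("CA", "C", base + [1.5, 0.0, 0.0]),
        ("C", "C", base + [2.2, 1.3, 0.0]),
        ("O", "O", o),
    ])


class TestRMSF:
    def _static_frames(self, n=5):
        return [
            frame_from_atoms([
                _backbone_res("A", 1, [0.0, 0.0, 0.0]),
                _backbone_res("A", 2, [4.0, 0.0, 0.0]),
                _backbone_res("A", 3, [8.0, 0.0, 0.0]),
            ])
            for _ in range(n)
        ]

    def test_identical_frames_have_zero_rmsf(self):
        r = backbone_rmsf(self._static_frames())
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in r.values())

    def test_oscillating_atom_matches_direct_summation(self):
        """Residue 2's O oscillates +-d along z; the oracle reimplements the
        superposition (scipy's Kabsch, not the package's own SVD) and the
        RMSF by explicit summation."""
        from scipy.spatial.transform import Rotation

        d = 0.4
        frames = []
        for k in range(10):
            dz = d if k % 2 == 0 else -d
            frames.append(frame_from_atoms([
                _backbone_res("A", 1, [0.0, 0.0, 0.0]),
                _backbone_res("A", 2, [4.0, 0.0, 0.0],
                              o_offset=[1.2, 1.2, dz]),
                _backbone_res("A", 3, [8.0, 0.0, 0.0]),
            ]))
        r = backbone_rmsf(frames)

        # oracle: same protocol, independent implementation
        bb = [i for i in range(len(frames[0]))
              if frames[0].names[i] in ("N", "CA", "C", "O")]
        stack = np.array([f.coords[bb] for f in frames])

        def align(X, ref):
            xc, rc = X.mean(axis=0), ref.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref - rc, X - xc)
            return (X - xc) @ rot.as_matrix().T + rc

        ref = stack[0]
        for _ in range(2):
            aligned = np.array([align(X, ref) for X in stack])
            ref = aligned.mean(axis=0)
        # residue 2 backbone = atoms 4..7 of the backbone selection
        acc = 0.0
        cnt = 0
        for t in range(len(frames)):
            for a in range(4, 8):
                dv = aligned[t, a] - ref[a]
                acc += float(dv @ dv)
                cnt += 1
        expected = math.sqrt(acc / cnt)
        assert r[("A", 2, "")] == pytest.approx(expected, rel=1e-6)
        # the oscillation is partially absorbed by the fit but remains the
        # dominant signal of residue 2
        assert r[("A", 2, "")] > 2 * r[("A", 1, "")]

    def test_rigid_rotation_invariance(self):
        frames = []
        rng = np.random.default_rng(7)
        base = self._static_frames(1)[0]
        for k in range(6):
            c = base.coords + rng.normal(0, 0.1, base.coords.shape)
            frames.append(Frame(base.names, base.elements, base.resnames,
                                base.resids, base.icodes, base.chains,
                                c, base.occupancies))
        r0 = backbone_rmsf(frames)
        theta = 0.8
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0],
                      [0, 0, 1.0]])
        rot = [Frame(f.names, f.elements, f.resnames, f.resids, f.icodes,
                     f.chains, f.coords @ R.T + [3.0, -1.0, 2.0],
                     f.occupancies) for f in frames]
        r1 = backbone_rmsf(rot)
        for k in r0:
            assert r1[k] == pytest.approx(r0[k], abs=1e-6)

    def test_requires_two_frames(self):
        with pytest.raises(ValueError, match="two frames"):
            backbone_rmsf(self._static_frames(1))
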