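"""Survey pipeline: dedup, per-entry profiling, aggregation."""
import numpy as np
import pytest

from oxohb.hbond import BONDI_RADII, HBondCriterion
from oxohb.io import frame_from_atoms
from oxohb.survey import (
    EntryMeta,
    ResidueHBondProfile,
    aggregate,
    dedup_entries,
    run_survey,
    survey_entry,
)
from oxohb.synthetic import _SimpleAtom


def _res(resname, chain, resid, atoms):
    return (resname, chain, resid,
            [_SimpleAtom(n, e, p) for n, e, p in atoms])


class TestDedup:
    def test_keeps_highest_resolution_for_same_title(self):
        a = EntryMeta("1AAA", "Kinase complex", 2.5)
        b = EntryMeta("2BBB", "Kinase  COMPLEX ", 1.8)
        assert dedup_entries([a, b]) == [b]

    def test_distinct_titles_both_kept(self):
        a = EntryMeta("1AAA", "Kinase complex", 2.5)
        b = EntryMeta("2BBB", "Phosphatase complex", 1.8)
        assert dedup_entries([a, b]) == [a, b]

    def test_resolved_beats_unresolved(self):
        xray = EntryMeta("1AAA", "Receptor", 2.0, method="X-RAY")
        nmr = EntryMeta("2BBB", "Receptor", None, method="NMR")
        assert dedup_entries([nmr, xray]) == [xray]
        assert dedup_entries([nmr]) == [nmr]

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            EntryMeta("1AAA", "x", 0.0)


def _sep_with_donors(chain="A", bidentate=True, with_backbone=True,
                     offset=np.zeros(3)):
    """SEP contacted by an Arg (NH1+NH2 on two oxygens) and a backbone N."""
    o1 = np.array([0.0, 1.25, 0.0]) + offset
    o2 = np.array([0.0, -1.25, 0.0]) + offset
    o3 = np.array([-1.0, 0.0, 1.1]) + offset
    p = np.array([-0.8, 0.0, 0.0]) + offset
    groups = [_res("SEP", chain, 1, [
        ("P", "P", p), ("O1P", "O", o1), ("O2P", "O", o2), ("O3P", "O", o3),
    ])]
    if bidentate:
        n1 = o1 + [2.8, 0.0, 0.0]
        n2 = o2 + [2.8, 0.0, 0.0]
        groups.append(_res("ARG", chain, 2, [
            ("NH1", "N", n1), ("NH2", "N", n2),
            ("CZ", "C", (n1 + n2) / 2 + [1.0, 0.0, 0.0]),
        ]))
    if with_backbone:
        groups.append(_res("GLY", chain, 3, [
            ("N", "N", o3 + [0.0, 0.0, 2.9]),
            ("CA", "C", o3 + [1.4, 0.0, 3.6]),
        ]))
    return groups


class TestSurveyEntry:
    def test_bidentate_plus_backbone_profile(self):
        frame = frame_from_atoms(_sep_with_donors())
        profiles = survey_entry(frame, entry_id="E1", glu_requires_sep=False)
        assert len(profiles) == 1
        p = profiles[0]
        assert p.n_hbonds == 3
        assert p.donor_breakdown["arg_bidentate"] == 2
        assert p.donor_breakdown["backbone_amide"] == 1

    def test_isolated_residue_has_zero_bonds(self):
        frame = frame_from_atoms([
            _res("TYS", "A", 1, [
                ("S", "S", [0.0, 0.0, 0.0]), ("O1S", "O", [1.4, 0.0, 0.0]),
                ("O2S", "O", [-0.7, 1.2, 0.0]), ("O3S", "O", [-0.7, -1.2, 0.0]),
            ]),
        ])
        profiles = survey_entry(frame, entry_id="E2")
        assert len(profiles) == 1
        assert profiles[0].n_hbonds == 0

    def test_glu_only_counted_alongside_sep(self):
        glu = _res("GLU", "A", 5, [
            ("OE1", "O", [20.0, 0.0, 0.0]), ("OE2", "O", [21.0, 1.0, 0.0]),
        ])
        frame_without = frame_from_atoms([glu])
        assert survey_entry(frame_without, entry_id="X") == []
        frame_with = frame_from_atoms(_sep_with_donors() + [glu])
        names = {p.resname for p in survey_entry(frame_with, entry_id="X")}
        assert names == {"SEP", "GLU"}

    def test_incomplete_side_chain_skipped(self):
        frame = frame_from_atoms([
            _res("SEP", "A", 1, [("P", "P", [0.0, 0.0, 0.0]),
                                 ("O1P", "O", [1.5, 0.0, 0.0])]),
        ])
        assert survey_entry(frame, entry_id="E", glu_requires_sep=False) == []

    def test_counts_match_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        crit = HBondCriterion(mode="radius_sum")
        for _ in range(25):
            groups = [_res("SEP", "A", 1, [
                ("P", "P", [0.0, 0.0, 0.0]),
                ("O1P", "O", rng.uniform(-2, 2, 3)),
                ("O2P", "O", rng.uniform(-2, 2, 3)),
                ("O3P", "O", rng.uniform(-2, 2, 3)),
            ])]
            donors = []
            for k in range(rng.integers(1, 6)):
                donors.append(("N", "N", rng.uniform(-5, 5, 3)))
            for k, d in enumerate(donors):
                groups.append(_res("GLY", "A", 10 + k, [d,
                              ("CA", "C", np.asarray(d[2]) + [1.4, 0, 0])]))
            frame = frame_from_atoms(groups)
            prof = survey_entry(frame, crit, entry_id="R",
                                glu_requires_sep=False)
            # oracle: plain double loop over donor N x acceptor O
            rsum = BONDI_RADII["N"] + BONDI_RADII["O"]
            expected = 0
            oxy = [np.asarray(g) for g in
                   (frame.coords[i] for i in range(len(frame))
                    if frame.names[i] in ("O1P", "O2P", "O3P"))]
            for i in range(len(frame)):
                if frame.names[i] == "N":
                    for o in oxy:
                        if np.linalg.norm(frame.coords[i] - o) < rsum:
                            expected += 1
            assert prof[0].n_hbonds == expected


def _profile(entry, chain, group, resname, n, breakdown=None, resid=1):
    bd = {c: 0 for c in
          ("arg_single", "arg_bidentate", "lys", "gln", "backbone_amide",
           "hydroxyl", "other")}
    bd.update(breakdown or {"other": n})
    return ResidueHBondProfile(entry, chain, resid, "", resname, n, bd,
                               chain_group=group)


class TestAggregate:
    def test_identical_chain_rounded_average(self):
        # counts 3 and 4 on identical chains -> rounded mean 4
        profiles = [_profile("E", "A", 0, "SEP", 3),
                    _profile("E", "B", 0, "SEP", 4)]
        s = aggregate(profiles)
        assert s.n_residues["SEP"] == 1
        assert s.histogram.loc["SEP", "4"] == 100.0

    def test_single_chain_identity(self):
        s = aggregate([_profile("E", "A", 0, "PTR", 2)])
        assert s.histogram.loc["PTR", "2"] == 100.0
        assert s.n_residues["PTR"] == 1

    def test_histogram_top_bin(self):
        profiles = [
            _profile("E%d" % k, "A", 0, "SEP", n, resid=1)
            for k, n in enumerate([0, 1, 1, 2, 3, 4, 4, 2, 6, 5])
        ]
        s = aggregate(profiles)
        assert s.n_residues["SEP"] == 10
        assert s.histogram.loc["SEP", ">=5"] == pytest.approx(20.0)
        assert s.histogram.loc["SEP"].sum() == pytest.approx(100.0)

    def test_donor_percentages_from_first_chain(self):
        profiles = [
            _profile("E", "A", 0, "SEP", 2, {"arg_bidentate": 2}),
            _profile("E", "B", 0, "SEP", 2, {"lys": 2}),
        ]
        s = aggregate(profiles)
        assert s.donor_percentages.loc["SEP", "arg_bidentate"] == 100.0
        assert s.donor_percentages.loc["SEP", "lys"] == 0.0

    def test_invariant_under_nonidentical_chain_order(self):
        p1 = _profile("E", "A", 0, "SEP", 1, {"lys": 1})
        p2 = _profile("E", "B", 1, "PTR", 3, {"arg_single": 3})
        assert aggregate([p1, p2]) == aggregate([p2, p1])

    def test_deterministic(self):
        profiles = [_profile("E", "A", 0, "TYS", 2, {"hydroxyl": 2})]
        assert aggregate(profiles) == aggregate(profiles)


def test_run_survey_end_to_end_with_dedup():
    f1 = frame_from_atoms(_sep_with_donors())          # 3 bonds
    f2 = frame_from_atoms(_sep_with_donors(bidentate=False))   # 1 bond
    meta = [
        EntryMeta("GOOD", "same protein", 1.5),
        EntryMeta("BAD", "Same  Protein", 2.5),
    ]
    s = run_survey({"GOOD": f1, "BAD": f2}, meta)
    # only the higher-resolution entry (3 bonds) survives dedup
    assert s.n_residues["SEP"] == 1
    assert s.histogram.loc["SEP", "3"] == 100.0
    assert s.donor_percentages.loc["SEP", "arg_bidentate"] == pytest.approx(
        100.0 * 2 / 3)
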