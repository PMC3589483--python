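"""Synthetic structure fixtures: posed pairs, trajectories with planted
hydrogen-bond occupancies, and toy survey entries.

Everything is written in standard (multi-model) PDB format so the same
parsers serve synthetic and real data, and every generator is
seed-deterministic.  Each trajectory/survey fixture carries a YAML
manifest recording the planted ground truth, and generation verifies the
ground truth against the package's own analysis stages (closed loop): a
jitter level that would flip a planted label triggers regeneration with
half the jitter, and an error if that fails.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fragments import build_fragment, pose_pair, resolve_kind
from .hbond import HBondCriterion, classify_frame
from .io import Frame, frame_from_atoms, read_structure, write_frames
from .survey import survey_entry

#: planted geometry: comfortably inside the 3.0 A / 20 deg criterion
_BOND_NO = 2.8
#: "none" frames keep every donor-acceptor pair beyond this
_APART_NO = 3.5


@dataclass
class FixtureSpec:
    """Parameters of a synthetic fixture.

    ``planted_pattern`` is a per-frame label sequence (``none``/``single``/
    ``bidentate``) for trajectories; ``planted_counts`` the per-chain
    intended hydrogen-bond counts for survey entries; ``jitter`` the
    standard deviation (A) of the Gaussian coordinate noise.
    """

    seed: int = 0
    n_frames: int = 10
    planted_pattern: list = field(default_factory=list)
    jitter: float = 0.05
    chains: int = 1
    planted_counts: list = field(default_factory=list)

    def __post_init__(self):
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        bad = set(self.planted_pattern) - {"none", "single", "bidentate"}
        if bad:
            raise ValueError(f"unknown planted labels: {bad}")
        if self.planted_pattern and len(self.planted_pattern) != self.n_frames:
            raise ValueError("planted_pattern length != n_frames")


# ---------------------------------------------------------------------------
# posed-pair fixture
# ---------------------------------------------------------------------------

def make_pair_fixture(acceptor: str, donor: str, mode: str, distance: float,
                      out) -> Path:
    """Export a posed two-fragment complex as a single-model PDB file."""
    acc_kind = resolve_kind(acceptor)
    don_kind = resolve_kind(donor)
    pair = pose_pair(build_fragment(acc_kind), build_fragment(don_kind),
                     mode, distance)
    frame = frame_from_atoms([
        (pair.acceptor.resname, "A", 1, pair.acceptor.atoms),
        (pair.donor.resname, "B", 1, pair.donor.atoms),
    ])
    out = Path(out)
    write_frames([frame], out,
                 title=f"{acc_kind}/{don_kind} {mode} pose at {distance:.2f} A")
    return out


def measure_pair_fixture(path, mode: str, acceptor: str, donor: str) -> float:
    """Re-measure the scan coordinate of a pair fixture from its PDB file."""
    frame = read_structure(path)[0]
    _, _, _, acc_anchors = _anchors(acceptor)
    _, _, _, don_anchors = _anchors(donor)

    def pos(chain, name):
        m = (frame.chains == chain) & (frame.names == name)
        return frame.coords[np.flatnonzero(m)[0]]

    if mode == "collinear":
        n_name, _h = don_anchors["collinear_donor"]
        return float(np.linalg.norm(
            pos("B", n_name) - pos("A", acc_anchors["collinear_oxygen"])
        ))
    cz = don_anchors["bidentate_center"]
    return float(np.linalg.norm(pos("B", cz) - pos("A", acc_anchors["center"])))


def _anchors(kind):
    from .fragments import load_template
    return load_template(resolve_kind(kind))


# ---------------------------------------------------------------------------
# trajectory fixture
# ---------------------------------------------------------------------------

def _pair_frame(label: str, rng, jitter: float) -> Frame:
    """One frame of the two-residue toy system (SEP acceptor, ARG donor)."""
    acc = build_fragment("pser2")
    don = build_fragment("arg")
    if label == "bidentate":
        pair = pose_pair(acc, don, "coplanar", 4.05)
        a, d = pair.acceptor, pair.donor
    elif label == "single":
        pair = pose_pair(acc, don, "collinear", _BOND_NO)
        a, d = pair.acceptor, pair.donor
    else:
        pair = pose_pair(acc, don, "collinear", 8.0)
        a, d = pair.acceptor, pair.donor
    frame = frame_from_atoms([
        ("SEP", "A", 1, a.atoms),
        ("ARG", "A", 2, d.atoms),
    ])
    if jitter > 0:
        frame.coords = frame.coords + rng.normal(0.0, jitter,
                                                 frame.coords.shape)
    return frame


def make_trajectory_fixture(spec: FixtureSpec, out) -> Path:
    """Multi-model PDB with the prescribed per-frame hydrogen-bond labels.

    The planted labels are re-derived with the distance/angle criterion
    after generation; jitter is halved (up to 6 times) if it flips any
    label, and generation fails if the pattern still cannot be realized.
    """
    if not spec.planted_pattern:
        raise ValueError("trajectory fixture requires planted_pattern")
    out = Path(out)
    criterion = HBondCriterion()
    jitter = spec.jitter
    for _attempt in range(7):
        rng = np.random.default_rng(spec.seed)
        frames = [_pair_frame(lbl, rng, jitter)
                  for lbl in spec.planted_pattern]
        got = [
            classify_frame(fr, ("A", 2), ("A", 1), criterion, k).label
            for k, fr in enumerate(frames)
        ]
        if got == list(spec.planted_pattern):
            break
        jitter *= 0.5
    else:
        raise RuntimeError("jitter flips planted labels even after halving")
    write_frames(frames, out, title="synthetic trajectory fixture")
    manifest = {
        "kind": "trajectory",
        "seed": spec.seed,
        "jitter": jitter,
        "donor_residue": "A:2",
        "acceptor_residue": "A:1",
        "labels": list(spec.planted_pattern),
    }
    with out.with_suffix(".manifest.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# survey fixture
# ---------------------------------------------------------------------------

def _rodrigues(v, axis, deg):
    axis = axis / np.linalg.norm(axis)
    t = math.radians(deg)
    return (v * math.cos(t) + np.cross(axis, v) * math.sin(t)
            + axis * np.dot(axis, v) * (1 - math.cos(t)))


def _donor_positions(acc_posed, n_bonded: int, blocked=()) -> list:
    """Deterministic positions for bonded glycine-N donors around the
    acceptor oxygens: 2.9 A from the target oxygen (inside the 3.07 A
    Bondi N+O sum), at least 3.3 A from every other oxygen and from
    previously placed donors.  Raises when the geometric capacity of the
    three-oxygen group is exceeded."""
    o_names = [n for n in ("O1P", "O2P", "O3P")]
    p = acc_posed.position("P")
    oxy = {n: acc_posed.position(n) for n in o_names}
    placed = [np.asarray(b) for b in blocked]
    out = []
    tilts = [(0.0, 0.0), (40.0, 0.0), (-40.0, 0.0), (40.0, 90.0),
             (-40.0, 90.0), (70.0, 0.0), (70.0, 90.0)]
    for k in range(n_bonded):
        ok = None
        for name in o_names:
            o = oxy[name]
            away = (o - p) / np.linalg.norm(o - p)
            perp = np.cross(away, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(away, [0.0, 1.0, 0.0])
            perp = perp / np.linalg.norm(perp)
            for tilt, spin in tilts:
                d = _rodrigues(away, _rodrigues(perp, away, spin), tilt)
                cand = o + 2.9 * d
                others = [oxy[m] for m in o_names if m != name]
                if any(np.linalg.norm(cand - q) < 3.3 for q in others):
                    continue
                if any(np.linalg.norm(cand - q) < 3.0 for q in placed):
                    continue
                ok = (cand, d)
                break
            if ok:
                break
        if ok is None:
            raise ValueError(
                "planted bond count exceeds the fixture's geometric capacity"
            )
        out.append(ok)
        placed.append(ok[0])
    return out


def _survey_chain(chain_id: str, n_bonds: int, n_donor_slots: int, rng,
                  jitter: float, bidentate_arg: bool = False,
                  chain_offset=np.zeros(3)) -> list:
    """A toy chain: one SEP residue plus ``n_donor_slots`` glycine donors,
    of which enough are placed in contact (2.9 A N...O, inside the Bondi
    radius sum) to give exactly ``n_bonds`` bonds; the rest are parked
    ~8 A away.  ``bidentate_arg`` adds a chelating Arg contributing two of
    the bonds.  All chains built with the same ``n_donor_slots`` and
    ``bidentate_arg`` have identical residue sequences.
    """
    acc = build_fragment("pser2")
    resid = 2
    blocked = []
    if bidentate_arg:
        if n_bonds < 2:
            raise ValueError("bidentate Arg needs at least 2 planted bonds")
        pair = pose_pair(acc, build_fragment("arg"), "coplanar", 4.0)
        acc_posed = pair.acceptor
        groups = [("SEP", chain_id, 1,
                   [_shift(a, chain_offset) for a in acc_posed.atoms]),
                  ("ARG", chain_id, resid,
                   [_shift(a, chain_offset) for a in pair.donor.atoms])]
        resid += 1
        n_gly_bonded = n_bonds - 2
        blocked = [pair.donor.position("NH1"), pair.donor.position("NH2")]
    else:
        acc_posed = acc
        groups = [("SEP", chain_id, 1,
                   [_shift(a, chain_offset) for a in acc.atoms])]
        n_gly_bonded = n_bonds
    if n_gly_bonded > n_donor_slots:
        raise ValueError("n_bonds exceeds available donor slots")
    spots = _donor_positions(acc_posed, n_gly_bonded, blocked)
    # parked (non-bonding) donors complete the common chain sequence
    p = acc_posed.position("P")
    for k in range(n_donor_slots):
        if k < n_gly_bonded:
            n_pos, d = spots[k]
        else:
            ang = 2.0 * math.pi * (k + 1) / (n_donor_slots + 1)
            d = np.array([math.cos(ang), math.sin(ang), -0.7])
            d = d / np.linalg.norm(d)
            n_pos = p + 8.0 * d
        gly = _glycine_n(n_pos, d)
        groups.append(("GLY", chain_id, resid,
                       [_shift(a, chain_offset) for a in gly]))
        resid += 1
    if jitter > 0:
        groups = [
            (resname, ch, rid,
             [_shift(a, rng.normal(0.0, jitter, 3)) for a in atoms])
            for resname, ch, rid, atoms in groups
        ]
    return groups


class _SimpleAtom:
    __slots__ = ("name", "element", "position")

    def __init__(self, name, element, position):
        self.name = name
        self.element = element
        self.position = np.asarray(position, dtype=float)


def _shift(a, dv):
    return _SimpleAtom(a.name, a.element, np.asarray(a.position) + dv)


def _glycine_n(n_pos, direction) -> list:
    """Minimal glycine backbone (N, CA, C, O) with N at n_pos, pointing
    away from the acceptor along ``direction``."""
    d = direction / np.linalg.norm(direction)
    # arbitrary perpendicular
    perp = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(d, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    CA = n_pos + 1.46 * d
    C = CA + 1.52 * (0.5 * d + 0.866 * perp)
    O = C + 1.23 * perp
    return [
        _SimpleAtom("N", "N", n_pos),
        _SimpleAtom("CA", "C", CA),
        _SimpleAtom("C", "C", C),
        _SimpleAtom("O", "O", O),
    ]


def make_survey_fixture(spec: FixtureSpec, out, entry_id: str = "SYN1",
                        title: str = "synthetic survey entry",
                        resolution: float | None = 1.5,
                        bidentate_arg: bool = False):
    """Write a toy survey entry and return (pdb path, metadata row).

    The entry holds ``spec.chains`` sequence-identical chains; chain i
    carries ``spec.planted_counts[i]`` hydrogen bonds to its SEP residue.
    Planted counts are verified against the survey stage after generation.
    """
    counts = list(spec.planted_counts)
    if len(counts) != spec.chains:
        raise ValueError("planted_counts length must equal chains")
    out = Path(out)
    jitter = spec.jitter
    n_slots = max((c - (2 if bidentate_arg else 0)) for c in counts)
    for _attempt in range(7):
        rng = np.random.default_rng(spec.seed)
        groups = []
        for ci, n_bonds in enumerate(counts):
            chain_id = chr(ord("A") + ci)
            offset = np.array([40.0 * ci, 0.0, 0.0])
            groups.extend(
                _survey_chain(chain_id, n_bonds, n_slots, rng, jitter,
                              bidentate_arg=bidentate_arg,
                              chain_offset=offset)
            )
        frame = frame_from_atoms(groups)
        profiles = survey_entry(frame, entry_id=entry_id,
                                glu_requires_sep=False)
        got = [p.n_hbonds for p in profiles if p.resname == "SEP"]
        if got == counts:
            break
        jitter *= 0.5
    else:
        raise RuntimeError("could not realize planted survey counts")
    write_frames([frame], out, title=title)
    manifest = {
        "kind": "survey",
        "entry_id": entry_id,
        "seed": spec.seed,
        "jitter": jitter,
        "chains": spec.chains,
        "planted_counts": counts,
        "bidentate_arg": bidentate_arg,
    }
    with out.with_suffix(".manifest.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    meta = {
        "id": entry_id,
        "title": title,
        "resolution": resolution,
        "method": "SYNTHETIC",
    }
    return out, meta
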