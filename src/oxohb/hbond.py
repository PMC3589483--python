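"""Hydrogen-bond detection, single/bidentate classification, occupancies
and backbone RMSF.

Two geometric criteria are implemented:

``distance_angle``
    donor-N...acceptor-O distance <= 3.0 A and the D-H...A angle within
    20 degrees of linearity (the default criteria of common trajectory
    analysis tools); requires hydrogens.

``radius_sum``
    heavy-atom distance below the sum of the two atomic radii (Bondi van
    der Waals radii by default) -- the more permissive criterion used for
    surveying experimental structures, where hydrogen positions are
    usually absent.

An Arg-oxoanion contact is *bidentate* when, within one frame, at least
two hydrogen bonds involve two distinct guanidinium nitrogens and two
distinct acceptor oxygens; otherwise any contact is *single*.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import kabsch

#: Bondi van der Waals radii (A); overridable per criterion
BONDI_RADII = {"N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80, "C": 1.70,
               "H": 1.20}

#: side-chain donor heavy atoms by residue, with donor category
SIDECHAIN_DONORS = {
    ("ARG", "NE"): "arg", ("ARG", "NH1"): "arg", ("ARG", "NH2"): "arg",
    ("LYS", "NZ"): "lys",
    ("GLN", "NE2"): "gln",
    ("ASN", "ND2"): "other",
    ("HIS", "ND1"): "other", ("HIS", "NE2"): "other",
    ("TRP", "NE1"): "other",
    ("SER", "OG"): "hydroxyl",
    ("THR", "OG1"): "hydroxyl",
    ("TYR", "OH"): "hydroxyl",
}

#: side-chain acceptor oxygens of the surveyed residues (bridging ester
#: oxygens deliberately excluded)
SIDECHAIN_ACCEPTORS = {
    "SEP": ("O1P", "O2P", "O3P"),
    "PTR": ("O1P", "O2P", "O3P"),
    "TYS": ("O1S", "O2S", "O3S"),
    "GLU": ("OE1", "OE2"),
}

WATER_RESNAMES = {"HOH", "WAT"}

_H_BOND_MAX = 1.25  # A, covalent N/O-H attachment cutoff


@dataclass(frozen=True)
class AtomRef:
    chain: str
    resid: int
    icode: str
    resname: str
    name: str
    index: int


@dataclass
class HBondCriterion:
    mode: str = "distance_angle"
    distance_cutoff: float = 3.0
    angle_cutoff: float = 20.0
    radius_table: dict = field(default_factory=lambda: dict(BONDI_RADII))

    def __post_init__(self):
        if self.mode not in ("distance_angle", "radius_sum"):
            raise ValueError(f"unknown criterion mode {self.mode!r}")
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        missing = {"N", "O", "P", "S", "C"} - set(self.radius_table)
        if missing:
            raise ValueError(f"radius table missing elements: {missing}")


@dataclass
class HBond:
    donor_atom: AtomRef
    acceptor_atom: AtomRef
    distance: float
    hydrogen: AtomRef | None = None
    angle: float | None = None


@dataclass
class FrameClassification:
    frame: int
    donor_residue: tuple
    acceptor_residue: tuple
    label: str               # none | single | bidentate
    bonds: list[HBond]


@dataclass
class OccupancyRecord:
    n_frames: int
    any_pct: float
    single_pct: float
    bidentate_pct: float
    labels: list[str]


def _atom_ref(frame, i: int) -> AtomRef:
    return AtomRef(frame.chains[i], int(frame.resids[i]), frame.icodes[i],
                   frame.resnames[i], frame.names[i], i)


def _donor_indices(frame, include_backbone=True):
    """Indices of donor heavy atoms with their category."""
    out = []
    for i in range(len(frame)):
        rn, an = frame.resnames[i], frame.names[i]
        if rn in WATER_RESNAMES:
            continue
        if (rn, an) in SIDECHAIN_DONORS:
            out.append((i, SIDECHAIN_DONORS[(rn, an)]))
        elif include_backbone and an == "N" and frame.elements[i] == "N":
            out.append((i, "backbone_amide"))
    return out


def _acceptor_indices(frame):
    out = []
    for i in range(len(frame)):
        names = SIDECHAIN_ACCEPTORS.get(frame.resnames[i])
        if names and frame.names[i] in names:
            out.append(i)
    return out


def _attached_hydrogens(frame, i: int) -> list[int]:
    same_res = frame.residue_mask(frame.chains[i], int(frame.resids[i]),
                                  frame.icodes[i])
    idx = np.flatnonzero(same_res & (frame.elements == "H"))
    if len(idx) == 0:
        return []
    d = np.linalg.norm(frame.coords[idx] - frame.coords[i], axis=1)
    return [int(j) for j, dj in zip(idx, d) if dj <= _H_BOND_MAX]


def detect_hbonds(frame, criterion: HBondCriterion | None = None,
                  donor_indices=None, acceptor_indices=None) -> list[HBond]:
    """All donor-acceptor hydrogen bonds in one frame under a criterion.

    Donors default to the configured side-chain donor set plus backbone
    amide nitrogens; acceptors default to the side-chain oxygens of
    GLU/SEP/PTR/TYS.  Same-residue pairs are excluded.
    """
    criterion = criterion or HBondCriterion()
    donors = (
        [(i, None) for i in donor_indices]
        if donor_indices is not None
        else _donor_indices(frame)
    )
    acceptors = (
        list(acceptor_indices) if acceptor_indices is not None
        else _acceptor_indices(frame)
    )
    if not donors or not acceptors:
        return []

    if criterion.mode == "distance_angle":
        has_h = bool(np.any(frame.elements == "H"))
        if not has_h:
            raise ValueError(
                "distance_angle criterion requires hydrogens in the frame"
            )

    bonds = []
    acc = np.array(acceptors, dtype=int)
    acc_xyz = frame.coords[acc]
    for i, _cat in donors:
        dvec = acc_xyz - frame.coords[i]
        dist = np.linalg.norm(dvec, axis=1)
        for j, dj in zip(acc, dist):
            if (frame.chains[i] == frame.chains[j]
                    and frame.resids[i] == frame.resids[j]
                    and frame.icodes[i] == frame.icodes[j]):
                continue
            if criterion.mode == "radius_sum":
                rsum = (criterion.radius_table[frame.elements[i]]
                        + criterion.radius_table[frame.elements[j]])
                if dj < rsum:
                    bonds.append(HBond(_atom_ref(frame, i),
                                       _atom_ref(frame, int(j)), float(dj)))
            else:
                if dj > criterion.distance_cutoff:
                    continue
                for h in _attached_hydrogens(frame, i):
                    v1 = frame.coords[i] - frame.coords[h]
                    v2 = frame.coords[j] - frame.coords[h]
                    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = float(np.degrees(np.arccos(np.clip(c, -1, 1))))
                    if 180.0 - ang <= criterion.angle_cutoff:
                        bonds.append(
                            HBond(_atom_ref(frame, i), _atom_ref(frame, int(j)),
                                  float(dj), hydrogen=_atom_ref(frame, h),
                                  angle=ang)
                        )
                        break  # one bond per donor-acceptor pair
    return bonds


def _parse_residue(res) -> tuple:
    """Accept (chain, resid[, icode]) tuples or 'B:47' strings."""
    if isinstance(res, str):
        chain, _, num = res.partition(":")
        return (chain, int(num), "")
    if len(res) == 2:
        return (res[0], int(res[1]), "")
    return (res[0], int(res[1]), res[2])


def classify_frame(frame, donor_residue, acceptor_residue,
                   criterion: HBondCriterion | None = None,
                   frame_index: int = 0) -> FrameClassification:
    """Label the donor-acceptor residue contact as none/single/bidentate."""
    criterion = criterion or HBondCriterion()
    dres = _parse_residue(donor_residue)
    ares = _parse_residue(acceptor_residue)
    dmask = frame.residue_mask(*dres)
    amask = frame.residue_mask(*ares)
    if not dmask.any():
        raise ValueError(f"donor residue {dres} not found")
    if not amask.any():
        raise ValueError(f"acceptor residue {ares} not found")
    donor_idx = [i for i, _ in _donor_indices(frame) if dmask[i]]
    acc_idx = [i for i in _acceptor_indices(frame) if amask[i]]
    bonds = detect_hbonds(frame, criterion, donor_indices=donor_idx,
                          acceptor_indices=acc_idx)
    label = classify_bonds(bonds)
    return FrameClassification(frame_index, dres, ares, label, bonds)


def classify_bonds(bonds) -> str:
    """none/single/bidentate from a list of bonds between one donor and one
    acceptor residue."""
    if not bonds:
        return "none"
    donor_ns = {b.donor_atom.name for b in bonds}
    acc_os = {b.acceptor_atom.name for b in bonds}
    if len(bonds) >= 2 and len(donor_ns) >= 2 and len(acc_os) >= 2:
        return "bidentate"
    return "single"


def occupancy(trajectory, donor_residue, acceptor_residue,
              criterion: HBondCriterion | None = None) -> OccupancyRecord:
    """Percentage of frames in which the residue pair is hydrogen bonded,
    split into single and bidentate contributions."""
    frames = list(trajectory)
    if not frames:
        raise ValueError("empty trajectory")
    labels = [
        classify_frame(fr, donor_residue, acceptor_residue, criterion, k).label
        for k, fr in enumerate(frames)
    ]
    n = len(labels)
    n_single = labels.count("single")
    n_bid = labels.count("bidentate")
    return OccupancyRecord(
        n_frames=n,
        any_pct=100.0 * (n_single + n_bid) / n,
        single_pct=100.0 * n_single / n,
        bidentate_pct=100.0 * n_bid / n,
        labels=labels,
    )


BACKBONE_ATOMS = ("N", "CA", "C", "O")


def backbone_rmsf(trajectory, residue_range=None) -> dict:
    """Per-residue backbone RMSF (A) after least-squares superposition.

    Each frame is superposed (backbone atoms) onto the mean structure --
    obtained by aligning to the first frame, averaging, then re-aligning
    to the average -- and the RMSF of residue r is the root mean square
    displacement of its backbone atoms from their time-averaged positions.
    ``residue_range`` optionally restricts the report to (lo, hi) resids.
    """
    frames = list(trajectory)
    if len(frames) < 2:
        raise ValueError("RMSF requires at least two frames")
    f0 = frames[0]
    keys = []
    index_of = {}
    for chain, resid, icode, resname, idx in f0.residues():
        sel = {f0.names[i]: i for i in idx if f0.names[i] in BACKBONE_ATOMS}
        if len(sel) < len(BACKBONE_ATOMS):
            continue
        if residue_range is not None and not (
                residue_range[0] <= resid <= residue_range[1]):
            continue
        keys.append((chain, resid, icode))
        index_of[(chain, resid, icode)] = [sel[n] for n in BACKBONE_ATOMS]
    if not keys:
        raise ValueError("no residues with complete backbone found")

    rows = np.concatenate([index_of[k] for k in keys])
    # all frames must present the same atom layout (multi-model PDB)
    stack = np.array([fr.coords[rows] for fr in frames])

    ref = stack[0]
    for _ in range(2):
        aligned = []
        for X in stack:
            R, t = kabsch(X, ref)
            aligned.append(X @ R.T + t)
        aligned = np.array(aligned)
        ref = aligned.mean(axis=0)
    disp2 = ((aligned - ref) ** 2).sum(axis=-1)   # (n_frames, n_atoms)

    out = {}
    nb = len(BACKBONE_ATOMS)
    for r, k in enumerate(keys):
        sl = slice(r * nb, (r + 1) * nb)
        out[k] = float(np.sqrt(disp2[:, sl].mean()))
    return out
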