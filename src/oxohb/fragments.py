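"""Side-chain-analog fragments and constrained two-fragment poses.

A fragment is a rigid, idealized model of a residue side chain: propionate
for Glu, methylguanidinium for Arg, methylammonium for Lys,
N-methylacetamide for the backbone amide, and phospho/sulfo fragments
truncated at C-beta for the modified residues (pSer, pTyr in the -2 and -1
protonation states, and sTyr).  Templates carry idealized internal geometry
and Lennard-Jones parameters; partial charges are attached from the
charge-set files managed by :mod:`oxohb.charges`.

Two fragments can be posed as a hydrogen-bonded complex in either of two
constrained geometries used for rigid distance scans:

* ``collinear`` - a single hydrogen bond with N-H-O and H-O-(P/S/C) angles
  of 180 degrees; the scan coordinate is the N-O distance.
* ``coplanar`` - the symmetric bidentate arrangement of an Arg guanidinium
  chelating two oxoanion oxygens, all four H/O atoms coplanar (dihedral 0);
  the scan coordinate is the CZ-to-(P/S/carboxylate-C) distance.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib.resources import files
from typing import Iterable

import numpy as np

from .geometry import orthonormal_frame, unit

ACCEPTOR_KINDS = (
    "GLU_ANALOG",
    "PSER_M2",
    "PSER_M1",
    "PTYR_M2",
    "PTYR_M1",
    "STYR",
)
DONOR_KINDS = ("ARG_ANALOG", "LYS_ANALOG", "AMIDE_ANALOG")
FRAGMENT_KINDS = ACCEPTOR_KINDS + DONOR_KINDS

#: short aliases accepted anywhere a fragment kind is expected (CLI included)
KIND_ALIASES = {
    "glu": "GLU_ANALOG",
    "pser2": "PSER_M2",
    "pser1": "PSER_M1",
    "ptyr2": "PTYR_M2",
    "ptyr1": "PTYR_M1",
    "styr": "STYR",
    "arg": "ARG_ANALOG",
    "lys": "LYS_ANALOG",
    "amide": "AMIDE_ANALOG",
}

MIN_SCAN_DISTANCE = 2.25


def resolve_kind(kind: str) -> str:
    k = str(kind)
    k = KIND_ALIASES.get(k.lower(), k.upper())
    if k not in FRAGMENT_KINDS:
        raise ValueError(f"unknown fragment kind: {kind!r}")
    return k


@dataclass(frozen=True)
class AtomRecord:
    """One atom: label, element, Cartesian position (A), partial charge (e)
    and Lennard-Jones parameters (sigma A, epsilon kcal/mol)."""

    name: str
    element: str
    position: np.ndarray
    charge: float = 0.0
    sigma: float = 0.0
    epsilon: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.array(self.position, dtype=float).reshape(3)
        )
        if self.sigma <= 0:
            raise ValueError(f"atom {self.name}: sigma must be > 0")
        if self.epsilon < 0:
            raise ValueError(f"atom {self.name}: epsilon must be >= 0")


@dataclass
class Fragment:
    """A rigid side-chain analog with charges and anchor-atom metadata."""

    kind: str
    atoms: list[AtomRecord]
    net_charge: int
    resname: str
    anchors: dict = field(default_factory=dict)

    def __post_init__(self):
        total = sum(a.charge for a in self.atoms)
        if abs(total - self.net_charge) > 1e-6:
            raise ValueError(
                f"{self.kind}: charge sum {total:.6f} != net charge "
                f"{self.net_charge}"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def names(self) -> list[str]:
        return [a.name for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([a.sigma for a in self.atoms])

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([a.epsilon for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def position(self, name: str) -> np.ndarray:
        for a in self.atoms:
            if a.name == name:
                return a.position
        raise KeyError(f"{self.kind}: no atom named {name!r}")

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Fragment":
        """Rigid-body copy: positions -> R @ r + t."""
        atoms = [
            replace(a, position=R @ a.position + np.asarray(t, dtype=float))
            for a in self.atoms
        ]
        return Fragment(self.kind, atoms, self.net_charge, self.resname, dict(self.anchors))

    def with_charges(self, charges: dict, net_charge: int | None = None) -> "Fragment":
        missing = set(self.names) ^ set(charges)
        if missing:
            raise ValueError(
                f"{self.kind}: charge set does not match template atoms: "
                f"{sorted(missing)}"
            )
        atoms = [replace(a, charge=float(charges[a.name])) for a in self.atoms]
        return Fragment(
            self.kind,
            atoms,
            self.net_charge if net_charge is None else net_charge,
            self.resname,
            dict(self.anchors),
        )


@dataclass
class PairComplex:
    """Two fragments posed in a constrained scan geometry.

    Both fragments are expressed in a common laboratory frame: the scan
    axis is x, the acceptor sits at positive-x-facing origin-side and the
    donor approaches from the opposite side.
    """

    acceptor: Fragment
    donor: Fragment
    mode: str
    distance: float
    coordinate_def: str

    @property
    def atoms(self) -> list[AtomRecord]:
        return list(self.acceptor.atoms) + list(self.donor.atoms)


# ---------------------------------------------------------------------------
# template loading
# ---------------------------------------------------------------------------

_TEMPLATE_CACHE: dict[str, tuple] = {}


def _parse_anchor_field(text: str) -> dict:
    anchors: dict = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition("=")
        key = key.strip()
        val = val.strip()
        if key == "donor_pairs":
            anchors[key] = [tuple(p.split(":")) for p in val.split(",")]
        elif key == "bidentate_oxygens":
            anchors[key] = val.split(",")
        elif key == "collinear_donor":
            anchors[key] = tuple(val.split(":"))
        else:
            anchors[key] = val
    return anchors


def load_template(kind: str):
    """Read a packaged fragment template (no charges attached)."""
    kind = resolve_kind(kind)
    if kind in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[kind]
    res = files("oxohb.data.fragments") / f"{kind.lower()}.tsv"
    try:
        text = res.read_text()
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"no template for fragment kind {kind}") from exc
    meta = {}
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        name, el, x, y, z, s, e = line.split("\t")
        rows.append((name, el, (float(x), float(y), float(z)), float(s), float(e)))
    out = (
        rows,
        int(meta["net_charge"]),
        meta["resname"],
        _parse_anchor_field(meta.get("anchors", "")),
    )
    _TEMPLATE_CACHE[kind] = out
    return out


def build_fragment(kind: str, charge_source: str | None = None) -> Fragment:
    """Build a fragment with idealized geometry, charges and LJ parameters.

    ``charge_source`` selects the packaged charge-set provenance; by default
    the ESP-style set is used for modified residues and the force-field set
    for the standard analogs.
    """
    from .charges import default_source, load_charge_set

    kind = resolve_kind(kind)
    rows, net, resname, anchors = load_template(kind)
    atoms = [
        AtomRecord(name, el, pos, 0.0, s, e) for (name, el, pos, s, e) in rows
    ]
    frag = Fragment(kind, atoms, 0, resname, anchors)
    cs = load_charge_set(kind, charge_source or default_source(kind))
    frag = frag.with_charges(cs.charges, cs.net_charge)
    return frag


# ---------------------------------------------------------------------------
# posing
# ---------------------------------------------------------------------------

def _spin_reference(frag: Fragment, p0: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """First atom with an appreciable off-axis component, for fixing the
    free rotation about the scan axis deterministically."""
    for a in frag.atoms:
        v = a.position - p0
        v_perp = v - np.dot(v, axis) * axis
        if np.linalg.norm(v_perp) > 0.2:
            return a.position
    raise ValueError(f"{frag.kind}: cannot fix rotation about axis")


def _place(frag: Fragment, p_origin_name: str, x_dir_to_name: str,
           target_origin: np.ndarray, target_x: np.ndarray) -> Fragment:
    """Rigid transform putting atom ``p_origin_name`` at ``target_origin``
    with the bond towards ``x_dir_to_name`` along ``target_x``; the spin
    about the axis is fixed by a deterministic reference atom."""
    p0 = frag.position(p_origin_name)
    axis = unit(frag.position(x_dir_to_name) - p0)
    ref = _spin_reference(frag, p0, axis)
    local = orthonormal_frame(axis, ref - p0)
    world = orthonormal_frame(target_x, np.array([0.0, 1.0, 0.0])
                              if abs(target_x[1]) < 0.9 else np.array([0.0, 0.0, 1.0]))
    R = world.T @ local
    t = np.asarray(target_origin, dtype=float) - R @ p0
    return frag.transformed(R, t)


def _pose_collinear(acceptor: Fragment, donor: Fragment, distance: float):
    center = acceptor.anchors["center"]
    o_name = acceptor.anchors["collinear_oxygen"]
    if "collinear_donor" not in donor.anchors:
        raise ValueError(f"{donor.kind} has no collinear donor anchor")
    n_name, h_name = donor.anchors["collinear_donor"]

    # acceptor: O at origin, center along +x
    acc = _place(acceptor, o_name, center,
                 np.zeros(3), np.array([1.0, 0.0, 0.0]))
    # donor: N at (-d, 0, 0), N->H along +x (towards O)
    don = _place(donor, n_name, h_name,
                 np.array([-distance, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))
    coord = f"{n_name}(donor)-{o_name}(acceptor) N-O distance"
    return acc, don, coord


def _bisector_frame(frag: Fragment, apex: str, a1: str, a2: str):
    """Orthonormal frame at ``apex``: e1 along the bisector of apex->a1 and
    apex->a2, e2 towards a1, e3 the plane normal."""
    p = frag.position(apex)
    u1 = unit(frag.position(a1) - p)
    u2 = unit(frag.position(a2) - p)
    e1 = unit(u1 + u2)
    return orthonormal_frame(e1, u1), p


def _pose_coplanar(acceptor: Fragment, donor: Fragment, distance: float):
    if donor.kind != "ARG_ANALOG":
        raise ValueError("coplanar bidentate pose requires the Arg analog donor")
    center = acceptor.anchors["center"]
    o1, o2 = acceptor.anchors["bidentate_oxygens"]
    pairs = donor.anchors["donor_pairs"]
    (n1, _h1), (n2, _h2) = pairs

    # acceptor: center at origin, O1/O2 bisector along +x, O1 on +y side
    local, p = _bisector_frame(acceptor, center, o1, o2)
    world = np.eye(3)
    R = world.T @ local
    acc = acceptor.transformed(R, -R @ p)

    # donor: CZ at (d,0,0), NH bisector along -x, NH1 on +y side
    local_d, p_d = _bisector_frame(donor, donor.anchors["bidentate_center"], n1, n2)
    world_d = orthonormal_frame(np.array([-1.0, 0.0, 0.0]),
                                np.array([0.0, 1.0, 0.0]))
    Rd = world_d.T @ local_d
    don = donor.transformed(Rd, np.array([distance, 0.0, 0.0]) - Rd @ p_d)
    cz = donor.anchors["bidentate_center"]
    coord = f"{cz}(donor)-{center}(acceptor) distance"
    return acc, don, coord


def pose_pair(acceptor: Fragment, donor: Fragment, mode: str,
              distance: float) -> PairComplex:
    """Pose two fragments at a given scan distance.

    ``mode`` is ``"collinear"`` or ``"coplanar"``; the latter is only
    defined for the Arg analog donor.  ``distance`` is the N-O distance
    (collinear) or the CZ-to-center distance (coplanar), in Angstroms,
    and must be at least 2.25 A.
    """
    if mode not in ("collinear", "coplanar"):
        raise ValueError(f"unknown pose mode: {mode!r}")
    if distance < MIN_SCAN_DISTANCE:
        raise ValueError(
            f"scan distance {distance} A below minimum {MIN_SCAN_DISTANCE} A"
        )
    if acceptor.kind not in ACCEPTOR_KINDS:
        raise ValueError(f"{acceptor.kind} is not an acceptor fragment")
    if donor.kind not in DONOR_KINDS:
        raise ValueError(f"{donor.kind} is not a donor fragment")
    if mode == "collinear":
        acc, don, coord = _pose_collinear(acceptor, donor, distance)
    else:
        acc, don, coord = _pose_coplanar(acceptor, donor, distance)
    return PairComplex(acc, don, mode, float(distance), coord)


def min_heavy_distance(pair: PairComplex) -> float:
    """Smallest intermolecular heavy-atom distance in a posed complex."""
    ai = [i for i, e in enumerate(pair.acceptor.elements) if e != "H"]
    di = [i for i, e in enumerate(pair.donor.elements) if e != "H"]
    ca = pair.acceptor.coords[ai]
    cd = pair.donor.coords[di]
    d = np.linalg.norm(ca[:, None, :] - cd[None, :, :], axis=-1)
    return float(d.min())
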