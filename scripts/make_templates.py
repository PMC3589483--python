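"""Regenerate the packaged fragment-template and charge-set data files.

Builds idealized side-chain-analog geometries (standard small-molecule bond
lengths and angles, documented inline) for the nine fragment kinds and writes
them as plain-text templates under ``src/oxohb/data``.  Charge sets for the
unmodified analogs follow a standard OPLS-type fixed-charge assignment; the
ESP-style sets for the phosphorylated/sulfated fragments are synthetic
assignments constructed for this package (marked ``esp-synthetic``).

Run from the repository root:  python scripts/make_templates.py
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
FRAG_DIR = ROOT / "src" / "oxohb" / "data" / "fragments"
CHG_DIR = ROOT / "src" / "oxohb" / "data" / "charges"


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def rot_z(deg):
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def place(a, b, c, r, theta_deg, phi_deg):
    """NeRF placement: new atom bonded to a, angle with b, dihedral with c."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    ab = unit(np.asarray(a) - np.asarray(b))
    n = unit(np.cross(unit(np.asarray(b) - np.asarray(c)), ab))
    m = np.cross(n, ab)
    d = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(phi),
            r * math.sin(theta) * math.sin(phi),
        ]
    )
    return np.asarray(a) + d[0] * ab + d[1] * m + d[2] * n


def tetra_completion(d1, d2):
    """Two unit directions completing a tetrahedral center with bonds d1, d2."""
    b = -unit(unit(d1) + unit(d2))
    n = unit(np.cross(d1, d2))
    half = math.radians(109.47 / 2.0)
    return (
        b * math.cos(half) + n * math.sin(half),
        b * math.cos(half) - n * math.sin(half),
    )


def methyl(c, parent, ref, r=1.09):
    """Three staggered H positions on methyl carbon c bonded to parent."""
    out = []
    for phi in (60.0, 180.0, 300.0):
        out.append(place(c, parent, ref, r, 109.47, phi))
    return out


# Lennard-Jones parameters by atom class (sigma A, epsilon kcal/mol),
# OPLS-type values; polar hydrogens get a small placeholder sigma.
LJ = {
    "C3": (3.50, 0.066),   # sp3 carbon
    "CO": (3.75, 0.105),   # carboxylate / amide carbonyl carbon
    "CZG": (2.25, 0.050),  # guanidinium carbon
    "CA": (3.55, 0.070),   # aromatic carbon
    "HC": (2.50, 0.030),   # H on sp3 carbon
    "HA": (2.42, 0.030),   # aromatic H
    "HP": (0.50, 0.010),   # polar H (on N or O)
    "N": (3.25, 0.170),
    "O2": (2.96, 0.210),   # carbonyl / carboxylate / oxoanion terminal O
    "OS": (2.90, 0.140),   # ester (bridging) O
    "OH": (3.00, 0.170),   # protonated oxoanion O
    "P": (3.74, 0.200),
    "S": (3.55, 0.250),
}


def atom(name, element, pos, cls):
    s, e = LJ[cls]
    return (name, element, np.asarray(pos, dtype=float), s, e)


def build_glu():
    """Propionate (Glu side-chain analog), carboxylate C at the origin."""
    CD = np.zeros(3)
    a = math.radians(63.0)  # half of the 126 deg O-C-O angle
    OE1 = 1.25 * np.array([math.cos(a), math.sin(a), 0.0])
    OE2 = 1.25 * np.array([math.cos(a), -math.sin(a), 0.0])
    CG = np.array([-1.52, 0.0, 0.0])
    CB = place(CG, CD, OE1, 1.53, 111.0, 0.0)
    hg1, hg2 = tetra_completion(unit(CD - CG), unit(CB - CG))
    HG2 = CG + 1.09 * hg1
    HG3 = CG + 1.09 * hg2
    atoms = [
        atom("CD", "C", CD, "CO"),
        atom("OE1", "O", OE1, "O2"),
        atom("OE2", "O", OE2, "O2"),
        atom("CG", "C", CG, "C3"),
        atom("HG2", "H", HG2, "HC"),
        atom("HG3", "H", HG3, "HC"),
        atom("CB", "C", CB, "C3"),
    ]
    for i, h in enumerate(methyl(CB, CG, CD), 1):
        atoms.append(atom(f"HB{i}", "H", h, "HC"))
    anchors = "center=CD; collinear_oxygen=OE1; bidentate_oxygens=OE1,OE2"
    return atoms, anchors, "GLU"


def build_arg():
    """Methylguanidinium (Arg analog); NH1/NH2 bisector along +x."""
    CZ = np.zeros(3)
    NH1 = 1.33 * np.array([math.cos(math.radians(60)), math.sin(math.radians(60)), 0.0])
    NH2 = NH1 * np.array([1.0, -1.0, 1.0])
    NE = np.array([-1.33, 0.0, 0.0])
    # in-plane H at 120 deg from the N-CZ bond; HH11/HH21 are the pair anti
    # to NE (the chelating hydrogens in the bidentate pose)
    HH11 = NH1 + 1.01 * unit(rot_z(120.0) @ unit(CZ - NH1))
    HH12 = NH1 + 1.01 * unit(rot_z(-120.0) @ unit(CZ - NH1))
    HH21 = NH2 + 1.01 * unit(rot_z(-120.0) @ unit(CZ - NH2))
    HH22 = NH2 + 1.01 * unit(rot_z(120.0) @ unit(CZ - NH2))
    HE = NE + 1.01 * unit(rot_z(120.0) @ unit(CZ - NE))
    CD = NE + 1.46 * unit(rot_z(-120.0) @ unit(CZ - NE))
    atoms = [
        atom("CZ", "C", CZ, "CZG"),
        atom("NE", "N", NE, "N"),
        atom("HE", "H", HE, "HP"),
        atom("NH1", "N", NH1, "N"),
        atom("HH11", "H", HH11, "HP"),
        atom("HH12", "H", HH12, "HP"),
        atom("NH2", "N", NH2, "N"),
        atom("HH21", "H", HH21, "HP"),
        atom("HH22", "H", HH22, "HP"),
        atom("CD", "C", CD, "C3"),
    ]
    for i, h in enumerate(methyl(CD, NE, CZ), 1):
        atoms.append(atom(f"HD{i}", "H", h, "HC"))
    anchors = (
        "bidentate_center=CZ; donor_pairs=NH1:HH11,NH2:HH21; "
        "collinear_donor=NH1:HH11"
    )
    return atoms, anchors, "ARG"


def build_lys():
    """Methylammonium (Lys analog); the scan N-H bond along +x."""
    NZ = np.zeros(3)
    HZ1 = np.array([1.01, 0.0, 0.0])
    t = math.radians(109.47)
    CE = 1.49 * np.array([math.cos(t), math.sin(t), 0.0])
    d1, d2 = tetra_completion(unit(HZ1), unit(CE))
    HZ2 = NZ + 1.01 * d1
    HZ3 = NZ + 1.01 * d2
    atoms = [
        atom("NZ", "N", NZ, "N"),
        atom("HZ1", "H", HZ1, "HP"),
        atom("HZ2", "H", HZ2, "HP"),
        atom("HZ3", "H", HZ3, "HP"),
        atom("CE", "C", CE, "C3"),
    ]
    for i, h in enumerate(methyl(CE, NZ, HZ1), 1):
        atoms.append(atom(f"HE{i}", "H", h, "HC"))
    anchors = "collinear_donor=NZ:HZ1"
    return atoms, anchors, "LYS"


def build_amide():
    """trans-N-methylacetamide (backbone amide analog)."""
    N = np.zeros(3)
    H = np.array([1.01, 0.0, 0.0])
    C = 1.335 * np.array([math.cos(math.radians(119)), math.sin(math.radians(119)), 0.0])
    O = place(C, N, H, 1.23, 122.5, 180.0)   # O trans to the amide H
    CT1 = place(C, N, H, 1.52, 116.0, 0.0)
    CT2 = 1.45 * np.array(
        [math.cos(math.radians(-119)), math.sin(math.radians(-119)), 0.0]
    )
    atoms = [
        atom("N", "N", N, "N"),
        atom("H", "H", H, "HP"),
        atom("C", "C", C, "CO"),
        atom("O", "O", O, "O2"),
        atom("CT1", "C", CT1, "C3"),
        atom("CT2", "C", CT2, "C3"),
    ]
    for i, h in enumerate(methyl(CT1, C, N), 1):
        atoms.append(atom(f"H1{i}", "H", h, "HC"))
    for i, h in enumerate(methyl(CT2, N, C), 1):
        atoms.append(atom(f"H2{i}", "H", h, "HC"))
    anchors = "collinear_donor=N:H"
    return atoms, anchors, "NMA"


def _oxoanion_core(center_el, r_term, r_ester, protonated):
    """Tetrahedral oxoanion XO3-OR core, center at origin, terminal O1/O2
    symmetric about +x in the xy-plane (terminal O-X-O 114 deg)."""
    X = np.zeros(3)
    a = math.radians(57.0)
    O1 = r_term * np.array([math.cos(a), math.sin(a), 0.0])
    O2 = r_term * np.array([math.cos(a), -math.sin(a), 0.0])
    d_up, d_dn = tetra_completion(unit(O1), unit(O2))
    suff = "P" if center_el == "P" else "S"
    r3 = (r_term + 0.07) if protonated else r_term
    O3 = r3 * d_up
    OG = r_ester * d_dn
    atoms = [
        atom(suff, center_el, X, "P" if center_el == "P" else "S"),
        atom(f"O1{suff}", "O", O1, "O2"),
        atom(f"O2{suff}", "O", O2, "O2"),
        atom(f"O3{suff}", "O", O3, "OH" if protonated else "O2"),
    ]
    if protonated:
        HOP = place(O3, X, O1, 0.98, 110.0, 180.0)
        atoms.append(atom("HOP", "H", HOP, "HP"))
    return atoms, X, O1, OG, suff


def build_pser(protonated):
    atoms, P, O1, OG, suff = _oxoanion_core("P", 1.51, 1.64, protonated)
    atoms.append(atom("OG", "O", OG, "OS"))
    CB = place(OG, P, O1, 1.42, 119.0, 60.0)
    atoms.append(atom("CB", "C", CB, "C3"))
    for i, h in enumerate(methyl(CB, OG, P), 1):
        atoms.append(atom(f"HB{i}", "H", h, "HC"))
    anchors = (
        f"center={suff}; collinear_oxygen=O1{suff}; "
        f"bidentate_oxygens=O1{suff},O2{suff}"
    )
    return atoms, anchors, "SEP"


def _aryl(atoms, OG, X, O1):
    """Attach a p-cresyl group to the ester oxygen OG."""
    CZ = place(OG, X, O1, 1.38, 119.0, 60.0)
    CE1 = place(CZ, OG, X, 1.39, 120.0, 90.0)
    CE2 = place(CZ, CE1, OG, 1.39, 120.0, 180.0)
    CD1 = place(CE1, CZ, OG, 1.39, 120.0, 180.0)
    CG = place(CD1, CE1, CZ, 1.39, 120.0, 0.0)
    CD2 = place(CG, CD1, CE1, 1.39, 120.0, 0.0)
    # ring-closure check
    assert abs(np.linalg.norm(CD2 - CE2) - 1.39) < 0.02
    HE1 = place(CE1, CZ, CD1, 1.08, 120.0, 180.0)
    HE2 = place(CE2, CZ, CD2, 1.08, 120.0, 180.0)
    HD1 = place(CD1, CE1, CZ, 1.08, 120.0, 180.0)
    HD2 = place(CD2, CG, CD1, 1.08, 120.0, 180.0)
    CB = place(CG, CD1, CE1, 1.51, 120.0, 180.0)
    atoms += [
        atom("OH", "O", OG, "OS"),
        atom("CZ", "C", CZ, "CA"),
        atom("CE1", "C", CE1, "CA"),
        atom("HE1", "H", HE1, "HA"),
        atom("CE2", "C", CE2, "CA"),
        atom("HE2", "H", HE2, "HA"),
        atom("CD1", "C", CD1, "CA"),
        atom("HD1", "H", HD1, "HA"),
        atom("CD2", "C", CD2, "CA"),
        atom("HD2", "H", HD2, "HA"),
        atom("CG", "C", CG, "CA"),
        atom("CB", "C", CB, "C3"),
    ]
    for i, h in enumerate(methyl(CB, CG, CD1), 1):
        atoms.append(atom(f"HB{i}", "H", h, "HC"))
    return atoms


def build_ptyr(protonated):
    atoms, P, O1, OG, suff = _oxoanion_core("P", 1.51, 1.64, protonated)
    atoms = _aryl(atoms, OG, P, O1)
    anchors = (
        f"center={suff}; collinear_oxygen=O1{suff}; "
        f"bidentate_oxygens=O1{suff},O2{suff}"
    )
    return atoms, anchors, "PTR"


def build_styr():
    atoms, S, O1, OG, suff = _oxoanion_core("S", 1.455, 1.60, False)
    atoms = _aryl(atoms, OG, S, O1)
    anchors = "center=S; collinear_oxygen=O1S; bidentate_oxygens=O1S,O2S"
    return atoms, anchors, "TYS"


# ---------------------------------------------------------------------------
# charge sets
# ---------------------------------------------------------------------------

CHARGES = {
    "GLU_ANALOG": (
        -1,
        "force-field",
        {
            "CD": 0.700, "OE1": -0.800, "OE2": -0.800, "CG": -0.220,
            "HG2": 0.060, "HG3": 0.060, "CB": -0.180,
            "HB1": 0.060, "HB2": 0.060, "HB3": 0.060,
        },
    ),
    "ARG_ANALOG": (
        +1,
        "force-field",
        {
            "CZ": 0.640, "NE": -0.700, "HE": 0.440,
            "NH1": -0.800, "HH11": 0.460, "HH12": 0.460,
            "NH2": -0.800, "HH21": 0.460, "HH22": 0.460,
            "CD": 0.200, "HD1": 0.060, "HD2": 0.060, "HD3": 0.060,
        },
    ),
    "LYS_ANALOG": (
        +1,
        "force-field",
        {
            "NZ": -0.300, "HZ1": 0.330, "HZ2": 0.330, "HZ3": 0.330,
            "CE": 0.130, "HE1": 0.060, "HE2": 0.060, "HE3": 0.060,
        },
    ),
    "AMIDE_ANALOG": (
        0,
        "force-field",
        {
            "N": -0.500, "H": 0.300, "C": 0.500, "O": -0.500,
            "CT1": -0.180, "CT2": 0.020,
            "H11": 0.060, "H12": 0.060, "H13": 0.060,
            "H21": 0.060, "H22": 0.060, "H23": 0.060,
        },
    ),
    "PSER_M2": (
        -2,
        "esp-synthetic",
        {
            "P": 1.300, "O1P": -0.950, "O2P": -0.950, "O3P": -0.950,
            "OG": -0.600, "CB": 0.030, "HB1": 0.040, "HB2": 0.040, "HB3": 0.040,
        },
    ),
    "PSER_M1": (
        -1,
        "esp-synthetic",
        {
            "P": 1.320, "O1P": -0.880, "O2P": -0.880, "O3P": -0.620,
            "HOP": 0.440, "OG": -0.560, "CB": 0.030,
            "HB1": 0.050, "HB2": 0.050, "HB3": 0.050,
        },
    ),
    "PTYR_M2": (
        -2,
        "esp-synthetic",
        {
            "P": 1.280, "O1P": -0.920, "O2P": -0.920, "O3P": -0.920,
            "OH": -0.660, "CZ": 0.260, "CG": -0.150,
            "CD1": -0.120, "HD1": 0.120, "CD2": -0.120, "HD2": 0.120,
            "CE1": -0.140, "HE1": 0.140, "CE2": -0.140, "HE2": 0.140,
            "CB": -0.150, "HB1": 0.060, "HB2": 0.060, "HB3": 0.060,
        },
    ),
    "PTYR_M1": (
        -1,
        "esp-synthetic",
        {
            "P": 1.300, "O1P": -0.860, "O2P": -0.860, "O3P": -0.600,
            "HOP": 0.440, "OH": -0.560, "CZ": 0.260, "CG": -0.150,
            "CD1": -0.120, "HD1": 0.120, "CD2": -0.120, "HD2": 0.120,
            "CE1": -0.140, "HE1": 0.140, "CE2": -0.140, "HE2": 0.140,
            "CB": -0.150, "HB1": 0.060, "HB2": 0.060, "HB3": 0.060,
        },
    ),
    "STYR": (
        -1,
        "esp-synthetic",
        {
            "S": 1.250, "O1S": -0.660, "O2S": -0.660, "O3S": -0.660,
            "OH": -0.500, "CZ": 0.260, "CG": -0.060,
            "CD1": -0.120, "HD1": 0.120, "CD2": -0.120, "HD2": 0.120,
            "CE1": -0.140, "HE1": 0.140, "CE2": -0.140, "HE2": 0.140,
            "CB": -0.150, "HB1": 0.060, "HB2": 0.060, "HB3": 0.060,
        },
    ),
}

BUILDERS = {
    "GLU_ANALOG": build_glu,
    "ARG_ANALOG": build_arg,
    "LYS_ANALOG": build_lys,
    "AMIDE_ANALOG": build_amide,
    "PSER_M2": lambda: build_pser(False),
    "PSER_M1": lambda: build_pser(True),
    "PTYR_M2": lambda: build_ptyr(False),
    "PTYR_M1": lambda: build_ptyr(True),
    "STYR": build_styr,
}


def main():
    FRAG_DIR.mkdir(parents=True, exist_ok=True)
    CHG_DIR.mkdir(parents=True, exist_ok=True)
    for kind, builder in BUILDERS.items():
        atoms, anchors, resname = builder()
        net, prov, charges = CHARGES[kind]
        names = [a[0] for a in atoms]
        assert set(names) == set(charges), (
            kind,
            set(names) ^ set(charges),
        )
        total = sum(charges.values())
        assert abs(total - net) < 1e-9, (kind, total)
        path = FRAG_DIR / f"{kind.lower()}.tsv"
        with path.open("w") as fh:
            fh.write("# fragment template (synthetic idealized geometry)\n")
            fh.write(f"# kind: {kind}\n")
            fh.write(f"# resname: {resname}\n")
            fh.write(f"# net_charge: {net}\n")
            fh.write(f"# anchors: {anchors}\n")
            fh.write("# columns: name element x y z sigma epsilon\n")
            for name, el, pos, s, e in atoms:
                fh.write(
                    f"{name}\t{el}\t{pos[0]:.6f}\t{pos[1]:.6f}\t{pos[2]:.6f}"
                    f"\t{s:.3f}\t{e:.3f}\n"
                )
        cpath = CHG_DIR / f"{kind.lower()}.{prov}.txt"
        with cpath.open("w") as fh:
            fh.write(f"# kind: {kind}\n")
            fh.write(f"# net_charge: {net}\n")
            fh.write(f"# provenance: {prov}\n")
            for name in names:
                fh.write(f"{name}\t{charges[name]:.4f}\n")
        print(f"wrote {path.name} ({len(atoms)} atoms) and {cpath.name}")


if __name__ == "__main__":
    main()
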