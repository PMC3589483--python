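"""Partial-charge sets and charge-distribution summaries.

Charge sets are shipped as plain-text two-column files (atom name, charge in
elementary-charge units) with a short header declaring the fragment kind,
the net charge and the provenance label.  Two provenances are packaged:

``force-field``
    standard OPLS-type fixed charges for the unmodified analogs
    (propionate, methylguanidinium, methylammonium, N-methylacetamide).

``esp-synthetic``
    ESP-style charge distributions for the phosphorylated / sulfated
    fragments.  These are synthetic assignments constructed for this
    package: they reproduce the formal net charges (-2 for dianionic
    phosphates, -1 for protonated phosphates and for the sulfate) and the
    qualitative pattern of ESP fits to such groups (strong negative terminal
    oxygens for dianions, weaker ones for monoanions), not any particular
    quantum-chemical fit.

User files in the same format can be loaded from an explicit path.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import numpy as np

from .fragments import Fragment, load_template, resolve_kind

#: 1 e*Angstrom in Debye
EA_TO_DEBYE = 4.8032

#: atomic masses (amu) for the center-of-mass origin convention
MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
          "P": 30.974, "S": 32.06}

_MODIFIED = {"PSER_M2", "PSER_M1", "PTYR_M2", "PTYR_M1", "STYR"}


def default_source(kind: str) -> str:
    return "esp-synthetic" if resolve_kind(kind) in _MODIFIED else "force-field"


@dataclass
class ChargeSet:
    kind: str
    charges: dict[str, float]
    provenance: str
    net_charge: int

    def __post_init__(self):
        total = sum(self.charges.values())
        if abs(total - self.net_charge) > 1e-6:
            raise ValueError(
                f"{self.kind} charge set: sum {total:.6f} != declared net "
                f"charge {self.net_charge}"
            )


def _parse(text: str, kind: str, provenance: str) -> ChargeSet:
    meta = {}
    charges: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed charge line {lineno}: {line!r}")
        name, q = parts
        if name in charges:
            raise ValueError(f"duplicate atom {name!r} in charge set")
        charges[name] = float(q)
    net = int(meta.get("net_charge", round(sum(charges.values()))))
    prov = meta.get("provenance", provenance)
    file_kind = meta.get("kind", kind)
    cs = ChargeSet(file_kind, charges, prov, net)
    # validate against the fragment template: no silent renames
    rows, tpl_net, _, _ = load_template(file_kind)
    tpl_names = {r[0] for r in rows}
    mismatch = tpl_names ^ set(charges)
    if mismatch:
        raise ValueError(
            f"{file_kind}: charge-set atoms do not match template: "
            f"{sorted(mismatch)}"
        )
    if net != tpl_net:
        raise ValueError(
            f"{file_kind}: net charge {net} inconsistent with template "
            f"net charge {tpl_net}"
        )
    return cs


def load_charge_set(kind: str, source: str = "default") -> ChargeSet:
    """Load and validate a packaged (or user) charge set.

    ``source`` is a provenance label (``force-field``, ``esp-synthetic``) or
    a filesystem path to a user file in the same format.
    """
    kind = resolve_kind(kind)
    if source == "default":
        source = default_source(kind)
    p = Path(str(source))
    if p.suffix and p.exists():
        return _parse(p.read_text(), kind, "user")
    res = files("oxohb.data.charges") / f"{kind.lower()}.{source}.txt"
    try:
        text = res.read_text()
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            f"no packaged charge set for ({kind}, {source})"
        ) from exc
    return _parse(text, kind, source)


def write_charge_set(cs: ChargeSet, path) -> None:
    """Write a charge set in the packaged plain-text format (round-trips
    bitwise through :func:`load_charge_set` with ``repr``-exact floats)."""
    with open(path, "w") as fh:
        fh.write(f"# kind: {cs.kind}\n")
        fh.write(f"# net_charge: {cs.net_charge}\n")
        fh.write(f"# provenance: {cs.provenance}\n")
        for name, q in cs.charges.items():
            fh.write(f"{name}\t{q!r}\n")


def dipole_vector(fragment: Fragment, origin="com") -> np.ndarray:
    """Dipole vector (Debye) of a fragment's point charges.

    ``origin`` is ``"com"`` (center of mass, the convention applied for
    charged species), ``"origin"`` (the coordinate origin) or an explicit
    3-vector.  For a neutral fragment the result is origin-independent.
    """
    q = fragment.charges
    r = fragment.coords
    if isinstance(origin, str):
        if origin == "com":
            m = np.array([MASSES[e] for e in fragment.elements])
            o = (m[:, None] * r).sum(axis=0) / m.sum()
        elif origin == "origin":
            o = np.zeros(3)
        else:
            raise ValueError(f"unknown origin convention {origin!r}")
    else:
        o = np.asarray(origin, dtype=float)
    return EA_TO_DEBYE * (q[:, None] * (r - o)).sum(axis=0)


def dipole_moment(fragment: Fragment, origin="com") -> float:
    """Magnitude of :func:`dipole_vector`, in Debye."""
    return float(np.linalg.norm(dipole_vector(fragment, origin)))
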