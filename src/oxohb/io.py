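"""PDB-format structure reading and writing.

Multi-model PDB files are the trajectory format: MODEL/ENDMDL records
delimit frames.  The modified residues SEP (phosphoserine), PTR
(phosphotyrosine) and TYS (sulfotyrosine) are recognized whether deposited
as ATOM or HETATM.  Alternate locations are collapsed to the
highest-occupancy conformer; insertion codes are preserved as part of the
residue identifier.  Parsing is delegated to gemmi.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

MODIFIED_RESNAMES = {"SEP", "PTR", "TYS"}


@dataclass
class Frame:
    """One structure snapshot as flat numpy-backed atom arrays."""

    names: np.ndarray          # atom names
    elements: np.ndarray       # element symbols, upper case
    resnames: np.ndarray
    resids: np.ndarray         # author residue numbers (int)
    icodes: np.ndarray         # insertion codes ('' when absent)
    chains: np.ndarray
    coords: np.ndarray         # (n, 3) float, Angstroms
    occupancies: np.ndarray

    def __len__(self) -> int:
        return len(self.names)

    def residue_mask(self, chain: str, resid: int, icode: str = "") -> np.ndarray:
        return (
            (self.chains == chain)
            & (self.resids == resid)
            & (self.icodes == icode)
        )

    def residues(self):
        """Iterate (chain, resid, icode, resname, index-array) in file order."""
        seen = {}
        order = []
        for i in range(len(self)):
            key = (self.chains[i], int(self.resids[i]), self.icodes[i])
            if key not in seen:
                seen[key] = []
                order.append((key, self.resnames[i]))
            seen[key].append(i)
        for key, resname in order:
            yield key[0], key[1], key[2], resname, np.array(seen[key])


def _frame_from_model(model: gemmi.Model) -> Frame:
    names, elements, resnames, resids, icodes, chains, xyz, occ = (
        [], [], [], [], [], [], [], [],
    )
    for chain in model:
        for res in chain:
            # keep one conformer per atom name: highest occupancy wins
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in best.values():
                names.append(at.name)
                elements.append(at.element.name.upper())
                resnames.append(res.name)
                resids.append(res.seqid.num)
                icodes.append((res.seqid.icode or " ").strip())
                chains.append(chain.name)
                xyz.append([at.pos.x, at.pos.y, at.pos.z])
                occ.append(at.occ)
    return Frame(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        icodes=np.array(icodes, dtype=object),
        chains=np.array(chains, dtype=object),
        coords=np.array(xyz, dtype=float).reshape(-1, 3),
        occupancies=np.array(occ, dtype=float),
    )


def read_structure(path) -> list[Frame]:
    """Read a single- or multi-model PDB file as a list of frames."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    st.setup_entities()
    frames = [_frame_from_model(m) for m in st]
    if not frames:
        raise ValueError(f"no models found in {path}")
    return frames


def read_metadata(st_path) -> dict:
    """Entry title / resolution / method from a PDB header."""
    st = gemmi.read_pdb(str(st_path))
    res = st.resolution if st.resolution and st.resolution > 0 else None
    return {
        "id": st.name,
        "title": st.get_info("_struct.title") or "",
        "resolution": res,
        "method": st.get_info("_exptl.method") or "",
    }


def write_frames(frames, path, resname_is_het=None, title: str | None = None
                 ) -> None:
    """Write frames as a (multi-)model PDB file.

    Modified residues (SEP/PTR/TYS) and any residue listed in
    ``resname_is_het`` are emitted as HETATM records, mirroring archive
    conventions.
    """
    het = set(MODIFIED_RESNAMES)
    if resname_is_het:
        het |= set(resname_is_het)
    lines = []
    if title:
        lines.append(f"TITLE     {title[:70]}")
    multi = len(frames) > 1
    for imodel, fr in enumerate(frames, 1):
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        serial = 0
        for i in range(len(fr)):
            serial += 1
            record = "HETATM" if fr.resnames[i] in het else "ATOM  "
            name = fr.names[i]
            # PDB column rule: 1-3 char names start in column 14
            aname = name if len(name) >= 4 else f" {name:<3s}"
            x, y, z = fr.coords[i]
            el = fr.elements[i]
            lines.append(
                f"{record}{serial:5d} {aname:<4s}{'':1s}{fr.resnames[i]:<3s} "
                f"{fr.chains[i]:1s}{int(fr.resids[i]):4d}{fr.icodes[i] or '':1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{fr.occupancies[i]:6.2f}{0.0:6.2f}"
                f"          {el:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def frame_from_atoms(atom_groups) -> Frame:
    """Assemble a frame from (resname, chain, resid, atoms) groups, where
    each atom supplies .name, .element and .position (fragment atoms work
    directly)."""
    names, elements, resnames, resids, icodes, chains, xyz = (
        [], [], [], [], [], [], [],
    )
    for resname, chain, resid, atoms in atom_groups:
        for a in atoms:
            names.append(a.name)
            elements.append(a.element.upper())
            resnames.append(resname)
            resids.append(resid)
            icodes.append("")
            chains.append(chain)
            xyz.append(np.asarray(a.position, dtype=float))
    n = len(names)
    return Frame(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        icodes=np.array(icodes, dtype=object),
        chains=np.array(chains, dtype=object),
        coords=np.array(xyz, dtype=float).reshape(n, 3),
        occupancies=np.ones(n),
    )
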