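"""Survey of hydrogen bonds made by modified residues across structures.

Pipeline: deduplicate entries by normalized title keeping the highest
resolution; for each retained entry count, per chain, the hydrogen bonds
made by the side chains of GLU / SEP / PTR / TYS residues under the
heavy-atom radius-sum criterion; split Arg contributions into single and
bidentate; average counts over identical chains (rounded, half away from
zero) and take the donor breakdown from the first identical chain; and
aggregate into a bond-count histogram and a donor-category percentage
table.  Glu residues are surveyed only within entries that also contain a
phosphoserine, mirroring the reference-set convention for the unmodified
comparison residue.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hbond import (
    HBondCriterion,
    SIDECHAIN_ACCEPTORS,
    classify_bonds,
    detect_hbonds,
    _acceptor_indices,
    _donor_indices,
)

DONOR_CATEGORIES = (
    "arg_single", "arg_bidentate", "lys", "gln", "backbone_amide",
    "hydroxyl", "other",
)

HISTOGRAM_BINS = ("0", "1", "2", "3", "4", ">=5")

ACCEPTOR_KINDS = ("GLU", "SEP", "PTR", "TYS")


@dataclass
class EntryMeta:
    entry_id: str
    title: str
    resolution: float | None = None
    method: str = ""

    def __post_init__(self):
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError(f"{self.entry_id}: resolution must be > 0")


@dataclass
class ResidueHBondProfile:
    entry_id: str
    chain: str
    resid: int
    icode: str
    resname: str
    n_hbonds: int
    donor_breakdown: dict = field(default_factory=dict)
    chain_group: int = 0    # identical-chain group within the entry

    def __post_init__(self):
        total = sum(self.donor_breakdown.values())
        if total != self.n_hbonds:
            raise ValueError("donor breakdown does not sum to n_hbonds")


def normalize_title(title: str) -> str:
    return re.sub(r"\s+", " ", title.strip().lower())


def dedup_entries(entries) -> list[EntryMeta]:
    """Keep one entry per normalized title: the best-resolved one, or an
    unresolved (e.g. NMR) entry only when its group has no resolved member.
    Output preserves first-appearance group order."""
    groups: dict[str, list[EntryMeta]] = {}
    order = []
    for e in entries:
        key = normalize_title(e.title)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(e)
    kept = []
    for key in order:
        group = groups[key]
        resolved = [e for e in group if e.resolution is not None]
        if resolved:
            kept.append(min(resolved, key=lambda e: e.resolution))
        else:
            kept.append(group[0])
    return kept


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _chain_sequences(frame) -> dict[str, tuple]:
    seqs: dict[str, list] = {}
    for chain, resid, icode, resname, _idx in frame.residues():
        seqs.setdefault(chain, []).append(resname)
    return {c: tuple(s) for c, s in seqs.items()}


def survey_entry(frame, criterion: HBondCriterion | None = None,
                 entry_id: str = "", glu_requires_sep: bool = True,
                 ) -> list[ResidueHBondProfile]:
    """Hydrogen-bond profiles for every surveyed residue in every chain.

    A residue missing any of its side-chain acceptor atoms is skipped.
    Arg donors contribute their bonds to ``arg_single`` or
    ``arg_bidentate`` according to the per-residue-pair classification.
    """
    criterion = criterion or HBondCriterion(mode="radius_sum")
    donors = _donor_indices(frame)
    acceptors = _acceptor_indices(frame)
    bonds = detect_hbonds(frame, criterion, donor_indices=[i for i, _ in donors],
                          acceptor_indices=acceptors)
    donor_cat = {}
    for i, cat in donors:
        donor_cat[i] = cat

    has_sep = bool(np.any(frame.resnames == "SEP"))

    # identical-chain grouping by residue-name sequence
    seqs = _chain_sequences(frame)
    group_of: dict[str, int] = {}
    seen: dict[tuple, int] = {}
    for chain in seqs:
        s = seqs[chain]
        if s not in seen:
            seen[s] = len(seen)
        group_of[chain] = seen[s]

    # bonds grouped by acceptor residue
    by_residue: dict[tuple, list] = {}
    for b in bonds:
        key = (b.acceptor_atom.chain, b.acceptor_atom.resid,
               b.acceptor_atom.icode)
        by_residue.setdefault(key, []).append(b)

    profiles = []
    for chain, resid, icode, resname, idx in frame.residues():
        if resname not in SIDECHAIN_ACCEPTORS:
            continue
        if resname == "GLU" and glu_requires_sep and not has_sep:
            continue
        present = {frame.names[i] for i in idx}
        if not set(SIDECHAIN_ACCEPTORS[resname]) <= present:
            continue   # incomplete side chain: skip
        rbonds = by_residue.get((chain, resid, icode), [])
        breakdown = {c: 0 for c in DONOR_CATEGORIES}
        # split by donor residue; classify Arg contacts per residue pair
        by_donor_res: dict[tuple, list] = {}
        for b in rbonds:
            dkey = (b.donor_atom.chain, b.donor_atom.resid,
                    b.donor_atom.icode)
            by_donor_res.setdefault(dkey, []).append(b)
        for dkey, dbonds in by_donor_res.items():
            cat = donor_cat[dbonds[0].donor_atom.index]
            if cat == "arg":
                label = classify_bonds(dbonds)
                cat = "arg_bidentate" if label == "bidentate" else "arg_single"
            breakdown[cat] += len(dbonds)
        profiles.append(
            ResidueHBondProfile(
                entry_id=entry_id,
                chain=chain,
                resid=resid,
                icode=icode,
                resname=resname,
                n_hbonds=len(rbonds),
                donor_breakdown=breakdown,
                chain_group=group_of[chain],
            )
        )
    return profiles


@dataclass
class SurveySummary:
    histogram: pd.DataFrame        # % of residues per bond-count bin
    donor_percentages: pd.DataFrame
    n_residues: dict

    def __eq__(self, other):
        return (
            self.histogram.equals(other.histogram)
            and self.donor_percentages.equals(other.donor_percentages)
            and self.n_residues == other.n_residues
        )


def aggregate(profiles) -> SurveySummary:
    """Identical-chain averaging and summary tables.

    Within one entry, profiles of the same residue position in chains of
    the same chain group are merged: the reported bond count is the
    rounded (half away from zero) mean over chains, the donor breakdown is
    taken from the first chain of the group.
    """
    merged: dict[tuple, dict] = {}
    order = []
    for p in profiles:
        key = (p.entry_id, p.chain_group, p.resid, p.icode, p.resname)
        if key not in merged:
            merged[key] = {"counts": [], "first": p}
            order.append(key)
        merged[key]["counts"].append(p.n_hbonds)

    records = []
    for key in order:
        m = merged[key]
        p = m["first"]
        records.append(
            {
                "resname": p.resname,
                "n_hbonds": _round_half_away(float(np.mean(m["counts"]))),
                "breakdown": p.donor_breakdown,
            }
        )

    hist = pd.DataFrame(0.0, index=list(ACCEPTOR_KINDS),
                        columns=list(HISTOGRAM_BINS))
    donors = pd.DataFrame(0.0, index=list(ACCEPTOR_KINDS),
                          columns=list(DONOR_CATEGORIES))
    n_res = {k: 0 for k in ACCEPTOR_KINDS}
    for rec in records:
        k = rec["resname"]
        n_res[k] += 1
        b = min(rec["n_hbonds"], 5)
        hist.loc[k, HISTOGRAM_BINS[b]] += 1
        for cat, cnt in rec["breakdown"].items():
            donors.loc[k, cat] += cnt
    for k in ACCEPTOR_KINDS:
        if n_res[k]:
            hist.loc[k] = 100.0 * hist.loc[k] / n_res[k]
        total_bonds = donors.loc[k].sum()
        if total_bonds:
            donors.loc[k] = 100.0 * donors.loc[k] / total_bonds
    return SurveySummary(histogram=hist, donor_percentages=donors,
                         n_residues=n_res)


def run_survey(frames_by_entry: dict, metadata: list,
               criterion: HBondCriterion | None = None) -> SurveySummary:
    """End-to-end survey: dedup entries, profile each retained entry's
    first model, aggregate."""
    kept = dedup_entries(metadata)
    profiles = []
    for meta in kept:
        if meta.entry_id not in frames_by_entry:
            raise KeyError(f"no structure for entry {meta.entry_id}")
        frame = frames_by_entry[meta.entry_id]
        profiles.extend(survey_entry(frame, criterion, entry_id=meta.entry_id))
    return aggregate(profiles)
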