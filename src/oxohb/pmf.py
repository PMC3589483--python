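"""Rigid distance scans and well depths.

A scan varies the constrained hydrogen-bond coordinate from 2.25 to 11.0 A
at 0.25 A intervals, then refines at 0.05 A steps around the coarse
minimum.  The well depth is the total interaction energy at the refined
minimum minus the value at the 11.0 A reference; an all-repulsive curve
(minimum at 11.0 A) is flagged and assigned well depth 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import EnergyBreakdown, GridSpec, pair_energy
from .fragments import build_fragment, pose_pair, resolve_kind

COARSE_START = 2.25
COARSE_STOP = 11.0
COARSE_STEP = 0.25
FINE_STEP = 0.05
REFINE_HALF_WIDTH = 0.25
REFERENCE_DISTANCE = 11.0

#: acceptor rows and donor columns of the summary well-depth table
TABLE_ACCEPTORS = ("GLU_ANALOG", "PSER_M2", "PSER_M1",
                   "PTYR_M2", "PTYR_M1", "STYR")
TABLE_COLUMNS = (
    ("Arg collinear", "ARG_ANALOG", "collinear"),
    ("Arg coplanar", "ARG_ANALOG", "coplanar"),
    ("Lys", "LYS_ANALOG", "collinear"),
    ("Amide", "AMIDE_ANALOG", "collinear"),
)
ROW_LABELS = {
    "GLU_ANALOG": "Glu",
    "PSER_M2": "pSer(-2)",
    "PSER_M1": "pSer(-1)",
    "PTYR_M2": "pTyr(-2)",
    "PTYR_M1": "pTyr(-1)",
    "STYR": "sTyr",
}


@dataclass
class PMFCurve:
    """Energy-versus-distance profile with refined minimum."""

    acceptor: str
    donor: str
    mode: str
    points: list[tuple[float, EnergyBreakdown]]
    min_distance: float
    well_depth: float
    all_repulsive: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "distance_A": d,
                    "elec_kcal": e.elec,
                    "lj_kcal": e.lj,
                    "total_kcal": e.total,
                }
                for d, e in self.points
            ]
        )

    def total_at(self, distance: float) -> float:
        for d, e in self.points:
            if abs(d - distance) < 1e-9:
                return e.total
        raise KeyError(f"no scan point at {distance} A")


def coarse_distances() -> np.ndarray:
    n = int(round((COARSE_STOP - COARSE_START) / COARSE_STEP)) + 1
    return COARSE_START + COARSE_STEP * np.arange(n)


def _argmin(distances, energies):
    """Index of the minimum energy; ties broken towards smaller distance."""
    e = np.asarray(energies)
    return int(np.flatnonzero(e == e.min())[0])


def scan_curve(energy_fn, acceptor: str, donor: str, mode: str) -> PMFCurve:
    """Run the coarse + fine scan protocol with ``energy_fn(distance) ->
    EnergyBreakdown``; shared by the PB-backed scan and the tests."""
    coarse = coarse_distances()
    points = {float(d): energy_fn(float(d)) for d in coarse}
    totals = [points[float(d)].total for d in coarse]
    i_min = _argmin(coarse, totals)
    d_coarse = float(coarse[i_min])

    lo = max(COARSE_START, d_coarse - REFINE_HALF_WIDTH)
    hi = min(COARSE_STOP, d_coarse + REFINE_HALF_WIDTH)
    n = int(round((hi - lo) / FINE_STEP)) + 1
    for d in lo + FINE_STEP * np.arange(n):
        d = round(float(d), 6)
        if d not in points:
            points[d] = energy_fn(d)

    dists = sorted(points)
    totals = [points[d].total for d in dists]
    j = _argmin(dists, totals)
    d_min = dists[j]
    if not (lo - 1e-9 <= d_min <= hi + 1e-9) and d_min != REFERENCE_DISTANCE:
        # the refined minimum must stay inside the refinement window unless
        # the curve is monotonically repulsive
        raise RuntimeError(
            f"fine-scan minimum {d_min} escaped the refinement window "
            f"[{lo}, {hi}]"
        )
    e_ref = points[REFERENCE_DISTANCE].total
    all_rep = abs(d_min - REFERENCE_DISTANCE) < 1e-9
    if all_rep:
        warnings.warn(
            f"{acceptor}/{donor} ({mode}): all-repulsive curve, "
            "well depth set to 0",
            stacklevel=2,
        )
        depth = 0.0
    else:
        depth = totals[j] - e_ref
    return PMFCurve(
        acceptor=acceptor,
        donor=donor,
        mode=mode,
        points=[(d, points[d]) for d in dists],
        min_distance=d_min,
        well_depth=depth,
        all_repulsive=all_rep,
    )


def scan_pmf(acceptor: str, donor: str, mode: str,
             grid: GridSpec | None = None,
             charge_source: str | None = None) -> PMFCurve:
    """Full rigid-scan PMF for one acceptor/donor/mode combination."""
    acceptor = resolve_kind(acceptor)
    donor = resolve_kind(donor)
    grid = grid or GridSpec()
    acc = build_fragment(acceptor, charge_source)
    don = build_fragment(donor, charge_source)
    cache: dict = {}

    def energy(d: float) -> EnergyBreakdown:
        return pair_energy(pose_pair(acc, don, mode, d), grid,
                           monomer_cache=cache)

    return scan_curve(energy, acceptor, donor, mode)


def well_depth_table(curves) -> pd.DataFrame:
    """Arrange curves as the acceptor-by-donor well-depth matrix (kcal/mol).

    Rows are the six acceptors, columns Arg collinear / Arg coplanar /
    Lys / Amide; raises if a requested cell is missing.
    """
    lookup = {(c.acceptor, c.donor, c.mode): c for c in curves}
    data = {}
    for label, donor, mode in TABLE_COLUMNS:
        col = []
        for acc in TABLE_ACCEPTORS:
            key = (acc, donor, mode)
            if key not in lookup:
                raise KeyError(f"missing PMF curve for {key}")
            col.append(lookup[key].well_depth)
        data[label] = col
    return pd.DataFrame(
        data, index=[ROW_LABELS[a] for a in TABLE_ACCEPTORS]
    )
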