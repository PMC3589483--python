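"""Interaction energetics: finite-difference Poisson-Boltzmann
electrostatics plus OPLS-form Lennard-Jones.

The electrostatic interaction of a posed pair is computed as a
cross-interaction energy: the potential generated by the acceptor's
charges, solved in the two-dielectric geometry of the *full* complex
(interior dielectric inside the union of atom spheres of both fragments,
solvent dielectric outside), evaluated at the donor's charges.  Grid
self-energies cancel exactly in this decomposition, so no vacuum-reference
subtraction is needed.

The dielectric cavity uses per-atom radii derived from the Lennard-Jones
sigma (R_i = 2^(1/6) * sigma_i / 2, the LJ-minimum van der Waals radius).
Defaults follow the standard continuum setup for these scans: four grid
points per Angstrom, interior dielectric 1, exterior dielectric 80, zero
ionic strength.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from ._pb import KE, solve_cascadic
from .fragments import PairComplex

__all__ = [
    "GridSpec",
    "EnergyBreakdown",
    "PotentialMap",
    "lj_energy",
    "solve_pb",
    "elec_interaction",
    "pair_energy",
    "born_solvation_energy",
    "atom_radius",
]

#: dielectric-boundary radius from the LJ sigma
_RADIUS_FACTOR = 2.0 ** (1.0 / 6.0) / 2.0


def atom_radius(sigma: float) -> float:
    """Cavity radius (A) assigned to an atom with LJ parameter ``sigma``."""
    return _RADIUS_FACTOR * sigma


@dataclass
class GridSpec:
    """Finite-difference grid and solver settings.

    spacing
        grid spacing in A (default 0.25, i.e. four points per Angstrom)
    padding
        solvent margin around the solute bounding box, >= 8 A
    eps_in, eps_out
        interior / exterior dielectric constants
    ionic_strength
        must be zero (the Poisson limit; salt is out of scope)
    convergence_tol
        maximum allowed potential update per sweep, kcal/mol/e
    """

    spacing: float = 0.25
    padding: float = 8.0
    eps_in: float = 1.0
    eps_out: float = 80.0
    ionic_strength: float = 0.0
    convergence_tol: float = 1e-6
    max_sweeps: int = 10000
    omega: float | None = None
    cascade_levels: int = 2

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if not (self.eps_out >= self.eps_in >= 1):
            raise ValueError("require eps_out >= eps_in >= 1")
        if self.padding < 8.0:
            raise ValueError("padding must be >= 8 A")
        if self.ionic_strength != 0.0:
            raise NotImplementedError(
                "only zero ionic strength (pure Poisson) is supported"
            )


@dataclass
class EnergyBreakdown:
    """Electrostatic + Lennard-Jones interaction energy, kcal/mol."""

    elec: float
    lj: float

    @property
    def total(self) -> float:
        return self.elec + self.lj


class PotentialMap:
    """A solved potential on a regular grid, kcal/mol/e, with trilinear
    interpolation at arbitrary points."""

    def __init__(self, origin, spacing, values, sweeps=0):
        self.origin = np.asarray(origin, dtype=float)
        self.spacing = float(spacing)
        self.values = values
        self.sweeps = sweeps

    def at(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (pts - self.origin) / self.spacing
        return map_coordinates(self.values, idx.T, order=1, mode="nearest")


def _grid_geometry(coords, radii, grid: GridSpec):
    """Grid origin and shape for a padded solute box.

    The origin is snapped onto the absolute lattice {m*h}, so an atom's
    position relative to the nearest grid node depends only on its absolute
    coordinates.  Grid self-energies of the spread charges then cancel
    exactly between solves of the same atoms in different boxes (complex
    versus isolated fragment), which the total-energy interaction route
    relies on.
    """
    h = grid.spacing
    lo = (coords - radii[:, None]).min(axis=0) - grid.padding
    hi = (coords + radii[:, None]).max(axis=0) + grid.padding
    origin = np.floor(lo / h) * h
    shape = tuple(int(np.ceil((hi[d] - origin[d]) / h)) + 1 for d in range(3))
    return origin, shape


def solve_pb(atoms, grid: GridSpec | None = None, source_charges=None
             ) -> PotentialMap:
    """Solve the Poisson equation for a collection of atoms.

    ``atoms`` supply both the dielectric cavity (via their positions and
    sigma-derived radii) and, unless ``source_charges`` overrides them, the
    source charge density.  ``source_charges`` may be a per-atom array with
    zeros for atoms that shape the cavity but carry no source charge.
    """
    grid = grid or GridSpec()
    atoms = list(atoms)
    coords = np.array([a.position for a in atoms])
    radii = np.array([atom_radius(a.sigma) for a in atoms])
    q = (np.array([a.charge for a in atoms])
         if source_charges is None else np.asarray(source_charges, dtype=float))
    if q.shape[0] != coords.shape[0]:
        raise ValueError("source_charges length mismatch")
    origin, shape = _grid_geometry(coords, radii, grid)
    u, sweeps = solve_cascadic(
        origin, grid.spacing, shape, coords, radii, q,
        grid.eps_in, grid.eps_out, grid.convergence_tol, grid.max_sweeps,
        grid.omega, grid.cascade_levels,
    )
    return PotentialMap(origin, grid.spacing, u, sweeps)


def lj_energy(pair: PairComplex) -> float:
    """Intermolecular Lennard-Jones energy, kcal/mol.

    OPLS functional form with geometric-mean combining rules for both
    sigma and epsilon; intramolecular terms are excluded by construction.
    """
    ca, cd = pair.acceptor.coords, pair.donor.coords
    sa, sd = pair.acceptor.sigmas, pair.donor.sigmas
    ea, ed = pair.acceptor.epsilons, pair.donor.epsilons
    d = np.linalg.norm(ca[:, None, :] - cd[None, :, :], axis=-1)
    if np.any(d == 0.0):
        raise ValueError("coincident intermolecular atoms")
    sig = np.sqrt(sa[:, None] * sd[None, :])
    eps = np.sqrt(ea[:, None] * ed[None, :])
    x6 = (sig / d) ** 6
    return float(np.sum(4.0 * eps * (x6 * x6 - x6)))


def elec_interaction(pair: PairComplex, grid: GridSpec | None = None) -> float:
    """Cross-interaction electrostatic energy of a posed pair, kcal/mol.

    Sum over donor atoms of q_i * phi_acc(r_i), where phi_acc is the PB
    potential of the acceptor's charges solved in the dielectric geometry
    of the full complex.  Symmetric under role swap up to solver tolerance.
    """
    grid = grid or GridSpec()
    atoms = pair.atoms
    n_acc = len(pair.acceptor.atoms)
    q_all = np.array([a.charge for a in atoms])
    src = q_all.copy()
    src[n_acc:] = 0.0
    phi = solve_pb(atoms, grid, source_charges=src)
    donor_pts = pair.donor.coords
    donor_q = pair.donor.charges
    return float(np.dot(donor_q, phi.at(donor_pts)))


def total_grid_energy(atoms, grid: GridSpec | None = None) -> float:
    """Total electrostatic grid energy 0.5 * sum_i q_i phi(r_i), kcal/mol.

    Contains the (large, discretization-dependent) self-energy of the
    spread charges; only differences between solves of the same atoms on
    lattice-aligned grids are physically meaningful.
    """
    grid = grid or GridSpec()
    atoms = list(atoms)
    phi = solve_pb(atoms, grid)
    pts = np.array([a.position for a in atoms])
    q = np.array([a.charge for a in atoms])
    return 0.5 * float(np.dot(q, phi.at(pts)))


def _fragment_energy_cached(frag, grid: GridSpec, cache: dict | None) -> float:
    """Grid energy of an isolated fragment; cached by the fragment kind and
    the sub-grid fractional offsets of its atoms (a rigid translation by a
    lattice vector does not change the discretized energy)."""
    if cache is None:
        return total_grid_energy(frag.atoms, grid)
    frac = np.round((frag.coords / grid.spacing) % 1.0, 6) % 1.0
    key = (frag.kind, grid.spacing, frac.tobytes())
    if key not in cache:
        cache[key] = total_grid_energy(frag.atoms, grid)
    return cache[key]


def elec_interaction_total(pair: PairComplex, grid: GridSpec | None = None,
                           monomer_cache: dict | None = None) -> float:
    """Electrostatic interaction energy including desolvation, kcal/mol.

    Total grid energy of the complex minus the grid energies of the two
    isolated fragments, each solved with the identical discretization on a
    lattice-aligned grid so that self-energies cancel exactly.  Unlike the
    cross term of :func:`elec_interaction`, this contains the positive
    desolvation contribution from each fragment losing part of its reaction
    field as the partner cavity displaces solvent.
    """
    grid = grid or GridSpec()
    g_complex = total_grid_energy(pair.atoms, grid)
    g_acc = _fragment_energy_cached(pair.acceptor, grid, monomer_cache)
    g_don = _fragment_energy_cached(pair.donor, grid, monomer_cache)
    return g_complex - g_acc - g_don


def pair_energy(pair: PairComplex, grid: GridSpec | None = None,
                elec_model: str = "total",
                monomer_cache: dict | None = None) -> EnergyBreakdown:
    """Interaction energy of a posed pair (PB electrostatics + LJ).

    ``elec_model`` selects the electrostatic decomposition: ``"total"``
    (complex minus monomers; includes desolvation and is the quantity the
    distance scans report) or ``"cross"`` (charges of one fragment in the
    potential of the other; no desolvation).
    """
    if elec_model == "total":
        elec = elec_interaction_total(pair, grid, monomer_cache)
    elif elec_model == "cross":
        elec = elec_interaction(pair, grid)
    else:
        raise ValueError(f"unknown elec_model {elec_model!r}")
    return EnergyBreakdown(elec=elec, lj=lj_energy(pair))


def born_solvation_energy(q: float, R: float, grid: GridSpec | None = None
                          ) -> float:
    """FD-PB solvation energy of a Born ion (charge ``q`` centered in a
    sphere of radius ``R``), kcal/mol.

    Computed as 0.5 * q * (phi_solvated - phi_uniform) at the ion center,
    where the uniform reference is solved on the identical grid with the
    interior dielectric everywhere; the grid self-energy cancels in the
    difference.  The closed form is -KE/2 * q^2 (1/eps_in - 1/eps_out) / R.
    """
    grid = grid or GridSpec()
    center = np.zeros((1, 3))
    radii = np.array([R])
    charges = np.array([float(q)])
    origin, shape = _grid_geometry(center, radii, grid)
    args = (origin, grid.spacing, shape, center, radii, charges)
    u1, _ = solve_cascadic(*args, grid.eps_in, grid.eps_out,
                           grid.convergence_tol, grid.max_sweeps,
                           grid.omega, grid.cascade_levels)
    u0, _ = solve_cascadic(*args, grid.eps_in, grid.eps_in,
                           grid.convergence_tol, grid.max_sweeps,
                           grid.omega, grid.cascade_levels)
    m1 = PotentialMap(origin, grid.spacing, u1)
    m0 = PotentialMap(origin, grid.spacing, u0)
    rxn = float(m1.at(center)[0] - m0.at(center)[0])
    return 0.5 * q * rxn


def born_closed_form(q: float, R: float, eps_in: float = 1.0,
                     eps_out: float = 80.0) -> float:
    """Analytic Born solvation energy, kcal/mol."""
    return -0.5 * KE * q * q * (1.0 / eps_in - 1.0 / eps_out) / R
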