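"""Excluded-volume models: simple, Fraser (Gaussian dummy atoms), grid.

All three models describe the solvent volume displaced by the solute as a
set of dummy scatterers whose amplitude is *subtracted* from the atomic
amplitude, yielding excess (contrast) scattering. Each model conserves
electrons: its total dummy weight equals ``rho0`` times its own volume
definition.

* simple -- the grid-estimated molecular volume is spread evenly over the
  atoms: every atom gets a co-located dummy of weight rho0 V / N with one
  common Gaussian form factor. No free excluded-volume parameter.
* fraser -- per-atom Gaussian dummies sized by a per-species volume table;
  a single fitted scale gamma adjusts all volumes simultaneously through
  the common-mean-radius multiplier (volume within +/-25% by default).
* grid -- atoms are re-expanded to a space-filling minimum radius
  (default sqrt(3) x cell width) and one dummy of cell-sized Gaussian
  volume is placed in every marked cell. Dummies within one (6-connected)
  cell of unmarked space form the *exterior* layer; a fitted scale applied
  to the exterior only emulates growing/shrinking the surface by up to
  1 A without rebuilding the histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .formfactors import (VolumeTable, gaussian_radius, load_volume_table,
                          lookup_volume, volume_scale_factor)
from .grid import OccupancyGrid
from .structures import Structure

__all__ = ["ExcludedVolumeModel", "simple_model", "fraser_model",
           "grid_model", "surface_scaling_bounds", "RHO_BULK",
           "DEFAULT_SIMPLE_RADIUS", "FRASER_VOLUME_TOLERANCE"]

RHO_BULK = 0.334  # bulk water electron density [e / A^3]
DEFAULT_SIMPLE_RADIUS = 1.62  # common Gaussian radius of the simple model [A]
FRASER_VOLUME_TOLERANCE = 0.25  # +/- fraction of volume spanned by gamma
DEFAULT_MIN_RADIUS_FACTOR = math.sqrt(3.0)  # grid re-expansion, x cell width


@dataclass
class ExvClass:
    """One excluded-volume form-factor class within a model."""

    id: str
    r_x: float  # Gaussian radius [A]
    scalable: bool  # does the model's fitted scale act on this class?


@dataclass
class ExcludedVolumeModel:
    """Dummy-scatterer description of the displaced solvent.

    ``class_index[i]`` points into ``classes`` for dummy i. ``volume`` is
    the model's own volume definition (grid volume or summed table
    volumes); total weight equals ``rho0 * volume``.
    """

    mode: str  # "simple" | "fraser" | "grid"
    positions: np.ndarray
    weights: np.ndarray
    class_index: np.ndarray
    classes: List[ExvClass]
    rho0: float
    volume: float
    r_mean: float  # radius entering the common scale-factor multiplier [A]
    gamma_bounds: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float)
        self.class_index = np.asarray(self.class_index, dtype=int)

    @property
    def total_displaced_electrons(self) -> float:
        return float(self.weights.sum())

    @property
    def n_free_scale(self) -> int:
        """1 if this model fits an excluded-volume scale, else 0."""
        return 1 if self.gamma_bounds is not None else 0

    def register_form_factors(self, registry):
        for cls in self.classes:
            registry.register_exv(cls.id, cls.r_x)

    def amplitude_multiplier(self, class_id: str, q, gamma: float = 1.0):
        """q-dependent multiplier for one class at scale ``gamma``.

        Non-scalable classes (interior grid dummies, the simple model)
        always return 1.
        """
        cls = next(c for c in self.classes if c.id == class_id)
        q = np.asarray(q, dtype=float)
        if gamma == 1.0 or not cls.scalable:
            return np.ones_like(q)
        return volume_scale_factor(q, gamma, self.r_mean)


def simple_model(structure: Structure, grid: OccupancyGrid,
                 rho0: float = RHO_BULK,
                 r_bar: float = DEFAULT_SIMPLE_RADIUS) -> ExcludedVolumeModel:
    """Evenly distributed excluded volume on the atomic positions.

    The average displaced electron count rho0 V_grid / N is carried by a
    dummy at every atom position, all sharing one Gaussian form factor of
    radius ``r_bar``. Equivalent to subtracting that average from each
    atom's scattering weight; there is no fitted excluded-volume scale.
    """
    structure.require_atoms()
    volume = grid.estimate_volume()
    n = len(structure)
    n_bar = rho0 * volume / n
    return ExcludedVolumeModel(
        mode="simple",
        positions=structure.positions,
        weights=np.full(n, n_bar),
        class_index=np.zeros(n, dtype=int),
        classes=[ExvClass("exv:simple", r_bar, scalable=False)],
        rho0=rho0, volume=volume, r_mean=r_bar, gamma_bounds=None)


def fraser_model(structure: Structure,
                 table: Optional[VolumeTable] = None,
                 rho0: float = RHO_BULK,
                 volume_tolerance: float = FRASER_VOLUME_TOLERANCE
                 ) -> ExcludedVolumeModel:
    """Per-species Gaussian dummy atoms co-located with the atoms.

    Each atom displaces its tabulated species volume V_s, i.e. carries a
    dummy of weight rho0 V_s and Gaussian radius (V_s / pi^(3/2))^(1/3).
    The fitted scale gamma spans volumes within ``volume_tolerance``
    (gamma^3 in [1 - tol, 1 + tol]) through the common mean-radius
    multiplier.
    """
    structure.require_atoms()
    if table is None:
        mode = "explicit" if structure.has_explicit_hydrogens else "implicit"
        table = load_volume_table("minimum_fluctuation", mode)
    classes: List[ExvClass] = []
    class_of: Dict[str, int] = {}
    idx = np.zeros(len(structure), dtype=int)
    weights = np.zeros(len(structure))
    for i, atom in enumerate(structure):
        species = atom.ff_class
        v = lookup_volume(species, table)
        if species not in class_of:
            class_of[species] = len(classes)
            classes.append(ExvClass(f"exv:{table.table_id}:{species}",
                                    gaussian_radius(v), scalable=True))
        idx[i] = class_of[species]
        weights[i] = rho0 * v
    r_mean = float(np.mean([classes[j].r_x for j in idx]))
    g_lo = (1.0 - volume_tolerance) ** (1.0 / 3.0)
    g_hi = (1.0 + volume_tolerance) ** (1.0 / 3.0)
    return ExcludedVolumeModel(
        mode="fraser",
        positions=structure.positions,
        weights=weights,
        class_index=idx,
        classes=classes,
        rho0=rho0, volume=float(weights.sum() / rho0), r_mean=r_mean,
        gamma_bounds=(g_lo, g_hi))


def _exterior_mask(mask: np.ndarray) -> np.ndarray:
    """Marked cells with an unmarked 6-neighbor (grid boundary counts)."""
    ext = np.zeros_like(mask)
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(padded, shift, axis=axis)
            sl = tuple(slice(1, -1) for _ in range(3))
            ext |= mask & ~rolled[sl]
    return ext


def grid_model(grid: OccupancyGrid, structure: Structure,
               rho0: float = RHO_BULK,
               min_radius: Optional[float] = None,
               fit_surface: bool = True) -> ExcludedVolumeModel:
    """Space-filling excluded volume: one Gaussian dummy per marked cell.

    Atoms are re-expanded with radius max(vdW, min_radius) -- default
    sqrt(3) x cell width, one cell diagonal, so the marking closes small
    internal cavities. Every marked cell receives a dummy at its center
    with weight rho0 w^3 and a Gaussian sphere of the cell volume.
    Exterior dummies (6-connected to unmarked space) are scalable when
    ``fit_surface`` is on; interior dummies never are.
    """
    structure.require_atoms()
    w = grid.cell_width
    if min_radius is None:
        min_radius = DEFAULT_MIN_RADIUS_FACTOR * w
    radii = np.maximum(structure.vdw_radii, min_radius)
    mask = grid.expansion_mask(radii)
    ext = _exterior_mask(mask)
    idx_cells = np.argwhere(mask)
    centers = grid.origin + (idx_cells + 0.5) * w
    is_ext = ext[tuple(idx_cells.T)]
    r_cell = gaussian_radius(w ** 3)
    classes = [ExvClass("exv:grid:interior", r_cell, scalable=False),
               ExvClass("exv:grid:exterior", r_cell, scalable=fit_surface)]
    n_cells = len(idx_cells)
    volume = n_cells * w ** 3
    bounds = surface_scaling_bounds(w) if fit_surface else None
    return ExcludedVolumeModel(
        mode="grid",
        positions=centers,
        weights=np.full(n_cells, rho0 * w ** 3),
        class_index=is_ext.astype(int),
        classes=classes,
        rho0=rho0, volume=volume, r_mean=r_cell,
        gamma_bounds=bounds)


def surface_scaling_bounds(cell_width: float,
                           shell_delta: float = 1.0) -> Tuple[float, float]:
    """gamma bounds for the grid model's exterior-layer scaling.

    The exterior layer is one cell thick, so scaling its volume by
    gamma^3 in [1 - delta/w, 1 + delta/w] grows or shrinks the effective
    surface layer by ``shell_delta`` (default 1 A). The lower bound is
    floored at a small positive volume.
    """
    lo3 = max(1.0 - shell_delta / cell_width, 0.05)
    hi3 = 1.0 + shell_delta / cell_width
    return (lo3 ** (1.0 / 3.0), hi3 ** (1.0 / 3.0))
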