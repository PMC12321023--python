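"""Explicit dummy-water hydration shell by radial-line placement.

From every atom center, a fixed set of radial directions is cast and a
water candidate proposed at ``r_a + r_w + offset_delta + N(0, sigma)``
along each line. The negative ``offset_delta`` pulls the shell slightly
closer than the sum of vdW radii (the first hydration peak sits closer to
the surface than hard-sphere contact), and the Gaussian jitter broadens
the otherwise sharp shell. Each candidate is then scored by re-casting the
direction set from the candidate itself, marking every line at fixed
fractions of the water radius and checking the corresponding occupancy
cells: the weighted fraction of clear marks must reach the acceptance
threshold. This crowding score suppresses the excess density that the
concave geometry of pockets and cavities would otherwise produce.

Accepted waters immediately mark their volume on the grid so later
candidates see them; the waters themselves live at continuous coordinates,
the grid is used only for collision detection. The solvent density
produced this way is empirical, so the water amplitudes carry a free
scaling parameter ``c`` during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial import cKDTree

from .grid import OccupancyGrid
from .structures import Structure

__all__ = ["HydrationParams", "WaterSet", "generate_directions",
           "place_waters", "surface_distance_distribution"]

WATER_ELECTRONS = 10.0
WATER_FF_CLASS = "H2O"


@dataclass
class HydrationParams:
    """Tunable parameters of the placement algorithm (lengths in A)."""

    n_directions: int = 26
    offset_delta: float = -0.5
    jitter_sigma: float = 0.5
    water_radius: float = 1.4
    acceptance_threshold: float = 0.7
    rng_seed: int = 0
    # probe marks along each re-cast line, as fractions of water_radius,
    # with outward-decreasing weights (nearest mark sits inside the
    # would-be water volume)
    probe_fractions: tuple = (0.5, 1.0, 1.5)
    probe_weights: tuple = (3.0, 2.0, 1.0)

    def __post_init__(self):
        if self.n_directions < 6:
            raise ValueError("n_directions must be >= 6")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.water_radius <= 0:
            raise ValueError("water_radius must be > 0")


@dataclass
class WaterSet:
    """Dummy hydration waters: positions plus common weight and form factor."""

    positions: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3)))
    weight_per_water: float = WATER_ELECTRONS
    ff_class: str = WATER_FF_CLASS

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.positions)


def generate_directions(n: int = 26) -> np.ndarray:
    """Unit direction vectors of the cubic neighborhood.

    n = 6: face neighbors; n = 14: faces + corners; n = 26: the full set of
    normalized nonzero offsets of the 3x3x3 neighborhood (45 degrees
    between neighboring lines). The set is closed under negation. Order is
    fixed (lexicographic in the integer offsets) for determinism.
    """
    if n not in (6, 14, 26):
        raise ValueError("n_directions must be one of 6, 14, 26")
    offsets = []
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                if i == j == k == 0:
                    continue
                nz = abs(i) + abs(j) + abs(k)
                if n == 6 and nz != 1:
                    continue
                if n == 14 and nz == 2:
                    continue
                offsets.append((i, j, k))
    dirs = np.array(offsets, dtype=float)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def place_waters(grid: OccupancyGrid, structure: Structure,
                 params: Optional[HydrationParams] = None) -> WaterSet:
    """Generate the dummy-water hydration shell on an expanded grid.

    Deterministic for a fixed ``params.rng_seed``: atoms are processed in
    order, directions in fixed lexicographic order, and the jitter stream
    is consumed once per candidate regardless of the outcome.
    """
    params = params or HydrationParams()
    structure.require_atoms()
    rng = np.random.default_rng(params.rng_seed)
    dirs = generate_directions(params.n_directions)
    r_w = params.water_radius
    probe_d = np.array(params.probe_fractions) * r_w
    probe_w = np.array(params.probe_weights, dtype=float)
    weight_total = probe_w.sum() * len(dirs)
    # probe offsets: (n_dirs * n_marks, 3)
    probes = (dirs[:, None, :] * probe_d[None, :, None]).reshape(-1, 3)
    probe_weights = np.tile(probe_w, len(dirs))

    positions = structure.positions
    radii = structure.vdw_radii
    atom_tree = cKDTree(positions)
    max_r = float(radii.max())

    cell_diag = np.sqrt(3.0) * grid.cell_width
    min_ww = max(2.0 * r_w - cell_diag, 0.0)

    accepted: List[np.ndarray] = []
    acc_arr = np.zeros((0, 3))
    for i in range(len(positions)):
        for d in dirs:
            dist = radii[i] + r_w + params.offset_delta \
                + rng.normal(0.0, params.jitter_sigma)
            cand = positions[i] + dist * d
            # hard constraint: outside every atom's vdW sphere
            near = atom_tree.query_ball_point(cand, max_r)
            if any(np.linalg.norm(cand - positions[j]) < radii[j] for j in near):
                continue
            # hard constraint: water-water separation
            if len(acc_arr) and \
                    np.min(np.linalg.norm(acc_arr - cand, axis=1)) < min_ww:
                continue
            if grid.is_occupied(grid.index_of(cand)):
                continue
            # crowding score: weighted fraction of clear probe marks
            clear = ~grid.occupied_at_points(cand + probes)
            score = float(probe_weights[clear].sum()) / weight_total
            if score >= params.acceptance_threshold:
                accepted.append(cand)
                acc_arr = np.asarray(accepted)
                grid.mark_water(cand, r_w)
    return WaterSet(positions=np.asarray(accepted).reshape(-1, 3))


def surface_distance_distribution(waters: WaterSet, structure: Structure,
                                  bin_width: float = 0.1):
    """Histogram of water distances to the nearest atom *surface*.

    The distance of each water is its center distance to the closest atom
    minus that atom's vdW radius. Returns (bin_edges, counts); an empty
    water set yields empty arrays.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(waters) == 0:
        return np.zeros(1), np.zeros(0, dtype=int)
    pos = structure.positions
    radii = structure.vdw_radii
    d = np.linalg.norm(waters.positions[:, None, :] - pos[None, :, :], axis=2)
    surface = (d - radii[None, :]).min(axis=1)
    lo = min(0.0, surface.min())
    n_bins = int(np.ceil((surface.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(surface, bins=edges)
    return edges, counts
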