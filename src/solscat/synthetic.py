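"""Synthetic inputs: toy structures and noisy model-generated datasets.

These generators make every part of the pipeline testable offline: compact
pseudo-protein clusters with bond-like nearest-neighbor spacing stand in
for real structures, and datasets drawn from the forward model itself (with
known scale, background, hydration scale and multiplicative-plus-floor
Gaussian noise) support parameter-recovery and goodness-of-fit checks.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .config import RunConfig
from .fitting import SaxsDataset
from .pipeline import ProfileCalculator
from .structures import Atom, Structure

__all__ = ["make_toy_structure", "make_cubic_lattice_structure",
           "make_shell_structure", "make_synthetic_dataset"]

_TOY_ELEMENTS = ("C", "C", "C", "N", "O")  # rough organic composition
# covalent bond lengths [A] (C=O, C-N amide, aromatic C-C, C-N single,
# C-O, C-C single, and a long C-S-like bond), with a small
# vibration-scale spread; keeps the sharply peaked nearest-neighbor
# distance distribution of real molecules
_BOND_LENGTHS = (1.23, 1.33, 1.39, 1.45, 1.52, 1.54, 1.78)
_BOND_SIGMA = 0.01
_MIN_SEPARATION = 1.2  # [A]; keeps every nearest-neighbor distance bond-like


def make_toy_structure(n_atoms: int, seed: int = 0) -> Structure:
    """Compact random cluster of C/N/O pseudo-atoms.

    Atoms attach at bond-like distances (sharply peaked around covalent
    bond lengths, all within 1.2-1.8 A) to a random existing atom, biased
    toward the cluster center so the result is globular; no two atoms come
    closer than 1 A. Deterministic for a fixed seed.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    positions = [np.zeros(3)]
    elements = ["C"]
    parent_of = {0: None}
    # near-tetrahedral bond angles give the sharp second-neighbor distance
    # peaks of real molecules; a radial cap keeps the cluster globular
    max_radius = 1.45 * 1.2 * n_atoms ** (1.0 / 3.0) + 2.0
    while len(positions) < n_atoms:
        i = int(rng.integers(len(positions)))
        p = positions[i]
        if parent_of[i] is None:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
        else:
            bond = p - positions[parent_of[i]]
            bond /= np.linalg.norm(bond)
            angle = np.deg2rad(rng.normal(109.5, 5.0))
            t = rng.normal(size=3)
            t -= (t @ bond) * bond
            t /= np.linalg.norm(t)
            direction = np.cos(angle) * bond + np.sin(angle) * t
        dist = (_BOND_LENGTHS[rng.integers(len(_BOND_LENGTHS))]
                + rng.normal(0.0, _BOND_SIGMA))
        cand = p + dist * direction
        if np.linalg.norm(cand) > max_radius:
            continue
        arr = np.asarray(positions)
        if np.min(np.linalg.norm(arr - cand, axis=1)) < _MIN_SEPARATION:
            continue
        parent_of[len(positions)] = i
        positions.append(cand)
        elements.append(_TOY_ELEMENTS[rng.integers(len(_TOY_ELEMENTS))])
    atoms = [Atom(position=p, element=e, residue_name="TOY",
                  atom_name=f"{e}{i + 1}")
             for i, (p, e) in enumerate(zip(positions, elements))]
    return Structure(atoms=atoms)


def make_cubic_lattice_structure(n_side: int, spacing: float = 1.5,
                                 element: str = "C") -> Structure:
    """Highly ordered cubic-lattice cluster (crystal-like binning fixture)."""
    atoms = []
    for i in range(n_side):
        for j in range(n_side):
            for k in range(n_side):
                atoms.append(Atom(
                    position=np.array([i, j, k], dtype=float) * spacing,
                    element=element, residue_name="LAT",
                    atom_name=f"{element}{len(atoms) + 1}"))
    return Structure(atoms=atoms)


def make_shell_structure(radius: float = 6.0, spacing: float = 2.0,
                         element: str = "C") -> Structure:
    """Hollow spherical shell of atoms (concave-cavity hydration fixture).

    Atoms are placed on a Fibonacci lattice over the sphere with
    approximately the requested spacing.
    """
    n = max(8, int(4.0 * np.pi * radius ** 2 / spacing ** 2))
    i = np.arange(n)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    pos = radius * np.stack([np.sin(phi) * np.cos(theta),
                             np.sin(phi) * np.sin(theta),
                             np.cos(phi)], axis=1)
    atoms = [Atom(position=p, element=element, residue_name="SHL",
                  atom_name=f"{element}{j + 1}") for j, p in enumerate(pos)]
    return Structure(atoms=atoms)


def make_synthetic_dataset(structure: Structure,
                           params: Optional[Dict[str, float]] = None,
                           noise_rel: float = 0.02,
                           noise_floor: float = 0.0,
                           seed: int = 0,
                           config: Optional[RunConfig] = None,
                           calculator: Optional[ProfileCalculator] = None
                           ) -> SaxsDataset:
    """Dataset drawn from the forward model with known ground truth.

    The model curve a*I(q; c, gamma) + b is computed on the internal q
    grid, Gaussian noise with sigma(q) = noise_rel*|I| + noise_floor is
    added, and the sigma column reports that true noise scale. With zero
    noise the intensities equal the model curve exactly (the reported
    sigma then falls back to a uniform weighting scale).
    """
    params = {"a": 1.0, "b": 0.0, "c": 1.0, "gamma": 1.0, **(params or {})}
    if calculator is None:
        calculator = ProfileCalculator(structure, config or RunConfig())
    curve = params["a"] * calculator.intensity(
        c=params["c"], gamma=params["gamma"]) + params["b"]
    sigma = noise_rel * np.abs(curve) + noise_floor
    rng = np.random.default_rng(seed)
    noisy = curve + rng.normal(size=len(curve)) * sigma
    reported = sigma.copy()
    if np.any(reported <= 0):
        fallback = max(1e-6 * float(np.max(np.abs(curve))), 1e-30)
        reported[reported <= 0] = fallback
    return SaxsDataset(calculator.q.copy(), noisy, reported)
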