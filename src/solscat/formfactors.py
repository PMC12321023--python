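"""Atomic, unified-group and excluded-volume form factors.

All form factors are *normalized*: ``f(0) = 1``. The electron count of a
scatterer is carried separately as its weight, so the Debye sum uses
``w_i w_j f_i(q) f_j(q)``.

Vacuum atomic factors use the International Tables 4-Gaussian X-ray
parameterization (exported from :mod:`gemmi` at import time),

    f_raw(q) = c + sum_k a_k exp(-b_k (q / 4 pi)^2),

with the convention q = 4 pi sin(theta) / lambda. Unified atomic groups
(CH, CH2, NH3, the water molecule, ...) are modeled as the heavy atom plus
its n covalently bound hydrogens co-centered, i.e. the coefficient sum of
the constituents, renormalized at q = 0.

The excluded volume of an atom is a Gaussian sphere of density
exp(-r^2 / r_x^2) with integral V_x = pi^(3/2) r_x^3, whose normalized form
factor is exp(-q^2 r_x^2 / 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Tuple

import gemmi
import numpy as np

__all__ = [
    "FormFactorClass",
    "FormFactorRegistry",
    "default_registry",
    "normalized_ff",
    "exv_ff",
    "gaussian_volume",
    "gaussian_radius",
    "volume_scale_factor",
    "VolumeTable",
    "lookup_volume",
    "load_volume_table",
]

FOUR_PI = 4.0 * math.pi

# Elements covered by the built-in registry; anything else is created on
# demand from gemmi's tables.
_COMMON_ELEMENTS = (
    "H", "C", "N", "O", "F", "P", "S", "CL", "SE", "BR", "I",
    "NA", "MG", "K", "CA", "MN", "FE", "CU", "ZN",
)


def _it92_coefs(element: str) -> Tuple[Tuple[float, ...], Tuple[float, ...], float]:
    el = gemmi.Element(element.capitalize())
    if el.atomic_number == 0:
        raise KeyError(f"unknown element {element!r}")
    it = el.it92
    if it is None:
        raise KeyError(f"no form-factor coefficients for element {element!r}")
    return tuple(it.a), tuple(it.b), float(it.c)


@dataclass(frozen=True)
class FormFactorClass:
    """A normalized scattering form factor.

    ``kind`` is one of ``vacuum_atom``, ``unified_group``, ``water_group``
    or ``exv_gaussian``. Gaussian-sum kinds carry (a, b, c) coefficients;
    ``exv_gaussian`` carries the Gaussian excluded-volume radius ``r_x`` [A].
    """

    id: str
    kind: str
    a: Tuple[float, ...] = ()
    b: Tuple[float, ...] = ()
    c: float = 0.0
    r_x: float = 0.0
    _norm: float = field(default=0.0, repr=False)

    def __post_init__(self):
        if self.kind == "exv_gaussian":
            if self.r_x <= 0:
                raise ValueError("exv_gaussian class requires r_x > 0")
        else:
            object.__setattr__(self, "_norm", float(sum(self.a) + self.c))
            if self._norm <= 0:
                raise ValueError(f"non-positive q=0 value for class {self.id!r}")

    def __call__(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if np.any(q < 0):
            raise ValueError("q must be non-negative")
        if self.kind == "exv_gaussian":
            return np.exp(-(q ** 2) * self.r_x ** 2 / 4.0)
        stol2 = (q / FOUR_PI) ** 2
        val = np.full_like(stol2, self.c, dtype=float)
        for a_k, b_k in zip(self.a, self.b):
            val += a_k * np.exp(-b_k * stol2)
        return val / self._norm


class FormFactorRegistry:
    """Maps class ids to :class:`FormFactorClass` instances.

    Ids are element symbols ("C"), hydrogenated groups ("CH2", "NH3"),
    the water group "H2O", or excluded-volume classes registered by the
    excluded-volume models ("exv:...").
    """

    def __init__(self):
        self._classes: Dict[str, FormFactorClass] = {}
        for el in _COMMON_ELEMENTS:
            a, b, c = _it92_coefs(el)
            self._classes[el] = FormFactorClass(el, "vacuum_atom", a, b, c)
        for heavy in ("C", "N", "O", "S"):
            for n_h in (1, 2, 3):
                self._register_group(heavy, n_h)
        ha, hb, hc = _it92_coefs("H")
        oa, ob, oc = _it92_coefs("O")
        self._classes["H2O"] = FormFactorClass(
            "H2O", "water_group", oa + ha + ha, ob + hb + hb, oc + 2 * hc
        )

    def _register_group(self, heavy: str, n_h: int) -> FormFactorClass:
        gid = group_id(heavy, n_h)
        a, b, c = _it92_coefs(heavy)
        ha, hb, hc = _it92_coefs("H")
        cls = FormFactorClass(
            gid, "unified_group", a + ha * n_h, b + hb * n_h, c + n_h * hc
        )
        self._classes[gid] = cls
        return cls

    def get(self, class_id: str) -> FormFactorClass:
        try:
            return self._classes[class_id]
        except KeyError:
            pass
        # build unknown element / group classes lazily
        if class_id.startswith("exv"):
            raise KeyError(f"excluded-volume class {class_id!r} not registered")
        heavy, n_h = _parse_group_id(class_id)
        if n_h == 0:
            a, b, c = _it92_coefs(heavy)
            cls = FormFactorClass(heavy, "vacuum_atom", a, b, c)
            self._classes[heavy] = cls
            return cls
        return self._register_group(heavy, n_h)

    def register_exv(self, class_id: str, r_x: float) -> FormFactorClass:
        cls = FormFactorClass(class_id, "exv_gaussian", r_x=float(r_x))
        self._classes[class_id] = cls
        return cls

    def __contains__(self, class_id: str) -> bool:
        return class_id in self._classes

    def ids(self):
        return list(self._classes)


def group_id(element: str, n_h: int) -> str:
    """Class id for an element with ``n_h`` implicit hydrogens."""
    el = element.upper()
    if n_h == 0:
        return el
    if el == "O" and n_h == 2:
        return "H2O"
    return f"{el}H" if n_h == 1 else f"{el}H{n_h}"


def _parse_group_id(class_id: str) -> Tuple[str, int]:
    if class_id == "H2O":
        return "O", 2
    if "H" in class_id[1:]:
        pos = class_id.rindex("H")
        heavy = class_id[:pos]
        rest = class_id[pos + 1:]
        if heavy and (rest == "" or rest.isdigit()):
            return heavy, int(rest) if rest else 1
    return class_id, 0


default_registry = FormFactorRegistry()


def normalized_ff(cls, q, registry: Optional[FormFactorRegistry] = None) -> np.ndarray:
    """Evaluate a normalized form factor at scattering vector q [1/A].

    ``cls`` may be a class id or a :class:`FormFactorClass`.
    """
    if isinstance(cls, str):
        cls = (registry or default_registry).get(cls)
    return cls(q)


def exv_ff(q, r_x: float) -> np.ndarray:
    """Normalized Gaussian-sphere excluded-volume form factor.

    exp(-q^2 r_x^2 / 4) in the q = 4 pi sin(theta)/lambda convention.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    if r_x <= 0:
        raise ValueError("r_x must be positive")
    return np.exp(-(q ** 2) * r_x ** 2 / 4.0)


def gaussian_volume(r_x: float) -> float:
    """Volume [A^3] of the Gaussian sphere with radius parameter r_x: pi^(3/2) r_x^3."""
    if r_x <= 0:
        raise ValueError("radius must be positive")
    return math.pi ** 1.5 * r_x ** 3


def gaussian_radius(volume: float) -> float:
    """Inverse of :func:`gaussian_volume`."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (volume / math.pi ** 1.5) ** (1.0 / 3.0)


def volume_scale_factor(q, gamma: float, r_m: float) -> np.ndarray:
    """Common excluded-volume scaling multiplier.

    gamma^3 exp(-q^2 r_m^2 (gamma^2 - 1) / 4), where gamma scales every
    excluded-volume radius and r_m is the structure's mean Gaussian radius.
    The per-species radius dependence is removed by the shared r_m, so the
    same multiplier applies to all excluded-volume amplitudes.
    """
    if gamma <= 0 or r_m <= 0:
        raise ValueError("gamma and r_m must be positive")
    q = np.asarray(q, dtype=float)
    return gamma ** 3 * np.exp(-(q ** 2) * r_m ** 2 * (gamma ** 2 - 1.0) / 4.0)


# ---------------------------------------------------------------------------
# Excluded-volume tables

_TABLE_IDS = ("minimum_fluctuation", "voronoi", "vdw", "traube")


@dataclass(frozen=True)
class VolumeTable:
    """Per-species displaced solvent volumes [A^3] with uncertainties."""

    table_id: str
    hydrogen_mode: str  # "implicit" or "explicit"
    entries: Dict[str, Tuple[float, float]]

    def __post_init__(self):
        for sp, (v, u) in self.entries.items():
            if v <= 0:
                raise ValueError(f"non-positive volume for {sp!r}")
            if u < 0:
                raise ValueError(f"negative uncertainty for {sp!r}")


def _read_volume_tsv(name: str) -> Dict[str, Tuple[float, float]]:
    entries: Dict[str, Tuple[float, float]] = {}
    text = resources.files("solscat").joinpath("data", name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sp, vol, unc = line.split("\t")
        entries[sp] = (float(vol), float(unc))
    return entries


def _vdw_table(hydrogen_mode: str) -> Dict[str, Tuple[float, float]]:
    """Hard-sphere 4/3 pi r^3 volumes from the bundled vdW radii."""
    from .structures import vdw_radius  # local import to avoid a cycle

    entries: Dict[str, Tuple[float, float]] = {}
    elements = ("H", "C", "N", "O", "S", "P", "SE")
    for el in elements:
        r = vdw_radius(el)
        entries[el] = (4.0 / 3.0 * math.pi * r ** 3, 0.0)
    v_h = entries["H"][0]
    if hydrogen_mode == "implicit":
        for heavy in ("C", "N", "O", "S"):
            for n_h in (1, 2, 3):
                entries[group_id(heavy, n_h)] = (
                    entries[heavy][0] + n_h * v_h, 0.0)
    entries["H2O"] = (entries["O"][0] + 2 * v_h, 0.0)
    return entries


_volume_cache: Dict[Tuple[str, str], VolumeTable] = {}


def load_volume_table(table_id: str = "minimum_fluctuation",
                      hydrogen_mode: str = "implicit") -> VolumeTable:
    """Load a bundled excluded-volume table.

    ``table_id`` is one of minimum_fluctuation, voronoi, vdw, traube. The
    implicit/explicit hydrogen-mode variants are separate tables; callers
    normally pick the mode matching the structure's hydrogen treatment.
    """
    if table_id not in _TABLE_IDS:
        raise KeyError(f"unknown volume table {table_id!r}; choose from {_TABLE_IDS}")
    if hydrogen_mode not in ("implicit", "explicit"):
        raise ValueError("hydrogen_mode must be 'implicit' or 'explicit'")
    key = (table_id, hydrogen_mode)
    if key not in _volume_cache:
        if table_id == "vdw":
            entries = _vdw_table(hydrogen_mode)
        elif table_id == "traube":
            entries = _read_volume_tsv(f"volumes_traube_{hydrogen_mode}.tsv")
        else:
            entries = _read_volume_tsv(
                f"volumes_{table_id}_{hydrogen_mode}_synthetic.tsv")
        _volume_cache[key] = VolumeTable(table_id, hydrogen_mode, entries)
    return _volume_cache[key]


def lookup_volume(species: str, table: VolumeTable) -> float:
    """Displaced volume [A^3] of a form-factor species in ``table``."""
    try:
        return table.entries[species][0]
    except KeyError:
        raise KeyError(
            f"species {species!r} not present in volume table "
            f"{table.table_id!r} ({table.hydrogen_mode} hydrogens)"
        ) from None
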