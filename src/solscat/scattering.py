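"""Debye-equation evaluation with weighted distance binning.

The orientation-averaged intensity of a set of point scatterers is

    I(q) = sum_ij w_i w_j f_i(q) f_j(q) sinc(q r_ij),

evaluated here through per-form-factor-class-pair distance histograms so
that the exact product f_i f_j applies to every pair (no effective-atom
approximation). In *weighted* binning, each bin's representative distance
is the weight-averaged distance of its contents, which removes the large
high-q errors that plain bin centers produce for ordered (lattice-like)
structures; self-pairs (i = j) are carried exactly at distance zero.

sinc is evaluated through a precomputed cubic-spline lookup table
(absolute error < 1e-5 against direct evaluation), and the full
unbinned double sum :func:`exact_debye` is retained as the test oracle.

The total model amplitude is A = A_a - A_x + c A_w (atoms, excluded
volume, hydration), whose square decomposes into the six partials
I_aa, I_ax, I_aw, I_xx, I_xw, I_ww; cross partials are stored with their
sign and combinatorial factor 2 included, so the partials always sum to
the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import cdist

from .formfactors import FormFactorRegistry, default_registry

__all__ = [
    "DEFAULT_Q", "default_q_grid", "ScattererSet",
    "WeightedDistanceHistogram", "build_histogram", "cross_histogram",
    "debye_from_histogram", "exact_debye", "sinc", "sinc_lookup",
    "ScatteringProfile", "assemble_profile", "write_profile", "read_profile",
    "binning_error_report", "PARTIAL_NAMES",
]

PARTIAL_NAMES = ("aa", "ax", "aw", "xx", "xw", "ww")

DEFAULT_BIN_WIDTH = 0.1  # [A]


def default_q_grid(q_min: float = 0.001, q_max: float = 1.0,
                   n: int = 100) -> np.ndarray:
    """The internal q grid: n points linear on [q_min, q_max] [1/A]."""
    return np.linspace(q_min, q_max, n)


DEFAULT_Q = default_q_grid()


def sinc(x) -> np.ndarray:
    """sin(x)/x with sinc(0) = 1 (direct evaluation)."""
    return np.sinc(np.asarray(x, dtype=float) / math.pi)


class _SincTable:
    """Cubic-spline lookup for sinc, extended on demand."""

    def __init__(self, step: float = 0.05, x_max: float = 256.0):
        self.step = step
        self._build(x_max)

    def _build(self, x_max: float):
        self.x_max = x_max
        grid = np.arange(0.0, x_max + self.step, self.step)
        self._spline = CubicSpline(grid, sinc(grid))

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        hi = float(x.max(initial=0.0))
        if hi > self.x_max:
            self._build(hi * 1.5)
        return self._spline(x)


_sinc_table = _SincTable()


def sinc_lookup(x) -> np.ndarray:
    """Table-interpolated sinc (abs error < 1e-5 vs :func:`sinc`)."""
    return _sinc_table(x)


# ---------------------------------------------------------------------------
# Scatterer sets

@dataclass
class ScattererSet:
    """Weighted point scatterers tagged with form-factor classes.

    ``category`` is 'a' (atoms), 'w' (hydration waters) or 'x' (excluded
    volume dummies).
    """

    positions: np.ndarray
    weights: np.ndarray
    class_labels: List[str]
    class_index: np.ndarray
    category: str

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float)
        self.class_index = np.asarray(self.class_index, dtype=int)

    def __len__(self):
        return len(self.positions)

    @classmethod
    def from_structure(cls, structure) -> "ScattererSet":
        labels: List[str] = []
        index = np.zeros(len(structure), dtype=int)
        seen: Dict[str, int] = {}
        for i, a in enumerate(structure):
            lab = a.ff_class
            if lab not in seen:
                seen[lab] = len(labels)
                labels.append(lab)
            index[i] = seen[lab]
        return cls(structure.positions, structure.weights, labels, index, "a")

    @classmethod
    def from_waters(cls, waters) -> "ScattererSet":
        n = len(waters)
        return cls(waters.positions,
                   np.full(n, waters.weight_per_water),
                   [waters.ff_class], np.zeros(n, dtype=int), "w")

    @classmethod
    def from_excluded_volume(cls, model) -> "ScattererSet":
        return cls(model.positions, model.weights,
                   [c.id for c in model.classes], model.class_index, "x")

    def by_class(self):
        for ci, label in enumerate(self.class_labels):
            sel = self.class_index == ci
            if sel.any():
                yield label, self.positions[sel], self.weights[sel]


# ---------------------------------------------------------------------------
# Distance histograms

@dataclass
class _PairBins:
    """Compressed per-bin data for one class pair."""

    d_repr: np.ndarray  # representative distance per occupied bin [A]
    weight: np.ndarray  # summed pair weight per occupied bin [e^2]


@dataclass
class WeightedDistanceHistogram:
    """Per class-pair binned pair distances.

    ``pairs`` maps an unordered class-label pair (i <= j in first-seen
    order) to its bins. For a self histogram both orders of unlike pairs
    are counted (factor 2 folded in) and the exact self-terms sit at
    distance zero, so the total weight equals (sum w)^2. Cross-category
    histograms are single-counted; signs and factors are applied at
    assembly.
    """

    bin_width: float
    weighted: bool
    category: str
    pairs: Dict[Tuple[str, str], _PairBins] = field(default_factory=dict)

    @property
    def total_weight(self) -> float:
        return float(sum(p.weight.sum() for p in self.pairs.values()))


_BLOCK = 1024


def _accumulate(p1, w1, p2, w2, bin_width, n_bins, exclude_diagonal):
    """Blocked pair binning; returns (weight per bin, weight*distance per bin)."""
    sums = np.zeros(n_bins)
    sums_d = np.zeros(n_bins)
    inv = 1.0 / bin_width
    for i0 in range(0, len(p1), _BLOCK):
        block = slice(i0, min(i0 + _BLOCK, len(p1)))
        d = cdist(p1[block], p2)
        wmat = np.outer(w1[block], w2)
        if exclude_diagonal:
            rows = np.arange(block.start, block.stop)
            cols = rows  # identical sets
            wmat[rows - block.start, cols] = 0.0
        bins = np.minimum((d * inv).astype(np.int64), n_bins - 1).ravel()
        wflat = wmat.ravel()
        sums += np.bincount(bins, weights=wflat, minlength=n_bins)
        sums_d += np.bincount(bins, weights=wflat * d.ravel(),
                              minlength=n_bins)
    return sums, sums_d


def _compress(sums, sums_d, bin_width, weighted) -> _PairBins:
    occ = np.nonzero(sums)[0]
    w = sums[occ]
    if weighted:
        d = sums_d[occ] / w
    else:
        d = (occ + 0.5) * bin_width
    return _PairBins(d_repr=d, weight=w)


def _n_bins(p1, p2, bin_width) -> int:
    lo = np.minimum(p1.min(axis=0), p2.min(axis=0))
    hi = np.maximum(p1.max(axis=0), p2.max(axis=0))
    d_max = float(np.linalg.norm(hi - lo))
    return int(d_max / bin_width) + 2


def build_histogram(scatterers: ScattererSet,
                    bin_width: float = DEFAULT_BIN_WIDTH,
                    weighted: bool = True) -> WeightedDistanceHistogram:
    """Self distance histogram of one scatterer set.

    All N(N-1)/2 distinct pair distances enter per (class pair) with both
    orders counted; self-pairs contribute weight w^2 exactly at distance
    zero. Weighted mode stores per-bin weighted mean distances, unweighted
    mode stores bin centers.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(scatterers) == 0:
        raise ValueError("empty scatterer set")
    cat = scatterers.category
    hist = WeightedDistanceHistogram(bin_width, weighted, cat + cat)
    groups = list(scatterers.by_class())
    for a in range(len(groups)):
        la, pa, wa = groups[a]
        for b in range(a, len(groups)):
            lb, pb, wb = groups[b]
            n_bins = _n_bins(pa, pb, bin_width)
            if a == b:
                sums, sums_d = _accumulate(pa, wa, pa, wa, bin_width,
                                           n_bins, exclude_diagonal=True)
                bins = _compress(sums, sums_d, bin_width, weighted)
                # exact self terms at distance zero
                bins = _PairBins(
                    d_repr=np.concatenate(([0.0], bins.d_repr)),
                    weight=np.concatenate(([float((wa ** 2).sum())],
                                           bins.weight)))
            else:
                sums, sums_d = _accumulate(pa, wa, pb, wb, bin_width,
                                           n_bins, exclude_diagonal=False)
                bins = _compress(2.0 * sums, 2.0 * sums_d, bin_width, weighted)
            hist.pairs[(la, lb)] = bins
    return hist


def cross_histogram(set_a: ScattererSet, set_b: ScattererSet,
                    bin_width: float = DEFAULT_BIN_WIDTH,
                    weighted: bool = True) -> WeightedDistanceHistogram:
    """Single-counted cross histogram between two scatterer sets."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("empty scatterer set")
    hist = WeightedDistanceHistogram(bin_width, weighted,
                                     set_a.category + set_b.category)
    for la, pa, wa in set_a.by_class():
        for lb, pb, wb in set_b.by_class():
            n_bins = _n_bins(pa, pb, bin_width)
            sums, sums_d = _accumulate(pa, wa, pb, wb, bin_width, n_bins,
                                       exclude_diagonal=False)
            hist.pairs[(la, lb)] = _compress(sums, sums_d, bin_width, weighted)
    return hist


# ---------------------------------------------------------------------------
# Debye evaluation

class CategoryCurves:
    """Precomputed per-pair structure curves S_ij(q) = sum_b W_b sinc(q d_b).

    Separating S_ij from the form factors lets the fit rescale amplitudes
    (hydration scale, excluded-volume scale) without re-binning.
    """

    def __init__(self, hist: WeightedDistanceHistogram, q: np.ndarray,
                 registry: Optional[FormFactorRegistry] = None,
                 use_lookup: bool = True):
        self.q = np.asarray(q, dtype=float)
        self.category = hist.category
        reg = registry or default_registry
        kernel = sinc_lookup if use_lookup else sinc
        self._entries = []
        ff_cache: Dict[str, np.ndarray] = {}
        for (la, lb), bins in hist.pairs.items():
            for lab in (la, lb):
                if lab not in ff_cache:
                    ff_cache[lab] = reg.get(lab)(self.q)
            s = kernel(np.outer(self.q, bins.d_repr)) @ bins.weight
            self._entries.append((la, lb, s))
        self._ff = ff_cache

    def intensity(self, multipliers: Optional[Dict[str, np.ndarray]] = None
                  ) -> np.ndarray:
        """sum over class pairs of f_i m_i f_j m_j S_ij."""
        out = np.zeros_like(self.q)
        for la, lb, s in self._entries:
            amp_a = self._ff[la]
            amp_b = self._ff[lb]
            if multipliers:
                if la in multipliers:
                    amp_a = amp_a * multipliers[la]
                if lb in multipliers:
                    amp_b = amp_b * multipliers[lb]
            out += amp_a * amp_b * s
        return out


def debye_from_histogram(hist: WeightedDistanceHistogram, q,
                         registry: Optional[FormFactorRegistry] = None,
                         multipliers: Optional[Dict[str, np.ndarray]] = None,
                         use_lookup: bool = True) -> np.ndarray:
    """Intensity contribution of one histogram on a q grid [1/A]."""
    return CategoryCurves(hist, np.asarray(q, dtype=float), registry,
                          use_lookup).intensity(multipliers)


def exact_debye(positions: np.ndarray, amplitudes: np.ndarray,
                q: np.ndarray) -> np.ndarray:
    """Unbinned O(N^2) Debye double sum (test oracle).

    ``amplitudes`` has shape (N,) for q-independent weights or (N, n_q)
    for full per-scatterer amplitudes w_i f_i(q) (signs allowed).
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    q = np.asarray(q, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.ndim == 1:
        amplitudes = np.repeat(amplitudes[:, None], len(q), axis=1)
    d = cdist(positions, positions)
    out = np.empty(len(q))
    for k, qk in enumerate(q):
        a = amplitudes[:, k]
        out[k] = a @ (sinc(qk * d) @ a)
    return out


def set_amplitudes(scatterers: ScattererSet, q: np.ndarray,
                   registry: Optional[FormFactorRegistry] = None,
                   multipliers: Optional[Dict[str, np.ndarray]] = None
                   ) -> np.ndarray:
    """Per-scatterer amplitude array w_i f_i(q) (N, n_q) for the oracle."""
    reg = registry or default_registry
    q = np.asarray(q, dtype=float)
    out = np.zeros((len(scatterers), len(q)))
    for ci, label in enumerate(scatterers.class_labels):
        sel = scatterers.class_index == ci
        if not sel.any():
            continue
        f = reg.get(label)(q)
        if multipliers and label in multipliers:
            f = f * multipliers[label]
        out[sel] = scatterers.weights[sel, None] * f[None, :]
    return out


# ---------------------------------------------------------------------------
# Profile assembly

@dataclass
class ScatteringProfile:
    """Total intensity and its six partials on a q grid."""

    q: np.ndarray
    partials: Dict[str, np.ndarray]

    @property
    def I_total(self) -> np.ndarray:
        return sum(self.partials[name] for name in PARTIAL_NAMES)

    def partial(self, name: str) -> np.ndarray:
        return self.partials[name]


def assemble_profile(curves: Dict[str, Optional[CategoryCurves]],
                     q: np.ndarray,
                     c: float = 1.0,
                     gamma: float = 1.0,
                     exv_model=None) -> ScatteringProfile:
    """Combine category curves into total + partial intensities.

    Amplitude convention A = A_a - gamma-scaled A_x + c A_w; the stored
    partials include their sign and the factor 2 on cross terms, so
    I_total = I_aa + I_ax + I_aw + I_xx + I_xw + I_ww identically.
    """
    q = np.asarray(q, dtype=float)
    zeros = np.zeros_like(q)
    mult: Dict[str, np.ndarray] = {}
    if exv_model is not None and gamma != 1.0:
        for cls in exv_model.classes:
            mult[cls.id] = exv_model.amplitude_multiplier(cls.id, q, gamma)

    def ev(key):
        cc = curves.get(key)
        return cc.intensity(mult) if cc is not None else zeros

    partials = {
        "aa": ev("aa"),
        "xx": ev("xx"),
        "ww": c * c * ev("ww"),
        "ax": -2.0 * ev("ax"),
        "aw": 2.0 * c * ev("aw"),
        "xw": -2.0 * c * ev("xw"),
    }
    return ScatteringProfile(q=q, partials=partials)


def write_profile(profile: ScatteringProfile, path) -> None:
    """Write q, total and six partials as whitespace-separated text."""
    header = "q I_total " + " ".join(f"I_{n}" for n in PARTIAL_NAMES)
    cols = [profile.q, profile.I_total] + \
        [profile.partials[n] for n in PARTIAL_NAMES]
    np.savetxt(path, np.column_stack(cols), header=header)


def read_profile(path) -> ScatteringProfile:
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] != 2 + len(PARTIAL_NAMES):
        raise ValueError("profile file must have q, total and six partials")
    partials = {name: data[:, 2 + i] for i, name in enumerate(PARTIAL_NAMES)}
    return ScatteringProfile(q=data[:, 0], partials=partials)


# ---------------------------------------------------------------------------
# Binning diagnostics

def binning_error_report(structure, widths: Sequence[float],
                         q: Optional[np.ndarray] = None) -> Dict[float, Dict[str, float]]:
    """Max relative deviation of binned vs exact Debye per bin width.

    Computed for the structure's atomic scatterers, in both unweighted
    (bin-center) and weighted binning, over the given q grid.
    """
    q = DEFAULT_Q if q is None else np.asarray(q, dtype=float)
    sset = ScattererSet.from_structure(structure)
    amps = set_amplitudes(sset, q)
    ref = exact_debye(sset.positions, amps, q)
    report: Dict[float, Dict[str, float]] = {}
    for w in widths:
        entry = {}
        for weighted, name in ((False, "unweighted"), (True, "weighted")):
            hist = build_histogram(sset, bin_width=w, weighted=weighted)
            intensity = debye_from_histogram(hist, q, use_lookup=False)
            entry[name] = float(np.max(np.abs(intensity - ref) / ref))
        report[float(w)] = entry
    return report
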