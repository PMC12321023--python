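"""Histogramming, Debye evaluation, partials, sinc lookup, binning errors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from solscat.config import RunConfig
from solscat.pipeline import ProfileCalculator
from solscat.scattering import (DEFAULT_Q, ScattererSet, build_histogram,
                                cross_histogram, debye_from_histogram,
                                exact_debye, read_profile, set_amplitudes,
                                sinc, sinc_lookup, write_profile)
from solscat.synthetic import make_cubic_lattice_structure, make_toy_structure


def _unit_set(positions, weights=None, label="C"):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    return ScattererSet(positions, w, [label], np.zeros(n, dtype=int), "a")


class _FlatRegistry:
    """Form factor identically 1 (isolates the distance part)."""

    def get(self, class_id):
        return lambda q: np.ones_like(np.asarray(q, dtype=float))


def test_two_scatterer_histograms_weighted_vs_unweighted():
    pos = [[0.0, 0, 0], [1.23, 0, 0]]
    for weighted, expected in ((False, 1.25), (True, 1.23)):
        h = build_histogram(_unit_set(pos), bin_width=0.5, weighted=weighted)
        bins = h.pairs[("C", "C")]
        assert bins.d_repr[0] == 0.0 and bins.weight[0] == 2.0  # self terms
        assert bins.d_repr[1] == pytest.approx(expected)
        assert bins.weight[1] == 2.0


def test_three_collinear_atoms_weight_enumeration():
    pos = [[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]
    h = build_histogram(_unit_set(pos), bin_width=0.5, weighted=True)
    bins = h.pairs[("C", "C")]
    off = {round(d, 6): w for d, w in zip(bins.d_repr, bins.weight) if d > 0}
    assert off == {1.0: 4.0, 2.0: 2.0}  # ordered pairs
    assert sum(off.values()) == 6.0
    assert h.total_weight == 9.0  # (sum w)^2 with self terms


@given(st.integers(min_value=2, max_value=30), st.integers(0, 10))
def test_histogram_total_weight_identity(n, seed):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-5, 5, size=(n, 3))
    w = rng.uniform(0.5, 9.0, size=n)
    h = build_histogram(_unit_set(pos, w), bin_width=0.3)
    assert h.total_weight == pytest.approx(w.sum() ** 2, rel=1e-9)


def test_empty_set_rejected():
    with pytest.raises(ValueError):
        build_histogram(_unit_set(np.zeros((0, 3))))


def test_two_unit_scatterers_closed_form():
    d = 2.7
    q = np.linspace(1e-6, 1.2, 60)
    h = build_histogram(_unit_set([[0, 0, 0], [d, 0, 0]]), bin_width=0.1)
    intensity = debye_from_histogram(h, q, registry=_FlatRegistry())
    expected = 2.0 + 2.0 * np.sin(q * d) / (q * d)
    assert np.allclose(intensity, expected, rtol=1e-6)
    assert intensity[0] == pytest.approx(4.0, rel=1e-9)  # (sum w)^2 at q->0
    # at q d = pi the cross term vanishes
    h2 = debye_from_histogram(h, np.array([np.pi / d]),
                              registry=_FlatRegistry())
    assert h2[0] == pytest.approx(2.0, abs=1e-6)


def test_exact_debye_permutation_invariant_and_q0():
    rng = np.random.default_rng(3)
    pos = rng.uniform(-4, 4, size=(15, 3))
    w = rng.uniform(1, 8, size=15)
    q = np.linspace(1e-4, 1, 20)
    i1 = exact_debye(pos, w, q)
    perm = rng.permutation(15)
    i2 = exact_debye(pos[perm], w[perm], q)
    assert np.allclose(i1, i2, rtol=1e-12)
    assert i1[0] == pytest.approx(w.sum() ** 2, rel=1e-6)


@pytest.mark.parametrize("n_atoms, seed", [(20, 1), (35, 2), (50, 3)])
def test_binned_debye_matches_exact_oracle(n_atoms, seed):
    """Weighted 0.1 A binning reproduces the unbinned double sum to 1e-3
    over the default q grid."""
    s = make_toy_structure(n_atoms, seed=seed)
    sset = ScattererSet.from_structure(s)
    ref = exact_debye(sset.positions, set_amplitudes(sset, DEFAULT_Q),
                      DEFAULT_Q)
    h = build_histogram(sset, bin_width=0.1, weighted=True)
    binned = debye_from_histogram(h, DEFAULT_Q)
    assert np.max(np.abs(binned - ref) / ref) < 1e-3


def test_sinc_lookup_accuracy():
    x = np.linspace(0, 200, 400001)
    assert np.max(np.abs(sinc_lookup(x) - sinc(x))) < 1e-5
    # extends on demand beyond the initial table
    x_big = np.array([5000.0])
    assert sinc_lookup(x_big)[0] == pytest.approx(sinc(x_big)[0], abs=1e-5)


def test_cross_histogram_single_counts():
    a = _unit_set([[0.0, 0, 0]], weights=[2.0])
    b = ScattererSet(np.array([[1.5, 0, 0]]), np.array([3.0]),
                     ["H2O"], np.zeros(1, dtype=int), "w")
    h = cross_histogram(a, b, bin_width=0.1)
    bins = h.pairs[("C", "H2O")]
    assert bins.weight.sum() == pytest.approx(6.0)
    assert h.category == "aw"


# -- assembled profiles -----------------------------------------------------

def test_partial_sum_identity_and_positivity(calc30):
    p = calc30.profile(c=0.83)
    total = sum(p.partials[k] for k in p.partials)
    assert np.allclose(p.I_total, total, rtol=1e-10)
    assert np.all(p.I_total >= 0)


def test_zero_hydration_scale_kills_water_partials(calc30):
    p = calc30.profile(c=0.0)
    assert np.all(p.partials["aw"] == 0)
    assert np.all(p.partials["ww"] == 0)
    assert np.all(p.partials["xw"] == 0)


def test_no_exv_means_total_equals_aa(toy30):
    """With the excluded-volume weights zeroed the total reduces to I_aa."""
    import dataclasses
    cfg = dataclasses.replace(RunConfig(), hydrate=False)
    calc = ProfileCalculator(toy30, cfg)
    calc.exv_model.weights[:] = 0.0
    calc._curves = calc._build_curves()
    p = calc.profile()
    assert np.allclose(p.I_total, p.partials["aa"], rtol=1e-12)


def test_full_system_against_amplitude_square_oracle(calc30):
    """Assembled binned profile vs the direct signed-amplitude double sum
    on the identical scatterers (within binning tolerance)."""
    c = 0.7
    q = calc30.q
    sa = ScattererSet.from_structure(calc30.structure)
    sx = ScattererSet.from_excluded_volume(calc30.exv_model)
    sw = ScattererSet.from_waters(calc30.waters)
    amps = np.vstack([
        set_amplitudes(sa, q, calc30.registry),
        -set_amplitudes(sx, q, calc30.registry),
        c * set_amplitudes(sw, q, calc30.registry)])
    pos = np.vstack([sa.positions, sx.positions, sw.positions])
    ref = exact_debye(pos, amps, q)
    total = calc30.profile(c=c).I_total
    assert np.max(np.abs(total - ref) / np.abs(ref)) < 1e-2


def test_profile_io_round_trip(tmp_path, calc30):
    p = calc30.profile()
    path = tmp_path / "profile.dat"
    write_profile(p, path)
    back = read_profile(path)
    assert np.allclose(back.q, p.q)
    for name in p.partials:
        assert np.allclose(back.partials[name], p.partials[name], rtol=1e-12)
    assert np.allclose(back.I_total, p.I_total, rtol=1e-12)


# -- binning error study ----------------------------------------------------

def test_lattice_suffers_more_than_random_cluster():
    """Ordered structures amplify the bin-center error."""
    from solscat.scattering import binning_error_report
    rnd = make_toy_structure(64, seed=4)
    lat = make_cubic_lattice_structure(4, spacing=1.5)
    w = 0.1
    r_rnd = binning_error_report(rnd, [w])[w]
    r_lat = binning_error_report(lat, [w])[w]
    assert r_lat["unweighted"] > r_rnd["unweighted"]
    assert r_lat["unweighted"] > 10 * r_lat["weighted"]
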