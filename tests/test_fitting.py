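"""Chi-square machinery and parameter recovery on synthetic data."""

import dataclasses

import numpy as np
import pytest

from solscat.config import RunConfig
from solscat.fitting import (SaxsDataset, fit, read_saxs_dat, reduced_chi2,
                             solve_linear)
from solscat.pipeline import ProfileCalculator
from solscat.synthetic import make_synthetic_dataset, make_toy_structure


def _dataset(n=50, seed=0):
    rng = np.random.default_rng(seed)
    q = np.linspace(0.01, 0.5, n)
    shape = np.exp(-q * 3.0) + 0.1
    sigma = np.full(n, 0.05)
    return q, shape, sigma


# -- dataset I/O ------------------------------------------------------------

def test_read_saxs_dat_basic(tmp_path):
    p = tmp_path / "d.dat"
    p.write_text("0.01 10.0 0.1\n0.02 9.0 0.1\n0.03 8.0 0.1\n")
    ds = read_saxs_dat(p)
    assert len(ds) == 3
    assert ds.q[0] == 0.01 and ds.intensity[2] == 8.0


def test_read_saxs_dat_headers_and_bad_sigma(tmp_path):
    body = "0.01 10.0 0.1\n0.02 9.0 0.0\n0.03 8.0 0.1\n"
    plain = tmp_path / "plain.dat"
    plain.write_text(body)
    with_header = tmp_path / "hdr.dat"
    with_header.write_text("# my experiment\nq I err\n" + body)
    d1, d2 = read_saxs_dat(plain), read_saxs_dat(with_header)
    assert len(d1) == len(d2) == 2  # sigma <= 0 row dropped
    assert np.array_equal(d1.q, d2.q)


def test_read_saxs_dat_rejects_garbage(tmp_path):
    p = tmp_path / "bad.dat"
    p.write_text("just words\n1.0 2.0\n")
    with pytest.raises(ValueError):
        read_saxs_dat(p)


def test_dataset_invariants():
    with pytest.raises(ValueError):
        SaxsDataset(np.array([0.1, 0.2]), np.array([1.0, 1.0]),
                    np.array([0.1, -0.1]))
    with pytest.raises(ValueError):
        SaxsDataset(np.array([0.2, 0.1]), np.array([1.0, 1.0]),
                    np.array([0.1, 0.1]))


# -- reduced chi2 -----------------------------------------------------------

def test_reduced_chi2_values():
    q, shape, sigma = _dataset()
    ds = SaxsDataset(q, shape.copy(), sigma)
    assert reduced_chi2(ds, shape, nu=len(q) - 3) == 0.0
    # each residual exactly one sigma -> chi2 = N / nu
    ds2 = SaxsDataset(q, shape + sigma, sigma)
    n = len(q)
    assert reduced_chi2(ds2, shape, nu=n - 3) == pytest.approx(n / (n - 3))
    # doubling sigma divides chi2 by 4
    ds4 = SaxsDataset(q, shape + sigma, 2 * sigma)
    assert reduced_chi2(ds4, shape, nu=n - 3) == pytest.approx(n / (n - 3) / 4)
    with pytest.raises(ValueError):
        reduced_chi2(ds, shape, nu=0)


# -- linear solve -----------------------------------------------------------

def test_solve_linear_exact_recovery():
    q, shape, sigma = _dataset()
    ds = SaxsDataset(q, 2.5 * shape + 0.1, sigma)
    a, b = solve_linear(ds, shape)
    assert a == pytest.approx(2.5, rel=1e-12)
    assert b == pytest.approx(0.1, rel=1e-9)


def test_solve_linear_without_background():
    q, shape, sigma = _dataset()
    ds = SaxsDataset(q, 3.0 * shape, sigma)
    a, b = solve_linear(ds, shape, fit_background=False)
    assert a == pytest.approx(3.0, rel=1e-12)
    assert b == 0.0


def test_solve_linear_degenerate_shape():
    q, shape, sigma = _dataset()
    ds = SaxsDataset(q, shape, sigma)
    with pytest.raises(ValueError):
        solve_linear(ds, np.ones_like(q))


def test_solve_linear_matches_grid_search():
    rng = np.random.default_rng(5)
    q, shape, sigma = _dataset()
    ds = SaxsDataset(q, 1.7 * shape + 0.3 + rng.normal(0, 0.05, len(q)),
                     sigma)
    a, b = solve_linear(ds, shape)

    def chi2(aa, bb):
        return np.sum(((ds.intensity - aa * shape - bb) / sigma) ** 2)

    # closed form beats (or ties) a fine brute-force grid around it
    grid = np.linspace(-0.01, 0.01, 21)
    best = min(chi2(a + da, b + db) for da in grid for db in grid)
    assert chi2(a, b) <= best + 1e-6


def test_solve_linear_unbiased_under_noise():
    q, shape, sigma = _dataset()
    rng = np.random.default_rng(11)
    estimates = []
    for _ in range(200):
        ds = SaxsDataset(q, 2.0 * shape + 0.1
                         + rng.normal(0, 0.05, len(q)), sigma)
        estimates.append(solve_linear(ds, shape)[0])
    se = np.std(estimates) / np.sqrt(len(estimates))
    assert abs(np.mean(estimates) - 2.0) < 3 * se + 1e-9


# -- full fits --------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_and_calc():
    s = make_toy_structure(40, seed=3)
    cfg = RunConfig()
    return s, cfg, ProfileCalculator(s, cfg)


def test_noiseless_self_fit_recovers_parameters(toy_and_calc):
    s, cfg, calc = toy_and_calc
    truth = {"a": 2.5, "b": 10.0, "c": 0.8}
    ds = make_synthetic_dataset(s, truth, noise_rel=0.0, calculator=calc)
    r = fit(s, ds, config=cfg, calculator=calc, seed=1)
    assert r.a == pytest.approx(truth["a"], rel=1e-3)
    assert r.b == pytest.approx(truth["b"], rel=1e-3)
    assert r.c == pytest.approx(truth["c"], rel=1e-3)
    assert r.chi2_reduced < 1e-4
    assert r.nu == 100 - 3 and r.d is None


def test_noisy_self_fit_chi2_near_one(toy_and_calc):
    s, cfg, calc = toy_and_calc
    chis = []
    for seed in range(20):
        ds = make_synthetic_dataset(s, {"a": 2.5, "b": 10.0, "c": 0.8},
                                    noise_rel=0.02, seed=seed,
                                    calculator=calc)
        chis.append(fit(s, ds, config=cfg, calculator=calc,
                        seed=1).chi2_reduced)
    assert all(0.5 <= c <= 1.5 for c in chis)
    assert abs(np.mean(chis) - 1.0) < 0.2


def test_fraser_gamma_recovery():
    s = make_toy_structure(40, seed=3)
    cfg = dataclasses.replace(RunConfig(), exv_mode="fraser")
    calc = ProfileCalculator(s, cfg)
    ds = make_synthetic_dataset(s, {"a": 1.5, "b": 0.5, "c": 0.9,
                                    "gamma": 1.05},
                                noise_rel=0.0, calculator=calc)
    r = fit(s, ds, config=cfg, calculator=calc, seed=1)
    lo, hi = calc.gamma_bounds
    assert lo <= r.d <= hi
    assert r.d == pytest.approx(1.05, abs=0.02)
    assert r.nu == 100 - 4


def test_fit_determinism(toy_and_calc):
    s, cfg, calc = toy_and_calc
    ds = make_synthetic_dataset(s, {"a": 1.0, "b": 0.0, "c": 1.0},
                                noise_rel=0.02, seed=5, calculator=calc)
    r1 = fit(s, ds, config=cfg, calculator=calc, seed=9)
    r2 = fit(s, ds, config=cfg, calculator=calc, seed=9)
    assert (r1.a, r1.b, r1.c) == (r2.a, r2.b, r2.c)


def test_interpolation_exact_at_internal_nodes(toy_and_calc):
    """The cubic interpolation onto data q reproduces the directly
    computed model at the internal grid nodes."""
    from scipy.interpolate import CubicSpline
    s, cfg, calc = toy_and_calc
    intensity = calc.intensity(c=0.8)
    spline = CubicSpline(calc.q, intensity)
    assert np.allclose(spline(calc.q), intensity, rtol=1e-13)
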