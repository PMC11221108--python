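"""Baseline fitting, pathlength operators, TMPP and MBLL inversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fnirsim import experiments as xp
from fnirsim.acquisition import GateSet, gate_counts
from fnirsim.forward_models import (
    BilayerGeometry,
    OpticalProperties,
    ReflectanceCurve,
    SlabGeometry,
    TimeGrid,
    slab_td_reflectance,
)
from fnirsim.inversion import (
    cw_mbll,
    fit_homogeneous_baseline,
    mean_total_pathlength,
    tmpp_invert,
    tmpp_pathlengths,
    unmix_chromophores,
)
MASTER_SEED = 0
from fnirsim.tissue_dynamics import default_extinction_table
_T = default_extinction_table()
BASE_PROPS_690 = OpticalProperties(
    30.0 * _T.factors(690.0)[0] + 20.0 * _T.factors(690.0)[1], 10.0, 1.4
)
BILAYER_GEOM = BilayerGeometry(10.0, 1.0, 4.0)
GRID20 = TimeGrid(0.0, 5.0, 0.020)
GRID8 = TimeGrid(0.0, 5.0, 0.008)
SLAB = SlabGeometry(5.0)
TRUTH = OpticalProperties(0.0864, 10.0, 1.4)


def test_baseline_fit_recovers_noiseless_truth():
    curve = slab_td_reflectance(TRUTH, SLAB, 3.0, GRID8)
    y = 1e6 * curve.values / curve.values.sum()
    init = OpticalProperties(0.12, 8.0, 1.4)
    fit = fit_homogeneous_baseline(y, GRID8, 3.0, SLAB, init)
    assert fit.converged
    assert fit.props.mua == pytest.approx(TRUTH.mua, rel=5e-3)
    assert fit.props.musp == pytest.approx(TRUTH.musp, rel=5e-3)


def test_baseline_fit_from_truth_is_immediate():
    curve = slab_td_reflectance(TRUTH, SLAB, 3.0, GRID8)
    y = 1e6 * curve.values / curve.values.sum()
    fit = fit_homogeneous_baseline(y, GRID8, 3.0, SLAB, TRUTH)
    assert fit.converged
    assert fit.n_evaluations <= 5
    assert fit.props.mua == pytest.approx(TRUTH.mua, rel=1e-6)


def test_baseline_fit_recovers_from_poisson_noise():
    rng = np.random.default_rng(17)
    curve = slab_td_reflectance(TRUTH, SLAB, 3.0, GRID8)
    expect = 1e6 * curve.values / curve.values.sum()
    mean_dtof = rng.poisson(np.tile(expect, (2000, 1))).mean(axis=0)
    fit = fit_homogeneous_baseline(
        mean_dtof, GRID8, 3.0, SLAB, OpticalProperties(0.1, 9.0, 1.4)
    )
    assert fit.props.mua == pytest.approx(TRUTH.mua, rel=0.01)
    assert fit.props.musp == pytest.approx(TRUTH.musp, rel=0.01)


def test_baseline_fit_requires_statistics():
    with pytest.raises(ValueError):
        fit_homogeneous_baseline(
            np.ones(GRID8.n_bins), GRID8, 3.0, SLAB, TRUTH
        )


def test_total_pathlength_identity():
    """Σ_j L_j(t) = v·t for identical layers (point-sampled curves)."""
    op = tmpp_pathlengths(
        BASE_PROPS_690, BASE_PROPS_690, BILAYER_GEOM, 4.0, GRID20,
        point_sampled=True,
    )
    t = GRID20.centers()
    mask = op.baseline_curve > 1e-6 * op.baseline_curve.max()
    total = op.pathlengths_t.sum(axis=1)
    rel = np.abs(total[mask] - op.speed * t[mask]) / (op.speed * t[mask])
    assert rel.max() < 0.005


def test_gate_pathlength_structure(tmpp_operators):
    """Early gates are blind to the deep layer; L_dw grows with time."""
    op1 = tmpp_operators[1.0]["operators"][690.0]
    assert op1.gate_pathlengths[0, 1] / op1.gate_pathlengths[0, 0] < 0.02
    l_dw = op1.pathlengths_t[:, 1]
    good = op1.baseline_curve > 1e-6 * op1.baseline_curve.max()
    assert np.all(np.diff(l_dw[good]) >= -1e-3 * max(l_dw.max(), 1.0))
    # deep-layer pathlength is substantial in the late gates
    assert op1.gate_pathlengths[-1, 1] > op1.gate_pathlengths[-1, 0]


def test_finite_difference_step_validation():
    op = tmpp_pathlengths(
        BASE_PROPS_690, BASE_PROPS_690, BILAYER_GEOM, 4.0, GRID20,
        validate=True,
    )
    assert op.pathlengths_t.min() >= 0.0


def test_tmpp_zero_perturbation_is_unbiased(tmpp_operators):
    """With constant concentrations the retrieved Δμa has zero mean.

    The log debiasing is exact to O(1/N²): over gates with ≥ 100 baseline
    counts the mean is statistically zero; with the default 10-count
    threshold the marginal gates may leave a small constant offset
    (≲ 5·10⁻⁴ 1/cm, irrelevant to any spectral quantity)."""
    cfg = xp.get_case("B_UP", MASTER_SEED)
    from dataclasses import replace

    quiet = replace(cfg, perturbations=(), case_id="B_quiet")
    dtofs = xp.simulate_point(quiet, 1e5, 120.0, 20.0, 4.0)
    op = tmpp_operators[4.0]["operators"][690.0]
    gated = gate_counts(dtofs[690.0], op.gates)
    result = tmpp_invert(gated, op, min_gate_counts=100.0)
    n = result.delta_mua.shape[0]
    for j in range(len(result.layers)):
        series = result.delta_mua[:, j]
        se = series.std(ddof=1) / np.sqrt(n)
        assert abs(series.mean()) < 3 * se + 1e-6
    default = tmpp_invert(gated, op)
    assert np.max(np.abs(default.delta_mua.mean(axis=0))) < 5e-4


def test_tmpp_rejects_insufficient_gates(tmpp_operators):
    op = tmpp_operators[4.0]["operators"][690.0]
    cfg = xp.get_case("B_UP", MASTER_SEED)
    dtofs = xp.simulate_point(cfg, 1e5, 30.0, 20.0, 4.0)
    gated = gate_counts(dtofs[690.0], op.gates)
    with pytest.raises(ValueError, match="usable gates"):
        tmpp_invert(gated, op, min_gate_counts=1e12)


def test_mbll_inversion_identity():
    path = 25.0
    delta = 3.4e-4
    i0 = 1e6
    intensity = np.full(200, i0 * np.exp(-delta * path))
    # constant series: baseline is the mean, so Δμa ≡ 0
    assert np.allclose(cw_mbll(intensity, path), 0.0)
    # two-level series recovers the imposed step around the mean
    stepped = np.concatenate([np.full(100, i0), np.full(100, i0 * np.exp(-delta * path))])
    rec = cw_mbll(stepped, path)
    assert rec[-1] - rec[0] == pytest.approx(delta, rel=1e-10)
    with pytest.raises(ValueError):
        cw_mbll(np.array([1.0, 0.0, 2.0]), path)


def test_mean_total_pathlength_is_count_weighted_mean_time():
    curve = slab_td_reflectance(TRUTH, SLAB, 3.0, GRID8)
    path = mean_total_pathlength(curve)
    v = TRUTH.speed
    t_mean = (GRID8.centers() * curve.values).sum() / curve.values.sum()
    assert path == pytest.approx(v * t_mean, rel=1e-12)
    assert 5.0 < path < 60.0  # physically sensible for 3 cm separation


@given(
    do2=st.floats(min_value=-1.0, max_value=1.0),
    dhb=st.floats(min_value=-1.0, max_value=1.0),
)
@settings(max_examples=25, derandomize=True)
def test_unmixing_round_trip(do2, dhb, extinction_table):
    e = extinction_table.matrix([690.0, 830.0])
    dmua = e @ np.array([do2, dhb])
    out = unmix_chromophores(
        {690.0: np.array([dmua[0]]), 830.0: np.array([dmua[1]])},
        extinction_table,
    )
    assert out["O2Hb"][0] == pytest.approx(do2, abs=1e-10)
    assert out["HHb"][0] == pytest.approx(dhb, abs=1e-10)


def test_unmixing_zero_and_errors(extinction_table):
    out = unmix_chromophores(
        {690.0: np.zeros(5), 830.0: np.zeros(5)}, extinction_table
    )
    assert np.all(out["O2Hb"] == 0) and np.all(out["HHb"] == 0)
    with pytest.raises(ValueError):
        unmix_chromophores({690.0: np.zeros(5)}, extinction_table)
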