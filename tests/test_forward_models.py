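"""Forward diffusion models: slab oracle, bilayer consistency, invariants."""

import numpy as np
import pytest

from fnirsim.forward_models import (
    BilayerGeometry,
    OpticalProperties,
    ReflectanceCurve,
    SlabGeometry,
    TimeGrid,
    bilayer_td_reflectance,
    bilayer_td_reflectance_multi,
    cached_mua_grids,
    cw_intensity,
    internal_reflection_parameter,
    slab_td_reflectance,
)

PROPS = OpticalProperties(0.1, 10.0, 1.4)
SLAB = SlabGeometry(5.0)
GRID8 = TimeGrid(0.0, 5.0, 0.008)
GRID20 = TimeGrid(0.0, 5.0, 0.020)
BGEOM = BilayerGeometry(10.0, 1.0, 4.0)

# Frozen flux values (per ns) at bin centers, computed once with an
# independently coded oracle: sine-series eigenfunction expansion in depth
# times the lateral Gaussian kernel (scratch evaluation, 4000 modes,
# insensitive to doubling the mode count).  props=(0.1, 10, 1.4), sdd=3 cm.
SLAB_ORACLE_FLUX = {
    0.5: 3.538865239463714e-05,
    1.004: 5.4157708067858825e-05,
    2.5: 1.5468611923319658e-06,
    3.996: 3.153757049038406e-08,
}
# CW intensity ratio I(sdd=4)/I(sdd=1) at mua=0.1136, quadrature of the
# oracle curves over 0-10 ns
CW_RATIO_ORACLE = 0.00026115019293102243


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        OpticalProperties(-0.1, 10.0)
    with pytest.raises(ValueError):
        OpticalProperties(0.1, 0.0)
    with pytest.raises(ValueError):
        slab_td_reflectance(PROPS, SLAB, -1.0, GRID8)
    with pytest.raises(ValueError):
        bilayer_td_reflectance(PROPS, PROPS, BGEOM, 12.0, GRID20)
    with pytest.raises(ValueError):
        TimeGrid(0.0, 5.0, -0.01)


def test_internal_reflection_parameter_values():
    # index-matched boundary has A near 1; tissue-like n=1.4 near 3.25
    assert internal_reflection_parameter(1.0) == pytest.approx(1.0, abs=0.08)
    assert internal_reflection_parameter(1.4) == pytest.approx(3.25, abs=0.01)


def test_slab_matches_independent_eigenfunction_oracle():
    curve = slab_td_reflectance(PROPS, SLAB, 3.0, GRID8)
    t = GRID8.centers()
    for ti, ref_flux in SLAB_ORACLE_FLUX.items():
        i = int(np.argmin(np.abs(t - ti)))
        assert t[i] == pytest.approx(ti, abs=1e-12)
        assert curve.values[i] / GRID8.dt == pytest.approx(ref_flux, rel=1e-10)


def test_absorption_enters_only_through_exponential_factor():
    """R(t; μa) = R(t; 0) · exp(−μa v t) to machine precision."""
    with_abs = slab_td_reflectance(PROPS, SLAB, 3.0, GRID8).values
    no_abs = slab_td_reflectance(
        OpticalProperties(0.0, PROPS.musp, PROPS.n), SLAB, 3.0, GRID8
    ).values
    predicted = no_abs * np.exp(-PROPS.mua * PROPS.speed * GRID8.centers())
    np.testing.assert_allclose(with_abs, predicted, rtol=0, atol=1e-14 * with_abs.max())


def test_causality_at_early_times():
    """The diffuse signal at finite SDD vanishes as t → 0+."""
    curve = slab_td_reflectance(PROPS, SLAB, 3.0, GRID8)
    assert curve.values[0] < 1e-12 * curve.values.max()


def test_cw_intensity_linearity_and_oracle_ratio():
    curve = slab_td_reflectance(PROPS, SLAB, 3.0, GRID8)
    zero = ReflectanceCurve(GRID8, np.zeros(GRID8.n_bins))
    assert cw_intensity(zero) == 0.0
    scaled = ReflectanceCurve(GRID8, 7.0 * curve.values)
    assert cw_intensity(scaled) == pytest.approx(7.0 * cw_intensity(curve), rel=1e-12)

    props = OpticalProperties(0.1136, 10.0, 1.4)
    i1 = cw_intensity(slab_td_reflectance(props, SLAB, 1.0, GRID8))
    i4 = cw_intensity(slab_td_reflectance(props, SLAB, 4.0, GRID8))
    # small residual vs the oracle from window truncation and quadrature
    assert i4 / i1 == pytest.approx(CW_RATIO_ORACLE, rel=5e-4)


def test_grid_refinement_stability():
    """Halving dt changes the integrated curve by far less than 0.1%."""
    coarse = slab_td_reflectance(PROPS, SLAB, 3.0, GRID8).total()
    fine = slab_td_reflectance(PROPS, SLAB, 3.0, TimeGrid(0, 5, 0.004)).total()
    assert fine == pytest.approx(coarse, rel=1e-3)


@pytest.mark.parametrize("sdd", [1.0, 4.0])
def test_identical_layer_bilayer_degenerates_to_slab(
    degenerate_bilayer_curves, sdd
):
    """Equal layers in the 10 cm cylinder reproduce the infinite slab to 1%."""
    bil, slabs = degenerate_bilayer_curves
    reference = slabs[sdd]
    mask = reference >= 1e-6 * reference.max()
    rel = np.abs(bil[sdd][mask] - reference[mask]) / reference[mask]
    assert rel.max() < 0.01


def test_deep_layer_absorption_attenuates_late_photons():
    """Raising the DW-layer μa suppresses the curve increasingly with t."""
    base = bilayer_td_reflectance_multi(
        PROPS, PROPS, BGEOM, (3.0,), GRID20, point_sampled=True
    )[0]
    pert = bilayer_td_reflectance_multi(
        PROPS, OpticalProperties(0.12, 10.0, 1.4), BGEOM, (3.0,), GRID20,
        point_sampled=True,
    )[0]
    mask = base > 1e-6 * base.max()
    ratio = pert[mask] / base[mask]
    assert np.all(ratio <= 1.0 + 1e-9)
    assert np.all(np.diff(ratio) <= 1e-5)  # monotone non-increasing


def test_early_photons_at_short_sdd_stay_superficial():
    """For t ≤ 500 ps at SDD = 1 cm, a UP-layer μa step changes the curve
    like the same step applied to the whole medium (within 5%)."""
    step = 0.005
    base = bilayer_td_reflectance_multi(PROPS, PROPS, BGEOM, (1.0,), GRID20)[0]
    up = bilayer_td_reflectance_multi(
        OpticalProperties(PROPS.mua + step, 10.0, 1.4), PROPS, BGEOM, (1.0,), GRID20
    )[0]
    both = bilayer_td_reflectance_multi(
        OpticalProperties(PROPS.mua + step, 10.0, 1.4),
        OpticalProperties(PROPS.mua + step, 10.0, 1.4),
        BGEOM, (1.0,), GRID20,
    )[0]
    t = GRID20.centers()
    sel = (t <= 0.5) & (base > 1e-6 * base.max())
    dlog_up = np.log(up[sel] / base[sel])
    dlog_both = np.log(both[sel] / base[sel])
    assert np.max(np.abs(dlog_up - dlog_both) / np.abs(dlog_both)) < 0.05


def test_mua_grid_interpolation_error_below_tolerance():
    """Bilinear log-R interpolation is certified below 0.05% off-node."""
    # the default-tissue baseline at 690 nm: shares the memoized grid with
    # the full bilayer pipeline
    from fnirsim.tissue_dynamics import default_extinction_table

    table = default_extinction_table()
    base = OpticalProperties(
        30.0 * table.factors(690.0)[0] + 20.0 * table.factors(690.0)[1],
        10.0, 1.4,
    )
    grids = cached_mua_grids(base, base, BGEOM, (1.0, 4.0), GRID20)
    interp = grids[4.0]
    mu_u = base.mua * 1.0042
    mu_d = base.mua * 0.9971
    direct = bilayer_td_reflectance_multi(
        OpticalProperties(mu_u, 10.0, 1.4),
        OpticalProperties(mu_d, 10.0, 1.4),
        BGEOM, (4.0,), GRID20,
    )[0]
    approx = interp.curves(np.array([mu_u]), np.array([mu_d]))[0]
    mask = direct > 1e-6 * direct.max()
    assert np.max(np.abs(approx[mask] - direct[mask]) / direct[mask]) < 5e-4
    with pytest.raises(ValueError):
        interp.curves(np.array([base.mua * 1.1]), np.array([base.mua]))
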