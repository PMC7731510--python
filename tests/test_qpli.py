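import numpy as np
import pytest
from scipy.special import i0, i1

from valveoptics import (
    PolarizationStack,
    axial_circular_variance,
    directional_variance,
    fit_retardation_orientation,
    qpli_region_summary,
    rasterize,
    RegionAnnotation,
)


def forward_stack(delta_deg, phi_deg, b=100.0, k=18, shape=None):
    """Evaluate I(theta) = B (1 + sin d sin 2(theta - phi)) on an even grid."""
    angles = np.arange(k) * (180.0 / k)
    delta = np.atleast_2d(np.asarray(delta_deg, float))
    phi = np.atleast_2d(np.asarray(phi_deg, float))
    if shape:
        delta = np.broadcast_to(delta, shape)
        phi = np.broadcast_to(phi, shape)
    theta = np.deg2rad(angles)[:, None, None]
    frames = b * (
        1.0 + np.sin(np.deg2rad(delta))[None] * np.sin(2 * (theta - np.deg2rad(phi)[None]))
    )
    return PolarizationStack(frames=frames, angles_deg=angles)


def test_noiseless_recovery_to_1e6_degrees():
    fibers = fit_retardation_orientation(forward_stack(30.0, 20.0))
    np.testing.assert_allclose(fibers.retardation_deg, 30.0, atol=1e-6)
    np.testing.assert_allclose(fibers.orientation_deg, 20.0, atol=1e-6)


def test_full_modulation_gives_90_degrees_exactly():
    fibers = fit_retardation_orientation(forward_stack(90.0, 45.0))
    np.testing.assert_allclose(fibers.retardation_deg, 90.0, atol=1e-9)


def test_constant_intensity_zero_retardation_undefined_orientation():
    stack = PolarizationStack(
        frames=np.full((8, 3, 3), 50.0), angles_deg=np.arange(8) * 22.5
    )
    fibers = fit_retardation_orientation(stack)
    np.testing.assert_allclose(fibers.retardation_deg, 0.0, atol=1e-9)
    assert np.isnan(fibers.orientation_deg).all()
    assert fibers.valid.all()


def test_all_zero_pixel_invalid_not_error():
    stack = forward_stack(20.0, 10.0, shape=(2, 2))
    frames = stack.frames.copy()
    frames[:, 0, 0] = 0.0
    fibers = fit_retardation_orientation(
        PolarizationStack(frames=frames, angles_deg=stack.angles_deg), intensity_floor=1e-9
    )
    assert not fibers.valid[0, 0]
    assert np.isnan(fibers.retardation_deg[0, 0])
    assert fibers.valid[1, 1]


def test_gain_invariance_of_estimates():
    base = fit_retardation_orientation(forward_stack(35.0, 70.0))
    stack = forward_stack(35.0, 70.0)
    scaled = fit_retardation_orientation(
        PolarizationStack(frames=stack.frames * 7.3, angles_deg=stack.angles_deg)
    )
    np.testing.assert_allclose(scaled.retardation_deg, base.retardation_deg, atol=1e-9)
    np.testing.assert_allclose(scaled.orientation_deg, base.orientation_deg, atol=1e-9)


@pytest.mark.parametrize("shift", [17.0, 90.0, 155.0])
def test_orientation_equivariance_mod_180(shift):
    base = fit_retardation_orientation(forward_stack(40.0, 30.0)).orientation_deg
    rotated = fit_retardation_orientation(forward_stack(40.0, 30.0 + shift)).orientation_deg
    np.testing.assert_allclose(np.mod(rotated - base, 180.0), shift % 180.0, atol=1e-6)


def test_uneven_grid_rejected_then_fit_by_least_squares():
    stack = forward_stack(25.0, 60.0, k=12)
    angles = stack.angles_deg.copy()
    angles[3] += 4.0  # break even spacing
    frames = forward_stack(25.0, 60.0, k=12).frames  # regenerate at original grid
    theta = np.deg2rad(angles)[:, None, None]
    frames = 100.0 * (
        1.0 + np.sin(np.deg2rad(25.0)) * np.sin(2 * (theta - np.deg2rad(60.0)))
    ) * np.ones_like(frames)
    bad = PolarizationStack(frames=frames, angles_deg=angles)
    with pytest.raises(ValueError, match="even grid"):
        fit_retardation_orientation(bad)
    fibers = fit_retardation_orientation(bad, allow_uneven=True)
    np.testing.assert_allclose(fibers.retardation_deg, 25.0, atol=1e-6)
    np.testing.assert_allclose(fibers.orientation_deg, 60.0, atol=1e-6)


def test_too_few_angles_rejected():
    with pytest.raises(ValueError, match=">= 4"):
        PolarizationStack(frames=np.ones((3, 2, 2)), angles_deg=np.array([0.0, 60.0, 120.0]))


def test_noisy_rmse_below_one_degree(rng):
    """2% Gaussian noise, 10^4 pixels: retardation RMSE under a degree."""
    shape = (100, 100)
    delta = rng.uniform(5.0, 50.0, size=shape)
    phi = rng.uniform(0.0, 180.0, size=shape)
    stack = forward_stack(delta, phi, shape=shape)
    noisy = stack.frames + rng.normal(0.0, 0.02 * stack.frames.max(), size=stack.frames.shape)
    fibers = fit_retardation_orientation(
        PolarizationStack(frames=noisy, angles_deg=stack.angles_deg)
    )
    rmse = np.sqrt(np.mean((fibers.retardation_deg - delta) ** 2))
    assert rmse < 1.0


# ---- directional variance ----


def aligned_fibers(orientation=30.0, shape=(21, 21)):
    stack = forward_stack(40.0, orientation, shape=shape)
    return fit_retardation_orientation(stack)


def test_variance_zero_for_aligned_field():
    vm = directional_variance(aligned_fibers(), window=11, min_count=10)
    inner = vm.directional_variance[8:13, 8:13]
    np.testing.assert_allclose(inner, 0.0, atol=1e-9)


def test_variance_one_for_orthogonal_axial_pair():
    assert axial_circular_variance(np.array([0.0, 90.0] * 50)) == pytest.approx(1.0, abs=1e-12)
    # per-pixel: alternating 0/90 columns inside the window
    shape = (21, 21)
    phi = np.where(np.indices(shape)[1] % 2 == 0, 0.0, 90.0)
    fibers = fit_retardation_orientation(forward_stack(40.0, phi, shape=shape))
    vm = directional_variance(fibers, window=11, min_count=10)
    # windows hold 66/55 or 55/66 pixels of each orientation: V = 1 - 1/11
    assert vm.directional_variance[10, 10] == pytest.approx(1.0 - 1.0 / 11.0, abs=1e-9)


@pytest.mark.parametrize("kappa", [0.5, 2.0, 8.0])
def test_variance_matches_bessel_closed_form(kappa, rng):
    """Monte-Carlo axial von Mises sample matches V = 1 - I1(k)/I0(k)."""
    phi2 = rng.vonmises(0.0, kappa, size=100_000)
    orientations = np.degrees(np.mod(phi2 / 2.0, np.pi))
    v = axial_circular_variance(orientations)
    assert v == pytest.approx(1.0 - i1(kappa) / i0(kappa), abs=0.01)


def test_variance_monotone_in_concentration(rng):
    vs = []
    for kappa in (0.5, 2.0, 8.0):
        phi2 = rng.vonmises(0.0, kappa, size=50_000)
        vs.append(axial_circular_variance(np.degrees(np.mod(phi2 / 2.0, np.pi))))
    assert vs[0] > vs[1] > vs[2]


def test_variance_window_validation_and_min_count():
    fibers = aligned_fibers()
    with pytest.raises(ValueError, match="odd"):
        directional_variance(fibers, window=10)
    vm = directional_variance(fibers, window=11, min_count=200)
    assert not vm.valid.any()  # 11x11 window can never hold 200 collagen pixels


def test_variance_bounded_on_phantom(noisy_phantom):
    fibers = fit_retardation_orientation(noisy_phantom.polarization_stack)
    vm = directional_variance(fibers)
    vals = vm.directional_variance[vm.valid]
    assert vals.size > 0
    assert np.all((vals >= 0.0) & (vals <= 1.0))


# ---- region summary ----


def square_masks(n=21):
    ann = RegionAnnotation([("root", np.array([(0, 0), (n, 0), (n, n), (0, n)], float))])
    return rasterize(ann, (n, n))


def test_region_summary_uniform_retardation():
    fibers = fit_retardation_orientation(forward_stack(25.0, 40.0, shape=(21, 21)))
    vm = directional_variance(fibers)
    tab = qpli_region_summary(fibers, vm, square_masks())
    assert tab.avg_retardation_deg.iloc[0] == pytest.approx(25.0, abs=1e-6)
    assert tab.collagen_density.iloc[0] == 1.0
    assert tab.avg_directional_variance.iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_region_summary_half_collagen_density():
    delta = np.zeros((20, 21))
    delta[:10] = 40.0  # lower half below the 5-degree threshold
    fibers = fit_retardation_orientation(forward_stack(delta, 10.0, shape=(20, 21)))
    vm = directional_variance(fibers)
    ann = RegionAnnotation([("root", np.array([(0, 0), (21, 0), (21, 20), (0, 20)], float))])
    tab = qpli_region_summary(fibers, vm, rasterize(ann, (20, 21)))
    assert tab.collagen_density.iloc[0] == pytest.approx(0.5)
    assert tab.avg_retardation_deg.iloc[0] == pytest.approx(40.0, abs=1e-6)
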