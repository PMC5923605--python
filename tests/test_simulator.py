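"""Simulator ground-truth conservation, determinism and point-process shape."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from nebudose import (
    DepositionParams,
    ImageCalibration,
    simulate_deposition,
    simulate_endpoint_readouts,
)
from nebudose.units import disk_area_nm2


def make_params(nm100, field, **kwargs):
    defaults = dict(particle=nm100, n_particles=20, field=field, seed=0)
    defaults.update(kwargs)
    return DepositionParams(**defaults)


def test_same_seed_bit_identical(nm100, field256):
    p = make_params(nm100, field256, mode="clustered", stacking_prob=0.3, seed=7)
    img1, gt1 = simulate_deposition(p)
    img2, gt2 = simulate_deposition(p)
    assert np.array_equal(img1.intensities, img2.intensities)
    assert np.array_equal(gt1.centers_nm, gt2.centers_nm)
    assert gt1.true_mass_ug == gt2.true_mass_ug


def test_different_seed_differs(nm100, field256):
    img1, _ = simulate_deposition(make_params(nm100, field256, seed=1))
    img2, _ = simulate_deposition(make_params(nm100, field256, seed=2))
    assert not np.array_equal(img1.intensities, img2.intensities)


@pytest.mark.parametrize("mode", ["homogeneous", "clustered"])
@pytest.mark.parametrize("stacking", [0.0, 0.5])
def test_mass_conservation_exact(nm100, field256, mode, stacking):
    """true_mass = n × ρπd³/6 and true_dose = mass / field area, exactly."""
    p = make_params(nm100, field256, mode=mode, stacking_prob=stacking, n_particles=40)
    _, gt = simulate_deposition(p)
    assert gt.n_particles == int(gt.multiplicity.sum()) == 40
    assert gt.true_mass_ug == gt.n_particles * nm100.mass_ug
    assert gt.true_dose_ug_cm2 == gt.true_mass_ug / field256.field_area_cm2
    # all rendered centers lie on the field
    assert (gt.centers_nm[:, 0] >= 0).all() and (gt.centers_nm[:, 0] <= 2500).all()
    assert (gt.centers_nm[:, 1] >= 0).all() and (gt.centers_nm[:, 1] <= 2500).all()


def test_thousand_particle_mass(nm100):
    """1000 spheres of d = 100 nm, ρ = 3.84 g/cm³ weigh ≈ 1000 × 2.01e-9 µg."""
    field = ImageCalibration(10_000.0, 10_000.0, 1024, 1024)
    _, gt = simulate_deposition(make_params(nm100, field, n_particles=1000))
    assert gt.true_mass_ug == pytest.approx(1000 * 2.0106e-9, rel=1e-3)


def test_zero_particles_blank_field(nm100, field256):
    p = make_params(nm100, field256, n_particles=0, noise_sd=0.0)
    img, gt = simulate_deposition(p)
    assert gt.true_dose_ug_cm2 == 0.0
    assert (img.intensities == p.background_level).all()


def test_subunity_expected_count_warns_and_empties(nm100, field256):
    tiny = 0.1 * nm100.mass_ug / field256.field_area_cm2  # expected count 0.1
    p = DepositionParams(particle=nm100, target_dose_ug_cm2=tiny, field=field256, seed=0)
    with pytest.warns(UserWarning, match="empty field"):
        _, gt = simulate_deposition(p)
    assert gt.n_particles == 0


def test_multiplicities_one_without_stacking(nm100, field256):
    _, gt = simulate_deposition(make_params(nm100, field256, n_particles=50))
    assert (gt.multiplicity == 1).all()
    assert len(gt.centers_nm) == 50


def test_stacking_reduces_rendered_centers(nm100, field256):
    _, gt = simulate_deposition(
        make_params(nm100, field256, n_particles=50, stacking_prob=0.6, seed=3)
    )
    assert gt.n_particles == 50
    assert len(gt.centers_nm) < 50
    assert gt.multiplicity.max() > 1


def test_subpixel_particle_rejected(nm101, field256):
    # 6.5 nm particle on a ~9.8 nm pitch grid cannot be rendered
    with pytest.raises(ValueError, match="finer calibration"):
        simulate_deposition(make_params(nm101, field256, n_particles=5))


def test_pixelated_area_close_to_disk_area(nm100):
    """At low coverage without stacking, mean rendered area per particle is
    within 10% of the ideal projected disk π d²/4 (pixelation bias bound)."""
    field = ImageCalibration(1250.0, 1250.0, 128, 128)
    total_px_area_nm2 = 0.0
    total_particles = 0
    for seed in range(100):
        p = DepositionParams(
            particle=nm100, n_particles=3, field=field, noise_sd=0.0, seed=seed
        )
        img, gt = simulate_deposition(p)
        mask = img.intensities > p.background_level
        total_px_area_nm2 += mask.sum() * field.pixel_area_nm2
        total_particles += gt.n_particles
    per_particle = total_px_area_nm2 / total_particles
    ideal = disk_area_nm2(nm100.primary_diameter_nm)
    assert abs(per_particle - ideal) / ideal <= 0.10


def _median_nn_nm(centers):
    tree = cKDTree(centers)
    dist, _ = tree.query(centers, k=2)
    return float(np.median(dist[:, 1]))


def test_clustering_shrinks_nearest_neighbor_distance(nm100):
    """Thomas-process fields have markedly closer neighbours than uniform
    fields of the same intensity; with one particle per cluster the two
    processes coincide in distribution."""
    field = ImageCalibration(10_000.0, 10_000.0, 1024, 1024)
    n = 300
    nn_homog, nn_clustered, nn_degenerate = [], [], []
    for seed in range(10):
        _, gt_h = simulate_deposition(
            DepositionParams(particle=nm100, n_particles=n, field=field, seed=seed)
        )
        _, gt_c = simulate_deposition(
            DepositionParams(
                particle=nm100, n_particles=n, field=field, mode="clustered",
                mean_cluster_size=20.0, cluster_radius_nm=150.0, seed=seed,
            )
        )
        _, gt_d = simulate_deposition(
            DepositionParams(
                particle=nm100, n_particles=n, field=field, mode="clustered",
                mean_cluster_size=1.0, cluster_radius_nm=5000.0, seed=seed,
            )
        )
        nn_homog.append(_median_nn_nm(gt_h.centers_nm))
        nn_clustered.append(_median_nn_nm(gt_c.centers_nm))
        nn_degenerate.append(_median_nn_nm(gt_d.centers_nm))
    assert np.median(nn_clustered) < 0.5 * np.median(nn_homog)
    assert np.median(nn_degenerate) == pytest.approx(np.median(nn_homog), rel=0.2)


def test_endpoint_readouts_noiseless_exact():
    r = simulate_endpoint_readouts(
        true_viability=0.8, true_passage=0.5, noise_sd=0.0, n_replicates=2
    )
    assert r.sample_signals == pytest.approx(50.0 + 1000.0 * 0.8)
    assert r.control_signals == pytest.approx(1050.0)
    # half the mass-balance ceiling: C_Bl = 0.5 × C0 V_Ap / V_Bl
    assert r.basolateral_concentrations == pytest.approx(0.5 * 0.4 * 0.5 / 1.5)


def test_endpoint_readouts_respect_mass_balance():
    for seed in range(50):
        r = simulate_endpoint_readouts(
            true_viability=1.0, true_passage=0.99, noise_sd=40.0, seed=seed
        )
        lhs = r.basolateral_concentrations * r.basolateral_volume_ml
        assert (lhs <= r.c0 * r.apical_volume_ml + 1e-12).all()


def test_endpoint_readouts_deterministic():
    a = simulate_endpoint_readouts(0.7, 0.2, noise_sd=15.0, seed=11)
    b = simulate_endpoint_readouts(0.7, 0.2, noise_sd=15.0, seed=11)
    assert np.array_equal(a.sample_signals, b.sample_signals)
    assert np.array_equal(a.basolateral_concentrations, b.basolateral_concentrations)


def test_params_validation(nm100, field256):
    with pytest.raises(ValueError, match="exactly one"):
        DepositionParams(particle=nm100, field=field256)
    with pytest.raises(ValueError, match="stacking_prob"):
        DepositionParams(particle=nm100, n_particles=1, field=field256, stacking_prob=1.5)
    with pytest.raises(ValueError, match="particle_level"):
        DepositionParams(
            particle=nm100, n_particles=1, field=field256,
            background_level=200, particle_level=100,
        )
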