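"""Synthetic cucumber generator: mass model, rendering, dataset assembly."""

import dataclasses

import numpy as np
import pytest
from skimage import measure

from massgrader.grading_rules import assign_grade
from massgrader.synthetic_data import (
    DatasetManifest,
    GeneratorConfig,
    RadiusProfile,
    compute_mass,
    generate_dataset,
    render_topview,
    sample_geometry,
    silhouette_mask,
)

from conftest import straight_geometry


# ---------------------------------------------------------------------------
# mass model: solid-of-revolution volume against closed forms


@pytest.mark.parametrize(
    "kind,exponent,closed_form",
    [
        # cylinder: V = pi r^2 L
        ("sine", 0.0, lambda r, L: np.pi * r**2 * L),
        # cone: V = pi r^2 L / 3
        ("linear", 0.0, lambda r, L: np.pi * r**2 * L / 3.0),
        # ellipsoid of revolution, semi-axes (L/2, r): V = 2/3 pi r^2 L
        ("ellipse", 0.0, lambda r, L: 2.0 / 3.0 * np.pi * r**2 * L),
    ],
)
def test_volume_matches_closed_form(kind, exponent, closed_form):
    r, length, rho = 15.0, 250.0, 0.00095
    geom = straight_geometry(r_max=r, length=length, kind=kind, exponent=exponent)
    mass = compute_mass(geom, density=rho, noise_sd=0.0)
    assert mass == pytest.approx(rho * closed_form(r, length), rel=5e-3)


def test_cylinder_mass_value():
    geom = straight_geometry(r_max=15.0, length=250.0, kind="sine", exponent=0.0)
    assert compute_mass(geom, 0.00095, 0.0) == pytest.approx(167.9, abs=0.5)


def test_mass_noise_free_is_repeatable_and_linear_in_density():
    geom = straight_geometry()
    m1 = compute_mass(geom, 0.00095, 0.0)
    m2 = compute_mass(geom, 0.00095, 0.0)
    assert m1 == m2
    assert compute_mass(geom, 0.00095 / 2, 0.0) == pytest.approx(m1 / 2, rel=1e-12)


def test_mass_noise_deterministic_in_seed():
    geom = straight_geometry()
    assert compute_mass(geom, 0.00095, 1.0, rng_seed=42) == compute_mass(
        geom, 0.00095, 1.0, rng_seed=42
    )
    assert compute_mass(geom, 0.00095, 1.0, rng_seed=42) != compute_mass(
        geom, 0.00095, 1.0, rng_seed=43
    )


def test_mass_monotone_in_radius_scale():
    geom = straight_geometry(r_max=12.0)
    base = compute_mass(geom, 0.00095, 0.0)
    for k in (1.1, 1.5, 2.0):
        scaled = dataclasses.replace(
            geom, radius_profile=RadiusProfile(12.0 * k, "sine", 0.25)
        )
        bigger = compute_mass(scaled, 0.00095, 0.0)
        assert bigger > base
        base = bigger


def test_degenerate_geometry_rejected():
    geom = straight_geometry()
    with pytest.raises(ValueError):
        dataclasses.replace(geom, length=0.0)
    with pytest.raises(ValueError):
        compute_mass(geom, density=-1.0)


# ---------------------------------------------------------------------------
# geometry sampling


def test_sample_geometry_deterministic(desk_config):
    g1 = sample_geometry(77, desk_config)
    g2 = sample_geometry(77, desk_config)
    assert g1 == g2


def test_sample_geometry_straight_when_curvature_range_degenerate():
    cfg = GeneratorConfig.desk(curvature_range=(0.0, 0.0))
    geom = sample_geometry(5, cfg)
    assert geom.curvature_amplitude == 0.0
    ys = [p[1] for p in geom.spine_control_points]
    assert max(abs(y) for y in ys) < 1e-9


def test_invalid_range_is_configuration_error():
    with pytest.raises(ValueError):
        GeneratorConfig(length_range=(300.0, 200.0))


def test_induced_masses_span_grading_interval(desk_config):
    masses = []
    for seed in range(1000):
        geom = sample_geometry(seed, desk_config)
        masses.append(
            compute_mass(geom, desk_config.density, desk_config.noise_sd, seed + 1)
        )
    masses = np.asarray(masses)
    inside = np.mean((masses >= 95.0) & (masses <= 248.0))
    assert inside >= 0.99
    # the interval is actually exercised, not just a narrow band inside it
    assert masses.min() < 120 and masses.max() > 220


# ---------------------------------------------------------------------------
# rendering


def test_render_background_matches_tray_base(desk_config):
    geom = sample_geometry(3, desk_config)
    img = render_topview(geom, 96, rng_seed=4, mm_per_px=desk_config.mm_per_px)
    mask = silhouette_mask(geom, 96, rng_seed=4, mm_per_px=desk_config.mm_per_px)
    bg = img[~mask]
    from massgrader.synthetic_data import TrayStyle

    base = np.array(TrayStyle().base_rgb)
    assert np.all(np.abs(bg.mean(axis=0) - base) <= 2.0)


def test_render_deterministic_and_hue_independent_silhouette(desk_config):
    geom = sample_geometry(8, desk_config)
    img1 = render_topview(geom, 96, rng_seed=9, mm_per_px=desk_config.mm_per_px)
    img2 = render_topview(geom, 96, rng_seed=9, mm_per_px=desk_config.mm_per_px)
    assert np.array_equal(img1, img2)
    recolored = dataclasses.replace(geom, hue_seed=geom.hue_seed + 1)
    m1 = silhouette_mask(geom, 96, rng_seed=9, mm_per_px=desk_config.mm_per_px)
    m2 = silhouette_mask(recolored, 96, rng_seed=9, mm_per_px=desk_config.mm_per_px)
    assert np.array_equal(m1, m2)


def test_render_body_single_connected_component(desk_config):
    geom = sample_geometry(21, desk_config)
    mask = silhouette_mask(geom, 96, rng_seed=2, mm_per_px=desk_config.mm_per_px)
    labels = measure.label(mask)
    assert labels.max() == 1


def test_render_smooth_when_texture_disabled(desk_config):
    geom = sample_geometry(13, desk_config)
    plain = dataclasses.replace(geom, has_flower=False, spine_density=0.0)
    img = render_topview(plain, 96, rng_seed=6, mm_per_px=desk_config.mm_per_px)
    speckled = dataclasses.replace(geom, has_flower=False, spine_density=3.0)
    img_s = render_topview(speckled, 96, rng_seed=6, mm_per_px=desk_config.mm_per_px)
    mask = silhouette_mask(geom, 96, rng_seed=6, mm_per_px=desk_config.mm_per_px)
    # speckles add bright, high-variance pixels inside the body
    assert img_s[mask].astype(float).var() > img[mask].astype(float).var()


def test_render_rejects_oversized_geometry(desk_config):
    geom = sample_geometry(3, desk_config)
    with pytest.raises(ValueError, match="margin"):
        render_topview(geom, 96, rng_seed=1, mm_per_px=desk_config.mm_per_px / 4)


# ---------------------------------------------------------------------------
# dataset generation


def test_tiny_dataset_counts_and_consistency(tiny_dataset):
    assert tiny_dataset.grade_counts() == {1: 10, 2: 10, 3: 10}
    for rec in tiny_dataset.records:
        assert assign_grade(rec.mass_g) == rec.grade
        assert (tiny_dataset.root / rec.filename).exists()
    names = [r.filename for r in tiny_dataset.records]
    assert len(set(names)) == len(names)


def test_one_per_grade(tmp_path, desk_config):
    manifest = generate_dataset(3, (1, 1, 1), tmp_path, seed=4, gen_config=desk_config)
    assert manifest.grade_counts() == {1: 1, 2: 1, 3: 1}
    assert len(list(tmp_path.glob("*.png"))) == 3


def test_manifest_regeneration_is_byte_identical(tmp_path, desk_config):
    a = tmp_path / "a"
    b = tmp_path / "b"
    generate_dataset(6, (2, 2, 2), a, seed=9, gen_config=desk_config)
    generate_dataset(6, (2, 2, 2), b, seed=9, gen_config=desk_config)
    assert (a / "manifest.csv").read_bytes() == (b / "manifest.csv").read_bytes()


def test_grade_targets_must_sum(tmp_path, desk_config):
    with pytest.raises(ValueError):
        generate_dataset(5, (1, 1, 1), tmp_path, seed=0, gen_config=desk_config)


def test_manifest_roundtrip(tmp_path, desk_config):
    manifest = generate_dataset(3, (1, 1, 1), tmp_path, seed=2, gen_config=desk_config)
    loaded = DatasetManifest.load(tmp_path / "manifest.csv")
    assert [r.filename for r in loaded.records] == [
        r.filename for r in manifest.records
    ]
    assert loaded.masses() == pytest.approx(manifest.masses(), abs=1e-3)
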