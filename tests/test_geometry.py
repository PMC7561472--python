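"""Surface extraction, domain classification and descriptor oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import blastomorph as bm
from blastomorph.geometry import CONTACT, EXPOSED, JUNCTIONAL

from conftest import (
    as_embryo,
    make_ball_chain_labels,
    make_ball_labels,
    make_two_ball_labels,
)

SPHERE_AREA_20 = 4 * np.pi * 20.0**2  # ≈ 5026.5 µm²


# ---------------------------------------------------------------------------
# surfaces and shape descriptors
# ---------------------------------------------------------------------------
@pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (2.0, 1.0, 1.0)])
def test_ball_mesh_area_matches_analytic(spacing):
    labels = make_ball_labels(20.0, spacing)
    mesh = bm.extract_surfaces(as_embryo(labels, spacing))[1]
    assert mesh.area == pytest.approx(SPHERE_AREA_20, rel=0.05)


def test_ball_shape_descriptors():
    labels = make_ball_labels(20.0)
    mesh = bm.extract_surfaces(as_embryo(labels))[1]
    d = bm.shape_descriptors(labels == 1, (1, 1, 1), mesh.area)
    assert 0.95 <= d["sphericity"] <= 1.05
    assert d["oblateness"] < 0.05
    assert d["prolateness"] < 0.05
    assert d["volume"] == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.01)


def _ellipsoid_labels(a, b, c):
    axes = [np.arange(-(m + 3), m + 4, 1.0) for m in (a, b, c)]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    return (((Z / a) ** 2 + (Y / b) ** 2 + (X / c) ** 2) <= 1).astype(np.int16)


@pytest.mark.parametrize(
    "axes, prolateness, oblateness",
    [((20, 10, 10), 0.5, 0.0), ((20, 20, 10), 0.0, 0.5)],
)
def test_ellipsoid_descriptors_recover_axes(axes, prolateness, oblateness):
    labels = _ellipsoid_labels(*axes)
    mesh = bm.extract_surfaces(as_embryo(labels))[1]
    d = bm.shape_descriptors(labels == 1, (1, 1, 1), mesh.area)
    assert d["prolateness"] == pytest.approx(prolateness, abs=0.05)
    assert d["oblateness"] == pytest.approx(oblateness, abs=0.05)


def test_two_cell_cube_split_areas():
    """A 20 µm cube split by a plane: each half has 5 outer half/full faces
    plus the shared face; analytic area = 2*(10*20) + 2*(10*20) + 2*(20*20)."""
    labels = np.zeros((26, 26, 26), dtype=np.int16)
    labels[3:23, 3:23, 3:13] = 1
    labels[3:23, 3:23, 13:23] = 2
    emb = as_embryo(labels)
    # sharp-edged solids are meshed unsmoothed (smoothing rounds corners)
    meshes = bm.extract_surfaces(emb, smoothing_um=0.0)
    analytic = 2 * (10 * 20) + 2 * (10 * 20) + 2 * (20 * 20)
    for cid in (1, 2):
        assert meshes[cid].area == pytest.approx(analytic, rel=0.05)


def test_tiny_cell_skipped_with_warning():
    labels = make_ball_labels(10.0)
    labels[0, 0, 0] = 2  # a one-voxel "cell"
    with pytest.warns(UserWarning, match="cell 2"):
        meshes = bm.extract_surfaces(as_embryo(labels))
    assert set(meshes) == {1}


def test_resolution_convergence_of_descriptors():
    """Descriptors at 0.5 µm and 1 µm sampling differ by < 5%."""
    vals = {}
    for s in (1.0, 0.5):
        labels = _scaled_ellipsoid(14, 10, 8, s)
        emb = as_embryo(labels, (s, s, s))
        mesh = bm.extract_surfaces(emb)[1]
        vals[s] = bm.shape_descriptors(labels == 1, (s, s, s), mesh.area)
    for key in ("volume", "total_area", "sphericity"):
        assert vals[0.5][key] == pytest.approx(vals[1.0][key], rel=0.05)


def _scaled_ellipsoid(a, b, c, s):
    axes = [np.arange(-(m + 3), m + 3 + s, s) for m in (a, b, c)]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    return (((Z / a) ** 2 + (Y / b) ** 2 + (X / c) ** 2) <= 1).astype(np.int16)


# ---------------------------------------------------------------------------
# domain classification
# ---------------------------------------------------------------------------
def test_isolated_cell_is_all_exposed():
    labels = make_ball_labels(12.0)
    emb = as_embryo(labels)
    dm = bm.classify_domains(bm.extract_surfaces(emb), emb)
    pos = bm.position_descriptors(dm[1])
    assert pos["prop_exposed"] == 1.0
    assert pos["contact_area"] == 0.0
    assert np.isnan(pos["aj_ratio"])


def test_two_ball_contact_matches_spherical_cap():
    R, d = 16.0, 27.2
    labels = make_two_ball_labels(R, d)
    emb = as_embryo(labels)
    surfaces = bm.extract_surfaces(emb)
    dm = bm.classify_domains(surfaces, emb, bm.DomainParams(1.0, 0.0))
    cap = 2 * np.pi * R * (R - d / 2)
    c1 = dm[1].domain_area(CONTACT)
    c2 = dm[2].domain_area(CONTACT)
    assert c1 == pytest.approx(cap, rel=0.10)
    assert c2 == pytest.approx(cap, rel=0.10)
    # symmetry of identical balls
    assert abs(c1 - c2) / c1 < 0.02
    # prop_contact against the cap/total oracle
    pos = bm.position_descriptors(dm[1])
    total_oracle = 4 * np.pi * R**2 - cap + np.pi * (R**2 - (d / 2) ** 2)
    assert pos["prop_contact"] == pytest.approx(cap / total_oracle, rel=0.10)
    # junctional band girdles the contact rim once enabled
    dmw = bm.classify_domains(surfaces, emb, bm.DomainParams(1.0, 1.0))
    assert dmw[1].domain_area(JUNCTIONAL) > 0
    assert dmw[1].neighbour_id[dmw[1].face_domain == CONTACT].max() == 2


def test_zero_junction_width_disables_band(embryo8):
    embryo, _, _ = embryo8
    dm = bm.classify_domains(bm.extract_surfaces(embryo), embryo, bm.DomainParams(1.0, 0.0))
    for _, cell in dm:
        pos = bm.position_descriptors(cell)
        assert pos["junctional_area"] == 0.0
        assert pos["prop_exposed"] + pos["prop_contact"] == pytest.approx(1.0, abs=1e-9)


def test_area_conservation_and_proportion_sum(embryo8):
    embryo, _, _ = embryo8
    dm = bm.classify_domains(bm.extract_surfaces(embryo), embryo)
    for _, cell in dm:
        pos = bm.position_descriptors(cell)
        total = pos["exposed_area"] + pos["junctional_area"] + pos["contact_area"]
        assert total == pytest.approx(pos["total_area"], rel=1e-12)
        psum = pos["prop_exposed"] + pos["prop_junctional"] + pos["prop_contact"]
        assert psum == pytest.approx(1.0, abs=1e-9)


def test_contact_monotone_in_delta_and_junction_monotone_in_width():
    labels = make_two_ball_labels()
    emb = as_embryo(labels)
    surfaces = bm.extract_surfaces(emb)
    contact_areas = []
    for delta in (0.5, 1.0, 2.0, 4.0):
        dm = bm.classify_domains(surfaces, emb, bm.DomainParams(delta, 0.0))
        contact_areas.append(dm[1].domain_area(CONTACT))
    assert all(a <= b + 1e-9 for a, b in zip(contact_areas, contact_areas[1:]))
    junction_areas = []
    for w in (0.0, 1.0, 2.0, 4.0):
        dm = bm.classify_domains(surfaces, emb, bm.DomainParams(1.0, w))
        junction_areas.append(dm[1].domain_area(JUNCTIONAL))
    assert all(a <= b + 1e-9 for a, b in zip(junction_areas, junction_areas[1:]))


def test_domed_cap_has_larger_aj_ratio_than_flat():
    """Two constructions differing only in apical-cap curvature share the
    same junction rim; the protruding (domed) cap must score a larger
    A/J ratio."""
    aj = {}
    for domed in (False, True):
        labels = _capped_cell_labels(domed)
        emb = as_embryo(labels)
        dm = bm.classify_domains(bm.extract_surfaces(emb), emb, bm.DomainParams(1.0, 1.5))
        aj[domed] = bm.position_descriptors(dm[2])["aj_ratio"]
    assert aj[True] > aj[False]


def _capped_cell_labels(domed, R=10.0):
    shape = (40, 34, 34)
    labels = np.zeros(shape, dtype=np.int16)
    labels[4:16, 2:32, 2:32] = 1  # base slab cell
    Z, Y, X = np.indices(shape, dtype=float)
    cyl = (np.sqrt((Y - 16) ** 2 + (X - 16) ** 2) <= R) & (Z >= 16) & (Z < 20)
    labels[cyl] = 2
    if domed:
        dome = (Z - 20) ** 2 + (Y - 16) ** 2 + (X - 16) ** 2 <= R**2
        labels[dome & (Z >= 20)] = 2
    return labels


# ---------------------------------------------------------------------------
# voxel-face oracle
# ---------------------------------------------------------------------------
def test_oracle_single_ball_all_exposed():
    df = bm.voxel_face_domains(make_ball_labels(10.0))
    assert df.loc[1, "prop_exposed"] == 1.0
    assert df.loc[1, "contact_area"] == 0.0


def test_oracle_partition_on_synthetic_embryo(embryo8):
    embryo, _, _ = embryo8
    df = bm.voxel_face_domains(embryo.cell_labels, embryo.voxel_spacing, 1.0)
    assert np.allclose(df["exposed_area"] + df["contact_area"], df["total_area"])
    assert (df["total_area"] > 0).all()


def test_mesh_agrees_with_voxel_face_oracle(embryo8):
    """Mesh domain proportions track the brute-force oracle within 15%."""
    embryo, _, _ = embryo8
    dm = bm.classify_domains(
        bm.extract_surfaces(embryo), embryo, bm.DomainParams(1.0, 0.0)
    )
    oracle = bm.voxel_face_domains(embryo.cell_labels, embryo.voxel_spacing, 1.0)
    for cid, cell in dm:
        mesh_p = cell.domain_area(EXPOSED) / cell.total_area
        assert mesh_p == pytest.approx(oracle.loc[cid, "prop_exposed"], rel=0.15)


def test_mesh_and_oracle_rank_cells_identically():
    """On cells with distinct exposures the two routes give the same order."""
    labels = make_ball_chain_labels()
    emb = as_embryo(labels)
    dm = bm.classify_domains(bm.extract_surfaces(emb), emb, bm.DomainParams(1.0, 0.0))
    oracle = bm.voxel_face_domains(labels, (1, 1, 1), 1.0)
    cids = sorted(dm.cells)
    mesh_p = [dm[c].domain_area(EXPOSED) / dm[c].total_area for c in cids]
    oracle_p = [oracle.loc[c, "prop_exposed"] for c in cids]
    assert len(set(np.round(oracle_p, 3))) == len(cids)  # exposures distinct
    assert np.array_equal(np.argsort(mesh_p), np.argsort(oracle_p))
    assert spearmanr(mesh_p, oracle_p)[0] == pytest.approx(1.0)


@settings(deadline=None, max_examples=10)
@given(seed=st.integers(0, 10_000))
def test_oracle_partition_property_on_random_blobs(seed):
    """Exposed + contact always equals total area, for any label geometry."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 4, size=(12, 12, 12)).astype(np.int16)
    df = bm.voxel_face_domains(labels, (1.0, 0.7, 0.7), contact_distance=1.0)
    assert np.allclose(df["exposed_area"] + df["contact_area"], df["total_area"])
    assert (df["prop_exposed"].dropna() <= 1.0).all()
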