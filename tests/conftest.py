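import numpy as np
import pytest

import blastomorph as bm


def make_ball_labels(radius=20.0, spacing=(1.0, 1.0, 1.0), margin=4.0):
    """Digital ball of given physical radius, label 1."""
    sp = np.asarray(spacing, float)
    axes = [np.arange(-(radius + margin), radius + margin + s, s) for s in sp]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    return ((Z**2 + Y**2 + X**2) <= radius**2).astype(np.int16)


def make_two_ball_labels(radius=16.0, distance=27.2, spacing=(1.0, 1.0, 1.0)):
    """Two overlapping digital balls along x, labels 1 and 2 (nearest-centre)."""
    sp = np.asarray(spacing, float)
    m = radius + 3
    zax = np.arange(-m, m + sp[0], sp[0])
    yax = np.arange(-m, m + sp[1], sp[1])
    xax = np.arange(-m, distance + m + sp[2], sp[2])
    Z, Y, X = np.meshgrid(zax, yax, xax, indexing="ij")
    d1 = Z**2 + Y**2 + X**2
    d2 = Z**2 + Y**2 + (X - distance) ** 2
    inside = (d1 <= radius**2) | (d2 <= radius**2)
    return np.where(inside, np.where(d1 <= d2, 1, 2), 0).astype(np.int16)


def make_ball_chain_labels(radius=10.0, centres_x=(0.0, 16.0, 32.0, 51.0)):
    """Chain of balls with distinct overlap depths -> well-separated exposures."""
    m = radius + 3
    zax = np.arange(-m, m + 1.0)
    xax = np.arange(-m, max(centres_x) + m + 1.0)
    Z, Y, X = np.meshgrid(zax, zax, xax, indexing="ij")
    dists = np.stack([Z**2 + Y**2 + (X - cx) ** 2 for cx in centres_x])
    inside = (dists <= radius**2).any(axis=0)
    nearest = dists.argmin(axis=0) + 1
    return np.where(inside, nearest, 0).astype(np.int16)


def as_embryo(labels, spacing=(1.0, 1.0, 1.0), channels=None, nuclei=None, eid="test"):
    return bm.LabelledEmbryo(
        cell_labels=labels,
        nucleus_labels=np.zeros_like(labels) if nuclei is None else nuclei,
        channels=channels or {},
        voxel_spacing=spacing,
        embryo_id=eid,
    )


@pytest.fixture(scope="session")
def embryo8():
    """Noiseless compacted 8-cell sphere embryo with ground truth."""
    cfg = bm.SyntheticConfig(n_cells=8, seed=3)
    return bm.generate_embryo(cfg) + (cfg,)


@pytest.fixture(scope="session")
def records8(embryo8):
    embryo, truth, _ = embryo8
    return bm.quantify_embryo(embryo), truth
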