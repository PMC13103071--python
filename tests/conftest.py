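"""Shared fixtures: tiny analytic masks and a small fitted QC model.

Everything is generated programmatically; the "small" cohort runs on 48-voxel
grids so the whole suite stays fast while exercising the same code paths as
full-size data.
"""

from __future__ import annotations

import numpy as np
import pytest

import maskqc as mq
from maskqc.features import extract_features

SMALL_MODES = ((15.0, 13.0, 11.0), (17.0, 14.5, 12.0), (14.0, 13.5, 9.5))


def make_mask(shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0), fill=None, identifier="m"):
    """A mask with an explicit foreground slab (defaults to a centered cube)."""
    vox = np.zeros(shape, dtype=bool)
    if fill is None:
        fill = tuple(slice(2, s - 2) for s in shape)
    vox[fill] = True
    return mq.BrainMask(vox, spacing, identifier)


def random_blob_mask(rng, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)):
    """A random connected-ish blob: a few overlapping spheres inside the grid."""
    vox = np.zeros(shape, dtype=bool)
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij", sparse=True)
    n_spheres = rng.integers(1, 4)
    for _ in range(n_spheres):
        center = rng.uniform(4, np.asarray(shape) - 4)
        radius = rng.uniform(2.0, 4.5)
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        vox |= d2 <= radius**2
    if not vox.any():
        vox[tuple(s // 2 for s in shape)] = True
    return mq.BrainMask(vox, spacing, "blob")


@pytest.fixture(scope="session")
def small_recipe():
    return mq.MaskRecipe(shape=(48, 48, 48), semi_axes=SMALL_MODES[0])


@pytest.fixture(scope="session")
def small_cohort(small_recipe):
    """32 clean + 6 corrupt masks on 48-cube grids, with manifest and sources."""
    # no add_blob: the 15 mm HD95 clearance cannot fit on a 48-voxel grid
    masks, manifest, sources = mq.build_cohort(
        32, 6, recipe=small_recipe, seed=5, modes=SMALL_MODES,
        kinds=("erode", "dilate", "punch_holes", "truncate_axial", "translate"),
    )
    return masks, manifest, sources


@pytest.fixture(scope="session")
def small_model(small_cohort):
    """A QC model fitted on the small cohort's clean masks."""
    masks, manifest, _ = small_cohort
    clean = [m for m, c in zip(masks, manifest["category"]) if c == "clean"]
    X = np.stack([extract_features(m).values for m in clean])
    return mq.MaskQC(clustering_runs=40, random_state=5, min_baseline=30).fit(X)


@pytest.fixture(scope="session")
def small_clean_masks(small_cohort):
    masks, manifest, _ = small_cohort
    return [m for m, c in zip(masks, manifest["category"]) if c == "clean"]
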