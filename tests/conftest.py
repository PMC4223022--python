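"""Shared fixtures: small grids, digitized spheres, and the published
per-observer GTV summary tables used as reference inputs."""

import numpy as np
import pytest

from trifuse.volumes import GridSpec, GTVMask


def make_sphere_mask(radius_mm, n=40, spacing=1.0, center=(0.0, 0.0, 0.0)):
    """Digitized sphere on an n^3 grid centered on the world origin."""
    origin = tuple(-(n - 1) * spacing / 2.0 for _ in range(3))
    grid = GridSpec((n,) * 3, (spacing,) * 3, origin)
    ax = origin[0] + np.arange(n) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(
        (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    )
    return GTVMask(data=r <= radius_mm, grid=grid)


@pytest.fixture
def sphere_mask():
    return make_sphere_mask


@pytest.fixture
def rng():
    return np.random.default_rng(20140)


# ---------------------------------------------------------------------------
# Published summary tables (per-observer GTV volumes, ADSC, repeat contours)
# used as fixed reference inputs for the statistics pipeline.
# ---------------------------------------------------------------------------

# Per-observer GTV volumes (cm^3) by patient, dual- vs tri-modality scheme,
# with the printed per-patient COV (2 decimals).
VOLUMES_DUAL = {
    "p1": [19.91, 22.72, 20.47],
    "p2": [14.39, 17.01, 13.94],
    "p3": [2.96, 2.92, 1.82],
}
VOLUMES_TRI = {
    "p1": [17.91, 19.82, 17.69],
    "p2": [12.61, 14.09, 13.27],
    "p3": [1.89, 1.92, 1.64],
}
COV_DUAL_PRINTED = {"p1": 0.07, "p2": 0.11, "p3": 0.25}
COV_TRI_PRINTED = {"p1": 0.06, "p2": 0.06, "p3": 0.08}
MEAN_COV_PRINTED = {"dual": 0.14, "tri": 0.07}

# Per-observer ADSC (cm) with printed mean/SD (2 decimals).
ADSC_DUAL = {
    "p1": [1.77, 1.86, 1.79],
    "p2": [1.58, 1.67, 1.58],
    "p3": [0.95, 0.97, 0.85],
}
ADSC_TRI = {
    "p1": [1.73, 1.77, 1.72],
    "p2": [1.51, 1.56, 1.53],
    "p3": [0.83, 0.84, 0.82],
}
ADSC_PRINTED = {
    ("dual", "p1"): (1.81, 0.05),
    ("dual", "p2"): (1.61, 0.05),
    ("dual", "p3"): (0.92, 0.06),
    ("tri", "p1"): (1.74, 0.03),
    ("tri", "p2"): (1.53, 0.03),
    ("tri", "p3"): (0.83, 0.01),
}

# Intra-observer repeat-contour summaries: mean, SD (cm^3) and printed COV
# per (observer, patient) and scheme.
INTRA = {
    ("o1", "p1"): ((21.52, 1.48, 0.07), (17.15, 0.68, 0.04)),
    ("o1", "p2"): ((14.05, 0.34, 0.02), (12.44, 0.16, 0.01)),
    ("o1", "p3"): ((2.64, 0.29, 0.11), (1.87, 0.02, 0.01)),
    ("o2", "p1"): ((22.52, 1.00, 0.04), (19.76, 0.31, 0.02)),
    ("o2", "p2"): ((16.46, 0.51, 0.03), (14.08, 0.13, 0.01)),
    ("o2", "p3"): ((2.79, 0.12, 0.04), (1.94, 0.02, 0.01)),
    ("o3", "p1"): ((20.28, 0.96, 0.05), (17.55, 0.47, 0.03)),
    ("o3", "p2"): ((14.63, 0.60, 0.04), (13.40, 0.17, 0.01)),
    ("o3", "p3"): ((1.99, 0.16, 0.08), (1.66, 0.02, 0.01)),
}
INTRA_COV_DUAL = [v[0][2] for v in INTRA.values()]
INTRA_COV_TRI = [v[1][2] for v in INTRA.values()]
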