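import numpy as np
import pytest

from rtimagerisk import (
    AnalysisConfig,
    DoseGrid,
    ProtocolSpec,
    StructureSet,
    load_manifest,
)
from rtimagerisk.grids import ROI
from rtimagerisk.synthdata import CohortSpec, generate_cohort


def make_grid(shape=(8, 8, 8), spacing=1.0, value=0.0, origin=None, frame_ref="1.2.3.4.5.1"):
    shape = tuple(shape)
    values = np.full(shape, float(value))
    if origin is None:
        origin = np.zeros(3)
    return DoseGrid(
        origin=np.asarray(origin, float),
        spacing=np.array([spacing] * 3, float),
        values=values,
        frame_ref=frame_ref,
    )


def circle_contour(center, radius, z, n=32):
    theta = 2 * np.pi * np.arange(n) / n
    return np.column_stack([
        center[0] + radius * np.cos(theta),
        center[1] + radius * np.sin(theta),
        np.full(n, float(z)),
    ])


def square_contour(x0, y0, side, z):
    return np.array([
        [x0, y0, z],
        [x0 + side, y0, z],
        [x0 + side, y0 + side, z],
        [x0, y0 + side, z],
    ], dtype=float)


def cylinder_structure(name="Sphere", center=(5.0, 5.0), radius=3.0,
                       z_slices=(2.0, 3.0, 4.0), frame_ref="1.2.3.4.5.1"):
    contours = [circle_contour(center, radius, z) for z in z_slices]
    return StructureSet(rois=[ROI(name=name, contours=contours)], frame_ref=frame_ref)


@pytest.fixture(scope="session")
def breast_cohort(tmp_path_factory):
    """A small seeded synthetic breast cohort shared across tests."""
    out = tmp_path_factory.mktemp("breast_cohort")
    spec = CohortSpec(site="breast", n_patients=6, seed=11)
    manifest = generate_cohort(spec, out)
    return {"spec": spec, "manifest": manifest, "records": load_manifest(manifest)}


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def imaging_only_config():
    return AnalysisConfig(imaging_only=True)


@pytest.fixture
def protocol_5mu():
    return ProtocolSpec(label="5MU", mu_per_fraction=5.0, n_fractions=25)


@pytest.fixture
def protocol_10mu():
    return ProtocolSpec(label="10MU", mu_per_fraction=10.0, n_fractions=25)
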