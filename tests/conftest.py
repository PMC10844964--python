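import numpy as np
import pytest
from shapely.geometry import box

from spatialtme.io_tables import CellRecord, TissueClass
from spatialtme.spatial import TissueGeometry


def make_cell(
    cell_id="c0",
    x=0.0,
    y=0.0,
    sample_id="S0",
    tissue=TissueClass.STROMA,
    intensities=None,
    confidence=0.9,
    area=None,
    phenotype=None,
):
    return CellRecord(
        sample_id=sample_id,
        cell_id=cell_id,
        x_um=x,
        y_um=y,
        tissue_class=tissue,
        intensities=intensities or {},
        confidence=confidence,
        cell_area_um2=area,
        phenotype=phenotype,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disc_geometry():
    """Single circular nest, radius 100 µm, centered in a 1x1 mm frame."""
    return TissueGeometry.from_discs("S0", [(500.0, 500.0, 100.0)], box(0, 0, 1000, 1000))


@pytest.fixture
def halfplane_geometry():
    """Epithelium occupying x < 500 µm of a 1x1 mm frame."""
    return TissueGeometry.from_polygons(
        "S0", [box(0, 0, 500, 1000)], box(0, 0, 1000, 1000)
    )


def random_cells(rng, n, sample_id="S0", extent=(0, 1000), prefix="c"):
    xs = rng.uniform(*extent, n)
    ys = rng.uniform(*extent, n)
    return [
        make_cell(f"{prefix}{i}", xs[i], ys[i], sample_id=sample_id) for i in range(n)
    ]
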