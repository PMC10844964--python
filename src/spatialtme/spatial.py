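"""Spatial statistics relative to the epithelium/tumor-stroma boundary.

Distances are signed: negative inside an epithelium/tumor region,
positive in the stroma.  Densities are cells/mm²; band areas come from a
rasterized Euclidean distance transform of the tissue geometry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box, mapping, shape
from shapely.geometry.base import BaseGeometry

from .io_tables import CellRecord, TissueClass

__all__ = [
    "TissueGeometry",
    "DistanceProfile",
    "NearestDistanceResult",
    "ContactRule",
    "ContactResult",
    "signed_distance",
    "signed_distance_xy",
    "band_areas",
    "density_profile",
    "nearest_distance",
    "count_contacts",
]

# raster label codes
LBL_OUTSIDE, LBL_STROMA, LBL_EPI = 0, 1, 2


class NoBoundaryError(ValueError):
    """Geometry has no epithelium/tumor region, hence no boundary."""


@dataclass
class TissueGeometry:
    """Epithelium/tumor region of one sample, as polygons or a label mask.

    Polygon representation: ``epi`` (union of closed simple polygons, µm
    coordinates) inside a ``frame`` polygon.  Mask representation: integer
    grid with 0=outside, 1=stroma, 2=epithelium/tumor and a µm/px scale.
    """

    sample_id: str
    epi: BaseGeometry | None = None
    frame: Polygon | None = None
    mask: np.ndarray | None = None
    um_per_px: float | None = None
    # optional exact parameterization when the epithelium is a set of
    # disjoint discs (x_um, y_um, radius_um); enables closed-form distances
    discs: tuple[tuple[float, float, float], ...] | None = None
    _band_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.mask is not None:
            if self.um_per_px is None or self.um_per_px <= 0:
                raise ValueError("mask geometry requires positive um_per_px")
        elif self.frame is None:
            raise ValueError("polygon geometry requires a frame polygon")
        if self.epi is not None and not self.epi.is_valid:
            raise ValueError(f"sample {self.sample_id}: invalid epithelium polygon")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_polygons(
        cls,
        sample_id: str,
        epi_polygons: Sequence[Polygon] | BaseGeometry | None,
        frame: Polygon,
    ) -> "TissueGeometry":
        if epi_polygons is None:
            epi = None
        elif isinstance(epi_polygons, BaseGeometry):
            epi = epi_polygons if not epi_polygons.is_empty else None
        else:
            epi = shapely.union_all(list(epi_polygons)) if epi_polygons else None
        return cls(sample_id=sample_id, epi=epi, frame=frame)

    @classmethod
    def from_discs(
        cls,
        sample_id: str,
        discs: Sequence[tuple[float, float, float]],
        frame: Polygon,
        quad_segs: int = 64,
    ) -> "TissueGeometry":
        """Geometry whose epithelium/tumor regions are disjoint discs.

        Polygonal approximations back the generic interfaces; distances
        and band areas use the exact circle parameterization.
        """
        polys = [
            shapely.Point(x, y).buffer(r, quad_segs=quad_segs) for x, y, r in discs
        ]
        epi = shapely.union_all(polys) if polys else None
        return cls(
            sample_id=sample_id,
            epi=epi,
            frame=frame,
            discs=tuple((float(x), float(y), float(r)) for x, y, r in discs),
        )

    @classmethod
    def from_mask(
        cls, sample_id: str, mask: np.ndarray, um_per_px: float
    ) -> "TissueGeometry":
        return cls(sample_id=sample_id, mask=np.asarray(mask), um_per_px=um_per_px)

    # -- basic queries ---------------------------------------------------
    @property
    def is_mask(self) -> bool:
        return self.mask is not None

    @property
    def has_epi(self) -> bool:
        if self.is_mask:
            return bool((self.mask == LBL_EPI).any())
        return self.epi is not None and not self.epi.is_empty and self.epi.area > 0

    def epi_area_mm2(self) -> float:
        if self.is_mask:
            return float((self.mask == LBL_EPI).sum()) * self.um_per_px**2 / 1e6
        if self.discs is not None:
            return float(sum(np.pi * r**2 for _, _, r in self.discs)) / 1e6
        return (self.epi.area if self.epi is not None else 0.0) / 1e6

    def _disc_signed(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Closed-form signed distance to the union of disjoint discs."""
        assert self.discs
        best = np.full(xs.shape, np.inf)
        inside = np.zeros(xs.shape, dtype=bool)
        for cx, cy, r in self.discs:
            rho = np.hypot(xs - cx, ys - cy)
            best = np.minimum(best, np.abs(rho - r))
            inside |= rho < r
        return np.where(inside, -best, best)

    def interface(self) -> BaseGeometry:
        """Epithelium/stroma interface: the epi boundary minus any stretch
        that coincides with the frame border."""
        bnd = self.epi.boundary
        if self.frame is not None:
            stripped = bnd.difference(self.frame.boundary)
            if not stripped.is_empty:
                return stripped
        return bnd

    def stroma_area_mm2(self) -> float:
        if self.is_mask:
            return float((self.mask == LBL_STROMA).sum()) * self.um_per_px**2 / 1e6
        stroma = self.frame if self.epi is None else self.frame.difference(self.epi)
        return stroma.area / 1e6

    def frame_area_mm2(self) -> float:
        return self.epi_area_mm2() + self.stroma_area_mm2()

    # -- rasterization ---------------------------------------------------
    def label_grid(self, resolution: float | None = None) -> tuple[np.ndarray, float]:
        """Label mask (0/1/2) and its µm/px scale.

        Mask geometries return their native grid; polygon geometries are
        rasterized at ``resolution`` µm/px (pixel-center sampling) over
        the frame bounding box, anchored at the frame's (minx, miny).
        """
        if self.is_mask:
            return self.mask, float(self.um_per_px)
        if resolution is None or resolution <= 0:
            raise ValueError("polygon geometry requires a positive raster resolution")
        minx, miny, maxx, maxy = self.frame.bounds
        nx = max(1, int(np.ceil((maxx - minx) / resolution)))
        ny = max(1, int(np.ceil((maxy - miny) / resolution)))
        xs = minx + (np.arange(nx) + 0.5) * resolution
        ys = miny + (np.arange(ny) + 0.5) * resolution
        gx, gy = np.meshgrid(xs, ys)
        labels = np.zeros((ny, nx), dtype=np.uint8)
        frame_prep = self.frame
        shapely.prepare(frame_prep)
        in_frame = shapely.contains_xy(frame_prep, gx.ravel(), gy.ravel()).reshape(
            ny, nx
        )
        labels[in_frame] = LBL_STROMA
        if self.epi is not None and not self.epi.is_empty:
            epi_prep = self.epi
            shapely.prepare(epi_prep)
            in_epi = shapely.contains_xy(epi_prep, gx.ravel(), gy.ravel()).reshape(
                ny, nx
            )
            labels[in_frame & in_epi] = LBL_EPI
        return labels, float(resolution)

    def signed_distance_grid(
        self, resolution: float | None = None
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Per-pixel signed distance (µm) and in-frame mask.

        Distances use a Euclidean distance transform with a half-pixel
        correction so the implicit boundary sits between epithelium and
        stroma pixels rather than on epithelium pixel centers.
        """
        if self.discs is not None and not self.is_mask:
            if not self.discs:
                raise NoBoundaryError(f"sample {self.sample_id}: no boundary")
            scale = float(resolution if resolution else 2.0)
            minx, miny, maxx, maxy = self.frame.bounds
            nx = max(1, int(np.ceil((maxx - minx) / scale)))
            ny = max(1, int(np.ceil((maxy - miny) / scale)))
            xs = minx + (np.arange(nx) + 0.5) * scale
            ys = miny + (np.arange(ny) + 0.5) * scale
            gx, gy = np.meshgrid(xs, ys)
            signed = self._disc_signed(gx, gy)
            rect = abs(self.frame.area - (maxx - minx) * (maxy - miny)) < 1e-6
            if rect:
                in_frame = np.ones((ny, nx), dtype=bool)
            else:
                frame_prep = self.frame
                shapely.prepare(frame_prep)
                in_frame = shapely.contains_xy(
                    frame_prep, gx.ravel(), gy.ravel()
                ).reshape(ny, nx)
            return signed, in_frame, scale

        labels, scale = self.label_grid(resolution)
        if not (labels == LBL_EPI).any():
            raise NoBoundaryError(f"sample {self.sample_id}: no boundary")
        epi = labels == LBL_EPI
        # distances are to the epithelium/stroma interface: stroma pixels
        # measure to the nearest epithelium pixel and vice versa, so frame
        # borders never act as a boundary
        d_out = distance_transform_edt(labels != LBL_EPI) * scale
        d_in = distance_transform_edt(labels != LBL_STROMA) * scale
        half = 0.5 * scale
        signed = np.where(
            epi, -np.maximum(d_in - half, 0.0), np.maximum(d_out - half, 0.0)
        )
        return signed, labels != LBL_OUTSIDE, scale

    # -- serialization ---------------------------------------------------
    def to_geojson(self, path: str | Path) -> None:
        if self.is_mask:
            raise ValueError("mask geometry cannot be written as GeoJSON")
        features = [
            {
                "type": "Feature",
                "properties": {"role": "frame", "sample_id": self.sample_id},
                "geometry": mapping(self.frame),
            }
        ]
        if self.epi is not None:
            props = {"role": "epi_tumor", "sample_id": self.sample_id}
            if self.discs is not None:
                props["discs"] = [list(d) for d in self.discs]
            features.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": mapping(self.epi),
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    def to_mask_file(self, path: str | Path, resolution: float = 2.0) -> None:
        """Write the label mask (0=outside, 1=stroma, 2=epithelium) as TIFF/PNG."""
        import imageio.v3 as iio

        labels, _ = self.label_grid(resolution)
        iio.imwrite(path, labels.astype(np.uint8))

    @classmethod
    def from_mask_file(
        cls, path: str | Path, um_per_px: float, sample_id: str = ""
    ) -> "TissueGeometry":
        """Read an 8/16-bit label mask image (0=outside, 1=stroma, 2=epi)."""
        import imageio.v3 as iio

        mask = np.asarray(iio.imread(path))
        if mask.ndim != 2:
            raise ValueError(f"{path}: expected a single-channel label mask")
        return cls.from_mask(sample_id or Path(path).stem, mask, um_per_px)

    @classmethod
    def from_geojson(cls, path: str | Path, sample_id: str | None = None) -> "TissueGeometry":
        with open(path) as fh:
            data = json.load(fh)
        frame = None
        epi_parts = []
        discs: list[tuple[float, float, float]] | None = None
        sid = sample_id
        for feat in data["features"]:
            geom = shape(feat["geometry"])
            props = feat.get("properties", {})
            role = props.get("role")
            sid = sid or props.get("sample_id")
            if role == "frame":
                frame = geom
            elif role == "epi_tumor":
                epi_parts.append(geom)
                if "discs" in props:
                    discs = [tuple(map(float, d)) for d in props["discs"]]
        if frame is None:
            raise ValueError(f"{path}: no frame feature")
        epi = shapely.union_all(epi_parts) if epi_parts else None
        return cls(
            sample_id=sid or "",
            epi=epi,
            frame=frame,
            discs=tuple(discs) if discs else None,
        )


# ---------------------------------------------------------------------------
# signed distance of cells
# ---------------------------------------------------------------------------

def signed_distance_xy(
    geom: TissueGeometry, xs: np.ndarray, ys: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized signed distance for raw coordinates.

    Returns (signed_um, in_frame, inside_epi) arrays aligned with the
    inputs; ``signed_um`` is NaN outside the frame.
    """
    if not geom.has_epi:
        raise NoBoundaryError(f"sample {geom.sample_id}: no boundary")
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)

    if geom.discs is not None and not geom.is_mask:
        signed = geom._disc_signed(xs, ys)
        pts = shapely.points(xs, ys)
        frame_prep = geom.frame
        shapely.prepare(frame_prep)
        in_frame = shapely.covers(frame_prep, pts)
        inside = signed < 0
        return np.where(in_frame, signed, np.nan), in_frame, inside

    if geom.is_mask:
        grid, in_frame_grid, scale = geom.signed_distance_grid()
        cols = np.clip((xs / scale).astype(int), 0, geom.mask.shape[1] - 1)
        rows = np.clip((ys / scale).astype(int), 0, geom.mask.shape[0] - 1)
        in_frame = in_frame_grid[rows, cols]
        signed = np.where(in_frame, grid[rows, cols], np.nan)
        inside = geom.mask[rows, cols] == LBL_EPI
        return signed, in_frame, inside

    pts = shapely.points(xs, ys)
    boundary = geom.interface()
    dist = shapely.distance(pts, boundary)
    frame_prep = geom.frame
    shapely.prepare(frame_prep)
    in_frame = shapely.covers(frame_prep, pts)
    epi_prep = geom.epi
    shapely.prepare(epi_prep)
    inside = shapely.covers(epi_prep, pts)
    signed = np.where(in_frame, np.where(inside, -dist, dist), np.nan)
    return signed, in_frame, inside


def signed_distance(
    cells: Sequence[CellRecord],
    geom: TissueGeometry,
    resolution: float = 2.0,
) -> dict[str, float]:
    """Signed µm distance of each cell to the epithelium/stroma boundary.

    Negative inside an epithelium/tumor region, positive in stroma; a cell
    exactly on the boundary gets -0.0 (inside wins).  Cells outside the
    sample frame are excluded from the result.  Polygon geometries are
    exact; mask geometries are accurate to raster tolerance.
    """
    if not geom.has_epi:
        raise NoBoundaryError(f"sample {geom.sample_id}: no boundary")
    if not cells:
        return {}
    xs = np.array([c.x_um for c in cells])
    ys = np.array([c.y_um for c in cells])
    signed, in_frame, _ = signed_distance_xy(geom, xs, ys)
    return {
        c.cell_id: float(d) for c, d, ok in zip(cells, signed, in_frame) if ok
    }


# ---------------------------------------------------------------------------
# band areas and density profiles
# ---------------------------------------------------------------------------

def band_areas(
    geom: TissueGeometry,
    bin_edges: Sequence[float],
    resolution: float = 2.0,
) -> np.ndarray:
    """Area (mm²) of each signed-distance band inside the sample frame.

    Computed by rasterizing the geometry at ``resolution`` µm/px and
    applying an exact Euclidean distance transform inside and outside the
    epithelium/tumor region.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be sorted and strictly increasing")
    min_width = float(np.min(np.diff(edges)))
    if resolution > min_width / 4.0:
        raise ValueError(
            f"raster resolution {resolution} µm/px coarser than bin width/4 "
            f"({min_width / 4.0} µm)"
        )
    key = (tuple(np.round(edges, 9)), float(resolution))
    cached = geom._band_cache.get(key)
    if cached is not None:
        return cached.copy()
    signed, in_frame, scale = geom.signed_distance_grid(resolution)
    values = signed[in_frame]
    counts, _ = np.histogram(values, bins=edges)
    areas = counts * (scale**2) / 1e6
    geom._band_cache[key] = areas
    return areas.copy()


@dataclass
class DistanceProfile:
    """Binned signed-distance density profile, aggregated across samples.

    ``density`` is the pooled estimate (total counts over total band
    area); ``mean_density``/``se`` are the unweighted across-sample mean
    and standard error.  Bins with zero band area in a sample are treated
    as missing for that sample.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    band_area_mm2: np.ndarray
    density: np.ndarray
    n_samples: int
    se: np.ndarray
    mean_density: np.ndarray
    per_sample_density: Mapping[str, np.ndarray] = field(default_factory=dict)
    per_sample_counts: Mapping[str, np.ndarray] = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_um": self.bin_edges[:-1],
                "bin_right_um": self.bin_edges[1:],
                "bin_center_um": self.bin_centers,
                "count": self.counts,
                "band_area_mm2": self.band_area_mm2,
                "density_per_mm2": self.density,
                "mean_density_per_mm2": self.mean_density,
                "se_per_mm2": self.se,
                "n_samples": self.n_samples,
            }
        )


def density_profile(
    cells_of_subset: Sequence[CellRecord],
    geom_by_sample: Mapping[str, TissueGeometry],
    bin_width: float = 25.0,
    distance_range: tuple[float, float] = (-500.0, 500.0),
    resolution: float = 2.0,
) -> DistanceProfile:
    """Cell density (cells/mm²) per signed-distance bin, mean ± SE across samples.

    Every sample present in ``geom_by_sample`` contributes, including
    samples with zero cells of the subset.  Cells of samples without a
    geometry are ignored.
    """
    if not geom_by_sample:
        raise ValueError("no samples")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = distance_range
    n_bins = int(round((hi - lo) / bin_width))
    if not np.isclose(lo + n_bins * bin_width, hi):
        raise ValueError("distance_range must be an integer number of bin widths")
    edges = lo + np.arange(n_bins + 1) * bin_width

    cells_by_sample: dict[str, list[CellRecord]] = {sid: [] for sid in geom_by_sample}
    for c in cells_of_subset:
        if c.sample_id in cells_by_sample:
            cells_by_sample[c.sample_id].append(c)

    per_density: dict[str, np.ndarray] = {}
    per_counts: dict[str, np.ndarray] = {}
    total_counts = np.zeros(n_bins, dtype=int)
    total_area = np.zeros(n_bins)
    for sid, geom in geom_by_sample.items():
        areas = band_areas(geom, edges, resolution=resolution)
        dists = signed_distance(cells_by_sample[sid], geom, resolution=resolution)
        counts, _ = np.histogram(list(dists.values()), bins=edges)
        dens = np.where(areas > 0, counts / np.where(areas > 0, areas, 1.0), np.nan)
        per_density[sid] = dens
        per_counts[sid] = counts
        total_counts += counts
        total_area += areas

    stack = np.vstack(list(per_density.values()))
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean_density = np.nanmean(stack, axis=0)
        n_eff = np.sum(~np.isnan(stack), axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(n_bins)
        se = np.where(n_eff > 1, sd / np.sqrt(np.maximum(n_eff, 1)), 0.0)
    pooled = np.where(total_area > 0, total_counts / np.where(total_area > 0, total_area, 1.0), np.nan)
    return DistanceProfile(
        bin_edges=edges,
        counts=total_counts,
        band_area_mm2=total_area,
        density=pooled,
        n_samples=len(geom_by_sample),
        se=np.nan_to_num(se),
        mean_density=mean_density,
        per_sample_density=per_density,
        per_sample_counts=per_counts,
    )


# ---------------------------------------------------------------------------
# nearest distances
# ---------------------------------------------------------------------------

@dataclass
class NearestDistanceResult:
    """Per-cell nearest distance to a reference cell type, plus its mean (MND)."""

    per_cell: Mapping[str, float]
    mnd: float
    n_from: int
    n_to: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": list(self.per_cell), "nearest_um": list(self.per_cell.values())}
        )


def nearest_distance(
    from_cells: Sequence[CellRecord], to_cells: Sequence[CellRecord]
) -> NearestDistanceResult:
    """Euclidean distance from each from-cell to its nearest to-cell.

    A to-cell with a cell_id identical to the from-cell is excluded, so a
    set queried against itself yields nearest non-self distances.
    """
    if not to_cells:
        raise ValueError("no reference cells")
    if not from_cells:
        return NearestDistanceResult({}, float("nan"), 0, len(to_cells))
    to_xy = np.array([[c.x_um, c.y_um] for c in to_cells])
    to_ids = [c.cell_id for c in to_cells]
    from_xy = np.array([[c.x_um, c.y_um] for c in from_cells])
    tree = cKDTree(to_xy)
    k = min(2, len(to_cells))
    dists, idxs = tree.query(from_xy, k=k)
    if k == 1:
        dists = dists[:, None]
        idxs = idxs[:, None]
    per_cell: dict[str, float] = {}
    for i, cell in enumerate(from_cells):
        chosen = None
        for j in range(k):
            if to_ids[idxs[i, j]] != cell.cell_id:
                chosen = dists[i, j]
                break
        if chosen is None:
            # sole candidate shares the id: fall back to full scan
            d = np.hypot(to_xy[:, 0] - cell.x_um, to_xy[:, 1] - cell.y_um)
            valid = [dd for dd, tid in zip(d, to_ids) if tid != cell.cell_id]
            if not valid:
                continue
            chosen = min(valid)
        per_cell[cell.cell_id] = float(chosen)
    mnd = float(np.mean(list(per_cell.values()))) if per_cell else float("nan")
    return NearestDistanceResult(per_cell, mnd, len(from_cells), len(to_cells))


# ---------------------------------------------------------------------------
# cell-cell contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactRule:
    """Centroid+radius contact rule.

    Two cells are in contact iff their centroid distance is at most
    r_ref + r_partner + slack, with r = sqrt(area/π) when a cell area is
    available and ``default_radius_um`` otherwise.
    """

    default_radius_um: float = 5.0
    slack_um: float = 1.0

    def __post_init__(self) -> None:
        if self.slack_um < 0:
            raise ValueError("negative slack")
        if self.default_radius_um <= 0:
            raise ValueError("default radius must be positive")

    def radius(self, cell: CellRecord) -> float:
        if cell.cell_area_um2 is not None:
            return float(np.sqrt(cell.cell_area_um2 / np.pi))
        return self.default_radius_um


@dataclass
class ContactResult:
    """Contact counts per reference cell and aggregate contact fractions."""

    per_reference_cell: Mapping[str, Mapping[str, int]]
    contact_fraction: Mapping[str, float]
    rule: ContactRule

    def total_contacts(self, label: str) -> int:
        return sum(counts.get(label, 0) for counts in self.per_reference_cell.values())

    def to_dataframe(self) -> pd.DataFrame:
        labels = sorted(self.contact_fraction)
        rows = []
        for cid, counts in self.per_reference_cell.items():
            rows.append({"cell_id": cid, **{lb: counts.get(lb, 0) for lb in labels}})
        return pd.DataFrame(rows)


def count_contacts(
    ref_cells: Sequence[CellRecord],
    partner_cells_by_label: Mapping[str, Sequence[CellRecord]],
    rule: ContactRule = ContactRule(),
) -> ContactResult:
    """Count partner cells in contact with each reference cell.

    A partner sharing the reference cell's cell_id (the same physical
    cell appearing in both roles) never counts as its own contact.
    """
    per_ref: dict[str, dict[str, int]] = {c.cell_id: {} for c in ref_cells}
    fractions: dict[str, float] = {}
    if not ref_cells:
        return ContactResult(per_ref, {lb: 0.0 for lb in partner_cells_by_label}, rule)
    ref_xy = np.array([[c.x_um, c.y_um] for c in ref_cells])
    ref_r = np.array([rule.radius(c) for c in ref_cells])
    ref_tree = cKDTree(ref_xy)
    for label, partners in partner_cells_by_label.items():
        touched = np.zeros(len(ref_cells), dtype=bool)
        if len(partners) > 0:
            p_xy = np.array([[c.x_um, c.y_um] for c in partners])
            p_r = np.array([rule.radius(c) for c in partners])
            p_ids = [c.cell_id for c in partners]
            max_reach = ref_r.max() + p_r.max() + rule.slack_um
            pairs = ref_tree.query_ball_point(p_xy, r=max_reach)
            for j, ref_idx in enumerate(pairs):
                if not ref_idx:
                    continue
                ref_idx = np.asarray(ref_idx)
                d = np.hypot(
                    ref_xy[ref_idx, 0] - p_xy[j, 0], ref_xy[ref_idx, 1] - p_xy[j, 1]
                )
                ok = d <= ref_r[ref_idx] + p_r[j] + rule.slack_um
                for i in ref_idx[ok]:
                    if ref_cells[i].cell_id == p_ids[j]:
                        continue
                    counts = per_ref[ref_cells[i].cell_id]
                    counts[label] = counts.get(label, 0) + 1
                    touched[i] = True
        fractions[label] = float(touched.mean())
    return ContactResult(per_ref, fractions, rule)
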