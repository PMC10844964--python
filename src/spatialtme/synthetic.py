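"""Synthetic cohort generation with full ground truth.

Generates tumor-nest geometries, cell point patterns whose intensity
varies with signed distance to the nest boundary (boundary-accumulating
or compartment-uniform), bimodal log-normal marker intensities,
distance-dependent checkpoint status, classifier confidences, and
survival times whose hazard depends on cell density in one distance
band.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .io_tables import CellRecord, SurvivalRecord, TissueClass
from .spatial import DistanceProfile, TissueGeometry, signed_distance_xy

__all__ = [
    "UniformModel",
    "BoundaryExpModel",
    "MarkerModel",
    "CheckpointModel",
    "SurvivalModel",
    "SyntheticConfig",
    "Cohort",
    "generate_geometry",
    "sample_cells",
    "sample_survival",
    "generate_cohort",
    "make_profile",
    "sample_band_profiles",
    "fit_boundary_decay",
]

CIRCLE_SEGMENTS = 64  # quad_segs for disc polygons; boundary error < 0.01 µm at r=500


# ---------------------------------------------------------------------------
# model components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformModel:
    """Spatially uniform intensity within one compartment (or both)."""

    rate_per_mm2: float
    compartment: str = "stroma"  # stroma | epi | both

    @property
    def peak_rate(self) -> float:
        return self.rate_per_mm2

    def rate(self, signed_um: np.ndarray, inside: np.ndarray) -> np.ndarray:
        if self.compartment == "both":
            return np.full(signed_um.shape, self.rate_per_mm2)
        want_inside = self.compartment == "epi"
        return np.where(inside == want_inside, self.rate_per_mm2, 0.0)


@dataclass(frozen=True)
class BoundaryExpModel:
    """Exponential accumulation toward the boundary: rate0 * exp(-|d|/tau)."""

    rate0_per_mm2: float
    tau_um: float
    side: str = "both"  # stroma | tumor | both

    def __post_init__(self) -> None:
        if self.tau_um <= 0:
            raise ValueError("tau must be positive")

    @property
    def peak_rate(self) -> float:
        return self.rate0_per_mm2

    def rate(self, signed_um: np.ndarray, inside: np.ndarray) -> np.ndarray:
        lam = self.rate0_per_mm2 * np.exp(-np.abs(signed_um) / self.tau_um)
        if self.side == "stroma":
            lam = np.where(inside, 0.0, lam)
        elif self.side == "tumor":
            lam = np.where(inside, lam, 0.0)
        return lam


SpatialModel = UniformModel | BoundaryExpModel


@dataclass(frozen=True)
class MarkerModel:
    """Two-component log-normal intensity model on the log10 scale."""

    log10_mean_lo: float = 0.6
    log10_mean_hi: float = 2.2
    log10_sd_lo: float = 0.25
    log10_sd_hi: float = 0.25


@dataclass(frozen=True)
class CheckpointModel:
    """Distance-dependent probability of checkpoint-hi status.

    P(hi | d) = p_far + (p_near - p_far) * exp(-|d|/tau); labels absent
    from ``p_near_by_label`` use ``p_baseline`` at all distances.
    """

    p_near_by_label: Mapping[str, float] = field(default_factory=dict)
    p_far: float = 0.05
    tau_um: float = 75.0
    p_baseline: float = 0.02

    def prob_hi(self, label: str, signed_um: np.ndarray) -> np.ndarray:
        if label not in self.p_near_by_label:
            return np.full(np.shape(signed_um), self.p_baseline)
        p_near = self.p_near_by_label[label]
        return self.p_far + (p_near - self.p_far) * np.exp(
            -np.abs(signed_um) / self.tau_um
        )


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential survival with log-linear effect of the band covariate.

    hazard = h0 * exp(beta * z) with z the standardized band density;
    each patient is independently censored with probability
    ``censoring_rate`` (censoring time uniform on (0, event time)).
    """

    h0: float = 0.02  # events per month
    beta: float = 0.0
    censoring_rate: float = 0.2
    n_patients: int = 40
    band_center_um: float = 75.0

    def __post_init__(self) -> None:
        if self.h0 <= 0:
            raise ValueError("baseline hazard h0 must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")


# marker hi-sets per generated cell label
DEFAULT_MARKERS = ("CK", "CD45", "CD3", "CD68", "CD163", "PD-L1", "PD-1")
LABEL_HI_MARKERS: dict[str, frozenset[str]] = {
    "Tumor": frozenset({"CK"}),
    "Tcell": frozenset({"CD45", "CD3"}),
    "Leukocyte": frozenset({"CD45"}),
    "CD68hiCD163lo": frozenset({"CD45", "CD68"}),
    "CD68hiCD163hi": frozenset({"CD45", "CD68", "CD163"}),
    "CD68loCD163hi": frozenset({"CD45", "CD163"}),
}


def _default_subsets() -> dict[str, SpatialModel]:
    return {
        "Tumor": UniformModel(800.0, "epi"),
        "Tcell": BoundaryExpModel(500.0, 60.0, "both"),
        "Leukocyte": UniformModel(400.0, "stroma"),
        "CD68hiCD163lo": BoundaryExpModel(300.0, 50.0, "both"),
        "CD68hiCD163hi": BoundaryExpModel(200.0, 60.0, "both"),
        "CD68loCD163hi": UniformModel(120.0, "stroma"),
    }


def _default_intensity() -> dict[str, MarkerModel]:
    return {m: MarkerModel() for m in DEFAULT_MARKERS}


def _default_checkpoints() -> dict[str, CheckpointModel]:
    return {
        "PD-L1": CheckpointModel(
            p_near_by_label={
                "Tumor": 0.5,
                "CD68hiCD163lo": 0.6,
                "CD68hiCD163hi": 0.7,
                "Tcell": 0.4,
                "CD68loCD163hi": 0.15,
            }
        ),
        "PD-1": CheckpointModel(
            p_near_by_label={"Tcell": 0.6, "CD68hiCD163hi": 0.2, "CD68hiCD163lo": 0.15}
        ),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Complete recipe for one synthetic cohort."""

    seed: int = 0
    frame_mm: tuple[float, float] = (3.0, 3.0)
    n_nests: int = 3
    nest_radius_um: tuple[float, float] = (150.0, 350.0)
    nest_margin_um: float = 50.0
    subsets: Mapping[str, SpatialModel] = field(default_factory=_default_subsets)
    intensity: Mapping[str, MarkerModel] = field(default_factory=_default_intensity)
    checkpoints: Mapping[str, CheckpointModel] = field(
        default_factory=_default_checkpoints
    )
    confidence_beta: tuple[float, float] = (8.0, 1.5)
    cell_radius_um: tuple[float, float] = (5.0, 0.8)  # mean, sd
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    covariate_label: str = "CD68hiCD163hi"  # label whose band density drives hazard
    band_width_um: float = 25.0


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def generate_geometry(
    cfg: SyntheticConfig, rng: np.random.Generator, sample_id: str = "S000"
) -> TissueGeometry:
    """Place non-overlapping disc nests in the frame by rejection sampling."""
    w_um, h_um = cfg.frame_mm[0] * 1000.0, cfg.frame_mm[1] * 1000.0
    frame = box(0.0, 0.0, w_um, h_um)
    if cfg.n_nests == 0:
        return TissueGeometry.from_polygons(sample_id, None, frame)
    r_lo, r_hi = cfg.nest_radius_um
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < cfg.n_nests:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError(
                f"could not place {cfg.n_nests} nests in 10,000 attempts; "
                "use fewer or smaller nests"
            )
        r = float(rng.uniform(r_lo, r_hi))
        if 2 * (r + cfg.nest_margin_um) > min(w_um, h_um):
            continue
        x = float(rng.uniform(r + cfg.nest_margin_um, w_um - r - cfg.nest_margin_um))
        y = float(rng.uniform(r + cfg.nest_margin_um, h_um - r - cfg.nest_margin_um))
        if all(
            math.hypot(x - px, y - py) > r + pr + cfg.nest_margin_um
            for px, py, pr in placed
        ):
            placed.append((x, y, r))
    return TissueGeometry.from_discs(
        sample_id, placed, frame, quad_segs=CIRCLE_SEGMENTS
    )


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

def _draw_intensity(
    rng: np.random.Generator, model: MarkerModel, hi: np.ndarray
) -> np.ndarray:
    mu = np.where(hi, model.log10_mean_hi, model.log10_mean_lo)
    sd = np.where(hi, model.log10_sd_hi, model.log10_sd_lo)
    return 10 ** rng.normal(mu, sd)


def sample_cells(
    cfg: SyntheticConfig,
    geom: TissueGeometry,
    rng: np.random.Generator,
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Inhomogeneous-Poisson cell sampling by uniform candidates + thinning.

    Returns the emitted cells together with a ground-truth table (one row
    per cell: true label, compartment, signed distance, checkpoint
    status per marker).
    """
    w_um, h_um = cfg.frame_mm[0] * 1000.0, cfg.frame_mm[1] * 1000.0
    frame_area_mm2 = cfg.frame_mm[0] * cfg.frame_mm[1]
    cells: list[CellRecord] = []
    truth_rows: list[dict] = []
    counter = 0
    checkpoint_markers = list(cfg.checkpoints)
    for label in sorted(cfg.subsets):
        model = cfg.subsets[label]
        lam_max = model.peak_rate
        if lam_max <= 0:
            continue
        n_cand = rng.poisson(lam_max * frame_area_mm2)
        if n_cand == 0:
            continue
        xs = rng.uniform(0.0, w_um, n_cand)
        ys = rng.uniform(0.0, h_um, n_cand)
        signed, in_frame, inside = signed_distance_xy(geom, xs, ys)
        lam = np.where(in_frame, model.rate(signed, inside), 0.0)
        keep = rng.uniform(0.0, 1.0, n_cand) < lam / lam_max
        xs, ys, signed, inside = xs[keep], ys[keep], signed[keep], inside[keep]
        n = len(xs)
        if n == 0:
            continue
        hi_set = LABEL_HI_MARKERS.get(label, frozenset())
        ck_hi: dict[str, np.ndarray] = {}
        for marker in checkpoint_markers:
            p = cfg.checkpoints[marker].prob_hi(label, signed)
            ck_hi[marker] = rng.uniform(0.0, 1.0, n) < p
        intensities = {}
        for marker in cfg.intensity:
            if marker in checkpoint_markers:
                hi = ck_hi[marker]
            else:
                hi = np.full(n, marker in hi_set)
            intensities[marker] = _draw_intensity(rng, cfg.intensity[marker], hi)
        conf = rng.beta(*cfg.confidence_beta, n)
        radius = np.clip(rng.normal(*cfg.cell_radius_um, n), 1.0, None)
        area = np.pi * radius**2
        for i in range(n):
            cid = f"{geom.sample_id}_c{counter:06d}"
            counter += 1
            cells.append(
                CellRecord(
                    sample_id=geom.sample_id,
                    cell_id=cid,
                    x_um=float(xs[i]),
                    y_um=float(ys[i]),
                    tissue_class=TissueClass.EPI_TUMOR
                    if inside[i]
                    else TissueClass.STROMA,
                    intensities={m: float(v[i]) for m, v in intensities.items()},
                    confidence=float(conf[i]),
                    phenotype=label,
                    cell_area_um2=float(area[i]),
                )
            )
            row = {
                "sample_id": geom.sample_id,
                "cell_id": cid,
                "true_label": label,
                "true_compartment": "epi" if inside[i] else "stroma",
                "true_signed_um": float(signed[i]),
            }
            for marker in checkpoint_markers:
                row[f"true_{marker}_hi"] = bool(ck_hi[marker][i])
            truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return cells, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def sample_survival(
    cfg: SyntheticConfig,
    band_density_by_patient: Mapping[str, float],
    rng: np.random.Generator,
) -> list[SurvivalRecord]:
    """Exponential survival times with hazard h0 * exp(beta * z).

    z is the standardized band density across patients.  Each patient is
    independently censored with probability ``censoring_rate``; censored
    follow-up is uniform on (0, latent event time).
    """
    model = cfg.survival
    if len(band_density_by_patient) < 2:
        raise ValueError("need at least 2 patients")
    pids = list(band_density_by_patient)
    dens = np.array([band_density_by_patient[p] for p in pids], dtype=float)
    sd = dens.std()
    z = (dens - dens.mean()) / sd if sd > 0 else np.zeros_like(dens)
    hazard = model.h0 * np.exp(model.beta * z)
    latent = rng.exponential(1.0 / hazard)
    censored = rng.uniform(0.0, 1.0, len(pids)) < model.censoring_rate
    obs = np.where(censored, rng.uniform(0.0, 1.0, len(pids)) * latent, latent)
    obs = np.maximum(obs, 1e-6)
    return [
        SurvivalRecord(
            patient_id=pid,
            time=float(t),
            event=not bool(c),
            sample_ids=(pid.replace("P", "S", 1),),
        )
        for pid, t, c in zip(pids, obs, censored)
    ]


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated cohort: per-sample cells + geometry, survival, ground truth."""

    config: SyntheticConfig
    cells_by_sample: dict[str, list[CellRecord]]
    geom_by_sample: dict[str, TissueGeometry]
    survival: list[SurvivalRecord]
    ground_truth: pd.DataFrame
    true_band_density: dict[str, float]

    @property
    def sample_to_patient(self) -> dict[str, str]:
        out = {}
        for rec in self.survival:
            for sid in rec.sample_ids:
                out[sid] = rec.patient_id
        return out

    def all_cells(self) -> list[CellRecord]:
        return [c for cells in self.cells_by_sample.values() for c in cells]


def _true_band_density(
    cfg: SyntheticConfig, truth: pd.DataFrame, geom: TissueGeometry
) -> float:
    """Ground-truth density (cells/mm²) of the covariate label in the hazard band."""
    from .spatial import band_areas

    center = cfg.survival.band_center_um
    half = cfg.band_width_um / 2.0
    edges = [center - half, center + half]
    area = band_areas(geom, edges)[0]
    if area <= 0 or truth.empty:
        return 0.0
    sub = truth[truth["true_label"] == cfg.covariate_label]
    if "true_PD-L1_hi" in sub.columns:
        sub = sub[sub["true_PD-L1_hi"]]
    n = int(
        ((sub["true_signed_um"] > edges[0]) & (sub["true_signed_um"] <= edges[1])).sum()
    )
    return n / area


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Generate a full multi-patient cohort (one sample per patient)."""
    rng = np.random.default_rng(cfg.seed)
    cells_by_sample: dict[str, list[CellRecord]] = {}
    geom_by_sample: dict[str, TissueGeometry] = {}
    truth_frames = []
    band_density: dict[str, float] = {}
    for i in range(cfg.survival.n_patients):
        pid = f"P{i:03d}"
        sid = f"S{i:03d}"
        geom = generate_geometry(cfg, rng, sample_id=sid)
        cells, truth = sample_cells(cfg, geom, rng)
        cells_by_sample[sid] = cells
        geom_by_sample[sid] = geom
        truth_frames.append(truth)
        band_density[pid] = _true_band_density(cfg, truth, geom)
    survival = sample_survival(cfg, band_density, rng)
    ground_truth = (
        pd.concat(truth_frames, ignore_index=True) if truth_frames else pd.DataFrame()
    )
    return Cohort(
        config=cfg,
        cells_by_sample=cells_by_sample,
        geom_by_sample=geom_by_sample,
        survival=survival,
        ground_truth=ground_truth,
        true_band_density=band_density,
    )


# ---------------------------------------------------------------------------
# light-weight profile fixtures and recovery diagnostics
# ---------------------------------------------------------------------------

def make_profile(
    bin_edges: Sequence[float], density: Sequence[float]
) -> DistanceProfile:
    """Wrap a density vector into a single-sample DistanceProfile."""
    edges = np.asarray(bin_edges, dtype=float)
    dens = np.asarray(density, dtype=float)
    area = np.ones(len(edges) - 1)
    counts = np.round(dens * area).astype(int)
    return DistanceProfile(
        bin_edges=edges,
        counts=counts,
        band_area_mm2=area,
        density=dens,
        n_samples=1,
        se=np.zeros_like(dens),
        mean_density=dens,
        per_sample_density={"s": dens},
        per_sample_counts={"s": counts},
    )


def sample_band_profiles(
    rng: np.random.Generator,
    n_patients: int,
    bin_edges: Sequence[float],
    mean_density: float = 40.0,
    sd_density: float = 15.0,
) -> dict[str, DistanceProfile]:
    """Independent near-normal band densities per patient (fast survival fixtures)."""
    edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(edges) - 1
    out = {}
    for i in range(n_patients):
        dens = np.clip(rng.normal(mean_density, sd_density, n_bins), 0.0, None)
        out[f"P{i:03d}"] = make_profile(edges, dens)
    return out


def fit_boundary_decay(
    bin_centers: Sequence[float], densities: Sequence[float]
) -> float:
    """Decay length (µm) of an exponential density profile on the stromal side.

    Least-squares line on log density over bins with positive density and
    positive center; returns -1/slope.
    """
    centers = np.asarray(bin_centers, dtype=float)
    dens = np.asarray(densities, dtype=float)
    ok = (centers > 0) & np.isfinite(dens) & (dens > 0)
    if ok.sum() < 3:
        raise ValueError("need >= 3 positive stromal bins to fit a decay")
    slope, _ = np.polyfit(centers[ok], np.log(dens[ok]), 1)
    if slope >= 0:
        return float("inf")
    return float(-1.0 / slope)
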