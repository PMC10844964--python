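"""Configuration-driven orchestration of the full analysis.

Stages: read/generate tables -> confidence filter -> marker thresholds ->
cell typing -> compartment summaries -> distance profiles -> nearest
distances -> contacts -> correlation screen -> distance-band survival
splits.  All outputs are CSV/JSON plus a manifest for auditability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_tables, phenotyping, spatial, stats, synthetic
from .io_tables import CellRecord, SurvivalRecord, TissueClass
from .phenotyping import CheckpointStatus, SubsetDefinition, ThresholdFit, ThresholdMethod
from .spatial import ContactRule, TissueGeometry

logger = logging.getLogger("spatialtme")

__all__ = ["RunConfig", "run", "assign_cell_types", "summarize_compartments"]

SUBSET_MARKERS = ("CD68", "CD163")
CHECKPOINT_MARKERS = ("PD-L1", "PD-1")
TYPING_MARKERS = ("CK", "CD45", "CD3")


@dataclass
class Population:
    """A survival-analysis cell population: a cell type plus checkpoint state."""

    name: str
    cell_type: str
    checkpoint: Mapping[str, str] = field(default_factory=dict)  # marker -> HI|LO

    @classmethod
    def from_dict(cls, d: Mapping) -> "Population":
        return cls(
            name=d["name"],
            cell_type=d["cell_type"],
            checkpoint=dict(d.get("checkpoint", {})),
        )


def _default_populations() -> list[Population]:
    # the three distance-band populations examined for survival association
    return [
        Population("CD68hiCD163hi_PD-L1hi", "CD68hiCD163hi", {"PD-L1": "HI"}),
        Population("Tcell_PD-1hi", "Tcell", {"PD-1": "HI"}),
        Population("Tumor_PD-L1lo", "Tumor", {"PD-L1": "LO"}),
    ]


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    output_dir: Path
    seed: int = 0
    mode: str = "synthetic"  # synthetic | tables
    synthetic: synthetic.SyntheticConfig | None = None
    cell_tables: list[Path] = field(default_factory=list)
    geometry_paths: dict[str, Path] = field(default_factory=dict)
    clinical_path: Path | None = None
    dialect: io_tables.TableDialect = field(default_factory=io_tables.TableDialect)
    min_confidence: float = 0.5
    threshold_methods: dict[str, dict] = field(default_factory=dict)
    # half-bin offset puts bin centers on multiples of the bin width, so
    # the default survival bands (-25, 25, 75) are exact bin centers
    bin_width: float = 25.0
    distance_range: tuple[float, float] = (-512.5, 512.5)
    bands: tuple[float, ...] = (-25.0, 25.0, 75.0)
    alpha: float = 0.05
    resolution: float = 2.0
    mask_um_per_px: float = 2.0
    contact_rule: ContactRule = field(default_factory=ContactRule)
    populations: list[Population] = field(default_factory=_default_populations)

    def __post_init__(self) -> None:
        lo, hi = self.distance_range
        centers = lo + self.bin_width / 2.0 + self.bin_width * np.arange(
            int(round((hi - lo) / self.bin_width))
        )
        for band in self.bands:
            if not np.any(np.isclose(centers, band)):
                raise ValueError(
                    f"band {band} is not a bin center under bin_width="
                    f"{self.bin_width}, range={self.distance_range}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {
            "output_dir": Path(raw.get("output_dir", "spatialtme_out")),
            "seed": int(raw.get("seed", 0)),
            "mode": raw.get("mode", "synthetic"),
            "min_confidence": float(raw.get("min_confidence", 0.5)),
            "bin_width": float(raw.get("bin_width", 25.0)),
            "alpha": float(raw.get("alpha", 0.05)),
            "resolution": float(raw.get("resolution", 2.0)),
            "mask_um_per_px": float(raw.get("mask_um_per_px", 2.0)),
        }
        if "distance_range" in raw:
            kwargs["distance_range"] = tuple(float(v) for v in raw["distance_range"])
        if "bands" in raw:
            kwargs["bands"] = tuple(float(v) for v in raw["bands"])
        if "threshold_methods" in raw:
            kwargs["threshold_methods"] = dict(raw["threshold_methods"])
        if "contact" in raw:
            c = raw["contact"]
            kwargs["contact_rule"] = ContactRule(
                default_radius_um=float(c.get("default_radius_um", 5.0)),
                slack_um=float(c.get("slack_um", 1.0)),
            )
        if "populations" in raw:
            kwargs["populations"] = [
                Population.from_dict(p) for p in raw["populations"]
            ]
        if kwargs["mode"] == "synthetic":
            syn = raw.get("synthetic", {})
            surv = syn.get("survival", {})
            kwargs["synthetic"] = synthetic.SyntheticConfig(
                seed=int(raw.get("seed", 0)),
                frame_mm=tuple(syn.get("frame_mm", (3.0, 3.0))),
                n_nests=int(syn.get("n_nests", 3)),
                survival=synthetic.SurvivalModel(
                    h0=float(surv.get("h0", 0.02)),
                    beta=float(surv.get("beta", 0.0)),
                    censoring_rate=float(surv.get("censoring_rate", 0.2)),
                    n_patients=int(surv.get("n_patients", 10)),
                    band_center_um=float(surv.get("band_center_um", 75.0)),
                ),
            )
        else:
            inp = raw.get("input", {})
            kwargs["cell_tables"] = [Path(p) for p in inp.get("cell_tables", [])]
            kwargs["geometry_paths"] = {
                k: Path(v) for k, v in inp.get("geometries", {}).items()
            }
            if inp.get("clinical"):
                kwargs["clinical_path"] = Path(inp["clinical"])
            if "dialect" in inp:
                d = inp["dialect"]
                kwargs["dialect"] = io_tables.TableDialect(
                    marker_cols=dict(d.get("marker_cols", {})),
                    um_per_unit=float(d.get("um_per_unit", 1.0)),
                    **{
                        k: d[k]
                        for k in (
                            "sample_col",
                            "cell_id_col",
                            "x_col",
                            "y_col",
                            "tissue_col",
                            "confidence_col",
                        )
                        if k in d
                    },
                )
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# cell typing
# ---------------------------------------------------------------------------

def fit_all_thresholds(
    cells: Sequence[CellRecord],
    markers: Sequence[str],
    methods: Mapping[str, Mapping] | None = None,
) -> dict[str, ThresholdFit]:
    """Fit one cohort-level threshold per marker (pooled over all samples)."""
    methods = methods or {}
    fits = {}
    for marker in markers:
        spec = dict(methods.get(marker, {}))
        method = ThresholdMethod(spec.pop("method", "GAUSSIAN_MIXTURE_2"))
        values = [c.intensities[marker] for c in cells if marker in c.intensities]
        fits[marker] = phenotyping.fit_marker_threshold(
            values, method=method, params=spec, marker=marker
        )
    return fits


def assign_cell_types(
    cells: Sequence[CellRecord], fits: Mapping[str, ThresholdFit]
) -> dict[str, str]:
    """Threshold-based cell typing: Tumor, CD68/CD163 subsets, Tcell, Leukocyte, Other."""
    subset_def = SubsetDefinition(
        {m: fits[m].threshold for m in SUBSET_MARKERS if m in fits}
    )
    out: dict[str, str] = {}
    for cell in cells:
        if "CK" in fits and cell.intensities.get("CK", 0.0) > fits["CK"].threshold:
            out[cell.cell_id] = "Tumor"
            continue
        label = phenotyping.classify_cd68_cd163(cell, subset_def)
        if label != "CD68loCD163lo":
            out[cell.cell_id] = label
            continue
        if "CD3" in fits and cell.intensities.get("CD3", 0.0) > fits["CD3"].threshold:
            out[cell.cell_id] = "Tcell"
        elif (
            "CD45" in fits
            and cell.intensities.get("CD45", 0.0) > fits["CD45"].threshold
        ):
            out[cell.cell_id] = "Leukocyte"
        else:
            out[cell.cell_id] = "Other"
    return out


def checkpoint_status(
    cells: Sequence[CellRecord],
    fits: Mapping[str, ThresholdFit],
    markers: Sequence[str] = CHECKPOINT_MARKERS,
) -> dict[str, dict[str, str]]:
    """Per-cell HI/LO status for each checkpoint marker."""
    out: dict[str, dict[str, str]] = {}
    for cell in cells:
        out[cell.cell_id] = {
            m: phenotyping.classify_checkpoint(cell, m, fits[m].threshold).value
            for m in markers
            if m in fits and m in cell.intensities
        }
    return out


def summarize_compartments(
    cells: Sequence[CellRecord],
    geom: TissueGeometry,
    types: Mapping[str, str],
) -> pd.DataFrame:
    """Per cell type: cells/mm² in EPI_TUMOR and STROMA plus relative %.

    Cells with tissue class OTHER are excluded.  A zero-area compartment
    yields NaN densities (flagged undefined).
    """
    areas = {
        TissueClass.EPI_TUMOR: geom.epi_area_mm2(),
        TissueClass.STROMA: geom.stroma_area_mm2(),
    }
    rows = []
    labels = sorted(set(types.values()))
    for compartment, area in areas.items():
        comp_cells = [c for c in cells if c.tissue_class is compartment]
        total = len(comp_cells)
        for label in labels:
            n = sum(1 for c in comp_cells if types.get(c.cell_id) == label)
            rows.append(
                {
                    "sample_id": geom.sample_id,
                    "compartment": compartment.value,
                    "cell_type": label,
                    "count": n,
                    "area_mm2": area,
                    "density_per_mm2": n / area if area > 0 else float("nan"),
                    "relative_pct": 100.0 * n / total if total > 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the run itself
# ---------------------------------------------------------------------------

def _population_filter(
    cells: Sequence[CellRecord],
    pop: Population,
    types: Mapping[str, str],
    ck_status: Mapping[str, Mapping[str, str]],
) -> list[CellRecord]:
    out = []
    for c in cells:
        if types.get(c.cell_id) != pop.cell_type:
            continue
        status = ck_status.get(c.cell_id, {})
        if all(status.get(m) == want for m, want in pop.checkpoint.items()):
            out.append(c)
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


def _config_digest(config: RunConfig) -> str:
    blob = repr(
        (
            config.seed,
            config.mode,
            config.min_confidence,
            config.bin_width,
            config.distance_range,
            config.bands,
            config.alpha,
            config.resolution,
            sorted(config.threshold_methods.items()),
            [(p.name, p.cell_type, sorted(p.checkpoint.items())) for p in config.populations],
            config.synthetic,
        )
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write all outputs under ``output_dir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_digest": _config_digest(config),
        "seed": config.seed,
        "mode": config.mode,
        "stages": {},
    }

    # --- stage: load or generate -------------------------------------------
    if config.mode == "synthetic":
        if config.synthetic is None:
            raise ValueError("synthetic mode requires a synthetic config")
        cohort = synthetic.generate_cohort(config.synthetic)
        cells_by_sample = cohort.cells_by_sample
        geom_by_sample = cohort.geom_by_sample
        survival = cohort.survival
        sample_to_patient = cohort.sample_to_patient
    else:
        cells: list[CellRecord] = []
        for path in config.cell_tables:
            cells.extend(io_tables.read_cell_table(path, config.dialect))
        cells_by_sample = {}
        for c in cells:
            cells_by_sample.setdefault(c.sample_id, []).append(c)
        geom_by_sample = {}
        for sid, path in config.geometry_paths.items():
            if Path(path).suffix.lower() in {".geojson", ".json"}:
                geom_by_sample[sid] = TissueGeometry.from_geojson(path, sample_id=sid)
            else:
                geom_by_sample[sid] = TissueGeometry.from_mask_file(
                    path, um_per_px=config.mask_um_per_px, sample_id=sid
                )
        survival = (
            io_tables.read_clinical_table(config.clinical_path)
            if config.clinical_path
            else []
        )
        sample_to_patient = {
            sid: rec.patient_id for rec in survival for sid in rec.sample_ids
        }
    n_raw = sum(len(v) for v in cells_by_sample.values())
    manifest["stages"]["load"] = {"n_cells": n_raw, "n_samples": len(cells_by_sample)}
    logger.info("load: %d cells over %d samples", n_raw, len(cells_by_sample))

    # --- stage: confidence filter ------------------------------------------
    cells_by_sample = {
        sid: io_tables.filter_by_confidence(v, config.min_confidence)
        for sid, v in cells_by_sample.items()
    }
    all_cells = [c for v in cells_by_sample.values() for c in v]
    manifest["stages"]["confidence_filter"] = {
        "min_confidence": config.min_confidence,
        "n_cells": len(all_cells),
    }
    logger.info("confidence filter: %d cells retained", len(all_cells))

    # --- stage: thresholds and typing --------------------------------------
    markers = sorted(
        {m for c in all_cells for m in c.intensities}
        & set(SUBSET_MARKERS + CHECKPOINT_MARKERS + TYPING_MARKERS)
    )
    fits = fit_all_thresholds(all_cells, markers, config.threshold_methods)
    with open(out / "thresholds.json", "w") as fh:
        json.dump({m: f.to_dict() for m, f in fits.items()}, fh, indent=2, sort_keys=True)
    types = assign_cell_types(all_cells, fits)
    ck_status = checkpoint_status(all_cells, fits)
    manifest["stages"]["thresholds"] = {m: fits[m].threshold for m in fits}
    manifest["stages"]["typing"] = {
        label: sum(1 for t in types.values() if t == label)
        for label in sorted(set(types.values()))
    }

    # spatially analyzable cells exclude tissue-class OTHER
    spatial_by_sample = {
        sid: [c for c in v if c.tissue_class is not TissueClass.OTHER]
        for sid, v in cells_by_sample.items()
    }

    # --- stage: compartment summaries --------------------------------------
    comp_frames = [
        summarize_compartments(spatial_by_sample[sid], geom_by_sample[sid], types)
        for sid in sorted(geom_by_sample)
        if sid in spatial_by_sample
    ]
    if comp_frames:
        _write_csv(pd.concat(comp_frames, ignore_index=True), out / "compartments.csv")

    # --- stage: distance profiles per cell type ----------------------------
    usable_geoms = {
        sid: g for sid, g in geom_by_sample.items() if g.has_epi
    }
    profile_frames = []
    cell_types = sorted(set(types.values()) - {"Other"})
    for label in cell_types:
        subset = [
            c
            for sid in usable_geoms
            for c in spatial_by_sample.get(sid, [])
            if types.get(c.cell_id) == label
        ]
        prof = spatial.density_profile(
            subset,
            usable_geoms,
            bin_width=config.bin_width,
            distance_range=config.distance_range,
            resolution=config.resolution,
        )
        df = prof.to_dataframe()
        df.insert(0, "cell_type", label)
        profile_frames.append(df)
    if profile_frames:
        _write_csv(pd.concat(profile_frames, ignore_index=True), out / "profiles.csv")
    manifest["stages"]["profiles"] = {"n_cell_types": len(profile_frames)}

    # --- stage: nearest distances to tumor cells ---------------------------
    mnd_rows = []
    for sid in sorted(usable_geoms):
        sample_cells = spatial_by_sample.get(sid, [])
        tumor = [c for c in sample_cells if types.get(c.cell_id) == "Tumor"]
        if not tumor:
            continue
        for label in cell_types:
            if label == "Tumor":
                continue
            from_cells = [c for c in sample_cells if types.get(c.cell_id) == label]
            if not from_cells:
                continue
            res = spatial.nearest_distance(from_cells, tumor)
            mnd_rows.append(
                {
                    "sample_id": sid,
                    "cell_type": label,
                    "n_cells": res.n_from,
                    "mnd_um": res.mnd,
                }
            )
    if mnd_rows:
        _write_csv(pd.DataFrame(mnd_rows), out / "nearest_distances.csv")

    # --- stage: checkpoint proportions -------------------------------------
    ck_rows = []
    for marker in CHECKPOINT_MARKERS:
        if marker not in fits:
            continue
        hi_ids = {
            cid for cid, st in ck_status.items() if st.get(marker) == "HI"
        }
        total_hi = sum(1 for c in all_cells if c.cell_id in hi_ids)
        for label in cell_types:
            of_type = [c for c in all_cells if types.get(c.cell_id) == label]
            n_hi = sum(1 for c in of_type if c.cell_id in hi_ids)
            ck_rows.append(
                {
                    "marker": marker,
                    "cell_type": label,
                    "n_cells": len(of_type),
                    "n_hi": n_hi,
                    "pct_hi_of_type": 100.0 * n_hi / len(of_type) if of_type else float("nan"),
                    "pct_of_all_hi": 100.0 * n_hi / total_hi if total_hi else float("nan"),
                }
            )
    if ck_rows:
        _write_csv(pd.DataFrame(ck_rows), out / "checkpoint_proportions.csv")

    # --- stage: contacts of PD-1hi T cells with PD-L1hi partners -----------
    contact_rows = []
    for sid in sorted(usable_geoms):
        sample_cells = spatial_by_sample.get(sid, [])
        refs = [
            c
            for c in sample_cells
            if types.get(c.cell_id) == "Tcell"
            and ck_status.get(c.cell_id, {}).get("PD-1") == "HI"
        ]
        if not refs:
            continue
        partners = {}
        for label in cell_types:
            partners[label] = [
                c
                for c in sample_cells
                if types.get(c.cell_id) == label
                and ck_status.get(c.cell_id, {}).get("PD-L1") == "HI"
            ]
        res = spatial.count_contacts(refs, partners, config.contact_rule)
        for label, frac in sorted(res.contact_fraction.items()):
            contact_rows.append(
                {
                    "sample_id": sid,
                    "reference": "Tcell_PD-1hi",
                    "partner": f"{label}_PD-L1hi",
                    "n_reference_cells": len(refs),
                    "contact_fraction": frac,
                    "total_contacts": res.total_contacts(label),
                }
            )
    if contact_rows:
        _write_csv(pd.DataFrame(contact_rows), out / "contacts.csv")

    # --- stage: survival association ---------------------------------------
    screen_df = pd.DataFrame()
    split_rows = []
    if survival and usable_geoms:
        pop_profiles: dict[str, dict[str, spatial.DistanceProfile]] = {}
        for pop in config.populations:
            by_patient: dict[str, spatial.DistanceProfile] = {}
            for sid, geom in usable_geoms.items():
                pid = sample_to_patient.get(sid)
                if pid is None:
                    continue
                pop_cells = _population_filter(
                    spatial_by_sample.get(sid, []), pop, types, ck_status
                )
                by_patient[pid] = spatial.density_profile(
                    pop_cells,
                    {sid: geom},
                    bin_width=config.bin_width,
                    distance_range=config.distance_range,
                    resolution=config.resolution,
                )
            pop_profiles[pop.name] = by_patient

        # correlation screen: band densities vs outcome encodings
        feat_cols = {}
        for pop in config.populations:
            for band in config.bands:
                cov = stats.band_covariate(pop_profiles[pop.name], band)
                feat_cols[f"{pop.name}@{band:g}um"] = cov
        feats = pd.DataFrame(feat_cols)
        outcomes = pd.DataFrame(
            {
                "event": {r.patient_id: float(r.event) for r in survival},
                "time_months": {r.patient_id: r.time for r in survival},
            }
        )
        screen_df = stats.spearman_screen(feats, outcomes, alpha=config.alpha)
        _write_csv(screen_df, out / "correlation_screen.csv")

        km_frames = []
        for pop in config.populations:
            for band in config.bands:
                cov = {
                    pid: v
                    for pid, v in stats.band_covariate(
                        pop_profiles[pop.name], band
                    ).items()
                    if v is not None
                }
                if len(cov) < 2:
                    continue
                for split_name, splitter in (
                    ("median", stats.median_split),
                    ("threshold0", stats.threshold_split),
                ):
                    hi, lo = splitter(cov)
                    if not hi or not lo:
                        continue
                    try:
                        split = stats.km_logrank(
                            survival, hi, lo, band_center=band, covariate=pop.name
                        )
                    except ValueError:
                        continue
                    split_rows.append(
                        {
                            "population": pop.name,
                            "band_center_um": band,
                            "split": split_name,
                            "n_hi": len(hi),
                            "n_lo": len(lo),
                            "logrank_chi2": split.logrank_chi2,
                            "p": split.p,
                            "hi_better": split.o_minus_e_hi < 0,
                        }
                    )
                    km = split.km_dataframe()
                    km.insert(0, "population", pop.name)
                    km.insert(1, "band_center_um", band)
                    km.insert(2, "split", split_name)
                    km_frames.append(km)
        if split_rows:
            _write_csv(pd.DataFrame(split_rows), out / "survival_splits.csv")
        if km_frames:
            _write_csv(pd.concat(km_frames, ignore_index=True), out / "km_curves.csv")
    manifest["stages"]["survival"] = {"n_splits": len(split_rows)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: outputs in %s", out)
    return manifest
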