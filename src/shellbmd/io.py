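"""File formats, configuration and the end-to-end pipeline.

NIfTI is the canonical volume format (a sidecar JSON next to each file
records the virtual-monoenergetic energy); DICOM series import is
provided for scanner exports.  Tabular outputs are CSV with documented
column order, specs/models/logs are JSON.  Voxel indexing is 0-based
and half-open, physical coordinates are mm.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationModel, fit_calibration, measure_insert_vois
from .cohort import (
    animal_site_means,
    compare_groups_per_site,
    comparisons_to_frame,
    summarize_groups,
)
from .mapping import compute_bmd_map
from .morphometry import LandmarkPair, compute_ratios
from .roi import (
    PAIRED_SITES,
    ROI,
    SiteMeasurement,
    apply_exclusions,
    compare_sides,
    extract_roi_values,
    histogram,
    summarize_roi,
)
from .synthetic import PhantomSpec
from .volumes import BMDMap, GridMismatchError, SpectralVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_bmd_map",
    "load_spectral_pair",
    "load_dicom_series",
    "model_to_json",
    "model_from_json",
    "rois_to_json",
    "rois_from_json",
    "landmarks_from_json",
    "phantom_spec_from_json",
    "RunConfig",
    "RunLog",
    "run_pipeline",
    "pool_paired_sites",
]


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def save_volume(volume: SpectralVolume, path) -> Path:
    """Write a spectral volume as NIfTI plus an energy sidecar JSON."""
    path = Path(path)
    img = nib.Nifti1Image(volume.voxels, _affine(volume.spacing_mm, volume.origin_mm))
    nib.save(img, path)
    _sidecar_path(path).write_text(json.dumps({"energy_kev": volume.energy_kev}))
    return path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.parent / (name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def load_volume(path, energy_kev: float | None = None) -> SpectralVolume:
    """Read a NIfTI volume; energy comes from the sidecar unless given."""
    path = Path(path)
    img = nib.load(path)
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    if energy_kev is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"no energy given and no sidecar {sidecar}")
        energy_kev = json.loads(sidecar.read_text())["energy_kev"]
    return SpectralVolume(
        voxels=np.asarray(img.get_fdata(), dtype=float),
        energy_kev=energy_kev,
        spacing_mm=spacing,
        origin_mm=origin,
    )


def save_bmd_map(bmd_map: BMDMap, path) -> Path:
    """Write a BMD map as float32 NIfTI plus a provenance sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(
        bmd_map.voxels.astype(np.float32), _affine(bmd_map.spacing_mm, bmd_map.origin_mm)
    )
    nib.save(img, path)
    prov = {k: v for k, v in bmd_map.provenance.items() if k != "roi_values"}
    _sidecar_path(path).write_text(json.dumps(prov, default=str))
    return path


def load_spectral_pair(path_50, path_200) -> tuple[SpectralVolume, SpectralVolume]:
    """Load a co-registered (50, 200) keV pair, verifying grid equality."""
    v50 = load_volume(path_50)
    v200 = load_volume(path_200)
    if not v50.same_grid(v200):
        raise GridMismatchError(
            f"pair is not co-registered: {v50.grid()} vs {v200.grid()}"
        )
    if (v50.energy_kev, v200.energy_kev) != (50.0, 200.0):
        raise ValueError(
            f"expected energies (50, 200) keV, got ({v50.energy_kev}, {v200.energy_kev})"
        )
    return v50, v200


def load_dicom_series(directory, energy_kev: float | None = None) -> SpectralVolume:
    """Stack a single-frame DICOM series into a SpectralVolume.

    Slices are sorted by their position along the slice normal; rescale
    slope/intercept are applied to recover HU.  Axes are reordered to
    the package's (x, y, z) convention (DICOM pixel arrays are
    row-major, i.e. (y, x)).
    """
    import pydicom

    directory = Path(directory)
    files = sorted(directory.glob("*.dcm")) or sorted(directory.iterdir())
    slices = [pydicom.dcmread(f) for f in files if f.is_file()]
    if not slices:
        raise ValueError(f"no DICOM files found in {directory}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    arrays = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    vol_zyx = np.stack(arrays, axis=0)          # (z, row=y, col=x)
    voxels = np.transpose(vol_zyx, (2, 1, 0))   # -> (x, y, z)
    ds0 = slices[0]
    row_sp, col_sp = (float(v) for v in ds0.PixelSpacing)
    if len(slices) > 1:
        dz = float(slices[1].ImagePositionPatient[2]) - float(ds0.ImagePositionPatient[2])
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    origin = tuple(float(v) for v in ds0.ImagePositionPatient)
    if energy_kev is None:
        energy_kev = float(getattr(ds0, "KVP", 0.0)) or 0.0
    return SpectralVolume(
        voxels=voxels,
        energy_kev=energy_kev,
        spacing_mm=(col_sp, row_sp, abs(dz)),
        origin_mm=origin,
    )


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def model_to_json(model: CalibrationModel, path=None) -> str:
    payload = {
        "slope_50": model.slope_50,
        "intercept_50": model.intercept_50,
        "slope_200": model.slope_200,
        "intercept_200": model.intercept_200,
        "rho_ref": model.rho_ref,
        "fit_r2_pair": list(model.fit_r2_pair),
        "bilinear": list(model.bilinear) if model.bilinear else None,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source) -> CalibrationModel:
    if isinstance(source, (str, Path)) and Path(source).exists():
        data = json.loads(Path(source).read_text())
    else:
        data = json.loads(source)
    return CalibrationModel(
        slope_50=data["slope_50"],
        intercept_50=data["intercept_50"],
        slope_200=data["slope_200"],
        intercept_200=data["intercept_200"],
        rho_ref=data["rho_ref"],
        fit_r2_pair=tuple(data.get("fit_r2_pair", (float("nan"),) * 2)),
        bilinear=tuple(data["bilinear"]) if data.get("bilinear") else None,
    )


def rois_to_json(rois: list[ROI], path=None) -> str:
    payload = {
        "rois": [
            {
                "animal_id": r.animal_id,
                "site": r.site,
                "side": r.side,
                "plane": r.plane,
                "slice_index": r.slice_index,
                "polygon_mm": r.polygon_mm,
            }
            for r in rois
        ]
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def rois_from_json(source) -> list[ROI]:
    if isinstance(source, (str, Path)) and Path(source).exists():
        data = json.loads(Path(source).read_text())
    else:
        data = json.loads(source)
    return [ROI(**{**rec, "polygon_mm": [tuple(p) for p in rec["polygon_mm"]]}) for rec in data["rois"]]


def landmarks_from_json(source) -> list[LandmarkPair]:
    if isinstance(source, (str, Path)) and Path(source).exists():
        data = json.loads(Path(source).read_text())
    else:
        data = json.loads(source)
    return [
        LandmarkPair(
            location=rec["location"],
            axis=rec["axis"],
            endpoints=(tuple(rec["p0"]), tuple(rec["p1"])),
        )
        for rec in data["pairs"]
    ]


def phantom_spec_from_json(source) -> PhantomSpec:
    if isinstance(source, (str, Path)) and Path(source).exists():
        data = json.loads(Path(source).read_text())
    else:
        data = json.loads(source)
    kwargs = dict(data)
    for key in ("insert_densities", "background_hu_pair", "volume_shape", "spacing_mm", "origin_mm"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "insert_centers" in kwargs:
        kwargs["insert_centers"] = tuple(tuple(c) for c in kwargs["insert_centers"])
    return PhantomSpec(**kwargs)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``model_json`` or the phantom triple (``phantom_hu50``,
    ``phantom_hu200``, ``phantom_spec_json``) must be provided.  Every
    referenced path must exist at run start.
    """

    out_dir: str
    subjects: list[dict] = field(default_factory=list)
    model_json: str | None = None
    phantom_hu50: str | None = None
    phantom_hu200: str | None = None
    phantom_spec_json: str | None = None
    missing_sites: list[tuple] = field(default_factory=list)
    clamp: str = "floor-zero"
    voi_shrink: float = 0.7
    rho_ref: float | None = None
    alpha_side: float = 1e-4
    bonferroni_m: int = 6
    histogram_bin_width: float = 25.0
    seed: int = 0

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        data["missing_sites"] = [tuple(m) for m in data.get("missing_sites", [])]
        return cls(**data)

    def validate(self) -> None:
        if self.model_json is None and not (
            self.phantom_hu50 and self.phantom_hu200 and self.phantom_spec_json
        ):
            raise ValueError("need either model_json or a phantom volume pair + spec")
        paths = [self.model_json, self.phantom_hu50, self.phantom_hu200, self.phantom_spec_json]
        for subj in self.subjects:
            paths += [subj.get("hu50"), subj.get("hu200"), subj.get("rois"), subj.get("landmarks")]
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not (0 < self.voi_shrink <= 1):
            raise ValueError("voi_shrink must lie in (0, 1]")
        if not (0 < self.alpha_side < 1):
            raise ValueError("alpha_side must lie in (0, 1)")
        if self.histogram_bin_width <= 0:
            raise ValueError("histogram_bin_width must be positive")


class RunLog:
    """Timestamped stage events plus config echo and exclusion summary."""

    def __init__(self, config_echo: dict):
        self.events: list[dict] = []
        self.config_echo = config_echo
        self.exclusion_summary: dict | None = None

    def log(self, stage: str, event: str, **details) -> None:
        self.events.append(
            {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage, "event": event, **details}
        )

    def to_json(self, path=None) -> str:
        payload = {
            "package_version": __version__,
            "config": self.config_echo,
            "events": self.events,
            "exclusion_summary": self.exclusion_summary,
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def pool_paired_sites(
    measurements: list[SiteMeasurement], alpha_side: float = 1e-4
):
    """Run the left/right consistency gate over every paired site.

    Returns a dict mapping (animal_id, site) to a
    :class:`~shellbmd.roi.SideComparison`, suitable for
    :func:`shellbmd.roi.apply_exclusions`.  Side pooling itself happens
    downstream (animal-level means concatenate the retained sides).
    """
    by_key: dict[tuple, dict] = {}
    for m in measurements:
        if m.status != "retained":
            continue
        if m.site in PAIRED_SITES:
            by_key.setdefault((m.animal_id, m.site), {})[m.side] = m
    side_results = {}
    for (animal_id, site), sides in sorted(by_key.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        left = sides.get("left")
        right = sides.get("right")
        side_results[(animal_id, site)] = compare_sides(
            None if left is None else left.pixel_values,
            None if right is None else right.pixel_values,
            alpha_side=alpha_side,
        )
    return side_results


def run_pipeline(config: RunConfig) -> dict:
    """Calibrate -> map -> ROI stats -> cohort stats (-> morphometry).

    Writes model JSON, per-subject BMD maps, ROI statistics, the
    group/site summary and comparison tables, histograms, the exclusion
    accounting and a run log under ``config.out_dir``.  Deterministic
    given config + seed.  Any stage error aborts with the stage named.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(config_echo={k: str(v) for k, v in vars(config).items()})
    bundle: dict = {"log": log}

    def stage(name):
        log.log(name, "start")
        return name

    current = stage("calibrate")
    try:
        if config.model_json is not None:
            model = model_from_json(config.model_json)
        else:
            v50, v200 = load_spectral_pair(config.phantom_hu50, config.phantom_hu200)
            spec = phantom_spec_from_json(config.phantom_spec_json)
            samples = measure_insert_vois(v50, v200, spec, voi_shrink=config.voi_shrink)
            model = fit_calibration(samples, rho_ref=config.rho_ref)
        model_to_json(model, out / "model.json")
        bundle["model"] = model
        log.log(current, "done")

        current = stage("map")
        measurements: list[SiteMeasurement] = []
        animals: dict = {}
        landmark_rows = []
        for subj in config.subjects:
            animal_id = subj["animal_id"]
            animals[animal_id] = subj["group"]
            v50, v200 = load_spectral_pair(subj["hu50"], subj["hu200"])
            bmd_map = compute_bmd_map(v50, v200, model, clamp=config.clamp)
            save_bmd_map(bmd_map, out / f"bmd_{animal_id}.nii.gz")
            for roi in rois_from_json(subj["rois"]):
                values = extract_roi_values(roi, bmd_map)
                measurements.append(
                    SiteMeasurement(
                        animal_id=animal_id,
                        site=roi.site,
                        side=roi.side,
                        pixel_values=values,
                        stats=summarize_roi(values, bmd_map.voxel_volume_mm3()),
                        roi=roi,
                    )
                )
            if subj.get("landmarks"):
                ratios = compute_ratios(landmarks_from_json(subj["landmarks"]))
                landmark_rows.append(
                    {
                        "animal_id": animal_id,
                        "group": subj["group"],
                        "gular_hw": ratios.ratios.get("gular"),
                        "shoulder_hw": ratios.ratios.get("shoulder"),
                        "total_hw": ratios.ratios.get("total"),
                    }
                )
        log.log(current, "done", measurements=len(measurements))

        current = stage("roi-stats")
        side_results = pool_paired_sites(measurements, alpha_side=config.alpha_side)
        report, retained = apply_exclusions(
            measurements, config.missing_sites, side_results
        )
        for (animal_id, site), res in side_results.items():
            if res.outcome == "excluded":
                log.log(current, "side-difference exclusion", animal_id=animal_id, site=site, p=res.p)
        for m_missing in config.missing_sites:
            log.log(current, "missing site", site=list(m_missing))
        log.exclusion_summary = {
            "planned": report.planned,
            "obtained": report.obtained,
            "retained": report.retained,
            "missing": [list(m) for m in report.missing],
            "excluded": [list(e) for e in report.excluded],
        }
        stats_rows = []
        for m in measurements:
            s = m.stats
            stats_rows.append(
                {
                    "animal_id": m.animal_id,
                    "group": animals[m.animal_id],
                    "site": m.site,
                    "side": m.side,
                    "status": m.status,
                    "mean": s.mean,
                    "median": s.median,
                    "sd": s.sd,
                    "minimum": s.minimum,
                    "maximum": s.maximum,
                    "p1": s.p1,
                    "p99": s.p99,
                    "pixel_count": s.pixel_count,
                    "total_volume_mm3": s.total_volume_mm3,
                }
            )
        pd.DataFrame(stats_rows).to_csv(out / "roi_stats.csv", index=False)
        bundle["exclusion_report"] = report
        bundle["retained"] = retained
        log.log(current, "done", retained=report.retained)

        current = stage("cohort-stats")
        summary = summarize_groups(retained, animals)
        summary.to_csv(out / "group_site_summary.csv", index=False)
        comparisons = compare_groups_per_site(
            retained, animals, bonferroni_m=config.bonferroni_m
        )
        comparisons_to_frame(comparisons).to_csv(out / "group_comparisons.csv", index=False)
        hist_rows = []
        groups_frame = animal_site_means(retained, animals)
        for (g, site), sel in groups_frame.groupby(["group", "site"]):
            values = np.concatenate(
                [
                    m.pixel_values
                    for m in retained
                    if m.site == site and animals[m.animal_id] == g
                ]
            )
            h = histogram(values, bin_width=config.histogram_bin_width)
            for edge, count in zip(h.bin_edges[:-1], h.normalized_counts):
                hist_rows.append(
                    {"group": g, "site": site, "bin_left_edge": edge, "normalized_count": count}
                )
        pd.DataFrame(hist_rows).to_csv(out / "histograms.csv", index=False)
        bundle["summary"] = summary
        bundle["comparisons"] = comparisons
        log.log(current, "done", comparisons=len(comparisons))

        if landmark_rows:
            current = stage("morph")
            pd.DataFrame(landmark_rows).to_csv(out / "morphometry.csv", index=False)
            log.log(current, "done", animals=len(landmark_rows))
    except Exception as exc:
        log.log(current, "error", message=str(exc))
        log.to_json(out / "run_log.json")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out / "exclusions.json").write_text(json.dumps(log.exclusion_summary, indent=2))
    log.to_json(out / "run_log.json")
    return bundle
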