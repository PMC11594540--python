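"""Plate-level orchestration: layouts, run configuration, pipelines, IO.

A plate run is defined by a layout (well -> condition/dose/replicate), a
directory of multi-page TIFF stacks named ``<well>_<field>.tif``, and a
RunConfig carrying every parameter that affects the outputs. The periphery
pipeline composes midplane selection, segmentation, QC, dilation, ring
profiling, edge metrics and dose statistics; the distortion pipeline
composes registration, error curves, expansion factors and the plate-level
ANOVA. All outputs are tidy CSVs plus a provenance record, and a rerun from
the same config reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .dosestats import aggregate_condition, dose_response_table
from .edgemetrics import extract_metrics
from .nucmask import NoNucleusError, dilate_mask, qc_filter, segment_nucleus, select_midplane
from .ringprof import interpolate_profile, normalize_profile, peel_rings, ring_means
from . import distortqc, synthim

__all__ = [
    "WellInfo",
    "PlateLayout",
    "RunConfig",
    "per_post_volume",
    "write_stack",
    "read_stack",
    "analyze_nucleus_stack",
    "run_periphery_pipeline",
    "run_distortion_pipeline",
    "simulate_plate_metrics",
    "dose_response_from_metrics",
]


@dataclass(frozen=True)
class WellInfo:
    condition: str
    dose: float = 0.0
    dose_unit: str = ""
    replicate: int = 1


@dataclass
class PlateLayout:
    """Mapping from well ids (e.g. "B03") to experimental conditions."""

    wells: dict[str, WellInfo]
    excluded_wells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.excluded_wells) & set(self.wells)
        self.wells = {w: v if isinstance(v, WellInfo) else WellInfo(**v) for w, v in self.wells.items()}

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        data = yaml.safe_load(Path(path).read_text())
        return cls(wells=data.get("wells", {}), excluded_wells=data.get("excluded", []))

    def to_yaml(self, path) -> None:
        data = {
            "wells": {w: dataclasses.asdict(v) for w, v in self.wells.items()},
            "excluded": list(self.excluded_wells),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class RunConfig:
    """Every knob that affects outputs, serialized into the provenance record."""

    threshold_method: str = "otsu"
    dilation_iterations: int | None = None  # None -> max(3, 0.1 * equivalent radius)
    min_area: float = 500.0
    min_solidity: float = 0.85
    allow_border: bool = False
    target_length: int = 500
    normalization: str = "max1"
    domain_cap: float = 0.4
    smoothing: int = 0
    unit: str = "nucleus"
    control_label: str = "control"
    ttest_variant: str = "student"
    alpha: float = 0.05
    correction: str | None = None
    grid_spacing: int = 24
    blur_sigma: float = 8.0
    feature_quantile: float = 0.6
    bin_width: float = 2.0
    n_pairs_per_bin: int = 2000
    cutoff: float = 40.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.pop("exmplate_version", None)
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["exmplate_version"] = __version__
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def per_post_volume(total_mass_ug: float, n_posts: int = 12, density_ug_per_nl: float = 1.0) -> int:
    """Volume of gel solution retained per device post, in nL (nearest integer).

    The device's 12 posts collectively retain ``total_mass_ug`` of solution;
    at density 1 ug/nL the per-post volume is mass / (n_posts * density).
    """
    if n_posts < 1:
        raise ValueError("n_posts must be >= 1")
    if total_mass_ug < 0:
        raise ValueError("total_mass_ug must be >= 0")
    if density_ug_per_nl <= 0:
        raise ValueError("density must be positive")
    return int(round(total_mass_ug / (n_posts * density_ug_per_nl)))


# ---------------------------------------------------------------------------
# TIFF + ground-truth sidecar IO


def write_stack(path, stack: synthim.SyntheticStack) -> None:
    """Write a stack as 16-bit multi-page TIFF plus a JSON ground-truth sidecar."""
    path = Path(path)
    planes = stack.planes
    lo, hi = float(planes.min()), float(planes.max())
    scale = 60000.0 / (hi - lo) if hi > lo else 1.0
    data = np.round((planes - lo) * scale).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack", metadata=None)
    sidecar = {
        "pixel_size": stack.pixel_size,
        "intensity_offset": lo,
        "intensity_scale": scale,
        "noise": list(stack.noise),
        "seed": stack.seed,
        "midplane": stack.midplane,
        "nuclei": [
            {
                "center": list(shape.center),
                "base_radius": shape.base_radius,
                "harmonics": [list(h) for h in shape.harmonics],
                "profile": dataclasses.asdict(profile),
                "z_half": z_half,
            }
            for shape, profile, z_half in stack.nuclei
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF (float array, original intensity scale if a
    sidecar is present) and its ground-truth sidecar dict (empty if absent)."""
    path = Path(path)
    planes = tifffile.imread(path).astype(float)
    if planes.ndim == 2:
        planes = planes[None]
    sidecar_path = path.with_suffix(".json")
    meta: dict = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        planes = planes / meta.get("intensity_scale", 1.0) + meta.get("intensity_offset", 0.0)
    return planes, meta


# ---------------------------------------------------------------------------
# Periphery pipeline


def analyze_nucleus_stack(planes: np.ndarray, config: RunConfig) -> dict:
    """Run one stack through midplane -> mask -> QC -> rings -> profile -> metrics.

    Returns a record dict; rejected or empty fields carry ``accepted=False``
    with the failure reasons and no profile/metrics.
    """
    planes = np.asarray(planes, dtype=float)
    if planes.ndim == 2:
        planes = planes[None]
    rec: dict = {"plane_index": -1, "accepted": False, "reasons": [], "area": 0, "solidity": np.nan}
    try:
        idx = select_midplane(planes, config.threshold_method)
        mask = segment_nucleus(planes[idx], config.threshold_method, plane_index=idx)
    except NoNucleusError:
        rec["reasons"] = ["no_nucleus"]
        return rec
    rec["plane_index"] = idx
    rec["area"] = mask.area
    qc = qc_filter(mask, config.min_area, config.min_solidity, config.allow_border)
    rec["solidity"] = qc.solidity
    rec["reasons"] = qc.reasons
    if not qc.accepted:
        return rec
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # border-truncation warning recorded via QC instead
        dilated = dilate_mask(mask, config.dilation_iterations)
    rings = peel_rings(dilated)
    if rings.n_rings < 2:
        rec["reasons"] = ["no_nucleus"]
        return rec
    means = ring_means(rings, planes[idx])
    profile = interpolate_profile(means, target_length=config.target_length)
    profile = normalize_profile(profile, mode=config.normalization)
    rec.update(
        accepted=True,
        profile=profile,
        n_rings=rings.n_rings,
        metrics=extract_metrics(profile, domain_cap=config.domain_cap, smoothing=config.smoothing),
    )
    return rec


def _fmt_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_periphery_pipeline(image_root, layout: PlateLayout, config: RunConfig, out_dir) -> dict:
    """Analyze every field on the plate and write QC, profile, metric and
    comparison tables (CSV) plus a provenance record.

    Fields in excluded or unmapped wells are skipped (logged in the QC table
    as skipped); unreadable files become per-field error entries and the run
    continues. A condition whose accepted set is empty is an error.
    """
    image_root = Path(image_root)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(list(image_root.glob("*.tif")) + list(image_root.glob("*.tiff")))
    if not paths:
        raise FileNotFoundError(f"no TIFF files under {image_root}")

    qc_rows, metric_rows, profile_rows = [], [], []
    records = []  # (condition, replicate, profile)
    for path in paths:
        well = path.stem.split("_")[0]
        field_id = path.stem
        if well in layout.excluded_wells or well not in layout.wells:
            continue
        info = layout.wells[well]
        try:
            planes, _ = read_stack(path)
            rec = analyze_nucleus_stack(planes, config)
        except Exception as exc:  # unreadable/mismatched file: log and continue
            qc_rows.append(
                {"field": field_id, "well": well, "condition": info.condition,
                 "plane_index": -1, "area": 0, "solidity": np.nan,
                 "accepted": False, "reasons": f"read_error:{type(exc).__name__}"}
            )
            continue
        qc_rows.append(
            {"field": field_id, "well": well, "condition": info.condition,
             "plane_index": rec["plane_index"], "area": rec["area"],
             "solidity": rec["solidity"], "accepted": rec["accepted"],
             "reasons": ";".join(rec["reasons"])}
        )
        if not rec["accepted"]:
            continue
        records.append((info.condition, info.replicate, rec["profile"]))
        row = {"field": field_id, "well": well, "condition": info.condition,
               "replicate": info.replicate, **rec["metrics"].as_dict(),
               "domain_cap": config.domain_cap, "smoothing": config.smoothing}
        metric_rows.append(row)
        for u, v in zip(rec["profile"].positions, rec["profile"].values):
            profile_rows.append(
                {"field": field_id, "condition": info.condition, "u": u, "relative_intensity": v}
            )

    conditions = sorted({info.condition for w, info in layout.wells.items() if w not in layout.excluded_wells})
    accepted_by_cond = {c: [r for r in records if r[0] == c] for c in conditions}
    for c, recs in accepted_by_cond.items():
        if not recs:
            raise NoNucleusError(f"no accepted nuclei for condition {c!r}")

    summaries = []
    for c in conditions:
        recs = accepted_by_cond[c]
        summaries.append(
            aggregate_condition(
                [r[2] for r in recs],
                unit=config.unit,
                replicate_ids=[r[1] for r in recs] if config.unit == "replicate" else None,
                condition=c,
                domain_cap=config.domain_cap,
                smoothing=config.smoothing,
            )
        )
    comparisons = dose_response_table(
        summaries, config.control_label, variant=config.ttest_variant,
        alpha=config.alpha, correction=config.correction,
    )

    mean_rows = []
    for s in summaries:
        u = np.linspace(0, 1, len(s.mean_profile))
        for ui, m, e in zip(u, s.mean_profile, s.sem_profile):
            mean_rows.append({"condition": s.condition, "u": ui, "mean": m, "sem": e})

    _fmt_csv(pd.DataFrame(qc_rows), out_dir / "qc.csv")
    _fmt_csv(pd.DataFrame(metric_rows), out_dir / "metrics.csv")
    _fmt_csv(pd.DataFrame(profile_rows), out_dir / "profiles.csv")
    _fmt_csv(pd.DataFrame(mean_rows), out_dir / "condition_profiles.csv")
    _fmt_csv(comparisons, out_dir / "comparisons.csv")
    config.to_yaml(out_dir / "provenance.yaml")
    return {
        "qc": pd.DataFrame(qc_rows),
        "metrics": pd.DataFrame(metric_rows),
        "summaries": summaries,
        "comparisons": comparisons,
    }


# ---------------------------------------------------------------------------
# Distortion pipeline


def run_distortion_pipeline(pairs_manifest, config: RunConfig, out_dir) -> dict:
    """Register each matched pre/post field, compute its error curve and
    expansion factor, and compare plates by ANOVA + Tukey HSD.

    ``pairs_manifest`` is a CSV path or DataFrame with columns pre_path,
    post_path, plate, field and optionally distance_to_center and pixel_size
    (post-expansion um/px, default 1). Unregistrable fields are flagged and
    excluded from summaries.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pairs_manifest if isinstance(pairs_manifest, pd.DataFrame) else pd.read_csv(pairs_manifest)
    if manifest.empty:
        raise ValueError("pairs manifest is empty")

    rows, curves = [], []
    for _, entry in manifest.iterrows():
        pre, _ = read_stack(entry["pre_path"])
        post, _ = read_stack(entry["post_path"])
        pre2d, post2d = pre.max(axis=0), post.max(axis=0)  # max projections
        ps = float(entry.get("pixel_size", 1.0) or 1.0)
        row = {"plate": entry.get("plate", "plate1"), "field": entry.get("field", ""),
               "distance_to_center": entry.get("distance_to_center", np.nan)}
        try:
            dfield = distortqc.register_nonrigid(
                pre2d, post2d, grid_spacing=config.grid_spacing,
                blur_sigma=config.blur_sigma, feature_quantile=config.feature_quantile,
                pixel_size=ps,
            )
            curve = distortqc.error_curve(
                dfield, n_pairs_per_bin=config.n_pairs_per_bin,
                bin_width=config.bin_width, cutoff=config.cutoff, seed=config.seed,
            )
        except (distortqc.UnregistrableError, ValueError) as exc:
            row.update(registered=False, error=str(exc), avg_percent_error=np.nan,
                       expansion_factor=np.nan)
            rows.append(row)
            continue
        row.update(
            registered=True, error="",
            avg_percent_error=curve.average_percent_error,
            expansion_factor=dfield.similarity.scale,
        )
        rows.append(row)
        for l, r, n in zip(curve.lengths, curve.rmse, curve.n_pairs):
            curves.append({"plate": row["plate"], "field": row["field"],
                           "length_um": l, "rmse_um": r, "n_pairs": n})

    summary = pd.DataFrame(rows)
    _fmt_csv(summary, out_dir / "field_summary.csv")
    _fmt_csv(pd.DataFrame(curves), out_dir / "error_curves.csv")

    ok = summary[summary["registered"]]
    anova = None
    groups = {p: g["expansion_factor"].to_numpy() for p, g in ok.groupby("plate")}
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        anova = distortqc.compare_plates(groups, alpha=config.alpha)
        _fmt_csv(anova.pairwise, out_dir / "plate_tukey.csv")
        (out_dir / "plate_anova.json").write_text(
            json.dumps({"f_statistic": anova.f_statistic, "p_value": anova.p_value}, indent=1)
        )
    config.to_yaml(out_dir / "provenance.yaml")
    return {"summary": summary, "anova": anova}


# ---------------------------------------------------------------------------
# In-memory plate simulation (used for calibration/power studies and examples)


def simulate_plate_metrics(
    seed: int,
    doses=synthim.DEFAULT_DOSES,
    effect_model=None,
    n_replicates: int = 4,
    n_nuclei: int = 25,
    config: RunConfig | None = None,
    **series_kwargs,
) -> pd.DataFrame:
    """Simulate a plate and run the full periphery analysis in memory.

    Each replicate gets an independent seeded batch of nuclei per dose; every
    nucleus image runs through the complete midplane/mask/ring/metric chain.
    Returns per-nucleus rows (condition, replicate, metrics, true amplitude).
    """
    if config is None:
        config = RunConfig(min_area=200.0)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        series = synthim.make_dose_series(
            doses=doses,
            effect_model=effect_model,
            n_nuclei_per_dose=n_nuclei,
            seed=int(rng.integers(0, 2**31 - 1)),
            **series_kwargs,
        )
        for dose, stacks in series.items():
            for stack in stacks:
                rec = analyze_nucleus_stack(stack.planes, config)
                if not rec["accepted"]:
                    continue
                rows.append(
                    {"condition": dose, "replicate": rep,
                     "true_amplitude": stack.nuclei[0][1].peak_amplitude,
                     "profile": rec["profile"], **rec["metrics"].as_dict()}
                )
    return pd.DataFrame(rows)


def dose_response_from_metrics(
    metrics: pd.DataFrame, config: RunConfig | None = None
) -> pd.DataFrame:
    """Aggregate simulated (or pipeline) per-nucleus rows and test each dose
    against control using the configured unit of replication."""
    if config is None:
        config = RunConfig(unit="replicate")
    summaries = []
    for cond, grp in metrics.groupby("condition", sort=True):
        summaries.append(
            aggregate_condition(
                list(grp["profile"]),
                unit=config.unit,
                replicate_ids=grp["replicate"].to_numpy() if config.unit == "replicate" else None,
                condition=cond,
                domain_cap=config.domain_cap,
                smoothing=config.smoothing,
            )
        )
    return dose_response_table(
        summaries, config.control_label, variant=config.ttest_variant,
        alpha=config.alpha, correction=config.correction,
    )
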