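"""End-to-end cohort analysis: QC -> binarization -> vessel exclusion ->
region rasterization -> void metrics -> cohort statistics.

``run_cohort_analysis`` drives the whole chain over a collection of eye
records and produces the cohort report: a tidy per-eye/per-region
metrics table, group-comparison tables (median/IQR + Mann-Whitney) for
the macular subfields, peripapillary annulus, peripheral circles and
whole-region totals, Spearman correlations with choroidal thickness, an
optional between-session reproducibility table, and a provenance block.

Per-eye failures (a region outside all scans, an empty analyzable area)
degrade to missing rows with logged reasons rather than aborting the
cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .binarize import PhansalkarParams, TriStateMap, binarize_cc, normalize_intensity, phansalkar_threshold
from .metrics import VoidMetrics, region_void_metrics
from .regions import (
    MACULAR_SUBFIELDS,
    PERIPHERAL_CIRCLES,
    REGION_NAMES,
    rasterize_region,
    select_scan_for_region,
    standard_regions,
)
from .scan_model import (
    ContractError,
    EmptyRegionError,
    EyeRecord,
    QCError,
    RegionCoverageError,
    qc_filter,
    read_scan,
    write_scan,
)
from .stats import mann_whitney, repeatability_anova, shapiro_wilk, spearman
from .vessel_mask import apply_exclusion, segment_large_vessels

__all__ = [
    "RunConfig",
    "CohortReport",
    "analyze_eye",
    "run_cohort_analysis",
    "write_cohort",
    "read_cohort",
]

log = logging.getLogger("ccvoids")

#: Derived whole-region totals reported alongside the seven base regions.
TOTAL_REGIONS = {"macula": MACULAR_SUBFIELDS, "periphery": PERIPHERAL_CIRCLES}


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of a cohort analysis run."""

    min_ssi: float = 8.0
    phansalkar: PhansalkarParams = field(default_factory=PhansalkarParams)
    min_component_px: int = 50
    dilation_px: int = 2
    min_void_px: int = 1
    regions: tuple[str, ...] = REGION_NAMES
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = list(d["regions"])
        return d


@dataclass
class CohortReport:
    """Cohort-level output tables plus provenance."""

    metrics: pd.DataFrame
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    failures: pd.DataFrame
    repeatability: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "metrics.csv", index=False)
        _format_comparisons(self.comparisons).to_csv(outdir / "comparisons.csv", index=False)
        self.correlations.to_csv(outdir / "correlations.csv", index=False)
        self.failures.to_csv(outdir / "failures.csv", index=False)
        if self.repeatability is not None:
            self.repeatability.to_csv(outdir / "repeatability.csv", index=False)
        (outdir / "provenance.json").write_text(json.dumps(self.provenance, indent=1))
        return outdir


def _format_comparisons(df: pd.DataFrame) -> pd.DataFrame:
    """Human-readable comparison table: 'median (q1-q3)' at one decimal."""
    if df.empty:
        return df
    out = df.copy()
    for grp in ("control", "myopic"):
        out[f"{grp}_median_iqr"] = [
            f"{m:.1f} ({q1:.1f}–{q3:.1f})"
            for m, q1, q3 in zip(df[f"{grp}_median"], df[f"{grp}_q1"], df[f"{grp}_q3"])
        ]
    return out


def analyze_eye(eye: EyeRecord, config: RunConfig = RunConfig()) -> tuple[list[VoidMetrics], list[tuple[str, str]]]:
    """Run the image chain for one eye.

    Returns per-region :class:`VoidMetrics` and a list of
    ``(region, reason)`` failures.  Each region is measured on one scan:
    the central scan when it fully contains the region, else the gaze
    scan nearest the region centre.
    """
    retained = qc_filter(eye.scans, config.min_ssi)
    cc_scans = {s.gaze: s for s in retained if s.slab == "CC"}
    scp_scans = {s.gaze: s for s in retained if s.slab == "SCP"}
    usable = {g: cc_scans[g].geometry for g in cc_scans if g in scp_scans}
    failures: list[tuple[str, str]] = []
    if not usable:
        return [], [(name, "no CC+SCP scan pair passed QC") for name in config.regions]
    specs = standard_regions(eye.fovea_mm, eye.disc_center_mm, eye.disc_radius_mm, eye.laterality)
    tsmap_cache: dict[str, TriStateMap] = {}
    results: list[VoidMetrics] = []
    for name in config.regions:
        spec = specs[name]
        try:
            gaze = select_scan_for_region(spec, usable)
            if gaze not in tsmap_cache:
                cc = cc_scans[gaze]
                norm, constant = normalize_intensity(cc)
                if constant:
                    raise EmptyRegionError("constant CC image (no dynamic range)")
                thresholds = phansalkar_threshold(norm, config.phansalkar)
                tsmap = binarize_cc(norm, thresholds)
                mask = segment_large_vessels(
                    scp_scans[gaze], config.min_component_px, config.dilation_px
                )
                tsmap_cache[gaze] = apply_exclusion(tsmap, mask)
            geometry = usable[gaze]
            region_mask = rasterize_region(spec, geometry)
            results.append(
                region_void_metrics(
                    tsmap_cache[gaze], region_mask, geometry,
                    region=name, min_void_px=config.min_void_px,
                )
            )
        except (RegionCoverageError, EmptyRegionError) as exc:
            log.warning("eye %s region %s skipped: %s", eye.subject_id, name, exc)
            failures.append((name, str(exc)))
    return results, failures


def _metrics_frame(cohort: Sequence[EyeRecord], config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, fail_rows = [], []
    for eye in cohort:
        mets, fails = analyze_eye(eye, config)
        for m in mets:
            rows.append(
                {
                    "subject_id": eye.subject_id,
                    "group": eye.group,
                    "region": m.region,
                    "analyzable_area_mm2": m.analyzable_area_mm2,
                    "analyzable_px": m.analyzable_px,
                    "void_px": m.void_px,
                    "total_void_area_pct": m.total_void_area_pct,
                    "void_count": m.void_count,
                    "mean_void_area_um2": m.mean_void_area_um2,
                }
            )
        for region, reason in fails:
            fail_rows.append({"subject_id": eye.subject_id, "region": region, "reason": reason})
    return pd.DataFrame(rows), pd.DataFrame(fail_rows, columns=["subject_id", "region", "reason"])


def _add_totals(metrics: pd.DataFrame) -> pd.DataFrame:
    """Whole-region rows: analyzable-area-weighted combination of subfields."""
    extra = []
    for total_name, parts in TOTAL_REGIONS.items():
        sub = metrics[metrics["region"].isin(parts)]
        for (sid, grp), g in sub.groupby(["subject_id", "group"], sort=False):
            if len(g) < len(parts):
                continue  # a subfield failed; no total for this eye
            apx = int(g["analyzable_px"].sum())
            vpx = int(g["void_px"].sum())
            count = int(g["void_count"].sum())
            area_um2 = float((g["mean_void_area_um2"].fillna(0) * g["void_count"]).sum())
            extra.append(
                {
                    "subject_id": sid,
                    "group": grp,
                    "region": total_name,
                    "analyzable_area_mm2": float(g["analyzable_area_mm2"].sum()),
                    "analyzable_px": apx,
                    "void_px": vpx,
                    "total_void_area_pct": 100.0 * vpx / apx,
                    "void_count": count,
                    "mean_void_area_um2": area_um2 / count if count else float("nan"),
                }
            )
    if extra:
        metrics = pd.concat([metrics, pd.DataFrame(extra)], ignore_index=True)
    return metrics


def _comparisons(metrics: pd.DataFrame) -> pd.DataFrame:
    rows = []
    order = list(REGION_NAMES) + list(TOTAL_REGIONS)
    for region in order:
        sub = metrics[metrics["region"] == region]
        a = sub.loc[sub["group"] == "control", "total_void_area_pct"].to_numpy()
        b = sub.loc[sub["group"] == "myopic", "total_void_area_pct"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        u, p = mann_whitney(b, a)  # U reported for the myopic sample
        row = {"region": region, "n_control": len(a), "n_myopic": len(b)}
        for name, vals in (("control", a), ("myopic", b)):
            row[f"{name}_median"] = float(np.median(vals))
            row[f"{name}_q1"] = float(np.percentile(vals, 25))
            row[f"{name}_q3"] = float(np.percentile(vals, 75))
            row[f"{name}_shapiro_p"] = shapiro_wilk(vals)[1] if len(vals) >= 3 else float("nan")
        row["u_statistic"] = u
        row["p_value"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def _correlations(metrics: pd.DataFrame, cohort: Sequence[EyeRecord]) -> pd.DataFrame:
    """Spearman rho between myopic void percent and choroidal thickness."""
    thick = {
        (eye.subject_id, region): value
        for eye in cohort
        if eye.group == "myopic"
        for region, value in eye.choroidal_thickness_um.items()
    }
    rows = []
    for region in REGION_NAMES:
        sub = metrics[(metrics["region"] == region) & (metrics["group"] == "myopic")]
        pairs = [
            (v, thick[(sid, region)])
            for sid, v in zip(sub["subject_id"], sub["total_void_area_pct"])
            if (sid, region) in thick
        ]
        if len(pairs) < 3:
            continue
        x, y = zip(*pairs)
        rho, p = spearman(x, y)
        rows.append({"region": region, "n": len(pairs), "rho": rho, "p_value": p})
    return pd.DataFrame(rows, columns=["region", "n", "rho", "p_value"])


def run_cohort_analysis(
    cohort: Sequence[EyeRecord],
    config: RunConfig = RunConfig(),
    repeat_cohort: Sequence[EyeRecord] | None = None,
) -> CohortReport:
    """Analyze a cohort end to end and assemble the report.

    Raises :class:`QCError` when quality control leaves no analyzable
    eye.  Deterministic given the cohort and configuration.
    """
    if not cohort:
        raise ContractError("cohort is empty")
    ids = [eye.subject_id for eye in cohort]
    if len(set(ids)) != len(ids):
        raise ContractError("one eye per subject: duplicate subject_id in cohort")
    metrics, failures = _metrics_frame(cohort, config)
    if metrics.empty:
        raise QCError("no eye produced any analyzable region after QC")
    metrics = _add_totals(metrics)
    comparisons = _comparisons(metrics)
    correlations = _correlations(metrics, cohort)
    repeatability = None
    if repeat_cohort is not None:
        m2, _ = _metrics_frame(repeat_cohort, config)
        m2 = _add_totals(m2)
        rows = []
        for region in list(REGION_NAMES) + list(TOTAL_REGIONS):
            s1 = metrics[metrics["region"] == region].set_index("subject_id")["total_void_area_pct"]
            s2 = m2[m2["region"] == region].set_index("subject_id")["total_void_area_pct"]
            common = s1.index.intersection(s2.index)
            if len(common) < 2:
                continue
            f, p = repeatability_anova(s1.loc[common].to_numpy(), s2.loc[common].to_numpy())
            rows.append({"region": region, "n": len(common), "f_statistic": f, "p_value": p})
        repeatability = pd.DataFrame(rows, columns=["region", "n", "f_statistic", "p_value"])
    provenance = {
        "software": f"ccvoids {_version}",
        "config": config.to_dict(),
        "n_eyes": len(cohort),
        "n_eyes_with_metrics": int(metrics["subject_id"].nunique()),
        "void_pct_denominator": "analyzable area (region minus vessel exclusion)",
        "multiple_testing_correction": "none",
    }
    return CohortReport(
        metrics=metrics,
        comparisons=comparisons,
        correlations=correlations,
        failures=failures,
        repeatability=repeatability,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# cohort directory interchange
# ---------------------------------------------------------------------------

def write_cohort(
    eyes: Sequence[EyeRecord],
    outdir: str | Path,
    truth: pd.DataFrame | None = None,
) -> Path:
    """Write a cohort directory: per-eye scans (TIFF + JSON sidecars),
    per-eye metadata, one covariate CSV row per eye, optional truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cov_rows = []
    for eye in eyes:
        eyedir = outdir / eye.subject_id
        eyedir.mkdir(exist_ok=True)
        for scan in eye.scans:
            write_scan(scan, eyedir / f"{scan.slab}_{scan.gaze}.tif")
        meta = {
            "subject_id": eye.subject_id,
            "group": eye.group,
            "axial_length_mm": eye.axial_length_mm,
            "choroidal_thickness_um": eye.choroidal_thickness_um,
            "fovea_mm": list(eye.fovea_mm),
            "disc_center_mm": list(eye.disc_center_mm),
            "disc_radius_mm": eye.disc_radius_mm,
        }
        (eyedir / "eye.json").write_text(json.dumps(meta, indent=1))
        cov_rows.append(
            {
                "subject_id": eye.subject_id,
                "group": eye.group,
                "axial_length_mm": eye.axial_length_mm,
                "laterality": eye.laterality,
            }
        )
    pd.DataFrame(cov_rows).to_csv(outdir / "covariates.csv", index=False)
    if truth is not None:
        truth.to_csv(outdir / "truth.csv", index=False)
    return outdir


def read_cohort(indir: str | Path) -> tuple[list[EyeRecord], pd.DataFrame | None]:
    """Read a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    if not indir.is_dir():
        raise FileNotFoundError(f"cohort directory not found: {indir}")
    eyes = []
    for eyedir in sorted(p for p in indir.iterdir() if p.is_dir()):
        meta_path = eyedir / "eye.json"
        if not meta_path.exists():
            raise FileNotFoundError(f"missing metadata file: {meta_path}")
        meta = json.loads(meta_path.read_text())
        scans = [read_scan(p) for p in sorted(eyedir.glob("*.tif"))]
        eyes.append(
            EyeRecord(
                subject_id=meta["subject_id"],
                group=meta["group"],
                axial_length_mm=meta["axial_length_mm"],
                scans=scans,
                choroidal_thickness_um=meta.get("choroidal_thickness_um", {}),
                fovea_mm=tuple(meta.get("fovea_mm", (0.0, 0.0))),
                disc_center_mm=tuple(meta.get("disc_center_mm", (4.5, 0.0))),
                disc_radius_mm=meta.get("disc_radius_mm", 0.75),
            )
        )
    truth_path = indir / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return eyes, truth
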