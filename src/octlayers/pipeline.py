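"""End-to-end pipeline: simulate -> segment -> analyze, with config and manifest.

All coordinates in output files are 0-based with half-open intervals.  Every
output is a pure function of (manifest, config, seed): re-running a stage
over the same inputs reproduces its files byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers as bm
from . import stats as st
from .preprocess import BScanImage, GaborBankParams, denoise, trim_optic_disc
from .segment import LayerSet, SegmentParams, segment_layers
from .synth import CohortParams, NoiseParams, generate_cohort, write_cohort

log = logging.getLogger("octlayers")

__all__ = [
    "PipelineConfig",
    "Manifest",
    "cmd_simulate",
    "cmd_segment",
    "cmd_analyze",
    "run_all",
]

SSI_THRESHOLD = 40.0  # device signal-strength index below which scans are excluded


@dataclass
class PipelineConfig:
    """All stage parameters in one serializable object."""

    seed: int = 0
    # preprocessing
    gaussian_kernel_size: int = 11
    disc_trim_fraction: float = 0.15
    gabor_kernel_size: int = 6
    gabor_orientations: tuple[float, ...] = (0.0, float(np.pi / 2))
    gabor_wavelengths: tuple[float, ...] = (4.0,)
    # segmentation
    svr_dilation: float = 0.016
    svr_c: float = 100.0
    svr_epsilon_px: float = 0.25
    mislabel_threshold_px: float = 8.0
    # biomarkers
    zone_fraction: float = 0.20
    # simulation
    n_eyes: dict = field(default_factory=lambda: {"normal": 33, "NPDR": 36, "PDR": 15})
    orientations: tuple[str, ...] = ("horizontal",)
    speckle_shape: float | None = 16.0
    depth_scale: float = 0.33
    # statistics
    benjamini_hochberg: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gabor_orientations"] = list(self.gabor_orientations)
        d["gabor_wavelengths"] = list(self.gabor_wavelengths)
        d["orientations"] = list(self.orientations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("gabor_orientations", "gabor_wavelengths", "orientations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                import yaml

                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                import yaml

                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d)

    # stage-parameter views -------------------------------------------------
    def gabor_bank(self) -> GaborBankParams:
        return GaborBankParams(kernel_size=self.gabor_kernel_size,
                               orientations=self.gabor_orientations,
                               wavelengths=self.gabor_wavelengths)

    def segment_params(self) -> SegmentParams:
        return SegmentParams(dilation=self.svr_dilation, svr_c=self.svr_c,
                             epsilon_px=self.svr_epsilon_px,
                             mislabel_threshold_px=self.mislabel_threshold_px,
                             gabor=self.gabor_bank())

    def cohort_params(self, seed: int | None = None) -> CohortParams:
        return CohortParams(
            n_eyes=dict(self.n_eyes), orientations=tuple(self.orientations),
            seed=self.seed if seed is None else seed,
            depth_scale=self.depth_scale, trim_fraction=self.disc_trim_fraction,
            zone_fraction=self.zone_fraction,
            noise=NoiseParams(speckle_shape=self.speckle_shape),
        )


MANIFEST_COLUMNS = ["scan_path", "scan_id", "patient_id", "eye", "orientation",
                    "laterality", "disc_side", "group", "age", "sex", "quality_ssi"]


@dataclass
class Manifest:
    """The cohort manifest: one row per scan file."""

    table: pd.DataFrame
    root: Path

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if self.table["scan_path"].duplicated().any():
            raise ValueError("manifest scan paths must be unique")
        bad = set(self.table["group"]) - {"normal", "NPDR", "PDR"}
        if bad:
            raise ValueError(f"unknown groups in manifest: {sorted(bad)}")

    @classmethod
    def load(cls, path: str | Path) -> "Manifest":
        path = Path(path)
        return cls(table=pd.read_csv(path), root=path.parent)

    @property
    def excluded(self) -> pd.Series:
        """Quality gate: scans with SSI below threshold are flagged excluded."""
        ssi = pd.to_numeric(self.table["quality_ssi"], errors="coerce")
        return ssi < SSI_THRESHOLD

    def __len__(self) -> int:
        return len(self.table)


def cmd_simulate(config: PipelineConfig, outdir: str | Path,
                 seed: int | None = None) -> pd.DataFrame:
    """Generate the synthetic cohort on disk; returns the manifest table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.cohort_params(seed))
    manifest = write_cohort(cohort, outdir)
    config.save(outdir / "config.json")
    log.info("simulated %d scans into %s", len(manifest), outdir)
    return manifest


def _segment_one(img: BScanImage, config: PipelineConfig) -> tuple[LayerSet, int]:
    den = denoise(img, kernel_size=config.gaussian_kernel_size)
    trimmed, offset = trim_optic_disc(den, config.disc_trim_fraction) \
        if img.orientation == "horizontal" else (den, 0)
    layers = segment_layers(trimmed, config.segment_params())
    return layers, offset


def save_overlay(img: BScanImage, layers: LayerSet, path: str | Path,
                 column_offset: int = 0) -> None:
    """QC overlay: IPL green, OPL band blue, EZ orange, on the grayscale scan."""
    import imageio.v3 as iio

    rgb = np.stack([img.pixels] * 3, axis=-1)
    h = img.height

    def paint(depth, cols, color):
        rr = np.clip(np.round(depth).astype(int), 0, h - 1)
        rgb[rr, cols] = color

    cols = layers.ipl.columns + column_offset
    cols = np.clip(cols, 0, img.width - 1)
    paint(layers.ipl.depth, cols, (0.0, 0.9, 0.1))
    paint(layers.opl_upper.depth, cols, (0.1, 0.3, 1.0))
    paint(layers.opl_lower.depth, cols, (0.1, 0.3, 1.0))
    paint(layers.ez.depth, cols, (1.0, 0.6, 0.0))
    iio.imwrite(path, np.round(rgb * 255).astype(np.uint8))


def cmd_segment(manifest: Manifest, config: PipelineConfig, outdir: str | Path,
                overlays: bool = False) -> list[str]:
    """Segment every included scan; one LayerSet CSV (+ optional overlay) each.

    Scans failing the SSI quality gate are skipped with a log entry.
    Per-scan failures are logged and the run continues; an error is raised
    only if every scan fails.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    done, failed = [], []
    excluded = manifest.excluded
    for i, row in manifest.table.iterrows():
        sid = row["scan_id"]
        if excluded.iloc[i]:
            log.warning("skipping %s: SSI %.1f below %.0f", sid,
                        row["quality_ssi"], SSI_THRESHOLD)
            continue
        try:
            img = BScanImage.from_file(
                manifest.root / row["scan_path"],
                orientation=row["orientation"], laterality=row["laterality"],
                disc_side=row["disc_side"],
                quality_ssi=float(row["quality_ssi"]))
            layers, offset = _segment_one(img, config)
            df = layers.to_frame(column_offset=offset)
            df.to_csv(outdir / f"{sid}.layers.csv", index=False)
            with open(outdir / f"{sid}.layers.json", "w") as fh:
                json.dump({"scan_id": sid, "column_offset": offset,
                           "coordinates": "0-based half-open, original image frame"},
                          fh)
            if overlays:
                trimmed, _ = trim_optic_disc(img, config.disc_trim_fraction) \
                    if img.orientation == "horizontal" else (img, 0)
                save_overlay(trimmed, layers, outdir / f"{sid}.overlay.png")
            done.append(sid)
        except Exception as exc:  # per-scan isolation
            log.error("scan %s failed: %s", sid, exc)
            failed.append(sid)
    if not done:
        raise RuntimeError(f"all {len(failed)} scans failed segmentation")
    return done


def _record_for_scan(layers: LayerSet, offset: int, row: pd.Series,
                     config: PipelineConfig) -> bm.BiomarkerRecord:
    orientation = row["orientation"]
    fov = bm.locate_fovea(layers, orientation)
    part = bm.partition_zones((layers.start, layers.end), fov.column,
                              orientation, laterality=row["laterality"],
                              disc_side=row["disc_side"],
                              zone_fraction=config.zone_fraction)
    return bm.compute_record(layers, part, patient_id=row["patient_id"],
                             eye=row["eye"], group=row["group"],
                             age=float(row["age"]), sex=row["sex"])


def cmd_analyze(manifest: Manifest, layers_dir: str | Path,
                config: PipelineConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Biomarker table + GEE comparison table + ROC table.

    The biomarker CSV has one row per eye, columns named in the
    ``VAR.H.zone`` / ``VAR.V.zone`` scheme.  ROC is run for the two clinical
    contrasts: diabetic (NPDR+PDR) vs normal, and PDR vs NPDR.
    """
    layers_dir, outdir = Path(layers_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for _, row in manifest.table.iterrows():
        sid = row["scan_id"]
        fp = layers_dir / f"{sid}.layers.csv"
        if not fp.exists():
            continue
        with open(layers_dir / f"{sid}.layers.json") as fh:
            offset = json.load(fh)["column_offset"]
        layers = LayerSet.from_frame(pd.read_csv(fp), column_offset=offset)
        records.append(_record_for_scan(layers, offset, row, config))
    if not records:
        raise ValueError("no layer sets found to analyze")
    missing_age = [r.patient_id for r in records if not np.isfinite(r.age)]
    if missing_age:
        raise ValueError(f"missing age covariate for: {sorted(set(missing_age))}")

    rows = pd.DataFrame([r.to_row() for r in records])
    covar_cols = ["patient_id", "eye", "group", "age", "sex"]
    value_cols = [c for c in rows.columns if c not in covar_cols]
    merged = rows.groupby(["patient_id", "eye"], as_index=False).agg(
        {**{c: "first" for c in ["group", "age", "sex"]},
         **{c: "mean" for c in value_cols}})
    merged = merged[covar_cols + sorted(value_cols)]
    merged.to_csv(outdir / "biomarkers.csv", index=False, float_format="%.6f")

    groups_present = sorted(merged["group"].unique())
    comparison_rows = []
    if set(groups_present) >= {"normal", "NPDR", "PDR"}:
        for var in sorted(value_cols):
            if merged[var].dropna().empty:
                continue
            try:
                contrast = st.pairwise_contrasts(merged, var)
            except Exception as exc:
                log.warning("GEE failed for %s: %s", var, exc)
                continue
            comparison_rows.append({"biomarker": var, **contrast})
    else:
        log.warning("pairwise GEE table skipped: need all three groups, have %s",
                    groups_present)
    comparison = pd.DataFrame(comparison_rows)
    if len(comparison):
        if config.benjamini_hochberg:
            from statsmodels.stats.multitest import multipletests

            comparison["p_overall_bh"] = multipletests(
                comparison["p_overall"], method="fdr_bh")[1]
        comparison.to_csv(outdir / "comparisons.csv", index=False,
                          float_format="%.6g")

    roc_rows = []
    contrasts = {
        "diabetic_vs_normal": (merged["group"].isin(["NPDR", "PDR"]).astype(int),
                               merged["group"].notna()),
        "PDR_vs_NPDR": ((merged["group"] == "PDR").astype(int),
                        merged["group"].isin(["NPDR", "PDR"])),
    }
    for name, (labels, rows_mask) in contrasts.items():
        for var in sorted(value_cols):
            sub = merged[rows_mask]
            lab = labels[rows_mask]
            ok = sub[var].notna()
            if lab[ok].nunique() < 2 or ok.sum() < 4:
                continue
            r = st.roc_auc(sub.loc[ok, var], lab[ok])
            roc_rows.append({"contrast": name, "biomarker": var,
                             "auc": r.auc, "ci_low": r.ci_low,
                             "ci_high": r.ci_high, "polarity": r.polarity,
                             "n": int(ok.sum())})
    roc = pd.DataFrame(roc_rows)
    if len(roc):
        roc.to_csv(outdir / "roc.csv", index=False, float_format="%.6g")
    return {"biomarkers": merged, "comparisons": comparison, "roc": roc}


def run_all(config: PipelineConfig, outdir: str | Path,
            seed: int | None = None, overlays: bool = False) -> dict[str, pd.DataFrame]:
    """simulate -> segment -> analyze in one call; returns analyze's tables."""
    outdir = Path(outdir)
    cmd_simulate(config, outdir, seed=seed)
    manifest = Manifest.load(outdir / "manifest.csv")
    cmd_segment(manifest, config, outdir / "layers", overlays=overlays)
    return cmd_analyze(manifest, outdir / "layers", config, outdir / "analysis")
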