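"""End-to-end orchestration: quantify a study, compare modalities, report.

``run_quantify`` walks a study manifest per animal and modality:
preprocess every frame, register each consecutive-week pair (earlier week
fixed, later week moving), segment each visit, then compute per-visit
vessel density, per-interval vessel growth density on the common overlay
region, and same-session repeatability errors from replicate scans.
Failed registrations are logged and excluded from downstream statistics,
never silently dropped.

``run_compare_modalities`` matches OCTA and ICGA growth measurements of
the same (animal, interval) and computes Bland-Altman limits of
agreement, Pearson correlation and the paired t-test, pooled and
stratified by treatment arm.

``run_report`` renders the weekly density trend per arm/route, the
Bland-Altman plots and a machine-readable JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ArtefactSaturationError,
    DegenerateImageError,
    RegistrationFailure,
    SampleSizeError,
    ValidationError,
)
from .io_formats import (
    ImageFrame,
    MeasurementTable,
    StudyManifest,
    read_image,
    write_image,
    write_measurements,
)
from .preprocessing import DEFAULT_PREPROCESS, PreprocessParams, preprocess
from .quantification import growth_density, repeatability_error, vessel_density
from .registration import register_pair
from .segmentation import (
    DEFAULT_SEGMENTATION,
    BinaryVesselMask,
    SegmentationParams,
    segment_frame,
)
from .stats import bland_altman, group_summary, paired_t_test, pearson_correlation

logger = logging.getLogger("cnvquant")

ROI_FULL = "full"
ROI_LIMBAL_DISK = "limbal_disk"


@dataclass
class PipelineConfig:
    """Resolved configuration of one quantification run."""

    preprocess: dict[str, PreprocessParams] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_PREPROCESS.items()}
    )
    segmentation: dict[str, SegmentationParams] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_SEGMENTATION.items()}
    )
    registration_floor: float = 0.2
    registration_max_rotation_deg: float = 10.0
    roi: str = ROI_LIMBAL_DISK
    roi_radius_frac: float = 0.46  # matches the simulator's limbal arc
    register_replicates: bool = False
    save_intermediates: bool = False
    seed: int = 0

    _KNOWN_KEYS = {
        "preprocess",
        "segmentation",
        "registration_floor",
        "registration_max_rotation_deg",
        "roi",
        "roi_radius_frac",
        "register_replicates",
        "save_intermediates",
        "seed",
    }

    def validate(self) -> None:
        for p in self.preprocess.values():
            p.validate()
        for s in self.segmentation.values():
            s.validate()
        if not -1.0 <= self.registration_floor <= 1.0:
            raise ValidationError("registration_floor must lie in [-1, 1]")
        if self.roi not in (ROI_FULL, ROI_LIMBAL_DISK):
            raise ValidationError(f"unknown roi spec {self.roi!r}")
        if not 0.0 < self.roi_radius_frac <= 0.5:
            raise ValidationError("roi_radius_frac must lie in (0, 0.5]")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - cls._KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for section, params_cls in (("preprocess", PreprocessParams),
                                    ("segmentation", SegmentationParams)):
            block = data.get(section)
            if block is not None:
                parsed = dict(getattr(cfg, section))  # keep unmentioned modalities
                for modality, fields_ in block.items():
                    defaults = getattr(cfg, section).get(modality)
                    base = {} if defaults is None else dict(vars(defaults))
                    unknown_f = set(fields_) - set(vars(params_cls()))
                    if unknown_f:
                        raise ValidationError(
                            f"unknown {section} keys for {modality}: {sorted(unknown_f)}"
                        )
                    base.update(fields_)
                    if "scales" in base:
                        base["scales"] = tuple(base["scales"])
                    parsed[modality] = params_cls(**base)
                setattr(cfg, section, parsed)
        for key in cls._KNOWN_KEYS - {"preprocess", "segmentation"}:
            if key in data:
                setattr(cfg, key, data[key])
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def resolved(self) -> dict:
        """Echo of every parameter actually used (for the run log)."""
        return {
            "preprocess": {k: vars(v) for k, v in self.preprocess.items()},
            "segmentation": {k: vars(v) for k, v in self.segmentation.items()},
            "registration_floor": self.registration_floor,
            "registration_max_rotation_deg": self.registration_max_rotation_deg,
            "roi": self.roi,
            "roi_radius_frac": self.roi_radius_frac,
            "register_replicates": self.register_replicates,
            "save_intermediates": self.save_intermediates,
            "seed": self.seed,
        }

    def build_roi(self, shape: tuple[int, int]) -> np.ndarray:
        if self.roi == ROI_FULL:
            return np.ones(shape, dtype=bool)
        h, w = shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        radius = self.roi_radius_frac * min(shape)
        yy, xx = np.mgrid[0:h, 0:w]
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


@dataclass
class QuantifyResult:
    table: MeasurementTable
    repeatability: pd.DataFrame  # animal, modality, week, arm, route, error_pct
    registration_failures: list[dict]
    registration_scores: pd.DataFrame  # animal, modality, interval, score, dx, dy, rot


def _load_frames(
    manifest: StudyManifest, base_dir: Path
) -> dict[tuple[str, str, int, int], ImageFrame]:
    frames = {}
    for rec in manifest:
        path = Path(rec.file_path)
        if not path.is_absolute():
            path = base_dir / path
        frames[rec.key] = read_image(path, rec)
    return frames


def run_quantify(
    manifest: StudyManifest,
    config: PipelineConfig | None = None,
    base_dir: str | Path = ".",
    out_dir: str | Path | None = None,
) -> QuantifyResult:
    """Quantify a whole study: densities, growths, repeatability.

    ``base_dir`` anchors relative manifest paths.  When ``out_dir`` is
    given the measurement table, repeatability table and (with
    ``save_intermediates``) per-stage images are written there.
    """
    config = config or PipelineConfig()
    config.validate()
    logger.info("resolved config: %s", json.dumps(config.resolved(), default=str))
    base_dir = Path(base_dir)
    frames = _load_frames(manifest, base_dir)

    rows = []
    repeat_rows = []
    failures: list[dict] = []
    reg_rows = []
    groups = sorted({(r.animal_id, r.modality) for r in manifest})
    for animal, modality in groups:
        recs = manifest.select(animal_id=animal, modality=modality)
        weeks = sorted({r.week for r in recs})
        arm, route = recs[0].arm, recs[0].route
        pre_params = config.preprocess.get(modality)
        seg_params = config.segmentation.get(modality)

        processed: dict[tuple[int, int], ImageFrame] = {}
        masks: dict[tuple[int, int], BinaryVesselMask] = {}
        roi = None
        for rec in recs:
            try:
                frame = preprocess(frames[rec.key], pre_params)
            except ArtefactSaturationError as exc:
                logger.warning(
                    "%s %s week %s rep %s unusable: %s",
                    animal, modality, rec.week, rec.replicate, exc,
                )
                continue
            if roi is None:
                roi = config.build_roi(frame.shape)
            processed[(rec.week, rec.replicate)] = frame
            masks[(rec.week, rec.replicate)] = segment_frame(frame, roi, seg_params)

        # per-visit density from replicate 1, repeatability from (1, 2)
        densities = {}
        for week in weeks:
            if (week, 1) not in masks:
                continue
            meas = vessel_density(masks[(week, 1)])
            densities[week] = meas
            reps = sorted(r for (w, r) in masks if w == week)
            if len(reps) >= 2:
                err = repeatability_error(masks[(week, reps[0])], masks[(week, reps[1])])
                repeat_rows.append(
                    {
                        "animal_id": animal,
                        "modality": modality,
                        "week": week,
                        "arm": arm,
                        "route": route,
                        "repeatability_error_pct": err,
                    }
                )

        # consecutive-week growth on the registered common region
        growths = {}
        for week_a, week_b in zip(weeks[:-1], weeks[1:]):
            if week_b != week_a + 1:
                continue
            if (week_a, 1) not in processed or (week_b, 1) not in processed:
                continue
            try:
                reg = register_pair(
                    processed[(week_b, 1)],
                    processed[(week_a, 1)],
                    max_rotation_deg=config.registration_max_rotation_deg,
                    score_floor=config.registration_floor,
                )
            except (RegistrationFailure, DegenerateImageError) as exc:
                logger.warning(
                    "registration failed for %s %s weeks %d-%d: %s",
                    animal, modality, week_a, week_b, exc,
                )
                failures.append(
                    {
                        "animal_id": animal,
                        "modality": modality,
                        "interval": f"{week_a}-{week_b}",
                        "reason": str(exc),
                    }
                )
                continue
            reg_rows.append(
                {
                    "animal_id": animal,
                    "modality": modality,
                    "interval": f"{week_a}-{week_b}",
                    "score": reg.score,
                    "dx": reg.transform.dx,
                    "dy": reg.transform.dy,
                    "rotation_deg": reg.transform.rotation_deg,
                }
            )
            growth, change = growth_density(masks[(week_a, 1)], masks[(week_b, 1)], reg)
            growths[week_b] = growth
            if out_dir is not None and config.save_intermediates:
                gallery = Path(out_dir) / "change_maps"
                gallery.mkdir(parents=True, exist_ok=True)
                write_image(
                    change.to_rgb(),
                    gallery / f"{animal}_{modality}_w{week_a}-w{week_b}.png",
                )

        for week in weeks:
            if week not in densities:
                continue
            growth = growths.get(week)
            rows.append(
                {
                    "animal_id": animal,
                    "modality": modality,
                    "week": week,
                    "arm": arm,
                    "route": route,
                    "vessel_density_pct": densities[week].vessel_density_pct,
                    "growth_density_pct": (
                        np.nan if growth is None else growth.growth_density_pct
                    ),
                    "interval": "" if growth is None else f"{week - 1}-{week}",
                }
            )

    table = MeasurementTable(data=pd.DataFrame(rows))
    repeatability = pd.DataFrame(
        repeat_rows,
        columns=[
            "animal_id", "modality", "week", "arm", "route",
            "repeatability_error_pct",
        ],
    )
    reg_scores = pd.DataFrame(
        reg_rows,
        columns=["animal_id", "modality", "interval", "score", "dx", "dy", "rotation_deg"],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_measurements(table, out / "measurements.csv")
        repeatability.to_csv(out / "repeatability.csv", index=False)
        reg_scores.to_csv(out / "registrations.csv", index=False)
        if failures:
            (out / "registration_failures.json").write_text(json.dumps(failures, indent=2))
    return QuantifyResult(
        table=table,
        repeatability=repeatability,
        registration_failures=failures,
        registration_scores=reg_scores,
    )


def matched_growth_pairs(table: MeasurementTable) -> pd.DataFrame:
    """OCTA/ICGA growth measurements matched by (animal, interval)."""
    df = table.data
    df = df[df["interval"].astype(str).str.len() > 0]
    df = df[np.isfinite(df["growth_density_pct"].astype(float))]
    wide = df.pivot_table(
        index=["animal_id", "interval", "arm", "route"],
        columns="modality",
        values="growth_density_pct",
        aggfunc="first",
    ).reset_index()
    if "OCTA" not in wide.columns or "ICGA" not in wide.columns:
        return pd.DataFrame(columns=["animal_id", "interval", "arm", "route", "OCTA", "ICGA"])
    return wide.dropna(subset=["OCTA", "ICGA"])


def run_compare_modalities(table: MeasurementTable) -> dict:
    """Between-modality agreement of growth densities, pooled and per arm.

    Raises :class:`SampleSizeError` with fewer than 3 matched pairs.
    """
    pairs = matched_growth_pairs(table)
    if len(pairs) < 3:
        raise SampleSizeError(
            f"modality comparison needs >= 3 matched pairs, got {len(pairs)}"
        )

    def agreement(sub: pd.DataFrame) -> dict:
        x = sub["OCTA"].to_numpy(float)
        y = sub["ICGA"].to_numpy(float)
        out = {"n": len(sub), "bland_altman": bland_altman(x, y).to_dict()}
        try:
            out["pearson"] = vars(pearson_correlation(x, y))
            out["paired_t"] = vars(paired_t_test(x, y))
        except (ValidationError, SampleSizeError) as exc:
            out["note"] = str(exc)
        return out

    report = {"pooled": agreement(pairs), "by_arm": {}}
    for arm, sub in pairs.groupby("arm"):
        if len(sub) >= 3:
            report["by_arm"][arm] = agreement(sub)
        else:
            report["by_arm"][arm] = {"n": len(sub), "note": "fewer than 3 pairs"}
    assert sum(len(s) for _, s in pairs.groupby("arm")) == len(pairs)
    return report


def run_report(
    table: MeasurementTable,
    stats_report: dict | None,
    out_dir: str | Path,
    repeatability: pd.DataFrame | None = None,
) -> dict:
    """Write the report bundle: trend plot, Bland-Altman plots, JSON summary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = table.data
    summary: dict = {"n_measurements": int(len(df)), "figures": []}

    if len(df) == 0:
        summary["note"] = "no data"
    else:
        fig, ax = plt.subplots(figsize=(7, 5))
        for (arm, route), sub in df[df["modality"] == "OCTA"].groupby(["arm", "route"]):
            g = sub.groupby("week")["vessel_density_pct"].agg(["mean", "std"])
            ax.errorbar(
                g.index, g["mean"], yerr=g["std"].fillna(0.0),
                marker="o", capsize=3, label=f"{arm} / {route}",
            )
        ax.set_xlabel("study week")
        ax.set_ylabel("vessel density (%)")
        ax.set_title("Weekly vessel density by arm (OCTA)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        trend_path = out / "trend_density_by_arm.png"
        fig.savefig(trend_path, dpi=120)
        plt.close(fig)
        summary["figures"].append(trend_path.name)

        trend = {}
        for (arm, route), sub in df.groupby(["arm", "route"]):
            for modality, sub2 in sub.groupby("modality"):
                weekly = {}
                for week, sub3 in sub2.groupby("week"):
                    weekly[int(week)] = group_summary(
                        sub3["vessel_density_pct"].to_numpy(float)
                    ).to_dict()
                trend[f"{arm}|{route}|{modality}"] = weekly
        summary["weekly_density"] = trend

    if stats_report is not None:
        summary["modality_agreement"] = stats_report
        for scope, block in [("pooled", stats_report.get("pooled", {}))] + list(
            stats_report.get("by_arm", {}).items()
        ):
            ba = block.get("bland_altman")
            if not ba:
                continue
            pairs = np.asarray(ba["pairs"], dtype=float)
            fig, ax = plt.subplots(figsize=(6, 4.5))
            ax.scatter(pairs[:, 0], pairs[:, 1], s=18, alpha=0.8)
            ax.axhline(ba["mean_diff"], color="k", label=f"mean {ba['mean_diff']:.2f}%")
            for v, lab in ((ba["loa_low"], "LOA low"), (ba["loa_high"], "LOA high")):
                ax.axhline(v, color="r", ls="--", lw=1, label=f"{lab} {v:.2f}%")
            ax.set_xlabel("average growth density of both modalities (%)")
            ax.set_ylabel("difference OCTA - ICGA (%)")
            ax.set_title(f"Bland-Altman: vessel growth density ({scope})")
            ax.legend(fontsize=8)
            fig.tight_layout()
            p = out / f"bland_altman_{scope}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            summary["figures"].append(p.name)

    if repeatability is not None and len(repeatability) > 0:
        summary["repeatability"] = {
            modality: group_summary(
                sub["repeatability_error_pct"].to_numpy(float)
            ).to_dict()
            for modality, sub in repeatability.groupby("modality")
        }

    (out / "report.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
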