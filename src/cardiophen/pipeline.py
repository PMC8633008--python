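"""End-to-end experiment: simulate arms, measure every assay, compare to CTR.

An experiment mirrors a dose-response design: a control arm (``CTR``) and
any number of treated arms, each defined purely by *measurement-level*
effect multipliers on the synthetic ground truth (beat-frequency
multiplier, disorganized-ROI fraction, sarcomere-period multiplier, cell
area multiplier, CTF volume multiplier). Arms are labels; the software
models measurement behavior, not pharmacology. For every arm and assay the
pipeline generates synthetic samples, measures them with the corresponding
module, and compares each metric across arms with one-way ANOVA + LSD.

Reruns with the same config and seed are bit-identical; every output table
carries the SHA-256 hash of the canonical config + seed (the run manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as statsmod
from .kinematics import summarize_kinematics
from .morphometry import CellMask, measure_cells
from .synthetic import (
    BeatSpec,
    StackSpec,
    StriationSpec,
    make_beat_trajectories,
    make_cell_mask,
    make_striation_image,
    make_zstack,
)
from .texture import TextureROI, score_roi_batch
from .volumetry import CoreStack, compute_ctf

__all__ = ["ArmSpec", "ExperimentConfig", "ExperimentResult", "run_experiment",
           "load_config", "write_bundle"]

logger = logging.getLogger(__name__)

#: baseline study conditions shared by all arms (multipliers act on these)
BASELINE = {
    "beat_frequency_hz": 1.0,
    "fps": 30.0,
    "duration_s": 10.0,
    "amplitude_px": 2.0,
    "jitter_sd_px": 0.05,
    "n_markers": 12,
    "frequency_cv": 0.05,  # per-recording biological variability
    "striation_period_px": 10.0,
    "striation_noise_sd": 0.05,
    "roi_size": (64, 64),
    "pixel_size_um": 0.1,
    "cell_semi_major_px": (60.0, 5.0),  # mean, sd
    "cell_semi_minor_px": (35.0, 3.0),
    "stack_slices": 8,
    "stack_size": (64, 64),
    "stack_signal_area_px": 400.0,
    "stack_signal_level": 200.0,
    "stack_background_level": 50.0,
    "stack_noise_sd": 2.0,
}


@dataclass(frozen=True)
class ArmSpec:
    """One experimental condition, defined by effect multipliers on CTR."""

    label: str
    beat_frequency_multiplier: float = 1.0
    disorganized_fraction: float = 0.0
    period_multiplier: float = 1.0
    area_multiplier: float = 1.0
    ctf_volume_multiplier: float = 1.0

    def validate(self) -> None:
        for name in ("beat_frequency_multiplier", "period_multiplier",
                     "area_multiplier", "ctf_volume_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.label}: {name} must be > 0")
        if not 0 <= self.disorganized_fraction <= 1:
            raise ValueError(f"{self.label}: disorganized_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ExperimentConfig:
    arms: tuple[ArmSpec, ...]
    n_per_arm: int = 20
    seed: int = 0

    def validate(self) -> None:
        labels = [a.label for a in self.arms]
        if "CTR" not in labels:
            raise ValueError("a CTR arm is required")
        if len(set(labels)) != len(labels):
            raise ValueError("arm labels must be unique")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2 for inference")
        for arm in self.arms:
            arm.validate()

    def to_dict(self) -> dict:
        return {
            "arms": [dataclasses.asdict(a) for a in self.arms],
            "n_per_arm": self.n_per_arm,
            "seed": self.seed,
        }

    @property
    def manifest_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    tables: dict[str, pd.DataFrame]
    anova: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict


def load_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    arms = tuple(ArmSpec(**a) for a in raw["arms"])
    return ExperimentConfig(
        arms=arms,
        n_per_arm=int(raw.get("n_per_arm", 20)),
        seed=int(raw.get("seed", 0)),
    )


def _child_seed(root: int, *path: int) -> int:
    """Deterministic per-(arm, assay, sample) seed below 2^31."""
    state = np.random.SeedSequence(entropy=root, spawn_key=tuple(path))
    return int(state.generate_state(1)[0] % (2**31))


def _kinematics_assay(config: ExperimentConfig) -> pd.DataFrame:
    rows = []
    for ai, arm in enumerate(config.arms):
        for i in range(config.n_per_arm):
            seed = _child_seed(config.seed, 0, ai, i)
            rng = np.random.default_rng(seed)
            freq = (
                BASELINE["beat_frequency_hz"]
                * arm.beat_frequency_multiplier
                * rng.lognormal(0.0, BASELINE["frequency_cv"])
            )
            spec = BeatSpec(
                n_markers=BASELINE["n_markers"],
                beat_frequency=freq,
                displacement_amplitude=BASELINE["amplitude_px"],
                fps=BASELINE["fps"],
                duration=BASELINE["duration_s"],
                jitter_sd=BASELINE["jitter_sd_px"],
                seed=seed,
            )
            traj, truth = make_beat_trajectories(spec)
            summary = summarize_kinematics(traj)
            rows.append(
                {"label": arm.label, "sample": i,
                 "true_frequency_hz": truth["true_frequency_hz"],
                 **summary.to_row()}
            )
    return pd.DataFrame(rows)


def _texture_assay(config: ExperimentConfig) -> pd.DataFrame:
    rois = []
    for ai, arm in enumerate(config.arms):
        n_disorganized = int(round(arm.disorganized_fraction * config.n_per_arm))
        for i in range(config.n_per_arm):
            seed = _child_seed(config.seed, 1, ai, i)
            disorganized = i < n_disorganized
            spec = StriationSpec(
                image_size=BASELINE["roi_size"],
                period=BASELINE["striation_period_px"] * arm.period_multiplier,
                disorganization=1.0 if disorganized else 0.0,
                noise_sd=BASELINE["striation_noise_sd"],
                pixel_size=BASELINE["pixel_size_um"],
                seed=seed,
            )
            image, _ = make_striation_image(spec)
            rois.append(
                TextureROI(
                    image=image,
                    pixel_size=spec.pixel_size,
                    label=arm.label,
                    organization_call="disorganized" if disorganized else "organized",
                    roi_id=f"{arm.label}-{i}",
                )
            )
    return score_roi_batch(rois)


def _shape_assay(config: ExperimentConfig) -> pd.DataFrame:
    cells = []
    for ai, arm in enumerate(config.arms):
        scale = np.sqrt(arm.area_multiplier)
        for i in range(config.n_per_arm):
            rng = np.random.default_rng(_child_seed(config.seed, 2, ai, i))
            a = max(8.0, rng.normal(*BASELINE["cell_semi_major_px"])) * scale
            b = max(6.0, rng.normal(*BASELINE["cell_semi_minor_px"])) * scale
            orientation = rng.uniform(0, 180)
            mask, _ = make_cell_mask(a, b, orientation,
                                     pixel_size=BASELINE["pixel_size_um"])
            cells.append(CellMask(mask=mask, pixel_size=BASELINE["pixel_size_um"],
                                  cell_id=f"{arm.label}-{i}", label=arm.label))
    return measure_cells(cells)


def _ctf_assay(config: ExperimentConfig) -> pd.DataFrame:
    rows = []
    h, w = BASELINE["stack_size"]
    for ai, arm in enumerate(config.arms):
        side = float(np.sqrt(BASELINE["stack_signal_area_px"]
                             * arm.ctf_volume_multiplier))
        signal_roi = ((2.0, 2.0), (2.0 + side, 2.0), (2.0 + side, 2.0 + side),
                      (2.0, 2.0 + side))
        background_roi = ((w - 24.0, h - 24.0), (w - 4.0, h - 24.0),
                          (w - 4.0, h - 4.0), (w - 24.0, h - 4.0))
        for i in range(config.n_per_arm):
            seed = _child_seed(config.seed, 3, ai, i)
            spec = StackSpec(
                n_slices=BASELINE["stack_slices"],
                slice_size=(h, w),
                signal_region=signal_roi,
                signal_level=BASELINE["stack_signal_level"],
                background_level=BASELINE["stack_background_level"],
                noise_sd=BASELINE["stack_noise_sd"],
                seed=seed,
            )
            stack, _ = make_zstack(spec)
            core = CoreStack(slices=stack, signal_roi=signal_roi,
                             background_rois=[background_roi],
                             stack_id=f"{arm.label}-{i}", label=arm.label)
            rows.append(compute_ctf(core).to_row())
    return pd.DataFrame(rows)


#: (assay table name, metric columns compared across arms)
_ASSAYS = {
    "kinematics": ("chronotropy_hz", "kinematic_inotropy_px_s",
                   "dynamic_inotropy_px_s2", "ergotropy_px2_s2"),
    "texture": ("fourier_score", "gabor_score", "haralick_correlation",
                "sarcomere_length_um"),
    "shape": ("area_um2", "eccentricity", "circularity", "elongation"),
    "ctf": ("ctf",),
}


def _compare(tables: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    anova_rows, comparison_rows = [], []
    for assay, metrics in _ASSAYS.items():
        df = tables[assay]
        for metric in metrics:
            if metric not in df.columns:
                continue
            sub = df[["label", metric]].dropna()
            counts = sub.groupby("label").size()
            if len(counts) < 2 or (counts < 2).any():
                continue
            data = statsmod.GroupedMeasurements(
                groups={g: s[metric].to_numpy() for g, s in sub.groupby("label")},
                metric_name=metric,
            )
            res = statsmod.one_way_anova(data)
            anova_rows.append({"assay": assay, "metric": metric,
                               "f_statistic": res.f_statistic,
                               "p_value": res.p_value,
                               "df_between": res.df_between,
                               "df_within": res.df_within})
            for comp in statsmod.lsd_posthoc(data):
                if "CTR" not in comp.pair:
                    continue
                row = comp.to_row()
                # orient every contrast as treated vs CTR
                if row["group_a"] != "CTR":
                    row = {
                        "group_a": "CTR", "group_b": row["group_a"],
                        "mean_difference": -row["mean_difference"],
                        "ci95_low": -row["ci95_high"],
                        "ci95_high": -row["ci95_low"],
                        "p_value": row["p_value"],
                        "fold_change": 1.0 / row["fold_change"]
                        if row["fold_change"] else np.nan,
                    }
                row.update(assay=assay, metric=metric,
                           significant=row["p_value"] < statsmod.ALPHA)
                comparison_rows.append(row)
    return pd.DataFrame(anova_rows), pd.DataFrame(comparison_rows)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Simulate -> measure -> compare; deterministic given (config, seed)."""
    config.validate()
    tables: dict[str, pd.DataFrame] = {}
    stage_timings = {}
    for name, fn in (("kinematics", _kinematics_assay), ("texture", _texture_assay),
                     ("shape", _shape_assay), ("ctf", _ctf_assay)):
        t0 = time.perf_counter()
        try:
            tables[name] = fn(config)
        except Exception:
            logger.exception("assay %s failed; bundle continues without it", name)
            tables[name] = pd.DataFrame()
        stage_timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("assay %s done in %.2fs", name, stage_timings[name])

    anova, comparisons = _compare(tables)
    manifest = {
        "config": config.to_dict(),
        "manifest_hash": config.manifest_hash,
        "package": "cardiophen",
    }
    for df in list(tables.values()) + [anova, comparisons]:
        if len(df):
            df["manifest_hash"] = config.manifest_hash
    return ExperimentResult(tables=tables, anova=anova,
                            comparisons=comparisons, manifest=manifest)


def write_bundle(result: ExperimentResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    result.anova.to_csv(out / "anova.csv", index=False)
    result.comparisons.to_csv(out / "comparisons.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
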