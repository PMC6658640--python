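"""End-to-end orchestration: simulate -> measure -> score -> compare.

Every run is deterministic given the seed and writes a manifest (config
hash, seed, package and library versions) sufficient to re-derive the
report. Reports deliberately contain no timestamps so repeated runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deauville import score_study, scores_table
from .phantom import (
    CohortConfig,
    ReconProfile,
    StudyMeta,
    SyntheticStudy,
    default_profiles,
    generate_cohort,
)
from .stats import compare_settings, report_to_text
from .suv import measure_study, measurements_table
from .table1_fixtures import load_table1
from .stats import (
    bonferroni,
    discordance_count,
    major_discordance_count,
    pairs_from_crosstab,
    wilcoxon_signed_rank,
)
from .volumes import read_mask, read_volume, write_mask, write_volume

__all__ = ["PipelineConfig", "run_full", "validate_paper_tables",
           "write_cohort", "read_cohort"]

METRICS = ("suv_max", "suv_peak")


@dataclass
class PipelineConfig:
    """Configuration for a full simulate/measure/score/compare run."""

    n_studies: int = 54
    seed: int = 0
    metrics: tuple[str, ...] = METRICS
    ds5_multiplier: float = 2.0
    erosion_voxels: int = 3
    responder_boundary: int = 3
    noise_cv: float = 0.10
    profiles: dict[str, ReconProfile] | None = None
    cohort: CohortConfig | None = None
    out_dir: str | Path | None = None

    def __post_init__(self):
        if not self.metrics:
            raise ValueError("at least one metric is required")
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unknown metric {m!r}")
        if self.profiles is not None and len(self.profiles) < 2:
            raise ValueError("at least 2 reconstruction profiles are required")

    def resolved_profiles(self) -> dict[str, ReconProfile]:
        return self.profiles if self.profiles is not None else default_profiles(
            noise_cv=self.noise_cv
        )

    def resolved_cohort(self) -> CohortConfig:
        if self.cohort is not None:
            return self.cohort
        return CohortConfig(n_studies=self.n_studies, seed=self.seed,
                            noise_cv=self.noise_cv)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        profiles = raw.pop("profiles", None)
        if profiles is not None:
            raw["profiles"] = {
                name: ReconProfile(name=name, **p) for name, p in profiles.items()
            }
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            raw["cohort"] = CohortConfig(**cohort)
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return cls(**raw)


def _config_digest(config: PipelineConfig) -> str:
    blob = {
        "n_studies": config.n_studies,
        "seed": config.seed,
        "metrics": list(config.metrics),
        "ds5_multiplier": config.ds5_multiplier,
        "erosion_voxels": config.erosion_voxels,
        "responder_boundary": config.responder_boundary,
        "noise_cv": config.noise_cv,
        "profiles": {
            name: {k: v for k, v in asdict(p).items()}
            for name, p in sorted(config.resolved_profiles().items())
        },
        "cohort": asdict(config.resolved_cohort()),
    }
    return hashlib.sha256(json.dumps(blob, sort_keys=True).encode()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "to_dataframe"):  # ContingencyTable
        return {
            "row_method": obj.row_method,
            "col_method": obj.col_method,
            "row_levels": list(obj.row_levels),
            "col_levels": list(obj.col_levels),
            "counts": obj.counts.tolist(),
        }
    if hasattr(obj, "test_name"):  # TestResult
        return {
            "test": obj.test_name,
            "statistic": obj.statistic,
            "z": obj.z_value,
            "p": obj.p_value,
            "n": obj.n_effective,
            "df": obj.df,
            "correction": obj.correction,
            "alpha_effective": obj.alpha_effective,
            "significant": obj.significant,
            "flags": obj.flags,
        }
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_full(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the complete pipeline; optionally persist all artifacts.

    Returns {"studies", "measurements", "scores", "reports", "manifest"}.
    With ``out_dir`` set, writes measurements.csv, scores.csv,
    report.json, report.txt and manifest.json.
    """
    out_dir = out_dir if out_dir is not None else config.out_dir
    profiles = config.resolved_profiles()
    cohort_cfg = config.resolved_cohort()
    studies = generate_cohort(cohort_cfg, profiles)

    per_study_meas = {
        s.study_id: measure_study(
            s.volumes, s.masks, s.meta, erosion_voxels=config.erosion_voxels
        )
        for s in studies
    }
    meas_df = measurements_table(per_study_meas)

    score_frames = []
    reports = {}
    for metric in config.metrics:
        per_study_scores = {
            sid: score_study(meas, metric=metric, multiplier=config.ds5_multiplier)
            for sid, meas in per_study_meas.items()
        }
        sdf = scores_table(per_study_scores, boundary=config.responder_boundary)
        score_frames.append(sdf)
        reports[metric] = compare_settings(
            sdf, metric=metric, boundary=config.responder_boundary
        )
    scores_df = pd.concat(score_frames, ignore_index=True)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "n_studies": cohort_cfg.n_studies,
        "config_sha256": _config_digest(config),
        "profiles": sorted(profiles),
        "metrics": list(config.metrics),
    }
    result = {
        "studies": studies,
        "measurements": meas_df,
        "scores": scores_df,
        "reports": reports,
        "manifest": manifest,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meas_df.to_csv(out / "measurements.csv", index=False)
        scores_df.to_csv(out / "scores.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(_jsonable(reports), indent=2, sort_keys=True) + "\n"
        )
        (out / "report.txt").write_text(
            "\n\n".join(
                f"== metric: {m} ==\n{report_to_text(r)}" for m, r in reports.items()
            )
            + "\n"
        )
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return result


# ---------------------------------------------------------------------------
# Cohort persistence (NIfTI volumes + masks, YAML metadata)


def write_cohort(studies: list[SyntheticStudy], out_dir: str | Path) -> None:
    """Persist a cohort: one directory per study with NIfTI volumes/masks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in studies:
        sdir = out / s.study_id
        sdir.mkdir(exist_ok=True)
        for name, vol in s.volumes.items():
            write_volume(vol, sdir / f"{name}.nii.gz")
        for label, mask in s.masks.items():
            suffix = label.replace("blood_pool", "bloodpool").replace("lesion_", "lesion")
            write_mask(mask, sdir / f"mask_{suffix}.nii.gz")
        meta = {
            "study_id": s.study_id,
            "injected_activity_MBq": s.meta.injected_activity_MBq,
            "body_weight_kg": s.meta.body_weight_kg,
            "injection_time_min": s.meta.injection_time_min,
            "acquisition_time_min": s.meta.acquisition_time_min,
            "radionuclide_half_life_min": s.meta.radionuclide_half_life_min,
            "true_uptakes": {k: float(v) for k, v in s.true_uptakes.items()},
        }
        (sdir / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_cohort(in_dir: str | Path) -> list[dict]:
    """Load a persisted cohort as dicts with volumes, masks and meta."""
    studies = []
    for sdir in sorted(Path(in_dir).iterdir()):
        if not sdir.is_dir():
            continue
        meta_raw = yaml.safe_load((sdir / "meta.yaml").read_text())
        meta = StudyMeta(
            injected_activity_MBq=meta_raw["injected_activity_MBq"],
            body_weight_kg=meta_raw["body_weight_kg"],
            injection_time_min=meta_raw.get("injection_time_min", 0.0),
            acquisition_time_min=meta_raw.get("acquisition_time_min", 60.0),
            radionuclide_half_life_min=meta_raw.get("radionuclide_half_life_min", 109.77),
        )
        volumes = {}
        masks = {}
        for path in sorted(sdir.glob("*.nii*")):
            stem = path.name.split(".nii")[0]
            if stem.startswith("mask_"):
                tail = stem[5:]
                if tail.startswith("lesion"):
                    masks[f"lesion_{int(tail[6:])}"] = read_mask(
                        path, "lesion", index=int(tail[6:])
                    )
                elif tail == "bloodpool":
                    masks["blood_pool"] = read_mask(path, "blood_pool")
                else:
                    masks[tail] = read_mask(path, tail)
            else:
                volumes[stem] = read_volume(path)
        studies.append(
            {
                "study_id": meta_raw["study_id"],
                "volumes": volumes,
                "masks": masks,
                "meta": meta,
                "true_uptakes": meta_raw.get("true_uptakes", {}),
            }
        )
    return studies


# ---------------------------------------------------------------------------
# Recomputation of the published cross-tabulation statistics


def validate_paper_tables(alpha: float = 0.05) -> dict:
    """Recompute every statistic derivable from the embedded cross-tabulations.

    For each published panel: discordance count/percentage, responder-
    boundary (major) discordances, and the pairwise Wilcoxon signed-rank
    p-value at the Bonferroni-corrected level. The Friedman tests over
    the three settings are *not* recomputable from pairwise tables (the
    per-study joint triples cannot be recovered) and are reported as such.
    """
    tables = load_table1()
    out: dict = {
        "n": 54,
        "alpha_bonferroni": bonferroni(alpha, 3),
        "panels": {},
        "friedman": {
            "recomputable": False,
            "reason": "pairwise cross-tabulations do not determine the "
                      "per-study joint triples required by the Friedman test",
        },
    }
    for panel, table in tables.items():
        count, frac = discordance_count(table)
        pairs = pairs_from_crosstab(table)
        test = wilcoxon_signed_rank(pairs, alpha=alpha, correction="bonferroni", m=3)
        out["panels"][panel] = {
            "metric": table.metric,
            "comparison": f"{table.row_method}_vs_{table.col_method}",
            "n": table.total,
            "discordant": count,
            "discordant_pct": round(100.0 * frac, 1),
            "major_discordant": major_discordance_count(table),
            "wilcoxon_z": test.z_value,
            "wilcoxon_p": test.p_value,
            "significant": test.significant,
        }
    return out
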