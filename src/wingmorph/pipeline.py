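"""End-to-end per-sex analysis: superimposition, size and allometry tests,
PCA, cross-validated species classification, disparity and observer effects.

Sexes are analysed separately throughout — mosquito wings are sexually
dimorphic in both size and shape, and pooling sexes confounds species
contrasts.  A pooled escape hatch exists for exploration and warns loudly.

Every number in the report is a deterministic function of (input, config,
seed); the JSON serialization is byte-stable so identical runs produce
identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import landmark_differences, loocv_classify, pca
from .datatypes import LandmarkDataset, Sex, Species
from .gpa import gpa
from .io import read_csv, read_tps, validate_dataset, write_csv
from .stats import (
    allometry_regression,
    morphological_disparity,
    observer_repeatability,
    observer_size_effect,
    size_anova,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Settings for one full study analysis."""

    input: str | None = None
    fmt: str = "auto"  # "tps" | "csv" | "auto"
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 100
    project: bool = True
    n_perm_size: int = 0  # classical F test by default
    n_perm_allometry: int = 1000
    n_perm_observer: int = 500
    n_perm_disparity: int = 500
    allometry_log_size: bool = False
    lda_priors: str = "proportional"
    lda_feature_mode: str = "pca"
    pooled: bool = False
    force: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_perm_size", "n_perm_allometry", "n_perm_observer",
                     "n_perm_disparity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        """Hash of the result-relevant settings (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_dataset(path: str | Path, fmt: str = "auto") -> LandmarkDataset:
    path = Path(path)
    if fmt == "auto":
        fmt = "tps" if path.suffix.lower() == ".tps" else "csv"
    if fmt == "tps":
        return read_tps(path)
    if fmt == "csv":
        return read_csv(path)
    raise ValueError(f"unknown input format {fmt!r}")


def _sanitize(obj):
    """Make a report JSON-serializable with plain Python scalars."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _analyze_one_sex(
    dataset: LandmarkDataset,
    meta: pd.DataFrame,
    config: AnalysisConfig,
    seed: int,
) -> dict:
    """All analysis stages for one sex's base (single-observer) data plus the
    replicated observer subset when present."""
    base_mask = (meta["replicate"] == 1).to_numpy()
    block: dict = {}

    base = dataset.subset(base_mask)
    base_meta = meta[base_mask].reset_index(drop=True)
    species = base_meta["species"].to_numpy()
    n_by_species = {s: int(np.sum(species == s)) for s in np.unique(species)}
    block["n"] = n_by_species

    res = gpa(base, tol=config.gpa_tol, max_iter=config.gpa_max_iter,
              project=config.project)
    vecs = res.shape_vectors()
    block["gpa"] = {
        "iterations": res.iterations,
        "converged": res.converged,
        "projected": res.projected,
        "final_q": res.q_trace[-1] if res.q_trace else 0.0,
    }

    two_species = len(n_by_species) == 2 and min(n_by_species.values()) >= 2
    if two_species:
        block["size_anova"] = size_anova(
            res.centroid_sizes, species,
            n_permutations=config.n_perm_size, seed=seed,
        ).to_dict()

    block["allometry"] = allometry_regression(
        vecs, res.centroid_sizes,
        n_permutations=config.n_perm_allometry,
        seed=seed + 1,
        log_size=config.allometry_log_size,
    ).to_dict()

    p = pca(vecs)
    block["pca"] = {
        "n_components": p.m,
        "explained_variance_ratio": p.explained_variance_ratio.tolist(),
        "pc1_pc2_pct": float(100.0 * p.explained_variance_ratio[:2].sum()),
    }

    if two_species and min(n_by_species.values()) >= 3 and len(base) >= 6:
        report = loocv_classify(
            vecs, species, ids=base_meta["id"].to_numpy(),
            priors=config.lda_priors, feature_mode=config.lda_feature_mode,
        )
        block["classification"] = report.to_dict()
        block["landmark_differences"] = landmark_differences(
            vecs, species, single_landmark_loocv=False
        ).to_dict()
    else:
        logger.warning("classification skipped: need two species with >= 3 each")

    if two_species:
        block["disparity"] = morphological_disparity(
            vecs, species,
            n_permutations=config.n_perm_disparity, seed=seed + 2,
        ).to_dict()

    # observer analyses on the replicated-digitization subset
    rep_mask = (meta["replicate"] > 1).to_numpy()
    observers = meta["observer"].to_numpy()
    if rep_mask.sum() >= 6 and len(np.unique(observers[rep_mask])) >= 2:
        rep = dataset.subset(rep_mask)
        rep_meta = meta[rep_mask].reset_index(drop=True)
        rep_res = gpa(rep, tol=config.gpa_tol, max_iter=config.gpa_max_iter,
                      project=config.project)
        rep_vecs = rep_res.shape_vectors()
        obs_block: dict = {
            "n_measurements": int(len(rep)),
            "n_observers": int(len(np.unique(rep_meta["observer"]))),
        }
        obs_block["size_anova"] = observer_size_effect(
            rep_res.centroid_sizes,
            rep_meta["observer"].to_numpy(),
            specimens=rep_meta["id"].to_numpy(),
            n_permutations=config.n_perm_observer,
            seed=seed + 3,
        ).to_dict()
        obs_block["repeatability"] = observer_repeatability(
            rep_vecs,
            rep_meta["id"].to_numpy(),
            rep_meta["observer"].to_numpy(),
            rep_meta["species"].to_numpy(),
        ).to_dict()
        rep_species = rep_meta["species"].to_numpy()
        rep_counts = {s: int(np.sum(rep_species == s)) for s in np.unique(rep_species)}
        if len(rep_counts) == 2 and min(rep_counts.values()) >= 3 and len(rep) >= 6:
            obs_block["classification"] = loocv_classify(
                rep_vecs, rep_species, ids=rep_meta["id"].to_numpy(),
                priors=config.lda_priors, feature_mode=config.lda_feature_mode,
            ).to_dict()
        block["observer"] = obs_block

    return block


def run_analysis(
    config: AnalysisConfig,
    dataset: LandmarkDataset | None = None,
) -> dict:
    """Execute the full study analysis and return the StudyReport dict.

    The dataset is loaded from ``config.input`` unless passed directly.
    When ``config.out_dir`` is set, writes the JSON report plus CSV tables
    (superimposed coordinates with centroid sizes, PCA scores, per-specimen
    LOOCV assignments).
    """
    if dataset is None:
        if config.input is None:
            raise ValueError("config.input is required when no dataset is passed")
        dataset = load_dataset(config.input, config.fmt)

    validation = validate_dataset(dataset)
    if not validation.ok and not config.force:
        raise ValueError(
            "dataset failed validation (use force to override):\n" + str(validation)
        )

    meta = dataset.metadata_frame()
    report: dict = {
        "provenance": {
            "package": "wingmorph",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.content_hash(),
            "input": config.input,
            "n_configurations": len(dataset),
            "landmark_count": dataset.landmark_count,
            "validation_warnings": len(validation.warnings),
        },
        "sexes": {},
    }

    if config.pooled:
        logger.warning(
            "POOLED ANALYSIS REQUESTED: sexes are being mixed. Wing size and "
            "shape are sexually dimorphic; species contrasts from pooled data "
            "are confounded. Interpret with caution."
        )
        report["sexes"]["pooled"] = _analyze_one_sex(
            dataset, meta, config, config.seed
        )
    else:
        for offset, sex in enumerate((Sex.FEMALE, Sex.MALE)):
            mask = (meta["sex"] == sex.value).to_numpy()
            if mask.sum() == 0:
                continue
            sex_ds = dataset.subset(mask)
            sex_meta = meta[mask].reset_index(drop=True)
            report["sexes"][sex.value] = _analyze_one_sex(
                sex_ds, sex_meta, config, config.seed + 10 * offset
            )

    report = _sanitize(report)
    if config.out_dir is not None:
        _write_outputs(report, dataset, config)
    return report


def report_to_json(report: dict) -> str:
    """Canonical byte-stable JSON serialization of a StudyReport."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"


def summarize(report: dict) -> str:
    """Human-readable summary with display rounding (full precision stays in
    the JSON): F to 2 dp, R² to 3 dp, PV to 6 dp, accuracy to 1 dp percent."""
    lines = []
    for sex, block in report.get("sexes", {}).items():
        lines.append(f"== {sex} ==")
        n = block.get("n", {})
        lines.append("  n: " + ", ".join(f"{k}={v}" for k, v in sorted(n.items())))
        if "size_anova" in block:
            s = block["size_anova"]
            p = s["parametric_p"] if s["p_value"] is None else s["p_value"]
            lines.append(
                f"  size ANOVA: F{s['df_model']},{s['df_resid']} = "
                f"{s['F']:.2f}, P = {p:.3f}"
            )
        if "allometry" in block:
            a = block["allometry"]
            lines.append(
                f"  allometry: F{a['df_model']},{a['df_resid']} = {a['F']:.2f}, "
                f"R² = {a['r_squared']:.3f}, P = {a['p_value']:.3f}"
            )
        if "pca" in block:
            lines.append(
                f"  PCA: PC1+PC2 explain {block['pca']['pc1_pc2_pct']:.1f}%"
            )
        if "classification" in block:
            c = block["classification"]
            lines.append(
                f"  LOOCV accuracy: {100 * c['accuracy']:.1f}% "
                f"(confusion {c['confusion']})"
            )
        if "disparity" in block:
            for g, v in sorted(block["disparity"]["group_variances"].items()):
                lines.append(f"  Procrustes variance [{g}]: {v:.6f}")
        if "observer" in block:
            o = block["observer"]
            s = o["size_anova"]
            lines.append(
                f"  observer size ANOVA: F = {s['F']:.2f}, Z = {s['z_score']:.2f}, "
                f"R² = {s['r_squared']:.3f}, P = {s['p_value']:.3f}"
            )
            r = o["repeatability"]
            lines.append(
                f"  within-specimen PV: {r['within_specimen_pv']:.6f} "
                f"(ratio to within-species: {r['ratio']:.2f})"
            )
            if "classification" in o:
                lines.append(
                    f"  observer-replicate LOOCV accuracy: "
                    f"{100 * o['classification']['accuracy']:.1f}%"
                )
    return "\n".join(lines)


def _write_outputs(report: dict, dataset: LandmarkDataset, config: AnalysisConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_to_json(report), encoding="utf-8")
    (out / "summary.txt").write_text(summarize(report) + "\n", encoding="utf-8")

    meta = dataset.metadata_frame()
    # superimposed coordinates + centroid size, per sex, plus PCA scores
    for sex, block in report["sexes"].items():
        if sex == "pooled":
            mask = np.ones(len(dataset), dtype=bool)
        else:
            mask = (meta["sex"] == sex).to_numpy()
        base_mask = mask & (meta["replicate"] == 1).to_numpy()
        if base_mask.sum() == 0:
            continue
        sub = dataset.subset(base_mask)
        sub_meta = meta[base_mask].reset_index(drop=True)
        res = gpa(sub, tol=config.gpa_tol, max_iter=config.gpa_max_iter,
                  project=config.project)
        k = sub.landmark_count
        cols = {}
        flat = res.shape_vectors()
        for j in range(k):
            cols[f"x{j + 1}"] = flat[:, 2 * j]
            cols[f"y{j + 1}"] = flat[:, 2 * j + 1]
        df = pd.concat(
            [sub_meta, pd.DataFrame(cols), pd.Series(res.centroid_sizes, name="centroid_size")],
            axis=1,
        )
        df.to_csv(out / f"superimposed_{sex}.csv", index=False, float_format="%.9f")
        p = pca(flat)
        scores = pd.DataFrame(
            p.scores, columns=[f"PC{j + 1}" for j in range(p.m)]
        )
        scores.insert(0, "id", sub_meta["id"])
        scores.to_csv(out / f"pca_scores_{sex}.csv", index=False, float_format="%.9f")
        if "classification" in block:
            pd.DataFrame(block["classification"]["per_specimen"]).to_csv(
                out / f"loocv_{sex}.csv", index=False
            )
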