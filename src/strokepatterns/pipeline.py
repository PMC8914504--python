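"""Pipeline orchestration: parcellation -> patterns -> model -> sensitivity
-> lesion network mapping, from a single YAML-able configuration.

Every stage writes its outputs under ``out_dir/<stage>/`` and registers
them, with content hashes, in a JSON result-bundle manifest, so that a
re-run with the same configuration and inputs can be verified
bit-for-bit for the deterministic stages.  Stages whose inputs are absent
(e.g. no connectome directory -> no LNM) are skipped with a logged notice.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .parcellation import (AtlasSpec, assemble_matrix, compare_lesion_anatomy,
                           parcellate_lesion, read_matrix, region_columns,
                           VOLUME_COLUMN)
from .patterns import affiliated_regions, fit_nmf
from .outcome import (build_design, compare_baseline_characteristics,
                      fit_hierarchical_logistic, hpdi,
                      posterior_predictive_auc, sex_difference,
                      substantial_effect)
from .sensitivity import downsample_and_refit
from .lnm import run_lnm

logger = logging.getLogger("strokepatterns")


@dataclass
class PipelineConfig:
    """Everything a full run needs; only ``seed`` is mandatory."""

    seed: int
    out_dir: str = "results"
    masks_dir: Optional[str] = None
    atlas_dir: Optional[str] = None
    lesion_matrix: Optional[str] = None
    cohort: Optional[str] = None
    connectomes_male: Optional[str] = None
    connectomes_female: Optional[str] = None
    networks: Optional[str] = None
    k_patterns: int = 10
    draws: int = 5000
    warmup: int = 1000
    chains: int = 4
    sensitivity_reps: int = 20
    lnm_variants: int = 100
    affiliation_threshold: float = 0.05
    hpdi_mass: float = 0.90

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("pipeline config must set a seed")
        cfg = cls(**raw)
        for attr in ("masks_dir", "atlas_dir", "lesion_matrix", "cohort",
                     "connectomes_male", "connectomes_female", "networks"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ResultBundle:
    """Stage manifests (with content hashes) plus the config snapshot."""

    config: dict
    version: str = _version
    stages: dict = field(default_factory=dict)

    def register(self, stage: str, paths: dict, extra: dict = None) -> None:
        manifest = {"outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                                for k, p in paths.items()},
                    "status": "completed"}
        if extra:
            manifest["info"] = extra
        self.stages[stage] = manifest

    def skip(self, stage: str, reason: str) -> None:
        logger.info("stage %s skipped: %s", stage, reason)
        self.stages[stage] = {"status": "skipped", "reason": reason}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"version": self.version, "config": self.config,
             "stages": self.stages}, indent=2))


def load_atlas_dir(atlas_dir) -> AtlasSpec:
    """Read the three layer label images + region table written by the
    synthetic fixture writer (``atlas_<layer>.nii`` + ``atlas_regions.csv``)."""
    d = Path(atlas_dir)
    imgs = {layer: nib.load(str(d / f"atlas_{layer}.nii"))
            for layer in ("cortical", "subcortical", "tract")}
    table = pd.read_csv(d / "atlas_regions.csv")
    affine = imgs["cortical"].affine
    return AtlasSpec(cortical=imgs["cortical"], subcortical=imgs["subcortical"],
                     tract=imgs["tract"], region_table=table, affine=affine)


def render_effects_table(draws, mass: float = 0.90) -> pd.DataFrame:
    """Per-pattern posterior summary in the reporting style of the study:
    posterior mean, 90% HPDI and substantial flag per sex, plus the
    men - women difference row."""
    rows = []
    for j in range(1, draws.k + 1):
        for sex, arr in (("male", draws.flat(draws.beta_male)[:, j - 1]),
                         ("female", draws.flat(draws.beta_female)[:, j - 1])):
            iv = hpdi(arr, mass)
            rows.append({
                "pattern": j, "quantity": sex,
                "mean": float(arr.mean()),
                "hpdi_lower": iv.lower, "hpdi_upper": iv.upper,
                "substantial": not iv.contains(0.0)})
        d = sex_difference(draws, j, mass)
        rows.append({
            "pattern": j, "quantity": "difference_men_minus_women",
            "mean": d.mean, "hpdi_lower": d.interval.lower,
            "hpdi_upper": d.interval.upper, "substantial": d.substantial})
    return pd.DataFrame(rows)


def format_effects_table(table: pd.DataFrame) -> str:
    lines = []
    for _, r in table.iterrows():
        flag = " *" if r["substantial"] else ""
        lines.append(
            f"pattern #{int(r['pattern'])} {r['quantity']:<27s} "
            f"mean {r['mean']:+.2f}  90% HPDI "
            f"[{r['hpdi_lower']:+.2f}, {r['hpdi_upper']:+.2f}]{flag}")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute all stages; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(config=asdict(config))

    # --- parcellation ---------------------------------------------------
    stage_dir = out / "parcellation"
    stage_dir.mkdir(exist_ok=True)
    if config.masks_dir and config.atlas_dir:
        atlas = load_atlas_dir(config.atlas_dir)
        mask_paths = sorted(Path(config.masks_dir).glob("*.nii*"))
        rows = [parcellate_lesion(nib.load(str(p)), atlas)
                for p in mask_paths]
        matrix = assemble_matrix(rows, [p.name.split(".")[0]
                                        for p in mask_paths])
        logger.info("parcellated %d masks", len(rows))
    elif config.lesion_matrix:
        atlas = (load_atlas_dir(config.atlas_dir)
                 if config.atlas_dir else None)
        matrix = read_matrix(config.lesion_matrix)
        logger.info("loaded precomputed lesion matrix (%d patients)",
                    len(matrix))
    else:
        raise ValueError("need either masks_dir+atlas_dir or lesion_matrix")
    matrix_path = stage_dir / "lesion_matrix.csv"
    matrix.to_csv(matrix_path)

    cohort = pd.read_csv(config.cohort, index_col="patient_id")
    anatomy, volume_test = compare_lesion_anatomy(
        matrix, cohort["sex"])
    anatomy_path = stage_dir / "lesion_anatomy_by_sex.csv"
    anatomy.to_csv(anatomy_path)
    bundle.register("parcellation",
                    {"lesion_matrix": matrix_path,
                     "lesion_anatomy_by_sex": anatomy_path},
                    {"volume_test": volume_test})

    # --- patterns -------------------------------------------------------
    stage_dir = out / "patterns"
    stage_dir.mkdir(exist_ok=True)
    X = matrix[region_columns(matrix)]
    expressions, basis = fit_nmf(X, k=config.k_patterns, seed=config.seed)
    h_path = stage_dir / "basis.csv"
    w_path = stage_dir / "expressions.csv"
    basis.to_frame().to_csv(h_path)
    expressions.to_csv(w_path)
    affiliated = {j: affiliated_regions(basis, j,
                                        config.affiliation_threshold)
                  for j in range(1, basis.k + 1)}
    aff_path = stage_dir / "affiliated_regions.json"
    aff_path.write_text(json.dumps(affiliated, indent=2))
    bundle.register("patterns",
                    {"basis": h_path, "expressions": w_path,
                     "affiliated_regions": aff_path},
                    {"n_iter": basis.n_iter,
                     "relative_error": basis.relative_error})

    # --- outcome model --------------------------------------------------
    stage_dir = out / "model"
    stage_dir.mkdir(exist_ok=True)
    design = build_design(cohort, expressions)
    post = fit_hierarchical_logistic(
        design, draws=config.draws, warmup=config.warmup,
        chains=config.chains, seed=config.seed)
    auc = posterior_predictive_auc(post, design)
    effects = render_effects_table(post, config.hpdi_mass)
    eff_path = stage_dir / "effects.csv"
    effects.to_csv(eff_path, index=False)
    (stage_dir / "effects.txt").write_text(format_effects_table(effects))
    baseline = compare_baseline_characteristics(cohort)
    base_path = stage_dir / "baseline_characteristics.csv"
    baseline.to_csv(base_path)
    np.savez(stage_dir / "posterior_draws.npz",
             alpha=post.alpha, mu=post.mu, tau=post.tau,
             beta_male=post.beta_male, beta_female=post.beta_female,
             gamma=post.gamma)
    manifest = {"parameters": ["alpha", "mu", "tau", "beta_male",
                               "beta_female", "gamma"],
                "covariates": post.covariate_names,
                "seed": post.seed, "auc": auc,
                "diagnostics": post.diagnostics}
    (stage_dir / "posterior_manifest.json").write_text(
        json.dumps(manifest, indent=2))
    bundle.register("model",
                    {"effects": eff_path,
                     "baseline_characteristics": base_path},
                    {"auc": auc, "diagnostics": post.diagnostics})

    # --- sensitivity ----------------------------------------------------
    stage_dir = out / "sensitivity"
    stage_dir.mkdir(exist_ok=True)
    results, summary = downsample_and_refit(
        cohort, expressions, n_reps=config.sensitivity_reps,
        seed=config.seed, draws=config.draws, warmup=config.warmup,
        chains=config.chains)
    sens_path = stage_dir / "downsampling_summary.csv"
    summary.to_csv(sens_path)
    reps = pd.DataFrame(
        [{"repetition": r.repetition, "n_patients": r.n_patients,
          **{f"diff_flag_{j + 1}": bool(f)
             for j, f in enumerate(r.difference_flags)}}
         for r in results])
    reps_path = stage_dir / "downsampling_repetitions.csv"
    reps.to_csv(reps_path, index=False)
    bundle.register("sensitivity",
                    {"summary": sens_path, "repetitions": reps_path})

    # --- lesion network mapping -----------------------------------------
    if (config.connectomes_male and config.connectomes_female
            and config.networks and config.atlas_dir):
        stage_dir = out / "lnm"
        stage_dir.mkdir(exist_ok=True)
        male_imgs = [nib.load(str(p)) for p in
                     sorted(Path(config.connectomes_male).glob("*.nii*"))]
        female_imgs = [nib.load(str(p)) for p in
                       sorted(Path(config.connectomes_female).glob("*.nii*"))]
        networks = nib.load(str(config.networks))
        intensity, contrast = run_lnm(
            basis, atlas, male_imgs, female_imgs, networks,
            n_variants=config.lnm_variants, seed=config.seed,
            threshold=config.affiliation_threshold)
        int_path = stage_dir / "network_intensity.csv"
        con_path = stage_dir / "sex_contrast.csv"
        intensity.to_csv(int_path, index=False)
        contrast.to_csv(con_path, index=False)
        per_pattern = (contrast[contrast["significant"]]
                       .groupby("pattern").size())
        bundle.register("lnm", {"intensity": int_path, "contrast": con_path},
                        {"significant_per_pattern":
                         {int(k): int(v) for k, v in per_pattern.items()}})
    else:
        bundle.skip("lnm", "connectome inputs not configured")

    bundle.write(out / "bundle.json")
    return bundle
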