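"""Synthetic study data with known ground truth.

Everything the downstream pipeline consumes can be generated here:

* a region-lesion matrix with vascular-territory structure (sparse gamma
  pattern expressions times a non-negative territory basis, with Poisson
  voxel noise),
* a cohort table whose binary 3-month outcome (mRS > 2) is drawn from a
  known sex-specific hierarchical logistic model,
* small three-layer label atlases and binary lesion masks that round-trip
  exactly through the parcellation module,
* sex-specific resting-state connectome fixtures with controllable
  per-network connectivity differences.

The ``paper_shape`` preset mirrors the marginal structure of a multi-centre
acute-ischaemic-stroke cohort: n = 822, 39.2% women, the Table-1 risk-factor
prevalences per sex, and an overall unfavourable-outcome rate near 28%.
All randomness flows through one seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .parcellation import (AtlasSpec, DEFAULT_LAYER_SIZES, LAYERS,
                           VOLUME_COLUMN)

SEX_MALE = "M"
SEX_FEMALE = "F"

RISK_FACTORS = ("hypertension", "atrial_fibrillation", "diabetes",
                "ischaemic_heart_disease", "prior_stroke", "smoking")

# Table-style per-sex marginals used by the paper_shape preset:
# (male, female) prevalences / moments.
_PAPER_RISK_PREVALENCE = {
    "hypertension": (0.630, 0.659),
    "atrial_fibrillation": (0.146, 0.202),
    "diabetes": (0.230, 0.199),
    "ischaemic_heart_disease": (0.218, 0.130),
    "prior_stroke": (0.094, 0.102),
    "smoking": (0.610, 0.457),
}
_PAPER_AGE = {"M": (63.9, 14.2), "F": (65.8, 16.2)}
_PAPER_N = 822
_PAPER_FRACTION_FEMALE = 322 / 822


def territory_basis(n_patterns: int = 10, n_regions: int = 129,
                    rng: Optional[np.random.Generator] = None,
                    low: float = 0.5, high: float = 1.0) -> np.ndarray:
    """Non-negative basis of contiguous, disjoint region territories.

    Each pattern owns a contiguous block of regions with loadings drawn
    uniformly in [low, high]; blocks partition the region axis, mimicking
    lesion topographies constrained to vascular territories.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_patterns > n_regions:
        raise ValueError("more patterns than regions")
    H = np.zeros((n_patterns, n_regions))
    bounds = np.linspace(0, n_regions, n_patterns + 1).astype(int)
    for j in range(n_patterns):
        lo, hi = bounds[j], bounds[j + 1]
        H[j, lo:hi] = rng.uniform(low, high, size=hi - lo)
    return H


@dataclass
class GeneratorConfig:
    """Ground-truth configuration of the cohort generator.

    Sex coding is 'M'/'F'; ``true_coefficients`` has shape (2, n_patterns)
    with row 0 = male, row 1 = female effects, on the log-odds scale per
    standard deviation of pattern expression.  ``covariate_effects`` are
    log-odds coefficients for the standardized continuous covariates (age,
    age squared, lesion volume), the female indicator and the six
    cardiovascular risk-factor indicators.
    """

    n_patients: int = 400
    n_regions: int = 129
    n_patterns: int = 10
    true_basis: Optional[np.ndarray] = None
    true_coefficients: Optional[np.ndarray] = None
    covariate_effects: Optional[dict] = None
    intercept: float = -1.1
    sex_ratio: float = _PAPER_FRACTION_FEMALE  # fraction female
    expression_shape: float = 0.25   # gamma shape < 1 -> territory-dominant
    expression_scale: float = 100.0  # voxels per unit loading
    age_mean: dict = field(default_factory=lambda: dict(_PAPER_AGE))
    risk_prevalence: dict = field(
        default_factory=lambda: {k: v for k, v in
                                 _PAPER_RISK_PREVALENCE.items()})
    voxel_volume_mm3: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValueError("sex_ratio must lie strictly in (0, 1)")
        if self.true_basis is None:
            self.true_basis = territory_basis(
                self.n_patterns, self.n_regions,
                np.random.default_rng(self.rng_seed + 1))
        self.true_basis = np.asarray(self.true_basis, dtype=float)
        if self.true_basis.shape != (self.n_patterns, self.n_regions):
            raise ValueError("true_basis shape mismatch")
        if (self.true_basis < 0).any():
            raise ValueError("true_basis must be non-negative")
        if not ((self.true_basis > 0).sum(axis=1) >= 1).all():
            raise ValueError("every basis row needs at least one positive "
                             "loading")
        if self.true_coefficients is None:
            self.true_coefficients = np.zeros((2, self.n_patterns))
        self.true_coefficients = np.asarray(self.true_coefficients,
                                            dtype=float)
        if self.true_coefficients.shape != (2, self.n_patterns):
            raise ValueError("true_coefficients must have shape "
                             "(2, n_patterns): rows male, female")
        if self.covariate_effects is None:
            self.covariate_effects = {
                "age": 0.0, "age2": 0.0, "sex": 0.0, "volume": 0.0,
                **{rf: 0.0 for rf in RISK_FACTORS}}
        unknown = (set(self.covariate_effects)
                   - {"age", "age2", "sex", "volume", *RISK_FACTORS})
        if unknown:
            raise ValueError(f"unknown covariate effects: {sorted(unknown)}")


def paper_shape_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Preset matching the published cohort's marginal structure."""
    defaults = dict(
        n_patients=_PAPER_N,
        sex_ratio=_PAPER_FRACTION_FEMALE,
        intercept=-1.35,
        covariate_effects={
            "age": 0.45, "age2": 0.10, "sex": 0.35, "volume": 0.55,
            "hypertension": 0.15, "atrial_fibrillation": 0.25,
            "diabetes": 0.20, "ischaemic_heart_disease": 0.20,
            "prior_stroke": 0.25, "smoking": 0.10},
        rng_seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def default_region_table(layer_sizes: dict = DEFAULT_LAYER_SIZES
                         ) -> pd.DataFrame:
    """Canonical 129-row region table (cortical, subcortical, tract order).

    Within each layer the first half of the regions is assigned to the left
    hemisphere and the remainder to the right.
    """
    rows = []
    prefix = {"cortical": "ctx", "subcortical": "sub", "tract": "wm"}
    for layer in LAYERS:
        n = layer_sizes[layer]
        for lab in range(1, n + 1):
            hemi = "L" if lab <= n // 2 + n % 2 else "R"
            rows.append({"layer": layer, "label": lab,
                         "name": f"{prefix[layer]}{lab:03d}",
                         "hemisphere": hemi})
    return pd.DataFrame(rows)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_cohort(config: GeneratorConfig):
    """Draw a cohort from the generative model.

    Returns ``(lesion_matrix, true_expressions, cohort)``:

    * ``lesion_matrix`` — patients x 129 integer counts plus
      ``lesion_volume_ml``;
    * ``true_expressions`` — the latent non-negative pattern expressions;
    * ``cohort`` — demographics, risk factors, sex, mRS and outcome.

    The linear predictor applies the sex-appropriate pattern coefficients to
    the (sample-)standardized expressions, so ``true_coefficients`` are on
    the same per-SD scale the fitted model reports.
    """
    rng = np.random.default_rng(config.rng_seed)
    n, k = config.n_patients, config.n_patterns
    ids = [f"p{i:05d}" for i in range(1, n + 1)]

    female = rng.random(n) < config.sex_ratio
    sex = np.where(female, SEX_FEMALE, SEX_MALE)

    # sparse gamma expressions: most patients load on one or two territories
    W = rng.gamma(config.expression_shape, config.expression_scale,
                  size=(n, k))
    rates = W @ config.true_basis
    counts = rng.poisson(rates)
    volume_ml = counts.sum(axis=1) * config.voxel_volume_mm3 / 1000.0

    age = np.empty(n)
    for s, key in ((~female, SEX_MALE), (female, SEX_FEMALE)):
        mu, sd = config.age_mean[key]
        age[s] = np.clip(rng.normal(mu, sd, size=int(s.sum())), 18.0, 100.0)
    risks = {}
    for rf in RISK_FACTORS:
        p_m, p_f = config.risk_prevalence[rf]
        p = np.where(female, p_f, p_m)
        risks[rf] = (rng.random(n) < p).astype(int)

    W_std = np.apply_along_axis(_standardize, 0, W)
    age_c = age - age.mean()
    eff = config.covariate_effects
    eta = (config.intercept
           + np.where(female,
                      W_std @ config.true_coefficients[1],
                      W_std @ config.true_coefficients[0])
           + eff["age"] * _standardize(age)
           + eff["age2"] * _standardize(age_c ** 2)
           + eff["sex"] * female.astype(float)
           + eff["volume"] * _standardize(volume_ml))
    for rf in RISK_FACTORS:
        eta = eta + eff[rf] * risks[rf]
    if not np.all(np.isfinite(eta)):
        bad = [name for name, v in eff.items() if not np.isfinite(v)]
        raise ValueError(
            "non-finite linear predictor; check coefficient scales "
            f"(non-finite covariate effects: {bad or 'pattern coefficients'})")
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < prob).astype(int)
    # mRS consistent with the binary outcome: >2 iff unfavourable
    mrs = np.where(y == 1, rng.integers(3, 7, size=n),
                   rng.integers(0, 3, size=n))

    columns = [f"{r['layer']}_{int(r['label'])}_{r['name']}"
               for _, r in default_region_table(
                   _layer_sizes_for(config.n_regions)).iterrows()]
    lesion = pd.DataFrame(counts, index=pd.Index(ids, name="patient_id"),
                          columns=columns)
    lesion[VOLUME_COLUMN] = volume_ml
    expressions = pd.DataFrame(
        W, index=lesion.index,
        columns=[f"pattern_{j + 1}" for j in range(k)])
    cohort = pd.DataFrame({
        "age": age, "sex": sex, **risks,
        VOLUME_COLUMN: volume_ml, "mrs": mrs, "unfavourable": y,
    }, index=lesion.index)
    return lesion, expressions, cohort


def _layer_sizes_for(n_regions: int) -> dict:
    """Split a non-default region count across the three layers."""
    if n_regions == sum(DEFAULT_LAYER_SIZES.values()):
        return dict(DEFAULT_LAYER_SIZES)
    base = {"cortical": max(n_regions - 10, 1)}
    rest = n_regions - base["cortical"]
    base["subcortical"] = max(rest // 2, 1) if rest >= 2 else 1
    base["tract"] = n_regions - base["cortical"] - base["subcortical"]
    if base["tract"] < 1:
        raise ValueError("n_regions too small to split across three layers")
    return base


# ----------------------------------------------------------------------
# atlas + lesion-mask fixtures
# ----------------------------------------------------------------------

def fixture_atlas(grid_shape: Sequence[int] = (24, 24, 18),
                  layer_sizes: dict = DEFAULT_LAYER_SIZES,
                  voxel_volume_mm3: float = 1.0,
                  region_size: Optional[int] = None,
                  scatter: bool = True) -> AtlasSpec:
    """Deterministic three-layer label atlas with disjoint layers.

    Left-hemisphere regions occupy the x < nx/2 slab, right-hemisphere
    regions the rest; within each slab regions are blocks of
    ``region_size`` voxels carved from the flattened voxel list (cortical
    first, then subcortical, then tract).  Layers never overlap, so lesion
    masks generated from a count matrix round-trip exactly.

    With ``scatter`` (default) blocks are assigned to regions in a strided
    order, so regions with consecutive labels — which form one generator
    territory — are spread across the slab rather than packed side by
    side.  This gives every territory support in several functional
    networks of the connectome fixtures, mirroring how real vascular
    territories cut across network boundaries.
    """
    grid_shape = tuple(int(v) for v in grid_shape)
    nx = grid_shape[0]
    table = default_region_table(layer_sizes)
    flat = np.arange(int(np.prod(grid_shape)))
    x = np.unravel_index(flat, grid_shape)[0]
    pools = {"L": flat[x < nx // 2], "R": flat[x >= nx // 2]}
    per_side = {h: int((table["hemisphere"] == h).sum()) for h in "LR"}
    if region_size is None:
        region_size = min(len(pools[h]) // max(per_side[h], 1)
                          for h in "LR")
    if region_size < 1:
        raise ValueError("grid too small for the requested regions")

    block_order = {}
    for h in "LR":
        n_blocks = per_side[h]
        order = np.arange(n_blocks)
        if scatter:
            # strided permutation: consecutive regions land far apart
            stride = max(n_blocks // 7, 1)
            while n_blocks > 1 and np.gcd(stride, n_blocks) != 1:
                stride += 1
            order = (order * stride) % n_blocks
        block_order[h] = order

    layers = {layer: np.zeros(int(np.prod(grid_shape)), dtype=np.int32)
              for layer in LAYERS}
    cursor = {"L": 0, "R": 0}
    for _, row in table.iterrows():
        h = row["hemisphere"]
        block = block_order[h][cursor[h]]
        start = block * region_size
        voxels = pools[h][start:start + region_size]
        if len(voxels) < region_size:
            raise ValueError("grid too small for the requested regions")
        layers[row["layer"]][voxels] = int(row["label"])
        cursor[h] += 1
    return AtlasSpec(
        cortical=layers["cortical"].reshape(grid_shape),
        subcortical=layers["subcortical"].reshape(grid_shape),
        tract=layers["tract"].reshape(grid_shape),
        region_table=table, affine=np.eye(4),
        voxel_volume_mm3=voxel_volume_mm3,
        layer_sizes=dict(layer_sizes))


def clip_matrix_to_atlas(lesion: pd.DataFrame, atlas: AtlasSpec
                         ) -> pd.DataFrame:
    """Cap region counts at each region's voxel count (volume recomputed)."""
    out = lesion.copy()
    cols = atlas.column_names()
    sizes = np.array([len(atlas.region_support(row["layer"],
                                               int(row["label"])))
                      for _, row in atlas.region_table.iterrows()])
    out[cols] = np.minimum(out[cols].to_numpy(int), sizes[None, :])
    out[VOLUME_COLUMN] = (out[cols].sum(axis=1)
                          * atlas.voxel_volume_mm3 / 1000.0)
    return out


def generate_lesion_images(lesion: pd.DataFrame, atlas: AtlasSpec) -> dict:
    """Binary masks whose per-region counts equal the matrix exactly.

    For each region the first ``count`` voxels of its sorted flat-index
    support are lesioned — fully deterministic.  Requires a layer-disjoint
    atlas, otherwise exact counts cannot be guaranteed.
    """
    if not atlas.layers_disjoint():
        raise ValueError("atlas layers overlap; exact mask generation needs "
                         "disjoint layers")
    cols = atlas.column_names()
    missing = [c for c in cols if c not in lesion.columns]
    if missing:
        raise ValueError(f"lesion matrix lacks columns: {missing[:3]} ...")
    supports = {c: atlas.region_support(row["layer"], int(row["label"]))
                for c, (_, row) in zip(cols, atlas.region_table.iterrows())}
    images = {}
    for pid, row in lesion[cols].iterrows():
        mask = np.zeros(int(np.prod(atlas.shape)), dtype=np.uint8)
        for c in cols:
            cnt = int(row[c])
            sup = supports[c]
            if cnt > len(sup):
                raise ValueError(
                    f"patient {pid}: requested {cnt} voxels in region {c} "
                    f"but the region has only {len(sup)}")
            if cnt:
                mask[sup[:cnt]] = 1
        images[pid] = nib.Nifti1Image(mask.reshape(atlas.shape),
                                      atlas.affine)
    return images


# ----------------------------------------------------------------------
# connectome fixtures
# ----------------------------------------------------------------------

@dataclass
class ConnectomeFixtureConfig:
    """Sex-specific normative-connectome fixture parameters.

    The study-scale normative sample is 346 subjects per sex
    (``PAPER_N_PER_SEX``); the default fixture uses 20 per sex on a small
    grid.  ``sex_effect`` multiplies the shared within-network latent
    signal for female subjects, per network (14 values; 1.0 = no sex
    difference).
    """

    PAPER_N_PER_SEX = 346

    n_subjects_per_sex: int = 20
    grid_shape: Sequence[int] = (20, 20, 10)
    n_timepoints: int = 150
    n_networks: int = 14
    network_labels: Optional[np.ndarray] = None
    sex_effect: Optional[np.ndarray] = None
    signal_strength: float = 0.5
    noise_sd: float = 1.0
    global_strength: float = 1.0  # physiological global-signal amplitude
    subject_sd: float = 0.0   # between-subject spread of network amplitude
    local_strength: float = 0.0  # parcel-level (local) signal amplitude
    parcel_size: int = 25        # voxels per local-coherence parcel
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be at least 10")
        if self.network_labels is None:
            self.network_labels = fixture_network_labels(
                self.grid_shape, self.n_networks)
        self.network_labels = np.asarray(self.network_labels, dtype=np.int32)
        if self.network_labels.shape != self.grid_shape:
            raise ValueError("network label grid mismatch")
        present = set(np.unique(self.network_labels)) - {0}
        expected = set(range(1, self.n_networks + 1))
        if not expected <= present:
            raise ValueError(
                f"networks {sorted(expected - present)} have no voxels")
        if self.sex_effect is None:
            self.sex_effect = np.ones(self.n_networks)
        self.sex_effect = np.asarray(self.sex_effect, dtype=float)
        if self.sex_effect.shape != (self.n_networks,):
            raise ValueError("sex_effect needs one value per network")


def fixture_network_labels(grid_shape: Sequence[int],
                           n_networks: int = 14) -> np.ndarray:
    """Hemisphere-split network parcellation covering the whole grid.

    Networks 1..7 tile the left slab (x < nx/2), 8..14 the right slab,
    as contiguous blocks of the flattened voxel list.
    """
    grid_shape = tuple(int(v) for v in grid_shape)
    if n_networks % 2:
        raise ValueError("n_networks must be even (7 per hemisphere)")
    half = n_networks // 2
    flat = np.arange(int(np.prod(grid_shape)))
    x = np.unravel_index(flat, grid_shape)[0]
    nx = grid_shape[0]
    labels = np.zeros(flat.size, dtype=np.int32)
    for side, (sel, offset) in enumerate(
            (((x < nx // 2), 0), ((x >= nx // 2), half))):
        pool = flat[sel]
        if len(pool) < half:
            raise ValueError("grid too small to contain all networks")
        blocks = np.array_split(pool, half)
        for i, b in enumerate(blocks):
            labels[b] = offset + i + 1
    return labels.reshape(grid_shape)


def generate_connectomes(config: ConnectomeFixtureConfig):
    """Male and female 4D resting-state fixtures.

    Each subject's voxel time series stacks four components: a global
    physiological signal shared by every voxel (what global-signal
    regression exists to remove), a within-network latent (the network
    signal), optionally a local parcel latent (short-range coherence,
    parcels of ``parcel_size`` voxels within each network) and i.i.d.
    voxel noise.  Network amplitudes can carry a subject-specific factor
    (spread ``subject_sd``).  ``sex_effect`` multiplies the network latent
    for female subjects, after which the series is rescaled to its
    male-law variance — the effect is a pure within-network coherence
    (connectivity) difference, not a BOLD-amplitude difference.
    Returns ``(male_images, female_images, network_image)``.
    """
    rng = np.random.default_rng(config.rng_seed)
    labels = config.network_labels.ravel()
    n_vox = labels.size
    T = config.n_timepoints
    # fixed parcellation of each network into local-coherence parcels
    parcel_of = np.zeros(n_vox, dtype=np.int64)
    n_parcels = 0
    for net in range(1, config.n_networks + 1):
        vox = np.flatnonzero(labels == net)
        for start in range(0, len(vox), config.parcel_size):
            parcel_of[vox[start:start + config.parcel_size]] = n_parcels
            n_parcels += 1
    out = {}
    for sex, effect in ((SEX_MALE, np.ones(config.n_networks)),
                        (SEX_FEMALE, config.sex_effect)):
        imgs = []
        for _ in range(config.n_subjects_per_sex):
            raw = rng.standard_normal((config.n_networks, T),
                                      dtype=np.float32)
            if T >= config.n_networks:
                # exactly orthogonal network latents: inter-network sample
                # correlations vanish identically instead of fluctuating
                # at the 1/sqrt(T) scale
                q, _ = np.linalg.qr(raw.T)
                latents = np.ascontiguousarray(q.T) * np.float32(
                    np.sqrt(T))
            else:
                # too few timepoints to orthogonalize 14 series
                latents = raw
            global_sig = rng.standard_normal(T, dtype=np.float32)
            amp = np.clip(
                1.0 + config.subject_sd * rng.standard_normal(
                    config.n_networks), 0.1, None)
            data = config.noise_sd * rng.standard_normal(
                (n_vox, T), dtype=np.float32)
            if config.local_strength > 0:
                local = rng.standard_normal((n_parcels, T),
                                            dtype=np.float32)
                data += config.local_strength * local[parcel_of]
            for net in range(1, config.n_networks + 1):
                sel = labels == net
                a = config.signal_strength * amp[net - 1]
                e = effect[net - 1]
                # the sex effect divides the voxel noise: within-network
                # coherence rises by the same factor as amplifying the
                # latent, but the network's latent and global-signal
                # loadings keep their male-law values, so the whole-brain
                # mean (hence global-signal regression) is sex-invariant
                data[sel] = data[sel] / e + np.float32(a) * latents[net - 1]
            data += np.float32(config.global_strength) * global_sig
            img = nib.Nifti1Image(
                data.reshape(*config.grid_shape, T), np.eye(4))
            imgs.append(img)
        out[sex] = imgs
    network_img = nib.Nifti1Image(config.network_labels, np.eye(4))
    return out[SEX_MALE], out[SEX_FEMALE], network_img


# ----------------------------------------------------------------------
# on-disk fixtures
# ----------------------------------------------------------------------

def write_cohort_fixture(config: GeneratorConfig, out_dir,
                         with_images: bool = False,
                         atlas: Optional[AtlasSpec] = None) -> dict:
    """Write cohort CSVs (and optionally masks + atlas) plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lesion, expressions, cohort = generate_cohort(config)
    paths = {}
    if with_images:
        if atlas is None:
            atlas = fixture_atlas()
        lesion = clip_matrix_to_atlas(lesion, atlas)
        masks = generate_lesion_images(lesion, atlas)
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        for pid, img in masks.items():
            nib.save(img, mask_dir / f"{pid}.nii")
        for layer in LAYERS:
            p = out / f"atlas_{layer}.nii"
            nib.save(nib.Nifti1Image(atlas.layer_image(layer),
                                     atlas.affine), p)
        atlas.region_table.to_csv(out / "atlas_regions.csv", index=False)
        paths["masks"] = str(mask_dir)
    lesion.to_csv(out / "lesion_matrix.csv")
    expressions.to_csv(out / "true_expressions.csv")
    cohort.to_csv(out / "cohort.csv")
    sidecar = {"seed": config.rng_seed, "n_patients": config.n_patients,
               "n_patterns": config.n_patterns,
               "n_regions": config.n_regions,
               "sex_ratio": config.sex_ratio,
               "intercept": config.intercept,
               "covariate_effects": config.covariate_effects,
               "true_coefficients": config.true_coefficients.tolist()}
    (out / "generator.json").write_text(json.dumps(sidecar, indent=2))
    paths.update({"lesion_matrix": str(out / "lesion_matrix.csv"),
                  "cohort": str(out / "cohort.csv")})
    return paths


def write_connectome_fixture(config: ConnectomeFixtureConfig,
                             out_dir) -> dict:
    out = Path(out_dir)
    male, female, network_img = generate_connectomes(config)
    paths = {}
    for sex, imgs in (("male", male), ("female", female)):
        d = out / sex
        d.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(imgs):
            nib.save(img, d / f"sub{i:03d}.nii")
        paths[sex] = str(d)
    nib.save(network_img, out / "networks.nii")
    sidecar = {"seed": config.rng_seed,
               "n_subjects_per_sex": config.n_subjects_per_sex,
               "grid_shape": list(config.grid_shape),
               "n_timepoints": config.n_timepoints,
               "sex_effect": np.asarray(config.sex_effect).tolist()}
    (out / "generator.json").write_text(json.dumps(sidecar, indent=2))
    paths["networks"] = str(out / "networks.nii")
    return paths
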