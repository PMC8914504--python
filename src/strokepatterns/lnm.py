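"""Lesion network mapping on sex-specific normative connectomes.

Each of the 10 lesion patterns is perturbed into 100 variants by sampling a
random number and subset of its affiliated regions (normalized NMF loading
> 0.05).  Every variant's atlas-support mask seeds a whole-brain
functional-connectivity map in a male and a female normative connectome:
per healthy subject, the global signal is regressed out, the seed time
series (mean over mask voxels) is correlated with every voxel, correlations
are Fisher z-transformed, and a one-sample t-map across subjects is formed.
The positive and negative t-values are summed ("intensity") within the 14
hemisphere-specific cortical networks and compared between the male- and
female-connectome maps by two-sided t-tests with Benjamini-Hochberg FDR
correction over the 14 x 10 family, separately per sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .parcellation import AtlasSpec, _as_array

R_CLIP = 0.999999
POSITIVE, NEGATIVE = "positive", "negative"


@dataclass(frozen=True)
class PatternVariant:
    """A random subset of one pattern's affiliated regions."""

    pattern_id: int
    index: int
    regions: tuple  # region column names

    def __post_init__(self):
        if len(self.regions) < 1:
            raise ValueError("a variant needs at least one region")


def sample_variants(affiliated: Sequence[str], n_variants: int = 100,
                    seed: int = 0, pattern_id: int = 0) -> list:
    """Variants of a pattern: size m ~ Uniform{1..|affiliated|}, then m
    regions drawn uniformly without replacement.  Deterministic given seed.
    """
    affiliated = list(affiliated)
    if not affiliated:
        raise ValueError("affiliated region set is empty")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_variants):
        m = int(rng.integers(1, len(affiliated) + 1))
        chosen = rng.choice(len(affiliated), size=m, replace=False)
        out.append(PatternVariant(
            pattern_id=pattern_id, index=i,
            regions=tuple(affiliated[j] for j in sorted(chosen))))
    return out


def variant_mask(variant: PatternVariant, atlas: AtlasSpec) -> np.ndarray:
    """Boolean seed mask: union of the chosen regions' atlas support."""
    lookup = {}
    for _, row in atlas.region_table.iterrows():
        name = f"{row['layer']}_{int(row['label'])}_{row['name']}"
        lookup[name] = (row["layer"], int(row["label"]))
    mask = np.zeros(int(np.prod(atlas.shape)), dtype=bool)
    for region in variant.regions:
        if region not in lookup:
            raise KeyError(f"region '{region}' not in atlas")
        layer, label = lookup[region]
        mask[atlas.region_support(layer, label)] = True
    if not mask.any():
        raise ValueError(f"variant {variant.pattern_id}/{variant.index} "
                         "has an empty seed mask")
    return mask.reshape(atlas.shape)


@dataclass
class ConnectomeData:
    """Preprocessed normative connectome: per-subject residual series.

    ``residuals`` is a list of (n_voxels, T) arrays after demeaning and
    (optionally) global-signal regression; ``norms`` holds the per-voxel
    L2 norms used to normalize correlations (0 for constant voxels).
    """

    residuals: list
    norms: list
    grid_shape: tuple
    sex: str
    gsr: bool

    @property
    def n_subjects(self) -> int:
        return len(self.residuals)


def preprocess_connectome(images, sex: str = "",
                          gsr: bool = True) -> ConnectomeData:
    """Demean voxel time series and regress out the global signal.

    The global signal is the mean time series over all voxels with nonzero
    variance; regression is per-voxel simple least squares (with
    intercept, i.e. on demeaned series).
    """
    residuals, norms = [], []
    grid_shape = None
    for img in images:
        data = np.asarray(_as_array(img), dtype=np.float32)
        if data.ndim != 4:
            raise ValueError("connectome images must be 4D")
        if grid_shape is None:
            grid_shape = data.shape[:3]
        elif data.shape[:3] != grid_shape:
            raise ValueError("connectome subjects on differing grids")
        V = data.reshape(-1, data.shape[3])
        V = V - V.mean(axis=1, keepdims=True)
        if gsr:
            vox_var = (V ** 2).sum(axis=1)
            g = V[vox_var > 0].mean(axis=0)
            gg = g @ g
            if gg > 0:
                V = V - np.outer((V @ g) / gg, g)
        nrm = np.sqrt((V ** 2).sum(axis=1))
        residuals.append(V)
        norms.append(nrm)
    if grid_shape is None:
        raise ValueError("no subject images supplied")
    return ConnectomeData(residuals, norms, tuple(grid_shape), sex, gsr)


@dataclass
class ConnectivityTMap:
    """Voxel-wise one-sample t map of Fisher-z lesion connectivity."""

    t: np.ndarray
    n_subjects: int
    sex: str

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least two subjects for a t map")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("t map contains non-finite values")


def lesion_connectivity(seed_mask: np.ndarray,
                        connectome,
                        gsr: bool = True,
                        variant: Optional[PatternVariant] = None
                        ) -> ConnectivityTMap:
    """Seed-based group connectivity t map for one lesion (variant) mask.

    ``connectome`` is either a :class:`ConnectomeData` or an iterable of 4D
    images (preprocessed on the fly).  Per subject: Pearson r of every
    voxel's residual series with the seed-mean series, Fisher z with r
    clipped to +-0.999999; constant voxels get r = 0 by convention.  The
    group map is the one-sample t statistic across subjects (voxels with
    zero variance across subjects get t = 0).
    """
    if not isinstance(connectome, ConnectomeData):
        connectome = preprocess_connectome(connectome, gsr=gsr)
    mask = np.asarray(_as_array(seed_mask)).astype(bool)
    if mask.shape != connectome.grid_shape:
        raise ValueError("seed mask grid does not match connectome grid")
    flat = mask.ravel()
    z_maps = []
    for V, nrm in zip(connectome.residuals, connectome.norms):
        s = V[flat].mean(axis=0)
        s_norm = np.sqrt(s @ s)
        if s_norm == 0:
            ident = ("" if variant is None
                     else f" (variant {variant.pattern_id}/{variant.index})")
            raise ValueError(f"zero-variance seed time series{ident}")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (V @ s) / (nrm * s_norm)
        r[nrm == 0] = 0.0  # constant voxel convention
        z_maps.append(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))
    Z = np.vstack(z_maps)
    n = Z.shape[0]
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    nz = sd > 0
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    return ConnectivityTMap(t=t.reshape(connectome.grid_shape),
                            n_subjects=n, sex=connectome.sex)


def network_intensity(tmap: ConnectivityTMap, network_labels,
                      n_networks: int = 14) -> pd.DataFrame:
    """Signed sums of t-values within each cortical network.

    Returns one row per (network, sign) with the positive intensity
    (sum of t > 0, hence >= 0) and negative intensity (sum of t < 0).
    """
    labels = np.asarray(_as_array(network_labels)).astype(int)
    if labels.shape != tmap.t.shape:
        raise ValueError("network label grid does not match t map grid")
    t = tmap.t.ravel()
    lab = labels.ravel()
    rows = []
    for net in range(1, n_networks + 1):
        sel = lab == net
        if not sel.any():
            raise ValueError(f"network {net} has zero voxels")
        tv = t[sel]
        rows.append({"network": net, "sign": POSITIVE,
                     "intensity": float(tv[tv > 0].sum())})
        rows.append({"network": net, "sign": NEGATIVE,
                     "intensity": float(tv[tv < 0].sum())})
    return pd.DataFrame(rows)


def sex_contrast(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Male-vs-female comparison of network intensities across variants.

    ``table`` needs columns pattern, variant, sex, network, sign,
    intensity with the same number of variants per sex in every cell.
    Two-sided Welch t-tests per (pattern, network, sign); BH-FDR within
    each sign's 14-networks x 10-patterns family; flags at adjusted
    p < alpha.
    """
    required = {"pattern", "variant", "sex", "network", "sign", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"intensity table lacks columns {sorted(missing)}")
    rows = []
    for (pattern, network, sign), cell in table.groupby(
            ["pattern", "network", "sign"]):
        male = cell.loc[cell["sex"] == "M", "intensity"].to_numpy(float)
        female = cell.loc[cell["sex"] == "F", "intensity"].to_numpy(float)
        if male.size != female.size:
            raise ValueError(
                f"unequal variant counts for pattern {pattern}, network "
                f"{network}, {sign}: {male.size} vs {female.size}")
        if male.var() == 0 and female.var() == 0:
            t_stat = 0.0
            p = 1.0 if male.mean() == female.mean() else 0.0
        else:
            t_stat, p = stats.ttest_ind(male, female, equal_var=False)
        rows.append({"pattern": pattern, "network": network, "sign": sign,
                     "t_stat": float(t_stat), "p": float(p),
                     "mean_male": float(male.mean()),
                     "mean_female": float(female.mean())})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for sign in (POSITIVE, NEGATIVE):
        sel = out["sign"] == sign
        if sel.any():
            _, adj, _, _ = multipletests(out.loc[sel, "p"],
                                         method="fdr_bh")
            out.loc[sel, "p_fdr"] = adj
    out["significant"] = out["p_fdr"] < alpha
    return out


def _batch_tmaps(masks: np.ndarray, connectome: ConnectomeData
                 ) -> np.ndarray:
    """t maps for many seed masks at once (one GEMM per subject).

    ``masks`` is (n_seeds, n_voxels) boolean; returns (n_voxels, n_seeds)
    group t values.  Numerically identical to per-variant
    :func:`lesion_connectivity`.
    """
    sizes = masks.sum(axis=1).astype(np.float32)
    if (sizes == 0).any():
        raise ValueError("empty seed mask in batch")
    M = masks.astype(np.float32) / sizes[:, None]
    n_vox = masks.shape[1]
    z_sum = np.zeros((n_vox, masks.shape[0]))
    z_sumsq = np.zeros_like(z_sum)
    n = connectome.n_subjects
    for V, nrm in zip(connectome.residuals, connectome.norms):
        S = M @ V                                    # seeds x T
        s_norm = np.sqrt((S * S).sum(axis=1))
        if (s_norm == 0).any():
            raise ValueError("zero-variance seed time series in batch")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (V @ S.T) / (nrm[:, None] * s_norm[None, :])
        r[nrm == 0, :] = 0.0
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
        z_sum += z
        z_sumsq += z * z
    mean = z_sum / n
    var = (z_sumsq - n * mean * mean) / (n - 1)
    var[var < 0] = 0.0
    sd = np.sqrt(var)
    t = np.zeros_like(mean)
    nz = sd > 0
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    return t


def run_lnm(basis, atlas: AtlasSpec, male_images, female_images,
            network_labels, n_variants: int = 100, seed: int = 0,
            threshold: float = 0.05, gsr: bool = True,
            n_networks: int = 14):
    """Full LNM stage for all patterns of a fitted basis.

    Returns ``(intensity_table, contrast_table)``.  Variant sampling seeds
    are derived per pattern from ``seed``; the same variants are used
    against the male and the female connectome.
    """
    from .patterns import affiliated_regions

    male = preprocess_connectome(male_images, sex="M", gsr=gsr)
    female = preprocess_connectome(female_images, sex="F", gsr=gsr)
    ss = np.random.SeedSequence(seed)
    pattern_seeds = ss.spawn(basis.k)
    all_variants = []
    for pid in range(1, basis.k + 1):
        regions = affiliated_regions(basis, pid, threshold)
        all_variants.extend(sample_variants(
            regions, n_variants,
            seed=int(pattern_seeds[pid - 1].generate_state(1)[0] % (2**31)),
            pattern_id=pid))
    masks = np.vstack([variant_mask(v, atlas).ravel()
                       for v in all_variants])

    labels = np.asarray(_as_array(network_labels)).astype(int).ravel()
    onehot = np.zeros((n_networks, labels.size))
    for net in range(1, n_networks + 1):
        sel = labels == net
        if not sel.any():
            raise ValueError(f"network {net} has zero voxels")
        onehot[net - 1, sel] = 1.0

    records = []
    for conn in (male, female):
        t = _batch_tmaps(masks, conn)                  # voxels x seeds
        pos = onehot @ np.where(t > 0, t, 0.0)         # networks x seeds
        neg = onehot @ np.where(t < 0, t, 0.0)
        for i, var in enumerate(all_variants):
            for net in range(1, n_networks + 1):
                records.append((var.pattern_id, var.index, conn.sex, net,
                                POSITIVE, pos[net - 1, i]))
                records.append((var.pattern_id, var.index, conn.sex, net,
                                NEGATIVE, neg[net - 1, i]))
    intensity = pd.DataFrame(records, columns=[
        "pattern", "variant", "sex", "network", "sign", "intensity"])
    contrast = sex_contrast(intensity)
    return intensity, contrast
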