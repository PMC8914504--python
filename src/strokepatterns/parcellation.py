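"""Atlas parcellation of binary stroke-lesion masks.

Lesion masks are reduced to a 129-dimensional lesion-load vector: the number
of lesioned voxels inside each of 94 cortical regions, 15 subcortical
regions and 20 white-matter tracts.  The three atlas layers are independent
label images on a shared grid — a voxel may count toward both a cortical
region and a tract.  Total lesion volume is reported in ml
(voxels x voxel volume / 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

LAYERS = ("cortical", "subcortical", "tract")
DEFAULT_LAYER_SIZES = {"cortical": 94, "subcortical": 15, "tract": 20}
VOLUME_COLUMN = "lesion_volume_ml"

_AFFINE_ATOL = 1e-4


def _as_array(img) -> np.ndarray:
    if isinstance(img, nib.spatialimages.SpatialImage):
        return np.asanyarray(img.dataobj)
    return np.asarray(img)


def discretize_probabilistic_atlas(prob_maps: np.ndarray,
                                   floor: float = 0.25) -> np.ndarray:
    """Maximum-probability discrete labels from a stack of probability maps.

    ``prob_maps`` has shape ``(n_regions, *grid)`` with values in [0, 1];
    voxels whose winning probability is below ``floor`` stay background (0).
    Returned labels are 1-based.
    """
    prob_maps = np.asarray(prob_maps, dtype=float)
    winner = np.argmax(prob_maps, axis=0)
    best = np.take_along_axis(prob_maps, winner[None], axis=0)[0]
    labels = (winner + 1).astype(np.int32)
    labels[best < floor] = 0
    return labels


@dataclass
class AtlasSpec:
    """Three-layer label atlas on a common grid.

    ``region_table`` has one row per region with columns
    ``layer``, ``label`` (integer, unique within its layer), ``name`` and
    ``hemisphere`` ('L'/'R'/'B'), ordered cortical, subcortical, tract —
    the column order of every lesion matrix.
    """

    cortical: np.ndarray
    subcortical: np.ndarray
    tract: np.ndarray
    region_table: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_volume_mm3: float = 1.0
    layer_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_LAYER_SIZES))

    def __post_init__(self) -> None:
        self.cortical = _as_array(self.cortical).astype(np.int32)
        self.subcortical = _as_array(self.subcortical).astype(np.int32)
        self.tract = _as_array(self.tract).astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=float)
        shapes = {self.cortical.shape, self.subcortical.shape,
                  self.tract.shape}
        if len(shapes) != 1:
            raise ValueError(f"atlas layers have differing grids: {shapes}")
        for layer in LAYERS:
            labels = self.layer_labels(layer)
            if len(labels) != len(set(labels)):
                raise ValueError(f"duplicate region labels in layer {layer}")
            expected = self.layer_sizes[layer]
            if len(labels) != expected:
                raise ValueError(
                    f"layer {layer} has {len(labels)} regions in the region "
                    f"table, expected {expected}")
            present = set(np.unique(self.layer_image(layer))) - {0}
            missing = set(labels) - present
            if missing:
                raise ValueError(
                    f"layer {layer}: labels {sorted(missing)} absent from "
                    "the label image")

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.cortical.shape

    @property
    def n_regions(self) -> int:
        return len(self.region_table)

    def layer_image(self, layer: str) -> np.ndarray:
        return {"cortical": self.cortical, "subcortical": self.subcortical,
                "tract": self.tract}[layer]

    def layer_labels(self, layer: str) -> list:
        sub = self.region_table[self.region_table["layer"] == layer]
        return [int(v) for v in sub["label"]]

    def column_names(self) -> list:
        return [f"{row['layer']}_{int(row['label'])}_{row['name']}"
                for _, row in self.region_table.iterrows()]

    def region_support(self, layer: str, label: int) -> np.ndarray:
        """Sorted flat voxel indices of one region."""
        img = self.layer_image(layer)
        return np.flatnonzero(img.ravel() == label)

    def layers_disjoint(self) -> bool:
        occupied = ((self.cortical > 0).astype(int)
                    + (self.subcortical > 0).astype(int)
                    + (self.tract > 0).astype(int))
        return bool((occupied <= 1).all())


def _check_mask(mask_img, atlas: AtlasSpec) -> np.ndarray:
    data = _as_array(mask_img)
    if data.shape != atlas.shape:
        raise ValueError(
            f"mask grid {data.shape} does not match atlas grid {atlas.shape}")
    if isinstance(mask_img, nib.spatialimages.SpatialImage):
        if not np.allclose(mask_img.affine, atlas.affine, atol=_AFFINE_ATOL):
            raise ValueError(
                "mask affine does not match atlas affine:\n"
                f"mask:\n{mask_img.affine}\natlas:\n{atlas.affine}")
    vals = np.unique(data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask is not binary; values found: {vals[:10]}")
    return data.astype(bool)


def parcellate_lesion(mask_img, atlas: AtlasSpec) -> pd.Series:
    """Per-region lesioned-voxel counts plus total volume for one mask.

    Each atlas layer is counted independently, so a voxel labelled in both
    the cortical and the tract layer contributes to both counts.
    """
    mask = _check_mask(mask_img, atlas)
    counts = []
    for layer in LAYERS:
        img = atlas.layer_image(layer)
        labels = atlas.layer_labels(layer)
        # bincount over labelled voxels only
        hit = np.bincount(img[mask].ravel(),
                          minlength=max(labels, default=0) + 1)
        counts.extend(int(hit[lab]) for lab in labels)
    volume_ml = float(mask.sum()) * atlas.voxel_volume_mm3 / 1000.0
    index = atlas.column_names() + [VOLUME_COLUMN]
    return pd.Series(counts + [volume_ml], index=index, name=None)


def assemble_matrix(rows: Iterable[pd.Series],
                    patient_ids: Sequence[str]) -> pd.DataFrame:
    """Stack per-patient parcellation rows into a lesion matrix.

    Patient order follows the input order; duplicate ids are an error.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes}")
    rows = list(rows)
    if len(rows) != len(ids):
        raise ValueError("number of rows differs from number of patient ids")
    if not rows:
        # empty matrix still carries the canonical columns when possible
        return pd.DataFrame(columns=[], index=pd.Index([], name="patient_id"))
    df = pd.DataFrame(rows)
    df.index = pd.Index(ids, name="patient_id")
    return df


def region_columns(matrix: pd.DataFrame) -> list:
    return [c for c in matrix.columns if c != VOLUME_COLUMN]


def compare_lesion_anatomy(matrix: pd.DataFrame,
                           sex: pd.Series,
                           alpha: float = 0.05):
    """Sex comparison of lesion anatomy, family-wise (Bonferroni) corrected.

    Per region: a two-sample (Welch) t-test on lesioned-voxel counts and a
    two-sided Fisher's exact test on affected/not-affected status, each
    Bonferroni-corrected over the 129-region family.  The whole-brain
    lesion-volume t-test is returned alongside.

    Returns ``(region_df, volume_test)``.
    """
    sex = pd.Series(sex).reindex(matrix.index)
    if sex.isna().any():
        raise ValueError("sex labels missing for some patients")
    groups = sex.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two sex groups, found {list(groups)}")
    g1, g2 = sorted(map(str, groups))
    m1 = matrix.loc[sex.astype(str) == g1]
    m2 = matrix.loc[sex.astype(str) == g2]
    if len(m1) < 2 or len(m2) < 2:
        raise ValueError("need at least two patients per sex group")

    cols = region_columns(matrix)
    n_family = len(cols)
    records = []
    for col in cols:
        a, b = m1[col].to_numpy(float), m2[col].to_numpy(float)
        if a.var() == 0 and b.var() == 0 and a.mean() == b.mean():
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
        aff1, aff2 = int((a > 0).sum()), int((b > 0).sum())
        table = [[aff1, len(a) - aff1], [aff2, len(b) - aff2]]
        _, f_p = stats.fisher_exact(table, alternative="two-sided")
        records.append({
            "region": col,
            f"n_affected_{g1}": aff1, f"n_affected_{g2}": aff2,
            "t_stat": float(t_stat), "t_p": float(t_p),
            "t_p_bonf": min(1.0, float(t_p) * n_family),
            "fisher_p": float(f_p),
            "fisher_p_bonf": min(1.0, float(f_p) * n_family),
        })
    region_df = pd.DataFrame.from_records(records).set_index("region")
    region_df["t_significant"] = region_df["t_p_bonf"] < alpha
    region_df["fisher_significant"] = region_df["fisher_p_bonf"] < alpha

    if VOLUME_COLUMN in matrix.columns:
        v1 = m1[VOLUME_COLUMN].to_numpy(float)
        v2 = m2[VOLUME_COLUMN].to_numpy(float)
        vt, vp = stats.ttest_ind(v1, v2, equal_var=False)
        volume_test = {"t_stat": float(vt), "p": float(vp),
                       f"mean_{g1}": float(v1.mean()),
                       f"mean_{g2}": float(v2.mean())}
    else:
        volume_test = None
    return region_df, volume_test


def load_mask(path) -> nib.Nifti1Image:
    return nib.load(str(path))


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=True)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="patient_id")
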