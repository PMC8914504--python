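"""Lesion network mapping: variant sampling, connectivity oracles, FDR."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from strokepatterns import (fixture_network_labels, generate_connectomes,
                            lesion_connectivity, network_intensity,
                            preprocess_connectome, sample_variants,
                            sex_contrast)
from strokepatterns.lnm import (ConnectivityTMap, PatternVariant,
                                _batch_tmaps, variant_mask)
from strokepatterns.synthetic import ConnectomeFixtureConfig


class TestSampleVariants:
    def test_single_region(self):
        variants = sample_variants(["r1"], n_variants=20, seed=0)
        assert all(v.regions == ("r1",) for v in variants)

    def test_inclusion_probability(self):
        """|affiliated| = 5: closed-form inclusion probability is
        (1/5) * sum_m m/5 = 0.6."""
        regions = [f"r{i}" for i in range(5)]
        variants = sample_variants(regions, n_variants=10_000, seed=1)
        for r in regions:
            freq = np.mean([r in v.regions for v in variants])
            se = np.sqrt(0.6 * 0.4 / 10_000)
            assert abs(freq - 0.6) < 3 * se

    def test_sizes_uniform(self):
        regions = [f"r{i}" for i in range(4)]
        variants = sample_variants(regions, n_variants=8000, seed=2)
        sizes = np.array([len(v.regions) for v in variants])
        for m in (1, 2, 3, 4):
            assert abs((sizes == m).mean() - 0.25) < 0.02

    def test_seeded_determinism(self):
        a = sample_variants(list("abcde"), 50, seed=3)
        b = sample_variants(list("abcde"), 50, seed=3)
        assert [v.regions for v in a] == [v.regions for v in b]

    def test_empty_affiliated_raises(self):
        with pytest.raises(ValueError, match="empty"):
            sample_variants([], 10, seed=0)


@pytest.fixture(scope="module")
def tiny_connectome():
    cfg = ConnectomeFixtureConfig(n_subjects_per_sex=4, n_timepoints=20,
                                  rng_seed=7)
    male, female, net_img = generate_connectomes(cfg)
    return cfg, male, female, net_img


class TestLesionConnectivity:
    def test_brute_force_oracle(self):
        """4 subjects on a tiny grid: regress, correlate, atanh, t —
        computed per voxel by hand."""
        rng = np.random.default_rng(0)
        n_vox, T, n_sub = 6, 20, 4
        subject_data = [rng.normal(size=(n_vox, T)) for _ in range(n_sub)]
        mask = np.zeros(n_vox, dtype=bool)
        mask[:2] = True

        z_all = []
        for D in subject_data:
            D = D - D.mean(axis=1, keepdims=True)
            g = D.mean(axis=0)
            D = D - np.outer(D @ g / (g @ g), g)
            s = D[mask].mean(axis=0)
            z = []
            for v in range(n_vox):
                r = np.corrcoef(D[v], s)[0, 1]
                z.append(np.arctanh(np.clip(r, -0.999999, 0.999999)))
            z_all.append(z)
        Z = np.array(z_all)
        t_oracle = Z.mean(0) / (Z.std(0, ddof=1) / np.sqrt(n_sub))

        imgs = [d.reshape(n_vox, 1, 1, T) for d in subject_data]
        conn = preprocess_connectome(imgs, sex="M", gsr=True)
        tmap = lesion_connectivity(mask.reshape(n_vox, 1, 1), conn)
        np.testing.assert_allclose(tmap.t.ravel(), t_oracle, atol=5e-4)

    def test_constant_voxel_convention(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(5, 1, 1, 15))
        data[3] = 2.5  # constant series
        conn = preprocess_connectome([data], sex="M", gsr=False)
        mask = np.zeros((5, 1, 1), dtype=bool)
        mask[0] = True
        conn2 = preprocess_connectome([data, data + 0.0], sex="M",
                                      gsr=False)
        tmap = lesion_connectivity(mask, conn2)
        assert tmap.t[3, 0, 0] == 0.0

    def test_seed_plus_noise_positive_everywhere(self):
        """Every voxel equals the seed mean plus tiny noise: all r near 1,
        t large and positive."""
        rng = np.random.default_rng(2)
        base = rng.normal(size=20)
        imgs = []
        for _ in range(4):
            d = base[None, :] + 0.05 * rng.normal(size=(8, 20))
            imgs.append(d.reshape(8, 1, 1, 20))
        conn = preprocess_connectome(imgs, sex="M", gsr=False)
        mask = np.zeros((8, 1, 1), dtype=bool)
        mask[:3] = True
        tmap = lesion_connectivity(mask, conn)
        assert (tmap.t > 10).all()

    def test_subject_order_invariance(self, tiny_connectome):
        cfg, male, _, _ = tiny_connectome
        mask = np.zeros(cfg.grid_shape, dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        t1 = lesion_connectivity(mask,
                                 preprocess_connectome(male, sex="M"))
        t2 = lesion_connectivity(mask,
                                 preprocess_connectome(male[::-1],
                                                       sex="M"))
        np.testing.assert_allclose(t1.t, t2.t, atol=1e-4)

    def test_finite_everywhere(self, tiny_connectome):
        cfg, male, _, _ = tiny_connectome
        mask = np.zeros(cfg.grid_shape, dtype=bool)
        mask[0, 0, 0] = True
        tmap = lesion_connectivity(mask, preprocess_connectome(male,
                                                               sex="M"))
        assert np.isfinite(tmap.t).all()

    def test_batch_matches_single(self, tiny_connectome):
        cfg, male, _, _ = tiny_connectome
        conn = preprocess_connectome(male, sex="M")
        rng = np.random.default_rng(3)
        masks = rng.random((4, int(np.prod(cfg.grid_shape)))) < 0.05
        batch = _batch_tmaps(masks, conn)
        for i in range(4):
            single = lesion_connectivity(
                masks[i].reshape(cfg.grid_shape), conn)
            np.testing.assert_allclose(single.t.ravel(), batch[:, i],
                                       rtol=1e-4, atol=1e-3)

    def test_two_subject_minimum(self):
        with pytest.raises(ValueError, match="two subjects"):
            ConnectivityTMap(t=np.zeros((2, 2, 2)), n_subjects=1, sex="M")


class TestNetworkIntensity:
    def _tmap(self, t):
        return ConnectivityTMap(t=t, n_subjects=4, sex="M")

    def test_all_zero(self):
        labels = fixture_network_labels((14, 2, 1))
        rows = network_intensity(self._tmap(np.zeros((14, 2, 1))), labels)
        assert (rows["intensity"] == 0).all()

    def test_localized_positive(self):
        labels = fixture_network_labels((14, 2, 1))
        t = np.zeros((14, 2, 1))
        t[labels == 3] = 1.0
        rows = network_intensity(self._tmap(t), labels)
        n3pos = rows[(rows.network == 3) & (rows.sign == "positive")]
        assert n3pos["intensity"].iloc[0] == (labels == 3).sum()
        others = rows[~((rows.network == 3) & (rows.sign == "positive"))]
        assert (others["intensity"] == 0).all()

    def test_voxel_loop_oracle(self):
        rng = np.random.default_rng(4)
        labels = fixture_network_labels((14, 4, 2))
        t = rng.normal(size=(14, 4, 2))
        rows = network_intensity(self._tmap(t), labels)
        for net in range(1, 15):
            pos = neg = 0.0
            for idx in np.ndindex(t.shape):
                if labels[idx] == net:
                    if t[idx] > 0:
                        pos += t[idx]
                    else:
                        neg += t[idx]
            got = rows[rows.network == net].set_index("sign")["intensity"]
            assert got["positive"] == pytest.approx(pos)
            assert got["negative"] == pytest.approx(neg)
        assert (rows[rows.sign == "positive"]["intensity"] >= 0).all()
        assert (rows[rows.sign == "negative"]["intensity"] <= 0).all()

    def test_missing_network_raises(self):
        labels = np.ones((4, 4, 1), dtype=int)  # only network 1 present
        with pytest.raises(ValueError, match="zero voxels"):
            network_intensity(self._tmap(np.zeros((4, 4, 1))), labels,
                              n_networks=14)


class TestSexContrast:
    def _table(self, male_vals, female_vals, n_networks=2, n_patterns=2):
        rows = []
        for p in range(1, n_patterns + 1):
            for net in range(1, n_networks + 1):
                for sign in ("positive", "negative"):
                    for i, v in enumerate(male_vals):
                        rows.append((p, i, "M", net, sign, v))
                    for i, v in enumerate(female_vals):
                        rows.append((p, i, "F", net, sign, v))
        return pd.DataFrame(rows, columns=["pattern", "variant", "sex",
                                           "network", "sign", "intensity"])

    def test_identical_values_no_flags(self):
        vals = list(np.linspace(1, 5, 30))
        out = sex_contrast(self._table(vals, vals))
        assert (out["p"] == 1.0).all() | (out["p"] > 0.99).all()
        assert not out["significant"].any()

    def test_shifted_values_flagged(self):
        rng = np.random.default_rng(5)
        male = rng.normal(0, 1, 100)
        female = male + 10
        out = sex_contrast(self._table(list(male), list(female)))
        assert out["significant"].all()

    def test_unequal_counts_raise(self):
        t = self._table([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match="unequal"):
            sex_contrast(t)

    def test_fdr_adjustment_monotone(self):
        rng = np.random.default_rng(6)
        male = rng.normal(0, 1, 50)
        out = sex_contrast(self._table(list(male),
                                       list(male + rng.normal(0, 1, 50))))
        assert (out["p_fdr"] >= out["p"] - 1e-12).all()


def test_bh_fdr_step_up_oracle():
    """BH on a simple p-vector equals the hand-computed step-up values."""
    p = np.arange(1, 15) * 0.01  # 0.01 .. 0.14
    p[0] = 0.001
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    m = len(p)
    order = np.argsort(p)
    hand = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        hand[i] = running_min
    np.testing.assert_allclose(adj, hand, rtol=1e-12)


def test_variant_mask_union(small_atlas):
    names = small_atlas.column_names()
    var = PatternVariant(pattern_id=1, index=0,
                         regions=(names[0], names[5]))
    mask = variant_mask(var, small_atlas)
    r0 = small_atlas.region_table.iloc[0]
    r5 = small_atlas.region_table.iloc[5]
    expected = set(small_atlas.region_support(r0["layer"],
                                              int(r0["label"])))
    expected |= set(small_atlas.region_support(r5["layer"],
                                               int(r5["label"])))
    assert set(np.flatnonzero(mask.ravel())) == expected
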