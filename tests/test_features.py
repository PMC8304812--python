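import itertools
from collections import Counter

import numpy as np
import pytest

import oracles
from radstab import (
    ExtractionConfig,
    FEATURE_NAMES,
    CONTINUOUS_FIRSTORDER,
    COARSENESS_SENTINEL,
    NoduleMask,
    PhantomSpec,
    QuantisationConfig,
    VoxelVolume,
    WindowSettings,
    build_glcm,
    build_gldm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    clip_volume,
    extract_all,
    first_order,
    generate_phantom,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    quantise_volume,
)
from conftest import mask_of, qvol

CFG = ExtractionConfig()
WINDOW = WindowSettings()


def glcm_counter(m) -> Counter:
    return Counter(
        {(i + 1, j + 1): int(v) for (i, j), v in np.ndenumerate(m.counts) if v}
    )


def table_counter(m) -> Counter:
    """(level, col+1) counts for GLRLM/GLSZM matrices."""
    return Counter(
        {(i + 1, j + 1): int(v) for (i, j), v in np.ndenumerate(m.counts) if v}
    )


def gldm_counter(m) -> Counter:
    return Counter(
        {(i + 1, j): int(v) for (i, j), v in np.ndenumerate(m.counts) if v}
    )


# ---------------------------------------------------------------------------
# First-order
# ---------------------------------------------------------------------------

class TestFirstOrder:
    def test_constant_region(self):
        vol = VoxelVolume(values=np.full((3, 3, 3), -100.0))
        q = quantise_volume(vol, WINDOW, QuantisationConfig(32))
        f = first_order(vol, q, mask_of((3, 3, 3)))
        assert f["firstorder_Uniformity"] == 1.0
        assert f["firstorder_Entropy"] == 0.0
        assert f["firstorder_Range"] == 0.0
        assert f["firstorder_Std"] == 0.0
        assert np.isnan(f["firstorder_Skewness"])
        assert np.isnan(f["firstorder_Kurtosis"])

    def test_uniform_histogram_maximises_entropy(self):
        # one voxel in each of the 32 bins -> Entropy = log2(32) = 5 bits
        ng = 32
        bw = WINDOW.width / ng
        centres = WINDOW.ct_min + (np.arange(ng) + 0.5) * bw
        vol = VoxelVolume(values=centres.reshape(-1, 1, 1))
        q = quantise_volume(vol, WINDOW, QuantisationConfig(ng))
        f = first_order(vol, q, mask_of((ng, 1, 1)))
        assert f["firstorder_Entropy"] == pytest.approx(5.0)
        assert f["firstorder_Uniformity"] == pytest.approx(1.0 / ng)

    def test_hand_computed_moments(self):
        vol = VoxelVolume(values=np.array([-100.0, -50.0, 0.0, 50.0]).reshape(-1, 1, 1))
        q = quantise_volume(vol, WINDOW, QuantisationConfig(32))
        f = first_order(vol, q, mask_of((4, 1, 1)))
        assert f["firstorder_Mean"] == pytest.approx(-25.0)
        assert f["firstorder_Range"] == pytest.approx(150.0)
        assert f["firstorder_MAD"] == pytest.approx(50.0)

    def test_empty_mask_rejected(self):
        vol = VoxelVolume(values=np.zeros((2, 2, 2)))
        q = quantise_volume(vol, WINDOW, QuantisationConfig(32))
        with pytest.raises(ValueError, match="empty mask"):
            first_order(vol, q, mask_of(np.zeros((2, 2, 2), dtype=bool)))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

class TestGLCM:
    def test_single_pair_along_z(self):
        q = qvol(np.array([[[1, 2]]]), 2)
        mats = build_glcm(q, mask_of((1, 1, 2)))
        nonempty = [m for m in mats if not m.is_empty]
        assert len(nonempty) == 1
        assert nonempty[0].direction == (0, 0, 1)
        p = nonempty[0].counts / nonempty[0].counts.sum()
        assert p[0, 1] == pytest.approx(0.5)
        assert p[1, 0] == pytest.approx(0.5)

    def test_constant_region_mass_at_11(self):
        q = qvol(np.ones((2, 2, 2), dtype=int), 4)
        for m in build_glcm(q, mask_of((2, 2, 2))):
            if not m.is_empty:
                assert m.counts[0, 0] == m.counts.sum()

    def test_single_voxel_all_empty(self):
        q = qvol(np.ones((1, 1, 1), dtype=int), 2)
        mats = build_glcm(q, mask_of((1, 1, 1)))
        assert len(mats) == 13
        assert all(m.is_empty for m in mats)
        feats = glcm_features(mats)
        assert all(np.isnan(v) for v in feats.values())

    def test_contrast_on_two_level_pair(self):
        q = qvol(np.array([[[1, 2]]]), 2)
        f = glcm_features(build_glcm(q, mask_of((1, 1, 2))))
        assert f["glcm_Contr"] == pytest.approx(1.0)

    def test_constant_region_degenerate_values(self):
        q = qvol(np.ones((2, 2, 2), dtype=int), 4)
        f = glcm_features(build_glcm(q, mask_of((2, 2, 2))))
        assert f["glcm_Contr"] == 0.0
        assert f["glcm_ID"] == pytest.approx(1.0)
        assert f["glcm_JointEnergy"] == pytest.approx(1.0)
        assert f["glcm_MaxProb"] == pytest.approx(1.0)
        assert f["glcm_Corr"] == 1.0  # zero marginal variance convention
        assert f["glcm_IDN"] == pytest.approx(1.0)
        assert f["glcm_IDMN"] == pytest.approx(1.0)

    def test_idn_idmn_bounds(self):
        rng = np.random.default_rng(0)
        q = qvol(rng.integers(1, 5, (4, 4, 4)), 4)
        f = glcm_features(build_glcm(q, mask_of((4, 4, 4))))
        for key in ("glcm_IDN", "glcm_IDMN"):
            assert 0.0 < f[key] <= 1.0

    def test_symmetry_and_normalisation(self):
        rng = np.random.default_rng(1)
        q = qvol(rng.integers(1, 4, (4, 4, 4)), 4)
        mask = mask_of(rng.random((4, 4, 4)) > 0.3)
        for m in build_glcm(q, mask):
            np.testing.assert_array_equal(m.counts, m.counts.T)
            if not m.is_empty:
                p = m.counts / m.counts.sum()
                assert p.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

class TestGLDM:
    def test_constant_cube_dependence_seven(self):
        q = qvol(np.ones((2, 2, 2), dtype=int), 2)
        m = build_gldm(q, mask_of((2, 2, 2)))
        assert gldm_counter(m) == Counter({(1, 7): 8})

    def test_single_voxel(self):
        q = qvol(np.full((1, 1, 1), 2, dtype=int), 4)
        m = build_gldm(q, mask_of((1, 1, 1)))
        assert gldm_counter(m) == Counter({(2, 0): 1})
        f = gldm_features(m)
        assert f["gldm_SDE"] == pytest.approx(1.0)  # size indexes as j+1

    def test_strict_ramp_no_dependence(self):
        q = qvol(np.array([[[1, 2, 3]]]), 4)
        m = build_gldm(q, mask_of((1, 1, 3)))
        assert all(j == 0 for (_, j) in gldm_counter(m))

    def test_constant_cube_features(self):
        q = qvol(np.ones((2, 2, 2), dtype=int), 2)
        f = gldm_features(build_gldm(q, mask_of((2, 2, 2))))
        assert f["gldm_DE"] == 0.0
        assert f["gldm_DNN"] == pytest.approx(1.0)
        assert f["gldm_LGLE"] > 0 and f["gldm_HGLE"] > 0

    def test_alpha_relaxes_dependence(self):
        q = qvol(np.array([[[1, 2, 3]]]), 4)
        m = build_gldm(q, mask_of((1, 1, 3)), ExtractionConfig(gldm_alpha=1.0))
        # with alpha=1 every neighbour differs by exactly 1 -> all dependent
        assert {j for (_, j) in gldm_counter(m)} == {1, 2}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

class TestGLRLM:
    def test_runs_along_x(self):
        q = qvol(np.array([1, 1, 2]).reshape(3, 1, 1), 2)
        mats = build_glrlm(q, mask_of((3, 1, 1)))
        mx = next(m for m in mats if m.direction == (1, 0, 0))
        assert table_counter(mx) == Counter({(1, 2): 1, (2, 1): 1})

    def test_constant_bar_runs(self):
        q = qvol(np.ones((1, 1, 4), dtype=int), 2)
        mats = build_glrlm(q, mask_of((1, 1, 4)))
        mz = next(m for m in mats if m.direction == (0, 0, 1))
        mx = next(m for m in mats if m.direction == (1, 0, 0))
        assert table_counter(mz) == Counter({(1, 4): 1})
        assert table_counter(mx) == Counter({(1, 1): 4})

    def test_hand_computed_sre_rp(self):
        q = qvol(np.array([1, 1, 2]).reshape(3, 1, 1), 2)
        mx = next(m for m in build_glrlm(q, mask_of((3, 1, 1))) if m.direction == (1, 0, 0))
        f = glrlm_features([mx], n_voxels=3)
        assert f["glrlm_RP"] == pytest.approx(2.0 / 3.0)
        assert f["glrlm_SRE"] == pytest.approx(0.625)

    def test_lre_maximal_along_longest_extent(self):
        q = qvol(np.ones((1, 1, 6), dtype=int), 2)
        mats = build_glrlm(q, mask_of((1, 1, 6)))
        lre = {m.direction: glrlm_features([m], 6)["glrlm_LRE"] for m in mats}
        assert max(lre, key=lre.get) == (0, 0, 1)

    def test_single_voxel(self):
        q = qvol(np.ones((1, 1, 1), dtype=int), 2)
        f = glrlm_features(build_glrlm(q, mask_of((1, 1, 1))), n_voxels=1)
        assert f["glrlm_SRE"] == pytest.approx(1.0)
        assert f["glrlm_RP"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

class TestGLSZM:
    def test_bar_plus_detached_voxel(self):
        lv = np.zeros((5, 1, 1), dtype=int)
        lv[0:3] = 1
        lv[4] = 2
        mask = lv > 0
        m = build_glszm(qvol(lv, 2), mask_of(mask))
        assert table_counter(m) == Counter({(1, 3): 1, (2, 1): 1})

    def test_constant_connected_region(self):
        m = build_glszm(qvol(np.ones((2, 3, 2), dtype=int), 2), mask_of((2, 3, 2)))
        assert table_counter(m) == Counter({(1, 12): 1})

    def test_checkerboard_joins_diagonally(self):
        idx = np.indices((2, 2, 2)).sum(axis=0)
        lv = 1 + idx % 2
        m = build_glszm(qvol(lv, 2), mask_of((2, 2, 2)))
        assert table_counter(m) == Counter({(1, 4): 1, (2, 4): 1})

    def test_single_zone_features(self):
        m = build_glszm(qvol(np.ones((2, 2, 2), dtype=int), 2), mask_of((2, 2, 2)))
        f = glszm_features(m, n_voxels=8)
        assert f["glszm_ZP"] == pytest.approx(1.0 / 8.0)
        assert f["glszm_SAE"] == pytest.approx(1.0 / 64.0)
        assert f["glszm_ZE"] == 0.0
        assert f["glszm_GLNN"] == pytest.approx(1.0)

    def test_two_zone_percentage(self):
        lv = np.zeros((5, 1, 1), dtype=int)
        lv[0:3] = 1
        lv[4] = 2
        m = build_glszm(qvol(lv, 2), mask_of(lv > 0))
        f = glszm_features(m, n_voxels=4)
        assert f["glszm_ZP"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

class TestNGTDM:
    def test_constant_region_zero_differences(self):
        m = build_ngtdm(qvol(np.ones((2, 2, 2), dtype=int), 2), mask_of((2, 2, 2)))
        assert m.counts[0, 1] == 0.0  # s_1 = 0
        f = ngtdm_features(m)
        assert f["ngtdm_Contrast"] == 0.0
        assert f["ngtdm_Complexity"] == 0.0
        assert f["ngtdm_Coarseness"] == COARSENESS_SENTINEL

    def test_hand_computed_1x1x3(self):
        m = build_ngtdm(qvol(np.array([[[1, 2, 1]]]), 2), mask_of((1, 1, 3)))
        n_i, s_i = m.counts[:, 0], m.counts[:, 1]
        assert n_i[0] == 2 and s_i[0] == pytest.approx(2.0)
        assert n_i[1] == 1 and s_i[1] == pytest.approx(1.0)
        f = ngtdm_features(m)
        assert f["ngtdm_Coarseness"] == pytest.approx(0.6)

    def test_single_voxel_empty(self):
        m = build_ngtdm(qvol(np.ones((1, 1, 1), dtype=int), 2), mask_of((1, 1, 1)))
        assert m.is_empty
        assert all(np.isnan(v) for v in ngtdm_features(m).values())


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence (small version; the full 200-volume sweep
# lives in the acceptance suite)
# ---------------------------------------------------------------------------

def random_cases(n, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        shape = tuple(rng.integers(1, 5, size=3))
        ng = int(rng.integers(2, 5))
        lv = rng.integers(1, ng + 1, size=shape)
        mask = rng.random(shape) > rng.uniform(0.1, 0.5)
        if not mask.any():
            mask.flat[rng.integers(0, mask.size)] = True
        yield lv, mask, ng


def assert_all_builders_match(lv, mask, ng):
    q = qvol(lv, ng)
    msk = mask_of(mask)
    masked_lv = np.where(mask, lv, 0)

    for m in build_glcm(q, msk):
        assert glcm_counter(m) == oracles.bf_glcm(masked_lv, mask, m.direction)
    assert gldm_counter(build_gldm(q, msk)) == oracles.bf_gldm(masked_lv, mask)
    for m in build_glrlm(q, msk):
        assert table_counter(m) == oracles.bf_glrlm(masked_lv, mask, m.direction)
    assert table_counter(build_glszm(q, msk)) == oracles.bf_glszm(masked_lv, mask)

    m = build_ngtdm(q, msk)
    ref = oracles.bf_ngtdm(masked_lv, mask)
    for lvl in range(1, ng + 1):
        entry = ref.get(lvl, {"n": 0, "s": 0.0})
        assert m.counts[lvl - 1, 0] == entry["n"]
        assert m.counts[lvl - 1, 1] == pytest.approx(entry["s"])


@pytest.mark.parametrize("case", list(random_cases(40, seed=123)),
                         ids=lambda c: f"shape{c[0].shape}-ng{c[2]}")
def test_builders_match_bruteforce(case):
    lv, mask, ng = case
    assert_all_builders_match(lv, mask, ng)


# ---------------------------------------------------------------------------
# extract_all and cross-cutting invariants
# ---------------------------------------------------------------------------

class TestExtractAll:
    def test_census_88(self):
        vol, mask = generate_phantom(PhantomSpec(seed=0))
        fv = extract_all(vol, mask)
        assert len(fv) == 88
        assert tuple(fv.values) == FEATURE_NAMES

    def test_constant_nodule_degenerate_census(self):
        spec = PhantomSpec(noise_sigma=0.0, core_hu=-100.0, rim_hu=-100.0, seed=0)
        vol, mask = generate_phantom(spec)
        fv = extract_all(vol, mask)
        undefined = {k for k, v in fv.values.items() if np.isnan(v)}
        assert undefined == {"firstorder_Skewness", "firstorder_Kurtosis"}

    def test_deterministic(self):
        vol, mask = generate_phantom(PhantomSpec(seed=2))
        a = extract_all(vol, mask)
        b = extract_all(vol, mask)
        assert a.values == b.values

    def test_empty_mask_rejected(self):
        vol, mask = generate_phantom(PhantomSpec(seed=2))
        empty = NoduleMask(values=np.zeros(vol.shape, dtype=bool))
        with pytest.raises(ValueError, match="empty mask"):
            extract_all(vol, empty)

    def test_shape_mismatch_rejected(self):
        vol, _ = generate_phantom(PhantomSpec(seed=2))
        bad = NoduleMask(values=np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError, match="shape mismatch"):
            extract_all(vol, bad)

    def test_continuous_firstorder_invariant_to_ng(self):
        vol, mask = generate_phantom(PhantomSpec(seed=3))
        readings = {
            ng: extract_all(vol, mask, q=QuantisationConfig(ng)) for ng in (32, 64, 128, 256)
        }
        for name in CONTINUOUS_FIRSTORDER:
            vals = {readings[ng][name] for ng in readings}
            assert len(vals) == 1, name

    @pytest.mark.parametrize("ng", [32, 256])
    def test_entropy_uniformity_bounds(self, ng):
        vol, mask = generate_phantom(PhantomSpec(seed=4))
        fv = extract_all(vol, mask, q=QuantisationConfig(ng))
        assert 0.0 <= fv["firstorder_Entropy"] <= np.log2(ng)
        assert 1.0 / ng <= fv["firstorder_Uniformity"] <= 1.0

    def test_storage_order_invariance(self):
        vol, mask = generate_phantom(PhantomSpec(seed=5))
        f_vol = VoxelVolume(values=np.asfortranarray(vol.values), spacing=vol.spacing)
        f_mask = NoduleMask(values=np.asfortranarray(mask.values), spacing=mask.spacing)
        assert extract_all(vol, mask).values == extract_all(f_vol, f_mask).values
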