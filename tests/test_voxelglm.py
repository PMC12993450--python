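"""Voxel-wise GLM, smoothness estimation and RFT thresholds."""

import numpy as np
import pytest
import scipy.stats as sps

from ventricsf.volumes import ScalarVolume
from ventricsf import voxelglm as G

VOX = (2.0, 2.0, 2.0)


def _design(n, rng, with_cov=False):
    x = rng.standard_normal(n)
    cols = [np.ones(n), (x - x.mean()) / x.std(ddof=1)]
    names = ["intercept", "x"]
    if with_cov:
        c = rng.standard_normal(n)
        cols.append((c - c.mean()) / c.std(ddof=1))
        names.append("c")
    contrast = np.zeros(len(cols))
    contrast[1] = 1.0
    return G.DesignMatrix(X=np.column_stack(cols), names=tuple(names), contrast=contrast)


def _vols(arrs):
    return [ScalarVolume(data=a, voxel_size_mm=VOX) for a in arrs]


def test_perfect_fit_t_is_capped():
    rng = np.random.default_rng(0)
    d = _design(12, rng)
    x = d.X[:, 1]
    arrs = [np.full((8, 8, 8), 2.0 * xi) for xi in x]
    mask = np.ones((8, 8, 8), bool)
    res = G.fit_voxelwise(_vols(arrs), d, mask)
    assert (res.tmap.data[mask] == G.T_CAP).all()
    assert res.degenerate_mask[mask].all()


def test_pure_noise_t_follows_t_distribution():
    rng = np.random.default_rng(1)
    n = 40
    d = _design(n, rng)
    arrs = [rng.standard_normal((12, 12, 12)) for _ in range(n)]
    mask = np.ones((12, 12, 12), bool)
    res = G.fit_voxelwise(_vols(arrs), d, mask)
    ks = sps.kstest(res.tmap.data[mask], sps.t(df=res.df).cdf)
    assert ks.pvalue > 0.01
    assert res.df == n - 2


def test_matches_per_voxel_scalar_ols_oracle():
    rng = np.random.default_rng(2)
    n = 15
    d = _design(n, rng, with_cov=True)
    arrs = [rng.standard_normal((8, 8, 8)) for _ in range(n)]
    mask = rng.random((8, 8, 8)) > 0.3
    res = G.fit_voxelwise(_vols(arrs), d, mask)
    Y = np.stack([a[mask] for a in arrs])
    X = d.X
    for j in [0, 5, 17, Y.shape[1] - 1]:
        beta = np.linalg.solve(X.T @ X, X.T @ Y[:, j])
        r = Y[:, j] - X @ beta
        s2 = r @ r / (n - X.shape[1])
        t_oracle = beta[1] / np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.tmap.data[mask][j] == pytest.approx(t_oracle, abs=1e-8)
    assert (res.tmap.data[~mask] == 0).all()


def test_contrast_negation_flips_t():
    rng = np.random.default_rng(3)
    d = _design(12, rng)
    arrs = [rng.standard_normal((8, 8, 8)) for _ in range(12)]
    mask = np.ones((8, 8, 8), bool)
    res_pos = G.fit_voxelwise(_vols(arrs), d, mask)
    d_neg = G.DesignMatrix(X=d.X, names=d.names, contrast=-d.contrast)
    res_neg = G.fit_voxelwise(_vols(arrs), d_neg, mask)
    assert np.allclose(res_pos.tmap.data, -res_neg.tmap.data)


def test_orthogonal_covariate_only_changes_df():
    """Adding a covariate orthogonal to predictor and outcome rescales t by
    exactly the df adjustment."""
    n = 20
    rng = np.random.default_rng(4)
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    c = rng.standard_normal(n)
    c -= c @ x / (x @ x) * x
    c -= c.mean()
    y = 0.5 * x + rng.standard_normal(n)
    y -= c @ y / (c @ c) * c  # make outcome orthogonal to the covariate too
    arrs = [np.full((8, 8, 8), yi) for yi in y]
    mask = np.ones((8, 8, 8), bool)
    d1 = G.DesignMatrix(
        X=np.column_stack([np.ones(n), x]), names=("i", "x"), contrast=np.array([0.0, 1.0])
    )
    d2 = G.DesignMatrix(
        X=np.column_stack([np.ones(n), x, c]),
        names=("i", "x", "c"),
        contrast=np.array([0.0, 1.0, 0.0]),
    )
    t1 = G.fit_voxelwise(_vols(arrs), d1, mask).tmap.data[4, 4, 4]
    t2 = G.fit_voxelwise(_vols(arrs), d2, mask).tmap.data[4, 4, 4]
    assert t2 == pytest.approx(t1 * np.sqrt((n - 3) / (n - 2)), rel=1e-8)


# --- smoothness estimation ------------------------------------------------

def test_fwhm_recovery_and_white_noise():
    rng = np.random.default_rng(5)
    shape = (24, 24, 24)
    mask = np.ones(shape, bool)
    ests = []
    for _ in range(6):
        arrs = [G.simulate_smooth_field(shape, 8.0, VOX, rng) for _ in range(8)]
        d = G.DesignMatrix(X=np.ones((8, 1)), names=("i",), contrast=np.array([1.0]))
        res = G.fit_voxelwise(_vols(arrs), d, mask)
        ests.append(np.mean(G.estimate_fwhm(res.residuals, mask, VOX)))
    assert abs(np.mean(ests) - 8.0) / 8.0 <= 0.15
    # unsmoothed white noise: estimate below two voxels
    arrs = [rng.standard_normal(shape) for _ in range(8)]
    d = G.DesignMatrix(X=np.ones((8, 1)), names=("i",), contrast=np.array([1.0]))
    res = G.fit_voxelwise(_vols(arrs), d, mask)
    assert all(f < 4.0 for f in G.estimate_fwhm(res.residuals, mask, VOX))


def test_fwhm_scales_with_kernel():
    rng = np.random.default_rng(6)
    shape = (24, 24, 24)
    mask = np.ones(shape, bool)
    d = G.DesignMatrix(X=np.ones((8, 1)), names=("i",), contrast=np.array([1.0]))

    def est(fwhm):
        arrs = [G.simulate_smooth_field(shape, fwhm, VOX, rng) for _ in range(8)]
        res = G.fit_voxelwise(_vols(arrs), d, mask)
        return np.mean(G.estimate_fwhm(res.residuals, mask, VOX))

    ratios = [est(12.0) / est(6.0) for _ in range(3)]
    assert 1.7 <= np.mean(ratios) <= 2.3


def test_single_residual_volume_rejected():
    with pytest.raises(ValueError):
        G.estimate_fwhm(np.zeros((1, 8, 8, 8)), np.ones((8, 8, 8), bool), VOX)


# --- RFT thresholds -------------------------------------------------------

def _null_result(rng, shape=(24, 24, 24), n=20, fwhm=8.0):
    d = _design(n, rng)
    arrs = [G.simulate_smooth_field(shape, fwhm, VOX, rng) for _ in range(n)]
    mask = np.ones(shape, bool)
    return G.fit_voxelwise(_vols(arrs), d, mask)


def test_rft_threshold_exceeds_uncorrected():
    rng = np.random.default_rng(7)
    res = G.rft_threshold(_null_result(rng), alpha=0.05)
    uncorrected = sps.t.isf(0.025, res.df)
    assert res.corrected_threshold >= uncorrected
    assert (np.abs(res.tmap.data[res.significant_mask]) >= res.corrected_threshold).all()


def test_rft_below_bonferroni_for_smooth_fields():
    rng = np.random.default_rng(8)
    res = _null_result(rng, shape=(32, 32, 32), n=40)
    out = G.rft_threshold(res, alpha=0.05)
    n_vox = 32**3
    bonf = sps.t.isf(0.05 / n_vox / 2, out.df)
    assert out.corrected_threshold < bonf


def test_rft_threshold_monotone_in_alpha_and_resels():
    rng = np.random.default_rng(9)
    res = _null_result(rng)
    t_05 = G.rft_threshold(res, alpha=0.05, fwhm_mm=8.0).corrected_threshold
    t_001 = G.rft_threshold(res, alpha=0.001, fwhm_mm=8.0).corrected_threshold
    assert t_001 > t_05
    # halving the FWHM increases resels, which must raise the bar
    t_small_fwhm = G.rft_threshold(res, alpha=0.05, fwhm_mm=4.0).corrected_threshold
    assert t_small_fwhm > t_05


def test_fdr_mode(sample_bundle):
    rng = np.random.default_rng(10)
    n = 20
    d = _design(n, rng)
    x = d.X[:, 1]
    signal = np.zeros((12, 12, 12))
    signal[4:8, 4:8, 4:8] = 1.0
    arrs = [0.8 * xi * signal + rng.standard_normal((12, 12, 12)) for xi in x]
    res = G.fit_voxelwise(_vols(arrs), d, np.ones((12, 12, 12), bool))
    out = G.fdr_threshold(res, q=0.05)
    assert out.mode == "voxel-fdr"
    sig = out.significant_mask
    assert sig.sum() > 0
    assert sig[signal > 0].mean() > sig[signal == 0].mean()


def test_voxelwise_qualitative_pattern(default_cohort):
    """On aligned phantoms, ventricular volume associates positively with
    cortical amyloid (significant voxels inside grey-matter labels) while
    ventricular radioactivity shows no positive cortical association."""
    from ventricsf.phantom import ParticipantRecord, simulate_phantom
    from ventricsf.petquant import mask_meninges, smooth_to_fwhm
    from ventricsf.volumes import GridSpec, GREY_MATTER_LABELS

    grid = GridSpec(shape=(64, 64, 64), voxel_size_mm=(3.0, 3.0, 3.0))
    df = default_cohort.iloc[np.linspace(0, 377, 48).astype(int)].copy()
    df["icv"] = 1.45e6  # align head anatomy; ventricles still vary
    vols, ref_labels = [], None
    for i, (_, r) in enumerate(df.iterrows()):
        b = simulate_phantom(ParticipantRecord.from_row(r), grid=grid, seed=1000 + i)
        if ref_labels is None:
            ref_labels = b.labels
        vols.append(smooth_to_fwhm(mask_meninges(b.amyloid, b.labels), 8.0))
    mask = ref_labels.head_mask() & ~ref_labels.mask("meninges")
    gm = ref_labels.union_mask(GREY_MATTER_LABELS)

    d_vv = G.build_design(df, "latent_vv", covariates=("age", "sex", "apoe4"))
    res = G.rft_threshold(G.fit_voxelwise(vols, d_vv, mask), alpha=0.05)
    pos_sig = res.significant_mask & (res.tmap.data > 0)
    assert pos_sig.any(), "expected positive cortical amyloid association with VV"
    # the cortical composite is broadly significant-positive ...
    neo = ref_labels.mask("neocortex_composite")
    assert pos_sig[neo].mean() > 0.5
    # ... while the CSF-filled ventricle interior associates negatively
    from ventricsf.petquant import make_vr_mask

    vr_core = make_vr_mask(ref_labels, erosion_mm=3.0)
    assert not pos_sig[vr_core].any()
    assert (res.tmap.data[vr_core] < 0).mean() > 0.5

    d_vr = G.build_design(df, "latent_vr_amyloid", covariates=("age", "sex", "apoe4"))
    res_vr = G.rft_threshold(G.fit_voxelwise(vols, d_vr, mask), alpha=0.05)
    pos_vr = res_vr.significant_mask & (res_vr.tmap.data > 0) & gm
    assert pos_vr.sum() == 0, "VR must not associate positively with cortical amyloid"
    neg_vr = res_vr.significant_mask & (res_vr.tmap.data < 0) & gm
    assert neg_vr.sum() >= 0  # negative cortical associations are the expected direction
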