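"""Correlations, canonical correlation + permutation null, mixed models,
FDR, and candidate selection."""

import numpy as np
import pandas as pd
import pytest

from accumloc.regressors import build_segments, concatenate_segments
from accumloc.spectral import WindowTable
from accumloc.stats import (
    LMEResult,
    canonical_correlation,
    correlate_electrode,
    fdr_bh,
    fisher_z,
    fit_cell_model,
    fit_regressor_contrast,
    permutation_null,
    select_candidates,
)


def _table(rts, fs=50.0, buffer=0.3):
    rts = np.asarray(rts, float)
    n = np.round((rts + 2 * buffer) * fs).astype(int)
    return WindowTable(
        trial_ids=np.arange(len(rts)),
        rts=rts,
        start_idx=np.concatenate([[0], np.cumsum(n)[:-1]]),
        n_samples=n,
        fs=fs,
        buffer=buffer,
    )


def test_correlate_trivial_cases():
    x = np.sin(np.linspace(0, 10, 500))
    r, z = correlate_electrode(x, x)
    assert r == pytest.approx(1.0)
    assert np.isfinite(z)  # clipped instead of infinite
    r2, _ = correlate_electrode(x, -x)
    assert r2 == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        correlate_electrode(x, x[:-1])
    with pytest.raises(ValueError):
        correlate_electrode(np.zeros(500), x)


def test_correlation_attenuation_by_additive_noise():
    """E[r] follows the classic attenuation factor 1/sqrt(1 + sig^2/var)."""
    rng = np.random.default_rng(0)
    reg = np.tile(np.linspace(0, 1, 100), 300)
    sigma = 0.5
    feat = reg + rng.normal(0, sigma, reg.size)
    r, _ = correlate_electrode(feat, reg)
    expected = 1.0 / np.sqrt(1.0 + sigma**2 / reg.var())
    assert r == pytest.approx(expected, abs=0.02)


def test_cca_reduces_to_pearson_for_single_electrode():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(400)
    y = -0.6 * x + rng.standard_normal(400)
    res = canonical_correlation(x[None, :], y)
    assert res.r == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-10)


def test_cca_perfect_linear_combination():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((4, 300))
    y = 2.0 * X[0] - 1.5 * X[2]
    res = canonical_correlation(X, y)
    assert res.r == pytest.approx(1.0, abs=1e-8)
    assert not res.ridge_used


def test_cca_matches_ols_multiple_correlation():
    """r_c equals sqrt(R^2) from an independent least-squares fit."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        X = rng.standard_normal((5, 200))
        y = rng.standard_normal(200) + 0.3 * X[1]
        res = canonical_correlation(X, y)
        Xc = (X - X.mean(axis=1, keepdims=True)).T
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        r2 = 1.0 - np.sum((yc - Xc @ beta) ** 2) / np.sum(yc**2)
        assert res.r == pytest.approx(np.sqrt(r2), abs=1e-8)


def test_cca_rank_deficient_falls_back_to_ridge():
    rng = np.random.default_rng(4)
    base = rng.standard_normal(100)
    X = np.stack([base, base, rng.standard_normal(100)])
    res = canonical_correlation(X, rng.standard_normal(100))
    assert res.ridge_used
    assert 0.0 <= res.r <= 1.0


def test_permutation_null_degenerate_and_planted():
    rng = np.random.default_rng(5)
    # identical durations: every permutation rebuilds the same regressor
    table = _table([1.2] * 6)
    X = rng.standard_normal((3, table.total_length))
    res = permutation_null(X, table, ter=0.4, kind="ramp", n_perm=5, rng=rng)
    np.testing.assert_allclose(res.null, res.observed, atol=1e-12)
    # a feature that *is* the aligned ramp beats its shuffled null
    table2 = _table(np.random.default_rng(6).uniform(0.7, 2.3, 30))
    segs = build_segments("ramp", table2, 0.4)
    aligned = concatenate_segments(segs)
    X2 = np.stack([aligned + rng.normal(0, 0.3, aligned.size) for _ in range(4)])
    res2 = permutation_null(X2, table2, ter=0.4, kind="ramp", n_perm=200, rng=rng)
    assert res2.observed > res2.null_p99
    assert res2.percentile == 100.0


def _corr_df(
    n_subj=4,
    n_elec=12,
    bands=("delta", "theta"),
    areas=("A1", "A2"),
    cell_bump=None,
    noise=0.0,
    subj_sd=0.0,
    elec_sd=0.0,
    seed=0,
    kinds=("ramp",),
    kind_shift=None,
):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        se = rng.normal(0, subj_sd) if subj_sd else 0.0
        for e in range(n_elec):
            ee = rng.normal(0, elec_sd) if elec_sd else 0.0
            area = areas[e % len(areas)]
            for band in bands:
                for kind in kinds:
                    mu = 0.0
                    if cell_bump and (band, area) == cell_bump[0]:
                        mu += cell_bump[1]
                    if kind_shift:
                        mu += kind_shift.get(kind, 0.0)
                    rows.append(
                        {
                            "subject": f"S{s}",
                            "electrode": f"S{s}E{e}",
                            "area": area,
                            "band": band,
                            "regressor": kind,
                            "z": mu + se + ee + (rng.normal(0, noise) if noise else 0.0),
                        }
                    )
    return pd.DataFrame(rows)


def test_cell_balanced_noiseless_equals_cell_means():
    """With no noise and no random effects the fit is the per-cell mean."""
    df = _corr_df(cell_bump=(("theta", "A1"), 0.1))
    res = fit_cell_model(df, min_electrodes=10)
    grand = df["z"].mean()
    for _, row in res.table.iterrows():
        cell = df[(df["band"] == row["band"]) & (df["area"] == row["area"])]
        assert row["estimate"] == pytest.approx(cell["z"].mean() - grand, abs=1e-6)
    bump = res.table.query("band == 'theta' and area == 'A1'").iloc[0]
    assert bump["p"] < 1e-6 and bump["estimate"] > 0


def test_cell_all_equal_gives_zero_coefficients():
    df = _corr_df()
    res = fit_cell_model(df, min_electrodes=10)
    np.testing.assert_allclose(res.table["estimate"], 0.0, atol=1e-12)


def test_cell_area_filter_and_empty_input():
    df = _corr_df(n_elec=12, areas=("A1", "A1", "A2"))  # A2 has only 4 electrodes/subj... 16 total
    res = fit_cell_model(df, min_electrodes=20)
    assert set(res.table["area"]) == {"A1"}
    with pytest.raises(ValueError):
        fit_cell_model(df, min_electrodes=10_000)


def test_cell_recovers_variance_components():
    """REML variance components land near their generating values.

    At 20 subjects the subject-variance estimate itself has ~30% sampling
    error, so the subject check is loose; the electrode component pools
    600 levels and is tested tighter.
    """
    df = _corr_df(
        n_subj=20, n_elec=30, noise=0.05, subj_sd=0.05, elec_sd=0.04, seed=42
    )
    res = fit_cell_model(df, min_electrodes=10)
    assert res.method == "reml"
    assert res.random_effects["subject_var"] == pytest.approx(0.0025, rel=0.5)
    assert res.random_effects["electrode_var"] == pytest.approx(0.0016, rel=0.5)
    assert res.random_effects["residual_var"] == pytest.approx(0.0025, rel=0.3)


def test_contrast_model_forced_and_null():
    df = _corr_df(
        bands=("theta",),
        areas=("A1",),
        kinds=("ramp", "downramp", "boxcar"),
        kind_shift={"ramp": 0.2},
    )
    res = fit_regressor_contrast(df)
    for _, row in res.table.iterrows():
        assert row["ramp_minus_alt"] == pytest.approx(0.2, abs=1e-8)
        assert not row["alt_better"]
        assert row["p"] < 1e-6
    res0 = fit_regressor_contrast(_corr_df(bands=("theta",), areas=("A1",), kinds=("ramp", "downramp", "boxcar")))
    np.testing.assert_allclose(res0.table["ramp_minus_alt"], 0.0, atol=1e-10)


def test_contrast_model_estimates_known_effect_with_noise():
    df = _corr_df(
        n_subj=10,
        n_elec=30,
        bands=("theta",),
        areas=("A1",),
        kinds=("ramp", "boxcar"),
        kind_shift={"ramp": 0.1},
        noise=0.05,
        seed=9,
    )
    res = fit_regressor_contrast(df)
    row = res.table.iloc[0]
    assert row["ramp_minus_alt"] == pytest.approx(0.1, abs=0.02)


def test_fdr_step_up_examples():
    assert fdr_bh(np.array([0.01, 0.02, 0.03, 0.04, 0.05]), 0.05).all()
    assert not fdr_bh(np.ones(10), 0.05).any()
    assert fdr_bh(np.array([]), 0.05).size == 0
    with pytest.raises(ValueError):
        fdr_bh(np.array([1.5]))


def _brute_force_bh(p, q):
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    mask = np.zeros(m, bool)
    mask[order[:k_max]] = True
    return mask


def test_fdr_matches_brute_force_enumeration():
    base = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
    for bits in range(32):
        p = np.where([(bits >> i) & 1 for i in range(5)], 1 - base, base)
        np.testing.assert_array_equal(fdr_bh(p, 0.05), _brute_force_bh(p, 0.05))


def _fake_cell_model(cells):
    rows = [
        {"band": b, "area": a, "estimate": est, "se": 0.01, "t": est / 0.01, "p": p,
         "n_electrodes": 20}
        for (b, a), (est, p) in cells.items()
    ]
    return LMEResult(table=pd.DataFrame(rows), centering=0.0, method="reml")


def _fake_contrast(rows):
    return LMEResult(
        table=pd.DataFrame(
            [
                {"alternative": alt, "ramp_minus_alt": d, "se": 0.01, "p": p,
                 "alt_better": d < 0}
                for alt, d, p in rows
            ]
        ),
        centering=0.0,
        method="reml",
    )


def test_select_candidates_decision_logic():
    cell_model = _fake_cell_model(
        {
            ("theta", "A1"): (0.2, 1e-10),   # clean ramp cell
            ("alpha", "A2"): (0.2, 1e-10),   # boxcar fits better -> excluded
            ("delta", "A3"): (0.2, 1e-10),   # downramp tie -> depends on variant
            ("beta", "A4"): (-0.3, 1e-10),   # wrong sign -> not a candidate
            ("raw", "A5"): (0.01, 0.9),      # not significant
        }
    )
    contrast = {
        ("theta", "A1"): _fake_contrast([("downramp", 0.2, 1e-9), ("boxcar", 0.05, 1e-9)]),
        ("alpha", "A2"): _fake_contrast([("downramp", 0.2, 1e-9), ("boxcar", -0.1, 1e-9)]),
        ("delta", "A3"): _fake_contrast([("downramp", 0.0, 0.9), ("boxcar", 0.05, 1e-9)]),
    }
    out = select_candidates(cell_model, contrast, q=0.05, exclude_downramp_ties=True)
    sel = {(r["band"], r["area"]): r["selected"] for _, r in out.iterrows()}
    assert sel[("theta", "A1")]
    assert not sel[("alpha", "A2")]
    assert not sel[("delta", "A3")]  # tie with downramp excluded in this variant
    assert not sel[("beta", "A4")] and not sel[("raw", "A5")]
    out2 = select_candidates(cell_model, contrast, q=0.05, exclude_downramp_ties=False)
    sel2 = {(r["band"], r["area"]): r["selected"] for _, r in out2.iterrows()}
    assert sel2[("delta", "A3")]  # tie allowed when the variant is off


def test_fisher_z_clipping():
    assert np.isfinite(fisher_z(1.0))
    assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
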