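"""Localization statistics: per-electrode correlations, canonical
correlation with a duration-permutation null, and the two mixed-effects
models that find (band, area) cells with above-average ramp fits.

Model 1 ("cell model"): Fisher-z, grand-mean-centered correlations of each
electrode's features with the ramp regressor, modeled without a global
intercept as band x area cell effects plus random intercepts for subject
and electrode.  Model 2 ("regressor contrast"): within one cell, the same
correlations for all three regressors, modeled as a regressor-kind fixed
effect (ramp as reference) with the same random structure; its ramp -
downramp and ramp - boxcar contrasts drive candidate selection.

Mixed models are estimated by REML via statsmodels MixedLM (electrode
intercepts as a variance component nested in subject groups), with an OLS
fallback when variance components are unestimable (e.g. noiseless input).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .bands import FEATURES
from .regressors import REGRESSOR_KINDS, build_segments, concatenate_segments
from .spectral import FeatureBundle, WindowTable

__all__ = [
    "correlate_electrode",
    "build_corr_table",
    "canonical_correlation",
    "CCAResult",
    "fisher_z",
    "build_null_regressors",
    "cca_with_null",
    "permutation_null",
    "PermutationResult",
    "fit_cell_model",
    "fit_regressor_contrast",
    "fdr_bh",
    "select_candidates",
]

logger = logging.getLogger(__name__)

Z_CLIP = float(np.arctanh(1.0 - 1e-12))


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """atanh with |r| = 1 clipped just inside the boundary."""
    r = np.clip(r, -(1.0 - 1e-12), 1.0 - 1e-12)
    return np.arctanh(r)


def correlate_electrode(feature: np.ndarray, regressor: np.ndarray) -> tuple[float, float]:
    """Pearson r and Fisher z of a feature series against a regressor."""
    feature = np.asarray(feature, float)
    regressor = np.asarray(regressor, float)
    if feature.shape != regressor.shape:
        raise ValueError("feature and regressor lengths differ")
    if feature.std() == 0 or regressor.std() == 0:
        raise ValueError("zero-variance input to correlation")
    r = float(np.corrcoef(feature, regressor)[0, 1])
    return r, float(fisher_z(r))


def build_corr_table(
    bundles: list[FeatureBundle],
    ter_map: dict[str, float],
    kinds: tuple[str, ...] = REGRESSOR_KINDS,
) -> pd.DataFrame:
    """Correlation records for every electrode x feature x regressor kind.

    Per-trial regressor segments are built once per session and kind, then
    concatenated per electrode over that electrode's retained trials so
    feature and regressor boundaries coincide.  Zero-variance features are
    dropped with a log entry.
    """
    rows = []
    for bundle in bundles:
        ter = ter_map[bundle.subject_id]
        segs = {k: build_segments(k, bundle.table, ter) for k in kinds}
        for ch in range(len(bundle.channel_labels)):
            keep = np.nonzero(bundle.electrode_keep(ch))[0]
            if keep.size == 0:
                logger.info(
                    "electrode %s: all trials excluded", bundle.channel_labels[ch]
                )
                continue
            regs = {k: concatenate_segments(segs[k], keep) for k in kinds}
            for feat in FEATURES:
                series = bundle.series(feat, ch)
                for k in kinds:
                    try:
                        r, z = correlate_electrode(series.values, regs[k])
                    except ValueError:
                        logger.info(
                            "dropped zero-variance record: %s %s %s",
                            bundle.channel_labels[ch],
                            feat,
                            k,
                        )
                        continue
                    rows.append(
                        {
                            "subject": bundle.subject_id,
                            "electrode": bundle.channel_labels[ch],
                            "area": bundle.channel_areas[ch],
                            "band": feat,
                            "regressor": k,
                            "r": r,
                            "z": z,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class CCAResult:
    r: float
    weights: np.ndarray
    ridge_used: bool = False


def canonical_correlation(
    X: np.ndarray, y: np.ndarray, ridge: float | None = None
) -> CCAResult:
    """Canonical correlation of an electrode set with a single regressor.

    With a one-dimensional second set this is the multiple correlation of
    regressing ``y`` on the electrode matrix ``X`` (electrodes x samples).
    Rank-deficient electrode matrices fall back to a ridge-regularized
    solve (lambda = 1e-6 * trace / n_electrodes), flagged on the result.
    Weights are scale-normalized to unit norm with positive correlation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim == 1:
        X = X[None, :]
    n_e, n_s = X.shape
    if y.shape != (n_s,):
        raise ValueError("regressor length does not match the feature samples")
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x electrodes
    yc = y - y.mean()
    ny = np.linalg.norm(yc)
    if ny == 0:
        raise ValueError("zero-variance regressor")

    gram = Xc.T @ Xc
    ridge_used = False
    if ridge is None and (n_s <= n_e or np.linalg.matrix_rank(gram) < n_e):
        ridge = 1e-6 * np.trace(gram) / n_e
        ridge_used = True
    if ridge:
        gram = gram + ridge * np.eye(n_e)
        w = np.linalg.solve(gram, Xc.T @ yc)
    else:
        w, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    yhat = Xc @ w
    nyh = np.linalg.norm(yhat)
    if nyh == 0:
        return CCAResult(r=0.0, weights=np.zeros(n_e), ridge_used=ridge_used)
    r = float(yhat @ yc / (nyh * ny))
    if r < 0:  # orientation convention: the fitted combination correlates positively
        w, r = -w, -r
    return CCAResult(r=r, weights=w / np.linalg.norm(w), ridge_used=ridge_used)


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    percentile: float  # percentile rank of the observed value in the null
    null_p99: float

    @property
    def exceeds_p99(self) -> bool:
        return self.observed > self.null_p99


def build_null_regressors(
    segments: list[np.ndarray], n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Matrix (samples x n_perm) of duration-shuffled regressors.

    Each column concatenates the per-trial segments in a uniformly random
    order, preserving the multiset of segment lengths and the total length.
    """
    n = int(sum(len(s) for s in segments))
    Y = np.empty((n, n_perm))
    for p in range(n_perm):
        order = rng.permutation(len(segments))
        pos = 0
        col = Y[:, p]
        for i in order:
            s = segments[i]
            col[pos : pos + len(s)] = s
            pos += len(s)
    return Y


def cca_with_null(
    X: np.ndarray, y_obs: np.ndarray, Y_null: np.ndarray, percentile: float = 99.0
) -> PermutationResult:
    """Observed canonical correlation against a precomputed null matrix."""
    Xc = (X - X.mean(axis=1, keepdims=True)).T
    q, r_mat = np.linalg.qr(Xc)
    diag = np.abs(np.diag(r_mat))
    if diag.min() < 1e-10 * max(diag.max(), 1e-30):
        # rank-deficient: fall back to the (slower) ridge path per draw
        observed = canonical_correlation(X, y_obs).r
        null = np.array(
            [canonical_correlation(X, Y_null[:, p]).r for p in range(Y_null.shape[1])]
        )
    else:
        yc = y_obs - y_obs.mean()
        ny = np.linalg.norm(yc)
        observed = float(np.linalg.norm(q.T @ yc) / ny) if ny > 0 else 0.0
        Yc = Y_null - Y_null.mean(axis=0, keepdims=True)
        nn = np.linalg.norm(Yc, axis=0)
        nn[nn == 0] = np.inf
        null = np.linalg.norm(q.T @ Yc, axis=0) / nn

    pct = 100.0 * float((null < observed).mean())
    return PermutationResult(
        observed=float(observed),
        null=null,
        percentile=pct,
        null_p99=float(np.percentile(null, percentile)),
    )


def permutation_null(
    X: np.ndarray,
    table: WindowTable,
    ter: float,
    kind: str,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    percentile: float = 99.0,
) -> PermutationResult:
    """Canonical correlation of the aligned regressor vs a shuffled-duration null.

    The null rebuilds the regressor ``n_perm`` times with the per-trial
    durations uniformly rearranged (feature series fixed, total length
    preserved) and recomputes the canonical correlation each time.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = rng or np.random.default_rng()
    segs = build_segments(kind, table, ter)
    y_obs = concatenate_segments(segs)
    Y = build_null_regressors(segs, n_perm, rng)
    return cca_with_null(X, y_obs, Y, percentile=percentile)


# ---------------------------------------------------------------------------
# mixed-effects localization models


@dataclass
class LMEResult:
    table: pd.DataFrame
    centering: float
    method: str  # "reml" or "ols-fallback"
    random_effects: dict = field(default_factory=dict)


def _guarded_pvalues(params: pd.Series, bse: pd.Series, pvalues: pd.Series) -> pd.Series:
    """Replace NaN p-values from zero standard errors (noiseless fits)."""
    out = pvalues.copy()
    for name in out.index:
        if not np.isfinite(out[name]):
            out[name] = 1.0 if abs(params[name]) < 1e-12 else 0.0
    return out


def _fit_mixed(formula: str, df: pd.DataFrame) -> tuple[object, str, dict]:
    """REML MixedLM with subject groups and electrode variance component;
    OLS fallback on numerical failure."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                formula,
                data=df,
                groups="subject",
                re_formula="1",
                vc_formula={"electrode": "0 + C(electrode)"},
            )
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        fe_bse = res.bse.iloc[: len(res.fe_params)]
        if not (
            np.all(np.isfinite(res.fe_params)) and np.all(np.isfinite(fe_bse))
        ):
            raise ValueError("non-finite fixed-effect estimates")
        re_var = {
            "subject_var": float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0,
            "electrode_var": float(res.vcomp[0]) if len(res.vcomp) else 0.0,
            "residual_var": float(res.scale),
        }
        return res, "reml", re_var
    except Exception as exc:  # singular / unestimable variance components
        logger.warning("mixed model failed (%s); falling back to fixed effects", exc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.ols(formula, data=df).fit()
        return res, "ols-fallback", {}


def fit_cell_model(
    records: pd.DataFrame,
    min_electrodes: int = 10,
    centering: float | None = None,
) -> LMEResult:
    """Cell model: z ~ -1 + band:area with subject and electrode intercepts.

    ``records`` must contain ramp-regressor correlation rows (columns
    subject, electrode, area, band, z).  Areas with fewer than
    ``min_electrodes`` electrodes are excluded.  The centering constant
    (grand mean of the table's Fisher z) is computed once and recorded.
    """
    df = records[records["regressor"] == "ramp"].copy() if "regressor" in records else records.copy()
    if df.empty:
        raise ValueError("no ramp correlation records")
    counts = df.groupby("area")["electrode"].nunique()
    good_areas = counts[counts >= min_electrodes].index
    df = df[df["area"].isin(good_areas)].copy()
    if df.empty:
        raise ValueError(f"no area has >= {min_electrodes} electrodes")
    if centering is None:
        centering = float(df["z"].mean())
    df["z_centered"] = df["z"] - centering
    df["cell"] = df["band"] + ":" + df["area"]

    res, method, re_var = _fit_mixed("z_centered ~ 0 + C(cell)", df)
    params = res.params.filter(like="C(cell)")
    bse = res.bse.reindex(params.index)
    pvals = _guarded_pvalues(params, bse, res.pvalues.reindex(params.index))
    rows = []
    for name in params.index:
        cell = name.split("[")[1].rstrip("]")
        band, area = cell.split(":", 1)
        se = float(bse[name])
        rows.append(
            {
                "band": band,
                "area": area,
                "estimate": float(params[name]),
                "se": se,
                "t": float(params[name]) / se if se > 0 else np.inf * np.sign(params[name] or 1),
                "p": float(pvals[name]),
                "n_electrodes": int(
                    df.loc[df["cell"] == cell, "electrode"].nunique()
                ),
            }
        )
    table = pd.DataFrame(rows).sort_values(["band", "area"]).reset_index(drop=True)
    return LMEResult(table=table, centering=centering, method=method, random_effects=re_var)


def fit_regressor_contrast(
    records: pd.DataFrame,
    centering: float | None = None,
) -> LMEResult:
    """Regressor-contrast model within one (band, area) cell.

    ``records`` holds that cell's correlation rows for all regressor kinds.
    Returns one row per alternative kind with the ramp-minus-alternative
    contrast: positive ``ramp_minus_alt`` means the ramp fits better.
    """
    kinds = records["regressor"].unique()
    if len(kinds) < 2:
        raise ValueError("need at least two regressor levels")
    df = records.copy()
    if centering is None:
        centering = float(df["z"].mean())
    df["z_centered"] = df["z"] - centering

    res, method, re_var = _fit_mixed(
        "z_centered ~ C(regressor, Treatment(reference='ramp'))", df
    )
    params = res.params.filter(like="C(regressor")
    bse = res.bse.reindex(params.index)
    pvals = _guarded_pvalues(params, bse, res.pvalues.reindex(params.index))
    rows = []
    for name in params.index:
        kind = name.split("[T.")[1].rstrip("]")
        coef = float(params[name])  # mean(alt) - mean(ramp)
        rows.append(
            {
                "alternative": kind,
                "ramp_minus_alt": -coef,
                "se": float(bse[name]),
                "p": float(pvals[name]),
                "alt_better": coef > 0,
            }
        )
    return LMEResult(
        table=pd.DataFrame(rows), centering=centering, method=method, random_effects=re_var
    )


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def select_candidates(
    cell_model: LMEResult,
    contrasts_by_cell: dict[tuple[str, str], LMEResult],
    q: float = 0.05,
    exclude_downramp_ties: bool = True,
) -> pd.DataFrame:
    """Combine the two models into the candidate (area, band) table.

    A cell is a candidate when its ramp correlation is significantly above
    average (model 1, BH-FDR at ``q``, positive estimate) and no
    alternative regressor fits significantly better (model 2 contrasts,
    BH-FDR across the contrast family).  With ``exclude_downramp_ties``
    (the default variant), cells where the downramp merely *ties* the ramp
    are also excluded — only a significantly worse downramp fit passes;
    boxcar ties are allowed.
    """
    t1 = cell_model.table.copy()
    t1["cell_sig"] = fdr_bh(t1["p"].to_numpy(), q) & (t1["estimate"] > 0)

    contrast_ps, contrast_keys = [], []
    for key, res in contrasts_by_cell.items():
        for _, row in res.table.iterrows():
            contrast_ps.append(row["p"])
            contrast_keys.append((key, row["alternative"]))
    contrast_sig = (
        dict(zip(contrast_keys, fdr_bh(np.array(contrast_ps), q))) if contrast_ps else {}
    )

    rows = []
    for _, row in t1.iterrows():
        key = (row["band"], row["area"])
        rec = {
            "band": row["band"],
            "area": row["area"],
            "cell_estimate": row["estimate"],
            "cell_p": row["p"],
            "cell_significant": bool(row["cell_sig"]),
            "ramp_vs_downramp_p": np.nan,
            "ramp_vs_boxcar_p": np.nan,
            "selected": False,
            "reason": "",
        }
        if not row["cell_sig"]:
            rec["reason"] = "not significant in cell model"
            rows.append(rec)
            continue
        contrast = contrasts_by_cell.get(key)
        if contrast is None:
            rec["reason"] = "no regressor-contrast fit"
            rows.append(rec)
            continue
        verdicts = {}
        for _, c in contrast.table.iterrows():
            alt = c["alternative"]
            sig = contrast_sig.get((key, alt), False)
            verdicts[alt] = {
                "p": float(c["p"]),
                "alt_better_sig": bool(c["alt_better"] and sig),
                "ramp_better_sig": bool(not c["alt_better"] and sig),
            }
            rec[f"ramp_vs_{alt}_p"] = float(c["p"])
        reasons = []
        ok = True
        for alt, v in verdicts.items():
            if v["alt_better_sig"]:
                ok = False
                reasons.append(f"{alt} fits significantly better")
        if exclude_downramp_ties and "downramp" in verdicts:
            if not verdicts["downramp"]["ramp_better_sig"]:
                ok = False
                reasons.append("downramp ties the ramp fit")
        rec["selected"] = ok
        rec["reason"] = "; ".join(reasons) if reasons else "candidate"
        rows.append(rec)
    return pd.DataFrame(rows)
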