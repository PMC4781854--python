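"""End-to-end orchestration: simulate -> preprocess -> features ->
regressors/statistics -> time courses, with a machine-readable report.

Every stage communicates through plain containers (Session, FeatureBundle,
pandas tables), so a run can be resumed from any stage's persisted output.
Runs are deterministic given (config, seed): all randomness flows from one
SeedSequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import FEATURES
from .behavior import fit_ez_from_trials
from .config import RunConfig
from .containers import Session, TrialRecord
from .preprocessing import (
    ExclusionResult,
    apply_exclusion_rules,
    compute_artifact_mask,
    epoch_session,
    notch_filter,
)
from .regressors import REGRESSOR_KINDS, build_segments, concatenate_segments
from .spectral import FeatureBundle, compute_feature_bundle
from .stats import (
    build_corr_table,
    build_null_regressors,
    cca_with_null,
    fdr_bh,
    fisher_z,
    fit_cell_model,
    fit_regressor_contrast,
    select_candidates,
)
from .synthetic import (
    ArtifactSpec,
    BehaviorDesign,
    NoiseConfig,
    PlantedEffect,
    simulate_session,
)
from .timecourse import accumulator_diagnostics, binned_average
from . import io as aio

__all__ = [
    "simulate_cohort",
    "preprocess_session",
    "CleanedSession",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def channel_area_plan(config: RunConfig) -> list[str]:
    """Round-robin assignment of channels to the configured areas."""
    return [config.areas[i % len(config.areas)] for i in range(config.n_channels)]


def simulate_cohort(config: RunConfig) -> list[Session]:
    """Synthetic cohort under the configured design, plants, and artifacts."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects)
    areas = channel_area_plan(config)
    planted = [PlantedEffect(**d) for d in config.planted_effects]
    noise = NoiseConfig(
        pink_sd=config.pink_sd,
        pink_exponent=config.pink_exponent,
        carrier_amplitude=config.carrier_amplitude,
    )
    a_rate, k_rate, v_rate = config.artifact_rates
    art = None
    if a_rate or k_rate or v_rate:
        art = ArtifactSpec(amplitude_rate=a_rate, kurtosis_rate=k_rate, variance_rate=v_rate)
    design = BehaviorDesign(n_blocks=config.n_blocks, trials_per_block=config.trials_per_block)
    sessions = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sessions.append(
            simulate_session(
                f"S{i:02d}",
                rng,
                design=design,
                channel_areas=areas,
                planted=planted,
                noise_cfg=noise,
                artifact_spec=art,
                fs=config.fs,
            )
        )
    return sessions


@dataclass
class CleanedSession:
    session: Session  # notch-filtered signal, full trial list
    exclusion: ExclusionResult

    @property
    def retained_trials(self) -> list[TrialRecord]:
        return [self.session.trials[i] for i in self.exclusion.retained_trials]


def preprocess_session(session: Session, config: RunConfig) -> CleanedSession:
    """Notch -> epoch -> three-step detection -> exclusion rules."""
    filtered = session.with_signal(
        notch_filter(session.signal, session.fs, config.notch_band).astype(np.float32)
    )
    epochs = epoch_session(filtered)
    mask = compute_artifact_mask(
        epochs, config.amplitude_sd, config.kurtosis_threshold, config.variance_sd
    )
    excl = apply_exclusion_rules(
        epochs,
        mask,
        rt_cap=config.rt_cap,
        trial_channel_frac=config.trial_channel_frac,
        channel_trial_frac=config.channel_trial_frac,
        min_correct_per_class=config.min_correct_per_class,
    )
    return CleanedSession(session=filtered, exclusion=excl)


def estimate_ter(session: Session, config: RunConfig) -> float:
    """Per-participant non-decision time per the configured mode."""
    if config.ter_mode == "zero":
        return 0.0
    if config.ter_mode == "supplied":
        return float(config.ter_supplied)
    return max(fit_ez_for_session(session, config).ter, 0.0)


def fit_ez_for_session(session: Session, config: RunConfig):
    """EZ fit on a session's behavior (trials within the RT cap)."""
    use = [t for t in session.trials if t.rt <= config.rt_cap]
    return fit_ez_from_trials(
        np.array([t.correct for t in use]), np.array([t.rt for t in use])
    )


def behavioral_summary(sessions: list[Session], config: RunConfig) -> dict:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                {
                    "subject": s.subject_id,
                    "class": t.stimulus_class,
                    "correct": t.correct,
                    "rt": t.rt,
                    "summed_similarity": t.summed_similarity,
                    "list_length": t.list_length,
                }
            )
    df = pd.DataFrame(rows)
    fast = df[df["rt"] <= config.rt_cap]
    per_subj = df.groupby("subject").agg(acc=("correct", "mean"))
    rt_subj = fast[fast["correct"]].groupby("subject")["rt"].mean()
    out = {
        "mean_accuracy_pct": float(100 * per_subj["acc"].mean()),
        "mean_rt_ms": float(1000 * rt_subj.mean()),
        "by_class": {
            c: {
                "accuracy_pct": float(100 * g["correct"].mean()),
                "mean_rt_ms": float(1000 * g.loc[g["correct"], "rt"].mean()),
            }
            for c, g in fast.groupby("class")
        },
    }
    faces = fast[fast["class"] == "face"].copy()
    if len(faces) >= config.evidence_levels:
        faces["level"] = pd.qcut(
            faces["summed_similarity"], config.evidence_levels, labels=False, duplicates="drop"
        )
        out["face_evidence_levels"] = {
            f"level{int(k)}": {
                "accuracy_pct": float(100 * g["correct"].mean()),
                "mean_rt_ms": float(1000 * g.loc[g["correct"], "rt"].mean()),
                "mean_summed_similarity": float(g["summed_similarity"].mean()),
            }
            for k, g in faces.groupby("level")
        }
    return out


def cohort_cca(
    bundles: list[FeatureBundle],
    ter_map: dict[str, float],
    config: RunConfig,
    rng: np.random.Generator,
) -> dict:
    """Canonical correlation against the shuffled-duration null.

    Runs per participant (electrodes cannot be pooled across subjects),
    Fisher-transforms the canonical correlations, and averages observed and
    null values across participants so each contributes equally.  In the
    default whole-brain mode the electrode set is all retained channels; in
    per-area mode one CCA runs per Brodmann area (keyed by area in the
    summary).
    """
    per_area = config.cca_mode == "per_area"
    per: dict = {}
    for bundle in bundles:
        # CCA needs a common sample axis across electrodes, so it runs on all
        # retained trials; residual per-cell exclusions only apply to the
        # per-electrode regressions
        tab = bundle.table
        if tab.n_trials < 2:
            logger.warning("subject %s: too few trials for CCA", bundle.subject_id)
            continue
        sel = np.arange(tab.total_length)
        ter = ter_map[bundle.subject_id]
        if per_area:
            groups = {
                area: [c for c, a in enumerate(bundle.channel_areas) if a == area]
                for area in sorted(set(bundle.channel_areas))
            }
        else:
            groups = {"whole_brain": list(range(len(bundle.channel_areas)))}
        for kind in REGRESSOR_KINDS:
            segs = build_segments(kind, tab, ter)
            y_obs = concatenate_segments(segs)
            Y = build_null_regressors(segs, config.n_perm, rng)
            for fi, feat in enumerate(FEATURES):
                for group, chans in groups.items():
                    X = bundle.data[fi][chans][:, sel]
                    res = cca_with_null(X, y_obs, Y)
                    cell = per.setdefault((feat, kind, group), {"obs_z": [], "null_z": []})
                    cell["obs_z"].append(fisher_z(res.observed))
                    cell["null_z"].append(fisher_z(res.null))
    summary: dict = {}
    for (feat, kind, group), cell in per.items():
        obs_mean = float(np.mean(cell["obs_z"]))
        null_mean = np.mean(np.array(cell["null_z"]), axis=0)
        p99 = float(np.percentile(null_mean, 99))
        entry = {
            "observed_mean_z": obs_mean,
            "null_p99_z": p99,
            "exceeds_null_p99": bool(obs_mean > p99),
            "percentile": float(100 * np.mean(null_mean < obs_mean)),
        }
        node = summary.setdefault(feat, {})
        if per_area:
            node.setdefault(kind, {})[group] = entry
        else:
            node[kind] = entry
    return summary


def run_pipeline(
    config: RunConfig,
    sessions: list[Session] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute all stages and return (and optionally write) the run report."""
    stage = "simulate"
    try:
        if sessions is None:
            sessions = simulate_cohort(config)
        rng_stats = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(
            config.n_subjects + 1
        )[-1])

        stage = "preprocess"
        cleaned: list[CleanedSession] = []
        exclusion_reports = {}
        for s in sessions:
            cs = preprocess_session(s, config)
            exclusion_reports[s.subject_id] = cs.exclusion.report
            if cs.exclusion.participant_excluded:
                logger.info("participant %s excluded", s.subject_id)
                continue
            cleaned.append(cs)
        if not cleaned:
            raise RuntimeError("all participants excluded")

        stage = "features"
        bundles: list[FeatureBundle] = []
        bundle_trials: dict[str, list[TrialRecord]] = {}
        for cs in cleaned:
            b = compute_feature_bundle(
                cs.session,
                cs.exclusion.retained_trials,
                cs.exclusion.retained_channels,
                cs.exclusion.cell_excluded,
                buffer=config.buffer,
            )
            bundles.append(b)
            bundle_trials[b.subject_id] = cs.retained_trials

        stage = "regressors"
        ter_map = {cs.session.subject_id: estimate_ter(cs.session, config) for cs in cleaned}

        stage = "stats"
        corr = build_corr_table(bundles, ter_map)
        cca = (
            cohort_cca(bundles, ter_map, config, rng_stats) if config.run_cca else {}
        )
        cell_model = fit_cell_model(corr, min_electrodes=config.min_electrodes_per_area)
        centering_all = float(corr["z"].mean())
        sig_mask = fdr_bh(cell_model.table["p"].to_numpy(), config.fdr_q) & (
            cell_model.table["estimate"].to_numpy() > 0
        )
        contrasts_by_cell = {}
        for _, row in cell_model.table[sig_mask].iterrows():
            cell = corr[(corr["band"] == row["band"]) & (corr["area"] == row["area"])]
            contrasts_by_cell[(row["band"], row["area"])] = fit_regressor_contrast(
                cell, centering=centering_all
            )
        candidates = select_candidates(
            cell_model, contrasts_by_cell, q=config.fdr_q, exclude_downramp_ties=config.exclude_downramp_ties
        )

        stage = "timecourse"
        cohort = [(b, bundle_trials[b.subject_id]) for b in bundles]
        timecourse_report = {}
        for _, row in candidates[candidates["selected"]].iterrows():
            rt_bins = binned_average(
                cohort, row["area"], row["band"], binning="rt", rt_edges=config.rt_bin_edges
            )
            ev_bins = binned_average(
                cohort,
                row["area"],
                row["band"],
                binning="evidence",
                stimulus_class="face",
                evidence_levels=config.evidence_levels,
            )
            diag = accumulator_diagnostics(rt_bins, ev_bins) if len(rt_bins) >= 2 else None
            timecourse_report[f"{row['band']}:{row['area']}"] = {
                "rt_bins": {
                    a.label: {
                        "n_trials": a.n_trials,
                        "median_rt": a.median_rt,
                        "values": a.values.round(5).tolist(),
                    }
                    for a in rt_bins
                },
                "diagnostics": None
                if diag is None
                else {
                    "peak_latency": diag.peak_latency,
                    "peak_amplitude": diag.peak_amplitude,
                    "mean_slope": diag.mean_slope,
                    "latency_scales_with_rt": diag.latency_scales_with_rt,
                    "amplitude_rt_invariant": diag.amplitude_rt_invariant,
                    "slope_scales_with_evidence": diag.slope_scales_with_evidence,
                    "stats": diag.stats,
                },
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "behavior": behavioral_summary(sessions, config),
        "exclusion": exclusion_reports,
        "non_decision_time_s": ter_map,
        "cca": cca,
        "cell_model_table": cell_model.table.round(6).to_dict(orient="records"),
        "cell_method": cell_model.method,
        "candidates": candidates.round(6).to_dict(orient="records"),
        "selected_cells": [
            f"{r['band']}:{r['area']}"
            for _, r in candidates[candidates["selected"]].iterrows()
        ],
        "timecourse": timecourse_report,
        "n_timeouts": int(
            sum(
                s.ground_truth.n_timeouts
                for s in sessions
                if s.ground_truth is not None
            )
        ),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        aio.write_json(out / "report.json", report)
        aio.write_tsv(out / "corr_records.tsv", corr)
        aio.write_tsv(out / "cell_model.tsv", cell_model.table)
        aio.write_tsv(out / "candidates.tsv", candidates)
        excl_df = pd.DataFrame(
            [{"subject": k, **v} for k, v in exclusion_reports.items()]
        )
        aio.write_tsv(out / "exclusion_report.tsv", excl_df)
        ez_rows = []
        for cs in cleaned:
            est = fit_ez_for_session(cs.session, config)
            ez_rows.append(
                {
                    "subject_id": cs.session.subject_id,
                    "Pc": est.pc,
                    "VRT": est.vrt,
                    "MRT": est.mrt,
                    "v": est.v,
                    "a": est.a,
                    "Ter": est.ter,
                    "ter_used": ter_map[cs.session.subject_id],
                }
            )
        aio.write_tsv(out / "ez_estimates.tsv", pd.DataFrame(ez_rows))
        for s in sessions:
            aio.write_trial_table(out / f"{s.subject_id}_trials.tsv", s.trials)
    return report
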