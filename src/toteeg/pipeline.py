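"""End-to-end study replica: simulate -> spectra -> parameterize -> statistics.

``run_full_analysis`` executes the whole analysis chain on a synthetic (or
supplied) study: single-trial pre/post-stimulus spectra, spectral
parameterization (aperiodic exponent, alpha peak), block-wise cluster
permutation F-tests on the power spectra, behavioural and alpha-measure
block ANOVAs, time-frequency single-trial regressions with and without
trial order, scalar alpha-measure regressions, AIC model comparison and the
between-model coefficient contrast. Results are written as CSV/JSON plus a
run manifest with config snapshot, seeds and per-stage digests.

The default analysis scale is a desk-scale replica (few participants,
reduced permutation count, two time-frequency channels of interest); the
full-scale design lives in the generator defaults and is selected by
passing a full-size ``SessionConfig`` and ``AnalysisSettings``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavstats, specfit, spectral, trialreg
from .config import SessionConfig
from .containers import write_trial_table
from .layouts import biosemi32_layout
from .permstats import build_adjacency, cluster_permutation_test
from .synth import generate_session_eeg, generate_trial_table

__all__ = ["AnalysisSettings", "run_full_analysis",
           "participant_alpha_measures", "alpha_regression_suite"]

logger = logging.getLogger(__name__)

SCALAR_MEASURES = ("alpha_pow", "alpha_cf", "exponent")


@dataclass
class AnalysisSettings:
    pre_window: tuple[float, float] = (-1.0, 0.0)
    post_window: tuple[float, float] = (0.0, 1.0)
    pad_length: float = 10.0
    fit_range: tuple[float, float] = (3.0, 40.0)
    alpha_range: tuple[float, float] = (6.0, 15.0)
    tf_win_length: float = 0.5
    tf_step: float = 0.02
    tf_pad: float = 1.0
    tf_time_range: tuple[float, float] = (-1.0, 1.0)
    tf_channels: tuple[str, ...] = ("O1", "Oz")   # channels of interest
    cluster_freq_step: float = 0.5   # decimated grid for the block F-test
    n_perm: int = 200
    point_alpha: float = 0.05
    cluster_alpha_f: float = 0.05
    cluster_alpha_t: float = 0.025
    rt_trim_sd: float = 3.0
    figures: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ----------------------------------------------------------------------
# reusable building blocks

def participant_alpha_measures(config: SessionConfig, participant: int,
                               window: tuple[float, float] = (-1.0, 0.0),
                               settings: AnalysisSettings | None = None,
                               table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Trial table plus parameterized per-trial spectral measures for one window.

    Simulates the participant, computes channel-averaged single-trial
    spectra for the window, parameterizes each, and returns the trial table
    with ``exponent``, ``alpha_present``, ``alpha_cf``, ``alpha_pow`` and
    ``rt_keep`` (3-SD trim mask) columns appended.
    """
    settings = settings or AnalysisSettings()
    if table is None:
        table = generate_trial_table(config, participant)
    epochs = generate_session_eeg(table, config, participant)
    spec = spectral.epoch_power_spectrum(
        epochs, time_window=window, pad_length=settings.pad_length)
    fits = specfit.fit_trial_spectra(
        spec, average_channels=True, alpha_range=settings.alpha_range,
        fit_range=settings.fit_range)
    out = table.copy().reset_index(drop=True)
    for col in ("exponent", "offset", "r_squared", "alpha_present",
                "alpha_cf", "alpha_pow"):
        out[col] = fits[col].to_numpy()
    out["rt_keep"] = behavstats.rt_trim(out["rt"].to_numpy(), settings.rt_trim_sd)
    return out


def _scalar_fits(measures: dict[int, pd.DataFrame], outcome: str,
                 include_tot: bool) -> list[trialreg.RegressionFit]:
    """Stage-one fits of one scalar measure for every participant.

    Trials failing the RT trim are excluded; trials without a detected
    alpha peak are missing in alpha_cf/alpha_pow and so drop out listwise —
    identically for both models of a comparison pair.
    """
    fits = []
    for pid, df in measures.items():
        sub = df[df["rt_keep"]].reset_index(drop=True)
        y = sub[outcome].to_numpy(dtype=float)
        if outcome in ("alpha_cf", "alpha_pow"):
            y = np.where(sub["alpha_present"].to_numpy(bool), y, np.nan)
        fits.append(trialreg.fit_trial_regression(
            y, sub, include_tot=include_tot, outcome_name=outcome))
    return fits


def alpha_regression_suite(measures: dict[int, pd.DataFrame],
                           outcomes: tuple[str, ...] = SCALAR_MEASURES) -> dict:
    """Two-stage regression suite over scalar spectral measures.

    For each outcome: group-level tests of the noToT and withToT models
    (BH-FDR within each model's predictor family), the per-participant AIC
    comparison, and the paired contrast of the RT coefficient.
    """
    results = {}
    for outcome in outcomes:
        fits_no = _scalar_fits(measures, outcome, include_tot=False)
        fits_with = _scalar_fits(measures, outcome, include_tot=True)
        group_no = trialreg.group_level_test(fits_no)
        group_with = trialreg.group_level_test(fits_with)
        comparison = trialreg.compare_models_aic(fits_no, fits_with)
        contrast = trialreg.coefficient_contrast(fits_no, fits_with, predictor="rt")
        results[outcome] = {
            "group_no_tot": group_no, "group_with_tot": group_with,
            "aic": comparison, "rt_contrast": contrast,
            "fits_no": fits_no, "fits_with": fits_with,
        }
    return results


def _group_row(group: pd.DataFrame, predictor: str) -> pd.Series:
    return group.set_index("predictor").loc[predictor]


# ----------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_full_analysis(config: SessionConfig,
                      settings: AnalysisSettings | None = None,
                      out_dir: str | Path | None = None) -> dict:
    """Execute the full study replica; returns the report dict.

    When ``out_dir`` is given, tables, JSON results, figures and the run
    manifest are written there. Numeric outputs depend only on the config
    (including its seed) and settings.
    """
    settings = settings or AnalysisSettings()
    t_start = time.monotonic()
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        report = _run_stages(config, settings, out_dir, timings)
    except Exception:
        logger.exception("pipeline failed")
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            (Path(out_dir) / "manifest.json").write_text(json.dumps(
                {"failed_stage": timings.get("_current", stage),
                 "config": _jsonify(config.to_dict())}, indent=2))
        raise
    if out_dir is not None:
        out = Path(out_dir)
        manifest = {
            "config": _jsonify(config.to_dict()),
            "settings": _jsonify(settings.to_dict()),
            "seed": config.seed,
            "timings_s": {k: round(v, 3) for k, v in timings.items() if not k.startswith("_")},
            "total_s": round(time.monotonic() - t_start, 3),
            "outputs": {p.name: _digest(p) for p in sorted(out.glob("*"))
                        if p.is_file() and p.name != "manifest.json"},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def _run_stages(config: SessionConfig, settings: AnalysisSettings,
                out_dir: str | Path | None, timings: dict) -> dict:
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    perm_seed = int(np.random.SeedSequence(config.seed, spawn_key=(97,)).generate_state(1)[0]
                    % (2 ** 31))

    # ---------------- stage: simulate + spectra + specfit -----------------
    timings["_current"] = "simulate"
    t0 = time.monotonic()
    pids = list(range(1, config.n_participants + 1))
    tables: dict[int, pd.DataFrame] = {}
    measures_pre: dict[int, pd.DataFrame] = {}
    measures_post: dict[int, pd.DataFrame] = {}
    block_spec_pre, block_spec_post = [], []
    coef_maps = {"noToT": [], "withToT": []}
    aic_tf = {"noToT": [], "withToT": []}
    tf_axes: dict = {}

    ch_names = None
    for pid in pids:
        table = generate_trial_table(config, pid)
        tables[pid] = table
        epochs = generate_session_eeg(table, config, pid)
        ch_names = epochs.ch_names
        keep = behavstats.rt_trim(table["rt"].to_numpy(), settings.rt_trim_sd)

        for window, store_m, store_b in (
                (settings.pre_window, measures_pre, block_spec_pre),
                (settings.post_window, measures_post, block_spec_post)):
            spec = spectral.epoch_power_spectrum(
                epochs, time_window=window, pad_length=settings.pad_length)
            # decimated block-mean spectra per channel for the cluster F-test
            dec = max(int(round(settings.cluster_freq_step / spec.df)), 1)
            fsel = slice(0, None, dec)
            blocks = table["block"].to_numpy()
            bmeans = np.stack([
                spec.power[(blocks == b) & keep].mean(axis=0)[:, fsel]
                for b in range(1, config.n_blocks + 1)])
            store_b.append(bmeans)
            if "cluster_freqs" not in tf_axes:
                tf_axes["cluster_freqs"] = spec.freqs[fsel]

            fits = specfit.fit_trial_spectra(
                spec, average_channels=True, alpha_range=settings.alpha_range,
                fit_range=settings.fit_range)
            m = table.copy().reset_index(drop=True)
            m["window"] = "pre" if window == settings.pre_window else "post"
            for col in ("offset", "exponent", "r_squared", "mae", "n_peaks",
                        "alpha_present", "alpha_cf", "alpha_pow"):
                m[col] = fits[col].to_numpy()
            m["rt_keep"] = keep
            store_m[pid] = m

        # time-frequency regression at channels of interest
        coi = [c for c in settings.tf_channels if c in epochs.ch_names]
        if not coi:
            coi = epochs.ch_names[: min(2, len(epochs.ch_names))]
        idx = [epochs.ch_names.index(c) for c in coi]
        tf = spectral.time_frequency(
            epochs, win_length=settings.tf_win_length, step=settings.tf_step,
            pad_length=settings.tf_pad, time_range=settings.tf_time_range)
        tf_axes.update({"tf_freqs": tf.freqs, "tf_times": tf.times, "tf_channels": coi})
        pw = tf.power[:, idx][keep]
        sub = table.loc[keep].reset_index(drop=True)
        shape = pw.shape[1:]
        flat = pw.reshape(pw.shape[0], -1)
        for model, include_tot in (("noToT", False), ("withToT", True)):
            coefs, aic = trialreg.fit_trial_regression_maps(
                flat, sub, include_tot=include_tot)
            coef_maps[model].append(coefs.reshape((-1,) + shape))
            aic_tf[model].append(np.nanmean(aic))
    timings["simulate_spectra_fit"] = time.monotonic() - t0

    all_tables = pd.concat(tables.values(), ignore_index=True)
    if out is not None:
        write_trial_table(all_tables, out / "trial_table.csv")
        pd.concat(measures_pre.values(), ignore_index=True).to_csv(
            out / "trial_measures_pre.csv", index=False)
        pd.concat(measures_post.values(), ignore_index=True).to_csv(
            out / "trial_measures_post.csv", index=False)

    # ---------------- stage: behavioural statistics -----------------------
    timings["_current"] = "behaviour"
    t0 = time.monotonic()
    keep_mask = all_tables.groupby("participant")["rt"].transform(
        lambda s: behavstats.rt_trim(s.to_numpy(), settings.rt_trim_sd)).astype(bool)
    trimmed = all_tables[keep_mask]
    psych = behavstats.psychometric_summary(trimmed)
    behaviour_anovas = {}
    for col in ("p_correct", "p_confident", "mean_rt"):
        pivot = psych.pivot_table(index="participant", columns=["block", "contrast"],
                                  values=col, sort=True)
        n_b = psych["block"].nunique()
        n_c = psych["contrast"].nunique()
        arr = pivot.to_numpy().reshape(-1, n_b, n_c)
        res = behavstats.rm_anova(arr, factor_names=("block", "contrast"))
        behaviour_anovas[col] = res.table.to_dict(orient="records")
    # follow-up: Tukey HSD on the block main effect for RT
    rt_block = psych.pivot_table(index="participant", columns="block",
                                 values="mean_rt").to_numpy()
    rt_anova = behavstats.rm_anova(rt_block, factor_names=("block",))
    eff = rt_anova.effect("block")
    tukey_rt = behavstats.tukey_hsd(
        rt_block.mean(axis=0), eff["ms_error"], eff["df2"],
        n_per_cell=rt_block.shape[0])
    timings["behaviour"] = time.monotonic() - t0

    # ---------------- stage: block cluster F on spectra -------------------
    timings["_current"] = "cluster_f"
    t0 = time.monotonic()
    layout = biosemi32_layout().subset([c for c in ch_names])
    adjacency = build_adjacency(layout) if len(ch_names) > 2 else None
    cluster_results = {}
    for name, stack in (("pre", block_spec_pre), ("post", block_spec_post)):
        data = np.stack(stack)  # P x B x ch x F
        res = cluster_permutation_test(
            data, stat="dependent_F", adjacency=adjacency,
            point_alpha=settings.point_alpha, cluster_alpha=settings.cluster_alpha_f,
            n_perm=settings.n_perm, min_channels=2 if adjacency is not None else 1,
            seed=perm_seed)
        cluster_results[name] = res
        if out is not None:
            res.to_json(out / f"cluster_F_{name}.json")
    timings["cluster_f"] = time.monotonic() - t0

    # ---------------- stage: alpha-measure block ANOVAs -------------------
    timings["_current"] = "alpha_block_anova"
    t0 = time.monotonic()
    alpha_block = {}
    for name, measures in (("pre", measures_pre), ("post", measures_post)):
        per = {}
        for meas in SCALAR_MEASURES:
            mat = np.full((len(pids), config.n_blocks), np.nan)
            for i, pid in enumerate(pids):
                df = measures[pid]
                sel = df["rt_keep"]
                if meas != "exponent":
                    sel = sel & df["alpha_present"]
                sub = df[sel]
                mat[i] = sub.groupby("block")[meas].mean().reindex(
                    range(1, config.n_blocks + 1)).to_numpy()
            res = behavstats.rm_anova(mat, factor_names=("block",))
            per[meas] = res.table.to_dict(orient="records")
        alpha_block[name] = per
    timings["alpha_block_anova"] = time.monotonic() - t0

    # ---------------- stage: scalar two-stage regressions -----------------
    timings["_current"] = "scalar_regression"
    t0 = time.monotonic()
    scalar = {}
    for name, measures in (("pre", measures_pre), ("post", measures_post)):
        scalar[name] = alpha_regression_suite(measures)
    timings["scalar_regression"] = time.monotonic() - t0

    # ---------------- stage: TF group cluster tests -----------------------
    timings["_current"] = "tf_group"
    t0 = time.monotonic()
    coi = tf_axes["tf_channels"]
    adj_coi = (build_adjacency(biosemi32_layout().subset(coi))
               if len(coi) > 1 else None)
    predictor_order = {"noToT": trialreg.PREDICTORS_NO_TOT,
                       "withToT": trialreg.PREDICTORS_WITH_TOT}
    tf_group = {}
    for model in ("noToT", "withToT"):
        maps = np.stack(coef_maps[model])  # P x pred x ch x f x t
        per_pred = {}
        for j, pred in enumerate(predictor_order[model]):
            res = trialreg.group_level_cluster_test(
                maps[:, j], adjacency=adj_coi, n_perm=settings.n_perm,
                cluster_alpha=settings.cluster_alpha_t,
                min_channels=2 if adj_coi is not None else 1, seed=perm_seed + 1 + j)
            per_pred[pred] = res
        tf_group[model] = per_pred
    # between-model contrast of the RT coefficient map
    j_rt = predictor_order["noToT"].index("rt")
    rt_diff = np.stack(coef_maps["withToT"])[:, j_rt] - np.stack(coef_maps["noToT"])[:, j_rt]
    tf_rt_contrast = trialreg.group_level_cluster_test(
        rt_diff, adjacency=adj_coi, n_perm=settings.n_perm,
        cluster_alpha=settings.cluster_alpha_t,
        min_channels=2 if adj_coi is not None else 1, seed=perm_seed + 31)
    tf_aic = {
        "mean_delta": float(np.mean(np.array(aic_tf["noToT"]) - np.array(aic_tf["withToT"]))),
    }
    timings["tf_group"] = time.monotonic() - t0

    # ---------------- report ----------------------------------------------
    timings["_current"] = "report"

    def sig(group_df, pred):
        row = _group_row(group_df, pred)
        return bool(row["p_fdr"] < 0.05)

    pre_pow = scalar["pre"]["alpha_pow"]
    pre_cf = scalar["pre"]["alpha_cf"]
    post_pow = scalar["post"]["alpha_pow"]
    headline = {
        "alpha_pow_rt_sig_no_tot": sig(pre_pow["group_no_tot"], "rt"),
        "alpha_pow_rt_sig_with_tot": sig(pre_pow["group_with_tot"], "rt"),
        "alpha_cf_rt_sig_no_tot": sig(pre_cf["group_no_tot"], "rt"),
        "alpha_cf_rt_sig_with_tot": sig(pre_cf["group_with_tot"], "rt"),
        "post_alpha_pow_conf_sig_with_tot": sig(post_pow["group_with_tot"], "confidence"),
        "tot_sign_alpha_pow": float(_group_row(pre_pow["group_with_tot"], "tot")["mean_coef"]),
        "tot_sign_alpha_cf": float(_group_row(pre_cf["group_with_tot"], "tot")["mean_coef"]),
        "mean_delta_aic_alpha_pow": pre_pow["aic"].mean_delta,
        "delta_aic_p_alpha_pow": pre_pow["aic"].p,
    }
    report = {
        "n_participants": len(pids),
        "n_trials": config.n_trials,
        "behaviour_anovas": behaviour_anovas,
        "tukey_rt_blocks": tukey_rt.to_dict(orient="records"),
        "cluster_F": {
            name: {"min_p": res.min_p(),
                   "n_significant": len(res.significant),
                   "max_f_sum": max((c["stat_sum"] for c in res.clusters), default=0.0)}
            for name, res in cluster_results.items()},
        "alpha_block_anovas": alpha_block,
        "scalar_regression": {
            win: {meas: {
                "group_no_tot": r["group_no_tot"].to_dict(orient="records"),
                "group_with_tot": r["group_with_tot"].to_dict(orient="records"),
                "delta_aic_mean": r["aic"].mean_delta,
                "delta_aic_t": r["aic"].t, "delta_aic_p": r["aic"].p,
                "rt_contrast": r["rt_contrast"],
            } for meas, r in per.items()}
            for win, per in scalar.items()},
        "tf_group": {
            model: {pred: {"min_p": res.min_p(),
                           "n_significant": len(res.significant)}
                    for pred, res in per.items()}
            for model, per in tf_group.items()},
        "tf_rt_contrast": {"min_p": tf_rt_contrast.min_p(),
                           "n_significant": len(tf_rt_contrast.significant)},
        "tf_aic": tf_aic,
        "headline": headline,
    }
    if out is not None:
        (out / "report.json").write_text(
            json.dumps(_jsonify(report), indent=2, sort_keys=True))
        psych.to_csv(out / "psychometric.csv", index=False)
        if settings.figures:
            _figures(out, tf_axes, block_spec_pre, tf_group, config)
    return report


def _figures(out: Path, tf_axes: dict, block_spec_pre: list, tf_group: dict,
             config: SessionConfig) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    freqs = tf_axes["cluster_freqs"]
    data = np.stack(block_spec_pre)  # P x B x ch x F
    for b in range(config.n_blocks):
        ax.loglog(freqs, data[:, b].mean(axis=(0, 1)), label=f"block {b + 1}")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power (a.u./Hz)")
    ax.legend(fontsize=7)
    ax.set_title("pre-stimulus scalp-mean spectra by block")
    fig.tight_layout()
    fig.savefig(out / "fig_block_spectra.png", dpi=110)
    plt.close(fig)


def scalar_study(config: SessionConfig,
                 window: tuple[float, float] = (-1.0, 0.0),
                 outcomes: tuple[str, ...] = SCALAR_MEASURES) -> dict:
    """One simulated study through the scalar (alpha-measure) analysis chain.

    Simulates every participant, parameterizes single-trial spectra in the
    given window, runs the two-stage regressions with and without trial
    order, and summarises the quantities the time-on-task logic turns on:
    FDR-corrected group p of each predictor under both models, the ToT
    coefficient, the AIC comparison, the between-model RT-coefficient
    contrast, the block ANOVA on the aperiodic exponent, and the alpha-peak
    detection rate.
    """
    pids = list(range(1, config.n_participants + 1))
    measures = {pid: participant_alpha_measures(config, pid, window=window)
                for pid in pids}
    suite = alpha_regression_suite(measures, outcomes=outcomes)

    out = {"outcomes": {}, "measures": measures}
    for meas, r in suite.items():
        no = r["group_no_tot"].set_index("predictor")
        wi = r["group_with_tot"].set_index("predictor")
        out["outcomes"][meas] = {
            "rt_p_no_tot": float(no.loc["rt", "p_fdr"]),
            "rt_p_with_tot": float(wi.loc["rt", "p_fdr"]),
            "conf_p_no_tot": float(no.loc["confidence", "p_fdr"]),
            "conf_p_with_tot": float(wi.loc["confidence", "p_fdr"]),
            "conf_coef_with_tot": float(wi.loc["confidence", "mean_coef"]),
            "tot_coef": float(wi.loc["tot", "mean_coef"]),
            "tot_p": float(wi.loc["tot", "p_fdr"]),
            "delta_aic": r["aic"].delta_aic.tolist(),
            "delta_aic_mean": r["aic"].mean_delta,
            "delta_aic_p": r["aic"].p,
            "rt_contrast_t": r["rt_contrast"]["t"],
            "rt_contrast_p": r["rt_contrast"]["p"],
        }
    # block ANOVA on the aperiodic exponent (generated stationary)
    mat = np.full((len(pids), config.n_blocks), np.nan)
    for i, pid in enumerate(pids):
        df = measures[pid]
        sub = df[df["rt_keep"]]
        mat[i] = sub.groupby("block")["exponent"].mean().reindex(
            range(1, config.n_blocks + 1)).to_numpy()
    anova = behavstats.rm_anova(mat, factor_names=("block",)).table.iloc[0]
    out["exponent_block_p"] = float(anova["p"])
    out["exponent_block_p_gg"] = float(anova["p_gg"])
    out["alpha_detection_rate"] = float(
        np.mean([m["alpha_present"].mean() for m in measures.values()]))
    return out


#: desk-scale study conditions used by the validation suites: 12 participants,
#: 125 trials in 5 blocks of 25, 8 channels, 2-s epochs around onset
STUDY_SCALE = dict(n_participants=12, trials_per_block=25, n_channels=8,
                   epoch_window=(-1.0, 1.0))


def make_study_config(regime: str, seed: int) -> SessionConfig:
    factory = {"null": SessionConfig.null_regime,
               "spurious": SessionConfig.spurious_regime,
               "genuine": SessionConfig.genuine_regime}[regime]
    return factory(seed=seed, **STUDY_SCALE)


# convenience used by the CLI
def default_ci_config(regime: str = "spurious", seed: int = 0,
                      n_participants: int = 6) -> SessionConfig:
    factory = {"null": SessionConfig.null_regime,
               "spurious": SessionConfig.spurious_regime,
               "genuine": SessionConfig.genuine_regime}[regime]
    return factory(n_participants=n_participants, trials_per_block=30,
                   n_channels=8, epoch_window=(-1.5, 1.5), seed=seed)
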