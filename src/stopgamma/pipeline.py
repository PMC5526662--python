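"""End-to-end analysis: synthetic (or imported) cohort -> preprocessing ->
behavior -> contact selection -> time-frequency power / ISPC -> contrasts ->
group statistics -> machine-readable summary.

The contrasts mirror the study design:

* ``stop_vs_prev_tap`` — power aligned to the stop cue vs. the last regular
  tap aligned to where the cue would have occurred one tap earlier,
* ``success_vs_fail`` — successful vs. failed stop trials,
* ``prestop_window`` — the same contrast restricted to the 350 ms before
  the cue (tonic pre-stop differences),
* ``band_timecourses`` — 60-90 Hz gamma time courses with a 1-D cluster
  test,
* ``peak_latency`` — per-subject gamma peak latencies, success vs. fail,
* ``corr_extent_gamma`` — per-subject max Spearman correlation between
  movement extent and gamma in the stopping window, Fisher-z group test,
* ``tap_metric_correlations`` — movement extent vs. last-tap covariates
  with Fisher-z group tests and BH-FDR,
* ``cz_theta`` — the slow 3-5 Hz Cz response to the cue,
* ``ispc_change`` — baseline-normalized STN-EEG phase coupling.

Everything is seeded and deterministic: identical config -> byte-identical
summary JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as st

from . import behavior as bhv
from . import connectivity as conn
from . import spectral as spc
from . import stats as sgs
from .core_io import Recording
from .preprocess import PreprocConfig, preprocess_recording
from .synthetic import SimConfig, simulate_dataset

__all__ = ["AnalysisConfig", "run_pipeline", "report", "subject_analysis"]

log = logging.getLogger(__name__)

GAMMA_BAND = (60.0, 90.0)
THETA_BAND = (3.0, 5.0)


@dataclass
class AnalysisConfig:
    """Settings for one pipeline run over a (synthetic) cohort."""

    sim: SimConfig = field(default_factory=SimConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    fbank: spc.FilterbankSpec = field(default_factory=spc.FilterbankSpec)
    ispc: conn.ISPCSpec = field(default_factory=conn.ISPCSpec)
    behavior: bhv.BehaviorConfig = field(default_factory=bhv.BehaviorConfig)
    contrasts: tuple[str, ...] = (
        "stop_vs_prev_tap",
        "success_vs_fail",
        "band_timecourses",
        "peak_latency",
    )
    bands_which: str = "high"  # filterbank portion for the STN maps
    epoch_window: tuple[float, float] = (-0.5, 0.4)
    latency_window: tuple[float, float] = (0.0, 0.32)  # s; covers both burst latencies
    n_perm: int = 1000
    alpha: float = 0.05
    stats_seed: int = 1234
    stop_window_end: float | None = None  # s; None = mean failed-tap latency

    def validate(self) -> None:
        known = {
            "stop_vs_prev_tap", "success_vs_fail", "prestop_window",
            "band_timecourses", "peak_latency", "corr_extent_gamma",
            "tap_metric_correlations", "cz_theta", "ispc_change",
        }
        bad = set(self.contrasts) - known
        if bad:
            raise ValueError(f"unknown contrasts {sorted(bad)}")


def _align_times(events, trials):
    """Stop-cue times for the analysable (non-excluded) trials."""
    keep = trials.loc[~trials["excluded"]]
    return keep["stop_time"].to_numpy(), keep


def subject_analysis(rec: Recording, events: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    """All per-subject quantities used by the group stage.

    Preprocesses the recording, derives the trial table from the pressure /
    goniometer channels, selects the STN bipolar with the strongest
    tap-locked gamma modulation, computes the filterbank power map on it,
    epochs around the stop cue / virtual stop / regular taps, and
    normalizes to the regular-tap baseline.
    """
    rec = preprocess_recording(rec, cfg.preproc)
    trials = bhv.derive_trial_table(events, rec, cfg.behavior)
    stop_times, kept = _align_times(events, trials)

    interval = cfg.sim.metronome_interval / 1000.0
    taps = spc.regular_tap_times(events)
    candidates = {n: rec.channel(n) for n in rec.pick("lfp_bipolar") if "contra" in n}
    if not candidates:
        candidates = {n: rec.channel(n) for n in rec.pick("lfp_bipolar")}
    best, mod_index = spc.select_bipolar(candidates, rec.sample_rate, taps, interval)

    tf = spc.tf_power(rec.channel(best), rec.sample_rate, cfg.fbank,
                      which=cfg.bands_which, subject_id=rec.subject_id)

    tap_epochs, _, _ = spc.epoch_tf(tf, taps, cfg.epoch_window)
    stop_epochs, rel, kept_ix = spc.epoch_tf(tf, stop_times, cfg.epoch_window)
    kept = kept.iloc[kept_ix]
    virt = spc.virtual_stop_times(events)
    virt = virt.loc[virt.index.intersection(kept["trial_idx"])].to_numpy()
    virt_epochs, _, _ = spc.epoch_tf(tf, virt, cfg.epoch_window)

    stop_norm = spc.normalize_to_regular_taps(stop_epochs, tap_epochs)
    virt_norm = spc.normalize_to_regular_taps(virt_epochs, tap_epochs)

    success = (kept["outcome"] != "failed").to_numpy()
    failed_lat = kept.loc[kept["outcome"] == "failed"]
    # stopping window: cue -> average failed tap (the time left to stop)
    if cfg.stop_window_end is not None:
        stop_end = cfg.stop_window_end
    elif len(failed_lat):
        nxt = []
        pres = rec.channel(rec.pick("pressure")[0])
        det = bhv.detect_taps(pres, rec.sample_rate, cfg.behavior)
        for _, row in failed_lat.iterrows():
            after = det.loc[det["onset"] >= row["stop_time"], "onset"]
            if len(after):
                nxt.append(float(after.iloc[0]) - row["stop_time"])
        stop_end = float(np.mean(nxt)) if nxt else 0.156
    else:
        stop_end = 0.156

    out = dict(
        subject_id=rec.subject_id,
        rec=rec,
        events=events,
        trials=trials,
        kept=kept,
        selected_bipolar=best,
        modulation_index=mod_index,
        freqs=tf.freqs,
        rel_times=rel,
        stop_epochs_norm=stop_norm,
        virt_epochs_norm=virt_norm,
        success_mask=success,
        stop_window_end=stop_end,
        eog_scales=rec.meta.get("eog_scales", {}),
    )
    if "cz_theta" in cfg.contrasts and "Cz" in rec.channel_names:
        low = spc.FilterbankSpec(low_range=(3.0, 8.0))
        tf_cz = spc.tf_power(rec.channel("Cz"), rec.sample_rate, low, which="low")
        cz_tap, _, _ = spc.epoch_tf(tf_cz, taps, cfg.epoch_window)
        cz_stop, _, _ = spc.epoch_tf(tf_cz, stop_times, cfg.epoch_window)
        out["cz_theta_norm"] = spc.normalize_to_regular_taps(cz_stop, cz_tap)
        out["cz_freqs"] = tf_cz.freqs
    if "ispc_change" in cfg.contrasts:
        target = "C3" if rec.tapping_hand == "right" else "C4"
        if target in rec.channel_names:
            m = conn.ispc_map(rec.channel(best), rec.channel(target),
                              rec.sample_rate, stop_times,
                              (-0.5, cfg.epoch_window[1]), cfg.ispc, cfg.fbank,
                              which=cfg.bands_which)
            out["ispc_norm"] = conn.normalize_ispc(m, cfg.ispc.baseline)
    return out


def _mean_or_nan(ep):
    return ep.mean(axis=0) if len(ep) else None


def run_pipeline(cfg: AnalysisConfig, dataset=None) -> dict:
    """Run the full analysis; returns the report bundle.

    *dataset* defaults to ``simulate_dataset(cfg.sim)``; pass a list of
    ``(Recording, events, ...)`` tuples to analyse imported data.  The
    bundle contains per-subject results, group-level cluster statistics per
    requested contrast and a JSON-serializable ``summary``.
    """
    cfg.validate()
    if dataset is None:
        dataset = simulate_dataset(cfg.sim)
    subjects = [subject_analysis(rec, events, cfg) for rec, events, *_ in dataset]

    summary: dict = {
        "n_subjects": len(subjects),
        "seeds": {"sim": cfg.sim.seed, "stats": cfg.stats_seed},
        "n_perm": cfg.n_perm,
        "contrasts": sorted(cfg.contrasts),
        "selected_bipolars": {s["subject_id"]: s["selected_bipolar"] for s in subjects},
    }

    # behavioral marginals (measured, not copied from config)
    all_trials = pd.concat([s["trials"] for s in subjects], ignore_index=True)
    ok = all_trials[~all_trials["excluded"]]
    summary["behavior"] = {
        "n_trials": int(len(all_trials)),
        "n_analysed": int(len(ok)),
        "success_rate_pct": float(100.0 * (ok["outcome"] != "failed").mean()),
        "full_stop_rate_pct": float(100.0 * (ok["outcome"] == "full").mean()),
        "mean_stop_delay_ms": float(ok["stop_delay"].mean()),
        "mean_tap_sound_offset_ms": float(ok["tap_sound_offset"].mean()),
        "mean_stop_window_end_ms": float(
            np.mean([s["stop_window_end"] for s in subjects]) * 1000.0
        ),
    }

    freqs = subjects[0]["freqs"]
    rel = subjects[0]["rel_times"]
    bundle: dict = {"config": cfg, "subjects": subjects, "summary": summary,
                    "freqs": freqs, "rel_times": rel}

    def stack(key_fn):
        maps = [key_fn(s) for s in subjects]
        keep = [m for m in maps if m is not None]
        return np.stack(keep) if keep else None

    if "success_vs_fail" in cfg.contrasts or "prestop_window" in cfg.contrasts \
            or "band_timecourses" in cfg.contrasts:
        succ = stack(lambda s: _mean_or_nan(s["stop_epochs_norm"][s["success_mask"]]))
        fail = stack(lambda s: _mean_or_nan(s["stop_epochs_norm"][~s["success_mask"]]))
    if "success_vs_fail" in cfg.contrasts:
        win = (rel >= -0.35) & (rel <= 0.35)
        res = sgs.cluster_permutation(succ[:, :, win] - fail[:, :, win],
                                      n_perm=cfg.n_perm, alpha=cfg.alpha,
                                      seed=cfg.stats_seed)
        bundle["success_vs_fail"] = res
        bundle["success_vs_fail_axes"] = (freqs, rel[win])
        summary["success_vs_fail"] = _cluster_summary(res, freqs, rel[win])
    if "stop_vs_prev_tap" in cfg.contrasts:
        allstop = stack(lambda s: _mean_or_nan(s["stop_epochs_norm"]))
        prev = stack(lambda s: _mean_or_nan(s["virt_epochs_norm"]))
        win = (rel >= -0.35) & (rel <= 0.35)
        res = sgs.cluster_permutation(allstop[:, :, win] - prev[:, :, win],
                                      n_perm=cfg.n_perm, alpha=cfg.alpha,
                                      seed=cfg.stats_seed + 1)
        bundle["stop_vs_prev_tap"] = res
        summary["stop_vs_prev_tap"] = _cluster_summary(res, freqs, rel[win])
    if "prestop_window" in cfg.contrasts:
        win = (rel >= -0.35) & (rel < 0.0)
        res = sgs.cluster_permutation(succ[:, :, win] - fail[:, :, win],
                                      n_perm=cfg.n_perm, alpha=cfg.alpha,
                                      seed=cfg.stats_seed + 2)
        bundle["prestop_window"] = res
        summary["prestop_window"] = _cluster_summary(res, freqs, rel[win])
    if "band_timecourses" in cfg.contrasts:
        tc_s = spc.band_timecourse(succ, freqs, GAMMA_BAND)
        tc_f = spc.band_timecourse(fail, freqs, GAMMA_BAND)
        win = (rel >= -0.1) & (rel <= 0.35)
        res = sgs.cluster_permutation_1d(tc_s[:, win] - tc_f[:, win],
                                         n_perm=cfg.n_perm, alpha=cfg.alpha,
                                         seed=cfg.stats_seed + 3)
        bundle["band_timecourses"] = res
        bundle["gamma_tc"] = dict(success=tc_s, fail=tc_f, times=rel)
        summary["band_timecourses"] = _cluster_summary(res, None, rel[win])
    if "peak_latency" in cfg.contrasts:
        lat_s, lat_f = [], []
        for s in subjects:
            tc = spc.band_timecourse(
                _mean_or_nan(s["stop_epochs_norm"][s["success_mask"]]),
                freqs, GAMMA_BAND)
            lat_s.append(spc.peak_latency(tc, rel, cfg.latency_window))
            tc = spc.band_timecourse(
                _mean_or_nan(s["stop_epochs_norm"][~s["success_mask"]]),
                freqs, GAMMA_BAND)
            lat_f.append(spc.peak_latency(tc, rel, cfg.latency_window))
        lat_s, lat_f = np.array(lat_s), np.array(lat_f)
        if len(lat_s) >= 5:
            stat, p, used = sgs.paired_test(lat_s, lat_f)
        else:  # too few subjects for the normality-gated test
            stat, p, used = float("nan"), float("nan"), "none"
        summary["peak_latency"] = {
            "per_subject_success_ms": [round(v, 3) for v in lat_s],
            "per_subject_fail_ms": [round(v, 3) for v in lat_f],
            "mean_success_ms": float(lat_s.mean()),
            "mean_fail_ms": float(lat_f.mean()),
            "statistic": stat, "p": p, "test_used": used,
        }
    if "corr_extent_gamma" in cfg.contrasts:
        rhos = []
        per_subj = []
        for s in subjects:
            ext = s["kept"]["movement_extent"].to_numpy()
            rho, fhz, tsec, ci = sgs.max_corr_search(
                s["stop_epochs_norm"], freqs, rel, ext, GAMMA_BAND,
                (0.0, s["stop_window_end"]), n_boot=500, seed=cfg.stats_seed + 10)
            rhos.append(rho)
            per_subj.append(dict(subject=s["subject_id"], rho=rho, freq_hz=fhz,
                                 time_s=tsec, ci=list(ci)))
        t, p, ci = sgs.fisherz_group_test([r for r in rhos if np.isfinite(r)])
        summary["corr_extent_gamma"] = {"per_subject": per_subj,
                                        "group_t": t, "group_p": p, "group_ci": list(ci)}
    if "tap_metric_correlations" in cfg.contrasts:
        summary["tap_metric_correlations"] = _tap_metric_table(subjects, cfg)
    if "cz_theta" in cfg.contrasts:
        maps = stack(lambda s: _mean_or_nan(s.get("cz_theta_norm", np.empty((0, 1, 1)))))
        if maps is not None:
            cz_freqs = subjects[0]["cz_freqs"]
            tc = spc.band_timecourse(maps, cz_freqs, THETA_BAND)
            win = (rel >= 0.0) & (rel <= 0.35)
            summary["cz_theta"] = {
                "mean_post_cue_pct": float(tc[:, win].mean()),
                "mean_pre_cue_pct": float(tc[:, (rel >= -0.35) & (rel < 0.0)].mean()),
            }
            bundle["cz_theta_tc"] = tc
    if "ispc_change" in cfg.contrasts:
        maps = [s.get("ispc_norm") for s in subjects]
        maps = [m for m in maps if m is not None]
        if maps:
            stackv = np.stack([m.values for m in maps])
            itimes = maps[0].times
            win = np.isfinite(stackv).all(axis=(0, 1))
            res = sgs.cluster_permutation(stackv[:, :, win], n_perm=cfg.n_perm,
                                          alpha=cfg.alpha, seed=cfg.stats_seed + 4)
            bundle["ispc_change"] = res
            bundle["ispc_axes"] = (maps[0].freqs, itimes[win])
            summary["ispc_change"] = _cluster_summary(res, maps[0].freqs, itimes[win])
    return bundle


def _cluster_summary(res, freqs, times) -> dict:
    items = []
    for c in res.clusters:
        d = dict(sign=c.sign, mass=round(float(c.mass), 6),
                 p_perm=round(float(c.p_perm), 6), n_pixels=int(c.mask.sum()))
        bb = c.bbox()
        if freqs is not None and len(bb) == 2:
            d["freq_hz"] = [float(freqs[bb[0][0]]), float(freqs[bb[0][1] - 1])]
            d["time_s"] = [round(float(times[bb[1][0]]), 4),
                           round(float(times[bb[1][1] - 1]), 4)]
        else:
            d["time_s"] = [round(float(times[bb[-1][0]]), 4),
                           round(float(times[bb[-1][1] - 1]), 4)]
        items.append(d)
    items.sort(key=lambda d: (-abs(d["mass"])))
    sig = res.significant()
    return {"clusters": items, "n_significant": len(sig),
            "max_abs_mass": round(max((abs(c.mass) for c in res.clusters), default=0.0), 6)}


def _tap_metric_table(subjects, cfg: AnalysisConfig) -> dict:
    """Movement extent vs. last-tap covariates: per-subject Spearman,
    Fisher-z group t-tests and BH-FDR over the covariate family."""
    metrics = ["soundOffset", "downTime", "maxPres", "tapNr",
               "peakVelDown", "upMvmt", "peakVelUp"]
    per_subject = {m: [] for m in metrics}
    for s in subjects:
        tm = bhv.tap_metrics(s["events"], s["rec"], cfg.behavior)
        merged = tm.merge(s["kept"][["trial_idx", "movement_extent"]], on="trial_idx")
        for m in metrics:
            x = merged[m].to_numpy(dtype=float)
            y = merged["movement_extent"].to_numpy(dtype=float)
            good = np.isfinite(x) & np.isfinite(y)
            if good.sum() >= 5 and np.ptp(x[good]) > 0:
                per_subject[m].append(float(st.spearmanr(x[good], y[good]).statistic))
    rows = {}
    ps = []
    for m in metrics:
        rhos = np.array(per_subject[m], dtype=float)
        rhos = rhos[np.isfinite(rhos)]
        if len(rhos) >= 2:
            t, p, _ = sgs.fisherz_group_test(rhos)
            rows[m] = dict(rho_mean=float(rhos.mean()), rho_sd=float(rhos.std(ddof=1)),
                           t=t, p=p)
            ps.append(p)
        else:
            rows[m] = dict(rho_mean=float("nan"), rho_sd=float("nan"),
                           t=float("nan"), p=float("nan"))
            ps.append(1.0)
    adj = sgs.bh_fdr(ps)
    for m, q in zip(metrics, adj):
        rows[m]["p_fdr"] = float(q)
    return rows


def report(bundle: dict, out_dir) -> list[Path]:
    """Write the machine-readable outputs; returns the written paths.

    ``summary.json`` (sorted keys, deterministic bytes), the pooled trial
    table as TSV, and one NPY-free TSV per gamma time course.  Two runs
    with identical config and seeds produce identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    summary_path = out / "summary.json"
    summary_path.write_text(
        json.dumps(_jsonable(bundle["summary"]), sort_keys=True, indent=1) + "\n"
    )
    written.append(summary_path)
    trials = pd.concat(
        [s["trials"].assign(subject=s["subject_id"]) for s in bundle["subjects"]],
        ignore_index=True,
    )
    tpath = out / "trials.tsv"
    trials.to_csv(tpath, sep="\t", index=False, float_format="%.6g")
    written.append(tpath)
    if "gamma_tc" in bundle:
        tc = bundle["gamma_tc"]
        df = pd.DataFrame(
            dict(time_s=tc["times"],
                 gamma_success_pct=tc["success"].mean(axis=0),
                 gamma_fail_pct=tc["fail"].mean(axis=0))
        )
        gpath = out / "gamma_timecourse.tsv"
        df.to_csv(gpath, sep="\t", index=False, float_format="%.6g")
        written.append(gpath)
    return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj
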