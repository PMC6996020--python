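"""Simulate -> analyze -> compare orchestration.

``AnalysisConfig`` pins every analysis constant (band definitions,
epoch geometry, filter order, PAC bins, coherence windows, artifact and
immobility thresholds); the defaults are the study's stated values.
``run_simulate`` writes a synthetic cohort to disk, ``run_analyze``
produces one row of measures per animal, and ``run_compare`` performs
the group-level statistics, including chance-level tests, the circular
phase-lag comparison and movement-confound residualization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, connectivity, coupling, group_stats, preprocess, spectral
from .synthetic import CohortConfig, SessionBundle, generate_cohort
from . import session_io

__all__ = ["AnalysisConfig", "run_simulate", "run_analyze", "run_compare",
           "analyze_session", "summarize_comparison"]


@dataclass
class AnalysisConfig:
    theta_band: tuple = (6.0, 12.0)
    lg_band: tuple = (60.0, 120.0)
    hg_band: tuple = (140.0, 160.0)
    epoch_window_s: float = 5.0      # half-window around the crossing
    epoch_pad_s: float = 1.0         # discarded after filtering/wavelets
    filter_order: int = 400
    pac_bins: int = 30
    coherence_window_s: float = 1.0
    coherence_overlap_s: float = 0.5
    artifact_z: float = 6.0
    artifact_grad: float = 6.0
    immobility_threshold_cm_s: float = 2.0
    boxcar_ms: float = 400.0
    latency_limit_s: float = 120.0
    wavelet_cycles: float = 5.0
    freq_min: float = 1.0
    freq_max: float = 160.0
    freq_step: float = 0.5
    habituation_s: float = 100.0
    compute_habituation: bool = True
    compute_speed_fit: bool = True
    compute_mpfc_pac: bool = True

    def freq_grid(self) -> np.ndarray:
        return spectral.default_freq_grid(self.freq_min, self.freq_max,
                                          self.freq_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("theta_band", "lg_band", "hg_band"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown analysis-config fields: {sorted(unknown)}")
        d = dict(d)
        for k in ("theta_band", "lg_band", "hg_band"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# simulate

def _cohort_configs_from_doc(doc) -> dict:
    """Mapping group -> CohortConfig from a YAML document or mapping."""
    if isinstance(doc, (str, Path)):
        with open(doc) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or not doc:
        raise ValueError("cohort config must map group names to parameter maps")
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    configs = {}
    for group, params in doc.items():
        params = params or {}
        unknown = set(params) - known
        if unknown:
            raise ValueError(
                f"unknown generator field(s) under '{group}': {sorted(unknown)}")
        configs[group] = CohortConfig(**params)
        configs[group].validate()
    return configs


def run_simulate(cohort_doc, out_dir, n_animals: int, seed: int) -> Path:
    """Generate a cohort per the config document and write it to disk."""
    configs = _cohort_configs_from_doc(cohort_doc)
    bundles = generate_cohort(configs, n_animals=n_animals, seed=seed)
    return session_io.write_cohort(bundles, out_dir)


# ---------------------------------------------------------------------------
# analyze

def _circular_agg(phase_lags: list) -> tuple:
    if not phase_lags:
        return np.nan, np.nan
    mean, r = connectivity.circular_mean(np.array(phase_lags))
    return mean, r


def analyze_session(bundle: SessionBundle,
                    config: AnalysisConfig | None = None,
                    log: list | None = None) -> dict:
    """All per-animal measures for one session.

    Behavioural measures come from the full event table even when LFP
    epochs are rejected for artifacts; LFP measures average over the
    artifact-free decision-point epochs.
    """
    if config is None:
        config = AnalysisConfig()
    fs = bundle.fs_lfp
    boxcar = max(1, int(round(config.boxcar_ms / 1000.0 * bundle.fs_track)))

    row: dict = {"animal_id": bundle.animal_id, "group": bundle.group}

    # ---- behaviour -------------------------------------------------------
    outcomes = behavior.score_trials(bundle.events)
    row["alternation_rate"] = behavior.alternation_rate(outcomes)
    usable = outcomes[~outcomes["excluded"]]
    row["median_latency_s"] = float(np.median(
        np.concatenate([usable["latency_sample"], usable["latency_choice"]])))
    row["n_trials"] = int(len(outcomes))
    row["n_trials_excluded_latency"] = int(outcomes["excluded"].sum())

    if bundle.tracking is not None:
        ms = behavior.movement_summary(
            bundle.tracking, bundle.events, window=boxcar,
            threshold=config.immobility_threshold_cm_s)
        row["mean_speed_cm_s"] = ms.mean_speed
        row["immobility_proportion"] = ms.immobility_proportion
        row["predecision_immobility"] = ms.predecision_immobility
    else:
        row["mean_speed_cm_s"] = np.nan
        row["immobility_proportion"] = np.nan
        row["predecision_immobility"] = np.nan

    # ---- decision-point epochs ------------------------------------------
    freqs = config.freq_grid()
    epochs = preprocess.extract_epochs(
        bundle.lfp, fs, bundle.events,
        window_s=config.epoch_window_s, pad_s=config.epoch_pad_s)
    spectra = {ch: [] for ch in bundle.lfp}
    run_power = {ch: {"sample": [], "choice": []} for ch in bundle.lfp}
    pac_vals = {"hpc": {"lg": [], "hg": []}, "mpfc": {"lg": [], "hg": []}}
    coh_vals = {"theta": [], "lg": [], "hg": []}
    lags = []
    n_used = n_rejected = 0
    for ep in epochs:
        ep = preprocess.detrend_demean(ep)
        keep, reason = preprocess.screen_artifacts(
            ep, z_thresh=config.artifact_z, grad_thresh=config.artifact_grad)
        if log is not None:
            log.append({"animal_id": bundle.animal_id, "trial_id": ep.trial_id,
                        "run": ep.run, "kept": keep, "reason": reason})
        if not keep:
            n_rejected += 1
            continue
        n_used += 1
        for ch, x in ep.data.items():
            _, power = spectral.morlet_tfr(
                x, fs, freqs=freqs, n_cycles=config.wavelet_cycles,
                trim_s=config.epoch_pad_s)
            spec = spectral.normalized_spectrum(power, freqs)
            spectra[ch].append(spec.power)
            ts = spectral.theta_summary(spec, config.theta_band)
            run_power[ch][ep.run].append(ts.theta_power)
        for band_name, band in (("lg", config.lg_band), ("hg", config.hg_band)):
            pac_vals["hpc"][band_name].append(coupling.pac_vector_length(
                ep.data["hpc"], fs, phase_band=config.theta_band,
                amp_band=band, n_bins=config.pac_bins,
                order=config.filter_order,
                trim_s=config.epoch_pad_s).vector_length)
            if config.compute_mpfc_pac:
                pac_vals["mpfc"][band_name].append(coupling.pac_vector_length(
                    ep.data["mpfc"], fs, phase_band=config.theta_band,
                    amp_band=band, n_bins=config.pac_bins,
                    order=config.filter_order,
                    trim_s=config.epoch_pad_s).vector_length)
        trimmed = preprocess.trim_epoch(ep, config.epoch_pad_s)
        cs = connectivity.coherence_spectrum(
            trimmed.data["hpc"], trimmed.data["mpfc"], fs,
            window_s=config.coherence_window_s,
            overlap_s=config.coherence_overlap_s)
        coh_vals["theta"].append(connectivity.band_coherence(cs, config.theta_band))
        coh_vals["lg"].append(connectivity.band_coherence(cs, config.lg_band))
        coh_vals["hg"].append(connectivity.band_coherence(cs, config.hg_band))
        lag = connectivity.theta_phase_lag(
            ep.data["hpc"], ep.data["mpfc"], fs, band=config.theta_band,
            order=config.filter_order, trim_s=config.epoch_pad_s)
        if lag.reliable:
            lags.append(lag.phase_rad)
    row["n_epochs_used"] = n_used
    row["n_epochs_rejected"] = n_rejected

    for ch in bundle.lfp:
        if spectra[ch]:
            mean_spec = spectral.PowerSpectrum(
                freqs=freqs, power=np.mean(spectra[ch], axis=0))
            ts = spectral.theta_summary(mean_spec, config.theta_band)
            row[f"theta_power_{ch}"] = ts.theta_power
            row[f"theta_peak_{ch}"] = ts.peak_frequency
        else:
            row[f"theta_power_{ch}"] = row[f"theta_peak_{ch}"] = np.nan
        for run in ("sample", "choice"):
            vals = run_power[ch][run]
            row[f"theta_power_{ch}_{run}"] = float(np.mean(vals)) if vals else np.nan
    for band_name in ("lg", "hg"):
        row[f"pac_{band_name}_hpc"] = (float(np.mean(pac_vals["hpc"][band_name]))
                                       if pac_vals["hpc"][band_name] else np.nan)
        if config.compute_mpfc_pac:
            row[f"pac_{band_name}_mpfc"] = (
                float(np.mean(pac_vals["mpfc"][band_name]))
                if pac_vals["mpfc"][band_name] else np.nan)
    for band_name in ("theta", "lg", "hg"):
        row[f"coherence_{band_name}"] = (float(np.mean(coh_vals[band_name]))
                                         if coh_vals[band_name] else np.nan)
    row["phase_lag_rad"], row["phase_lag_resultant"] = _circular_agg(lags)
    row["time_lag_s"] = (row["phase_lag_rad"]
                         / connectivity.THETA_CENTER_ANGULAR_FREQ
                         if np.isfinite(row["phase_lag_rad"]) else np.nan)

    # ---- movement-conditioned theta and the speed-frequency fit ----------
    if config.compute_speed_fit and bundle.tracking is not None:
        xf = spectral.bandpass_zero_phase(
            bundle.lfp["hpc"], config.theta_band, fs, config.filter_order)
        xf = spectral.trim_edges(xf, fs, 1.0)
        amp, _, inst_f, _ = spectral.analytic_features(xf, fs)
        n = len(bundle.lfp["hpc"])
        t_lfp = (np.arange(n) / fs)[int(fs):-int(fs)]
        sm = behavior.smooth_speed(bundle.tracking["speed_cm_s"].to_numpy(),
                                   boxcar)
        speed = np.interp(t_lfp, bundle.tracking["time_s"].to_numpy(), sm)
        moving = speed >= config.immobility_threshold_cm_s
        if moving.any():
            row["theta_power_hpc_move"] = float(np.mean(amp[moving] ** 2))
        else:
            row["theta_power_hpc_move"] = np.nan
        try:
            fit = spectral.speed_frequency_fit(inst_f, speed, moving)
            row["speed_freq_intercept"] = fit.intercept
            row["speed_freq_slope"] = fit.slope
        except ValueError:
            row["speed_freq_intercept"] = row["speed_freq_slope"] = np.nan

    # ---- habituation segment (pre-trial, same spectral pipeline) ---------
    if config.compute_habituation:
        n_hab = int(config.habituation_s * fs)
        if len(bundle.lfp["hpc"]) >= n_hab and n_hab >= 4 * fs:
            for ch in bundle.lfp:
                seg = bundle.lfp[ch][:n_hab]
                seg = seg - np.polyval(np.polyfit(np.arange(n_hab), seg, 1),
                                       np.arange(n_hab))
                _, power = spectral.morlet_tfr(
                    seg, fs, freqs=freqs, n_cycles=config.wavelet_cycles,
                    trim_s=config.epoch_pad_s)
                ts = spectral.theta_summary(
                    spectral.normalized_spectrum(power, freqs), config.theta_band)
                row[f"theta_power_hab_{ch}"] = ts.theta_power
                row[f"theta_peak_hab_{ch}"] = ts.peak_frequency
    return row


def run_analyze(cohort, config: AnalysisConfig | None = None,
                log: list | None = None) -> pd.DataFrame:
    """One row of measures per animal; ``cohort`` is a path or bundles."""
    if isinstance(cohort, (str, Path)):
        cohort = session_io.read_cohort(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    rows = [analyze_session(b, config, log=log) for b in cohort]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compare

_ID_COLS = {"animal_id", "group", "n_trials", "n_epochs_used",
            "n_epochs_rejected", "n_trials_excluded_latency"}
_MOVEMENT_SENSITIVE = ("coherence_theta", "pac_hg_hpc", "pac_lg_hpc")


def run_compare(measures: pd.DataFrame, config: AnalysisConfig | None = None,
                group_col: str = "group", alpha: float = 0.05) -> dict:
    """Group statistics over a per-animal measures table.

    Produces a normality-gated comparison per measure, per-group
    chance-level tests for the alternation rate, a Watson-Williams test
    on phase lags, and — when pre-decision immobility differs
    significantly between groups — residualized comparisons of the
    movement-sensitive coupling measures.
    """
    groups = list(dict.fromkeys(measures[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if len(groups) > 2:
        raise ValueError("pairwise comparison expects exactly 2 groups")
    ga = measures[measures[group_col] == groups[0]]
    gb = measures[measures[group_col] == groups[1]]

    report: dict = {"groups": groups, "comparisons": {}, "chance_tests": {},
                    "residualized": {}, "phase_lag": None, "alpha": alpha}

    numeric = [c for c in measures.columns
               if c not in _ID_COLS and c != group_col
               and pd.api.types.is_numeric_dtype(measures[c])]
    for col in numeric:
        a = ga[col].dropna().to_numpy()
        b = gb[col].dropna().to_numpy()
        if len(a) < 3 or len(b) < 3:
            continue
        if col in ("phase_lag_rad", "time_lag_s", "phase_lag_resultant"):
            continue   # circular / derived quantities handled separately
        comp = group_stats.compare_groups(a, b, measure=col,
                                          groups=tuple(groups))
        report["comparisons"][col] = comp.to_dict()

    if "alternation_rate" in measures.columns:
        for g, gdf in ((groups[0], ga), (groups[1], gb)):
            rates = gdf["alternation_rate"].dropna().to_numpy()
            if len(rates) >= 3:
                ct = group_stats.chance_test(rates)
                report["chance_tests"][g] = {
                    "p_value": ct.p_value, "statistic": ct.statistic,
                    "mean_rate": float(np.mean(rates))}

    if "phase_lag_rad" in measures.columns:
        la = ga["phase_lag_rad"].dropna().to_numpy()
        lb = gb["phase_lag_rad"].dropna().to_numpy()
        if len(la) >= 5 and len(lb) >= 5:
            ww = group_stats.watson_williams(la, lb)
            report["phase_lag"] = {
                "f_statistic": ww.f_statistic, "p_value": ww.p_value,
                "pooled_resultant": ww.pooled_resultant,
                "valid": ww.valid, "flags": ww.flags,
                "circular_means": [connectivity.circular_mean(la)[0],
                                   connectivity.circular_mean(lb)[0]]}

    imm = report["comparisons"].get("predecision_immobility")
    movement_differs = imm is not None and imm["p_value"] < alpha
    report["movement_differs"] = bool(movement_differs)
    if movement_differs:
        cov = measures["predecision_immobility"].to_numpy()
        labels = measures[group_col].to_numpy()
        for col in _MOVEMENT_SENSITIVE:
            if col not in measures.columns:
                continue
            vals = measures[col].to_numpy()
            ok = np.isfinite(vals) & np.isfinite(cov)
            if ok.sum() < 6:
                continue
            rc = group_stats.residualize(vals[ok], cov[ok], labels[ok],
                                         measure=col)
            report["residualized"][col] = {
                "slope": rc.slope, "intercept": rc.intercept,
                "comparison": rc.comparison.to_dict()}
    return report


def summarize_comparison(report: dict) -> str:
    """Human-readable rendering of a ``run_compare`` report."""
    a, b = report["groups"]
    lines = [f"Group comparison: {a} vs {b} (alpha={report['alpha']})", ""]
    for name, c in sorted(report["comparisons"].items()):
        star = "*" if c["p_value"] < report["alpha"] else " "
        lines.append(
            f"{star} {name:28s} {c['test']:>13s}  stat={c['statistic']:8.3f}"
            f"  p={c['p_value']:.4f}  means={c['mean'][0]:.3f}/{c['mean'][1]:.3f}")
    if report["chance_tests"]:
        lines.append("")
        for g, ct in report["chance_tests"].items():
            verdict = ("above/below chance" if ct["p_value"] < report["alpha"]
                       else "at chance")
            lines.append(f"  alternation vs 0.5 [{g}]: mean={ct['mean_rate']:.3f}"
                         f" p={ct['p_value']:.4f} ({verdict})")
    if report["phase_lag"]:
        pl = report["phase_lag"]
        lines.append("")
        lines.append(
            f"  phase lag (Watson-Williams): F={pl['f_statistic']:.3f}"
            f" p={pl['p_value']:.4f} means="
            f"{pl['circular_means'][0]:.3f}/{pl['circular_means'][1]:.3f} rad"
            + ("" if pl["valid"] else "  [low concentration]"))
    if report["residualized"]:
        lines.append("")
        for name, rc in report["residualized"].items():
            c = rc["comparison"]
            star = "*" if c["p_value"] < report["alpha"] else " "
            lines.append(f"{star} residualized {name:20s} p={c['p_value']:.4f}")
    return "\n".join(lines)


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
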