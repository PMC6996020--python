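"""Qualitative replication on simulated cohorts.

Two cohort contrasts mirror the study's headline findings:

* Dp1Tyb vs WT — lower peak theta frequency (8.63 vs 9.02 Hz group
  means), stronger theta-HG coupling, higher hippocampal-mPFC theta
  coherence, longer trial latencies; theta-LG coupling unchanged.
* Dp10Yey vs WT — alternation at chance (vs above chance in WT) and
  weaker theta-LG coupling; theta frequency and theta-HG coupling
  unchanged.

``replication_pattern`` generates both contrasts at n animals per
group, extracts the relevant measures with the package's estimators on
a 60-s continuous recording per animal, runs the group statistics, and
reports whether the expected pattern of significant / non-significant
comparisons is reproduced.  Problem sizes (60 s of LFP, 10 trials per
animal) are scaled for fast simulation studies.
"""

from __future__ import annotations

import numpy as np

from . import behavior, connectivity, coupling, group_stats, spectral
from .synthetic import CohortConfig, constant_speed, derive_seed, \
    generate_behavior, generate_lfp_pair

__all__ = ["dp1tyb_contrast_configs", "dp10yey_contrast_configs",
           "quick_animal_measures", "replication_pattern"]

ALPHA = 0.05


def dp1tyb_contrast_configs() -> dict:
    wt = CohortConfig(theta_intercept=9.02, theta_slope=0.0,
                      pac_depth_lg=0.3, pac_depth_hg=0.2,
                      target_coherence=0.70, latency_log_mean=1.0,
                      alternation_prob=0.75, n_trials=10)
    dp1tyb = wt.replace(theta_intercept=8.63, pac_depth_hg=0.4,
                        target_coherence=0.85, latency_log_mean=1.6)
    return {"WT": wt, "Dp1Tyb": dp1tyb}


def dp10yey_contrast_configs() -> dict:
    wt = CohortConfig(theta_intercept=9.02, theta_slope=0.0,
                      pac_depth_lg=0.3, pac_depth_hg=0.2,
                      target_coherence=0.70, latency_log_mean=1.0,
                      alternation_prob=0.75, n_trials=10)
    dp10yey = wt.replace(alternation_prob=0.5, pac_depth_lg=0.15)
    return {"WT": wt, "Dp10Yey": dp10yey}


def quick_animal_measures(config: CohortConfig, seed: int,
                          lfp_duration_s: float = 60.0) -> dict:
    """The measures the replication checks need, for one animal."""
    fs = config.fs_lfp
    lfp, _ = generate_lfp_pair(config, constant_speed(12.0, lfp_duration_s),
                               lfp_duration_s, seed=seed)
    freqs = np.arange(4.0, 16.5, 0.5)
    _, power = spectral.morlet_tfr(lfp["hpc"], fs, freqs=freqs)
    peak = spectral.theta_summary(
        spectral.normalized_spectrum(power, freqs)).peak_frequency
    pac_lg = coupling.pac_vector_length(lfp["hpc"], fs,
                                        amp_band=(60, 120)).vector_length
    pac_hg = coupling.pac_vector_length(lfp["hpc"], fs,
                                        amp_band=(140, 160)).vector_length
    coh = connectivity.band_coherence(
        connectivity.coherence_spectrum(lfp["hpc"], lfp["mpfc"], fs))
    events, _, _ = generate_behavior(config, seed)
    outcomes = behavior.score_trials(events)
    usable = outcomes[~outcomes["excluded"]]
    latency = float(np.median(np.concatenate(
        [usable["latency_sample"], usable["latency_choice"]])))
    return {"theta_peak": peak, "pac_lg": pac_lg, "pac_hg": pac_hg,
            "coherence_theta": coh,
            "alternation_rate": behavior.alternation_rate(outcomes),
            "median_latency": latency}


def _group_measures(configs: dict, n_per_group: int, seed: int) -> dict:
    out = {}
    for gi, (group, cfg) in enumerate(configs.items()):
        rows = [quick_animal_measures(cfg, derive_seed(seed, 100 + gi, ai))
                for ai in range(n_per_group)]
        out[group] = {k: np.array([r[k] for r in rows]) for k in rows[0]}
    return out


def replication_pattern(seed: int, n_per_group: int = 10,
                        alpha: float = ALPHA) -> dict:
    """Check the expected pattern of (non-)significant comparisons.

    Returns a mapping check-name -> bool plus ``"all"``.
    """
    def p2(a, b):
        return group_stats.compare_groups(a, b).p_value

    checks = {}

    m = _group_measures(dp1tyb_contrast_configs(), n_per_group, seed)
    wt, mut = m["WT"], m["Dp1Tyb"]
    checks["dp1tyb_theta_freq_lower"] = (
        p2(wt["theta_peak"], mut["theta_peak"]) < alpha
        and mut["theta_peak"].mean() < wt["theta_peak"].mean())
    checks["dp1tyb_pac_hg_higher"] = (
        p2(wt["pac_hg"], mut["pac_hg"]) < alpha
        and mut["pac_hg"].mean() > wt["pac_hg"].mean())
    checks["dp1tyb_coherence_higher"] = (
        p2(wt["coherence_theta"], mut["coherence_theta"]) < alpha
        and mut["coherence_theta"].mean() > wt["coherence_theta"].mean())
    checks["dp1tyb_latency_longer"] = (
        p2(wt["median_latency"], mut["median_latency"]) < alpha
        and mut["median_latency"].mean() > wt["median_latency"].mean())
    checks["dp1tyb_pac_lg_unchanged"] = p2(wt["pac_lg"], mut["pac_lg"]) >= alpha

    m = _group_measures(dp10yey_contrast_configs(), n_per_group,
                        derive_seed(seed, 7))
    wt, mut = m["WT"], m["Dp10Yey"]
    checks["dp10yey_wt_above_chance"] = (
        group_stats.chance_test(wt["alternation_rate"]).p_value < alpha
        and wt["alternation_rate"].mean() > 0.5)
    checks["dp10yey_alternation_at_chance"] = (
        group_stats.chance_test(mut["alternation_rate"]).p_value >= alpha)
    checks["dp10yey_pac_lg_lower"] = (
        p2(wt["pac_lg"], mut["pac_lg"]) < alpha
        and mut["pac_lg"].mean() < wt["pac_lg"].mean())
    checks["dp10yey_pac_hg_unchanged"] = p2(wt["pac_hg"], mut["pac_hg"]) >= alpha
    checks["dp10yey_theta_freq_unchanged"] = (
        p2(wt["theta_peak"], mut["theta_peak"]) >= alpha)

    checks["all"] = all(checks.values())
    return checks
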