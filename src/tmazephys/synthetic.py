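"""Synthetic T-maze session generator.

Produces two-channel (hippocampus, mPFC) LFP plus trial events and a
tracking/speed trace with the statistical structure the downstream
analysis assumes, so that every stage of the pipeline can be validated
by parameter recovery:

* theta (6-12 Hz) as a frequency-modulated sinusoid whose instantaneous
  frequency follows ``theta_intercept + theta_slope * speed``;
* two gamma carriers (band-limited Gaussian noise in 60-120 Hz and
  140-160 Hz) whose envelopes are modulated by hippocampal theta phase
  with depth ``k`` (envelope ``1 + k*cos(phase)``), hippocampus only;
* a shared narrowband theta background calibrated so that the
  hippocampus-mPFC magnitude-squared coherence across the theta band
  approximates ``target_coherence``, with the mPFC copy phase-delayed
  by ``phase_lead`` radians (hippocampus leads);
* 1/f background noise, independent per channel;
* spontaneous-alternation behaviour with controllable alternation
  probability, log-normal run latencies and immobile bouts.

Every generative parameter is recorded in the returned bundle so tests
can compare recovered quantities against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SessionBundle",
    "generate_lfp_pair",
    "generate_behavior",
    "generate_session",
    "generate_cohort",
    "constant_speed",
]

THETA_BAND = (6.0, 12.0)
LOW_GAMMA_BAND = (60.0, 120.0)
HIGH_GAMMA_BAND = (140.0, 160.0)
ACQUISITION_BAND = (0.2, 160.0)  # hardware bandpass of the transmitter


@dataclass
class CohortConfig:
    """Generative parameters for one simulated genotype group.

    Amplitudes are in microvolts, frequencies in Hz, times in seconds.
    ``pac_depth_*`` are the envelope modulation depths ``k`` in [0, 1];
    the vector-length coupling measure of such an envelope is ``k/2``.
    """

    theta_intercept: float = 9.0      # Hz at zero running speed
    theta_slope: float = 0.02         # Hz per cm/s
    theta_amp: float = 100.0          # µV
    pac_depth_lg: float = 0.3         # 60-120 Hz depth, hippocampus only
    pac_depth_hg: float = 0.3         # 140-160 Hz depth, hippocampus only
    gamma_amp_lg: float = 15.0        # µV RMS of the low-gamma carrier
    gamma_amp_hg: float = 8.0         # µV RMS of the high-gamma carrier
    target_coherence: float = 0.7     # theta-band msc, hpc vs mpfc
    phase_lead: float = 1.0           # rad, hippocampus leads mPFC
    noise_exponent: float = 1.0       # 1/f^exponent background slope
    noise_amp: float = 40.0           # µV total std of the background
    alternation_prob: float = 0.75
    latency_log_mean: float = 1.2     # log-seconds (median ~3.3 s)
    latency_log_sd: float = 0.4
    immobility_frac: float = 0.15     # fraction of pre-decision time
    n_trials: int = 10
    habituation_s: float = 100.0      # quiet period before the first trial
    inter_run_interval_s: float = 20.0
    choice_theta_gain: float = 1.0    # theta amplitude gain on choice runs
    fs_lfp: float = 512.0
    fs_track: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("pac_depth_lg", "pac_depth_hg", "alternation_prob",
                     "immobility_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not 0.0 <= self.target_coherence <= 0.99:
            raise ValueError("target_coherence must lie in [0, 0.99]")
        if not -np.pi < self.phase_lead <= np.pi:
            raise ValueError("phase_lead must lie in (-pi, pi]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.fs_lfp <= 0 or self.fs_track <= 0:
            raise ValueError("sampling rates must be positive")

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SessionBundle:
    """One animal-session: LFP pair, event table, tracking and truth."""

    animal_id: str
    group: str
    lfp: dict                    # {"hpc": ndarray, "mpfc": ndarray} in µV
    fs_lfp: float
    events: pd.DataFrame         # trial_id, run, door_raise_s, decision_cross_s, arm
    tracking: pd.DataFrame | None  # time_s, speed_cm_s at fs_track
    fs_track: float
    truth: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.lfp["hpc"]) / self.fs_lfp

    def validate(self) -> None:
        n = {ch: len(x) for ch, x in self.lfp.items()}
        if len(set(n.values())) != 1:
            raise ValueError(f"LFP channels differ in length: {n}")
        dur = self.duration_s
        ev = self.events
        if (ev["decision_cross_s"] <= ev["door_raise_s"]).any():
            bad = ev.loc[ev["decision_cross_s"] <= ev["door_raise_s"], "trial_id"]
            raise ValueError(
                f"decision crossing precedes door raise in trial(s) {list(bad)}")
        if (ev["decision_cross_s"] > dur).any() or (ev["door_raise_s"] < 0).any():
            bad = ev.loc[ev["decision_cross_s"] > dur, "trial_id"]
            raise ValueError(
                f"event times outside recording duration in trial(s) {list(bad)}")
        for _, g in ev.groupby("trial_id"):
            t = np.concatenate([g["door_raise_s"].to_numpy(),
                                g["decision_cross_s"].to_numpy()])
            # within a trial: sample door < sample cross < choice door < choice cross
            order = g.sort_values("door_raise_s")
            times = np.ravel(order[["door_raise_s", "decision_cross_s"]].to_numpy())
            if not np.all(np.diff(times) > 0):
                raise ValueError(
                    f"event times not strictly increasing in trial {g['trial_id'].iloc[0]}")


# ---------------------------------------------------------------------------
# seeding helpers

def _child_seed(*keys: int) -> np.random.SeedSequence:
    """Deterministic counter-based sub-stream derivation."""
    return np.random.SeedSequence([int(k) & 0x7FFFFFFF for k in keys])


def derive_seed(*keys: int) -> int:
    """A reproducible integer seed (< 2**31) derived from the given keys."""
    return int(_child_seed(*keys).generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# spectral-domain noise synthesis

def _spectral_noise(n: int, fs: float, amp_profile: np.ndarray,
                    rng: np.random.Generator,
                    phase_rotation: float = 0.0,
                    coefficients: np.ndarray | None = None):
    """Gaussian noise with per-frequency rfft coefficient std ``amp_profile``.

    Returns ``(signal, coefficients)``.  Passing ``coefficients`` back in
    reuses a previous draw (for shared components across channels);
    ``phase_rotation`` rotates every positive-frequency coefficient by
    ``-phase_rotation`` radians, i.e. a constant phase delay.
    """
    m = n // 2 + 1
    if coefficients is None:
        z = (rng.standard_normal(m) + 1j * rng.standard_normal(m)) / np.sqrt(2.0)
        coefficients = amp_profile * z
        coefficients[0] = 0.0
    coef = coefficients
    if phase_rotation != 0.0:
        coef = coef * np.exp(-1j * phase_rotation)
    x = np.fft.irfft(coef, n) * 1.0
    return x, coefficients


def _profile_band(freqs: np.ndarray, band: tuple, exponent: float = 0.0):
    lo, hi = band
    prof = np.zeros_like(freqs)
    sel = (freqs >= lo) & (freqs <= hi)
    with np.errstate(divide="ignore"):
        prof[sel] = np.where(freqs[sel] > 0, freqs[sel] ** (-exponent / 2.0), 0.0)
    return prof


def _profile_variance(n: int, amp_profile: np.ndarray) -> float:
    """Expected time-domain variance of ``_spectral_noise`` output."""
    return 2.0 * np.sum(amp_profile[1:] ** 2) / n ** 2


def _scale_to_std(n: int, amp_profile: np.ndarray, std: float) -> np.ndarray:
    var = _profile_variance(n, amp_profile)
    if var <= 0 or std <= 0:
        return np.zeros_like(amp_profile)
    return amp_profile * (std / np.sqrt(var))


def _band_power(n: int, freqs: np.ndarray, amp_profile: np.ndarray,
                band: tuple) -> float:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return 2.0 * np.sum(amp_profile[sel] ** 2) / n ** 2


# ---------------------------------------------------------------------------
# LFP generation

def constant_speed(value: float, duration: float, fs_track: float = 25.0):
    """A flat speed trace, handy for fixed-frequency theta."""
    n = int(round(duration * fs_track)) + 1
    return pd.DataFrame({
        "time_s": np.arange(n) / fs_track,
        "speed_cm_s": np.full(n, float(value)),
    })


def _upsample_speed(tracking: pd.DataFrame, n: int, fs: float) -> np.ndarray:
    t = np.arange(n) / fs
    return np.interp(t, tracking["time_s"].to_numpy(),
                     tracking["speed_cm_s"].to_numpy())


def generate_lfp_pair(config: CohortConfig, speed_trace: pd.DataFrame,
                      duration: float, seed: int,
                      theta_gain_windows: Sequence[tuple] = ()):
    """Generate an aligned (hippocampus, mPFC) LFP pair.

    Parameters
    ----------
    speed_trace : DataFrame with ``time_s`` and ``speed_cm_s`` covering
        ``duration`` (sampled at the tracking rate).
    theta_gain_windows : optional ``(t0, t1, gain)`` triples; the theta
        component amplitude is multiplied by ``gain`` inside each window
        (used to emulate run-specific theta power changes).

    Returns
    -------
    (lfp, info) where ``lfp = {"hpc": ..., "mpfc": ...}`` in µV and
    ``info`` records the realized theta phase and calibration details.

    Notes
    -----
    Theta-band coherence is calibrated from the closed form
    ``msc = P_s**2 / ((P_s + P_i1) (P_s + P_i2))`` applied per frequency
    bin: a shared 6-12 Hz background with the same spectral shape as the
    independent 1/f noise is added to both channels with power ratio
    ``c = sqrt(C) / (1 - sqrt(C))`` relative to the in-band noise, which
    makes the in-band coherence approximately flat at ``C``.
    """
    config.validate()
    if duration < 4.0:
        raise ValueError("duration must be >= 4 s (filter transients)")
    fs = config.fs_lfp
    n = int(round(duration * fs))
    if speed_trace["time_s"].iloc[-1] < duration - 1.0 / config.fs_track - 1e-9:
        raise ValueError("speed trace does not cover the requested duration")

    rng_theta = np.random.default_rng(_child_seed(seed, 11))
    rng_noise1 = np.random.default_rng(_child_seed(seed, 12))
    rng_noise2 = np.random.default_rng(_child_seed(seed, 13))
    rng_shared = np.random.default_rng(_child_seed(seed, 14))
    rng_gamma1 = np.random.default_rng(_child_seed(seed, 15))
    rng_gamma2 = np.random.default_rng(_child_seed(seed, 16))

    freqs = np.fft.rfftfreq(n, 1.0 / fs)

    # --- theta: FM sinusoid driven by running speed -----------------------
    v = _upsample_speed(speed_trace, n, fs)
    f_inst = config.theta_intercept + config.theta_slope * v
    phi0 = rng_theta.uniform(0.0, 2.0 * np.pi)
    phase = phi0 + 2.0 * np.pi * np.cumsum(f_inst) / fs
    gain = np.ones(n)
    for (t0, t1, g) in theta_gain_windows:
        i0, i1 = max(0, int(t0 * fs)), min(n, int(t1 * fs))
        gain[i0:i1] = g
    theta_hpc = config.theta_amp * gain * np.cos(phase)
    theta_mpfc = config.theta_amp * gain * np.cos(phase - config.phase_lead)

    # --- independent 1/f background ---------------------------------------
    prof_noise = _scale_to_std(
        n, _profile_band(freqs, ACQUISITION_BAND, config.noise_exponent),
        config.noise_amp)
    n1, _ = _spectral_noise(n, fs, prof_noise, rng_noise1)
    n2, _ = _spectral_noise(n, fs, prof_noise, rng_noise2)

    # --- shared theta-band background, coherence-calibrated ---------------
    C = config.target_coherence
    if C > 0:
        c = np.sqrt(C) / (1.0 - np.sqrt(C))
        prof_shared = np.sqrt(c) * np.where(
            (freqs >= THETA_BAND[0]) & (freqs <= THETA_BAND[1]), prof_noise, 0.0)
    else:
        c = 0.0
        prof_shared = np.zeros_like(freqs)
    b_hpc, coef_b = _spectral_noise(n, fs, prof_shared, rng_shared)
    b_mpfc, _ = _spectral_noise(n, fs, prof_shared, rng_shared,
                                phase_rotation=config.phase_lead,
                                coefficients=coef_b)

    # --- gamma carriers ----------------------------------------------------
    def carrier(band, amp, rng):
        prof = _scale_to_std(n, _profile_band(freqs, band), amp)
        g, _ = _spectral_noise(n, fs, prof, rng)
        return g

    modulation_lg = 1.0 + config.pac_depth_lg * np.cos(phase)
    modulation_hg = 1.0 + config.pac_depth_hg * np.cos(phase)
    lg_hpc = carrier(LOW_GAMMA_BAND, config.gamma_amp_lg, rng_gamma1) * modulation_lg
    hg_hpc = carrier(HIGH_GAMMA_BAND, config.gamma_amp_hg, rng_gamma1) * modulation_hg
    lg_mpfc = carrier(LOW_GAMMA_BAND, config.gamma_amp_lg, rng_gamma2)
    hg_mpfc = carrier(HIGH_GAMMA_BAND, config.gamma_amp_hg, rng_gamma2)

    hpc = theta_hpc + b_hpc + lg_hpc + hg_hpc + n1
    mpfc = theta_mpfc + b_mpfc + lg_mpfc + hg_mpfc + n2

    info = {
        "theta_phase": phase,
        "inst_frequency": f_inst,
        "shared_to_noise_ratio": c,
        "inband_noise_power": _band_power(n, freqs, prof_noise, THETA_BAND),
        "inband_shared_power": _band_power(n, freqs, prof_shared, THETA_BAND),
    }
    return {"hpc": hpc, "mpfc": mpfc}, info


def generate_envelope_model(k: float, duration: float, fs: float = 512.0,
                            theta_freq: float = 9.0,
                            carrier_band: tuple = (76.0, 104.0),
                            theta_amp: float = 100.0,
                            carrier_amp: float = 15.0,
                            seed: int = 0) -> np.ndarray:
    """The pure envelope model: theta tone + carrier with envelope 1+k*cos(phase).

    The carrier band is inset from the analysis band (default 76-104 Hz
    inside 60-120 Hz) so that the modulation sidebands at +-theta_freq
    stay inside the analysis bandpass and the vector-length measure of
    the signal equals ``k/2`` exactly in the long-signal limit.  This
    is the oracle signal for PAC estimator checks; the full session
    generator instead uses carriers spanning the whole gamma band,
    whose measured coupling is attenuated by sideband truncation (see
    the methods note).
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError("modulation depth k must lie in [0, 1]")
    n = int(round(duration * fs))
    rng = np.random.default_rng(_child_seed(seed, 31))
    t = np.arange(n) / fs
    phase = 2.0 * np.pi * theta_freq * t
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    prof = _scale_to_std(n, _profile_band(freqs, carrier_band), carrier_amp)
    carrier, _ = _spectral_noise(n, fs, prof, rng)
    return theta_amp * np.cos(phase) + carrier * (1.0 + k * np.cos(phase))


# ---------------------------------------------------------------------------
# behaviour generation

def _ou_speed(n: int, dt: float, rng: np.random.Generator,
              mean: float = 12.0, theta: float = 0.5, sigma: float = 8.0):
    """Clipped Ornstein-Uhlenbeck running-speed process (cm/s)."""
    v = np.empty(n)
    v[0] = max(mean + sigma * rng.standard_normal() * 0.5, 0.0)
    e = np.exp(-theta * dt)
    s = sigma * np.sqrt((1.0 - e ** 2) / (2.0 * theta))
    for i in range(1, n):
        v[i] = mean + (v[i - 1] - mean) * e + s * rng.standard_normal()
    return np.clip(v, 0.0, None)


def generate_behavior(config: CohortConfig, seed: int):
    """Generate the trial event table and tracking trace for one session.

    Each trial comprises a sample run and a choice run; the choice arm
    differs from the sample arm with probability ``alternation_prob``.
    Run latencies are log-normal; immobile bouts (speed < 2 cm/s) are
    inserted into each pre-decision interval so that they occupy
    approximately ``immobility_frac`` of it.

    Returns ``(events, tracking, duration_s)``.
    """
    config.validate()
    rng = np.random.default_rng(_child_seed(seed, 21))
    fs_t = config.fs_track

    rows = []
    cursor = config.habituation_s
    for trial in range(config.n_trials):
        sample_arm = "L" if rng.random() < 0.5 else "R"
        alternate = rng.random() < config.alternation_prob
        choice_arm = ({"L": "R", "R": "L"}[sample_arm] if alternate else sample_arm)
        for run, arm in (("sample", sample_arm), ("choice", choice_arm)):
            latency = float(np.clip(
                rng.lognormal(config.latency_log_mean, config.latency_log_sd),
                0.75, 200.0))
            door = cursor
            cross = door + latency
            rows.append({"trial_id": trial, "run": run,
                         "door_raise_s": round(door, 3),
                         "decision_cross_s": round(cross, 3),
                         "arm": arm})
            cursor = cross + config.inter_run_interval_s
    duration = cursor + 10.0
    events = pd.DataFrame(rows)

    n_track = int(round(duration * fs_t)) + 1
    speed = _ou_speed(n_track, 1.0 / fs_t, rng)
    t = np.arange(n_track) / fs_t

    # immobile bouts within each pre-decision interval
    for _, ev in events.iterrows():
        lat = ev["decision_cross_s"] - ev["door_raise_s"]
        bout = config.immobility_frac * lat
        if bout <= 0:
            # ensure the animal is actually moving pre-decision
            sel = (t >= ev["door_raise_s"]) & (t < ev["decision_cross_s"])
            speed[sel] = np.clip(speed[sel], 4.0, None)
            continue
        start = ev["door_raise_s"] + rng.uniform(0.0, lat - bout)
        sel_move = (t >= ev["door_raise_s"]) & (t < ev["decision_cross_s"])
        speed[sel_move] = np.clip(speed[sel_move], 4.0, None)
        sel = (t >= start) & (t < start + bout)
        speed[sel] = rng.uniform(0.0, 1.0, sel.sum())

    tracking = pd.DataFrame({"time_s": t, "speed_cm_s": speed})
    return events, tracking, duration


# ---------------------------------------------------------------------------
# full sessions and cohorts

def generate_session(config: CohortConfig, animal_id: str = "sim0",
                     group: str = "sim", seed: int | None = None) -> SessionBundle:
    """Generate one complete session bundle (behaviour + LFP + truth)."""
    if seed is None:
        seed = config.seed
    events, tracking, duration = generate_behavior(config, seed)
    gain_windows = []
    if config.choice_theta_gain != 1.0:
        for _, ev in events[events["run"] == "choice"].iterrows():
            gain_windows.append((ev["door_raise_s"] - 6.0,
                                 ev["decision_cross_s"] + 6.0,
                                 config.choice_theta_gain))
    lfp, info = generate_lfp_pair(config, tracking, duration, seed,
                                  theta_gain_windows=gain_windows)
    truth = {"config": config.to_dict(), "seed": seed,
             "shared_to_noise_ratio": info["shared_to_noise_ratio"]}
    bundle = SessionBundle(animal_id=animal_id, group=group, lfp=lfp,
                           fs_lfp=config.fs_lfp, events=events,
                           tracking=tracking, fs_track=config.fs_track,
                           truth=truth)
    bundle.validate()
    return bundle


def generate_cohort(configs: Mapping[str, CohortConfig], n_animals: int,
                    seed: int) -> list[SessionBundle]:
    """Generate ``n_animals`` sessions per group with independent seeds."""
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    groups = list(configs)
    if not groups:
        raise ValueError("no groups given")
    if len(set(groups)) != len(groups):
        raise ValueError("duplicate group names")
    bundles = []
    for gi, group in enumerate(groups):
        for ai in range(n_animals):
            s = derive_seed(seed, gi, ai)
            bundles.append(generate_session(
                configs[group], animal_id=f"{group}_{ai:02d}",
                group=group, seed=s))
    return bundles
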