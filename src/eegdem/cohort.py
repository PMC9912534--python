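"""Synthetic cohort generator: subject metadata plus raw resting-state EEG.

A single latent *disease severity* per subject (group mean + jitter, on a
0-1 scale from healthy to advanced dementia) drives both sides of the data:

* the EEG signal model — posterior theta amplitude rises, slow-wave power
  grows (lowering Hjorth mobility) and posterior alpha amplitude falls as
  severity increases;
* the clinical table — group means and SDs of age, MMSE, MoCA, disease
  course and CSF analytes follow configurable per-group distributions, and a
  set of *couplings* plants target Pearson correlations between EEG
  quantities and clinical columns within the combined MCI+AD pool.

Couplings are realized analytically: for a coupled column the within-group
loading on the EEG pathway variable is solved (given the configured group
means/SDs and the pathway's simulated pooled moments) so that the pooled
MCI+AD correlation equals the configured target in expectation. With
strongly separated group means the solved within-group loading can take
either sign; it is whatever value makes the pooled correlation come out
right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .containers import Recording
from .montage import MONTAGE_16, POSTERIOR_CHANNELS

GROUPS = ("HC", "MCI", "AD", "DLB", "FTD", "VCI")

#: Per-group clinical distributions: mean/SD pairs (fractions for sex/APOE).
#: ADO is derived as age - COD, so only COD has its own distribution.
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, tuple[float, float] | float | None]] = {
    "HC":  {"age": (63.85, 8.20), "male_fraction": 0.4228,
            "MMSE": (28.62, 1.09), "MoCA": None, "COD": None,
            "abeta42": None, "abeta40": None, "t_tau": None, "p_tau": None,
            "apoe_e4_fraction": None},
    "MCI": {"age": (64.77, 9.30), "male_fraction": 0.3598,
            "MMSE": (22.70, 4.48), "MoCA": (16.22, 5.01), "COD": (1.98, 1.91),
            "abeta42": (587.46, 439.59), "abeta40": (8572.50, 6108.20),
            "t_tau": (316.58, 289.84), "p_tau": (76.79, 51.92),
            "apoe_e4_fraction": 0.4386},
    "AD":  {"age": (64.60, 9.75), "male_fraction": 0.3667,
            "MMSE": (11.63, 6.28), "MoCA": (7.02, 4.87), "COD": (2.90, 2.49),
            "abeta42": (408.29, 217.28), "abeta40": (8286.91, 6000.22),
            "t_tau": (506.21, 316.95), "p_tau": (104.39, 51.94),
            "apoe_e4_fraction": 0.52},
    "VCI": {"age": (67.18, 9.80), "male_fraction": 0.5439,
            "MMSE": (13.51, 6.98), "MoCA": (7.74, 4.86), "COD": (1.75, 1.97),
            "abeta42": None, "abeta40": None, "t_tau": None, "p_tau": None,
            "apoe_e4_fraction": None},
    "FTD": {"age": (61.36, 8.69), "male_fraction": 0.4894,
            "MMSE": (12.20, 7.41), "MoCA": (7.68, 6.74), "COD": (2.79, 1.65),
            "abeta42": None, "abeta40": None, "t_tau": None, "p_tau": None,
            "apoe_e4_fraction": None},
    "DLB": {"age": (72.01, 9.07), "male_fraction": 0.6190,
            "MMSE": (12.76, 6.44), "MoCA": (5.94, 5.65), "COD": (2.00, 2.31),
            "abeta42": None, "abeta40": None, "t_tau": None, "p_tau": None,
            "apoe_e4_fraction": None},
}

#: Mean latent severity per diagnostic group (0 = healthy .. 1 = advanced).
DEFAULT_SEVERITY_MEANS = {
    "HC": 0.10, "MCI": 0.45, "AD": 0.80, "DLB": 0.75, "FTD": 0.70, "VCI": 0.65,
}

#: Planted pooled (MCI+AD) correlations: column -> (EEG pathway, target r).
#: Magnitudes follow the brain-CSF and brain-cognition effects the pipeline
#: is designed to detect.
DEFAULT_COUPLINGS: dict[str, tuple[str, float]] = {
    "p_tau":   ("theta", 0.442),
    "abeta42": ("theta", -0.358),
    "MMSE":    ("mobility", 0.44),
    "MoCA":    ("mobility", 0.44),
}


@dataclass(frozen=True)
class EffectProfile:
    """Severity-dependent modulation of the EEG signal model.

    Slopes are fractional changes over the full severity range; channel
    weights (length 16, montage order) localize each effect. The defaults
    plant a parieto-occipital pattern: theta amplitude and slow-wave power
    rise (mobility falls) over posterior channels, posterior alpha
    amplitude falls.
    """

    theta_slope: float = 2.0          # theta RMS multiplier: 1 + slope*latent*w
    alpha_slope: float = -0.35        # alpha RMS multiplier
    mobility_slope: float = 1.0       # slow-wave RMS: base * slope * latent * w
    entropy_slope: float = 0.0        # white-noise floor multiplier
    theta_weights: tuple[float, ...] = None  # type: ignore[assignment]
    alpha_weights: tuple[float, ...] = None  # type: ignore[assignment]
    mobility_weights: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        posterior = tuple(1.0 if ch in POSTERIOR_CHANNELS else 0.0
                          for ch in MONTAGE_16)
        if self.theta_weights is None:
            object.__setattr__(self, "theta_weights", posterior)
        if self.alpha_weights is None:
            object.__setattr__(self, "alpha_weights", posterior)
        if self.mobility_weights is None:
            object.__setattr__(self, "mobility_weights", posterior)


def null_profile() -> EffectProfile:
    """No severity effect on the EEG at all (chance-level cohort)."""
    return EffectProfile(theta_slope=0.0, alpha_slope=0.0,
                         mobility_slope=0.0, entropy_slope=0.0)


@dataclass(frozen=True)
class NoiseModel:
    """Background signal levels, all in microvolt RMS per channel."""

    one_over_f_exponent: float = 1.3   # power-spectrum exponent of background
    background_rms: float = 6.0
    white_rms: float = 1.5
    alpha_base_posterior: float = 6.0
    alpha_base_central: float = 3.0
    alpha_base_frontal: float = 1.5
    theta_base: float = 3.0
    alpha_shared_fraction: float = 0.5  # fraction of alpha power from a
                                        # common posterior source (gives the
                                        # data a stable dominant topography)


@dataclass(frozen=True)
class CohortConfig:
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 30, "MCI": 30, "AD": 30})
    sampling_rate: float = 200.0
    duration: float = 600.0            # seconds per recording
    montage: tuple[str, ...] = MONTAGE_16
    severity_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_MEANS))
    severity_sd: float = 0.08
    pathway_jitter: float = 0.03       # extra jitter on each EEG pathway latent
    effect_profile: EffectProfile = field(default_factory=EffectProfile)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    couplings: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_COUPLINGS))
    demographics: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_DEMOGRAPHICS.items()})
    csf_fraction: float = 1.0          # fraction of MCI/AD with CSF measured
    apoe_fraction: float = 1.0         # fraction of MCI/AD with APOE typed
    artifact_rate: float = 0.0         # expected fraction of corrupted samples
    seed: int = 0

    def __post_init__(self):
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("subject counts must be non-negative")
        n_samp = self.duration * self.sampling_rate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration x sampling_rate must be an integer")
        for col, (path, r) in self.couplings.items():
            if not abs(r) < 1.0:
                raise ValueError(f"coupling magnitude for {col} must be < 1")
            if path not in ("theta", "mobility"):
                raise ValueError(f"unknown EEG pathway {path!r}")
        if not 0.0 <= self.artifact_rate < 0.5:
            raise ValueError("artifact_rate must be in [0, 0.5)")
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {unknown}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def to_yaml(self, path: str | Path) -> None:
        flat = {
            "n_per_group": dict(self.n_per_group),
            "sampling_rate": self.sampling_rate,
            "duration": self.duration,
            "severity_sd": self.severity_sd,
            "pathway_jitter": self.pathway_jitter,
            "theta_slope": self.effect_profile.theta_slope,
            "alpha_slope": self.effect_profile.alpha_slope,
            "mobility_slope": self.effect_profile.mobility_slope,
            "entropy_slope": self.effect_profile.entropy_slope,
            "csf_fraction": self.csf_fraction,
            "apoe_fraction": self.apoe_fraction,
            "artifact_rate": self.artifact_rate,
            "seed": self.seed,
            "couplings": {c: [p, r] for c, (p, r) in self.couplings.items()},
        }
        Path(path).write_text(yaml.safe_dump(flat, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        flat = yaml.safe_load(Path(path).read_text())
        profile_keys = {k: flat.pop(k) for k in
                        ("theta_slope", "alpha_slope", "mobility_slope",
                         "entropy_slope") if k in flat}
        couplings = {c: (p, float(r)) for c, (p, r) in
                     flat.pop("couplings", dict(DEFAULT_COUPLINGS)).items()}
        return cls(effect_profile=EffectProfile(**profile_keys),
                   couplings=couplings, **flat)


def null_config(**overrides) -> CohortConfig:
    """A cohort with no EEG effect and no planted couplings."""
    defaults = dict(effect_profile=null_profile(), couplings={})
    defaults.update(overrides)
    return CohortConfig(**defaults)


# --------------------------------------------------------------------------
# EEG pathway variables
# --------------------------------------------------------------------------

def _slow_power(theta_latent: np.ndarray, mobility_latent: np.ndarray,
                profile: EffectProfile) -> np.ndarray:
    """Total posterior theta-band oscillator power multiplier: the theta
    oscillator (theta latent) plus the slow-wave component (mobility
    latent), powers additive for independent components."""
    return ((1.0 + profile.theta_slope * theta_latent) ** 2
            + (profile.mobility_slope * mobility_latent) ** 2)


def _theta_pathway(theta_latent: np.ndarray, mobility_latent: np.ndarray,
                   profile: EffectProfile) -> np.ndarray:
    """Pathway variable tracking measured posterior theta band power."""
    return _slow_power(theta_latent, mobility_latent, profile)


def _mobility_pathway(theta_latent: np.ndarray, mobility_latent: np.ndarray,
                      profile: EffectProfile) -> np.ndarray:
    """Monotone stand-in for measured posterior Hjorth mobility.

    Mobility falls as slow-wave power rises, so the pathway variable is the
    negated slow-power multiplier: correlations planted against it carry
    the sign convention "higher mobility <-> higher score".
    """
    return -_slow_power(theta_latent, mobility_latent, profile)


_PATHWAYS = {"theta": _theta_pathway, "mobility": _mobility_pathway}

#: Internal seed for the moment-calibration draws; independent of the user
#: seed so that coupling solutions depend only on the configuration.
_CALIBRATION_SEED = 987_654_321
_CALIBRATION_N = 200_000


def _severity_draw(rng: np.random.Generator, mean: float, sd: float,
                   n: int) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=n), 0.02, 0.98)


def _pathway_moments(config: CohortConfig, pathway: str,
                     pool: tuple[str, ...]) -> dict[str, tuple[float, float]]:
    """Large-sample mean/variance of a pathway variable per pooled group."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    fn = _PATHWAYS[pathway]
    out = {}
    for g in pool:
        s = _severity_draw(rng, config.severity_means[g], config.severity_sd,
                           _CALIBRATION_N)
        t = np.clip(s + rng.normal(0, config.pathway_jitter, _CALIBRATION_N),
                    0.0, 1.0)
        u = np.clip(s + rng.normal(0, config.pathway_jitter, _CALIBRATION_N),
                    0.0, 1.0)
        x = fn(t, u, config.effect_profile)
        out[g] = (float(x.mean()), float(x.var()))
    return out


def _column_transform(column: str):
    """Validity truncation applied to a generated clinical column."""
    if column in ("MMSE", "MoCA"):
        return lambda v: np.round(np.clip(v, 0, 30))
    if column in _CSF_FLOORS:
        floor = _CSF_FLOORS[column]
        return lambda v: np.clip(v, floor, None)
    return lambda v: v


def _calibration_draws(config: CohortConfig, pathway: str,
                       pool: tuple[str, ...],
                       weights: np.ndarray) -> dict[str, np.ndarray]:
    """Large fixed-seed draws of the pathway variable, sized per pool weight."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    fn = _PATHWAYS[pathway]
    out = {}
    for g, w in zip(pool, weights):
        n = max(int(round(w * _CALIBRATION_N)), 1000)
        s = _severity_draw(rng, config.severity_means[g], config.severity_sd, n)
        t = np.clip(s + rng.normal(0, config.pathway_jitter, n), 0.0, 1.0)
        u = np.clip(s + rng.normal(0, config.pathway_jitter, n), 0.0, 1.0)
        out[g] = fn(t, u, config.effect_profile)
    return out


def solve_coupling_loading(config: CohortConfig, column: str,
                           pool: tuple[str, ...] = ("MCI", "AD"),
                           ) -> tuple[float, dict[str, float]]:
    """Solve the within-group loading beta that realizes a planted coupling.

    For the coupled column V with configured per-group mean/SD (mu_g,
    sigma_g) and pathway variable X, subjects in the pool are drawn as

        V = mu_g + beta * (X - E[X|g]) + sigma_res_g * eps

    with sigma_res_g chosen to keep Var(V|g) = sigma_g^2. Because the
    column's validity truncation (score clipping, analyte floors) distorts
    the correlation, beta is found by root-finding the pooled correlation of
    large fixed-seed simulated draws that include that truncation, so the
    pooled MCI+AD Pearson r of the *published* values matches the target.
    """
    from scipy.optimize import brentq

    pathway, target_r = config.couplings[column]
    weights = np.array([config.n_per_group.get(g, 0) for g in pool], float)
    if weights.sum() == 0:
        weights = np.ones(len(pool))
    weights = weights / weights.sum()
    mu = {g: config.demographics[g][column][0] for g in pool}
    sigma = {g: config.demographics[g][column][1] for g in pool}
    draws = _calibration_draws(config, pathway, pool, weights)
    transform = _column_transform(column)
    eps_rng = np.random.default_rng(_CALIBRATION_SEED + 1)
    eps = {g: eps_rng.standard_normal(len(draws[g])) for g in pool}
    ex = {g: float(draws[g].mean()) for g in pool}
    vx = {g: float(draws[g].var()) for g in pool}

    def sigma_res_for(beta: float) -> dict[str, float]:
        out = {}
        for g in pool:
            resid_var = sigma[g] ** 2 - beta**2 * vx[g]
            out[g] = float(np.sqrt(max(resid_var, (0.15 * sigma[g]) ** 2)))
        return out

    def realized_r(beta: float) -> float:
        s_res = sigma_res_for(beta)
        xs, vs = [], []
        for g in pool:
            x = draws[g]
            v = transform(mu[g] + beta * (x - ex[g]) + s_res[g] * eps[g])
            xs.append(x)
            vs.append(v)
        x_all, v_all = np.concatenate(xs), np.concatenate(vs)
        return float(np.corrcoef(x_all, v_all)[0, 1])

    # analytic starting point (no truncation) and bracket for the root
    var_w = float(weights @ np.array([vx[g] for g in pool]))
    ex_arr = np.array([ex[g] for g in pool])
    mu_arr = np.array([mu[g] for g in pool])
    cov_b = float(weights @ ((ex_arr - weights @ ex_arr)
                             * (mu_arr - weights @ mu_arr)))
    sd_x = np.sqrt(var_w + float(weights @ (ex_arr - weights @ ex_arr) ** 2))
    sd_v = np.sqrt(float(weights @ np.array([sigma[g] for g in pool]) ** 2)
                   + float(weights @ (mu_arr - weights @ mu_arr) ** 2))
    beta0 = (target_r * sd_x * sd_v - cov_b) / var_w
    span = max(abs(beta0), sd_v / sd_x) + 1e-9
    lo, hi = beta0 - 2 * span, beta0 + 2 * span
    f_lo, f_hi = realized_r(lo) - target_r, realized_r(hi) - target_r
    for _ in range(6):
        if f_lo * f_hi <= 0:
            break
        lo, hi = lo - span, hi + span
        f_lo, f_hi = realized_r(lo) - target_r, realized_r(hi) - target_r
    if f_lo * f_hi > 0:
        warnings.warn(f"coupling for {column}: target r={target_r} not "
                      f"reachable with the configured group moments; using "
                      f"the analytic loading")
        beta = beta0
    else:
        beta = float(brentq(lambda b: realized_r(b) - target_r, lo, hi,
                            xtol=1e-4 * (abs(beta0) + 1)))
    return beta, sigma_res_for(beta)


# --------------------------------------------------------------------------
# Signal model
# --------------------------------------------------------------------------

def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float, rms: float) -> np.ndarray:
    """FFT-shaped Gaussian noise with power spectrum ~ 1/f^exponent."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = (np.maximum(freqs[nz], 0.5)) ** (-exponent / 2.0)
    spec = (rng.standard_normal(len(freqs))
            + 1j * rng.standard_normal(len(freqs))) * shape
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                      low: float, high: float, rms: float) -> np.ndarray:
    """Band-limited oscillatory component: filtered white noise."""
    if rms <= 0:
        return np.zeros(n)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * int(fs)))
    x = x[int(fs):int(fs) + n]
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _alpha_base(noise: NoiseModel) -> np.ndarray:
    base = np.full(len(MONTAGE_16), noise.alpha_base_frontal)
    for i, ch in enumerate(MONTAGE_16):
        if ch in POSTERIOR_CHANNELS:
            base[i] = noise.alpha_base_posterior
        elif ch.startswith(("C", "P", "T")):
            base[i] = noise.alpha_base_central
    return base


def _inject_spikes(rng: np.random.Generator, signal: np.ndarray, fs: float,
                   rate: float, channel_sd: np.ndarray) -> np.ndarray:
    """Add transient high-amplitude spike artifacts; returns sample mask."""
    n = signal.shape[1]
    mask = np.zeros(n, dtype=bool)
    if rate <= 0:
        return mask
    mean_dur = 0.125  # seconds, mean of U(0.05, 0.2)
    n_events = rng.poisson(rate * (n / fs) / mean_dur)
    for _ in range(n_events):
        dur = int(rng.uniform(0.05, 0.2) * fs)
        start = int(rng.integers(0, max(1, n - dur)))
        pulse = np.hanning(max(dur, 2))
        amp = rng.uniform(8.0, 12.0, size=signal.shape[0]) * channel_sd
        sign = rng.choice([-1.0, 1.0])
        signal[:, start:start + dur] += sign * amp[:, None] * pulse[:dur]
        mask[start:start + dur] = True
    return mask


def generate_recording(subject_severity: float, config: CohortConfig,
                       rng: np.random.Generator | None = None,
                       theta_latent: float | None = None,
                       mobility_latent: float | None = None,
                       subject_id: str = "synthetic") -> Recording:
    """Synthesize one resting-state recording at the given disease severity.

    The signal per channel is a sum of a fixed 1/f background, a
    posterior-dominant alpha oscillator (partly shared across channels, so
    the data has a stable dominant topography), a theta oscillator whose
    posterior amplitude grows with the theta latent, a slow-wave component
    driven by the mobility latent (extra low-frequency power lowers Hjorth
    mobility), a white-noise floor, and optional spike artifacts.
    """
    if not 0.0 <= subject_severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    s = subject_severity
    t_lat = s if theta_latent is None else theta_latent
    u_lat = s if mobility_latent is None else mobility_latent
    prof, noise = config.effect_profile, config.noise_model
    fs, n = config.sampling_rate, config.n_samples
    n_ch = len(config.montage)

    alpha_base = _alpha_base(noise)
    theta_w = np.asarray(prof.theta_weights)
    alpha_w = np.asarray(prof.alpha_weights)
    mob_w = np.asarray(prof.mobility_weights)

    alpha_rms = alpha_base * np.maximum(1.0 + prof.alpha_slope * s * alpha_w, 0.05)
    theta_rms = noise.theta_base * np.maximum(1.0 + prof.theta_slope * t_lat * theta_w, 0.05)
    # the mobility dial is a second slow (theta-band) component: extra
    # low-frequency power lowers the RMS frequency without touching the
    # broadband 1/f background
    slow_rms = noise.theta_base * prof.mobility_slope * u_lat * mob_w
    white_rms = noise.white_rms * max(1.0 + prof.entropy_slope * s, 0.05)

    shared_alpha = _narrowband_noise(rng, n, fs, 8.0, 12.0, 1.0)
    f_shared = noise.alpha_shared_fraction
    out = np.empty((n_ch, n))
    for c in range(n_ch):
        bg = _one_over_f_noise(rng, n, fs, noise.one_over_f_exponent,
                               noise.background_rms)
        a_sh = np.sqrt(f_shared) * alpha_rms[c] * shared_alpha
        a_ind = _narrowband_noise(rng, n, fs, 8.0, 12.0,
                                  np.sqrt(1 - f_shared) * alpha_rms[c])
        th = _narrowband_noise(rng, n, fs, 4.0, 8.0, theta_rms[c])
        sl = _narrowband_noise(rng, n, fs, 4.0, 8.0, slow_rms[c])
        wh = white_rms * rng.standard_normal(n)
        out[c] = bg + a_sh + a_ind + th + sl + wh

    channel_sd = out.std(axis=1)
    mask = _inject_spikes(rng, out, fs, config.artifact_rate, channel_sd)
    return Recording(out, fs, tuple(config.montage), subject_id,
                     artifact_truth=mask)


# --------------------------------------------------------------------------
# Metadata + cohort assembly
# --------------------------------------------------------------------------

_CSF_FLOORS = {"abeta42": 50.0, "abeta40": 500.0, "t_tau": 30.0, "p_tau": 5.0}
_COUPLING_POOL = ("MCI", "AD")


def generate_subject_table(config: CohortConfig) -> pd.DataFrame:
    """Draw the clinical table, including the latent truth columns.

    Columns prefixed ``latent_`` are generator ground truth (severity and
    the two EEG pathway latents/variables) retained for parameter-recovery
    tests; they are not part of the clinical record.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    rows = []
    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        demo = config.demographics[group]
        sev = _severity_draw(rng, config.severity_means[group],
                             config.severity_sd, n)
        t_lat = np.clip(sev + rng.normal(0, config.pathway_jitter, n), 0, 1)
        u_lat = np.clip(sev + rng.normal(0, config.pathway_jitter, n), 0, 1)
        x_theta = _theta_pathway(t_lat, u_lat, config.effect_profile)
        x_mob = _mobility_pathway(t_lat, u_lat, config.effect_profile)

        age = np.clip(rng.normal(*demo["age"], size=n), 40, 95)
        sex = np.where(rng.random(n) < demo["male_fraction"], "male", "female")
        if demo["COD"] is not None:
            cod = np.clip(rng.normal(*demo["COD"], size=n), 0.1, None)
            ado = age - cod
        else:
            cod = np.full(n, np.nan)
            ado = np.full(n, np.nan)
        for i in range(n):
            rows.append({
                "subject_id": f"{group}{i:04d}", "group": group,
                "age": age[i], "sex": sex[i], "ADO": ado[i], "COD": cod[i],
                "latent_severity": sev[i], "latent_theta": t_lat[i],
                "latent_mobility": u_lat[i],
                "latent_theta_pathway": x_theta[i],
                "latent_mobility_pathway": x_mob[i],
            })
    table = pd.DataFrame(rows)
    if table.empty:
        cols = ["subject_id", "group", "age", "sex", "ADO", "COD", "MMSE",
                "MoCA", "abeta42", "abeta40", "abeta_ratio", "t_tau", "p_tau",
                "apoe_e4"]
        return pd.DataFrame(columns=cols)

    # Coupled + uncoupled clinical scores and CSF analytes.
    loadings = {col: solve_coupling_loading(config, col)
                for col in config.couplings
                if all(config.demographics[g].get(col) is not None
                       for g in _COUPLING_POOL)}
    pathway_cols = {"theta": "latent_theta_pathway",
                    "mobility": "latent_mobility_pathway"}
    moments = {p: _pathway_moments(config, p, _COUPLING_POOL)
               for p in ("theta", "mobility")}

    for col in ("MMSE", "MoCA", "abeta42", "abeta40", "t_tau", "p_tau"):
        values = np.full(len(table), np.nan)
        for group in GROUPS:
            idx = np.flatnonzero(table["group"].to_numpy() == group)
            if len(idx) == 0:
                continue
            demo = config.demographics[group]
            if demo.get(col) is None:
                continue
            mu, sg = demo[col]
            eps = rng.standard_normal(len(idx))
            if col in loadings and group in _COUPLING_POOL:
                beta, sigma_res = loadings[col]
                pathway = config.couplings[col][0]
                x = table.loc[idx, pathway_cols[pathway]].to_numpy()
                ex_g = moments[pathway][group][0]
                v = mu + beta * (x - ex_g) + sigma_res[group] * eps
            else:
                v = mu + sg * eps
            if col in ("MMSE", "MoCA"):
                v = np.round(np.clip(v, 0, 30))
            else:
                v = np.clip(v, _CSF_FLOORS[col], None)
            values[idx] = v
        table[col] = values

    # Missingness: CSF/APOE ascertainment restricted to a fraction of MCI/AD.
    patient = table["group"].isin(_COUPLING_POOL).to_numpy()
    csf_keep = patient & (rng.random(len(table)) < config.csf_fraction)
    for col in ("abeta42", "abeta40", "t_tau", "p_tau"):
        table.loc[~csf_keep, col] = np.nan
    table["abeta_ratio"] = table["abeta42"] / table["abeta40"]

    apoe = np.full(len(table), np.nan)
    for group in _COUPLING_POOL:
        frac = config.demographics[group]["apoe_e4_fraction"]
        idx = np.flatnonzero((table["group"] == group).to_numpy()
                             & (rng.random(len(table)) < config.apoe_fraction))
        apoe[idx] = (rng.random(len(idx)) < frac).astype(float)
    table["apoe_e4"] = apoe

    order = ["subject_id", "group", "age", "sex", "MMSE", "MoCA", "ADO",
             "COD", "abeta42", "abeta40", "abeta_ratio", "t_tau", "p_tau",
             "apoe_e4", "latent_severity", "latent_theta", "latent_mobility",
             "latent_theta_pathway", "latent_mobility_pathway"]
    return table[order].reset_index(drop=True)


def _recording_rng(config: CohortConfig, subject_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(1, subject_index))
    return np.random.default_rng(ss)


def iter_recordings(config: CohortConfig,
                    table: pd.DataFrame) -> Iterator[Recording]:
    """Stream one Recording per table row (memory-friendly for big cohorts)."""
    for i, row in table.reset_index(drop=True).iterrows():
        yield generate_recording(
            row["latent_severity"], config, rng=_recording_rng(config, i),
            theta_latent=row["latent_theta"],
            mobility_latent=row["latent_mobility"],
            subject_id=row["subject_id"])


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, list[Recording]]:
    """Generate the full cohort: clinical table plus one recording each.

    Identical config (including seed) reproduces bit-identical outputs. For
    large cohorts prefer :func:`generate_subject_table` +
    :func:`iter_recordings` to avoid holding every signal in memory.
    """
    table = generate_subject_table(config)
    return table, list(iter_recordings(config, table))
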