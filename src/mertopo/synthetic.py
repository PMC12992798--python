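"""Synthetic STN-DBS cohorts with the statistical structure of an
intraoperative MER study.

The generator emulates a mixed local-anesthesia (LA) / propofol
general-anesthesia (GA) cohort: per-patient infusion rates, straight
Ben-Gun-style microelectrode trajectories through a parametric ellipsoid
atlas of the STN and SNr, bursty single-unit spike trains whose firing
rate and burst index follow condition-specific distributions,
depth-indexed background-RMS profiles with a dose-dependent STN plateau,
and 4-channel frontal EEG whose spectral edge frequency (SEF95) tracks
the propofol dose.  Everything is seeded and deterministic.

Default feature parameters are set to the group means/SDs of the study
population the generator emulates (e.g. firing rate 28.47 ± 14.00 Hz
awake vs 21.07 ± 14.37 Hz under propofol; burst index 5.59 ± 4.58 vs
11.98 ± 9.53), so study-scale regeneration produces cohorts with the
same group-level statistical structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sp_stats

from .exceptions import ConfigurationError, GenerationError
from .eeg import BAND, EEGRecord
from .nrms import TrajectoryProfile
from .spatial import (
    AtlasGeometry,
    ElectrodeModel,
    Ellipsoid,
    TrajectoryGeometry,
    classify_structure,
    electrode_center,
    locate_mer_site,
    snr_span,
    stn_span,
    sweetspot_distance,
)
from .spike_features import SpikeSegment

__all__ = [
    "FeatureParams",
    "CohortConfig",
    "Cohort",
    "TrajectoryRecord",
    "ElectrodeRecord",
    "default_atlas",
    "generate_cohort",
    "generate_spike_train",
    "generate_rms_profile",
    "generate_eeg",
    "nrms_suppression",
    "expected_sef95",
    "expected_bi_mean",
    "write_cohort",
]

#: Common log-space SD of the intra-burst and inter-burst ISI components.
BURST_SIGMA = 0.3

#: Weight of the short-ISI (intra-burst) component.
BURST_WEIGHT_SHORT = 0.5


@dataclass
class FeatureParams:
    """Per-condition targets for generated single-unit features.

    Depth is mm to the planned target (positive = dorsal); units per
    trajectory is the Poisson mean of isolated-unit counts.
    """

    fr_mean: float
    fr_sd: float
    bi_mean: float
    bi_sd: float
    depth_mean: float
    depth_sd: float
    units_per_trajectory: float


# GA subgroup FR/BI defaults pool to the GA group means at the emulated
# unit proportions (148 low-dose : 96 high-dose).
DEFAULT_FEATURE_PARAMS: dict[str, FeatureParams] = {
    "LA": FeatureParams(28.47, 14.00, 5.59, 4.58, 2.32, 3.01, 5.8),
    "GA_low": FeatureParams(23.0, 14.37, 10.2, 9.0, 2.39, 2.94, 4.9),
    "GA_high": FeatureParams(18.0, 14.37, 14.7, 10.0, -0.07, 2.38, 3.6),
}

# Final-electrode z-deviation from the sweetspot (mm), per dose condition.
DEFAULT_ELECTRODE_ZDEV: dict[str, tuple[float, float]] = {
    "LA": (-0.39, 0.91),
    "GA_low": (-0.16, 1.22),
    "GA_high": (-1.55, 0.93),
}


@dataclass
class CohortConfig:
    """Study-level parameters of the synthetic cohort."""

    n_patients: int = 25
    frac_la: float = 11 / 25
    propofol_mean: float = 3.9
    propofol_sd: float = 1.8
    propofol_range: tuple[float, float] = (1.0, 7.5)
    trajectories_per_hemisphere: int = 3
    dose_threshold: float = 4.0
    feature_params: dict[str, FeatureParams] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_PARAMS)
    )
    #: Spearman-scale coupling between burst index and sweetspot distance
    #: (negative correlation of that magnitude in each condition).
    bi_distance_rho: float = 0.45
    depth_range: tuple[float, float] = (-4.5, 9.5)
    segment_duration_range: tuple[float, float] = (5.0, 15.0)
    snr_mean: float = 8.01
    snr_sd: float = 3.02
    #: Expected number of low-quality segments per trajectory, by reason
    #: (ratios follow the emulated study's exclusion flowchart).
    reject_rates: dict[str, float] = field(
        default_factory=lambda: {"short": 0.26, "snr": 0.40, "anatomy": 0.22}
    )
    # background-RMS profile model
    rms_depth_step: float = 0.5
    rms_depth_range: tuple[float, float] = (-5.0, 10.0)
    rms_baseline_uv: float = 20.0
    rms_plateau_stn: float = 2.0
    rms_plateau_snr: float = 1.4
    rms_noise_sigma: float = 0.12
    suppression_rate: float = 0.35  # per mg/kg/h above the dose threshold
    # EEG / sedation model
    sef95_intercept: float = 26.0
    sef95_slope: float = -2.2  # Hz per mg/kg/h
    sef95_noise_sd: float = 1.0
    la_sef95_mean: float = 23.0
    la_sef95_sd: float = 1.5
    eeg_fs: float = 250.0
    eeg_duration: float = 60.0
    eeg_n_channels: int = 4
    eeg_rms_uv: float = 25.0
    # trajectory geometry
    trajectory_xy_jitter: float = 1.2
    electrode_zdev: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ELECTRODE_ZDEV)
    )

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0 <= self.frac_la <= 1:
            raise ConfigurationError("frac_la must lie in [0, 1]")
        lo, hi = self.propofol_range
        if not (0 < lo < hi <= 20):
            raise ConfigurationError("propofol_range must lie within (0, 20]")
        for name in ("propofol_sd", "snr_sd", "sef95_noise_sd", "la_sef95_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for cond, fp in self.feature_params.items():
            for fname in ("fr_sd", "bi_sd", "depth_sd"):
                if getattr(fp, fname) < 0:
                    raise ConfigurationError(f"feature_params[{cond}].{fname} must be >= 0")
            if fp.fr_mean <= 0 or fp.bi_mean < 1:
                raise ConfigurationError(
                    f"feature_params[{cond}]: fr_mean must be > 0 and bi_mean >= 1"
                )
        if self.trajectories_per_hemisphere < 1:
            raise ConfigurationError("trajectories_per_hemisphere must be >= 1")
        if self.dose_threshold <= 0:
            raise ConfigurationError("dose_threshold must be > 0")


@dataclass
class TrajectoryRecord:
    trajectory_id: str
    patient_id: str
    hemisphere: str
    condition: str  # LA | GA
    propofol_rate: float | None
    geometry: TrajectoryGeometry
    span: tuple[float, float] | None
    profile: TrajectoryProfile


@dataclass
class ElectrodeRecord:
    electrode_id: str
    patient_id: str
    hemisphere: str
    dose_condition: str  # LA | GA_low | GA_high
    model: ElectrodeModel


@dataclass
class Cohort:
    config: CohortConfig
    seed: int
    atlas: AtlasGeometry
    patients: pd.DataFrame
    trajectories: list[TrajectoryRecord]
    segments: list[SpikeSegment]
    eeg: dict[str, EEGRecord]
    electrodes: list[ElectrodeRecord]


def default_atlas() -> AtlasGeometry:
    """Parametric stand-in for an imaging-defined STN/SNr atlas.

    Axis-aligned ellipsoids in a right-handed mm frame, z dorsal-positive;
    a vertical trajectory through the STN center traverses ~5.6 mm of STN
    and then the SNr.  The sweetspot sits in the dorsolateral STN octant.
    The values are configurable stand-ins, not anatomical claims.
    """
    stn = Ellipsoid(center=(12.0, -10.0, -6.0), semi_axes=(5.0, 4.0, 2.8))
    snr_nucleus = Ellipsoid(center=(12.0, -10.0, -10.8), semi_axes=(5.5, 4.5, 2.0))
    return AtlasGeometry(
        stn=stn, snr_nucleus=snr_nucleus, sweetspot=np.array([14.0, -9.0, -4.4])
    )


# --- elementary dose-response functions --------------------------------------

def nrms_suppression(
    dose: float | None, threshold: float = 4.0, rate: float = 0.35
) -> float:
    """Multiplicative suppression of the STN background plateau.

    1 for no propofol or doses at/below the threshold, decaying
    exponentially above it; non-increasing in dose.
    """
    if dose is None:
        return 1.0
    if dose <= threshold:
        return 1.0
    return float(np.exp(-rate * (dose - threshold)))


def expected_sef95(dose: float | None, config: CohortConfig) -> float:
    """Noise-free SEF95 (Hz) at a given propofol dose (linear slowing)."""
    if dose is None:
        return config.la_sef95_mean
    raw = config.sef95_intercept + config.sef95_slope * dose
    return float(np.clip(raw, BAND[0] + 2.0, BAND[1] - 2.0))


def expected_bi_mean(dose: float | None, config: CohortConfig) -> float:
    """Expected burst-index mean at a dose (condition-level step model)."""
    fp = config.feature_params
    if dose is None:
        return fp["LA"].bi_mean
    return fp["GA_low" if dose <= config.dose_threshold else "GA_high"].bi_mean


# --- helpers -----------------------------------------------------------------

@lru_cache(maxsize=256)
def _solve_trunc_loc(mean: float, sd: float, low: float, high: float) -> float:
    """Location of a truncated normal whose truncated mean equals ``mean``."""

    def trunc_mean(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return sp_stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    lo_b, hi_b = mean - 4 * sd, mean + 4 * sd
    try:
        return float(optimize.brentq(trunc_mean, lo_b, hi_b))
    except ValueError:
        return float(mean)


def _matched_truncnorm(
    mean: float, sd: float, low: float, high: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal draws whose *truncated* mean equals ``mean``.

    Solves for the underlying location so truncation does not bias the
    sample mean away from the configured target.
    """
    if sd == 0:
        return np.full(size, np.clip(mean, low, high))
    loc = _solve_trunc_loc(float(mean), float(sd), float(low), float(high))
    a, b = (low - loc) / sd, (high - loc) / sd
    return sp_stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _shifted_lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of X where 1 + exp(N(mu, sigma^2)) has given mean/sd."""
    m = max(mean - 1.0, 1e-6)
    sigma2 = np.log(1.0 + (sd / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


# --- spike trains ------------------------------------------------------------

def generate_spike_train(
    duration: float,
    target_fr: float,
    target_bi: float,
    seed: int | np.random.Generator = 0,
    sigma: float = BURST_SIGMA,
    w_short: float = BURST_WEIGHT_SHORT,
) -> np.ndarray:
    """Spike times (s) from a two-regime renewal process.

    ISIs are drawn i.i.d. from a two-component lognormal mixture whose
    component geometric means have ratio ``target_bi`` and whose overall
    mean rate is ``target_fr``; ``target_bi = 1`` degenerates to a single
    lognormal component.  Times are sorted within [0, duration].
    """
    if duration < 3.0:
        raise GenerationError("duration must be >= 3 s")
    if target_fr <= 0:
        raise GenerationError("target_fr must be > 0")
    if target_bi < 1:
        raise GenerationError("target_bi must be >= 1")
    if target_fr * duration < 10:
        raise GenerationError(
            f"infeasible train: target_fr * duration = {target_fr * duration:g} < 10"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # component geometric means: exp(mu_l) = bi * exp(mu_s); overall mean
    # ISI = (w exp(mu_s) + (1-w) exp(mu_l)) e^{sigma^2/2} = 1 / fr
    mean_isi = 1.0 / target_fr
    mu_s = np.log(mean_isi) - sigma**2 / 2 - np.log(w_short + (1 - w_short) * target_bi)
    mu_l = mu_s + np.log(target_bi)
    n_draw = int(np.ceil(duration * target_fr * 1.6 + 30))
    times: list[np.ndarray] = []
    t = rng.uniform(0, mean_isi)  # random start phase
    total = np.empty(0)
    while True:
        comp = rng.random(n_draw) < w_short
        isi = np.exp(rng.normal(np.where(comp, mu_s, mu_l), sigma))
        chunk = t + np.cumsum(isi)
        total = np.concatenate([total, chunk])
        if total[-1] > duration:
            break
        t = total[-1]
    return total[total <= duration]


# --- RMS profiles ------------------------------------------------------------

def generate_rms_profile(
    trajectory_id: str,
    geometry: TrajectoryGeometry,
    atlas: AtlasGeometry,
    propofol_dose: float | None,
    seed: int | np.random.Generator = 0,
    config: CohortConfig | None = None,
    condition: str | None = None,
) -> TrajectoryProfile:
    """Depth-indexed background RMS for one pass through the atlas.

    Baseline RMS outside the nuclei; an elevated plateau inside the STN
    scaled by :func:`nrms_suppression` of the propofol dose (and a milder
    SNr elevation); multiplicative lognormal noise.
    """
    cfg = config or CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = cfg.rms_depth_range
    depths = np.arange(hi, lo - 1e-9, -cfg.rms_depth_step)
    span = stn_span(geometry, atlas)
    span_snr = snr_span(geometry, atlas)
    s = nrms_suppression(propofol_dose, cfg.dose_threshold, cfg.suppression_rate)
    base = cfg.rms_baseline_uv * np.exp(rng.normal(0.0, 0.3))
    level = np.ones_like(depths)
    if span is not None:
        inside = (depths <= span[0]) & (depths >= span[1])
        level[inside] += (cfg.rms_plateau_stn - 1.0) * s
    if span_snr is not None:
        inside = (depths <= span_snr[0]) & (depths >= span_snr[1])
        level[inside] += (cfg.rms_plateau_snr - 1.0) * s
    noise = np.exp(rng.normal(0.0, cfg.rms_noise_sigma, size=depths.size))
    rms_values = base * level * noise
    durations = rng.uniform(10.0, 30.0, size=depths.size)
    if condition is None:
        condition = "LA" if propofol_dose is None else "GA"
    return TrajectoryProfile(
        trajectory_id=trajectory_id,
        condition=condition,
        propofol_rate=propofol_dose,
        depths=depths,
        durations=durations,
        rms=rms_values,
        stn_entry=None if span is None else span[0],
        stn_exit=None if span is None else span[1],
    )


# --- EEG ---------------------------------------------------------------------

def _solve_sef95_decay(target: float, band: tuple[float, float] = BAND) -> float:
    """Decay constant tau of S(f) = exp(-f / tau) whose band SEF95 is target."""
    f_lo, f_hi = band

    def edge(tau):
        # F = -tau * log(0.05 e^{-lo/tau} + 0.95 e^{-hi/tau})
        return -tau * np.log(
            0.05 * np.exp(-f_lo / tau) + 0.95 * np.exp(-f_hi / tau)
        )

    lo_t, hi_t = 1e-2, 1e5
    if not edge(lo_t) < target < edge(hi_t):
        raise GenerationError(
            f"target SEF95 {target:g} Hz unreachable within band {band}"
        )
    return float(optimize.brentq(lambda t: edge(t) - target, lo_t, hi_t))


def generate_eeg(
    target_sef95: float,
    duration: float = 60.0,
    n_channels: int = 4,
    fs: float = 250.0,
    seed: int | np.random.Generator = 0,
    amplitude_uv: float = 25.0,
    band: tuple[float, float] = BAND,
) -> EEGRecord:
    """Colored-noise EEG whose band-limited SEF95 matches a target.

    Channels are white noise shaped in the frequency domain by an
    exponential-decay power profile whose rate is solved numerically
    against the SEF95 definition; out-of-band power is attenuated to a
    negligible floor.
    """
    if duration < 30:
        raise GenerationError("duration must be >= 30 s")
    if not band[0] < target_sef95 < min(band[1], fs / 2):
        raise GenerationError(
            f"target SEF95 {target_sef95:g} Hz outside ({band[0]}, "
            f"{min(band[1], fs / 2):g})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tau = _solve_sef95_decay(target_sef95, band)
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.exp(-freqs / tau)
    out_of_band = (freqs < band[0]) | (freqs > band[1])
    shape[out_of_band] *= 1e-4
    shape[0] = 0.0
    amp = np.sqrt(shape)
    channels = np.empty((n_channels, n))
    for ch in range(n_channels):
        spec = np.fft.rfft(rng.standard_normal(n))
        x = np.fft.irfft(spec * amp, n=n)
        x *= amplitude_uv / np.sqrt(np.mean(x**2))
        channels[ch] = x
    return EEGRecord(channels=channels, fs=fs, mer_window=(0.0, duration))


# --- cohort ------------------------------------------------------------------

def generate_cohort(config: CohortConfig | None = None, seed: int = 1) -> Cohort:
    """Generate a full synthetic cohort (deterministic for a fixed seed).

    LA patients carry no propofol dose; GA doses are truncated-normal on
    the configured range.  Single-unit burst-index targets are coupled to
    sweetspot distance within each anesthesia condition (negative
    correlation of configured magnitude) while preserving the marginal
    condition distributions.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    atlas = default_atlas()
    n_la = int(round(cfg.frac_la * cfg.n_patients))

    # patients and doses
    rows = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:02d}"
        if i < n_la:
            cond, dose = "LA", None
        else:
            cond = "GA"
            dose = float(
                _matched_truncnorm(
                    cfg.propofol_mean,
                    cfg.propofol_sd,
                    cfg.propofol_range[0],
                    cfg.propofol_range[1],
                    1,
                    rng,
                )[0]
            )
        rows.append({"patient_id": pid, "condition": cond, "propofol_rate": dose})
    patients = pd.DataFrame(rows)

    def dose_condition(cond: str, dose: float | None) -> str:
        if cond == "LA":
            return "LA"
        return "GA_low" if dose <= cfg.dose_threshold else "GA_high"

    target_base = atlas.stn.center - np.array([0.0, 0.0, atlas.stn.semi_axes[2]])

    trajectories: list[TrajectoryRecord] = []
    segments: list[SpikeSegment] = []
    pending_units: list[dict] = []  # BI targets assigned after placement
    electrodes: list[ElectrodeRecord] = []
    eeg: dict[str, EEGRecord] = {}
    seg_counter = 0

    for prow in patients.itertuples(index=False):
        dose = prow.propofol_rate if prow.condition == "GA" else None
        dcond = dose_condition(prow.condition, dose)
        fp = cfg.feature_params[dcond]
        for hemi in ("left", "right"):
            hemi_trajs: list[TrajectoryRecord] = []
            for j in range(cfg.trajectories_per_hemisphere):
                tid = f"{prow.patient_id}_{hemi[0]}{j + 1}"
                offset = rng.normal(0.0, cfg.trajectory_xy_jitter, size=2)
                geometry = TrajectoryGeometry(
                    target_point=target_base + np.array([offset[0], offset[1], 0.0]),
                    direction=(0.0, 0.0, -1.0),
                )
                span = stn_span(geometry, atlas)
                profile = generate_rms_profile(
                    tid, geometry, atlas, dose, rng, cfg, condition=prow.condition
                )
                rec = TrajectoryRecord(
                    trajectory_id=tid,
                    patient_id=prow.patient_id,
                    hemisphere=hemi,
                    condition=prow.condition,
                    propofol_rate=dose,
                    geometry=geometry,
                    span=span,
                    profile=profile,
                )
                trajectories.append(rec)
                hemi_trajs.append(rec)

                # isolated single units, placed on the nuclei's depth support
                # of this trajectory (the emulated depth statistics describe
                # units retained inside STN/SNr)
                span_nigra = snr_span(geometry, atlas)
                if span is not None:
                    depth_hi = span[0]
                    depth_lo = span_nigra[1] if span_nigra is not None else span[1]
                elif span_nigra is not None:
                    depth_hi, depth_lo = span_nigra
                else:
                    depth_hi = depth_lo = None
                n_units = rng.poisson(fp.units_per_trajectory) if depth_hi is not None else 0
                if n_units > 0:
                    # round bounds for the cached location solve
                    depths = _matched_truncnorm(
                        fp.depth_mean,
                        fp.depth_sd,
                        round(depth_lo + 0.05, 1),
                        round(depth_hi - 0.05, 1),
                        n_units,
                        rng,
                    )
                    frs = _matched_truncnorm(
                        fp.fr_mean, fp.fr_sd, 2.5, fp.fr_mean + 6 * fp.fr_sd, n_units, rng
                    )
                    for depth, fr in zip(depths, frs):
                        seg_counter += 1
                        xyz = locate_mer_site(geometry, float(depth), 0.0)
                        if (
                            classify_structure(xyz, atlas) == "other"
                            and span is not None
                        ):
                            # landed in the inter-nucleus gap; redraw in STN
                            depth = float(rng.uniform(span[1] + 0.05, span[0] - 0.05))
                            xyz = locate_mer_site(geometry, depth, 0.0)
                        pending_units.append(
                            {
                                "segment_id": f"S{seg_counter:04d}",
                                "patient_id": prow.patient_id,
                                "hemisphere": hemi,
                                "trajectory_id": tid,
                                "depth": float(depth),
                                "fr": float(fr),
                                "duration": float(
                                    rng.uniform(*cfg.segment_duration_range)
                                ),
                                "snr": float(
                                    _matched_truncnorm(
                                        cfg.snr_mean, cfg.snr_sd, 3.05, 25.0, 1, rng
                                    )[0]
                                ),
                                "condition": prow.condition,
                                "dose_condition": dcond,
                                "structure": classify_structure(xyz, atlas),
                                "distance": sweetspot_distance(xyz, atlas.sweetspot),
                            }
                        )

                # low-quality segments exercising the exclusion filters
                for reason, rate in cfg.reject_rates.items():
                    for _ in range(rng.poisson(rate)):
                        seg_counter += 1
                        depth = float(rng.uniform(*cfg.depth_range))
                        duration = float(rng.uniform(*cfg.segment_duration_range))
                        snr = float(
                            _matched_truncnorm(cfg.snr_mean, cfg.snr_sd, 3.05, 25.0, 1, rng)[0]
                        )
                        single = True
                        if reason == "short":
                            duration = float(rng.uniform(1.0, 2.9))
                        elif reason == "snr":
                            if rng.random() < 0.5:
                                snr = float(rng.uniform(0.5, 2.9))
                            else:
                                single = False
                        else:  # anatomy: dorsal of the STN
                            depth = float(rng.uniform(7.0, 9.4))
                        xyz = locate_mer_site(geometry, depth, 0.0)
                        structure = (
                            "other"
                            if reason == "anatomy"
                            else classify_structure(xyz, atlas)
                        )
                        fr = max(float(rng.normal(fp.fr_mean, fp.fr_sd)), 4.0)
                        bi_t = 1.0 + float(rng.lognormal(0.8, 0.6))
                        # short segments: draw a >=3 s train and crop
                        full = generate_spike_train(max(duration, 3.0), fr, bi_t, rng)
                        train = full[full <= duration]
                        if train.size < 2:
                            continue
                        segments.append(
                            SpikeSegment(
                                segment_id=f"S{seg_counter:04d}",
                                patient_id=prow.patient_id,
                                hemisphere=hemi,
                                trajectory_id=tid,
                                depth_to_target=depth,
                                duration=duration,
                                spike_times=train,
                                snr=snr,
                                is_single_unit=single,
                                structure_imaging=structure,
                                structure_intraop=structure,
                            )
                        )

            # final electrode: central trajectory of this hemisphere
            central = hemi_trajs[0]
            zmu, zsd = cfg.electrode_zdev[dcond]
            zdev = float(rng.normal(zmu, zsd))
            center_z = atlas.sweetspot[2] + zdev
            txy = central.geometry.target_point[:2]
            contacts = np.array(
                [[txy[0], txy[1], center_z + dz] for dz in (-3.0, -1.0, 1.0, 3.0)]
            )
            model = electrode_center(
                ElectrodeModel(contact_positions=contacts), atlas.sweetspot
            )
            electrodes.append(
                ElectrodeRecord(
                    electrode_id=f"{prow.patient_id}_{hemi[0]}",
                    patient_id=prow.patient_id,
                    hemisphere=hemi,
                    dose_condition=dcond,
                    model=model,
                )
            )

        # EEG for the MER window of this patient
        target = expected_sef95(dose, cfg) + float(
            rng.normal(0.0, cfg.sef95_noise_sd if dose is not None else cfg.la_sef95_sd)
        )
        target = float(np.clip(target, BAND[0] + 1.5, BAND[1] - 1.5))
        eeg[prow.patient_id] = generate_eeg(
            target,
            duration=cfg.eeg_duration,
            n_channels=cfg.eeg_n_channels,
            fs=cfg.eeg_fs,
            seed=rng,
            amplitude_uv=cfg.eeg_rms_uv,
        )

    # burst-index targets: couple to sweetspot distance within condition
    for cond in ("LA", "GA"):
        units = [u for u in pending_units if u["condition"] == cond]
        if not units:
            continue
        dist = np.array([u["distance"] for u in units])
        # rank-gaussianised distance scores
        ranks = sp_stats.rankdata(dist, method="average")
        z = sp_stats.norm.ppf(ranks / (len(units) + 1.0))
        rho = cfg.bi_distance_rho
        eps = rng.standard_normal(len(units))
        g = -rho * z + np.sqrt(max(1.0 - rho**2, 0.0)) * eps
        for u, gi in zip(units, g):
            fp = cfg.feature_params[u["dose_condition"]]
            mu, sg = _shifted_lognormal_params(fp.bi_mean, fp.bi_sd)
            u["bi"] = 1.0 + float(np.exp(mu + sg * gi))

    # synthesise the spike trains of the good units
    for u in pending_units:
        train = generate_spike_train(u["duration"], u["fr"], u["bi"], rng)
        if train.size < 2:
            continue
        segments.append(
            SpikeSegment(
                segment_id=u["segment_id"],
                patient_id=u["patient_id"],
                hemisphere=u["hemisphere"],
                trajectory_id=u["trajectory_id"],
                depth_to_target=u["depth"],
                duration=u["duration"],
                spike_times=train,
                snr=u["snr"],
                is_single_unit=True,
                structure_imaging=u["structure"],
                structure_intraop=u["structure"],
            )
        )

    segments.sort(key=lambda s: s.segment_id)
    return Cohort(
        config=cfg,
        seed=seed,
        atlas=atlas,
        patients=patients,
        trajectories=trajectories,
        segments=segments,
        eeg=eeg,
        electrodes=electrodes,
    )


# --- on-disk cohort ----------------------------------------------------------

def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort as delimited-text tables plus a JSON manifest.

    Layout: patients.tsv, trajectories.tsv, rms_profiles.tsv (long format),
    segments.tsv with spikes/<segment_id>.txt sidecars, eeg/<patient>.csv
    (header row carries fs and the MER window), electrodes.tsv,
    manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.patients.to_csv(outdir / "patients.tsv", sep="\t", index=False)

    traj_rows, rms_rows = [], []
    for t in cohort.trajectories:
        g = t.geometry
        traj_rows.append(
            {
                "trajectory_id": t.trajectory_id,
                "patient_id": t.patient_id,
                "hemisphere": t.hemisphere,
                "condition": t.condition,
                "propofol_rate": "" if t.propofol_rate is None else t.propofol_rate,
                "target_x": g.target_point[0],
                "target_y": g.target_point[1],
                "target_z": g.target_point[2],
                "dir_x": g.direction[0],
                "dir_y": g.direction[1],
                "dir_z": g.direction[2],
                "implantation_offset": g.implantation_offset,
                "stn_entry": "" if t.span is None else t.span[0],
                "stn_exit": "" if t.span is None else t.span[1],
            }
        )
        for d, dur, r in zip(t.profile.depths, t.profile.durations, t.profile.rms):
            rms_rows.append(
                {
                    "trajectory_id": t.trajectory_id,
                    "depth": d,
                    "duration": dur,
                    "rms": r,
                }
            )
    pd.DataFrame(traj_rows).to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
    pd.DataFrame(rms_rows).to_csv(outdir / "rms_profiles.tsv", sep="\t", index=False)

    seg_rows = []
    spike_dir = outdir / "spikes"
    spike_dir.mkdir(exist_ok=True)
    for s in cohort.segments:
        seg_rows.append(
            {
                "segment_id": s.segment_id,
                "patient_id": s.patient_id,
                "hemisphere": s.hemisphere,
                "trajectory_id": s.trajectory_id,
                "depth_to_target": s.depth_to_target,
                "duration": s.duration,
                "snr": s.snr,
                "is_single_unit": s.is_single_unit,
                "structure_imaging": s.structure_imaging,
                "structure_intraop": s.structure_intraop,
            }
        )
        np.savetxt(spike_dir / f"{s.segment_id}.txt", s.spike_times, fmt="%.6f")
    pd.DataFrame(seg_rows).to_csv(outdir / "segments.tsv", sep="\t", index=False)

    eeg_dir = outdir / "eeg"
    eeg_dir.mkdir(exist_ok=True)
    for pid, rec in cohort.eeg.items():
        header = ",".join(
            [f"# fs={rec.fs}", f"mer_start={rec.mer_window[0]}", f"mer_end={rec.mer_window[1]}"]
        )
        cols = ",".join(f"ch{i + 1}" for i in range(rec.channels.shape[0]))
        with open(eeg_dir / f"{pid}.csv", "w") as fh:
            fh.write(header + "\n" + cols + "\n")
            np.savetxt(fh, rec.channels.T, delimiter=",", fmt="%.4f")

    elec_rows = []
    for e in cohort.electrodes:
        for k, c in enumerate(e.model.contact_positions):
            elec_rows.append(
                {
                    "electrode_id": e.electrode_id,
                    "patient_id": e.patient_id,
                    "hemisphere": e.hemisphere,
                    "dose_condition": e.dose_condition,
                    "contact": k,
                    "x": c[0],
                    "y": c[1],
                    "z": c[2],
                }
            )
    pd.DataFrame(elec_rows).to_csv(outdir / "electrodes.tsv", sep="\t", index=False)

    manifest = {
        "seed": cohort.seed,
        "n_patients": cohort.config.n_patients,
        "config": _config_to_jsonable(cohort.config),
        "sweetspot": list(map(float, cohort.atlas.sweetspot)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _config_to_jsonable(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["feature_params"] = {k: asdict(v) if not isinstance(v, dict) else v
                           for k, v in cfg.feature_params.items()}
    return d
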