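"""Single-unit spike-train features for microelectrode recordings.

Implements the rate-based features used to characterise STN/SNr units
during DBS surgery:

* firing rate (FR) — inverse of the mean interspike interval (ISI);
* burst index (BI) — ratio of the two component means of a two-component
  Gaussian mixture fitted to the log-ISI distribution (higher = burstier);
* robust coefficient of variation (CV) — median absolute deviation of the
  ISI distribution divided by its median (MAD unscaled);
* a signal-to-noise estimate and the segment quality filters
  (duration ≥ 3 s, SNR ≥ 3, isolated single unit, inside STN or SNr).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError

__all__ = [
    "SpikeSegment",
    "UnitFeatures",
    "BurstIndexFit",
    "interspike_intervals",
    "firing_rate",
    "burst_index",
    "coefficient_of_variation",
    "estimate_snr",
    "extract_features",
    "quality_filter",
    "read_segments",
    "write_unit_features",
]

#: Minimum number of ISIs for a reliable two-component mixture fit.
MIN_ISI_FOR_BI = 30

#: Variance floor for the log-ISI mixture, in (natural-log units)^2.
VARIANCE_FLOOR = 1e-4

#: Mixture components with weight below this are treated as collapsed.
WEIGHT_FLOOR = 0.05

#: Component means closer than this (log-units) are treated as collapsed.
COLLAPSE_EPS = 0.05

#: SNR reported for effectively noiseless traces.
SNR_CAP = 1e6


@dataclass
class SpikeSegment:
    """One MER segment: an isolated unit's spike times plus metadata.

    ``depth_to_target`` is signed distance in mm along the trajectory from
    the planned target (the ventral STN border); positive = dorsal of
    target.  ``structure_imaging`` is the imaging-defined structure label,
    ``structure_intraop`` the intra-operative team's label.
    """

    segment_id: str
    patient_id: str
    hemisphere: str
    trajectory_id: str
    depth_to_target: float
    duration: float
    spike_times: np.ndarray
    snr: float
    is_single_unit: bool = True
    structure_imaging: str = "unlabelled"
    structure_intraop: str = "unlabelled"

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.duration <= 0:
            raise ValueError(f"segment {self.segment_id}: duration must be > 0")
        if self.spike_times.size:
            if self.spike_times.min() < 0 or self.spike_times.max() > self.duration:
                raise ValueError(
                    f"segment {self.segment_id}: spike times outside [0, duration]"
                )
            if np.any(np.diff(self.spike_times) <= 0):
                raise ValueError(
                    f"segment {self.segment_id}: spike times not strictly increasing"
                )
        if self.snr < 0:
            raise ValueError(f"segment {self.segment_id}: snr must be >= 0")


@dataclass
class BurstIndexFit:
    """Result of the two-component log-ISI mixture fit."""

    bi: float
    degenerate: bool
    mu_short: float
    mu_long: float
    sigmas: tuple[float, float]
    weights: tuple[float, float]
    log_likelihood: float


@dataclass
class UnitFeatures:
    """Rate-based features of one isolated unit."""

    fr: float
    bi: float
    bi_degenerate: bool
    cv: float
    n_spikes: int
    n_isi: int


def interspike_intervals(segment_or_times) -> np.ndarray:
    """Interspike intervals (s) of a segment or a raw spike-time array.

    Raises :class:`InsufficientDataError` for fewer than two spikes and
    ``ValueError`` for non-increasing timestamps.
    """
    times = (
        segment_or_times.spike_times
        if isinstance(segment_or_times, SpikeSegment)
        else np.asarray(segment_or_times, dtype=float)
    )
    if times.size < 2:
        raise InsufficientDataError("need at least 2 spikes to form ISIs")
    isi = np.diff(times)
    if np.any(isi <= 0):
        raise ValueError("spike times must be strictly increasing")
    return isi


def firing_rate(isi: Sequence[float]) -> float:
    """Firing rate (Hz) as the inverse of the mean ISI."""
    isi = np.asarray(isi, dtype=float)
    if isi.size == 0:
        raise InsufficientDataError("need at least 1 ISI for firing rate")
    return 1.0 / float(np.mean(isi))


def coefficient_of_variation(isi: Sequence[float]) -> float:
    """Robust CV: median absolute deviation of the ISIs over their median.

    The MAD is unscaled (no normal-consistency constant 1.4826).
    """
    isi = np.asarray(isi, dtype=float)
    if isi.size == 0:
        raise InsufficientDataError("need at least 1 ISI for CV")
    med = float(np.median(isi))
    mad = float(np.median(np.abs(isi - med)))
    return mad / med


def _em_1d_two_component(
    x: np.ndarray,
    mu_init: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """EM for a two-component 1-D Gaussian mixture with a variance floor.

    Returns (means, variances, weights, log-likelihood)."""
    n = x.size
    mu = mu_init.astype(float).copy()
    var = np.full(2, max(np.var(x), VARIANCE_FLOOR))
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    for _ in range(max_iter):
        # E step in log space for stability
        log_pdf = (
            -0.5 * np.log(2 * np.pi * var[:, None])
            - 0.5 * (x[None, :] - mu[:, None]) ** 2 / var[:, None]
        )
        log_joint = np.log(np.maximum(w[:, None], 1e-300)) + log_pdf
        m = log_joint.max(axis=0)
        lse = m + np.log(np.exp(log_joint - m).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(log_joint - lse)
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp @ x) / nk
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
        var = np.maximum(var, VARIANCE_FLOOR)
        if ll - ll_old < tol * max(1.0, abs(ll)):
            ll_old = ll
            break
        ll_old = ll
    return mu, var, w, ll_old


def burst_index(
    isi: Sequence[float],
    seed: int = 0,
    n_restarts: int = 10,
    min_isi: int = MIN_ISI_FOR_BI,
    ratio_space: str = "geometric",
) -> BurstIndexFit:
    """Burst index from a two-component Gaussian mixture on log ISIs.

    The mixture is fitted by EM to the natural-log ISIs; the burst index is
    the ratio of the two component means.  With ``ratio_space="geometric"``
    (default) the ratio is taken between the geometric-mean ISIs of the two
    components, ``exp(mu_long - mu_short)``; ``"linear"`` instead uses the
    lognormal component means ``exp(mu + sigma^2/2)``.

    Fits where the components collapse onto each other (mean separation
    below :data:`COLLAPSE_EPS` log-units or a component weight below
    :data:`WEIGHT_FLOOR`) carry the ``degenerate`` flag and report BI = 1:
    a unimodal ISI distribution has no burst/inter-burst structure to
    measure.

    Restarts: the first initialisation places the component means at the
    25th/75th log-ISI percentiles; the remainder jitter those positions
    (seeded).  The best log-likelihood wins.
    """
    isi = np.asarray(isi, dtype=float)
    if isi.size < min_isi:
        raise InsufficientDataError(
            f"need at least {min_isi} ISIs for the burst index, got {isi.size}"
        )
    if ratio_space not in ("geometric", "linear"):
        raise ValueError("ratio_space must be 'geometric' or 'linear'")
    x = np.log(isi)
    q25, q75 = np.percentile(x, [25, 75])
    rng = np.random.default_rng(seed)
    spread = max(float(x.std()), 1e-3)

    best = None
    for r in range(n_restarts):
        if r == 0:
            mu0 = np.array([q25, q75])
        else:
            mu0 = np.array([q25, q75]) + rng.normal(0.0, 0.5 * spread, size=2)
        mu, var, w, ll = _em_1d_two_component(x, mu0)
        if best is None or ll > best[3]:
            best = (mu, var, w, ll)
    mu, var, w, ll = best

    order = np.argsort(mu)
    mu_s, mu_l = mu[order]
    var_s, var_l = var[order]
    w_s, w_l = w[order]

    degenerate = (mu_l - mu_s) < COLLAPSE_EPS or min(w_s, w_l) < WEIGHT_FLOOR
    if degenerate:
        bi = 1.0
    elif ratio_space == "geometric":
        bi = float(np.exp(mu_l - mu_s))
    else:
        bi = float(np.exp(mu_l + var_l / 2.0) / np.exp(mu_s + var_s / 2.0))
    return BurstIndexFit(
        bi=bi,
        degenerate=bool(degenerate),
        mu_short=float(mu_s),
        mu_long=float(mu_l),
        sigmas=(float(np.sqrt(var_s)), float(np.sqrt(var_l))),
        weights=(float(w_s), float(w_l)),
        log_likelihood=float(ll),
    )


def estimate_snr(
    raw_trace: Sequence[float],
    spike_indices: Sequence[int],
    exclusion_halfwidth: int = 10,
) -> float | None:
    """Signal-to-noise of a trace with marked spike peaks.

    SNR = mean absolute spike-peak amplitude over the robust noise SD of
    the spike-free trace (MAD / 0.6745).  Samples within
    ``exclusion_halfwidth`` of any spike index are excluded from the noise
    estimate.  Returns ``None`` when there are no spikes; noiseless traces
    are capped at :data:`SNR_CAP`.
    """
    trace = np.asarray(raw_trace, dtype=float)
    idx = np.asarray(spike_indices, dtype=int)
    if trace.size == 0:
        raise ValueError("empty trace")
    if idx.size == 0:
        return None
    if idx.min() < 0 or idx.max() >= trace.size:
        raise ValueError("spike indices outside trace")
    peak = float(np.mean(np.abs(trace[idx])))
    mask = np.ones(trace.size, dtype=bool)
    for i in idx:
        lo = max(0, i - exclusion_halfwidth)
        hi = min(trace.size, i + exclusion_halfwidth + 1)
        mask[lo:hi] = False
    noise = trace[mask]
    if noise.size == 0:
        return SNR_CAP
    mad = float(np.median(np.abs(noise - np.median(noise))))
    sigma = mad / 0.6745
    if sigma <= 0:
        return SNR_CAP
    return min(peak / sigma, SNR_CAP)


def extract_features(
    segment: SpikeSegment, seed: int = 0, ratio_space: str = "geometric"
) -> UnitFeatures:
    """FR, BI and CV for one segment.

    BI is flagged degenerate (and reported as 1) when the segment has too
    few ISIs for a reliable mixture fit or the fit collapses.
    """
    isi = interspike_intervals(segment)
    fr = firing_rate(isi)
    cv = coefficient_of_variation(isi)
    if isi.size >= MIN_ISI_FOR_BI:
        fit = burst_index(isi, seed=seed, ratio_space=ratio_space)
        bi, degen = fit.bi, fit.degenerate
    else:
        bi, degen = 1.0, True
    return UnitFeatures(
        fr=fr,
        bi=bi,
        bi_degenerate=degen,
        cv=cv,
        n_spikes=int(segment.spike_times.size),
        n_isi=int(isi.size),
    )


# --- quality filters ---------------------------------------------------------

MIN_DURATION_S = 3.0
MIN_SNR = 3.0
VALID_STRUCTURES = ("STN", "SNr")


def quality_filter(
    segments: Iterable[SpikeSegment],
) -> tuple[list[SpikeSegment], dict[str, int]]:
    """Apply the segment inclusion rules.

    Retained segments satisfy, in this order of precedence: duration >= 3 s
    ("short"); SNR >= 3 and unequivocal single-unit isolation ("snr");
    imaging-defined location inside STN or SNr ("anatomy").  A segment is
    tallied once, under the first rule it fails.
    """
    kept: list[SpikeSegment] = []
    tally: dict[str, int] = {}
    for seg in segments:
        if seg.duration < MIN_DURATION_S:
            tally["short"] = tally.get("short", 0) + 1
        elif seg.snr < MIN_SNR or not seg.is_single_unit:
            tally["snr"] = tally.get("snr", 0) + 1
        elif seg.structure_imaging not in VALID_STRUCTURES:
            tally["anatomy"] = tally.get("anatomy", 0) + 1
        else:
            kept.append(seg)
    return kept, tally


# --- tabular I/O -------------------------------------------------------------

def read_segments(segments_tsv: str | Path, spike_dir: str | Path | None = None) -> list[SpikeSegment]:
    """Read segments.tsv plus per-segment spike-time sidecar files.

    The sidecar for segment ``S`` is ``<spike_dir>/<S>.txt`` with one spike
    time in seconds per line; ``spike_dir`` defaults to ``spikes/`` next to
    the table.
    """
    segments_tsv = Path(segments_tsv)
    if spike_dir is None:
        spike_dir = segments_tsv.parent / "spikes"
    spike_dir = Path(spike_dir)
    df = pd.read_csv(segments_tsv, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        times = np.loadtxt(spike_dir / f"{row.segment_id}.txt", ndmin=1)
        out.append(
            SpikeSegment(
                segment_id=str(row.segment_id),
                patient_id=str(row.patient_id),
                hemisphere=str(row.hemisphere),
                trajectory_id=str(row.trajectory_id),
                depth_to_target=float(row.depth_to_target),
                duration=float(row.duration),
                spike_times=times,
                snr=float(row.snr),
                is_single_unit=bool(row.is_single_unit),
                structure_imaging=str(row.structure_imaging),
                structure_intraop=str(row.structure_intraop),
            )
        )
    return out


def write_unit_features(
    features: dict[str, UnitFeatures], path: str | Path
) -> pd.DataFrame:
    """Write unit_features.tsv keyed by segment_id; returns the table."""
    df = pd.DataFrame(
        [
            {
                "segment_id": seg_id,
                "fr": f.fr,
                "bi": f.bi,
                "bi_degenerate": f.bi_degenerate,
                "cv": f.cv,
                "n_spikes": f.n_spikes,
                "n_isi": f.n_isi,
            }
            for seg_id, f in features.items()
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
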