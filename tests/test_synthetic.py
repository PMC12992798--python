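"""Synthetic cohort generator: determinism, configuration validation,
dose model, feature fidelity, dose-response monotonicity."""

import numpy as np
import pandas as pd
import pytest

from mertopo import spike_features as sf
from mertopo import synthetic
from mertopo.exceptions import ConfigurationError, GenerationError
from mertopo.spatial import TrajectoryGeometry, stn_span
from mertopo.synthetic import (
    CohortConfig,
    default_atlas,
    generate_cohort,
    generate_eeg,
    generate_rms_profile,
    generate_spike_train,
    nrms_suppression,
    expected_sef95,
    expected_bi_mean,
)


def test_cohort_seeded_determinism(small_config, tmp_path):
    a = generate_cohort(small_config, seed=7)
    b = generate_cohort(small_config, seed=7)
    pd.testing.assert_frame_equal(a.patients, b.patients)
    assert len(a.segments) == len(b.segments)
    for sa, sb in zip(a.segments, b.segments):
        assert sa.segment_id == sb.segment_id
        np.testing.assert_array_equal(sa.spike_times, sb.spike_times)
    for pid in a.eeg:
        np.testing.assert_array_equal(a.eeg[pid].channels, b.eeg[pid].channels)
    # byte-identical on disk
    synthetic.write_cohort(a, tmp_path / "a")
    synthetic.write_cohort(b, tmp_path / "b")
    for name in ("patients.tsv", "segments.tsv", "rms_profiles.tsv", "electrodes.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_all_la_cohort():
    cfg = CohortConfig(n_patients=4, frac_la=1.0, trajectories_per_hemisphere=1)
    c = generate_cohort(cfg, seed=3)
    assert (c.patients["condition"] == "LA").all()
    assert c.patients["propofol_rate"].isna().all()


def test_invalid_config_names_field():
    cfg = CohortConfig(frac_la=1.4)
    with pytest.raises(ConfigurationError, match="frac_la"):
        generate_cohort(cfg, seed=1)
    cfg = CohortConfig(propofol_range=(0.0, 7.5))
    with pytest.raises(ConfigurationError, match="propofol_range"):
        generate_cohort(cfg, seed=1)


def test_ga_dose_distribution_study_scale():
    """25 patients, 11 LA / 14 GA: dose sample mean within 0.5 of 3.9."""
    c = generate_cohort(CohortConfig(), seed=1)
    doses = c.patients["propofol_rate"].dropna()
    assert len(doses) == 14
    assert doses.between(1.0, 7.5).all()
    assert abs(doses.mean() - 3.9) < 0.5


# --- spike trains ------------------------------------------------------------

def test_spike_train_degenerate_bi():
    train = generate_spike_train(60.0, 20.0, 1.0, seed=5)
    fit = sf.burst_index(np.diff(train), seed=0)
    assert fit.bi <= 1.5


def test_spike_train_bi_calibration():
    """Median extracted BI over independent seeds is within 25% of target."""
    values = []
    for seed in range(50):
        train = generate_spike_train(60.0, 20.0, 10.0, seed=seed)
        values.append(sf.burst_index(np.diff(train), seed=0).bi)
    assert np.median(values) == pytest.approx(10.0, rel=0.25)


def test_spike_train_rate_calibration():
    frs = []
    for seed in range(30):
        train = generate_spike_train(60.0, 20.0, 5.0, seed=seed)
        frs.append(sf.firing_rate(np.diff(train)))
    assert np.mean(frs) == pytest.approx(20.0, rel=0.15)


def test_spike_train_valid_and_errors():
    train = generate_spike_train(10.0, 30.0, 4.0, seed=2)
    assert train.min() >= 0 and train.max() <= 10.0
    assert np.all(np.diff(train) > 0)
    with pytest.raises(GenerationError):
        generate_spike_train(10.0, 0.5, 2.0, seed=0)  # fr * duration < 10
    with pytest.raises(GenerationError):
        generate_spike_train(2.0, 30.0, 2.0, seed=0)


# --- RMS profiles ------------------------------------------------------------

def _central_geometry():
    atlas = default_atlas()
    target = atlas.stn.center - np.array([0, 0, atlas.stn.semi_axes[2]])
    return TrajectoryGeometry(target_point=target, direction=(0, 0, -1)), atlas


def test_rms_profile_stn_elevation():
    g, atlas = _central_geometry()
    p = generate_rms_profile("t", g, atlas, None, seed=1)
    span = stn_span(g, atlas)
    inside = (p.depths <= span[0]) & (p.depths >= span[1])
    above = p.depths > span[0]
    assert p.rms[inside].mean() > p.rms[above].mean()


def test_rms_profile_dose_suppression():
    g, atlas = _central_geometry()
    base = generate_rms_profile("t", g, atlas, None, seed=9)
    supp = generate_rms_profile("t", g, atlas, 7.5, seed=9)
    span = stn_span(g, atlas)
    inside = (base.depths <= span[0]) & (base.depths >= span[1])
    # same seed: identical noise, strictly lower plateau under 7.5 mg/kg/h
    assert np.all(supp.rms[inside] < base.rms[inside])
    assert nrms_suppression(3.0) == pytest.approx(1.0, abs=0.05)


def test_dose_response_monotonicity():
    doses = np.linspace(0.5, 10.0, 40)
    cfg = CohortConfig()
    supp = [nrms_suppression(d) for d in doses]
    sef = [expected_sef95(d, cfg) for d in doses]
    bi = [expected_bi_mean(d, cfg) for d in doses]
    assert np.all(np.diff(supp) <= 1e-12)
    assert np.all(np.diff(sef) <= 1e-12)
    assert np.all(np.diff(bi) >= -1e-12)


# --- EEG ---------------------------------------------------------------------

def test_eeg_determinism_and_errors():
    a = generate_eeg(15.0, seed=4)
    b = generate_eeg(15.0, seed=4)
    np.testing.assert_array_equal(a.channels, b.channels)
    assert a.channels.shape[0] == 4
    with pytest.raises(GenerationError):
        generate_eeg(0.2, seed=1)  # below the band
    with pytest.raises(GenerationError):
        generate_eeg(15.0, duration=10, seed=1)


# --- parameter fidelity ------------------------------------------------------

def test_feature_parameter_fidelity():
    """At n >= 1000 units of one condition, generated FR / BI / depth
    sample means land within 5% (relative) of the configured targets."""
    cfg = CohortConfig(
        n_patients=12,
        frac_la=1.0,
        trajectories_per_hemisphere=4,
        feature_params={
            "LA": synthetic.FeatureParams(28.47, 14.0, 5.59, 4.58, 2.32, 3.01, 12.0),
            "GA_low": synthetic.DEFAULT_FEATURE_PARAMS["GA_low"],
            "GA_high": synthetic.DEFAULT_FEATURE_PARAMS["GA_high"],
        },
        bi_distance_rho=0.0,
    )
    c = generate_cohort(cfg, seed=21)
    good = [s for s in c.segments
            if s.is_single_unit and s.snr >= 3 and s.duration >= 3
            and s.structure_imaging in ("STN", "SNr")]
    assert len(good) >= 1000
    frs, bis = [], []
    for s in good:
        isi = np.diff(s.spike_times)
        frs.append(sf.firing_rate(isi))
        if isi.size >= sf.MIN_ISI_FOR_BI:
            bis.append(sf.burst_index(isi, seed=0).bi)
    assert np.mean(frs) == pytest.approx(28.47, rel=0.05)
    assert np.mean(bis) == pytest.approx(5.59, rel=0.05)


def test_segments_respect_invariants(small_cohort):
    for s in small_cohort.segments:
        assert s.duration > 0
        if s.spike_times.size:
            assert 0 <= s.spike_times[0] and s.spike_times[-1] <= s.duration
            assert np.all(np.diff(s.spike_times) > 0)
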