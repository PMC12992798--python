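"""Unit-feature extraction: ISIs, firing rate, burst index, robust CV,
SNR estimation and the segment quality filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mertopo.exceptions import InsufficientDataError
from mertopo import spike_features as sf


# --- ISIs and firing rate ----------------------------------------------------

@pytest.mark.parametrize(
    "times, expected",
    [
        ([0.0, 0.1, 0.3], [0.1, 0.2]),
        (np.arange(0, 0.95, 0.1), [0.1] * 9),  # regular 10 Hz over 1 s
    ],
)
def test_interspike_intervals(times, expected):
    np.testing.assert_allclose(sf.interspike_intervals(times), expected, atol=1e-12)


def test_isi_errors():
    with pytest.raises(InsufficientDataError):
        sf.interspike_intervals([0.5])
    with pytest.raises(ValueError):
        sf.interspike_intervals([0.1, 0.1, 0.2])  # duplicate timestamp


@pytest.mark.parametrize(
    "isi, expected",
    [([0.1] * 9, 10.0), ([0.5], 2.0), ([0.1, 0.3], 5.0)],
)
def test_firing_rate(isi, expected):
    assert sf.firing_rate(isi) == pytest.approx(expected)


# --- robust CV ---------------------------------------------------------------

def test_cv_examples():
    assert sf.coefficient_of_variation([0.1] * 50) == 0.0
    # median 2, unscaled MAD 1
    assert sf.coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5)


def test_cv_exponential_closed_form(rng):
    """For Exp(1) ISIs, MAD/median -> asinh(1/2)/ln 2 (sinh(m) = 1/2)."""
    isi = rng.exponential(1.0, size=200_000)
    expected = np.arcsinh(0.5) / np.log(2)
    assert sf.coefficient_of_variation(isi) == pytest.approx(expected, rel=0.01)


# --- burst index -------------------------------------------------------------

def test_bi_two_point_masses():
    """Two ISI point masses at 5 and 50 ms force the component means."""
    isi = np.array([0.005] * 500 + [0.05] * 500)
    fit = sf.burst_index(isi, seed=0)
    assert not fit.degenerate
    assert fit.bi == pytest.approx(10.0, rel=0.01)


def test_bi_collapse_to_degenerate():
    isi = np.full(200, 0.010)
    fit = sf.burst_index(isi, seed=0)
    assert fit.degenerate
    assert fit.bi == 1.0


def test_bi_lognormal_mixture_oracle(rng):
    """Generating geometric-mean ratio 0.06/0.004 = 15 is recovered."""
    comp = rng.random(2000) < 0.5
    x = np.where(comp, np.log(0.004), np.log(0.06)) + rng.normal(0, 0.2, 2000)
    fit = sf.burst_index(np.exp(x), seed=3)
    assert fit.bi == pytest.approx(15.0, rel=0.10)


def test_bi_seed_independence_when_separated(rng):
    isi = np.concatenate([rng.lognormal(np.log(0.004), 0.2, 500),
                          rng.lognormal(np.log(0.06), 0.2, 500)])
    values = [sf.burst_index(isi, seed=s).bi for s in range(5)]
    assert np.ptp(values) / np.mean(values) < 1e-6


def test_bi_against_sklearn_gmm(rng):
    """Independent cross-check of the EM fit on a well-separated mixture."""
    from sklearn.mixture import GaussianMixture

    comp = rng.random(3000) < 0.4
    logisi = np.where(comp, np.log(0.005), np.log(0.045)) + rng.normal(0, 0.25, 3000)
    fit = sf.burst_index(np.exp(logisi), seed=0)
    gm = GaussianMixture(2, n_init=5, random_state=0).fit(logisi[:, None])
    mu = np.sort(gm.means_.ravel())
    assert fit.bi == pytest.approx(np.exp(mu[1] - mu[0]), rel=0.02)


def test_bi_min_isi_guard():
    with pytest.raises(InsufficientDataError):
        sf.burst_index(np.full(10, 0.01), seed=0)


def test_bi_linear_ratio_space(rng):
    isi = np.concatenate([rng.lognormal(np.log(0.004), 0.2, 1000),
                          rng.lognormal(np.log(0.06), 0.2, 1000)])
    geo = sf.burst_index(isi, seed=0, ratio_space="geometric").bi
    lin = sf.burst_index(isi, seed=0, ratio_space="linear").bi
    # equal component sigmas make the two readings agree closely here
    assert lin == pytest.approx(geo, rel=0.05)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 10))
def test_bi_scale_invariance_fr_covariance(scale, seed):
    """Multiplying ISIs by c leaves BI and CV unchanged, divides FR by c."""
    rng = np.random.default_rng(seed)
    isi = np.concatenate([rng.lognormal(np.log(0.005), 0.3, 200),
                          rng.lognormal(np.log(0.05), 0.3, 200)])
    bi0 = sf.burst_index(isi, seed=0).bi
    bi1 = sf.burst_index(isi * scale, seed=0).bi
    assert bi1 == pytest.approx(bi0, rel=1e-3)
    assert sf.firing_rate(isi * scale) == pytest.approx(sf.firing_rate(isi) / scale)
    assert sf.coefficient_of_variation(isi * scale) == pytest.approx(
        sf.coefficient_of_variation(isi)
    )


# --- SNR ---------------------------------------------------------------------

def test_snr_construction_oracle(rng):
    """A trace built with known peak amplitude A and noise sigma gives ~A/sigma."""
    sigma, amp = 2.0, 12.0
    trace = rng.normal(0, sigma, 50_000)
    idx = np.arange(500, 50_000, 500)
    trace[idx] = amp
    snr = sf.estimate_snr(trace, idx)
    assert snr == pytest.approx(amp / sigma, rel=0.10)


def test_snr_edge_cases():
    assert sf.estimate_snr(np.zeros(100), []) is None
    trace = np.zeros(1000)
    trace[[100, 500]] = 5.0
    assert sf.estimate_snr(trace, [100, 500]) == sf.SNR_CAP


# --- quality filter ----------------------------------------------------------

def _segment(seg_id, duration=5.0, snr=8.0, single=True, structure="STN"):
    times = np.linspace(0.05, duration - 0.05, 40)
    return sf.SpikeSegment(
        segment_id=seg_id, patient_id="P01", hemisphere="left",
        trajectory_id="T1", depth_to_target=2.0, duration=duration,
        spike_times=times, snr=snr, is_single_unit=single,
        structure_imaging=structure,
    )


def test_quality_filter_tally_and_precedence():
    segs = (
        [_segment(f"a{i}", duration=2.0) for i in range(2)]            # short
        + [_segment(f"b{i}", snr=1.0) for i in range(2)]               # low SNR
        + [_segment("b2", single=False)]                               # multi-unit
        + [_segment("c0", structure="other")]                          # anatomy
        + [_segment(f"d{i}") for i in range(4)]                        # clean
    )
    kept, tally = sf.quality_filter(segs)
    assert len(kept) == 4
    assert tally == {"short": 2, "snr": 3, "anatomy": 1}
    # a segment failing two rules is counted under the first rule only
    both = _segment("e0", duration=1.0, snr=0.5)
    _, tally2 = sf.quality_filter([both])
    assert tally2 == {"short": 1}


def test_quality_filter_all_pass():
    kept, tally = sf.quality_filter([_segment(f"x{i}") for i in range(3)])
    assert len(kept) == 3 and tally == {}
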