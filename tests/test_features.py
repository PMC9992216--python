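"""Feature operators: hand-computed examples, loop-oracle agreement, scaling
laws, and feature-matrix assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oracles
from emgsrd import SRDGroup, SegmentationParams, generate_recording
from emgsrd.features import (
    FeatureMatrix,
    FeatureParams,
    build_feature_matrix,
    feature_set_functions,
    m_asm,
    m_msr,
    mav,
    norm_logdet,
    norm_rsd,
    ntdf_vector,
    rms,
    sis,
    ssc,
    td4_vector,
    wl,
    zc,
)
from emgsrd.simulate import SimConfig, default_profiles

P = FeatureParams()


@pytest.mark.parametrize(
    "func,x,expected",
    [
        (mav, [1, -1, 2, -2], 1.5),
        (mav, [0, 0, 0], 0.0),
        (wl, [5, 5, 5], 0.0),
        (wl, [0, 1, 0, 1], 3.0),
        (sis, [1, 2, 2], 9.0),
        (sis, [0, 0], 0.0),
        (m_msr, [4, 9, 16], 3.0),
        (m_msr, [0, 0, 0], 0.0),
        (m_asm, [4, 4, 4, 4], (3 * 2 + 4**0.75) / 4),
        (m_asm, [0, 0, 0], 0.0),
        (rms, [3, 4], np.sqrt(12.5)),
        (rms, [-2, -2], 2.0),
        (norm_logdet, [1, 1, 1, 1], 0.25),
    ],
)
def test_hand_computed_values(func, x, expected):
    assert func(np.asarray(x, float)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "x,thr,expected",
    [
        ([1, -1, 1, -1], 0.01, 3),
        ([1, 2, 3], 0.01, 0),
        ([0.001, -0.001], 0.01, 0),
    ],
)
def test_zero_crossings(x, thr, expected):
    assert zc(np.asarray(x, float), FeatureParams(zc_threshold=thr)) == expected


@pytest.mark.parametrize(
    "x,expected",
    [([0, 1, 0, 1, 0], 3), ([1, 2, 3, 4], 0)],
)
def test_slope_sign_changes(x, expected):
    assert ssc(np.asarray(x, float), P) == expected


def test_norm_rsd_hand_value():
    # first difference of [0,2,0] is [2,-2]; normalize by k=3
    assert norm_rsd(np.array([0.0, 2.0, 0.0]), 1) == pytest.approx(
        np.sqrt(8 / 3), rel=1e-12
    )
    assert norm_rsd(np.array([3.0, 3.0, 3.0, 3.0]), 1) == 0.0
    assert norm_rsd(np.array([3.0, 3.0, 3.0, 3.0]), 2) == 0.0


_ORACLES = [
    (mav, oracles.mav_oracle),
    (wl, oracles.wl_oracle),
    (lambda x: zc(x, P), lambda x: oracles.zc_oracle(x, P.zc_threshold)),
    (lambda x: ssc(x, P), lambda x: oracles.ssc_oracle(x, P.ssc_threshold)),
    (sis, oracles.sis_oracle),
    (lambda x: norm_rsd(x, 1), oracles.norm_rsd1_oracle),
    (lambda x: norm_rsd(x, 2), oracles.norm_rsd2_oracle),
    (norm_logdet, oracles.norm_logdet_oracle),
    (m_msr, oracles.m_msr_oracle),
    (m_asm, oracles.m_asm_oracle),
    (rms, oracles.rms_oracle),
]


def test_operators_match_loop_oracles(rng):
    """All 11 operators agree with explicit-loop oracles on random windows."""
    for _ in range(100):
        k = int(rng.integers(3, 200))
        x = rng.normal(scale=rng.uniform(0.01, 10), size=k)
        for op, oracle in _ORACLES:
            assert op(x) == pytest.approx(oracle(list(x)), rel=1e-9, abs=1e-12)


@given(
    arrays(np.float64, st.integers(4, 60), elements=st.floats(-100, 100)),
    st.floats(0.1, 10),
)
def test_amplitude_scaling_laws(x, c):
    """MAV, WL, RMS scale by c; SIS by c^2; ZC/SSC invariant at zero threshold."""
    p0 = FeatureParams(zc_threshold=0.0, ssc_threshold=0.0)
    for op, power in [(mav, 1), (wl, 1), (rms, 1), (sis, 2)]:
        assert op(c * x) == pytest.approx(c**power * op(x), rel=1e-9, abs=1e-9)
    assert zc(c * x, p0) == zc(x, p0)
    assert ssc(c * x, p0) == ssc(x, p0)


def test_norm_logdet_homogeneity(rng):
    x = rng.normal(size=50)
    for c in (0.5, 3.0, 10.0):
        assert norm_logdet(c * x) == pytest.approx(c * norm_logdet(x), rel=1e-6)


def test_vector_compositions(rng):
    x = rng.normal(size=150)
    td4 = td4_vector(x, P)
    assert np.allclose(td4, [mav(x), wl(x), zc(x, P), ssc(x, P)])
    ntdf = ntdf_vector(x)
    expected = [sis(x), norm_rsd(x, 1), norm_rsd(x, 2), norm_logdet(x), m_msr(x), m_asm(x)]
    assert np.allclose(ntdf, expected)
    zeros = np.zeros(100)
    assert np.allclose(td4_vector(zeros, P), 0.0)
    assert m_asm(zeros) == 0.0


def test_operators_reject_too_short_windows():
    with pytest.raises(ValueError):
        wl(np.array([1.0]))
    with pytest.raises(ValueError):
        ssc(np.array([1.0, 2.0]), P)
    with pytest.raises(ValueError):
        mav(np.array([]))


def _two_recordings():
    cfg = SimConfig(n_subjects=1, fs=1000.0, duration_s=1.0, seed=3)
    profs = default_profiles(0)
    return [
        generate_recording(profs[0], cfg, subject_id=0, trial_index=1),
        generate_recording(profs[1], cfg, subject_id=0, trial_index=1),
    ]


@pytest.mark.parametrize("feature_set,d", [("TD4", 4), ("NTDF", 6), ("RMS", 1)])
def test_feature_matrix_shape(feature_set, d):
    """1 s at 1000 Hz with 150/100 ms windows gives 9 windows x 8 channels x d."""
    recs = _two_recordings()
    fm = build_feature_matrix(recs, SRDGroup(1.0), SegmentationParams(), feature_set)
    assert fm.values.shape == (18, 8 * d)
    assert np.all(np.isfinite(fm.values))
    assert list(fm.labels[:9]) == [recs[0].class_code] * 9
    # channel-major column order
    names = [f for _, f in [(None, n) for n in fm.columns]]
    assert names[0].startswith("ch1_") and names[d].startswith("ch2_")


def test_feature_matrix_concat_equals_union():
    recs = _two_recordings()
    srd, seg = SRDGroup(1.0), SegmentationParams()
    whole = build_feature_matrix(recs, srd, seg, "TD4")
    parts = [build_feature_matrix([r], srd, seg, "TD4") for r in recs]
    merged = FeatureMatrix.concat(parts)
    assert np.array_equal(whole.values, merged.values)
    assert np.array_equal(whole.labels, merged.labels)


def test_feature_matrix_mixed_fs_rejected():
    recs = _two_recordings()
    recs[1].fs = 2000.0
    with pytest.raises(ValueError):
        build_feature_matrix(recs, SRDGroup(0.5), SegmentationParams(), "RMS")


def test_feature_matrix_csv_roundtrip(tmp_path):
    fm = build_feature_matrix(
        _two_recordings(), SRDGroup(1.0), SegmentationParams(), "NTDF"
    )
    path = tmp_path / "fm.csv"
    fm.to_csv(path)
    back = FeatureMatrix.from_csv(path)
    assert np.allclose(back.values, fm.values, rtol=0, atol=1e-15)
    assert np.array_equal(back.labels, fm.labels)
    assert back.columns == fm.columns
    assert back.meta == fm.meta
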