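import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram

from swdeemd import (
    DEFAULT_FEATURES,
    EEMDConfig,
    EXTENDED_FEATURES,
    SynthConfig,
    WindowConfig,
    build_feature_matrix,
    extract_features,
    preprocess_wd_eemd,
    window_signal,
)
from swdeemd.synthetic import gen_components


def brute_force_features(y):
    """Loop-level evaluation of the nine printed formulas, independent of
    the vectorised implementation."""
    m = len(y)
    mav = sum(abs(v) for v in y) / m
    rms = (sum(v * v for v in y) / m) ** 0.5
    zc = sum(
        1
        for j in range(m - 1)
        if (y[j] > 0 and y[j + 1] < 0) or (y[j] < 0 and y[j + 1] > 0)
    )
    ssc = sum(
        1
        for j in range(1, m - 1)
        if (y[j] > y[j - 1] and y[j] > y[j + 1])
        or (y[j] < y[j - 1] and y[j] < y[j + 1])
    )
    var = sum(v * v for v in y) / (m - 1)
    dasdv = (sum((y[j + 1] - y[j]) ** 2 for j in range(m - 1)) / (m - 1)) ** 0.5
    aac = sum(abs(y[j + 1] - y[j]) for j in range(m - 1)) / m
    mu = sum(y) / m
    sigma = (sum((v - mu) ** 2 for v in y) / m) ** 0.5
    if sigma == 0:
        skew = kurt = 0.0
    else:
        skew = sum((v - mu) ** 3 for v in y) / m / sigma**3
        kurt = sum((v - mu) ** 4 for v in y) / m / sigma**4
    return dict(
        MAV=mav, RMS=rms, ZC=zc, SSC=ssc, VAR=var, DASDV=dasdv, AAC=aac,
        Skew=skew, Kurt=kurt,
    )


def test_hand_evaluated_examples():
    got = extract_features(np.array([1.0, -1.0, 2.0, -2.0])).as_dict()
    assert got["MAV"] == pytest.approx(1.5)
    assert got["ZC"] == 3
    assert got["AAC"] == pytest.approx(2.25)


def test_constant_window():
    c = -4.0
    fv = extract_features(np.full(4, c))
    got = fv.as_dict()
    assert got["MAV"] == got["RMS"] == abs(c)
    assert got["ZC"] == got["SSC"] == got["DASDV"] == got["AAC"] == 0
    assert got["VAR"] == pytest.approx(4 * c * c / 3)  # literal sum-of-squares form
    assert got["Skew"] == got["Kurt"] == 0.0 and fv.degenerate


def test_literal_variance_vs_central_option():
    ones = np.ones(4)
    assert extract_features(ones).as_dict()["VAR"] == pytest.approx(4 / 3)
    assert (
        extract_features(ones, central_variance=True).as_dict()["VAR"] == 0.0
    )


def test_matches_brute_force_oracle(rng):
    for _ in range(200):
        y = rng.standard_normal(rng.integers(3, 200))
        got = extract_features(y).as_dict()
        want = brute_force_features(list(y))
        for name in DEFAULT_FEATURES:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name


def test_gaussian_moments(rng):
    y = rng.standard_normal(100_000)
    got = extract_features(y).as_dict()
    assert abs(got["Skew"]) < 0.03
    assert abs(got["Kurt"] - 3.0) < 0.1


@settings(max_examples=50, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 1000))
def test_scale_behaviour(scale, seed):
    y = np.random.default_rng(seed).standard_normal(64)
    base = extract_features(y).as_dict()
    scaled = extract_features(scale * y).as_dict()
    for lin in ("MAV", "RMS", "DASDV", "AAC"):
        assert scaled[lin] == pytest.approx(scale * base[lin], rel=1e-9)
    assert scaled["VAR"] == pytest.approx(scale**2 * base["VAR"], rel=1e-9)
    for inv in ("ZC", "SSC", "Skew", "Kurt"):
        assert scaled[inv] == pytest.approx(base[inv], rel=1e-9, abs=1e-9)


def test_counting_extremes():
    alternating = np.array([1.0, -1.0] * 10)  # M = 20
    got = extract_features(alternating).as_dict()
    assert got["ZC"] == 19 and got["SSC"] == 18
    monotone = np.arange(20.0)
    assert extract_features(monotone).as_dict()["SSC"] == 0


def test_feature_window_validation():
    with pytest.raises(ValueError):
        extract_features(np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        extract_features(np.array([1.0, np.nan, 2.0]))
    with pytest.raises(ValueError):
        extract_features(np.ones(5), bank=("MAV", "XYZ"))


def test_window_boundaries():
    cfg = WindowConfig()
    assert cfg.window_samples == 256 and cfg.step_samples == 192
    wins = window_signal(np.arange(1000.0), cfg)
    assert len(wins) == 4  # floor((1000-256)/192)+1
    assert [int(w[0]) for w in wins] == [0, 192, 384, 576]
    assert len(window_signal(np.arange(256.0), cfg)) == 1
    assert window_signal(np.arange(255.0), cfg) == []


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 3000),
    w_ms=st.integers(2, 500),
    overlap=st.floats(0.0, 0.9),
)
def test_window_index_bookkeeping(n, w_ms, overlap):
    cfg = WindowConfig(window_ms=w_ms, overlap_fraction=overlap)
    x = np.arange(float(n))
    wins = window_signal(x, cfg)
    w, s = cfg.window_samples, cfg.step_samples
    expected = 0 if n < w else (n - w) // s + 1
    assert len(wins) == expected
    for i, win in enumerate(wins):
        assert len(win) == w and win[0] == i * s  # starts at 0, S, 2S, ...


def test_preprocess_zero_signal_and_additivity(fast_eemd_cfg):
    out = preprocess_wd_eemd(np.zeros(600), eemd_cfg=fast_eemd_cfg)
    assert np.abs(out).max() == 0.0
    # output is exactly (everything) minus (residual + modes beyond 3)
    rng = np.random.default_rng(8)
    x = rng.standard_normal(900)
    from swdeemd import eemd, wd_denoise

    den = wd_denoise(x)
    modes = eemd(den, fast_eemd_cfg)
    expect = modes.reconstruct() - (modes.sum_imfs() - modes.sum_imfs(3)) - modes.residual
    np.testing.assert_allclose(
        preprocess_wd_eemd(x, eemd_cfg=fast_eemd_cfg), expect, atol=1e-10
    )


def test_preprocess_removes_low_frequency_contaminants():
    """PLI + baseline wander: the kept IMF1-3 sum loses >=80% of the
    sub-5 Hz band power (it lands in discarded modes and residual)."""
    cfg = SynthConfig(healthy_duration_s=4.0)
    parts = gen_components(cfg, "healthy", seed=11)
    x = (parts["clean"] + parts["wgn"] + parts["pli"] + parts["baseline"])[:, 0]
    out = preprocess_wd_eemd(x, eemd_cfg=EEMDConfig(ensemble_size=10, seed=2))

    def low_power(sig):
        f, p = periodogram(sig, fs=cfg.sampling_rate)
        return p[f < 5.0].sum()

    assert low_power(out) <= 0.2 * low_power(x)


def test_build_matrix_shapes_and_row_counts(small_dataset, win_cfg):
    m = build_feature_matrix(small_dataset[:2], arm="raw")
    expected_rows = sum(
        len(window_signal(r.samples[:, 0], win_cfg)) for r in small_dataset[:2]
    )
    assert m.n_rows == expected_rows
    assert m.n_columns == 4 * 9
    assert m.column_names[0] == "RF_MAV" and m.column_names[-1] == "ST_Kurt"
    ext = build_feature_matrix(small_dataset[:1], arm="raw", bank=EXTENDED_FEATURES)
    assert ext.n_columns == 44


def test_build_matrix_empty_and_mismatch(small_dataset):
    empty = build_feature_matrix([])
    assert empty.n_rows == 0 and empty.n_columns == 36
    from swdeemd import Recording

    odd = Recording(
        samples=np.random.default_rng(0).standard_normal((500, 2)),
        channel_names=("RF", "BF"),
    )
    with pytest.raises(ValueError, match="channel mismatch"):
        build_feature_matrix([small_dataset[0], odd], arm="raw")
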