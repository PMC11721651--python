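"""EDA windowing, specific-response classification and resonance detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resogest.corpus import EDATrace
from resogest.eda import (
    CoverageError,
    InsufficientDataError,
    ResponseWindow,
    classify_specific,
    detect_resonance,
    extract_window,
)
from resogest.simulate import SimConfig, scr_kernel, simulate_corpus
from resogest.features import build_feature_table
from resogest.eda import append_eda_outcomes, build_response_table

from conftest import simple_gesture


def _window(samples):
    return ResponseWindow(
        gesture_id="g", participant_id="p", window_start=0.0,
        window_end=len(samples) / 4.0, samples=np.asarray(samples, float),
    )


# ---------------------------------------------------------------------------
# window extraction


def test_extract_window_half_open_sample_count():
    # gesture 2.0-3.0 s, pad 1.5 -> [2.0, 4.5) at 4 Hz = 10 samples
    g = simple_gesture(onset=2.0, offset=3.0, nucleus=(2.2, 2.8))
    trace = EDATrace("p", [2.0] * 40, sampling_rate=4.0, t0=0.0)
    w = extract_window(g, trace)
    assert len(w.samples) == 10
    assert not w.truncated
    assert w.window_start == 2.0 and w.window_end == 4.5


def test_extract_window_truncation_flagged():
    g = simple_gesture(onset=2.0, offset=4.0, nucleus=(2.2, 3.8))
    trace = EDATrace("p", [2.0] * 20, sampling_rate=4.0, t0=0.0)  # ends at 5
    w = extract_window(g, trace)
    assert w.truncated
    assert len(w.samples) == 12  # [2.0, 5.0) available


def test_extract_window_outside_trace_is_coverage_error():
    g = simple_gesture(onset=20.0, offset=22.0, nucleus=(20.4, 21.4))
    trace = EDATrace("p", [2.0] * 20, sampling_rate=4.0, t0=0.0)
    with pytest.raises(CoverageError):
        extract_window(g, trace)


# ---------------------------------------------------------------------------
# specific classification


def test_constant_window_not_specific():
    w = classify_specific(_window([2.0] * 8))
    assert w.amplitude == 0.0 and w.specific is False


def test_rise_above_threshold_is_specific():
    w = classify_specific(_window([0.30, 0.32, 0.35, 0.37]))
    assert w.amplitude == pytest.approx(0.07)
    assert w.specific is True


def test_exact_threshold_rise_is_not_specific():
    w = classify_specific(_window([0.30, 0.35]))
    assert w.amplitude == pytest.approx(0.05)
    assert w.specific is False  # strictly larger than 0.05 required


def test_declining_window_amplitude_floored_at_zero():
    w = classify_specific(_window([2.5, 2.4, 2.3, 2.2]))
    assert w.amplitude == 0.0


def test_single_sample_window_rejected():
    with pytest.raises(InsufficientDataError):
        classify_specific(_window([2.0]))


@given(
    st.lists(st.floats(0.01, 50.0, allow_nan=False), min_size=2,
             max_size=100)
)
@settings(max_examples=200, deadline=None)
def test_amplitude_matches_bruteforce_pairwise_max(samples):
    """Running-minimum amplitude equals the brute-force maximum of
    samples[j] - samples[i] over all ordered pairs i < j."""
    w = classify_specific(_window(samples))
    brute = max(
        0.0,
        max(samples[j] - samples[i]
            for i in range(len(samples))
            for j in range(i + 1, len(samples))),
    )
    assert w.amplitude == pytest.approx(brute, abs=1e-12)


@given(
    st.floats(0.05, 1.0),
    st.floats(0.0, 3.0),
    st.integers(8, 40),
    st.booleans(),
)
@settings(max_examples=100, deadline=None)
def test_scr_on_monotone_baseline_never_lowers_amplitude(
    amp, onset, n, declining
):
    """Adding a causal SCR onto a monotone baseline cannot decrease the
    trough-to-peak amplitude of the window."""
    t = np.arange(n) / 4.0
    base = 2.0 + (-0.01 if declining else 0.01) * t
    before = classify_specific(_window(base)).amplitude
    bump = scr_kernel(t - onset, amp, 0.75, 2.0)
    after = classify_specific(_window(base + bump)).amplitude
    assert after >= before - 1e-12


def test_lower_threshold_never_reduces_specific_count():
    rng = np.random.default_rng(5)
    windows = [_window(2.0 + np.cumsum(rng.normal(0, 0.02, 12)))
               for _ in range(40)]
    counts = []
    for thr in (0.10, 0.05, 0.02, 0.01):
        counts.append(
            sum(classify_specific(w, thr).specific for w in windows)
        )
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# resonance


def _classified(gid, pid, specific):
    w = _window([2.0, 2.0, 2.0, 2.0])
    w.gesture_id, w.participant_id = gid, pid
    w.amplitude, w.specific = (0.2, True) if specific else (0.0, False)
    return w


def test_triad_narrator_plus_one_recipient_resonates():
    g = simple_gesture("g1")
    windows = [_classified("g1", "narr", True),
               _classified("g1", "recB", True),
               _classified("g1", "recC", False)]
    rec = detect_resonance(g, windows)
    assert rec.n_specific == 2 and rec.EDA_G_resonance is True


def test_narrator_alone_does_not_resonate():
    g = simple_gesture("g1")
    windows = [_classified("g1", "narr", True),
               _classified("g1", "recB", False),
               _classified("g1", "recC", False)]
    assert detect_resonance(g, windows).EDA_G_resonance is False


def test_dyad_both_specific_resonates():
    g = simple_gesture("g1")
    windows = [_classified("g1", "narr", True),
               _classified("g1", "recB", True)]
    assert detect_resonance(g, windows).EDA_G_resonance is True


def test_two_recipients_without_narrator_depends_on_flag():
    g = simple_gesture("g1")
    windows = [_classified("g1", "narr", False),
               _classified("g1", "recB", True),
               _classified("g1", "recC", True)]
    assert detect_resonance(g, windows).EDA_G_resonance is True
    strict = detect_resonance(
        g, windows, require_narrator=True, narrator_id="narr"
    )
    assert strict.EDA_G_resonance is False


def test_mismatched_gesture_id_rejected():
    g = simple_gesture("g1")
    with pytest.raises(ValueError, match="g2"):
        detect_resonance(g, [_classified("g2", "narr", True)])


# ---------------------------------------------------------------------------
# recovery against simulator ground truth


def test_specific_detection_recovers_ground_truth():
    """In the high-SNR regime, window classification recovers the true
    per-gesture, per-participant response indicators with sensitivity and
    specificity >= 0.95."""
    cfg = SimConfig.detection_recovery(
        n_recordings=3, stories_per_recording=3, gestures_per_story=(6, 14),
        seed=0,
    )
    hits = {True: [0, 0], False: [0, 0]}  # truth -> [n, correct]
    for rec in simulate_corpus(cfg):
        table = build_feature_table(
            rec.recording, rec.stories, rec.gestures, rec.ipus, rec.quotes
        )
        table = append_eda_outcomes(table, rec.gestures, rec.traces)
        resp = build_response_table(table, rec.gestures, rec.traces)
        for _, row in resp.iterrows():
            truth = rec.truth.responses[row.gesture_id][row.participant_id]
            hits[truth][0] += 1
            hits[truth][1] += bool(row.EDA_specific) == truth
    sensitivity = hits[True][1] / hits[True][0]
    specificity = hits[False][1] / hits[False][0]
    assert sensitivity >= 0.95
    assert specificity >= 0.95
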