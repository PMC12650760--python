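"""Codon profiles, smoothing, normalization, classification, onset."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from riboprox import (
    CodonCounts,
    GeneClass,
    LibraryStats,
    TranscriptModel,
    classify_gene,
    codon_log2_profile,
    coverage_gate,
    estimate_onset,
    metagene_curve,
    normalize_profile,
    smooth_profile,
)
from riboprox.enrichment import EnrichmentRecord
from riboprox.metagene import PositionalProfile


def make_counts(gene_id, counts, library_id="lib"):
    arr = np.asarray(counts, dtype=float)
    return CodonCounts(gene_id, library_id, arr, float(arr.sum()), 0)


def brute_force_smooth(raw, hw=10):
    out = []
    n = len(raw)
    for i in range(n):
        window = raw[max(0, i - hw) : min(n, i + hw + 1)]
        out.append(sum(window) / len(window))
    return np.array(out)


def brute_force_onset(values, rise=0.5, sustain=50):
    n = len(values)
    for p in range(1, n + 1):
        end = min(p + sustain, n)
        if all(values[i - 1] >= rise for i in range(p, end + 1)):
            return p
    return None


# ---------------------------------------------------------------------------
# raw profile
# ---------------------------------------------------------------------------


def test_codon_log2_profile_pseudocount_arithmetic():
    # totals of 1e6 make count == RPM
    stats = LibraryStats("lib", 1e6)
    pd = make_counts("G", [0.7, 0.0, 0.0])
    inp = make_counts("G", [0.3, 0.0, 0.3])
    raw = codon_log2_profile(pd, inp, stats, stats)
    assert raw[0] == pytest.approx(1.0)  # log2(0.8 / 0.4)
    assert raw[1] == pytest.approx(0.0)  # log2(0.1 / 0.1)
    assert raw[2] == pytest.approx(-2.0)  # log2(0.1 / 0.4)


def test_codon_profile_rejects_length_mismatch():
    stats = LibraryStats("lib", 1e6)
    with pytest.raises(ValueError):
        codon_log2_profile(make_counts("G", [1, 2]), make_counts("G", [1, 2, 3]), stats, stats)


def test_raw_profile_depth_invariance():
    stats = LibraryStats("lib", 1e6)
    pd = make_counts("G", [5.0, 2.0, 0.0, 7.5])
    inp = make_counts("G", [1.0, 2.0, 3.0, 4.0])
    base = codon_log2_profile(pd, inp, stats, stats)
    for k in (2, 10):
        pd_k = make_counts("G", np.asarray([5.0, 2.0, 0.0, 7.5]) * k)
        scaled = codon_log2_profile(pd_k, inp, LibraryStats("lib", 1e6 * k), stats)
        np.testing.assert_allclose(scaled, base, atol=1e-12)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def test_smoothing_constant_profile_is_fixed_point():
    np.testing.assert_allclose(smooth_profile(np.full(57, 3.25)), np.full(57, 3.25))


def test_smoothing_length_one_is_identity():
    np.testing.assert_allclose(smooth_profile(np.array([2.5])), [2.5])


def test_smoothing_first_codons_average_preceding_plus_ten_subsequent():
    ramp = np.arange(1.0, 101.0)
    sm = smooth_profile(ramp)
    # codon 1: mean of codons 1..11; codon 5: mean of codons 1..15
    assert sm[0] == pytest.approx(np.mean(ramp[0:11]))
    assert sm[4] == pytest.approx(np.mean(ramp[0:15]))
    # interior codon 50: mean of codons 40..60; last codon: mean of 90..100
    assert sm[49] == pytest.approx(np.mean(ramp[39:60]))
    assert sm[99] == pytest.approx(np.mean(ramp[89:100]))


def test_smoothing_matches_bruteforce_on_random_profiles(rng):
    for n in (1, 2, 5, 10, 11, 21, 50, 199):
        raw = rng.normal(size=n)
        np.testing.assert_allclose(smooth_profile(raw), brute_force_smooth(list(raw)), atol=1e-9)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_normalize_example_and_degenerate_case():
    np.testing.assert_allclose(
        normalize_profile([0.5, -2.0, 1.0]), [0.25, -1.0, 0.5]
    )
    np.testing.assert_allclose(normalize_profile(np.zeros(5)), np.zeros(5))


@given(
    hnp.arrays(
        float,
        st.integers(1, 200),
        elements=st.floats(-1e6, 1e6, allow_nan=False),
    )
)
def test_normalization_bounded_and_idempotent(values):
    normalized = normalize_profile(values)
    assert np.all(np.abs(normalized) <= 1.0 + 1e-12)
    if np.any(values != 0):
        assert np.max(np.abs(normalized)) == pytest.approx(1.0)
    np.testing.assert_allclose(normalize_profile(normalized), normalized, atol=1e-12)


# ---------------------------------------------------------------------------
# coverage gate
# ---------------------------------------------------------------------------


def test_coverage_gate_boundary_inclusive(params):
    gate = lambda total: coverage_gate(
        CodonCounts("G", "inp", np.full(200, total / 200), total, 0), params
    )
    assert gate(600.0) is True  # mean exactly 3.0
    assert gate(599.9) is False
    assert coverage_gate(CodonCounts("G", "inp", np.empty(0), 0.0, 0), params) is False


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def record(log2, passed=True):
    return EnrichmentRecord("G", 2.0 ** log2, 1.0, log2, 100.0, passed, True)


@pytest.mark.parametrize(
    "log2,length,expected",
    [
        (1.8, 520, GeneClass.LONG_COTRANSLATIONAL),
        (2.3, 150, GeneClass.SHORT_MRNA_TARGETED),
        (-0.5, 520, GeneClass.POST_TRANSLATIONAL),
        (2.0, 300, GeneClass.UNCLASSIFIED),  # between the length cut-offs
        (1.0, 520, GeneClass.UNCLASSIFIED),  # between the enrichment thresholds
        (-0.2, 520, GeneClass.UNCLASSIFIED),
        (1.5, 520, GeneClass.UNCLASSIFIED),  # thresholds are strict
        (-0.3, 520, GeneClass.UNCLASSIFIED),
    ],
)
def test_classification_rules(log2, length, expected, params):
    assert classify_gene(record(log2), length, params) is expected


def test_classification_requires_filter_passing_record(params):
    with pytest.raises(ValueError):
        classify_gene(record(2.0, passed=False), 520, params)


# ---------------------------------------------------------------------------
# metagene aggregation
# ---------------------------------------------------------------------------


def profile(gene_id, normalized):
    arr = np.asarray(normalized, dtype=float)
    return PositionalProfile(gene_id, arr, arr, arr, 5.0, True)


def test_metagene_mean_and_short_transcript_exclusion():
    profiles = {
        "A": profile("A", [0.2, 0.2]),
        "B": profile("B", [0.6, 0.6, 0.9]),
    }
    curve = metagene_curve(profiles, ["A", "B"])
    assert curve.mean[0] == pytest.approx(0.4)
    assert list(curve.n_transcripts) == [2, 2, 1]
    # beyond the shorter transcript: only B contributes, sd collapses to 0
    assert curve.mean[2] == pytest.approx(0.9)
    assert curve.sd[2] == 0.0


def test_metagene_single_member_equals_its_profile():
    p = profile("A", [0.1, -0.4, 1.0])
    curve = metagene_curve({"A": p}, ["A"])
    np.testing.assert_allclose(curve.mean, p.normalized)
    assert np.all(curve.sd == 0.0)


def test_metagene_membership_counts_non_increasing(rng):
    profiles = {
        f"G{i}": profile(f"G{i}", rng.normal(size=int(rng.integers(1, 80))))
        for i in range(25)
    }
    curve = metagene_curve(profiles, list(profiles))
    assert np.all(np.diff(curve.n_transcripts) <= 0)


def test_metagene_empty_membership_gives_empty_curve():
    assert len(metagene_curve({}, [])) == 0


# ---------------------------------------------------------------------------
# onset estimation
# ---------------------------------------------------------------------------


def test_onset_none_without_crossing_and_first_codon_when_constant():
    assert estimate_onset(np.zeros(400)) is None
    assert estimate_onset(np.ones(400)) == 1
    assert estimate_onset(np.empty(0)) is None


def test_onset_ignores_transient_peaks():
    v = np.zeros(400)
    v[100:120] = 1.0  # 20-codon blip, shorter than the 50-codon sustain
    v[300:] = 1.0
    assert estimate_onset(v) == 301


def test_onset_on_smoothed_step_matches_bruteforce_oracle():
    """A hard step at codon 300, smoothed and normalized, yields an onset
    within a window of the true step, and agrees with the rule's
    brute-force evaluation exactly."""
    step = np.zeros(600)
    step[299:] = 1.0  # first enriched codon is codon 300 (1-based)
    normalized = normalize_profile(smooth_profile(step))
    onset = estimate_onset(normalized)
    assert onset == brute_force_onset(list(normalized))
    assert 290 <= onset <= 311


def test_onset_matches_bruteforce_on_noisy_profiles(rng):
    for _ in range(20):
        v = np.clip(rng.normal(0.45, 0.3, size=200), -1, 1)
        assert estimate_onset(v) == brute_force_onset(list(v))
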