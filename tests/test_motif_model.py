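import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regulon_rewire import motif_model as mm
from conftest import random_pssm


# ---------------------------------------------------------------------------
# PSSM construction and scoring
# ---------------------------------------------------------------------------

def test_toy_pssm_frequencies_and_ic(toy_pssm):
    # free position: each base seen once in four sites
    assert np.allclose(toy_pssm.freq[2], [0.25, 0.25, 0.25, 0.25])
    assert toy_pssm.ic == pytest.approx(8.0)


def test_single_site_ic_is_two_bits_per_position():
    p = mm.build_pssm(["GAT"], pseudocount=0.0)
    assert p.ic == pytest.approx(6.0)


def test_uniform_pssm_has_zero_ic(uniform_pssm):
    assert uniform_pssm.ic == pytest.approx(0.0)
    assert mm.score_word(uniform_pssm, "AC") == pytest.approx(0.0)
    assert mm.score_word(uniform_pssm, "TG") == pytest.approx(0.0)


def test_score_word_consensus_and_sentinel(toy_pssm):
    assert mm.score_word(toy_pssm, "GAATC") == pytest.approx(8.0)
    assert mm.score_word(toy_pssm, "TAATC") == -math.inf


def test_score_word_validates_input(toy_pssm):
    with pytest.raises(ValueError):
        mm.score_word(toy_pssm, "GAAT")
    with pytest.raises(ValueError):
        mm.score_word(toy_pssm, "GAXTC")


def test_build_pssm_rejects_ragged_and_empty():
    with pytest.raises(ValueError):
        mm.build_pssm([])
    with pytest.raises(ValueError):
        mm.build_pssm(["GAATC", "GAAT"])


@settings(deadline=None, derandomize=True, max_examples=30)
@given(seed=st.integers(0, 10_000), length=st.integers(1, 8))
def test_ic_nonnegative_and_rows_normalized(seed, length):
    p = random_pssm(np.random.default_rng(seed), length)
    assert p.ic >= 0
    assert np.allclose(p.freq.sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# Mixture
# ---------------------------------------------------------------------------

def test_mixture_weights_default_to_collection_sizes():
    ten = ["GAATC"] * 10
    thirty = ["GATTC"] * 30
    mix = mm.build_mixture([ten, thirty])
    assert mix.weights == pytest.approx((0.25, 0.75))
    mix2 = mm.build_mixture([ten, thirty], weights=[0.5, 0.5])
    assert mix2.weights == pytest.approx((0.5, 0.5))
    single = mm.build_mixture([ten])
    assert single.weights == (1.0,)


def test_mixture_of_identical_components_scores_like_component():
    sites = ["GAATC", "GACTC", "GAGTC", "GATTC"]
    comp = mm.build_pssm(sites)
    mix = mm.build_mixture([sites, sites], weights=[0.3, 0.7])
    for word in ("GAATC", "TTTTT", "GATTC"):
        assert mm.score_mixture(mix, word) == pytest.approx(mm.score_word(comp, word))


def test_mixture_with_degenerate_weight_equals_first_component(toy_pssm, uniform_pssm):
    sites_a = ["GAATC", "GACTC", "GAGTC", "GATTC"]
    sites_b = ["AAAAA"] * 4
    mix = mm.build_mixture([sites_a, sites_b], weights=[1.0, 0.0], pseudocount=0.0)
    comp = mm.build_pssm(sites_a, pseudocount=0.0)
    assert mm.score_mixture(mix, "GAATC") == pytest.approx(mm.score_word(comp, "GAATC"))


def test_mixture_logsumexp_of_zero_and_neginf_is_minus_one():
    # component 1 scores 0 everywhere; component 2 scores -inf on 'C'
    uniform = list("ACGT")
    only_a = ["A"]
    mix = mm.build_mixture([uniform, only_a], weights=[0.5, 0.5], pseudocount=0.0)
    assert mm.score_mixture(mix, "C") == pytest.approx(-1.0)


def test_mixture_rejects_length_mismatch():
    with pytest.raises(ValueError):
        mm.build_mixture([["GAATC"], ["GAAT"]])


# ---------------------------------------------------------------------------
# Exact score distribution and FPR
# ---------------------------------------------------------------------------

def test_toy_distribution_probability_of_consensus(toy_pssm):
    dist = mm.exact_score_distribution(toy_pssm)
    assert dist.prob.sum() == pytest.approx(1.0)
    assert mm.fpr_at(dist, 8.0) == pytest.approx(1 / 256)
    assert mm.fpr_at(dist, float(dist.support[0])) == pytest.approx(1.0)
    assert mm.fpr_at(dist, math.inf) == 0.0


def test_convolution_matches_enumeration_for_toy(toy_pssm):
    de = mm.exact_score_distribution(toy_pssm, method="enumerate")
    dc = mm.exact_score_distribution(toy_pssm, method="convolve")
    assert np.allclose(de.support, dc.support)
    assert np.allclose(de.prob, dc.prob)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10_000), length=st.integers(2, 8))
def test_convolution_matches_enumeration_random_pssms(seed, length):
    """The two exact-distribution routes agree within one bin."""
    p = random_pssm(np.random.default_rng(seed), length)
    de = mm.exact_score_distribution(p, method="enumerate")
    dc = mm.exact_score_distribution(p, method="convolve")
    delta = de.bin_width
    for t in np.linspace(de.support[0], de.support[-1], 23):
        assert mm.fpr_at(dc, t + delta + 1e-9) - 1e-9 <= mm.fpr_at(de, t) <= mm.fpr_at(dc, t - delta - 1e-9) + 1e-9


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10_000))
def test_fpr_nonincreasing_in_threshold(seed):
    p = random_pssm(np.random.default_rng(seed), 5)
    dist = mm.exact_score_distribution(p)
    fprs = [mm.fpr_at(dist, t) for t in dist.support]
    assert all(a >= b - 1e-12 for a, b in zip(fprs, fprs[1:]))
    assert fprs[0] == pytest.approx(1.0)


def test_mixture_distribution_requires_enumeration():
    sites = ["GAATC"] * 3
    mix = mm.build_mixture([sites, ["GATTC"] * 3])
    with pytest.raises(ValueError):
        mm.exact_score_distribution(mix, method="convolve")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def test_calibration_toy_threshold_is_ic(toy_pssm):
    thr = mm.calibrate_threshold(toy_pssm)
    assert thr.t == pytest.approx(8.0)
    assert thr.achieved_fpr == pytest.approx(2.0 ** -8)
    assert not thr.saturated


def test_calibration_uniform_motif_accepts_everything(uniform_pssm):
    thr = mm.calibrate_threshold(uniform_pssm)
    dist = mm.exact_score_distribution(uniform_pssm)
    assert thr.t == pytest.approx(float(dist.support[0]))
    assert thr.achieved_fpr == pytest.approx(1.0)


def test_calibration_threshold_weakly_increases_with_ic():
    sites = ["GAATC", "GACTC", "GAGTC", "GATTC"]
    doubled = [s + s for s in sites]
    t1 = mm.calibrate_threshold(mm.build_pssm(sites, pseudocount=0.25))
    t2 = mm.calibrate_threshold(mm.build_pssm(doubled, pseudocount=0.25))
    assert t2.ic > t1.ic
    assert t2.t >= t1.t


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10_000), length=st.integers(2, 7))
def test_calibration_invariants(seed, length):
    """-log2 FPR(t*) >= IC, and the preceding support point fails the bound."""
    p = random_pssm(np.random.default_rng(seed), length)
    dist = mm.exact_score_distribution(p)
    thr = mm.calibrate_threshold(p, dist=dist)
    if thr.saturated:
        return
    assert -math.log2(thr.achieved_fpr) >= thr.ic - 1e-9
    finite = dist.support[np.isfinite(dist.support)]
    below = finite[finite < thr.t]
    if below.size and thr.ic > 0:
        prev = float(below[-1])
        assert -math.log2(mm.fpr_at(dist, prev)) < thr.ic


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def test_pssm_tsv_roundtrip(tmp_path, toy_pssm):
    path = tmp_path / "motif.tsv"
    mm.write_pssm(toy_pssm, path)
    back = mm.read_pssm(path)
    assert np.allclose(back.freq, toy_pssm.freq)
    assert np.allclose(back.background, toy_pssm.background)
    assert back.ic == pytest.approx(toy_pssm.ic)
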