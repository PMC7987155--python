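import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from regulon_rewire import conservation_scoring as cons
from regulon_rewire.genome_scan import MotifHit


def _hit(score, start=0):
    return MotifHit("c", start, start + 7, "+", score=score)


def _toy_group():
    return cons.OrthologGroup(
        "g1",
        members={"A": "a1", "B": "b1", "C": "c1"},
        hits={"A": [_hit(8.0), _hit(6.0, 20)], "B": [_hit(7.0)], "C": []},
    )


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

def test_rbh_diagonal_dominant_pairs_all():
    table = pd.DataFrame([[9.0, 1.0], [2.0, 8.0]], index=["a1", "a2"], columns=["b1", "b2"])
    omap = cons.reciprocal_best_hits(table)
    assert set(omap.pairs) == {("a1", "b1"), ("a2", "b2")}


def test_rbh_requires_reciprocity():
    # a2's best is b1, but b1's best is a1
    table = pd.DataFrame([[9.0, 1.0], [5.0, 2.0]], index=["a1", "a2"], columns=["b1", "b2"])
    omap = cons.reciprocal_best_hits(table)
    assert set(omap.pairs) == {("a1", "b1")}


def test_rbh_tie_for_best_pairs_nothing():
    table = pd.DataFrame([[5.0, 5.0]], index=["a1"], columns=["b1", "b2"])
    assert cons.reciprocal_best_hits(table).pairs == ()


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000), na=st.integers(1, 8), nb=st.integers(1, 8))
def test_rbh_is_symmetric(seed, na, nb):
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(rng.random((na, nb)),
                         index=[f"a{i}" for i in range(na)],
                         columns=[f"b{j}" for j in range(nb)])
    fwd = set(cons.reciprocal_best_hits(table).pairs)
    rev = {(a, b) for b, a in cons.reciprocal_best_hits(table.T).pairs}
    assert fwd == rev


# ---------------------------------------------------------------------------
# <WSmax>
# ---------------------------------------------------------------------------

def test_group_statistics_toy_values():
    score = cons.group_statistics(_toy_group())
    assert score.mean_smax == pytest.approx(7.5)
    assert score.pervasiveness == pytest.approx(2 / 3)
    assert score.mean_nsites == pytest.approx(1.5)
    assert cons.wsmax_score(score) == pytest.approx(7.5)


def test_wsmax_single_species_single_site_is_the_score():
    g = cons.OrthologGroup("g", {"A": "a"}, {"A": [_hit(5.5)]})
    assert cons.wsmax_score(cons.group_statistics(g)) == pytest.approx(5.5)


def test_wsmax_zero_without_sites():
    g = cons.OrthologGroup("g", {"A": "a", "B": "b"}, {"A": [], "B": []})
    score = cons.group_statistics(g)
    assert (score.mean_smax, score.pervasiveness, score.mean_nsites) == (0.0, 0.0, 0.0)
    assert score.wsmax == 0.0


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_wsmax_invariant_under_species_relabeling(seed):
    rng = np.random.default_rng(seed)
    n_sp = int(rng.integers(2, 8))
    species = [f"sp{i}" for i in range(n_sp)]
    hits = {
        sp: [_hit(float(rng.uniform(1, 10))) for _ in range(int(rng.integers(0, 4)))]
        for sp in species
    }
    members = {sp: f"gene_{sp}" for sp in species}
    base = cons.group_statistics(cons.OrthologGroup("g", members, hits))
    perm = rng.permutation(species)
    relabel = dict(zip(species, perm))
    members2 = {relabel[sp]: members[sp] for sp in species}
    hits2 = {relabel[sp]: hits[sp] for sp in species}
    other = cons.group_statistics(cons.OrthologGroup("g", members2, hits2))
    assert other.wsmax == pytest.approx(base.wsmax)


def test_group_rejects_hits_for_non_members():
    with pytest.raises(ValueError):
        cons.OrthologGroup("g", {"A": "a"}, {"B": [_hit(1.0)]})


# ---------------------------------------------------------------------------
# Posterior probability of regulation
# ---------------------------------------------------------------------------

def test_posterior_worked_example():
    # one position, s = 10, q = 0.01, pi = 0.5:
    # L = 0.99 + 0.01 * 1024 = 11.23 -> posterior = 11.23 / 12.23
    p = cons.posterior_regulation([10.0], prior=0.5, site_density=0.01)
    assert p == pytest.approx(11.23 / 12.23, abs=1e-6)


def test_posterior_equals_prior_under_null():
    assert cons.posterior_regulation([], prior=0.3) == pytest.approx(0.3)
    assert cons.posterior_regulation([0.0] * 500, prior=0.3, site_density=0.01) == pytest.approx(0.3)


def test_posterior_neginf_contributes_background_factor():
    p0 = cons.posterior_regulation([-np.inf] * 10, prior=0.5, site_density=0.1)
    # each -inf position multiplies L by (1-q) < 1, pulling below the prior
    assert p0 < 0.5


@settings(deadline=None, derandomize=True, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_posterior_bounded_and_monotone_in_scores(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(0, 3, size=30)
    p = cons.posterior_regulation(scores, prior=0.5, site_density=0.02)
    assert 0.0 <= p <= 1.0
    bumped = scores.copy()
    bumped[int(rng.integers(0, 30))] += 2.0
    assert cons.posterior_regulation(bumped, prior=0.5, site_density=0.02) >= p


# ---------------------------------------------------------------------------
# Ranking table
# ---------------------------------------------------------------------------

def _groups_with_wsmax():
    g_hi = cons.OrthologGroup("hi", {"A": "a", "B": "b", "C": "c"},
                              {"A": [_hit(8.0), _hit(6.0, 20)], "B": [_hit(7.0)], "C": []})
    g_mid = cons.OrthologGroup("mid", {"A": "a2", "B": "b2"}, {"A": [_hit(6.0)], "B": []})
    g_zero = cons.OrthologGroup("zero", {"A": "a3", "B": "b3"}, {"A": [], "B": []})
    return [g_mid, g_zero, g_hi]


def test_ranking_sorted_and_normalized():
    df = cons.rank_and_export(_groups_with_wsmax())
    assert list(df["group_id"]) == ["hi", "mid", "zero"]
    assert df["wsmax"].tolist() == pytest.approx([7.5, 3.0, 0.0])
    assert df["wsmax_norm"].tolist() == pytest.approx([1.0, 0.4, 0.0])


def test_ranking_min_species_filter_and_absent_members():
    df = cons.rank_and_export(_groups_with_wsmax(), min_species=3)
    assert list(df["group_id"]) == ["hi"]
    # species C is a member with no sites: posterior cell present (NaN without
    # posteriors given); non-member species are absent entirely
    df_all = cons.rank_and_export(_groups_with_wsmax(),
                                  posteriors={"mid": {"A": 0.7, "B": 0.2}})
    row_mid = df_all[df_all.group_id == "mid"].iloc[0]
    assert row_mid["posterior_A"] == pytest.approx(0.7)
    assert np.isnan(row_mid["posterior_C"])  # absent ortholog, not zero


def test_ranking_all_equal_normalizes_to_zero():
    g1 = cons.OrthologGroup("g1", {"A": "a"}, {"A": [_hit(5.0)]})
    g2 = cons.OrthologGroup("g2", {"A": "b"}, {"A": [_hit(5.0)]})
    df = cons.rank_and_export([g1, g2])
    assert df["wsmax_norm"].tolist() == [0.0, 0.0]


# ---------------------------------------------------------------------------
# Spearman + permutation
# ---------------------------------------------------------------------------

def test_spearman_perfect_correlations():
    x = np.arange(1.0, 11.0)
    res = cons.spearman_permutation(x, x, n_perm=199, seed=1)
    assert res.rho == pytest.approx(1.0)
    res_rev = cons.spearman_permutation(x, x[::-1], n_perm=199, seed=1)
    assert res_rev.rho == pytest.approx(-1.0)


def test_spearman_p_lower_bound_when_rho_extreme():
    rng = np.random.default_rng(0)
    x = rng.normal(size=12)
    order = np.argsort(x)
    y = np.empty_like(x)
    y[order] = np.arange(12.0)  # same ordering as x -> rho 1
    res = cons.spearman_permutation(x, y, n_perm=199, seed=5)
    # identity and full-reversal permutations still tie |rho| = 1
    assert res.p_perm <= 2 / (199 + 1) + 1e-12
    assert res.p_perm >= 1 / (199 + 1)


def test_spearman_matches_scipy_on_ties():
    x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
    y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0])
    res = cons.spearman_permutation(x, y, n_perm=19, seed=0)
    assert res.rho == pytest.approx(stats.spearmanr(x, y).statistic)


def test_spearman_rejects_constant_or_short_input():
    with pytest.raises(ValueError):
        cons.spearman_permutation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
    with pytest.raises(ValueError):
        cons.spearman_permutation([1.0, 2.0], [1.0, 2.0])


def test_spearman_deterministic_given_seed():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=20), rng.normal(size=20)
    a = cons.spearman_permutation(x, y, n_perm=99, seed=7)
    b = cons.spearman_permutation(x, y, n_perm=99, seed=7)
    assert (a.rho, a.p_perm) == (b.rho, b.p_perm)
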