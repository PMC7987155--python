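"""Cross-species conservation scoring of promoter motif evidence.

For each ortholog group (one gene per species, paired by reciprocal best
similarity) the promoter-site evidence is folded into the conservation
statistic

    <WSmax> = <s_max> * (Sp_site / Sp_orth) * <|sites|>

where ``<s_max>`` is the mean, over species with at least one significant
site, of the best site score (bits); ``Sp_site / Sp_orth`` is the
pervasiveness — the fraction of ortholog-bearing species that carry a site;
and ``<|sites|>`` is the mean site count over site-bearing species.  A group
with no sites anywhere scores 0.  High values flag groups whose promoters
retain strong, widespread, and numerous motif instances — residual evidence
of conserved regulation.

Independently, a per-species **posterior probability of regulation**
combines all scanned positions of one promoter under an independent-sites
mixture: each scanned position is a site with probability ``q`` (default one
expected site per window) and contributes its likelihood ratio ``2**s``;
the promoter likelihood ratio is ``L = prod_j [(1-q) + q * 2**s_j]`` and the
posterior is ``pi*L / (pi*L + 1 - pi)`` with prior ``pi`` (default 0.5).
A promoter with no signal (all scores 0, or nothing scanned) posts exactly
the prior.

Rank agreement between a candidate statistic and ChIP enrichment is tested
with Spearman correlation and a seeded permutation test (two-sided, the
add-one rule ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_scan import MotifHit
from .regulon_sets import OrthologMap

__all__ = [
    "OrthologGroup",
    "GroupScore",
    "CorrelationResult",
    "reciprocal_best_hits",
    "group_statistics",
    "wsmax_score",
    "posterior_regulation",
    "rank_and_export",
    "spearman_permutation",
    "DEFAULT_PRIOR",
]

DEFAULT_PRIOR = 0.5


@dataclass(frozen=True)
class OrthologGroup:
    """Per-species members and promoter-collapsed significant hits."""

    group_id: str
    members: dict[str, str]              # species_id -> gene_id
    hits: dict[str, list[MotifHit]]      # species_id -> collapsed hits

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"group {self.group_id!r} has no members")
        stray = set(self.hits) - set(self.members)
        if stray:
            raise ValueError(f"group {self.group_id!r}: hits for non-member species {sorted(stray)}")

    @property
    def sp_orth(self) -> set[str]:
        return set(self.members)

    @property
    def sp_site(self) -> set[str]:
        return {sp for sp, hs in self.hits.items() if hs}


@dataclass(frozen=True)
class GroupScore:
    group_id: str
    mean_smax: float
    pervasiveness: float
    mean_nsites: float

    @property
    def wsmax(self) -> float:
        return self.mean_smax * self.pervasiveness * self.mean_nsites


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_perm: float
    n: int
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# Reciprocal best hits
# ---------------------------------------------------------------------------

def reciprocal_best_hits(score_table: pd.DataFrame) -> OrthologMap:
    """Pair genes by reciprocal unique best similarity.

    ``score_table``: rows = genes of species A, columns = genes of species B,
    values = nonnegative similarity (higher = more similar); missing
    comparisons as NaN.  A pair (a, b) is kept iff b is a's *unique* best hit
    and a is b's unique best hit; any tie for best disqualifies both sides.
    """
    values = score_table.to_numpy(dtype=float)

    def unique_best(mat: np.ndarray) -> np.ndarray:
        """Per-row index of the unique maximum, -1 if tied or all-NaN."""
        out = np.full(mat.shape[0], -1)
        for i, row in enumerate(mat):
            if np.all(np.isnan(row)):
                continue
            m = np.nanmax(row)
            idx = np.nonzero(row == m)[0]
            if len(idx) == 1:
                out[i] = idx[0]
        return out

    best_b_for_a = unique_best(values)
    best_a_for_b = unique_best(values.T)
    pairs = []
    for i, j in enumerate(best_b_for_a):
        if j >= 0 and best_a_for_b[j] == i:
            pairs.append((str(score_table.index[i]), str(score_table.columns[j])))
    return OrthologMap(pairs=tuple(pairs))


# ---------------------------------------------------------------------------
# <WSmax>
# ---------------------------------------------------------------------------

def group_statistics(group: OrthologGroup) -> GroupScore:
    """The three <WSmax> factors; all zero when no species carries a site.

    ``<s_max>`` and ``<|sites|>`` average over site-bearing species only —
    the pervasiveness ratio already accounts for species without sites.
    """
    sp_site = sorted(group.sp_site)
    n_orth = len(group.sp_orth)
    if not sp_site:
        return GroupScore(group.group_id, 0.0, 0.0, 0.0)
    smax = [max(h.score for h in group.hits[sp]) for sp in sp_site]
    nsites = [len(group.hits[sp]) for sp in sp_site]
    return GroupScore(
        group_id=group.group_id,
        mean_smax=float(np.mean(smax)),
        pervasiveness=len(sp_site) / n_orth,
        mean_nsites=float(np.mean(nsites)),
    )


def wsmax_score(components: GroupScore) -> float:
    """Product of the three factors."""
    return components.wsmax


# ---------------------------------------------------------------------------
# Posterior probability of regulation
# ---------------------------------------------------------------------------

def posterior_regulation(
    promoter_scores,
    prior: float = DEFAULT_PRIOR,
    site_density: float | None = None,
    window_length: int | None = None,
) -> float:
    """Posterior that a promoter is regulated, from its per-position scores.

    ``promoter_scores`` are the log2 likelihood-ratio scores of every scanned
    position (both strands); ``-inf`` entries contribute the background
    factor ``1 - q``.  ``site_density`` defaults to ``1 / window_length``
    (one expected site per promoter window) or, failing that, to
    ``1 / n_positions``.
    """
    scores = np.asarray(list(promoter_scores), dtype=float)
    if not (0 < prior < 1):
        raise ValueError("prior must lie in (0, 1)")
    if scores.size == 0:
        return prior
    if site_density is None:
        site_density = 1.0 / (window_length if window_length else scores.size)
    q = site_density
    if not (0 < q < 1):
        raise ValueError("site_density must lie in (0, 1)")
    finite = np.isfinite(scores)
    # log2 L = sum log2((1-q) + q*2^s); -inf scores give log2(1-q)
    log_factors = np.where(
        finite, np.log2((1 - q) + q * np.exp2(np.where(finite, scores, 0.0))), np.log2(1 - q)
    )
    log_odds = np.log2(prior / (1 - prior)) + log_factors.sum()
    # posterior = 1 / (1 + 2^-log_odds), computed stably
    if log_odds > 60:
        return 1.0
    if log_odds < -60:
        return 0.0
    return float(1.0 / (1.0 + 2.0 ** (-log_odds)))


# ---------------------------------------------------------------------------
# Ranking / heatmap table
# ---------------------------------------------------------------------------

def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def rank_and_export(
    groups: list[OrthologGroup],
    posteriors: dict[str, dict[str, float]] | None = None,
    species_order: list[str] | None = None,
    min_species: int = 0,
    top_k: int | None = None,
    extra_columns: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """Ranked conservation table (the heatmap's numbers, not its rendering).

    Groups with fewer than ``min_species`` ortholog-bearing species are
    dropped; the rest are sorted by <WSmax> descending (ties broken by
    group_id) and annotated with min-max normalized ortholog counts and
    <WSmax> over the retained set.  Per-species posterior columns hold NaN
    for absent orthologs — distinct from a posterior of 0.
    """
    kept = [g for g in groups if len(g.sp_orth) >= min_species]
    if not kept:
        return pd.DataFrame()
    scores = {g.group_id: group_statistics(g) for g in kept}
    order = sorted(kept, key=lambda g: (-scores[g.group_id].wsmax, g.group_id))
    if species_order is None:
        species_order = sorted({sp for g in kept for sp in g.members})
    wsmax = np.array([scores[g.group_id].wsmax for g in order])
    n_orth = np.array([len(g.sp_orth) for g in order], dtype=float)
    rows = []
    for g, w, wn, no, non in zip(order, wsmax, _minmax(wsmax), n_orth, _minmax(n_orth)):
        row: dict = {"group_id": g.group_id}
        if extra_columns:
            for col, mapping in extra_columns.items():
                row[col] = mapping.get(g.group_id, "")
        row.update(
            {"wsmax": w, "wsmax_norm": wn, "n_orth": int(no), "n_orth_norm": non}
        )
        for sp in species_order:
            if sp not in g.members:
                row[f"posterior_{sp}"] = np.nan
            elif posteriors is not None:
                row[f"posterior_{sp}"] = posteriors.get(g.group_id, {}).get(sp, np.nan)
            else:
                row[f"posterior_{sp}"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    if top_k is not None:
        df = df.head(top_k)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Spearman + permutation
# ---------------------------------------------------------------------------

def spearman_permutation(
    x, y, n_perm: int = 999, seed: int = 0
) -> CorrelationResult:
    """Spearman rho with a two-sided permutation p-value.

    Ranks use midranks for ties.  ``y`` is permuted ``n_perm`` times with a
    PCG64 generator seeded by ``seed``; the p-value uses the add-one rule and
    therefore lies in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = _pearson(rx, ry)
    rng = np.random.Generator(np.random.PCG64(seed))
    count = 0
    # permuting rank vectors is equivalent to permuting y itself
    rx_c = rx - rx.mean()
    denom_x = np.sqrt((rx_c ** 2).sum())
    ry_c = ry - ry.mean()
    denom_y = np.sqrt((ry_c ** 2).sum())
    for _ in range(n_perm):
        perm = rng.permutation(ry_c)
        rho_b = (rx_c @ perm) / (denom_x * denom_y)
        if abs(rho_b) >= abs(rho_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return CorrelationResult(rho=float(rho_obs), p_perm=float(p), n=int(x.size),
                             n_perm=int(n_perm), seed=int(seed))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a ** 2).sum() * (b ** 2).sum()))


def aggregate_enrichment(
    gene_groups: dict[str, str],
    gene_enrichment: dict[str, float],
    how: str = "max",
) -> dict[str, float]:
    """Per-ortholog-group ChIP enrichment (default: max over member genes'
    promoter-window peak enrichment) for rank-correlation against <WSmax>."""
    agg: dict[str, list[float]] = {}
    for gene, grp in gene_groups.items():
        if gene in gene_enrichment:
            agg.setdefault(grp, []).append(gene_enrichment[gene])
    if how == "max":
        return {g: max(v) for g, v in agg.items()}
    if how == "mean":
        return {g: float(np.mean(v)) for g, v in agg.items()}
    raise ValueError("how must be 'max' or 'mean'")
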