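"""Position-specific scoring matrices, mixture motifs, and threshold calibration.

The extended-GANTC promoter scan rests on three pieces that live here:

1.  A **PSSM** built from an aligned collection of binding sites.  Position
    frequencies are Laplace-smoothed, ``freq = (count + alpha) / (n + 4*alpha)``,
    and words are scored by the summed per-position log2 likelihood ratio
    against a background distribution ("bits").  The motif's information
    content is ``IC = sum_pos sum_b freq * log2(freq / background_b)``.

2.  A two-or-more component **mixture motif**: site collections from different
    species are combined with weights proportional to collection size, and a
    word's mixture score is the log-sum-exp of component scores,
    ``log2(sum_m lambda_m * 2**s_m)``, so the score remains the log
    likelihood ratio of the site mixture versus background.

3.  **Threshold calibration**: the exact score distribution of a background
    word is computed (exhaustive enumeration of all 4**L words for short
    motifs, per-position convolution for longer additive PSSMs), and the
    significance threshold is the smallest score ``t*`` whose false positive
    rate satisfies ``-log2(FPR(t*)) >= IC``.  A hit is significant when its
    score is **>=** the threshold; ties at the threshold count as passing.

Scores of words containing a zero-frequency base (possible only with
``alpha = 0``) are the ``-inf`` sentinel; ``-inf`` propagates through sums,
carries probability mass in the score distribution, but never serves as a
calibrated threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PSSM",
    "MixtureMotif",
    "ScoreDistribution",
    "Threshold",
    "UNIFORM_BACKGROUND",
    "build_pssm",
    "score_word",
    "build_mixture",
    "score_mixture",
    "exact_score_distribution",
    "fpr_at",
    "calibrate_threshold",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

UNIFORM_BACKGROUND = {b: 0.25 for b in BASES}

DEFAULT_PSEUDOCOUNT = 0.25  # Laplace-style, proportional to uniform background
DEFAULT_BIN_WIDTH = 0.01    # bits
_ENUM_MAX_LENGTH = 12       # exhaustive 4**L enumeration bound


def _background_array(background: dict[str, float] | None) -> np.ndarray:
    bg = UNIFORM_BACKGROUND if background is None else background
    arr = np.array([float(bg[b]) for b in BASES])
    if np.any(arr <= 0):
        raise ValueError("background probabilities must be positive")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError("background probabilities must sum to 1")
    return arr


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSSM:
    """Per-position base frequencies with background, as a log-odds scorer.

    ``freq`` has shape (L, 4) over bases A, C, G, T and rows summing to 1;
    ``background`` is the length-4 background distribution; ``ic`` is the
    information content in bits.
    """

    freq: np.ndarray
    background: np.ndarray
    pseudocount: float
    ic: float = field(init=False)

    def __post_init__(self):
        freq = np.asarray(self.freq, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4 or freq.shape[0] < 1:
            raise ValueError("freq must be an (L, 4) matrix with L >= 1")
        if np.any(np.abs(freq.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each position's frequencies must sum to 1")
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "background", bg)
        # 0 * log(0) := 0
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(freq > 0, freq * np.log2(freq / bg[None, :]), 0.0)
        object.__setattr__(self, "ic", float(terms.sum()))

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) matrix of log2(freq/background); -inf where freq == 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.freq / self.background[None, :])


def build_pssm(
    sites: list[str],
    background: dict[str, float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PSSM:
    """Build a PSSM from equal-length aligned sites.

    ``freq[pos][b] = (count + alpha) / (n + 4 * alpha)`` with per-base
    additive pseudocount ``alpha >= 0``.
    """
    if not sites:
        raise ValueError("site collection is empty")
    sites = [s.upper() for s in sites]
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ValueError("ragged site lengths in collection")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = np.zeros((L, 4))
    for s in sites:
        for pos, base in enumerate(s):
            if base not in _BASE_INDEX:
                raise ValueError(f"site {s!r}: invalid base {base!r}")
            counts[pos, _BASE_INDEX[base]] += 1
    n = len(sites)
    freq = (counts + pseudocount) / (n + 4 * pseudocount)
    return PSSM(freq=freq, background=_background_array(background), pseudocount=pseudocount)


def _encode(word: str) -> np.ndarray:
    word = word.upper()
    try:
        return np.array([_BASE_INDEX[b] for b in word])
    except KeyError as exc:
        raise ValueError(f"word {word!r} contains a non-ACGT character") from exc


def score_word(pssm: PSSM, word: str) -> float:
    """Score a word of length L: sum of per-position log2(freq/background).

    Returns ``-inf`` if any matched frequency is zero.
    """
    idx = _encode(word)
    if len(idx) != pssm.length:
        raise ValueError(f"word length {len(idx)} != motif length {pssm.length}")
    lo = pssm.log_odds
    return float(lo[np.arange(pssm.length), idx].sum())


# ---------------------------------------------------------------------------
# Mixture motif
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureMotif:
    """Equal-length PSSM components with nonnegative weights summing to 1."""

    components: tuple[PSSM, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if not self.components:
            raise ValueError("mixture needs at least one component")
        L = self.components[0].length
        if any(c.length != L for c in self.components):
            raise ValueError("mixture components must share a motif length")
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.components) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def length(self) -> int:
        return self.components[0].length

    @property
    def ic(self) -> float:
        """Weight-averaged component information content (bits)."""
        return float(sum(w * c.ic for w, c in zip(self.weights, self.components)))


def build_mixture(
    collections: dict[str, list[str]] | list[list[str]],
    background: dict[str, float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    weights: list[float] | None = None,
) -> MixtureMotif:
    """Combine site collections into a mixture motif.

    Default component weights are proportional to collection sizes.
    """
    if isinstance(collections, dict):
        collections = [collections[k] for k in collections]
    if not collections:
        raise ValueError("no site collections given")
    comps = tuple(build_pssm(c, background=background, pseudocount=pseudocount) for c in collections)
    if weights is None:
        sizes = np.array([len(c) for c in collections], dtype=float)
        w = sizes / sizes.sum()
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    return MixtureMotif(components=comps, weights=tuple(float(x) for x in w))


def score_mixture(mix: MixtureMotif, word: str) -> float:
    """log2 of the weighted sum of component likelihood ratios.

    ``-inf`` only when every component scores ``-inf``.
    """
    scores = np.array([score_word(c, word) for c in mix.components])
    return _logsumexp2(scores, np.asarray(mix.weights))


def _logsumexp2(scores: np.ndarray, weights: np.ndarray) -> float:
    mask = np.isfinite(scores)
    if not mask.any():
        return float("-inf")
    s, w = scores[mask], weights[mask]
    m = s.max()
    return float(m + np.log2(np.sum(w * np.exp2(s - m))))


# ---------------------------------------------------------------------------
# Exact background score distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreDistribution:
    """Binned distribution of the motif score of a random background word.

    ``support`` is ascending and may start with ``-inf`` (words hitting a
    zero frequency); ``prob`` sums to 1.
    """

    support: np.ndarray
    prob: np.ndarray
    bin_width: float

    def __post_init__(self):
        support = np.asarray(self.support, dtype=float)
        prob = np.asarray(self.prob, dtype=float)
        if support.shape != prob.shape:
            raise ValueError("support and prob must align")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly ascending")
        if abs(prob.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "prob", prob)


@dataclass(frozen=True)
class Threshold:
    """A calibrated score threshold with its achieved FPR."""

    t: float
    achieved_fpr: float
    ic: float
    saturated: bool = False  # True when IC was not achievable; t is max support

    def __post_init__(self):
        if not (0 < self.achieved_fpr <= 1):
            raise ValueError("achieved_fpr must lie in (0, 1]")


def _bin_scores(scores: np.ndarray, probs: np.ndarray, bin_width: float) -> ScoreDistribution:
    finite = np.isfinite(scores)
    p_neg_inf = probs[~finite].sum()
    binned = np.round(scores[finite] / bin_width) * bin_width
    support, inverse = np.unique(binned, return_inverse=True)
    prob = np.bincount(inverse, weights=probs[finite], minlength=len(support))
    if p_neg_inf > 0:
        support = np.concatenate([[-np.inf], support])
        prob = np.concatenate([[p_neg_inf], prob])
    # absorb float fuzz so the sum-to-1 invariant holds exactly enough
    prob = prob / prob.sum()
    return ScoreDistribution(support=support, prob=prob, bin_width=bin_width)


def _enumerate_component_scores(pssms: list[PSSM], bg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-words score matrix (n_components, 4**L) and word probabilities."""
    L = pssms[0].length
    word_scores = [np.zeros(1) for _ in pssms]
    word_prob = np.ones(1)
    for pos in range(L):
        word_prob = (word_prob[:, None] * bg[None, :]).ravel()
        for k, p in enumerate(pssms):
            col = p.log_odds[pos]
            word_scores[k] = (word_scores[k][:, None] + col[None, :]).ravel()
    return np.vstack(word_scores), word_prob


def exact_score_distribution(
    motif: PSSM | MixtureMotif,
    background: dict[str, float] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    method: str = "auto",
) -> ScoreDistribution:
    """Exact (up to binning) distribution of the background-word score.

    ``method='enumerate'`` walks all ``4**L`` words (L <= 12); it is the only
    exact route for a mixture, whose score is not position-additive.
    ``method='convolve'`` convolves per-position binned score distributions
    and applies to plain PSSMs of any length.  ``'auto'`` enumerates short
    motifs and convolves longer PSSMs.
    """
    bg = _background_array(background)
    is_mixture = isinstance(motif, MixtureMotif)
    L = motif.length
    if method == "auto":
        method = "enumerate" if L <= _ENUM_MAX_LENGTH else "convolve"
    if method == "enumerate":
        if L > _ENUM_MAX_LENGTH:
            raise ValueError(
                f"exhaustive enumeration unsupported for L={L} > {_ENUM_MAX_LENGTH}"
                + ("; a long mixture motif has no exact path" if is_mixture else "; use method='convolve'")
            )
        comps = list(motif.components) if is_mixture else [motif]
        scores, probs = _enumerate_component_scores(comps, bg)
        if is_mixture:
            w = np.asarray(motif.weights)[:, None]
            finite_any = np.isfinite(scores).any(axis=0)
            with np.errstate(invalid="ignore"):
                m = np.where(finite_any, np.max(np.where(np.isfinite(scores), scores, -np.inf), axis=0), 0.0)
                shifted = np.where(np.isfinite(scores), np.exp2(scores - m[None, :]), 0.0)
                total = (w * shifted).sum(axis=0)
            word_scores = np.where(finite_any, m + np.log2(np.where(total > 0, total, 1.0)), -np.inf)
        else:
            word_scores = scores[0]
        return _bin_scores(word_scores, probs, bin_width)
    if method == "convolve":
        if is_mixture:
            raise ValueError("convolution applies only to additive PSSMs, not mixtures")
        return _convolved_distribution(motif, bg, bin_width)
    raise ValueError(f"unknown method {method!r}")


def _convolved_distribution(pssm: PSSM, bg: np.ndarray, bin_width: float) -> ScoreDistribution:
    """Per-position convolution of binned log-odds scores on an integer grid."""
    lo = pssm.log_odds
    p_finite = np.ones(1)       # pmf over integer bins, offset tracked separately
    offset = 0                  # grid index of p_finite[0]
    p_inf = 0.0                 # mass already fallen into -inf
    for pos in range(pssm.length):
        col, bcol = lo[pos], bg
        finite = np.isfinite(col)
        p_inf += p_finite.sum() * bcol[~finite].sum()
        if not finite.any():
            return ScoreDistribution(
                support=np.array([-np.inf]), prob=np.array([1.0]), bin_width=bin_width
            )
        bins = np.round(col[finite] / bin_width).astype(int)
        w = bcol[finite]
        lo_bin, hi_bin = bins.min(), bins.max()
        kernel = np.zeros(hi_bin - lo_bin + 1)
        np.add.at(kernel, bins - lo_bin, w)
        p_finite = np.convolve(p_finite, kernel)
        offset += lo_bin
    idx = np.nonzero(p_finite > 0)[0]
    support = (offset + idx) * bin_width
    prob = p_finite[idx]
    if p_inf > 0:
        support = np.concatenate([[-np.inf], support])
        prob = np.concatenate([[p_inf], prob])
    prob = prob / prob.sum()
    return ScoreDistribution(support=support, prob=prob, bin_width=bin_width)


def fpr_at(dist: ScoreDistribution, t: float) -> float:
    """P(score >= t) under the background distribution."""
    if t == -np.inf:
        return 1.0
    return float(dist.prob[dist.support >= t].sum())


def calibrate_threshold(
    motif: PSSM | MixtureMotif,
    background: dict[str, float] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    dist: ScoreDistribution | None = None,
) -> Threshold:
    """Smallest support score ``t*`` with ``-log2(FPR(t*)) >= IC``.

    With IC = 0 (frequencies equal background) the minimum support is
    returned with FPR 1.  If even the largest finite support cannot reach the
    IC (possible for very high-IC motifs at coarse bins), the max-support
    threshold is returned flagged ``saturated=True``.
    """
    if dist is None:
        dist = exact_score_distribution(motif, background=background, bin_width=bin_width)
    ic = motif.ic
    finite_support = dist.support[np.isfinite(dist.support)]
    if finite_support.size == 0:
        raise ValueError("motif has no finite-score words under this background")
    # tail probabilities P(score >= s) for each finite support point
    finite_probs = dist.prob[np.isfinite(dist.support)]
    tails = np.cumsum(finite_probs[::-1])[::-1]
    if ic <= 0:
        t = float(dist.support[0])
        return Threshold(t=t, achieved_fpr=fpr_at(dist, t), ic=ic)
    ok = -np.log2(tails) >= ic
    if ok.any():
        i = int(np.argmax(ok))
        return Threshold(t=float(finite_support[i]), achieved_fpr=float(tails[i]), ic=ic)
    return Threshold(
        t=float(finite_support[-1]), achieved_fpr=float(tails[-1]), ic=ic, saturated=True
    )


# ---------------------------------------------------------------------------
# Motif serialization (TSV log-odds matrix with metadata header lines)
# ---------------------------------------------------------------------------

def write_pssm(pssm: PSSM, path) -> None:
    with open(path, "w") as fh:
        fh.write("# background\t" + "\t".join(f"{x:.10g}" for x in pssm.background) + "\n")
        fh.write(f"# pseudocount\t{pssm.pseudocount:.10g}\n")
        fh.write("position\t" + "\t".join(BASES) + "\n")
        for pos in range(pssm.length):
            row = "\t".join(f"{x:.10g}" for x in pssm.freq[pos])
            fh.write(f"{pos}\t{row}\n")


def read_pssm(path) -> PSSM:
    background = None
    pseudocount = DEFAULT_PSEUDOCOUNT
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# background"):
                background = np.array([float(x) for x in line.split("\t")[1:]])
            elif line.startswith("# pseudocount"):
                pseudocount = float(line.split("\t")[1])
            elif line.startswith(("position", "#")) or not line:
                continue
            else:
                rows.append([float(x) for x in line.split("\t")[1:]])
    if background is None:
        background = _background_array(None)
    return PSSM(freq=np.array(rows), background=background, pseudocount=pseudocount)
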