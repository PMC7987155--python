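"""Seeded generators emulating every input the pipeline consumes.

The generators mirror the data shapes of a GcrA/CcrM-style study: promoter
windows of 300 bp (200 upstream + 100 downstream of the translational start)
across ~23 species and ~200 ortholog groups with binding sites planted from
the extended-GANTC PWM at controlled per-group conservation; RNA-seq-like
negative-binomial count tables with planted log2 fold changes; ChIP peaks
centred on planted sites plus spurious peaks; and strand-resolved IPD ratios
from well-separated methylated / unmethylated lognormal distributions.

Every generator takes an explicit seed (through :class:`SimConfig`) and is
byte-deterministic given the same configuration.  Ground truth — planted
site coordinates and words, regulated group ids, true fold changes, true
methylation states — is returned alongside the data so recovery can be
scored exactly.

The p-values in the emitted expression table come from a two-sided
two-sample t-test on log2(count+1); this is a deliberate, documented
stand-in for a full count-model differential-expression fit, keeping the
filtering logic testable without modelling library normalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_scan import MotifHit, PromoterRegion
from .io_formats import ExpressionRecord, GeneAnnotation, GenomeSequence, IpdRecord, PeakRecord
from .methylation_calls import MethylationState
from .motif_model import BASES, PSSM, build_pssm

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "EXTENDED_GANTC_CONSENSUS",
    "extended_gantc_sites",
    "default_planting_pssm",
    "generate_genome",
    "generate_ortholog_promoter_set",
    "generate_expression_counts",
    "generate_chip_and_ipd",
]

EXTENDED_GANTC_CONSENSUS = "YGAKTCK"

_IUPAC_EXPAND = {"A": "A", "C": "C", "G": "G", "T": "T",
                 "Y": "CT", "K": "GT", "R": "AG", "M": "AC",
                 "S": "CG", "W": "AT", "N": "ACGT"}


def extended_gantc_sites() -> list[str]:
    """The 8 words of the degenerate extended-GANTC consensus YGAKTCK."""
    return ["".join(w) for w in itertools.product(*(_IUPAC_EXPAND[c] for c in EXTENDED_GANTC_CONSENSUS))]


def default_planting_pssm(pseudocount: float = 0.25) -> PSSM:
    """PSSM over the expanded extended-GANTC consensus; the default planted motif."""
    return build_pssm(extended_gantc_sites(), pseudocount=pseudocount)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Ortholog-promoter block: ``n_species`` species, ``n_groups`` ortholog
    groups of which the first ``n_regulated`` are truly regulated; each
    member promoter of a regulated group receives sites with probability
    ``conservation_regulated`` (others ``conservation_background``), the
    site count drawn Poisson(``site_lambda``) floored at 1.  Expression
    block: negative-binomial counts with planted |log2fc| ~ U(1, 3) on a
    ``frac_de`` fraction of genes.  ChIP/IPD block: peak width/jitter,
    genome-wide spurious-peak rate per bp, lognormal IPD laws.
    """

    seed: int
    # promoters / conservation
    n_species: int = 23
    n_groups: int = 200
    n_regulated: int = 20
    presence_prob: float = 0.95
    promoter_length: int = 300
    conservation_regulated: float = 0.9
    conservation_background: float = 0.05
    site_lambda: float = 1.0
    gc: float = 0.5
    site_sampling: str = "pwm"  # "pwm" (letter-wise) or "consensus" (max-scoring)
    # expression
    n_genes: int = 2000
    frac_de: float = 0.05
    log2fc_low: float = 1.0
    log2fc_high: float = 3.0
    nb_mean: float = 500.0
    nb_dispersion: float = 0.05
    replicates: int = 3
    # ChIP / IPD
    peak_width: int = 200
    peak_jitter: int = 20
    spurious_rate: float = 1e-4          # spurious peaks per bp
    enrichment_mu: float = np.log(5.0)   # lognormal enrichment
    enrichment_sigma: float = 0.5
    ipd_meth_mu: float = np.log(2.0)
    ipd_meth_sigma: float = 0.15
    ipd_unmeth_mu: float = np.log(0.85)
    ipd_unmeth_sigma: float = 0.10
    qv: float = 40.0
    # per-site truth-state frequencies (full, hemi, unmethylated), matching the
    # observed genome-wide partition 7765 : 19 : 16 of 7800 occurrences
    state_probs: tuple[float, float, float] = (7765 / 7800, 19 / 7800, 16 / 7800)

    def __post_init__(self):
        for name in ("presence_prob", "conservation_regulated", "conservation_background",
                     "gc", "frac_de"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.state_probs) - 1.0) > 1e-9:
            raise ValueError("state_probs must sum to 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.Generator(np.random.PCG64([self.seed, stream]))


@dataclass
class SyntheticTruth:
    """Planted ground truth, locatable in the emitted data."""

    planted_sites: dict = field(default_factory=dict)       # (group, species) -> [(pos, strand, word)]
    regulated_groups: set = field(default_factory=set)
    de_genes: set = field(default_factory=set)
    true_log2fc: dict = field(default_factory=dict)         # gene -> float
    methylation_states: dict = field(default_factory=dict)  # site key -> MethylationState


# ---------------------------------------------------------------------------
# Random genomes
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])


def generate_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    n_genes: int = 0,
    gene_length: int = 900,
    strands: str = "alternate",
) -> tuple[GenomeSequence, list[GeneAnnotation]]:
    """An i.i.d. random contig plus ``n_genes`` evenly spaced gene annotations."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.Generator(np.random.PCG64([seed, 917]))
    genome = GenomeSequence(id="synthetic_contig", seq=_random_seq(rng, length, gc))
    genes = []
    if n_genes:
        pitch = length // n_genes
        if pitch <= gene_length:
            raise ValueError("genome too short for evenly spaced genes of this length")
        for i in range(n_genes):
            start = i * pitch + (pitch - gene_length) // 2
            strand = "+" if strands == "forward" or i % 2 == 0 else "-"
            genes.append(
                GeneAnnotation(gene_id=f"g{i:04d}", contig=genome.id,
                               start=start, end=start + gene_length, strand=strand)
            )
    return genome, genes


# ---------------------------------------------------------------------------
# Ortholog promoter sets with planted sites
# ---------------------------------------------------------------------------

def _sample_site(rng: np.random.Generator, pssm: PSSM, how: str) -> str:
    if how == "consensus":
        word = []
        for pos in range(pssm.length):
            row = pssm.freq[pos]
            best = np.nonzero(row == row.max())[0]
            word.append(BASES[rng.choice(best)])
        return "".join(word)
    if how == "pwm":
        return "".join(BASES[rng.choice(4, p=pssm.freq[pos])] for pos in range(pssm.length))
    raise ValueError("site_sampling must be 'pwm' or 'consensus'")


def _plant(rng: np.random.Generator, seq: list[str], k: int, pssm: PSSM, how: str,
           max_tries: int = 200) -> list[tuple[int, str, str]]:
    """Plant k non-overlapping sites at uniform random positions."""
    L = pssm.length
    placed: list[tuple[int, str, str]] = []
    occupied: set[int] = set()
    for _ in range(k):
        for _try in range(max_tries):
            pos = int(rng.integers(0, len(seq) - L + 1))
            if all(p not in occupied for p in range(pos, pos + L)):
                word = _sample_site(rng, pssm, how)
                seq[pos : pos + L] = list(word)
                occupied.update(range(pos, pos + L))
                placed.append((pos, "+", word))
                break
        else:
            raise RuntimeError(f"could not place {k} non-overlapping sites in window")
    return placed


def generate_ortholog_promoter_set(
    config: SimConfig,
    pssm: PSSM | None = None,
) -> tuple[dict[tuple[str, str], PromoterRegion], SyntheticTruth]:
    """Promoters for each (group, species) pair with sites planted per the
    group's conservation level.

    Each pair is present with probability ``presence_prob``.  A present
    promoter of a regulated group receives, with probability
    ``conservation_regulated``, ``max(1, Poisson(site_lambda))`` planted
    sites sampled from the PWM; background groups use
    ``conservation_background``.
    """
    if pssm is None:
        pssm = default_planting_pssm()
    rng = config.rng(stream=1)
    promoters: dict[tuple[str, str], PromoterRegion] = {}
    truth = SyntheticTruth()
    species = [f"sp{j:02d}" for j in range(config.n_species)]
    for gi in range(config.n_groups):
        group = f"grp{gi:04d}"
        regulated = gi < config.n_regulated
        if regulated:
            truth.regulated_groups.add(group)
        conservation = (
            config.conservation_regulated if regulated else config.conservation_background
        )
        for sp in species:
            if rng.random() >= config.presence_prob:
                continue
            seq = list(_random_seq(rng, config.promoter_length, config.gc))
            planted: list[tuple[int, str, str]] = []
            if rng.random() < conservation:
                k = max(1, int(rng.poisson(config.site_lambda)))
                planted = _plant(rng, seq, k, pssm, config.site_sampling)
            key = (group, sp)
            promoters[key] = PromoterRegion(
                gene_id=f"{group}@{sp}",
                contig=f"{group}@{sp}",
                window=(0, config.promoter_length),
                strand="+",
                seq="".join(seq),
            )
            if planted:
                truth.planted_sites[key] = planted
    return promoters, truth


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def generate_expression_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, list[ExpressionRecord], SyntheticTruth]:
    """Negative-binomial count matrix and the derived expression table.

    Columns ``wt_1..wt_R`` and ``mut_1..mut_R``; the mutant mean of a DE gene
    is the WT mean scaled by ``2**true_log2fc`` with sign chosen at random.
    The emitted ``log2fc`` is measured from simulated counts as
    ``log2((mean_mut + 0.5) / (mean_wt + 0.5))``; ``pvalue`` is the
    two-sided t-test on log2(count + 1).
    """
    if config.replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    rng = config.rng(stream=2)
    truth = SyntheticTruth()
    n, reps = config.n_genes, config.replicates
    genes = [f"gene{g:05d}" for g in range(n)]
    base_mean = rng.lognormal(mean=np.log(config.nb_mean), sigma=1.0, size=n)
    is_de = rng.random(n) < config.frac_de
    lfc = np.zeros(n)
    n_de = int(is_de.sum())
    magnitudes = rng.uniform(config.log2fc_low, config.log2fc_high, size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc[is_de] = magnitudes * signs
    for g, de, f in zip(genes, is_de, lfc):
        truth.true_log2fc[g] = float(f)
        if de:
            truth.de_genes.add(g)

    r = 1.0 / config.nb_dispersion  # NB size parameter; var = m + dispersion * m^2

    def nb_draws(mean: np.ndarray) -> np.ndarray:
        p = np.broadcast_to(r / (r + mean[:, None]), (n, reps))
        return rng.negative_binomial(r, p)

    wt = nb_draws(base_mean)
    mut = nb_draws(base_mean * np.exp2(lfc))
    counts = pd.DataFrame(
        np.hstack([wt, mut]),
        index=genes,
        columns=[f"wt_{i+1}" for i in range(reps)] + [f"mut_{i+1}" for i in range(reps)],
    )
    log_wt = np.log2(wt + 1.0)
    log_mut = np.log2(mut + 1.0)
    with np.errstate(invalid="ignore"):
        tres = stats.ttest_ind(log_mut, log_wt, axis=1)
    pvals = np.where(np.isnan(tres.pvalue), 1.0, tres.pvalue)
    obs_lfc = np.log2((mut.mean(axis=1) + 0.5) / (wt.mean(axis=1) + 0.5))
    records = [
        ExpressionRecord(g, float(f), float(p)) for g, f, p in zip(genes, obs_lfc, pvals)
    ]
    return counts, records, truth


# ---------------------------------------------------------------------------
# ChIP peaks and IPD tables
# ---------------------------------------------------------------------------

def generate_chip_and_ipd(
    config: SimConfig,
    sites: list[MotifHit],
    genome_length: int,
    contig: str = "synthetic_contig",
) -> tuple[list[PeakRecord], list[IpdRecord], SyntheticTruth]:
    """ChIP peaks over planted sites plus spurious peaks, and per-site IPDs.

    One true peak of ``peak_width`` is centred on each planted site with
    uniform jitter in ``[-peak_jitter, peak_jitter]``; spurious peaks arrive
    as a Poisson process at ``spurious_rate`` per bp.  Each site draws a true
    methylation state from ``state_probs`` and emits one IPD record per
    strand: methylated strands ~ LogNormal(ipd_meth_mu, ipd_meth_sigma),
    unmethylated ~ LogNormal(ipd_unmeth_mu, ipd_unmeth_sigma), QV fixed.
    """
    rng = config.rng(stream=3)
    peaks: list[PeakRecord] = []
    truth = SyntheticTruth()
    half = config.peak_width // 2
    for site in sites:
        centre = (site.start + site.end) // 2
        if config.peak_jitter:
            centre += int(rng.integers(-config.peak_jitter, config.peak_jitter + 1))
        start = max(0, centre - half)
        end = min(genome_length, centre + half)
        if start < end:
            peaks.append(
                PeakRecord(site.contig, start, end,
                           float(rng.lognormal(config.enrichment_mu, config.enrichment_sigma)))
            )
    n_spurious = int(rng.poisson(config.spurious_rate * genome_length))
    for _ in range(n_spurious):
        start = int(rng.integers(0, max(1, genome_length - config.peak_width)))
        peaks.append(
            PeakRecord(contig, start, start + config.peak_width,
                       float(rng.lognormal(config.enrichment_mu, config.enrichment_sigma)))
        )
    peaks.sort(key=lambda p: (p.contig, p.start))

    # hemi mass splits evenly between the two strand-only states
    ipd: list[IpdRecord] = []
    for site in sites:
        u = rng.random()
        if u < config.state_probs[0]:
            state = MethylationState.FULL
        elif u < config.state_probs[0] + config.state_probs[1]:
            state = (MethylationState.HEMI_FORWARD_ONLY if rng.random() < 0.5
                     else MethylationState.HEMI_REVERSE_ONLY)
        else:
            state = MethylationState.UNMETHYLATED
        truth.methylation_states[(site.contig, site.start)] = state
        meth_fwd = state in (MethylationState.FULL, MethylationState.HEMI_FORWARD_ONLY)
        meth_rev = state in (MethylationState.FULL, MethylationState.HEMI_REVERSE_ONLY)
        for strand, is_meth in (("+", meth_fwd), ("-", meth_rev)):
            mu, sigma = (
                (config.ipd_meth_mu, config.ipd_meth_sigma) if is_meth
                else (config.ipd_unmeth_mu, config.ipd_unmeth_sigma)
            )
            ipd.append(
                IpdRecord(site.contig, site.start, strand,
                          float(rng.lognormal(mu, sigma)), config.qv)
            )
    return peaks, ipd, truth
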