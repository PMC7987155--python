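"""Genome-wide motif enumeration and promoter scanning.

Promoter windows are anchored on the translational start: the default scanning
window spans 200 bp upstream to 100 bp downstream of the first base of the
start codon, taken irrespective of any other annotated features and truncated
at contig ends.  Genes predicted to lie in one operon are represented by the
operon's lead (5'-most same-strand) gene, whose promoter stands for all
members.

Two counting conventions coexist deliberately.  Genome-wide enumeration of a
palindromic motif (GANTC) reports forward and reverse matches separately, so
both-strand counts are exactly twice the forward count.  Within a single
promoter's significant-hit list, the forward/reverse pair reading the same
palindromic interval is one biological site and is collapsed to the
higher-scoring strand, so downstream site counts are not inflated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .io_formats import GeneAnnotation, GenomeSequence
from .motif_model import MixtureMotif, PSSM, Threshold, score_mixture, score_word

__all__ = [
    "MotifHit",
    "PromoterRegion",
    "OperonAssignment",
    "enumerate_iupac_sites",
    "predict_operons",
    "extract_promoters",
    "scan_promoter_hits",
    "window_overlap",
    "DEFAULT_SCAN_WINDOW",
    "DEFAULT_CCRM_WINDOW",
    "DEFAULT_PEAK_WINDOW",
    "DEFAULT_OPERON_MAX_GAP",
]

# (upstream, downstream) of the translational start, in bases
DEFAULT_SCAN_WINDOW = (200, 100)   # conservation scanning
DEFAULT_CCRM_WINDOW = (200, 0)     # CcrM direct-target rule
DEFAULT_PEAK_WINDOW = (100, 100)   # GcrA ChIP peak overlap
DEFAULT_OPERON_MAX_GAP = 50        # intergenic bases

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence in forward-strand 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    score: float | None = None


@dataclass(frozen=True)
class PromoterRegion:
    """Promoter window of an operon-lead gene.

    ``window`` is the forward-strand interval; ``seq`` is oriented 5'->3'
    relative to the gene (reverse-complemented for minus-strand genes).
    """

    gene_id: str
    contig: str
    window: tuple[int, int]
    strand: str
    seq: str


@dataclass(frozen=True)
class OperonAssignment:
    """Maps every gene to its operon and the operon's lead gene."""

    operon_of: dict[str, str]
    lead_of: dict[str, str]

    def lead(self, gene_id: str) -> str:
        return self.lead_of.get(gene_id, gene_id)

    @property
    def lead_genes(self) -> set[str]:
        return set(self.lead_of.values())


# ---------------------------------------------------------------------------
# Fixed IUPAC enumeration
# ---------------------------------------------------------------------------

def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {motif!r}")
        allowed = IUPAC[ch]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    # lookahead for overlapping matches
    return re.compile(f"(?=({''.join(parts)}))")


def iupac_revcomp(motif: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    return "".join(comp[c] for c in reversed(motif.upper()))


def enumerate_iupac_sites(
    genome: GenomeSequence | str,
    iupac_motif: str,
    strands: str = "both",
) -> list[MotifHit]:
    """All (possibly overlapping) matches of a fixed IUPAC motif.

    Reverse-strand matches are located by matching the reverse-complement
    pattern on the forward sequence, and reported in forward coordinates with
    ``strand='-'``.  For a palindromic motif every interval therefore appears
    once per strand.
    """
    if isinstance(genome, str):
        genome = GenomeSequence(id="seq", seq=genome.upper())
    if strands not in ("forward", "both"):
        raise ValueError("strands must be 'forward' or 'both'")
    L = len(iupac_motif)
    hits = [
        MotifHit(genome.id, m.start(), m.start() + L, "+")
        for m in _iupac_regex(iupac_motif).finditer(genome.seq)
    ]
    if strands == "both":
        rc = iupac_revcomp(iupac_motif)
        hits += [
            MotifHit(genome.id, m.start(), m.start() + L, "-")
            for m in _iupac_regex(rc).finditer(genome.seq)
        ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Operons
# ---------------------------------------------------------------------------

def predict_operons(
    annotations: list[GeneAnnotation],
    max_gap: int = DEFAULT_OPERON_MAX_GAP,
) -> OperonAssignment:
    """Distance-rule operon prediction.

    Consecutive same-strand genes on one contig whose intergenic gap is
    ``<= max_gap`` share an operon; the lead is the 5'-most member (smallest
    start for ``+`` operons, largest end for ``-`` operons).  Genes carrying
    an explicit ``operon_id`` annotation keep it, grouped as given.
    """
    operon_of: dict[str, str] = {}
    lead_of: dict[str, str] = {}

    explicit = [g for g in annotations if g.operon_id is not None]
    implicit = [g for g in annotations if g.operon_id is None]

    groups: dict[str, list[GeneAnnotation]] = {}
    for g in explicit:
        groups.setdefault(g.operon_id, []).append(g)

    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in implicit:
        by_contig.setdefault(g.contig, []).append(g)
    counter = 0
    for contig in sorted(by_contig):
        genes = sorted(by_contig[contig], key=lambda g: (g.start, g.end))
        current: list[GeneAnnotation] = []
        for g in genes:
            if (
                current
                and g.strand == current[-1].strand
                and g.start - current[-1].end <= max_gap
            ):
                current.append(g)
            else:
                if current:
                    groups[f"operon_{counter:05d}"] = current
                    counter += 1
                current = [g]
        if current:
            groups[f"operon_{counter:05d}"] = current
            counter += 1

    for op_id, members in groups.items():
        strand = members[0].strand
        lead = (
            min(members, key=lambda g: g.start)
            if strand == "+"
            else max(members, key=lambda g: g.end)
        )
        for g in members:
            operon_of[g.gene_id] = op_id
            lead_of[g.gene_id] = lead.gene_id
    return OperonAssignment(operon_of=operon_of, lead_of=lead_of)


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------

def promoter_interval(
    gene: GeneAnnotation, upstream: int, downstream: int, contig_length: int | None = None
) -> tuple[int, int]:
    """Forward-strand interval of the (upstream, downstream) window around the
    translational start, truncated at contig edges when a length is given."""
    if gene.strand == "+":
        start, end = gene.start - upstream, gene.start + downstream
    else:
        start, end = gene.end - downstream, gene.end + upstream
    start = max(0, start)
    if contig_length is not None:
        end = min(end, contig_length)
    return start, max(start, end)


def extract_promoters(
    annotations: list[GeneAnnotation],
    genome: list[GenomeSequence] | GenomeSequence,
    upstream: int = DEFAULT_SCAN_WINDOW[0],
    downstream: int = DEFAULT_SCAN_WINDOW[1],
    operons: OperonAssignment | None = None,
) -> list[PromoterRegion]:
    """Promoter windows for operon-lead genes, strand-oriented 5'->3'.

    Without an operon assignment every gene is its own lead.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window sizes must be nonnegative")
    contigs = {genome.id: genome} if isinstance(genome, GenomeSequence) else {g.id: g for g in genome}
    by_id = {g.gene_id: g for g in annotations}
    if operons is None:
        leads = [g.gene_id for g in annotations]
    else:
        seen: set[str] = set()
        leads = []
        for g in annotations:
            lead = operons.lead(g.gene_id)
            if lead not in seen:
                seen.add(lead)
                leads.append(lead)
    promoters = []
    for gene_id in leads:
        gene = by_id[gene_id]
        if gene.contig not in contigs:
            raise KeyError(f"gene {gene_id!r}: contig {gene.contig!r} absent from genome")
        contig = contigs[gene.contig]
        start, end = promoter_interval(gene, upstream, downstream, contig.length)
        seq = contig.seq[start:end]
        if gene.strand == "-":
            seq = revcomp(seq)
        promoters.append(
            PromoterRegion(gene_id=gene_id, contig=gene.contig, window=(start, end),
                           strand=gene.strand, seq=seq)
        )
    return promoters


# ---------------------------------------------------------------------------
# Calibrated PSSM scanning
# ---------------------------------------------------------------------------

def _score(motif: PSSM | MixtureMotif, word: str) -> float:
    if isinstance(motif, MixtureMotif):
        return score_mixture(motif, word)
    return score_word(motif, word)


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


def window_scores(
    motif: PSSM | MixtureMotif, seq: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized forward- and reverse-read scores of every length-L window.

    Returns ``(starts, fwd, rev)`` restricted to windows free of ``N``.
    ``rev[i]`` is the score of the reverse complement of the window at
    ``starts[i]`` — i.e. the minus-strand read of the same interval.
    """
    L = motif.length
    codes = np.fromiter((_BASE_CODE[c] for c in seq), dtype=np.int64, count=len(seq))
    if len(codes) < L:
        empty = np.empty(0)
        return empty.astype(int), empty, empty
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win >= 0).all(axis=1)
    win = win[valid]
    starts = np.nonzero(valid)[0]
    comps = motif.components if isinstance(motif, MixtureMotif) else (motif,)
    pos_idx = np.arange(L)
    fwd_comp, rev_comp = [], []
    for c in comps:
        lo = c.log_odds
        # reverse-complement read: position j of the window maps to motif
        # position L-1-j with the complemented base 3 - b
        lo_rc = lo[::-1, ::-1]
        fwd_comp.append(lo[pos_idx[None, :], win].sum(axis=1))
        rev_comp.append(lo_rc[pos_idx[None, :], win].sum(axis=1))
    if isinstance(motif, MixtureMotif):
        w = np.asarray(motif.weights)
        fwd = _logsumexp2_rows(np.vstack(fwd_comp), w)
        rev = _logsumexp2_rows(np.vstack(rev_comp), w)
    else:
        fwd, rev = fwd_comp[0], rev_comp[0]
    return starts, fwd, rev


def _logsumexp2_rows(scores: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Column-wise log2(sum_m w_m 2^s_m) with -inf handled."""
    finite_any = np.isfinite(scores).any(axis=0)
    m = np.where(finite_any, np.max(np.where(np.isfinite(scores), scores, -np.inf), axis=0), 0.0)
    with np.errstate(invalid="ignore"):
        shifted = np.where(np.isfinite(scores), np.exp2(scores - m[None, :]), 0.0)
    total = (weights[:, None] * shifted).sum(axis=0)
    return np.where(finite_any & (total > 0), m + np.log2(np.where(total > 0, total, 1.0)), -np.inf)


def scan_promoter_hits(
    promoter: PromoterRegion,
    motif: PSSM | MixtureMotif,
    threshold: Threshold | float,
    collapse_palindromic: bool = True,
) -> list[MotifHit]:
    """Significant motif hits (score >= threshold) on both strands of a window.

    Windows containing ``N`` are excluded.  When the forward and reverse reads
    of the same interval both pass (a palindromic site), they collapse to one
    hit keeping the higher score.  Hit coordinates are forward-strand contig
    coordinates.
    """
    t = threshold.t if isinstance(threshold, Threshold) else float(threshold)
    L = motif.length
    win_start, _win_end = promoter.window
    fwd_seq = promoter.seq if promoter.strand == "+" else revcomp(promoter.seq)
    starts, fwd, rev = window_scores(motif, fwd_seq)
    raw: list[MotifHit] = []
    for i, sf, sr in zip(starts, fwd, rev):
        start, end = win_start + int(i), win_start + int(i) + L
        if sf >= t:
            raw.append(MotifHit(promoter.contig, start, end, "+", score=float(sf)))
        if sr >= t:
            raw.append(MotifHit(promoter.contig, start, end, "-", score=float(sr)))
    if collapse_palindromic:
        best: dict[tuple[int, int], MotifHit] = {}
        for h in raw:
            key = (h.start, h.end)
            prev = best.get(key)
            if prev is None or h.score > prev.score:
                best[key] = h
        raw = list(best.values())
    return sorted(raw, key=lambda h: (h.start, h.strand))


def hits_to_bed6(hits: list[MotifHit], path, name: str = "hit") -> None:
    """Write hits as BED6; the score column is bits x 100, integer."""
    with open(path, "w") as fh:
        for h in hits:
            score = 0 if h.score is None else int(round(h.score * 100))
            fh.write(f"{h.contig}\t{h.start}\t{h.end}\t{name}\t{score}\t{h.strand}\n")


def promoters_to_fasta(promoters: list[PromoterRegion], path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.gene_id}|{p.contig}:{p.window[0]}-{p.window[1]}({p.strand})\n{p.seq}\n")


# ---------------------------------------------------------------------------
# Window / feature overlap
# ---------------------------------------------------------------------------

def window_overlap(
    gene: GeneAnnotation,
    window: tuple[int, int],
    features: list,
) -> tuple[bool, list]:
    """Half-open intersection of the gene's (upstream, downstream) window with
    feature intervals (motif hits or ChIP peaks) on the same contig."""
    upstream, downstream = window
    w_start, w_end = promoter_interval(gene, upstream, downstream)
    overlapping = [
        f for f in features
        if getattr(f, "contig", gene.contig) == gene.contig
        and f.start < w_end and w_start < f.end
    ]
    return bool(overlapping), overlapping
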