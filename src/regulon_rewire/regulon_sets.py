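"""Regulon definition and cross-species comparison cascades.

A regulon here is an expression-defined gene set: genes passing a raw
p-value cutoff (strict, default P < 0.01) and a fold-change cutoff
(non-strict on the fold scale, default 2-fold, i.e. ``|log2fc| >= 1``),
optionally restricted to one direction.  Direct-target evidence is then
annotated per gene: a GANTC site in the CcrM window (200 bp upstream of the
translational start), a ChIP peak overlapping the regulator window
(-100..+100), and whether any overlapping peak itself contains a GANTC site.
Operon members inherit the flags of their operon-lead gene, whose promoter
is the one scanned.

Cross-species comparison is a cascade of nested stages — e.g. regulon in
species A -> orthologs present in B -> ortholog has peak+site -> meets
P < 0.01 -> meets the 1.75-fold lower-expression rule — mirroring
concentric-circle regulon comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from .genome_scan import (
    DEFAULT_CCRM_WINDOW,
    DEFAULT_PEAK_WINDOW,
    MotifHit,
    OperonAssignment,
    window_overlap,
)
from .io_formats import ExpressionRecord, GeneAnnotation, PeakRecord

__all__ = [
    "RegulonRecord",
    "CascadeResult",
    "OrthologMap",
    "filter_differential",
    "annotate_direct_targets",
    "compare_regulons_cascade",
    "relative_expression_ddct",
]


@dataclass(frozen=True)
class RegulonRecord:
    gene_id: str
    log2fc: float
    pvalue: float
    has_promoter_gantc: bool
    has_peak: bool
    peak_has_gantc: bool

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one ortholog pairs between two species (injective per direction)."""

    pairs: tuple[tuple[str, str], ...]
    a_to_b: dict[str, str] = field(init=False)
    b_to_a: dict[str, str] = field(init=False)

    def __post_init__(self):
        a_to_b: dict[str, str] = {}
        b_to_a: dict[str, str] = {}
        for a, b in self.pairs:
            if a in a_to_b or b in b_to_a:
                raise ValueError(f"ortholog map not injective at pair ({a!r}, {b!r})")
            a_to_b[a] = b
            b_to_a[b] = a
        object.__setattr__(self, "a_to_b", a_to_b)
        object.__setattr__(self, "b_to_a", b_to_a)


@dataclass(frozen=True)
class CascadeResult:
    """Ordered nested gene sets with counts; each stage a subset of the last."""

    stages: tuple[str, ...]
    sets: dict[str, frozenset[str]]

    def count(self, stage: str) -> int:
        return len(self.sets[stage])

    @property
    def counts(self) -> list[int]:
        return [len(self.sets[s]) for s in self.stages]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\tgenes\n")
            for s in self.stages:
                genes = ",".join(sorted(self.sets[s]))
                fh.write(f"{s}\t{len(self.sets[s])}\t{genes}\n")


# ---------------------------------------------------------------------------
# Differential-expression filtering
# ---------------------------------------------------------------------------

def filter_differential(
    records: list[ExpressionRecord],
    min_fold: float = 2.0,
    max_p: float = 0.01,
    direction: str = "any",
) -> set[str]:
    """Genes with ``pvalue < max_p`` (strict) and ``|log2fc| >= log2(min_fold)``
    (non-strict), optionally restricted to up- or down-regulation."""
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    if direction not in ("any", "up", "down"):
        raise ValueError("direction must be 'any', 'up' or 'down'")
    lfc_cut = math.log2(min_fold)
    out = set()
    for r in records:
        if r.pvalue >= max_p or abs(r.log2fc) < lfc_cut:
            continue
        if direction == "up" and r.log2fc <= 0:
            continue
        if direction == "down" and r.log2fc >= 0:
            continue
        out.add(r.gene_id)
    return out


# ---------------------------------------------------------------------------
# Direct-target annotation
# ---------------------------------------------------------------------------

def annotate_direct_targets(
    de_genes: set[str],
    annotations: list[GeneAnnotation],
    expression: list[ExpressionRecord],
    gantc_hits: list[MotifHit],
    peaks: list[PeakRecord],
    operons: OperonAssignment | None = None,
    gantc_window: tuple[int, int] = DEFAULT_CCRM_WINDOW,
    peak_window: tuple[int, int] = DEFAULT_PEAK_WINDOW,
) -> list[RegulonRecord]:
    """Per-gene promoter evidence flags for differentially expressed genes.

    Flags are computed on each gene's operon-lead annotation (the lead's
    promoter is the operon's promoter); operon members inherit them.
    ``peak_has_gantc`` asks whether any peak overlapping the regulator window
    itself contains a GANTC hit.
    """
    by_id = {g.gene_id: g for g in annotations}
    expr = {r.gene_id: r for r in expression}
    records = []
    for gene_id in sorted(de_genes):
        if gene_id not in by_id:
            raise KeyError(f"DE gene {gene_id!r} has no annotation")
        lead_id = operons.lead(gene_id) if operons is not None else gene_id
        lead = by_id.get(lead_id, by_id[gene_id])
        has_gantc, _ = window_overlap(lead, gantc_window, gantc_hits)
        has_peak, over_peaks = window_overlap(lead, peak_window, peaks)
        peak_has_gantc = any(
            any(h.contig == p.contig and h.start < p.end and p.start < h.end for h in gantc_hits)
            for p in over_peaks
        )
        r = expr[gene_id]
        records.append(
            RegulonRecord(
                gene_id=gene_id,
                log2fc=r.log2fc,
                pvalue=r.pvalue,
                has_promoter_gantc=has_gantc,
                has_peak=has_peak,
                peak_has_gantc=peak_has_gantc,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Cross-species cascades
# ---------------------------------------------------------------------------

def compare_regulons_cascade(
    regulon_a: set[str],
    ortholog_map: OrthologMap,
    stages: list[tuple[str, Callable[[str], bool]]],
    label_a: str = "regulon_A",
    label_orth: str = "orthologs_in_B",
) -> CascadeResult:
    """Nest the species-A regulon through ortholog presence and B-side predicates.

    ``stages`` are (label, predicate) pairs evaluated on species-B gene ids in
    order; each stage keeps the subset of the previous stage satisfying its
    predicate, so counts are non-increasing by construction.
    """
    labels = [label_a, label_orth] + [lbl for lbl, _ in stages]
    if len(set(labels)) != len(labels):
        raise ValueError("cascade stage labels must be unique")
    sets: dict[str, frozenset[str]] = {label_a: frozenset(regulon_a)}
    current = frozenset(
        ortholog_map.a_to_b[g] for g in regulon_a if g in ortholog_map.a_to_b
    )
    sets[label_orth] = current
    for lbl, pred in stages:
        current = frozenset(g for g in current if pred(g))
        sets[lbl] = current
    return CascadeResult(stages=tuple(labels), sets=sets)


def flag_predicate(records: list[RegulonRecord] | dict[str, RegulonRecord],
                   attr: str) -> Callable[[str], bool]:
    """Predicate over gene ids reading a boolean flag off RegulonRecords;
    genes without a record fail the predicate."""
    table = records if isinstance(records, dict) else {r.gene_id: r for r in records}
    return lambda gene_id: gene_id in table and bool(getattr(table[gene_id], attr))


def expression_predicate(
    expression: list[ExpressionRecord],
    max_p: float | None = None,
    min_fold: float | None = None,
    direction: str = "any",
) -> Callable[[str], bool]:
    """Predicate applying p / fold / direction cutoffs to an expression table."""
    table = {r.gene_id: r for r in expression}

    def pred(gene_id: str) -> bool:
        r = table.get(gene_id)
        if r is None:
            return False
        if max_p is not None and not (r.pvalue < max_p):
            return False
        if min_fold is not None and abs(r.log2fc) < math.log2(min_fold):
            return False
        if direction == "down" and r.log2fc >= 0:
            return False
        if direction == "up" and r.log2fc <= 0:
            return False
        return True

    return pred


# ---------------------------------------------------------------------------
# RT-qPCR
# ---------------------------------------------------------------------------

def relative_expression_ddct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref) in the test condition minus the same
    difference in the control condition.
    """
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
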