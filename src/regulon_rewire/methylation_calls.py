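"""Strand-resolved methylation calling from SMRT IPD ratios.

The interpulse-duration (IPD) ratio compares the polymerase dwell time at a
base to an in-silico unmethylated control; a ratio above 1 at an adenine
indicates m6A on the template strand.  A strand counts as methylated only
when its IPD ratio exceeds the threshold **and** its basecall quality value
passes (default QV >= 30, i.e. 99.9% accuracy); a failing QV is treated
conservatively as unmethylated.  A ratio of exactly 1.0 falls on neither side
of the published rule (<1 unmethylated, >1 methylated) and is resolved as
unmethylated.

For a palindromic motif (GANTC, AATT) one occurrence carries one interrogated
adenine per strand and yields a single call that may be fully methylated,
hemimethylated on either strand, or unmethylated.  Non-palindromic adenine
motifs are called per strand occurrence with the reverse field unused.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .genome_scan import MotifHit

__all__ = [
    "MethylationState",
    "MethylationCall",
    "MotifMethylationSummary",
    "call_site_methylation",
    "summarize_motif_methylation",
    "DEFAULT_IPD_THRESHOLD",
    "DEFAULT_MIN_QV",
]

DEFAULT_IPD_THRESHOLD = 1.0
DEFAULT_MIN_QV = 30.0


class MethylationState(str, Enum):
    FULL = "full"
    HEMI_FORWARD_ONLY = "hemi_forward_only"
    HEMI_REVERSE_ONLY = "hemi_reverse_only"
    UNMETHYLATED = "unmethylated"

    @property
    def methylated(self) -> bool:
        """At least one strand methylated."""
        return self is not MethylationState.UNMETHYLATED


@dataclass(frozen=True)
class MethylationCall:
    site: MotifHit | None
    state: MethylationState
    ipd_forward: float
    ipd_reverse: float
    qv_pass: bool


@dataclass(frozen=True)
class MotifMethylationSummary:
    """Per-motif accounting: occurrences, methylated occurrences, fraction.

    ``fraction`` is **truncated** (not rounded) to the requested number of
    decimals: 7765/7800 = 0.9955... reports as 0.99 at two decimals and
    150/455 = 0.3296... as 0.329 at three.
    """

    motif: str
    n_genome: int
    n_methylated: int
    fraction: float

    def __post_init__(self):
        if not (0 <= self.n_methylated <= self.n_genome):
            raise ValueError("need 0 <= n_methylated <= n_genome")


def _strand_methylated(ipd: float, qv: float, ipd_threshold: float, min_qv: float) -> bool:
    if ipd <= 0:
        raise ValueError(f"IPD ratio must be positive, got {ipd}")
    return ipd > ipd_threshold and qv >= min_qv


def call_site_methylation(
    ipd_forward: float,
    ipd_reverse: float,
    ipd_threshold: float = DEFAULT_IPD_THRESHOLD,
    qv_forward: float = 40.0,
    qv_reverse: float = 40.0,
    min_qv: float = DEFAULT_MIN_QV,
    site: MotifHit | None = None,
) -> MethylationCall:
    """Classify one palindromic motif occurrence from its two strand IPDs."""
    fwd = _strand_methylated(ipd_forward, qv_forward, ipd_threshold, min_qv)
    rev = _strand_methylated(ipd_reverse, qv_reverse, ipd_threshold, min_qv)
    if fwd and rev:
        state = MethylationState.FULL
    elif fwd:
        state = MethylationState.HEMI_FORWARD_ONLY
    elif rev:
        state = MethylationState.HEMI_REVERSE_ONLY
    else:
        state = MethylationState.UNMETHYLATED
    return MethylationCall(
        site=site,
        state=state,
        ipd_forward=ipd_forward,
        ipd_reverse=ipd_reverse,
        qv_pass=qv_forward >= min_qv and qv_reverse >= min_qv,
    )


def truncate_fraction(n: int, total: int, precision: int) -> float:
    """Exact decimal truncation of n/total via integer arithmetic."""
    if total == 0:
        return 0.0
    scale = 10 ** precision
    return (n * scale // total) / scale


def summarize_motif_methylation(
    calls: list[MethylationCall],
    motif: str,
    n_genome: int | None = None,
    precision: int = 2,
) -> MotifMethylationSummary:
    """Count occurrences with at least one methylated strand.

    ``n_genome`` defaults to the number of calls; it may be given explicitly
    when calls cover only a subset of genomic occurrences.
    """
    n_methylated = sum(1 for c in calls if c.state.methylated)
    if n_genome is None:
        n_genome = len(calls)
    if n_methylated > n_genome:
        raise ValueError("more methylated calls than genomic occurrences")
    return MotifMethylationSummary(
        motif=motif,
        n_genome=n_genome,
        n_methylated=n_methylated,
        fraction=truncate_fraction(n_methylated, n_genome, precision),
    )


def calls_to_tsv(calls: list[MethylationCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstate\tipd_forward\tipd_reverse\n")
        for c in calls:
            contig, start, end = ("", "", "")
            if c.site is not None:
                contig, start, end = c.site.contig, c.site.start, c.site.end
            fh.write(f"{contig}\t{start}\t{end}\t{c.state.value}\t"
                     f"{c.ipd_forward:.6g}\t{c.ipd_reverse:.6g}\n")
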