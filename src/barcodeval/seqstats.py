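"""Per-region sequence-characteristics summaries.

A *variable* site is an alignment column showing at least two distinct
unambiguous bases (A/C/G/T) among its non-gap, non-ambiguous states; a
*parsimony-informative* site additionally requires at least two of those
bases to occur in at least two rows each. Variation involving only gaps or
ambiguity codes does not make a site variable — indels are tabulated
separately, one event per distinct (start, end) gap run across rows.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

from barcodeval.seqio import Alignment, TaxonMap, UNAMBIGUOUS


def percent(count: int, denom: int, decimals: int = 1) -> float:
    """``100*count/denom`` rounded half-away-from-zero to ``decimals`` places.

    This is the single rounding rule used for every reported percentage, so
    printed tables are reproducible bit-for-bit.
    """
    if denom <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= count <= denom):
        raise ValueError("count must lie in [0, denom]")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(denom)).quantize(q, ROUND_HALF_UP)
    )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half-away-from-zero, the convention used in all reported tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, ROUND_HALF_UP))


def standard_exclusion(aln: Alignment, taxa: TaxonMap) -> Alignment:
    """Drop outgroup sequences and sequences of species sampled only once.

    This is the study-wide filter applied before summary statistics and
    distance partitioning, leaving only species that can in principle be
    evaluated (>= 2 conspecific individuals, ingroup only).
    """
    members = {
        sp: ids for sp, ids in taxa.species_members().items() if len(ids) >= 2
    }
    keep = {sid for ids in members.values() for sid in ids if sid in aln}
    if len(keep) < 2:
        raise ValueError("fewer than 2 sequences remain after exclusion")
    return aln.subset(keep)


@dataclass(frozen=True)
class SeqStatsSummary:
    """The per-region characteristics row of the evaluation table."""

    n_accessions: int
    raw_length_min: int
    raw_length_max: int
    aligned_length: int
    n_variable: int
    pct_variable: float
    n_informative: int
    pct_informative: float
    n_indels: int
    indel_length_min: int | None
    indel_length_max: int | None

    def to_dict(self) -> dict:
        return asdict(self)


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' in one row as half-open (start, end) intervals."""
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def alignment_summary(
    aln: Alignment,
    taxa: TaxonMap | None = None,
    exclude: bool = True,
) -> SeqStatsSummary:
    """Summarize one aligned region.

    With ``exclude=True`` (and a taxon map) the standard study filter is
    applied first: outgroups and single-individual species are removed.
    Terminal gap runs count as indel events like internal ones; identical
    events shared by several rows (same start and end) are counted once,
    reflecting a single mutational origin.
    """
    if taxa is not None and exclude:
        aln = standard_exclusion(aln, taxa)

    n_variable = 0
    n_informative = 0
    rows = [r.sequence for r in aln]
    for col in range(aln.length):
        counts = Counter(row[col] for row in rows)
        bases = {b: n for b, n in counts.items() if b in UNAMBIGUOUS}
        if len(bases) >= 2:
            n_variable += 1
            if sum(1 for n in bases.values() if n >= 2) >= 2:
                n_informative += 1

    events = {run for row in rows for run in _gap_runs(row)}
    lengths = sorted(end - start for start, end in events)

    raw_lengths = [len(r.degapped()) for r in aln]
    return SeqStatsSummary(
        n_accessions=len(aln),
        raw_length_min=min(raw_lengths),
        raw_length_max=max(raw_lengths),
        aligned_length=aln.length,
        n_variable=n_variable,
        pct_variable=percent(n_variable, aln.length),
        n_informative=n_informative,
        pct_informative=percent(n_informative, aln.length),
        n_indels=len(events),
        indel_length_min=lengths[0] if lengths else None,
        indel_length_max=lengths[-1] if lengths else None,
    )
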