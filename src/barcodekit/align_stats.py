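"""Per-alignment sequence characteristics.

Reports, for any locus alignment, the quantities a barcode evaluation table
lists: variable sites, parsimony-informative sites, conserved sites, indel
events and mean pairwise identity.

Conventions
-----------
* Only unambiguous bases (A, C, G, T) contribute to variability; IUPAC
  ambiguity codes and gaps never make a column variable.
* An *indel event* is a maximal run of gap characters in one sequence; runs
  with an identical (start, end) span in several sequences are counted once.
* Pairwise identity averages, over all sequence pairs, the fraction of
  compared sites that are identical.  By default a gap aligned to a base
  counts as a compared, non-identical site and gap-vs-gap is excluded; set
  ``gap_vs_base="exclude"`` to drop gap-vs-base sites from the comparison.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

from .seqio import BASES, LocusAlignment

__all__ = ["AlignmentStats", "column_states", "compute_stats", "indel_events"]


@dataclass(frozen=True)
class AlignmentStats:
    n_seqs: int
    aligned_length: int
    variable_sites: int
    informative_sites: int
    conserved_sites: int
    indel_events: int
    pairwise_identity: float  # percent


def column_states(aln: LocusAlignment, col: int) -> tuple[Counter, int, int]:
    """Tally one alignment column (1-based).

    Returns ``(base_counts, n_gaps, n_ambiguous)`` where ``base_counts``
    covers unambiguous bases only.
    """
    column = aln.column(col)
    bases = Counter(c for c in column if c in BASES)
    gaps = column.count("-")
    ambiguous = len(column) - sum(bases.values()) - gaps
    return bases, gaps, ambiguous


def indel_events(aln: LocusAlignment) -> int:
    """Count distinct maximal gap runs, merging identical spans across sequences."""
    spans: set[tuple[int, int]] = set()
    for rec in aln.records:
        start = None
        for i, c in enumerate(rec.seq):
            if c == "-":
                if start is None:
                    start = i
            elif start is not None:
                spans.add((start, i))
                start = None
        if start is not None:
            spans.add((start, len(rec.seq)))
    return len(spans)


def _pairwise_identity(aln: LocusAlignment, gap_vs_base: str) -> float:
    if len(aln.records) < 2:
        return 100.0
    total = 0.0
    npairs = 0
    for a, b in itertools.combinations(aln.records, 2):
        same = 0
        compared = 0
        for x, y in zip(a.seq, b.seq):
            if x == "-" and y == "-":
                continue
            if x == "-" or y == "-":
                if gap_vs_base == "exclude":
                    continue
                compared += 1  # counted, never identical
                continue
            compared += 1
            if x == y:
                same += 1
        if compared:
            total += same / compared
            npairs += 1
    return 100.0 * total / npairs if npairs else 100.0


def compute_stats(aln: LocusAlignment, gap_vs_base: str = "diff") -> AlignmentStats:
    """Compute the per-locus characteristics table for an alignment.

    * variable: columns with >= 2 distinct unambiguous bases;
    * informative (parsimony): columns with >= 2 bases each present in >= 2
      sequences;
    * conserved: columns with exactly one base state and no gaps.
    """
    if len(aln.records) < 2:
        raise ValueError("need at least 2 sequences")
    if gap_vs_base not in ("diff", "exclude"):
        raise ValueError("gap_vs_base must be 'diff' or 'exclude'")
    variable = informative = conserved = 0
    for col in range(1, aln.length + 1):
        bases, gaps, _ambig = column_states(aln, col)
        if len(bases) >= 2:
            variable += 1
            if sum(1 for n in bases.values() if n >= 2) >= 2:
                informative += 1
        elif len(bases) == 1 and gaps == 0:
            conserved += 1
    return AlignmentStats(
        n_seqs=len(aln.records),
        aligned_length=aln.length,
        variable_sites=variable,
        informative_sites=informative,
        conserved_sites=conserved,
        indel_events=indel_events(aln),
        pairwise_identity=_pairwise_identity(aln, gap_vs_base),
    )
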