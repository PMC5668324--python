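"""Character-based identification and CAPS assay design.

A *pure diagnostic character* is an alignment column where every member of a
species carries one fixed base that no other individual carries — the basis
for character-based barcoding and for species-specific assays.  Conjunctions
of such (position, state) pairs form classification rules; rules are induced
on a stratified training slice and scored on the held-out test slice.

For wet-lab deployment a diagnostic SNP becomes a CAPS (cleaved amplified
polymorphic sequence) marker when the base exchange creates or destroys a
restriction-enzyme recognition site overlapping the SNP, so that a digest
separates the species on a gel.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import BASES, LocusAlignment

__all__ = [
    "DiagnosticCharacter",
    "DiagnosticRule",
    "RuleInductionResult",
    "RestrictionEnzyme",
    "CAPSAssay",
    "DEFAULT_ENZYMES",
    "find_diagnostic_characters",
    "induce_rules",
    "classify_by_rules",
    "scan_restriction_sites",
    "design_caps",
]

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class DiagnosticCharacter:
    """A (position, state) fixed in one species and absent from all others."""

    locus: str
    position: int  # 1-based alignment column
    state: str
    species: str
    degapped_positions: Mapping[str, int] = field(default=None, compare=False, hash=False)


@dataclass(frozen=True)
class DiagnosticRule:
    """Conjunction of (position, state) pairs characterising one species."""

    species: str
    conjuncts: tuple[tuple[int, str], ...]
    train_coverage: float
    false_positive_rate: float


@dataclass(frozen=True)
class RuleInductionResult:
    rules: tuple[DiagnosticRule, ...]
    test_correct_pct: float
    test_misidentified_pct: float
    test_not_identified_pct: float
    n_test: int
    skipped_species: tuple[str, ...]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme as an IUPAC-degenerate recognition string."""

    name: str
    recognition: str
    cut_offset: int | None = None  # top-strand cut, optional

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError("recognition site must be >= 4 bp")
        bad = set(self.recognition) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"invalid IUPAC codes in site: {sorted(bad)}")

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == self.recognition.translate(_COMPLEMENT)[::-1]


#: Enzymes used for Decalepis matK CAPS assays, extensible via config.
DEFAULT_ENZYMES: tuple[RestrictionEnzyme, ...] = (
    RestrictionEnzyme("BstXI", "CCANNNNNNTGG"),
    RestrictionEnzyme("MnlI", "CCTC"),
    RestrictionEnzyme("HphI", "GGTGA"),
    RestrictionEnzyme("AlwI", "GGATC"),
)


@dataclass(frozen=True)
class CAPSAssay:
    """A diagnostic SNP whose state change flips a restriction site."""

    locus: str
    species: str
    snp_position: int  # 1-based alignment column
    target_state: str
    other_states: tuple[str, ...]
    enzyme: str
    target_cuts: bool  # True: site present in target, absent elsewhere
    site_position: int  # 1-based start of the (created/destroyed) site


def _degapped_position(seq: str, col: int) -> int | None:
    """Map a 1-based alignment column to the 1-based ungapped coordinate."""
    if seq[col - 1] == "-":
        return None
    return col - seq[:col].count("-")


def find_diagnostic_characters(
    aln: LocusAlignment,
    species: str | None = None,
    ids: Iterable[str] | None = None,
) -> list[DiagnosticCharacter]:
    """Exhaustively scan columns for pure species-diagnostic characters.

    A column qualifies for a species when all its members share one
    unambiguous base there and no non-member carries that base.  Gaps or
    ambiguity codes at the column disqualify it for the members; non-members
    with gap/ambiguity simply cannot match the state.  Restricting ``ids``
    scans a subset (used for train slices).
    """
    records = aln.records
    if ids is not None:
        wanted = set(ids)
        records = [r for r in records if r.individual_id in wanted]
    all_species = {r.species for r in records}
    if species is not None and species not in all_species:
        raise KeyError(f"unknown species {species!r}")
    targets = [species] if species is not None else sorted(all_species)
    out: list[DiagnosticCharacter] = []
    for sp in targets:
        members = [r for r in records if r.species == sp]
        others = [r for r in records if r.species != sp]
        if not members or not others:
            continue
        for col in range(1, aln.length + 1):
            states = {r.seq[col - 1] for r in members}
            if len(states) != 1:
                continue
            state = next(iter(states))
            if state not in BASES:
                continue
            if any(r.seq[col - 1] == state for r in others):
                continue
            degapped = {
                r.individual_id: _degapped_position(r.seq, col) for r in members
            }
            out.append(
                DiagnosticCharacter(
                    locus=aln.locus,
                    position=col,
                    state=state,
                    species=sp,
                    degapped_positions=degapped,
                )
            )
    return out


def _rule_matches(rule_conjuncts, seq: str) -> bool:
    return all(seq[pos - 1] == state for pos, state in rule_conjuncts)


def _candidate_conjuncts(
    members: list, others: list, length: int
) -> list[tuple[int, str]]:
    """(position, state) pairs fixed and unambiguous within the species."""
    cands = []
    for col in range(1, length + 1):
        states = {r.seq[col - 1] for r in members}
        if len(states) == 1:
            state = next(iter(states))
            if state in BASES and any(r.seq[col - 1] != state for r in others):
                cands.append((col, state))
    return cands


def _exhaustive_rule(
    members, others, candidates
) -> tuple[tuple[int, str], ...] | None:
    """Smallest conjunction with perfect train separation (size, then lexicographic)."""
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            if not any(_rule_matches(combo, r.seq) for r in others):
                return combo
    return None


def _greedy_rule(members, others, candidates) -> tuple[tuple[int, str], ...] | None:
    remaining = list(others)
    chosen: list[tuple[int, str]] = []
    pool = list(candidates)
    while remaining:
        best = None
        best_excluded = -1
        for cand in pool:
            excluded = sum(1 for r in remaining if r.seq[cand[0] - 1] != cand[1])
            # ties broken by lowest position (pool is position-ordered)
            if excluded > best_excluded:
                best, best_excluded = cand, excluded
        if best is None or best_excluded == 0:
            return None
        chosen.append(best)
        pool.remove(best)
        remaining = [r for r in remaining if r.seq[best[0] - 1] == best[1]]
    return tuple(chosen)


def induce_rules(
    aln: LocusAlignment,
    slice_fraction: float = 0.9,
    seed: int | None = None,
    exhaustive_limit: int = 12,
) -> RuleInductionResult:
    """Induce per-species classification rules with train/test slicing.

    Individuals are split stratified by species (``slice_fraction`` of each
    species trains, at least one per side).  Per species, the rule is the
    smallest perfect conjunction over candidate fixed positions (exhaustive
    when there are at most ``exhaustive_limit`` candidates, deterministic
    greedy non-member exclusion otherwise).  Emitted rules have full train
    coverage and zero train false positives by construction.  Species with a
    single member are excluded from slicing.
    """
    if not 0 < slice_fraction < 1:
        raise ValueError("slice_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_species: dict[str, list] = {}
    for r in aln.records:
        by_species.setdefault(r.species, []).append(r)
    train, test, skipped = [], [], []
    for sp in sorted(by_species):
        recs = by_species[sp]
        if len(recs) < 2:
            skipped.append(sp)
            continue
        n_train = min(max(int(round(slice_fraction * len(recs))), 1), len(recs) - 1)
        order = rng.permutation(len(recs))
        train.extend(recs[i] for i in order[:n_train])
        test.extend(recs[i] for i in order[n_train:])
    if not train or not test:
        raise ValueError("train/test slicing produced an empty side")
    rules: list[DiagnosticRule] = []
    train_species = sorted({r.species for r in train})
    for sp in train_species:
        members = [r for r in train if r.species == sp]
        others = [r for r in train if r.species != sp]
        candidates = _candidate_conjuncts(members, others, aln.length)
        if not candidates:
            continue
        # single pure diagnostic characters first
        singles = [
            c for c in candidates
            if not any(r.seq[c[0] - 1] == c[1] for r in others)
        ]
        if singles:
            conj: tuple[tuple[int, str], ...] | None = (singles[0],)
        elif len(candidates) <= exhaustive_limit:
            conj = _exhaustive_rule(members, others, candidates)
        else:
            conj = _greedy_rule(members, others, candidates)
        if conj is None:
            continue
        fp = sum(_rule_matches(conj, r.seq) for r in others) / len(others)
        cov = sum(_rule_matches(conj, r.seq) for r in members) / len(members)
        assert cov == 1.0 and fp == 0.0, "rule not sound on train"
        rules.append(
            DiagnosticRule(
                species=sp,
                conjuncts=conj,
                train_coverage=cov,
                false_positive_rate=fp,
            )
        )
    correct = mis = 0
    for r in test:
        assigned = classify_by_rules(rules, r.seq)
        if assigned is None:
            continue
        if assigned == r.species:
            correct += 1
        else:
            mis += 1
    n_test = len(test)
    return RuleInductionResult(
        rules=tuple(rules),
        test_correct_pct=100.0 * correct / n_test,
        test_misidentified_pct=100.0 * mis / n_test,
        test_not_identified_pct=100.0 * (n_test - correct - mis) / n_test,
        n_test=n_test,
        skipped_species=tuple(skipped),
    )


def classify_by_rules(
    rules: Sequence[DiagnosticRule], seq: str
) -> str | None:
    """Species whose rule uniquely matches ``seq``; ``None`` if none or several."""
    hits = [r.species for r in rules if _rule_matches(r.conjuncts, seq)]
    if len(set(hits)) == 1:
        return hits[0]
    return None


def _iupac_regex(site: str) -> re.Pattern:
    return re.compile(
        "(?=(" + "".join(
            c if len(IUPAC_SETS[c]) == 1 else "[" + IUPAC_SETS[c] + "]"
            for c in site
        ) + "))"
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_restriction_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """1-based start positions of recognition sites on an ungapped sequence.

    Both strands are scanned; reverse-strand hits are reported on forward
    coordinates (start of the matched stretch).  Overlapping matches are all
    reported.
    """
    if "-" in seq:
        raise ValueError("sequence contains gap characters; degap first")
    seq = seq.upper()
    site = enzyme.recognition.upper()
    hits = {m.start(1) + 1 for m in _iupac_regex(site).finditer(seq)}
    if not enzyme.is_palindromic:
        rc = reverse_complement(site)
        hits |= {m.start(1) + 1 for m in _iupac_regex(rc).finditer(seq)}
    return sorted(hits)


def _species_consensus(records: list, length: int) -> str:
    """Majority base per column; ties or gap-majority yield 'N' (skipped)."""
    cons = []
    for col in range(length):
        counts: dict[str, int] = {}
        for r in records:
            c = r.seq[col]
            if c in BASES:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            cons.append("-")
            continue
        top = max(counts.values())
        winners = [b for b, n in counts.items() if n == top]
        cons.append(winners[0] if len(winners) == 1 else "N")
    return "".join(cons)


def design_caps(
    aln: LocusAlignment,
    enzymes: Sequence[RestrictionEnzyme] = DEFAULT_ENZYMES,
    species: str | None = None,
) -> list[CAPSAssay]:
    """Find CAPS assays: diagnostic SNPs whose exchange flips a digest.

    For every pure diagnostic SNP, the degapped per-species consensus around
    the SNP (a window of site-length − 1 on each side) is scanned with the
    target state and with each non-target species' state substituted; an
    assay is emitted when exactly one of the two digests cuts within the
    window for *every* non-target species.
    """
    if not enzymes:
        raise ValueError("empty enzyme panel")
    chars = find_diagnostic_characters(aln, species=species)
    by_species: dict[str, list] = {}
    for r in aln.records:
        by_species.setdefault(r.species, []).append(r)
    consensus = {
        sp: _species_consensus(recs, aln.length) for sp, recs in by_species.items()
    }
    assays: list[CAPSAssay] = []
    for ch in chars:
        cons = consensus[ch.species]
        if cons[ch.position - 1] != ch.state:
            continue
        other_states = tuple(
            sorted(
                {
                    consensus[sp][ch.position - 1]
                    for sp in by_species
                    if sp != ch.species
                    and consensus[sp][ch.position - 1] in BASES
                }
            )
        )
        if not other_states or ch.state in other_states:
            continue
        for enz in enzymes:
            w = len(enz.recognition) - 1
            lo = max(0, ch.position - 1 - w)
            hi = min(aln.length, ch.position + w)
            window = cons[lo:hi].replace("-", "")
            if "N" in window or len(window) < len(enz.recognition):
                continue
            snp_off = ch.position - 1 - lo - cons[lo:ch.position - 1].count("-")
            target_window = window
            target_hits = [
                p
                for p in scan_restriction_sites(target_window, enz)
                if p <= snp_off + 1 <= p + len(enz.recognition) - 1
            ]
            flipped = True
            other_hits_all = []
            for st in other_states:
                other_window = (
                    window[:snp_off] + st + window[snp_off + 1:]
                )
                other_hits = [
                    p
                    for p in scan_restriction_sites(other_window, enz)
                    if p <= snp_off + 1 <= p + len(enz.recognition) - 1
                ]
                other_hits_all.append(other_hits)
                if bool(other_hits) == bool(target_hits):
                    flipped = False
                    break
            if not flipped:
                continue
            site_pos = (
                target_hits[0] if target_hits else other_hits_all[0][0]
            ) + lo
            assays.append(
                CAPSAssay(
                    locus=ch.locus,
                    species=ch.species,
                    snp_position=ch.position,
                    target_state=ch.state,
                    other_states=other_states,
                    enzyme=enz.name,
                    target_cuts=bool(target_hits),
                    site_position=site_pos,
                )
            )
            break  # first suitable enzyme per SNP
    return assays
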