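"""Distance-based species identification: Best Match, Best Close Match and
All Species Barcodes.

Each individual is queried in turn against all remaining references
(leave-one-out):

* **BM** — the query is assigned from the set of references at minimum
  distance (ties within a small tolerance).  All conspecific -> correct; all
  allospecific -> incorrect; mixed -> ambiguous.
* **BCM** — as BM, but a best match farther than an intra-specific distance
  threshold yields *no match*.  The default threshold is the 95th percentile
  of all intra-specific pairwise distances of the dataset.
* **All Species Barcodes (ASB)** — strictest criterion: correct only when the
  within-threshold match set consists of *every* conspecific reference and no
  allospecific one.

Aggregate rates pool ambiguous and no-match outcomes as "not identified".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .distances import DistanceMatrix, distance_matrix
from .seqio import BarcodeDataset, concatenate

__all__ = [
    "MatchResult",
    "IdentificationRates",
    "best_match",
    "bcm_threshold",
    "best_close_match",
    "all_species_barcodes",
    "classify_all",
    "identification_rates",
]

#: Tie tolerance on proportion distances (exact-tie semantics).
DEFAULT_EPSILON = 1e-9


@dataclass(frozen=True)
class MatchResult:
    query_id: str
    method: str  # BM | BCM | ASB
    outcome: str  # correct | incorrect | ambiguous | no_match
    best_ids: tuple[str, ...]
    best_distance: float | None  # percent
    threshold: float | None = None  # percent (BCM/ASB)


@dataclass(frozen=True)
class IdentificationRates:
    method: str
    n_queries: int
    correct_pct: float
    misidentified_pct: float
    not_identified_pct: float


def _partition_outcome(
    best_species: set[str], query_species: str
) -> str:
    if best_species == {query_species}:
        return "correct"
    if query_species in best_species:
        return "ambiguous"
    return "incorrect"


def best_match(
    query_id: str,
    m: DistanceMatrix,
    species_map: Mapping[str, str],
    epsilon: float = DEFAULT_EPSILON,
) -> MatchResult:
    """Assign a query to the species of its closest reference(s)."""
    qi = m.index(query_id)
    refs = [i for i in range(m.n) if i != qi]
    if not refs:
        raise ValueError("no references besides the query")
    dists = m.d[qi, refs]
    dmin = float(np.min(dists))
    best = [refs[k] for k in range(len(refs)) if dists[k] <= dmin + epsilon]
    best_ids = tuple(m.ids[i] for i in best)
    best_species = {species_map[m.ids[i]] for i in best}
    outcome = _partition_outcome(best_species, species_map[query_id])
    return MatchResult(
        query_id=query_id,
        method="BM",
        outcome=outcome,
        best_ids=best_ids,
        best_distance=100.0 * dmin if math.isfinite(dmin) else math.inf,
    )


def bcm_threshold(
    m: DistanceMatrix,
    species_map: Mapping[str, str],
    percentile: float = 95.0,
) -> float:
    """Intra-specific distance threshold (percent) at the given percentile.

    Linear interpolation over all finite intra-specific pairwise distances of
    the full dataset.
    """
    intra = [
        float(m.d[i, j])
        for i in range(m.n)
        for j in range(i + 1, m.n)
        if species_map[m.ids[i]] == species_map[m.ids[j]]
        and math.isfinite(m.d[i, j])
    ]
    if not intra:
        raise ValueError("no conspecific pairs to derive a threshold from")
    return 100.0 * float(np.percentile(intra, percentile))


def best_close_match(
    query_id: str,
    m: DistanceMatrix,
    species_map: Mapping[str, str],
    threshold: float,
    epsilon: float = DEFAULT_EPSILON,
) -> MatchResult:
    """BM restricted to best matches within ``threshold`` (percent)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    bm = best_match(query_id, m, species_map, epsilon)
    if bm.best_distance is None or bm.best_distance > threshold + 100.0 * epsilon:
        return MatchResult(
            query_id=query_id,
            method="BCM",
            outcome="no_match",
            best_ids=(),
            best_distance=bm.best_distance,
            threshold=threshold,
        )
    return MatchResult(
        query_id=query_id,
        method="BCM",
        outcome=bm.outcome,
        best_ids=bm.best_ids,
        best_distance=bm.best_distance,
        threshold=threshold,
    )


def all_species_barcodes(
    query_id: str,
    m: DistanceMatrix,
    species_map: Mapping[str, str],
    threshold: float,
    epsilon: float = DEFAULT_EPSILON,
    tolerate_far_allospecifics: bool = False,
) -> MatchResult:
    """Strict criterion over the whole within-threshold match set.

    Correct only when the match set is non-empty and contains every
    conspecific reference and no allospecific one.  With
    ``tolerate_far_allospecifics`` an allospecific inside the threshold is
    tolerated if it is farther than every conspecific.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    qi = m.index(query_id)
    refs = [i for i in range(m.n) if i != qi]
    if not refs:
        raise ValueError("no references besides the query")
    thr = threshold / 100.0
    inside = [i for i in refs if m.d[qi, i] <= thr + epsilon]
    query_species = species_map[m.ids[qi]]
    conspecifics = [i for i in refs if species_map[m.ids[i]] == query_species]
    dmin = float(np.min(m.d[qi, refs]))
    if not inside:
        return MatchResult(
            query_id=query_id,
            method="ASB",
            outcome="no_match",
            best_ids=(),
            best_distance=100.0 * dmin if math.isfinite(dmin) else math.inf,
            threshold=threshold,
        )
    inside_species = {species_map[m.ids[i]] for i in inside}
    inside_set = set(inside)
    complete = set(conspecifics) <= inside_set and bool(conspecifics)
    allo_inside = [i for i in inside if species_map[m.ids[i]] != query_species]
    pure = not allo_inside
    if not pure and tolerate_far_allospecifics and conspecifics:
        max_con = max(float(m.d[qi, i]) for i in conspecifics)
        pure = all(float(m.d[qi, i]) > max_con + epsilon for i in allo_inside)
    if complete and pure:
        outcome = "correct"
    else:
        outcome = _partition_outcome(inside_species, query_species)
        if outcome == "correct":
            # all matches conspecific but the set is incomplete: the strict
            # criterion fails without a positive misidentification
            outcome = "ambiguous"
    best_ids = tuple(sorted(m.ids[i] for i in inside))
    return MatchResult(
        query_id=query_id,
        method="ASB",
        outcome=outcome,
        best_ids=best_ids,
        best_distance=100.0 * dmin if math.isfinite(dmin) else math.inf,
        threshold=threshold,
    )


def classify_all(
    m: DistanceMatrix,
    species_map: Mapping[str, str],
    method: str,
    threshold: float | None = None,
    percentile: float = 95.0,
    epsilon: float = DEFAULT_EPSILON,
) -> list[MatchResult]:
    """Leave-one-out identification of every individual.

    The query is removed from the reference set, but the BCM/ASB threshold is
    computed once on the full dataset (batch behaviour).
    """
    method = method.upper()
    if method not in ("BM", "BCM", "ASB"):
        raise ValueError(f"unknown method {method!r}")
    if method in ("BCM", "ASB") and threshold is None:
        threshold = bcm_threshold(m, species_map, percentile)
    out = []
    for query in m.ids:
        if method == "BM":
            out.append(best_match(query, m, species_map, epsilon))
        elif method == "BCM":
            out.append(best_close_match(query, m, species_map, threshold, epsilon))
        else:
            out.append(
                all_species_barcodes(query, m, species_map, threshold, epsilon)
            )
    return out


def rates_from_results(results: Sequence[MatchResult]) -> IdentificationRates:
    n = len(results)
    correct = sum(r.outcome == "correct" for r in results)
    mis = sum(r.outcome == "incorrect" for r in results)
    not_id = n - correct - mis  # ambiguous + no_match pooled
    return IdentificationRates(
        method=results[0].method if results else "?",
        n_queries=n,
        correct_pct=100.0 * correct / n,
        misidentified_pct=100.0 * mis / n,
        not_identified_pct=100.0 * not_id / n,
    )


def identification_rates(
    dataset: BarcodeDataset,
    loci: Sequence[str],
    method: str,
    threshold: float | None = None,
    percentile: float = 95.0,
) -> IdentificationRates:
    """Leave-one-out identification rates for a locus (combination)."""
    aln = concatenate(dataset, list(loci))
    m = distance_matrix(aln)
    results = classify_all(
        m, aln.species_map, method, threshold=threshold, percentile=percentile
    )
    return rates_from_results(results)
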