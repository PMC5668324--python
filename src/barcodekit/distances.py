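"""Kimura two-parameter (K2P) distances and barcode-gap analysis.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions from transversions.  With *P* the proportion of
transitions and *Q* the proportion of transversions among the compared sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites where either sequence has a gap or an IUPAC ambiguity code are excluded
pair by pair (pairwise deletion).  Distances are stored as proportions and
rendered as percentages in reports.  Saturated pairs (a non-positive logarithm
argument) are flagged as undefined and stored as ``inf``; they are excluded
from means but never silently zeroed.

Barcode-gap analysis is per species ("local" gap): a species shows a gap when
its maximum intra-specific distance is smaller than its nearest-neighbour
distance, i.e. the dot lies above the 1:1 line of an intra-vs-NN scatter plot.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .seqio import LocusAlignment

__all__ = [
    "NoOverlapError",
    "DistanceMatrix",
    "SpeciesSummary",
    "k2p_distance",
    "distance_matrix",
    "species_summaries",
    "divergence_means",
    "distance_histogram",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class NoOverlapError(ValueError):
    """A sequence pair shares no site with unambiguous bases in both."""


def k2p_distance(a: str, b: str) -> tuple[float, int]:
    """K2P distance between two equal-length gapped sequences.

    Returns ``(distance, compared_sites)``; the distance is ``inf`` when the
    correction is undefined (1-2P-Q <= 0 or 1-2Q <= 0).
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    compared = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        compared += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if compared == 0:
        raise NoOverlapError("no overlap: zero compared sites")
    p = transitions / compared
    q = transversions / compared
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf, compared
    # + 0.0 normalises the IEEE -0.0 arising from log(1.0)
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0, compared


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with compared-site counts.

    ``d`` holds proportions (``inf`` marks undefined/saturated entries);
    ``sites`` holds the pairwise-deletion compared-site counts.
    """

    ids: list[str]
    d: np.ndarray
    sites: np.ndarray

    def index(self, individual_id: str) -> int:
        try:
            return self.ids.index(individual_id)
        except ValueError:
            raise KeyError(f"{individual_id!r} not in distance matrix") from None

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances as a flat array (each pair once)."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def distance_matrix(aln: LocusAlignment) -> DistanceMatrix:
    """All-pairs K2P matrix under pairwise deletion.

    Raises :class:`NoOverlapError` naming the pair if any two sequences share
    no compared site.
    """
    if len(aln.records) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(aln.records)
    # integer encoding: A,C,G,T -> 0..3, anything else -> -1 (excluded)
    lut = np.full(256, -1, dtype=np.int8)
    for k, base in enumerate("ACGT"):
        lut[ord(base)] = k
    enc = np.stack(
        [lut[np.frombuffer(r.seq.encode(), dtype=np.uint8)] for r in aln.records]
    )
    purine = (enc == 0) | (enc == 2)
    valid = enc >= 0
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        compared = int(both.sum())
        if compared == 0:
            raise NoOverlapError(
                f"no overlap between {aln.records[i].individual_id!r} and "
                f"{aln.records[j].individual_id!r}"
            )
        diff = both & (enc[i] != enc[j])
        ts = int((diff & (purine[i] == purine[j])).sum())
        tv = int(diff.sum()) - ts
        p, q = ts / compared, tv / compared
        w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
        dist = (
            -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0
            if w1 > 0.0 and w2 > 0.0
            else math.inf
        )
        d[i, j] = d[j, i] = dist
        sites[i, j] = sites[j, i] = compared
    np.fill_diagonal(sites, aln.length)
    return DistanceMatrix(ids=aln.ids, d=d, sites=sites)


@dataclass(frozen=True)
class SpeciesSummary:
    """Intra-specific spread and nearest-neighbour distance for one species.

    All distances are percentages.  ``gap_present`` is the local barcode-gap
    criterion ``max_intra < nn_distance``.
    """

    species: str
    n_individuals: int
    max_intra: float
    mean_intra: float
    nn_species: str
    nn_all_tied: tuple[str, ...]
    nn_distance: float
    gap_present: bool


def _intra_distances(m: DistanceMatrix, members: list[int]) -> list[float]:
    return [
        float(m.d[i, j])
        for i, j in itertools.combinations(members, 2)
        if math.isfinite(m.d[i, j])
    ]


def species_summaries(
    m: DistanceMatrix, species_map: Mapping[str, str]
) -> list[SpeciesSummary]:
    """Per-species intra/NN summary (the barcode-gap table).

    Singleton species report ``max_intra = mean_intra = 0``.  Nearest
    neighbour ties (within float equality) report all tied species, with the
    alphabetically first as primary.
    """
    unmapped = [i for i in m.ids if i not in species_map]
    if unmapped:
        raise KeyError(f"individuals without species: {unmapped}")
    by_species: dict[str, list[int]] = {}
    for idx, indiv in enumerate(m.ids):
        by_species.setdefault(species_map[indiv], []).append(idx)
    if len(by_species) < 2:
        raise ValueError("need at least 2 species for nearest-neighbour analysis")
    out = []
    for species in sorted(by_species):
        members = by_species[species]
        others = [
            (idx, sp)
            for sp, idxs in by_species.items()
            if sp != species
            for idx in idxs
        ]
        intra = _intra_distances(m, members)
        max_intra = max(intra) if intra else 0.0
        mean_intra = float(np.mean(intra)) if intra else 0.0
        nn_dist = math.inf
        for i in members:
            for j, _sp in others:
                if m.d[i, j] < nn_dist:
                    nn_dist = float(m.d[i, j])
        tied = sorted(
            {
                sp
                for i in members
                for j, sp in others
                if math.isclose(m.d[i, j], nn_dist, rel_tol=0.0, abs_tol=1e-12)
            }
        )
        out.append(
            SpeciesSummary(
                species=species,
                n_individuals=len(members),
                max_intra=100.0 * max_intra,
                mean_intra=100.0 * mean_intra,
                nn_species=tied[0],
                nn_all_tied=tuple(tied),
                nn_distance=100.0 * nn_dist,
                gap_present=bool(100.0 * max_intra < 100.0 * nn_dist),
            )
        )
    return out


def divergence_means(
    m: DistanceMatrix, species_map: Mapping[str, str]
) -> dict[str, float]:
    """Overall intra-/inter-specific divergence means, in percent.

    Both conventions for the intra-specific average are returned:
    ``intra_mean_pairs`` (mean over all conspecific pairs) and
    ``intra_mean_species`` (mean of per-species means).  Saturated pairs are
    excluded.
    """
    by_species: dict[str, list[int]] = {}
    for idx, indiv in enumerate(m.ids):
        by_species.setdefault(species_map[indiv], []).append(idx)
    intra_all: list[float] = []
    species_means: list[float] = []
    for members in by_species.values():
        vals = _intra_distances(m, members)
        intra_all.extend(vals)
        if vals:
            species_means.append(float(np.mean(vals)))
    inter = [
        float(m.d[i, j])
        for i, j in itertools.combinations(range(m.n), 2)
        if species_map[m.ids[i]] != species_map[m.ids[j]]
        and math.isfinite(m.d[i, j])
    ]
    return {
        "intra_mean_pairs": 100.0 * float(np.mean(intra_all)) if intra_all else 0.0,
        "intra_mean_species": (
            100.0 * float(np.mean(species_means)) if species_means else 0.0
        ),
        "inter_mean_pairs": 100.0 * float(np.mean(inter)) if inter else 0.0,
    }


def distance_histogram(
    m: DistanceMatrix,
    species_map: Mapping[str, str],
    bin_width: float = 0.005,
) -> pd.DataFrame:
    """Frequency distribution of intra- vs inter-specific distances.

    Bins are half-open ``[k*w, (k+1)*w)`` on proportion distances; each pair
    falls in exactly one series.  Undefined (saturated) pairs are excluded.
    Returns a DataFrame with columns ``bin_left``, ``intra``, ``inter``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    intra, inter = [], []
    for i, j in itertools.combinations(range(m.n), 2):
        dist = m.d[i, j]
        if not math.isfinite(dist):
            continue
        same = species_map[m.ids[i]] == species_map[m.ids[j]]
        (intra if same else inter).append(dist)
    all_d = intra + inter
    n_bins = max(int(max(all_d) // bin_width) + 1, 1) if all_d else 1
    edges = np.arange(n_bins + 1) * bin_width
    intra_counts, _ = np.histogram(intra, bins=edges)
    inter_counts, _ = np.histogram(inter, bins=edges)
    # np.histogram closes the last bin on the right; values equal to the last
    # edge cannot occur because edges extend past the maximum.
    return pd.DataFrame(
        {"bin_left": edges[:-1], "intra": intra_counts, "inter": inter_counts}
    )
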