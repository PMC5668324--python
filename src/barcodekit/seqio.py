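"""Reading, writing and assembling species-annotated barcode alignments.

A barcode study works from one aligned multi-FASTA per locus, where every
sequence belongs to a known individual of a known species.  Headers follow a
configurable scheme, by default ``individual|Genus_species`` (e.g.
``Da1|Decalepis_arayalpathra``).  Loci are combined end-to-end for multi-locus
("tiered") analyses, and all multi-locus subsets of a locus panel can be
enumerated for exhaustive evaluation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "LocusAlignment",
    "BarcodeDataset",
    "AlignmentError",
    "HeaderError",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "load_manifest",
    "concatenate",
    "enumerate_combinations",
]

#: Unambiguous bases.
BASES = frozenset("ACGT")
#: Every character accepted in an aligned barcode sequence: IUPAC nucleotide
#: codes plus the gap character.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised when sequences violate alignment invariants."""


class HeaderError(ValueError):
    """Raised when a FASTA header cannot be parsed into (individual, species)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence tied to an individual and its species."""

    individual_id: str
    species: str
    locus: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise AlignmentError(f"empty sequence for {self.individual_id!r}")
        if not self.species:
            raise ValueError(f"empty species for {self.individual_id!r}")
        bad = [(i, c) for i, c in enumerate(self.seq, 1) if c not in IUPAC_DNA]
        if bad:
            pos, c = bad[0]
            raise AlignmentError(
                f"non-IUPAC character {c!r} at position {pos} in "
                f"{self.individual_id!r} ({self.locus})"
            )


class LocusAlignment:
    """Equal-length gapped DNA sequences for one locus.

    Parameters
    ----------
    locus:
        Locus name (e.g. ``"matK"``).
    records:
        Ordered :class:`SequenceRecord` objects, all of identical length.
    boundaries:
        Optional ``{locus: (start, end)}`` map (0-based half-open column
        spans) recording member-locus partitions of a concatenated alignment.
    """

    def __init__(
        self,
        locus: str,
        records: Sequence[SequenceRecord],
        boundaries: Mapping[str, tuple[int, int]] | None = None,
    ) -> None:
        records = list(records)
        if not records:
            raise AlignmentError(f"alignment {locus!r} has no records")
        length = len(records[0].seq)
        for r in records:
            if len(r.seq) != length:
                raise AlignmentError(
                    f"unequal aligned lengths in {locus!r}: {r.individual_id!r} "
                    f"has {len(r.seq)} columns, expected {length}"
                )
        ids = [r.individual_id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate individual ids in {locus!r}: {dup}")
        self.locus = locus
        self.records = records
        self.length = length
        self.boundaries = dict(boundaries) if boundaries else {locus: (0, length)}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.individual_id for r in self.records]

    @property
    def species_map(self) -> dict[str, str]:
        return {r.individual_id: r.species for r in self.records}

    @property
    def n_species(self) -> int:
        return len({r.species for r in self.records})

    def column(self, col: int) -> str:
        """Return alignment column ``col`` (1-based) as a string."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} out of range 1..{self.length}")
        return "".join(r.seq[col - 1] for r in self.records)

    def subset(self, ids: Iterable[str]) -> "LocusAlignment":
        wanted = set(ids)
        recs = [r for r in self.records if r.individual_id in wanted]
        missing = wanted - {r.individual_id for r in recs}
        if missing:
            raise KeyError(f"ids absent from {self.locus!r}: {sorted(missing)}")
        return LocusAlignment(self.locus, recs, boundaries=self.boundaries)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<LocusAlignment {self.locus!r}: {len(self.records)} seqs × "
            f"{self.length} bp, {self.n_species} species>"
        )


@dataclass
class BarcodeDataset:
    """A named set of locus alignments over a shared individual panel."""

    loci: dict[str, LocusAlignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        smap: dict[str, str] = {}
        for aln in self.loci.values():
            for r in aln.records:
                prev = smap.setdefault(r.individual_id, r.species)
                if prev != r.species:
                    raise ValueError(
                        f"individual {r.individual_id!r} mapped to both "
                        f"{prev!r} and {r.species!r}"
                    )

    @property
    def species_map(self) -> dict[str, str]:
        smap: dict[str, str] = {}
        for aln in self.loci.values():
            smap.update(aln.species_map)
        return smap

    @property
    def locus_names(self) -> list[str]:
        return list(self.loci)

    def add(self, aln: LocusAlignment) -> None:
        self.loci[aln.locus] = aln
        self.__post_init__()


def _normalise_species(name: str) -> str:
    return name.replace("_", " ").strip()


def _parse_header(header: str, header_scheme: str) -> tuple[str, str]:
    """Split a FASTA header into (individual_id, species).

    ``header_scheme`` is a delimiter-based pattern of the two tokens ``id``
    and ``species``, default ``"id|species"``.  Species underscores are
    normalised to spaces.
    """
    try:
        delim = header_scheme.replace("id", "").replace("species", "") or "|"
        order = header_scheme.split(delim)
    except Exception as exc:  # pragma: no cover
        raise HeaderError(f"bad header scheme {header_scheme!r}") from exc
    parts = header.split(delim, 1)
    if len(parts) != 2 or not all(parts):
        raise HeaderError(
            f"header {header!r} does not match scheme {header_scheme!r}"
        )
    fields = dict(zip(order, parts))
    return fields["id"].strip(), _normalise_species(fields["species"])


def read_aligned_fasta(
    path: str | Path,
    locus: str,
    header_scheme: str = "id|species",
) -> LocusAlignment:
    """Read one locus alignment from an aligned FASTA file.

    Sequences are uppercased and RNA ``U`` is converted to ``T``.  All
    sequences must have the same aligned length; violations raise
    :class:`AlignmentError` naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        indiv, species = _parse_header(rec.description, header_scheme)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(SequenceRecord(indiv, species, locus, seq))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return LocusAlignment(locus, records)


def write_aligned_fasta(
    aln: LocusAlignment,
    path: str | Path,
    header_scheme: str = "id|species",
) -> None:
    """Write an alignment back to FASTA with the same header scheme."""
    out = []
    for r in aln.records:
        header = header_scheme.replace(
            "id", r.individual_id
        ).replace("species", r.species.replace(" ", "_"))
        out.append(_BioSeqRecord(Seq(r.seq), id=header, description=""))
    SeqIO.write(out, str(path), "fasta-2line")


def load_manifest(path: str | Path, header_scheme: str = "id|species") -> BarcodeDataset:
    """Load a dataset from a JSON manifest mapping locus name -> FASTA path.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    ds = BarcodeDataset()
    for locus, fasta in spec.items():
        fasta = Path(fasta)
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        ds.add(read_aligned_fasta(fasta, locus, header_scheme))
    return ds


def concatenate(dataset: BarcodeDataset, loci: Sequence[str]) -> LocusAlignment:
    """Join loci end-to-end per individual, in the given locus order.

    Every individual of the first requested locus must be present in all
    requested loci.  The combined alignment records the member-locus column
    spans in ``boundaries``.
    """
    if not loci:
        raise ValueError("no loci requested")
    for name in loci:
        if name not in dataset.loci:
            raise KeyError(f"locus {name!r} not in dataset")
    if len(loci) == 1:
        return dataset.loci[loci[0]]
    id_sets = {name: set(dataset.loci[name].ids) for name in loci}
    union = set().union(*id_sets.values())
    missing = {
        name: sorted(union - ids) for name, ids in id_sets.items() if union - ids
    }
    if missing:
        raise AlignmentError(
            "individuals missing from some loci: "
            + "; ".join(f"{k}: {v}" for k, v in missing.items())
        )
    order = dataset.loci[loci[0]].ids
    smap = dataset.species_map
    by_locus = {
        name: {r.individual_id: r.seq for r in dataset.loci[name].records}
        for name in loci
    }
    records = []
    combined_name = "+".join(loci)
    for indiv in order:
        seq = "".join(by_locus[name][indiv] for name in loci)
        records.append(SequenceRecord(indiv, smap[indiv], combined_name, seq))
    boundaries: dict[str, tuple[int, int]] = {}
    offset = 0
    for name in loci:
        ln = dataset.loci[name].length
        boundaries[name] = (offset, offset + ln)
        offset += ln
    return LocusAlignment(combined_name, records, boundaries=boundaries)


def enumerate_combinations(locus_names: Iterable[str]) -> list[tuple[str, ...]]:
    """All multi-locus subsets (size >= 2) of a locus panel.

    Ordered by subset size, then lexicographically; a panel of *k* loci yields
    ``2**k - 1 - k`` subsets (e.g. 26 for the five standard plant barcodes).
    """
    names = sorted(set(locus_names))
    if len(names) < 2:
        raise ValueError("need at least 2 loci to enumerate combinations")
    combos: list[tuple[str, ...]] = []
    for size in range(2, len(names) + 1):
        combos.extend(itertools.combinations(names, size))
    return combos
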