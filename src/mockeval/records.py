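"""Sequence records, lineages, and file formats.

The in-memory carrier throughout the pipeline is :class:`SequenceRecord`: one
nucleotide sequence with an id, optional per-base Phred qualities, and an
integer read-count weight (used after dereplication).  Reference databases
couple accessioned marker sequences to ranked lineages and carry the synonym
and subgeneric-rank tables used during adjudication.

FASTA/FASTQ parsing and writing go through Biopython; the rank-delimited
taxonomy file ("accession<TAB>k__X;p__Y;...;s__Genus species;") is the
mothur-style dialect and is handled here directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: Taxonomic ranks, root first.  Species names are binomials whose first
#: whitespace token is the genus.
RANKS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species",
)

RANK_PREFIXES: tuple[str, ...] = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: Placeholder suffix conventions marking an unannotated name.  A species
#: ending in " sp" or any rank equal to/ending in "unclassified" counts as
#: unclassified at that rank.
UNANNOTATED_SUFFIXES: tuple[str, ...] = (" sp", "_sp", "unclassified")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def genus_of(name: str) -> str:
    """Genus = first whitespace token of a binomial."""
    return name.split()[0] if name else name


def is_unannotated(name: str) -> bool:
    """True when a taxon name carries an unannotated placeholder."""
    low = name.strip().lower()
    if not low:
        return True
    return low.endswith(" sp") or low.endswith("_sp") or low == "sp" \
        or low.endswith("unclassified")


@dataclass
class SequenceRecord:
    """One nucleotide sequence with optional qualities and a count weight."""

    id: str
    sequence: str
    qualities: list[int] | None = None
    weight: int = 1

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if self.weight < 1:
            raise ValueError(f"{self.id}: weight must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=r.id, sequence=str(r.seq))
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = (
        _BioRecord(Seq(r.sequence), id=r.id, description="") for r in records
    )
    SeqIO.write(bio, str(path), "fasta")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    out = []
    for r in SeqIO.parse(str(path), "fastq"):
        out.append(
            SequenceRecord(
                id=r.id,
                sequence=str(r.seq),
                qualities=list(r.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    def _gen() -> Iterator[_BioRecord]:
        for r in records:
            if r.qualities is None:
                raise ValueError(f"{r.id}: FASTQ output requires qualities")
            b = _BioRecord(Seq(r.sequence), id=r.id, description="")
            b.letter_annotations["phred_quality"] = list(r.qualities)
            yield b

    SeqIO.write(_gen(), str(path), "fastq")


# ---------------------------------------------------------------------------
# Reference databases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DBEntry:
    """One accessioned marker sequence bound to a ranked lineage."""

    accession: str
    lineage: tuple[str, ...]          # kingdom ... species, len == len(RANKS)
    marker: str                        # "ITS1" | "ITS2"
    sequence: str

    @property
    def species(self) -> str:
        return self.lineage[-1]

    @property
    def genus(self) -> str:
        return self.lineage[-2]


@dataclass
class ReferenceDatabase:
    """Marker reference sequences plus synonym and subgeneric-rank tables.

    ``synonym_map`` maps species name -> species name (applied to both calls
    and truth before comparison, after symmetric/transitive closure);
    ``subgeneric_map`` maps species name -> (rank kind, name) with kind one of
    section / series / species_complex.
    """

    name: str
    entries: list[DBEntry] = field(default_factory=list)
    synonym_map: dict[str, str] = field(default_factory=dict)
    subgeneric_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.marker, e.accession)
            if key in seen:
                raise ValueError(f"duplicate accession {e.accession} for {e.marker}")
            seen.add(key)
            if len(e.lineage) != len(RANKS):
                raise ValueError(
                    f"{e.accession}: lineage has {len(e.lineage)} ranks, "
                    f"expected {len(RANKS)}"
                )

    def entries_for(self, marker: str) -> list[DBEntry]:
        return [e for e in self.entries if e.marker == marker]

    def species_names(self, marker: str | None = None) -> set[str]:
        es = self.entries if marker is None else self.entries_for(marker)
        return {e.species for e in es}

    # -- persistence ------------------------------------------------------

    def write(self, fasta_path: str | Path, taxonomy_path: str | Path,
              marker: str | None = None) -> None:
        entries = self.entries if marker is None else self.entries_for(marker)
        write_fasta(
            (SequenceRecord(id=e.accession, sequence=e.sequence) for e in entries),
            fasta_path,
        )
        with open(taxonomy_path, "w") as fh:
            for e in entries:
                fh.write(f"{e.accession}\t{format_lineage(e.lineage)}\n")

    @classmethod
    def from_files(cls, name: str, fasta_path: str | Path,
                   taxonomy_path: str | Path, marker: str) -> "ReferenceDatabase":
        taxa = read_taxonomy(taxonomy_path)
        entries = []
        for rec in read_fasta(fasta_path):
            if rec.id not in taxa:
                raise ValueError(f"{fasta_path}: accession {rec.id} missing from "
                                 f"{taxonomy_path}")
            entries.append(DBEntry(rec.id, taxa[rec.id], marker, rec.sequence))
        return cls(name=name, entries=entries)


def format_lineage(lineage: tuple[str, ...]) -> str:
    """Rank-delimited form: ``k__X;p__Y;...;s__Genus species;``"""
    parts = [
        f"{pre}{name.replace(' ', '_')}"
        for pre, name in zip(RANK_PREFIXES, lineage)
    ]
    return ";".join(parts) + ";"


def parse_lineage(text: str) -> tuple[str, ...]:
    fields = [f for f in text.strip().split(";") if f]
    names = []
    for i, f in enumerate(fields):
        if i < len(RANK_PREFIXES) and f.startswith(RANK_PREFIXES[i]):
            f = f[len(RANK_PREFIXES[i]):]
        names.append(f.replace("_", " "))
    if len(names) != len(RANKS):
        raise ValueError(f"lineage {text!r} has {len(names)} ranks, "
                         f"expected {len(RANKS)}")
    return tuple(names)


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                acc, tax = line.split("\t", 1)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: expected 'accession<TAB>lineage'"
                ) from exc
            out[acc] = parse_lineage(tax)
    return out


def closure_canonicalize(synonym_map: Mapping[str, str]) -> dict[str, str]:
    """Resolve a synonym map to canonical representatives.

    Chains (A->B, B->C) resolve to the chain end; the symmetric closure is
    taken so that both directions of a pair canonicalize identically.
    """
    canon: dict[str, str] = {}

    def resolve(name: str) -> str:
        seen = [name]
        cur = name
        while cur in synonym_map and synonym_map[cur] not in seen:
            cur = synonym_map[cur]
            seen.append(cur)
        return cur

    for key in set(synonym_map) | set(synonym_map.values()):
        canon[key] = resolve(key)
    return canon
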