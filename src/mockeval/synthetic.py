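"""Synthetic study inputs: taxonomies, marker sequences, reference
databases, defined mock communities (DMCs), and error-bearing paired reads.

The generators emulate the statistical structure the downstream analysis
assumes: ~51 species over ~35 genera; 37 five-species communities at equal
20% theoretical abundance, four of which contain only four distinct genera
and the last two of which are identical-composition technical replicates;
reference databases of differing completeness and annotation depth;
confusable congener groups whose markers lie within the 0.03 clustering
cutoff; planted long homopolymers; substitution sequencing errors shaped by
a decaying quality profile; and two-parent single-crossover chimeras.

Every generator is a pure function of its parameters and a seed; one RNG
stream is derived per (seed, operation, entity) so entities are locally
reproducible.  Each simulated read carries its true species and chimera
status in a sidecar truth table keyed by read id.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._align import distance
from .records import SequenceRecord, genus_of, revcomp

MARKERS = ("ITS1", "ITS2")

#: Fixed 25-base anchors standing in for the conserved rRNA/primer regions
#: flanking each marker; amplicon = 5' anchor + marker + 3' anchor.  They let
#: marker extraction be an exact, testable flank-trimming step.
DEFAULT_FLANKS: dict[str, tuple[str, str]] = {
    "ITS1": ("ACCTGCGGAAGGATCATTACCGAGT", "CGATGAAGAACGCAGCGAAATGCGA"),
    "ITS2": ("GTGAATCATCGAATCTTTGAACGCA", "CCTCCGCTTATTGATATGCTTAAGT"),
}


def rng_for(seed: int, *keys: str | int) -> np.random.Generator:
    """Derive a reproducible stream for (seed, op_name, entity...)."""
    words = [int(seed) & 0xFFFFFFFF]
    for k in keys:
        if isinstance(k, int):
            words.append(k & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(k).encode()))
    return np.random.default_rng(np.random.SeedSequence(words))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_sites: int) -> str:
    """Substitute exactly ``n_sites`` distinct positions."""
    if n_sites <= 0:
        return seq
    chars = list(seq)
    sites = rng.choice(len(chars), size=min(n_sites, len(chars)), replace=False)
    for p in sites:
        old = chars[p]
        choices = [c for c in "ACGT" if c != old]
        chars[p] = choices[rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgenericRank:
    kind: str   # section | series | species_complex
    name: str


@dataclass
class SpeciesSpec:
    """One synthetic species: binomial name, markers, copy-number weight."""

    species_name: str
    genus: str
    subgeneric_rank: SubgenericRank | None = None
    marker_seqs: dict[str, str] = field(default_factory=dict)
    copy_number_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.genus != genus_of(self.species_name):
            raise ValueError(
                f"genus {self.genus!r} != first token of {self.species_name!r}")
        if self.copy_number_weight <= 0:
            raise ValueError("copy_number_weight must be positive")
        for marker, seq in self.marker_seqs.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"{self.species_name} {marker}: non-ACGT base")
            if not 150 <= len(seq) <= 600:
                raise ValueError(
                    f"{self.species_name} {marker}: length {len(seq)} "
                    "outside [150, 600]")


@dataclass(frozen=True)
class MockCommunitySpec:
    """Ground truth for one DMC: five members at 20% each."""

    dmc_id: str
    members: tuple[str, ...]
    theoretical_abundances: dict[str, float]
    replicate_of: str | None = None

    def __post_init__(self) -> None:
        if len(self.members) != len(set(self.members)):
            raise ValueError(f"{self.dmc_id}: duplicate members")
        if set(self.theoretical_abundances) != set(self.members):
            raise ValueError(f"{self.dmc_id}: abundance keys != members")
        total = sum(self.theoretical_abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.dmc_id}: abundances sum to {total}")

    @property
    def genera(self) -> set[str]:
        return {genus_of(m) for m in self.members}


@dataclass
class ReadSimParams:
    """Read-simulation settings for one community/marker."""

    reads_per_community: int = 1000
    substitution_error_rate: float = 0.002
    chimera_rate: float = 0.01
    copy_number_skew: bool = False
    read_length: int = 250
    flanks: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_FLANKS))
    quality_start: int = 38      # expected Phred at read start
    quality_end: int = 18        # expected Phred at read end (monotone decay)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_community <= 0:
            raise ValueError("reads_per_community must be positive")
        for r in (self.substitution_error_rate, self.chimera_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for f5, f3 in self.flanks.values():
            if not f5 or not f3:
                raise ValueError("flank anchors must be non-empty")
        if self.quality_end > self.quality_start:
            raise ValueError("quality profile must be non-increasing")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def generate_taxonomy(n_genera: int = 35,
                      species_per_genus: int | list[int] | None = None,
                      seed: int = 0) -> list[SpeciesSpec]:
    """Generate species skeletons (names + subgeneric ranks, no sequences).

    The default profile draws 1-3 species per genus so that 35 genera yield
    at least 51 species, mirroring the scale of the benchmark communities.
    """
    if n_genera < 1:
        raise ValueError("n_genera must be >= 1")
    rng = rng_for(seed, "taxonomy")
    if species_per_genus is None:
        counts = list(rng.choice([1, 2, 3], size=n_genera, p=[0.45, 0.35, 0.2]))
        # default profile guarantee: >= 51 species when 35+ genera requested
        while n_genera >= 35 and sum(counts) < max(51, n_genera):
            counts[int(rng.integers(0, n_genera))] += 1
    elif isinstance(species_per_genus, int):
        if species_per_genus < 1:
            raise ValueError("species_per_genus must be >= 1")
        counts = [species_per_genus] * n_genera
    else:
        counts = list(species_per_genus)
        if len(counts) != n_genera or any(c < 1 for c in counts):
            raise ValueError("species_per_genus list must give >=1 per genus")

    out: list[SpeciesSpec] = []
    for g in range(n_genera):
        genus = f"Genus{g + 1:02d}"
        for s in range(counts[g]):
            sub = None
            if counts[g] >= 2:
                # block species pairwise into sections within multi-species genera
                sub = SubgenericRank("section", f"{genus}-sect{s // 2 + 1}")
            out.append(SpeciesSpec(
                species_name=f"{genus} species{s + 1}",
                genus=genus,
                subgeneric_rank=sub,
            ))
    return out


def lineage_for(spec: SpeciesSpec) -> tuple[str, ...]:
    """Deterministic nested higher lineage derived from the genus index."""
    g = int(spec.genus.replace("Genus", "")) - 1
    return (
        "Fungi",
        f"Phylum{g // 16 + 1:02d}",
        f"Class{g // 8 + 1:02d}",
        f"Order{g // 4 + 1:02d}",
        f"Family{g // 2 + 1:02d}",
        spec.genus,
        spec.species_name,
    )


# ---------------------------------------------------------------------------
# Marker sequences
# ---------------------------------------------------------------------------

def generate_marker_sequences(
    skeletons: list[SpeciesSpec],
    base_divergence: dict[str, float] | None = None,
    confusable_groups: list[set[str]] | None = None,
    homopolymer_plants: list[tuple[str, str, str, int]] | None = None,
    seed: int = 0,
    markers: tuple[str, ...] = MARKERS,
    d_conf: float = 0.03,
) -> list[SpeciesSpec]:
    """Attach marker sequences to species skeletons.

    Each genus gets an independent random ancestral sequence per marker
    (length ~ N(280, 40) clipped to [180, 380] so quality-trimmed paired
    250-bp reads still overlap); species mutate away from it at the
    intra-genus rate.  Species
    in a confusable group are instead mutated from a common group leader by
    at most floor(L * d_conf / 2) sites each, which bounds every pairwise
    distance in the group by d_conf.  Homopolymer plants overwrite a slice
    with a verbatim single-base run.
    """
    div = {"intra_genus": 0.08}
    if base_divergence:
        div.update(base_divergence)
    confusable_groups = confusable_groups or []
    homopolymer_plants = homopolymer_plants or []

    by_name = {s.species_name: s for s in skeletons}
    group_of: dict[str, int] = {}
    for gi, grp in enumerate(confusable_groups):
        genera = {genus_of(n) for n in grp}
        if len(genera) != 1:
            raise ValueError(f"confusable group {sorted(grp)} spans genera {genera}")
        missing = grp - set(by_name)
        if missing:
            raise ValueError(f"confusable group names not in taxonomy: {missing}")
        for n in grp:
            group_of[n] = gi

    for marker in markers:
        roots: dict[str, str] = {}
        leaders: dict[int, str] = {}
        for spec in skeletons:
            rng = rng_for(seed, "markers", marker, spec.genus)
            if spec.genus not in roots:
                length = int(np.clip(rng.normal(280, 40), 180, 380))
                roots[spec.genus] = _random_seq(rng, length)
        for spec in skeletons:
            rng = rng_for(seed, "markers", marker, spec.species_name)
            root = roots[spec.genus]
            gi = group_of.get(spec.species_name)
            if gi is not None:
                if gi not in leaders:
                    leaders[gi] = _mutate(
                        rng_for(seed, "markers", marker, f"group{gi}"),
                        root, int(len(root) * div["intra_genus"]))
                leader = leaders[gi]
                k = int(len(leader) * d_conf / 2)
                # d_conf = 0 plants identical markers across the group,
                # modelling congeners indistinguishable in this region
                n_mut = 0 if k == 0 else int(rng.integers(1, k + 1))
                seq = _mutate(rng, leader, n_mut)
            else:
                n_mut = rng.binomial(len(root), div["intra_genus"])
                seq = _mutate(rng, root, int(n_mut))
            by_name[spec.species_name].marker_seqs = dict(
                by_name[spec.species_name].marker_seqs)
            by_name[spec.species_name].marker_seqs[marker] = seq

    for species_name, marker, base, run_length in homopolymer_plants:
        if run_length < 1:
            raise ValueError("homopolymer run_length must be >= 1")
        spec = by_name[species_name]
        seq = spec.marker_seqs[marker]
        rng = rng_for(seed, "homopolymer", marker, species_name)
        if run_length >= len(seq):
            raise ValueError("homopolymer longer than marker")
        pos = int(rng.integers(10, len(seq) - run_length - 10))
        spec.marker_seqs[marker] = seq[:pos] + base * run_length + seq[pos + run_length:]

    # no two species may share identical markers unless both sit in the
    # same confusable group (identical congeneric markers are then allowed)
    for marker in markers:
        seen: dict[str, str] = {}
        for spec in skeletons:
            seq = spec.marker_seqs.get(marker)
            if seq is None:
                continue
            while seq in seen and seen[seq] != spec.species_name and not (
                spec.species_name in group_of
                and group_of.get(seen[seq]) == group_of[spec.species_name]
            ):
                seq = _mutate(rng_for(seed, "dedup", marker, spec.species_name),
                              seq, 1)
                spec.marker_seqs[marker] = seq
            seen[seq] = spec.species_name
    return skeletons


# ---------------------------------------------------------------------------
# Reference databases
# ---------------------------------------------------------------------------

def build_reference_db(
    species: list[SpeciesSpec],
    marker: str,
    completeness: float = 1.0,
    unannotated_fraction: float = 0.0,
    synonym_renames: dict[str, str] | None = None,
    name: str = "refdb",
    seed: int = 0,
):
    """Build a reference database from species specs.

    ``completeness`` subsamples species (seeded); ``unannotated_fraction``
    truncates entries at genus by replacing the species epithet with the
    "sp" placeholder; ``synonym_renames`` stores entries under an alternate
    binomial while recording the pairing in the synonym map.
    """
    from .records import DBEntry, ReferenceDatabase

    if not species:
        raise ValueError("species list is empty")
    if not 0.0 <= completeness <= 1.0 or not 0.0 <= unannotated_fraction <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    synonym_renames = synonym_renames or {}

    rng = rng_for(seed, "refdb", name, marker)
    withm = [s for s in species if marker in s.marker_seqs]
    n_keep = int(round(completeness * len(withm)))
    keep_idx = sorted(rng.choice(len(withm), size=n_keep, replace=False))
    kept = [withm[i] for i in keep_idx]

    n_unann = int(round(unannotated_fraction * len(kept)))
    unann_idx = set(rng.choice(len(kept), size=n_unann, replace=False).tolist())

    entries = []
    synonym_map: dict[str, str] = {}
    subgeneric_map: dict[str, tuple[str, str]] = {}
    for i, spec in enumerate(kept):
        lineage = list(lineage_for(spec))
        if i in unann_idx:
            lineage[-1] = f"{spec.genus} sp"
        elif spec.species_name in synonym_renames:
            alt = synonym_renames[spec.species_name]
            lineage[-1] = alt
            lineage[-2] = genus_of(alt)
            synonym_map[spec.species_name] = alt
            synonym_map[alt] = spec.species_name
        entries.append(DBEntry(
            accession=f"{name}-{marker}-{i + 1:05d}",
            lineage=tuple(lineage),
            marker=marker,
            sequence=spec.marker_seqs[marker],
        ))
        if spec.subgeneric_rank is not None:
            subgeneric_map[spec.species_name] = (
                spec.subgeneric_rank.kind, spec.subgeneric_rank.name)

    return ReferenceDatabase(
        name=name, entries=entries,
        synonym_map=synonym_map, subgeneric_map=subgeneric_map,
    )


# ---------------------------------------------------------------------------
# Mock communities
# ---------------------------------------------------------------------------

def build_mock_communities(
    pool: list[SpeciesSpec],
    n_communities: int = 37,
    size: int = 5,
    distinct_genus_rule: bool = True,
    n_genus_exceptions: int = 4,
    include_replicate_pair: bool = True,
    seed: int = 0,
) -> list[MockCommunitySpec]:
    """Compose DMCs: ``size`` members each at equal theoretical abundance.

    Under the default profile, all communities draw members from distinct
    genera except a fixed set of exceptions (communities 1, 18, 19 and 34
    when 37 are built) which contain one within-genus pair, and the last two
    communities are identical-composition technical replicates.
    """
    if size < 1 or n_communities < 1:
        raise ValueError("size and n_communities must be positive")
    names = [s.species_name for s in pool]
    by_genus: dict[str, list[str]] = {}
    for n in names:
        by_genus.setdefault(genus_of(n), []).append(n)
    if distinct_genus_rule and len(by_genus) < size:
        raise ValueError(
            f"pool has {len(by_genus)} genera; {size} needed for the genus rule")

    # mirror the benchmark layout: exceptions at positions 1, 18, 19, 34 (1-based)
    exception_pos = {0, 17, 18, 33} if n_communities >= 34 else \
        set(range(min(n_genus_exceptions, max(0, n_communities - 2))))
    exception_pos = set(list(sorted(exception_pos))[:n_genus_exceptions]) \
        if distinct_genus_rule else set()
    multi_genera = [g for g, sp in by_genus.items() if len(sp) >= 2]
    if distinct_genus_rule and exception_pos and not multi_genera:
        raise ValueError("genus-rule exceptions need a genus with >= 2 species")

    rng = rng_for(seed, "communities")
    abund = 1.0 / size
    out: list[MockCommunitySpec] = []
    n_unique = n_communities - 1 if (include_replicate_pair
                                     and n_communities >= 2) else n_communities
    for i in range(n_unique):
        if distinct_genus_rule:
            if i in exception_pos:
                g2 = multi_genera[int(rng.integers(0, len(multi_genera)))]
                pair = list(rng.choice(by_genus[g2], size=2, replace=False))
                other_genera = [g for g in by_genus if g != g2]
                chosen_g = rng.choice(other_genera, size=size - 2, replace=False)
                members = pair + [
                    by_genus[g][int(rng.integers(0, len(by_genus[g])))]
                    for g in chosen_g]
            else:
                chosen_g = rng.choice(sorted(by_genus), size=size, replace=False)
                members = [
                    by_genus[g][int(rng.integers(0, len(by_genus[g])))]
                    for g in chosen_g]
        else:
            members = list(rng.choice(names, size=size, replace=False))
        out.append(MockCommunitySpec(
            dmc_id=f"dmc{i + 1:02d}",
            members=tuple(members),
            theoretical_abundances={m: abund for m in members},
        ))
    if include_replicate_pair and n_communities >= 2:
        last = out[-1]
        out.append(MockCommunitySpec(
            dmc_id=f"dmc{n_communities:02d}",
            members=last.members,
            theoretical_abundances=dict(last.theoretical_abundances),
            replicate_of=last.dmc_id,
        ))
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _error_probs(params: ReadSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-position substitution probabilities along a read.

    Linear Phred decay from quality_start to quality_end; per-base error
    probability follows 10^(-Q/10) rescaled so its mean equals the requested
    substitution rate.
    """
    L = params.read_length
    quals = np.linspace(params.quality_start, params.quality_end, L)
    p = 10.0 ** (-quals / 10.0)
    if params.substitution_error_rate == 0.0:
        return np.zeros(L), quals.round().astype(int)
    p = p * (params.substitution_error_rate / p.mean())
    return np.clip(p, 0.0, 0.75), quals.round().astype(int)


def _apply_substitutions(rng, seq: str, probs: np.ndarray) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < probs[: len(arr)]
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in idx:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_reads(
    community: MockCommunitySpec,
    species: list[SpeciesSpec],
    marker: str,
    params: ReadSimParams,
) -> tuple[list[SequenceRecord], list[SequenceRecord], pd.DataFrame]:
    """Simulate paired 250-bp reads for one community and marker.

    Returns (forward reads, reverse reads, truth table).  Per-species counts
    are multinomial on theoretical abundance x copy-number weight (when skew
    is on); chimeric reads join a prefix of one member's amplicon to the
    suffix of another's at a uniform interior breakpoint; forward and
    reverse reads are the two amplicon ends (reverse strand for R2) so that
    merging is possible whenever the amplicon fits in 2 x read_length.
    """
    by_name = {s.species_name: s for s in species}
    missing = [m for m in community.members if m not in by_name
               or marker not in by_name[m].marker_seqs]
    if missing:
        raise ValueError(f"{community.dmc_id}: no {marker} sequence for {missing}")

    f5, f3 = params.flanks[marker]
    amplicons = {
        m: f5 + by_name[m].marker_seqs[marker] + f3 for m in community.members
    }
    warnings: list[str] = []
    for m, amp in amplicons.items():
        if params.read_length < len(amp) / 2:
            warnings.append(
                f"{m}: amplicon {len(amp)} bp > 2x read length; pairs may not overlap")

    rng = rng_for(params.seed, "reads", community.dmc_id, marker)
    members = list(community.members)
    probs = np.array([community.theoretical_abundances[m] for m in members])
    if params.copy_number_skew:
        w = np.array([by_name[m].copy_number_weight for m in members])
        probs = probs * w
    probs = probs / probs.sum()
    counts = rng.multinomial(params.reads_per_community, probs)

    n_chim = rng.binomial(params.reads_per_community, params.chimera_rate)
    chim_flags = np.zeros(params.reads_per_community, dtype=bool)
    if n_chim:
        chim_flags[rng.choice(params.reads_per_community, size=n_chim,
                              replace=False)] = True

    sources = np.repeat(np.arange(len(members)), counts)
    err_probs, quals = _error_probs(params)
    qual_list = list(quals)

    fwd: list[SequenceRecord] = []
    rev: list[SequenceRecord] = []
    rows = []
    for ridx in range(params.reads_per_community):
        sp = members[sources[ridx]]
        chim_parent = ""
        if chim_flags[ridx] and len(members) > 1:
            others = [m for m in members if m != sp]
            mate = others[int(rng.integers(0, len(others)))]
            amp_a, amp_b = amplicons[sp], amplicons[mate]
            bp = int(rng.integers(1, min(len(amp_a), len(amp_b))))
            template = amp_a[:bp] + amp_b[bp:]
            chim_parent = mate
        else:
            template = amplicons[sp]
            chim_flags[ridx] = False
        L = params.read_length
        f_seq = template[:L]
        r_seq = revcomp(template[-L:] if len(template) >= L else template)
        f_seq = _apply_substitutions(rng, f_seq, err_probs)
        r_seq = _apply_substitutions(rng, r_seq, err_probs)
        rid = f"{community.dmc_id}_{marker}_r{ridx:06d}"
        fwd.append(SequenceRecord(id=f"{rid}/1", sequence=f_seq,
                                  qualities=qual_list[: len(f_seq)]))
        rev.append(SequenceRecord(id=f"{rid}/2", sequence=r_seq,
                                  qualities=qual_list[: len(r_seq)]))
        rows.append((rid, community.dmc_id, sp, bool(chim_flags[ridx]),
                     chim_parent))

    truth = pd.DataFrame(
        rows, columns=["read_id", "dmc_id", "species", "is_chimera",
                       "chimera_partner"])
    truth.attrs["warnings"] = warnings
    return fwd, rev, truth


def verify_confusable_group(species: list[SpeciesSpec], group: set[str],
                            marker: str, d_conf: float = 0.03) -> bool:
    """Check all pairwise marker distances within a group are <= d_conf."""
    by_name = {s.species_name: s for s in species}
    seqs = [by_name[n].marker_seqs[marker] for n in sorted(group)]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if distance(seqs[i], seqs[j]) > d_conf:
                return False
    return True
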