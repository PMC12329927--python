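"""End-to-end orchestration: configuration, the full simulate -> preprocess
-> OTU -> classify -> evaluate run, and tidy result tables.

A run is a pure function of its :class:`RunConfig`; the manifest records
the config hash, seeds, and per-stage record counts so reruns with the
same config are reproducible.  Combinations follow the
DATABASE-SOFTWARE-SETTING nomenclature: BLAST with strict or loose
adjudication, and the naive-Bayes (WANG) and nearest-neighbour (KNN)
classifiers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _cls
from . import evaluate as _ev
from . import otu as _otu
from . import preprocess as _pp
from . import synthetic as _syn
from .records import ReferenceDatabase, SequenceRecord

SOFTWARE_SETTINGS = (
    ("BLAST", "STRICT"), ("BLAST", "LOOSE"),
    ("MOTHUR", "WANG"), ("MOTHUR", "KNN"),
)


@dataclass
class DatabaseConfig:
    name: str
    completeness: float = 1.0
    unannotated_fraction: float = 0.0
    synonym_renames: dict[str, str] = field(default_factory=dict)


@dataclass
class RunConfig:
    seed: int = 0
    n_genera: int = 35
    n_communities: int = 37
    markers: tuple[str, ...] = ("ITS1", "ITS2")
    databases: tuple[DatabaseConfig, ...] = (
        DatabaseConfig(name="dbcomplete"),
        DatabaseConfig(name="dbpartial", completeness=0.9,
                       unannotated_fraction=0.1),
    )
    reads_per_community: int = 1000
    substitution_error_rate: float = 0.002
    chimera_rate: float = 0.01
    copy_number_skew: bool = False
    confusable_groups: tuple[tuple[str, ...], ...] = ()
    #: max pairwise distance within a confusable group; 0 plants identical
    #: markers (congeners indistinguishable in the sequenced region)
    confusable_distance: float = 0.03
    homopolymer_plants: tuple[tuple[str, str, str, int], ...] = ()
    sanger_mode: bool = False
    levels: tuple[str, ...] = ("species", "genus")

    def __post_init__(self) -> None:
        if not self.markers or not self.databases:
            raise ValueError("markers and databases must be non-empty")
        for m in self.markers:
            if m not in _syn.MARKERS:
                raise ValueError(f"unknown marker {m!r}")

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_config_dict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        dbs = raw.pop("databases", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if dbs is not None:
            cfg.databases = tuple(DatabaseConfig(**d) for d in dbs)
        return cfg


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["databases"] = [asdict(db) for db in cfg.databases]
    return json.loads(json.dumps(d, default=list))


@dataclass
class RunResult:
    config: RunConfig
    species: list[_syn.SpeciesSpec]
    communities: list[_syn.MockCommunitySpec]
    databases: dict[str, ReferenceDatabase]
    #: (dmc_id, marker) -> pre-filter OTU list
    otus_raw: dict[tuple[str, str], list[_otu.OTU]]
    #: (dmc_id, marker) -> post-filter OTU list
    otus: dict[tuple[str, str], list[_otu.OTU]]
    #: (otu_id, marker, db, software) -> classification
    classifications: dict[tuple[str, str, str, str], _cls.ClassificationResult]
    calls: pd.DataFrame
    metrics: pd.DataFrame
    l1: pd.DataFrame
    manifest: dict


def _classify_rep(rep: SequenceRecord, db: ReferenceDatabase, marker: str,
                  software: str, setting: str, seed: int,
                  nb_model: _cls.KmerModel | None) -> _cls.ClassificationResult:
    if software == "BLAST":
        res = _cls.tophit_search(rep, db, marker)
    elif setting == "WANG":
        res = _cls.nb_classify(rep, db, marker, model=nb_model, seed=seed)
    else:
        res = _cls.knn_classify(rep, db, marker)
    return _cls.truncate_unannotated(res, db)


def run_all(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute the full benchmark and return (and optionally write) results."""
    seed = config.seed
    skeletons = _syn.generate_taxonomy(n_genera=config.n_genera, seed=seed)
    species = _syn.generate_marker_sequences(
        skeletons,
        confusable_groups=[set(g) for g in config.confusable_groups],
        homopolymer_plants=list(config.homopolymer_plants),
        seed=seed, markers=config.markers,
        d_conf=config.confusable_distance,
    )
    communities = _syn.build_mock_communities(
        species, n_communities=config.n_communities, seed=seed)

    # one database object per name holding entries for all markers
    databases: dict[str, ReferenceDatabase] = {}
    for dbc in config.databases:
        merged = None
        for m in config.markers:
            db = _syn.build_reference_db(
                species, marker=m, completeness=dbc.completeness,
                unannotated_fraction=dbc.unannotated_fraction,
                synonym_renames=dict(dbc.synonym_renames),
                name=dbc.name, seed=seed)
            if merged is None:
                merged = db
            else:
                merged.entries.extend(db.entries)
                merged.synonym_map.update(db.synonym_map)
                merged.subgeneric_map.update(db.subgeneric_map)
        databases[dbc.name] = merged

    sim = _syn.ReadSimParams(
        reads_per_community=config.reads_per_community,
        substitution_error_rate=config.substitution_error_rate,
        chimera_rate=config.chimera_rate,
        copy_number_skew=config.copy_number_skew,
        seed=seed,
    )

    stage_counts: dict[str, int] = {}
    otus_raw: dict[tuple[str, str], list[_otu.OTU]] = {}
    otus_kept: dict[tuple[str, str], list[_otu.OTU]] = {}
    for comm in communities:
        for marker in config.markers:
            if config.sanger_mode:
                markers_in = [
                    SequenceRecord(id=f"{comm.dmc_id}_{marker}_{m}",
                                   sequence=sp.marker_seqs[marker])
                    for m in comm.members
                    for sp in [next(s for s in species if s.species_name == m)]
                ]
                markers_clean, screened = _pp.screen_sequences(markers_in)
                pre = _pp.PreprocessResult(
                    markers=markers_clean,
                    log={"input_pairs": len(markers_in),
                         "screened_out": len(screened),
                         "markers": len(markers_clean)},
                    rejected=screened)
            else:
                fwd, rev, _truth = _syn.simulate_reads(comm, species, marker, sim)
                pre = _pp.preprocess_pairs(fwd, rev, sim.flanks[marker])
            raw, log = _otu.run_otu_pipeline(
                pre.markers, dmc_id=comm.dmc_id,
                sanger_mode=config.sanger_mode, skip_rare_filter=True)
            otus_raw[(comm.dmc_id, marker)] = raw
            kept = raw if config.sanger_mode else _otu.filter_rare(raw)
            otus_kept[(comm.dmc_id, marker)] = kept
            for k, v in {**pre.log, **log}.items():
                stage_counts[k] = stage_counts.get(k, 0) + v

    # classification of representatives, full grid
    nb_models = {
        (name, m): _cls.KmerModel(db, m)
        for name, db in databases.items() for m in config.markers
    }
    # classify every pre-filter OTU so threshold sweeps can re-adjudicate
    # at thresholds below the default without gaps
    classifications: dict[tuple[str, str, str, str], _cls.ClassificationResult] = {}
    for (dmc_id, marker), otus in otus_raw.items():
        for o in otus:
            # classify under the OTU id so downstream joins (calls, L1)
            # resolve to the OTU rather than to the representative read
            rep = SequenceRecord(id=o.otu_id,
                                 sequence=o.representative.sequence)
            for name, db in databases.items():
                for software, setting in SOFTWARE_SETTINGS:
                    key = (o.otu_id, marker, name, f"{software}-{setting}")
                    if software == "BLAST":
                        shared = (o.otu_id, marker, name, "BLAST")
                        if shared in classifications:
                            classifications[key] = classifications[shared]
                            continue
                    res = _classify_rep(rep, db, marker,
                                        software, setting, seed,
                                        nb_models[(name, marker)])
                    classifications[key] = res
                    if software == "BLAST":
                        classifications[(o.otu_id, marker, name, "BLAST")] = res

    # adjudication
    truths = {c.dmc_id: c for c in communities}
    call_rows = []
    calls_store: dict[tuple, list[_ev.AdjudicatedCall]] = {}
    for (dmc_id, marker), otus in otus_kept.items():
        truth = truths[dmc_id]
        for name, db in databases.items():
            for software, setting in SOFTWARE_SETTINGS:
                combo = f"{name.upper()}-{software}-{setting}"
                adjud_setting = ("loose" if setting == "LOOSE" else "strict") \
                    if software == "BLAST" else "strict"
                for level in config.levels:
                    bucket = calls_store.setdefault(
                        (dmc_id, marker, name, software, setting, level), [])
                    for o in otus:
                        res = classifications[
                            (o.otu_id, marker, name, f"{software}-{setting}")]
                        call = _ev.adjudicate(res, truth, level, adjud_setting,
                                              db.synonym_map, seed)
                        bucket.append(call)
                        call_rows.append({
                            "dmc_id": dmc_id, "marker": marker,
                            "combination": combo, "level": level,
                            "otu_id": o.otu_id, "verdict": call.verdict,
                            "matched_taxon": call.matched_taxon or "",
                            "group_size": call.equivalence_group_size,
                        })
    calls_df = pd.DataFrame(call_rows)

    # metrics per combination x marker x level (+ consensus when both markers)
    metric_rows = []
    l1_rows = []
    for name in databases:
        for software, setting in SOFTWARE_SETTINGS:
            combo = f"{name.upper()}-{software}-{setting}"
            for level in config.levels:
                for marker in config.markers:
                    counts = []
                    for comm in communities:
                        calls = calls_store.get(
                            (comm.dmc_id, marker, name, software, setting,
                             level), [])
                        cc = _ev.confusion_counts(calls, level)
                        counts.append(cc.get(
                            comm.dmc_id,
                            _ev.ConfusionCounts(comm.dmc_id, level)))
                        prof = _ev.abundance_profile(
                            otus_kept[(comm.dmc_id, marker)], calls,
                            comm, level, databases[name].synonym_map)
                        if prof.l1 is not None and not config.sanger_mode:
                            l1_rows.append({
                                "dmc_id": comm.dmc_id, "marker": marker,
                                "combination": combo, "level": level,
                                "l1": prof.l1})
                    row = _ev.metrics(counts, combination=combo, level=level)
                    metric_rows.append({
                        "combination": combo, "marker": marker, "level": level,
                        **{k: getattr(row, k) for k in (
                            "precision_mean", "precision_sd", "recall_mean",
                            "recall_sd", "f1_mean", "f1_sd",
                            "n_dmcs_precision", "n_dmcs_recall")},
                    })
                if len(config.markers) == 2:
                    counts = []
                    for comm in communities:
                        c1 = calls_store.get(
                            (comm.dmc_id, config.markers[0], name, software,
                             setting, level), [])
                        c2 = calls_store.get(
                            (comm.dmc_id, config.markers[1], name, software,
                             setting, level), [])
                        outcome = _ev.consensus_combine(
                            c1, c2, comm, level, databases[name].synonym_map)
                        counts.append(outcome.counts())
                    row = _ev.metrics(counts, combination=combo, level=level)
                    metric_rows.append({
                        "combination": combo, "marker": "consensus",
                        "level": level,
                        **{k: getattr(row, k) for k in (
                            "precision_mean", "precision_sd", "recall_mean",
                            "recall_sd", "f1_mean", "f1_sd",
                            "n_dmcs_precision", "n_dmcs_recall")},
                    })
    metrics_df = pd.DataFrame(metric_rows)
    l1_df = pd.DataFrame(l1_rows)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "config": _config_dict(config),
        "stage_counts": stage_counts,
        "n_species": len(species),
        "n_communities": len(communities),
        "n_classifications": len(classifications),
    }
    result = RunResult(
        config=config, species=species, communities=communities,
        databases=databases, otus_raw=otus_raw, otus=otus_kept,
        classifications=classifications, calls=calls_df,
        metrics=metrics_df, l1=l1_df, manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: RunResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = result.manifest["config_hash"]
    for df, fname in ((result.calls, "calls.tsv"),
                      (result.metrics, "metrics.tsv"),
                      (result.l1, "l1.tsv")):
        df = df.copy()
        if len(df):
            df.insert(0, "config_hash", h)
        df.to_csv(out / fname, sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    # OTU membership table and representatives
    rows = []
    reps = []
    for (dmc_id, marker), otus in result.otus.items():
        for o in otus:
            for sid, w in o.members.items():
                rows.append({"config_hash": h, "otu_id": o.otu_id,
                             "seq_id": sid, "weight": w, "dmc_id": dmc_id,
                             "marker": marker})
            reps.append(SequenceRecord(id=o.otu_id,
                                       sequence=o.representative.sequence))
    pd.DataFrame(rows).to_csv(out / "otu_members.tsv", sep="\t", index=False)
    from .records import write_fasta
    write_fasta(reps, out / "representatives.fasta")
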