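"""End-to-end orchestration: reads -> clonotypes -> ranking -> trees -> report.

The pipeline mirrors the screening strategy: one unselected round-0 library
is shared by all panning arms; each arm's final-round reads are processed
into amino-acid clonotypes; clones are ranked by amplification fold vs
round 0; the per-library and combined top-K sets are placed on
neighbor-joining trees; clusters and cross-library identical-CDR3 groups
are merged into a mono- vs multi-specific candidate report.

Every stage's declared output file is written under ``output_dir`` together
with a machine-readable run manifest (parameters, input checksums), so a
run is reproducible byte-for-byte from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

from . import annotate, crossreact, phylo, ranking, reads, simulate

__all__ = [
    "LibraryInput",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "make_fixtures",
    "FixtureSet",
    "load_run_config",
]

log = logging.getLogger("vhhscreen")


@dataclass(frozen=True)
class LibraryInput:
    name: str
    fastq_r1: str
    fastq_r2: str
    round_index: int = 2

    def __post_init__(self) -> None:
        if self.round_index < 1:
            raise ValueError(f"library {self.name}: round_index must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    round0_r1: str
    round0_r2: str
    libraries: tuple[LibraryInput, ...]
    output_dir: str
    top_k: int = 50
    cluster_homology_threshold: float = 0.988
    cdr3_mode: str = "exact"
    cdr3_identity_threshold: float = 0.98
    zero_policy: str = "floor1"
    read_params: reads.ReadParams = field(default_factory=reads.ReadParams)
    seed: int = 0

    def __post_init__(self) -> None:
        names = [lib.name for lib in self.libraries]
        if len(set(names)) != len(names):
            raise ValueError("library names must be unique")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class PipelineResult:
    output_dir: str
    summaries: list[ranking.LibrarySummary]
    ranked: dict[str, list[ranking.CloneRecord]]
    clusters: list[phylo.SpecificityGroup]
    cdr3_groups: list[crossreact.CDR3Group]
    report: crossreact.CandidateReport
    attrition: dict[str, dict[str, int]]
    manifest_path: str


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _annotate_topk(records: list[ranking.CloneRecord]) -> list[ranking.CloneRecord]:
    out = []
    for rec in records:
        ann = annotate.extract_cdr3(rec.aa_seq)
        out.append(dataclasses.replace(rec, cdr3=ann.cdr3 if ann.status == "ok" else ""))
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; write every declared interface file + manifest."""
    inputs = [config.round0_r1, config.round0_r2]
    for lib in config.libraries:
        inputs.extend([lib.fastq_r1, lib.fastq_r2])
    for path in inputs:
        if not os.path.exists(path):
            raise FileNotFoundError(f"input FASTQ not found: {path}")
    out = config.output_dir
    os.makedirs(out, exist_ok=True)

    log.info("processing round-0 library")
    r0 = reads.process_fastq_pair(config.round0_r1, config.round0_r2, config.read_params)
    reads.write_attrition_tsv(r0, os.path.join(out, "round0.attrition.tsv"))
    reads.write_accepted_fasta(r0, os.path.join(out, "round0.accepted.fasta"))
    if not r0.aa_counts:
        raise RuntimeError("stage read_processing: round-0 library yielded no accepted reads")

    summaries = [
        ranking.library_summary(r0.aa_counts, 2 * r0.attrition["input_pairs"], "round0")
    ]
    ranked: dict[str, list[ranking.CloneRecord]] = {}
    attrition = {"round0": r0.attrition}
    combined_seqs: dict[str, str] = {}

    for lib in config.libraries:
        log.info("processing library %s (round %d)", lib.name, lib.round_index)
        proc = reads.process_fastq_pair(lib.fastq_r1, lib.fastq_r2, config.read_params)
        attrition[lib.name] = proc.attrition
        reads.write_attrition_tsv(proc, os.path.join(out, f"{lib.name}.attrition.tsv"))
        reads.write_accepted_fasta(proc, os.path.join(out, f"{lib.name}.accepted.fasta"))
        if not proc.aa_counts:
            raise RuntimeError(
                f"stage read_processing: library {lib.name} yielded no accepted reads"
            )
        summaries.append(
            ranking.library_summary(proc.aa_counts, 2 * proc.attrition["input_pairs"], lib.name)
        )
        records = ranking.build_records(
            proc.aa_counts, r0.aa_counts, proc.hinge, config.zero_policy
        )
        top = _annotate_topk(ranking.rank_and_select(records, config.top_k, lib.name))
        ranked[lib.name] = top
        ranking.write_ranked_tsv(top, os.path.join(out, f"{lib.name}.ranked.tsv"))
        ranking.write_topk_fasta(top, os.path.join(out, f"{lib.name}.top{config.top_k}.fasta"))
        combined_seqs.update({c.clone_id: c.aa_seq for c in top})

        if len(top) >= 3:
            dm = phylo.distance_matrix({c.clone_id: c.aa_seq for c in top})
            tree = phylo.neighbor_joining(dm)
            with open(os.path.join(out, f"{lib.name}.nj.nwk"), "w") as fh:
                fh.write(phylo.write_newick(tree) + "\n")

    ranking.write_summary_tsv(summaries, os.path.join(out, "library_summary.tsv"))

    log.info("building combined tree over %d clones", len(combined_seqs))
    clusters: list[phylo.SpecificityGroup] = []
    if len(combined_seqs) >= 3:
        dm = phylo.distance_matrix(combined_seqs)
        tree = phylo.neighbor_joining(dm)
        with open(os.path.join(out, "combined.nj.nwk"), "w") as fh:
            fh.write(phylo.write_newick(tree) + "\n")
        phylo.write_phylip(dm, os.path.join(out, "combined.distances.phylip"))
        clusters = phylo.extract_clusters(
            tree, combined_seqs, config.cluster_homology_threshold, dm=dm
        )
    phylo.write_clusters_tsv(clusters, os.path.join(out, "clusters.tsv"))

    cdr3_groups, excluded = crossreact.group_by_cdr3(
        ranked, config.cdr3_mode, config.cdr3_identity_threshold
    )
    all_records = {c.clone_id: c for top in ranked.values() for c in top}
    report = crossreact.candidate_report(clusters, cdr3_groups, all_records, excluded)
    crossreact.write_candidate_tsv(report, os.path.join(out, "candidates.tsv"))
    crossreact.write_cdr3_matrix_tsv(
        cdr3_groups, [lib.name for lib in config.libraries],
        os.path.join(out, "cdr3_groups.tsv"),
    )

    manifest = {
        "package": "vhhscreen",
        "parameters": {
            "top_k": config.top_k,
            "cluster_homology_threshold": config.cluster_homology_threshold,
            "cdr3_mode": config.cdr3_mode,
            "cdr3_identity_threshold": config.cdr3_identity_threshold,
            "zero_policy": config.zero_policy,
            "seed": config.seed,
            "read_params": dataclasses.asdict(config.read_params),
            "libraries": [dataclasses.asdict(lib) for lib in config.libraries],
        },
        "input_checksums": {path: _md5(path) for path in inputs},
    }
    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        output_dir=out,
        summaries=summaries,
        ranked=ranked,
        clusters=clusters,
        cdr3_groups=cdr3_groups,
        report=report,
        attrition=attrition,
        manifest_path=manifest_path,
    )


@dataclass
class FixtureSet:
    """A simulated experiment ready to run through the pipeline."""

    repertoire: list[simulate.SyntheticClone]
    count_tables: dict[str, "object"]  # cell line -> per-round count DataFrame
    run_config: RunConfig
    truth_path: str


def make_fixtures(
    config: simulate.PanningConfig,
    out_dir: str,
    emit_all_rounds: bool = False,
    top_k: int = 50,
    read_params: reads.ReadParams | None = None,
) -> FixtureSet:
    """Simulate an experiment and write its FASTQ + ground truth to disk.

    One round-0 R1/R2 pair (shared across arms) plus, per cell line, the
    final round's pair — or every round's when ``emit_all_rounds`` is set.
    Returns a :class:`FixtureSet` whose ``run_config`` points the analysis
    pipeline at the generated files.
    """
    os.makedirs(out_dir, exist_ok=True)
    repertoire = simulate.generate_repertoire(config)
    tables = {}
    libraries = []
    r0_paths: tuple[str, str] | None = None
    for line in config.cell_lines:
        table = simulate.simulate_panning(repertoire, line, config)
        tables[line] = table
        if r0_paths is None:
            paths = simulate.emit_fastq(table, repertoire, config, out_dir, "unselected", rounds=[0])
            r0_paths = paths[0]
        final = config.rounds
        rounds = list(range(1, final + 1)) if emit_all_rounds else [final]
        paths = simulate.emit_fastq(table, repertoire, config, out_dir, line, rounds=rounds)
        libraries.append(
            LibraryInput(line, paths[final][0], paths[final][1], round_index=final)
        )

    truth_path = os.path.join(out_dir, "ground_truth.tsv")
    simulate.truth_table(repertoire, tables).to_csv(truth_path, sep="\t")

    run_config = RunConfig(
        round0_r1=r0_paths[0],
        round0_r2=r0_paths[1],
        libraries=tuple(libraries),
        output_dir=os.path.join(out_dir, "analysis"),
        top_k=top_k,
        read_params=read_params or reads.ReadParams(),
        seed=config.seed,
    )
    _write_run_config_yaml(run_config, os.path.join(out_dir, "run_config.yaml"))
    return FixtureSet(repertoire, tables, run_config, truth_path)


def _write_run_config_yaml(config: RunConfig, path: str) -> None:
    import yaml

    raw = dataclasses.asdict(config)
    raw["libraries"] = [dataclasses.asdict(lib) for lib in config.libraries]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def load_run_config(path: str) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rp = reads.ReadParams(**raw.get("read_params", {}))
    libs = tuple(LibraryInput(**d) for d in raw["libraries"])
    keys = {
        k: raw[k]
        for k in (
            "round0_r1", "round0_r2", "output_dir", "top_k",
            "cluster_homology_threshold", "cdr3_mode", "cdr3_identity_threshold",
            "zero_policy", "seed",
        )
        if k in raw
    }
    return RunConfig(libraries=libs, read_params=rp, **keys)
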