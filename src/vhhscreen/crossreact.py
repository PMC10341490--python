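"""Cross-library identical-CDR3 grouping and the final candidate report.

Clones from different panning arms that share an identical CDR3 (or, in
relaxed mode, CDR3s at >= 98% identity) are grouped; groups spanning two or
more libraries are flagged cross-reactive, the screen's multi-specific
candidates.  The candidate report merges this evidence with the tree
clusters: CDR3 sharing outranks tree-cluster purity, so a clone inside a
single-library cluster that shares a CDR3 across libraries is still
reported multi-specific.  All calls are computational predictions of
binding specificity, not validated binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotate import cdr3_identity
from .phylo import SpecificityGroup
from .ranking import CloneRecord

__all__ = [
    "CDR3Group",
    "CandidateRow",
    "CandidateReport",
    "group_by_cdr3",
    "candidate_report",
    "write_candidate_tsv",
    "write_cdr3_matrix_tsv",
]


@dataclass(frozen=True)
class CDR3Group:
    """Clones (possibly from several libraries) sharing a CDR3."""

    group_id: str
    cdr3_representative: str
    members: tuple[CloneRecord, ...]
    libraries_present: frozenset[str]

    @property
    def multiplicity(self) -> int:
        return len(self.libraries_present)

    @property
    def is_cross_reactive(self) -> bool:
        return self.multiplicity >= 2

    @property
    def representative(self) -> CloneRecord:
        return _representative(self.members)


def _representative(members: Sequence[CloneRecord]) -> CloneRecord:
    """Highest-fold member; ties broken by earliest library name."""
    return min(members, key=lambda c: (-c.fold, c.library, c.clone_id))


def group_by_cdr3(
    ranked_clones: Mapping[str, Sequence[CloneRecord]],
    mode: str = "exact",
    identity_threshold: float = 0.98,
) -> tuple[list[CDR3Group], list[str]]:
    """Group per-library top-K clones by CDR3 identity.

    ``exact`` mode hash-groups on the CDR3 string; ``homology`` mode
    single-links CDR3s whose pairwise identity is at least
    ``identity_threshold``.  Returns ``(groups, excluded_clone_ids)`` where
    the excluded list holds clones without a usable CDR3 annotation.
    Groups are sorted by multiplicity then maximum member fold (both
    descending); cross-reactive groups are labelled X, Y, Z, ...
    """
    if mode not in ("exact", "homology"):
        raise ValueError(f"unknown mode {mode!r}")
    clones: list[CloneRecord] = []
    excluded: list[str] = []
    for lib in ranked_clones:
        for c in ranked_clones[lib]:
            if c.cdr3:
                clones.append(c)
            else:
                excluded.append(c.clone_id)

    buckets: dict[int, list[CloneRecord]] = {}
    if mode == "exact":
        by_cdr3: dict[str, list[CloneRecord]] = {}
        for c in clones:
            by_cdr3.setdefault(c.cdr3, []).append(c)
        buckets = dict(enumerate(by_cdr3.values()))
    else:
        uniq = sorted({c.cdr3 for c in clones})
        parent = list(range(len(uniq)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                if cdr3_identity(uniq[i], uniq[j]) >= identity_threshold:
                    parent[find(i)] = find(j)
        pos = {s: i for i, s in enumerate(uniq)}
        grouped: dict[int, list[CloneRecord]] = {}
        for c in clones:
            grouped.setdefault(find(pos[c.cdr3]), []).append(c)
        buckets = dict(enumerate(grouped.values()))

    raw = []
    for members in buckets.values():
        members = tuple(sorted(members, key=lambda c: (c.library, c.clone_id)))
        libs = frozenset(c.library for c in members)
        raw.append((members, libs))
    raw.sort(key=lambda ml: (-len(ml[1]), -max(c.fold for c in ml[0]),
                             _representative(ml[0]).clone_id))

    groups = []
    n_cross = 0
    n_single = 0
    for members, libs in raw:
        if len(libs) >= 2:
            gid = _cross_label(n_cross)
            n_cross += 1
        else:
            gid = f"cdr3_{n_single}"
            n_single += 1
        rep = _representative(members)
        groups.append(CDR3Group(gid, rep.cdr3, members, libs))
    return groups, excluded


def _cross_label(i: int) -> str:
    return ("X", "Y", "Z")[i] if i < 3 else f"X{i + 1}"


@dataclass(frozen=True)
class CandidateRow:
    row_id: str
    kind: str  # cdr3_group | cluster
    representative: str
    predicted_specificity: str  # mono_specific | multi_specific
    target_libraries: tuple[str, ...]
    member_clone_ids: tuple[str, ...]
    evidence: str


@dataclass(frozen=True)
class CandidateReport:
    rows: tuple[CandidateRow, ...]
    unclustered_singletons: tuple[str, ...]
    excluded_no_cdr3: tuple[str, ...]


def candidate_report(
    clusters: Sequence[SpecificityGroup],
    cdr3_groups: Sequence[CDR3Group],
    all_records: Mapping[str, CloneRecord],
    excluded_no_cdr3: Sequence[str] = (),
) -> CandidateReport:
    """Merge tree-cluster and CDR3-sharing evidence into one candidate table.

    Cross-reactive CDR3 groups claim their members first and are reported
    multi-specific (CDR3 evidence dominates cluster purity); remaining
    cluster members form one row per cluster, mono- or multi-specific by
    library composition.  Every top-K clone lands in exactly one row or in
    the unclustered-singletons appendix.
    """
    rows: list[CandidateRow] = []
    claimed: set[str] = set()

    for g in cdr3_groups:
        if not g.is_cross_reactive:
            continue
        members = tuple(c.clone_id for c in g.members)
        rows.append(
            CandidateRow(
                row_id=g.group_id,
                kind="cdr3_group",
                representative=g.representative.clone_id,
                predicted_specificity="multi_specific",
                target_libraries=tuple(sorted(g.libraries_present)),
                member_clone_ids=members,
                evidence=f"identical CDR3 {g.cdr3_representative} in "
                         f"{g.multiplicity} libraries",
            )
        )
        claimed.update(members)

    in_cluster_rows: set[str] = set()
    for cl in clusters:
        remaining = tuple(m for m in cl.member_clone_ids if m not in claimed)
        if not remaining:
            continue
        comp: dict[str, int] = {}
        for m in remaining:
            lib = all_records[m].library
            comp[lib] = comp.get(lib, 0) + 1
        libs = tuple(sorted(comp))
        spec = "mono_specific" if len(libs) == 1 else "multi_specific"
        rep = _representative([all_records[m] for m in remaining])
        rows.append(
            CandidateRow(
                row_id=f"cluster_{cl.group_id}",
                kind="cluster",
                representative=rep.clone_id,
                predicted_specificity=spec,
                target_libraries=libs,
                member_clone_ids=remaining,
                evidence=f"tree cluster {cl.group_id}, min homology "
                         f"{cl.min_pairwise_homology:.4f}",
            )
        )
        in_cluster_rows.update(remaining)

    covered = claimed | in_cluster_rows
    singletons = tuple(sorted(cid for cid in all_records if cid not in covered))
    return CandidateReport(tuple(rows), singletons, tuple(excluded_no_cdr3))


def write_candidate_tsv(report: CandidateReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("row_id\tkind\trepresentative\tpredicted_specificity\t"
                 "target_libraries\tmembers\tevidence\n")
        for r in report.rows:
            fh.write(
                f"{r.row_id}\t{r.kind}\t{r.representative}\t{r.predicted_specificity}\t"
                f"{','.join(r.target_libraries)}\t{','.join(r.member_clone_ids)}\t"
                f"{r.evidence}\n"
            )
        for cid in report.unclustered_singletons:
            fh.write(f"singleton\tsingleton\t{cid}\tunclassified\t\t{cid}\t\n")


def write_cdr3_matrix_tsv(
    cdr3_groups: Sequence[CDR3Group], libraries: Sequence[str], path
) -> None:
    """Cross-reactive groups x libraries matrix of member clone ranks."""
    with open(path, "w") as fh:
        fh.write("group\tcdr3\t" + "\t".join(libraries) + "\n")
        for g in cdr3_groups:
            if not g.is_cross_reactive:
                continue
            cells = []
            for lib in libraries:
                ranks = sorted(
                    int(c.clone_id.rsplit("_", 1)[1])
                    for c in g.members
                    if c.library == lib
                )
                cells.append(",".join(str(r) for r in ranks))
            fh.write(f"{g.group_id}\t{g.cdr3_representative}\t" + "\t".join(cells) + "\n")
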