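"""Clonotype dereplication, library summaries, and amplification-fold ranking.

The ranking statistic of the screen is the amplification fold: the ratio of
a clone's frequency in an enriched library to its frequency in the
unselected round-0 library, where frequency denominators are each library's
merged-read total.  Clones unseen at round 0 are handled by a configurable
pseudocount policy so folds stay finite; clones are ranked by descending
fold and the top K per library feed the phylogeny stage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CloneRecord",
    "LibrarySummary",
    "dereplicate",
    "library_summary",
    "counts_from_marginals",
    "amplification_fold",
    "build_records",
    "rank_and_select",
    "write_ranked_tsv",
    "write_summary_tsv",
    "write_topk_fasta",
    "read_topk_fasta",
]


@dataclass(frozen=True)
class CloneRecord:
    """A dereplicated amino-acid clonotype with its enrichment statistics."""

    clone_id: str
    aa_seq: str
    count_r0: int
    count_final: int
    freq_r0: float
    freq_final: float
    fold: float
    hinge: str = "unassigned"
    cdr3: str = ""
    library: str = ""
    r0_floored: bool = False


@dataclass(frozen=True)
class LibrarySummary:
    """Per-library sequencing summary: counts and percentages vs merged reads."""

    library: str
    total_reads: int
    merged: int
    single_occurrence: int
    unique_sequences: int
    highest_frequency_count: int
    single_occurrence_pct: float
    unique_sequences_pct: float
    highest_frequency_pct: float


def dereplicate(aa_seqs: Iterable[str]) -> dict[str, int]:
    """Exact-match grouping of amino-acid sequences into clonotype counts."""
    return dict(Counter(aa_seqs))


def _pct(count: int, merged: int) -> float:
    """100 * count / merged, rounded half-up to 2 decimals."""
    q = (Decimal(count) * 100 / Decimal(merged)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def library_summary(
    counts: Mapping[str, int], total_reads: int, library: str = ""
) -> LibrarySummary:
    """Summary statistics of a dereplicated library.

    ``single_occurrence`` counts clonotypes seen exactly once,
    ``unique_sequences`` the distinct clonotypes, and
    ``highest_frequency_count`` the top clonotype's read count; the three
    percentages are relative to the merged-read total (the 100% row).
    """
    if not counts:
        raise ValueError("library_summary requires a non-empty count table")
    merged = sum(counts.values())
    single = sum(1 for c in counts.values() if c == 1)
    unique = len(counts)
    highest = max(counts.values())
    return LibrarySummary(
        library=library,
        total_reads=total_reads,
        merged=merged,
        single_occurrence=single,
        unique_sequences=unique,
        highest_frequency_count=highest,
        single_occurrence_pct=_pct(single, merged),
        unique_sequences_pct=_pct(unique, merged),
        highest_frequency_pct=_pct(highest, merged),
    )


def counts_from_marginals(
    merged: int, single_occurrence: int, unique: int, highest: int
) -> dict[str, int]:
    """Construct a count multiset matching printed library marginals.

    Builds ``single_occurrence`` singletons, one top clone of ``highest``
    reads, and spreads the remaining reads evenly (counts between 2 and
    ``highest``) over the remaining ``unique - single_occurrence - 1``
    clonotypes.  Used to validate summary arithmetic against published
    tables when only the marginals are known.
    """
    n_mid = unique - single_occurrence - 1
    remaining = merged - single_occurrence - highest
    if n_mid < 0 or remaining < 0:
        raise ValueError("inconsistent marginals")
    if n_mid == 0 and remaining != 0:
        raise ValueError("inconsistent marginals")
    counts: dict[str, int] = {}
    i = 0
    for _ in range(single_occurrence):
        counts[f"c{i}"] = 1
        i += 1
    counts[f"c{i}"] = highest
    i += 1
    if n_mid:
        q, r = divmod(remaining, n_mid)
        if q < 2 or q + 1 > highest:
            raise ValueError("marginals not representable with mid counts in [2, highest]")
        for j in range(n_mid):
            counts[f"c{i}"] = q + (1 if j < r else 0)
            i += 1
    return counts


def amplification_fold(
    count_final: int,
    merged_final: int,
    count_r0: int,
    merged_r0: int,
    zero_policy: str = "floor1",
) -> float:
    """Frequency ratio of a clone between the final and round-0 libraries.

    ``fold = (count_final / merged_final) / (count_r0_eff / merged_r0)``
    where a clone unobserved at round 0 gets an effective count of 1
    (``floor1``, default) or 0.5 (``pseudo0.5``) so the ratio stays finite.
    A clone unobserved in the final library has fold 0.
    """
    if min(count_final, count_r0) < 0 or min(merged_final, merged_r0) < 1:
        raise ValueError("counts must be >= 0 and merged totals >= 1")
    if count_final == 0:
        return 0.0
    if count_r0 > 0:
        eff = float(count_r0)
    elif zero_policy == "floor1":
        eff = 1.0
    elif zero_policy == "pseudo0.5":
        eff = 0.5
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    return (count_final / merged_final) / (eff / merged_r0)


def build_records(
    final_counts: Mapping[str, int],
    r0_counts: Mapping[str, int],
    hinge: Mapping[str, str] | None = None,
    zero_policy: str = "floor1",
) -> list[CloneRecord]:
    """One unranked :class:`CloneRecord` per clonotype of the final library."""
    merged_final = sum(final_counts.values())
    merged_r0 = sum(r0_counts.values())
    if merged_final < 1 or merged_r0 < 1:
        raise ValueError("both libraries must contain reads")
    records = []
    for aa, c_final in final_counts.items():
        c0 = r0_counts.get(aa, 0)
        records.append(
            CloneRecord(
                clone_id="",
                aa_seq=aa,
                count_r0=c0,
                count_final=c_final,
                freq_r0=c0 / merged_r0,
                freq_final=c_final / merged_final,
                fold=amplification_fold(c_final, merged_final, c0, merged_r0, zero_policy),
                hinge=(hinge or {}).get(aa, "unassigned"),
                r0_floored=c0 == 0,
            )
        )
    return records


def rank_and_select(
    clones: Sequence[CloneRecord], k: int, library: str = ""
) -> list[CloneRecord]:
    """Top-``k`` clones by descending fold, with deterministic tie-breaks.

    Ties break by higher final frequency, then lexicographic amino-acid
    sequence; clone ids are assigned ``<library>_<rank>`` with rank starting
    at 1.  Returns ``min(k, n)`` records.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(clones, key=lambda c: (-c.fold, -c.freq_final, c.aa_seq))[:k]
    return [
        replace(c, clone_id=f"{library}_{rank}" if library else f"_{rank}", library=library)
        for rank, c in enumerate(ordered, start=1)
    ]


def write_ranked_tsv(records: Sequence[CloneRecord], path) -> None:
    cols = (
        "clone_id\tfold\tfreq_r0\tfreq_final\tcount_r0\tcount_final\t"
        "r0_floored\thinge\tcdr3\taa_seq\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in records:
            fh.write(
                f"{c.clone_id}\t{c.fold:.2f}\t{c.freq_r0:.6g}\t{c.freq_final:.6g}\t"
                f"{c.count_r0}\t{c.count_final}\t{int(c.r0_floored)}\t"
                f"{c.hinge}\t{c.cdr3}\t{c.aa_seq}\n"
            )


def write_summary_tsv(summaries: Sequence[LibrarySummary], path) -> None:
    """Cross-library summary table in the published layout (counts + %)."""
    with open(path, "w") as fh:
        fh.write("parameter\t" + "\t".join(s.library for s in summaries) + "\n")
        rows = [
            ("total_reads", lambda s: str(s.total_reads)),
            ("merged", lambda s: f"{s.merged}(100%)"),
            ("single_occurrence", lambda s: f"{s.single_occurrence}({s.single_occurrence_pct:.2f}%)"),
            ("unique_sequences", lambda s: f"{s.unique_sequences}({s.unique_sequences_pct:.2f}%)"),
            ("highest_frequency", lambda s: f"{s.highest_frequency_count}({s.highest_frequency_pct:.2f}%)"),
        ]
        for name, fmt in rows:
            fh.write(name + "\t" + "\t".join(fmt(s) for s in summaries) + "\n")


def write_topk_fasta(records: Sequence[CloneRecord], path) -> None:
    with open(path, "w") as fh:
        for c in records:
            fh.write(f">{c.clone_id}|fold={c.fold:.2f}|hinge={c.hinge}|cdr3={c.cdr3}\n{c.aa_seq}\n")


def read_topk_fasta(path) -> list[CloneRecord]:
    """Read back a :func:`write_topk_fasta` file into minimal records."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(kv.split("=", 1) for kv in rec.description.split("|")[1:])
        clone_id = rec.id.split("|")[0]
        out.append(
            CloneRecord(
                clone_id=clone_id,
                aa_seq=str(rec.seq),
                count_r0=0,
                count_final=0,
                freq_r0=0.0,
                freq_final=0.0,
                fold=float(fields.get("fold", 0.0)),
                hinge=fields.get("hinge", "unassigned"),
                cdr3=fields.get("cdr3", ""),
                library=clone_id.rsplit("_", 1)[0],
            )
        )
    return out
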