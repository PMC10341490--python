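"""Paired-end amplicon read processing for VHH sequencing libraries.

Re-implements the merge / filter / trim / translate stage that turns raw
2 x 300 bp paired-end reads into in-frame VHH amino-acid sequences with a
hinge-class label:

1. :func:`merge_pair` — best ungapped overlap of R1 with the reverse
   complement of R2, quality-aware consensus in the overlap;
2. :func:`quality_filter` — expected-error filter (sum of Phred error
   probabilities);
3. :func:`trim_and_classify` — locate the common forward primer and one of
   the two hinge-specific reverse primers (IUPAC-aware, mismatch-tolerant),
   trim to the insert, and classify the hinge as short (IgG2) or long
   (IgG3);
4. :func:`translate_frame0` — translate in the frame anchored by the
   forward primer, rejecting internal stops and too-short products.

Every rejection is a counted category so a per-stage attrition report always
sums back to the number of input pairs.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "FWD_PRIMER",
    "REV_PRIMER_SHORT",
    "REV_PRIMER_LONG",
    "ReadParams",
    "ReadPair",
    "MergedRead",
    "TrimResult",
    "ProcessedLibrary",
    "revcomp",
    "iupac_match_positions",
    "merge_pair",
    "expected_errors",
    "quality_filter",
    "trim_and_classify",
    "translate_frame0",
    "process_fastq_pair",
    "write_accepted_fasta",
    "write_attrition_tsv",
]

# MiSeq amplicon primers: common forward primer plus hinge-specific reverse
# primers distinguishing the short (IgG2) and long (IgG3) camelid isotypes
FWD_PRIMER = "GGTGCAGCTCGTGGAGTCTGGGGG"
REV_PRIMER_SHORT = "GGGGTCTTCGCTGTGGTGCGC"  # IgG2, short hinge
REV_PRIMER_LONG = "GTGGTTTTGGTGTCTTGGGTTC"  # IgG3, long hinge

_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)

# IUPAC nucleotide codes as A/C/G/T bitmasks
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "M": 3, "R": 5, "W": 9, "S": 6, "Y": 10, "K": 12,
    "V": 7, "H": 11, "D": 13, "B": 14, "N": 15,
}
_CHAR_BITS = np.zeros(256, dtype=np.uint8)
for _c, _b in _IUPAC_BITS.items():
    _CHAR_BITS[ord(_c)] = _b
    _CHAR_BITS[ord(_c.lower())] = _b

_PHRED_ERR = 10.0 ** (-np.arange(128) / 10.0)


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _bits(seq: str) -> np.ndarray:
    arr = _CHAR_BITS[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if np.any(arr == 0):
        bad = seq[int(np.argmax(arr == 0))]
        raise ValueError(f"non-IUPAC nucleotide character {bad!r}")
    return arr


def iupac_match_positions(pattern: str, seq: str, max_mismatches: int = 0) -> list[int]:
    """All start positions where ``pattern`` matches ``seq`` IUPAC-aware.

    A position matches when the pattern's base set intersects the sequence's
    base set (so ``K`` matches G or T).  Up to ``max_mismatches`` failing
    columns are tolerated.
    """
    p = _bits(pattern)
    s = _bits(seq)
    n, m = len(s), len(p)
    out = []
    for off in range(n - m + 1):
        mm = int(np.count_nonzero((s[off : off + m] & p) == 0))
        if mm <= max_mismatches:
            out.append(off)
    return out


@dataclass
class ReadPair:
    read_id: str
    r1_seq: str
    r2_seq: str
    r1_qual: np.ndarray
    r2_qual: np.ndarray

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    read_id: str
    seq: str
    qual: np.ndarray
    overlap_len: int
    mismatches_in_overlap: int


@dataclass
class TrimResult:
    seq: str | None
    hinge: str | None  # "short_IgG2" | "long_IgG3"
    reason: str | None  # None | no_fwd_primer | no_rev_primer | ambiguous_rev_primer


@dataclass(frozen=True)
class ReadParams:
    """Merge / filter / trim / translate parameters.

    Defaults are community-standard amplicon settings; all are
    config-exposed because the upstream tooling's exact values are not
    recoverable.
    """

    min_overlap: int = 20
    max_mismatch_frac: float = 0.1
    max_expected_errors: float = 1.0
    fwd_primer: str = FWD_PRIMER
    rev_primer_short: str = REV_PRIMER_SHORT
    rev_primer_long: str = REV_PRIMER_LONG
    max_primer_mismatches: int = 2
    primer_window: int = 5
    frame_offset: int = 0
    min_aa_len: int = 90


_SEED_LEN = 20
_QUAL_CAP = 60


def _overlap_candidates(a: bytes, brc: bytes, min_overlap: int) -> list[int]:
    """Candidate overlap lengths from exact 20-mer seeds of brc found in a."""
    La = len(a)
    cands: set[int] = set()
    for s in (0, _SEED_LEN * 2, _SEED_LEN * 4):
        if s + _SEED_LEN > len(brc):
            break
        seed = brc[s : s + _SEED_LEN]
        pos = a.find(seed)
        while pos != -1:
            o = La - pos + s
            if min_overlap <= o <= min(La, len(brc)):
                cands.add(o)
            pos = a.find(seed, pos + 1)
    return sorted(cands)


def _best_overlap(
    a: np.ndarray, brc: np.ndarray, min_overlap: int, max_mismatch_frac: float
) -> tuple[int, int] | None:
    """Exhaustive scan: (overlap, matches) maximizing matches, or None."""
    La, Lb = len(a), len(brc)
    best: tuple[int, int] | None = None
    for o in range(min_overlap, min(La, Lb) + 1):
        matches = int(np.count_nonzero(a[La - o :] == brc[:o]))
        if (o - matches) / o > max_mismatch_frac:
            continue
        if best is None or matches > best[1] or (matches == best[1] and o > best[0]):
            best = (o, matches)
    return best


def _merge_oriented(
    a_seq: str,
    a_qual: np.ndarray,
    b_seq: str,
    b_qual: np.ndarray,
    min_overlap: int,
    max_mismatch_frac: float,
) -> tuple[str, np.ndarray, int, int] | None:
    brc_seq = revcomp(b_seq)
    a_b = a_seq.encode()
    brc_b = brc_seq.encode()
    a = np.frombuffer(a_b, dtype=np.uint8)
    brc = np.frombuffer(brc_b, dtype=np.uint8)
    La = len(a)

    best: tuple[int, int] | None = None
    for o in _overlap_candidates(a_b, brc_b, min_overlap):
        matches = int(np.count_nonzero(a[La - o :] == brc[:o]))
        if (o - matches) / o > max_mismatch_frac:
            continue
        if best is None or matches > best[1] or (matches == best[1] and o > best[0]):
            best = (o, matches)
    if best is None:
        best = _best_overlap(a, brc, min_overlap, max_mismatch_frac)
    if best is None:
        return None

    o, matches = best
    bq = b_qual[::-1]
    ov_a, ov_b = a[La - o :], brc[:o]
    qa, qb = a_qual[La - o :], bq[:o]
    agree = ov_a == ov_b
    cons = np.where(qa >= qb, ov_a, ov_b)
    cons_q = np.where(
        agree,
        np.minimum(qa.astype(np.int64) + qb, _QUAL_CAP),
        np.maximum(np.abs(qa.astype(np.int64) - qb), 2),
    )
    seq = a_seq[: La - o] + cons.tobytes().decode() + brc_seq[o:]
    qual = np.concatenate([a_qual[: La - o], cons_q, bq[o:]])
    return seq, qual, o, o - matches


def merge_pair(
    pair: ReadPair, min_overlap: int = 20, max_mismatch_frac: float = 0.1
) -> MergedRead | None:
    """Merge mates on their best ungapped overlap; ``None`` if none passes.

    R1 is overlapped against the reverse complement of R2 (and the flipped
    orientation is also tried, since sequencer output strand is not
    guaranteed); among overlaps of at least ``min_overlap`` bases with a
    mismatch fraction at most ``max_mismatch_frac``, the one maximizing
    matched bases wins.  At overlap mismatches the consensus takes the
    higher-quality base; agreeing bases get a combined (summed, capped)
    quality.
    """
    if not pair.r1_seq or not pair.r2_seq:
        return None
    res = _merge_oriented(
        pair.r1_seq, pair.r1_qual, pair.r2_seq, pair.r2_qual, min_overlap, max_mismatch_frac
    )
    if res is None:
        res = _merge_oriented(
            pair.r2_seq, pair.r2_qual, pair.r1_seq, pair.r1_qual, min_overlap, max_mismatch_frac
        )
    if res is None:
        return None
    seq, qual, o, mm = res
    return MergedRead(pair.read_id, seq, qual, o, mm)


def expected_errors(qual: np.ndarray) -> float:
    """Sum of per-base error probabilities implied by Phred scores."""
    return float(_PHRED_ERR[np.asarray(qual, dtype=np.int64)].sum())


def quality_filter(read: MergedRead, max_expected_errors: float = 1.0) -> bool:
    """Pass iff the read's expected error count is within the threshold."""
    return expected_errors(read.qual) <= max_expected_errors


def _find_primer_5p(seq_bits: np.ndarray, primer: str, window: int, max_mm: int) -> int | None:
    """Best start offset of primer within the 5' window, or None."""
    p = _bits(primer)
    m = len(p)
    best_off, best_mm = None, max_mm + 1
    for off in range(0, min(window, len(seq_bits) - m) + 1):
        mm = int(np.count_nonzero((seq_bits[off : off + m] & p) == 0))
        if mm < best_mm:
            best_off, best_mm = off, mm
    return best_off


def _find_site_3p(seq_bits: np.ndarray, site: str, window: int, max_mm: int) -> tuple[int, int] | None:
    """Best (start, mismatches) of a primer site within the 3' window."""
    p = _bits(site)
    m = len(p)
    L = len(seq_bits)
    best: tuple[int, int] | None = None
    for shift in range(0, window + 1):
        start = L - m - shift
        if start < 0:
            break
        mm = int(np.count_nonzero((seq_bits[start : start + m] & p) == 0))
        if mm <= max_mm and (best is None or mm < best[1]):
            best = (start, mm)
    return best


def trim_and_classify(seq: str, params: ReadParams = ReadParams()) -> TrimResult:
    """Locate primers, trim to the insert, classify the hinge.

    The forward primer must sit within ``primer_window`` bases of the 5'
    end; the reverse-complemented site of one of the two hinge-specific
    reverse primers within the same window of the 3' end (IUPAC-aware, up to
    ``max_primer_mismatches`` mismatches each).  The hinge class follows the
    better-matching reverse primer; an exact tie is rejected as ambiguous.
    The returned insert excludes both primers, shifted by ``frame_offset``
    bases to fix the reading frame.
    """
    bits = _bits(seq)
    fwd_off = _find_primer_5p(bits, params.fwd_primer, params.primer_window,
                              params.max_primer_mismatches)
    if fwd_off is None:
        return TrimResult(None, None, "no_fwd_primer")
    hits = []
    for hinge, primer in (
        ("short_IgG2", params.rev_primer_short),
        ("long_IgG3", params.rev_primer_long),
    ):
        hit = _find_site_3p(bits, revcomp(primer), params.primer_window,
                            params.max_primer_mismatches)
        if hit is not None:
            hits.append((hit[1], hinge, hit[0]))
    if not hits:
        return TrimResult(None, None, "no_rev_primer")
    hits.sort()
    if len(hits) == 2 and hits[0][0] == hits[1][0]:
        return TrimResult(None, None, "ambiguous_rev_primer")
    mm, hinge, site_start = hits[0]
    start = fwd_off + len(params.fwd_primer) + params.frame_offset
    if start >= site_start:
        return TrimResult(None, None, "no_rev_primer")
    return TrimResult(seq[start:site_start], hinge, None)


_CODON_AA: dict[str, str] = {}


def _codon_map() -> dict[str, str]:
    if not _CODON_AA:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_AA.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_AA[stop] = "*"
    return _CODON_AA


def translate_frame0(nt: str, min_aa_len: int = 90) -> tuple[str | None, str | None]:
    """Translate frame 0; returns ``(aa_seq, None)`` or ``(None, reason)``.

    The trailing partial codon is dropped; ambiguous codons translate to
    ``X``.  Internal stop codons reject with ``stop_codon``; products
    shorter than ``min_aa_len`` reject with ``too_short``.
    """
    _bits(nt)  # validates the alphabet
    table = _codon_map()
    nt = nt.upper()
    aa_chars = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aa_chars.append(table.get(nt[i : i + 3], "X"))
    aa = "".join(aa_chars)
    stop = aa.find("*")
    if stop != -1:
        if stop < len(aa) - 1:
            return None, "stop_codon"
        aa = aa[:-1]
    if len(aa) < min_aa_len:
        return None, "too_short"
    return aa, None


# ---------------------------------------------------------------------------
# library-level processing
# ---------------------------------------------------------------------------

_TRIM_STAGES = ("no_fwd_primer", "no_rev_primer", "ambiguous_rev_primer",
                "stop_codon", "too_short")


@dataclass
class ProcessedLibrary:
    """Accepted clonotype counts plus the per-stage attrition of one library."""

    aa_counts: dict[str, int]
    hinge: dict[str, str]
    attrition: dict[str, int]

    @property
    def accepted(self) -> int:
        return sum(self.aa_counts.values())


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream synchronized mate pairs from two FASTQ files (offset-33)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        for (id1, s1, q1), (_id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            yield ReadPair(
                id1.split()[0],
                s1,
                s2,
                np.frombuffer(q1.encode(), dtype=np.uint8).astype(np.int64) - 33,
                np.frombuffer(q2.encode(), dtype=np.uint8).astype(np.int64) - 33,
            )


def process_fastq_pair(r1_path, r2_path, params: ReadParams = ReadParams()) -> ProcessedLibrary:
    """Run merge -> expected-error filter -> trim -> translate over a library.

    Identical merged sequences are collapsed before the trim/translate
    stages (those stages depend only on the sequence), which keeps the
    per-read attrition accounting exact while avoiding redundant work.
    """
    att = Counter(
        {
            "input_pairs": 0,
            "merged": 0,
            "no_merge": 0,
            "low_quality": 0,
            "passed_filter": 0,
            **{s: 0 for s in _TRIM_STAGES},
            "accepted": 0,
        }
    )
    seq_counts: Counter[str] = Counter()
    for pair in iter_fastq_pairs(r1_path, r2_path):
        att["input_pairs"] += 1
        merged = merge_pair(pair, params.min_overlap, params.max_mismatch_frac)
        if merged is None:
            att["no_merge"] += 1
            continue
        att["merged"] += 1
        if not quality_filter(merged, params.max_expected_errors):
            att["low_quality"] += 1
            continue
        att["passed_filter"] += 1
        seq_counts[merged.seq] += 1

    aa_counts: Counter[str] = Counter()
    hinge_votes: dict[str, Counter] = {}
    for seq, n in seq_counts.items():
        trim = trim_and_classify(seq, params)
        if trim.seq is None:
            trim_rc = trim_and_classify(revcomp(seq), params)
            if trim_rc.seq is not None:
                trim = trim_rc
        if trim.seq is None:
            att[trim.reason] += n
            continue
        aa, reason = translate_frame0(trim.seq, params.min_aa_len)
        if aa is None:
            att[reason] += n
            continue
        aa_counts[aa] += n
        hinge_votes.setdefault(aa, Counter())[trim.hinge] += n
    att["accepted"] = sum(aa_counts.values())
    hinge = {aa: votes.most_common(1)[0][0] for aa, votes in hinge_votes.items()}
    return ProcessedLibrary(dict(aa_counts), hinge, dict(att))


_HINGE_TAG = {"short_IgG2": "IgG2", "long_IgG3": "IgG3"}


def write_accepted_fasta(lib: ProcessedLibrary, path) -> None:
    """FASTA of accepted amino-acid clonotypes with count and hinge tags."""
    items = sorted(lib.aa_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        for i, (aa, n) in enumerate(items, 1):
            tag = _HINGE_TAG.get(lib.hinge.get(aa, ""), "NA")
            fh.write(f">seq{i};count={n}|hinge={tag}\n{aa}\n")


def read_accepted_fasta(path) -> ProcessedLibrary:
    """Read back a :func:`write_accepted_fasta` file (counts from headers)."""
    from Bio import SeqIO

    inv_tag = {v: k for k, v in _HINGE_TAG.items()}
    aa_counts: dict[str, int] = {}
    hinge: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        head, _, tag = rec.description.partition("|hinge=")
        count = int(head.split("count=")[1])
        aa = str(rec.seq)
        aa_counts[aa] = aa_counts.get(aa, 0) + count
        hinge[aa] = inv_tag.get(tag.strip(), "unassigned")
    total = sum(aa_counts.values())
    att = {"input_pairs": total, "merged": total, "passed_filter": total, "accepted": total}
    return ProcessedLibrary(aa_counts, hinge, att)


def write_attrition_tsv(lib: ProcessedLibrary, path) -> None:
    total = max(lib.attrition.get("input_pairs", 0), 1)
    with open(path, "w") as fh:
        fh.write("stage\tcount\tfraction\n")
        for stage, n in lib.attrition.items():
            fh.write(f"{stage}\t{n}\t{n / total:.6f}\n")
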