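"""Synthetic VHH phage-display panning simulator.

Generates a ground-truthed nanobody (VHH) repertoire, runs iterative
whole-cell panning rounds in which binder clones are enriched according to
clone-specific selection weights, and emits error-bearing overlapping
paired-end FASTQ reads (2 x 300 bp MiSeq dialect) so the downstream analysis
stages can be exercised and validated against known truth.

The emulated amplicon has the layout

    fwd_primer | FR1'-CDR1-FR2-CDR2-FR3-CDR3-FR4-hinge tail | revcomp(rev_primer)

where the reverse primer is hinge-class specific (short IgG2 hinge vs long
IgG3 hinge), mirroring the two camelid heavy-chain isotypes amplified in a
VHH sequencing library.  Framework regions are fixed scaffolds carrying the
canonical CDR3 anchors (FR3 ends in ``...YYC``, FR4 starts with ``WGQG``);
CDR1/CDR2/CDR3 are drawn at random per clone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reads import FWD_PRIMER, REV_PRIMER_LONG, REV_PRIMER_SHORT, revcomp

__all__ = [
    "ConfigurationError",
    "GenerationError",
    "PanningConfig",
    "SyntheticClone",
    "generate_repertoire",
    "initial_frequencies",
    "simulate_panning",
    "emit_round_fastq",
    "emit_fastq",
    "truth_table",
]


class ConfigurationError(ValueError):
    """Raised when a :class:`PanningConfig` is internally inconsistent."""


class GenerationError(RuntimeError):
    """Raised when a clone cannot be turned into valid paired-end reads."""


# fixed framework scaffolds; FR3 ends with the conserved Cys anchor context
# and FR4 starts with the conserved Trp anchor so CDR3 extraction is
# exercised exactly as on real VHH domains
FR1B = "GGLVQAGGSLRLSCAAS"
FR2 = "MGWFRQAPGKEREFVA"
FR3 = "DSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYC"
FR4 = "WGQGTQVTVSS"
HINGE_TAILS = {"short_IgG2": "AHHSEDPS", "long_IgG3": "EPKTPKPQPQPQ"}
REV_PRIMERS = {"short_IgG2": REV_PRIMER_SHORT, "long_IgG3": REV_PRIMER_LONG}

# CDR alphabet excludes Cys and Trp so the anchor motifs stay unambiguous
_CDR_ALPHABET = "ADEFGHIKLMNPQRSTVY"

_STANDARD_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _STANDARD_CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _STANDARD_CODONS.setdefault(aa, []).append(codon)
        for codons in _STANDARD_CODONS.values():
            codons.sort()
    return _STANDARD_CODONS


DEFAULT_CELL_LINES = ("S1T", "HepG2", "SKBR3", "KYSE520")


@dataclass(frozen=True)
class PanningConfig:
    """Parameters of a simulated panning experiment.

    Defaults give a tractable but realistic screen: a 1,000-clone library,
    2% single-line binders plus 0.5% cross-reactive binders with lognormal
    per-round selection advantages, two selection rounds at 100,000 reads
    per round, and a 0.5% mean per-base sequencing error rate.
    """

    seed: int
    n_clones: int = 1000
    binder_fraction: float = 0.02
    cross_reactive_fraction: float = 0.005
    enrichment_lognormal_params: tuple[float, float] = (3.0, 0.5)
    rounds: int = 2
    reads_per_round: int = 100_000
    per_base_error_rate: float = 0.005
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    dirichlet_alpha: float = 0.1
    read_len: int = 300
    min_overlap: int = 20
    cdr3_len_range: tuple[int, int] = (5, 18)

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ConfigurationError("n_clones must be >= 1")
        for name in ("binder_fraction", "cross_reactive_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.binder_fraction + self.cross_reactive_fraction >= 1.0:
            raise ConfigurationError("binder fractions must sum to < 1")
        if self.rounds < 1:
            raise ConfigurationError("rounds must be >= 1")
        if self.reads_per_round < 1:
            raise ConfigurationError("reads_per_round must be >= 1")
        if self.per_base_error_rate < 0:
            raise ConfigurationError("per_base_error_rate must be >= 0")
        if not self.cell_lines:
            raise ConfigurationError("at least one cell line is required")
        if self.dirichlet_alpha <= 0:
            raise ConfigurationError("dirichlet_alpha must be > 0")


@dataclass(frozen=True)
class SyntheticClone:
    """One ground-truth VHH clone of the simulated library."""

    clone_id: str
    aa_seq: str
    nt_seq: str
    hinge: str  # "short_IgG2" | "long_IgG3"
    binding_weight: Mapping[str, float]
    true_cdr3: str


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _stream_key(label: str) -> int:
    return zlib.crc32(label.encode())


def generate_repertoire(config: PanningConfig) -> list[SyntheticClone]:
    """Generate the ground-truth clone set for a panning simulation.

    Exactly ``round(n_clones * binder_fraction)`` clones carry a selection
    weight > 1 for exactly one cell line (allocated round-robin over the
    configured lines) and ``round(n_clones * cross_reactive_fraction)``
    carry weights > 1 for two or three lines; all other weights are 1
    (neutral).  Weights are drawn from the configured lognormal.
    Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed, 1)
    codons = _codon_table()
    mu, sigma = config.enrichment_lognormal_params
    n = config.n_clones
    n_bind = int(round(n * config.binder_fraction))
    n_cross = int(round(n * config.cross_reactive_fraction))
    lines = config.cell_lines
    lo, hi = config.cdr3_len_range

    clones: list[SyntheticClone] = []
    seen_aa: set[str] = set()
    width = len(str(n - 1))
    for i in range(n):
        hinge = "short_IgG2" if rng.random() < 0.5 else "long_IgG3"
        cdr1 = "".join(rng.choice(list(_CDR_ALPHABET), size=8))
        cdr2 = "".join(rng.choice(list(_CDR_ALPHABET), size=8))
        while True:
            k = int(rng.integers(lo, hi + 1))
            cdr3 = "".join(rng.choice(list(_CDR_ALPHABET), size=k))
            aa = FR1B + cdr1 + FR2 + cdr2 + FR3 + cdr3 + FR4 + HINGE_TAILS[hinge]
            if aa not in seen_aa:
                break
        seen_aa.add(aa)

        weights = {line: 1.0 for line in lines}
        if i < n_bind:
            target = lines[i % len(lines)]
            weights[target] = float(rng.lognormal(mu, sigma))
        elif i < n_bind + n_cross:
            k_lines = int(rng.integers(2, min(3, len(lines)) + 1))
            chosen = rng.choice(len(lines), size=k_lines, replace=False)
            for j in sorted(chosen):
                weights[lines[j]] = float(rng.lognormal(mu, sigma))

        nt = FWD_PRIMER
        nt += "".join(codons[aa_char][rng.integers(len(codons[aa_char]))] for aa_char in aa)
        nt += revcomp(REV_PRIMERS[hinge])
        clones.append(
            SyntheticClone(
                clone_id=f"clone_{i:0{width}d}",
                aa_seq=aa,
                nt_seq=nt,
                hinge=hinge,
                binding_weight=weights,
                true_cdr3=cdr3,
            )
        )
    return clones


def initial_frequencies(config: PanningConfig) -> np.ndarray:
    """Round-0 library composition, shared by every panning arm.

    A symmetric Dirichlet with small concentration produces the skewed
    clone-size spectrum of an immune library: a few dominant clones and a
    long tail of rare ones.
    """
    rng = _rng(config.seed, 2)
    return rng.dirichlet(np.full(config.n_clones, config.dirichlet_alpha))


def simulate_panning(
    repertoire: Sequence[SyntheticClone],
    cell_line: str,
    config: PanningConfig,
    p0: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate panning rounds against one target cell line.

    Returns a clone x round count table (columns ``round_0`` ...
    ``round_R``).  Round 0 is drawn once per config (identical across cell
    lines, as a single unselected library is split over the panning arms);
    each later round is a multinomial sample of ``reads_per_round`` draws
    with per-clone probability proportional to (previous-round frequency x
    binding weight for the target line).  ``p0`` overrides the Dirichlet
    round-0 composition (useful for controlled experiments).
    """
    if cell_line not in config.cell_lines:
        raise KeyError(f"unknown cell line {cell_line!r}; configured: {config.cell_lines}")
    n = len(repertoire)
    w = np.array([c.binding_weight[cell_line] for c in repertoire], dtype=float)
    if np.any(w < 0):
        raise ConfigurationError("binding weights must be >= 0")

    if p0 is None:
        p0 = initial_frequencies(config)
    elif len(p0) != n:
        raise ConfigurationError("p0 length must match the repertoire size")
    rng0 = _rng(config.seed, 3)
    counts = [rng0.multinomial(config.reads_per_round, p0)]
    rng = _rng(config.seed, 4, _stream_key(cell_line))
    for _ in range(config.rounds):
        freq = counts[-1] / counts[-1].sum()
        p = freq * w
        p /= p.sum()
        counts.append(rng.multinomial(config.reads_per_round, p))

    table = pd.DataFrame(
        np.column_stack(counts),
        index=[c.clone_id for c in repertoire],
        columns=[f"round_{r}" for r in range(config.rounds + 1)],
    )
    table.index.name = "clone_id"
    return table


# ---------------------------------------------------------------------------
# FASTQ emission with a quality-aware substitution error model
# ---------------------------------------------------------------------------

_BASE_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i
_IDX_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _cycle_quality_profile(read_len: int, error_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle Phred qualities and error probabilities.

    Emulates Illumina-style cycle-dependent degradation: quality holds a
    high plateau over most of the read and falls off steeply in the last
    ~50 cycles (``~ 0.03 + 12.6 x^12`` in relative cycle position ``x``),
    rescaled so the mean per-base error over the read equals ``error_rate``.
    With overlapping 2 x 300 mates this places most errors in each mate's
    3' tail, where the partner's accurate 5' head covers the same amplicon
    position, so the merge consensus can correct them — the geometry
    long-amplicon paired-end protocols rely on.  Substitutions are injected
    at exactly the rate each emitted quality implies, so Phred scores are
    calibrated and expected-error filtering is informative.
    """
    if error_rate <= 0:
        return np.full(read_len, 40, dtype=np.uint8), np.zeros(read_len)
    x = (np.arange(read_len) + 0.5) / read_len
    shape = 0.03 + 12.6 * x**12
    e = np.minimum(error_rate * shape / shape.mean(), 0.75)
    q = np.clip(np.round(-10 * np.log10(e)), 2, 41).astype(np.uint8)
    return q, 10.0 ** (-q.astype(float) / 10.0)


def _simulate_reads(
    template: str, count: int, error_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised read simulation: returns (bases, quality) uint8 matrices."""
    L = len(template)
    tpl = _BASE_IDX[np.frombuffer(template.encode(), dtype=np.uint8)]
    bases = np.tile(tpl, (count, 1))

    q, perr = _cycle_quality_profile(L, error_rate)
    qual = np.tile(q, (count, 1))
    if error_rate > 0:
        err = rng.random((count, L)) < perr[None, :]
        idx = np.nonzero(err)
        if idx[0].size:
            shift = rng.integers(1, 4, size=idx[0].size).astype(np.uint8)
            bases[idx] = (bases[idx] + shift) % 4
    return _IDX_BASE[bases], qual + 33


def emit_round_fastq(
    counts: Mapping[str, int],
    repertoire: Sequence[SyntheticClone],
    config: PanningConfig,
    r1_path,
    r2_path,
    rng: np.random.Generator,
    read_prefix: str = "read",
) -> None:
    """Write one round's R1/R2 FASTQ pair (Sanger offset-33 qualities).

    R1 is the 5' ``read_len`` of each amplicon and R2 the reverse complement
    of its 3' ``read_len``, so mates overlap in the middle.  Per-clone read
    counts match ``counts`` exactly.  An empty table yields two valid empty
    files.
    """
    by_id = {c.clone_id: c for c in repertoire}
    L_read = config.read_len
    serial = 0
    r1_chunks: list[bytes] = []
    r2_chunks: list[bytes] = []
    for clone_id in counts:
        c = int(counts[clone_id])
        if c <= 0:
            continue
        clone = by_id[clone_id]
        L = len(clone.nt_seq)
        if L > 2 * L_read - config.min_overlap:
            raise GenerationError(
                f"amplicon of {clone.clone_id} ({L} nt) too long for "
                f"2x{L_read} reads with >= {config.min_overlap} nt overlap"
            )
        r1_tpl = clone.nt_seq[:L_read]
        r2_tpl = revcomp(clone.nt_seq[-L_read:])
        b1, q1 = _simulate_reads(r1_tpl, c, config.per_base_error_rate, rng)
        b2, q2 = _simulate_reads(r2_tpl, c, config.per_base_error_rate, rng)
        for k in range(c):
            rid = f"@{read_prefix}:{serial}".encode()
            serial += 1
            r1_chunks.append(b"\n".join([rid, b1[k].tobytes(), b"+", q1[k].tobytes()]))
            r2_chunks.append(b"\n".join([rid, b2[k].tobytes(), b"+", q2[k].tobytes()]))
    with open(r1_path, "wb") as fh:
        fh.write(b"\n".join(r1_chunks) + (b"\n" if r1_chunks else b""))
    with open(r2_path, "wb") as fh:
        fh.write(b"\n".join(r2_chunks) + (b"\n" if r2_chunks else b""))


def emit_fastq(
    count_table: pd.DataFrame,
    repertoire: Sequence[SyntheticClone],
    config: PanningConfig,
    out_dir,
    prefix: str,
    rounds: Sequence[int] | None = None,
) -> dict[int, tuple[str, str]]:
    """Emit R1/R2 FASTQ pairs for the requested rounds of a count table.

    Returns ``{round: (r1_path, r2_path)}``.  Byte-identical output for
    identical (config, seed, prefix).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    if rounds is None:
        rounds = [int(col.split("_")[1]) for col in count_table.columns]
    out: dict[int, tuple[str, str]] = {}
    for r in rounds:
        rng = _rng(config.seed, 5, _stream_key(prefix), r)
        r1 = os.path.join(out_dir, f"{prefix}_round{r}_R1.fastq")
        r2 = os.path.join(out_dir, f"{prefix}_round{r}_R2.fastq")
        emit_round_fastq(
            count_table[f"round_{r}"].to_dict(),
            repertoire,
            config,
            r1,
            r2,
            rng,
            read_prefix=f"{prefix}.r{r}",
        )
        out[r] = (r1, r2)
    return out


def truth_table(
    repertoire: Sequence[SyntheticClone],
    count_tables: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Ground-truth table: clone identity, CDR3, hinge, weights, counts."""
    rows = []
    for c in repertoire:
        row: dict[str, object] = {
            "clone_id": c.clone_id,
            "aa_seq": c.aa_seq,
            "cdr3": c.true_cdr3,
            "hinge": c.hinge,
        }
        for line, w in c.binding_weight.items():
            row[f"weight_{line}"] = w
        rows.append(row)
    df = pd.DataFrame(rows).set_index("clone_id")
    if count_tables:
        for lib, table in count_tables.items():
            for col in table.columns:
                df[f"{lib}_{col}"] = table[col]
    return df
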