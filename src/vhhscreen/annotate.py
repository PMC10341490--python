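"""CDR3 localisation and identity scoring for VHH amino-acid sequences.

CDR3 — the third complementarity-determining region, the dominant
antigen-binding loop — is the unit of identity used for cross-library
grouping of clones.  Boundaries follow an IMGT-like convention: the loop
between the conserved FR3 cysteine (Cys104 equivalent) and the conserved
FR4 tryptophan (Trp118 equivalent), anchors excluded by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

__all__ = ["VHHAnnotation", "extract_cdr3", "cdr3_identity", "alignment_stats"]

_CYS_MOTIF = re.compile(r"(?=[YFW][YFAVLI]C)")
_TRP_MOTIF = re.compile(r"WG.G")

CDR3_MIN_LEN = 3
CDR3_MAX_LEN = 40
_CYS_SEARCH_LIMIT = 110  # the conserved cysteine sits in the first ~110 residues


@dataclass(frozen=True)
class VHHAnnotation:
    """CDR3 annotation of one VHH amino-acid sequence.

    ``status`` is ``ok`` when both anchors were found in order and the CDR3
    length is plausible; failures are statuses (not exceptions) so that
    attrition stays countable.
    """

    aa_seq: str
    cdr3: str
    cys_anchor_pos: int  # 0-based index of the conserved FR3 Cys (-1 if absent)
    trp_anchor_pos: int  # 0-based index of the conserved FR4 Trp (-1 if absent)
    status: str  # ok | no_cys_anchor | no_trp_anchor | anchors_crossed | bad_cdr3_length


def extract_cdr3(aa_seq: str, include_anchors: bool = False) -> VHHAnnotation:
    """Locate CDR3 between its conserved anchor residues.

    The cysteine anchor is the C of the last ``[YFW][YFAVLI]C`` motif match
    whose C lies in the first 110 residues (falling back to the last C
    before position 110); the tryptophan anchor is the W of the first
    ``WG.G`` motif at or after cys+4 (falling back to the first W after the
    cysteine).  CDR3 spans the residues strictly between the anchors unless
    ``include_anchors`` is set.
    """
    window = aa_seq[: _CYS_SEARCH_LIMIT + 2]
    cys = -1
    for m in _CYS_MOTIF.finditer(window):
        if m.start() + 2 < _CYS_SEARCH_LIMIT:
            cys = m.start() + 2
    if cys == -1:
        cys = aa_seq.rfind("C", 0, _CYS_SEARCH_LIMIT)
    if cys == -1:
        return VHHAnnotation(aa_seq, "", -1, -1, "no_cys_anchor")

    m = _TRP_MOTIF.search(aa_seq, cys + 4)
    trp = m.start() if m else aa_seq.find("W", cys + 1)
    if trp == -1:
        return VHHAnnotation(aa_seq, "", cys, -1, "no_trp_anchor")
    if trp <= cys:
        return VHHAnnotation(aa_seq, "", cys, trp, "anchors_crossed")

    cdr3 = aa_seq[cys : trp + 1] if include_anchors else aa_seq[cys + 1 : trp]
    core_len = trp - cys - 1
    if not CDR3_MIN_LEN <= core_len <= CDR3_MAX_LEN:
        return VHHAnnotation(aa_seq, cdr3, cys, trp, "bad_cdr3_length")
    return VHHAnnotation(aa_seq, cdr3, cys, trp, "ok")


def alignment_stats(a: str, b: str) -> tuple[int, int, list[tuple[int, str]]]:
    """Global unit-cost alignment of two sequences via edlib.

    Returns ``(matches, columns, ops)`` where ``ops`` is the parsed extended
    cigar (count, op) with op in ``=XID``.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    ops = [(int(n), op) for n, op in re.findall(r"(\d+)([=XID])", res["cigar"])]
    matches = sum(n for n, op in ops if op == "=")
    columns = sum(n for n, _op in ops)
    return matches, columns, ops


def cdr3_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global alignment of two CDR3s.

    Match scores 1, mismatches and gap columns 0.  The alignment used is the
    minimal-column optimal one (exactly ``||a|-|b||`` gap columns plus
    substitutions), so identity equals ``(L - edits) / L`` with
    ``L = max(|a|, |b|)``; this makes the measure symmetric and
    ``identity(x, x) == 1``.
    """
    if not a or not b:
        raise ValueError("cdr3_identity requires non-empty sequences")
    edits = edlib.align(a, b, mode="NW")["editDistance"]
    length = max(len(a), len(b))
    return (length - edits) / length
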