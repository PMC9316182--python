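"""InDel discovery between two genome sequences and marker-candidate design.

Two assembled sequences of the same chromosome region are globally
aligned; maximal runs of inserted or deleted bases at least
``min_len`` long (default 5 bp) become InDel calls, and each call is
turned into a PCR marker candidate by extracting ``flank`` bp
(default 500) of reference sequence on either side.  The expected
product-size difference between the two templates equals the indel
length, which is what makes the marker scorable on a gel.

Alignment is delegated to edlib (global Needleman-Wunsch with a
doubling band); the edit script is re-expressed relative to the
reference: 'I' bases are present only in the alternate, 'D' bases only
in the reference.  Calls are left-aligned within repeat runs.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import edlib

_NUCLEOTIDES = set("ACGTN")


class IndelKind(enum.Enum):
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class IndelCall:
    """One insertion/deletion event, anchored on the reference.

    ``ref_pos`` is the 1-based position of the last reference base
    before the event (0 when the event is at the very start).
    """

    ref_name: str
    alt_name: str
    ref_pos: int
    kind: IndelKind
    sequence: str  # the inserted or deleted bases

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MarkerCandidate:
    name: str
    indel: IndelCall
    left_flank: str
    right_flank: str

    @property
    def expected_size_difference(self) -> int:
        return self.indel.length


EditScript = list[tuple[str, int]]  # ops: '=' match, 'X' substitution, 'I', 'D'


def _check_nucleotides(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _NUCLEOTIDES
    if bad:
        raise ValueError(f"{label}: non-nucleotide characters {sorted(bad)}")
    return seq


def align_pair(ref: str, alt: str) -> EditScript:
    """Minimal-edit global alignment of ``alt`` against ``ref``.

    Returns an edit script of (op, length) runs that reconstructs
    ``alt`` from ``ref``: '=' and 'X' consume both sequences, 'I'
    consumes the alternate only, 'D' the reference only.
    """
    ref = _check_nucleotides(ref, "reference")
    alt = _check_nucleotides(alt, "alternate")
    if not ref or not alt:
        raise ValueError("both sequences must be non-empty")
    result = edlib.align(ref, alt, mode="NW", task="path")
    script: EditScript = []
    num = ""
    for ch in result["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        # edlib's cigar is relative to the query (here: ref), so its 'D'
        # consumes the alternate only and its 'I' the reference only
        op = {"=": "=", "X": "X", "D": "I", "I": "D"}[ch]
        script.append((op, int(num)))
        num = ""
    return script


def apply_script(ref: str, script: EditScript, alt: str) -> str:
    """Reconstruct the alternate from the reference and the edit script."""
    out = []
    i = j = 0
    for op, length in script:
        if op == "=":
            out.append(ref[i : i + length])
            i += length
            j += length
        elif op == "X":
            out.append(alt[j : j + length])
            i += length
            j += length
        elif op == "I":
            out.append(alt[j : j + length])
            j += length
        else:  # 'D'
            i += length
    return "".join(out)


def _left_align(ref: str, pos: int, seq: str) -> tuple[int, str]:
    """Shift an indel left through identical context (VCF-style)."""
    while pos >= 1 and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


@dataclass(frozen=True)
class _Segment:
    op: str
    length: int
    ref_start: int  # 0-based
    alt_start: int


def _segments(script: EditScript) -> list[_Segment]:
    segs = []
    i = j = 0
    for op, length in script:
        segs.append(_Segment(op, length, i, j))
        if op in ("=", "X"):
            i += length
            j += length
        elif op == "I":
            j += length
        else:
            i += length
    return segs


def _clusters(segs: list[_Segment], merge_window: int) -> list[list[_Segment]]:
    """Group non-match segments separated by < merge_window matched bases.

    A minimal-edit alignment fragments one long biological indel into
    several gaps whenever bases inside the event coincidentally match
    nearby sequence (saving one edit per chance match); clustering
    re-joins those fragments for affine realignment.
    """
    clusters: list[list[_Segment]] = []
    current: list[_Segment] = []
    for seg in segs:
        if seg.op == "=" and seg.length >= merge_window:
            if current:
                clusters.append(current)
                current = []
        elif seg.op == "=":
            if current:
                current.append(seg)
        else:
            current.append(seg)
    if current:
        clusters.append(current)
    # drop trailing internal matches
    for cluster in clusters:
        while cluster and cluster[-1].op == "=":
            cluster.pop()
    return [c for c in clusters if any(s.op in ("I", "D") for s in c)]


def _affine_gaps(
    a: str, b: str, ref_offset: int
) -> list[tuple[int, IndelKind, str]]:
    """Gap runs of an affine-gap global alignment of b against a.

    Returns (0-based ref anchor, kind, sequence) triples.  The heavy
    gap-open penalty keeps each biological event in one contiguous gap.
    """
    from Bio import Align

    if not a:
        return [(ref_offset, IndelKind.INSERTION, b)] if b else []
    if not b:
        return [(ref_offset, IndelKind.DELETION, a)]
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-2,
        open_gap_score=-6,
        extend_gap_score=-0.1,
    )
    alignment = aligner.align(a, b)[0]
    blocks_a, blocks_b = alignment.aligned
    gaps = []
    prev_a = prev_b = 0
    boundaries = list(zip(blocks_a, blocks_b)) + [((len(a), len(a)), (len(b), len(b)))]
    for (a_start, a_end), (b_start, b_end) in boundaries:
        if a_start > prev_a:
            gaps.append((ref_offset + prev_a, IndelKind.DELETION, a[prev_a:a_start]))
        if b_start > prev_b:
            gaps.append((ref_offset + prev_a, IndelKind.INSERTION, b[prev_b:b_start]))
        prev_a, prev_b = a_end, b_end
    return gaps


def call_indels(
    ref: str,
    alt: str,
    script: EditScript | None = None,
    min_len: int = 5,
    ref_name: str = "ref",
    alt_name: str = "alt",
    merge_window: int = 20,
    context: int = 30,
) -> list[IndelCall]:
    """Extract indels of at least ``min_len`` bp from an alignment.

    Gap runs closer than ``merge_window`` matched bases are treated as
    fragments of one event and realigned locally with affine gap costs
    (plus up to ``context`` bp of flanking matches), so a single
    biological insertion or deletion yields a single call.  Calls are
    left-aligned within repeat runs; calls shorter than ``min_len`` are
    discarded.
    """
    ref = ref.upper()
    alt = alt.upper()
    if script is None:
        script = align_pair(ref, alt)
    segs = _segments(script)
    calls = []
    for cluster in _clusters(segs, merge_window):
        first, last = cluster[0], cluster[-1]
        ref_end = last.ref_start + (last.length if last.op != "I" else 0)
        alt_end = last.alt_start + (last.length if last.op != "D" else 0)
        if len(cluster) == 1 and first.op in ("I", "D"):
            # a clean, isolated gap: no realignment needed
            seq = (
                alt[first.alt_start : alt_end]
                if first.op == "I"
                else ref[first.ref_start : ref_end]
            )
            kind = IndelKind.INSERTION if first.op == "I" else IndelKind.DELETION
            gaps = [(first.ref_start, kind, seq)]
        else:
            pad_l = min(context, first.ref_start, first.alt_start)
            pad_r = min(context, len(ref) - ref_end, len(alt) - alt_end)
            a = ref[first.ref_start - pad_l : ref_end + pad_r]
            b = alt[first.alt_start - pad_l : alt_end + pad_r]
            gaps = _affine_gaps(a, b, first.ref_start - pad_l)
        for pos0, kind, seq in gaps:
            pos, seq = _left_align(ref, pos0, seq)
            if len(seq) >= min_len:
                calls.append(IndelCall(ref_name, alt_name, pos, kind, seq))
    return sorted(calls, key=lambda c: (c.ref_pos, c.kind.value))


def design_candidates(
    ref: str,
    calls: list[IndelCall],
    flank: int = 500,
    chromosome: str = "06",
) -> list[MarkerCandidate]:
    """Extract ``flank``-bp reference flanks around each call.

    Calls without a full flank on both sides are skipped with a
    warning.  Candidates are named ``P<chrom>gInDel-<ordinal>``.
    """
    ref = ref.upper()
    chrom = chromosome.zfill(2)
    candidates = []
    ordinal = 0
    for call in calls:
        left_start = call.ref_pos - flank  # 0-based slice start
        if call.kind is IndelKind.DELETION:
            right_begin = call.ref_pos + call.length
        else:
            right_begin = call.ref_pos
        if left_start < 0 or right_begin + flank > len(ref):
            warnings.warn(
                f"indel at ref position {call.ref_pos} is within {flank} bp of a "
                "sequence end; skipped",
                stacklevel=2,
            )
            continue
        ordinal += 1
        candidates.append(
            MarkerCandidate(
                name=f"P{chrom}gInDel-{ordinal}",
                indel=call,
                left_flank=ref[left_start : call.ref_pos],
                right_flank=ref[right_begin : right_begin + flank],
            )
        )
    return candidates
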