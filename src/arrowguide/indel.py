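"""Amplicon indel quantification with a PAM-proximal window rule.

Reads are globally aligned to the amplicon reference with affine gap
penalties; a read counts as edited when it carries an insertion or deletion
that intersects a small window around the canonical SpCas9 blunt-cut
position, 3 bp 5' of the PAM.  Substitutions never count: the rule targets
the indel signature of non-homologous end joining, not sequencing error.

Gaps are left-normalized before calling so that a homopolymer indel always
reports its leftmost placement, independent of aligner tie-breaking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import Align, SeqIO

from scipy import stats as _scipy_stats

from .sequence_core import ProtospacerSite, SequenceLengthError, clean_seq

__all__ = [
    "AlignParams",
    "AmpliconRef",
    "IndelEvent",
    "ReadAlignment",
    "EditingSummary",
    "align_read",
    "call_window_edit",
    "indel_frequency",
    "discrimination_summary",
    "classify_reporter_frame",
    "replicate_ttest",
    "read_fastq",
]


@dataclass(frozen=True)
class AlignParams:
    """Global affine-gap alignment scores and read filters."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -10.0
    gap_extend: float = -1.0
    min_read_length: int = 50
    min_identity: float = 0.60  # matches / alignment columns; below -> unaligned


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class AmpliconRef:
    """An amplicon reference with its protospacer site and cut window.

    ``cut_offset`` is the 0-based reference coordinate of the blunt cut
    (3 bp 5' of the PAM on the protospacer strand); an indel is called
    "edited" when it intersects ``[cut_offset - window_halfwidth,
    cut_offset + window_halfwidth]``.
    """

    sequence: str
    site: ProtospacerSite
    cut_offset: int = -1  # -1: derive from the site
    window_halfwidth: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_seq(self.sequence, allow_empty=False, name="amplicon"))
        if self.cut_offset < 0:
            object.__setattr__(self, "cut_offset", self.site.cut_offset)
        if not 0 < self.cut_offset < len(self.sequence):
            raise ValueError(f"cut_offset {self.cut_offset} outside amplicon [0, {len(self.sequence)}]")
        if self.window_halfwidth < 0:
            raise ValueError("window_halfwidth must be >= 0")
        if not (self.window_start >= 0 and self.window_end <= len(self.sequence)):
            raise ValueError("cut window extends beyond the amplicon")

    @property
    def window_start(self) -> int:
        return self.cut_offset - self.window_halfwidth

    @property
    def window_end(self) -> int:  # inclusive
        return self.cut_offset + self.window_halfwidth


@dataclass(frozen=True)
class IndelEvent:
    """A single insertion or deletion relative to the reference.

    ``ref_pos`` is the left-normalized (leftmost equivalent) placement:
    insertions are anchored before reference coordinate ``ref_pos``,
    deletions remove ``[ref_pos, ref_pos + length)``.  ``seq`` holds the
    event's bases (inserted read bases, or deleted reference bases) in the
    normalized placement; it allows equivalent right-shifted placements
    through repeated sequence to be enumerated.
    """

    kind: str  # "insertion" | "deletion"
    ref_pos: int
    length: int
    seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in {"insertion", "deletion"}:
            raise ValueError(f"kind must be insertion/deletion, got {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.seq and len(self.seq) != self.length:
            raise ValueError("seq length must equal the event length")


@dataclass(frozen=True)
class ReadAlignment:
    """A read-to-reference alignment as runs of (op, length).

    Ops: ``=`` match, ``X`` substitution, ``I`` insertion (in read),
    ``D`` deletion (from reference).  ``aligned`` is False for reads below
    the length or identity floor; such reads carry no ops.
    """

    ops: tuple[tuple[str, int], ...]
    aligned: bool
    identity: float
    events: tuple[IndelEvent, ...]


def _left_normalize(events: list[tuple[str, int, str]], ref: str) -> list[IndelEvent]:
    """Shift indels left through repeated sequence (VCF-style canonical form).

    ``events`` are (kind, ref_pos, seq) with seq the deleted reference bases
    or the inserted read bases.
    """
    out = []
    for kind, pos, seq in events:
        s = seq
        while pos > 0 and s and ref[pos - 1] == s[-1]:
            s = ref[pos - 1] + s[:-1]
            pos -= 1
        out.append(IndelEvent(kind, pos, len(seq), s))
    return out


def _leftmost_placement(ev: IndelEvent, ref: str) -> int:
    """Leftmost ``ref_pos`` equivalent to the event's placement."""
    pos, s = ev.ref_pos, ev.seq or (ref[ev.ref_pos : ev.ref_pos + ev.length]
                                    if ev.kind == "deletion" else "")
    while pos > 0 and s and ref[pos - 1] == s[-1]:
        s = ref[pos - 1] + s[:-1]
        pos -= 1
    return pos


def _rightmost_placement(ev: IndelEvent, ref: str) -> int:
    """Rightmost ``ref_pos`` equivalent to the event's canonical placement."""
    pos, s = ev.ref_pos, ev.seq or (ref[ev.ref_pos : ev.ref_pos + ev.length]
                                    if ev.kind == "deletion" else "")
    if not s:
        return pos
    if ev.kind == "deletion":
        while pos + ev.length < len(ref) and ref[pos] == ref[pos + ev.length]:
            pos += 1
    else:
        while pos < len(ref) and s[0] == ref[pos]:
            s = s[1:] + ref[pos]
            pos += 1
    return pos


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def align_read(read: str, ref: AmpliconRef, params: AlignParams = DEFAULT_PARAMS) -> ReadAlignment:
    """Globally align one read to the amplicon and extract indel events.

    Reads shorter than ``params.min_read_length`` or whose best alignment has
    identity below ``params.min_identity`` are returned unaligned (they are
    excluded from editing denominators rather than miscounted).
    """
    read = clean_seq(read, name="read")
    if len(read) < params.min_read_length:
        return ReadAlignment((), False, 0.0, ())

    aligner = _make_aligner(params)
    aln = aligner.align(ref.sequence, read)[0]
    ref_aln, read_aln = str(aln[0]), str(aln[1])

    ops: list[tuple[str, int]] = []
    raw_events: list[tuple[str, int, str]] = []
    matches = 0
    ref_pos = 0
    i = 0
    ncols = len(ref_aln)
    while i < ncols:
        r, q = ref_aln[i], read_aln[i]
        if r == "-":  # insertion in read
            j = i
            while j < ncols and ref_aln[j] == "-":
                j += 1
            raw_events.append(("insertion", ref_pos, read_aln[i:j]))
            ops.append(("I", j - i))
            i = j
        elif q == "-":  # deletion from reference
            j = i
            while j < ncols and read_aln[j] == "-":
                j += 1
            raw_events.append(("deletion", ref_pos, ref_aln[i:j]))
            ops.append(("D", j - i))
            ref_pos += j - i
            i = j
        else:
            op = "=" if r == q else "X"
            if r == q:
                matches += 1
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + 1)
            else:
                ops.append((op, 1))
            ref_pos += 1
            i += 1

    identity = matches / ncols if ncols else 0.0
    if identity < params.min_identity:
        return ReadAlignment((), False, identity, ())
    events = tuple(_left_normalize(raw_events, ref.sequence))
    return ReadAlignment(tuple(ops), True, identity, events)


def call_window_edit(alignment: ReadAlignment, ref: AmpliconRef) -> tuple[bool, list[IndelEvent]]:
    """Decide whether an aligned read is edited under the cut-window rule.

    Edited iff at least one indel intersects the closed window
    ``[cut_offset - w, cut_offset + w]``: a deletion by interval overlap, an
    insertion by its anchor point.  An indel whose placement is ambiguous in
    repeated sequence counts if *any* equivalent placement, from the
    left-normalized one through the rightmost shift, intersects the window.
    Substitutions never count.  Returns (edited, events-in-window).
    """
    if not alignment.aligned:
        return False, []
    lo, hi = ref.window_start, ref.window_end
    in_window = []
    for ev in alignment.events:
        left = _leftmost_placement(ev, ref.sequence)
        right = _rightmost_placement(ev, ref.sequence)
        if ev.kind == "insertion":
            hit = left <= hi and right >= lo
        else:
            hit = left <= hi and right + ev.length - 1 >= lo
        if hit:
            in_window.append(ev)
    return bool(in_window), in_window


@dataclass
class EditingSummary:
    """Per-sample editing outcome within the PAM-proximal window."""

    n_reads_total: int
    n_reads_aligned: int
    n_reads_edited: int
    indel_frequency: float
    event_histogram: dict[str, int] = field(default_factory=dict)  # e.g. {"D3": 12, "I1": 4}
    window_halfwidth: int = 3

    def to_dict(self) -> dict:
        return {
            "n_reads_total": self.n_reads_total,
            "n_reads_aligned": self.n_reads_aligned,
            "n_reads_edited": self.n_reads_edited,
            "indel_frequency": self.indel_frequency,
            "event_histogram": dict(self.event_histogram),
            "window_halfwidth": self.window_halfwidth,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def read_fastq(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Parse FASTQ into [(read_id, sequence)]; duplicate IDs are rejected."""
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    parser = SeqIO.parse(str(path), "fastq")
    idx = 0
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            break
        except ValueError as e:
            raise ValueError(f"malformed FASTQ record at index {idx}: {e}") from e
        if rec.id in seen:
            raise ValueError(f"duplicate read ID {rec.id!r} at record index {idx}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq)))
        idx += 1
    return out


def indel_frequency(
    reads: Union[str, Path, Sequence[tuple[str, str]]],
    ref: AmpliconRef,
    params: AlignParams = DEFAULT_PARAMS,
) -> EditingSummary:
    """Editing frequency over aligned reads of one amplicon sample.

    ``reads`` is a FASTQ path or a sequence of (read_id, sequence) pairs.
    Frequency = edited / aligned; reads failing the length or identity floor
    are counted only in ``n_reads_total``.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    else:
        ids = [r[0] for r in reads]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate read IDs")
    if len(reads) == 0:
        raise ValueError("no reads supplied")

    n_aligned = 0
    n_edited = 0
    hist: dict[str, int] = {}
    for _, seq in reads:
        aln = align_read(seq, ref, params)
        if not aln.aligned:
            continue
        n_aligned += 1
        edited, events = call_window_edit(aln, ref)
        if edited:
            n_edited += 1
            for ev in events:
                key = ("I" if ev.kind == "insertion" else "D") + str(ev.length)
                hist[key] = hist.get(key, 0) + 1
    freq = n_edited / n_aligned if n_aligned else 0.0
    return EditingSummary(len(reads), n_aligned, n_edited, freq, hist, ref.window_halfwidth)


def discrimination_summary(mut: Union[EditingSummary, float], wt: Union[EditingSummary, float]) -> dict:
    """Allele discrimination of one guide: mutant vs wild-type editing rates.

    Accepts :class:`EditingSummary` objects or bare rates.  The ratio is
    ``inf`` when the wild-type rate is zero.
    """
    mut_rate = mut.indel_frequency if isinstance(mut, EditingSummary) else float(mut)
    wt_rate = wt.indel_frequency if isinstance(wt, EditingSummary) else float(wt)
    ratio = math.inf if wt_rate == 0 else mut_rate / wt_rate
    return {
        "mut_rate": mut_rate,
        "wt_rate": wt_rate,
        "ratio": ratio,
        "difference": mut_rate - wt_rate,
    }


def classify_reporter_frame(net_indel_length: int, frame_offset: int = 1) -> str:
    """Classify a net indel length against a frameshift reporter construct.

    The reporter places the downstream fluorophore ``frame_offset`` bases out
    of frame (1 or 2): an edit restores expression iff
    ``(net_indel_length + frame_offset) % 3 == 0``.  Net length is positive
    for insertions, negative for deletions.
    """
    if frame_offset not in (1, 2):
        raise ValueError("frame_offset must be 1 or 2")
    return "in_frame" if (net_indel_length + frame_offset) % 3 == 0 else "out_of_frame"


def replicate_ttest(rates_a: Sequence[float], rates_b: Sequence[float]) -> tuple[float, float]:
    """Unpaired two-sample t-test between replicate editing frequencies.

    Convenience wrapper for reports; returns (t statistic, p value).
    """
    res = _scipy_stats.ttest_ind(list(rates_a), list(rates_b))
    return float(res.statistic), float(res.pvalue)
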