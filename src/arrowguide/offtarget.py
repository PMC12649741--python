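"""Off-target site enumeration under mismatch and single-bulge budgets.

A candidate off-target is an NGG-adjacent window on either genomic strand
that aligns to the guide in one of three classes:

* ``none`` — 20-nt site, substitutions only, up to ``max_mm_no_bulge``;
* ``DNA`` bulge — the site carries 1-5 extra unpaired bases (gap in the
  guide), site length 20 + bulge size;
* ``RNA`` bulge — the guide carries 1-5 unpaired bases (gap in the DNA),
  site length 20 - bulge size;

bulged classes allow up to ``max_mm_with_bulge`` substitutions.  Exactly one
contiguous bulge per hit, the accepted convention for bulged off-target
search.  The scan is PAM-anchored (find NGG / CCN, extend): correct and
simple at desk-scale genome sizes, with no genome index.

Coordinates are 0-based half-open on the forward strand and cover the site
sequence only (the PAM is reported separately).  Positions are reported in
"bp from PAM" (PAM index) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .sequence_core import (
    ProtospacerSite,
    SequenceLengthError,
    clean_seq,
    hamming,
    read_fasta,
    revcomp,
)

__all__ = [
    "SearchBudget",
    "OffTargetHit",
    "find_offtargets",
    "compare_burden",
    "predict_t7e1_fragments",
    "cut_offset_from_pam_start",
    "hits_to_frame",
]

GUIDE_LEN = 20


@dataclass(frozen=True)
class SearchBudget:
    """Mismatch/bulge budget for the off-target scan.

    Defaults: up to 8 substitutions with no bulge, or up to 2 substitutions
    combined with a single 1-5 nt DNA or RNA bulge.  Bulges adjacent to the
    PAM (touching PAM index 1) are excluded by default; set
    ``allow_pam_adjacent_bulge`` to include them.
    """

    max_mm_no_bulge: int = 8
    max_mm_with_bulge: int = 2
    bulge_sizes: tuple[int, ...] = (1, 2, 3, 4, 5)
    bulge_kinds: tuple[str, ...] = ("DNA", "RNA")
    allow_pam_adjacent_bulge: bool = False

    def __post_init__(self) -> None:
        if self.max_mm_no_bulge < 0 or self.max_mm_with_bulge < 0:
            raise ValueError("mismatch budgets must be >= 0")
        if any(b < 1 for b in self.bulge_sizes):
            raise ValueError("bulge sizes must be >= 1")
        bad = set(self.bulge_kinds) - {"DNA", "RNA"}
        if bad:
            raise ValueError(f"unknown bulge kinds: {sorted(bad)}")


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic site matching a guide under some budget class.

    ``bulge_pam_index`` is the PAM-indexed alignment position of the
    PAM-proximal-most bulged element (None for bulge-free hits);
    ``mismatch_positions`` lists the mismatching guide positions in PAM-index
    coordinates.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    site_seq: str
    pam: str
    n_mismatches: int
    bulge_kind: str  # "none", "DNA", "RNA"
    bulge_size: int
    bulge_pam_index: int | None
    mismatch_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        expected = {
            "none": GUIDE_LEN,
            "DNA": GUIDE_LEN + self.bulge_size,
            "RNA": GUIDE_LEN - self.bulge_size,
        }[self.bulge_kind]
        if len(self.site_seq) != expected or self.end - self.start != expected:
            raise SequenceLengthError(
                f"{self.bulge_kind} hit with bulge {self.bulge_size} must span {expected} bp"
            )


def _mm_positions(a: str, b: str, pam_indices: Sequence[int]) -> list[int]:
    return [p for x, y, p in zip(a, b, pam_indices) if x != y or x == "N"]


def _align_none(guide: str, site: str) -> tuple[int, list[int]]:
    """Bulge-free alignment: per-position comparison, PAM-proximal end last."""
    n = len(guide)
    mis = _mm_positions(guide, site, [n - i for i in range(n)])
    return len(mis), mis


def _dna_bulge_alignments(guide: str, site: str, bulge: int, min_split: int):
    """All single-DNA-bulge alignments of a 20-nt guide to a (20+b)-nt site.

    The site's extra ``bulge`` bases sit between guide PAM positions
    ``split`` and ``split+1`` (``split`` guide bases on the PAM side of the
    bulge); ``split = 0`` puts the bulge between the PAM and the protospacer.
    Yields (n_mismatches, bulge_pam_index, mismatch_positions).
    """
    n = len(guide)
    for split in range(min_split, n):
        # PAM-proximal block: guide PAM positions 1..split
        prox = _mm_positions(guide[n - split :], site[len(site) - split :],
                             [split - i for i in range(split)]) if split else []
        dist = _mm_positions(guide[: n - split], site[: n - split],
                             [n - i for i in range(n - split)])
        yield len(prox) + len(dist), split + 1, sorted(prox + dist)


def _rna_bulge_alignments(guide: str, site: str, bulge: int, min_start: int):
    """All single-RNA-bulge alignments: ``bulge`` contiguous guide bases unpaired.

    The skipped guide bases occupy PAM positions start..start+bulge-1.
    Yields (n_mismatches, bulge_pam_index, mismatch_positions).
    """
    n = len(guide)
    for start in range(min_start, n - bulge + 2):
        # guide with PAM positions start..start+bulge-1 removed
        i0 = n - (start + bulge - 1) - 1  # 0-based 5'->3' index of most distal skipped base
        reduced = guide[:i0] + guide[i0 + bulge :]
        pam_idx = [p for p in range(n, 0, -1) if not start <= p <= start + bulge - 1]
        mis = _mm_positions(reduced, site, pam_idx)
        yield len(mis), start, mis


def _best_bulge_hit(guide: str, kind: str, candidates) -> tuple[int, int, list[int]] | None:
    """Pick (size, mm, bulge_pam_index, positions) minimizing
    (bulge_size, n_mismatches, PAM-proximity of the bulge)."""
    best = None
    for size, mm, bp, pos in candidates:
        key = (size, mm, -bp)
        if best is None or key < best[0]:
            best = (key, size, mm, bp, pos)
    if best is None:
        return None
    return best[1:]


def find_offtargets(
    guide: str,
    genome: Union[str, Path, Mapping[str, str]],
    budget: SearchBudget | None = None,
) -> list[OffTargetHit]:
    """Enumerate all candidate off-target sites for a guide in a genome.

    ``genome`` is a FASTA path or a {contig: sequence} mapping.  Every
    NGG-adjacent window on either strand that satisfies any budget class is
    reported exactly once per (PAM location, strand, bulge class); within a
    class the minimum-mismatch alignment is kept (smaller bulge first, then
    fewer mismatches, then the most PAM-distal bulge placement).  A perfect
    on-target site appears with ``n_mismatches == 0`` and no bulge.
    """
    guide = clean_seq(guide, allow_empty=False, name="guide")
    if len(guide) != GUIDE_LEN:
        raise SequenceLengthError(f"guide must be {GUIDE_LEN} nt, got {len(guide)}")
    if budget is None:
        budget = SearchBudget()
    if not isinstance(genome, Mapping):
        genome = read_fasta(genome)
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("genome is empty")

    min_dna_split = 0 if budget.allow_pam_adjacent_bulge else 1
    min_rna_start = 1 if budget.allow_pam_adjacent_bulge else 2

    hits: list[OffTargetHit] = []
    for contig_id, fwd in genome.items():
        fwd = clean_seq(fwd, name=f"contig {contig_id}")
        L = len(fwd)
        for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
            # PAM occupies seq[q:q+3]; protospacer-side windows end at q
            for q in range(2, L - 2):
                if seq[q + 1] != "G" or seq[q + 2] != "G":
                    continue
                pam = seq[q : q + 3]

                def emit(a: int, site: str, mm: int, kind: str, size: int,
                         bp: int | None, pos: Sequence[int]) -> None:
                    if strand == "+":
                        start, end = a, q
                    else:
                        start, end = L - q, L - a
                    hits.append(
                        OffTargetHit(contig_id, start, end, strand, site, pam,
                                     mm, kind, size, bp, tuple(pos))
                    )

                if q >= GUIDE_LEN:
                    site = seq[q - GUIDE_LEN : q]
                    mm, pos = _align_none(guide, site)
                    if mm <= budget.max_mm_no_bulge:
                        emit(q - GUIDE_LEN, site, mm, "none", 0, None, pos)

                if "DNA" in budget.bulge_kinds:
                    cands = []
                    for b in budget.bulge_sizes:
                        if q < GUIDE_LEN + b:
                            continue
                        site = seq[q - GUIDE_LEN - b : q]
                        for mm, bp, pos in _dna_bulge_alignments(guide, site, b, min_dna_split):
                            if mm <= budget.max_mm_with_bulge:
                                cands.append((b, mm, bp, pos))
                    best = _best_bulge_hit(guide, "DNA", cands)
                    if best is not None:
                        b, mm, bp, pos = best
                        emit(q - GUIDE_LEN - b, seq[q - GUIDE_LEN - b : q], mm, "DNA", b, bp, pos)

                if "RNA" in budget.bulge_kinds:
                    cands = []
                    for b in budget.bulge_sizes:
                        if b >= GUIDE_LEN or q < GUIDE_LEN - b:
                            continue
                        site = seq[q - (GUIDE_LEN - b) : q]
                        for mm, bp, pos in _rna_bulge_alignments(guide, site, b, min_rna_start):
                            if mm <= budget.max_mm_with_bulge:
                                cands.append((b, mm, bp, pos))
                    best = _best_bulge_hit(guide, "RNA", cands)
                    if best is not None:
                        b, mm, bp, pos = best
                        emit(q - (GUIDE_LEN - b), seq[q - (GUIDE_LEN - b) : q], mm, "RNA", b, bp, pos)

    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand, h.bulge_kind))
    return hits


def _mm_against_site(guide: str, hit: OffTargetHit,
                     allow_pam_adjacent_bulge: bool = False) -> int:
    """Minimum mismatches aligning a guide to a stored site under the hit's bulge class."""
    if hit.bulge_kind == "none":
        return _align_none(guide, hit.site_seq)[0]
    if hit.bulge_kind == "DNA":
        it = _dna_bulge_alignments(guide, hit.site_seq, hit.bulge_size,
                                   0 if allow_pam_adjacent_bulge else 1)
    else:
        it = _rna_bulge_alignments(guide, hit.site_seq, hit.bulge_size,
                                   1 if allow_pam_adjacent_bulge else 2)
    return min(mm for mm, _, _ in it)


def compare_burden(
    original: str,
    arrow: str,
    hits_of_original: Sequence[OffTargetHit],
) -> pd.DataFrame:
    """Per-site mismatch burden of an ARROW guide vs the original guide.

    For each off-target hit of the original guide, the ARROW guide is
    re-aligned to the stored site sequence under the same bulge class and the
    change in mismatch count is reported.  When the two guides differ by one
    base the delta is in {-1, 0, +1}; a site perfectly matched by the
    original guide always gains one mismatch.
    """
    original = clean_seq(original, allow_empty=False, name="original")
    arrow = clean_seq(arrow, allow_empty=False, name="arrow")
    if len(original) != len(arrow):
        raise SequenceLengthError("guides must have equal length")
    rows = []
    for h in hits_of_original:
        mm_arrow = _mm_against_site(arrow, h)
        rows.append(
            {
                "contig": h.contig_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "bulge_kind": h.bulge_kind,
                "mm_original": h.n_mismatches,
                "mm_arrow": mm_arrow,
                "delta": mm_arrow - h.n_mismatches,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "strand", "bulge_kind",
                 "mm_original", "mm_arrow", "delta"],
    )


def cut_offset_from_pam_start(pam_start: int) -> int:
    """Blunt-cut coordinate for a forward-strand site whose PAM starts at ``pam_start``.

    SpCas9 cuts 3 bp 5' of the PAM, between protospacer PAM positions 4 and 3.
    """
    return pam_start - 3


def predict_t7e1_fragments(amplicon_length: int, cut_offset: int) -> tuple[int, int]:
    """Fragment sizes expected on a gel after T7E1 cleavage at the cut site."""
    if not 0 < cut_offset < amplicon_length:
        raise ValueError(
            f"cut_offset {cut_offset} must be strictly inside (0, {amplicon_length})"
        )
    return cut_offset, amplicon_length - cut_offset


def hits_to_frame(hits: Iterable[OffTargetHit]) -> pd.DataFrame:
    rows = [
        {
            "contig": h.contig_id,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "site_seq": h.site_seq,
            "pam": h.pam,
            "n_mismatches": h.n_mismatches,
            "bulge_kind": h.bulge_kind,
            "bulge_size": h.bulge_size,
            "mismatch_pam_indices": ",".join(map(str, h.mismatch_positions)),
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "strand", "site_seq", "pam",
                 "n_mismatches", "bulge_kind", "bulge_size", "mismatch_pam_indices"],
    )
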