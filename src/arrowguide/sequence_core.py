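"""Sequence primitives, PAM scanning, and the PAM-indexed coordinate system.

Guides and protospacers are handled as DNA strings over {A,C,G,T,N}; RNA
input (U) is normalized to T on ingest and can be rendered back as U for
display.  Genomic intervals are 0-based half-open on the forward strand.
Positions within a protospacer are exposed in the field's "bp from PAM"
convention: PAM index 1 is the base immediately adjacent to the NGG PAM,
PAM index 20 the PAM-distal end.  For a 20-nt protospacer written 5'->3',
a 1-based string index ``i`` and a PAM index ``p`` are related by
``p = 21 - i``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

__all__ = [
    "AlphabetError",
    "SequenceLengthError",
    "VariantError",
    "NucSeqStr",
    "clean_seq",
    "revcomp",
    "to_rna",
    "to_pam_index",
    "from_pam_index",
    "hamming",
    "ProtospacerSite",
    "AllelePair",
    "scan_protospacers",
    "extract_site_window",
    "read_fasta",
    "write_fasta",
    "write_sites_bed",
]

NucSeqStr = str  # DNA string over {A,C,G,T,N}; plain str with validation

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains characters outside {A,C,G,T,N} (U accepted on ingest)."""


class SequenceLengthError(ValueError):
    """A sequence has the wrong length for the requested operation."""


class VariantError(ValueError):
    """An allele pair is not a simple SNV or is otherwise inconsistent."""


def clean_seq(s: str, *, allow_empty: bool = True, name: str = "sequence") -> str:
    """Normalize to uppercase DNA (U -> T) and validate the alphabet."""
    if not isinstance(s, str):
        raise AlphabetError(f"{name} must be a string, got {type(s).__name__}")
    out = s.upper().replace("U", "T")
    bad = set(out) - _VALID_BASES
    if bad:
        raise AlphabetError(
            f"{name} contains invalid characters {sorted(bad)}; allowed: A,C,G,T,N (U normalized to T)"
        )
    if not allow_empty and not out:
        raise SequenceLengthError(f"{name} must be non-empty")
    return out


def revcomp(s: str) -> str:
    """Watson-Crick reverse complement; N maps to N; involution."""
    return clean_seq(s)[::-1].translate(_COMPLEMENT)


def to_rna(s: str) -> str:
    """Render a DNA guide as RNA (T -> U) for reports."""
    return clean_seq(s).replace("T", "U")


def to_pam_index(i: int, length: int = 20) -> int:
    """Convert a 1-based 5'->3' string index to a PAM index (1 = PAM-adjacent)."""
    if not 1 <= i <= length:
        raise IndexError(f"5'->3' index {i} out of range [1, {length}]")
    return length + 1 - i


def from_pam_index(p: int, length: int = 20) -> int:
    """Inverse of :func:`to_pam_index`; round-trip is the identity."""
    if not 1 <= p <= length:
        raise IndexError(f"PAM index {p} out of range [1, {length}]")
    return length + 1 - p


def hamming(a: str, b: str) -> int:
    """Number of differing positions; N mismatches everything, including N.

    The conservative N rule means an ambiguous genomic base can never be
    credited as a match to a guide base.
    """
    a = clean_seq(a)
    b = clean_seq(b)
    if len(a) != len(b):
        raise SequenceLengthError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _is_pam(p: str) -> bool:
    # NGG: first base free (N in the genome still matches the N of NGG),
    # positions 2-3 must literally be G.
    return len(p) == 3 and p[1] == "G" and p[2] == "G"


@dataclass(frozen=True)
class ProtospacerSite:
    """A 20-nt SpCas9 target plus its NGG PAM, anchored on the forward strand.

    ``start``/``end`` are 0-based half-open forward-strand coordinates covering
    protospacer + PAM (23 bp).  ``protospacer`` and ``pam`` are stored in the
    site's own strand orientation.  ``variant_pam_index`` is set when the site
    was found by :func:`scan_protospacers` around a variant.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    variant_pam_index: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != 23:
            raise SequenceLengthError(
                f"site [{self.start},{self.end}) must span 23 bp (protospacer+PAM)"
            )
        object.__setattr__(self, "protospacer", clean_seq(self.protospacer, allow_empty=False, name="protospacer"))
        object.__setattr__(self, "pam", clean_seq(self.pam, allow_empty=False, name="pam"))
        if len(self.protospacer) != 20:
            raise SequenceLengthError("protospacer must be 20 nt")
        if not _is_pam(self.pam):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")

    @property
    def cut_offset(self) -> int:
        """Forward-strand coordinate of the blunt cut, 3 bp 5' of the PAM.

        The cut sits between PAM index 4 and 3 of the protospacer.
        """
        if self.strand == "+":
            return self.start + 17
        return self.start + 6


@dataclass(frozen=True)
class AllelePair:
    """Wild-type and mutant sequence contexts differing at a single SNV."""

    wt_context: str
    mut_context: str
    variant_offset: int
    wt_base: str
    mut_base: str

    def __post_init__(self) -> None:
        wt = clean_seq(self.wt_context, allow_empty=False, name="wt_context")
        mut = clean_seq(self.mut_context, allow_empty=False, name="mut_context")
        object.__setattr__(self, "wt_context", wt)
        object.__setattr__(self, "mut_context", mut)
        if len(wt) != len(mut):
            raise VariantError(
                f"contexts differ in length ({len(wt)} vs {len(mut)}): only SNVs are supported"
            )
        diffs = [i for i, (a, b) in enumerate(zip(wt, mut)) if a != b]
        if diffs != [self.variant_offset]:
            raise VariantError(
                f"contexts must differ exactly at variant_offset {self.variant_offset}; "
                f"observed differences at {diffs}"
            )
        if wt[self.variant_offset] != self.wt_base or mut[self.variant_offset] != self.mut_base:
            raise VariantError("wt_base/mut_base do not match the contexts at variant_offset")

    @classmethod
    def from_contexts(cls, wt_context: str, mut_context: str) -> "AllelePair":
        """Build a pair by locating the single differing position."""
        wt = clean_seq(wt_context, allow_empty=False, name="wt_context")
        mut = clean_seq(mut_context, allow_empty=False, name="mut_context")
        if len(wt) != len(mut):
            raise VariantError("contexts differ in length: only SNVs are supported")
        diffs = [i for i, (a, b) in enumerate(zip(wt, mut)) if a != b]
        if len(diffs) != 1:
            raise VariantError(f"expected exactly one differing base, found {len(diffs)}")
        off = diffs[0]
        return cls(wt, mut, off, wt[off], mut[off])


def scan_protospacers(
    context: str,
    variant_offset: int,
    contig_id: str = "context",
) -> list[ProtospacerSite]:
    """Find every NGG-adjacent 20-nt protospacer, on both strands, covering a variant.

    Each returned site is annotated with the variant's PAM index on that site.
    Returns an empty list when no window covers the offset.
    """
    context = clean_seq(context, allow_empty=False, name="context")
    n = len(context)
    if n < 23:
        raise SequenceLengthError("context must be at least 23 nt (protospacer + PAM)")
    if not 0 <= variant_offset < n:
        raise IndexError(f"variant_offset {variant_offset} outside context [0, {n})")

    sites: list[ProtospacerSite] = []
    # forward strand: protospacer context[s:s+20], PAM context[s+20:s+23]
    for s in range(0, n - 22):
        if context[s + 21] == "G" and context[s + 22] == "G" and s <= variant_offset < s + 20:
            # 1-based 5'->3' index of the variant within the protospacer
            i = variant_offset - s + 1
            sites.append(
                ProtospacerSite(
                    contig_id, s, s + 23, "+",
                    context[s : s + 20], context[s + 20 : s + 23],
                    variant_pam_index=to_pam_index(i),
                )
            )
    # minus strand: scan the reverse complement with the mirrored offset
    rc = revcomp(context)
    rc_off = n - 1 - variant_offset
    for s in range(0, n - 22):
        if rc[s + 21] == "G" and rc[s + 22] == "G" and s <= rc_off < s + 20:
            i = rc_off - s + 1
            sites.append(
                ProtospacerSite(
                    contig_id, n - (s + 23), n - s, "-",
                    rc[s : s + 20], rc[s + 20 : s + 23],
                    variant_pam_index=to_pam_index(i),
                )
            )
    sites.sort(key=lambda t: (t.start, t.strand))
    return sites


def extract_site_window(contig_seq: str, site: ProtospacerSite) -> tuple[str, str]:
    """Re-derive (protospacer, pam) from the genomic window of a site.

    Used to assert that stored fields round-trip through coordinates.
    """
    window = clean_seq(contig_seq)[site.start : site.end]
    if site.strand == "-":
        window = revcomp(window)
    return window[:20], window[20:]


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a (multi-record, line-wrapped) FASTA into {id: DNA string}."""
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = clean_seq(str(rec.seq), name=f"record {rec.id}")
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: dict[str, str], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sites_bed(sites: Iterable[ProtospacerSite], path: Union[str, Path]) -> None:
    """Write sites as 6-column BED-like TSV.

    Columns: contig, start, end, name, pam_index_of_variant, strand.
    """
    with open(path, "w") as fh:
        for k, s in enumerate(sites):
            p = s.variant_pam_index if s.variant_pam_index is not None else "."
            fh.write(f"{s.contig_id}\t{s.start}\t{s.end}\tsite{k}\t{p}\t{s.strand}\n")
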