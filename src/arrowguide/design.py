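"""Intentional-mismatch guide design for allele-specific editing (ARROW).

The design strategy: start from the guide perfectly matched to the *mutant*
allele, then introduce one deliberate mismatch at a position other than the
variant.  The resulting guide carries one mismatch against the mutant allele
but two against the wild-type allele, which pushes the wild-type target past
Cas9's single-mismatch tolerance while keeping the mutant target editable.

Which substitution to introduce at a given position is chosen from an
empirical mismatch-tolerance table: at each position the substitution with
the smallest reduction in measured indel rate is labelled H (highly
tolerant) and the one with the largest reduction L (low tolerant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .sequence_core import (
    AllelePair,
    AlphabetError,
    ProtospacerSite,
    SequenceLengthError,
    clean_seq,
    from_pam_index,
    hamming,
    revcomp,
    to_rna,
)

__all__ = [
    "BASES",
    "POSITION_PRESETS",
    "MismatchSpec",
    "ToleranceTable",
    "DesignedGuide",
    "DesignError",
    "enumerate_single_mismatch_variants",
    "enumerate_at_positions",
    "classify_tolerance",
    "default_design_positions",
    "design_arrow_guides",
    "guides_to_frame",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: Named position presets, in "bp from PAM" coordinates.  The seed region is
#: the PAM-proximal portion where mismatches are most disruptive; the default
#: six-position set spans both regimes.
POSITION_PRESETS: dict[str, tuple[int, ...]] = {
    "seed": (1, 3, 6),
    "nonseed": (9, 12, 15),
    "default6": (1, 3, 6, 9, 12, 15),
}


class DesignError(ValueError):
    """A design request violates the allele-discrimination rules."""


@dataclass(frozen=True)
class MismatchSpec:
    """One intentional substitution: put ``new_base`` at ``pam_index``."""

    pam_index: int
    new_base: str

    def __post_init__(self) -> None:
        if not 1 <= self.pam_index <= 20:
            raise IndexError(f"pam_index {self.pam_index} out of range [1, 20]")
        if self.new_base not in BASES:
            raise AlphabetError(f"new_base must be one of {BASES}, got {self.new_base!r}")


def apply_mismatch(guide: str, spec: MismatchSpec) -> str:
    """Return the guide with the substitution applied (PAM-indexed position)."""
    guide = clean_seq(guide, allow_empty=False, name="guide")
    i = from_pam_index(spec.pam_index, len(guide)) - 1
    if guide[i] == spec.new_base:
        raise DesignError(
            f"new_base {spec.new_base} equals the guide base at PAM index {spec.pam_index}: not a mismatch"
        )
    return guide[:i] + spec.new_base + guide[i + 1 :]


def enumerate_single_mismatch_variants(guide: str) -> list[tuple[MismatchSpec, str]]:
    """All one-base mismatched variants of a guide: 3 per position, 60 for 20 nt.

    Deterministic order: ascending PAM index, then base order A<C<G<T.
    Guides containing N are rejected (an ambiguous base has no well-defined
    substitution set).
    """
    guide = clean_seq(guide, allow_empty=False, name="guide")
    if "N" in guide:
        raise AlphabetError("guide contains N; mismatch enumeration requires unambiguous bases")
    n = len(guide)
    out: list[tuple[MismatchSpec, str]] = []
    for p in range(1, n + 1):
        i = from_pam_index(p, n) - 1
        for b in BASES:
            if b != guide[i]:
                out.append((MismatchSpec(p, b), guide[:i] + b + guide[i + 1 :]))
    return out


def enumerate_at_positions(
    guide: str, positions: Sequence[int]
) -> list[tuple[MismatchSpec, str]]:
    """Mismatch variants restricted to the given PAM-indexed positions.

    Exhaustive (3 substitutions per position); a subset of
    :func:`enumerate_single_mismatch_variants`.
    """
    guide = clean_seq(guide, allow_empty=False, name="guide")
    pos = list(positions)
    if len(set(pos)) != len(pos):
        raise ValueError(f"duplicate positions in {pos}")
    bad = [p for p in pos if not 1 <= p <= len(guide)]
    if bad:
        raise IndexError(f"positions out of range [1, {len(guide)}]: {bad}")
    wanted = set(pos)
    return [(m, v) for m, v in enumerate_single_mismatch_variants(guide) if m.pam_index in wanted]


# ---------------------------------------------------------------------------
# Mismatch tolerance

@dataclass
class ToleranceTable:
    """Empirical indel rate per (PAM index, substituted base).

    Rates are fractions in [0, 1] measured for guides carrying that single
    substitution; ``provenance`` labels the measurement source.
    """

    entries: dict[tuple[int, str], float]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for (p, b), r in self.entries.items():
            if not 1 <= p <= 20:
                raise IndexError(f"pam_index {p} out of range [1, 20]")
            if b not in BASES:
                raise AlphabetError(f"base {b!r} not in {BASES}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"indel rate {r} for ({p},{b}) outside [0, 1]")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "ToleranceTable":
        """Read a TSV with columns pam_index, new_base, indel_rate[, source]."""
        df = pd.read_csv(path, sep="\t")
        required = {"pam_index", "new_base", "indel_rate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tolerance TSV missing columns: {sorted(missing)}")
        entries = {
            (int(row.pam_index), str(row.new_base).upper().replace("U", "T")): float(row.indel_rate)
            for row in df.itertuples()
        }
        prov = str(df["source"].iloc[0]) if "source" in df.columns else str(path)
        return cls(entries, provenance=prov)

    def rates_at(self, pam_index: int) -> dict[str, float]:
        return {b: r for (p, b), r in self.entries.items() if p == pam_index}


def classify_tolerance(
    table: ToleranceTable, positions: Sequence[int]
) -> dict[int, dict[str, MismatchSpec]]:
    """Label, per position, the most (H) and least (L) tolerated substitution.

    H is the substitution with the highest measured indel rate (smallest
    reduction from the perfect match), L the lowest.  Ties are broken by base
    order A<C<G<T and logged.  Entry order in the table is irrelevant.
    """
    out: dict[int, dict[str, MismatchSpec]] = {}
    for p in positions:
        rates = table.rates_at(p)
        if len(rates) < 2:
            raise ValueError(
                f"tolerance table has {len(rates)} entries at position {p}; need at least 2"
            )
        ordered = sorted(rates.items())  # base order breaks ties
        h_base = max(ordered, key=lambda kv: (kv[1], -BASES.index(kv[0])))[0]
        l_base = min(ordered, key=lambda kv: (kv[1], BASES.index(kv[0])))[0]
        vals = sorted(rates.values())
        if vals[-1] == vals[-2] or vals[0] == vals[1]:
            logger.warning(
                "tolerance tie at position %d (rates %s); broken by base order A<C<G<T", p, rates
            )
        out[p] = {"H": MismatchSpec(p, h_base), "L": MismatchSpec(p, l_base)}
    return out


# ---------------------------------------------------------------------------
# ARROW guide design

@dataclass(frozen=True)
class DesignedGuide:
    """A mutant-matched guide carrying one intentional mismatch.

    Invariant (verified at construction time against the allele pair):
    exactly 1 mismatch vs the mutant protospacer and 2 vs the wild-type.
    """

    name: str
    sequence: str
    intentional_mismatch: MismatchSpec
    mm_vs_mut: int
    mm_vs_wt: int
    tolerance: str | None = None  # "H", "L", or None when no table was used

    @property
    def rna(self) -> str:
        return to_rna(self.sequence)


def default_design_positions(variant_pam_index: int) -> tuple[int, ...]:
    """The default intentional-mismatch position set for a given variant.

    Base set {1, 3, 6, 9, 12, 15}; the variant's own position is never used
    (a mismatch there would destroy allele discrimination).  When the variant
    sits at position 12 the neighbouring position 11 substitutes for it,
    keeping six positions; variants at other in-set positions simply drop
    that position.
    """
    base = [1, 3, 6, 9, 12, 15]
    if variant_pam_index == 12:
        return (1, 3, 6, 9, 11, 15)
    if variant_pam_index in base:
        return tuple(p for p in base if p != variant_pam_index)
    return tuple(base)


def _wt_protospacer(pair: AllelePair, site: ProtospacerSite) -> str:
    """Extract the wild-type protospacer for a site found on the mutant context."""
    if site.strand == "+":
        return pair.wt_context[site.start : site.start + 20]
    return revcomp(pair.wt_context[site.start + 3 : site.end])


def design_arrow_guides(
    pair: AllelePair,
    site: ProtospacerSite,
    positions: Sequence[int] | None = None,
    table: ToleranceTable | None = None,
    allow_variant_position: bool = False,
) -> list[DesignedGuide]:
    """Design allele-specific guides for a mutant-allele protospacer site.

    The site must come from scanning the *mutant* context so that its
    protospacer is the mutant-matched guide and covers the variant.  Each
    returned guide carries exactly one intentional mismatch; with a tolerance
    table, the H and L substitutions per position are emitted (names
    ``P<pos>-H``/``P<pos>-L``), otherwise all three substitutions
    (``P<pos>-<base>``).

    Every emitted guide is verified to have 1 mismatch against the mutant
    protospacer and 2 against the wild-type protospacer.
    """
    if site.variant_pam_index is None:
        raise DesignError("site must carry the variant's PAM index (use scan_protospacers)")
    mut_proto = site.protospacer
    wt_proto = _wt_protospacer(pair, site)
    if hamming(mut_proto, wt_proto) != 1:
        raise DesignError("mutant and wild-type protospacers must differ at exactly the variant")

    if positions is None:
        positions = default_design_positions(site.variant_pam_index)
    positions = list(positions)
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate positions in {positions}")
    if site.variant_pam_index in positions and not allow_variant_position:
        raise DesignError(
            f"position {site.variant_pam_index} is the variant position: an intentional "
            "mismatch there removes the single-base difference that discriminates the "
            "alleles (pass allow_variant_position=True to override)"
        )

    chosen: list[tuple[str, MismatchSpec, str | None]] = []
    if table is not None:
        labels = classify_tolerance(table, positions)
        for p in positions:
            for lab in ("H", "L"):
                spec = labels[p][lab]
                chosen.append((f"P{p}-{lab}", spec, lab))
    else:
        for spec, _ in enumerate_at_positions(mut_proto, positions):
            chosen.append((f"P{spec.pam_index}-{spec.new_base}", spec, None))

    guides: list[DesignedGuide] = []
    for name, spec, lab in chosen:
        seq = apply_mismatch(mut_proto, spec)
        mm_mut = hamming(seq, mut_proto)
        mm_wt = hamming(seq, wt_proto)
        if not (mm_mut == 1 and mm_wt == 2):
            # only reachable via allow_variant_position: touching the variant
            # base collapses the wild-type margin to <= 1 mismatch
            if spec.pam_index == site.variant_pam_index:
                logger.warning(
                    "guide %s touches the variant position: %d mismatches vs mutant, "
                    "%d vs wild-type (allele discrimination lost)", name, mm_mut, mm_wt
                )
            else:  # pragma: no cover - impossible by construction
                raise DesignError(
                    f"guide {name} violates the design rule: {mm_mut} mismatches vs "
                    f"mutant, {mm_wt} vs wild-type (expected 1 and 2)"
                )
        guides.append(DesignedGuide(name, seq, spec, mm_mut, mm_wt, tolerance=lab))
    return guides


def guides_to_frame(guides: Iterable[DesignedGuide]) -> pd.DataFrame:
    """Design report: one row per guide, RNA rendering included."""
    rows = [
        {
            "name": g.name,
            "sequence_rna": g.rna,
            "sequence_dna": g.sequence,
            "mismatch_pam_index": g.intentional_mismatch.pam_index,
            "mismatch_base": g.intentional_mismatch.new_base,
            "mm_vs_mut": g.mm_vs_mut,
            "mm_vs_wt": g.mm_vs_wt,
            "tolerance": g.tolerance if g.tolerance is not None else "",
        }
        for g in guides
    ]
    return pd.DataFrame(rows)
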