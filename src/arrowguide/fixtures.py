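"""Deterministic synthetic data: planted genomes, simulated amplicon reads,
and the built-in EGFR L858R / KRAS G12V worked examples.

All generators are pure functions of their seed (numpy PCG64 stream), so the
same configuration always yields byte-identical FASTA/FASTQ output.  The
worked examples carry the canonical guide pairs for the two cancer hotspot
mutations this toolkit was built around: EGFR L858R (variant 12 bp from the
PAM) and KRAS G12V (variant adjacent to the PAM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .design import default_design_positions
from .indel import AmpliconRef
from .sequence_core import AllelePair, ProtospacerSite, clean_seq, revcomp, scan_protospacers, to_rna

__all__ = [
    "PlantedSite",
    "SimulationConfig",
    "make_planted_genome",
    "simulate_amplicon_reads",
    "write_fastq",
    "WorkedExample",
    "worked_examples",
]


@dataclass(frozen=True)
class PlantedSite:
    """A guide-derived site to plant in a synthetic genome.

    The planted sequence is the guide with ``n_substitutions`` random base
    changes and, optionally, a single bulge: a DNA bulge inserts
    ``bulge_size`` random bases into the site, an RNA bulge deletes
    ``bulge_size`` contiguous guide bases.
    """

    guide: str
    n_substitutions: int = 0
    bulge_kind: str = "none"  # none | DNA | RNA
    bulge_size: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.bulge_kind not in {"none", "DNA", "RNA"}:
            raise ValueError(f"bulge_kind {self.bulge_kind!r}")
        if (self.bulge_kind == "none") != (self.bulge_size == 0):
            raise ValueError("bulge_size must be 0 iff bulge_kind is none")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class SimulationConfig:
    """Shared configuration for the synthetic-data generators.

    ``indel_length_distribution`` maps signed lengths (insertions positive,
    deletions negative) to probabilities summing to 1.  The default read
    simulation mimics a deep-sequenced amplicon: 2000 reads, Illumina-like
    0.1% per-base substitution error, short NHEJ-style indels concentrated
    at the cut site.
    """

    seed: int = 0
    genome_length: int = 5000
    gc_content: float = 0.5
    planted_sites: tuple[PlantedSite, ...] = ()
    read_count: int = 2000
    edited_fraction: float = 0.0
    indel_length_distribution: tuple[tuple[int, float], ...] = (
        (-3, 0.15), (-2, 0.15), (-1, 0.30), (1, 0.30), (2, 0.10),
    )
    substitution_error_rate: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.edited_fraction <= 1.0:
            raise ValueError("edited_fraction must be in [0, 1]")
        total = sum(p for _, p in self.indel_length_distribution)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"indel length probabilities sum to {total}, expected 1")
        if any(l == 0 for l, _ in self.indel_length_distribution):
            raise ValueError("indel lengths must be nonzero")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs)) if n else ""


def _distort(rng: np.random.Generator, site: PlantedSite) -> tuple[str, str]:
    """Build (site_seq, pam) from a planted-site spec; substitutions avoid
    bulge-deleted positions and the PAM."""
    guide = clean_seq(site.guide, allow_empty=False, name="guide")
    seq = list(guide)
    if site.n_substitutions:
        pos = rng.choice(len(seq), size=site.n_substitutions, replace=False)
        for i in sorted(pos):
            seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    s = "".join(seq)
    if site.bulge_kind == "DNA":
        # insert random bases strictly inside the protospacer, away from the
        # PAM-adjacent position (kept searchable under default budgets)
        j = int(rng.integers(2, len(s) - 1))
        s = s[:j] + _random_bases(rng, site.bulge_size, 0.5) + s[j:]
    elif site.bulge_kind == "RNA":
        j = int(rng.integers(1, len(s) - site.bulge_size - 1))
        s = s[:j] + s[j + site.bulge_size :]
    pam = rng.choice(list("ACGT")) + "GG"
    return s, pam


def make_planted_genome(
    cfg: SimulationConfig, contig_id: str = "synth"
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random background genome with guide-derived sites planted at known loci.

    Returns ({contig: sequence}, truth table).  The truth table records, per
    planted site, the forward-strand coordinates, strand, planted site
    sequence and PAM, and the distortions applied — the fields an off-target
    search is expected to recover.  Same config -> byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = [_distort(rng, s) for s in cfg.planted_sites]
    footprints = [len(s) + 3 for s, _ in sites]
    margin = 30
    need = sum(f + margin for f in footprints) + margin
    if cfg.genome_length < need:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small for {len(sites)} sites (need >= {need})"
        )

    genome = list(_random_bases(rng, cfg.genome_length, cfg.gc_content))
    # lay sites left to right with jitter, non-overlapping
    free = cfg.genome_length - need
    gaps = rng.multinomial(free, [1 / (len(sites) + 1)] * (len(sites) + 1)) if sites else []
    rows = []
    pos = margin
    for spec, (site_seq, pam), fp, extra in zip(cfg.planted_sites, sites, footprints, gaps):
        pos += int(extra)
        insert = site_seq + pam if spec.strand == "+" else revcomp(site_seq + pam)
        genome[pos : pos + fp] = list(insert)
        site_start = pos if spec.strand == "+" else pos + 3
        rows.append(
            {
                "contig": contig_id,
                "start": site_start,
                "end": site_start + len(site_seq),
                "strand": spec.strand,
                "site_seq": site_seq,
                "pam": pam,
                "n_substitutions": spec.n_substitutions,
                "bulge_kind": spec.bulge_kind,
                "bulge_size": spec.bulge_size,
            }
        )
        pos += fp + margin
    truth = pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "strand", "site_seq", "pam",
                 "n_substitutions", "bulge_kind", "bulge_size"],
    )
    return {contig_id: "".join(genome)}, truth


def simulate_amplicon_reads(
    ref: AmpliconRef, cfg: SimulationConfig
) -> tuple[list[tuple[str, str]], dict]:
    """Simulate amplicon reads with a known edited fraction.

    Each read is the full reference; with probability ``edited_fraction`` one
    indel (signed length drawn from the configured distribution) is placed
    uniformly within the cut window, then iid substitution errors are applied.
    Returns (reads as (id, seq) pairs, truth dict with per-read edit status).
    """
    rng = np.random.default_rng(cfg.seed)
    lengths = [l for l, _ in cfg.indel_length_distribution]
    probs = [p for _, p in cfg.indel_length_distribution]
    seq = ref.sequence
    lo, hi = ref.window_start, ref.window_end

    reads: list[tuple[str, str]] = []
    edited_flags: list[bool] = []
    for k in range(cfg.read_count):
        edited = bool(rng.random() < cfg.edited_fraction)
        r = seq
        if edited:
            net = int(lengths[rng.choice(len(lengths), p=probs)])
            pos = int(rng.integers(lo, hi + 1))
            if net > 0:
                r = r[:pos] + _random_bases(rng, net, 0.5) + r[pos:]
            else:
                r = r[: pos] + r[pos - net :]  # delete |net| bases at pos
        if cfg.substitution_error_rate > 0:
            arr = list(r)
            errs = np.nonzero(rng.random(len(arr)) < cfg.substitution_error_rate)[0]
            for i in errs:
                arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
            r = "".join(arr)
        reads.append((f"read{k:05d}", r))
        edited_flags.append(edited)

    truth = {
        "n_reads": cfg.read_count,
        "edited_fraction_requested": cfg.edited_fraction,
        "n_edited_true": int(sum(edited_flags)),
        "edited": edited_flags,
    }
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path: Union[str, Path], quality: int = 30) -> None:
    """Write (id, seq) pairs as 4-line FASTQ with a fixed quality score."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")


# ---------------------------------------------------------------------------
# Worked examples

@dataclass(frozen=True)
class WorkedExample:
    """One allele-specific design case: guides, allele pair, mutant site."""

    name: str
    wt_guide: str        # DNA, perfectly matched to the wild-type allele
    mut_guide: str       # DNA, perfectly matched to the mutant allele
    pair: AllelePair
    site: ProtospacerSite  # mutant-allele protospacer site covering the variant
    variant_pam_index: int
    design_positions: tuple[int, ...]

    @property
    def wt_guide_rna(self) -> str:
        return to_rna(self.wt_guide)

    @property
    def mut_guide_rna(self) -> str:
        return to_rna(self.mut_guide)


def _build_example(name: str, wt_guide: str, mut_guide: str) -> WorkedExample:
    # minimal context: the protospacer followed by an AGG PAM
    wt_ctx = wt_guide + "AGG"
    mut_ctx = mut_guide + "AGG"
    pair = AllelePair.from_contexts(wt_ctx, mut_ctx)
    sites = [
        s for s in scan_protospacers(mut_ctx, pair.variant_offset, contig_id=name)
        if s.strand == "+" and s.protospacer == mut_guide
    ]
    site = sites[0]
    return WorkedExample(
        name, wt_guide, mut_guide, pair, site,
        site.variant_pam_index,
        default_design_positions(site.variant_pam_index),
    )


def worked_examples() -> dict[str, WorkedExample]:
    """The two canonical hotspot-mutation design cases.

    EGFR L858R: the variant base sits 12 bp from the PAM; the default design
    set substitutes position 11 for the variant's 12.  KRAS G12V: the variant
    is the PAM-adjacent base (position 1), which drops position 1 from the
    design set.
    """
    return {
        "EGFR_L858R": _build_example(
            "EGFR_L858R",
            "TTTTGGGCTGGCCAAACTGC",  # wild-type-matched guide
            "TTTTGGGCGGGCCAAACTGC",  # L858R-matched guide
        ),
        "KRAS_G12V": _build_example(
            "KRAS_G12V",
            "CTTGTGGTAGTTGGAGCTGG",  # wild-type-matched guide
            "CTTGTGGTAGTTGGAGCTGT",  # G12V-matched guide
        ),
    }
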