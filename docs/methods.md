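# Methods

## Coordinate conventions

Genomic intervals are 0-based half-open on the forward strand. Guide-internal
positions use the field's "bp from PAM" convention (PAM index): position 1 is
the protospacer base adjacent to the NGG PAM, position 20 the PAM-distal end;
for a 20-nt protospacer written 5′→3′, PAM index `p` and 1-based string index
`i` satisfy `p = 21 − i`. Guides are stored as DNA (U→T on ingest) because all
comparisons are against DNA targets; reports render T→U. `N` is conservative:
it mismatches everything, including another `N`, so an ambiguous genomic base
never counts as a guide match. Only the NGG PAM is recognised; alternative
PAMs (e.g. NAG) are out of scope.

## Intentional-mismatch design

An allele-specific (ARROW) guide is the mutant-matched protospacer with one
deliberate substitution at a position other than the variant. Because the two
alleles differ only at the variant, any such guide has exactly 1 mismatch
against the mutant and 2 against the wild-type protospacer; both counts are
verified before a guide is emitted. An intentional mismatch *at* the variant
position necessarily collapses the wild-type margin to ≤1 (substituting the
wild-type base reconstructs the wild-type guide), so that position is
rejected by default; `allow_variant_position` permits it for exploration,
with the violated margins recorded on the emitted guides and a warning
logged.

Enumeration of candidate substitutions is exhaustive — 3 per position, 60
for a 20-nt guide — rather than sampled, so designs are reproducible without
a random state. Position presets: seed `{1,3,6}`, non-seed `{9,12,15}`,
default6 `{1,3,6,9,12,15}`. The default design set keeps six positions by
substituting 11 when the variant sits at 12 (the EGFR L858R case) and drops
the variant's position otherwise (KRAS G12V at position 1 leaves five).

H/L labels come from an empirical tolerance table (TSV input; measured indel
rate per position × substituted base): per position, H = argmax rate,
L = argmin rate. Ties are broken by base order A<C<G<T and logged; the label
assignment is invariant to table row order. The packaged EGFR/KRAS tables are
synthetic illustrations (seed positions less tolerant than distal ones) for
demonstrations and tests; real tables are experimental inputs. The toolkit
ranks or filters designed guides only through the table; it does not predict
indel rates from sequence.

## Off-target search

The search is PAM-anchored: every NGG on either strand is located (the minus
strand is scanned on the reverse complement and coordinates mapped back) and
the adjacent window aligned to the guide in three classes — bulge-free
(≤ `max_mm_no_bulge` substitutions, default 8), single DNA bulge (extra
unpaired bases in the DNA site, gap in the guide) and single RNA bulge
(unpaired guide bases, gap in the DNA), both with 1–5 nt bulges and
≤ `max_mm_with_bulge` substitutions (default 2). Exactly one contiguous bulge
per hit, the convention established by bulge-aware off-target searchers.
A site is reported at most once per (PAM location, strand, class); within a
class the reported alignment minimises (bulge size, mismatch count, then
prefers the most PAM-distal bulge placement) — mismatch minimisation is the
contract, the bulge-placement preference only breaks exact ties. Bulges
touching PAM index 1 are excluded by default (a bulge flush against the PAM
is biophysically implausible and would blur the PAM boundary); a flag
re-enables them. A linear scan was chosen over an FM-index: the target scale
is amplicons and desk-sized genomes where correctness and auditability
matter more than throughput.

Mismatch-burden comparison re-aligns the modified guide to each stored site
under the same bulge class and size and reports `mm_arrow − mm_original`.
For guides differing at one base the delta is bounded by ±1, and a site
perfectly matching the original guide always gains exactly +1 — the
mechanism by which an intentional mismatch also increases off-target
mismatch burden.

## Amplicon quantification

Reads are globally aligned (affine gaps: match +2, mismatch −3, open −10,
extend −1) via Biopython's `PairwiseAligner`. Reads shorter than 50 nt or
below 60% alignment identity (matches / alignment columns) are excluded from
the denominator as unaligned — contaminant reads should not deflate
frequencies. Base qualities are ignored by default.

A read is *edited* iff an insertion or deletion intersects the closed window
`[cut − w, cut + w]`, where the cut is the blunt position 3 bp 5′ of the PAM
and `w = 3` by default — the canonical cut is the landmark, and ±3 bp
matches common amplicon-analysis practice. Substitutions never count. Indels
are left-normalized, and an indel whose placement is ambiguous within
repeated sequence counts as in-window if *any* equivalent placement
intersects the window; without this, an indel created at the cut site inside
a homopolymer could canonicalise out of the window and silently deflate
frequencies. The frequency is `edited / aligned`; the discrimination summary
reports mutant/wild-type ratio (infinite when the wild-type rate is 0) and
difference. The frameshift-reporter helper classifies a net indel length
against a construct whose reporter is `k ∈ {1,2}` bases out of frame:
in-frame iff `(net + k) mod 3 == 0`. An unpaired t-test wrapper is provided
for replicate comparisons in reports.

Paired-end merging is out of scope; inputs are single or pre-merged reads.

## Synthetic data

Generators are pure functions of their integer seed (numpy PCG64), so
outputs are byte-stable across runs and platforms. Planted genomes draw an
iid background at a configurable GC content (default 50%; 0% gives a pure
A/T background with no spurious PAMs) and insert guide-derived sites —
optionally distorted by substitutions and/or one bulge — at non-overlapping,
recorded loci with a truth table of the expected hit fields. A planted
distortion is guaranteed to be recovered under a budget that admits exactly
its class; under wider budgets the search may legitimately prefer a tighter
alignment of the same locus (e.g. a smaller bulge plus mismatches).

Read simulation emits full-length amplicon copies; each read is edited with
the configured probability by placing one indel (signed length drawn from a
configurable distribution, default short NHEJ-like: 1–3 bp deletions, 1–2 bp
insertions) uniformly within the cut window, then applying iid substitution
errors (default 0.1%, Illumina-like). Defaults model a deep-sequenced
amplicon at n = 2000 reads. Not modelled: quality-dependent error profiles,
adapter content, coverage variation, large structural edits — so passing
recovery tests demonstrates correctness of the window rule and estimator,
not robustness to every real sequencing artefact.

## Problem sizes and numerical choices

Tests and the acceptance script use planted genomes of 2–5 kb and read sets
of n = 2000, sizes at which the naive-oracle cross-checks remain exhaustive;
the algorithms themselves are size-agnostic. Editing-fraction recovery is
asserted within 3σ binomial bounds at the simulated n. All tie-breaks
(H/L labels, bulge placement, alignment gap placement) are deterministic and
documented above; given identical inputs every pipeline stage is
reproducible bit-for-bit.

## Known limitations

No cleavage-efficiency scoring of off-target sites (CFD/MIT-style) and no
thermodynamic model of mismatch tolerance — tolerance enters only through
measured tables. The search is not indexed and is not intended for scanning
full mammalian genomes in production. The quantifier assumes one amplicon
per sample and does not phase multi-allelic read mixtures beyond the
mutant/wild-type comparison.
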