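# arrowguide

Allele-specific CRISPR–Cas9 editing of heterozygous point mutations is hard
because Cas9 tolerates single mismatches: a guide perfectly matched to a
mutant allele (e.g. *EGFR* L858R or *KRAS* G12V) usually still cleaves the
wild-type allele, which differs by only one base. `arrowguide` implements
the ARROW design strategy for this problem, plus the computational
machinery around it, for researchers designing allele-selective guides and
analysing their editing outcomes:

* **Design** — start from the guide perfectly matched to the *mutant*
  protospacer and introduce one deliberate mismatch at a chosen position
  (in "bp from PAM" coordinates). The result carries **1 mismatch against
  the mutant allele but 2 against the wild type**, pushing the wild-type
  target past Cas9's mismatch tolerance. Substitutions are picked from an
  empirical tolerance table: per position, the substitution with the
  smallest drop in indel rate is labelled **H** (highly tolerant), the
  largest drop **L** (low tolerant).
* **Off-target search** — enumerate NGG-adjacent sites on both strands of a
  genome that match a guide with up to 8 substitutions, or up to 2
  substitutions combined with a single 1–5 nt DNA or RNA bulge, and compare
  the per-site mismatch burden of an original vs an intentionally
  mismatched guide.
* **Quantification** — align amplicon reads to a reference (global, affine
  gaps) and call a read *edited* when an indel intersects a ±3 bp window
  around the blunt cut 3 bp 5′ of the PAM; summarise allele discrimination
  as mutant/wild-type rate ratio and difference.
* **Synthetic data** — seeded, byte-reproducible planted genomes and
  simulated amplicon read sets, plus the built-in EGFR L858R / KRAS G12V
  worked examples.

## Worked example

```python
import arrowguide as ag

egfr = ag.worked_examples()["EGFR_L858R"]
print(egfr.mut_guide_rna)          # UUUUGGGCGGGCCAAACUGC  (L858R-matched)
print(egfr.site.variant_pam_index) # 12  (variant is 12 bp from the PAM)

guides = ag.design_arrow_guides(egfr.pair, egfr.site)
g = guides[0]
print(g.name, g.rna, g.mm_vs_mut, g.mm_vs_wt)
# P1-A UUUUGGGCGGGCCAAACUGA 1 2
```

Every designed guide differs from the mutant protospacer at exactly one
position (the intentional mismatch) and from the wild-type protospacer at
two (intentional mismatch + the L858R base), which is the allele-selective
margin. The default position set is `{1, 3, 6, 9, 12, 15}` bp from the PAM,
with 11 standing in when the variant itself sits at 12 (as for EGFR L858R).

Off-target burden of an intentionally mismatched guide:

```python
kras = ag.worked_examples()["KRAS_G12V"]
cfg = ag.SimulationConfig(seed=7, genome_length=5000,
                          planted_sites=(ag.PlantedSite(kras.mut_guide),))
genome, truth = ag.make_planted_genome(cfg)
hits = ag.find_offtargets(kras.mut_guide, genome,
                          ag.SearchBudget(max_mm_no_bulge=4, bulge_sizes=()))
arrow = ag.design_arrow_guides(kras.pair, kras.site)[0]
print(ag.compare_burden(kras.mut_guide, arrow.sequence, hits)["delta"].tolist())
# [1]  — the perfect on-target site gains exactly one mismatch
```

The same workflows are available from a shell:

```bash
arrow design --wt <seq|fasta> --mut <seq|fasta> --positions default6
arrow offtarget --guide CTTGTGGTAGTTGGAGCTGT --genome genome.fa --max-mm 8 --bulge-mm 2 --bulge-sizes 1:5
arrow quantify --reads sample.fastq --amplicon amplicon.fa --variant-offset 68
```

Packaged tolerance tables under `arrowguide/data/` are synthetic,
illustrative values (real tables come from reporter experiments and are
supplied as TSV with columns `pam_index`, `new_base`, `indel_rate`,
`source`).

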