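"""Off-target enumeration under mismatch/bulge budgets, vs a naive oracle.

The oracle scans the forward strand directly for NGG (plus strand) and CCN
(minus strand) anchors and enumerates every bulge placement by string
surgery on the site/guide, independently of the package's PAM-anchored
implementation.
"""

import numpy as np
import pytest

import arrowguide as ag
from arrowguide.offtarget import cut_offset_from_pam_start

GUIDE = "CTTGTGGTAGTTGGAGCTGT"  # KRAS G12V mutant-matched guide


def _mm(a, b):
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def _bulge_candidates(guide, site, kind, size, allow_pam_adjacent=False):
    """All (n_mismatches, bulge_pam_index) single-bulge alignments."""
    n = len(guide)
    out = []
    if kind == "DNA":  # remove the `size` inserted site bases, compare rest
        lo = 0 if allow_pam_adjacent else 1
        for split in range(lo, n):  # guide bases PAM-side of the bulge
            surv = site[: n - split] + site[n + size - split :]
            out.append((_mm(guide, surv), split + 1))
    else:  # RNA: remove `size` contiguous guide bases
        lo = 1 if allow_pam_adjacent else 2
        for start in range(lo, n - size + 2):  # PAM index of proximal skipped base
            i0 = n - (start + size - 1) - 1
            reduced = guide[:i0] + guide[i0 + size :]
            out.append((_mm(reduced, site), start))
    return out


def oracle_hits(guide, genome, budget):
    """Hit set {(contig, start, end, strand, kind, size, mm)} by brute force."""
    hits = set()
    n = len(guide)
    for contig, fwd in genome.items():
        L = len(fwd)
        anchors = []
        for a in range(L - 2):
            if fwd[a + 1 : a + 3] == "GG":
                anchors.append(("+", a))
            if fwd[a : a + 2] == "CC":
                anchors.append(("-", a))
        for strand, a in anchors:
            def window(lo_fwd, length):
                if lo_fwd < 0 or lo_fwd + length > L:
                    return None
                w = fwd[lo_fwd : lo_fwd + length]
                return w if strand == "+" else ag.revcomp(w)

            def coords(length):
                return (a - length, a) if strand == "+" else (a + 3, a + 3 + length)

            # bulge-free
            s, e = coords(n)
            site = window(s, n)
            if site is not None and _mm(guide, site) <= budget.max_mm_no_bulge:
                hits.add((contig, s, e, strand, "none", 0, _mm(guide, site)))
            for kind in budget.bulge_kinds:
                best = None
                for size in budget.bulge_sizes:
                    length = n + size if kind == "DNA" else n - size
                    if length <= 0:
                        continue
                    s, e = coords(length)
                    site = window(s, length)
                    if site is None:
                        continue
                    for mm, bp in _bulge_candidates(
                        guide, site, kind, size, budget.allow_pam_adjacent_bulge
                    ):
                        if mm <= budget.max_mm_with_bulge:
                            key = (size, mm, -bp)
                            if best is None or key < best[0]:
                                best = (key, contig, s, e, strand, kind, size, mm)
                if best is not None:
                    hits.add(best[1:])
    return hits


def impl_hits(guide, genome, budget):
    return {
        (h.contig_id, h.start, h.end, h.strand, h.bulge_kind, h.bulge_size, h.n_mismatches)
        for h in ag.find_offtargets(guide, genome, budget)
    }


class TestFindOfftargets:
    def test_planted_perfect_site(self):
        cfg = ag.SimulationConfig(seed=3, genome_length=5000,
                                  planted_sites=(ag.PlantedSite(GUIDE),))
        genome, truth = ag.make_planted_genome(cfg)
        hits = ag.find_offtargets(GUIDE, genome, ag.SearchBudget(max_mm_no_bulge=0, bulge_sizes=()))
        perfect = [h for h in hits if h.n_mismatches == 0 and h.bulge_kind == "none"]
        assert len(perfect) == 1
        row = truth.iloc[0]
        h = perfect[0]
        assert (h.start, h.end, h.strand, h.site_seq) == (
            row.start, row.end, row.strand, row.site_seq,
        )

    def test_mismatch_budget_boundary(self):
        site = list(GUIDE)
        site[0], site[5] = "A", "C"  # 2 substitutions (guide has C,G there)
        assert _mm(GUIDE, "".join(site)) == 2
        genome = {"g": "T" * 25 + "".join(site) + "AGG" + "T" * 25}
        tight = ag.SearchBudget(max_mm_no_bulge=1, bulge_sizes=())
        loose = ag.SearchBudget(max_mm_no_bulge=2, bulge_sizes=())
        assert impl_hits(GUIDE, genome, tight) == set()
        (hit,) = ag.find_offtargets(GUIDE, genome, loose)
        assert hit.n_mismatches == 2 and hit.bulge_kind == "none"

    def test_rna_bulge_deleted_base(self):
        deleted = GUIDE[:10] + GUIDE[11:]  # drop one mid-guide base
        genome = {"g": "A" * 25 + deleted + "TGG" + "A" * 25}
        budget = ag.SearchBudget(max_mm_no_bulge=0, max_mm_with_bulge=0, bulge_sizes=(1,))
        hits = ag.find_offtargets(GUIDE, genome, budget)
        rna = [h for h in hits if h.bulge_kind == "RNA"]
        assert len(rna) == 1
        assert (rna[0].bulge_size, rna[0].n_mismatches) == (1, 0)
        assert rna[0].site_seq == deleted

    def test_dna_bulge_inserted_bases(self):
        inserted = GUIDE[:12] + "CA" + GUIDE[12:]
        genome = {"g": "T" * 25 + inserted + "CGG" + "T" * 25}
        budget = ag.SearchBudget(max_mm_no_bulge=0, max_mm_with_bulge=0, bulge_sizes=(1, 2))
        hits = ag.find_offtargets(GUIDE, genome, budget)
        dna = [h for h in hits if h.bulge_kind == "DNA"]
        assert len(dna) == 1
        assert (dna[0].bulge_size, dna[0].n_mismatches) == (2, 0)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            ag.find_offtargets(GUIDE, {"g": ""})

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_genomes(self, seed):
        r = np.random.default_rng(seed)
        genome = {"chr": "".join(r.choice(list("ACGT"), size=3000))}
        budget = ag.SearchBudget(max_mm_no_bulge=4, max_mm_with_bulge=2, bulge_sizes=(1, 2))
        assert impl_hits(GUIDE, genome, budget) == oracle_hits(GUIDE, genome, budget)

    def test_monotonic_in_mismatch_budget_and_bulge_size(self):
        r = np.random.default_rng(42)
        genome = {"chr": "".join(r.choice(list("ACGT"), size=4000))}
        counts_mm = [
            len(ag.find_offtargets(GUIDE, genome, ag.SearchBudget(max_mm_no_bulge=k, bulge_sizes=())))
            for k in (2, 4, 6, 8)
        ]
        assert counts_mm == sorted(counts_mm)
        counts_bulge = [
            len(ag.find_offtargets(
                GUIDE, genome,
                ag.SearchBudget(max_mm_no_bulge=0, max_mm_with_bulge=2,
                                bulge_sizes=tuple(range(1, b + 1)))))
            for b in (1, 2, 3)
        ]
        assert counts_bulge == sorted(counts_bulge)

    def test_strand_symmetry(self):
        r = np.random.default_rng(7)
        seq = "".join(r.choice(list("ACGT"), size=3000))
        budget = ag.SearchBudget(max_mm_no_bulge=4, max_mm_with_bulge=1, bulge_sizes=(1,))
        fwd = ag.find_offtargets(GUIDE, {"c": seq}, budget)
        rev = ag.find_offtargets(GUIDE, {"c": ag.revcomp(seq)}, budget)
        L = len(seq)
        mirrored = {
            (L - h.end, L - h.start, {"+": "-", "-": "+"}[h.strand],
             h.bulge_kind, h.bulge_size, h.n_mismatches)
            for h in rev
        }
        assert {
            (h.start, h.end, h.strand, h.bulge_kind, h.bulge_size, h.n_mismatches)
            for h in fwd
        } == mirrored


class TestCompareBurden:
    def test_perfect_site_gains_one_mismatch(self):
        arrow = GUIDE[:14] + ("A" if GUIDE[14] != "A" else "C") + GUIDE[15:]
        genome = {"g": "T" * 25 + GUIDE + "AGG" + "T" * 25}
        hits = ag.find_offtargets(GUIDE, genome, ag.SearchBudget(bulge_sizes=()))
        table = ag.compare_burden(GUIDE, arrow, hits)
        perfect = table[table.mm_original == 0]
        assert (perfect.delta == 1).all()

    def test_site_already_mismatched_at_intentional_position(self):
        # site carries T at PAM index 6 where the guide has A; the ARROW guide
        # switches to T there, so the site loses one mismatch
        i = 20 - 6
        assert GUIDE[i] == "A"
        site = GUIDE[:i] + "T" + GUIDE[i + 1 :]
        arrow = GUIDE[:i] + "T" + GUIDE[i + 1 :]
        genome = {"g": "A" * 25 + site + "GGG" + "A" * 25}
        hits = ag.find_offtargets(GUIDE, genome, ag.SearchBudget(bulge_sizes=()))
        table = ag.compare_burden(GUIDE, arrow, hits)
        row = table[(table.mm_original == 1)].iloc[0]
        assert row.delta == -1

    def test_deltas_match_positionwise_recount(self):
        planted = tuple(
            ag.PlantedSite(GUIDE, n_substitutions=k % 5, strand="+-"[k % 2])
            for k in range(20)
        )
        cfg = ag.SimulationConfig(seed=11, genome_length=4000, planted_sites=planted)
        genome, _ = ag.make_planted_genome(cfg)
        arrow = GUIDE[:17] + ("A" if GUIDE[17] != "A" else "G") + GUIDE[18:]
        hits = ag.find_offtargets(GUIDE, genome, ag.SearchBudget(max_mm_no_bulge=6, bulge_sizes=()))
        assert len(hits) >= 20
        table = ag.compare_burden(GUIDE, arrow, hits)
        for h, (_, row) in zip(hits, table.iterrows()):
            assert _mm(arrow, h.site_seq) == row.mm_arrow
            assert row.delta == _mm(arrow, h.site_seq) - _mm(GUIDE, h.site_seq)
        assert set(table.delta) <= {-1, 0, 1}

    def test_delta_bounded_by_guide_distance(self):
        planted = tuple(
            ag.PlantedSite(GUIDE, n_substitutions=k % 4,
                           bulge_kind="none" if k % 3 else "RNA",
                           bulge_size=0 if k % 3 else 1)
            for k in range(9)
        )
        cfg = ag.SimulationConfig(seed=13, genome_length=4000, planted_sites=planted)
        genome, _ = ag.make_planted_genome(cfg)
        other = "".join(
            b if k % 7 else ("A" if b != "A" else "T") for k, b in enumerate(GUIDE)
        )
        d = ag.hamming(GUIDE, other)
        budget = ag.SearchBudget(max_mm_no_bulge=5, max_mm_with_bulge=2, bulge_sizes=(1,))
        hits = ag.find_offtargets(GUIDE, genome, budget)
        table = ag.compare_burden(GUIDE, other, hits)
        assert (table.delta.abs() <= d).all()

    def test_unequal_guide_lengths_rejected(self):
        with pytest.raises(ag.SequenceLengthError):
            ag.compare_burden(GUIDE, GUIDE[:-1], [])


class TestT7E1Fragments:
    @pytest.mark.parametrize("amp,cut,expected", [(500, 200, (200, 300)), (100, 1, (1, 99))])
    def test_fragment_sizes(self, amp, cut, expected):
        frags = ag.predict_t7e1_fragments(amp, cut)
        assert frags == expected
        assert sum(frags) == amp

    def test_cut_is_three_bp_upstream_of_pam(self):
        assert cut_offset_from_pam_start(100) == 97

    def test_cut_from_protospacer_site(self, egfr):
        # site PAM starts at site.start + 20 on the plus strand
        assert egfr.site.cut_offset == egfr.site.start + 17

    @pytest.mark.parametrize("amp,cut", [(100, 0), (100, 100), (100, -5)])
    def test_out_of_range_cut_rejected(self, amp, cut):
        with pytest.raises(ValueError):
            ag.predict_t7e1_fragments(amp, cut)
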