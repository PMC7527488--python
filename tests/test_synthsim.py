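import numpy as np
import pytest

from ssrmine._seq import iupac_find_all
from ssrmine.diversity import GenotypeMatrix, locus_stats
from ssrmine.ssr_detect import find_perfect_ssrs
from ssrmine.synthsim import (
    GroupSpec,
    LocusSpec,
    SimConfig,
    default_sim_config,
    digest,
    digest_and_read,
    generate_barcodes,
    make_genome,
    sample_population,
    simulate,
)


def tiny_config(seed=3, loci=None, groups=None, **kw):
    loci = loci or (
        LocusSpec("AG", {8: 0.5, 10: 0.5}),
        LocusSpec("CAT", {5: 1.0}),
    )
    groups = groups or (GroupSpec("g", 3, inbreeding=0.0),)
    return SimConfig(loci=tuple(loci), groups=tuple(groups), seed=seed, **kw)


class TestSpecs:
    def test_freqs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            LocusSpec("AG", {8: 0.5, 10: 0.6})

    def test_motif_must_be_primitive(self):
        with pytest.raises(ValueError, match="primitive"):
            LocusSpec("AGAG", {5: 1.0})

    def test_inbreeding_bounds(self):
        with pytest.raises(ValueError):
            GroupSpec("g", 2, inbreeding=1.5)

    def test_default_config_shape(self):
        cfg = default_sim_config(1, n_loci=10, n_polymorphic=4)
        assert len(cfg.loci) == 10
        assert sum(s.polymorphic for s in cfg.loci) == 4
        assert cfg.n_accessions == 20


class TestMakeGenome:
    def test_deterministic_under_seed(self):
        t1 = make_genome(tiny_config())
        t2 = make_genome(tiny_config())
        assert t1.haplotype(t1.reference_counts()) == \
               t2.haplotype(t2.reference_counts())

    def test_zero_loci_genome_ssr_free(self):
        template = make_genome(tiny_config(loci=()))
        assert find_perfect_ssrs(template.haplotype([])) == []

    def test_planted_tracts_are_exactly_detected(self):
        cfg = default_sim_config(5, n_loci=10, n_polymorphic=5)
        template = make_genome(cfg)
        genome = template.haplotype(template.reference_counts())
        hits = find_perfect_ssrs(genome)
        assert sorted((h.motif, h.repeat_count) for h in hits) == \
               sorted((l.motif, max(l.alleles)) for l in template.loci)

    def test_each_tract_within_read_reach_of_a_cut_site(self):
        cfg = tiny_config()
        template = make_genome(cfg)
        genome = template.haplotype(template.reference_counts())
        cut_positions = [p + 1 for p in iupac_find_all(genome, "GCWGC")]
        for hit in find_perfect_ssrs(genome):
            assert any(0 < hit.end - c <= cfg.read_length
                       for c in cut_positions)


class TestSamplePopulation:
    def test_full_inbreeding_all_homozygous(self):
        cfg = tiny_config(groups=(GroupSpec("s", 10, inbreeding=1.0),))
        for gts in sample_population(cfg).values():
            assert all(a == b for a, b in gts)

    def test_single_allele_identical_homozygotes(self):
        cfg = tiny_config(loci=(LocusSpec("AG", {8: 1.0}),))
        for gts in sample_population(cfg).values():
            assert gts == [(8, 8)]

    def test_outbred_heterozygosity_matches_expectation(self):
        cfg = tiny_config(loci=(LocusSpec("AG", {8: 0.5, 10: 0.5}),),
                          groups=(GroupSpec("o", 500, inbreeding=0.0),))
        pop = sample_population(cfg)
        ho = np.mean([a != b for (a, b), in pop.values()])
        # [DERIVED] binomial: p=0.5, n=500 -> se = 0.0224, 3 se bound
        assert abs(ho - 0.5) < 3 * 0.0224

    def test_seeded_reproducibility(self):
        cfg = tiny_config()
        assert sample_population(cfg) == sample_population(cfg)

    def test_he_recovery_at_n200(self):
        cfg = tiny_config(seed=1,
                          loci=(LocusSpec("AG", {8: 0.6, 10: 0.3, 12: 0.1}),),
                          groups=(GroupSpec("o", 200, inbreeding=0.0),))
        pop = sample_population(cfg)
        m = GenotypeMatrix(list(pop), ["L0"],
                           {(a, "L0"): tuple(g[0]) for a, g in pop.items()})
        expected = 1 - (0.6 ** 2 + 0.3 ** 2 + 0.1 ** 2)
        assert abs(locus_stats(m, "L0").he - expected) <= 0.03


class TestDigest:
    def test_fragment_count(self):
        #  two sites -> 3 fragments on a linear template
        genome = "T" * 20 + "GCAGC" + "T" * 20 + "GCTGC" + "T" * 20
        frags = digest(genome)
        assert len(frags) == 3
        assert frags[0] == (0, 21)  # cut one base into the site
        assert frags[1] == (21, 46)

    def test_no_sites_single_fragment(self):
        assert digest("T" * 30) == [(0, 30)]


class TestDigestAndRead:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = tiny_config(error_rate=0.0)
        template = make_genome(cfg)
        pop = sample_population(cfg)
        reads, barcode_map, manifest = digest_and_read(cfg, template, pop)
        assert reads
        bc_by_acc = {acc: bc for bc, acc in barcode_map.items()}
        haplotypes = {
            (acc, h): template.haplotype([g[h] for g in pop[acc]])
            for acc in pop for h in (0, 1)
        }
        for read in reads:
            truth = manifest.reads[read.read_id]
            insert = read.sequence[len(bc_by_acc[truth.accession]):]
            assert insert in haplotypes[(truth.accession, truth.haplotype)]
            assert read.sequence.startswith(bc_by_acc[truth.accession])

    def test_read_length_and_quality(self):
        cfg = tiny_config()
        reads, _, _ = simulate(cfg)
        assert all(len(r) == cfg.read_length for r in reads)
        assert all(set(r.quality) <= {30, 15} for r in reads)

    def test_every_read_in_manifest(self):
        cfg = tiny_config()
        reads, _, manifest = simulate(cfg)
        assert {r.read_id for r in reads} == set(manifest.reads)

    def test_error_rate_within_3_sigma(self):
        cfg = tiny_config(error_rate=0.002,
                          groups=(GroupSpec("g", 10, inbreeding=0.0),))
        template = make_genome(cfg)
        pop = sample_population(cfg)
        reads, barcode_map, manifest = digest_and_read(cfg, template, pop)
        bc_by_acc = {acc: bc for bc, acc in barcode_map.items()}
        haplotypes = {
            (acc, h): template.haplotype([g[h] for g in pop[acc]])
            for acc in pop for h in (0, 1)
        }
        mismatches = bases = 0
        for read in reads:
            truth = manifest.reads[read.read_id]
            bc = bc_by_acc[truth.accession]
            hap = haplotypes[(truth.accession, truth.haplotype)]
            # reconstruct the error-free read from quality (Q15 = error)
            insert = read.sequence[len(bc):]
            bases += len(read)
            mismatches += sum(q == 15 for q in read.quality)
            # Q15 positions really differ from the template
            clean = [c for c, q in zip(read.sequence, read.quality) if q == 30]
            assert len(clean) == len(read) - sum(q == 15 for q in read.quality)
        rate = mismatches / bases
        sigma = np.sqrt(0.002 * 0.998 / bases)
        assert abs(rate - 0.002) < 3 * sigma

    def test_barcodes_pairwise_distant(self, rng):
        bcs = generate_barcodes(rng, 10, 6)
        assert len(set(bcs)) == 10
        for i, a in enumerate(bcs):
            for b in bcs[i + 1:]:
                assert sum(x != y for x, y in zip(a, b)) >= 3

    def test_manifest_round_trip_files(self, tmp_path):
        cfg = tiny_config()
        _, _, manifest = simulate(cfg)
        lp, rp = tmp_path / "loci.tsv", tmp_path / "reads.tsv"
        manifest.write(lp, rp)
        assert len(lp.read_text().splitlines()) == len(manifest.loci) + 1
        assert len(rp.read_text().splitlines()) == len(manifest.reads) + 1
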