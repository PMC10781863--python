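"""Generator contracts: determinism, planted truth, digestion, libraries,
Mendelian behaviour of the simulated F2."""

import math
import numpy as np
import pytest
from scipy import stats

from ddradmap.simdata import (
    Fragment,
    SimConfig,
    all_intercut_intervals,
    build_parent_genomes,
    digest_double,
    revcomp,
    rng_for,
    simulate_cultivar_panel,
    simulate_f2_population,
    simulate_read_pairs,
    write_fastq_pair,
)


def test_zero_divergence_parents_differ_only_at_causal():
    cfg = SimConfig(seed=3, n_chromosomes=1, chromosome_length=50_000,
                    divergence_rate=0.0)
    _, hap_a, hap_b, causal = build_parent_genomes(cfg)
    assert hap_b.variants == []
    assert hap_a.variants == [causal.variant]


def test_seeded_build_is_byte_identical(tmp_path):
    cfg = SimConfig(seed=5, n_chromosomes=1, chromosome_length=40_000)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    build_parent_genomes(cfg, d1)
    build_parent_genomes(cfg, d2)
    for f in ("reference.fa", "parentA.fa", "parentB.fa", "variants_truth.tsv"):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes()


def test_divergence_count_within_binomial_band():
    # binomial oracle: n ~ genome length, p = divergence rate
    cfg = SimConfig(seed=9, n_chromosomes=1, chromosome_length=1_000_000,
                    divergence_rate=0.001)
    _, hap_a, hap_b, causal = build_parent_genomes(cfg)
    n_div = len(hap_a.variants) + len(hap_b.variants) - 1  # minus the causal SNP
    mean = 1_000_000 * 0.001
    sd = math.sqrt(1_000_000 * 0.001 * 0.999)
    assert abs(n_div - mean) <= 3 * sd


def test_causal_gene_invariants(small_parents):
    ref, _, _, causal = small_parents
    g = causal.gene
    cds = ref.seq(g.chrom)[g.cds_start - 1 : g.cds_end]
    assert len(cds) % 3 == 0
    assert cds.startswith("ATG")
    assert cds[-3:] in {"TAA", "TAG", "TGA"}
    # the causal SNP falls in the stop codon
    assert g.cds_end - 2 <= causal.variant.pos <= g.cds_end


class TestDigestDouble:
    def test_no_sites_empty(self):
        assert digest_double([("c", "ACGT" * 30)], "PacI", "NlaIII", (1, 1000)) == []

    def test_toy_fragment_matches_site_scan_oracle(self):
        # 60-bp toy: one PacI site then one downstream NlaIII site
        seq = "G" * 10 + "TTAATTAA" + "A" * 20 + "CATG" + "G" * 18
        frags = digest_double([("c", seq)], "PacI", "NlaIII", (10, 60))
        # oracle: cut offsets from an exhaustive site scan
        cut_a = seq.find("TTAATTAA") + 5  # PacI TTAAT^TAA
        cut_b = seq.find("CATG") + 4  # NlaIII CATG^
        assert frags == [Fragment("c", cut_a + 1, cut_b, "PacI", "NlaIII")]
        assert frags[0].length == cut_b - cut_a

    def test_same_enzyme_both_ends_excluded(self):
        seq = "G" * 10 + "CATG" + "A" * 20 + "CATG" + "G" * 10
        assert digest_double([("c", seq)], "PacI", "NlaIII", (1, 100)) == []

    def test_intercut_intervals_tile_chromosome(self, small_parents):
        ref = small_parents[0]
        name, seq = ref.chromosomes[0]
        ivals = all_intercut_intervals(seq, "PacI", "NlaIII")
        assert ivals[0][0] == 1 and ivals[-1][1] == len(seq)
        for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
            assert s2 == e1 + 1
        assert sum(e - s + 1 for s, e in ivals) == len(seq)


class TestLibrary:
    def test_noise_free_reads_are_fragment_substrings(self):
        cfg = SimConfig(seed=1, error_rate=0.0, coverage=10.0)
        seqs = {"c": "G" * 5 + "TTAATTAA" + ("ACGTT" * 60) + "CATG" + "G" * 5}
        frags = digest_double(list(seqs.items()), "PacI", "NlaIII", (200, 600))
        assert len(frags) == 1
        fs = seqs["c"][frags[0].start - 1 : frags[0].end]
        pairs = list(simulate_read_pairs(frags, seqs, cfg, rng_for(1, "t"), "s"))
        assert pairs
        for _rid, r1, r2 in pairs:
            assert r1 == fs[: cfg.read_length]
            assert revcomp(r2) == fs[-cfg.read_length :]

    def test_pair_count_poisson_band(self, small_parents, small_cfg):
        ref, hap_a, _, _ = small_parents
        seqs = dict(ref.chromosomes)
        frags = digest_double(ref, "PacI", "NlaIII", (200, 600))
        n = sum(1 for _ in simulate_read_pairs(frags, seqs, small_cfg,
                                               rng_for(2, "t"), "s"))
        mean = small_cfg.coverage * len(frags)
        assert abs(n - mean) <= 3 * math.sqrt(mean)

    def test_same_seed_identical_fastq(self, tmp_path):
        cfg = SimConfig(seed=4, n_chromosomes=1, chromosome_length=60_000)
        ref, hap_a, hap_b, _ = build_parent_genomes(cfg)
        seqs = dict(ref.chromosomes)
        frags = digest_double(ref, "PacI", "NlaIII", (200, 600))
        outs = []
        for tag in ("x", "y"):
            p1, p2 = tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq"
            write_fastq_pair(
                simulate_read_pairs(frags, seqs, cfg, rng_for(7, "lib"), "s"), p1, p2
            )
            outs.append(p1.read_bytes() + p2.read_bytes())
        assert outs[0] == outs[1]


class TestF2:
    def test_f1_is_dominant(self, small_parents, small_cfg):
        # an F1 carries one allele from each parent everywhere, hence black
        from ddradmap.simdata import F2Individual, Gamete

        ref, _, _, causal = small_parents
        lengths = {n: len(s) for n, s in ref.chromosomes}
        g_a = Gamete({c: "A" for c in lengths}, {c: np.array([]) for c in lengths})
        g_b = Gamete({c: "B" for c in lengths}, {c: np.array([]) for c in lengths})
        v = causal.variant
        het = str(F2Individual("F1", (g_a, g_b), "?").genotype_at(v.chrom, v.pos))
        assert het == "AB"
        pop = simulate_f2_population(ref, causal, small_cfg)
        for ind in pop:
            if str(ind.genotype_at(v.chrom, v.pos)) == "AB":
                assert ind.phenotype == causal.dominant_phenotype

    def test_no_crossover_constant_within_chromosome(self, small_parents):
        ref, _, _, causal = small_parents
        cfg = SimConfig(seed=6, n_chromosomes=3, chromosome_length=300_000,
                        n_f2=10, crossover_rate=0.0)
        pop = simulate_f2_population(ref, causal, cfg)
        pos = np.array([1000, 100_000, 250_000])
        for ind in pop:
            for chrom, _ in ref.chromosomes:
                assert len(set(ind.genotype_at(chrom, pos).tolist())) == 1

    def test_recessive_class_matches_binomial_oracle(self, small_parents):
        # mean white count over many populations ~ Binomial(96, 1/4)
        ref, _, _, causal = small_parents
        cfg = SimConfig(seed=8, n_chromosomes=3, chromosome_length=300_000, n_f2=96)
        rng = rng_for(8, "reps")
        counts = []
        for _ in range(300):
            pop = simulate_f2_population(ref, causal, cfg, rng=rng)
            counts.append(sum(p.phenotype == "white" for p in pop))
        mc_se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - 96 * 0.25) <= 3 * mc_se

    def test_single_locus_segregates_1_2_1(self, small_parents):
        ref, _, _, causal = small_parents
        cfg = SimConfig(seed=13, n_chromosomes=3, chromosome_length=300_000,
                        n_f2=10_000)
        pop = simulate_f2_population(ref, causal, cfg)
        genos = [str(ind.genotype_at("chr2", 150_000)) for ind in pop]
        obs = [genos.count("AA"), genos.count("AB"), genos.count("BB")]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, [2500, 5000, 2500]))
        assert stats.chi2.sf(chi2, 2) > 0.01

    def test_phenotype_rule_exact(self, small_parents, small_cfg):
        ref, _, _, causal = small_parents
        v = causal.variant
        for ind in simulate_f2_population(ref, causal, small_cfg):
            homo_alt = str(ind.genotype_at(v.chrom, v.pos)) == "AA"
            assert (ind.phenotype == causal.recessive_phenotype) == homo_alt


class TestPanel:
    def test_all_alt_all_recessive(self, small_parents):
        causal = small_parents[3]
        cfg = SimConfig(seed=2, panel_size=10, panel_alt_freq=1.0)
        panel = simulate_cultivar_panel(cfg, causal)
        assert (panel["phenotype"] == "white").all()

    def test_panel_of_84_with_45_alt(self, small_parents):
        causal = small_parents[3]
        cfg = SimConfig(seed=2)  # defaults: 84 cultivars, 45/84 alt
        panel = simulate_cultivar_panel(cfg, causal)
        assert len(panel) == 84
        assert (panel["phenotype"] == "white").sum() == 45

    def test_shuffled_site_discordant_somewhere(self, small_parents):
        causal = small_parents[3]
        cfg = SimConfig(seed=2)
        panel = simulate_cultivar_panel(cfg, causal, extra_sites=[("chr1", 999)])
        causal_col = f"{causal.variant.chrom}:{causal.variant.pos}"
        assert (panel["chr1:999"] != panel[causal_col]).any()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_f2": 0},
        {"divergence_rate": 1.5},
        {"read_length": 300},  # exceeds min retained fragment length
        {"size_min": 700, "size_max": 600, "read_length": 100},
        {"enzyme_a": "NoSuchEnzyme"},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises((ValueError, KeyError)):
        SimConfig(**kwargs)
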