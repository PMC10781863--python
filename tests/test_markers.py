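"""Tag placement, biallelic pairing and presence/absence genotyping."""

import edlib
import numpy as np
import pandas as pd
import pytest

from ddradmap.markers import (
    GenotypeMatrix,
    collapse_cosegregating,
    filter_missing,
    genotype_population,
    pair_biallelic_tags,
    place_tag,
)
from ddradmap.radtags import TagSet, extract_tags, partition_tags
from ddradmap.simdata import (
    SimConfig,
    build_parent_genomes,
    digest_double,
    haplotype_sequences,
    revcomp,
    rng_for,
    simulate_f2_population,
    simulate_read_pairs,
)


def oracle_best_placements(tag, chroms, max_edit):
    """Exhaustive sliding-window alignment oracle, independent of seeding."""
    best = max_edit + 1
    hits = []
    L = len(tag)
    for name, seq in chroms:
        for strand, q in (("+", tag), ("-", revcomp(tag))):
            for off in range(len(seq) - L + 1 + max_edit):
                win = seq[off : off + L]
                if len(win) < L - max_edit:
                    continue
                d = edlib.align(q, win, mode="SHW")["editDistance"]
                if d < best:
                    best, hits = d, [(name, off, strand)]
                elif d == best:
                    hits.append((name, off, strand))
    return best, hits


class TestPlaceTag:
    def test_exact_substring_placed_at_offset(self):
        rng = rng_for(1, "ref")
        from ddradmap.simdata import random_sequence

        seq = random_sequence(rng, 2000)
        tag = seq[500:560]
        p = place_tag(tag, [("c", seq)], max_edit=2)
        assert p is not None
        assert (p.chrom, p.pos, p.strand, p.edit_distance) == ("c", 501, "+", 0)

    def test_one_substitution_matches_oracle(self):
        from ddradmap.simdata import random_sequence

        rng = rng_for(2, "ref")
        seq = random_sequence(rng, 1500)
        tag = list(seq[700:760])
        tag[30] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[30]]
        tag = "".join(tag)
        p = place_tag(tag, [("c", seq)], max_edit=2)
        best, hits = oracle_best_placements(tag, [("c", seq)], 2)
        assert p is not None and p.edit_distance == best == 1
        assert len({(n, s) for n, o, s in hits}) >= 1
        assert p.pos == 701

    def test_reverse_strand_placement(self):
        from ddradmap.simdata import random_sequence

        seq = random_sequence(rng_for(3, "ref"), 1000)
        tag = revcomp(seq[200:260])
        p = place_tag(tag, [("c", seq)], max_edit=1)
        assert p is not None and p.strand == "-" and p.pos == 201

    def test_multimapping_tag_discarded(self):
        from ddradmap.simdata import random_sequence

        core = random_sequence(rng_for(4, "ref"), 80)
        seq = random_sequence(rng_for(5, "x"), 300) + core + \
            random_sequence(rng_for(6, "y"), 300) + core
        assert place_tag(core[:60], [("c", seq)], max_edit=2) is None

    def test_unplaceable_tag_none(self):
        assert place_tag("A" * 40, [("c", "CGCT" * 200)], max_edit=2) is None


class TestPairing:
    def make_placed(self, seq, tags, max_edit=2):
        return [p for t in tags if (p := place_tag(t, [("c", seq)], max_edit))]

    def test_snp_pair_yields_snp_marker(self):
        from ddradmap.simdata import random_sequence

        seq = random_sequence(rng_for(7, "ref"), 2000)
        a = seq[300:400]
        b = a[:50] + {"A": "G", "G": "A", "C": "T", "T": "C"}[a[50]] + a[51:]
        markers = pair_biallelic_tags(
            self.make_placed(seq, [a]), self.make_placed(seq, [b])
        )
        assert len(markers) == 1
        m = markers[0]
        assert m.difference == "SNP" and m.n_edits == 1 and m.pos == 301

    def test_gap_pair_yields_indel_marker(self):
        from ddradmap.simdata import random_sequence

        seq = random_sequence(rng_for(8, "ref"), 2000)
        a = seq[600:700]
        b = a[:40] + a[42:] + seq[700:702]  # 2-bp deletion, same length
        markers = pair_biallelic_tags(
            self.make_placed(seq, [a]), self.make_placed(seq, [b])
        )
        assert len(markers) == 1
        assert markers[0].difference == "InDel"

    def test_unpaired_tag_yields_no_marker(self):
        from ddradmap.simdata import random_sequence

        seq = random_sequence(rng_for(9, "ref"), 3000)
        a = seq[100:200]
        b = seq[2000:2100]
        b = "C" + b[1:]  # ensure it differs from the reference elsewhere
        assert pair_biallelic_tags(
            self.make_placed(seq, [a]), self.make_placed(seq, [b])
        ) == []


def _mk(marker_id="c:1", a="AAAA", b="CCCC"):
    from ddradmap.markers import BiallelicMarker

    return BiallelicMarker(marker_id, "c", 1, a, b, "SNP", 1)


class TestGenotypeTruthTable:
    @pytest.mark.parametrize(
        "count_a,count_b,expected",
        [(2, 2, "AB"), (2, 0, "AA"), (0, 2, "BB"), (0, 0, "NA")],
    )
    def test_truth_table(self, count_a, count_b, expected):
        m = _mk()
        tags = {}
        if count_a:
            tags["AAAA"] = count_a
        if count_b:
            tags["CCCC"] = count_b
        gm = genotype_population({"i1": TagSet("i1", 4, tags)}, [m])
        assert gm.calls.at["c:1", "i1"] == expected

    def test_presence_min_respected(self):
        m = _mk()
        gm = genotype_population(
            {"i1": TagSet("i1", 4, {"AAAA": 1, "CCCC": 5})}, [m], presence_min=2
        )
        assert gm.calls.at["c:1", "i1"] == "BB"

    def test_duplicate_individuals_rejected(self):
        class Dup(dict):
            def keys(self):  # simulate duplicated ids from concatenated inputs
                return ["i1", "i1"]

            def __iter__(self):
                return iter(["i1", "i1"])

        with pytest.raises(ValueError, match="duplicate"):
            genotype_population(Dup(i1=TagSet("i1", 4, {})), [_mk()])


def matrix_from(calls: dict, pos=None, phenotype=None):
    df = pd.DataFrame(calls).T
    df.index.name = "locus"
    loci = pd.DataFrame(
        {
            "chrom": ["c"] * len(df),
            "pos": pos if pos is not None else range(1, len(df) + 1),
        },
        index=df.index,
    )
    ph = pd.Series(phenotype) if phenotype else None
    return GenotypeMatrix(df, loci, ph)


class TestCollapse:
    def test_identical_vectors_merge(self):
        m = matrix_from({"l1": ["AA", "AB"], "l2": ["AA", "AB"], "l3": ["BB", "AB"]})
        c = collapse_cosegregating(m)
        assert c.n_loci == 2
        assert c.collapse_members["l1"] == ["l1", "l2"]

    def test_k_distinct_vectors_k_loci(self):
        # vector-hashing oracle: the number of distinct call tuples
        rng = np.random.default_rng(0)
        calls = {f"l{i}": list(rng.choice(["AA", "AB", "BB"], 4)) for i in range(30)}
        k = len({tuple(v) for v in calls.values()})
        assert collapse_cosegregating(matrix_from(calls)).n_loci == k

    def test_idempotent_and_no_op_when_distinct(self):
        m = matrix_from({"l1": ["AA", "AB"], "l2": ["BB", "AB"]})
        c1 = collapse_cosegregating(m)
        c2 = collapse_cosegregating(c1)
        assert list(c1.calls.index) == list(c2.calls.index) == ["l1", "l2"]


class TestFilterMissing:
    def test_no_missing_unchanged(self):
        m = matrix_from({"l1": ["AA", "AB"]})
        assert filter_missing(m, 0.0).n_loci == 1

    def test_any_missing_dropped_at_zero(self):
        m = matrix_from({"l1": ["AA", "NA"], "l2": ["AA", "AB"]})
        assert list(filter_missing(m, 0.0).calls.index) == ["l2"]

    def test_fraction_threshold(self):
        row4 = ["NA"] * 4 + ["AA"] * 92
        row5 = ["NA"] * 5 + ["AA"] * 91
        m = matrix_from({"l4": row4, "l5": row5})
        kept = filter_missing(m, 0.05)
        assert list(kept.calls.index) == ["l4"]  # 4/96 kept, 5/96 dropped


def test_noise_free_calls_match_simulation_truth(tmp_path):
    """End-to-end genotyping on a noise-free simulation equals planted truth."""
    cfg = SimConfig(seed=21, n_chromosomes=1, chromosome_length=250_000,
                    n_f2=12, error_rate=0.0, coverage=12.0)
    ref, hap_a, hap_b, causal = build_parent_genomes(cfg)
    window = (cfg.size_min, cfg.size_max)

    def tagset(seq_maps, sample):
        from collections import Counter

        counts = Counter()
        for seqs in seq_maps:
            frags = digest_double(list(seqs.items()), cfg.enzyme_a, cfg.enzyme_b, window)
            for _rid, r1, _r2 in simulate_read_pairs(
                frags, seqs, cfg, rng_for(cfg.seed, f"lib:{sample}"), sample
            ):
                counts[r1[: cfg.read_length]] += 1
        return TagSet(sample, cfg.read_length, dict(counts), 1)

    ts_a = tagset([dict(haplotype_sequences(ref, hap_a))], "A")
    ts_b = tagset([dict(haplotype_sequences(ref, hap_b))], "B")
    part = partition_tags(ts_a.threshold(3), ts_b.threshold(3))
    placed_a = [p for t in part.unique_a if (p := place_tag(t, ref))]
    placed_b = [p for t in part.unique_b if (p := place_tag(t, ref))]
    markers = pair_biallelic_tags(placed_a, placed_b)
    assert markers, "simulation produced no biallelic markers"

    from ddradmap.simdata import gamete_sequences

    pop = simulate_f2_population(ref, causal, cfg)
    tagsets = {
        ind.id: tagset(
            [gamete_sequences(g, ref, hap_a, hap_b) for g in ind.gametes], ind.id
        )
        for ind in pop
    }
    gm = genotype_population(tagsets, markers)
    mismatches = checked = 0
    L = cfg.read_length
    for m in markers:
        for ind in pop:
            # a crossover inside the tag footprint makes the tag chimeric;
            # single-point truth does not apply there
            if any(
                ((g.breakpoints[m.chrom] >= m.pos) & (g.breakpoints[m.chrom] < m.pos + L)).any()
                for g in ind.gametes
            ):
                continue
            truth = str(ind.genotype_at(m.chrom, m.pos))
            call = gm.calls.at[m.marker_id, ind.id]
            if call != "NA":
                checked += 1
                if call != truth:
                    mismatches += 1
    assert checked > 0.9 * len(markers) * len(pop)
    assert mismatches == 0
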