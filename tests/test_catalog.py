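"""Conserved identification, families, arm pairs, first-base bias, novel
miRNA prediction."""

import numpy as np
import pytest

from srnakit._seq import revcomp_rna, to_dna
from srnakit.annotate import map_to_genome
from srnakit.catalog import (
    first_base_bias,
    group_families,
    identify_conserved,
    pair_arms,
    predict_novel,
)
from srnakit.fold import get_fold_engine
from srnakit.reads import SmallRNATag
from srnakit.refs import MatureMiRNA, Precursor

MATURE = "UGAGGUAGUAGGUUGUAUAGUU"  # 22 nt


def tag(seq, a=1, b=0):
    return SmallRNATag(seq, a, b)


class TestIdentifyConserved:
    def test_exact_match_zero_mismatches(self):
        records, assigned = identify_conserved([tag(MATURE)], [("mir-x", MATURE)])
        assert assigned[MATURE] == "mir-x"
        assert records[0].count_a == 1

    def test_three_mismatches_unassigned(self):
        mutated = "ACC" + MATURE[3:]  # 3 substitutions vs "UGA"
        _, assigned = identify_conserved([tag(mutated)], [("mir-x", MATURE)])
        assert mutated not in assigned

    def test_mismatch_zero_equals_exact_matching(self):
        rng = np.random.default_rng(3)
        matures = [
            ("m%d" % i, "".join(rng.choice(list("ACGU"), size=22)))
            for i in range(10)
        ]
        tags = [tag(seq) for _, seq in matures[:5]] + [
            tag("".join(rng.choice(list("ACGU"), size=22))) for _ in range(5)
        ]
        _, assigned = identify_conserved(tags, matures, max_mismatch=0)
        exact = {
            t.sequence: mid
            for t in tags
            for mid, seq in matures
            if t.sequence == seq
        }
        assert assigned == exact

    def test_tie_broken_by_lexicographic_id(self):
        # tag equidistant (2 mm) from two matures of equal length
        t = "AAC" + MATURE[3:]
        m1 = "AAA" + MATURE[3:]
        m2 = "CCC" + MATURE[3:]  # both 2 mm from t
        _, assigned = identify_conserved(
            [tag(t)], [("mir-b", m2), ("mir-a", m1)]
        )
        assert assigned[t] == "mir-a"

    def test_three_prime_extension_allowed(self):
        extended = MATURE + "UU"
        _, assigned = identify_conserved([tag(extended)], [("mir-x", MATURE)])
        assert assigned[extended] == "mir-x"

    def test_empty_mature_set_rejected(self):
        with pytest.raises(ValueError):
            identify_conserved([tag(MATURE)], [])


class TestFamilies:
    def test_shared_seed_same_family(self):
        a = ("mir-1", "UGAGGUAGUAGGUUGUAUAGUU")
        b = ("mir-2", "UGAGGUAGCCCCUUGUAUAGUU")  # same positions 2-8
        fams = group_families([a, b])
        assert sorted(fams[a[1][1:8]]) == ["mir-1", "mir-2"]

    def test_partition_property(self):
        rng = np.random.default_rng(9)
        matures = [
            (f"m{i}", "".join(rng.choice(list("ACGU"), size=22)))
            for i in range(30)
        ]
        fams = group_families(matures)
        members = [m for ids in fams.values() for m in ids]
        assert sorted(members) == sorted(m[0] for m in matures)
        assert len(fams) <= len(matures)


class TestPairArms:
    def make(self, count_5p, count_3p):
        prec = Precursor("pre-1", "N" * 80, (5, 27), (50, 72), "5p")
        # build records through identify_conserved for realism
        m5 = MatureMiRNA("mir-1-5p", MATURE, "pre-1", "5p")
        m3 = MatureMiRNA("mir-1-3p", revcomp_rna(MATURE), "pre-1", "3p")
        tags = []
        if count_5p:
            tags.append(tag(m5.sequence, count_5p, 0))
        if count_3p:
            tags.append(tag(m3.sequence, count_3p, 0))
        records, _ = identify_conserved(tags, [m5, m3])
        return records, [prec]

    def test_single_arm_gives_no_pair(self):
        records, precs = self.make(10, 0)
        assert pair_arms(records, precs) == []

    def test_both_arms_pair_with_their_counts(self):
        records, precs = self.make(10, 3)
        pairs = pair_arms(records, precs)
        assert len(pairs) == 1
        r5, r3 = pairs[0]
        assert r5.arm == "5p" and r5.count_a == 10
        assert r3.arm == "3p" and r3.count_a == 3

    def test_simulated_bundle_pairs_every_expressed_precursor(self, small_bundle, small_sim):
        from srnakit.reads import clean_reads, collapse_tags

        ra = clean_reads(small_sim.reads_a, small_sim.config.adapter).reads
        rb = clean_reads(small_sim.reads_b, small_sim.config.adapter).reads
        tags_ = collapse_tags(ra, rb)
        records, _ = identify_conserved(tags_, small_bundle.all_products())
        pairs = pair_arms(records, small_bundle.precursor_set)
        expressed_both = {
            r.precursor_id
            for r in records
            if r.arm == "5p" and r.total > 0
        } & {
            r.precursor_id
            for r in records
            if r.arm == "3p" and r.total > 0
        }
        assert len(pairs) == len(expressed_both)


class TestFirstBaseBias:
    def test_all_u_start(self):
        bias = first_base_bias([tag("U" + "ACG" * 7)])
        assert bias.loc[22, "U"] == 1.0

    def test_rows_sum_to_one(self, small_sim):
        from srnakit.reads import clean_reads, collapse_tags

        ra = clean_reads(small_sim.reads_a, small_sim.config.adapter).reads
        bias = first_base_bias(collapse_tags(ra))
        assert np.allclose(bias.sum(axis=1), 1.0, atol=1e-12)

    def test_generator_five_prime_u_parameter_recovered(self):
        from srnakit.simulate import generate_reference

        bundle = generate_reference(200, 0, rng_seed=7)
        frac = np.mean([m.sequence[0] == "U" for m in bundle.mature_set])
        assert 0.4 <= frac <= 0.6


class TestPredictNovel:
    ENGINE = get_fold_engine("nussinov")  # pinned: dependency-free engine

    def build_genome(self, mature):
        # A/C-only flanks and loop cannot base-pair: the planted stem is
        # the only structure any engine can find
        rng = np.random.default_rng(21)
        left = "".join(rng.choice(list("AC"), size=120))
        right = "".join(rng.choice(list("AC"), size=120))
        hairpin = to_dna(mature) + "CAACAACAA" + to_dna(revcomp_rna(mature))
        genome = {"chr1": left + hairpin + right}
        return genome, 120  # mature start

    def test_planted_hairpin_recovered(self):
        genome, start = self.build_genome(MATURE)
        hits = map_to_genome([MATURE], genome, 0)
        cands = predict_novel(
            hits, genome, self.ENGINE, flank_proximal=15, flank_distal=60
        )
        # the exact-reverse-complement star arm also maps (minus strand),
        # so both arms come back as candidate loci
        by_strand = {c.strand: c for c in cands}
        cand = by_strand["+"]
        assert cand.start == start
        assert cand.mfe <= -18.0
        assert cand.mature_sequence == MATURE

    def test_unstructured_locus_rejected(self):
        # A/C-only region cannot pair at all under any engine
        tag_seq = "ACACACACACACACACACAC"
        genome = {"chr1": "CA" * 100 + to_dna(tag_seq) + "AC" * 100}
        hits = map_to_genome([tag_seq], genome, 0)
        assert hits  # it does map ...
        cands = predict_novel(
            hits, genome, self.ENGINE, flank_proximal=15, flank_distal=60
        )
        assert cands == []  # ... but folds into nothing

    def test_mature_spanning_loop_rejected(self):
        # place the candidate tag across the terminal loop
        stem = "GGCGGCGGCGGCGGCGG"
        loop = "AAUAAUAAU"
        hairpin = stem + loop + revcomp_rna(stem)
        genome = {"chr1": "GT" * 60 + to_dna(hairpin) + "TG" * 60}
        spanning = hairpin[len(stem) - 6 : len(stem) + len(loop) + 6]
        hits = map_to_genome([spanning], genome, 0)
        cands = predict_novel(
            hits, genome, self.ENGINE, flank_proximal=15, flank_distal=60
        )
        assert cands == []

    def test_requires_engine(self):
        with pytest.raises(ValueError):
            predict_novel([], {"chr1": "ACGT"}, None)
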