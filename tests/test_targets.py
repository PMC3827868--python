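"""Duplex alignment, six-criterion filtering, and transcript scanning."""

import numpy as np
import pytest

from srnakit._seq import revcomp_rna
from srnakit.targets import (
    GU_PAIR,
    MISMATCH,
    WC_PAIR,
    AdditiveDuplexEnergy,
    ViennaDuplexEnergy,
    apply_filters,
    duplex_align,
    duplex_mfe,
    perfect_mfe,
    scan_targets,
)

MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"  # 22 nt
ENGINE = AdditiveDuplexEnergy()  # pinned engine: energies are deterministic


def reference_filters(states, mfe, perfect):
    """Independent position-by-position evaluation of the six criteria."""
    mm = [s == MISMATCH for s in states]
    gu = [s == GU_PAIR for s in states]
    L = len(states)
    c1 = sum(mm) + 0.5 * sum(gu) <= 4.0
    longest = cur = 0
    for f in mm:
        cur = cur + 1 if f else 0
        longest = max(longest, cur)
    c2 = longest <= 2
    c3 = True
    for p in range(2, 12):  # adjacent pair (p, p+1), both within 2..12
        if p < L and mm[p - 1] and mm[p]:
            c3 = False
    c4 = not any(mm[p - 1] for p in (10, 11) if p <= L)
    k = min(12, L)
    c5 = sum(mm[:k]) + 0.5 * sum(gu[:k]) <= 2.5
    c6 = perfect < 0 and mfe <= 0.75 * perfect
    return (c1, c2, c3, c4, c5, c6)


def aligned(mirna, site):
    dup = duplex_align(mirna, site)
    dup.perfect_mfe = perfect_mfe(mirna, ENGINE)
    duplex_mfe(dup, ENGINE)
    return dup


def site_with_states(mirna, changes):
    """Perfect-complement site mutated at given miRNA positions (1-based).

    ``changes`` maps position -> 'mm'/'gu'. Site index for miRNA position
    p is len-p (antiparallel).
    """
    site = list(revcomp_rna(mirna))
    L = len(mirna)
    for pos, kind in changes.items():
        m = mirna[pos - 1]
        i = L - pos
        if kind == "gu":
            assert m in "GU"
            site[i] = "U" if m == "G" else "G"
        else:
            site[i] = m  # same base never pairs
    return "".join(site)


class TestDuplexAlign:
    def test_perfect_complement_all_wc(self):
        dup = duplex_align(MIRNA, revcomp_rna(MIRNA))
        assert set(dup.pair_states) == {WC_PAIR}
        assert dup.mismatch_score == 0.0

    def test_single_gu_scores_half(self):
        site = site_with_states(MIRNA, {1: "gu"})
        dup = duplex_align(MIRNA, site)
        assert dup.mismatch_score == 0.5
        assert dup.pair_states[0] == GU_PAIR

    def test_three_gu_two_mismatch_scores_three_point_five(self):
        site = site_with_states(
            MIRNA, {1: "gu", 4: "gu", 8: "gu", 14: "mm", 20: "mm"}
        )
        dup = duplex_align(MIRNA, site)
        assert dup.mismatch_score == 3.5

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            duplex_align("", "ACGU")

    def test_site_length_bounds(self):
        with pytest.raises(ValueError):
            duplex_align(MIRNA, revcomp_rna(MIRNA)[: len(MIRNA) - 6])

    def test_longer_site_best_register(self):
        site = "AAAA" + revcomp_rna(MIRNA) + "CCC"
        dup = duplex_align(MIRNA, site)
        assert dup.mismatch_score == 0.0


class TestEnergies:
    def test_perfect_equals_duplex_on_same_input(self):
        dup = aligned(MIRNA, revcomp_rna(MIRNA))
        assert dup.mfe == dup.perfect_mfe

    def test_all_mismatch_essentially_unbound(self):
        dup = duplex_align("GGGGGGGGGGGGGGGGG", "GGGGGGGGGGGGGGGGG")
        assert ENGINE.energy(dup.mirna_sequence, dup.site_sequence, dup.pair_states) >= -1.0

    def test_appending_wc_pair_never_raises_energy(self):
        states = [WC_PAIR] * 10 + [MISMATCH] * 2
        e1 = ENGINE.energy("x", "y", states)
        e2 = ENGINE.energy("x", "y", states + [WC_PAIR])
        assert e2 <= e1

    def test_vienna_perfect_complement_strongly_bound(self):
        vienna = ViennaDuplexEnergy()
        e = vienna.energy(MIRNA, revcomp_rna(MIRNA), None)
        assert e < -15.0


class TestApplyFilters:
    def test_perfect_complement_passes_all(self):
        report = apply_filters(aligned(MIRNA, revcomp_rna(MIRNA)))
        assert report.passed
        assert report.values["mfe_ratio"] == pytest.approx(1.0)

    def test_position_ten_mismatch_fails_c4(self):
        report = apply_filters(aligned(MIRNA, site_with_states(MIRNA, {10: "mm"})))
        assert not report.c4 and not report.passed

    def test_mfe_ratio_threshold(self):
        dup = aligned(MIRNA, revcomp_rna(MIRNA))
        dup.perfect_mfe = -30.0
        dup.mfe = -20.0
        assert not apply_filters(dup).c6  # 66.7%
        dup.mfe = -25.0
        assert apply_filters(dup).c6  # 83.3%

    def test_adjacent_mismatches_in_seed_fail_c3(self):
        report = apply_filters(
            aligned(MIRNA, site_with_states(MIRNA, {5: "mm", 6: "mm"}))
        )
        assert not report.c3

    def test_matches_reference_implementation_on_random_duplexes(self):
        rng = np.random.default_rng(23)
        bases = list("ACGU")
        for _ in range(2000):
            L = int(rng.integers(19, 24))
            mirna = "".join(rng.choice(bases, size=L))
            # mix of near-complementary and random sites
            if rng.random() < 0.5:
                site = list(revcomp_rna(mirna))
                for _k in range(int(rng.integers(0, 6))):
                    site[int(rng.integers(0, L))] = rng.choice(bases)
                site = "".join(site)
            else:
                site = "".join(rng.choice(bases, size=L))
            dup = aligned(mirna, site)
            report = apply_filters(dup)
            expected = reference_filters(dup.pair_states, dup.mfe, dup.perfect_mfe)
            got = (report.c1, report.c2, report.c3, report.c4, report.c5, report.c6)
            assert got == expected

    def test_adding_mismatch_keeps_c1_c5_failing(self):
        # monotonicity: once the counting criteria fail, more mismatches
        # cannot make them pass
        base_changes = {2: "mm", 4: "mm", 6: "mm", 8: "mm", 13: "mm"}
        dup = aligned(MIRNA, site_with_states(MIRNA, base_changes))
        rep = apply_filters(dup)
        assert not rep.c1 or not rep.c5
        worse = dict(base_changes)
        worse[16] = "mm"
        rep2 = apply_filters(aligned(MIRNA, site_with_states(MIRNA, worse)))
        assert rep2.c1 <= rep.c1 and rep2.c5 <= rep.c5


class TestScanTargets:
    def test_planted_site_found_at_coordinates(self):
        rng = np.random.default_rng(31)
        body = "".join(rng.choice(list("ACGU"), size=400))
        site = revcomp_rna(MIRNA)
        transcript = body[:150] + site + body[150:]
        hits = scan_targets("mir-x", MIRNA, [("t1", transcript)], ENGINE)
        assert len(hits) >= 1
        best = min(hits, key=lambda sr: sr[0].mfe)
        assert best[0].site_start == 150
        assert best[0].site_end == 150 + len(MIRNA)
        assert best[1].passed

    def test_same_site_reported_per_mirna(self):
        site = revcomp_rna(MIRNA)
        transcript = "AAAA" + site + "AAAA"
        h1 = scan_targets("mir-1", MIRNA, [("t", transcript)], ENGINE)
        h2 = scan_targets("mir-2", MIRNA, [("t", transcript)], ENGINE)
        assert len(h1) == len(h2) == 1
        assert h1[0][0].mirna_id == "mir-1" and h2[0][0].mirna_id == "mir-2"

    def test_transcript_length_capped(self):
        with pytest.raises(ValueError):
            scan_targets("m", MIRNA, [("t", "A" * 100_001)], ENGINE)

    def test_overlapping_windows_merged(self):
        # two planted sites far apart stay distinct; overlapping windows
        # around one site collapse to a single record
        site = revcomp_rna(MIRNA)
        transcript = "GGGG" + site + "CCCCCCCCCCCC" + site + "GGGG"
        hits = scan_targets("m", MIRNA, [("t", transcript)], ENGINE)
        starts = sorted(sr[0].site_start for sr in hits)
        assert len(hits) == 2
        assert starts[0] == 4
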