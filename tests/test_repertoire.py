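import numpy as np
import pytest

from niltkit.genestruct import extract_cds
from niltkit.receptor import annotate_receptor
from niltkit.repertoire import (Clone, CloneSet, match_known, screen_positive,
                                summarize_clones)
from niltkit.simulate import simulate_clone_library


def _amplicons(truth, models, locus, genes):
    """Ig-exon nucleotide amplicons of the named intact genes."""
    out = {}
    for gid in genes:
        m = models[gid]
        cds = extract_cds(m, locus)
        start = m.exon_lengths[0]
        out[gid] = cds[start : start + m.exon_lengths[1]]
    return out


@pytest.fixture(scope="module")
def survey(small_truth, small_models):
    locus = small_truth.locus.seq
    genes = ["Ssa-NILT1", "Ssa-NILT5"]
    amp = _amplicons(small_truth, small_models, locus, genes)
    known_aa = [annotate_receptor(small_models[g], locus).region_seq("Ig1")
                for g in genes]
    return amp, known_aa


class TestScreen:
    def test_known_clone_kept(self, survey):
        amp, known_aa = survey
        seq = next(iter(amp.values()))
        kept = screen_positive(CloneSet([Clone("c1", seq, 1)]), known_aa)
        assert len(kept) == 1

    def test_random_sequence_discarded(self, survey):
        amp, known_aa = survey
        rng = np.random.default_rng(0)
        # random stop-free coding sequence of the same length
        codons = [c for c in
                  ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
                  if c not in ("TAA", "TAG", "TGA")]
        seq = "".join(rng.choice(codons, size=len(next(iter(amp.values()))) // 3))
        kept = screen_positive(CloneSet([Clone("r", seq, 1)]), known_aa)
        assert len(kept) == 0

    def test_empty_clone_set(self, survey):
        _, known_aa = survey
        assert len(screen_positive(CloneSet([]), known_aa)) == 0

    def test_untranslatable_clone_excluded_with_warning(self, survey):
        _, known_aa = survey
        # a stop codon in each forward frame
        seq = "TTAATTAATTAA"
        with pytest.warns(UserWarning, match="untranslatable"):
            kept = screen_positive(CloneSet([Clone("x", seq, 1)]), known_aa)
        assert len(kept) == 0

    def test_empty_known_set_rejected(self):
        with pytest.raises(ValueError, match="known"):
            screen_positive(CloneSet([]), [])


class TestSummarize:
    def test_retention_rule_and_aa_singletons(self):
        # A x4, B x3 retained; C,D,E singletons; E synonymous with C
        a = "ATGGCTAAAGAA"
        b = "ATGGCTAAAGAG"  # distinct nt, seen 3x
        c = "ATGTGTAAAGAA"
        d = "ATGGGGAAAGAA"
        e = "ATGTGCAAAGAA"  # synonymous with c (TGT->TGC, both Cys)
        clones = [Clone(f"a{i}", a, 1) for i in range(4)]
        clones += [Clone(f"b{i}", b, 1) for i in range(3)]
        clones += [Clone("c", c, 2), Clone("d", d, 2), Clone("e", e, 2)]
        summ = summarize_clones(CloneSet(clones))
        assert set(summ.retained) == {a, b}
        assert summ.retained == {a: 4, b: 3}
        assert summ.singleton_support == 3
        assert summ.singletons_aa == 2

    def test_all_identical(self):
        summ = summarize_clones(CloneSet([Clone(f"c{i}", "ATGGCT", 1)
                                          for i in range(5)]))
        assert len(summ.retained) == 1 and summ.singletons_aa == 0

    def test_conservation_invariant(self, survey):
        amp, known_aa = survey
        clones, _ = simulate_clone_library(amp, error_rate=0.01, seed=21)
        summ = summarize_clones(screen_positive(clones, known_aa))
        assert sum(summ.retained.values()) + summ.singleton_support == summ.n_positive


class TestMatchKnown:
    def test_exact_match_assigns_gene(self, survey):
        amp, _ = survey
        seq = amp["Ssa-NILT5"]
        summ = summarize_clones(CloneSet([Clone("1", seq, 1), Clone("2", seq, 2)]))
        assert match_known(summ, amp) == {seq: "Ssa-NILT5"}

    def test_one_mismatch_is_novel(self, survey):
        amp, _ = survey
        seq = amp["Ssa-NILT1"]
        mutated = ("C" if seq[50] != "C" else "G").join([seq[:50], seq[51:]])
        summ = summarize_clones(CloneSet([Clone("1", mutated, 1),
                                          Clone("2", mutated, 2)]))
        (label,) = match_known(summ, amp).values()
        assert label.startswith("novel")

    def test_novel_sequences_are_group_classified(self, survey):
        from Bio.Seq import Seq

        amp, _ = survey
        # synonymous recoding: same protein (group intact), different nt.
        # the Ig exon starts at CDS phase 1, so in-frame codons of the
        # amplicon begin at offset 2; recode one far from the diagnostics.
        seq = amp["Ssa-NILT1"]
        swapped = None
        for off in range(302, 332, 3):
            codon = seq[off : off + 3]
            for alt in ("GCA", "GCC", "GGA", "GGC", "AAA", "AAG", "GAA", "GAG"):
                if alt != codon and Seq(alt).translate() == Seq(codon).translate():
                    swapped = seq[:off] + alt + seq[off + 3 :]
                    break
            if swapped:
                break
        assert swapped is not None
        summ = summarize_clones(CloneSet([Clone("1", swapped, 1),
                                          Clone("2", swapped, 2)]))
        (label,) = match_known(summ, amp).values()
        assert label == "novel (group 1)"

    def test_empty_known_set_all_novel(self):
        summ = summarize_clones(CloneSet([Clone("1", "ATGGCT", 1),
                                          Clone("2", "ATGGCT", 2)]))
        (label,) = match_known(summ, {}).values()
        assert label.startswith("novel")

    def test_ambiguous_match_rejected(self):
        summ = summarize_clones(CloneSet([Clone("1", "ATGGCT", 1),
                                          Clone("2", "ATGGCT", 2)]))
        with pytest.raises(ValueError, match="multiple"):
            match_known(summ, {"g1": "ATGGCT", "g2": "ATGGCT"})


class TestCloneLibrary:
    def test_zero_error_clones_equal_templates(self, survey):
        amp, _ = survey
        clones, truth = simulate_clone_library(amp, error_rate=0.0, seed=8)
        for clone in clones.clones:
            assert clone.seq == amp[truth["clones"][clone.id]["template"]]
        assert truth["total_errors"] == 0

    def test_replicate_layout(self, survey):
        amp, _ = survey
        clones, _ = simulate_clone_library(amp, n_pcr=10, clones_per_pcr=10,
                                           error_rate=0.0, seed=1)
        assert len(clones) == 100
        reps = [c.replicate for c in clones.clones]
        assert sorted(set(reps)) == list(range(1, 11))
        assert all(reps.count(r) == 10 for r in range(1, 11))

    def test_error_tally_matches_truth(self, survey):
        amp, _ = survey
        clones, truth = simulate_clone_library(amp, error_rate=0.01, seed=4)
        observed = 0
        for clone in clones.clones:
            template = amp[truth["clones"][clone.id]["template"]]
            diff = sum(a != b for a, b in zip(clone.seq, template))
            assert diff == truth["clones"][clone.id]["n_errors"]
            observed += diff
        assert observed == truth["total_errors"]

    def test_zero_error_summary_matches_truth(self, survey):
        amp, known_aa = survey
        clones, truth = simulate_clone_library(amp, error_rate=0.0, seed=15)
        summ = summarize_clones(screen_positive(clones, known_aa))
        expected = {amp[n]: k for n, k in truth["multiplicities"].items() if k >= 2}
        assert summ.retained == expected
        if all(k != 1 for k in truth["multiplicities"].values()):
            assert summ.singletons_aa == 0

    def test_singletons_monotone_in_error_rate(self, survey):
        amp, known_aa = survey
        means = []
        for rate in (0.0, 0.004, 0.02):
            counts = []
            for seed in range(4):
                clones, _ = simulate_clone_library(amp, error_rate=rate, seed=seed)
                summ = summarize_clones(screen_positive(clones, known_aa))
                counts.append(summ.singletons_aa)
            means.append(np.mean(counts))
        assert means[0] <= means[1] <= means[2]

    def test_empty_template_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_clone_library({})
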