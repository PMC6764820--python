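"""IDR sequence analytics: runs, composition, pI, complexity, CDK motifs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repliphase.seqfeat import (
    DisorderProfile,
    Interval,
    SequenceRecord,
    cdk_site_scan,
    class_composition,
    feature_table,
    fraction_charged,
    gc_content,
    idr_from_scores,
    isoelectric_point,
    local_complexity,
    net_charge,
    reverse_complement,
    window_complexity,
)


def P(s, id="seq"):
    return SequenceRecord(id=id, residues=s, molecule="protein")


def D(s, id="seq"):
    return SequenceRecord(id=id, residues=s, molecule="dna")


# -- IDR extraction -----------------------------------------------------------

class TestIdrFromScores:
    def test_longest_run_returned(self):
        prof = DisorderProfile([0.9] * 10 + [0.1] * 5 + [0.9] * 3)
        assert idr_from_scores(prof) == Interval(1, 10)

    def test_tie_breaks_to_earliest(self):
        prof = DisorderProfile([0.2, 0.8, 0.8, 0.2, 0.9, 0.9, 0.2])
        assert idr_from_scores(prof) == Interval(2, 3)

    def test_no_disorder_returns_none(self):
        assert idr_from_scores(DisorderProfile([0.1, 0.2, 0.3])) is None

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_quadratic_enumeration(self, scores):
        """Brute force: score every (start, end) window that is entirely
        above the cutoff; the longest (earliest on ties) must match."""
        prof = DisorderProfile(scores)
        best = None
        for i in range(len(scores)):
            for j in range(i, len(scores)):
                if all(s > 0.5 for s in scores[i:j + 1]):
                    if best is None or (j - i + 1) > (best[1] - best[0] + 1):
                        best = (i + 1, j + 1)
        got = idr_from_scores(prof)
        if best is None:
            assert got is None
        else:
            assert (got.start, got.end) == best


# -- composition --------------------------------------------------------------

class TestComposition:
    def test_pure_classes(self):
        assert class_composition(P("FWY"))["aromatic"] == 1.0
        assert class_composition(P("DEHKR"))["charged"] == 1.0

    def test_fractions_sum_to_one(self):
        from repliphase.simulate import random_sequence

        rec = random_sequence(10_000, seed=3)
        comp = class_composition(rec)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_letter_tally(self):
        from repliphase.simulate import random_sequence
        from repliphase.seqfeat import AA_CLASSES

        rec = random_sequence(10_000, seed=4)
        comp = class_composition(rec)
        for name, members in AA_CLASSES.items():
            tally = sum(1 for ch in rec.residues if ch in members)
            assert comp[name] == tally / len(rec)

    def test_fcr_examples(self):
        assert fraction_charged(P("DEKR")) == 1.0
        assert fraction_charged(P("GGGG")) == 0.0
        # H counts as charged-class but is excluded from FCR
        assert fraction_charged(P("DHKG")) == 0.5

    def test_fcr_never_exceeds_charged_class(self):
        from repliphase.simulate import random_sequence

        rec = random_sequence(5000, seed=5)
        assert fraction_charged(rec) <= class_composition(rec)["charged"]

    def test_dna_rejected(self):
        with pytest.raises(ValueError):
            class_composition(D("ACGT"))


# -- isoelectric point --------------------------------------------------------

class TestIsoelectricPoint:
    def test_basic_and_acidic_bounds(self):
        assert isoelectric_point(P("K" * 20)) > 10
        assert isoelectric_point(P("D" * 20)) < 5

    def test_matches_fine_grid_scan(self):
        """Independent oracle: dense pH scan of the same charge model."""
        seq = "ACDEFGHIKLMNPQRSTVWY"
        grid = np.arange(0.0, 14.0, 1e-5)
        q = np.abs([net_charge(seq, ph) for ph in grid[::10]])
        coarse = grid[::10][np.argmin(q)]
        fine = np.arange(coarse - 1e-3, coarse + 1e-3, 1e-5)
        oracle = fine[np.argmin(np.abs([net_charge(seq, ph) for ph in fine]))]
        assert isoelectric_point(P(seq)) == pytest.approx(oracle, abs=1e-3)

    def test_agrees_with_independent_implementation(self):
        """Cross-check against Biopython's Bjellqvist-style pI on mixed
        sequences (different pKa table, so a coarse tolerance)."""
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        for seq in ("ACDEFGHIKLMNPQRSTVWY", "KRKRNSTQSPAKDEGGILMV" * 5,
                    "MKKRSSTPAKRQNDEHHVLI" * 3):
            assert isoelectric_point(P(seq)) == pytest.approx(
                IsoelectricPoint(seq).pi(), abs=0.3)

    def test_monotone_in_appended_charge(self):
        base = "ACDEFGHIKLMNPQRSTVWY"
        pi0 = isoelectric_point(P(base))
        assert isoelectric_point(P(base + "R")) > pi0
        assert isoelectric_point(P(base + "D")) < pi0


# -- compositional complexity -------------------------------------------------

class TestComplexity:
    def test_homopolymer_window_is_zero(self):
        assert window_complexity("A" * 20) == 0.0

    def test_all_distinct_closed_form(self):
        k = window_complexity("ACDEFGHIKLMNPQRSTVWY")
        assert k == pytest.approx(math.log(math.factorial(20))
                                  / (20 * math.log(20)))

    def test_matches_exact_factorial_oracle(self):
        from fractions import Fraction

        from repliphase.simulate import random_sequence

        rng_seqs = [random_sequence(20, seed=s).residues for s in range(20)]
        for s in rng_seqs:
            counts = [s.count(ch) for ch in set(s)]
            exact = Fraction(math.factorial(20),
                             math.prod(math.factorial(c) for c in counts))
            oracle = math.log(exact) / (20 * math.log(20))
            assert window_complexity(s) == pytest.approx(oracle, abs=1e-12)

    def test_relabeling_invariance(self):
        assert window_complexity("AALLLKKKKKSSSSSSTTTT") == pytest.approx(
            window_complexity("GGRRRYYYYYDDDDDDWWWW"))

    def test_center_assignment_and_edges(self):
        rec = P("A" * 10 + "ACDEFGHIKLMNPQRSTVWY" + "A" * 10)
        prof = local_complexity(rec, window=20)
        assert np.isnan(prof.scores[:10]).all()
        assert np.isnan(prof.scores[-9:]).all()
        assert prof.scores[10 + 10] == window_complexity(rec.residues[10:30])

    def test_summary_by_disorder(self):
        rec = P("A" * 40 + "ACDEFGHIKLMNPQRSTVWY" * 2)
        prof = local_complexity(rec)
        dis = DisorderProfile([0.9] * 40 + [0.1] * 40)
        s = prof.summary_by_disorder(dis)
        assert s["disordered_mean"] < s["ordered_mean"]

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_complexity(P("ACDEF"), window=20)


# -- CDK consensus scanning ---------------------------------------------------

class TestCdkScan:
    @pytest.mark.parametrize("seq,minimal,full", [
        ("SPAK", [1], [1]),
        ("TPGD", [1], []),
        ("SPSPKR", [1, 3], [3]),
    ])
    def test_examples(self, seq, minimal, full):
        hits = cdk_site_scan(P(seq))
        assert hits.minimal == minimal
        assert hits.full == full

    def test_matches_window_check(self):
        from repliphase.simulate import random_sequence

        rec = random_sequence(2000, seed=6)
        s = rec.residues
        minimal = [i + 1 for i in range(len(s) - 1)
                   if s[i] in "ST" and s[i + 1] == "P"]
        full = [i + 1 for i in range(len(s) - 3)
                if s[i] in "ST" and s[i + 1] == "P" and s[i + 3] in "KR"]
        hits = cdk_site_scan(rec)
        assert hits.minimal == minimal
        assert hits.full == full

    def test_full_subset_of_minimal_and_interval_monotone(self):
        from repliphase.simulate import random_sequence

        rec = random_sequence(500, seed=7)
        hits = cdk_site_scan(rec)
        assert set(hits.full) <= set(hits.minimal)
        narrow = cdk_site_scan(rec, Interval(100, 200))
        wide = cdk_site_scan(rec, Interval(50, 300))
        assert narrow.n_minimal <= wide.n_minimal
        assert narrow.n_full <= wide.n_full


# -- DNA utilities ------------------------------------------------------------

class TestGcContent:
    def test_extremes(self):
        assert gc_content(D("GCGC")) == 1.0
        assert gc_content(D("ATAT")) == 0.0

    def test_reverse_complement_preserves_gc(self):
        from repliphase.simulate import random_sequence

        rec = random_sequence(300, alphabet="dna", seed=8)
        assert gc_content(rec) == pytest.approx(gc_content(reverse_complement(rec)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content(D(""))


# -- feature tables -----------------------------------------------------------

class TestFeatureTable:
    def test_explicit_interval_used_verbatim(self):
        rec = P("K" * 50 + "A" * 50, id="basic")
        table = feature_table([rec], intervals={"basic": Interval(1, 50)})
        row = table.iloc[0]
        assert (row.idr_start, row.idr_end, row.idr_length) == (1, 50, 50)

    def test_empty_idr_gives_null_row(self):
        rec = P("ACDEFGHIKLMNPQRSTVWY", id="ordered")
        table = feature_table(
            [rec], disorder={"ordered": DisorderProfile([0.1] * 20)})
        assert table.iloc[0].idr_start is None

    def test_synthetic_basic_idr_features(self):
        """A construct with 70% K/R in its first 100 residues: basic pI
        and high FCR in the IDR row."""
        rng = np.random.default_rng(9)
        idr = "".join(rng.choice(list("KR")) if rng.random() < 0.7
                      else rng.choice(list("AGSTNQ")) for _ in range(100))
        rec = P(idr + "ACDEFGHILMNPQVWY" * 20, id="basic_idr")
        profile = DisorderProfile([0.9] * 100 + [0.1] * 320)
        table = feature_table([rec], disorder={"basic_idr": profile})
        row = table.iloc[0]
        assert (row.idr_start, row.idr_end) == (1, 100)
        assert row.pI > 9
        assert row.FCR >= 0.3
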