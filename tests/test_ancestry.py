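"""Diagnostic-index construction, read assignment, inclusion rules, and
the Welch concordance test, each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridscan import ancestry, simulate
from hybridscan._encoding import revcomp
from hybridscan.ancestry import (
    AMBIGUOUS,
    UNASSIGNED,
    ContributionProfile,
    build_diagnostic_index,
    inclusion_filter,
    mito_majority,
    species_contributions,
    welch_t,
)


def enumerate_diagnostic(seq1, seq2, k):
    """Brute-force oracle: canonical k-mer sets via python string ops."""
    def canon_set(seq):
        out = set()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            out.add(min(w, revcomp(w)))
        return out

    a, b = canon_set(seq1), canon_set(seq2)
    return a - b, b - a, a & b


class TestDiagnosticIndex:
    def test_identical_parents_have_no_diagnostics(self):
        p1, p2 = simulate.generate_parent_pair([5000], 0.0, mito_length=1000, seed=1)
        idx = build_diagnostic_index([p1, p2], 17)
        assert idx.n_diagnostic == 0
        assert idx.ambiguous_count > 0

    def test_diagnostic_fraction_matches_analytic_rate(self):
        # P(a k-mer overlaps >=1 substitution) = 1 - (1-d)^k ~ 0.83 at d=0.10
        p1, p2 = simulate.generate_parent_pair([100_000], 0.10, seed=2)
        idx = build_diagnostic_index([p1, p2], 17)
        per_species = np.bincount(idx.label_idx, minlength=2)
        distinct_sp1 = len(
            {min(p1.chromosomes[0][1][i : i + 17],
                 revcomp(p1.chromosomes[0][1][i : i + 17]))
             for i in range(0, 100_000 - 16)})
        frac = per_species[0] / distinct_sp1
        assert abs(frac - (1 - 0.9**17)) < 0.05

    def test_single_substitution_toy_matches_enumeration(self):
        rng = np.random.default_rng(3)
        seq1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        seq2 = seq1[:30] + ("A" if seq1[30] != "A" else "C") + seq1[31:]
        p1 = simulate.ParentGenome("a", [("c1", seq1)], [("cladeA", seq1[:20])])
        p2 = simulate.ParentGenome("b", [("c1", seq2)], [("cladeA", seq1[:20])])
        idx = build_diagnostic_index([p1, p2], 17)
        only1, only2, shared = enumerate_diagnostic(seq1, seq2, 17)
        assert idx.n_diagnostic == len(only1) + len(only2)
        assert idx.ambiguous_count == len(shared)

    def test_chromosome_shorter_than_k_rejected(self):
        p1 = simulate.ParentGenome("a", [("c1", "ACGTACGT")], [("cladeA", "ACG")])
        p2 = simulate.ParentGenome("b", [("c1", "TTGTACGA")], [("cladeA", "ACG")])
        with pytest.raises(ValueError):
            build_diagnostic_index([p1, p2], 17)

    @pytest.mark.parametrize("k", [16, 9, 33])
    def test_invalid_k_rejected(self, k, parent_pair):
        with pytest.raises(ValueError):
            build_diagnostic_index(list(parent_pair), k)


class TestAssignment:
    def test_unique_region_read_assigned(self, parent_pair, nuclear_index):
        p1, _p2 = parent_pair
        seq = p1.sequence("chr01")[1000:1100]
        reads = simulate.ReadSet(["r|sp1|chr01|1000|+"], [seq], 100, 0.0)
        table = ancestry.assign_reads(reads, nuclear_index)
        row = table.iloc[0]
        assert row["species"] == "sp1"
        assert row["chromosome"] == "chr01"
        assert row["position"] == 1000

    def test_reverse_complement_read_placed_identically(self, parent_pair, nuclear_index):
        p1, _ = parent_pair
        seq = revcomp(p1.sequence("chr02")[5000:5100])
        table = ancestry.assign_reads(
            simulate.ReadSet(["r|sp1|chr02|5000|-"], [seq], 100, 0.0), nuclear_index)
        assert table.iloc[0]["species"] == "sp1"
        assert table.iloc[0]["position"] == 5000
        assert table.iloc[0]["strand"] == "-"

    def test_balanced_hit_counts_are_ambiguous(self):
        # unrelated random parents: every k-mer diagnostic, so a half-and-half
        # chimeric read collects exactly equal hit counts
        rng = np.random.default_rng(9)
        mk = lambda: "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        p1 = simulate.ParentGenome("a", [("c1", mk())], [("cladeA", "ACGT" * 10)])
        p2 = simulate.ParentGenome("b", [("c1", mk())], [("cladeA", "TGCA" * 10)])
        idx = build_diagnostic_index([p1, p2], 17)
        a, b = p1.sequence("c1"), p2.sequence("c1")
        # flanking bases must differ so chimeric boundary k-mers cannot
        # coincidentally extend either genome's k-mers
        s2 = next(s for s in range(600, 1900)
                  if b[s] != a[150] and a[149] != b[s - 1])
        half = a[100:150] + b[s2 : s2 + 50]
        table = ancestry.assign_reads(
            simulate.ReadSet(["r|x|x|0|+"], [half], 100, 0.0), idx,
            min_hits=2, min_margin=1)
        assert table.iloc[0]["species"] == AMBIGUOUS
        assert table.iloc[0]["margin"] == 0

    def test_short_read_unassigned(self, nuclear_index):
        table = ancestry.assign_reads(
            simulate.ReadSet(["r|x|x|0|+"], ["ACGTACGT"], 8, 0.0), nuclear_index)
        assert table.iloc[0]["species"] == UNASSIGNED

    def test_recovery_on_simulated_cohort(self, parent_pair, nuclear_index, balanced_sample):
        truth, reads = balanced_sample
        table = ancestry.assign_reads(reads, nuclear_index)
        origin = [simulate.parse_read_name(n) for n in reads.names]
        df = table.assign(true_sp=[o[1] for o in origin],
                          true_chrom=[o[2] for o in origin])
        nuc = df[df["true_chrom"] != simulate.MITO]
        assigned = nuc[~nuc["species"].isin([AMBIGUOUS, UNASSIGNED])]
        assert len(assigned) / len(nuc) >= 0.95
        assert (assigned["species"] == assigned["true_sp"]).mean() >= 0.99

    def test_pure_parent_reads_specific(self, parent_pair, nuclear_index, balanced_sample):
        _truth, reads = balanced_sample
        origin = [simulate.parse_read_name(n) for n in reads.names]
        keep = [i for i, o in enumerate(origin) if o[1] == "sp1" and o[2] != simulate.MITO]
        pure = simulate.ReadSet([reads.names[i] for i in keep],
                                [reads.seqs[i] for i in keep], reads.read_length, 0.001)
        table = ancestry.assign_reads(pure, nuclear_index)
        assigned = table[~table["species"].isin([AMBIGUOUS, UNASSIGNED])]
        assert (assigned["species"] == "sp1").mean() >= 0.99

    def test_assignment_rate_rises_with_divergence(self):
        rates = []
        for div in (0.01, 0.05, 0.20):
            p1, p2 = simulate.generate_parent_pair([30_000], div, seed=20)
            idx = build_diagnostic_index([p1, p2], 17)
            truth = simulate.generate_hybrid((p1, p2), 0.5, sample_id="m", seed=21)
            reads = simulate.simulate_reads(truth, (p1, p2), 5.0, 30, 0.001,
                                            seed=22, mito_ratio=0.0)
            table = ancestry.assign_reads(reads, idx)
            rates.append((~table["species"].isin([AMBIGUOUS, UNASSIGNED])).mean())
        assert rates[0] <= rates[1] <= rates[2]

    def test_fraction_closure(self, nuclear_index, balanced_sample):
        _truth, reads = balanced_sample
        table = ancestry.assign_reads(reads, nuclear_index)
        fr, amb, un = species_contributions(table)
        assert abs(sum(fr.values()) + amb + un - 1.0) < 1e-9


class TestContributions:
    def test_fraction_arithmetic(self):
        table = pd.DataFrame({"species": ["sp1"] * 60 + ["sp2"] * 30 + [UNASSIGNED] * 10})
        fr, amb, un = species_contributions(table)
        assert fr == {"sp1": 0.60, "sp2": 0.30}
        assert amb == 0.0 and un == 0.10

    def test_all_unassigned_flagged(self):
        table = pd.DataFrame({"species": [UNASSIGNED] * 5})
        fr, _amb, un = species_contributions(table)
        assert fr == {} and un == 1.0

    def test_skewed_contribution_recovery(self, parent_pair, nuclear_index, mito_index):
        truth = simulate.generate_hybrid(parent_pair, 0.7, sample_id="c", seed=31)
        reads = simulate.simulate_reads(truth, parent_pair, 20.0, seed=32)
        prof = ancestry.compute_profile("c", reads, nuclear_index, mito_index)
        est = prof.nuclear_fraction["sp1"] / sum(prof.nuclear_fraction.values())
        assert abs(est - 0.7) <= 0.05


class TestInclusionFilter:
    def _profile(self, fractions, unassigned):
        return ContributionProfile(
            sample_id="s", nuclear_fraction=fractions, mito_fraction={},
            ambiguous=0.0, unassigned=unassigned,
            majority_nuclear=max(fractions, key=fractions.get) if fractions else None,
            majority_mito=None, majority_mito_clade=None, concordant=None)

    def test_two_parent_high_assignment_included(self):
        dec = inclusion_filter(self._profile({"a": 0.55, "b": 0.35}, 0.10))
        assert dec.include and dec.parents == ["a", "b"]

    def test_low_assignment_excluded(self):
        dec = inclusion_filter(self._profile({"a": 0.5, "b": 0.3}, 0.20))
        assert not dec.include and dec.reason == "low assignment"

    def test_three_parent_excluded(self):
        dec = inclusion_filter(self._profile({"a": 0.45, "b": 0.35, "c": 0.15}, 0.05))
        assert not dec.include and dec.reason == "not two-parent"

    def test_minor_introgression_below_floor_still_two_parent(self):
        dec = inclusion_filter(self._profile({"a": 0.60, "b": 0.36, "c": 0.04}, 0.0))
        assert dec.include and dec.parents == ["a", "b"]


class TestMito:
    def test_max_over_clades_rule(self):
        fractions = {("Seub", "holarctic"): 0.90, ("Seub", "PatB"): 0.05,
                     ("Scer", "cladeA"): 0.05}
        major, clade = mito_majority(fractions)
        assert (major, clade) == ("Seub", "holarctic")

    def test_tie_undefined(self):
        assert mito_majority({("a", "x"): 0.5, ("b", "y"): 0.5}) == (None, None)

    def test_zero_fractions_undefined(self):
        assert mito_majority({("a", "x"): 0.0}) == (None, None)

    def test_homoplasmic_donor_recovered(self, parent_pair, nuclear_index, mito_index):
        donor = parent_pair[1]
        truth = simulate.generate_hybrid(
            parent_pair, 0.5, mito_donor=(donor.species_id, donor.mito[1][0]),
            sample_id="m", seed=41)
        reads = simulate.simulate_reads(truth, parent_pair, 10.0, seed=42)
        prof = ancestry.compute_profile("m", reads, nuclear_index, mito_index)
        assert prof.majority_mito == donor.species_id
        assert prof.majority_mito_clade == donor.mito[1][0]
        assert prof.concordant is False or prof.majority_nuclear == donor.species_id


class TestWelch:
    def test_hand_computed_example(self):
        res = welch_t([1, 2, 3], [2, 4, 6, 8])
        assert res.t == pytest.approx(-3 / np.sqrt(2), abs=1e-9)
        assert res.df == pytest.approx(4.0754717, abs=1e-6)

    def test_matches_scipy_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 12))
            b = rng.normal(0.5, 2, rng.integers(2, 12))
            res = welch_t(a, b)
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(t_ref, abs=1e-9)
            assert res.p == pytest.approx(p_ref, abs=1e-9)

    def test_single_member_group_not_testable(self):
        res = welch_t([1.0], [2.0, 3.0])
        assert not res.testable

    def test_identical_groups_t_zero(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
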