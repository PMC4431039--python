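"""Gene-dropping and segment-dropping simulation calibration."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

import pedkit as pk
from pedkit.genedrop import (
    SegmentModel,
    TransmissionModel,
    allele_frequencies,
    classify_ancestor,
    drop_alleles,
    drop_segment,
    genotype_probs,
    ibd_sharing_prob,
)
from pedkit.demogenetics import genetic_contribution
from pedkit.pedigree import PedigreeError

from conftest import random_genealogies
from oracles import genedrop_exact, ibd_sharing_exact

N = 100_000

# Unit tests make dozens of Monte-Carlo comparisons; alpha = 1e-4 per check
# keeps the familywise false-alarm rate negligible while still catching any
# real miscalibration (a biased engine fails by many sigma).
CAL_Z = float(stats.norm.ppf(1 - 5e-5))


def binom_ci99(p: float, n: int, z: float = CAL_Z) -> tuple[float, float]:
    if p in (0.0, 1.0):
        return p, p
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


def single_sided_descent(g, ancestor: int, subject: int) -> bool:
    """True when at most one of the subject's parents descends from the
    ancestor, so the subject can never carry two copies of a single seeded
    allele and P(carry >= 1) = GC exactly.  (Collapse higher up the descent
    is harmless: a homozygous intermediate transmits with certainty, which
    exactly preserves the per-gamete expectation.)  The MRCA product
    identity requires this for both subjects."""
    desc = g.descendants(ancestor, include_self=True)
    return sum(1 for p in g.known_parents(subject) if p in desc) <= 1


class TestDropAlleles:
    def test_het_founder_child_half(self, trio):
        res = drop_alleles(trio, {1: 1}, [3], N, seed=1)
        p = float(np.mean(res.column(3) >= 1))
        lo, hi = binom_ci99(0.5, N)
        assert lo <= p <= hi

    def test_hom_founder_noncarrier_child_one_copy_exactly(self, trio):
        res = drop_alleles(trio, {1: 2}, [3], 5_000, seed=2)
        assert (res.column(3) == 1).all()

    def test_x_linked_like_blocks_father_son(self, trio):
        model = TransmissionModel({(1, 1): 0.0})
        res = drop_alleles(trio, {1: 1}, [3], 5_000, seed=3, model=model)
        assert (res.column(3) == 0).all()  # proband 3 is male

    def test_seed_reproducibility_and_thread_invariance(self, first_cousins):
        a = drop_alleles(first_cousins, {1: 1}, [7, 8], 70_000, seed=9)
        b = drop_alleles(first_cousins, {1: 1}, [7, 8], 70_000, seed=9)
        c = drop_alleles(first_cousins, {1: 1}, [7, 8], 70_000, seed=9, threads=3)
        assert (a.counts == b.counts).all()
        assert (a.counts == c.counts).all()
        d = drop_alleles(first_cousins, {1: 1}, [7, 8], 70_000, seed=10)
        assert not (a.counts == d.counts).all()

    def test_invalid_copies_rejected(self, trio):
        with pytest.raises(PedigreeError):
            drop_alleles(trio, {1: 3}, [3], 10)


class TestGenotypeProbs:
    def test_probabilities_sum_to_one(self, first_cousins):
        res = drop_alleles(first_cousins, {1: 1, 2: 2}, [7, 8, 9], 20_000, seed=4)
        gp = genotype_probs(res)
        sums = gp.groupby("id")["prob"].sum()
        assert np.allclose(sums, 1.0)

    def test_matches_exhaustive_enumeration(self):
        """Simulated genotype distributions sit inside 99% binomial CIs of the
        exact transmission enumeration on a 4-generation pedigree."""
        g = pk.build_genealogy(pk.worked_pedigree("second_cousins"))
        subjects = (11, 12, 13)
        exact = genedrop_exact(g, {1: 1}, subjects)
        res = drop_alleles(g, {1: 1}, subjects, N, seed=5)
        for k, s in enumerate(subjects):
            for copies in (0, 1, 2):
                truth = float(sum(
                    p for vec, p in exact.items() if vec[k] == copies
                ))
                est = float(np.mean(res.counts[:, k] == copies))
                lo, hi = binom_ci99(truth, N)
                assert lo - 1e-12 <= est <= hi + 1e-12, (s, copies)

    def test_exact_enumeration_on_random_small_pedigrees(self):
        for gi, g in enumerate(random_genealogies(3, n_founders=4,
                                                  n_generations=3,
                                                  max_individuals=12)):
            founder = sorted(g.founders)[0]
            subjects = tuple(sorted(g.probands))[:2]
            if not g.descendants(founder):
                continue
            exact = genedrop_exact(g, {founder: 1}, subjects)
            res = drop_alleles(g, {founder: 1}, subjects, N, seed=20 + gi)
            for k in range(len(subjects)):
                truth = float(sum(p for vec, p in exact.items() if vec[k] >= 1))
                est = float(np.mean(res.counts[:, k] >= 1))
                lo, hi = binom_ci99(truth, N)
                assert lo - 1e-12 <= est <= hi + 1e-12


class TestAlleleFrequencies:
    def test_mean_copies_tracks_gc(self, collapsed_gc):
        # GC(6, 1) = 1/2 through two grandparental paths.
        res = drop_alleles(collapsed_gc, {1: 1}, [6], N, seed=6)
        freq = allele_frequencies(res)[6]
        se = np.sqrt(0.5 * 0.5 / N)  # copies variance bounded by Bernoulli here
        assert abs(freq - 0.5) < 3 * se * 2

    def test_two_seeded_copies_double_the_mean(self, trio):
        res = drop_alleles(trio, {1: 2}, [3], 5_000, seed=7)
        assert allele_frequencies(res)[3] == 1.0

    def test_mean_equals_gc_times_copies_on_random_pedigrees(self):
        for gi, g in enumerate(random_genealogies(3)):
            founder = sorted(g.founders)[0]
            pro = sorted(g.probands)[:3]
            cm = genetic_contribution(g, pro, [founder])
            res = drop_alleles(g, {founder: 2}, pro, N, seed=30 + gi)
            freq = allele_frequencies(res)
            for p in pro:
                expect = 2 * cm[(p, founder)]
                se = np.sqrt(max(expect * (2 - expect), 1e-6) / N)
                assert abs(freq[p] - expect) < 4 * se + 1e-9


class TestIbdSharing:
    def test_two_children_of_het_founder(self, full_sibs):
        est = ibd_sharing_prob(full_sibs, (3, 4), 1, N, seed=8)
        lo, hi = binom_ci99(0.25, N)
        assert lo <= est["prob"] <= hi

    def test_mrca_product_property(self):
        """For an MRCA reached by tree-like descent, sharing probability
        equals the product of its genetic contributions to the two subjects
        (the ascending paths of the two subjects are disjoint)."""
        from itertools import combinations
        checked = 0
        for gi, g in enumerate(random_genealogies(12, n_founders=6,
                                                  n_generations=4)):
            pros = sorted(g.probands)
            for pro in combinations(pros[:5], 2):
                mrcas = g.find_mrca(pro)
                candidates = [
                    a for a in sorted(mrcas)
                    if all(single_sided_descent(g, a, s) for s in pro)
                ]
                if not candidates:
                    continue
                a = candidates[0]
                cm = genetic_contribution(g, pro, [a])
                product = cm[(pro[0], a)] * cm[(pro[1], a)]
                est = ibd_sharing_prob(g, pro, a, N, seed=40 + gi)
                assert abs(est["prob"] - product) <= CAL_Z * max(est["se"], 1e-5)
                checked += 1
                break  # one qualifying check per genealogy keeps this fast
            if checked >= 4:
                break
        assert checked >= 4

    def test_subject_double_descent_drops_below_product(self):
        """When a subject's own parents both descend from the MRCA, the
        subject can carry two copies of the same allele: P(carry >= 1) < GC
        and sharing falls below the GC product — verified by exact
        enumeration.  Expected value: (1/2 - 1/16)^2 = 49/256."""
        import pandas as pd
        # Founder 1 with two mates: sibs (3, 4) -> proband 5; sibs (6, 7)
        # -> proband 8.  MRCA of (5, 8) is founder 1, reached through BOTH
        # parents on each side.
        rows = [(1, 0, 0, 1), (2, 0, 0, 2), (9, 0, 0, 2),
                (3, 1, 2, 1), (4, 1, 2, 2), (6, 1, 9, 1), (7, 1, 9, 2),
                (5, 3, 4, 1), (8, 6, 7, 2)]
        g = pk.build_genealogy(
            pd.DataFrame(rows, columns=["ind", "father", "mother", "sex"])
        )
        assert classify_ancestor(g, (5, 8), 1) == "MRCA-Founder"
        cm = genetic_contribution(g, [5, 8], [1])
        product = cm[(5, 1)] * cm[(8, 1)]
        exact = float(ibd_sharing_exact(g, (5, 8), 1))
        assert exact == pytest.approx(49 / 256)
        assert exact < product - 1e-6

    def test_shared_path_above_mrca_rises_above_product(self):
        """A non-MRCA common ancestor is reached through overlapping paths,
        which positively correlates the two subjects' carrier states:
        sharing exceeds the GC product (exact value 5/32 here)."""
        import pandas as pd
        # Founder 1 -> sibs (3, 4) -> their child 5 -> probands 6, 7 by
        # unrelated spouses.  MRCA of (6, 7) is 5; founder 1 sits above it.
        rows = [(1, 0, 0, 1), (2, 0, 0, 2), (3, 1, 2, 1), (4, 1, 2, 2),
                (5, 3, 4, 1), (8, 0, 0, 2), (9, 0, 0, 2),
                (6, 5, 8, 1), (7, 5, 9, 2)]
        g = pk.build_genealogy(
            pd.DataFrame(rows, columns=["ind", "father", "mother", "sex"])
        )
        assert classify_ancestor(g, (6, 7), 1) == "Founder"
        cm = genetic_contribution(g, [6, 7], [1])
        product = cm[(6, 1)] * cm[(7, 1)]
        exact = float(ibd_sharing_exact(g, (6, 7), 1))
        assert exact > product + 1e-6

    def test_founder_above_mrca_exceeds_gc_product(self):
        """A common ancestor that is NOT most recent (a founder above the
        MRCA couple) shares strictly more than its GC product predicts,
        because the ascending paths from the two subjects overlap."""
        import pandas as pd
        # Founder couple (1, 2) -> full sibs (3, 4) -> incestuous pair
        # producing sibs (5, 6).  For pair (5, 6) the MRCAs are 3 and 4;
        # founders 1 and 2 are common ancestors above them.
        rows = [(1, 0, 0, 1), (2, 0, 0, 2), (3, 1, 2, 1), (4, 1, 2, 2),
                (5, 3, 4, 1), (6, 3, 4, 2)]
        g = pk.build_genealogy(
            pd.DataFrame(rows, columns=["ind", "father", "mother", "sex"])
        )
        pair = (5, 6)
        assert classify_ancestor(g, pair, 1) == "Founder"
        assert classify_ancestor(g, pair, 3) == "MRCA"
        cm = genetic_contribution(g, list(pair), [1])
        product = cm[(5, 1)] * cm[(6, 1)]
        exact = float(ibd_sharing_exact(g, pair, 1))
        assert exact > product + 1e-6
        est = ibd_sharing_prob(g, pair, 1, N, seed=11)
        assert abs(est["prob"] - exact) <= 3 * max(est["se"], 1e-5)

    def test_requires_common_ancestor(self, first_cousins):
        with pytest.raises(PedigreeError):
            ibd_sharing_prob(first_cousins, (7, 8), 5, 100)

    def test_classification_labels(self, first_cousins):
        import pandas as pd
        assert classify_ancestor(first_cousins, (7, 8), 1) == "MRCA-Founder"
        # Three stacked sib-mating generations: for the bottom pair (7, 8)
        # the middle generation is neither founder nor most recent.
        rows = [(1, 0, 0, 1), (2, 0, 0, 2), (3, 1, 2, 1), (4, 1, 2, 2),
                (5, 3, 4, 1), (6, 3, 4, 2), (7, 5, 6, 1), (8, 5, 6, 2)]
        g = pk.build_genealogy(
            pd.DataFrame(rows, columns=["ind", "father", "mother", "sex"])
        )
        assert classify_ancestor(g, (7, 8), 5) == "MRCA"
        assert classify_ancestor(g, (7, 8), 3) == "In between"
        assert classify_ancestor(g, (7, 8), 1) == "Founder"


class TestHomozygoteSurvival:
    def test_full_survival_matches_no_selection_exactly(self, incest_loop):
        base = drop_alleles(incest_loop, {1: 2, 2: 2}, [5], 20_000, seed=12)
        s1 = drop_alleles(
            incest_loop, {1: 2, 2: 2}, [5], 20_000, seed=12,
            model=TransmissionModel(homozygote_survival=1.0),
        )
        assert (base.counts == s1.counts).all()

    def test_selection_shifts_distribution_toward_enumeration(self):
        g = pk.build_genealogy(pk.worked_pedigree("incest_loop"))
        s = 0.25
        exact = genedrop_exact(g, {1: 2, 2: 2}, (5,), survival=s)
        res = drop_alleles(
            g, {1: 2, 2: 2}, [5], N, seed=13,
            model=TransmissionModel(homozygote_survival=s),
        )
        for copies in (0, 1, 2):
            truth = float(sum(p for vec, p in exact.items() if vec[0] == copies))
            est = float(np.mean(res.column(5) == copies))
            lo, hi = binom_ci99(truth, N)
            assert lo - 1e-12 <= est <= hi + 1e-12, copies

    def test_replicate_rejection_mode_keeps_survivors_only(self):
        g = pk.build_genealogy(pk.worked_pedigree("incest_loop"))
        res = drop_alleles(
            g, {1: 2, 2: 2}, [5], 20_000, seed=14,
            model=TransmissionModel(homozygote_survival=0.0,
                                    reject_replicates=True),
        )
        assert res.n_replicates < 20_000
        assert (res.column(5) < 2).all()


class TestSegmentDropping:
    def test_zero_recombination_reduces_to_allele_sharing(self, first_cousins):
        allele = ibd_sharing_prob(first_cousins, (7, 8), 1, 50_000, seed=15)
        seg = drop_segment(
            first_cousins, (7, 8), 1,
            SegmentModel(breakage_male=0.0, breakage_female=0.0),
            50_000, seed=15,
        )
        assert seg["prob"] == allele["prob"]  # identical stream, r = 0

    def test_certain_breakage_never_shares(self, full_sibs):
        seg = drop_segment(
            full_sibs, (3, 4), 1,
            SegmentModel(breakage_male=1.0, breakage_female=1.0),
            5_000, seed=16,
        )
        assert seg["prob"] == 0.0

    def test_sharing_decreases_with_segment_length(self):
        """Coupled seeds: longer segments can only lose replicates."""
        g = pk.build_genealogy(pk.worked_pedigree("second_cousins"))
        pair = (11, 12)
        probs = []
        for cm_len in (0.0, 3.3, 5.9, 12.6):
            seg = SegmentModel(length_male_cm=cm_len, length_female_cm=cm_len * 1.6)
            probs.append(
                drop_segment(g, pair, 1, seg, 200_000, seed=17)["prob"]
            )
        assert probs[0] > 0
        assert all(a >= b for a, b in zip(probs, probs[1:]))
        assert probs[0] > probs[-1]  # strict drop over the full range

    def test_segment_never_exceeds_allele_sharing(self):
        g = pk.build_genealogy(pk.worked_pedigree("second_cousins"))
        pair = (11, 12)
        allele = ibd_sharing_prob(g, pair, 1, 100_000, seed=18)
        seg = drop_segment(
            g, pair, 1, SegmentModel(length_male_cm=10, length_female_cm=17),
            100_000, seed=18,
        )
        assert seg["prob"] <= allele["prob"]

    def test_sex_specific_maps_enter_via_parent_sex(self):
        # Breakage on the male map only halts father-side transmission.
        g = pk.build_genealogy(pk.worked_pedigree("trio"))
        seg = SegmentModel(breakage_male=1.0, breakage_female=0.0)
        res = drop_alleles(g, {1: 1, 2: 1}, [3], 5_000, seed=19, segment=seg)
        gp = genotype_probs(res)
        p2 = gp[(gp["id"] == 3) & (gp["copies"] == 2)]["prob"].iloc[0]
        assert p2 == 0.0  # father's segment always breaks
        p1 = gp[(gp["id"] == 3) & (gp["copies"] == 1)]["prob"].iloc[0]
        lo, hi = binom_ci99(0.5, 5_000)
        assert lo <= p1 <= hi

    def test_haldane_lengths_match_exact_enumeration(self):
        g = pk.build_genealogy(pk.worked_pedigree("full_sibs"))
        seg = SegmentModel(length_male_cm=20.0, length_female_cm=40.0)
        rm, rf = seg.r(1), seg.r(2)
        exact = ibd_sharing_exact(g, (3, 4), 1, breakage={1: rm, 2: rf})
        est = drop_segment(g, (3, 4), 1, seg, N, seed=21)
        lo, hi = binom_ci99(float(exact), N)
        assert lo <= est["prob"] <= hi
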