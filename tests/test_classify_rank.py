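import random

import pytest

from gapmerdesign.candgen import GapmerCandidate
from gapmerdesign.classify_rank import classify, rank
from gapmerdesign.config import DesignConfig
from gapmerdesign.seqio import DataError

ZERO = {0: 0, 1: 0, 2: 0, 3: 0, 4: 0}


def make(gc=0.45, mfe=-1.0, score=0.1, counts=None, start=0):
    cand = GapmerCandidate(gene_id="g", start=start, window=20,
                           target_site="A" * 20, aso_sequence="T" * 20, gc=gc)
    cand.mfe = mfe
    cand.rnaseh1_score = score
    cand.offtarget_counts = dict(counts or ZERO)
    return cand


class TestClassify:
    def test_approved_drug_profile_is_favorable(self):
        assert classify(make(gc=0.45, mfe=-1.0, score=0.1)) == "favorable"

    @pytest.mark.parametrize("kwargs", [
        dict(mfe=-6.0),                       # strong self-structure
        dict(gc=0.65),                        # GC in (0.6, 0.75]
        dict(gc=0.25),                        # GC in [0.2, 0.3)
        dict(gc=0.15),                        # extrapolated extreme
        dict(gc=0.80),                        # extrapolated extreme
        dict(counts={**ZERO, 4: 11}),         # > 10 genes at 4 mismatches
        dict(score=0.5),                      # unpreferred RNase H1
    ])
    def test_any_single_bad_metric_is_unfavorable(self, kwargs):
        assert classify(make(**kwargs)) == "unfavorable"

    @pytest.mark.parametrize("kwargs", [
        dict(gc=0.30), dict(gc=0.60),         # closed favorable GC interval
        dict(mfe=-1.99), dict(score=0.19),
        dict(counts={**ZERO, 4: 10}),         # mm4 boundary stays favorable
    ])
    def test_favorable_boundaries(self, kwargs):
        assert classify(make(**kwargs)) == "favorable"

    @pytest.mark.parametrize("kwargs", [
        dict(mfe=-2.0),                       # "> -2" is strict
        dict(mfe=-5.0),                       # "< -5" is strict
        dict(score=0.2),                      # "< 0.2" is strict
        dict(counts={**ZERO, 3: 1}),          # one true off-target
    ])
    def test_between_the_rules_is_neutral(self, kwargs):
        assert classify(make(**kwargs)) == "neutral"

    def test_unfavorable_takes_precedence(self):
        # otherwise-favorable metrics, but off-target load fires the
        # unfavorable rule: the tier must be unfavorable, not neutral
        cand = make(counts={**ZERO, 4: 11})
        assert classify(cand) == "unfavorable"

    def test_unset_metric_named_in_error(self):
        cand = make()
        cand.mfe = None
        with pytest.raises(DataError, match="mfe"):
            classify(cand)
        cand = make()
        cand.offtarget_counts = {}
        with pytest.raises(DataError, match="offtarget_counts"):
            classify(cand)

    def test_every_candidate_gets_exactly_one_tier(self, rng):
        for _ in range(200):
            cand = make(gc=float(rng.uniform(0, 1)),
                        mfe=float(rng.uniform(-8, 0)),
                        score=float(rng.uniform(0, 1)),
                        counts={k: int(rng.integers(0, 13)) for k in range(5)})
            assert classify(cand) in ("favorable", "neutral", "unfavorable")


class TestRank:
    def test_rnaseh1_breaks_ties_between_favorables(self):
        a = make(score=0.05, start=5)
        b = make(score=0.15, start=3)
        ranked = rank([b, a])
        assert [c.rank for c in ranked] == [1, 2]
        assert ranked[0] is a

    def test_identical_metrics_fall_back_to_position(self):
        a = make(start=10)
        b = make(start=40)
        ranked = rank([b, a])
        assert ranked[0].start == 10

    def test_tier_dominates_all_metric_keys(self):
        fav = make(score=0.19)
        neut = make(score=0.01, counts={**ZERO, 3: 1})
        ranked = rank([neut, fav])
        assert ranked[0] is fav

    def test_rank_is_permutation_one_to_n(self, rng):
        cands = [make(gc=float(rng.uniform(0.2, 0.8)),
                      mfe=float(rng.uniform(-7, 0)),
                      score=float(rng.uniform(0, 0.8)), start=i)
                 for i in range(25)]
        ranked = rank(cands)
        assert sorted(c.rank for c in ranked) == list(range(1, 26))

    def test_input_permutation_invariance(self, rng):
        cands = [make(gc=float(rng.uniform(0.2, 0.8)),
                      mfe=float(rng.uniform(-7, 0)),
                      score=round(float(rng.uniform(0, 0.8)), 2), start=i)
                 for i in range(30)]
        reference = [(c.start, c.rank) for c in rank(list(cands))]
        shuffler = random.Random(7)
        for _ in range(5):
            shuffled = list(cands)
            shuffler.shuffle(shuffled)
            for c in shuffled:
                c.tier = c.rank = None
            result = [(c.start, c.rank) for c in rank(shuffled)]
            assert result == reference

    def test_weighted_mode_still_ranks_by_tier_first(self):
        cfg = DesignConfig(ranking="weighted")
        fav = make(score=0.19, mfe=-1.9)
        neut = make(score=0.01, counts={**ZERO, 3: 1})
        ranked = rank([neut, fav], cfg)
        assert ranked[0] is fav
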