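"""Evaluation metrics against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

import mhc2learn as m
from mhc2learn.io import Dataset, PeptideRecord
from mhc2learn.metrics import (auc, aupr, f1, balanced_acc, ppvn,
                               make_decoys, core_scan, stratified_report)


def brute_force_auc(scores, labels):
    """All-pairs concordance count with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def textbook_f1(tp, fp, fn):
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def textbook_balanced_acc(tp, fp, tn, fn):
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return (sens + spec) / 2


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 0]) == 1.0

    def test_interleaved_ranking(self):
        # concordant pairs: 3 of 4
        assert auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_all_tied_is_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 5, size=n) / 4.0  # force ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)


class TestPpvn:
    def test_precision_example(self):
        # 10 binders ranked first among 990 records, top 2% -> k=20
        scores = np.concatenate([np.linspace(1, 0.9, 10),
                                 np.linspace(0.5, 0, 980)])
        labels = np.concatenate([np.ones(10), np.zeros(980)])
        assert ppvn(scores, labels, 0.02, "precision") == 10 / 20
        assert ppvn(scores, labels, 0.02, "recall") == 1.0

    def test_worst_case_zero(self):
        scores = np.concatenate([np.zeros(5), np.ones(95)])
        labels = np.concatenate([np.ones(5), np.zeros(95)])
        assert ppvn(scores, labels, 0.02, "precision") == 0.0
        assert ppvn(scores, labels, 0.02, "recall") == 0.0

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            ppvn([1.0], [1], 0.0)
        with pytest.raises(ValueError):
            ppvn([1.0], [1], 1.0001)

    def test_recall_non_decreasing_in_fraction(self):
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        vals = [ppvn(scores, labels, f, "recall")
                for f in np.linspace(0.01, 1.0, 25)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_precision_random_ranking_expectation_is_prevalence(self):
        rng = np.random.default_rng(2)
        labels = np.array([1] * 30 + [0] * 70)
        vals = []
        for _ in range(1000):
            scores = rng.random(100)
            vals.append(ppvn(scores, labels, 0.1, "precision"))
        assert np.mean(vals) == pytest.approx(0.3, abs=0.02)

    def test_stable_tie_break(self):
        scores = np.array([0.5, 0.5, 0.5, 0.5])
        labels = np.array([1, 0, 0, 0])
        # k=1; the first record (a binder) wins the tie by stable order
        assert ppvn(scores, labels, 0.25, "precision") == 1.0


class TestF1AndBalancedAcc:
    def test_match_textbook_on_enumerated_tables(self):
        """Every 2x2 confusion table over small counts."""
        for tp, fp, tn, fn in itertools.product(range(4), repeat=4):
            if tp + fn == 0 or tn + fp == 0:
                continue  # needs both classes
            scores = ([0.9] * tp + [0.9] * fp + [0.1] * tn + [0.1] * fn)
            labels = ([1] * tp + [0] * fp + [0] * tn + [1] * fn)
            assert f1(scores, labels) == pytest.approx(
                textbook_f1(tp, fp, fn))
            assert balanced_acc(scores, labels) == pytest.approx(
                textbook_balanced_acc(tp, fp, tn, fn))


class TestMakeDecoys:
    def _hits(self, toy_proteome, n=5, L=12, seed=0):
        rng = np.random.default_rng(seed)
        seqs = list(toy_proteome.values())
        recs = []
        for _ in range(n):
            s = seqs[rng.integers(len(seqs))]
            i = int(rng.integers(len(s) - L))
            recs.append(PeptideRecord(peptide=s[i:i + L],
                                      allele="DRB1*07:01", label=1))
        return Dataset(recs)

    def test_98_to_1_design(self, toy_proteome):
        hits = self._hits(toy_proteome, n=3)
        decoys = make_decoys(hits, toy_proteome, per_hit=98, seed=0)
        assert len(decoys) == 3 * 98
        hit_lengths = [len(r.peptide) for r in hits.records]
        decoy_lengths = [len(r.peptide) for r in decoys.records]
        assert decoy_lengths == [L for L in hit_lengths for _ in range(98)]

    def test_no_overlap_with_hits(self, toy_proteome):
        hits = self._hits(toy_proteome, n=5)
        decoys = make_decoys(hits, toy_proteome, per_hit=98, seed=1)
        assert not ({r.peptide for r in decoys.records}
                    & {r.peptide for r in hits.records})

    def test_alphabet_clean(self, toy_proteome):
        # splice an X-containing protein into the proteome
        proteome = dict(toy_proteome)
        proteome["XPROT"] = "XXXX" + "ACDEFGHIKL" * 3 + "XXXX"
        hits = self._hits(toy_proteome, n=4)
        decoys = make_decoys(hits, proteome, per_hit=50, seed=2)
        from mhc2learn.io import AA_SET
        assert all(set(r.peptide) <= AA_SET for r in decoys.records)

    def test_deterministic(self, toy_proteome):
        hits = self._hits(toy_proteome, n=2)
        d1 = make_decoys(hits, toy_proteome, per_hit=10, seed=3)
        d2 = make_decoys(hits, toy_proteome, per_hit=10, seed=3)
        assert [r.peptide for r in d1.records] == \
               [r.peptide for r in d2.records]

    def test_empty_proteome_rejected(self, toy_proteome):
        with pytest.raises(ValueError):
            make_decoys(self._hits(toy_proteome), {}, per_hit=1, seed=0)


class TestCoreScan:
    OLIGO = "ACDEFGHIKLMNPQRSTV"   # 18-mer

    def test_eighteen_mer_gives_ten_windows(self):
        _, _, _, scores = core_scan(self.OLIGO, lambda w: 0.0)
        assert len(scores) == 10

    def test_constant_scorer_ties_to_offset_zero(self):
        offset, core, _, _ = core_scan(self.OLIGO, lambda w: 1.0)
        assert offset == 0 and core == self.OLIGO[:9]

    def test_peaked_scorer_found_by_brute_force(self):
        target = self.OLIGO[4:13]
        offset, core, score, scores = core_scan(
            self.OLIGO, lambda w: 1.0 if w == target else 0.1)
        brute = max(range(10),
                    key=lambda o: 1.0 if self.OLIGO[o:o + 9] == target
                    else 0.1)
        assert offset == brute == 4 and core == target

    def test_short_oligomer_rejected(self):
        with pytest.raises(ValueError):
            core_scan("ACDEFGHI", lambda w: 0.0)


class TestStratifiedReport:
    def test_overall_equals_pooled_direct_computation(self):
        rng = np.random.default_rng(5)
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        rep = stratified_report(scores, labels)
        assert rep.auc == pytest.approx(auc(scores, labels))
        assert rep.aupr == pytest.approx(aupr(scores, labels))

    def test_per_stratum_perfect_rankings(self):
        import pandas as pd
        scores = [0.9, 0.8, 0.2, 0.1] * 2
        labels = [1, 1, 0, 0] * 2
        meta = pd.DataFrame({
            "allele": ["DRB1*07:01"] * 4 + ["DQA1*05:01/DQB1*02:01"] * 4,
            "peptide": ["ACDEFGHIKLMN"] * 8})
        rep = stratified_report(scores, labels, meta)
        locus_rows = rep.strata[
            rep.strata.stratum.str.startswith("locus")]
        assert set(locus_rows.stratum) == {"locus:DR", "locus:DQ&DP"}
        assert (locus_rows.auc == 1.0).all()

    def test_single_class_stratum_is_nan_not_zero(self):
        import pandas as pd
        scores = [0.9, 0.8, 0.3, 0.1]
        labels = [1, 1, 1, 0]
        meta = pd.DataFrame({
            "allele": ["DRB1*07:01", "DRB1*07:01",
                       "DQA1*05:01/DQB1*02:01",
                       "DQA1*05:01/DQB1*02:01"],
            "peptide": ["ACDEFGHIKLMN"] * 4})
        rep = stratified_report(scores, labels, meta)
        dr = rep.strata[rep.strata.stratum == "locus:DR"].iloc[0]
        assert math.isnan(dr.auc)

    def test_json_round_trip(self, tmp_path):
        import json
        rep = stratified_report([0.9, 0.1], [1, 0])
        path = tmp_path / "report.json"
        rep.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["auc"] == 1.0
        assert "ppvn" in loaded
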