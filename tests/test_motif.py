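"""Motif deconvolution: EM soundness, recovery, core assignment."""

import itertools

import numpy as np
import pytest

import mhc2learn as m
from mhc2learn.io import AA_ALPHABET, Dataset, PeptideRecord
from mhc2learn.motif import (MotifMixture, fit_motifs, extend_peptides,
                             CORE_LEN, BACKGROUND_ID)

AAS = list(AA_ALPHABET)


def _random_seqs(n, length, rng):
    return ["".join(rng.choice(AAS, length)) for _ in range(n)]


def brute_force_offset_posterior(seq, pwm, prior, weights, background):
    """Independent enumeration of the (offset, background) posterior for
    a single sequence under a K=1 model.  Plain probability products."""
    idx = [AA_ALPHABET.index(a) if a in AA_ALPHABET else 20 for a in seq]
    bg = list(background) + [1.0]
    joint = []
    for o in range(len(prior)):
        if o + CORE_LEN > len(seq):
            joint.append(0.0)
            continue
        p = weights[0] * prior[o]
        for pos, a in enumerate(idx):
            if o <= pos < o + CORE_LEN:
                p *= (pwm[pos - o, a] if a < 20 else 1.0)
            else:
                p *= bg[a]
        joint.append(p)
    p_bg = weights[1]
    for a in idx:
        p_bg *= bg[a]
    joint.append(p_bg)
    joint = np.array(joint)
    return joint / joint.sum()


class TestExtendPeptides:
    def test_known_flanks_make_21mer(self):
        rec = PeptideRecord(peptide="A" * 15, allele="DRB1*07:01", label=1,
                            n_flank="CDE", c_flank="FGH")
        ext = extend_peptides(Dataset([rec]))
        assert ext == ["CDE" + "A" * 15 + "FGH"]

    def test_no_context_padded_with_x(self):
        rec = PeptideRecord(peptide="ACDEFGHIKLMN", allele="DRB1*07:01",
                            label=1)
        assert extend_peptides(Dataset([rec])) == ["XXXACDEFGHIKLMNXXX"]

    def test_short_flank_left_padded(self):
        rec = PeptideRecord(peptide="ACDEFGHIKLMN", allele="DRB1*07:01",
                            label=1, n_flank="DE", c_flank="FG")
        ext = extend_peptides(Dataset([rec]))
        assert ext[0].startswith("XDE") and ext[0].endswith("FGX")

    def test_proteome_lookup(self, toy_proteome):
        prot = next(iter(toy_proteome.values()))
        pep = prot[50:62]
        rec = PeptideRecord(peptide=pep, allele="DRB1*07:01", label=1)
        ext = extend_peptides(Dataset([rec]), toy_proteome)
        assert ext[0] == prot[47:65]


class TestEmSoundness:
    def test_k0_closed_form(self):
        rng = np.random.default_rng(0)
        seqs = _random_seqs(20, 12, rng)
        res = fit_motifs(seqs, n_motifs=0)
        model = MotifMixture(seqs, 0)
        expected = sum(
            sum(np.log(model.background[AA_ALPHABET.index(a)])
                for a in s) for s in seqs)
        assert res.loglik == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_loglik_monotone_on_fuzz_inputs(self, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(CORE_LEN, 22, size=40)
        seqs = [s for L in lengths for s in _random_seqs(1, int(L), rng)]
        res = fit_motifs(seqs, n_motifs=2, restarts=2, seed=seed)
        for segment in res.em_segments:
            diffs = np.diff(segment)
            assert (diffs >= -1e-8 * len(seqs)).all()

    def test_responsibilities_normalize(self):
        rng = np.random.default_rng(3)
        seqs = _random_seqs(30, 15, rng)
        res = fit_motifs(seqs, n_motifs=2, restarts=1, seed=0)
        resp = res.responsibilities(seqs)
        assert np.allclose(resp.sum(axis=1), 1.0)
        # total responsibility mass = number of peptides
        assert resp.sum() == pytest.approx(len(seqs))

    def test_restarts_deterministic(self):
        rng = np.random.default_rng(4)
        seqs = _random_seqs(25, 14, rng)
        r1 = fit_motifs(seqs, 1, restarts=2, seed=5)
        r2 = fit_motifs(seqs, 1, restarts=2, seed=5)
        assert np.array_equal(r1.pwms, r2.pwms)
        assert r1.loglik == r2.loglik

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            MotifMixture([], 1)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            MotifMixture(["ACDEF"], 1)

    def test_oracle_equivalence_small_n(self):
        """E-step responsibilities equal the brute-force enumeration of
        the offset posterior for K=1 on tiny inputs."""
        rng = np.random.default_rng(7)
        seqs = _random_seqs(6, 13, rng)
        res = fit_motifs(seqs, 1, restarts=1, seed=1)
        resp = res.responsibilities(seqs)
        for i, s in enumerate(seqs):
            oracle = brute_force_offset_posterior(
                s, res.pwms[0], res.offset_priors[0],
                [res.mixture_weights[0], res.mixture_weights[1]],
                res.background)
            assert np.allclose(resp[i], oracle, atol=1e-12)


class TestRecovery:
    def test_planted_pwm_recovered(self, sim_small):
        cfg, antigenic, _, truth = sim_small
        hits = antigenic.subset(antigenic.labels() == 1)
        res = fit_motifs(extend_peptides(hits), 1, restarts=10,
                         seed=cfg.seed)
        planted = truth.pwms[0, 0]
        matches = sum(
            planted[j].argmax() == res.pwms[0, j].argmax()
            for j in range(CORE_LEN))
        assert matches >= 8
        corr = np.corrcoef(planted.ravel(), res.pwms[0].ravel())[0, 1]
        assert corr >= 0.9

    def test_consensus_embedded_peptide_assigned_correctly(self):
        rng = np.random.default_rng(9)
        seqs = _random_seqs(200, 15, rng)
        # plant a sharp motif at offset 2 in half of them
        motif = "WWWHHHKKK"
        planted = [s[:2] + motif + s[11:] for s in seqs[:100]]
        res = fit_motifs(planted + seqs[100:], 1, restarts=10, seed=0)
        probe = "AC" + motif + "DEFG"
        a = res.assign_cores([probe])[0]
        assert a.motif_id == 0 and a.offset == 2

    def test_background_peptide_goes_to_background(self):
        rng = np.random.default_rng(10)
        seqs = _random_seqs(150, 15, rng)
        motif = "WWWHHHKKK"
        planted = [s[:2] + motif + s[11:] for s in seqs[:75]]
        res = fit_motifs(planted + seqs[75:], 1, restarts=10, seed=0)
        probe = "".join(rng.choice(list("ACDEFG"), 15))
        a = res.assign_cores([probe])[0]
        assert a.motif_id == BACKGROUND_ID


class TestOffsetFeature:
    def _results(self):
        rng = np.random.default_rng(11)
        seqs = _random_seqs(60, 14, rng)
        return fit_motifs(seqs, 1, restarts=1, seed=2)

    def test_modal_offset_scores_one(self):
        res = self._results()
        modal = int(res.offset_priors[0].argmax())
        a = m.CoreAssignment("X" * 14, 0, modal, 1.0)
        assert res.offset_feature(a) == 1.0

    def test_uniform_prior_scores_one_everywhere(self):
        res = self._results()
        res.offset_priors[0][:] = 1.0 / res.offset_priors.shape[1]
        for o in range(res.offset_priors.shape[1]):
            a = m.CoreAssignment("X" * 14, 0, o, 1.0)
            assert res.offset_feature(a) == pytest.approx(1.0)

    def test_background_assignment_scores_one(self):
        res = self._results()
        a = m.CoreAssignment("X" * 14, BACKGROUND_ID, None, 1.0)
        assert res.offset_feature(a) == 1.0

    def test_floor_keeps_feature_positive(self):
        res = self._results()
        worst = int(res.offset_priors[0].argmin())
        a = m.CoreAssignment("X" * 14, 0, worst, 1.0)
        assert 0 < res.offset_feature(a) <= 1.0


class TestLogos:
    def test_logo_and_pwm_files_per_motif(self, tmp_path):
        rng = np.random.default_rng(12)
        seqs = _random_seqs(40, 13, rng)
        res = fit_motifs(seqs, 2, restarts=1, seed=0)
        written = res.export_logos(tmp_path)
        assert len([w for w in written if w.endswith(".tsv")]) == 2
        assert len([w for w in written if w.endswith(".png")]) == 2

    def test_k0_background_chart_only(self, tmp_path):
        rng = np.random.default_rng(13)
        res = fit_motifs(_random_seqs(15, 12, rng), 0)
        written = res.export_logos(tmp_path)
        assert len(written) == 1 and "background" in written[0]
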