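"""Abundance filter, profile normalization, co-elution scoring, filter chain."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from xlscreen import cofrac, synthetic
from xlscreen.cofrac import CoelutionRecord, ElutionMatrix
from xlscreen.synthetic import SimConfig


def _matrix(intensities, **kw):
    P = intensities.shape[0]
    return ElutionMatrix(proteins=[f"P{i}" for i in range(P)],
                         intensities=intensities, **kw)


class TestFilterAbundance:
    def _abundance_matrix(self, peptides, ibaq):
        P = len(peptides)
        return ElutionMatrix(
            proteins=[f"P{i}" for i in range(P)],
            intensities=np.ones((P, 5, 3, 2)),
            peptide_counts=np.array(peptides),
            ibaq=np.array(ibaq),
        )

    def test_single_condition_pass_suffices(self):
        peptides = [[[5, 1]] * 3]  # passes crosslinked only
        ibaq = [[[1e8, 1e8]] * 3]
        m = self._abundance_matrix(peptides, ibaq)
        assert cofrac.filter_abundance(m) == ["P0"]

    def test_two_peptides_everywhere_removed(self):
        m = self._abundance_matrix([[[2, 2]] * 3], [[[1e9, 1e9]] * 3])
        assert cofrac.filter_abundance(m) == []

    def test_one_failing_replicate_fails_condition(self):
        peptides = [[[5, 5], [5, 5], [2, 5]]]  # replicate 3 fails crosslinked
        ibaq = [[[1e8, 1e6], [1e8, 1e6], [1e8, 1e6]]]  # untreated iBAQ too low
        m = self._abundance_matrix(peptides, ibaq)
        assert cofrac.filter_abundance(m) == []

    def test_ribosomal_removed(self):
        m = self._abundance_matrix([[[5, 5]] * 3], [[[1e8, 1e8]] * 3])
        assert cofrac.filter_abundance(m, ribosome_accessions={"P0"}) == []

    def test_planted_ledger_recovered(self, elution):
        retained = cofrac.filter_abundance(elution)
        assert retained == elution.ground_truth["abundance_pass"]


class TestNormalizeProfiles:
    def test_peak_scaled_to_one(self):
        arr = np.zeros((1, 10, 1, 2))
        arr[0, 4, 0, 0] = 5.0
        m = _matrix(arr)
        mean, _ = cofrac.normalize_profiles(m, ["P0"], "crosslinked",
                                            smooth_sigma=0.0)
        assert mean.max() == pytest.approx(1.0)

    def test_identical_replicates_zero_deviation(self):
        arr = np.zeros((1, 10, 2, 2))
        arr[0, :, 0, 0] = arr[0, :, 1, 0] = np.linspace(1, 10, 10)
        m = _matrix(arr)
        _, sd = cofrac.normalize_profiles(m, ["P0"], "crosslinked")
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_mean_sd_match_brute_force(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0.1, 5.0, size=(1, 20, 3, 2))
        m = _matrix(arr)
        mean, sd = cofrac.normalize_profiles(m, ["P0"], "untreated",
                                             smooth_sigma=0.0)
        profiles = arr[0, :, :, 1].T
        normed = profiles / profiles.max(axis=1, keepdims=True)
        np.testing.assert_allclose(mean, normed.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(sd, normed.std(axis=0), atol=1e-12)

    def test_all_zero_profile_excluded_with_warning(self):
        arr = np.zeros((2, 10, 1, 2))
        arr[0, 3, 0, 0] = 1.0
        m = _matrix(arr)
        with pytest.warns(UserWarning, match="all-zero"):
            mean, _ = cofrac.normalize_profiles(m, ["P0", "P1"], "crosslinked",
                                                smooth_sigma=0.0)
        assert mean.max() == pytest.approx(1.0)


class TestCoelutionScore:
    def test_identical_profiles_score_one(self):
        p = np.exp(-0.5 * ((np.arange(50) - 20) / 2.0) ** 2)[None, :]
        scores, flags = cofrac.coelution_score(p, p)
        assert scores[0] == pytest.approx(1.0)
        assert not flags[0]

    def test_anticorrelated_clamped_to_zero(self):
        x = np.linspace(0, 1, 50)[None, :]
        scores, _ = cofrac.coelution_score(x + 0.1, 1.1 - x, smooth_sigma=0.0)
        assert scores[0] == 0.0

    def test_zero_variance_flagged(self):
        flat = np.ones((1, 30))
        peak = np.exp(-0.5 * (np.arange(30) - 10.0) ** 2)[None, :]
        scores, flags = cofrac.coelution_score(flat, peak)
        assert scores[0] == 0.0 and flags[0]

    def test_separates_planted_pairs_from_random(self):
        member_scores, random_scores = [], []
        for seed in range(100):
            cfg = SimConfig(seed=seed, n_proteins=10,
                            complex_spec=[("MA", "MB", "MC")], labile_frac=0.0)
            m = synthetic.gen_elution_dataset(cfg, seed=seed)
            monos = [p for p in m.proteins if p.startswith("MONO")]
            s, _ = cofrac.coelution_score(m.profiles("MA", "crosslinked"),
                                          m.profiles("MB", "crosslinked"))
            member_scores.append(np.median(s))
            s, _ = cofrac.coelution_score(m.profiles(monos[0], "crosslinked"),
                                          m.profiles(monos[1], "crosslinked"))
            random_scores.append(np.median(s))
        member_scores, random_scores = map(np.asarray, (member_scores, random_scores))
        assert np.mean(member_scores > random_scores) >= 0.9
        u = mannwhitneyu(member_scores, random_scores, alternative="greater").statistic
        auroc = u / (len(member_scores) * len(random_scores))
        assert auroc > 0.9


def _record(pair, condition, scores, size=3, peak_ml=12.0, cid="c1"):
    return CoelutionRecord(pair=pair, condition=condition,
                           replicate_scores=scores, complex_id=cid,
                           complex_size=size, peak_elution_ml=peak_ml)


class TestCandidatePairs:
    def test_oversize_complex_contributes_nothing(self):
        recs = [_record(("A", "B"), "crosslinked", [1.0, 1.0, 1.0], size=11)]
        out = cofrac.candidate_pairs(recs)
        assert out["union"] == set()

    def test_late_elution_removed(self):
        recs = [_record(("A", "B"), "crosslinked", [1.0, 1.0, 1.0], peak_ml=19.5)]
        assert cofrac.candidate_pairs(recs)["union"] == set()

    def test_two_replicate_rule_either_condition(self):
        recs = [
            _record(("A", "B"), "crosslinked", [0.9, 0.85, 0.1]),
            _record(("C", "D"), "untreated", [0.9, 0.1, 0.1]),
        ]
        out = cofrac.candidate_pairs(recs)
        assert out["crosslinked"] == {("A", "B")}
        assert out["untreated"] == set()
        assert out["union"] == {("A", "B")}

    def test_expansion_combinatorics(self):
        for k in (2, 3, 5, 8):
            members = [f"M{i}" for i in range(k)]
            assert len(cofrac.expand_complex(members)) == k * (k - 1) // 2

    def test_candidate_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        recs = [_record((f"A{i}", f"B{i}"), "crosslinked", rng.uniform(0, 1, 3))
                for i in range(50)]
        counts = [len(cofrac.candidate_pairs(recs, score_cutoff=c)["union"])
                  for c in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_expansion_sum_matches_group_sizes(self, elution):
        complexes = {f"c{i}": members
                     for i, members in enumerate(elution.ground_truth["complexes"])}
        recs = cofrac.score_complexes(elution, complexes)
        pairs_per_condition = {
            (rec.complex_id, rec.condition)
            for rec in recs
        }
        n_pairs = len({(rec.complex_id, rec.pair) for rec in recs})
        expected = sum(len(m) * (len(m) - 1) // 2 for m in complexes.values())
        assert n_pairs == expected
        assert len(pairs_per_condition) == 2 * len(complexes)


class TestCompareConditions:
    def test_similar_and_directional(self):
        recs = [
            _record(("A", "B"), "crosslinked", [0.9, 0.9, 0.9]),
            _record(("A", "B"), "untreated", [0.9, 0.9, 0.9]),
            _record(("C", "D"), "crosslinked", [0.9, 0.9, 0.9]),
            _record(("C", "D"), "untreated", [0.2, 0.2, 0.2]),
            _record(("E", "F"), "crosslinked", [0.3, 0.3, 0.3]),
        ]
        out = cofrac.compare_conditions(recs)
        assert out[("A", "B")] == "similar"
        assert out[("C", "D")] == "higher_crosslinked"
        assert out[("E", "F")] == "missing"

    def test_stabilized_labile_pairs_shift_crosslinked(self):
        higher_labile, higher_stable = 0, 0
        for seed in range(12):
            cfg = SimConfig(seed=seed, n_proteins=8,
                            complex_spec=[("SA", "SB", "LC")],
                            labile_frac=0.0, stabilization_gain=1.0)
            m = synthetic.gen_elution_dataset(cfg, seed=seed)
            # plant one labile member by hand: regenerate with full lability
            cfg_lab = SimConfig(seed=seed, n_proteins=8,
                                complex_spec=[("SA", "SB", "LC")],
                                labile_frac=1.0, stabilization_gain=1.0)
            m_lab = synthetic.gen_elution_dataset(cfg_lab, seed=seed)
            for matrix, counter in ((m_lab, "labile"), (m, "stable")):
                recs = cofrac.score_complexes(
                    matrix, {"c": ["SA", "SB", "LC"]})
                out = cofrac.compare_conditions(recs, band=0.1)
                n_higher = sum(v == "higher_crosslinked" for v in out.values())
                if counter == "labile":
                    higher_labile += n_higher
                else:
                    higher_stable += n_higher
        assert higher_labile > higher_stable


class TestRocCurve:
    def test_boundary_cutoff_zero(self):
        recs = [_record(("A", "B"), "crosslinked", [0.9, 0.9, 0.9])]
        curve = cofrac.roc_curve([("A", "B")], [("X", "Y")], recs)
        assert len(curve) == 11
        cutoff, tpr, fpr = curve[0]
        assert (cutoff, tpr, fpr) == (0.0, 1.0, 1.0)

    def test_perfect_separation_hits_corner(self):
        recs = [_record(("A", "B"), "crosslinked", [0.95] * 3),
                _record(("X", "Y"), "crosslinked", [0.05] * 3)]
        curve = cofrac.roc_curve([("A", "B")], [("X", "Y")], recs)
        assert any(tpr == 1.0 and fpr == 0.0 for _, tpr, fpr in curve)

    def test_empty_known_set_rejected(self):
        with pytest.raises(ValueError):
            cofrac.roc_curve([], [("X", "Y")], [])

    def test_identical_distributions_tpr_tracks_fpr(self):
        diffs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            known = [(f"K{i}", f"K{i}x") for i in range(40)]
            decoy = [(f"D{i}", f"D{i}x") for i in range(40)]
            recs = [_record(p, "crosslinked", rng.uniform(0, 1, 3) ** 2)
                    for p in known + decoy]
            for _, tpr, fpr in cofrac.roc_curve(known, decoy, recs):
                diffs.append(tpr - fpr)
        # same score distribution: mean TPR-FPR within binomial error of 0
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 4 * se + 1e-9


def test_elution_matrix_csv_round_trip(tmp_path, elution):
    path = tmp_path / "elution.csv"
    elution.to_csv(path)
    again = ElutionMatrix.from_csv(path)
    assert again.proteins == sorted(elution.proteins)
    for prot in elution.proteins:
        for cond in cofrac.CONDITIONS:
            np.testing.assert_allclose(again.profiles(prot, cond),
                                       elution.profiles(prot, cond), rtol=1e-9)
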