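"""Attribute extraction, DCW, Monte-Carlo training and the domain rule."""

from collections import Counter

import numpy as np
import pytest

import ho1screen as h
from ho1screen.coral_qsar import (
    CoralModel, TrainingError, is_atom_token, threshold_from_param, tokenize,
)


class TestTokenize:
    @pytest.mark.parametrize("smiles,tokens", [
        ("CC", ["C", "C"]),
        ("C", ["C"]),
        ("c1c[nH]cn1", ["c", "1", "c", "[nH]", "c", "n", "1"]),
        ("ClCCBr", ["Cl", "C", "C", "Br"]),
        ("C%12CC%12", ["C", "%12", "C", "C", "%12"]),
        ("C(=O)O", ["C", "(", "=", "O", ")", "O"]),
    ])
    def test_streams(self, smiles, tokens):
        assert tokenize(smiles) == tokens

    def test_unterminated_bracket_reports_position(self):
        with pytest.raises(ValueError, match="position 2"):
            tokenize("CC[nH")


class TestExtractAttributes:
    def test_ethane_hand_enumeration(self):
        prof = h.extract_attributes("CC", assume_canonical=True)
        assert prof.atom_attributes == Counter({"C": 2})
        assert prof.pair_attributes == Counter({"C|C": 1})

    def test_single_token_no_pairs(self):
        prof = h.extract_attributes("C", assume_canonical=True)
        assert prof.atom_attributes == Counter({"C": 1})
        assert not prof.pair_attributes

    def test_bracket_atom_is_one_token(self):
        prof = h.extract_attributes("c1c[nH]cn1", assume_canonical=True)
        assert prof.atom_attributes["[nH]"] == 1
        assert prof.atom_attributes["c"] == 3

    def test_sk_total_equals_atom_token_count(self):
        records, _ = h.generate_library(h.LibrarySpec(n_total=40, seed=6))
        for r in records:
            prof = h.extract_attributes(r.smiles, assume_canonical=True)
            n_atoms = sum(is_atom_token(t) for t in tokenize(r.smiles))
            assert sum(prof.atom_attributes.values()) == n_atoms

    def test_extraction_canonicalizes_first(self):
        assert (h.extract_attributes("C1=CN=CN1").merged()
                == h.extract_attributes("c1c[nH]cn1").merged())


def brute_force_dcw(profile, weights):
    """Independent oracle: exhaustive per-occurrence summation."""
    total = 0.0
    merged = profile.merged()
    for attr in sorted(merged):
        for _ in range(merged[attr]):
            total += weights.get(attr, 0.0)
    return total


class TestComputeDcw:
    def test_worked_example(self):
        prof = h.AttributeProfile(atom_attributes=Counter({"C": 2}),
                                  pair_attributes=Counter({"C|C": 1}))
        model = CoralModel(weights={"A:C": 1.5, "P:C|C": 0.5})
        assert h.compute_dcw(prof, model) == pytest.approx(3.5)

    def test_zero_weights(self):
        prof = h.extract_attributes("Clc1ccccc1Cn1ccnc1")
        assert h.compute_dcw(prof, CoralModel(weights={})) == 0.0

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(123)
        records, _ = h.generate_library(h.LibrarySpec(n_total=50, seed=12))
        profiles = [h.extract_attributes(r.smiles, assume_canonical=True)
                    for r in records]
        attrs = sorted({a for p in profiles for a in p.merged()})
        for _ in range(100):
            prof = profiles[int(rng.integers(len(profiles)))]
            weights = {a: float(rng.normal()) for a in attrs
                       if rng.random() < 0.7}
            model = CoralModel(weights=weights)
            assert h.compute_dcw(prof, model) == pytest.approx(
                brute_force_dcw(prof, weights), abs=1e-12)

    def test_linearity_in_weights(self):
        prof = h.extract_attributes("COc1ccccc1Cn1ccnc1")
        attrs = list(prof.merged())
        rng = np.random.default_rng(5)
        w1 = {a: float(rng.normal()) for a in attrs}
        w2 = {a: float(rng.normal()) for a in attrs}
        m = lambda w: CoralModel(weights=w)  # noqa: E731
        sum_w = {a: w1[a] + w2[a] for a in attrs}
        assert h.compute_dcw(prof, m(sum_w)) == pytest.approx(
            h.compute_dcw(prof, m(w1)) + h.compute_dcw(prof, m(w2)))
        scaled = {a: 3.0 * w1[a] for a in attrs}
        assert h.compute_dcw(prof, m(scaled)) == pytest.approx(
            3.0 * h.compute_dcw(prof, m(w1)))


class TestTrain:
    def test_r2_non_decreasing_over_accepted_moves(
            self, qualifying_records, noise_free_activities):
        pairs = [(r.smiles, noise_free_activities[r.id])
                 for r in qualifying_records[:60]]
        model = h.train(pairs, n_epochs=2000, seed=1, record_history=True)
        hist = model.r2_history
        assert all(b >= a - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_identical_seeds_identical_models(
            self, qualifying_records, noise_free_activities):
        pairs = [(r.smiles, noise_free_activities[r.id])
                 for r in qualifying_records[:60]]
        m1 = h.train(pairs, n_epochs=2000, seed=4)
        m2 = h.train(pairs, n_epochs=2000, seed=4)
        assert m1.weights == m2.weights
        assert (m1.c0, m1.c1) == (m2.c0, m2.c1)

    def test_noise_free_recovery(self, trained_model, qualifying_records,
                                 noise_free_activities):
        assert trained_model.r2_train >= 0.99
        held_out = qualifying_records[200:]
        errs = []
        for rec in held_out:
            pred = h.predict(trained_model, rec.smiles)
            if pred.in_domain:
                errs.append(pred.pic50_pred - noise_free_activities[rec.id])
        assert len(errs) >= 50
        assert float(np.sqrt(np.mean(np.square(errs)))) <= 0.1

    def test_final_regression_is_least_squares(
            self, trained_model, qualifying_records, noise_free_activities):
        pairs = [(r.smiles, noise_free_activities[r.id])
                 for r in qualifying_records[:200]]
        dcw = np.array([h.predict(trained_model, s).dcw for s, _ in pairs])
        y = np.array([p for _, p in pairs])
        c1_ref, c0_ref = np.polyfit(dcw, y, 1)
        assert trained_model.c0 == pytest.approx(c0_ref, abs=1e-9)
        assert trained_model.c1 == pytest.approx(c1_ref, abs=1e-9)

    def test_blocked_attributes_have_zero_weight(self, trained_model):
        for attr, n in trained_model.training_census.items():
            if n < trained_model.threshold_t:
                assert trained_model.weights.get(attr, 0.0) == 0.0

    def test_too_few_molecules_error(self):
        with pytest.raises(TrainingError):
            h.train([("CCO", 4.0)] * 5)

    def test_identical_endpoints_error(self, qualifying_records):
        pairs = [(r.smiles, 4.0) for r in qualifying_records[:20]]
        with pytest.raises(TrainingError, match="identical"):
            h.train(pairs, n_epochs=10)

    def test_threshold_param_mapping(self):
        assert threshold_from_param(0.41, 200) == 1
        assert threshold_from_param(0.41, 1000) == 4
        assert threshold_from_param(0.0, 100) == 1


class TestPredict:
    def test_published_regression_intercept(self):
        model = h.published_ho1_model()
        assert h.predict_from_dcw(model, 0.0) == pytest.approx(
            0.0000163, abs=1e-10)

    def test_published_regression_at_dcw_100(self):
        model = h.published_ho1_model()
        assert h.predict_from_dcw(model, 100.0) == pytest.approx(
            4.7315263, abs=1e-6)

    def test_novel_attribute_out_of_domain(self, trained_model):
        # Br never occurs in the training decorations
        pred = h.predict(trained_model, "BrCCn1ccnc1")
        assert not pred.in_domain
        assert any("Br" in a for a in pred.novel_attributes)

    def test_prediction_invariant_to_respelling(self, trained_model):
        a = h.predict(trained_model, "Clc1ccccc1Cn1ccnc1")
        b = h.predict(trained_model, "c1ccc(Cl)c(c1)Cn1ccnc1")
        assert a.pic50_pred == pytest.approx(b.pic50_pred)
        assert a.in_domain == b.in_domain

    def test_serialization_round_trip_bit_exact(self, trained_model, tmp_path):
        p = tmp_path / "model.json"
        trained_model.to_json(p)
        back = CoralModel.from_json(p)
        assert back.weights == trained_model.weights
        assert back.training_census == trained_model.training_census
        assert (back.c0, back.c1) == (trained_model.c0, trained_model.c1)


class TestApplyQsarFilter:
    def test_planted_novel_fraction_flagged(self, trained_model):
        records, _ = h.generate_library(h.LibrarySpec(
            n_total=30, frac_qualifying=1.0, frac_disqualified=0.0,
            frac_decoy=0.0, seed=30))
        novel = [h.record_from_smiles(f"BrCC{'C' * i}n1ccnc1", f"NOV{i}")
                 for i in range(20)]
        in_domain, outliers, summary = h.apply_qsar_filter(
            records + novel, trained_model)
        outlier_ids = {rec.id for rec, _ in outliers}
        assert outlier_ids == {r.id for r in novel}
        assert summary["n_in_domain"] == 30 and summary["n_outliers"] == 20

    def test_graded_defect_rule(self, trained_model, qualifying_records):
        # a molecule made purely of training-common attributes scores low;
        # one full of never-trained tokens scores high
        low = h.attribute_defect(qualifying_records[0].smiles, trained_model)
        high = h.attribute_defect("BrC(Br)(Br)S(=O)(=O)Br", trained_model)
        assert 0.0 <= low < high <= 1.0
        recs = [qualifying_records[0],
                h.record_from_smiles("BrC(Br)(Br)S(=O)(=O)Br", "odd")]
        in_domain, outliers, _ = h.apply_qsar_filter(
            recs, trained_model, defect_cutoff=(low + high) / 2)
        assert [r.id for r, _ in outliers] == ["odd"]

    def test_empty_input(self, trained_model):
        in_domain, outliers, summary = h.apply_qsar_filter([], trained_model)
        assert in_domain == [] and outliers == []
        assert summary["pic50_min"] is None

    def test_all_in_domain_min_max(self, trained_model, qualifying_records):
        recs = qualifying_records[:20]
        in_domain, outliers, summary = h.apply_qsar_filter(recs, trained_model)
        preds = [p.pic50_pred for _, p in in_domain]
        if not outliers:
            assert summary["pic50_min"] == min(preds)
            assert summary["pic50_max"] == max(preds)
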