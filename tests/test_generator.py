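"""Vocabulary, LSTM training/sampling contracts, and generation metrics."""

from collections import Counter

import numpy as np
import pytest

from molforge import fixtures, generator
from molforge.errors import VocabularyError
from molforge.generator import GeneratorConfig, SmilesGenerator, TokenVocabulary


class TestVocabulary:
    def test_single_molecule_corpus_tokens(self):
        vocab = generator.build_vocabulary(["CCO"])
        assert vocab.tokens == ["<pad>", "^", "$", "C", "O"]

    def test_two_letter_elements_are_single_tokens(self):
        assert TokenVocabulary.tokenize("CCl") == ["C", "Cl"]
        assert TokenVocabulary.tokenize("BrC[nH]%12") == ["Br", "C", "[nH]", "%12"]

    def test_round_trip_on_corpus(self, corpus60):
        vocab = TokenVocabulary.from_corpus(corpus60)
        for smiles in corpus60:
            assert "".join(vocab.tokenize(smiles)) == smiles
            assert vocab.decode(vocab.encode(smiles)) == smiles

    def test_unknown_token_error_names_the_token(self):
        vocab = generator.build_vocabulary(["CCO"])
        with pytest.raises(VocabularyError, match="'Br'"):
            vocab.encode("CBr")

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            generator.build_vocabulary([])


class TestTraining:
    def test_loss_decreases(self, tiny_model):
        history = tiny_model.history
        assert history[-1]["train_loss"] < history[0]["train_loss"]
        assert min(h["val_loss"] for h in history) < history[0]["val_loss"] + 1e-9

    def test_pretrain_needs_ten_molecules(self):
        with pytest.raises(ValueError):
            generator.pretrain(["CCO"] * 5, 1)

    def test_sampling_deterministic_under_seed(self, tiny_model):
        assert tiny_model.sample(25, seed=7) == tiny_model.sample(25, seed=7)

    def test_serialization_preserves_samples(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        reloaded = SmilesGenerator.load(path)
        assert reloaded.vocab == tiny_model.vocab
        assert reloaded.sample(25, seed=7) == tiny_model.sample(25, seed=7)

    def test_single_molecule_overfit_is_modal_sample(self):
        cfg = GeneratorConfig(
            n_layers=1, hidden_size=32, embedding_size=16, val_fraction=0.0
        )
        model = SmilesGenerator(TokenVocabulary.from_corpus(["CCO"]), cfg, seed=0)
        model.fit(["CCO"], 200, seed=0)
        modal, _ = Counter(model.sample(50, temperature=0.5, seed=1)).most_common(1)[0]
        assert modal == "CCO"
        # low-temperature limit approaches argmax decoding
        assert set(model.sample(10, temperature=0.05, seed=2)) == {"CCO"}

    def test_non_finite_loss_aborts(self, corpus60, tiny_config):
        model = SmilesGenerator(
            TokenVocabulary.from_corpus(corpus60), tiny_config, seed=0
        )
        model.params["Wout"][:] = np.nan  # corrupted checkpoint / diverged state
        with pytest.raises(ArithmeticError, match="non-finite"):
            model.fit(corpus60, 1, seed=0)


class TestFineTune:
    def test_loglik_of_focused_set_increases(self, tiny_model, corpus60):
        focused = corpus60[:8]
        tuned = generator.fine_tune(tiny_model, focused, 5, seed=0)
        assert tuned.log_likelihood(focused) > tiny_model.log_likelihood(focused)

    def test_zero_epochs_is_identity(self, tiny_model, corpus60):
        tuned = generator.fine_tune(tiny_model, corpus60[:5], 0, seed=0)
        assert tuned.sample(15, seed=3) == tiny_model.sample(15, seed=3)

    def test_focused_subset_of_corpus_non_decreasing(self, tiny_model, corpus60):
        focused = corpus60[10:15]  # already seen in pretraining
        tuned = generator.fine_tune(tiny_model, focused, 3, seed=1)
        assert tuned.log_likelihood(focused) >= tiny_model.log_likelihood(focused)

    def test_sampling_shifts_toward_focused_series(self):
        """Transfer learning biases samples toward the focused scaffold family."""
        spec = fixtures.FixtureSpec(corpus_size=150, seed=2)
        corpus = fixtures.generate_corpus(spec)
        query = fixtures.query_compound(spec)
        model = generator.pretrain(
            corpus,
            30,
            seed=3,
            config=GeneratorConfig(
                n_layers=1, hidden_size=128, embedding_size=32, batch_size=16
            ),
        )
        from molforge import chem
        from molforge.chem import FingerprintKind, SimilarityMeasure

        qfp = chem.fingerprint(query, FingerprintKind.CIRCULAR)
        focused = sorted(
            corpus,
            key=lambda s: -chem.similarity(
                qfp,
                chem.fingerprint(s, FingerprintKind.CIRCULAR),
                SimilarityMeasure.TANIMOTO,
            ),
        )[:20]
        tuned = generator.fine_tune(model, focused, 25, seed=3)
        before, after = generator.focused_shift(
            model.sample(150, seed=5), tuned.sample(150, seed=5), focused
        )
        assert after > before


class TestSampling:
    def test_exact_count_and_length_bound(self, tiny_model):
        samples = tiny_model.sample(40, seed=9, max_length=30)
        assert len(samples) == 40
        for s in samples:
            assert len(TokenVocabulary.tokenize(s)) <= 30

    def test_parameter_validation(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.sample(0)
        with pytest.raises(ValueError):
            tiny_model.sample(5, temperature=0.0)


class TestEvaluateGeneration:
    def test_hand_counted_fractions(self):
        report = generator.evaluate_generation(
            ["CCO", "CCO", "C1CC", "c1ccccc1"], training_corpus=["CCO"]
        )
        assert report.validity == pytest.approx(0.75)
        assert report.uniqueness == pytest.approx(2 / 3)
        assert report.novelty == pytest.approx(0.5)

    def test_all_invalid_gives_nulls(self):
        report = generator.evaluate_generation(["C1CC", ")(", ""], ["CCO"])
        assert report.validity == 0.0
        assert report.uniqueness is None and report.novelty is None

    def test_samples_equal_to_training_have_zero_novelty(self, corpus60):
        report = generator.evaluate_generation(corpus60[:20], corpus60)
        assert report.novelty == 0.0
        assert report.validity == 1.0

    def test_fractions_bounded(self, tiny_model, corpus60):
        report = generator.evaluate_generation(
            tiny_model.sample(60, seed=4), corpus60, reference_actives=corpus60[:10]
        )
        for value in (report.validity, report.uniqueness, report.novelty,
                      report.internal_diversity, report.scaffold_overlap):
            if value is not None:
                assert 0.0 <= value <= 1.0

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            generator.evaluate_generation([], ["CCO"])
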