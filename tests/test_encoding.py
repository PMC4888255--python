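"""Feature encoding: positional/dependency scores and k-mer compositions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from donorpred.encoding import (
    FULL344,
    TABLE1_49,
    DegenerateModelError,
    FeatureSetManifest,
    FrequencyModelBundle,
    compositional_features,
    dependency_features,
    encode,
    positional_features,
)
from donorpred.frequency_models import (
    DependencyFrequencyModel,
    PositionalFrequencyModel,
    estimate_dependency,
    estimate_positional,
)
from donorpred.sequence_io import SpliceWindow
from donorpred.synthetic import GeneratorConfig, generate


def W(seq, label=None):
    return SpliceWindow(seq, label=label, source_id=seq)


def uniform_positional(L, tag="true"):
    p = np.full((L, 4), 0.25)
    p[:, 0] = 0.4
    p[:, 1] = 0.1  # make M != N
    return PositionalFrequencyModel(class_tag=tag, p=p, pseudocount=0, n_train=1)


def constant_dependency(L, value, tag="true"):
    q = np.full((L, L, 4, 4), value)
    return DependencyFrequencyModel(class_tag=tag, q=q, pseudocount=0, n_train=1)


class TestPositionalFeatures:
    def test_two_position_toy_log_score(self):
        # p(A at 1) = 0.5, p(G at 2) = 0.25 -> f1("AG") = -1 + -2 = -3
        p = np.array([[0.5, 0.2, 0.2, 0.1], [0.25, 0.25, 0.25, 0.25]])
        model = PositionalFrequencyModel("true", p, 0, 1)
        w = SpliceWindow("AG", source_id="toy")
        feats = positional_features(w, model, model)
        assert feats["f1"] == pytest.approx(-3.0)
        assert feats["f2"] == 0.0 and feats["f4"] == 0.0

    def test_consensus_window_scores_zero_under_own_model(self):
        w = W("AAAAAAAAGTAAAAA")
        model = estimate_positional([w], pseudocount=0)
        feats = positional_features(w, model, uniform_positional(15, "false"))
        assert feats["f1"] == pytest.approx(0.0)  # all logs of 1
        assert feats["f3"] == pytest.approx(0.0)  # sum p equals M

    def test_identical_models_null_contrasts(self):
        ws = generate(GeneratorConfig(n_true=30, n_false=30, seed=2))
        model = estimate_positional(ws[:30], pseudocount=1)
        for w in ws[:5]:
            feats = positional_features(w, model, model)
            assert feats["f2"] == pytest.approx(0.0, abs=1e-12)
            assert feats["f4"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_model_raises(self):
        p = np.full((15, 4), 0.25)  # M == N
        model = PositionalFrequencyModel("true", p, 0, 1)
        with pytest.raises(DegenerateModelError, match="true"):
            positional_features(W("AAAAAAAAGTAAAAA"), model, model)

    def test_zero_frequency_advises_smoothing(self):
        w = W("AAAAAAAAGTAAAAA")
        model = estimate_positional([w], pseudocount=0)
        other = W("CCCCCCCCGTCCCCC")
        with pytest.raises(ValueError, match="pseudocount"):
            positional_features(other, model, uniform_positional(15))

    def test_f3_nonpositive_under_own_training_model(self):
        ws = generate(GeneratorConfig(n_true=40, n_false=1, seed=6))[:40]
        model = estimate_positional(ws, pseudocount=0)
        try:
            for w in ws:
                feats = positional_features(w, model, uniform_positional(15, "false"))
                assert feats["f3"] <= 1e-9
        except ValueError:
            pytest.fail("training windows must have positive frequencies")


class TestDependencyFeatures:
    def test_own_single_sequence_model_scores_zero(self):
        w = W("AAAAAAAAGTAAAAA")
        dep = estimate_dependency([w], pseudocount=0)
        feats = dependency_features(w, dep, constant_dependency(15, 0.5, "false"))
        assert feats["f5"] == pytest.approx(0.0)
        assert feats["f7"] == pytest.approx(0.0)  # 2L(L-1) - 2L(L-1)

    def test_all_half_conditionals_at_length_15(self):
        # every q = 0.5: sum over 210 ordered pairs = 105,
        # f7 = 2*15*14 - 2*105 = 420 - 210 = 210
        dep = constant_dependency(15, 0.5)
        feats = dependency_features(W("AAAAAAAAGTAAAAA"), dep, dep)
        assert feats["f7"] == pytest.approx(210.0)
        assert feats["f5"] == pytest.approx(-210.0)  # 210 logs of 1/2
        assert feats["f6"] == 0.0 and feats["f8"] == 0.0

    def test_identical_models_null_contrasts(self):
        ws = generate(GeneratorConfig(n_true=25, n_false=25, seed=3))
        dep = estimate_dependency(ws[:25], pseudocount=1)
        feats = dependency_features(ws[30], dep, dep)
        assert feats["f6"] == pytest.approx(0.0, abs=1e-9)
        assert feats["f8"] == pytest.approx(0.0, abs=1e-9)


class TestCompositionalFeatures:
    def test_homopolymer_dinucleotides(self):
        feats = compositional_features(W("AAAAAAAAAAAAAAA"), k=2)
        assert feats["di_AA"] == pytest.approx(1.0)
        assert sum(v for n, v in feats.items() if n != "di_AA") == 0.0

    def test_di_counts_of_gt_window(self):
        feats = compositional_features(W("AAAAAAAAGTAAAAA"), k=2)
        assert feats["di_AA"] == pytest.approx(11 / 14)
        for mer in ("AG", "GT", "TA"):
            assert feats[f"di_{mer}"] == pytest.approx(1 / 14)

    def test_tetramer_counts_of_gt_window(self):
        feats = compositional_features(W("AAAAAAAAGTAAAAA"), k=4)
        assert feats["tet_AAAA"] == pytest.approx(7 / 12)
        for mer in ("AAAG", "AAGT", "AGTA", "GTAA", "TAAA"):
            assert feats[f"tet_{mer}"] == pytest.approx(1 / 12)

    @settings(max_examples=40, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=20), st.sampled_from([2, 3, 4]))
    def test_matches_naive_sliding_count_and_sums_to_one(self, seq, k):
        feats = compositional_features(SpliceWindow(seq, source_id="x"), k)
        n_windows = len(seq) - k + 1
        for mer in itertools.product("ACGT", repeat=k):
            mer = "".join(mer)
            naive = sum(seq[i : i + k] == mer for i in range(n_windows))
            key = {2: "di", 3: "tri", 4: "tet"}[k] + "_" + mer
            assert feats[key] == pytest.approx(naive / n_windows)
        assert sum(feats.values()) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            compositional_features(W("AAAAAAAAGTAAAAA"), k=5)


@pytest.fixture(scope="module")
def bundle():
    ws = generate(GeneratorConfig(n_true=60, n_false=60, seed=4))
    return FrequencyModelBundle(
        true_positional=estimate_positional(ws[:60], 1, class_tag="true"),
        false_positional=estimate_positional(ws[60:], 1, class_tag="false"),
        true_dependency=estimate_dependency(ws[:60], 1, class_tag="true"),
        false_dependency=estimate_dependency(ws[60:], 1, class_tag="false"),
    ), ws


class TestEncode:
    def test_full_set_has_344_features_in_blocks(self, bundle):
        models, ws = bundle
        mat = encode(ws[:3], models, FULL344)
        assert mat.shape == (3, 344)
        assert sum(c.startswith("tet_") for c in mat.columns) == 256
        assert sum(c.startswith("tri_") for c in mat.columns) == 64
        assert sum(c.startswith("di_") for c in mat.columns) == 16

    def test_reduced_set_has_49_features_with_block_counts(self, bundle):
        models, ws = bundle
        mat = encode(ws[0], models, TABLE1_49)
        assert mat.shape == (1, 49)
        assert sum(c.startswith("di_") for c in mat.columns) == 14
        assert sum(c.startswith("tri_") for c in mat.columns) == 15
        assert sum(c.startswith("tet_") for c in mat.columns) == 12

    def test_full_restricted_to_reduced_names_is_identical(self, bundle):
        models, ws = bundle
        full = encode(ws[:10], models, FULL344)
        reduced = encode(ws[:10], models, TABLE1_49)
        np.testing.assert_array_equal(
            full[list(TABLE1_49.names)].to_numpy(), reduced.to_numpy()
        )

    def test_deterministic_for_identical_windows(self, bundle):
        models, ws = bundle
        twice = encode([ws[0], ws[0]], models, TABLE1_49).to_numpy()
        np.testing.assert_array_equal(twice[0], twice[1])

    def test_kmer_blocks_are_probability_vectors(self, bundle):
        models, ws = bundle
        mat = encode(ws[:20], models, FULL344)
        for prefix in ("di_", "tri_", "tet_"):
            block = mat[[c for c in mat.columns if c.startswith(prefix)]]
            np.testing.assert_allclose(block.sum(axis=1), 1.0, atol=1e-9)

    def test_contrast_features_antisymmetric_under_model_swap(self, bundle):
        models, ws = bundle
        swapped = FrequencyModelBundle(
            true_positional=models.false_positional,
            false_positional=models.true_positional,
            true_dependency=models.false_dependency,
            false_dependency=models.true_dependency,
        )
        a = encode(ws[:5], models, FULL344)
        b = encode(ws[:5], swapped, FULL344)
        for f in ("f2", "f4", "f6", "f8"):
            np.testing.assert_allclose(a[f], -b[f], atol=1e-9)
        # true-only scores depend on whichever model sits in the true slot,
        # so they are not compared here; instead check they ignore the
        # false slot entirely
        shuffled_false = FrequencyModelBundle(
            true_positional=models.true_positional,
            false_positional=uniform_positional(15, "false"),
            true_dependency=models.true_dependency,
            false_dependency=constant_dependency(15, 0.5, "false"),
        )
        c = encode(ws[:5], shuffled_false, FULL344)
        for f in ("f1", "f3", "f5", "f7"):
            np.testing.assert_allclose(a[f], c[f], atol=1e-9)

    def test_unknown_manifest_name_is_configuration_error(self, bundle):
        models, ws = bundle
        bad = FeatureSetManifest(id="bad", names=("f1", "pentamer_AAAAA"))
        with pytest.raises(ValueError, match="unknown feature"):
            encode(ws[0], models, bad)

    def test_manifest_rejects_duplicates_and_round_trips(self):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureSetManifest(id="dup", names=("f1", "f1"))
        back = FeatureSetManifest.from_text(TABLE1_49.to_text(), id="table1_49")
        assert back.names == TABLE1_49.names
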