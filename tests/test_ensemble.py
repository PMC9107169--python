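"""Soft voting, module construction, and the end-to-end QC result."""

from fractions import Fraction

import numpy as np
import pytest

from ctqc.ensemble import (
    ClassProbabilities,
    build_body_part_module,
    build_contrast_module,
    run_imageqc,
    soft_vote,
)
from ctqc.phantom import BODY_PARTS, PhantomSpec, generate_phantom
from ctqc.preprocess import ConversionMethod, Plane


def cp(values, classes=None):
    classes = classes or tuple(f"c{i}" for i in range(len(values)))
    return ClassProbabilities(np.asarray(values, dtype=float), classes)


def exhaustive_vote(raw_vectors):
    """Oracle: per-class sums with exact rational arithmetic, then max."""
    sums = [
        sum(Fraction(v[i]).limit_denominator(10**12) for v in raw_vectors)
        for i in range(len(raw_vectors[0]))
    ]
    best = max(sums)
    return min(i for i, s in enumerate(sums) if s == best)


class TestSoftVote:
    def test_single_member_reduces_to_argmax(self):
        winner, scores = soft_vote([cp([0.6, 0.4])])
        assert winner == 0
        np.testing.assert_allclose(scores, [0.6, 0.4])

    def test_hand_summed_example(self):
        winner, scores = soft_vote([cp([0.6, 0.4]), cp([0.3, 0.7]), cp([0.2, 0.8])])
        assert winner == 1
        np.testing.assert_allclose(scores, [1.1, 1.9])

    def test_member_order_irrelevant(self, rng):
        vectors = [cp(v / v.sum()) for v in rng.uniform(0.01, 1, size=(5, 4))]
        base, base_scores = soft_vote(vectors)
        for _ in range(10):
            perm = rng.permutation(5)
            winner, scores = soft_vote([vectors[i] for i in perm])
            assert winner == base
            np.testing.assert_allclose(scores, base_scores)

    def test_tie_breaks_to_lowest_index(self):
        winner, _ = soft_vote([cp([0.5, 0.5])] * 3)
        assert winner == 0

    def test_soft_and_majority_voting_can_disagree(self):
        """Two of three members favour class 1, yet class 0 wins on summed mass."""
        members = [cp([0.9, 0.1]), cp([0.4, 0.6]), cp([0.45, 0.55])]
        majority = max((0, 1), key=lambda i: sum(np.argmax(m.values) == i for m in members))
        winner, scores = soft_vote(members)
        np.testing.assert_allclose(scores, [1.75, 1.25])
        assert winner == 0
        assert majority == 1
        assert winner != majority

    @pytest.mark.parametrize("m", [1, 3, 5])
    @pytest.mark.parametrize("n_classes", [2, 5])
    def test_matches_exhaustive_sum_oracle(self, m, n_classes, rng):
        for _ in range(60):
            raw = rng.uniform(0.001, 1, size=(m, n_classes))
            raw /= raw.sum(axis=1, keepdims=True)
            winner, _ = soft_vote([cp(v) for v in raw])
            assert winner == exhaustive_vote([list(v) for v in raw])

    def test_scale_invariance_of_argmax(self, rng):
        """Unnormalized sums: scaling every member equally moves scores, not the winner."""
        raw = rng.uniform(0.01, 1, size=(3, 5))
        raw /= raw.sum(axis=1, keepdims=True)
        vectors = [cp(v) for v in raw]
        winner, scores = soft_vote(vectors)
        for v in vectors:
            v.values = v.values * 7.3  # bypass normalization check deliberately
        winner_scaled, scores_scaled = soft_vote(vectors)
        assert winner_scaled == winner
        np.testing.assert_allclose(scores_scaled, scores * 7.3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            soft_vote([])

    def test_mismatched_class_sets_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            soft_vote([cp([0.5, 0.5], ("a", "b")), cp([0.5, 0.5], ("a", "c"))])

    def test_probability_contract_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cp([0.9, 0.3])
        with pytest.raises(ValueError, match="non-negative"):
            cp([1.2, -0.2])


class TestModuleConstruction:
    def _mip_models(self, factory, probs=None):
        probs = probs or [0.2] * 5
        probs = np.asarray(probs) / np.sum(probs)
        return [factory(probs, BODY_PARTS, ConversionMethod.MIP, p)
                for p in (Plane.AXIAL, Plane.SAGITTAL, Plane.CORONAL)]

    def _mid_models(self, factory, probs=(0.5, 0.5)):
        return [factory(probs, ("contrast", "non_contrast"), ConversionMethod.MID, p)
                for p in (Plane.AXIAL, Plane.SAGITTAL, Plane.CORONAL)]

    def test_body_module_canonical_plane_order(self, mock_model_factory):
        module = build_body_part_module(self._mip_models(mock_model_factory))
        assert module.m == 3
        assert module.n_classes == 5
        assert [p.value for _, p, _ in module.members] == ["axial", "sagittal", "coronal"]

    def test_missing_member_rejected(self, mock_model_factory):
        with pytest.raises(ValueError, match="missing member"):
            build_body_part_module(self._mip_models(mock_model_factory)[:2])

    def test_wrong_class_count_rejected(self, mock_model_factory):
        models = self._mip_models(mock_model_factory)
        models[1] = mock_model_factory([0.5, 0.5], ("a", "b"),
                                       ConversionMethod.MIP, Plane.SAGITTAL)
        with pytest.raises(ValueError, match="classes"):
            build_body_part_module(models)

    def test_unanimous_members_win(self, mock_model_factory):
        onehot = [0, 0, 1, 0, 0]  # chest
        module = build_body_part_module(self._mip_models(mock_model_factory, onehot))
        winner, _, _ = module.predict([None, None, None])
        assert module.classes[winner] == "chest"

    def test_contrast_module(self, mock_model_factory):
        module = build_contrast_module(self._mid_models(mock_model_factory))
        assert module.m == 3 and module.n_classes == 2

    def test_per_body_part_contrast_modules(self, mock_model_factory):
        triples = {part: self._mid_models(mock_model_factory) for part in BODY_PARTS}
        modules = build_contrast_module(triples, per_body_part=True)
        assert set(modules) == set(BODY_PARTS)
        assert all(m.m == 3 for m in modules.values())


@pytest.fixture(scope="module")
def volume():
    return generate_phantom(PhantomSpec("brain", True, (32, 64, 64), 5.0, seed=9))


class TestRunImageQC:

    def _modules(self, factory, body_probs, con_probs):
        body = build_body_part_module(
            [factory(body_probs, BODY_PARTS, ConversionMethod.MIP, p)
             for p in (Plane.AXIAL, Plane.SAGITTAL, Plane.CORONAL)])
        con = build_contrast_module(
            [factory(con_probs, ("contrast", "non_contrast"), ConversionMethod.MID, p)
             for p in (Plane.AXIAL, Plane.SAGITTAL, Plane.CORONAL)])
        return body, con

    def test_result_carries_votes_and_thumbnails(self, volume, mock_model_factory, tmp_path):
        body, con = self._modules(mock_model_factory, [0.1, 0.1, 0.6, 0.1, 0.1], [0.8, 0.2])
        result = run_imageqc(volume, body, con, thumbnail_dir=tmp_path)
        assert result.body_part == "chest"
        assert result.contrast == "contrast"
        assert len(result.body_member_probs) == 3
        assert len(result.contrast_member_probs) == 3
        assert result.body_scores["chest"] == pytest.approx(1.8)
        from pathlib import Path
        assert Path(result.thumbnail_mid).exists()
        assert Path(result.thumbnail_mip).exists()
        assert not result.body_tie

    def test_uniform_members_flag_tie(self, volume, mock_model_factory):
        body, con = self._modules(mock_model_factory, [0.2] * 5, [0.5, 0.5])
        result = run_imageqc(volume, body, con)
        assert result.body_tie and result.contrast_tie
        assert result.body_part == BODY_PARTS[0]  # lowest-index rule

    def test_determinism(self, volume, mock_model_factory):
        body, con = self._modules(mock_model_factory, [0.5, 0.2, 0.1, 0.1, 0.1], [0.3, 0.7])
        a = run_imageqc(volume, body, con)
        b = run_imageqc(volume, body, con)
        assert a.to_dict() == b.to_dict()

    def test_per_body_part_routing(self, volume, mock_model_factory):
        body, _ = self._modules(mock_model_factory, [0.6, 0.1, 0.1, 0.1, 0.1], [0.5, 0.5])
        routed = {
            "brain": build_contrast_module(
                [mock_model_factory([0.9, 0.1], ("contrast", "non_contrast"),
                                    ConversionMethod.MID, p)
                 for p in (Plane.AXIAL, Plane.SAGITTAL, Plane.CORONAL)]),
            "global": build_contrast_module(
                [mock_model_factory([0.1, 0.9], ("contrast", "non_contrast"),
                                    ConversionMethod.MID, p)
                 for p in (Plane.AXIAL, Plane.SAGITTAL, Plane.CORONAL)]),
        }
        result = run_imageqc(volume, body, routed)
        assert result.body_part == "brain"
        assert result.contrast == "contrast"  # brain triple, not the global one
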