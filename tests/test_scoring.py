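"""Edit-distance scoring, segmentation, and accuracy aggregation."""

import functools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphocomplex.languages import Scene
from morphocomplex.scoring import (
    NULL,
    aggregate_accuracy,
    exact_stem_match_proportion,
    levenshtein,
    normalized_levenshtein,
    read_productions,
    score_production,
    score_table,
    segment_word,
)


@functools.lru_cache(maxsize=None)
def lev_recursive(a: str, b: str) -> int:
    """Textbook recursive definition: independent oracle."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        lev_recursive(a[1:], b) + 1,
        lev_recursive(a, b[1:]) + 1,
        lev_recursive(a[1:], b[1:]) + (a[0] != b[0]),
    )


short = st.text(alphabet="abc", max_size=7)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a, b, d",
        [("kwako", "kwako", 0), ("an", "onk", 2), ("", "ak", 2), ("onk", "an", 2)],
    )
    def test_known_distances(self, a, b, d):
        assert levenshtein(a, b) == d

    @pytest.mark.parametrize(
        "a, b, nd", [("kwako", "kwako", 0.0), ("an", "onk", 2 / 3), ("", "ak", 1.0), ("", "", 0.0)]
    )
    def test_normalized(self, a, b, nd):
        assert normalized_levenshtein(a, b) == pytest.approx(nd)

    @settings(max_examples=300, derandomize=True)
    @given(short, short)
    def test_matches_recursive_oracle(self, a, b):
        assert levenshtein(a, b) == lev_recursive(a, b)

    @settings(max_examples=200, derandomize=True)
    @given(short, short)
    def test_symmetry_and_bounds(self, a, b):
        d = levenshtein(a, b)
        assert d == levenshtein(b, a)
        assert 0 <= normalized_levenshtein(a, b) <= 1
        assert d <= max(len(a), len(b))

    @settings(max_examples=200, derandomize=True)
    @given(short, short, short)
    def test_triangle_inequality(self, a, b, c):
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


EXP1_STEMS = {"won", "sum", "snap", "kwak", "twit", "woosh", "boing", "loop"}


class TestSegmentation:
    def test_exact_prefix(self):
        seg = segment_word("wonak", EXP1_STEMS)
        assert (seg.stem, seg.suffix, seg.method) == ("won", "ak", "exact_prefix")
        assert not seg.needs_review

    def test_zero_marked(self):
        seg = segment_word("snap", EXP1_STEMS)
        assert (seg.stem, seg.suffix, seg.method) == ("snap", NULL, "exact_prefix")

    def test_best_edit_fallback(self):
        # no stem is an exact prefix of "wanak"; the closest split is
        # prefix "wan" against stem "won" at distance 1, leaving "ak"
        seg = segment_word("wanak", EXP1_STEMS)
        assert (seg.stem, seg.suffix, seg.method) == ("wan", "ak", "best_edit")
        assert seg.needs_review

    def test_reconstruction_invariant(self):
        for word in ("wonak", "snap", "wanak", "looponk"):
            seg = segment_word(word, EXP1_STEMS)
            assert seg.surface == word

    def test_empty_word_errors(self):
        with pytest.raises(ValueError):
            segment_word("", EXP1_STEMS)


class TestScoreProduction:
    def test_perfect_reproduction(self, target):
        accs = score_production(
            ["wona", "kwako", "wooshan"], Scene("one", "duck", "straight"), target
        )
        assert [(a.stem_accuracy, a.suffix_accuracy) for a in accs] == [(1.0, 1.0)] * 3

    def test_wrong_verb_suffix(self, target):
        # produced suffix "onk" against target "an": distance 2, normalized 2/3
        accs = score_production(
            ["wona", "kwako", "wooshonk"], Scene("one", "duck", "straight"), target
        )
        assert accs[2].stem_accuracy == 1.0
        assert accs[2].suffix_accuracy == pytest.approx(1 / 3)

    def test_zero_marked_quantifier(self, target):
        # "won" bare: Q suffix NULL vs target "a" scores 1 - d("", "a")/1 = 0
        accs = score_production(
            ["won", "kwako", "wooshan"], Scene("one", "duck", "straight"), target
        )
        assert accs[0].stem_accuracy == 1.0
        assert accs[0].suffix_accuracy == 0.0

    def test_missing_word_scores_zero(self, target):
        accs = score_production(["wona", "kwako"], Scene("one", "duck", "straight"), target)
        assert (accs[2].stem_accuracy, accs[2].suffix_accuracy) == (0.0, 0.0)

    def test_scene_mismatch_errors(self, target):
        with pytest.raises(KeyError):
            score_production(["grolo", "nunj"], Scene(None, "dog", "bounce"), target)

    def test_accuracy_decreases_with_edits(self, target):
        """More random character edits cannot raise expected accuracy."""
        rng = np.random.default_rng(0)
        scene = Scene("two", "crocodile", "loop")
        base = ["sumuk", "snapop", "looponk"]

        def corrupt(words, n_edits):
            words = [list(w) for w in words]
            for _ in range(n_edits):
                w = words[rng.integers(3)]
                i = rng.integers(len(w))
                w[i] = "abcdefghijklmnopqrstuvwxyz"[rng.integers(26)]
            return ["".join(w) for w in words]

        means = []
        for n_edits in range(5):
            accs = [
                np.mean([
                    (a.stem_accuracy + a.suffix_accuracy) / 2
                    for a in score_production(corrupt(base, n_edits), scene, target)
                ])
                for _ in range(60)
            ]
            means.append(np.mean(accs))
        assert all(means[i] >= means[i + 1] - 0.02 for i in range(4))


class TestAggregation:
    def test_two_participant_grand_mean(self, target):
        scored = pd.DataFrame({
            "phase": [1] * 4,
            "participant_id": ["a", "a", "b", "b"],
            "stem_accuracy": [0.7, 0.9, 1.0, 1.0],
            "suffix_accuracy": [0.8, 0.8, 1.0, 1.0],
        })
        agg = aggregate_accuracy(scored)
        suffix = agg[agg["measure"] == "suffix"].iloc[0]
        assert suffix["mean"] == pytest.approx(0.9)  # mean of per-participant means
        assert suffix["n"] == 2

    def test_single_participant_degenerate_ci(self):
        scored = pd.DataFrame({
            "phase": [1, 1],
            "participant_id": ["a", "a"],
            "stem_accuracy": [1.0, 1.0],
            "suffix_accuracy": [1.0, 1.0],
        })
        agg = aggregate_accuracy(scored)
        assert (agg["ci_low"] == agg["mean"]).all()
        assert (agg["mean"] == 1.0).all()

    def test_noise_free_cohort_is_perfect_at_final_round(self, target):
        from morphocomplex.simulate import simulate_cohort, productions_to_frame

        df = productions_to_frame(simulate_cohort(target, n_participants=3, seed=11))
        scored = score_table(df[df["phase"] == 8], target)
        agg = aggregate_accuracy(scored)
        assert (agg["mean"] == 1.0).all()

    def test_hyphen_invariance(self, target, tmp_path):
        rows = [
            {"participant_id": "a", "phase": 1, "number": "one", "animal": "duck",
             "motion": "straight", "word1": w1, "word2": w2, "word3": w3, "condition": ""}
            for w1, w2, w3 in [("won-a", "kwak-o", "woosh-an"), ("wona", "kwako", "wooshan")]
        ]
        path = tmp_path / "prod.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        scored = score_table(read_productions(path), target)
        assert (scored["stem_accuracy"] == 1.0).all()
        assert (scored["suffix_accuracy"] == 1.0).all()


def test_exact_stem_match_proportion(target):
    rows = []
    for i, scene in enumerate(target.scenes):
        words = [w.surface for w in target.words_for(scene)]
        if i == 0:
            words[0] = "xona"  # one mangled stem out of 54 labels
        rows.append({
            "participant_id": "p1", "phase": 2,
            "number": scene.number, "animal": scene.animal, "motion": scene.motion,
            "word1": words[0], "word2": words[1], "word3": words[2], "condition": "",
        })
    props = exact_stem_match_proportion(pd.DataFrame(rows), target)
    assert props["p1"] == pytest.approx(53 / 54)
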