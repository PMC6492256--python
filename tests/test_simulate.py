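"""Synthetic learners, input mixing, and the dyadic interaction simulator."""

import numpy as np
import pandas as pd
import pytest

from morphocomplex.languages import Scene, generate_exp3_language
from morphocomplex.simulate import (
    DyadConfig,
    MixingDesign,
    SimLearnerConfig,
    build_learner_grammar,
    construct_training_phase,
    productions_to_frame,
    select_sources,
    simulate_cohort,
    simulate_dyad,
    simulate_dyads,
    simulate_learner_productions,
    trials_to_frame,
)


class TestSimulatedLearners:
    def test_target_grammar_reproduces_target(self, target):
        cfg = SimLearnerConfig(conditioning={"Q": None, "N": None, "V": None}, seed=5)
        recs = simulate_learner_productions(target, cfg, phases=[8])
        for r in recs:
            assert list(r.produced) == [w.surface for w in target.words_for(r.scene)]

    def test_empty_conditioning_is_invariant(self, target):
        cfg = SimLearnerConfig(conditioning={"Q": (), "N": (), "V": ()}, seed=2)
        grammar = build_learner_grammar(target, cfg)
        for wc in "QNV":
            assert len(set(grammar[wc].values())) == 1

    def test_zero_marking_rate_one_drops_all_suffixes(self, target):
        cfg = SimLearnerConfig(
            conditioning={"Q": ("Number",), "N": ("Number",), "V": ("Number",)},
            zero_marking_rate=1.0,
            seed=3,
        )
        recs = simulate_learner_productions(target, cfg, phases=[2])
        stems = {"Q": {"won", "sum"}, "N": {"kwak", "twit", "snap"}, "V": {"woosh", "boing", "loop"}}
        for r in recs:
            for wc, word in zip("QNV", r.produced):
                assert word in stems[wc]

    def test_deterministic_under_seed(self, target):
        cfg = SimLearnerConfig(conditioning={"Q": ("Number",), "N": None, "V": None},
                               noise_rate=0.1, zero_marking_rate=0.2, seed=9)
        a = productions_to_frame(simulate_learner_productions(target, cfg, [1, 2]))
        b = productions_to_frame(simulate_learner_productions(target, cfg, [1, 2]))
        pd.testing.assert_frame_equal(a, b)

    def test_cohort_reproducible(self, target):
        a = productions_to_frame(simulate_cohort(target, n_participants=3, seed=7))
        b = productions_to_frame(simulate_cohort(target, n_participants=3, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            SimLearnerConfig(conditioning={}, noise_rate=1.5)


class TestSourceSelection:
    def _cohort_frame(self, target, bad_words_by_participant):
        rows = []
        for pid, n_bad in bad_words_by_participant.items():
            for i, scene in enumerate(target.scenes):
                words = [w.surface for w in target.words_for(scene)]
                for j in range(3):
                    if i * 3 + j < n_bad:
                        words[j] = "x" + words[j][1:]
                rows.append({
                    "participant_id": pid, "phase": 2,
                    "number": scene.number, "animal": scene.animal,
                    "motion": scene.motion,
                    "word1": words[0], "word2": words[1], "word3": words[2],
                    "condition": "",
                })
        return pd.DataFrame(rows)

    def test_threshold_is_inclusive_at_ninety_percent(self, target):
        # 5/54 bad -> 0.907 selected; 6/54 -> 0.889 excluded; 0 bad -> selected
        df = self._cohort_frame(target, {"good": 0, "borderline": 5, "poor": 6})
        assert select_sources(df, target) == ["borderline", "good"]

    def test_requires_round_two(self, target):
        df = self._cohort_frame(target, {"a": 0}).assign(phase=8)
        with pytest.raises(ValueError):
            select_sources(df, target)


class TestTrainingPhaseConstruction:
    def _source_data(self, target, n_sources):
        data = {}
        for i in range(n_sources):
            data[f"s{i}"] = {
                scene: tuple(w.surface for w in target.words_for(scene))
                for scene in target.scenes
            }
        return data

    def test_small_counts_five_four(self, target):
        design = MixingDesign("small", "complex")
        items = construct_training_phase(design, self._source_data(target, 2), seed=0)
        assert len(items) == 9
        counts = pd.Series([src for _, _, src in items]).value_counts()
        assert sorted(counts) == [4, 5]

    def test_large_counts_two_and_ones(self, target):
        design = MixingDesign("large", "mixed")
        items = construct_training_phase(design, self._source_data(target, 8), seed=1)
        counts = pd.Series([src for _, _, src in items]).value_counts()
        assert sorted(counts) == [1] * 7 + [2]

    def test_source_count_mismatch_errors(self, target):
        with pytest.raises(ValueError):
            construct_training_phase(
                MixingDesign("large", "complex"), self._source_data(target, 2), seed=0
            )

    def test_scenes_distinct_and_paired_with_source_description(self, target):
        data = self._source_data(target, 2)
        data["s1"] = {s: ("ALT",) for s in target.scenes}  # distinguishable source
        items = construct_training_phase(MixingDesign("small", "mixed"), data, seed=5)
        scenes = [sc for sc, _, _ in items]
        assert len(set(scenes)) == 9
        for scene, desc, src in items:
            assert desc == data[src][scene]

    def test_scene_inclusion_frequency_half(self, target):
        """Each scene is sampled into a phase with probability 9/18."""
        data = self._source_data(target, 2)
        design = MixingDesign("small", "complex")
        counts = {s: 0 for s in target.scenes}
        n = 10000
        for seed in range(n):
            for scene, _, _ in construct_training_phase(design, data, seed=seed):
                counts[scene] += 1
        freqs = np.array(list(counts.values())) / n
        # 4 sigma around 0.5 at n=10000
        assert np.all(np.abs(freqs - 0.5) < 4 * np.sqrt(0.25 / n) + 1e-9)


class TestDyads:
    def test_complex_dyads_never_regularize(self):
        trials, post = simulate_dyads(10, "complex", seed=0)
        irr = trials[trials["item_type"] == "irregular"]
        assert irr["regularized"].sum() == 0
        assert post[post["item_type"] == "irregular"]["regularized"].sum() == 0

    def test_forced_adoption_regularizes_after_first_exposure(self):
        lang = generate_exp3_language(1)
        cfg = DyadConfig(dyad_type="mixed", p_adopt_after_exposure=1.0, p_persist=1.0, seed=4)
        trials, post = simulate_dyad(lang, cfg)
        df = trials_to_frame(trials)
        cpx = df[(df["director_role"] == "complex") & (df["item_type"] == "irregular")]
        assert cpx[cpx["round"] >= 2]["regularized"].all()
        post_df = trials_to_frame(post)
        assert post_df[(post_df["director_role"] == "complex")
                       & (post_df["item_type"] == "irregular")]["regularized"].all()

    def test_simple_speakers_always_regularize(self):
        trials, _ = simulate_dyads(10, "mixed", seed=2)
        simple = trials[(trials["director_role"] == "simple") & (trials["item_type"] == "irregular")]
        assert simple["regularized"].all()

    def test_first_regularization_follows_exposure(self):
        """A complex speaker's first regularized production of a cell is
        always preceded by the partner producing that exact form."""
        for seed in range(30):
            trials, _ = simulate_dyads(5, "mixed", seed=seed)
            for (dyad, animal, motion), grp in trials[
                trials["item_type"] == "irregular"
            ].groupby(["dyad_id", "animal", "motion"]):
                grp = grp.reset_index()
                cpx_reg = grp[(grp["director_role"] == "complex") & grp["regularized"]]
                if cpx_reg.empty:
                    continue
                first = cpx_reg.index[0]
                prior_simple = grp.loc[: first - 1]
                prior_simple = prior_simple[prior_simple["director_role"] == "simple"]
                assert (prior_simple["produced"] == grp.loc[first, "produced"]).any()

    def test_dyads_reproducible(self):
        a_t, a_p = simulate_dyads(4, "mixed", seed=9)
        b_t, b_p = simulate_dyads(4, "mixed", seed=9)
        pd.testing.assert_frame_equal(a_t, b_t)
        pd.testing.assert_frame_equal(a_p, b_p)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            DyadConfig(p_adopt_after_exposure=1.2)
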