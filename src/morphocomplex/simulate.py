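"""Synthetic participants for the three studies.

Nothing here is a cognitive model.  Simulated learners are grammars plus
noise: each learner conditions suffix choice on a configurable subset of
semantic features, with idiosyncratic form-to-cell assignments, optional
zero-marking, and character-level noise.  The mixing constructor builds
training sets by combining productions from 2 or 8 source speakers, and the
dyad simulator plays the director-matcher game between a speaker of the
full language and one trained only on its regular part, with a stochastic
accommodation rule.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .languages import (
    EXP1_ANIMALS,
    MOTION_LEVELS,
    NUMBER_LEVELS,
    LanguageSpec,
    Scene,
    regularized_description,
    render_description,
)

SIM_VERSION = "morphocomplex-sim-1"

_FEATURE_LEVELS = {
    "Number": NUMBER_LEVELS,
    "Animal": EXP1_ANIMALS,
    "Motion": MOTION_LEVELS,
}

_VOWELS = "aeiou"
_CONS = "bdfgjklmnprstvz"


@dataclass(frozen=True)
class ProductionRecord:
    participant_id: str
    phase: int | str
    scene: Scene
    produced: tuple[str, ...]
    condition: str | None = None


def productions_to_frame(records: list[ProductionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "phase": r.phase,
            "number": r.scene.number if r.scene.number is not None else "",
            "animal": r.scene.animal,
            "motion": r.scene.motion,
        }
        for i in range(3):
            row[f"word{i + 1}"] = r.produced[i] if i < len(r.produced) else ""
        row["condition"] = r.condition if r.condition is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)


# --- simulated learners -------------------------------------------------------


@dataclass
class SimLearnerConfig:
    """How one simulated learner deviates from the target language.

    ``conditioning`` maps each word class to the tuple of semantic features
    its suffix choice depends on; ``None`` means the learner reproduces the
    target's own suffix system for that class, the empty tuple a single
    invariant suffix.  ``noise_rate`` is a per-character edit probability
    applied to every produced word; ``zero_marking_rate`` the probability
    of dropping a suffix entirely (the observed early-learning rate is
    about 0.05).
    """

    conditioning: dict[str, tuple[str, ...] | None]
    suffix_source: str = "sampled_from_target"  # or "novel"
    noise_rate: float = 0.0
    zero_marking_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.noise_rate <= 1 or not 0 <= self.zero_marking_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")


def _novel_form(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        form = rng.choice(list(_VOWELS)) + "".join(
            rng.choice(list(_CONS), size=rng.integers(1, 3))
        )
        if form not in taken:
            return form


def _form_pool(target: LanguageSpec, word_class: str, config, rng, n: int) -> list[str]:
    """n distinct suffix forms: the target's inventory for the class first
    (unless the learner invents novel forms), topped up with novel ones."""
    pool: list[str] = []
    if config.suffix_source == "sampled_from_target":
        inventory = sorted({w.suffix for ws in target.entries.values() for w in ws if w.word_class == word_class and w.suffix})
        pool = list(rng.permutation(inventory))
    while len(pool) < n:
        pool.append(_novel_form(rng, set(pool)))
    return pool[:n]


def _three_feature_paradigm(target, word_class, config, rng) -> dict[Scene, str]:
    """A suffix system genuinely conditioned on all three features.

    Mirrors the target verb paradigm's shape — a special animal with its
    own singular/plural pair, a special motion overriding the plural — with
    the special levels, the number polarity, and the five forms drawn
    idiosyncratically.  (A saturated one-form-per-scene system would not
    count as 3-feature conditioning: it is indistinguishable from noise.)
    """
    forms = _form_pool(target, word_class, config, rng, 5)
    special_animal = rng.choice(EXP1_ANIMALS)
    special_motion = rng.choice(MOTION_LEVELS)
    marked_number = rng.choice(NUMBER_LEVELS)
    f_base, f_base_m, f_spec, f_spec_m, f_override = forms
    out = {}
    for scene in target.scenes:
        if scene.number == marked_number and scene.motion == special_motion:
            suf = f_override
        elif scene.animal == special_animal:
            suf = f_spec_m if scene.number == marked_number else f_spec
        else:
            suf = f_base_m if scene.number == marked_number else f_base
        out[scene] = suf
    return out


def _build_class_grammar(
    target: LanguageSpec, word_class: str, features, config, rng
) -> dict[Scene, str]:
    """Scene -> suffix for one word class under the configured conditioning."""
    scenes = target.scenes
    if features is None:
        return {
            s: next(w.suffix for w in target.entries[s] if w.word_class == word_class)
            for s in scenes
        }
    features = tuple(features)
    if len(features) == 3:
        return _three_feature_paradigm(target, word_class, config, rng)
    if not features:
        form = _form_pool(target, word_class, config, rng, 1)[0]
        return {s: form for s in scenes}
    # 1-2 features: one distinct form per conditioning cell, so the injected
    # partition is exactly identifiable.
    cells = sorted({tuple(getattr(s, f.lower()) for f in features) for s in scenes})
    forms = _form_pool(target, word_class, config, rng, len(cells))
    cell_form = dict(zip(cells, forms))
    return {s: cell_form[tuple(getattr(s, f.lower()) for f in features)] for s in scenes}


def _apply_char_noise(word: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return word
    out = []
    alphabet = string.ascii_lowercase
    for ch in word:
        if rng.random() < rate:
            op = rng.integers(3)
            if op == 0:  # substitute
                out.append(alphabet[rng.integers(26)])
            elif op == 1:  # delete
                pass
            else:  # insert before
                out.append(alphabet[rng.integers(26)])
                out.append(ch)
        else:
            out.append(ch)
    return "".join(out)


def build_learner_grammar(target: LanguageSpec, config: SimLearnerConfig) -> dict[str, dict[Scene, str]]:
    """The learner's fixed suffix system: word class -> scene -> suffix."""
    rng = np.random.default_rng(config.seed)
    return {
        wc: _build_class_grammar(target, wc, config.conditioning.get(wc), config, rng)
        for wc in target.word_classes
    }


def simulate_learner_productions(
    target: LanguageSpec,
    config: SimLearnerConfig,
    phases: list[int],
    participant_id: str = "sim",
    condition: str | None = None,
) -> list[ProductionRecord]:
    """One production per scene per phase under the learner's grammar.

    Stems come from the target (subject to character noise); suffixes from
    the learner grammar, with zero-marking then character noise applied.
    Deterministic given the config seed.
    """
    grammar = build_learner_grammar(target, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records = []
    for phase in phases:
        for scene in target.scenes:
            words = []
            for tw in target.entries[scene]:
                suffix = grammar[tw.word_class][scene]
                if suffix and rng.random() < config.zero_marking_rate:
                    suffix = ""
                word = _apply_char_noise(tw.stem, config.noise_rate, rng) + _apply_char_noise(
                    suffix, config.noise_rate, rng
                )
                words.append(word if word else tw.stem)
            records.append(
                ProductionRecord(participant_id, phase, scene, tuple(words), condition)
            )
    return records


#: Per-phase study conditions for an eight-round learning cohort: early
#: rounds condition on a single feature with noisy stems and the observed
#: ~5% zero-marking; middle rounds on two; late rounds reproduce the target.
DEFAULT_COHORT_SCHEDULE = {
    1: ({"Q": ("Number",), "N": ("Number",), "V": ("Motion",)}, 0.04, 0.08),
    2: ({"Q": ("Number",), "N": ("Number",), "V": ("Motion",)}, 0.02, 0.05),
    3: ({"Q": ("Number",), "N": ("Number",), "V": ("Number", "Motion")}, 0.02, 0.03),
    4: ({"Q": ("Number", "Animal"), "N": ("Number",), "V": ("Number", "Motion")}, 0.01, 0.02),
    5: ({"Q": ("Number", "Animal"), "N": ("Number", "Animal"), "V": ("Number", "Motion")}, 0.01, 0.01),
    6: ({"Q": None, "N": None, "V": None}, 0.005, 0.0),
    7: ({"Q": None, "N": None, "V": None}, 0.0, 0.0),
    8: ({"Q": None, "N": None, "V": None}, 0.0, 0.0),
}


def simulate_cohort(
    target: LanguageSpec,
    n_participants: int = 26,
    seed: int = 0,
    schedule: dict | None = None,
) -> list[ProductionRecord]:
    """An eight-round cohort of simulated learners, one production per
    scene per round, converging on the target language per the schedule."""
    schedule = DEFAULT_COHORT_SCHEDULE if schedule is None else schedule
    ss = np.random.SeedSequence(seed)
    records = []
    for i, child in enumerate(ss.spawn(n_participants)):
        base_seed = int(child.generate_state(1)[0] % (2**31))
        for phase, (conditioning, noise, zero) in schedule.items():
            config = SimLearnerConfig(
                conditioning=conditioning,
                noise_rate=noise,
                zero_marking_rate=zero,
                seed=base_seed + phase,
            )
            records.extend(
                simulate_learner_productions(
                    target, config, [phase], participant_id=f"p{i + 1:02d}"
                )
            )
    return records


# --- source selection and input mixing ---------------------------------------


def select_sources(
    exp1_records: pd.DataFrame, target: LanguageSpec, criterion: float = 0.90
) -> list[str]:
    """Participants whose round-2 stem productions exactly match the target
    stems for at least ``criterion`` of the labels."""
    from .scoring import exact_stem_match_proportion

    round2 = exp1_records[exp1_records["phase"].astype(int) == 2]
    if round2.empty:
        raise ValueError("records contain no round-2 phase")
    props = exact_stem_match_proportion(round2, target)
    return sorted(props[props >= criterion].index)


@dataclass(frozen=True)
class MixingDesign:
    """Input construction for one second-generation learner: 2 or 8 source
    speakers, all complex (round-8) or half simplified (round-2)."""

    population_size: str  # "small" (2 sources) or "large" (8 sources)
    composition: str  # "complex" or "mixed"

    @property
    def n_sources(self) -> int:
        return {"small": 2, "large": 8}[self.population_size]

    @property
    def per_source_counts(self) -> list[int]:
        return [5, 4] if self.population_size == "small" else [2] + [1] * 7

    @property
    def source_phases(self) -> list[int]:
        """Which round each source's productions are drawn from: round 8
        for complex sources, round 2 for the simplified half in mixed."""
        n = self.n_sources
        if self.composition == "complex":
            return [8] * n
        return [2] * (n // 2) + [8] * (n // 2)


def construct_training_phase(
    design: MixingDesign,
    source_data: dict[str, dict[Scene, tuple[str, ...]]],
    seed: int,
) -> list[tuple[Scene, tuple[str, ...], str]]:
    """One training phase: 9 of the 18 scenes sampled without replacement,
    divided across sources with counts {5,4} (small) or {2,1x7} (large, the
    double contributor chosen uniformly); each scene paired with its
    source's description.  Returns (scene, description, source) triples."""
    if len(source_data) != design.n_sources:
        raise ValueError(
            f"{design.population_size} design needs {design.n_sources} sources, got {len(source_data)}"
        )
    rng = np.random.default_rng(seed)
    sources = sorted(source_data)
    all_scenes = sorted(next(iter(source_data.values())), key=lambda s: (str(s.number), s.animal, s.motion))
    chosen = [all_scenes[i] for i in rng.choice(len(all_scenes), size=9, replace=False)]
    counts = list(rng.permutation(design.per_source_counts))
    assignment = [src for src, c in zip(sources, counts) for _ in range(c)]
    rng.shuffle(chosen)
    return [
        (scene, source_data[src][scene], src)
        for scene, src in zip(chosen, assignment)
    ]


# --- dyadic interaction -------------------------------------------------------

#: Per-opportunity adoption probability after exposure, calibrated so the
#: expected share of speakers ever regularizing over three rounds matches
#: the observed 29/40 (see docs/methods.md for the derivation).
DEFAULT_P_ADOPT = 0.411


@dataclass
class DyadConfig:
    dyad_type: str = "mixed"  # "complex" or "mixed"
    rounds: int = 3
    p_adopt_after_exposure: float = DEFAULT_P_ADOPT
    p_persist: float = 21 / 22
    p_match_known: float = 0.97
    p_match_unknown_irregular: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_adopt_after_exposure, self.p_persist, self.p_match_known, self.p_match_unknown_irregular):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TrialRecord:
    dyad_id: str
    dyad_type: str
    round: int | str
    director_id: str
    director_role: str  # "complex" or "simple"
    matcher_id: str | None
    scene: Scene
    produced: str
    item_type: str  # "regular" or "irregular" (in the full language)
    regularized: bool | None  # None for regular items
    matched_correctly: bool | None  # None for post-test solo productions


class _Agent:
    def __init__(self, agent_id: str, role: str, spec: LanguageSpec):
        self.id = agent_id
        self.role = role  # complex | simple
        self.spec = spec
        # complex-speaker accommodation state per irregular cell
        self.exposed: set = set()
        self.adopted: set = set()
        self.reverted: set = set()

    def produce(self, scene: Scene, config: DyadConfig, rng) -> tuple[str, bool | None]:
        cell = (scene.animal, scene.motion)
        irregular = cell in self.spec.irregular_cells
        if not irregular:
            return render_description(self.spec, scene), None
        if self.role == "simple":
            # never trained on the irregular pairing: regularize
            return regularized_description(self.spec, scene), True
        if cell in self.reverted:
            return render_description(self.spec, scene), False
        if cell in self.adopted:
            if rng.random() < config.p_persist:
                return regularized_description(self.spec, scene), True
            self.adopted.discard(cell)
            self.reverted.add(cell)
            return render_description(self.spec, scene), False
        if cell in self.exposed and rng.random() < config.p_adopt_after_exposure:
            self.adopted.add(cell)
            return regularized_description(self.spec, scene), True
        return render_description(self.spec, scene), False

    def knows_form(self, scene: Scene, description: str) -> bool:
        cell = (scene.animal, scene.motion)
        if self.role == "complex":
            return True  # trained on the full language; regularizations are transparent
        if cell in self.spec.irregular_cells:
            return description == regularized_description(self.spec, scene)
        return description == render_description(self.spec, scene)


def simulate_dyad(
    target: LanguageSpec, config: DyadConfig, dyad_id: str = "d1"
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Play one dyad: ``rounds`` rounds of alternating director-matcher
    trials over all 9 scenes per director per round, then one solo
    post-test pass each.

    In mixed dyads the simple agent was only trained on the seven regular
    scene-description pairings and regularizes the two irregular cells; a
    complex agent exposed to its partner's regularized form for a cell
    adopts it with ``p_adopt_after_exposure`` at the next opportunity and
    thereafter persists with ``p_persist`` (a persistence failure reverts
    the cell for good).  Matching succeeds with ``p_match_known`` for forms
    in the matcher's grammar and ``p_match_unknown_irregular`` otherwise.
    """
    rng = np.random.default_rng(config.seed)
    roles = ("complex", "complex") if config.dyad_type == "complex" else ("complex", "simple")
    agents = [_Agent(f"{dyad_id}_{role}{i}" if roles.count(role) > 1 else f"{dyad_id}_{role}", role, target)
              for i, role in enumerate(roles)]
    scenes = target.scenes
    trials: list[TrialRecord] = []

    for rnd in range(1, config.rounds + 1):
        orders = [list(rng.permutation(len(scenes))) for _ in agents]
        first = int(rng.integers(2))
        for t in range(len(scenes)):
            for j in (first, 1 - first):
                director, matcher = agents[j], agents[1 - j]
                scene = scenes[orders[j][t]]
                produced, regularized = director.produce(scene, config, rng)
                cell = (scene.animal, scene.motion)
                irregular = cell in target.irregular_cells
                if matcher.knows_form(scene, produced):
                    matched = rng.random() < config.p_match_known
                else:
                    matched = rng.random() < config.p_match_unknown_irregular
                # exposure: a complex matcher hears its partner's regularized form
                if irregular and regularized and matcher.role == "complex":
                    matcher.exposed.add(cell)
                trials.append(TrialRecord(
                    dyad_id, config.dyad_type, rnd, director.id, director.role,
                    matcher.id, scene, produced,
                    "irregular" if irregular else "regular",
                    regularized, bool(matched),
                ))

    posttest: list[TrialRecord] = []
    for agent in agents:
        for scene in scenes:
            cell = (scene.animal, scene.motion)
            irregular = cell in target.irregular_cells
            if agent.role == "simple":
                produced, regularized = (regularized_description(target, scene), True) if irregular \
                    else (render_description(target, scene), None)
            else:
                if irregular:
                    regularized = cell in agent.adopted
                    produced = regularized_description(target, scene) if regularized \
                        else render_description(target, scene)
                else:
                    produced, regularized = render_description(target, scene), None
            posttest.append(TrialRecord(
                dyad_id, config.dyad_type, "posttest", agent.id, agent.role,
                None, scene, produced,
                "irregular" if irregular else "regular",
                regularized if irregular else None, None,
            ))
    return trials, posttest


def simulate_dyads(
    n_dyads: int, dyad_type: str, seed: int, config: DyadConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_dyads`` dyads, each with its own randomly generated
    target language; returns (interaction trials, post-test) frames."""
    from .languages import generate_exp3_language

    base = config if config is not None else DyadConfig(dyad_type=dyad_type)
    ss = np.random.SeedSequence(seed)
    trials_all, post_all = [], []
    for i, child in enumerate(ss.spawn(n_dyads)):
        s1, s2 = (int(x % (2**31)) for x in child.generate_state(2))
        lang = generate_exp3_language(s1)
        cfg = replace(base, dyad_type=dyad_type, seed=s2)
        trials, post = simulate_dyad(lang, cfg, dyad_id=f"{dyad_type}_d{i + 1:03d}")
        trials_all.extend(trials)
        post_all.extend(post)
    return trials_to_frame(trials_all), trials_to_frame(post_all)


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "dyad_id": t.dyad_id,
            "dyad_type": t.dyad_type,
            "round": t.round,
            "director_id": t.director_id,
            "director_role": t.director_role,
            "matcher_id": t.matcher_id if t.matcher_id is not None else "",
            "animal": t.scene.animal,
            "motion": t.scene.motion,
            "produced": t.produced,
            "item_type": t.item_type,
            "regularized": t.regularized,
            "matched_correctly": t.matched_correctly,
        }
        for t in trials
    ])
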