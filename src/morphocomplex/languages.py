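"""Miniature artificial languages describing animal-motion scenes.

A scene is a meaning: how many animals (one/two), which animal, and which
motion they perform.  A language maps every scene to a short description.
Two language families are supported:

* the 18-scene learning-study language, whose descriptions are a quantifier,
  a noun, and a verb, each a stem plus a (possibly zero) number-marking
  suffix with several irregularities; and
* 9-scene noun-verb languages for the interaction study, whose complexity
  lives in two lexically irregular verb forms.

Stored forms are plain unhyphenated strings; the stem/suffix segmentation is
kept as a separate index on each entry (presentation hyphens are never part
of the strings themselves).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

NUMBER_LEVELS = ("one", "two")
EXP1_ANIMALS = ("duck", "bird", "crocodile")
EXP3_ANIMALS = ("duck", "dog", "crocodile")
MOTION_LEVELS = ("straight", "bounce", "loop")

WORD_CLASSES_EXP1 = ("Q", "N", "V")
WORD_CLASSES_EXP3 = ("N", "V")

#: Verb form inventory for randomly generated interaction-study languages.
EXP3_VERB_FORMS = ("jing", "rald", "nunj", "ferb", "yath")

#: Noun for each animal in the interaction-study languages.
EXP3_NOUNS = {"duck": "kwako", "dog": "grolo", "crocodile": "snapo"}

GENERATOR_VERSION = "morphocomplex-langgen-1"


@dataclass(frozen=True, order=True)
class Scene:
    """A meaning: (number, animal, motion).  ``number`` is None for the
    9-scene languages, which do not mark number."""

    number: str | None
    animal: str
    motion: str

    def __post_init__(self):
        if self.number is not None and self.number not in NUMBER_LEVELS:
            raise ValueError(f"bad number level: {self.number!r}")
        if self.motion not in MOTION_LEVELS:
            raise ValueError(f"bad motion level: {self.motion!r}")


@dataclass(frozen=True)
class Word:
    """One word of a description, stored segmented."""

    word_class: str
    stem: str
    suffix: str  # empty string for zero-marked / suffixless words

    @property
    def surface(self) -> str:
        return self.stem + self.suffix


@dataclass
class LanguageSpec:
    """A total mapping from scenes to segmented descriptions."""

    word_classes: tuple[str, ...]
    entries: dict[Scene, tuple[Word, ...]]
    irregular_cells: frozenset[tuple[str, str]] = frozenset()
    meta: dict = field(default_factory=dict)

    @property
    def scenes(self) -> list[Scene]:
        return sorted(self.entries, key=_scene_sort_key)

    def stems(self, word_class: str) -> set[str]:
        return {w.stem for ws in self.entries.values() for w in ws if w.word_class == word_class}

    def words_for(self, scene: Scene) -> tuple[Word, ...]:
        try:
            return self.entries[scene]
        except KeyError:
            raise KeyError(f"scene not in language: {scene}") from None


def _scene_sort_key(s: Scene):
    num = NUMBER_LEVELS.index(s.number) if s.number is not None else -1
    animals = EXP1_ANIMALS if s.animal in EXP1_ANIMALS else EXP3_ANIMALS
    return (num, animals.index(s.animal), MOTION_LEVELS.index(s.motion))


def exp1_scenes() -> list[Scene]:
    """All 18 scenes of the learning study (2 numbers x 3 animals x 3 motions)."""
    return sorted(
        (Scene(n, a, m) for n, a, m in itertools.product(NUMBER_LEVELS, EXP1_ANIMALS, MOTION_LEVELS)),
        key=_scene_sort_key,
    )


def exp3_scenes() -> list[Scene]:
    """All 9 scenes of the interaction study (3 animals x 3 motions, no number)."""
    return sorted(
        (Scene(None, a, m) for a, m in itertools.product(EXP3_ANIMALS, MOTION_LEVELS)),
        key=_scene_sort_key,
    )


# --- the 18-scene target language -------------------------------------------

_Q_STEMS = {"one": "won", "two": "sum"}
_N_STEMS = {"duck": "kwak", "bird": "twit", "crocodile": "snap"}
_V_STEMS = {"straight": "woosh", "bounce": "boing", "loop": "loop"}


def _exp1_q_suffix(scene: Scene) -> str:
    if scene.animal == "crocodile":
        return "u" if scene.number == "one" else "uk"
    return "a" if scene.number == "one" else "ak"


def _exp1_n_suffix(scene: Scene) -> str:
    if scene.number == "one" or scene.animal == "bird":
        return "o"
    return "op"


def _exp1_v_suffix(scene: Scene) -> str:
    if scene.number == "two" and scene.motion == "loop":
        return "onk"
    if scene.animal == "crocodile":
        return "en" if scene.number == "one" else "esp"
    return "an" if scene.number == "one" else "asp"


def build_exp1_target() -> LanguageSpec:
    """The target language of the learning study.

    Quantifier suffixes mark number and are irregular for the crocodile
    (-a/-ak vs -u/-uk); noun plural -op is dropped for the bird; verb
    suffixes mark number with an animal-conditioned vowel (-an/-asp vs
    -en/-esp) and all plural looping scenes take -onk.
    """
    entries: dict[Scene, tuple[Word, ...]] = {}
    for scene in exp1_scenes():
        entries[scene] = (
            Word("Q", _Q_STEMS[scene.number], _exp1_q_suffix(scene)),
            Word("N", _N_STEMS[scene.animal], _exp1_n_suffix(scene)),
            Word("V", _V_STEMS[scene.motion], _exp1_v_suffix(scene)),
        )
    return LanguageSpec(WORD_CLASSES_EXP1, entries, meta={"language": "exp1_target"})


# --- random 9-scene languages ------------------------------------------------


def valid_irregular_placements() -> list[frozenset[tuple[str, str]]]:
    """All unordered pairs of (animal, motion) cells sharing no animal and
    no motion.  There are 18 on the 3x3 grid."""
    cells = list(itertools.product(EXP3_ANIMALS, MOTION_LEVELS))
    return [
        frozenset({c1, c2})
        for c1, c2 in itertools.combinations(cells, 2)
        if c1[0] != c2[0] and c1[1] != c2[1]
    ]


def generate_exp3_language(seed: int) -> LanguageSpec:
    """Randomly generate a 9-scene noun-verb language.

    Three of the five verb forms are drawn at random as regular verbs for
    the three motions; the remaining two forms become irregular verbs,
    placed in two cells that share neither an animal nor a motion (the two
    forms are assigned to the two chosen cells in random order).
    Deterministic given ``seed``.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed)
    forms = list(EXP3_VERB_FORMS)
    order = rng.permutation(len(forms))
    regular = {m: forms[order[i]] for i, m in enumerate(MOTION_LEVELS)}
    irregular_forms = [forms[order[3]], forms[order[4]]]

    placements = valid_irregular_placements()
    cells = sorted(placements[rng.integers(len(placements))])
    rng.shuffle(irregular_forms)
    irregular = {cell: form for cell, form in zip(cells, irregular_forms)}

    entries: dict[Scene, tuple[Word, ...]] = {}
    for scene in exp3_scenes():
        verb = irregular.get((scene.animal, scene.motion), regular[scene.motion])
        entries[scene] = (
            Word("N", EXP3_NOUNS[scene.animal], ""),
            Word("V", verb, ""),
        )
    return LanguageSpec(
        WORD_CLASSES_EXP3,
        entries,
        irregular_cells=frozenset(irregular),
        meta={
            "language": "exp3_random",
            "seed": int(seed),
            "generator_version": GENERATOR_VERSION,
            "regular_verbs": regular,
            "irregular_verbs": {f"{a}|{m}": f for (a, m), f in irregular.items()},
        },
    )


def regularized_description(spec: LanguageSpec, scene: Scene) -> str:
    """The fully regular description of a scene: noun plus the regular verb
    of the scene's motion, ignoring any irregular cell."""
    regular = spec.meta.get("regular_verbs")
    if regular is None:
        raise ValueError("spec carries no regular-verb table")
    return f"{EXP3_NOUNS[scene.animal]} {regular[scene.motion]}"


# --- rendering and (de)serialization -----------------------------------------


def render_description(spec: LanguageSpec, scene: Scene) -> str:
    """Concatenate stem+suffix per word class, space-separated."""
    return " ".join(w.surface for w in spec.words_for(scene))


def _scene_to_json(s: Scene) -> dict:
    d = {"animal": s.animal, "motion": s.motion}
    if s.number is not None:
        d = {"number": s.number, **d}
    return d


def spec_to_json(spec: LanguageSpec) -> dict:
    return {
        "word_classes": list(spec.word_classes),
        "scenes": [_scene_to_json(s) for s in spec.scenes],
        "entries": [
            {
                "scene": _scene_to_json(s),
                "words": [
                    {"class": w.word_class, "stem": w.stem, "suffix": w.suffix}
                    for w in spec.entries[s]
                ],
            }
            for s in spec.scenes
        ],
        "irregular_cells": sorted(list(c) for c in spec.irregular_cells),
        "meta": spec.meta,
    }


def write_spec(spec: LanguageSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(spec_to_json(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")


def parse_spec(path) -> LanguageSpec:
    try:
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
    except json.JSONDecodeError as err:
        raise ValueError(f"malformed language spec {path}: {err.msg} at line {err.lineno} column {err.colno}") from err
    entries: dict[Scene, tuple[Word, ...]] = {}
    for entry in data["entries"]:
        sd = entry["scene"]
        scene = Scene(sd.get("number"), sd["animal"], sd["motion"])
        entries[scene] = tuple(
            Word(w["class"], w["stem"], w["suffix"]) for w in entry["words"]
        )
    return LanguageSpec(
        tuple(data["word_classes"]),
        entries,
        irregular_cells=frozenset(tuple(c) for c in data.get("irregular_cells", [])),
        meta=data.get("meta", {}),
    )


def validate_spec(spec: LanguageSpec) -> None:
    """Raise if a language violates its structural invariants."""
    for scene, words in spec.entries.items():
        classes = tuple(w.word_class for w in words)
        if classes != spec.word_classes:
            raise ValueError(f"scene {scene}: word classes {classes} != {spec.word_classes}")
    if spec.irregular_cells:
        if len(spec.irregular_cells) != 2:
            raise ValueError("expected exactly 2 irregular cells")
        (a1, m1), (a2, m2) = sorted(spec.irregular_cells)
        if a1 == a2 or m1 == m2:
            raise ValueError("irregular cells must share no animal and no motion")
        regular = spec.meta.get("regular_verbs", {})
        for (animal, motion) in spec.irregular_cells:
            verb = next(
                w.surface
                for w in spec.entries[Scene(None, animal, motion)]
                if w.word_class == "V"
            )
            if regular and verb == regular[motion]:
                raise ValueError(f"irregular verb equals the regular verb of {motion}")
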