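#!/usr/bin/env python
"""Mixing productions from multiple source speakers.

From the simulated cohort (02), selects source speakers whose round-2 stem
productions exactly match the target for at least 90% of labels, builds
training phases for the four input conditions (small/large x
complex/mixed: 2 or 8 sources, all round-8 data or half round-2), and
measures the conditioning complexity of each condition's pooled input.

The point of interest: learners simplify idiosyncratically, so pooling
several simplified round-2 systems yields input that is itself complex by
the conditioning measure - mixing masks individual-level simplification.

Writes results/exp2_source_selection.csv and results/exp2_pooled_input_complexity.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from morphocomplex.conditioning import best_model
from morphocomplex.languages import Scene, build_exp1_target
from morphocomplex.pipeline import _segment_suffixes
from morphocomplex.scoring import exact_stem_match_proportion, read_productions
from morphocomplex.simulate import MixingDesign, construct_training_phase, select_sources

OUT = Path(__file__).resolve().parent.parent / "results"
CONDITIONS = [("small", "complex"), ("small", "mixed"), ("large", "complex"), ("large", "mixed")]


def pooled_complexity(df, target):
    """Complexity of pooled suffix data per word class (all rows together,
    several observations per scene)."""
    suffixes = _segment_suffixes(df, target)
    out = {}
    for wc, grp in suffixes.groupby("word_class"):
        scenes = [Scene(r.number, r.animal, r.motion) for r in grp.itertuples(index=False)]
        out[wc] = best_model(scenes, list(grp["suffix"])).complexity
    return out


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)

    src = OUT / "exp1_productions.csv"
    if not src.exists():
        raise SystemExit(f"{src} missing - run analysis/02_simulate_learning_cohort.py first")
    target = build_exp1_target()
    cohort = read_productions(src)

    round2 = cohort[cohort["phase"].astype(int) == 2]
    props = exact_stem_match_proportion(round2, target)
    sources = select_sources(cohort, target)
    props.rename_axis("participant_id").reset_index().assign(
        selected=lambda d: d["participant_id"].isin(sources)
    ).to_csv(OUT / "exp2_source_selection.csv", index=False, float_format="%.6f")
    print(f"{len(sources)} of {props.size} simulated learners meet the >=90% "
          f"exact-stem criterion at round 2: {', '.join(sources)}")

    rows = []
    word_cols = ["word1", "word2", "word3"]
    for size, comp in CONDITIONS:
        design = MixingDesign(size, comp)
        chosen = list(rng.choice(sources, size=design.n_sources, replace=False))
        source_data = {}
        for pid, phase in zip(chosen, design.source_phases):
            sub = cohort[(cohort["participant_id"] == pid) & (cohort["phase"].astype(int) == phase)]
            source_data[pid] = {
                Scene(r.number, r.animal, r.motion): tuple(getattr(r, c) for c in word_cols)
                for r in sub.itertuples(index=False)
            }
        # pool several training phases' worth of input for a stable measure
        pooled = []
        for k in range(8):
            for scene, desc, src_id in construct_training_phase(
                design, source_data, seed=int(rng.integers(2**31))
            ):
                pooled.append({
                    "participant_id": f"{size}_{comp}", "phase": 0,
                    "number": scene.number, "animal": scene.animal, "motion": scene.motion,
                    "word1": desc[0], "word2": desc[1], "word3": desc[2], "condition": comp,
                })
        cx = pooled_complexity(pd.DataFrame(pooled), target)
        rows.append({"condition": f"{size}-{comp}", **{f"complexity_{k}": v for k, v in cx.items()}})
        print(f"{size}-{comp}: pooled-input complexity Q/N/V = "
              f"{cx['Q']}/{cx['N']}/{cx['V']}")

    pd.DataFrame(rows).to_csv(OUT / "exp2_pooled_input_complexity.csv", index=False)
    print("\nMixed-input conditions pool idiosyncratically simplified systems, so "
          "their pooled input is not systematically simpler than the complex conditions'.")


if __name__ == "__main__":
    main()
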