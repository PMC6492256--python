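"""Conditioning complexity of a suffix system via exhaustive model selection.

For one learner's suffix choices within a word class at one round, every
multinomial-logit model predicting suffix from semantic scene features is
fitted and the lowest-AIC model selected; the complexity score is the number
of distinct semantic features that model uses (0 for intercept-only up to 3).

The candidate predictor set contains, for each feature, both its full
partition and every two-way collapse that singles out one level (a 3-level
feature contributes the 3-way contrast plus three one-vs-rest binarizations;
the binary Number feature only its 2-way contrast).  A model includes at
most one variant per feature — a collapsed variant is nested inside the full
one, so co-inclusion would be collinear.  Candidate models are all additive
combinations plus, for each selection of two or more variants, the full
factorial model with all interactions among the included variants.

Fitting is plain maximum likelihood by quasi-Newton iteration with a hard
cap of 100 iterations and a relative log-likelihood tolerance of 1e-8.
Under complete separation the likelihood is left wherever the capped
iteration takes it, which keeps AIC values comparable with the conventional
capped-iteration multinomial fitters this procedure mirrors.  An optional
ridge penalty is available but off by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .languages import EXP1_ANIMALS, MOTION_LEVELS, NUMBER_LEVELS, Scene

FEATURES = ("Number", "Animal", "Motion")

_FEATURE_LEVELS = {
    "Number": NUMBER_LEVELS,
    "Animal": EXP1_ANIMALS,
    "Motion": MOTION_LEVELS,
}

MAX_ITER = 100
LOGLIK_RTOL = 1e-8
AIC_TIE_TOL = 1e-9


@dataclass(frozen=True)
class PredictorVariant:
    """One coded version of a semantic feature: the full partition or a
    one-vs-rest binarization (``split_level`` names the singled-out level;
    None means the full partition)."""

    feature: str
    split_level: str | None = None

    @property
    def name(self) -> str:
        if self.split_level is None:
            return self.feature
        return f"{self.feature}[{self.split_level}]"

    @property
    def n_columns(self) -> int:
        if self.split_level is not None:
            return 1
        return len(_FEATURE_LEVELS[self.feature]) - 1

    def columns(self, scenes: list[Scene]) -> np.ndarray:
        """Dummy-coded design columns, shape (n_scenes, n_columns)."""
        values = [getattr(s, self.feature.lower()) for s in scenes]
        if self.split_level is not None:
            return np.array([[v == self.split_level] for v in values], dtype=float)
        levels = _FEATURE_LEVELS[self.feature]
        return np.array(
            [[v == lev for lev in levels[1:]] for v in values], dtype=float
        )


def expand_variants(feature: str) -> list[PredictorVariant]:
    """Admissible codings of one feature: binary Number has just its 2-way
    contrast; 3-level features have the full 3-way contrast plus the three
    one-vs-rest collapses."""
    levels = _FEATURE_LEVELS[feature]
    if len(levels) == 2:
        return [PredictorVariant(feature)]
    return [PredictorVariant(feature)] + [
        PredictorVariant(feature, lev) for lev in levels
    ]


@dataclass(frozen=True)
class CandidateModel:
    variants: tuple[PredictorVariant, ...]
    factorial: bool = False  # include all interactions among the variants

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(sorted({v.feature for v in self.variants}, key=FEATURES.index))

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def formula(self) -> str:
        if not self.variants:
            return "Suffix ~ 1"
        sep = " * " if self.factorial else " + "
        return "Suffix ~ " + sep.join(v.name for v in self.variants)

    def design(self, scenes: list[Scene]) -> np.ndarray:
        """Design matrix with intercept; factorial models add every
        cross-product of one column from each variant in every subset of
        two or more variants."""
        n = len(scenes)
        blocks = [v.columns(scenes) for v in self.variants]
        cols = [np.ones((n, 1))] + list(blocks)
        if self.factorial and len(blocks) >= 2:
            for r in range(2, len(blocks) + 1):
                for subset in itertools.combinations(blocks, r):
                    for combo in itertools.product(*(b.T for b in subset)):
                        cols.append(np.prod(np.stack(combo), axis=0)[:, None])
        return np.hstack(cols)

    @property
    def n_slope_columns(self) -> int:
        ks = [v.n_columns for v in self.variants]
        m = sum(ks)
        if self.factorial and len(ks) >= 2:
            for r in range(2, len(ks) + 1):
                for subset in itertools.combinations(ks, r):
                    m += math.prod(subset)
        return m


def enumerate_models() -> list[CandidateModel]:
    """All candidate models in canonical order: every additive combination
    of at-most-one-variant-per-feature (including the intercept-only
    model), plus the full-factorial augmentation of every selection with
    two or more variants.  Ordered by feature count, then parameter
    columns, then formula."""
    choices = [[None] + expand_variants(f) for f in FEATURES]
    models = []
    for combo in itertools.product(*choices):
        variants = tuple(v for v in combo if v is not None)
        models.append(CandidateModel(variants))
        if len(variants) >= 2:
            models.append(CandidateModel(variants, factorial=True))
    models.sort(key=lambda m: (m.n_features, m.n_slope_columns, m.formula))
    return models


@dataclass
class FitResult:
    model: CandidateModel
    loglik: float
    k: int
    aic: float
    converged: bool
    n_iter: int


@dataclass
class ComplexityScore:
    best: FitResult
    complexity: int


def _nll_and_grad(beta_flat, X, Y, ridge):
    n, d = X.shape
    c1 = Y.shape[1] - 1
    beta = beta_flat.reshape(c1, d)
    eta = np.hstack([np.zeros((n, 1)), X @ beta.T])  # reference = category 0
    eta -= eta.max(axis=1, keepdims=True)
    expeta = np.exp(eta)
    denom = expeta.sum(axis=1, keepdims=True)
    logp = eta - np.log(denom)
    nll = -np.sum(Y * logp)
    P = expeta / denom
    G = (P - Y)[:, 1:]  # n x c1
    grad = (G.T @ X).ravel()
    if ridge:
        nll += 0.5 * ridge * np.sum(beta_flat**2)
        grad = grad + ridge * beta_flat
    return nll, grad


def fit_multinomial(
    X: np.ndarray,
    suffixes: list[str],
    model: CandidateModel | None = None,
    ridge: float = 0.0,
) -> FitResult:
    """Maximum-likelihood multinomial logit of suffix category on a design
    matrix (intercept included in X).

    Iteration is capped at 100 with a 1e-8 relative log-likelihood
    tolerance.  A single-category outcome is scored loglik 0 with k = 0
    (the zero-slope intercept model is then exact).  The parameter count is
    k = (C - 1) * (1 + m) for C outcome categories and m slope columns.
    """
    if len(suffixes) == 0:
        raise ValueError("empty data")
    X = np.asarray(X, dtype=float)
    categories = sorted(set(suffixes))
    C = len(categories)
    n, d = X.shape
    if C == 1:
        k = 0
        return FitResult(model, 0.0, k, 0.0, True, 0)

    idx = {c: j for j, c in enumerate(categories)}
    Y = np.zeros((n, C))
    for i, s in enumerate(suffixes):
        Y[i, idx[s]] = 1.0

    state = {"last": None, "converged": False, "iters": 0}

    def callback(xk):
        state["iters"] += 1
        ll = -_nll_and_grad(xk, X, Y, ridge)[0]
        last = state["last"]
        state["last"] = ll
        if last is not None and abs(ll - last) <= LOGLIK_RTOL * (abs(last) + 1e-12):
            state["converged"] = True
            raise StopIteration

    x0 = np.zeros((C - 1) * d)
    res = optimize.minimize(
        _nll_and_grad,
        x0,
        args=(X, Y, ridge),
        jac=True,
        method="BFGS",
        callback=callback,
        options={"maxiter": MAX_ITER, "gtol": 1e-10},
    )
    loglik = -_nll_and_grad(res.x, X, Y, 0.0)[0]
    k = (C - 1) * d
    aic = 2 * k - 2 * loglik
    return FitResult(model, float(loglik), k, float(aic), state["converged"] or res.success, state["iters"])


def fit_model(
    model: CandidateModel, scenes: list[Scene], suffixes: list[str], ridge: float = 0.0
) -> FitResult:
    fit = fit_multinomial(model.design(scenes), suffixes, model=model, ridge=ridge)
    return fit


def best_model(
    scenes: list[Scene], suffixes: list[str], ridge: float = 0.0
) -> ComplexityScore:
    """Fit every candidate model and return the lowest-AIC one with its
    feature-count complexity.  Ties within 1e-9 go to the model with fewer
    parameters, then canonical order."""
    if len(scenes) != len(suffixes):
        raise ValueError("scenes and suffixes must align")
    best_fit = None
    for model in enumerate_models():
        fit = fit_model(model, scenes, suffixes, ridge=ridge)
        if best_fit is None or fit.aic < best_fit.aic - AIC_TIE_TOL or (
            abs(fit.aic - best_fit.aic) <= AIC_TIE_TOL and fit.k < best_fit.k
        ):
            best_fit = fit
    return ComplexityScore(best_fit, best_fit.model.n_features)


def suffix_entropy(suffixes: list[str]) -> float:
    """Shannon entropy (bits) of the empirical suffix distribution."""
    if len(suffixes) == 0:
        raise ValueError("empty data")
    _, counts = np.unique(np.asarray(suffixes, dtype=object), return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def complexity_table(scored_suffixes, word_classes=("Q", "N", "V")):
    """Complexity and entropy per participant x phase x word class.

    ``scored_suffixes`` is a DataFrame with columns participant_id, phase,
    number, animal, motion, word_class, suffix (suffix "NULL" for
    zero-marked).  Returns one row per (participant, phase, word class)
    with the winning formula, loglik, k, AIC, complexity and entropy.
    """
    import pandas as pd

    rows = []
    for (pid, phase, wc), grp in scored_suffixes.groupby(
        ["participant_id", "phase", "word_class"], sort=True
    ):
        if wc not in word_classes:
            continue
        scenes = [
            Scene(rec.number if rec.number not in ("", "NA", None) else None, rec.animal, rec.motion)
            for rec in grp.itertuples(index=False)
        ]
        suffixes = list(grp["suffix"])
        score = best_model(scenes, suffixes)
        rows.append({
            "participant_id": pid,
            "phase": phase,
            "word_class": wc,
            "best_model_formula": score.best.model.formula,
            "loglik": score.best.loglik,
            "k": score.best.k,
            "aic": score.best.aic,
            "complexity": score.complexity,
            "entropy_bits": suffix_entropy(suffixes),
        })
    return pd.DataFrame(rows)
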