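"""PWM evaluation: Frobenius distance, Monte-Carlo p-values, baselines, ROC.

A predicted PWM is compared to an experimentally mapped ("gold") PWM by the
Frobenius distance — the square root of the sum of squared elementwise
differences, i.e. the norm of (gold − predicted). The associated p-value is
the probability that a *random* PWM lies at least as close to the gold
matrix; it is estimated by Monte Carlo with the add-one estimator, so it is
never zero and never smaller than 1/(n_random + 1). Because the reference
distribution of random PWMs is a modelling choice, every result records the
null model and seed used, and p-values from different nulls should not be
compared.

Three no-specificity baseline matrices are provided: M1 is uniform 0.05
everywhere; M2 and M3 are uniform except at the phospho column, where M2
puts 0.5 on S and T and M3 puts 1/3 on each of S, T and Y. Against a typical
serine/threonine gold matrix, M2 already achieves a small distance — a
reminder that Frobenius distance rewards hedged, low-information matrices
and is not by itself a measure of predictive power. Predictive power is
measured instead by ROC AUC of heptamer scores on labelled positives and
negatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .alphabet import AA_INDEX
from .errors import KinspecError
from .pwm import N_POSITIONS, PHOSPHO_COL, BackgroundFrequencies, PositionWeightMatrix
from .scoring import score_site

NULL_MODELS = ("uniform-simplex", "phospho-constrained")
DEFAULT_N_RANDOM = 10_000


def _as_matrix(x) -> np.ndarray:
    w = x.weights if isinstance(x, PositionWeightMatrix) else np.asarray(x, float)
    return np.asarray(w, dtype=float)


def frobenius_distance(A, B) -> float:
    """sqrt of the summed squared elementwise differences of two 20x7 matrices."""
    a, b = _as_matrix(A), _as_matrix(B)
    if a.shape != b.shape:
        raise KinspecError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def _random_weights(
    rng: np.random.Generator, n: int, null_model: str, phospho_alphabet: str = "STY"
) -> np.ndarray:
    """(n, 20, 7) column-stochastic draws under the named null."""
    if null_model not in NULL_MODELS:
        raise KinspecError(f"unknown null model {null_model!r}; use one of {NULL_MODELS}")
    # uniform Dirichlet on the 20-simplex, independently per column
    w = rng.dirichlet(np.ones(20), size=(n, N_POSITIONS)).transpose(0, 2, 1)
    if null_model == "phospho-constrained":
        idx = [AA_INDEX[a] for a in phospho_alphabet]
        col = np.zeros((n, 20))
        col[:, idx] = rng.dirichlet(np.ones(len(idx)), size=n)
        w[:, :, PHOSPHO_COL] = col
    return w


def random_pwm(
    seed: int | np.random.Generator, null_model: str = "uniform-simplex"
) -> PositionWeightMatrix:
    """One reproducible random PWM under the named null model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = _random_weights(rng, 1, null_model)[0]
    meta = {"null_model": null_model}
    if not isinstance(seed, np.random.Generator):
        meta["seed"] = seed
    return PositionWeightMatrix(weights=w, style="external", metadata=meta)


@dataclass(frozen=True)
class EvaluationResult:
    distance: float
    p_value: float
    n_random: int
    seed: int
    null_model: str


def frobenius_p_value(
    predicted,
    gold,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
    null_model: str = "uniform-simplex",
) -> EvaluationResult:
    """Monte-Carlo p-value for the observed Frobenius distance.

    p = (1 + #{random draws with distance <= observed}) / (n_random + 1).
    """
    if n_random < 100:
        raise KinspecError("n_random must be at least 100")
    g = _as_matrix(gold)
    d_obs = frobenius_distance(predicted, gold)
    rng = np.random.default_rng(seed)
    draws = _random_weights(rng, n_random, null_model)
    d = np.sqrt(((draws - g[None, :, :]) ** 2).sum(axis=(1, 2)))
    p = (1 + int((d <= d_obs).sum())) / (n_random + 1)
    return EvaluationResult(
        distance=d_obs, p_value=p, n_random=n_random, seed=seed, null_model=null_model
    )


def baseline_matrices(printed_thirds: bool = False):
    """The three no-specificity baselines (M1, M2, M3).

    M1: 0.05 everywhere. M2: 0.05 everywhere except the phospho column,
    where S and T carry 0.5 each and everything else 0. M3: likewise with
    S, T and Y carrying a third each — exact thirds by default;
    ``printed_thirds=True`` uses the rounded value 0.33 instead.
    """
    third = 0.33 if printed_thirds else 1.0 / 3.0
    m1 = np.full((20, N_POSITIONS), 0.05)

    m2 = np.full((20, N_POSITIONS), 0.05)
    m2[:, PHOSPHO_COL] = 0.0
    m2[AA_INDEX["S"], PHOSPHO_COL] = 0.5
    m2[AA_INDEX["T"], PHOSPHO_COL] = 0.5

    m3 = np.full((20, N_POSITIONS), 0.05)
    m3[:, PHOSPHO_COL] = 0.0
    for a in "STY":
        m3[AA_INDEX[a], PHOSPHO_COL] = third

    return tuple(
        PositionWeightMatrix(weights=m, style="baseline", metadata={"baseline": name})
        for name, m in (("M1", m1), ("M2", m2), ("M3", m3))
    )


def planted_site_auc(result, answer_key) -> float:
    """Mean per-kinase AUC of planted sites vs all other scanned sites.

    ``result`` is a :class:`~kinspec.scoring.PredictionResult` from a run on
    a synthetic proteome; ``answer_key`` the generator's planted-site list.
    Kinases whose result set has no planted site (or only planted sites)
    are skipped; averaging per kinase keeps score scales comparable.
    """
    planted = {(s.kinase_id, s.substrate_id, s.site_position) for s in answer_key}
    aucs = []
    for kid, sites in result.scored_sites.items():
        labels = [
            1 if (kid, s.substrate_id, s.site_position) in planted else 0
            for s in sites
        ]
        if 0 < sum(labels) < len(labels):
            aucs.append(
                float(roc_auc_score(labels, [s.score for s in sites]))
            )
    if not aucs:
        raise KinspecError("no kinase had both planted and decoy sites")
    return float(np.mean(aucs))


def roc_auc(
    pwm: PositionWeightMatrix,
    positives: Sequence[str],
    negatives: Sequence[str],
    bg: BackgroundFrequencies,
) -> float:
    """ROC AUC of heptamer scores over a labelled set (rank-sum; ties 0.5)."""
    if not positives or not negatives:
        raise KinspecError("both heptamer classes must be non-empty")
    scores = [score_site(pwm, h, bg) for h in positives] + [
        score_site(pwm, h, bg) for h in negatives
    ]
    labels = [1] * len(positives) + [0] * len(negatives)
    return float(roc_auc_score(labels, scores))
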