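"""Permutation significance testing and evaluation summaries.

Classifier performance on autocorrelated EEG segments is assessed against
an empirical null: shuffling the segment labels breaks any
label-prediction relationship, and repeating the shuffle B times yields a
null distribution of "permutation accuracies".  The empirical p-value uses
the add-one rule

    p = (#(Acc_perm >= Acc_obs) + 1) / (B + 1),

which is bounded below by 1/(B+1) — with B = 10,000 and no exceedances,
p = 1/10,001 ~ 9.99e-5.  The mean permutation accuracy doubles as the
chance level (50% for a balanced two-class problem, 33% for three states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sct

__all__ = [
    "PermutationResult",
    "permutation_test",
    "chance_level",
    "confusion",
    "score_distribution",
]


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a label-shuffling significance test."""

    acc_obs: float
    B: int
    acc_perm: np.ndarray
    exceedance_count: int
    p: float
    mean_perm_accuracy: float

    def __post_init__(self) -> None:
        assert 1 / (self.B + 1) <= self.p <= 1.0


def permutation_test(
    labels, predictions, B: int = 10_000, seed: int | np.random.Generator = 0
) -> PermutationResult:
    """Empirical p-value for observed accuracy under uniform label shuffles.

    Parameters
    ----------
    labels, predictions : array-like, same length
        True condition labels and the classifier's per-segment predictions.
    B : int
        Number of label permutations.
    seed : int or Generator
        Randomness source; results are reproducible for a fixed seed.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {predictions.shape} predictions")
    if labels.size == 0:
        raise ValueError("empty input")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    acc_obs = float((labels == predictions).mean())
    acc_perm = np.empty(B)
    for b in range(B):
        acc_perm[b] = (rng.permutation(labels) == predictions).mean()
    exceed = int((acc_perm >= acc_obs).sum())
    return PermutationResult(
        acc_obs=acc_obs,
        B=B,
        acc_perm=acc_perm,
        exceedance_count=exceed,
        p=(exceed + 1) / (B + 1),
        mean_perm_accuracy=float(acc_perm.mean()),
    )


def chance_level(
    labels, B: int = 10_000, seed: int | np.random.Generator = 0, predictions=None
) -> float:
    """Chance-level accuracy as the mean permutation accuracy.

    With predictions distributed like the labels (the default: the labels
    themselves stand in), the mean permutation accuracy converges to
    ``sum_i p_i^2`` over class frequencies — 1/k for balanced k-class
    labels.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("chance level needs at least two classes")
    if predictions is None:
        predictions = labels
    return permutation_test(labels, predictions, B=B, seed=seed).mean_perm_accuracy


def confusion(true_states, predicted_states) -> pd.DataFrame:
    """Row-normalised confusion matrix in percent.

    Rows are true states, columns predicted; each row sums to 100.  Raw
    per-row segment counts are attached as ``df.attrs["n_per_row"]``.
    """
    true_states = list(true_states)
    predicted_states = list(predicted_states)
    if len(true_states) != len(predicted_states):
        raise ValueError("length mismatch")
    if not true_states:
        raise ValueError("empty input")
    counts = pd.crosstab(
        pd.Series(true_states, name="true"), pd.Series(predicted_states, name="predicted")
    )
    # square it on the union alphabet, keeping first-seen order of true states
    alphabet = list(dict.fromkeys(true_states + predicted_states))
    counts = counts.reindex(index=alphabet, columns=alphabet, fill_value=0)
    counts = counts.loc[counts.sum(axis=1) > 0]
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.attrs["n_per_row"] = counts.sum(axis=1).to_dict()
    return pct


def score_distribution(
    scores, labels, kernel_width: float = 1.0, grid: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """Per-class Gaussian kernel density of classifier scores.

    The kernel standard deviation equals ``kernel_width`` in score units
    (width 1 on the -10..+10 engagement scale).  Each class density
    integrates to 1 over the returned grid.

    Returns
    -------
    grid : ndarray
    densities : dict class -> ndarray over ``grid``
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if grid is None:
        pad = 4 * kernel_width
        grid = np.linspace(scores.min() - pad, scores.max() + pad, 512)
    densities = {}
    for cls in np.unique(labels):
        s = scores[labels == cls]
        densities[cls] = sct.norm.pdf(grid[:, None], loc=s, scale=kernel_width).mean(axis=1)
    return grid, densities
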