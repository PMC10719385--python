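"""Evaluation statistics: permutation-based empirical chance level (with
p-value and Cohen's d), the 5x2-CV F-test and McNemar test for comparing two
classifiers, and inter-rater agreement (percentage agreement, Cohen's kappa)
between the two modality models' predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats as sps

from .util import child_seed


# --------------------------------------------------------------------- #
# permutation null
# --------------------------------------------------------------------- #
@dataclass
class NullDistribution:
    """Values of a statistic under train-label permutation."""

    values: np.ndarray
    statistic: str = "accuracy"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty null distribution")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite null values")

    @property
    def n_perm(self) -> int:
        return len(self.values)


def permutation_null(
    pipeline: Callable[[int], float], n_perm: int, seed: int = 0, statistic: str = "accuracy"
) -> NullDistribution:
    """Run ``pipeline`` once per permutation with a deterministic child seed.

    ``pipeline(perm_seed)`` must permute the training labels using the given
    seed, re-run the full cross-validated analysis and return the statistic.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    values = np.array([pipeline(child_seed(seed, i)) for i in range(n_perm)])
    return NullDistribution(values=values, statistic=statistic)


@dataclass(frozen=True)
class PermutationPValue:
    """Counting p-value: share of null values exceeding the observation.

    When no null value exceeds the observation the p-value is reported as
    "< 1/n_perm" rather than 0. An optional add-one estimator
    (count+1)/(n_perm+1) is available for downstream numeric use.
    """

    count: int
    n_perm: int

    @property
    def value(self) -> float:
        return self.count / self.n_perm

    @property
    def add_one(self) -> float:
        return (self.count + 1) / (self.n_perm + 1)

    @property
    def display(self) -> str:
        if self.count == 0:
            return f"< {1 / self.n_perm:g}"
        return f"{self.value:g}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.display


def perm_pvalue(observed: float, null: NullDistribution) -> PermutationPValue:
    """p = #{null > observed} / n_perm."""
    count = int(np.sum(null.values > observed))
    return PermutationPValue(count=count, n_perm=null.n_perm)


def cohens_d_vs_null(observed: float, null: NullDistribution) -> float:
    """Effect size of the observation against the permutation null:
    (observed - mean(null)) / sd(null), sample (n-1) standard deviation."""
    mean = float(np.mean(null.values))
    sd = float(np.std(null.values, ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):  # constant up to rounding
        raise ValueError("null distribution has zero standard deviation")
    return (observed - mean) / sd


# --------------------------------------------------------------------- #
# 5x2-CV F-test
# --------------------------------------------------------------------- #
@dataclass
class CVFTestResult:
    """Alpaydin's combined 5x2-CV F-test for two classifiers."""

    f_statistic: float
    p_value: float
    diffs: np.ndarray  # (5, 2) accuracy differences acc_A - acc_B
    df: tuple[int, int] = (10, 5)


def five_by_two_ftest(diffs: np.ndarray) -> CVFTestResult:
    """F statistic from the (5 replications x 2 folds) accuracy differences.

    f = (sum_ij d_ij^2) / (2 sum_i s_i^2) with s_i^2 the per-replication
    variance of the two fold differences; referenced to F(10, 5).
    """
    d = np.asarray(diffs, dtype=float)
    if d.shape != (5, 2):
        raise ValueError("expected a 5x2 matrix of accuracy differences")
    s2 = d.var(axis=1, ddof=1)  # per-replication variance of the 2 folds
    denom = 2.0 * s2.sum()
    if denom == 0:
        raise ValueError("all per-replication variances are zero; F statistic undefined")
    f = float((d**2).sum() / denom)
    p = float(sps.f.sf(f, 10, 5))
    return CVFTestResult(f_statistic=f, p_value=p, diffs=d)


def five_by_two_cv_ftest(
    evaluate_pair: Callable[[int, int, int], tuple[float, float]], seed: int = 0
) -> CVFTestResult:
    """Run 5 replications of twofold CV; ``evaluate_pair(rep, fold, seed)``
    trains both models on one half and returns their accuracies on the other,
    both models tested on the same data."""
    d = np.empty((5, 2))
    for i in range(5):
        for j in range(2):
            acc_a, acc_b = evaluate_pair(i, j, child_seed(seed, i, j))
            d[i, j] = acc_a - acc_b
    return five_by_two_ftest(d)


# --------------------------------------------------------------------- #
# McNemar test
# --------------------------------------------------------------------- #
@dataclass
class McNemarResult:
    """Continuity-corrected McNemar test on the discordant pairs of two
    classifiers, with Cohen's g effect size."""

    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    chi2: float
    p_value: float
    cohens_g: float
    df: int = 1


def mcnemar(preds_a: np.ndarray, preds_b: np.ndarray, truth: np.ndarray) -> McNemarResult:
    """chi2 = (|b - c| - 1)^2 / (b + c); g = |b/(b+c) - 1/2|."""
    preds_a, preds_b, truth = map(np.asarray, (preds_a, preds_b, truth))
    if not (len(preds_a) == len(preds_b) == len(truth)):
        raise ValueError("prediction and truth vectors must be aligned")
    ok_a = preds_a == truth
    ok_b = preds_b == truth
    b = int(np.sum(ok_a & ~ok_b))
    c = int(np.sum(~ok_a & ok_b))
    if b + c == 0:
        raise ValueError("no discordant predictions; McNemar statistic undefined")
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(sps.chi2.sf(chi2, 1))
    g = abs(b / (b + c) - 0.5)
    return McNemarResult(b=b, c=c, chi2=float(chi2), p_value=p, cohens_g=float(g))


# --------------------------------------------------------------------- #
# inter-rater agreement
# --------------------------------------------------------------------- #
@dataclass
class AgreementResult:
    """Consensus matrix and chance-corrected agreement of two prediction
    vectors (rows: rater A classes, columns: rater B)."""

    matrix: np.ndarray  # (F, F) counts
    percentage_agreement: float  # in percent
    p_e: float  # chance agreement probability
    kappa: float


def consensus_matrix(preds_a: np.ndarray, preds_b: np.ndarray, n_classes: int) -> np.ndarray:
    preds_a, preds_b = np.asarray(preds_a, dtype=int), np.asarray(preds_b, dtype=int)
    if len(preds_a) != len(preds_b):
        raise ValueError("prediction vectors must be aligned")
    m = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(m, (preds_a, preds_b), 1)
    return m


def percentage_agreement(preds_a: np.ndarray, preds_b: np.ndarray) -> float:
    """100 x #(A = B) / N."""
    preds_a, preds_b = np.asarray(preds_a), np.asarray(preds_b)
    if len(preds_a) != len(preds_b):
        raise ValueError("prediction vectors must be aligned")
    if len(preds_a) == 0:
        raise ValueError("empty prediction vectors")
    return 100.0 * float(np.mean(preds_a == preds_b))


def kappa_from_matrix(m: np.ndarray) -> float:
    """Cohen's kappa from an F x F consensus matrix."""
    m = np.asarray(m, dtype=float)
    n = m.sum()
    if n == 0:
        raise ValueError("empty consensus matrix")
    p_o = np.trace(m) / n
    p_e = float(np.sum(m.sum(axis=1) * m.sum(axis=0)) / n**2)
    if p_e == 1.0:
        raise ValueError("chance agreement is 1 (both raters constant and equal); kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def cohens_kappa(preds_a: np.ndarray, preds_b: np.ndarray) -> float:
    """kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginals."""
    preds_a, preds_b = np.asarray(preds_a), np.asarray(preds_b)
    classes = np.unique(np.concatenate([preds_a, preds_b]))
    code = {c: i for i, c in enumerate(classes)}
    a = np.array([code[v] for v in preds_a])
    b = np.array([code[v] for v in preds_b])
    return kappa_from_matrix(consensus_matrix(a, b, len(classes)))


def agreement(preds_a: np.ndarray, preds_b: np.ndarray, n_classes: int) -> AgreementResult:
    """Full agreement summary between two aligned integer prediction vectors."""
    m = consensus_matrix(preds_a, preds_b, n_classes)
    n = m.sum()
    p_e = float(np.sum(m.sum(axis=1) * m.sum(axis=0)) / n**2)
    return AgreementResult(
        matrix=m,
        percentage_agreement=percentage_agreement(preds_a, preds_b),
        p_e=p_e,
        kappa=kappa_from_matrix(m),
    )
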