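"""Cross-validation and permutation machinery.

Spearman rank correlation (average ranks, two-sided p), Benjamini-
Hochberg step-up FDR adjustment, an empiric permutation test with
``p = (n + 1) / (N + 1)``, and k-fold cross-validation of the
phenotype-based model-building pipeline (growth-associated reactions and
the normalization range are learned on the train folds only, models of
the test fold are built by transfer, and the test-set rank correlation
between predicted and measured growth is reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model_io import MetabolicModel, PrimegemError


class ConstantInputError(PrimegemError):
    """Correlation undefined because one input vector is constant."""


# ---------------------------------------------------------------------------
# Spearman / BH
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Average-rank Spearman rho with two-sided p-value.

    Requires equal lengths >= 3; a constant vector raises
    :class:`ConstantInputError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman needs two equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("spearman needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(pvalues: Sequence[float], alpha: float = 0.05,
              ) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (q-values, selected flags) with selected = q <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationOutcome:
    """An observed statistic against an empiric null distribution."""

    observed: float
    null_values: np.ndarray
    p_value: float
    direction: str

    @property
    def n_extreme(self) -> int:
        return int(round(self.p_value * (len(self.null_values) + 1) - 1))


def permutation_test(observed: float,
                     null_generator: Callable[[np.random.Generator], float],
                     n_permutations: int = 1000,
                     direction: str = "greater",
                     seed: int = 0) -> PermutationOutcome:
    """Empiric permutation test with ``p = (n + 1) / (N + 1)``.

    ``null_generator(rng)`` produces one null statistic per call; ``n`` is
    the number of null values at least as extreme as ``observed``
    (``direction='greater'``: null >= observed; ``'less'``: null <=
    observed).  The p-value floor is ``1/(N+1)`` and is attained when the
    observed statistic beats every null.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if direction not in ("greater", "less"):
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_permutations)
    for i in range(n_permutations):
        try:
            nulls[i] = null_generator(rng)
        except Exception as exc:
            raise PrimegemError(f"null generator failed at repeat {i}: {exc}")
    if direction == "greater":
        n = int((nulls >= observed).sum())
    else:
        n = int((nulls <= observed).sum())
    p = (n + 1) / (n_permutations + 1)
    return PermutationOutcome(float(observed), nulls, float(p), direction)


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-repeat test-set correlations from repeated k-fold CV."""

    repeat_values: np.ndarray        # one mean test rho per repeat (NaN = no folds)
    fold_values: List[List[float]]   # per repeat, per scored fold
    n_na_folds: int                  # folds dropped for an empty train association set
    k: int
    seed: int

    @property
    def mean(self) -> float:
        vals = self.repeat_values[~np.isnan(self.repeat_values)]
        return float(vals.mean()) if vals.size else float("nan")


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> List[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def kfold_cv(model: MetabolicModel, expr: pd.DataFrame, phenotype: pd.Series,
             k: int = 5, repeats: int = 1000, seed: int = 0,
             params=None) -> CVResult:
    """Repeated k-fold CV of growth prediction.

    Per repeat: samples are randomly partitioned into ``k`` folds (each
    sample in exactly one test fold).  For each fold, growth associations
    and the upper normalization bound are learned from the train samples
    alone, models of the test samples are built by transfer (the
    expression-to-bound normalization is re-anchored across the test
    cohort), and the Spearman correlation between predicted and measured
    growth on the test fold is recorded.  Folds whose train split yields
    no growth-associated reaction are counted as NA and excluded from the
    mean, never imputed.
    """
    from . import phenosim, prime_builder  # local import to avoid a cycle

    p = params or prime_builder.PrimeParams()
    samples = list(expr.columns)
    if len(samples) < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for {k}-fold CV")
    phenotype = phenotype.loc[samples]

    prep = prime_builder.prepare_base(model, expr, params=p)
    rng = np.random.default_rng(seed)
    repeat_values = np.full(repeats, np.nan)
    fold_values: List[List[float]] = []
    n_na = 0
    for rep in range(repeats):
        folds = _fold_indices(len(samples), k, rng)
        rhos: List[float] = []
        for test_idx in folds:
            test = [samples[i] for i in test_idx]
            train = [s for s in samples if s not in set(test)]
            assoc = prime_builder.find_growth_associated(
                prep.reaction_expr[train], phenotype.loc[train], alpha=p.alpha)
            selected = [a for a in assoc if a.selected]
            if not selected:
                n_na += 1
                continue
            try:
                rng_val = prime_builder.normalization_range_for(
                    prep, [a.reaction_id for a in selected], params=p)
                mset = prime_builder.build_models_transfer(
                    model, expr[test], selected, rng_val, params=p,
                    _prepared=prep)
            except PrimegemError:
                n_na += 1
                continue
            pred = phenosim.predict_growth(mset)
            rho, _ = spearman(pred.loc[test].to_numpy(),
                              phenotype.loc[test].to_numpy())
            rhos.append(rho)
        fold_values.append(rhos)
        if rhos:
            repeat_values[rep] = float(np.mean(rhos))
    return CVResult(repeat_values, fold_values, n_na, k, seed)
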