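"""Downstream directionality and coupling summaries over differential results.

* ``alpha`` — of the genes whose psi changed significantly between two
  states, the fraction whose psi is higher in the reference state, with an
  exact two-sided binomial test against the 50% null. Values above 0.5 mean
  the reference state favours distal polyA sites.
* ``rho`` — Spearman correlation between per-gene expression change and
  delta-psi, computed either across genes for one sample pair or across
  sample pairs for one gene. A negative rho means distal shifts accompany
  expression decreases.
* ``beta`` — Spearman correlation, across sample pairs, between a
  regulator's expression change and the median delta-psi of significantly
  changed genes, summarising whether the regulator pushes APA directionally.

All correlations are rank-based (average ranks on ties), so they are
invariant under strictly monotone transforms of either input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_PAIRS = 3


@dataclass(frozen=True)
class DirectionalityScore:
    """Fraction of significant genes shifted toward distal usage."""

    alpha: float
    k: int  # genes with positive delta-psi
    n: int  # significant genes with nonzero delta-psi
    p: float  # exact two-sided binomial p vs 0.5
    defined: bool = True


@dataclass(frozen=True)
class CouplingScore:
    """Spearman correlation between expression change and delta-psi."""

    rho: float
    n: int
    scope: str  # "per_pair" (across genes) or "per_gene" (across pairs)
    defined: bool = True


@dataclass(frozen=True)
class RegulatorCoupling:
    """Spearman correlation of regulator change with median delta-psi."""

    beta: float
    n_pairs: int
    defined: bool = True


def binomial_two_sided(k: int, n: int) -> float:
    """Exact two-sided binomial p against 0.5: double the smaller tail, cap at 1."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def alpha_score(diff_results: pd.DataFrame, fdr: float = 0.05) -> DirectionalityScore:
    """Directionality of significant psi changes.

    ``diff_results`` needs ``qval`` and ``deltapsi`` columns; the caller
    fixes the delta-psi orientation (reference minus intervention). Genes
    with delta-psi exactly 0 carry no direction and are excluded from both
    numerator and denominator. With no significant genes the score is
    flagged undefined.
    """
    sig = diff_results[(diff_results["qval"] < fdr) & diff_results["deltapsi"].notna()]
    sig = sig[sig["deltapsi"] != 0]
    n = len(sig)
    if n == 0:
        return DirectionalityScore(math.nan, 0, 0, math.nan, defined=False)
    k = int((sig["deltapsi"] > 0).sum())
    return DirectionalityScore(k / n, k, n, binomial_two_sided(k, n))


def _spearman(x: Sequence[float], y: Sequence[float], scope: str) -> CouplingScore:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must be the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < MIN_PAIRS or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CouplingScore(math.nan, n, scope, defined=False)
    rho = float(stats.spearmanr(x, y).statistic)
    if math.isnan(rho):
        return CouplingScore(math.nan, n, scope, defined=False)
    return CouplingScore(rho, n, scope)


def rho_per_pair(
    expression_changes: Sequence[float], delta_psis: Sequence[float]
) -> CouplingScore:
    """Coupling across genes for one sample pair.

    Inputs are gene-matched vectors of expression change and delta-psi for a
    single pair of samples; the caller applies the expression filter (no
    significance filter is applied to delta-psi). NA pairs are dropped;
    fewer than three complete pairs, or zero variance, yields an undefined
    score.
    """
    return _spearman(expression_changes, delta_psis, "per_pair")


def rho_per_gene(
    expression_changes: Sequence[float], delta_psis: Sequence[float]
) -> CouplingScore:
    """Coupling across sample pairs for one gene (roles transposed)."""
    return _spearman(expression_changes, delta_psis, "per_gene")


def beta_score(
    regulator_expression_change_by_pair: Sequence[float],
    median_delta_psi_by_pair: Sequence[float],
) -> RegulatorCoupling:
    """Regulator-level coupling across sample pairs.

    The second argument is, per pair, the median delta-psi over genes that
    changed significantly (q < 0.05) in that pair.
    """
    score = _spearman(
        regulator_expression_change_by_pair, median_delta_psi_by_pair, "per_pair"
    )
    return RegulatorCoupling(score.rho, score.n, defined=score.defined)
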