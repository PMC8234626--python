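"""Differential psi testing: mixed linear model, likelihood-ratio test, BH FDR.

For each gene, a linear mixed-effects model ``psi ~ condition (+ covariates)``
with a random intercept per replicate group is compared, by likelihood-ratio
test, to a null model lacking the condition term (covariates are retained in
the null). Models are fit by maximum likelihood — a requirement for a valid
LRT — and the p-value comes from a chi-squared distribution with one degree
of freedom, since only the single binary condition indicator is dropped. In a
plain two-condition design this behaves like a two-sample t-test but extends
naturally to designs with covariates such as library preparation or cell line.
Raw p-values are corrected with the Benjamini-Hochberg step-up.

When the mixed fit is singular or fails to converge the gene falls back to
ordinary least squares, recorded per gene in ``fit_status``.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

FDR_DEFAULT = 0.05


class DesignError(ValueError):
    """Invalid experimental design (conditions, replicates, covariates)."""


@dataclass
class DesignSpec:
    """Sample-to-condition mapping with optional covariates.

    ``condition`` maps sample id to one of exactly two condition labels.
    ``covariates`` (optional) holds one categorical column per covariate.
    ``replicate`` (optional) names the random-intercept grouping; when absent
    each sample is its own group and fitting reduces to ordinary least squares.
    """

    condition: pd.Series
    covariates: pd.DataFrame | None = None
    replicate: pd.Series | None = None

    def __post_init__(self) -> None:
        self.condition = self.condition.astype(str)
        levels = sorted(self.condition.unique())
        if len(levels) != 2:
            raise DesignError(
                f"exactly two condition levels required, got {levels}"
            )
        counts = self.condition.value_counts()
        if counts.min() < 2:
            raise DesignError(
                f"each condition needs at least two samples; got {dict(counts)}"
            )
        self.levels: tuple[str, str] = (levels[0], levels[1])
        if self.covariates is not None:
            self.covariates = self.covariates.loc[self.condition.index].astype(str)
            self._check_covariates()
        if self.replicate is not None:
            self.replicate = self.replicate.loc[self.condition.index].astype(str)

    def _check_covariates(self) -> None:
        cond = (self.condition == self.levels[1]).astype(float).to_numpy()
        base = [np.ones(len(cond))]
        for col in self.covariates.columns:
            values = self.covariates[col]
            for cond_level in self.levels:
                present = values[self.condition == cond_level].unique()
                if len(set(present) & set(values.unique())) < 1:
                    raise DesignError(f"covariate {col!r} empty in {cond_level}")
            dummies = pd.get_dummies(values, drop_first=True, dtype=float)
            base.extend(dummies[c].to_numpy() for c in dummies.columns)
        x0 = np.column_stack(base)
        x1 = np.column_stack(base + [cond])
        if np.linalg.matrix_rank(x1) <= np.linalg.matrix_rank(x0):
            raise DesignError(
                "condition is perfectly confounded with the covariates"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.condition.index)

    def design_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(full, null) fixed-effect design matrices; condition is the last
        column of the full matrix, coded 0 for the first (reference) level."""
        cond = (self.condition == self.levels[1]).astype(float).to_numpy()
        cols = [np.ones(len(cond))]
        if self.covariates is not None:
            for col in self.covariates.columns:
                dummies = pd.get_dummies(
                    self.covariates[col], drop_first=True, dtype=float
                )
                cols.extend(dummies[c].to_numpy() for c in dummies.columns)
        null = np.column_stack(cols)
        full = np.column_stack(cols + [cond])
        return full, null

    def groups(self) -> np.ndarray | None:
        if self.replicate is None:
            return None
        groups = self.replicate.to_numpy()
        if len(set(groups)) == len(groups):
            return None  # singleton groups: no random effect identifiable
        return groups


def design_from_samplesheet(
    samplesheet: pd.DataFrame,
    condition_column: str = "condition",
    covariate_columns: Sequence[str] = (),
    replicate_column: str | None = None,
) -> DesignSpec:
    """Build a :class:`DesignSpec` from a sample sheet indexed by sample id."""
    if condition_column not in samplesheet.columns:
        raise DesignError(f"sample sheet lacks column {condition_column!r}")
    for col in covariate_columns:
        if col not in samplesheet.columns:
            raise DesignError(f"sample sheet lacks covariate column {col!r}")
    covs = samplesheet[list(covariate_columns)] if covariate_columns else None
    rep = (
        samplesheet[replicate_column]
        if replicate_column and replicate_column in samplesheet.columns
        else None
    )
    return DesignSpec(
        condition=samplesheet[condition_column],
        covariates=covs,
        replicate=rep,
    )


# ---------------------------------------------------------------------------
# Per-gene likelihood-ratio test
# ---------------------------------------------------------------------------

_EPS = np.finfo(float).eps


def _loglik(y, x, groups) -> tuple[float, str]:
    """Maximised log-likelihood of y ~ x, mixed when groups allow it."""
    if groups is not None:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(y, x, groups=groups).fit(reml=False)
            if np.isfinite(fit.llf):
                return float(fit.llf), "mixed"
        except Exception:
            pass
    fit = sm.OLS(y, x).fit()
    return float(fit.llf), "ols"


def lrt_gene(psi_values: pd.Series, design: DesignSpec) -> tuple[float, str]:
    """Likelihood-ratio p-value for a condition effect on one gene's psi.

    Returns ``(p, fit_status)``. Degenerate inputs (zero variance, fit
    failure) yield p = 1 with a status flag rather than an exception.
    """
    y = psi_values.loc[design.samples].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("psi contains NA for a design sample; gene is untestable")
    if np.ptp(y) == 0.0:
        return 1.0, "zero_variance"
    full_x, null_x = design.design_matrices()
    groups = design.groups()
    try:
        llf_full, status_full = _loglik(y, full_x, groups)
        llf_null, status_null = _loglik(y, null_x, groups)
    except Exception:
        return 1.0, "fit_failed"
    status = status_full if status_full == status_null else "ols"
    lr = 2.0 * (llf_full - llf_null)
    if not np.isfinite(lr) or lr < 0:
        return 1.0, status  # optimizer noise; no evidence for the full model
    p = float(stats.chi2.sf(lr, df=1))
    return max(p, _EPS), status


def bh_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * N / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.isnan(p).any():
        raise ValueError("bh_correct requires finite p-values")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(n, dtype=float)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Whole-table differential test
# ---------------------------------------------------------------------------


def differential_apa(
    psi_table: pd.DataFrame,
    design: DesignSpec,
    fdr: float = FDR_DEFAULT,
) -> pd.DataFrame:
    """Test every gene for a condition effect on psi.

    ``psi_table`` is the gene x sample matrix from
    :func:`~apaquant.quantification.build_psi_table` (an ``apa_class`` column
    is carried through if present). Genes with NA psi in any design sample
    are reported untested with a reason code; tested genes get delta-psi
    (second condition level minus first), the LRT p-value, and the BH q-value.
    The returned frame's ``attrs`` record the orientation and FDR threshold.
    """
    missing = [s for s in design.samples if s not in psi_table.columns]
    if missing:
        raise DesignError(f"psi table lacks design samples: {missing}")

    level_a, level_b = design.levels
    samples_a = [s for s in design.samples if design.condition[s] == level_a]
    samples_b = [s for s in design.samples if design.condition[s] == level_b]

    apa_class = (
        psi_table["apa_class"]
        if "apa_class" in psi_table.columns
        else pd.Series("NA", index=psi_table.index)
    )
    values = psi_table[design.samples].astype(float)

    rows = []
    for gene_id, psi in values.iterrows():
        mean_a = psi[samples_a].mean()
        mean_b = psi[samples_b].mean()
        if psi.isna().any():
            rows.append(
                (gene_id, apa_class[gene_id], mean_a, mean_b, math.nan,
                 math.nan, math.nan, "not_fit", False, "na_psi")
            )
            continue
        p, status = lrt_gene(psi, design)
        rows.append(
            (gene_id, apa_class[gene_id], mean_a, mean_b, mean_b - mean_a,
             p, math.nan, status, True, "")
        )

    results = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "apa_class", "psi_mean_a", "psi_mean_b", "deltapsi",
            "pval", "qval", "fit_status", "tested", "untested_reason",
        ],
    ).set_index("gene_id")

    tested = results.index[results["tested"]]
    if len(tested):
        results.loc[tested, "qval"] = bh_correct(results.loc[tested, "pval"])
    results["significant"] = results["qval"] < fdr
    results.attrs.update(
        condition_a=level_a,
        condition_b=level_b,
        deltapsi_orientation=f"{level_b} - {level_a}",
        fdr=fdr,
    )
    return results


def write_results(results: pd.DataFrame, out_tsv: str | os.PathLike) -> None:
    cond_a = results.attrs.get("condition_a", "a")
    cond_b = results.attrs.get("condition_b", "b")
    out = results.rename(
        columns={
            "psi_mean_a": f"psi_mean_{cond_a}",
            "psi_mean_b": f"psi_mean_{cond_b}",
        }
    )
    out.to_csv(out_tsv, sep="\t", na_rep="NA", float_format="%.6g")
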