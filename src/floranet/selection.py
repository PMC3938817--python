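"""Model ranking: mean relative error and the Akaike information criterion.

MRE is the mean of |x - y| / x over gene-time pairs; it is reported three
ways: per gene (time-mean), as mean +/- SD across genes, and as one overall
number over all pairs.  Points where the observation sits at the positivity
floor are excluded (a relative error against zero is undefined) and the
exclusion count is reported.

AIC uses the Gaussian least-squares reduction AIC = N*ln(RSS/N) + 2k with
the *unweighted* residual sum of squares, N the number of residual points
and k the parameter count.  With equal residuals the AIC ordering therefore
collapses to the parameter-count ordering: mass action (15) < Michaelis-
Menten (23) < S-system (31).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import (
    POSITIVITY_FLOOR,
    KineticModel,
    build_flowering_topology,
    instantiate_model,
)
from .estimate import FitResult, Objective
from .simulate import TimeCourse


@dataclass
class MREResult:
    mean: float          # mean of per-gene errors, across genes
    sd: float            # SD of per-gene errors, across genes (population SD)
    per_gene: dict[str, float]
    overall: float       # mean over all gene-time pairs
    n_excluded: int


def compute_mre(observed: TimeCourse, predicted: TimeCourse) -> MREResult:
    """Relative-error summary of a prediction against observations.

    Grids must match; every species of ``observed`` must be present in
    ``predicted``.
    """
    if len(observed.times) != len(predicted.times) or not np.allclose(
        observed.times, predicted.times
    ):
        raise ValueError("observed and predicted time grids differ")
    missing = [l for l in observed.species_labels if l not in predicted.species_labels]
    if missing:
        raise ValueError(f"predicted time course lacks species {missing}")

    per_gene: dict[str, float] = {}
    all_errors: list[np.ndarray] = []
    n_excluded = 0
    for label in observed.species_labels:
        x = observed.column(label)
        y = predicted.column(label)
        ok = x > POSITIVITY_FLOOR
        n_excluded += int(np.sum(~ok))
        if not np.any(ok):
            continue
        err = np.abs(x[ok] - y[ok]) / x[ok]
        per_gene[label] = float(err.mean())
        all_errors.append(err)
    if not per_gene:
        raise ValueError("no usable observation points (all at the positivity floor)")
    gene_errs = np.array(list(per_gene.values()))
    pooled = np.concatenate(all_errors)
    return MREResult(
        mean=float(gene_errs.mean()),
        sd=float(gene_errs.std(ddof=0)),
        per_gene=per_gene,
        overall=float(pooled.mean()),
        n_excluded=n_excluded,
    )


def compute_aic(objective_rss: float, k: int, n_points: int) -> float:
    """Least-squares AIC: N*ln(RSS/N) + 2k.

    A perfect fit (RSS = 0) is reported as ``-inf`` with a warning rather
    than an error: it is the correct limit and flags likely overfitting.
    """
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    if k <= 0:
        raise ValueError("parameter count k must be positive")
    if objective_rss < 0:
        raise ValueError("RSS must be non-negative")
    if objective_rss == 0:
        warnings.warn("RSS is exactly 0 (perfect fit); AIC reported as -inf")
        return float("-inf")
    return n_points * float(np.log(objective_rss / n_points)) + 2 * k


@dataclass
class ReportRow:
    formalism: str
    dataset: str
    objective: float       # weighted O(p)
    rss: float             # unweighted residual sum of squares
    mre: MREResult
    k: int
    n_points: int
    aic: float


@dataclass
class ComparisonReport:
    rows: list[ReportRow]
    ranking: dict[str, list[str]] = field(default_factory=dict)

    def row(self, formalism: str, dataset: str) -> ReportRow:
        for r in self.rows:
            if r.formalism == formalism and r.dataset == dataset:
                return r
        raise KeyError(f"no row for ({formalism}, {dataset})")


def _rank(values: dict[str, float], k_by_formalism: dict[str, int]) -> list[str]:
    # ascending; ties broken by fewer parameters
    return sorted(values, key=lambda f: (values[f], k_by_formalism[f]))


def build_report(
    fits: Sequence[FitResult],
    datasets: Sequence[TimeCourse],
    *,
    models: Sequence[KineticModel] | None = None,
    objective_kwargs: dict | None = None,
) -> ComparisonReport:
    """Assemble the per-(formalism, dataset) comparison table and rankings.

    Each fit is paired positionally with its dataset.  Models are rebuilt on
    the canonical flowering topology from each fit's formalism unless given
    explicitly.  Rankings (per criterion, ascending = better) average each
    formalism's statistic over its datasets; ties go to the model with fewer
    parameters.
    """
    if len(fits) != len(datasets):
        raise ValueError("fits and datasets must pair up one-to-one")
    kwargs = objective_kwargs or {}
    if models is None:
        top = build_flowering_topology()
        models = [instantiate_model(top, fit.best_params.formalism) for fit in fits]

    seen = set()
    rows: list[ReportRow] = []
    for fit, data, model in zip(fits, datasets, models):
        key = (fit.best_params.formalism.value, data.genotype)
        if key in seen:
            raise ValueError(f"duplicate (formalism, dataset) pair {key}")
        seen.add(key)
        obj = Objective(model, data, **kwargs)
        op, rss, n = obj.residual_stats(fit.best_params)
        mre = compute_mre(data, obj.predict(fit.best_params))
        k = len(fit.best_params)
        rows.append(
            ReportRow(key[0], data.genotype, op, rss, mre, k, n, compute_aic(rss, k, n))
        )

    k_by = {}
    mre_by: dict[str, list[float]] = {}
    aic_by: dict[str, list[float]] = {}
    for r in rows:
        k_by[r.formalism] = r.k
        mre_by.setdefault(r.formalism, []).append(r.mre.overall)
        aic_by.setdefault(r.formalism, []).append(r.aic)
    ranking = {
        "mre": _rank({f: float(np.mean(v)) for f, v in mre_by.items()}, k_by),
        "aic": _rank({f: float(np.mean(v)) for f, v in aic_by.items()}, k_by),
    }
    return ComparisonReport(rows, ranking)
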