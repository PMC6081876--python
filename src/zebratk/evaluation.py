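"""Scoring, statistical tests and uncertainty analysis for BCF predictions.

All accuracy metrics operate on the log10 BCF scale.  The headline statistic
is the root-mean-square error of predicted vs. observed log10 BCF; systematic
bias is assessed with an exact two-sided binomial test on the count of
under-predictions; robustness to physiological parameter uncertainty is
assessed by resampling each body parameter from a log2-normal distribution
(sd 1 on the log2 scale, so ~68% of draws fall within half to twice the
literature value) and recomputing the dataset RMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binomtest, ttest_ind, ttest_rel

from .exceptions import InvalidInputError
from .physiology import (
    BODY_PARAMETERS,
    Chemical,
    Physiology1C,
    Physiology7C,
    blood_water_partition,
    get_parameter,
    with_parameter,
    PBW_SLOPE,
    PBW_INTERCEPT,
)
from . import models

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "SensitivityReport",
    "MODEL_SPECS",
    "rmse_log_bcf",
    "under_over_binomial",
    "split_train_validation",
    "sensitivity_analysis",
    "evaluate_dataset",
    "predict_log10_bcf",
    "species_rmse_histogram",
    "compare_species_rmse",
]

MODEL_SPECS = ("1c-literature", "1c-pbw-limit", "7c-literature", "7c-optimized")


@dataclass(frozen=True)
class EvaluationReport:
    """Aggregate accuracy of one model over one dataset."""

    rmse: float
    n: int
    n_under: int
    n_over: int
    n_ties: int
    binomial_p: float
    per_record_residuals: np.ndarray
    group_rmse: Mapping[str, float] | None = None


@dataclass(frozen=True)
class SensitivityReport:
    """Effect of resampling one body parameter on dataset RMSE."""

    parameter: str
    baseline_rmse: float
    sampled_rmse: np.ndarray
    interval_95: tuple[float, float]
    significant: bool
    n_resampled: int = 0
    sampled_values: np.ndarray | None = None


def rmse_log_bcf(predicted, observed) -> float:
    """Root-mean-square error on the log10 BCF scale."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise InvalidInputError("predicted and observed must have equal length")
    if pred.size < 1:
        raise InvalidInputError("need at least 1 record")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def under_over_binomial(predicted, observed) -> EvaluationReport:
    """Exact two-sided binomial test for systematic under-prediction.

    Counts strict under-predictions (``predicted < observed``) among non-tied
    records and tests them against success probability 1/2.  Exact ties are
    excluded from n; if every record is a tie the p-value is reported as 1.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise InvalidInputError("predicted and observed must have equal length")
    if pred.size == 0:
        raise InvalidInputError("need at least 1 record")
    residuals = pred - obs
    n_under = int(np.sum(residuals < 0))
    n_over = int(np.sum(residuals > 0))
    n_ties = int(np.sum(residuals == 0))
    n_effective = n_under + n_over
    if n_effective == 0:
        logger.info("all %d records are exact ties; binomial p reported as 1", n_ties)
        p = 1.0
    else:
        p = float(binomtest(n_under, n_effective, 0.5).pvalue)
    return EvaluationReport(
        rmse=rmse_log_bcf(pred, obs),
        n=int(pred.size),
        n_under=n_under,
        n_over=n_over,
        n_ties=n_ties,
        binomial_p=p,
        per_record_residuals=residuals,
    )


def split_train_validation(dataset, seed: int | None = None):
    """Seeded random partition into equal train/validation halves.

    For odd sizes the extra record goes to the training half (logged).
    Returns two objects of the same type as ``dataset`` via its ``subset``
    method (lists are also accepted).
    """
    n = len(dataset)
    if n < 2:
        raise InvalidInputError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = n // 2 + n % 2
    if n % 2:
        logger.info("odd dataset size %d: extra record assigned to training", n)
    train_idx, val_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
    if hasattr(dataset, "subset"):
        return dataset.subset(train_idx), dataset.subset(val_idx)
    return [dataset[i] for i in train_idx], [dataset[i] for i in val_idx]


# -- model dispatch ----------------------------------------------------------


def predict_log10_bcf(
    model_spec: str,
    phys,
    log10_kow,
    optimized_pair=None,
    alpha_rule=None,
) -> np.ndarray:
    """Predict log10 BCF for an array of log10 Kow under a named model spec.

    ``model_spec`` is one of :data:`MODEL_SPECS`.  ``7c-optimized`` replaces
    the physiology's (F_gill, k_m) with ``optimized_pair`` (anything with
    ``f_gill``/``k_m`` attributes or a 2-sequence).
    """
    kow = np.atleast_1d(np.asarray(log10_kow, dtype=float))
    if model_spec == "1c-pbw-limit":
        return PBW_SLOPE * kow + PBW_INTERCEPT
    if model_spec == "1c-literature":
        if not isinstance(phys, Physiology1C):
            raise InvalidInputError("1c-literature requires a Physiology1C")
        preds = [
            models.bcf_1c(phys, Chemical(f"c{i}", k)) for i, k in enumerate(kow)
        ]
        return np.log10(np.asarray(preds))
    if model_spec in ("7c-literature", "7c-optimized"):
        if not isinstance(phys, Physiology7C):
            raise InvalidInputError(f"{model_spec} requires a Physiology7C")
        f_gill, k_m = phys.F_gill, phys.k_m
        if model_spec == "7c-optimized":
            if optimized_pair is None:
                raise InvalidInputError("7c-optimized requires optimized_pair")
            if hasattr(optimized_pair, "f_gill"):
                f_gill, k_m = optimized_pair.f_gill, optimized_pair.k_m
            else:
                f_gill, k_m = optimized_pair
        alpha = 1.0
        if alpha_rule is not None:
            alpha = np.array([alpha_rule(k) for k in kow])
            bcf = np.array(
                [
                    models.bcf_7c_batch(phys, [k], f_gill, k_m, alpha=a)[0]
                    for k, a in zip(kow, alpha)
                ]
            )
            return np.log10(bcf)
        return np.log10(models.bcf_7c_batch(phys, kow, f_gill, k_m))
    raise InvalidInputError(f"unknown model spec {model_spec!r}; choose from {MODEL_SPECS}")


def evaluate_dataset(
    model_spec: str,
    phys,
    dataset,
    optimized_pair=None,
    alpha_rule=None,
    group_by: str | None = None,
) -> EvaluationReport:
    """Predict every record from its log10 Kow and aggregate accuracy.

    With ``group_by="species"`` the report additionally carries per-species
    RMSEs (for the cross-species histograms, bin width 0.2).
    """
    records = list(dataset)
    if not records:
        raise InvalidInputError("dataset is empty")
    kow = np.array([r.chemical.log10_kow for r in records])
    obs = np.array([r.log10_bcf_observed for r in records])
    pred = predict_log10_bcf(model_spec, phys, kow, optimized_pair, alpha_rule)
    report = under_over_binomial(pred, obs)
    if group_by is None:
        return report
    if group_by != "species":
        raise InvalidInputError("group_by supports only 'species'")
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(r.species, []).append(i)
    group_rmse = {
        sp: rmse_log_bcf(pred[ix], obs[ix]) for sp, ix in sorted(groups.items())
    }
    return EvaluationReport(
        rmse=report.rmse,
        n=report.n,
        n_under=report.n_under,
        n_over=report.n_over,
        n_ties=report.n_ties,
        binomial_p=report.binomial_p,
        per_record_residuals=report.per_record_residuals,
        group_rmse=group_rmse,
    )


def species_rmse_histogram(group_rmse: Mapping[str, float], bin_width: float = 0.2):
    """Histogram of per-species RMSE values (edges, counts)."""
    values = np.asarray(list(group_rmse.values()), dtype=float)
    if values.size == 0:
        raise InvalidInputError("no species groups")
    upper = np.ceil(values.max() / bin_width) * bin_width
    edges = np.arange(0.0, upper + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts


def compare_species_rmse(rmse_a, rmse_b, paired: bool = False) -> float:
    """Two-sided Student's t-test p-value comparing per-species RMSE sets."""
    a = np.asarray(rmse_a, dtype=float)
    b = np.asarray(rmse_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise InvalidInputError("paired test requires equal-length samples")
        return float(ttest_rel(a, b).pvalue)
    return float(ttest_ind(a, b).pvalue)


# -- parameter-uncertainty analysis -----------------------------------------


def sensitivity_analysis(
    phys7c: Physiology7C,
    best_pair,
    dataset,
    parameters: Sequence[str] | None = None,
    n_reps: int = 1000,
    seed: int | None = None,
    log2_sd: float = 1.0,
    max_resample: int = 1000,
) -> list[SensitivityReport]:
    """Resample each body parameter and test whether the calibrated RMSE moves.

    For each parameter independently: draw ``log2(value) ~ Normal(log2(lit),
    log2_sd^2)`` (sd 1 puts ~68% of draws within half to twice the literature
    value), rebuild the physiology with F_gill/k_m held at ``best_pair`` and
    every other parameter at literature, and recompute the dataset RMSE.  A
    parameter is flagged significant when the baseline RMSE falls outside the
    2.5--97.5 percentile band of the sampled RMSEs.  Draws that violate the
    physiology invariants are resampled (counted per parameter).
    """
    if n_reps < 2:
        raise InvalidInputError("n_reps must be >= 2")
    if parameters is None:
        parameters = BODY_PARAMETERS
    unknown = set(parameters) - set(BODY_PARAMETERS)
    if unknown:
        raise InvalidInputError(f"unknown body parameters: {sorted(unknown)}")
    records = list(dataset)
    if not records:
        raise InvalidInputError("dataset is empty")
    kow = np.array([r.chemical.log10_kow for r in records])
    obs = np.array([r.log10_bcf_observed for r in records])
    if hasattr(best_pair, "f_gill"):
        f_gill, k_m = best_pair.f_gill, best_pair.k_m
    else:
        f_gill, k_m = best_pair
    base_phys = phys7c.replace(F_gill=f_gill, k_m=k_m)
    baseline = rmse_log_bcf(
        np.log10(models.bcf_7c_batch(base_phys, kow, f_gill, k_m)), obs
    )

    rng = np.random.default_rng(seed)
    reports = []
    for name in parameters:
        lit = get_parameter(phys7c, name)
        sampled = np.empty(n_reps)
        values = np.empty(n_reps)
        n_resampled = 0
        for i in range(n_reps):
            for _attempt in range(max_resample):
                value = lit * 2.0 ** rng.normal(0.0, log2_sd)
                try:
                    p = with_parameter(base_phys, name, value)
                except InvalidInputError:
                    n_resampled += 1
                    continue
                break
            else:
                raise InvalidInputError(
                    f"could not draw a valid value for {name} in "
                    f"{max_resample} attempts"
                )
            values[i] = value
            sampled[i] = rmse_log_bcf(
                np.log10(models.bcf_7c_batch(p, kow, f_gill, k_m)), obs
            )
        lo, hi = np.percentile(sampled, [2.5, 97.5])
        reports.append(
            SensitivityReport(
                parameter=name,
                baseline_rmse=baseline,
                sampled_rmse=sampled,
                interval_95=(float(lo), float(hi)),
                significant=bool(baseline < lo or baseline > hi),
                n_resampled=n_resampled,
                sampled_values=values,
            )
        )
        if n_resampled:
            logger.info(
                "%s: %d invalid draws resampled out of %d",
                name, n_resampled, n_reps,
            )
    return reports
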