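"""Calibration of the 7C model's source and sink parameters.

Chemical enters the fish through the gills at a rate controlled by ``F_gill``
(source) and leaves through first-order liver decomposition at rate ``k_m``
(sink).  Three calibration workflows are provided, each scored against
observed log10 BCF data:

* :class:`SourceSinkModel` -- optimise (F_gill, k_m) jointly over a dataset
  with all other parameters fixed at literature values.
* :class:`AllParameterModel` -- optimise the full body-parameter vector
  (everything except F_gill and k_m by default; the subset is configurable).
* :func:`calibrate_per_chemical` -- optimise (F_gill, k_m) to reproduce a
  single observation to a relative error below 1e-3.

Because the steady-state BCF depends on (F_gill, k_m) only through an
effective source/sink balance, noise-free data constrain the pair to a 1-D
degeneracy curve rather than a point.  Pooling many per-chemical optima and
taking binned medians of F_gill against k_m (:func:`median_curve`) exposes a
saturating relationship,

    F_gill = F_max * k_m / (K + k_m),

fitted by :func:`fit_eq4`; substituting this curve for per-chemical
decomposition rates yields a model that needs no chemical-specific kinetic
measurements at all.  :func:`grid_scan` maps the RMSE landscape over a
log-spaced (k_m, F_gill) grid to visualise the degeneracy region.

Swarm optimisation runs on log10-transformed coordinates (uniform
initialisation there is log-uniform in the raw parameters), since the optima
span several decades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import ConvergenceError, InvalidInputError
from . import models
from .physiology import (
    BODY_PARAMETERS,
    BCFRecord,
    Physiology7C,
    default_physiology_7c,
    get_parameter,
)
from .pso import OptimizationResult, PSOConfig, pso_maximize, r2_vs_identity
from .evaluation import rmse_log_bcf

logger = logging.getLogger(__name__)

__all__ = [
    "SourceSinkPair",
    "Eq4Fit",
    "GridScan",
    "SourceSinkModel",
    "SourceSinkResults",
    "AllParameterModel",
    "AllParameterResults",
    "DEFAULT_SOURCE_SINK_BOUNDS",
    "calibrate_source_sink",
    "calibrate_all_parameters",
    "calibrate_per_chemical",
    "per_chemical_ensemble",
    "median_curve",
    "fit_eq4",
    "eq4_predict",
    "eq4_inverse",
    "grid_scan",
]

#: Search box for (F_gill [uL/s], k_m [1/s]); spans the RMSE-landscape grid
#: and contains the literature F_gill = 9.167 uL/s.
DEFAULT_SOURCE_SINK_BOUNDS = ((1e-7, 1e1), (1e-6, 1e-1))

#: Guard for the per-chemical relative-error score, which divides by the
#: observed log10 BCF and is ill-conditioned near BCF = 1.
LOG_BCF_GUARD = 0.05


@dataclass(frozen=True)
class SourceSinkPair:
    """A calibrated (F_gill, k_m) pair and its score."""

    f_gill: float
    k_m: float
    score: float
    chemical: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.f_gill <= 0 or self.k_m <= 0:
            raise InvalidInputError("F_gill and k_m must be positive")


@dataclass(frozen=True)
class Eq4Fit:
    """Fitted saturating source--sink relationship F = F_max * k/(K + k)."""

    f_max: float
    k_half: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.k_half <= 0:
            raise InvalidInputError("F_max and K must be positive")
        if self.r_squared > 1:
            raise InvalidInputError("r_squared cannot exceed 1")


@dataclass(frozen=True)
class GridScan:
    """RMSE of the 7C model over a log-spaced (k_m, F_gill) grid.

    ``rmse[i, j]`` corresponds to ``km_grid[i]``, ``fgill_grid[j]``.
    """

    km_grid: np.ndarray
    fgill_grid: np.ndarray
    rmse: np.ndarray
    contour_level: float = 1.0

    def __post_init__(self) -> None:
        for name in ("km_grid", "fgill_grid"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.size == 0 or np.any(np.diff(g) <= 0):
                raise InvalidInputError(f"{name} must be nonempty, strictly increasing")
            object.__setattr__(self, name, g)
        object.__setattr__(self, "rmse", np.asarray(self.rmse, dtype=float))
        if self.rmse.shape != (self.km_grid.size, self.fgill_grid.size):
            raise InvalidInputError("rmse shape does not match the grids")

    @property
    def min_rmse(self) -> float:
        return float(np.nanmin(self.rmse))

    def region_mask(self, level: float | None = None) -> np.ndarray:
        """Boolean mask of grid cells with RMSE below the contour level."""
        level = self.contour_level if level is None else level
        with np.errstate(invalid="ignore"):
            return self.rmse < level


# -- shared helpers ----------------------------------------------------------


def _dataset_arrays(dataset):
    records = list(dataset)
    if not records:
        raise InvalidInputError("dataset is empty")
    kow = np.array([r.chemical.log10_kow for r in records])
    obs = np.array([r.log10_bcf_observed for r in records])
    return records, kow, obs


def _log_bounds(bounds):
    return tuple((np.log10(lo), np.log10(hi)) for lo, hi in bounds)


# -- statsmodels-style model objects ----------------------------------------


class SourceSinkModel:
    """Source/sink calibration of the 7C model against observed BCF data.

    Parameters
    ----------
    dataset : iterable of BCFRecord (or DatasetTable)
        Observations; each record contributes its log10 Kow and observed
        log10 BCF.
    physiology : Physiology7C, optional
        Literature body parameters (default: shipped adult zebrafish set).
    bounds : pair of (lower, upper), optional
        Search box for (F_gill, k_m).

    ``fit`` maximises the R^2 of predicted vs. observed log10 BCF against the
    identity line with a particle swarm; all body parameters stay fixed.
    """

    def __init__(self, dataset, physiology: Physiology7C | None = None,
                 bounds=DEFAULT_SOURCE_SINK_BOUNDS):
        self.physiology = physiology or default_physiology_7c()
        self.records, self._kow, self._obs = _dataset_arrays(dataset)
        self.bounds = bounds
        self.nobs = len(self.records)

    @classmethod
    def from_dataframe(cls, df, physiology: Physiology7C | None = None, **kwargs):
        """Build from a DataFrame with columns chemical, log10_kow, log10_bcf."""
        from .data_io import DatasetTable

        return cls(DatasetTable.from_dataframe(df), physiology, **kwargs)

    # -- prediction and scoring --

    def predict(self, f_gill: float | None = None, k_m: float | None = None) -> np.ndarray:
        """Predicted log10 BCF per record (defaults: literature pair)."""
        f = self.physiology.F_gill if f_gill is None else f_gill
        k = self.physiology.k_m if k_m is None else k_m
        return np.log10(models.bcf_7c_batch(self.physiology, self._kow, f, k))

    def rmse(self, f_gill: float | None = None, k_m: float | None = None) -> float:
        return rmse_log_bcf(self.predict(f_gill, k_m), self._obs)

    def score(self, f_gill: float | None = None, k_m: float | None = None) -> float:
        """R^2 of predictions against the identity line."""
        return r2_vs_identity(self.predict(f_gill, k_m), self._obs)

    def _objective(self, log_positions: np.ndarray) -> np.ndarray:
        f = 10.0 ** log_positions[:, 0]
        k = 10.0 ** log_positions[:, 1]
        pred = np.log10(models.bcf_7c_batch(self.physiology, self._kow, f, k))
        resid = pred - self._obs
        ss_tot = np.sum((self._obs - self._obs.mean()) ** 2)
        return 1.0 - np.sum(resid**2, axis=-1) / ss_tot

    def fit(self, pso_config: PSOConfig | None = None, seed: int | None = None
            ) -> "SourceSinkResults":
        """Run the swarm and return a results object."""
        if pso_config is None:
            pso_config = PSOConfig(
                bounds=_log_bounds(self.bounds),
                score_cutoff=0.99,
                init="uniform",
                seed=seed,
            )
        else:
            pso_config = pso_config.replace(
                bounds=_log_bounds(self.bounds), init="uniform",
                seed=pso_config.seed if seed is None else seed,
            )
        opt = pso_maximize(self._objective, pso_config, vectorized=True)
        f_gill, k_m = 10.0 ** opt.best_position
        return SourceSinkResults(self, f_gill, k_m, opt)


class SourceSinkResults:
    """Calibrated source/sink pair with diagnostics.

    Attributes
    ----------
    f_gill, k_m : float
        The optimised pair (uL/s, 1/s).
    rmse, r_squared : float
        Training-set accuracy of the pair.
    """

    def __init__(self, model: SourceSinkModel, f_gill: float, k_m: float,
                 optimization: OptimizationResult):
        self.model = model
        self.f_gill = float(f_gill)
        self.k_m = float(k_m)
        self.optimization = optimization
        self.params = np.array([self.f_gill, self.k_m])
        self.r_squared = float(optimization.best_score)
        self.rmse = model.rmse(self.f_gill, self.k_m)
        self.nobs = model.nobs

    @property
    def pair(self) -> SourceSinkPair:
        return SourceSinkPair(
            f_gill=self.f_gill, k_m=self.k_m, score=self.rmse,
            seed=self.optimization.seed,
        )

    def predict(self, log10_kow=None) -> np.ndarray:
        """Predicted log10 BCF at the optimum (new chemicals via log10_kow)."""
        if log10_kow is None:
            return self.model.predict(self.f_gill, self.k_m)
        return np.log10(
            models.bcf_7c_batch(
                self.model.physiology, np.atleast_1d(log10_kow),
                self.f_gill, self.k_m,
            )
        )

    def evaluation(self, dataset=None):
        """Full evaluation report (under/over counts, binomial p) at the optimum."""
        from .evaluation import evaluate_dataset

        data = self.model.records if dataset is None else dataset
        return evaluate_dataset(
            "7c-optimized", self.model.physiology, data, optimized_pair=self
        )

    def sensitivity(self, parameters=None, n_reps: int = 1000,
                    seed: int | None = None):
        """Body-parameter uncertainty analysis around this optimum."""
        from .evaluation import sensitivity_analysis

        return sensitivity_analysis(
            self.model.physiology, self, self.model.records,
            parameters=parameters, n_reps=n_reps, seed=seed,
        )

    def influx_rate(self, alpha: float = 1.0) -> float:
        """Effective uptake rate alpha*F_gill/V_art (1/s) at the optimum."""
        return models.influx_rate(alpha, self.f_gill, self.model.physiology.V_art)

    def summary(self) -> str:
        opt = self.optimization
        lines = [
            "Source/sink calibration of the 7C bioconcentration model",
            "=" * 58,
            f"{'No. observations:':<28}{self.nobs}",
            f"{'F_gill (uL/s):':<28}{self.f_gill:.6g}",
            f"{'k_m (1/s):':<28}{self.k_m:.6g}",
            f"{'RMSE (log10 BCF):':<28}{self.rmse:.4f}",
            f"{'R^2 vs identity:':<28}{self.r_squared:.4f}",
            f"{'Influx rate (1/s, alpha=1):':<28}{self.influx_rate():.4g}",
            f"{'Iterations:':<28}{opt.iterations_run}",
            f"{'Converged (score cutoff):':<28}{opt.converged}",
            f"{'Seed:':<28}{opt.seed}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<SourceSinkResults F_gill={self.f_gill:.4g} k_m={self.k_m:.4g} "
            f"rmse={self.rmse:.4f}>"
        )


class AllParameterModel:
    """Calibrate an arbitrary subset of body parameters of the 7C model.

    By default every body parameter (flows, masses, lipid and water contents)
    is free while F_gill and k_m stay at their literature values; pass
    ``free_params`` to change the subset.  Bounds default to
    ``(literature/100, min(100*literature, 1))`` for fraction-valued
    parameters and ``(literature/100, 100*literature)`` otherwise.  Flow
    fractions are treated as unnormalised weights and renormalised to sum to
    1 inside the objective; candidate physiologies violating any invariant
    score ``-inf``.
    """

    def __init__(self, dataset, physiology: Physiology7C | None = None,
                 free_params: Sequence[str] | None = None, bounds=None):
        self.physiology = physiology or default_physiology_7c()
        self.records, self._kow, self._obs = _dataset_arrays(dataset)
        self.free_params = tuple(free_params or BODY_PARAMETERS)
        unknown = set(self.free_params) - set(BODY_PARAMETERS)
        if unknown:
            raise InvalidInputError(f"unknown body parameters: {sorted(unknown)}")
        if bounds is None:
            bounds = []
            for name in self.free_params:
                lit = get_parameter(self.physiology, name)
                upper = 100.0 * lit
                if name.split("_")[0] in ("f", "L", "W") or name.startswith("m_") and name != "m_tot":
                    upper = min(upper, 1.0)
                bounds.append((lit / 100.0, upper))
        self.bounds = tuple(bounds)
        self.nobs = len(self.records)

    def _build(self, values: np.ndarray) -> Physiology7C | None:
        flows = dict(self.physiology.flow_fractions)
        masses = dict(self.physiology.mass_fractions)
        lipids = dict(self.physiology.lipid_content)
        waters = dict(self.physiology.water_content)
        scalars = {"f_car": self.physiology.f_car, "m_tot": self.physiology.m_tot}
        target = {"f": flows, "m": masses, "L": lipids, "W": waters}
        abbrev = {"bld": "blood", "brn": "brain", "gon": "gonads",
                  "rpt": "rpt", "ppt": "ppt", "liv": "liver"}
        for name, value in zip(self.free_params, values):
            if name in scalars:
                scalars[name] = value
            else:
                prefix, _, a = name.partition("_")
                target[prefix][abbrev[a]] = value
        total = sum(flows.values())
        flows = {k: v / total for k, v in flows.items()}
        try:
            return self.physiology.replace(
                f_car=scalars["f_car"], m_tot=scalars["m_tot"],
                flow_fractions=flows, mass_fractions=masses,
                lipid_content=lipids, water_content=waters,
            )
        except InvalidInputError:
            return None

    def _objective(self, position: np.ndarray) -> float:
        phys = self._build(position)
        if phys is None:
            return -np.inf
        pred = np.log10(
            models.bcf_7c_batch(phys, self._kow, phys.F_gill, phys.k_m)
        )
        return r2_vs_identity(pred, self._obs)

    def score_literature(self) -> float:
        return self._objective(
            np.array([get_parameter(self.physiology, n) for n in self.free_params])
        )

    def fit(self, pso_config: PSOConfig | None = None, seed: int | None = None
            ) -> "AllParameterResults":
        if pso_config is None:
            pso_config = PSOConfig(bounds=self.bounds, score_cutoff=0.99, seed=seed)
        else:
            pso_config = pso_config.replace(
                bounds=self.bounds,
                seed=pso_config.seed if seed is None else seed,
            )
        opt = pso_maximize(self._objective, pso_config, vectorized=False)
        return AllParameterResults(self, opt)


class AllParameterResults:
    """Optimised body-parameter vector with diagnostics."""

    def __init__(self, model: AllParameterModel, optimization: OptimizationResult):
        self.model = model
        self.optimization = optimization
        self.params = optimization.best_position
        self.r_squared = float(optimization.best_score)
        self.physiology = model._build(self.params)
        pred = np.log10(
            models.bcf_7c_batch(
                self.physiology, model._kow,
                self.physiology.F_gill, self.physiology.k_m,
            )
        )
        self.rmse = rmse_log_bcf(pred, model._obs)
        self.nobs = model.nobs

    def summary(self) -> str:
        lines = [
            "All-parameter calibration of the 7C bioconcentration model",
            "=" * 60,
            f"{'No. observations:':<26}{self.nobs}",
            f"{'RMSE (log10 BCF):':<26}{self.rmse:.4f}",
            f"{'R^2 vs identity:':<26}{self.r_squared:.4f}",
            f"{'Iterations:':<26}{self.optimization.iterations_run}",
            f"{'Seed:':<26}{self.optimization.seed}",
            "",
            f"{'parameter':<12}{'literature':>14}{'optimized':>14}",
        ]
        for name, value in zip(self.model.free_params, self.params):
            lit = get_parameter(self.model.physiology, name)
            lines.append(f"{name:<12}{lit:>14.5g}{value:>14.5g}")
        return "\n".join(lines)


# -- functional calibration surface -----------------------------------------


def calibrate_source_sink(
    dataset,
    phys7c: Physiology7C | None = None,
    pso_config: PSOConfig | None = None,
    seed: int | None = None,
    bounds=DEFAULT_SOURCE_SINK_BOUNDS,
) -> SourceSinkPair:
    """Optimise (F_gill, k_m) over a dataset; returns the best pair and its RMSE."""
    res = SourceSinkModel(dataset, phys7c, bounds=bounds).fit(pso_config, seed=seed)
    return res.pair


def calibrate_all_parameters(
    dataset,
    phys7c: Physiology7C | None = None,
    pso_config: PSOConfig | None = None,
    free_params: Sequence[str] | None = None,
    seed: int | None = None,
    bounds=None,
) -> OptimizationResult:
    """Optimise the body-parameter subset; returns the raw swarm result."""
    model = AllParameterModel(dataset, phys7c, free_params=free_params, bounds=bounds)
    return model.fit(pso_config, seed=seed).optimization


def calibrate_per_chemical(
    record: BCFRecord,
    phys7c: Physiology7C | None = None,
    pso_config: PSOConfig | None = None,
    seed: int | None = None,
    bounds=DEFAULT_SOURCE_SINK_BOUNDS,
    rel_error_cutoff: float = 1e-3,
) -> SourceSinkPair:
    """Find an (F_gill, k_m) pair reproducing one observation.

    Particles are scored by the negative relative error
    ``|obs - pred| / |obs|`` on the log10 BCF scale and the swarm stops when
    it drops below ``rel_error_cutoff``.  Records with ``|log10 BCF| <
    0.05`` are refused: the relative error is ill-conditioned near BCF = 1.
    """
    phys7c = phys7c or default_physiology_7c()
    obs = record.log10_bcf_observed
    if abs(obs) < LOG_BCF_GUARD:
        raise InvalidInputError(
            f"observed log10 BCF {obs!r} is within {LOG_BCF_GUARD} of zero; "
            "the relative-error score is ill-defined for this record"
        )
    kow = np.array([record.chemical.log10_kow])

    def objective(log_positions: np.ndarray) -> np.ndarray:
        f = 10.0 ** log_positions[:, 0]
        k = 10.0 ** log_positions[:, 1]
        pred = np.log10(models.bcf_7c_batch(phys7c, kow, f, k))[..., 0]
        return -np.abs(obs - pred) / abs(obs)

    if pso_config is None:
        pso_config = PSOConfig(
            bounds=_log_bounds(bounds), n_particles=200, max_iterations=500,
            init="uniform", seed=seed,
        )
    else:
        pso_config = pso_config.replace(
            bounds=_log_bounds(bounds), init="uniform",
            seed=pso_config.seed if seed is None else seed,
        )
    pso_config = pso_config.replace(score_cutoff=-rel_error_cutoff)
    opt = pso_maximize(objective, pso_config, vectorized=True)
    if not opt.converged:
        logger.warning(
            "per-chemical calibration of %s stopped at relative error %.3g "
            "after %d iterations (cutoff %.3g)",
            record.chemical.name, -opt.best_score, opt.iterations_run,
            rel_error_cutoff,
        )
    f_gill, k_m = 10.0 ** opt.best_position
    return SourceSinkPair(
        f_gill=f_gill, k_m=k_m, score=-opt.best_score,
        chemical=record.chemical.name, seed=pso_config.seed,
    )


def per_chemical_ensemble(
    dataset,
    phys7c: Physiology7C | None = None,
    n_seeds: int = 1000,
    pso_config: PSOConfig | None = None,
    seed: int | None = None,
    skip_guarded: bool = True,
) -> list[SourceSinkPair]:
    """Pool per-chemical optima over repeated seeded runs.

    Runs :func:`calibrate_per_chemical` ``n_seeds`` times per record with
    derived seeds.  Records failing the near-zero guard are skipped (logged)
    unless ``skip_guarded`` is disabled.
    """
    records, _, _ = _dataset_arrays(dataset)
    rng = np.random.default_rng(seed)
    pairs: list[SourceSinkPair] = []
    for record in records:
        if skip_guarded and abs(record.log10_bcf_observed) < LOG_BCF_GUARD:
            logger.info(
                "skipping %s: |log10 BCF| = %.3g below guard %.3g",
                record.chemical.name, abs(record.log10_bcf_observed),
                LOG_BCF_GUARD,
            )
            continue
        for _ in range(n_seeds):
            run_seed = int(rng.integers(0, 2**31 - 1))
            pairs.append(
                calibrate_per_chemical(
                    record, phys7c, pso_config, seed=run_seed
                )
            )
    return pairs


# -- the saturating source/sink relationship ---------------------------------


def median_curve(pairs: Sequence[SourceSinkPair], n_bins: int = 50) -> np.ndarray:
    """Binned medians of F_gill against k_m over pooled calibration optima.

    Bins k_m on a log-spaced grid spanning the pooled range and reports the
    per-bin median F_gill at the geometric bin centre; empty bins are
    omitted.  Returns an array of shape (n_nonempty, 2): (k_m, median F).
    """
    pairs = list(pairs)
    if not pairs:
        raise InvalidInputError("no pairs to bin")
    km = np.array([p.k_m for p in pairs])
    fg = np.array([p.f_gill for p in pairs])
    if np.unique(km).size == 1:
        return np.array([[km[0], float(np.median(fg))]])
    edges = np.logspace(np.log10(km.min()), np.log10(km.max()), n_bins + 1)
    idx = np.clip(np.digitize(km, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            centre = np.sqrt(edges[b] * edges[b + 1])
            rows.append((centre, float(np.median(fg[mask]))))
    if len(rows) < 2:
        raise InvalidInputError(
            f"only {len(rows)} nonempty k_m bins; cannot form a median curve"
        )
    return np.array(rows)


def _eq4(km, f_max, k_half):
    return f_max * km / (k_half + km)


def fit_eq4(points) -> Eq4Fit:
    """Nonlinear least squares of F = F_max * k/(K + k) on the linear F scale.

    ``points`` is an (n, 2) array of (k_m, F_gill) or a sequence of pairs.
    Initial guess: F_max = max F, K = median k_m.
    """
    pts = np.asarray(
        [(p.k_m, p.f_gill) if isinstance(p, SourceSinkPair) else tuple(p) for p in points],
        dtype=float,
    )
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidInputError("need at least 3 (k_m, F_gill) points")
    km, fg = pts[:, 0], pts[:, 1]
    if np.any(km <= 0):
        raise InvalidInputError("k_m values must be positive")
    p0 = (float(fg.max()), float(np.median(km)))
    try:
        popt, _ = curve_fit(
            _eq4, km, fg, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise ConvergenceError(
            f"saturating fit did not converge from initial guess "
            f"F_max={p0[0]:.4g}, K={p0[1]:.4g}: {exc}"
        ) from exc
    fitted = _eq4(km, *popt)
    ss_tot = np.sum((fg - fg.mean()) ** 2)
    r2 = 1.0 - float(np.sum((fg - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return Eq4Fit(f_max=float(popt[0]), k_half=float(popt[1]), r_squared=r2)


def eq4_predict(fit: Eq4Fit, k_m):
    """F_gill on the saturating curve at k_m (0 at 0, F_max/2 at K, -> F_max)."""
    km = np.asarray(k_m, dtype=float)
    if np.any(km < 0):
        raise InvalidInputError("k_m must be >= 0")
    out = _eq4(km, fit.f_max, fit.k_half)
    return float(out) if out.ndim == 0 else out


def eq4_inverse(fit: Eq4Fit, f_gill):
    """Effective k_m implied by a measured F_gill: k = K*F/(F_max - F)."""
    f = np.asarray(f_gill, dtype=float)
    if np.any(f < 0) or np.any(f >= fit.f_max):
        raise InvalidInputError(
            f"F_gill must lie in [0, F_max = {fit.f_max!r}) for the inverse"
        )
    out = fit.k_half * f / (fit.f_max - f)
    return float(out) if out.ndim == 0 else out


# -- RMSE landscape ----------------------------------------------------------


def grid_scan(
    dataset,
    phys7c: Physiology7C | None = None,
    km_grid=None,
    fgill_grid=None,
    contour_level: float = 1.0,
    chunk: int = 200,
) -> GridScan:
    """RMSE of the 7C model over a log-spaced (k_m, F_gill) grid.

    Every other parameter stays at its literature value.  Failed model
    evaluations are recorded as NaN rather than aborting the scan.
    """
    phys7c = phys7c or default_physiology_7c()
    _, kow, obs = _dataset_arrays(dataset)
    km_grid = (
        np.logspace(-6, -1, 100) if km_grid is None
        else np.asarray(km_grid, dtype=float)
    )
    fgill_grid = (
        np.logspace(-7, 1, 100) if fgill_grid is None
        else np.asarray(fgill_grid, dtype=float)
    )
    kk, ff = np.meshgrid(km_grid, fgill_grid, indexing="ij")
    flat_k, flat_f = kk.ravel(), ff.ravel()
    out = np.full(flat_k.size, np.nan)
    for start in range(0, flat_k.size, chunk):
        sl = slice(start, start + chunk)
        try:
            bcf = models.bcf_7c_batch(phys7c, kow, flat_f[sl], flat_k[sl])
            with np.errstate(divide="ignore", invalid="ignore"):
                pred = np.log10(bcf)
            resid = pred - obs
            out[sl] = np.sqrt(np.mean(resid**2, axis=-1))
        except Exception as exc:  # record as missing, not fatal
            logger.warning("grid chunk %d failed: %s", start, exc)
    return GridScan(
        km_grid=km_grid, fgill_grid=fgill_grid,
        rmse=out.reshape(km_grid.size, fgill_grid.size),
        contour_level=contour_level,
    )
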