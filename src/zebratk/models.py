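"""Steady-state bioconcentration-factor models.

Two forward models map ``log10 Kow`` to a whole-body bioconcentration factor
(BCF), the steady-state ratio of body to aqueous concentration:

* ``bcf_1c`` -- the one-compartment closed form

      BCF = P_bw / (1 + (V_t * k_m / (F_gill * P_t)) * P_bw)

  which reduces to ``P_bw`` as ``k_m -> 0`` and is bounded above by ``P_bw``.

* ``bcf_7c`` -- the seven-compartment model: chemical enters arterial blood
  through the gills at rate ``alpha * F_gill * C_exp``, arterial blood
  perfuses brain, gonads, richly/poorly perfused tissue and liver
  (flow-limited exchange), gonads and richly perfused tissue drain through
  the liver, the liver holds the only metabolic sink (``k_m * V_liv *
  C_liv``), and venous blood returns to the gills where efflux
  ``alpha * F_gill * C_ven / P_bw`` closes the balance.  The steady state is
  the solution of a 7x7 linear system, solved directly.

Inverting either model gives the reverse-toxicokinetic relation
``C_exp = C_body / BCF`` (``predict_exposure``).

``ode_oracle`` integrates the corresponding mass-balance ODEs from zero
initial conditions and serves as an independent cross-check of the linear
solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import (
    ConvergenceError,
    DegenerateInputError,
    InvalidInputError,
    NumericalError,
)
from .physiology import (
    TISSUES,
    AlphaRule,
    Chemical,
    PartitionSet,
    Physiology1C,
    Physiology7C,
    blood_water_partition,
    partition_set,
    tissue_blood_partition,
)

__all__ = [
    "COMPARTMENTS",
    "SteadyState",
    "bcf_1c",
    "km_upper_bound",
    "build_7c_system",
    "bcf_7c",
    "bcf_7c_batch",
    "ode_oracle",
    "predict_exposure",
    "influx_rate",
]

#: Order of the unknowns in the 7C linear system.
COMPARTMENTS = ("arterial", "venous") + TISSUES


@dataclass(frozen=True)
class SteadyState:
    """Steady-state concentrations and the derived whole-body BCF.

    Concentrations are amount per uL in the same (arbitrary) amount unit as
    ``C_exp``; ``bcf`` is their dimensionless ratio and is independent of the
    numeric value of ``C_exp`` (the system is linear).
    """

    concentrations: Mapping[str, float]
    C_exp: float
    C_body: float
    bcf: float


# -- one-compartment model ---------------------------------------------------


def _p_t_1c(phys: Physiology1C, chemical: Chemical) -> tuple[float, float]:
    p_bw = blood_water_partition(chemical.log10_kow)
    p_t = tissue_blood_partition(chemical.log10_kow, phys.L_body, phys.W_body, p_bw)
    return p_bw, p_t


def bcf_1c(phys: Physiology1C, chemical: Chemical) -> float:
    """Whole-body BCF of the one-compartment model.

    Strictly decreasing in ``k_m`` and bounded above by ``P_bw``, which it
    attains at ``k_m = 0``.
    """
    p_bw, p_t = _p_t_1c(phys, chemical)
    if phys.F_gill == 0.0:
        if phys.k_m > 0.0:
            raise DegenerateInputError(
                "F_gill = 0 with k_m > 0: the metabolic correction term of the "
                "one-compartment BCF diverges"
            )
        return p_bw
    return p_bw / (1.0 + (phys.V_t * phys.k_m / (phys.F_gill * p_t)) * p_bw)


def km_upper_bound(phys: Physiology1C, p_bw: float, p_t: float | None = None) -> float:
    """Largest ``k_m`` compatible with BCF > 1 in the one-compartment model.

    Returns ``(F_gill * P_t / V_t) * (1 - 1/P_bw)``; negative when
    ``P_bw < 1``, signalling that no decomposition rate can yield BCF > 1.
    ``p_t`` defaults to the whole-body tissue--blood ratio at the P_bw given.
    """
    if p_bw <= 0:
        raise InvalidInputError("P_bw must be positive")
    if p_t is None:
        # recover log10 Kow from the regression to evaluate the body P_t
        log10_kow = (np.log10(p_bw) + 0.82) / 0.78
        p_t = tissue_blood_partition(log10_kow, phys.L_body, phys.W_body, p_bw)
    return (phys.F_gill * p_t / phys.V_t) * (1.0 - 1.0 / p_bw)


# -- seven-compartment model -------------------------------------------------


def build_7c_system(
    phys: Physiology7C,
    partitions: PartitionSet,
    c_exp: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the steady-state mass balances as ``A @ C = b``.

    Unknowns are ordered as :data:`COMPARTMENTS`.  Every row is written as
    ``outflow - inflow = source`` so that the time-dependent balances are
    ``V_i dC_i/dt = b_i - (A @ C)_i``.  ``b`` is proportional to ``c_exp``,
    so the solution -- and hence the BCF -- is linear in the exposure
    concentration.
    """
    q = {t: phys.tissue_flow(t) for t in TISSUES}
    q_lgr = q["liver"] + q["gonads"] + q["rpt"]
    v_liv = phys.tissue_volume("liver")
    p = partitions.P_tb
    a_f = partitions.alpha * phys.F_gill

    idx = {name: i for i, name in enumerate(COMPARTMENTS)}
    A = np.zeros((7, 7))
    b = np.zeros(7)

    # arterial: alpha*F*C_exp + f_car*C_ven - alpha*F*C_ven/P_bw - f_car*C_art = 0
    A[0, idx["arterial"]] = phys.f_car
    A[0, idx["venous"]] = a_f / partitions.P_bw - phys.f_car
    b[0] = a_f * c_exp

    # venous: returns from brain, ppt and liver balance the cardiac outflow
    A[1, idx["venous"]] = phys.f_car
    A[1, idx["brain"]] = -q["brain"] / p["brain"]
    A[1, idx["ppt"]] = -q["ppt"] / p["ppt"]
    A[1, idx["liver"]] = -q_lgr / p["liver"]

    # flow-limited exchange: Q_i * (C_i / P_i - C_art) = 0
    for t in ("brain", "gonads", "rpt", "ppt"):
        A[idx[t], idx["arterial"]] = -q[t]
        A[idx[t], idx[t]] = q[t] / p[t]

    # liver: inflow from arterial, gonads and rpt; outflow to venous; k_m sink
    A[6, idx["arterial"]] = -q["liver"]
    A[6, idx["gonads"]] = -q["gonads"] / p["gonads"]
    A[6, idx["rpt"]] = -q["rpt"] / p["rpt"]
    A[6, idx["liver"]] = q_lgr / p["liver"] + phys.k_m * v_liv

    return A, b


def _solve_7c(phys: Physiology7C, partitions: PartitionSet, c_exp: float) -> np.ndarray:
    A, b = build_7c_system(phys, partitions, c_exp)
    try:
        conc = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular 7C steady-state system "
            f"(F_gill={phys.F_gill!r}, k_m={phys.k_m!r}, "
            f"P_bw={partitions.P_bw!r}, alpha={partitions.alpha!r}): {exc}"
        ) from exc
    if not np.all(np.isfinite(conc)):
        raise NumericalError(
            "non-finite 7C steady state "
            f"(F_gill={phys.F_gill!r}, k_m={phys.k_m!r})"
        )
    return conc


def _body_average(phys: Physiology7C, conc: np.ndarray, include_blood: bool) -> float:
    vols = np.array([phys.volumes[c] for c in COMPARTMENTS])
    if include_blood:
        return float(conc @ vols / vols.sum())
    mask = np.array([c not in ("arterial", "venous") for c in COMPARTMENTS])
    return float(conc[mask] @ vols[mask] / vols[mask].sum())


def bcf_7c(
    phys: Physiology7C,
    chemical: Chemical,
    alpha_rule: AlphaRule | None = None,
    c_exp: float = 1.0,
    include_blood: bool = True,
) -> SteadyState:
    """Steady state of the seven-compartment model for one chemical.

    The whole-body concentration is the volume-weighted mean over all seven
    compartments (set ``include_blood=False`` to average tissues only).
    """
    if c_exp < 0:
        raise InvalidInputError("C_exp must be >= 0")
    parts = partition_set(chemical, phys, alpha_rule)
    conc = _solve_7c(phys, parts, c_exp)
    # bcf from the unit-exposure solution so it is defined even at c_exp = 0
    unit = conc / c_exp if c_exp > 0 else _solve_7c(phys, parts, 1.0)
    bcf = _body_average(phys, unit, include_blood)
    c_body = bcf * c_exp
    return SteadyState(
        concentrations=dict(zip(COMPARTMENTS, conc)),
        C_exp=c_exp,
        C_body=c_body,
        bcf=bcf,
    )


def bcf_7c_batch(
    phys: Physiology7C,
    log10_kow,
    f_gill,
    k_m,
    alpha=1.0,
    include_blood: bool = True,
) -> np.ndarray:
    """Vectorised 7C BCF over chemicals and (F_gill, k_m) pairs.

    ``log10_kow`` has shape ``(n_chem,)``; ``f_gill``, ``k_m`` and ``alpha``
    broadcast against each other to a pair shape ``S``.  Returns BCFs of
    shape ``S + (n_chem,)``.

    This is the same linear system as :func:`bcf_7c` reduced algebraically:
    brain/gonads/rpt/ppt equilibrate with arterial blood (``C_i = P_i *
    C_art``), the liver balance gives ``C_liv``, the venous balance gives
    ``C_ven = gamma * C_art`` and the gill balance then fixes ``C_art``.
    Agreement with the explicit solve is enforced by the test suite.
    """
    kow_log = np.atleast_1d(np.asarray(log10_kow, dtype=float))
    p_bw = 10.0 ** (0.78 * kow_log - 0.82)
    kow = 10.0 ** kow_log
    p = {
        t: (phys.lipid_content[t] * kow + phys.water_content[t]) / p_bw
        for t in TISSUES
    }

    f_gill = np.asarray(f_gill, dtype=float)[..., None]
    k_m = np.asarray(k_m, dtype=float)[..., None]
    alpha = np.asarray(alpha, dtype=float)[..., None]

    q = {t: phys.tissue_flow(t) for t in TISSUES}
    q_lgr = q["liver"] + q["gonads"] + q["rpt"]
    v_liv = phys.tissue_volume("liver")
    f_car = phys.f_car

    # liver concentration per unit C_art
    liv_per_art = q_lgr / (q_lgr / p["liver"] + k_m * v_liv)
    gamma = (
        q["brain"] + q["ppt"] + (q_lgr / p["liver"]) * liv_per_art
    ) / f_car
    a_f = alpha * f_gill
    denom = f_car - (f_car - a_f / p_bw) * gamma
    with np.errstate(divide="ignore", invalid="ignore"):
        c_art = a_f / denom  # per unit C_exp

    vols = phys.volumes
    num = (vols["arterial"] + vols["venous"] * gamma) * c_art
    v_sum = vols["arterial"] + vols["venous"]
    if not include_blood:
        num = np.zeros_like(c_art)
        v_sum = 0.0
    for t in TISSUES:
        c_t = liv_per_art * c_art if t == "liver" else p[t] * c_art
        num = num + vols[t] * c_t
        v_sum = v_sum + vols[t]
    return num / v_sum


def ode_oracle(
    phys: Physiology7C,
    chemical: Chemical,
    c_exp: float = 1.0,
    t_end: float | None = None,
    tol: float = 1e-8,
    alpha_rule: AlphaRule | None = None,
    include_blood: bool = True,
) -> SteadyState:
    """Steady state via time integration of the 7C mass-balance ODEs.

    Integrates ``V_i dC_i/dt`` from zero initial conditions with a stiff
    solver until all eigen-time-scales have decayed (default ``t_end`` is 40
    times the slowest time constant) and verifies convergence by comparing
    the states at ``t_end/2`` and ``t_end``: their normalised difference must
    fall below ``tol``.
    """
    if c_exp < 0:
        raise InvalidInputError("C_exp must be >= 0")
    parts = partition_set(chemical, phys, alpha_rule)
    A, b = build_7c_system(phys, parts, c_exp)
    vols = np.array([phys.volumes[c] for c in COMPARTMENTS])
    M = -A / vols[:, None]  # dC/dt = M C + s
    s = b / vols

    if t_end is None:
        eig = np.linalg.eigvals(M)
        slowest = np.min(np.abs(eig.real))
        if slowest <= 0:
            raise NumericalError("7C ODE system has a non-decaying mode")
        t_end = 60.0 / slowest

    scale = max(c_exp * parts.P_bw * (1.0 + max(parts.P_tb.values())), 1e-300)
    sol = solve_ivp(
        lambda _t, y: M @ y + s,
        (0.0, t_end),
        np.zeros(7),
        method="Radau",
        jac=lambda _t, _y: M,
        t_eval=[0.5 * t_end, t_end],
        rtol=1e-12,
        atol=1e-15 * scale,
    )
    if not sol.success:
        raise ConvergenceError(f"7C ODE integration failed: {sol.message}")
    y = sol.y[:, -1]
    residual = float(np.max(np.abs(y - sol.y[:, -2])) / scale)
    if residual > tol:
        raise ConvergenceError(
            f"7C ODE not at steady state by t_end={t_end:g}: "
            f"normalised state change over the final half-interval "
            f"{residual:.3e} > tol {tol:.3e}"
        )
    c_body = _body_average(phys, y, include_blood)
    bcf = c_body / c_exp if c_exp > 0 else 0.0
    return SteadyState(
        concentrations=dict(zip(COMPARTMENTS, y)),
        C_exp=c_exp,
        C_body=c_body,
        bcf=bcf,
    )


# -- reverse toxicokinetics and gill flux ------------------------------------


def predict_exposure(c_body: float, bcf: float) -> float:
    """Invert the steady state: ``C_exp = C_body / BCF``."""
    if bcf <= 0:
        raise InvalidInputError(f"BCF must be positive, got {bcf!r}")
    return c_body / bcf


def influx_rate(alpha: float, f_gill: float, v_art: float) -> float:
    """Effective first-order uptake rate into arterial blood.

    ``alpha * F_gill / V_art`` (1/s) -- reinterpretable as a gill-membrane
    permeability rather than a convective water flow.
    """
    if v_art <= 0:
        raise InvalidInputError("V_art must be positive")
    return alpha * f_gill / v_art
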