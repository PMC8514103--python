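"""Oncogene-induction protocols: schedules, time series, and trend observables.

Oncogenic RAS induction is modeled as three coupled time courses over a
−4 h … 48 h window (induction at t = 0):

* ``alpha_t`` — the adhesion weakening factor α drops monotonically from 1
  toward a floor (default 0.4), emulating the loss of integrin-mediated
  substrate adhesion over the first 24 h after induction;
* ``eps_active_t`` — the active peripheral contraction εc ramps linearly
  from 0 (starting at the onset of peripheral actomyosin buildup, default
  8 h) until the total peripheral contraction ε0c + εc doubles the
  homeostatic baseline by the end of the run;
* ``r_inner_t`` — the radius of the central (baseline-only) subdomain Ω1
  shrinks from R to R/3 alongside the contraction ramp, growing the annulus
  Ω2 that carries the active strain.

``simulate_protocol`` re-solves the quasi-static equilibrium at every
timepoint and records the deformed tissue area and the area-weighted mean
traction magnitude; trends are reported normalized to the pre-induction
reference timepoint t = −4 h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dewetsim.fem import (
    ContractileState,
    DisplacementField,
    ElasticMaterial,
    FoundationModel,
    LinearSystem,
    TractionFieldFE,
    assemble_contractile_load,
    assemble_elastic_stiffness,
    assemble_foundation_matrix,
    compute_traction,
    elasticity_matrix,
    element_foundation,
    _assemble,
    mean_traction_magnitude,
    solve_equilibrium,
)
from dewetsim.mesh import DiskMesh, partition_subdomains

CASES = ("combined", "adhesion_only", "contractility_only")

#: default induction-protocol parameters (hours, dimensionless, μm)
DEFAULTS = dict(
    t_start=-4.0,
    t_end=48.0,
    dt=1.0,
    eps0=0.05,
    alpha_min=0.4,
    alpha_drop_end=24.0,
    ramp_start=8.0,
    contraction_factor=2.0,
)


@dataclass(frozen=True)
class InductionSchedule:
    """Tabulated time courses of α, εc, and the Ω1 radius."""

    times: np.ndarray  # hours
    alpha_t: np.ndarray
    eps_active_t: np.ndarray
    r_inner_t: np.ndarray  # μm
    eps0: float

    def __post_init__(self):
        n = len(self.times)
        if not (len(self.alpha_t) == len(self.eps_active_t) == len(self.r_inner_t) == n):
            raise ValueError("all schedule series must have the same length as times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        tol = 1e-12
        if np.any(np.diff(self.alpha_t) > tol):
            raise ValueError("alpha_t must be non-increasing")
        if np.any(np.diff(self.eps_active_t) < -tol):
            raise ValueError("eps_active_t must be non-decreasing")
        if np.any(np.diff(self.r_inner_t) > tol):
            raise ValueError("r_inner_t must be non-increasing")
        if np.any(self.alpha_t < 0) or np.any(self.alpha_t > 1):
            raise ValueError("alpha_t must lie in [0, 1]")
        if np.any(self.eps_active_t < 0) or self.eps0 < 0:
            raise ValueError("contraction magnitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


def _ramp(times: np.ndarray, t0: float, t1: float, v0: float, v1: float) -> np.ndarray:
    """Piecewise-linear: v0 before t0, linear to v1 at t1, v1 after."""
    s = np.clip((times - t0) / (t1 - t0), 0.0, 1.0)
    return v0 + (v1 - v0) * s


def make_schedule(case: str, radius: float, **params) -> InductionSchedule:
    """Build the induction schedule for one of the three scenarios.

    ``combined`` ramps adhesion down and peripheral contraction up (the full
    RAS emulation); ``adhesion_only`` keeps contractility at baseline;
    ``contractility_only`` keeps α ≡ 1. Parameter defaults are in
    ``DEFAULTS``; any of them can be overridden by keyword.
    """
    if case not in CASES:
        raise ValueError(f"case must be one of {CASES}, got {case!r}")
    unknown = set(params) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown schedule parameters: {sorted(unknown)}")
    p = {**DEFAULTS, **params}
    if p["t_start"] >= p["t_end"] or p["dt"] <= 0:
        raise ValueError("inconsistent time window")
    if not 0 < p["alpha_min"] <= 1:
        raise ValueError("alpha_min must lie in (0, 1]")
    if p["contraction_factor"] < 1:
        raise ValueError("contraction_factor must be >= 1")
    if not p["t_start"] <= 0 <= p["ramp_start"] <= p["t_end"]:
        raise ValueError("ramp_start must lie in [0, t_end]")

    times = np.arange(p["t_start"], p["t_end"] + p["dt"] / 2.0, p["dt"])
    eps_end = (p["contraction_factor"] - 1.0) * p["eps0"]

    if case == "adhesion_only":
        alpha = _ramp(times, 0.0, p["alpha_drop_end"], 1.0, p["alpha_min"])
        eps_active = np.zeros_like(times)
        r_inner = np.full_like(times, radius)
    elif case == "contractility_only":
        alpha = np.ones_like(times)
        eps_active = _ramp(times, p["ramp_start"], p["t_end"], 0.0, eps_end)
        r_inner = _ramp(times, p["ramp_start"], p["t_end"], radius, radius / 3.0)
    else:
        alpha = _ramp(times, 0.0, p["alpha_drop_end"], 1.0, p["alpha_min"])
        eps_active = _ramp(times, p["ramp_start"], p["t_end"], 0.0, eps_end)
        r_inner = _ramp(times, p["ramp_start"], p["t_end"], radius, radius / 3.0)

    return InductionSchedule(
        times=times,
        alpha_t=alpha,
        eps_active_t=eps_active,
        r_inner_t=r_inner,
        eps0=p["eps0"],
    )


@dataclass
class SimulationTrace:
    """Per-timepoint observables of a protocol run."""

    times: np.ndarray
    area_um2: np.ndarray
    mean_traction_kpa: np.ndarray
    schedule: InductionSchedule
    params: dict = field(default_factory=dict)
    displacements: list[DisplacementField] | None = None
    tractions: list[TractionFieldFE] | None = None

    def to_dataframe(self, t_ref: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_h": self.times,
                "area_um2": self.area_um2,
                "mean_traction_kpa": self.mean_traction_kpa,
            }
        )
        if t_ref is None:
            t_ref = self.times[0]
        df["area_norm"] = normalize_trend(self.times, self.area_um2, t_ref).values
        df["traction_norm"] = normalize_trend(
            self.times, self.mean_traction_kpa, t_ref
        ).values
        return df


def deformed_area(mesh: DiskMesh, u: DisplacementField) -> float:
    """Area of the displaced tissue: shoelace sum over deformed element quads."""
    if not np.all(np.isfinite(u.values)):
        raise ValueError("displacement field contains non-finite values")
    xy = mesh.node_coords + u.values
    quads = xy[mesh.elements]  # (n_el, 4, 2)
    x, y = quads[..., 0], quads[..., 1]
    areas = 0.5 * np.sum(x * np.roll(y, -1, axis=1) - np.roll(x, -1, axis=1) * y, axis=1)
    if np.any(areas <= 0):
        warnings.warn(
            f"{int(np.sum(areas <= 0))} element(s) inverted in the deformed "
            "configuration; area sum may be unreliable",
            RuntimeWarning,
        )
    return float(areas.sum())


@dataclass(frozen=True)
class NormalizedTrend:
    """A time series divided by its value at the reference time."""

    times: np.ndarray
    values: np.ndarray
    t_ref: float


def normalize_trend(times, values, t_ref: float = -4.0) -> NormalizedTrend:
    """Normalize a series to its value at ``t_ref`` (must be on the grid)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    i = np.argmin(np.abs(times - t_ref))
    if abs(times[i] - t_ref) > 1e-9 * max(1.0, abs(t_ref)):
        raise ValueError(f"t_ref={t_ref} is not a timepoint of the series")
    ref = values[i]
    if ref == 0:
        raise ZeroDivisionError("reference value is zero; cannot normalize")
    return NormalizedTrend(times=times, values=values / ref, t_ref=float(times[i]))


def simulate_protocol(
    mesh: DiskMesh,
    material: ElasticMaterial,
    foundation: FoundationModel,
    schedule: InductionSchedule,
    record_fields: bool = False,
) -> SimulationTrace:
    """Run the quasi-static time series defined by an induction schedule.

    At each timepoint the subdomain partition is rebuilt from r_inner(t), the
    foundation matrix is reassembled with α(t)·k, the eigenstrain load with
    (ε0c, εc(t)), and the equilibrium is re-solved. With a viscous foundation
    (c > 0) the adhesion force gains the Kelvin–Voigt term c·du/dt,
    discretized by backward Euler; the first timepoint is treated as a
    steady state of the pre-induction (constant) schedule.
    """
    D = elasticity_matrix(material)
    K = assemble_elastic_stiffness(mesh, D)
    M = _assemble(mesh, element_foundation(mesh.element_size))  # unit-density

    areas = np.empty(len(schedule))
    mean_T = np.empty(len(schedule))
    us: list[DisplacementField] = []
    Ts: list[TractionFieldFE] = []
    u_prev: DisplacementField | None = None

    for i, t in enumerate(schedule.times):
        alpha = float(schedule.alpha_t[i])
        part = partition_subdomains(mesh, float(schedule.r_inner_t[i]))
        state = ContractileState(
            eps0=schedule.eps0, eps_active=float(schedule.eps_active_t[i]), partition=part
        )
        fnd_t = FoundationModel(k=foundation.k, alpha=alpha, c=foundation.c)
        Ks = alpha * foundation.k * M
        f = assemble_contractile_load(mesh, D, state)
        if foundation.c > 0.0 and u_prev is not None:
            dt = float(schedule.times[i] - schedule.times[i - 1])
            A = Ks + (foundation.c / dt) * M
            rhs = f + (foundation.c / dt) * (M @ u_prev.values.reshape(-1))
            u = solve_equilibrium(LinearSystem(K, A, rhs, mesh))
            T = compute_traction(u, fnd_t, u_prev=u_prev, dt=dt)
        else:
            try:
                u = solve_equilibrium(LinearSystem(K, Ks, f, mesh))
            except Exception as err:
                raise RuntimeError(
                    f"equilibrium solve failed at t = {t} h (step {i})"
                ) from err
            # first viscous step is a steady state: du/dt = 0
            T = compute_traction(
                u, FoundationModel(k=foundation.k, alpha=alpha, c=0.0)
            )
        areas[i] = deformed_area(mesh, u)
        mean_T[i] = mean_traction_magnitude(T, mesh)
        if record_fields:
            us.append(u)
            Ts.append(T)
        u_prev = u

    return SimulationTrace(
        times=schedule.times.copy(),
        area_um2=areas,
        mean_traction_kpa=mean_T,
        schedule=schedule,
        params=dict(
            E=material.E,
            nu=material.nu,
            constitutive_mode=material.constitutive_mode,
            k=foundation.k,
            c=foundation.c,
            n_diameter=mesh.n_diameter,
            radius=mesh.radius,
        ),
        displacements=us if record_fields else None,
        tractions=Ts if record_fields else None,
    )
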