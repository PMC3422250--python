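"""Core dynamics of the maize floral-transition gene network.

A single scaled state variable — *ZMM4* mRNA abundance, ``m`` — obeys a
linear ODE whose constant forcing term is gated by the binary allele states
of three upstream genetic elements:

    dm/dt = alpha1 * (ID1 + alpha2*ID1*DLF1 + alpha3*VGT1 + beta_eff) + omega * m

with ``m(0) = 0``. ``beta_eff`` is the basal *ZMM4* synthesis weight
``beta``, doubled for lines carrying a constitutive *PRO_UBI:ZMM4*
transgene (two expressed copies). The positive feedback rate ``omega``
makes the trajectory exponential; the floral transition status (FTS) flips
from 0 to 1 when ``m`` reaches a threshold (1.0 in scaled units), and the
crossing time is the predicted days to tassel initiation (DTI).

The model describes the run-up to the transition only; the post-peak
decline of *ZMM4* expression seen in real shoot apices is outside its
contract, so trajectories are meaningful up to the crossing and not beyond.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genotypes import GenotypeSpec

__all__ = [
    "DGNParameters",
    "SimulationSettings",
    "Trajectory",
    "HorizonExhaustedError",
    "regulatory_input",
    "derivative",
    "closed_form",
    "closed_form_dti",
    "simulate",
    "predict_dti",
    "read_parameters",
    "write_parameters",
]

_PARAM_NAMES = ("alpha1", "alpha2", "alpha3", "beta", "omega")

#: Reference fitted coefficients for the network (the values this package
#: ships as its calibrated default parameterization).
REFERENCE_PARAMETER_VALUES = {
    "alpha1": 0.002000,
    "alpha2": 6.489431,
    "alpha3": 53.204799,
    "beta": 0.821720,
    "omega": 0.086782,
}


class HorizonExhaustedError(RuntimeError):
    """The trajectory never reached the transition threshold within t_max."""

    def __init__(self, genotype: str, t_max: float):
        self.genotype = genotype
        self.t_max = t_max
        super().__init__(
            f"genotype {genotype!r}: mZMM4 threshold not reached within "
            f"t_max = {t_max} d"
        )


@dataclass(frozen=True)
class DGNParameters:
    """The five coefficients of the network ODE.

    alpha1 : overall scaling of the gene effects (d^-1 in scaled units)
    alpha2 : weight of the ID1 x DLF1 combination (dimensionless)
    alpha3 : weight of VGT1 alone (dimensionless)
    beta   : basal ZMM4 synthesis weight (dimensionless)
    omega  : positive-feedback rate (d^-1)

    All five must be strictly positive: the model has no meaning for
    negative synthesis or decay-style feedback, and the calibrated values
    are all positive.
    """

    alpha1: float
    alpha2: float
    alpha3: float
    beta: float
    omega: float

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @classmethod
    def reference(cls) -> "DGNParameters":
        """The package's reference fitted parameter set."""
        return cls(**REFERENCE_PARAMETER_VALUES)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "DGNParameters":
        values = list(values)
        if len(values) != 5:
            raise ValueError(f"expected 5 parameter values, got {len(values)}")
        return cls(**dict(zip(_PARAM_NAMES, map(float, values))))

    @property
    def names(self) -> tuple[str, ...]:
        return _PARAM_NAMES


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical settings for the forward-Euler simulation.

    dt        : integration step, days (default 0.01)
    t_max     : simulation horizon, days (default 100, safely past the
                latest reference genotype at ~46 d yet only 1e4 steps)
    m0        : initial scaled mZMM4 (default 0 — negligible plant size at
                planting)
    threshold : scaled mZMM4 level at which FTS flips to 1 (default 1.0,
                the maximum of expression scaled across genotypes)
    """

    dt: float = 0.01
    t_max: float = 100.0
    m0: float = 0.0
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.m0 < 0:
            raise ValueError("m0 must be non-negative")
        if self.threshold <= self.m0:
            raise ValueError("threshold must exceed the initial value m0")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))


@dataclass(frozen=True)
class Trajectory:
    """A simulated mZMM4 time course for one genotype.

    ``dti`` is None when the threshold was not reached within the horizon;
    use :func:`predict_dti` if that case should raise instead.
    """

    genotype: str
    times: np.ndarray
    mzmm4: np.ndarray
    fts: np.ndarray
    dti: float | None

    @property
    def reached_threshold(self) -> bool:
        return self.dti is not None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.genotype,
                "time": self.times,
                "mzmm4": self.mzmm4,
                "fts": self.fts,
            }
        )


def regulatory_input(genotype: GenotypeSpec, params: DGNParameters) -> float:
    """Constant forcing term of dm/dt for one genotype (d^-1).

    c = alpha1 * (ID1 + alpha2*ID1*DLF1 + alpha3*VGT1 + beta_eff), where
    beta_eff = 2*beta for *PRO_UBI:ZMM4* transgenic lines (the native plus
    the transgenic copy) and beta otherwise. The ID1 main effect carries an
    implicit unit coefficient; the ID1xDLF1 product term means DLF1 acts
    only in an ID1-functional background.
    """
    beta_eff = 2.0 * params.beta if genotype.zmm4_transgene else params.beta
    return params.alpha1 * (
        genotype.id1
        + params.alpha2 * genotype.id1 * genotype.dlf1
        + params.alpha3 * genotype.vgt1
        + beta_eff
    )


def derivative(m: float, c: float, params: DGNParameters) -> float:
    """Instantaneous rate of change dm/dt = c + omega*m."""
    return c + params.omega * m


def closed_form(
    c: float, omega: float, t: float | np.ndarray
) -> float | np.ndarray:
    """Exact solution of dm/dt = c + omega*m with m(0) = 0.

    m(t) = (c/omega) * (exp(omega*t) - 1) for omega != 0, and c*t in the
    omega -> 0 limit. Serves as the analytic oracle for the Euler
    integrator.
    """
    t = np.asarray(t, dtype=float)
    if omega == 0.0:
        out = c * t
    else:
        out = (c / omega) * np.expm1(omega * t)
    return float(out) if out.ndim == 0 else out


def closed_form_dti(c: float, omega: float, threshold: float = 1.0) -> float:
    """Exact threshold-crossing time t* = ln(1 + omega*threshold/c) / omega
    (threshold/c for omega = 0). Infinite when c = 0."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if c <= 0:
        return float("inf")
    if omega == 0.0:
        return threshold / c
    return float(np.log1p(omega * threshold / c) / omega)


def _euler_levels(
    c: float, omega: float, dt: float, m0: float, n_steps: int
) -> np.ndarray:
    """mZMM4 at Euler grid points 0..n_steps.

    The forward-Euler recurrence m_{k+1} = m_k*(1 + omega*dt) + c*dt is a
    linear map, so its iterates have the exact geometric-series form
    m_k = m0*r^k + (c/omega)*(r^k - 1), r = 1 + omega*dt, evaluated here
    vectorized. This is the Euler solution itself, not the continuous-time
    closed form.
    """
    k = np.arange(n_steps + 1, dtype=float)
    if omega == 0.0:
        return m0 + c * dt * k
    growth = np.log1p(omega * dt) * k
    with np.errstate(over="ignore"):
        rk = np.exp(growth)
    rk = np.where(np.isfinite(rk), rk, np.finfo(float).max)
    return m0 * rk + (c / omega) * (rk - 1.0)


def simulate(
    genotype: GenotypeSpec,
    params: DGNParameters,
    settings: SimulationSettings = SimulationSettings(),
) -> Trajectory:
    """Forward-Euler trajectory of mZMM4 for one genotype.

    FTS is 0 below the threshold and 1 at or above it; the DTI is the
    crossing time interpolated linearly between the two bracketing grid
    points, which keeps downstream objectives smooth in the parameters
    instead of stepping with the grid. ``dti`` is None if the threshold is
    not reached by ``t_max`` (no exception here; see :func:`predict_dti`).
    """
    c = regulatory_input(genotype, params)
    n = settings.n_steps
    times = np.arange(n + 1, dtype=float) * settings.dt
    m = _euler_levels(c, params.omega, settings.dt, settings.m0, n)
    fts = (m >= settings.threshold).astype(np.int8)
    dti = _interpolate_crossing(times, m, settings.threshold)
    return Trajectory(genotype.name, times, m, fts, dti)


def _interpolate_crossing(
    times: np.ndarray, m: np.ndarray, threshold: float
) -> float | None:
    above = np.nonzero(m >= threshold)[0]
    if above.size == 0:
        return None
    k = int(above[0])
    if k == 0:
        return float(times[0])
    frac = (threshold - m[k - 1]) / (m[k] - m[k - 1])
    return float(times[k - 1] + frac * (times[k] - times[k - 1]))


def predict_dti(
    genotype: GenotypeSpec,
    params: DGNParameters,
    settings: SimulationSettings = SimulationSettings(),
) -> float:
    """Predicted days to tassel initiation for one genotype.

    Raises :class:`HorizonExhaustedError` if the trajectory never reaches
    the threshold within the simulation horizon.
    """
    traj = simulate(genotype, params, settings)
    if traj.dti is None:
        raise HorizonExhaustedError(genotype.name, settings.t_max)
    return traj.dti


def write_parameters(params: DGNParameters, path: str | Path) -> None:
    pd.DataFrame(
        {"parameter": _PARAM_NAMES, "value": params.to_array()}
    ).to_csv(path, sep="\t", index=False)


def read_parameters(path: str | Path) -> DGNParameters:
    """Read a parameter vector from a two-column TSV ``parameter value``."""
    df = pd.read_csv(path, sep="\t")
    if not {"parameter", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'parameter' and 'value'")
    table = dict(zip(df["parameter"], df["value"]))
    missing = [n for n in _PARAM_NAMES if n not in table]
    if missing:
        raise ValueError(f"{path}: missing parameter row(s): {', '.join(missing)}")
    return DGNParameters(**{n: float(table[n]) for n in _PARAM_NAMES})
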