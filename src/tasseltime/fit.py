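"""Calibration of the floral-transition network to expression + phenology data.

The model is fitted statsmodels-style: build a :class:`DGNModel` from an
:class:`ObservationSet` (scaled *ZMM4* expression time series plus observed
days to tassel initiation, per genotype), call :meth:`DGNModel.fit`, and
read the estimates off the returned :class:`DGNResults`.

The objective is the unweighted sum of two squared-error terms,

    SSE = SSE_g + SSE_p
    SSE_g = sum_g sum_i (RNAp_{g,i} - RNAo_{g,i})^2     (expression)
    SSE_p = sum_g (DTIp_g - DTIo_g)^2                   (phenology)

with predictions from the forward-Euler simulation, minimized by
Nelder-Mead over log-transformed parameters so every candidate stays
strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .genotypes import GenotypeSpec
from .model import DGNParameters, SimulationSettings, simulate

__all__ = [
    "GenotypeObservations",
    "ObservationSet",
    "FitConfig",
    "DGNModel",
    "DGNResults",
    "scale_expression",
    "objective",
    "fit_parameters",
    "invert_closed_form",
    "check_identifiability",
    "IdentifiabilityError",
]


class IdentifiabilityError(ValueError):
    """The genotype panel cannot separate the regulatory coefficients."""


@dataclass(frozen=True)
class GenotypeObservations:
    """Sampling times, scaled expression values and observed DTI for one
    genotype."""

    genotype: GenotypeSpec
    times: np.ndarray
    rna_obs: np.ndarray
    dti_obs: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        rna = np.asarray(self.rna_obs, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "rna_obs", rna)
        name = self.genotype.name
        if times.ndim != 1 or times.size < 2:
            raise ValueError(f"{name}: need at least 2 sampling times")
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{name}: sampling times must be strictly increasing")
        if rna.shape != times.shape:
            raise ValueError(f"{name}: expression and time arrays differ in length")
        if np.any(rna < 0) or np.any(rna > 1):
            raise ValueError(f"{name}: scaled expression must lie in [0, 1]")
        if not np.isfinite(self.dti_obs) or self.dti_obs <= 0:
            raise ValueError(f"{name}: observed DTI must be positive")


@dataclass(frozen=True)
class ObservationSet:
    """Calibration data: one :class:`GenotypeObservations` per genotype."""

    observations: tuple[GenotypeObservations, ...]

    def __post_init__(self) -> None:
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        names = [o.genotype.name for o in obs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate genotype names in observation set")

    def __iter__(self):
        return iter(self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def genotypes(self) -> list[GenotypeSpec]:
        return [o.genotype for o in self.observations]

    @classmethod
    def from_frames(
        cls,
        expression: pd.DataFrame,
        phenotypes: pd.DataFrame,
        panel: Sequence[GenotypeSpec],
    ) -> "ObservationSet":
        """Assemble from long-format tables.

        ``expression`` needs columns ``name time rna_scaled``; ``phenotypes``
        needs ``name dti_obs``. Every name must resolve against ``panel``.
        """
        specs = {g.name: g for g in panel}
        dti = dict(zip(phenotypes["name"], phenotypes["dti_obs"]))
        obs = []
        for name, group in expression.groupby("name", sort=False):
            if name not in specs:
                raise ValueError(f"unknown genotype {name!r} in expression table")
            if name not in dti:
                raise ValueError(f"genotype {name!r} has no observed DTI")
            group = group.sort_values("time")
            obs.append(
                GenotypeObservations(
                    specs[name],
                    group["time"].to_numpy(float),
                    group["rna_scaled"].to_numpy(float),
                    float(dti[name]),
                )
            )
        return cls(tuple(obs))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        expr = pd.concat(
            [
                pd.DataFrame(
                    {
                        "name": o.genotype.name,
                        "time": o.times,
                        "rna_scaled": o.rna_obs,
                    }
                )
                for o in self.observations
            ],
            ignore_index=True,
        )
        pheno = pd.DataFrame(
            {
                "name": [o.genotype.name for o in self.observations],
                "dti_obs": [o.dti_obs for o in self.observations],
            }
        )
        return expr, pheno


def scale_expression(
    raw: Mapping[str, np.ndarray] | pd.DataFrame,
) -> Mapping[str, np.ndarray] | pd.DataFrame:
    """Scale raw expression to [0, 1] by the single global maximum across
    all genotypes and times (a shared denominator, not per-genotype).

    Accepts either a mapping of genotype name -> raw value array or a long
    DataFrame with a ``rna_raw`` column; returns the same shape with values
    divided by the global maximum. Idempotent on already-scaled data.
    """
    if isinstance(raw, pd.DataFrame):
        values = raw["rna_raw"].to_numpy(float)
        peak = _global_peak(values)
        out = raw.copy()
        out["rna_scaled"] = values / peak
        return out
    arrays = {k: np.asarray(v, dtype=float) for k, v in raw.items()}
    peak = _global_peak(np.concatenate(list(arrays.values())))
    return {k: v / peak for k, v in arrays.items()}


def _global_peak(values: np.ndarray) -> float:
    if values.size == 0 or np.nanmax(values) <= 0:
        raise ValueError("expression scaling requires at least one positive value")
    return float(np.nanmax(values))


def objective(
    params: DGNParameters,
    obs: ObservationSet,
    settings: SimulationSettings = SimulationSettings(),
    phenotype_weight: float = 1.0,
) -> tuple[float, float, float]:
    """Evaluate (sse_g, sse_p, sse) for a candidate parameter vector.

    Predicted expression is read off the Euler grid by linear interpolation
    at the observed sampling times. A genotype whose trajectory never
    reaches the threshold contributes DTIp = t_max — a finite pessimistic
    surrogate that keeps the objective decreasing toward feasibility
    instead of blowing up.
    """
    sse_g = 0.0
    sse_p = 0.0
    for o in obs:
        try:
            traj = simulate(o.genotype, params, settings)
        except Exception as exc:  # re-raise with genotype identity attached
            raise RuntimeError(f"simulation failed for {o.genotype.name!r}") from exc
        rna_pred = np.interp(o.times, traj.times, traj.mzmm4)
        sse_g += float(np.sum((rna_pred - o.rna_obs) ** 2))
        dti_pred = traj.dti if traj.dti is not None else settings.t_max
        sse_p += (dti_pred - o.dti_obs) ** 2
    sse_p *= phenotype_weight
    return sse_g, sse_p, sse_g + sse_p


# Alternating +50% / -33% multiplicative perturbation used to build the
# default optimizer start away from a supplied reference vector.
_DEFAULT_PERTURBATION = np.array([1.5, 2.0 / 3.0, 1.5, 2.0 / 3.0, 1.5])


@dataclass(frozen=True)
class FitConfig:
    """Nelder-Mead settings for :func:`fit_parameters`.

    The optimizer runs in log-parameter space by default, which enforces
    positivity without explicit bounds. ``restarts`` extra runs start from
    seeded multiplicative jitter around the best point so far.
    """

    start: DGNParameters | None = None
    fatol: float = 1e-10
    xatol: float = 1e-8
    max_iter: int = 5000
    restarts: int = 3
    log_space: bool = True
    jitter_sd: float = 0.2
    seed: int = 0
    phenotype_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.fatol <= 0 or self.xatol <= 0:
            raise ValueError("convergence tolerances must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.restarts < 0:
            raise ValueError("restarts must be non-negative")

    def perturbed_start(self, reference: DGNParameters) -> DGNParameters:
        """Default start: the reference vector perturbed coordinate-wise by
        alternating x1.5 / x(2/3) factors."""
        return DGNParameters.from_array(
            reference.to_array() * _DEFAULT_PERTURBATION
        )


@dataclass(frozen=True)
class FitDiagnostics:
    converged: bool
    iterations: int
    function_evals: int
    restarts_used: int
    message: str


def check_identifiability(panel: Sequence[GenotypeSpec]) -> None:
    """Reject panels whose allele design cannot separate alpha1..beta.

    The forcing constant is linear in (ID1, ID1*DLF1, VGT1, beta-copy
    multiplier); four regulatory coefficients need the panel's design matrix
    over those regressors to have rank 4.
    """
    rows = np.array(
        [
            [
                g.id1,
                g.id1 * g.dlf1,
                g.vgt1,
                2.0 if g.zmm4_transgene else 1.0,
            ]
            for g in panel
        ],
        dtype=float,
    )
    rank = np.linalg.matrix_rank(rows) if rows.size else 0
    if rank < 4:
        raise IdentifiabilityError(
            f"genotype panel spans only {rank} of the 4 regulatory input "
            "combinations needed to separate alpha1, alpha2, alpha3 and beta"
        )


def fit_parameters(
    obs: ObservationSet,
    config: FitConfig = FitConfig(),
    settings: SimulationSettings = SimulationSettings(),
) -> "DGNResults":
    """Estimate the five coefficients by Nelder-Mead.

    Deterministic for a fixed config: the initial simplex is scipy's
    default around the start point and restart jitter uses the config seed.
    Non-convergence is reported on the result, never raised silently.
    """
    check_identifiability(obs.genotypes)
    start = config.start
    if start is None:
        start = config.perturbed_start(DGNParameters.reference())

    def pack(p: DGNParameters) -> np.ndarray:
        arr = p.to_array()
        return np.log(arr) if config.log_space else arr

    def unpack(x: np.ndarray) -> DGNParameters:
        arr = np.exp(x) if config.log_space else x
        return DGNParameters.from_array(arr)

    def loss(x: np.ndarray) -> float:
        try:
            p = unpack(x)
        except (ValueError, OverflowError):
            return np.inf
        return objective(p, obs, settings, config.phenotype_weight)[2]

    rng = np.random.default_rng(config.seed)
    best: optimize.OptimizeResult | None = None
    x0 = pack(start)
    restarts_used = 0
    for attempt in range(config.restarts + 1):
        res = optimize.minimize(
            loss,
            x0,
            method="Nelder-Mead",
            options={
                "fatol": config.fatol,
                "xatol": config.xatol,
                "maxiter": config.max_iter,
                "maxfev": 10 * config.max_iter,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        restarts_used = attempt
        # jitter around the incumbent for the next start
        jitter = rng.normal(0.0, config.jitter_sd, size=5)
        x0 = best.x + (jitter if config.log_space else best.x * jitter)
    assert best is not None
    params = unpack(best.x)
    sse_g, sse_p, sse = objective(params, obs, settings, config.phenotype_weight)
    diagnostics = FitDiagnostics(
        converged=bool(best.success),
        iterations=int(best.nit),
        function_evals=int(best.nfev),
        restarts_used=restarts_used,
        message=str(best.message),
    )
    return DGNResults(
        model=DGNModel(obs, settings=settings),
        params=params,
        sse_g=sse_g,
        sse_p=sse_p,
        sse=sse,
        diagnostics=diagnostics,
        config=config,
    )


def invert_closed_form(
    constants: Mapping[str, float], omega: float
) -> DGNParameters:
    """Algebraic identifiability oracle: recover the coefficients from the
    four training genotypes' forcing constants.

    With c_id1 = alpha1*beta, c_dlf1 = alpha1*(1+beta),
    c_B73 = alpha1*(1+alpha2+beta) and c_Gaspe =
    alpha1*(1+alpha2+alpha3+beta):

        alpha1 = c_dlf1 - c_id1
        beta   = c_id1 / alpha1
        alpha2 = (c_B73 - c_dlf1) / alpha1
        alpha3 = (c_Gaspe - c_B73) / alpha1

    Composing with :func:`regulatory_input` is the identity on positive
    parameter vectors. Keys: ``id1``, ``dlf1``, ``b73``, ``gaspe``.
    """
    required = {"id1", "dlf1", "b73", "gaspe"}
    missing = required - set(constants)
    if missing:
        raise ValueError(f"missing forcing constant(s): {sorted(missing)}")
    c_id1 = constants["id1"]
    c_dlf1 = constants["dlf1"]
    c_b73 = constants["b73"]
    c_gaspe = constants["gaspe"]
    alpha1 = c_dlf1 - c_id1
    if alpha1 <= 0:
        raise ValueError(
            "degenerate forcing constants: need c_dlf1 > c_id1 to recover alpha1"
        )
    if len({c_id1, c_dlf1, c_b73, c_gaspe}) < 4:
        raise ValueError("degenerate forcing constants: values must be distinct")
    return DGNParameters(
        alpha1=alpha1,
        alpha2=(c_b73 - c_dlf1) / alpha1,
        alpha3=(c_gaspe - c_b73) / alpha1,
        beta=c_id1 / alpha1,
        omega=omega,
    )


class DGNModel:
    """Floral-transition network model bound to calibration data.

    Parameters
    ----------
    obs : ObservationSet
        Per-genotype scaled expression series and observed DTI.
    settings : SimulationSettings
        Euler grid and threshold used for every prediction.

    Examples
    --------
    >>> model = DGNModel.from_frames(expr_df, dti_df, panel)   # doctest: +SKIP
    >>> result = model.fit()                                   # doctest: +SKIP
    >>> print(result.summary())                                # doctest: +SKIP
    """

    def __init__(
        self,
        obs: ObservationSet,
        settings: SimulationSettings = SimulationSettings(),
    ):
        self.obs = obs
        self.settings = settings

    @classmethod
    def from_frames(
        cls,
        expression: pd.DataFrame,
        phenotypes: pd.DataFrame,
        panel: Sequence[GenotypeSpec],
        settings: SimulationSettings = SimulationSettings(),
    ) -> "DGNModel":
        return cls(ObservationSet.from_frames(expression, phenotypes, panel), settings)

    def objective(
        self, params: DGNParameters, phenotype_weight: float = 1.0
    ) -> tuple[float, float, float]:
        return objective(params, self.obs, self.settings, phenotype_weight)

    def fit(self, config: FitConfig = FitConfig()) -> "DGNResults":
        return fit_parameters(self.obs, config, self.settings)


@dataclass(frozen=True)
class DGNResults:
    """Fit outcome: estimated coefficients, objective decomposition and
    optimizer diagnostics. ``sse == sse_g + sse_p`` always."""

    model: DGNModel
    params: DGNParameters
    sse_g: float
    sse_p: float
    sse: float
    diagnostics: FitDiagnostics
    config: FitConfig

    @property
    def converged(self) -> bool:
        return self.diagnostics.converged

    def predict_dti(
        self, panel: Sequence[GenotypeSpec] | None = None
    ) -> pd.DataFrame:
        from .evaluation import predict_panel, records_to_frame

        panel = list(panel) if panel is not None else self.model.obs.genotypes
        return records_to_frame(
            predict_panel(panel, self.params, self.model.settings)
        )

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.params.names, "value": self.params.to_array()}
        )

    def summary(self) -> str:
        lines = [
            "Dynamic gene network fit (Nelder-Mead)",
            "=" * 46,
            f"genotypes:        {len(self.model.obs)}",
            f"converged:        {self.diagnostics.converged}",
            f"iterations:       {self.diagnostics.iterations}",
            f"function evals:   {self.diagnostics.function_evals}",
            f"SSE (expression): {self.sse_g:.6g}",
            f"SSE (phenotype):  {self.sse_p:.6g}",
            f"SSE (total):      {self.sse:.6g}",
            "-" * 46,
            f"{'parameter':<10}{'estimate':>14}",
        ]
        for name, value in zip(self.params.names, self.params.to_array()):
            lines.append(f"{name:<10}{value:>14.6f}")
        return "\n".join(lines)

    def save(self, params_path: str | Path, diagnostics_path: str | Path) -> None:
        import json

        self.params_frame().to_csv(params_path, sep="\t", index=False)
        payload = {
            "sse_g": self.sse_g,
            "sse_p": self.sse_p,
            "sse": self.sse,
            "converged": self.diagnostics.converged,
            "iterations": self.diagnostics.iterations,
            "function_evals": self.diagnostics.function_evals,
            "restarts_used": self.diagnostics.restarts_used,
            "message": self.diagnostics.message,
        }
        Path(diagnostics_path).write_text(json.dumps(payload, indent=2) + "\n")
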