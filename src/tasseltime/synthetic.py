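"""Synthetic calibration and evaluation data for the floral-transition model.

No raw expression series or leaf-count tables are distributed with the
original study, so this module fabricates datasets with the statistical
structure the pipeline assumes: per-genotype scaled *ZMM4* trajectories
rising along the exact closed-form solution toward the transition
threshold, observed DTI values at (or noisily around) the analytic
crossing time, and total leaf number (TLN) linked linearly to DTI.

Everything here is labelled synthetic; the TLN link coefficients in
particular are this package's own calibration choices (picked so B73 at
~21 d to transition carries ~19-20 leaves, a realistic temperate maize
value), never measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeSpec, training_panel
from .model import DGNParameters, closed_form, closed_form_dti, regulatory_input
from .fit import GenotypeObservations, ObservationSet

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_expression",
    "generate_tln",
    "generate_dataset",
    "tln_noise_for_r2",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    truth         : generating parameter vector (defaults to the package's
                    reference fitted values)
    panel         : genotypes to simulate (defaults to the four training
                    genotypes: Gaspe Flint, B73, dlf1, id1)
    n_samples     : sampling times per genotype, evenly spaced on
                    [0, analytic DTI] (default 10; real schedules were
                    genotype-dependent and are not recoverable)
    rna_noise_sd  : additive Gaussian noise on scaled expression (default 0)
    dti_noise_sd  : additive Gaussian noise on observed DTI, days (default 0)
    tln_intercept : leaves at DTI = 0 for the TLN link (default 12.0)
    tln_slope     : leaves per day of delayed transition (default 0.35)
    tln_noise_sd  : additive Gaussian noise on TLN, leaves (default 0)
    threshold     : scaled expression level defining the transition
    seed          : RNG seed; fixed seed -> bit-identical output
    """

    truth: DGNParameters = field(default_factory=DGNParameters.reference)
    panel: tuple[GenotypeSpec, ...] = field(
        default_factory=lambda: tuple(training_panel())
    )
    n_samples: int = 10
    rna_noise_sd: float = 0.0
    dti_noise_sd: float = 0.0
    tln_intercept: float = 12.0
    tln_slope: float = 0.35
    tln_noise_sd: float = 0.0
    threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 sampling times per genotype")
        for name in ("rna_noise_sd", "dti_noise_sd", "tln_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tln_slope <= 0:
            raise ValueError("tln_slope must be positive")


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated observations plus the truth record for recovery scoring."""

    observations: ObservationSet
    tln_table: pd.DataFrame
    truth: DGNParameters
    config: SyntheticConfig


def generate_expression(config: SyntheticConfig) -> ObservationSet:
    """Per-genotype scaled expression series and observed DTI.

    Sampling times are spread evenly over [0, t*_g] where t* is the analytic
    crossing time; expression values are the exact closed-form solution plus
    Gaussian noise, clipped to [0, 1]; observed DTI is t* plus Gaussian
    noise. Genotypes that can never reach the threshold are rejected.
    """
    rng = np.random.default_rng(config.seed)
    obs = []
    for g in config.panel:
        c = regulatory_input(g, config.truth)
        t_star = closed_form_dti(c, config.truth.omega, config.threshold)
        if not np.isfinite(t_star):
            raise ValueError(
                f"genotype {g.name!r} never reaches the transition threshold "
                "under the generating parameters"
            )
        times = np.linspace(0.0, t_star, config.n_samples)
        rna = closed_form(c, config.truth.omega, times)
        if config.rna_noise_sd > 0:
            rna = rna + rng.normal(0.0, config.rna_noise_sd, size=rna.shape)
        rna = np.clip(rna, 0.0, 1.0)
        dti_obs = t_star
        if config.dti_noise_sd > 0:
            dti_obs += rng.normal(0.0, config.dti_noise_sd)
        obs.append(GenotypeObservations(g, times, rna, float(dti_obs)))
    return ObservationSet(tuple(obs))


def generate_tln(
    config: SyntheticConfig, dti_values: pd.DataFrame | dict[str, float]
) -> pd.DataFrame:
    """Genotype-mean total leaf numbers linked linearly to DTI.

    TLN_g = intercept + slope * DTI_g + Gaussian noise; a draw that lands
    non-positive is resampled (truncation). Returns a frame with columns
    ``name tln``.
    """
    if isinstance(dti_values, pd.DataFrame):
        dti_map = dict(zip(dti_values["name"], dti_values["dti"]))
    else:
        dti_map = dict(dti_values)
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for name, dti in dti_map.items():
        tln = config.tln_intercept + config.tln_slope * float(dti)
        if config.tln_noise_sd > 0:
            draw = tln + rng.normal(0.0, config.tln_noise_sd)
            while draw <= 0:
                draw = tln + rng.normal(0.0, config.tln_noise_sd)
            tln = draw
        rows.append({"name": name, "tln": tln})
    return pd.DataFrame(rows)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full synthetic dataset: expression + DTI observations and a TLN table
    derived from each genotype's analytic transition time."""
    observations = generate_expression(config)
    dti_map = {
        o.genotype.name: closed_form_dti(
            regulatory_input(o.genotype, config.truth),
            config.truth.omega,
            config.threshold,
        )
        for o in observations
    }
    tln_table = generate_tln(config, dti_map)
    return SyntheticDataset(observations, tln_table, config.truth, config)


def tln_noise_for_r2(
    dti_values: Sequence[float], slope: float, r_squared: float
) -> float:
    """Noise standard deviation that makes the TLN~DTI regression attain a
    requested R-squared in expectation.

    For y = a + b*x + e over the fixed design x with noise variance s^2,
    E[SS_res] = (n-2) s^2 and E[SS_tot] = b^2 Sxx + (n-1) s^2 where
    Sxx = sum (x - mean x)^2. Approximating E[R^2] by the ratio of
    expectations, 1 - R^2 = (n-2) s^2 / (b^2 Sxx + (n-1) s^2), and solving
    for s gives

        s^2 = (1 - R^2) b^2 Sxx / ((n-2) - (1 - R^2)(n-1)).

    The finite-sample terms matter here: with a handful of genotype means
    the fitted line absorbs part of the noise, so the realized R^2 sits
    well above the naive population value b^2 var(x)/(b^2 var(x) + s^2).
    """
    if not 0 < r_squared <= 1:
        raise ValueError("r_squared must lie in (0, 1]")
    x = np.asarray(dti_values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 DTI values")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("DTI values must not be constant")
    denom = (n - 2) - (1.0 - r_squared) * (n - 1)
    if denom <= 0:
        raise ValueError(
            f"requested r_squared {r_squared} is below the noise floor "
            f"attainable with n = {n} genotypes"
        )
    return float(np.sqrt((1.0 - r_squared) * slope**2 * sxx / denom))
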