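"""Evaluation of the fitted network on genotype panels.

Predicts days to tassel initiation (DTI) for arbitrary binary-encoded
genotypes — including lines never used in calibration, such as the
*id1 dlf1* double mutant and *PRO_UBI:ZMM4* transgenic lines — and
regresses observed total leaf number (TLN) on predicted DTI. TLN is the
field-stable proxy for transition timing: leaf initiation stops at the
floral transition, so later transitions leave more leaves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeSpec
from .model import (
    DGNParameters,
    SimulationSettings,
    simulate,
)

__all__ = [
    "PredictionRecord",
    "RegressionSummary",
    "OrderingReport",
    "predict_panel",
    "records_to_frame",
    "linear_fit_tln_dti",
    "check_ordering",
]


@dataclass(frozen=True)
class PredictionRecord:
    """Predicted DTI for one genotype, optionally paired with an observed
    genotype-mean TLN. ``dti`` is None when the simulation horizon was
    exhausted (recorded, not dropped)."""

    name: str
    dti: float | None
    tln: float | None = None
    tln_se: float | None = None

    @property
    def horizon_exhausted(self) -> bool:
        return self.dti is None


@dataclass(frozen=True)
class RegressionSummary:
    """Ordinary least squares of TLN on predicted DTI."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def predict_panel(
    panel: Sequence[GenotypeSpec],
    params: DGNParameters,
    settings: SimulationSettings = SimulationSettings(),
    tln: dict[str, float] | pd.DataFrame | None = None,
) -> list[PredictionRecord]:
    """One prediction record per genotype; deterministic in its inputs.

    Transgenic lines route through the doubled basal-synthesis rule inside
    the simulation. A genotype that never reaches the threshold gets
    ``dti=None`` rather than aborting the rest of the panel.
    """
    if not panel:
        raise ValueError("genotype panel must be non-empty")
    if isinstance(tln, pd.DataFrame):
        tln = dict(zip(tln["name"], tln["tln"]))
    records = []
    for g in panel:
        traj = simulate(g, params, settings)
        records.append(
            PredictionRecord(
                name=g.name,
                dti=traj.dti,
                tln=None if tln is None else tln.get(g.name),
            )
        )
    return records


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"name": r.name, "dti": r.dti, "tln": r.tln}
            for r in records
        ]
    )


def linear_fit_tln_dti(records: Sequence[PredictionRecord]) -> RegressionSummary:
    """OLS regression of observed TLN (response) on predicted DTI.

    Requires at least three records carrying both quantities and a
    non-degenerate DTI spread. R^2 = 1 - SS_res/SS_tot.
    """
    pairs = [
        (r.dti, r.tln)
        for r in records
        if r.dti is not None and r.tln is not None
    ]
    if len(pairs) < 3:
        raise ValueError(
            f"need >= 3 genotypes with both predicted DTI and observed TLN, "
            f"got {len(pairs)}"
        )
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all predicted DTIs are equal")
    fit = stats.linregress(x, y)
    # rvalue**2 is NaN for a constant response; that is R^2 = 0 here
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        n=len(pairs),
    )


@dataclass(frozen=True)
class OrderingReport:
    """Pairwise checks of the expected transition-time ordering across the
    training genotypes plus the double-mutant equivalence."""

    gaspe_before_b73: bool
    b73_before_dlf1: bool
    dlf1_before_or_at_id1: bool
    id1_equals_double: bool | None

    @property
    def all_hold(self) -> bool:
        checks = [
            self.gaspe_before_b73,
            self.b73_before_dlf1,
            self.dlf1_before_or_at_id1,
        ]
        if self.id1_equals_double is not None:
            checks.append(self.id1_equals_double)
        return all(checks)


_ORDER_NAMES = {
    "gaspe": "Gaspe Flint",
    "b73": "B73",
    "dlf1": "dlf1 mutant",
    "id1": "id1 mutant",
    "double": "id1 dlf1",
}


def check_ordering(
    records: Sequence[PredictionRecord], tol: float = 1e-9
) -> OrderingReport:
    """Verify Gaspe < B73 < dlf1 <= id1 and (when present) id1 == double
    mutant, invariant to record order. Missing training genotypes are
    reported by name."""
    dti = {r.name: r.dti for r in records}
    missing = [
        label
        for key, label in _ORDER_NAMES.items()
        if key != "double" and label not in dti
    ]
    if missing:
        raise ValueError(f"ordering check missing genotype(s): {', '.join(missing)}")
    for label in _ORDER_NAMES.values():
        if label in dti and dti[label] is None:
            raise ValueError(f"genotype {label!r} has no finite predicted DTI")
    gaspe = dti[_ORDER_NAMES["gaspe"]]
    b73 = dti[_ORDER_NAMES["b73"]]
    dlf1 = dti[_ORDER_NAMES["dlf1"]]
    id1 = dti[_ORDER_NAMES["id1"]]
    double = dti.get(_ORDER_NAMES["double"])
    return OrderingReport(
        gaspe_before_b73=gaspe < b73 - tol,
        b73_before_dlf1=b73 < dlf1 - tol,
        dlf1_before_or_at_id1=dlf1 <= id1 + tol,
        id1_equals_double=(
            None if double is None else bool(abs(id1 - double) <= tol)
        ),
    )
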