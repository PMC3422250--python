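"""Table IO, packaged data resources and run manifests.

All tables are TSV: tab-separated, header row, UTF-8, '.' decimal. Times
are reported to 0.01 d, matching the integration step.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .genotypes import GenotypeSpec, read_genotypes
from .model import DGNParameters, Trajectory, read_parameters

__all__ = [
    "load_reference_parameters",
    "load_reference_genotypes",
    "load_grn_edges",
    "write_trajectories",
    "write_dti_summary",
    "write_manifest",
]


def _data_path(name: str):
    return resources.files("tasseltime.data").joinpath(name)


def load_reference_parameters() -> DGNParameters:
    """The packaged reference fitted parameter vector."""
    with resources.as_file(_data_path("reference_parameters.tsv")) as path:
        return read_parameters(path)


def load_reference_genotypes(as_printed: bool = False) -> list[GenotypeSpec]:
    """The packaged eight-genotype reference panel (TSV fixture).

    ``as_printed=True`` loads the variant reproducing the source table's
    transgenic-mutant rows verbatim, including their apparent ID1/DLF1
    column swap; the default variant is name-consistent.
    """
    name = "reference_genotypes_printed.tsv" if as_printed else "reference_genotypes.tsv"
    with resources.as_file(_data_path(name)) as path:
        return read_genotypes(path)


def load_grn_edges() -> pd.DataFrame:
    """Signed edge list of the simplified upstream regulatory network
    (documentation resource; the dynamic model collapses it to binary
    gates and is not parameterized from these edges)."""
    with resources.as_file(_data_path("grn_edges.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def write_trajectories(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    frame = pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
    frame["time"] = frame["time"].round(2)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_dti_summary(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "name": [t.genotype for t in trajectories],
            "dti": [
                "NA" if t.dti is None else f"{t.dti:.2f}" for t in trajectories
            ],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_manifest(
    path: str | Path,
    stage: str,
    inputs: dict[str, Any],
    parameters: dict[str, Any],
    seed: int | None = None,
) -> None:
    """Machine-readable record of a pipeline run (inputs, settings, seed,
    versions) written next to every output."""
    import tasseltime

    payload = {
        "stage": stage,
        "inputs": inputs,
        "parameters": parameters,
        "seed": seed,
        "versions": {
            "tasseltime": tasseltime.__version__,
            "python": platform.python_version(),
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
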