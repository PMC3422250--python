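"""Binary genotype encodings for the maize floral-transition network.

Each genotype is reduced to presence/absence of three genetic elements —
the early *VGT1* QTL allele, functional *ID1*, functional *DLF1* — plus a
flag for a constitutive *PRO_UBI:ZMM4* transgene. The native *ZMM4* copy is
present in every line and is therefore not stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "GenotypeSpec",
    "reference_panel",
    "training_panel",
    "read_genotypes",
    "write_genotypes",
    "panel_to_frame",
]

_BINARY = (0, 1)


@dataclass(frozen=True)
class GenotypeSpec:
    """One genotype's discrete inputs to the dynamic gene network.

    Parameters
    ----------
    name : str
        Genotype label, unique within a panel.
    vgt1 : int
        1 for the early (Gaspe Flint) *VGT1* allele, 0 otherwise.
    id1 : int
        1 for a functional *ID1* allele, 0 for the loss-of-function mutant.
    dlf1 : int
        1 for a functional *DLF1* allele, 0 for the loss-of-function mutant.
    zmm4_transgene : int
        1 if the line carries the *PRO_UBI:ZMM4* overexpression construct.
    """

    name: str
    vgt1: int
    id1: int
    dlf1: int
    zmm4_transgene: int = 0

    def __post_init__(self) -> None:
        for field in ("vgt1", "id1", "dlf1", "zmm4_transgene"):
            value = getattr(self, field)
            if value not in _BINARY:
                raise ValueError(
                    f"genotype {self.name!r}: {field} must be 0 or 1, got {value!r}"
                )
        if not self.name:
            raise ValueError("genotype name must be non-empty")


# Allele states as printed in the source genotype table. The two transgenic
# mutant rows print ID1/DLF1 values that contradict their names (the
# 'ZMM4 id1 mutant' row shows ID1=1, DLF1=0); this looks like a column swap
# between the two rows.
_PRINTED = [
    # name, vgt1, id1, dlf1, transgene
    ("B73", 0, 1, 1, 0),
    ("id1 mutant", 0, 0, 1, 0),
    ("dlf1 mutant", 0, 1, 0, 0),
    ("Gaspe Flint", 1, 1, 1, 0),
    ("id1 dlf1", 0, 0, 0, 0),
    ("ZMM4 B73", 0, 1, 1, 1),
    ("ZMM4 id1 mutant", 0, 1, 0, 1),
    ("ZMM4 dlf1 mutant", 0, 0, 1, 1),
]

# Name-consistent variant: an 'id1 mutant' background has ID1=0 regardless
# of the transgene, matching the non-transgenic single-mutant rows.
_NAME_CONSISTENT = [
    ("B73", 0, 1, 1, 0),
    ("id1 mutant", 0, 0, 1, 0),
    ("dlf1 mutant", 0, 1, 0, 0),
    ("Gaspe Flint", 1, 1, 1, 0),
    ("id1 dlf1", 0, 0, 0, 0),
    ("ZMM4 B73", 0, 1, 1, 1),
    ("ZMM4 id1 mutant", 0, 0, 1, 1),
    ("ZMM4 dlf1 mutant", 0, 1, 0, 1),
]

TRAINING_GENOTYPES = ("Gaspe Flint", "B73", "dlf1 mutant", "id1 mutant")


def reference_panel(as_printed: bool = False) -> list[GenotypeSpec]:
    """The eight-genotype reference panel.

    By default the two transgenic mutant rows are corrected so that allele
    states agree with the genotype names (an ``id1`` background always has
    ``id1=0``). Pass ``as_printed=True`` to reproduce the table rows exactly
    as published, swap and all.
    """
    rows = _PRINTED if as_printed else _NAME_CONSISTENT
    return [GenotypeSpec(*row) for row in rows]


def training_panel() -> list[GenotypeSpec]:
    """The four contrasting genotypes used to calibrate the model:
    Gaspe Flint (extreme early), B73 (temperate reference), and the late
    *dlf1* and *id1* single mutants."""
    panel = {g.name: g for g in reference_panel()}
    return [panel[name] for name in TRAINING_GENOTYPES]


def panel_to_frame(panel: Iterable[GenotypeSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": g.name,
                "vgt1": g.vgt1,
                "id1": g.id1,
                "dlf1": g.dlf1,
                "zmm4_transgene": g.zmm4_transgene,
            }
            for g in panel
        ]
    )


def write_genotypes(panel: Iterable[GenotypeSpec], path: str | Path) -> None:
    panel_to_frame(panel).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> list[GenotypeSpec]:
    """Read a genotype panel from a TSV with header
    ``name vgt1 id1 dlf1 zmm4_transgene``."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "vgt1", "id1", "dlf1", "zmm4_transgene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    panel: list[GenotypeSpec] = []
    seen: set[str] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            spec = GenotypeSpec(
                str(row.name),
                int(row.vgt1),
                int(row.id1),
                int(row.dlf1),
                int(row.zmm4_transgene),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        if spec.name in seen:
            raise ValueError(f"{path}: line {lineno}: duplicate genotype {spec.name!r}")
        seen.add(spec.name)
        panel.append(spec)
    return panel
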