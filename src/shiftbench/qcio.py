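"""I/O for isotropic shieldings and conformer energies.

Two on-disk representations are supported:

* the GIAO summary block of a quantum-chemistry NMR log (lines of the form
  ``<idx> <El> Isotropic = <value> Anisotropy = <value>``), read as a
  convenience importer; and
* a canonical comma-separated interchange table with columns
  ``compound_id,conformer_id,rel_energy,atom_index,shielding`` which round-trips
  at full floating-point precision and is the format every other module reads.

Energies in the canonical table are relative free energies in kcal/mol,
re-zeroed to each compound's minimum on read.  A table may instead carry an
``energy_hartree`` column with absolute energies, converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

__all__ = [
    "HARTREE_TO_KCAL_MOL",
    "ConformerShieldings",
    "MethodLabel",
    "ShieldingSet",
    "LogParseError",
    "TableFormatError",
    "parse_nmr_log",
    "read_shielding_table",
    "write_shielding_table",
]

HARTREE_TO_KCAL_MOL = 627.5094740631


class LogParseError(ValueError):
    """No shielding block found, or a malformed/duplicated atom line."""


class TableFormatError(ValueError):
    """Canonical shielding table is missing a column or has a bad cell."""


@dataclass(frozen=True)
class ConformerShieldings:
    """Per-conformer relative free energy plus per-atom isotropic shieldings.

    ``rel_energy`` is in kcal/mol relative to the compound's ensemble minimum
    (zero for the global minimum); ``shieldings`` maps 1-based atom index to
    sigma in ppm.
    """

    compound_id: str
    conformer_id: str
    rel_energy: float
    shieldings: Mapping[int, float]

    def __post_init__(self) -> None:
        if not self.shieldings:
            raise ValueError(
                f"{self.compound_id}/{self.conformer_id}: empty shieldings map"
            )
        if any(i < 1 for i in self.shieldings):
            raise ValueError(
                f"{self.compound_id}/{self.conformer_id}: atom indices must be positive"
            )
        object.__setattr__(self, "shieldings", dict(self.shieldings))


@dataclass(frozen=True)
class MethodLabel:
    """Structured tag for the model chemistry behind a shielding set."""

    functional: str
    basis: str
    gauge: str = "GIAO"  # GIAO | CSGT | IGAIM
    solvent: str = "PCM"  # PCM | CPCM | SMD | none
    geometry: str = ""

    _GAUGES = ("GIAO", "CSGT", "IGAIM")
    _SOLVENTS = ("PCM", "CPCM", "SMD", "none")

    def __post_init__(self) -> None:
        if not self.functional or not self.basis:
            raise ValueError("functional and basis must be non-empty")
        if self.gauge not in self._GAUGES:
            raise ValueError(f"gauge must be one of {self._GAUGES}")
        if self.solvent not in self._SOLVENTS:
            raise ValueError(f"solvent must be one of {self._SOLVENTS}")

    def __str__(self) -> str:
        tag = f"{self.gauge}-{self.solvent}-{self.functional}/{self.basis}"
        return f"{tag}//{self.geometry}" if self.geometry else tag


@dataclass
class ShieldingSet:
    """Conformer shieldings grouped per compound, under one method label."""

    method_label: MethodLabel
    conformers: dict[str, list[ConformerShieldings]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, confs in self.conformers.items():
            universes = {frozenset(c.shieldings) for c in confs}
            if len(universes) > 1:
                raise ValueError(
                    f"compound {cid!r}: conformers disagree on the atom-index universe"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShieldingSet):
            return NotImplemented
        return (
            self.method_label == other.method_label
            and self.conformers == other.conformers
        )


# `1  C    Isotropic =   100.5000   Anisotropy =  50.0`
_SHIELDING_LINE = re.compile(
    r"^\s*(\d+)\s+([A-Z][a-z]?)\s+Isotropic\s*=\s*(-?\d+\.?\d*(?:[eEdD][+-]?\d+)?)"
    r"\s+Anisotropy\s*=\s*-?\d+\.?\d*",
)


def parse_nmr_log(
    text: str, return_elements: bool = False
) -> Union[dict[int, float], tuple[dict[int, float], dict[int, str]]]:
    """Extract isotropic shieldings from GIAO summary lines of a log.

    Repeated summary blocks (e.g. from chained jobs in one log) are allowed;
    the last block wins.  A block is a maximal run of consecutive matching
    lines.  Duplicate atom indices within a single block raise
    :class:`LogParseError`.
    """
    if not text:
        raise LogParseError("empty log text")
    blocks: list[dict[int, float]] = []
    elements_blocks: list[dict[int, str]] = []
    current: dict[int, float] = {}
    current_el: dict[int, str] = {}
    for line in text.splitlines():
        m = _SHIELDING_LINE.match(line)
        if m:
            idx = int(m.group(1))
            if idx in current:
                raise LogParseError(f"duplicate atom index {idx} within one block")
            current[idx] = float(m.group(3).replace("D", "E").replace("d", "e"))
            current_el[idx] = m.group(2)
        elif current:
            blocks.append(current)
            elements_blocks.append(current_el)
            current, current_el = {}, {}
    if current:
        blocks.append(current)
        elements_blocks.append(current_el)
    if not blocks:
        raise LogParseError("no isotropic shielding block found in log text")
    if return_elements:
        return blocks[-1], elements_blocks[-1]
    return blocks[-1]


_REQUIRED = ("compound_id", "conformer_id", "atom_index", "shielding")


def read_shielding_table(
    path: Union[str, Path], method_label: MethodLabel | None = None
) -> ShieldingSet:
    """Read a canonical shielding table.

    Relative energies are re-zeroed to each compound's minimum.  If the table
    carries ``energy_hartree`` instead of ``rel_energy``, absolute energies are
    converted (1 hartree = 627.5094740631 kcal/mol) before re-zeroing.
    """
    df = pd.read_csv(
        path,
        dtype={"compound_id": str, "conformer_id": str},
        float_precision="round_trip",
    )
    for col in _REQUIRED:
        if col not in df.columns:
            raise TableFormatError(f"missing required column {col!r}")
    if "rel_energy" in df.columns:
        energy_col = "rel_energy"
        scale = 1.0
    elif "energy_hartree" in df.columns:
        energy_col = "energy_hartree"
        scale = HARTREE_TO_KCAL_MOL
    else:
        raise TableFormatError("missing required column 'rel_energy' (or 'energy_hartree')")

    for col in (energy_col, "shielding", "atom_index"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((bad | df[col].isna()).idxmax()) + 2  # 1-based + header
            raise TableFormatError(f"non-numeric cell in column {col!r} at file row {row}")

    if method_label is None:
        method_label = MethodLabel(functional="unknown", basis="unknown", solvent="none")

    conformers: dict[str, list[ConformerShieldings]] = {}
    for cid, cgrp in df.groupby("compound_id", sort=False):
        e0 = float(cgrp[energy_col].min()) * scale
        confs = []
        for conf_id, grp in cgrp.groupby("conformer_id", sort=False):
            energies = set(grp[energy_col])
            if len(energies) > 1:
                raise TableFormatError(
                    f"{cid}/{conf_id}: conflicting energies within one conformer"
                )
            confs.append(
                ConformerShieldings(
                    compound_id=cid,
                    conformer_id=conf_id,
                    rel_energy=float(grp[energy_col].iloc[0]) * scale - e0,
                    shieldings={
                        int(r.atom_index): float(r.shielding) for r in grp.itertuples()
                    },
                )
            )
        conformers[cid] = confs
    return ShieldingSet(method_label=method_label, conformers=conformers)


def write_shielding_table(sset: ShieldingSet, path: Union[str, Path]) -> None:
    """Write the canonical table with deterministic ordering.

    Rows are sorted by (compound_id, conformer_id, atom_index); floats are
    written with ``repr`` so a write-read-write cycle is byte-identical.
    """
    rows: list[tuple[str, str, str, int, str]] = []
    for cid in sorted(sset.conformers):
        for conf in sorted(sset.conformers[cid], key=lambda c: c.conformer_id):
            for idx in sorted(conf.shieldings):
                rows.append(
                    (cid, conf.conformer_id, repr(conf.rel_energy), idx,
                     repr(conf.shieldings[idx]))
                )
    with open(path, "w", newline="") as fh:
        fh.write("compound_id,conformer_id,rel_energy,atom_index,shielding\n")
        for r in rows:
            fh.write(",".join(map(str, r)) + "\n")
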