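"""Packaged experimental fixtures: the DELTA50 shift set and the probe-set summary.

DELTA50 is a 50-compound training set of ``1H``/``13C`` chemical shifts measured
in CDCl3 (TMS reference) and used to fit the linear scaling factors that map
computed isotropic shieldings onto chemical shifts.  The probe set is a table
of 20 larger organic compounds and natural products with per-method RMSD/MD
statistics, used to assess transferability of the fitted factors.

The packaged DELTA50 site list is a synthetic stand-in: compound identities
follow the published set, but the per-site values are literature-typical CDCl3
shifts constrained to the published summary facts (50 compounds, 114 proton and
143 carbon sites, shift ranges 0.25-9.80 and -2.9-219.4 ppm).  The probe-set
table is a direct transcription of the published summary statistics.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "Nucleus",
    "NucleusSite",
    "CompoundEntry",
    "ProbeRecord",
    "ValidationReport",
    "DatasetIntegrityError",
    "load_delta50",
    "load_probe_summary",
    "load_manifest",
    "validate_dataset",
]

_DATA_PACKAGE = "shiftbench.data"
DELTA50_FILE = "delta50_synthetic_shifts.csv"
PROBE_FILE = "probe_summary.csv"
MANIFEST_FILE = "manifest.json"

# physical plausibility windows for experimental shifts (ppm)
_SHIFT_WINDOW = {"H1": (-5.0, 15.0), "C13": (-10.0, 250.0)}


class DatasetIntegrityError(RuntimeError):
    """Raised when a packaged fixture is missing, corrupted, or off-manifest."""


class Nucleus(str, Enum):
    H1 = "H1"
    C13 = "C13"


@dataclass(frozen=True)
class NucleusSite:
    """One experimentally assigned shift site.

    A site may cover several symmetry-equivalent atoms (e.g. the three protons
    of a methyl group, or both ortho carbons of a monosubstituted ring); all of
    them share one experimental shift.
    """

    compound_id: str
    site_label: str
    nucleus: Nucleus
    atom_indices: tuple[int, ...]  # 1-based
    delta_exp: float  # ppm

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise ValueError(f"site {self.site_label!r}: empty atom_indices")
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValueError(f"site {self.site_label!r}: duplicate atom indices")
        if any(i < 1 for i in self.atom_indices):
            raise ValueError(f"site {self.site_label!r}: atom indices must be 1-based")
        lo, hi = _SHIFT_WINDOW[self.nucleus.value]
        if not (lo <= self.delta_exp <= hi):
            raise ValueError(
                f"site {self.site_label!r}: delta_exp {self.delta_exp} ppm outside "
                f"[{lo}, {hi}] for {self.nucleus.value}"
            )


@dataclass(frozen=True)
class CompoundEntry:
    compound_id: str
    name: str
    sites: tuple[NucleusSite, ...]
    n_conformers_expected: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError(f"compound {self.compound_id!r} has no sites")
        labels = [s.site_label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError(f"compound {self.compound_id!r}: duplicate site labels")

    def sites_for(self, nucleus: Nucleus) -> tuple[NucleusSite, ...]:
        return tuple(s for s in self.sites if s.nucleus == nucleus)


@dataclass(frozen=True)
class ProbeRecord:
    """One probe-set compound with per-method, per-nucleus RMSD/MD cells (ppm).

    ``rmsd``/``md`` maps are keyed by (method, nucleus) with method one of
    ``"method1"``, ``"method2"``, ``"previous"``; absent printed cells are
    simply missing keys.
    """

    name: str
    molecular_weight: float  # g/mol
    n_conformers: int  # within the 5 kcal/mol window
    n_conformers_is_lower_bound: bool
    rmsd: dict[tuple[str, Nucleus], float] = field(default_factory=dict)
    md: dict[tuple[str, Nucleus], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name!r}: molecular weight must be positive")
        if self.n_conformers < 1:
            raise ValueError(f"{self.name!r}: n_conformers must be >= 1")
        for key, r in self.rmsd.items():
            m = self.md.get(key)
            if m is not None and m < r:
                raise ValueError(f"{self.name!r} {key}: md {m} < rmsd {r}")


@dataclass(frozen=True)
class ValidationReport:
    n_compounds: int
    n_sites: dict[str, int]
    shift_range: dict[str, tuple[float, float]]
    duplicate_labels: tuple[str, ...]
    passed: bool
    messages: tuple[str, ...]

    def __str__(self) -> str:  # human-readable CLI output
        lines = [f"compounds: {self.n_compounds}"]
        for nuc in ("H1", "C13"):
            n = self.n_sites.get(nuc, 0)
            if n:
                lo, hi = self.shift_range[nuc]
                lines.append(f"{nuc} sites: {n} (range {lo:g} to {hi:g} ppm)")
            else:
                lines.append(f"{nuc} sites: 0")
        if self.duplicate_labels:
            lines.append("duplicate labels: " + ", ".join(self.duplicate_labels))
        lines.extend(self.messages)
        lines.append("PASS" if self.passed else "FAIL")
        return "\n".join(lines)


def _read_packaged(name: str) -> bytes:
    try:
        return resources.files(_DATA_PACKAGE).joinpath(name).read_bytes()
    except FileNotFoundError as exc:
        raise DatasetIntegrityError(f"packaged fixture {name!r} is missing") from exc


def load_manifest() -> dict:
    return json.loads(_read_packaged(MANIFEST_FILE))


def _check_checksum(name: str, raw: bytes, expected: str) -> None:
    got = hashlib.sha256(raw).hexdigest()
    if got != expected:
        raise DatasetIntegrityError(
            f"fixture {name!r} checksum mismatch (corrupted file?): "
            f"expected {expected[:12]}..., got {got[:12]}..."
        )


def load_delta50() -> list[CompoundEntry]:
    """Load the packaged DELTA50 site list.

    Returns one :class:`CompoundEntry` per compound, in file order, with
    equivalence-collapsed sites.  The file is checksum-verified against the
    packaged manifest before parsing.
    """
    manifest = load_manifest()["delta50"]
    raw = _read_packaged(DELTA50_FILE)
    _check_checksum(DELTA50_FILE, raw, manifest["sha256"])
    import io

    df = pd.read_csv(io.BytesIO(raw), dtype={"compound_id": str})
    entries: list[CompoundEntry] = []
    for cid, grp in df.groupby("compound_id", sort=False):
        sites = tuple(
            NucleusSite(
                compound_id=cid,
                site_label=row.site_label,
                nucleus=Nucleus(row.nucleus),
                atom_indices=tuple(int(t) for t in str(row.atom_indices).split(";")),
                delta_exp=float(row.delta_exp),
            )
            for row in grp.itertuples()
        )
        entries.append(CompoundEntry(compound_id=cid, name=grp["name"].iloc[0], sites=sites))
    if len(entries) != manifest["n_compounds"]:
        raise DatasetIntegrityError(
            f"{DELTA50_FILE}: expected {manifest['n_compounds']} compounds, "
            f"parsed {len(entries)}"
        )
    return entries


_PROBE_METHODS = {"m1": "method1", "m2": "method2", "prev": "previous"}


def load_probe_summary() -> list[ProbeRecord]:
    """Load the packaged probe-set summary (20 records)."""
    manifest = load_manifest()["probe"]
    raw = _read_packaged(PROBE_FILE)
    _check_checksum(PROBE_FILE, raw, manifest["sha256"])
    import io

    df = pd.read_csv(io.BytesIO(raw))
    records: list[ProbeRecord] = []
    for row in df.itertuples():
        rmsd: dict[tuple[str, Nucleus], float] = {}
        md: dict[tuple[str, Nucleus], float] = {}
        for short, method in _PROBE_METHODS.items():
            for nuc, tag in ((Nucleus.H1, "h"), (Nucleus.C13, "c")):
                r = getattr(row, f"{short}_{tag}_rmsd")
                m = getattr(row, f"{short}_{tag}_md")
                if not math.isnan(r):
                    rmsd[(method, nuc)] = float(r)
                if not math.isnan(m):
                    md[(method, nuc)] = float(m)
        records.append(
            ProbeRecord(
                name=row.name,
                molecular_weight=float(row.molecular_weight),
                n_conformers=int(row.n_conformers),
                n_conformers_is_lower_bound=bool(row.n_conformers_lower_bound),
                rmsd=rmsd,
                md=md,
            )
        )
    if len(records) != manifest["n_records"]:
        raise DatasetIntegrityError(
            f"{PROBE_FILE}: expected {manifest['n_records']} records, parsed {len(records)}"
        )
    return records


def validate_dataset(entries: list[CompoundEntry]) -> ValidationReport:
    """Cross-check a compound list against the packaged manifest.

    Reports per-nucleus site counts, shift range endpoints, and duplicate site
    labels; the pass flag requires exact agreement with the manifest counts.
    """
    manifest = load_manifest()["delta50"]
    n_sites = {"H1": 0, "C13": 0}
    mins: dict[str, float] = {}
    maxs: dict[str, float] = {}
    dupes: list[str] = []
    seen_compounds: set[str] = set()
    for entry in entries:
        if entry.compound_id in seen_compounds:
            dupes.append(entry.compound_id)
        seen_compounds.add(entry.compound_id)
        for site in entry.sites:
            nuc = site.nucleus.value
            n_sites[nuc] += 1
            mins[nuc] = min(mins.get(nuc, site.delta_exp), site.delta_exp)
            maxs[nuc] = max(maxs.get(nuc, site.delta_exp), site.delta_exp)

    messages: list[str] = []
    passed = True
    expected = {
        "n_compounds": manifest["n_compounds"],
        "H1": manifest["n_sites_h1"],
        "C13": manifest["n_sites_c13"],
    }
    if len(entries) != expected["n_compounds"]:
        passed = False
        messages.append(f"compound count {len(entries)} != manifest {expected['n_compounds']}")
    for nuc in ("H1", "C13"):
        if n_sites[nuc] != expected[nuc]:
            passed = False
            messages.append(f"{nuc} site count {n_sites[nuc]} != manifest {expected[nuc]}")
    if dupes:
        passed = False
        messages.append("duplicate compound ids present")

    shift_range = {
        nuc: (mins[nuc], maxs[nuc]) for nuc in ("H1", "C13") if nuc in mins
    }
    return ValidationReport(
        n_compounds=len(entries),
        n_sites=n_sites,
        shift_range=shift_range,
        duplicate_labels=tuple(dupes),
        passed=passed,
        messages=tuple(messages),
    )
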