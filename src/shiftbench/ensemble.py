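"""Boltzmann weighting of conformer ensembles and site-level shielding reduction.

Conformer populations follow w_i proportional to exp(-dG_i / RT) with dG_i the
relative free energy (kcal/mol, vibrational corrections included upstream).
Conformers above a free-energy window (default 5 kcal/mol) are excluded before
normalization.  Per-atom shieldings are then population-averaged across the
retained conformers, and symmetry-equivalent atoms within a site are averaged
arithmetically so that predictions line up one-to-one with the experimentally
assigned sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataset import NucleusSite
from .qcio import ConformerShieldings

__all__ = [
    "GAS_CONSTANT_KCAL",
    "EnsembleSettings",
    "boltzmann_weights",
    "ensemble_shieldings",
    "average_equivalent",
    "site_shielding",
    "dominant_conformer",
]

# kcal mol^-1 K^-1 (CODATA R scaled)
GAS_CONSTANT_KCAL = 1.98720425864e-3


@dataclass(frozen=True)
class EnsembleSettings:
    """Temperature, energy window, and dominance threshold for weighting.

    ``dominant_threshold`` is the population fraction above which an ensemble
    is considered single-conformer (the curation rule for the training set
    requires one conformer to carry at least 98% of the distribution).
    """

    temperature: float = 298.15  # K
    energy_window: float = 5.0  # kcal/mol above the minimum
    dominant_threshold: float = 0.98

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.energy_window < 0:
            raise ValueError("energy_window must be non-negative")
        if not (0 < self.dominant_threshold <= 1):
            raise ValueError("dominant_threshold must lie in (0, 1]")

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return GAS_CONSTANT_KCAL * self.temperature


def boltzmann_weights(
    rel_energies: Sequence[float], settings: EnsembleSettings | None = None
) -> np.ndarray:
    """Population weights for a conformer ensemble.

    Energies may carry an arbitrary offset; they are re-zeroed to the minimum.
    Conformers more than ``energy_window`` above the minimum get weight zero;
    the rest are normalized to sum to one.
    """
    settings = settings or EnsembleSettings()
    energies = np.asarray(rel_energies, dtype=float)
    if energies.size == 0:
        raise ValueError("empty energy list")
    if not np.all(np.isfinite(energies)):
        raise ValueError("energies must be finite")
    rel = energies - energies.min()
    keep = rel <= settings.energy_window
    weights = np.zeros_like(rel)
    w = np.exp(-rel[keep] / settings.rt)
    weights[keep] = w / w.sum()
    return weights


def ensemble_shieldings(
    conformers: Sequence[ConformerShieldings], weights: Sequence[float]
) -> dict[int, float]:
    """Population-weighted average shielding per atom.

    All conformers must share one atom-index universe and the weights must be
    aligned with ``conformers`` and sum to one.
    """
    if len(conformers) != len(weights):
        raise ValueError("weights do not align with conformers")
    if not conformers:
        raise ValueError("empty conformer list")
    if not math.isclose(float(np.sum(weights)), 1.0, abs_tol=1e-9):
        raise ValueError("weights must sum to 1")
    universe = set(conformers[0].shieldings)
    for conf in conformers[1:]:
        if set(conf.shieldings) != universe:
            offending = sorted(set(conf.shieldings) ^ universe)
            raise ValueError(
                f"conformer {conf.conformer_id!r} atom universe mismatch: {offending}"
            )
    return {
        a: float(sum(w * conf.shieldings[a] for conf, w in zip(conformers, weights)))
        for a in sorted(universe)
    }


def average_equivalent(sigmas: Mapping[int, float], site: NucleusSite) -> float:
    """Arithmetic mean shielding over a site's symmetry-equivalent atoms."""
    missing = [i for i in site.atom_indices if i not in sigmas]
    if missing:
        raise ValueError(
            f"site {site.site_label!r} of {site.compound_id!r}: "
            f"missing atom indices {missing}"
        )
    return float(np.mean([sigmas[i] for i in site.atom_indices]))


def site_shielding(
    conformers: Sequence[ConformerShieldings],
    site: NucleusSite,
    settings: EnsembleSettings | None = None,
) -> float:
    """Ensemble- then equivalence-averaged shielding for one site."""
    weights = boltzmann_weights([c.rel_energy for c in conformers], settings)
    return average_equivalent(ensemble_shieldings(conformers, weights), site)


def dominant_conformer(
    weights: Sequence[float], settings: EnsembleSettings | None = None
) -> tuple[int, bool]:
    """Index of the most populated conformer and whether it dominates.

    Ties break to the lowest index.  The flag is true when the top weight
    reaches ``settings.dominant_threshold``.
    """
    settings = settings or EnsembleSettings()
    arr = np.asarray(weights, dtype=float)
    if arr.size == 0:
        raise ValueError("empty weight list")
    idx = int(np.argmax(arr))  # argmax takes the first of tied maxima
    return idx, bool(arr[idx] >= settings.dominant_threshold)
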