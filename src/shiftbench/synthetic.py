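"""Synthetic shielding sets with known ground truth.

Every downstream stage (fitting, ensemble averaging, prediction, statistics)
can be exercised without a quantum-chemistry engine by generating shieldings
on a known line sigma = m*delta + b plus Gaussian noise.  The defaults mirror
the statistical structure of real benchmark residuals: homoscedastic scatter
of about 0.08 ppm for 1H and 1.5 ppm for 13C around the per-nucleus line
(real residuals additionally carry functional-group systematics, which are
deliberately not emulated here).

All randomness flows through one ``numpy.random.default_rng(seed)`` stream per
invocation, so identical truth records reproduce identical sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dataset import Nucleus
from .qcio import ConformerShieldings, MethodLabel, ShieldingSet
from .scaling import ScalingFactors

__all__ = [
    "DELTA50_SHIFT_RANGES",
    "ConformerSpec",
    "SyntheticTruth",
    "generate_shielding_set",
    "generate_conformer_ensemble",
]

# printed experimental shift ranges (ppm) of the training set, used as the
# sampling window when no explicit shifts are supplied
DELTA50_SHIFT_RANGES: dict[Nucleus, tuple[float, float]] = {
    Nucleus.H1: (0.25, 9.80),
    Nucleus.C13: (-2.9, 219.4),
}

# default residual scatter per nucleus (ppm), matching typical benchmark RMSDs
DEFAULT_NOISE_SD: dict[Nucleus, float] = {Nucleus.H1: 0.08, Nucleus.C13: 1.5}


@dataclass(frozen=True)
class ConformerSpec:
    """Ensemble shape for generated conformers."""

    count: int
    energy_spread: float  # kcal/mol, relative energies drawn uniform on [0, spread]
    sigma_jitter: float  # ppm, per-conformer shielding jitter around the site value

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("conformer count must be >= 1")
        if self.energy_spread < 0 or self.sigma_jitter < 0:
            raise ValueError("spread and jitter must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated shielding set."""

    factors: ScalingFactors
    noise_sd: float
    seed: int
    n_sites: int
    conformer_spec: Optional[ConformerSpec] = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_sites < 2:
            raise ValueError("need at least two sites")


def generate_shielding_set(
    truth: SyntheticTruth, deltas: Optional[Sequence[float]] = None
) -> tuple[ShieldingSet, dict]:
    """Generate a single-conformer shielding set on the truth line.

    sigma_i = m*delta_i + b + eps_i with eps_i ~ N(0, noise_sd^2).  When
    ``deltas`` is omitted, shifts are drawn uniformly over the training-set
    range for the truth nucleus.  Atom index i maps to site i (1-based).

    Returns the set plus a truth record (seed, line, noise, and the shifts
    used) suitable for serialization next to the generated data.
    """
    rng = np.random.default_rng(truth.seed)
    if deltas is None:
        lo, hi = DELTA50_SHIFT_RANGES[truth.factors.nucleus]
        delta = rng.uniform(lo, hi, size=truth.n_sites)
    else:
        delta = np.asarray(deltas, dtype=float)
        if delta.size != truth.n_sites:
            raise ValueError("deltas length must equal n_sites")
    sigma = truth.factors.slope_m * delta + truth.factors.intercept_b
    sigma = sigma + rng.normal(0.0, truth.noise_sd, size=delta.size)

    conf = ConformerShieldings(
        compound_id="synthetic",
        conformer_id="c1",
        rel_energy=0.0,
        shieldings={i + 1: float(s) for i, s in enumerate(sigma)},
    )
    sset = ShieldingSet(
        method_label=MethodLabel(
            functional="synthetic", basis="truth-line", solvent="none"
        ),
        conformers={"synthetic": [conf]},
    )
    record = {
        "seed": truth.seed,
        "nucleus": truth.factors.nucleus.value,
        "slope_m": truth.factors.slope_m,
        "intercept_b": truth.factors.intercept_b,
        "noise_sd": truth.noise_sd,
        "n_sites": truth.n_sites,
        "deltas": [float(d) for d in delta],
    }
    return sset, record


def generate_conformer_ensemble(
    truth: SyntheticTruth, deltas: Optional[Sequence[float]] = None
) -> tuple[list[ConformerShieldings], dict]:
    """Generate a jittered conformer ensemble around the truth line.

    Relative energies are uniform on [0, energy_spread] with the minimum
    re-zeroed; each conformer's shieldings are the site-line values plus
    independent N(0, sigma_jitter^2) jitter.  The truth record includes the
    exact ensemble-average shielding per atom for downstream checks.
    """
    if truth.conformer_spec is None:
        raise ValueError("truth.conformer_spec is required")
    spec = truth.conformer_spec
    rng = np.random.default_rng(truth.seed)
    if deltas is None:
        lo, hi = DELTA50_SHIFT_RANGES[truth.factors.nucleus]
        delta = rng.uniform(lo, hi, size=truth.n_sites)
    else:
        delta = np.asarray(deltas, dtype=float)
    base = truth.factors.slope_m * delta + truth.factors.intercept_b

    energies = rng.uniform(0.0, spec.energy_spread, size=spec.count)
    energies -= energies.min()
    conformers = [
        ConformerShieldings(
            compound_id="synthetic",
            conformer_id=f"c{k + 1}",
            rel_energy=float(energies[k]),
            shieldings={
                i + 1: float(base[i] + jit)
                for i, jit in enumerate(
                    rng.normal(0.0, spec.sigma_jitter, size=delta.size)
                )
            },
        )
        for k in range(spec.count)
    ]
    record = {
        "seed": truth.seed,
        "nucleus": truth.factors.nucleus.value,
        "slope_m": truth.factors.slope_m,
        "intercept_b": truth.factors.intercept_b,
        "noise_sd": truth.noise_sd,
        "conformer_count": spec.count,
        "energy_spread": spec.energy_spread,
        "sigma_jitter": spec.sigma_jitter,
        "deltas": [float(d) for d in delta],
        "rel_energies": [float(e) for e in energies],
    }
    # exact population-weighted average at default settings, for cross-checks
    from .ensemble import boltzmann_weights, ensemble_shieldings

    weights = boltzmann_weights(energies)
    record["true_ensemble_sigma"] = ensemble_shieldings(conformers, weights)
    return conformers, record
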