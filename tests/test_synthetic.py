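"""Synthetic-data generation: determinism, ground-truth recovery, pipelines."""

import numpy as np
import pytest

from shiftbench import (
    ConformerSpec,
    Nucleus,
    NucleusSite,
    RECOMMENDED_FACTORS,
    SyntheticTruth,
    boltzmann_weights,
    ensemble_shieldings,
    evaluate,
    fit_scaling,
    generate_conformer_ensemble,
    generate_shielding_set,
    predict_shifts,
)


def _sigmas(sset):
    return sset.conformers["synthetic"][0].shieldings


def test_same_seed_reproduces_identical_sets():
    truth = SyntheticTruth(
        factors=RECOMMENDED_FACTORS["method2"][Nucleus.C13],
        noise_sd=1.5, seed=42, n_sites=30,
    )
    s1, r1 = generate_shielding_set(truth)
    s2, r2 = generate_shielding_set(truth)
    assert _sigmas(s1) == _sigmas(s2)
    assert r1 == r2
    assert r1["seed"] == 42


def test_noiseless_generation_refits_published_line(delta50):
    """Exact on-line 13C shieldings over the training shifts refit the line."""
    truth = SyntheticTruth(
        factors=RECOMMENDED_FACTORS["method2"][Nucleus.C13],
        noise_sd=0.0, seed=1, n_sites=143,
    )
    deltas = [
        s.delta_exp for c in delta50 for s in c.sites_for(Nucleus.C13)
    ]
    sset, record = generate_shielding_set(truth, deltas=deltas)
    pairs = list(zip(record["deltas"], _sigmas(sset).values()))
    fitted = fit_scaling(pairs, Nucleus.C13)
    assert fitted.slope_m == pytest.approx(-1.0065, abs=1e-9)
    assert fitted.intercept_b == pytest.approx(196.0386, abs=1e-6)


def test_parameter_recovery_under_realistic_noise():
    """200 replicates at n=143, 1.5 ppm scatter: slope unbiased, rmsd ~ noise."""
    truth_line = RECOMMENDED_FACTORS["method2"][Nucleus.C13]
    slopes, rmsds, within = [], [], 0
    n = 143
    for rep in range(200):
        truth = SyntheticTruth(factors=truth_line, noise_sd=1.5, seed=1000 + rep,
                               n_sites=n)
        sset, record = generate_shielding_set(truth)
        pairs = list(zip(record["deltas"], _sigmas(sset).values()))
        fitted = fit_scaling(pairs, Nucleus.C13)
        slopes.append(fitted.slope_m)
        rmsds.append(fitted.fit_rmsd)
        # OLS sampling theory: se(m) = noise / (sigma_delta * sqrt(n))
        se = 1.5 / (np.std(record["deltas"]) * np.sqrt(n))
        if abs(fitted.slope_m - truth_line.slope_m) <= 3 * se:
            within += 1
    assert abs(np.mean(slopes) - truth_line.slope_m) < 0.005
    assert 1.3 <= np.mean(rmsds) <= 1.7
    assert within >= 0.99 * 200


def test_noiseless_full_pipeline_is_exact():
    """generate -> ensemble -> fit -> predict -> evaluate closes to zero error."""
    truth_line = RECOMMENDED_FACTORS["method1"][Nucleus.H1]
    truth = SyntheticTruth(
        factors=truth_line, noise_sd=0.0, seed=7, n_sites=20,
        conformer_spec=ConformerSpec(count=4, energy_spread=3.0, sigma_jitter=0.0),
    )
    conformers, record = generate_conformer_ensemble(truth)
    weights = boltzmann_weights([c.rel_energy for c in conformers])
    sigmas = ensemble_shieldings(conformers, weights)
    deltas = record["deltas"]
    pairs = [(deltas[i - 1], sigmas[i]) for i in sorted(sigmas)]
    fitted = fit_scaling(pairs, Nucleus.H1)
    preds = predict_shifts(
        [("synthetic", str(i), sigmas[i]) for i in sorted(sigmas)],
        fitted,
        delta_exp={("synthetic", str(i)): deltas[i - 1] for i in sorted(sigmas)},
    )
    summary = evaluate(preds)
    assert summary.rmsd <= 1e-9
    assert summary.md <= 1e-9


def test_conformer_ensemble_limits():
    line = RECOMMENDED_FACTORS["method1"][Nucleus.H1]
    # zero jitter: every conformer carries the exact site line
    truth = SyntheticTruth(
        factors=line, noise_sd=0.0, seed=3, n_sites=5,
        conformer_spec=ConformerSpec(count=3, energy_spread=2.0, sigma_jitter=0.0),
    )
    conformers, record = generate_conformer_ensemble(truth)
    first = conformers[0].shieldings
    assert all(c.shieldings == first for c in conformers)
    np.testing.assert_allclose(
        sorted(record["true_ensemble_sigma"].values()), sorted(first.values()),
        atol=1e-12,
    )
    # zero spread: all conformers weight-equivalent, average is the plain mean
    flat = SyntheticTruth(
        factors=line, noise_sd=0.0, seed=4, n_sites=5,
        conformer_spec=ConformerSpec(count=3, energy_spread=0.0, sigma_jitter=0.5),
    )
    confs, _ = generate_conformer_ensemble(flat)
    w = boltzmann_weights([c.rel_energy for c in confs])
    np.testing.assert_allclose(w, [1 / 3] * 3, atol=1e-12)
    avg = ensemble_shieldings(confs, w)
    for atom in avg:
        assert avg[atom] == pytest.approx(
            np.mean([c.shieldings[atom] for c in confs]), abs=1e-12
        )


def test_window_rule_excludes_high_energy_conformer():
    w = boltzmann_weights([0.0, 1.0, 6.0])
    assert w[2] == 0.0 and w[:2].sum() == pytest.approx(1.0, abs=1e-12)


def test_truth_validation():
    line = RECOMMENDED_FACTORS["method1"][Nucleus.H1]
    with pytest.raises(ValueError):
        SyntheticTruth(factors=line, noise_sd=-0.1, seed=1, n_sites=5)
    with pytest.raises(ValueError):
        SyntheticTruth(factors=line, noise_sd=0.1, seed=1, n_sites=1)
    with pytest.raises(ValueError):
        generate_conformer_ensemble(
            SyntheticTruth(factors=line, noise_sd=0.0, seed=1, n_sites=5)
        )
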