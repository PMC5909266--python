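"""Shared fixtures: small deterministic scans with known ground truth."""

import numpy as np
import pytest

import respsurro as rs


def two_tone_surrogate(n=351, dt=0.2, base=10.0):
    """Noiseless two-tone breathing-like trace (rich enough for rank-5 fits)."""
    t = np.arange(n) * dt
    return base + 4.0 * np.sin(2 * np.pi * t / 4.0) + 1.5 * np.sin(2 * np.pi * t / 2.7 + 0.3)


KNOWN_COEFFS = dict(a=(0.02,) * 3, b=(0.9,) * 3, c=(3.0,) * 3, d=(0.01,) * 3, e=(0.5,) * 3)


@pytest.fixture(scope="session")
def known_truth():
    return rs.CouplingTruth.uniform(**KNOWN_COEFFS)


@pytest.fixture(scope="session")
def two_tone_scan(known_truth):
    """Noiseless scan whose target is generated from KNOWN_COEFFS.

    All three markers carry the same trace, so each per-marker fit must
    recover the generating coefficients exactly.
    """
    w = two_tone_surrogate()
    surrogates = tuple(rs.SurrogateTrace(m, w, 0.2) for m in (1, 2, 3))
    target = rs.simulate_target(surrogates, known_truth, 0.2)
    return rs.Scan("two_tone", surrogates, target)


@pytest.fixture(scope="session")
def noiseless_params():
    """Deterministic breathing: no jitter, no noise, equal marker amplitudes."""
    return rs.BreathingParams(
        period_sd=0.0,
        amplitude_sd_frac=0.0,
        surrogate_noise_sd=0.0,
        marker_amplitudes=(8.0, 8.0, 8.0),
    )


@pytest.fixture(scope="session")
def shift_invariant_truth():
    """Coupling with no w^2 term: a constant surrogate shift moves the
    prediction by a constant, so median-based correction removes it exactly."""
    return rs.CouplingTruth.uniform(
        a=(0.0, 0.0, 0.0),
        b=(0.2, 1.5, 0.8),
        c=(1.0, -2.0, 0.5),
        d=(0.001, 0.002, 0.001),
        e=(0.05, 0.1, 0.05),
    )


@pytest.fixture(scope="session")
def drifted_pair(noiseless_params, shift_invariant_truth):
    """Noiseless pair differing only by surrogate shift 3 mm and target
    shift 2 mm per direction, with the target following the measured
    surrogate (the construction under which both drift-recovery clauses
    are exact)."""
    return rs.simulate_scan_pair(
        noiseless_params,
        shift_invariant_truth,
        seed=1,
        surrogate_shift=3.0,
        target_shift=(2.0, 2.0, 2.0),
        share_breathing=True,
        drift_in_coupling=True,
    )


@pytest.fixture(scope="session")
def noiseless_scan(noiseless_params, shift_invariant_truth):
    return rs.simulate_scan(
        "clean", noiseless_params, shift_invariant_truth,
        rng=np.random.default_rng(7),
    )
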