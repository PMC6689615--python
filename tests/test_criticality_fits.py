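"""Recovery of known ground truth by the scaling fits.

Every fitting routine is calibrated on synthetic data generated from the
model family it assumes, with frozen seeds, so failures indicate fitting
defects rather than statistical flukes.
"""

import numpy as np
import pytest

from homeoca.criticality import (
    extrapolate_dc_from_tf, fit_correlation_length, fit_power_exponent, fit_tf,
)
from homeoca.observables import CorrelationEstimate


# --- power-law exponent ---------------------------------------------------

def test_power_law_exact():
    x = np.arange(1, 200, dtype=float)
    fit = fit_power_exponent(x, x ** 0.5)
    assert fit.exponent == pytest.approx(0.5)
    assert fit.r2 == pytest.approx(1.0)
    fit2 = fit_power_exponent(x, 3.0 * x ** 1.26)
    assert fit2.exponent == pytest.approx(1.26)
    assert fit2.amplitude == pytest.approx(3.0)


def test_power_law_noisy_recovery(rng):
    x = np.arange(10, 301, dtype=float)
    for _ in range(100):
        y = x ** 0.24 * (1.0 + rng.normal(0, 0.05, x.size))
        fit = fit_power_exponent(x, y)
        assert fit.exponent == pytest.approx(0.24, abs=0.03)


def test_power_law_input_validation():
    x = np.arange(1, 50, dtype=float)
    with pytest.raises(ValueError):
        fit_power_exponent(x, np.concatenate([[0.0], x[1:]]))
    with pytest.raises(ValueError):
        fit_power_exponent(x[:4], x[:4])


# --- correlation length ---------------------------------------------------

def _corr_from(l, C):
    return CorrelationEstimate(l=np.asarray(l, float), C=np.asarray(C, float),
                               n_samples=np.full(len(l), 10 ** 4))


def test_correlation_length_free_fit_recovers_truth():
    l = np.arange(0, 41, dtype=float)
    C = np.zeros_like(l)
    C[1:] = l[1:] ** -0.643 * np.exp(-l[1:] / 10.0)
    C[0] = 1.0
    fit = fit_correlation_length(_corr_from(l, C))
    assert fit.xi == pytest.approx(10.0, abs=0.5)
    assert fit.alpha == pytest.approx(0.643, abs=0.02)


def test_correlation_length_fixed_alpha():
    l = np.arange(0, 31, dtype=float)
    C = np.zeros_like(l)
    C[1:] = l[1:] ** -0.89 * np.exp(-l[1:] / 6.0)
    fit = fit_correlation_length(_corr_from(l, C), alpha=0.89)
    assert fit.alpha_fixed
    assert fit.xi == pytest.approx(6.0, abs=0.3)


def test_pure_power_law_reports_unbounded_length():
    l = np.arange(0, 31, dtype=float)
    C = np.zeros_like(l)
    C[1:] = l[1:] ** -0.89
    fit = fit_correlation_length(_corr_from(l, C))
    assert fit.xi is None


def test_correlation_length_needs_positive_values():
    l = np.arange(0, 10, dtype=float)
    with pytest.raises(ValueError):
        fit_correlation_length(_corr_from(l, -np.ones_like(l)))


# --- lifetime of the active probability ----------------------------------

def test_tf_pure_exponential():
    t = np.arange(0, 800, dtype=float)
    fit = fit_tf(t, np.exp(-t / 100.0))
    assert fit.t_f == pytest.approx(100.0, rel=1e-6)


def test_tf_plateau_then_decay():
    t = np.arange(0, 400, dtype=float)
    p = np.where(t < 50, 1.0, np.exp(-(t - 50) / 30.0))
    fit = fit_tf(t, p)
    assert fit.t_f == pytest.approx(30.0, rel=1e-6)
    assert fit.plateau == pytest.approx(1.0)


def test_tf_censored_when_no_decay():
    t = np.arange(0, 300, dtype=float)
    fit = fit_tf(t, np.full_like(t, 0.8))
    assert fit.censored and fit.t_f is None


def test_tf_recovery_from_bernoulli_sessions(rng):
    """Empirical P_act from 500 sessions whose absorption times follow a
    plateau-then-exponential law with t_f = 200 recovers t_f within 20 %."""
    sessions, t0, tf_true = 500, 100, 200.0
    deaths = t0 + rng.exponential(tf_true, size=sessions)
    t = np.arange(0, 1600, dtype=float)
    p_act = (deaths[None, :] > t[:, None]).mean(axis=1)
    fit = fit_tf(t, p_act, sessions=sessions)
    assert fit.t_f == pytest.approx(tf_true, rel=0.2)


# --- lifetime divergence --------------------------------------------------

def test_dc_extrapolation_recovers_truth():
    d = np.array([0.06, 0.07, 0.09, 0.12])
    tf = np.abs(d - 0.05) ** -1.5
    fit = extrapolate_dc_from_tf(d, tf, side="above")
    assert fit.d_c == pytest.approx(0.05, abs=0.005)
    assert fit.mu == pytest.approx(1.5, abs=0.2)
    assert fit.residual < 1e-8
    assert not fit.flagged


def test_dc_extrapolation_from_below():
    d = np.array([0.01, 0.02, 0.03, 0.035])
    tf = np.abs(d - 0.04) ** -1.2
    fit = extrapolate_dc_from_tf(d, tf, side="below")
    assert fit.d_c == pytest.approx(0.04, abs=0.005)
    assert fit.mu == pytest.approx(1.2, abs=0.2)


def test_flat_lifetimes_are_flagged():
    d = np.array([0.06, 0.07, 0.09, 0.12])
    fit = extrapolate_dc_from_tf(d, np.full_like(d, 37.0), side="above")
    assert fit.flagged


def test_nonmonotone_lifetimes_are_flagged():
    d = np.array([0.06, 0.07, 0.09, 0.12])
    fit = extrapolate_dc_from_tf(d, np.array([50.0, 80.0, 20.0, 10.0]),
                                 side="above")
    assert fit.flagged
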