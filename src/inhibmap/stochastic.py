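"""Monte Carlo multi-site release: trial-by-trial IPSC charge variation and
its statistical comparison to recorded ensembles.

Each trial, every synaptic site releases independently with its calibrated
probability p_i and contributes its calibrated charge q_i when it does, so
the trial charge is a weighted Bernoulli sum with

    E[Q] = Σ p_i q_i        Var[Q] = Σ p_i (1 − p_i) q_i².

With k sites the noiseless distribution has at most 2^k atoms; the exact
enumeration is available as an oracle for the empirical histogram. Optional
Gaussian charge noise emulates the recording noise floor. Simulated and
recorded charge distributions are compared with the two-sample
Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .synapse import SynapseSite

__all__ = [
    "TrialEnsemble",
    "KSResult",
    "simulate_trials",
    "expected_moments",
    "exact_charge_distribution",
    "charge_histogram",
    "ks_two_sample",
]


@dataclass
class TrialEnsemble:
    """Simulated (or synthetic 'recorded') trial set: per-trial charges
    (fC), the per-trial released-site mask and the seed that generated it."""

    charges: np.ndarray            # (n_trials,)
    release_mask: np.ndarray       # (n_trials, n_sites) bool
    site_labels: list[str]
    seed: int | None = None
    noise_sd: float = 0.0

    @property
    def n_trials(self) -> int:
        return len(self.charges)

    @property
    def failure_rate(self) -> float:
        """Fraction of trials in which no site released."""
        return float(np.mean(~self.release_mask.any(axis=1)))


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


def _site_vectors(sites: list[SynapseSite]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    p, q, labels = [], [], []
    for s in sites:
        if s.release_p is None:
            raise ValueError(f"site {s.label}: release probability not set")
        if s.charge_i is None:
            raise ValueError(f"site {s.label}: charge not set")
        p.append(s.release_p)
        q.append(s.charge_i)
        labels.append(s.label)
    return np.asarray(p), np.asarray(q), labels


def simulate_trials(
    sites: list[SynapseSite],
    n_trials: int = 10_000,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> TrialEnsemble:
    """Simulate independent multi-site release: each trial, site i releases
    with probability p_i and contributes q_i fC; optional Gaussian
    measurement noise (sd in fC) is added to the trial charge. Deterministic
    given the seed."""
    p, q, labels = _site_vectors(sites)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_trials, len(sites))) < p
    charges = mask @ q
    if noise_sd > 0:
        charges = charges + rng.normal(0.0, noise_sd, size=n_trials)
    return TrialEnsemble(
        charges=charges,
        release_mask=mask,
        site_labels=labels,
        seed=seed,
        noise_sd=noise_sd,
    )


def expected_moments(sites: list[SynapseSite]) -> tuple[float, float]:
    """Closed-form (mean, variance) of the trial charge of the Bernoulli
    sum: Σp_i·q_i and Σp_i(1−p_i)·q_i²."""
    p, q, _ = _site_vectors(sites)
    return float(np.sum(p * q)), float(np.sum(p * (1.0 - p) * q**2))


def exact_charge_distribution(
    sites: list[SynapseSite],
) -> tuple[np.ndarray, np.ndarray]:
    """Exact noiseless outcome distribution by enumerating all release
    patterns (2^k for k sites): returns (charge values, probabilities),
    aggregated over patterns with equal total charge."""
    p, q, _ = _site_vectors(sites)
    k = len(p)
    if k > 20:
        raise ValueError("exact enumeration limited to 20 sites")
    outcomes: dict[float, float] = {}
    for pattern in itertools.product((0, 1), repeat=k):
        mask = np.asarray(pattern, dtype=bool)
        prob = float(np.prod(np.where(mask, p, 1.0 - p)))
        charge = round(float(q[mask].sum()), 9)
        outcomes[charge] = outcomes.get(charge, 0.0) + prob
    values = np.array(sorted(outcomes))
    probs = np.array([outcomes[v] for v in values])
    return values, probs


def charge_histogram(
    ensemble: TrialEnsemble, bin_width: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Binned trial-charge distribution: (bin edges fC, counts)."""
    if ensemble.n_trials == 0:
        raise ValueError("empty ensemble")
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    lo = min(0.0, ensemble.charges.min())
    hi = ensemble.charges.max() + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(ensemble.charges, bins=edges)
    return edges, counts


def ks_two_sample(a, b) -> KSResult:
    """Two-sample Kolmogorov–Smirnov comparison of charge distributions
    (asymptotic p-value)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sstats.ks_2samp(a, b, method="asymp")
    return KSResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=a.size,
        n2=b.size,
    )
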