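"""Synthetic data generators for every analysis stage.

Three generators with exactly known ground truth:

* a four-state Markov model of a junction base pair (CLOSED, FLIP5,
  FLIP3, OPEN on the stepwise-opening cycle) emitting the same distance
  channels the MD engine records, for validating state assignment,
  event extraction, free-energy estimation and detailed balance;
* a biased two-state sampler reproducing the statistical structure of a
  constant-force ensemble, for validating the reweighting estimator;
* saturating-exponential fluorescence unwinding traces with Gaussian
  noise, emulating helicase unwinding assays read out by a quenched
  fluorophore that lights up on strand separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .junction_states import CLOSED, FLIP3, FLIP5, OPEN

__all__ = [
    "JunctionMarkovModel",
    "KineticTrace",
    "junction_model",
    "sample_junction_series",
    "biased_two_state_sampler",
    "synth_unwinding_trace",
]

#: transitions allowed by the stepwise-opening topology (no direct
#: CLOSED <-> OPEN jumps)
_CYCLE_EDGES = ((CLOSED, FLIP5), (FLIP5, OPEN), (OPEN, FLIP3), (FLIP3, CLOSED))


@dataclass
class JunctionMarkovModel:
    """Reversible four-state jump process of one junction base pair.

    rates[i, j] is the transition rate i -> j; only the stepwise-cycle
    edges are nonzero unless direct CLOSED<->OPEN transitions were
    requested.  Emissions are Gaussian around per-state mean distance
    channels (pairing, 5'-stack, 3'-stack) and end-to-end x.
    """

    rates: np.ndarray  # (4, 4)
    emission_means: np.ndarray  # (4, 3): pairing, stack5, stack3 (A)
    emission_sd: float
    x_means: np.ndarray  # (4,) end-to-end distance per state (nm)
    x_sd: float
    context: str = "GC/CG"

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (4, 4) or (r < 0).any():
            raise ValueError("rates must be a nonnegative 4x4 matrix")
        np.fill_diagonal(r, 0.0)
        self.rates = r

    @property
    def generator(self) -> np.ndarray:
        q = self.rates.copy()
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary(self) -> np.ndarray:
        """Stationary distribution (null vector of the generator)."""
        q = self.generator
        a = np.vstack([q.T, np.ones(4)])
        b = np.zeros(5)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        return np.clip(pi, 0.0, None) / pi.sum()


def junction_model(
    stationary: Tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2),
    rate_scale: float = 1.0,
    emission_sd: float = 0.35,
    x_sd: float = 0.05,
    context: str = "GC/CG",
    allow_direct: bool = False,
) -> JunctionMarkovModel:
    """Reversible junction model with a prescribed stationary distribution.

    Rates on each allowed edge are k(a->b) = rate_scale * sqrt(pi_b/pi_a),
    which satisfies detailed balance for any pi (the Kolmogorov loop
    condition holds on the 4-cycle).  Emission means mimic an RNA
    junction: stacked/paired channels near 3.2-3.6 A, disrupted
    channels ~8 A higher; x grows from 1.4 nm (closed) to 2.4 nm (open).
    allow_direct adds CLOSED<->OPEN edges (breaking the stepwise
    topology) for testing pathway-ambiguity handling.
    """
    pi = np.asarray(stationary, dtype=float)
    if pi.shape != (4,) or (pi <= 0).any():
        raise ValueError("stationary distribution must be 4 positive values")
    pi = pi / pi.sum()
    rates = np.zeros((4, 4))
    edges = list(_CYCLE_EDGES) + ([(CLOSED, OPEN)] if allow_direct else [])
    for a, b in edges:
        rates[a, b] = rate_scale * math.sqrt(pi[b] / pi[a])
        rates[b, a] = rate_scale * math.sqrt(pi[a] / pi[b])
    base = np.array([3.0, 3.4, 3.6])
    bump = 8.0
    means = np.array([
        base,
        base + np.array([bump, bump, 0.0]),  # FLIP5: unpaired, 5'-stack broken
        base + np.array([bump, 0.0, bump]),  # FLIP3
        base + np.array([bump, bump, bump]),  # OPEN
    ])
    x_means = np.array([1.4, 1.9, 1.9, 2.4])
    return JunctionMarkovModel(rates, means, emission_sd, x_means, x_sd, context)


def sample_junction_series(
    model: JunctionMarkovModel,
    n_steps: int,
    dt: float,
    seed: int = 0,
) -> Tuple[np.ndarray, Dict[str, np.ndarray], np.ndarray]:
    """Discretized sampling of the jump process plus channel emissions.

    Returns (state series, distance channels shaped like a two-pair
    duplex with the sampled junction as pair 1, x series in nm).  dt
    must keep every per-step exit probability at or below 0.2.
    """
    q = model.rates
    exit_p = q.sum(axis=1) * dt
    if exit_p.max() > 0.2:
        raise ValueError(
            f"dt too large for discretized sampling (max exit probability {exit_p.max():.3f} > 0.2)"
        )
    rng = np.random.default_rng(seed)
    p = q * dt
    np.fill_diagonal(p, 0.0)
    stay = 1.0 - p.sum(axis=1)
    pmat = p + np.diag(stay)
    cum = np.cumsum(pmat, axis=1)
    u = rng.random(n_steps)
    states = np.empty(n_steps, dtype=np.int8)
    s = CLOSED
    for i in range(n_steps):
        s = int(np.searchsorted(cum[s], u[i]))
        states[i] = s
    em = model.emission_means[states] + model.emission_sd * rng.standard_normal((n_steps, 3))
    x = model.x_means[states] + model.x_sd * rng.standard_normal(n_steps)
    # shape the channels like a 2-pair duplex whose pair 1 is the junction;
    # pair 2 stays native (pairing constant at the closed mean)
    channels = {
        "pairing": np.column_stack([em[:, 0], np.full(n_steps, model.emission_means[CLOSED, 0])]),
        "stack5": em[:, 1:2],
        "stack3": em[:, 2:3],
    }
    return states, channels, x


def biased_two_state_sampler(
    dx_nm: float,
    beta_f: float,
    n: int,
    seed: int = 0,
    x0_nm: float = 0.0,
) -> np.ndarray:
    """Samples of x from a two-state system with equal unbiased weights.

    The two states sit at x0 and x0 + dx (nm); under a constant force
    the biased probabilities are proportional to exp(+beta_f * x), with
    beta_f in 1/nm.  Reweighting with the matching force must recover
    the 50/50 unbiased populations exactly in expectation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    w_hi = math.exp(beta_f * dx_nm)
    p_hi = w_hi / (1.0 + w_hi)
    hi = rng.random(n) < p_hi
    return np.where(hi, x0_nm + dx_nm, x0_nm)


@dataclass
class KineticTrace:
    """A fluorescence unwinding time course."""

    time_min: np.ndarray
    fluorescence: np.ndarray
    params: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if len(t) != len(f):
            raise ValueError("time and fluorescence lengths differ")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise ValueError("non-finite trace values")
        self.time_min, self.fluorescence = t, f


def synth_unwinding_trace(
    amplitude: float,
    rate: float,
    baseline: float,
    noise_sd: float,
    t_grid: np.ndarray,
    seed: int = 0,
) -> KineticTrace:
    """F(t) = baseline + amplitude (1 - exp(-rate t)) + Gaussian noise.

    Time in minutes; `rate` in 1/min (the observed unwinding rate that
    sets the ~25-300 min plateau timescales of typical assays).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    t = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    f = baseline + amplitude * (1.0 - np.exp(-rate * t)) + noise_sd * rng.standard_normal(len(t))
    return KineticTrace(
        time_min=t,
        fluorescence=f,
        params={"amplitude": amplitude, "rate": rate, "baseline": baseline,
                "noise_sd": noise_sd, "seed": seed},
    )
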