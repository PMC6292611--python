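"""Monte-Carlo checks and random panel generation.

Two binary outcomes with fixed marginals and a joint probability define
a four-cell multinomial (both, A only, B only, neither); sampling from
it validates the inclusion–exclusion composite rate empirically.  The
power simulator draws two-arm binomial trials and applies the pooled
two-proportion z-test, providing an independent check on the
sample-size kernels.  Only pairwise-exact simulation is offered: the
engine's three-or-more-component rates rest on an imputed third-order
term and are checked against printed reference tables instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model import (
    AssociationMatrix,
    AssociationScenario,
    DesignParams,
    OutcomeSpec,
    Panel,
    frechet_bounds,
)

__all__ = ["TrialSample", "sample_pair", "empirical_power", "generate_panel"]


@dataclass
class TrialSample:
    """n × 2 binary response matrix for one arm (columns: outcome A, B)."""

    responses: np.ndarray
    n: int
    seed: int

    @property
    def union_rate(self) -> float:
        """Empirical rate of the composite (either outcome) event."""
        if self.n == 0:
            return float("nan")
        return float(self.responses.any(axis=1).mean())


def sample_pair(p_a: float, p_b: float, joint: float, n: int, seed: int) -> TrialSample:
    """Draw n subjects for two binary outcomes with the given joint.

    Cell probabilities {both, A only, B only, neither} are non-negative
    exactly when the joint respects the Fréchet bounds.
    """
    low, up = frechet_bounds(p_a, p_b)
    if not low <= joint <= up:
        raise ValueError(
            f"joint {joint!r} outside Fréchet bounds [{low:.6g}, {up:.6g}]"
        )
    rng = np.random.default_rng(seed)
    cells = np.array([joint, p_a - joint, p_b - joint, 1.0 - p_a - p_b + joint])
    counts = rng.multinomial(n, cells)
    responses = np.zeros((n, 2), dtype=np.int8)
    both, a_only, b_only = counts[0], counts[1], counts[2]
    responses[:both] = 1
    responses[both:both + a_only, 0] = 1
    responses[both + a_only:both + a_only + b_only, 1] = 1
    rng.shuffle(responses, axis=0)
    return TrialSample(responses=responses, n=n, seed=seed)


def empirical_power(
    p1: float,
    p2: float,
    n_per_group: int,
    alpha: float = 0.05,
    reps: int = 100_000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Rejection rate of the pooled two-proportion z-test over simulated trials.

    Returns the empirical power and its 95% Wald confidence interval.
    Under p1 == p2 the estimate is the empirical type-I error.
    """
    if reps < 1000:
        raise ValueError(f"reps must be ≥ 1000 for a stable estimate; got {reps}")
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n_per_group, p1, size=reps)
    x2 = rng.binomial(n_per_group, p2, size=reps)
    ph1 = x1 / n_per_group
    ph2 = x2 / n_per_group
    pbar = (x1 + x2) / (2 * n_per_group)
    var = pbar * (1.0 - pbar) * (2.0 / n_per_group)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (ph1 - ph2) / np.sqrt(var), 0.0)
    reject = np.abs(z) > norm.ppf(1.0 - alpha / 2.0)
    est = float(reject.mean())
    half = 1.959963984540054 * np.sqrt(est * (1.0 - est) / reps)
    return est, (max(0.0, est - half), min(1.0, est + half))


def generate_panel(
    k: int,
    seed: int,
    rate_range: tuple[float, float] = (0.005, 0.15),
    rr_range: tuple[float, float] = (0.1, 1.4),
    design: DesignParams | None = None,
) -> Panel:
    """A reproducible random panel with scenario associations.

    Rates and risk ratios are uniform on their ranges; each pair gets a
    uniformly random scenario.  All panel invariants hold by
    construction for the default ranges (rr × rate < 1).
    """
    if not 2 <= k <= 10:
        raise ValueError(f"k must be in [2, 10]; got {k}")
    rng = np.random.default_rng(seed)
    scenarios = list(AssociationScenario)
    outcomes = [
        OutcomeSpec(
            label=f"outcome_{i}",
            control_rate=float(rng.uniform(*rate_range)),
            effect_rr=float(rng.uniform(*rr_range)),
        )
        for i in range(k)
    ]
    entries = {
        (i, j): scenarios[rng.integers(len(scenarios))]
        for i in range(k)
        for j in range(i + 1, k)
    }
    return Panel(
        outcomes=outcomes,
        associations=AssociationMatrix(entries),
        design=design or DesignParams(),
    )
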