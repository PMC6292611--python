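"""Domain types for composite-endpoint planning.

A *panel* is a set of K candidate binary outcomes for a two-arm trial,
each described by its control-arm event probability and the assumed
treatment effect (a risk ratio).  Pairwise association between outcomes
is expressed as the joint probability that both events occur in the same
patient; when its exact value is unknown it is imputed from one of nine
categorical scenarios anchored on the Fréchet bounds.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Union

__all__ = [
    "OutcomeSpec",
    "AssociationScenario",
    "AssociationMatrix",
    "DesignParams",
    "Panel",
    "JointCorrectionWarning",
    "rr_to_or",
    "or_to_rr",
    "frechet_bounds",
    "impute_joint",
    "correct_joint",
    "resolve_associations",
    "select_re",
]

MAX_OUTCOMES = 10


class JointCorrectionWarning(UserWarning):
    """A supplied joint probability fell outside its Fréchet bounds."""


@dataclass(frozen=True)
class OutcomeSpec:
    """One candidate endpoint: label, control-arm rate and risk ratio."""

    label: str
    control_rate: float
    effect_rr: float
    is_relevant: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.control_rate < 1.0:
            raise ValueError(
                f"control_rate must be in (0, 1); got {self.control_rate!r} "
                f"for outcome {self.label!r}"
            )
        if self.effect_rr <= 0.0:
            raise ValueError(
                f"effect_rr must be > 0; got {self.effect_rr!r} "
                f"for outcome {self.label!r}"
            )
        if self.effect_rr * self.control_rate >= 1.0:
            raise ValueError(
                f"effect_rr × control_rate must be < 1 so the treatment rate "
                f"is a probability; got {self.effect_rr!r} × "
                f"{self.control_rate!r} for outcome {self.label!r}"
            )

    @property
    def treatment_rate(self) -> float:
        """Treatment-arm event probability, RR × control rate."""
        return self.effect_rr * self.control_rate


class AssociationScenario(enum.Enum):
    """Nine categorical association strengths anchored on the Fréchet bounds.

    ``theta`` counts quarters of the distance from the independence
    product toward the relevant Fréchet bound: 1 = low, 2 = moderate,
    3 = strong, 4 = at the bound itself (``lowest``/``highest``).
    Negative scenarios move toward the lower bound, positive toward the
    upper; ``none`` is the independence product.
    """

    LOWEST = "lowest"
    STRONG_NEGATIVE = "strong_negative"
    MODERATE_NEGATIVE = "moderate_negative"
    LOW_NEGATIVE = "low_negative"
    NONE = "none"
    LOW_POSITIVE = "low_positive"
    MODERATE_POSITIVE = "moderate_positive"
    STRONG_POSITIVE = "strong_positive"
    HIGHEST = "highest"

    @property
    def theta(self) -> int:
        """Signed interpolation step, −4 … +4."""
        return _THETA[self]


_THETA = {
    AssociationScenario.LOWEST: -4,
    AssociationScenario.STRONG_NEGATIVE: -3,
    AssociationScenario.MODERATE_NEGATIVE: -2,
    AssociationScenario.LOW_NEGATIVE: -1,
    AssociationScenario.NONE: 0,
    AssociationScenario.LOW_POSITIVE: 1,
    AssociationScenario.MODERATE_POSITIVE: 2,
    AssociationScenario.STRONG_POSITIVE: 3,
    AssociationScenario.HIGHEST: 4,
}

AssociationEntry = Union[float, AssociationScenario]


@dataclass
class AssociationMatrix:
    """Strictly upper-triangular map of pairwise associations.

    Each unordered pair of outcome indices maps to either an exact joint
    probability or an :class:`AssociationScenario`.  Missing pairs
    default to ``NONE`` (independence).
    """

    entries: dict[tuple[int, int], AssociationEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[tuple[int, int], AssociationEntry] = {}
        for (i, j), v in self.entries.items():
            if i == j:
                raise ValueError(f"association pair ({i}, {j}) is a self-pair")
            key = (i, j) if i < j else (j, i)
            if key in normalized:
                raise ValueError(f"duplicate association entry for pair {key}")
            if isinstance(v, float | int) and not 0.0 <= v <= 1.0:
                raise ValueError(f"joint probability for pair {key} must be in [0, 1]; got {v!r}")
            normalized[key] = v
        self.entries = normalized

    def get(self, i: int, j: int) -> AssociationEntry:
        key = (i, j) if i < j else (j, i)
        return self.entries.get(key, AssociationScenario.NONE)

    def overwrite_all(self, k: int, scenario: AssociationScenario) -> "AssociationMatrix":
        """A new matrix with every pair of a K-outcome panel set to *scenario*."""
        return AssociationMatrix(
            {(i, j): scenario for i in range(k) for j in range(i + 1, k)}
        )


_METHODS = ("normal_mixed", "normal_pooled", "normal_unpooled", "arcsine", "arcsine_corrected")


@dataclass(frozen=True)
class DesignParams:
    """Two-arm design: two-sided type I error, target power, SSR formula."""

    alpha: float = 0.05
    power: float = 0.80
    method: str = "normal_mixed"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1); got {self.alpha!r}")
        if not 0.0 < self.power < 1.0:
            raise ValueError(f"power must be in (0, 1); got {self.power!r}")
        if self.alpha + (1.0 - self.power) >= 1.0:
            raise ValueError(
                f"alpha + (1 - power) must be < 1; got alpha={self.alpha!r}, "
                f"power={self.power!r}"
            )
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}; got {self.method!r}")


@dataclass
class Panel:
    """2–10 candidate outcomes, their associations and the design."""

    outcomes: list[OutcomeSpec]
    associations: AssociationMatrix = field(default_factory=AssociationMatrix)
    design: DesignParams = field(default_factory=DesignParams)

    def __post_init__(self) -> None:
        k = len(self.outcomes)
        if not 2 <= k <= MAX_OUTCOMES:
            raise ValueError(f"a panel needs 2 to {MAX_OUTCOMES} outcomes; got {k}")
        labels = [o.label for o in self.outcomes]
        if len(set(labels)) != k:
            raise ValueError(f"outcome labels must be unique; got {labels}")
        flagged = [o for o in self.outcomes if o.is_relevant]
        if len(flagged) > 1:
            raise ValueError(
                "at most one outcome may be flagged as the relevant endpoint; "
                f"got {[o.label for o in flagged]}"
            )
        for i, j in self.associations.entries:
            if not (0 <= i < k and 0 <= j < k):
                raise ValueError(f"association pair ({i}, {j}) out of range for K={k}")

    @property
    def k(self) -> int:
        return len(self.outcomes)

    def labels(self) -> list[str]:
        return [o.label for o in self.outcomes]

    def index_of(self, label: str) -> int:
        try:
            return self.labels().index(label)
        except ValueError:
            raise KeyError(f"no outcome labelled {label!r}") from None

    def with_scenario_everywhere(self, scenario: AssociationScenario) -> "Panel":
        return replace(self, associations=self.associations.overwrite_all(self.k, scenario))


def rr_to_or(rr: float, p_control: float) -> float:
    """Convert a risk ratio to the odds ratio at the given control rate."""
    if not 0.0 < p_control < 1.0:
        raise ValueError(f"p_control must be in (0, 1); got {p_control!r}")
    if rr <= 0.0:
        raise ValueError(f"rr must be > 0; got {rr!r}")
    if rr * p_control >= 1.0:
        raise ValueError(
            f"rr × p_control must be < 1; got {rr!r} × {p_control!r}"
        )
    return rr * (1.0 - p_control) / (1.0 - rr * p_control)


def or_to_rr(odds_ratio: float, p_control: float) -> float:
    """Convert an odds ratio to the risk ratio at the given control rate."""
    if not 0.0 < p_control < 1.0:
        raise ValueError(f"p_control must be in (0, 1); got {p_control!r}")
    if odds_ratio <= 0.0:
        raise ValueError(f"odds_ratio must be > 0; got {odds_ratio!r}")
    return odds_ratio / ((1.0 - p_control) + odds_ratio * p_control)


def frechet_bounds(p_a: float, p_b: float) -> tuple[float, float]:
    """Attainable range [max(0, pA+pB−1), min(pA, pB)] for a joint probability."""
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]; got {p!r}")
    return max(0.0, p_a + p_b - 1.0), min(p_a, p_b)


def impute_joint(p_a: float, p_b: float, scenario: AssociationScenario) -> float:
    """Joint probability implied by a categorical association scenario.

    Linear interpolation in quarters between the independence product
    and the relevant Fréchet bound: theta/4 of the distance, where theta
    is 1 (low), 2 (moderate), 3 (strong) or 4 (at the bound).
    """
    if not isinstance(scenario, AssociationScenario):
        raise ValueError(f"unknown association scenario {scenario!r}")
    low, up = frechet_bounds(p_a, p_b)
    ind = p_a * p_b
    theta = scenario.theta
    if theta >= 0:
        return ind + (up - ind) * (theta / 4.0)
    return ind - (ind - low) * (-theta / 4.0)


def correct_joint(
    p_a: float, p_b: float, j: float, pair: str | None = None
) -> float:
    """Replace an out-of-bounds joint by the independence product.

    A joint outside the Fréchet bounds is impossible for the stated
    marginals; it is silently impossible to honour, so the independence
    product is substituted and a :class:`JointCorrectionWarning` issued.
    Values inside the bounds pass through unchanged (idempotent).
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"proposed joint must be in [0, 1]; got {j!r}")
    low, up = frechet_bounds(p_a, p_b)
    if low <= j <= up:
        return j
    where = f" for pair {pair}" if pair else ""
    warnings.warn(
        f"joint probability {j:.6g}{where} outside Fréchet bounds "
        f"[{low:.6g}, {up:.6g}] for marginals ({p_a:.6g}, {p_b:.6g}); "
        f"replaced by independence product {p_a * p_b:.6g}",
        JointCorrectionWarning,
        stacklevel=2,
    )
    return p_a * p_b


def resolve_associations(
    panel: Panel,
) -> tuple[dict[tuple[int, int], float], dict[tuple[int, int], float]]:
    """Concrete per-arm joint probabilities for every outcome pair.

    Scenario entries are imputed from each arm's own marginals, so the
    categorical strength — not the numeric control-arm value — carries
    over to the treatment arm.  Exact entries apply to both arms and are
    corrected against each arm's Fréchet bounds.
    """
    control: dict[tuple[int, int], float] = {}
    treatment: dict[tuple[int, int], float] = {}
    for i in range(panel.k):
        for j in range(i + 1, panel.k):
            a, b = panel.outcomes[i], panel.outcomes[j]
            entry = panel.associations.get(i, j)
            pair = f"({a.label!r}, {b.label!r})"
            if isinstance(entry, AssociationScenario):
                control[i, j] = impute_joint(a.control_rate, b.control_rate, entry)
                treatment[i, j] = impute_joint(a.treatment_rate, b.treatment_rate, entry)
            else:
                control[i, j] = correct_joint(
                    a.control_rate, b.control_rate, float(entry), pair
                )
                treatment[i, j] = correct_joint(
                    a.treatment_rate, b.treatment_rate, float(entry), pair
                )
    return control, treatment


def select_re(panel: Panel) -> int:
    """Index of the relevant endpoint.

    The user-flagged outcome wins; otherwise the outcome whose
    single-endpoint trial needs the fewest subjects per group under the
    panel's design.  Ties break to the lowest index.
    """
    from .sample_size import sample_size

    for idx, o in enumerate(panel.outcomes):
        if o.is_relevant:
            return idx
    best_idx, best_n = 0, float("inf")
    for idx, o in enumerate(panel.outcomes):
        if o.effect_rr == 1.0:
            continue  # no effect: infinite sample size
        n = sample_size(o.control_rate, o.treatment_rate, panel.design).n_per_group
        if n < best_n:
            best_idx, best_n = idx, n
    return best_idx
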