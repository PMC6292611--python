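"""Per-group sample-size kernels for comparing two proportions.

All kernels target a two-sided test at level ``alpha`` with equal
allocation (n per group).  The default ``normal_mixed`` kernel uses the
pooled variance under the null for the alpha term and the unpooled
variance under the alternative for the beta term:

    n = (z_{1-α/2}·√(2·p̄(1−p̄)) + z_{1-β}·√(p₁(1−p₁)+p₂(1−p₂)))² / (p₁−p₂)²

with p̄ = (p₁+p₂)/2, rounded up to an integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .model import DesignParams

__all__ = ["SSRResult", "ssr_normal", "ssr_arcsine", "sample_size"]


@dataclass(frozen=True)
class SSRResult:
    """Per-group sample size and the unrounded solution it came from."""

    n_per_group: int
    raw_n: float
    p_control: float
    p_treatment: float
    method: str

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError(f"n_per_group must be ≥ 1; got {self.n_per_group}")


def _validate(p1: float, p2: float) -> None:
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must be in (0, 1); got {p!r}")
    if p1 == p2:
        raise ValueError("zero effect (p1 == p2): sample size is undefined")


def ssr_normal(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    variant: str = "mixed",
) -> SSRResult:
    """Normal-approximation sample size for two proportions.

    Variants differ in the variance used for the alpha and beta terms:
    ``mixed`` (pooled under H0, unpooled under H1 — the default),
    ``pooled`` (pooled throughout) and ``unpooled`` (unpooled throughout).
    """
    _validate(p1, p2)
    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_b = norm.ppf(power)
    pbar = (p1 + p2) / 2.0
    v_pooled = 2.0 * pbar * (1.0 - pbar)
    v_unpooled = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    d2 = (p1 - p2) ** 2
    if variant == "mixed":
        raw = (z_a * math.sqrt(v_pooled) + z_b * math.sqrt(v_unpooled)) ** 2 / d2
    elif variant == "pooled":
        raw = (z_a + z_b) ** 2 * v_pooled / d2
    elif variant == "unpooled":
        raw = (z_a + z_b) ** 2 * v_unpooled / d2
    else:
        raise ValueError(f"variant must be mixed, pooled or unpooled; got {variant!r}")
    return SSRResult(
        n_per_group=max(1, math.ceil(raw)),
        raw_n=raw,
        p_control=p1,
        p_treatment=p2,
        method=f"normal_{variant}",
    )


def ssr_arcsine(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    corrected: bool = False,
) -> SSRResult:
    """Sample size on the variance-stabilised arcsine scale.

    Uncorrected: n = (z_a+z_b)² / h² with Cohen's h = 2·asin√p₁ − 2·asin√p₂.
    Corrected: the transform uses the continuity-corrected argument
    (x+3/8)/(n+3/4) with x = p·n, which depends on n itself; the fixed
    point is found by iteration (tolerance 1e-9, at most 100 rounds).
    """
    _validate(p1, p2)
    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_b = norm.ppf(power)
    zsum2 = (z_a + z_b) ** 2

    def h_plain() -> float:
        return 2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2))

    if not corrected:
        raw = zsum2 / h_plain() ** 2
    else:
        raw = zsum2 / h_plain() ** 2  # start from the uncorrected solution
        for _ in range(100):
            t1 = 2.0 * math.asin(math.sqrt((p1 * raw + 0.375) / (raw + 0.75)))
            t2 = 2.0 * math.asin(math.sqrt((p2 * raw + 0.375) / (raw + 0.75)))
            if t1 == t2:
                raise ValueError(
                    "corrected arcsine transform collapsed the effect to zero "
                    f"at n={raw:.6g}; sample size undefined"
                )
            new = zsum2 / (t1 - t2) ** 2
            if abs(new - raw) < 1e-9:
                raw = new
                break
            raw = new
        else:
            raise ValueError(
                f"corrected arcsine iteration did not converge in 100 rounds "
                f"(last n={raw:.6g}, p1={p1}, p2={p2})"
            )
    return SSRResult(
        n_per_group=max(1, math.ceil(raw)),
        raw_n=raw,
        p_control=p1,
        p_treatment=p2,
        method="arcsine_corrected" if corrected else "arcsine",
    )


def sample_size(p1: float, p2: float, design: DesignParams) -> SSRResult:
    """Dispatch on ``design.method`` to the matching kernel."""
    if design.method.startswith("normal_"):
        return ssr_normal(p1, p2, design.alpha, design.power,
                          variant=design.method.removeprefix("normal_"))
    return ssr_arcsine(p1, p2, design.alpha, design.power,
                       corrected=design.method == "arcsine_corrected")
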