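"""Association and effect-size sensitivity sweeps.

Because the pairwise association between outcomes is rarely known, the
nine-scenario sweep replaces every pairwise entry with a single
categorical scenario, reruns the greedy selection, and reports the final
composite per scenario.  A second sweep varies one outcome's risk ratio
over a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import AssociationScenario, Panel
from .composite_engine import SelectionTrace, greedy_select
from .util import round_half_up

__all__ = ["SCENARIO_ORDER", "SensitivityRow", "sweep", "effect_sensitivity"]

# weakest joint (lower Fréchet bound) first, strongest last
SCENARIO_ORDER: tuple[AssociationScenario, ...] = (
    AssociationScenario.LOWEST,
    AssociationScenario.STRONG_NEGATIVE,
    AssociationScenario.MODERATE_NEGATIVE,
    AssociationScenario.LOW_NEGATIVE,
    AssociationScenario.NONE,
    AssociationScenario.LOW_POSITIVE,
    AssociationScenario.MODERATE_POSITIVE,
    AssociationScenario.STRONG_POSITIVE,
    AssociationScenario.HIGHEST,
)


@dataclass(frozen=True)
class SensitivityRow:
    """Final greedy composite under one global association scenario.

    ``rate_control_pct``, ``rr`` and ``pct_of_reference`` are rounded
    for display (2 dp, half-up) as in the run tables.
    """

    scenario: str
    components: tuple[str, ...]
    n_components: int
    rate_control_pct: float
    rr: float
    ssr: int
    pct_of_reference: float


def sweep(panel: Panel) -> list[SensitivityRow]:
    """Nine-scenario association sweep, ordered lowest → highest.

    Every pairwise association is overwritten by the scenario (the sweep
    is global, not per-pair), the greedy selection is rerun, and the
    final composite is reported.  The reference for the ``%`` column is
    the relevant endpoint's own sample size, which is scenario-free.
    """
    rows: list[SensitivityRow] = []
    for scenario in SCENARIO_ORDER:
        trace = greedy_select(panel.with_scenario_everywhere(scenario))
        final = trace.final
        ssr_ref = trace.records[0].ssr
        rows.append(
            SensitivityRow(
                scenario=scenario.value,
                components=final.components,
                n_components=len(final.components),
                rate_control_pct=round_half_up(100.0 * final.rate_control, 2),
                rr=round_half_up(final.rr, 2),
                ssr=final.ssr,
                pct_of_reference=round_half_up(100.0 * final.ssr / ssr_ref, 2),
            )
        )
    return rows


def effect_sensitivity(
    panel: Panel, outcome_label: str, rr_grid: list[float]
) -> list[dict]:
    """Rerun the greedy selection with one outcome's risk ratio varied.

    Returns one summary per grid point: the risk ratio tried, the final
    components and sample size, or an ``error`` entry when that risk
    ratio is inadmissible for the outcome's control rate (the sweep
    continues past bad points).
    """
    idx = panel.index_of(outcome_label)
    out: list[dict] = []
    for rr in rr_grid:
        try:
            new_outcome = replace(panel.outcomes[idx], effect_rr=rr)
            outcomes = list(panel.outcomes)
            outcomes[idx] = new_outcome
            trace: SelectionTrace = greedy_select(replace(panel, outcomes=outcomes))
        except ValueError as exc:
            out.append({"rr": rr, "error": str(exc)})
            continue
        out.append(
            {
                "rr": rr,
                "components": trace.final.components,
                "ssr": trace.final.ssr,
                "pct_of_reference": trace.final.pct_of_reference,
            }
        )
    return out
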