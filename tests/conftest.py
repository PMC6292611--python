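"""Shared fixtures: the two worked-example outcome panels.

Both panels come from a published two-arm trial of radial versus
femoral access in acute STEMI; control-arm rates are the femoral-arm
incidences and effects are risk ratios.  They exercise opposite
regimes: the ischemic panel has a common, weakly-affected outcome
(revascularization) while the bleeding panel has rarer outcomes with
strong protective effects.
"""

import pytest
from hypothesis import settings

from cesize import OutcomeSpec, Panel

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def ischemic_panel() -> Panel:
    return Panel(
        outcomes=[
            OutcomeSpec("Death", 0.023, 1.33),
            OutcomeSpec("Infarction", 0.0115, 0.73),
            OutcomeSpec("Stroke", 0.0029, 0.97),
            OutcomeSpec("CABG/Revascularization", 0.092, 0.85),
        ]
    )


@pytest.fixture()
def bleeding_panel() -> Panel:
    return Panel(
        outcomes=[
            OutcomeSpec("GI Bleeding", 0.0144, 0.19),
            OutcomeSpec("Hb drop >= 4 g/dl without overt bleeding", 0.0057, 0.48),
            OutcomeSpec("Hb drop >= 3 g/dl with overt bleeding", 0.0374, 0.22),
            OutcomeSpec("Hematoma > 15 cm", 0.06, 0.09, is_relevant=True),
            OutcomeSpec("Vascular Access Complication", 0.0115, 0.24),
        ]
    )
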