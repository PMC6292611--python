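"""Composite-endpoint arithmetic and the greedy selection algorithm.

A composite endpoint fires when any member outcome occurs, so its event
rate is the probability of the union.  For two components this is exact
inclusion–exclusion given the pairwise joint; when a third component is
considered, the joint between the running composite and the candidate is
rebuilt recursively, imputing the unknown third-order co-occurrence term
as the product of the two pairwise joints.

The greedy search seeds the composite with the relevant endpoint and, at
each step, absorbs the remaining candidate whose inclusion yields the
smallest per-group sample size, stopping when no candidate strictly
improves on the incumbent.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

from .model import Panel, frechet_bounds, resolve_associations, select_re
from .sample_size import sample_size

__all__ = [
    "CompositeState",
    "IterationRecord",
    "SelectionTrace",
    "combine_pair",
    "composite_candidate_joint",
    "greedy_select",
    "exhaustive_search",
    "pair_range_table",
]

_BOUND_TOL = 1e-12


def combine_pair(p_a: float, p_b: float, joint: float) -> float:
    """Union probability p_a + p_b − joint (inclusion–exclusion).

    The joint must lie within the Fréchet bounds of the marginals;
    callers holding user input should correct it first.
    """
    low, up = frechet_bounds(p_a, p_b)
    if not low - _BOUND_TOL <= joint <= up + _BOUND_TOL:
        raise ValueError(
            f"joint {joint!r} outside Fréchet bounds [{low:.6g}, {up:.6g}] "
            f"for marginals ({p_a!r}, {p_b!r})"
        )
    return p_a + p_b - joint


def composite_candidate_joint(j_ac: float, j_bc: float) -> float:
    """Joint of (A∪B) with C from the pairwise joints of A, B with C.

    Inclusion–exclusion gives j_AC + j_BC − π_ABC; the unknown
    third-order term π_ABC is imputed as the product j_AC·j_BC.
    """
    for name, j in (("j_ac", j_ac), ("j_bc", j_bc)):
        if not 0.0 <= j <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]; got {j!r}")
    return j_ac + j_bc - j_ac * j_bc


def _clamp_joint(j: float, p_comp: float, p_cand: float, context: str) -> float:
    """Clamp a recursed joint into the Fréchet bounds, warning if it moved."""
    low, up = frechet_bounds(p_comp, p_cand)
    if j < low - _BOUND_TOL or j > up + _BOUND_TOL:
        warnings.warn(
            f"recursed joint {j:.6g} for {context} clamped into Fréchet "
            f"bounds [{low:.6g}, {up:.6g}]",
            UserWarning,
            stacklevel=3,
        )
    return min(max(j, low), up)


@dataclass
class CompositeState:
    """A provisional composite: members, per-arm rates, per-arm joints
    with every remaining candidate (keyed by candidate index)."""

    member_indices: list[int]
    rate_control: float
    rate_treatment: float
    joint_control: dict[int, float]
    joint_treatment: dict[int, float]


@dataclass(frozen=True)
class IterationRecord:
    """One greedy step: the composite after adding ``added_label``."""

    step: int
    added_label: str
    components: tuple[str, ...]
    rate_control: float
    rate_treatment: float
    rr: float
    ssr: int
    pct_of_reference: float


@dataclass(frozen=True)
class SelectionTrace:
    records: tuple[IterationRecord, ...]
    stopped_reason: str  # "all_included" or "no_improvement"

    @property
    def final(self) -> IterationRecord:
        return self.records[-1]


PairJoints = dict[tuple[int, int], float]


def _pair(d: PairJoints, i: int, j: int) -> float:
    return d[(i, j) if i < j else (j, i)]


def _initial_state(panel: Panel, re_idx: int,
                   jc: PairJoints, jt: PairJoints) -> CompositeState:
    re = panel.outcomes[re_idx]
    others = [i for i in range(panel.k) if i != re_idx]
    return CompositeState(
        member_indices=[re_idx],
        rate_control=re.control_rate,
        rate_treatment=re.treatment_rate,
        joint_control={i: _pair(jc, re_idx, i) for i in others},
        joint_treatment={i: _pair(jt, re_idx, i) for i in others},
    )


def _extend(state: CompositeState, cand: int, panel: Panel,
            jc_pairs: PairJoints, jt_pairs: PairJoints) -> CompositeState:
    """Absorb candidate ``cand`` into the composite and recurse the joints."""
    pair = _pair
    o = panel.outcomes[cand]
    new_rc = combine_pair(state.rate_control, o.control_rate, state.joint_control[cand])
    new_rt = combine_pair(state.rate_treatment, o.treatment_rate, state.joint_treatment[cand])
    new_jc: dict[int, float] = {}
    new_jt: dict[int, float] = {}
    for other in state.joint_control:
        if other == cand:
            continue
        oo = panel.outcomes[other]
        ctx = f"(composite, {oo.label!r})"
        j = composite_candidate_joint(state.joint_control[other], pair(jc_pairs, cand, other))
        new_jc[other] = _clamp_joint(j, new_rc, oo.control_rate, ctx + " control arm")
        j = composite_candidate_joint(state.joint_treatment[other], pair(jt_pairs, cand, other))
        new_jt[other] = _clamp_joint(j, new_rt, oo.treatment_rate, ctx + " treatment arm")
    return CompositeState(
        member_indices=state.member_indices + [cand],
        rate_control=new_rc,
        rate_treatment=new_rt,
        joint_control=new_jc,
        joint_treatment=new_jt,
    )


def _degenerate(p1: float, p2: float) -> bool:
    # identical rates up to accumulated roundoff: no effect to detect
    return math.isclose(p1, p2, rel_tol=1e-12, abs_tol=1e-15)


def _state_ssr(state: CompositeState, panel: Panel) -> int | None:
    """Per-group sample size of the composite, or None when degenerate."""
    if _degenerate(state.rate_control, state.rate_treatment):
        return None
    return sample_size(state.rate_control, state.rate_treatment, panel.design).n_per_group


def _record(state: CompositeState, panel: Panel, step: int, added: str,
            ssr: int, ssr_ref: int) -> IterationRecord:
    return IterationRecord(
        step=step,
        added_label=added,
        components=tuple(panel.outcomes[i].label for i in state.member_indices),
        rate_control=state.rate_control,
        rate_treatment=state.rate_treatment,
        rr=state.rate_treatment / state.rate_control,
        ssr=ssr,
        pct_of_reference=round(100.0 * ssr / ssr_ref, 2),
    )


def greedy_select(panel: Panel) -> SelectionTrace:
    """Forward selection of the composite minimising the sample size.

    Starts from the relevant endpoint alone; each step provisionally
    combines every remaining candidate with the incumbent composite,
    keeps the one with the smallest per-group sample size if it is
    strictly below the incumbent's (ties break to the lowest index),
    and stops otherwise.
    """
    re_idx = select_re(panel)
    jc, jt = resolve_associations(panel)
    state = _initial_state(panel, re_idx, jc, jt)
    ssr_ref = _state_ssr(state, panel)
    if ssr_ref is None:
        raise ValueError(
            f"relevant endpoint {panel.outcomes[re_idx].label!r} has zero "
            "effect; its sample size is undefined"
        )
    records = [_record(state, panel, 1, panel.outcomes[re_idx].label, ssr_ref, ssr_ref)]
    incumbent = ssr_ref
    stopped = "all_included"
    while state.joint_control:
        best: tuple[int, int, CompositeState] | None = None  # (ssr, cand, state)
        for cand in sorted(state.joint_control):
            trial = _extend(state, cand, panel, jc, jt)
            n = _state_ssr(trial, panel)
            if n is None:
                continue
            if best is None or n < best[0]:
                best = (n, cand, trial)
        if best is None or best[0] >= incumbent:
            stopped = "no_improvement"
            break
        incumbent, cand, state = best
        records.append(
            _record(state, panel, len(records) + 1,
                    panel.outcomes[cand].label, incumbent, ssr_ref)
        )
    return SelectionTrace(records=tuple(records), stopped_reason=stopped)


def exhaustive_search(panel: Panel) -> tuple[tuple[int, ...], int]:
    """Best subset containing the relevant endpoint, by brute force.

    The joint recursion makes a composite's rate depend on the order its
    members were absorbed, so every insertion order (relevant endpoint
    first, as in the greedy search) is tried for every subset and the
    minimum kept.  This makes the result a true lower bound on anything
    the greedy search can reach under identical arithmetic.  Ties prefer
    the smaller subset, then lexicographic order.
    """
    re_idx = select_re(panel)
    jc, jt = resolve_associations(panel)
    others = [i for i in range(panel.k) if i != re_idx]
    best_subset: tuple[int, ...] | None = None
    best_n: int | None = None
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            members = tuple(sorted([re_idx, *extra]))
            subset_n: int | None = None
            for order in itertools.permutations(extra):
                state = _initial_state(panel, re_idx, jc, jt)
                for m in order:
                    state = _extend(state, m, panel, jc, jt)
                n = _state_ssr(state, panel)
                if n is not None and (subset_n is None or n < subset_n):
                    subset_n = n
            if subset_n is None:
                continue
            key = (subset_n, len(members), members)
            if best_n is None or key < (best_n, len(best_subset), best_subset):
                best_subset, best_n = members, subset_n
    assert best_subset is not None and best_n is not None
    return best_subset, best_n


def pair_range_table(panel: Panel) -> dict[str, tuple[int | None, int | None]]:
    """Per-candidate sample sizes at the two extremes of association.

    For each additional endpoint, the two-component composite with the
    relevant endpoint is evaluated with the per-arm joint set to the
    lower and to the upper Fréchet bound; entries where the extreme
    composite has identical rates in both arms are reported as None.
    """
    re_idx = select_re(panel)
    re = panel.outcomes[re_idx]
    out: dict[str, tuple[int | None, int | None]] = {}
    for i, o in enumerate(panel.outcomes):
        if i == re_idx:
            continue
        ssrs: list[int | None] = []
        for which in (0, 1):  # lower then upper bound
            p1 = combine_pair(re.control_rate, o.control_rate,
                              frechet_bounds(re.control_rate, o.control_rate)[which])
            p2 = combine_pair(re.treatment_rate, o.treatment_rate,
                              frechet_bounds(re.treatment_rate, o.treatment_rate)[which])
            if _degenerate(p1, p2):
                ssrs.append(None)
            else:
                ssrs.append(sample_size(p1, p2, panel.design).n_per_group)
        out[o.label] = (ssrs[0], ssrs[1])
    return out
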