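"""Thermodynamic-cycle assembly, uncertainty propagation and classification.

Relative stabilities come from a folding cycle: mutating WT -> mutant in the
unfolded reference peptide (leg dG_1) and in a folded state (leg dG_4 for
the autoinhibited/inactive conformation, dG_7 for the active one) gives

    ddG_state = dG_unfolded - dG_folded,

so ddG_state < 0 means the mutant is less stable than WT in that state.
A second cycle links the two folded states: the relative activation free
energy is

    ddG_activation = ddG_active - ddG_inactive  (= dG_4 - dG_7),

positive when activation is more favorable for the mutant than for WT.
Standard errors combine in quadrature (legs are estimated independently).

Classification follows the two-dimensional (ddG_inactive, ddG_active) plane:
oncogenic/activating mutations destabilize the inactive state and/or
overstabilize the active state; loss-of-function (piebald-like) mutations
destabilize the active state.  Juxtamembrane-domain mutants, whose active
state lacks the folded JM segment, are scored with ddG_active assumed 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .estimators import FreeEnergyEstimate

__all__ = [
    "ValueSE",
    "LegResult",
    "MutationCycle",
    "Classification",
    "LEG_TAGS",
    "state_ddg",
    "activation_ddg",
    "assemble_cycle",
    "classify_mutation",
    "propagate_quadrature",
    "DEFAULT_THRESHOLD_KJ",
]

#: Default decision threshold (kJ/mol): the typical error scale of
#: computational free-energy estimates, below which effects are "marginal".
DEFAULT_THRESHOLD_KJ = 4.0

LegTag = Literal["unfolded", "folded_inactive", "folded_active"]
LEG_TAGS: tuple[str, ...] = ("unfolded", "folded_inactive", "folded_active")


@dataclass(frozen=True)
class ValueSE:
    """An energy in kJ/mol with its standard error."""

    value: float
    se: float = 0.0

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be >= 0")

    def __sub__(self, other: "ValueSE") -> "ValueSE":
        return ValueSE(
            self.value - other.value, propagate_quadrature([self.se, other.se])
        )

    def round(self, ndigits: int = 1) -> "ValueSE":
        return ValueSE(round(self.value, ndigits), round(self.se, ndigits))


@dataclass(frozen=True)
class LegResult:
    """One alchemical leg of the cycle for one mutation."""

    mutation: str
    leg: LegTag
    estimate: FreeEnergyEstimate

    def __post_init__(self):
        if self.leg not in LEG_TAGS:
            raise ValueError(f"leg must be one of {LEG_TAGS}, got {self.leg!r}")


@dataclass(frozen=True)
class MutationCycle:
    """Per-state ddG values for one mutation, plus the activation ddG.

    ``ddg_active`` (and hence ``ddg_activation``) may be absent for mutants
    whose active state was not simulated (JM-domain mutations).  When both
    states are present the identity
    ``ddg_activation = ddg_active - ddg_inactive`` is enforced.
    """

    mutation: str
    ddg_inactive: ValueSE
    ddg_active: ValueSE | None = None
    ddg_activation: ValueSE | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.ddg_active is not None:
            expected = activation_ddg(self.ddg_inactive, self.ddg_active)
            if self.ddg_activation is None:
                object.__setattr__(self, "ddg_activation", expected)
            elif abs(self.ddg_activation.value - expected.value) > 1e-9:
                raise ValueError(
                    f"{self.mutation}: ddg_activation "
                    f"{self.ddg_activation.value} inconsistent with "
                    f"ddg_active - ddg_inactive = {expected.value}"
                )
        elif self.ddg_activation is not None:
            raise ValueError("ddg_activation given without ddg_active")


@dataclass(frozen=True)
class Classification:
    """Activating/deactivating call for one mutation with its rationale."""

    mutation: str
    label: Literal["activating", "deactivating", "neutral", "indeterminate"]
    rationale: str
    threshold: float


def propagate_quadrature(ses: Sequence[float] | Iterable[float]) -> float:
    """Combine independent standard errors: sqrt(sum of squares)."""
    total = 0.0
    for se in ses:
        if se < 0:
            raise ValueError("standard errors must be >= 0")
        total += se * se
    return math.sqrt(total)


def state_ddg(unfolded: LegResult, folded: LegResult) -> ValueSE:
    """Relative stability of the mutant in one folded state.

    ddG_state = dG(unfolded leg) - dG(folded leg); negative means the mutant
    is thermodynamically less stable than WT in that state.  Both legs must
    belong to the same mutation; the folded leg must be folded_inactive or
    folded_active, the other leg unfolded.
    """
    if unfolded.mutation != folded.mutation:
        raise ValueError(
            f"leg mutation mismatch: {unfolded.mutation!r} vs {folded.mutation!r}"
        )
    if unfolded.leg != "unfolded":
        raise ValueError(f"first leg must be 'unfolded', got {unfolded.leg!r}")
    if folded.leg not in ("folded_inactive", "folded_active"):
        raise ValueError(f"second leg must be a folded leg, got {folded.leg!r}")
    return ValueSE(
        unfolded.estimate.dg - folded.estimate.dg,
        propagate_quadrature(
            [unfolded.estimate.uncertainty, folded.estimate.uncertainty]
        ),
    )


def activation_ddg(ddg_inactive: ValueSE, ddg_active: ValueSE) -> ValueSE:
    """Relative activation free energy: ddG_active - ddG_inactive.

    Equivalently dG(folded-inactive leg) - dG(folded-active leg): the
    unfolded leg cancels.  Positive values mean the inactive -> active
    transition is more favorable for the mutant than for WT.
    """
    return ddg_active - ddg_inactive


def assemble_cycle(
    mutation: str, legs: Iterable[LegResult], notes: Sequence[str] = ()
) -> MutationCycle:
    """Build a MutationCycle from this mutation's leg estimates.

    Requires the unfolded and folded_inactive legs; folded_active is
    optional (JM-domain mutants).
    """
    by_tag = {}
    for leg in legs:
        if leg.mutation != mutation:
            raise ValueError(f"leg for {leg.mutation!r} passed to {mutation!r}")
        if leg.leg in by_tag:
            raise ValueError(f"duplicate leg {leg.leg!r} for {mutation!r}")
        by_tag[leg.leg] = leg
    if "unfolded" not in by_tag or "folded_inactive" not in by_tag:
        raise ValueError(
            f"{mutation}: need unfolded and folded_inactive legs, have "
            f"{sorted(by_tag)}"
        )
    ddg_inactive = state_ddg(by_tag["unfolded"], by_tag["folded_inactive"])
    ddg_active = (
        state_ddg(by_tag["unfolded"], by_tag["folded_active"])
        if "folded_active" in by_tag
        else None
    )
    return MutationCycle(
        mutation=mutation,
        ddg_inactive=ddg_inactive,
        ddg_active=ddg_active,
        notes=tuple(notes),
    )


def classify_mutation(
    cycle: MutationCycle,
    threshold: float = DEFAULT_THRESHOLD_KJ,
    assume_active_zero: bool = True,
) -> Classification:
    """Two-dimensional stability classification of a mutation.

    Rule, applied in order on (ddg_inactive, ddg_active) with threshold tau:

    1. ddg_active < -tau        -> deactivating (active state destabilized)
    2. ddg_inactive < -tau or
       ddg_active > +tau        -> activating
    3. otherwise                -> neutral

    A missing ddg_active is taken as 0 +/- 0 when ``assume_active_zero``
    (the JM-unfolded-in-active-state assumption); otherwise it is an error.
    The call degrades to 'indeterminate' when the ddG that decided it is
    smaller in magnitude than its own standard error.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    inact = cycle.ddg_inactive
    if cycle.ddg_active is not None:
        act = cycle.ddg_active
        act_note = ""
    elif assume_active_zero:
        act = ValueSE(0.0, 0.0)
        act_note = " (ddg_active assumed 0: JM domain unfolded in active state)"
    else:
        raise ValueError(f"{cycle.mutation}: ddg_active missing")

    if act.value < -threshold:
        label, decider, why = (
            "deactivating",
            act,
            f"ddg_active = {act.value:g} < -{threshold:g}",
        )
    elif inact.value < -threshold:
        label, decider, why = (
            "activating",
            inact,
            f"ddg_inactive = {inact.value:g} < -{threshold:g}",
        )
    elif act.value > threshold:
        label, decider, why = (
            "activating",
            act,
            f"ddg_active = {act.value:g} > {threshold:g}",
        )
    else:
        label, decider, why = (
            "neutral",
            None,
            f"|ddg| <= {threshold:g} in both states",
        )
    if decider is not None and abs(decider.value) < decider.se:
        label, why = "indeterminate", (
            f"{why}, but |value| < its SE {decider.se:g}"
        )
    return Classification(
        mutation=cycle.mutation,
        label=label,
        rationale=why + act_note,
        threshold=threshold,
    )
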