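"""Two-step mediation MR: product-of-coefficients decomposition.

For a protein whose total effect on an outcome (beta3, from the
primary MR) may act through a risk factor, the indirect effect is the
product of the protein-to-mediator effect (beta1, Step-2 MR) and the
mediator-to-outcome effect (beta2, Step-1 MR).  Uncertainty is
propagated by the first-order Delta method assuming the three
estimates come from non-overlapping samples (no covariance terms).
A reverse MR of the mediator on the protein flags bidirectional
relationships that would undermine the mediation model; flagged
results are annotated, not removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import Z95, MREstimate


@dataclass
class MediationInput:
    """The three effect estimates feeding one mediation decomposition.

    beta1/se1: exposure -> mediator (Step-2 MR);
    beta2/se2: mediator -> outcome (Step-1 MR);
    beta3/se3: total exposure -> outcome (primary MR).
    """

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta3: float
    se3: float

    def __post_init__(self):
        if min(self.se1, self.se2, self.se3) <= 0:
            raise ValueError("all standard errors must be > 0")
        if not np.isfinite([self.beta1, self.beta2, self.beta3]).all():
            raise ValueError("all effects must be finite")


@dataclass
class MediationResult:
    input: MediationInput
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    direct: float
    proportion: float | None
    proportion_ci: tuple[float, float] | None
    valid: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def proportion_pct(self) -> float | None:
        return None if self.proportion is None else 100 * self.proportion


def indirect_effect(inp: MediationInput) -> tuple[float, float, tuple[float, float]]:
    """Product-method indirect effect with Delta-method uncertainty.

    ``indirect = beta1 * beta2``;
    ``se = sqrt(beta1² se2² + beta2² se1²)`` (independent samples,
    first order); 95% CI at +/- 1.96 SE.
    """
    indirect = inp.beta1 * inp.beta2
    se = float(np.sqrt(inp.beta1**2 * inp.se2**2 + inp.beta2**2 * inp.se1**2))
    ci = (indirect - Z95 * se, indirect + Z95 * se)
    return indirect, se, ci


def proportion_mediated(inp: MediationInput, indirect: float,
                        indirect_se: float | None = None
                        ) -> tuple[float, tuple[float, float], list[str]]:
    """Share of the total effect carried by the mediator path.

    ``proportion = indirect / beta3``; the CI is first-order Delta on
    the ratio with independent numerator and denominator.  Notes flag
    inconsistent mediation (opposite signs, or |proportion| > 1).
    """
    if inp.beta3 == 0:
        raise ZeroDivisionError("proportion mediated undefined for beta3 = 0")
    if indirect_se is None:
        indirect_se = indirect_effect(inp)[1]
    prop = indirect / inp.beta3
    # var(a/b) ~ (1/b^2) var(a) + (a^2/b^4) var(b)
    var = (indirect_se**2 / inp.beta3**2
           + indirect**2 * inp.se3**2 / inp.beta3**4)
    se = float(np.sqrt(var))
    ci = (prop - Z95 * se, prop + Z95 * se)
    notes = []
    if indirect != 0 and np.sign(indirect) != np.sign(inp.beta3):
        notes.append("inconsistent mediation: indirect and total effects "
                     "have opposite signs")
    if abs(prop) > 1:
        notes.append("inconsistent mediation: |proportion| exceeds 1")
    return prop, ci, notes


def check_bidirectionality(mediator_to_exposure: MREstimate,
                           alpha: float = 4.99e-5) -> bool:
    """Reverse-MR validity check: the mediation model is flagged
    (returns False) when the mediator shows a significant causal effect
    back on the exposure at level ``alpha`` (strict inequality)."""
    return not (mediator_to_exposure.pval < alpha)


def mediate(inp: MediationInput,
            reverse_estimate: MREstimate | None = None,
            reverse_alpha: float = 4.99e-5) -> MediationResult:
    """Full decomposition: indirect, direct (= total - indirect),
    proportion mediated, and the reverse-MR validity flag."""
    indirect, ind_se, ind_ci = indirect_effect(inp)
    direct = inp.beta3 - indirect
    notes = []
    if inp.beta3 != 0:
        prop, prop_ci, prop_notes = proportion_mediated(inp, indirect, ind_se)
        notes.extend(prop_notes)
    else:
        prop, prop_ci = None, None
        notes.append("total effect is zero: proportion undefined")
    valid = True
    if reverse_estimate is not None:
        valid = check_bidirectionality(reverse_estimate, reverse_alpha)
        if not valid:
            notes.append(
                f"reverse MR significant (p={reverse_estimate.pval:.3g} < "
                f"{reverse_alpha:.3g}): possible bidirectionality")
    return MediationResult(
        input=inp, indirect=indirect, indirect_se=ind_se, indirect_ci=ind_ci,
        direct=direct, proportion=prop, proportion_ci=prop_ci,
        valid=valid, notes=notes,
    )
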