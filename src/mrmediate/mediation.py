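"""Two-step MR mediation via the product of coefficients.

The design estimates three causal paths from three independent GWAS:

* ``beta0`` — total effect, exposure -> outcome (initial MR);
* ``beta1`` — step one, exposure -> mediator;
* ``beta2`` — step two, mediator -> outcome.

The indirect (mediated) effect is ``beta1 * beta2`` with the first-order
delta-method standard error ``sqrt(beta1²·se2² + beta2²·se1²)`` (the two
steps come from non-overlapping samples, so their covariance is taken as
zero).  On a binary outcome the effects are log odds ratios, so the
indirect effect exponentiates to an odds-ratio scale.

A triple is classified as

* ``partial_mediation`` — beta0, beta1 and beta2 all significant;
* ``indirect_only``     — beta0 not significant, beta1, beta2 and the
  quantified indirect effect all significant;
* ``no_mediation``      — otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy import stats

from .errors import DataError, DomainError
from .estimators import Z95, MREstimate, ivw, _normal_p
from .harmonize import harmonize
from .instruments import (
    DEFAULT_CLUMP_R2,
    DEFAULT_CLUMP_WINDOW_BP,
    DEFAULT_F_MIN,
    DEFAULT_P_THRESHOLD,
    PairwiseLD,
    select_instruments,
)
from .io import as_frame, records_to_frame

logger = logging.getLogger(__name__)

PARTIAL_MEDIATION = "partial_mediation"
INDIRECT_ONLY = "indirect_only"
NO_MEDIATION = "no_mediation"


@dataclass
class IndirectEffect:
    """Product-of-coefficients indirect effect with delta-method CI."""

    beta: float
    se: float
    or_point: float
    or_lci: float
    or_uci: float
    pval: float


def indirect_effect(
    beta1: float, se1: float, beta2: float, se2: float, alpha: float = 0.05
) -> IndirectEffect:
    """Indirect effect ``beta1*beta2`` with delta-method uncertainty.

    The confidence level is ``1 - alpha`` (normal quantile); the p-value is
    a two-sided normal test of the indirect effect against zero.
    """
    if se1 <= 0 or se2 <= 0:
        raise DomainError(f"indirect_effect: standard errors must be positive, got {se1}, {se2}")
    z = Z95 if alpha == 0.05 else float(stats.norm.isf(alpha / 2))
    beta = beta1 * beta2
    se = math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    return IndirectEffect(
        beta=beta,
        se=se,
        or_point=math.exp(beta),
        or_lci=math.exp(beta - z * se),
        or_uci=math.exp(beta + z * se),
        pval=_normal_p(beta, se),
    )


def classify(
    p0: float, p1: float, p2: float, p_indirect: float, alpha: float = 0.05
) -> str:
    """Mediation case from the four path p-values (see module docstring)."""
    for name, p in (("p0", p0), ("p1", p1), ("p2", p2), ("p_indirect", p_indirect)):
        if not 0.0 < p <= 1.0:
            raise DomainError(f"classify: {name} must lie in (0, 1], got {p}")
    if p0 < alpha and p1 < alpha and p2 < alpha:
        return PARTIAL_MEDIATION
    if p0 >= alpha and p1 < alpha and p2 < alpha and p_indirect < alpha:
        return INDIRECT_ONLY
    return NO_MEDIATION


@dataclass
class MrSettings:
    """Knobs shared by the MR stages of a two-step analysis."""

    p_threshold: float = DEFAULT_P_THRESHOLD
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW_BP
    f_min: float = DEFAULT_F_MIN
    palindromic_eaf_window: float = 0.08
    effects_model: str = "random"
    n_boot: int = 1000
    seed: int = 0
    alpha: float = 0.05


@dataclass
class MediationResult:
    """One exposure -> mediator -> outcome triple's mediation analysis."""

    exposure: str
    mediator: str
    outcome: str
    beta0: float
    p0: float
    beta1: float
    se1: float
    p1: float
    beta2: float
    se2: float
    p2: float
    indirect_beta: float
    indirect_se: float
    or_point: float
    or_lci: float
    or_uci: float
    indirect_pval: float
    case: str
    audit: dict[str, MREstimate] = field(default_factory=dict)


def _mr_arm(exposure_stats, outcome_stats, settings, ld, exposure_name, outcome_name,
            exclude_snps=()) -> MREstimate:
    iset = select_instruments(
        exposure_stats,
        exposure_name=exposure_name,
        ld_matrix=ld,
        p_threshold=settings.p_threshold,
        clump_r2=settings.clump_r2,
        clump_window_bp=settings.clump_window_bp,
        f_min=settings.f_min,
    )
    records = [r for r in iset.records if r.snp_id not in set(exclude_snps)]
    if not records:
        raise DataError(
            f"{exposure_name}->{outcome_name}: no instruments left after mediator-overlap exclusion"
        )
    h = harmonize(
        records_to_frame(records),
        outcome_stats,
        palindromic_eaf_window=settings.palindromic_eaf_window,
        exposure_name=exposure_name,
        outcome_name=outcome_name,
    )
    return ivw(h, effects_model=settings.effects_model)


def run_two_step(
    exposure_stats,
    mediator_stats,
    outcome_stats,
    settings: MrSettings | None = None,
    ld: PairwiseLD | None = None,
    names: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
) -> MediationResult:
    """Full two-step MR mediation for one (exposure, mediator, outcome) triple.

    Runs three IVW arms: exposure->mediator (beta1), exposure->outcome
    (beta0, with any exposure instrument that also passes the instrument
    p-threshold for the mediator excluded, so the total-effect instruments
    are independent of the mediator), and mediator->outcome (beta2); then
    forms the product-of-coefficients indirect effect and classifies the
    triple.  The three intermediate estimates are retained in ``.audit``.
    """
    settings = settings or MrSettings()
    exp_name, med_name, out_name = names
    mediator_frame = as_frame(mediator_stats)
    mediator_hits = set(
        mediator_frame.loc[mediator_frame["pval"] < settings.p_threshold, "snp_id"].astype(str)
    )

    est1 = _mr_arm(exposure_stats, mediator_stats, settings, ld, exp_name, med_name)
    est0 = _mr_arm(
        exposure_stats, outcome_stats, settings, ld, exp_name, out_name,
        exclude_snps=mediator_hits,
    )
    est2 = _mr_arm(mediator_stats, outcome_stats, settings, ld, med_name, out_name)

    ind = indirect_effect(est1.beta, est1.se, est2.beta, est2.se, alpha=settings.alpha)
    case = classify(est0.pval, est1.pval, est2.pval, ind.pval, alpha=settings.alpha)
    return MediationResult(
        exposure=exp_name,
        mediator=med_name,
        outcome=out_name,
        beta0=est0.beta,
        p0=est0.pval,
        beta1=est1.beta,
        se1=est1.se,
        p1=est1.pval,
        beta2=est2.beta,
        se2=est2.se,
        p2=est2.pval,
        indirect_beta=ind.beta,
        indirect_se=ind.se,
        or_point=ind.or_point,
        or_lci=ind.or_lci,
        or_uci=ind.or_uci,
        indirect_pval=ind.pval,
        case=case,
        audit={"total": est0, "step1": est1, "step2": est2},
    )


def mediation_from_estimates(
    est0: MREstimate, est1: MREstimate, est2: MREstimate, alpha: float = 0.05
) -> MediationResult:
    """Combine three pre-computed MR estimates into a mediation result.

    Useful when the three arms were estimated elsewhere (e.g. published
    IVW tables with standard errors recovered from their CIs or p-values).
    """
    ind = indirect_effect(est1.beta, est1.se, est2.beta, est2.se, alpha=alpha)
    case = classify(est0.pval, est1.pval, est2.pval, ind.pval, alpha=alpha)
    return MediationResult(
        exposure=est1.exposure,
        mediator=est2.exposure,
        outcome=est2.outcome,
        beta0=est0.beta,
        p0=est0.pval,
        beta1=est1.beta,
        se1=est1.se,
        p1=est1.pval,
        beta2=est2.beta,
        se2=est2.se,
        p2=est2.pval,
        indirect_beta=ind.beta,
        indirect_se=ind.se,
        or_point=ind.or_point,
        or_lci=ind.or_lci,
        or_uci=ind.or_uci,
        indirect_pval=ind.pval,
        case=case,
    )
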