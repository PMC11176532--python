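"""Two-step MR mediation: mediator screening and proportion mediated.

A candidate mediator M of an exposure X → outcome Y effect must pass four
criteria: (1) M has a causal effect on Y in UVMR; (2) M has a direct effect
on Y controlled for X in MVMR; (3) X is causally associated with M but not
vice versa; (4) the X→M and M→Y effects point the same way as the total
effect. For a passing mediator the indirect effect is the product of
coefficients a·b — a the X→M effect from UVMR, b the M→Y direct effect
from MVMR — with a delta-method SE, and the proportion mediated is
indirect/total with the total treated as fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, MultivariableIVW
from .exceptions import EstimationError
from .instruments import harmonize_multi
from .pipeline import AnalysisConfig, PairResult, prepare_instruments, run_pair

Z95 = stats.norm.ppf(0.975)

CRITERIA = ("C1_mediator_on_outcome", "C2_direct_effect_mvmr",
            "C3_exposure_on_mediator_not_reverse", "C4_sign_consistency")


@dataclass(frozen=True)
class Effect:
    """A point estimate with its standard error (and optional p-value)."""

    beta: float
    se: float
    pval: float | None = None

    @classmethod
    def from_estimate(cls, est: MREstimate) -> "Effect":
        return cls(est.beta, est.se, est.pval)


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition for one mediator."""

    exposure: str
    mediator: str
    outcome: str
    a: Effect               # exposure → mediator (UVMR)
    b: Effect               # mediator → outcome direct, controlled (MVMR)
    total: Effect           # exposure → outcome (UVMR, primary method)
    indirect: float
    indirect_se: float
    proportion: float       # percent
    proportion_ci_low: float
    proportion_ci_high: float
    criteria: dict[str, bool | None] = field(default_factory=dict)


def indirect_effect(a: Effect, b: Effect) -> tuple[float, float]:
    """Product of coefficients a·b with the delta-method SE
    √(a²·SE_b² + b²·SE_a²)."""
    indirect = a.beta * b.beta
    se = np.sqrt(a.beta ** 2 * b.se ** 2 + b.beta ** 2 * a.se ** 2)
    return float(indirect), float(se)


def mediation_proportion(indirect: float, indirect_se: float, total: Effect,
                         floor_at_zero: bool = True
                         ) -> tuple[float, float, float]:
    """Proportion mediated, in percent, with a 95% CI.

    The CI propagates only the indirect effect's uncertainty, treating the
    total effect as fixed; endpoints are ordered. When the point estimate
    is positive but the lower endpoint is negative, the lower endpoint is
    floored at 0% for reporting.
    """
    if total.beta == 0:
        raise EstimationError("proportion undefined: total effect is 0")
    prop = indirect / total.beta
    lo = (indirect - Z95 * indirect_se) / total.beta
    hi = (indirect + Z95 * indirect_se) / total.beta
    lo, hi = min(lo, hi), max(lo, hi)
    if floor_at_zero and prop > 0 and lo < 0:
        lo = 0.0
    return 100.0 * prop, 100.0 * lo, 100.0 * hi


def _uvmr(exposure_table, outcome_table, ld, confounders, config
          ) -> PairResult:
    return run_pair(exposure_table, outcome_table, ld, confounders, config)


def _mvmr_direct(exposure_table, mediator_table, outcome_table, ld,
                 confounders, config):
    """Direct effects of [exposure, mediator] on the outcome (MVMR).

    Instruments are the union of each trait's own selection, harmonized
    jointly, complete-case.
    """
    sets = {}
    for table in (exposure_table, mediator_table):
        insts, _, flags, _ = prepare_instruments(table, ld, confounders,
                                                 config)
        if "outcome_only" in flags or not insts:
            raise EstimationError(
                f"no usable instruments for {table.trait_name!r}")
        sets[table.trait_name] = insts
    mh = harmonize_multi(
        sets,
        {exposure_table.trait_name: exposure_table,
         mediator_table.trait_name: mediator_table},
        outcome_table)
    return MultivariableIVW(mh).fit()


def screen_mediators(exposure_table, outcome_table, candidates: dict,
                     ld, confounders=None,
                     config: AnalysisConfig | None = None,
                     alpha: float = 0.05):
    """Apply the four-criterion mediator screen to candidate traits.

    ``candidates`` maps mediator name → SummaryTable. Criteria are
    evaluated in order and short-circuit at the first failure; the audit
    frame records a row per candidate with each criterion's verdict (None
    where not evaluated) and the failing criterion. Returns
    (selected_names, audit_frame).

    The UVMR criteria (C1, C3) are judged on the IVW p-value — the study's
    primary method — rather than the per-pair pleiotropy-switching rule:
    the screen needs a uniformly calibrated test across many candidate
    pairs, and switching estimators per pair inflates its error rates.
    The total effect reported downstream still follows the pleiotropy
    rule.
    """
    config = config or AnalysisConfig()
    total_res = _uvmr(exposure_table, outcome_table, ld, confounders, config)
    total_est = total_res.primary_estimate
    selected: list[str] = []
    audit_rows = []
    for name, med_table in candidates.items():
        verdicts: dict[str, bool | None] = {c: None for c in CRITERIA}
        fail = None
        try:
            # C1: mediator → outcome in UVMR
            r1 = _uvmr(med_table, outcome_table, ld, confounders, config)
            if "outcome_only" in r1.eligibility_flags or not r1.estimates:
                raise EstimationError("no_instruments")
            verdicts[CRITERIA[0]] = r1.estimates["ivw"].pval < alpha
            if not verdicts[CRITERIA[0]]:
                fail = CRITERIA[0]
            b_eff = None
            if fail is None:
                # C2: direct effect controlled for the exposure in MVMR
                mv = _mvmr_direct(exposure_table, med_table, outcome_table,
                                  ld, confounders, config)
                b_est = mv.estimate_for(med_table.trait_name)
                b_eff = Effect.from_estimate(b_est)
                verdicts[CRITERIA[1]] = b_est.pval < alpha
                if not verdicts[CRITERIA[1]]:
                    fail = CRITERIA[1]
            if fail is None:
                # C3: exposure → mediator, but not mediator → exposure
                fwd = _uvmr(exposure_table, med_table, ld, confounders,
                            config)
                rev = _uvmr(med_table, exposure_table, ld, confounders,
                            config)
                fwd_ivw = fwd.estimates.get("ivw")
                rev_ivw = rev.estimates.get("ivw")
                fwd_ok = fwd_ivw is not None and fwd_ivw.pval < alpha
                rev_null = rev_ivw is None or rev_ivw.pval >= alpha
                verdicts[CRITERIA[2]] = fwd_ok and rev_null
                if not verdicts[CRITERIA[2]]:
                    fail = CRITERIA[2]
            if fail is None:
                # C4: indirect effect points the same way as the total
                a_eff = Effect.from_estimate(fwd_ivw)
                same = (np.sign(a_eff.beta) * np.sign(b_eff.beta)
                        == np.sign(total_est.beta))
                verdicts[CRITERIA[3]] = bool(same)
                if not same:
                    fail = CRITERIA[3]
        except EstimationError as exc:
            fail = f"error:{exc}"
        if fail is None:
            selected.append(name)
        audit_rows.append({"mediator": name, **verdicts,
                           "failed_at": fail or "-",
                           "selected": fail is None})
    audit = pd.DataFrame(audit_rows)
    return selected, audit


def mediation_analysis(exposure_table, mediator_table, outcome_table, ld,
                       confounders=None,
                       config: AnalysisConfig | None = None,
                       criteria: dict | None = None) -> MediationResult:
    """Estimate the mediation proportion for one mediator.

    a (exposure → mediator) and the total effect come from UVMR with the
    pipeline's primary-method rule; b (mediator → outcome direct) comes
    from the MVMR controlled for the exposure.
    """
    config = config or AnalysisConfig()
    a_res = _uvmr(exposure_table, mediator_table, ld, confounders, config)
    if a_res.primary_estimate is None:
        raise EstimationError(
            f"no usable exposure→mediator estimate for "
            f"{mediator_table.trait_name!r}")
    a = Effect.from_estimate(a_res.primary_estimate)
    mv = _mvmr_direct(exposure_table, mediator_table, outcome_table, ld,
                      confounders, config)
    b = Effect.from_estimate(mv.estimate_for(mediator_table.trait_name))
    total_res = _uvmr(exposure_table, outcome_table, ld, confounders, config)
    total = Effect.from_estimate(total_res.primary_estimate)
    indirect, indirect_se = indirect_effect(a, b)
    prop, lo, hi = mediation_proportion(indirect, indirect_se, total)
    return MediationResult(
        exposure=exposure_table.trait_name,
        mediator=mediator_table.trait_name,
        outcome=outcome_table.trait_name,
        a=a, b=b, total=total, indirect=indirect, indirect_se=indirect_se,
        proportion=prop, proportion_ci_low=lo, proportion_ci_high=hi,
        criteria=criteria or {})


def write_mediation_table(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("exposure\tmediator\toutcome\ta_beta\ta_se\tb_beta\tb_se\t"
                 "total_beta\ttotal_se\tindirect\tindirect_se\t"
                 "proportion_pct\tci_low_pct\tci_high_pct\n")
        for r in results:
            fh.write("\t".join([
                r.exposure, r.mediator, r.outcome,
                *(f"{x:.6g}" for x in (
                    r.a.beta, r.a.se, r.b.beta, r.b.se, r.total.beta,
                    r.total.se, r.indirect, r.indirect_se, r.proportion,
                    r.proportion_ci_low, r.proportion_ci_high)),
            ]) + "\n")
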