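"""Orchestration of the bidirectional two-sample MR study.

``run_pair`` executes the full per-pair workflow — instrument selection,
clumping, strength filtering, confounder exclusion, harmonization, the
three estimators, and the sensitivity battery — and labels the primary
result. ``run_matrix`` runs every exposure × outcome pair in both
directions, isolating per-pair failures.

The primary method is IVW unless the Egger intercept indicates directional
pleiotropy (p < 0.05), in which case MR-Egger is primary. Significance is
Bonferroni-labelled: p < alpha/n_tests is significant, p < alpha nominal.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field

from .estimators import (
    IVW, MREgger, MRPresso, WeightedMedian, MREstimate, SensitivityReport,
    ivw as _ivw_fn,
)
from .exceptions import ConfigurationError
from .instruments import (
    clump, exclude_confounder_snps, filter_weak, harmonize,
    make_instruments, select_instruments,
)
from .sumstats import SummaryTable, write_results_table

logger = logging.getLogger("mrkit")


def derive_seed(root_seed: int, *labels) -> int:
    """A stable per-stage seed derived from the root seed and stage labels."""
    key = ":".join([str(root_seed), *map(str, labels)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


@dataclass
class AnalysisConfig:
    """Thresholds and seeds governing a full analysis.

    Defaults follow the study conventions: genome-wide significance 5e-8
    with a relaxed 5e-6 for listed traits, clumping at r² < 0.001 within
    10 Mb, instrument strength F > 10, nominal alpha 0.05 with a
    Bonferroni divisor of 5.
    """

    p_threshold_default: float = 5e-8
    p_threshold_relaxed: float = 5e-6
    relaxed_traits: list[str] = field(default_factory=list)
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    f_min: float = 10.0
    alpha_nominal: float = 0.05
    n_tests_bonferroni: int = 5
    n_boot: int = 1000
    n_presso_sim: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_threshold_default", "p_threshold_relaxed",
                     "alpha_nominal"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must lie in (0,1), got {v}")
        if self.n_tests_bonferroni < 1:
            raise ConfigurationError("n_tests_bonferroni must be ≥ 1")

    @property
    def alpha_bonferroni(self) -> float:
        return self.alpha_nominal / self.n_tests_bonferroni

    def threshold_for(self, trait_name: str) -> float:
        if trait_name in self.relaxed_traits:
            return self.p_threshold_relaxed
        return self.p_threshold_default

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Parse a flat ``key: value`` text config."""
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition(":")
                key = key.strip()
                value = value.strip()
                if key == "relaxed_traits":
                    kwargs[key] = [t.strip() for t in value.split(",") if t.strip()]
                elif key in ("clump_window_bp", "n_tests_bonferroni", "seed",
                             "n_boot", "n_presso_sim"):
                    kwargs[key] = int(float(value))
                elif key in ("p_threshold_default", "p_threshold_relaxed",
                             "clump_r2", "f_min", "alpha_nominal"):
                    kwargs[key] = float(value)
                else:
                    raise ConfigurationError(f"unknown config key {key!r}")
        return cls(**kwargs)


@dataclass
class PairResult:
    """Everything computed for one exposure → outcome analysis."""

    exposure: str
    outcome: str
    direction: str = "forward"
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    primary_method: str | None = None
    significance: str | None = None
    eligibility_flags: list[str] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)
    audit: list[tuple[str, str, str]] = field(default_factory=list)
    error: str | None = None

    @property
    def primary_estimate(self) -> MREstimate | None:
        if self.primary_method is None:
            return None
        return self.estimates.get(self.primary_method)


def choose_primary_method(sensitivity: SensitivityReport) -> str:
    """IVW unless the Egger intercept detects pleiotropy (p < 0.05)."""
    p = sensitivity.intercept_pval
    if p is not None and p < 0.05:
        return "egger"
    return "ivw"


def label_significance(pval: float, config: AnalysisConfig) -> str:
    """Bonferroni-corrected significance label for a primary p-value."""
    if not (0 <= pval <= 1):
        raise ConfigurationError(f"p-value out of [0,1]: {pval}")
    if pval < config.alpha_bonferroni:
        return "significant"
    if pval < config.alpha_nominal:
        return "nominal"
    return "null"


def prepare_instruments(exposure_table: SummaryTable, ld, confounders,
                        config: AnalysisConfig):
    """Selection → clumping → F filter → confounder exclusion, with audit.

    Returns (instruments, audit, flags, counts); ``flags`` contains
    ``outcome_only`` when the trait fails the instrument-strength rule and
    must not be used as an exposure.
    """
    audit: list[tuple[str, str, str]] = []
    flags: list[str] = []
    threshold = config.threshold_for(exposure_table.trait_name)
    selected = select_instruments(exposure_table, threshold)
    counts = {"selected": len(selected)}
    clumped = clump(selected, ld, config.clump_r2, config.clump_window_bp)
    clumped_ids = {r.variant_id for r in clumped}
    for r in selected:
        if r.variant_id not in clumped_ids:
            audit.append((r.variant_id, "clump", "ld_with_index_variant"))
    counts["clumped"] = len(clumped)

    insts = make_instruments(clumped)
    strong, mean_f = filter_weak(insts, config.f_min)
    for inst in insts:
        if inst.f_stat <= config.f_min:
            audit.append((inst.variant_id, "f_filter",
                          f"weak_instrument_f={inst.f_stat:.3g}"))
    counts["strong"] = len(strong)
    if not strong or mean_f <= config.f_min:
        flags.append("outcome_only")
        return [], audit, flags, counts

    kept, removed = exclude_confounder_snps(strong, confounders,
                                            config.p_threshold_default)
    for vid, reason in removed:
        audit.append((vid, "confounder_exclusion", reason))
    counts["post_confounder"] = len(kept)
    return kept, audit, flags, counts


def run_pair(exposure_table: SummaryTable, outcome_table: SummaryTable,
             ld, confounders=None, config: AnalysisConfig | None = None,
             direction: str = "forward") -> PairResult:
    """Full UVMR analysis of one exposure → outcome pair."""
    config = config or AnalysisConfig()
    result = PairResult(exposure=exposure_table.trait_name,
                        outcome=outcome_table.trait_name,
                        direction=direction)

    insts, audit, flags, counts = prepare_instruments(
        exposure_table, ld, confounders, config)
    result.audit = audit
    result.eligibility_flags = flags
    result.stage_counts = counts
    if "outcome_only" in flags:
        logger.info("%s -> %s: exposure ineligible (weak instruments)",
                    result.exposure, result.outcome)
        return result

    hset = harmonize(insts, outcome_table,
                     exposure_name=exposure_table.trait_name)
    for vid, reason in hset.dropped:
        result.audit.append((vid, "harmonize", reason))
    counts["harmonized"] = len(hset)
    logger.info("%s -> %s: %s", result.exposure, result.outcome,
                ", ".join(f"{k}={v}" for k, v in counts.items()))
    if len(hset) == 0:
        result.eligibility_flags.append("no_harmonized_instruments")
        return result

    binary = hset.outcome_binary
    names = (exposure_table.trait_name, outcome_table.trait_name)
    sens = SensitivityReport()

    est_ivw, q, q_pval = _ivw_fn(hset)
    result.estimates["ivw"] = est_ivw.with_names(*names)
    if len(hset) == 1:
        result.eligibility_flags.append("wald_ratio_fallback")
    else:
        sens.q, sens.q_df, sens.q_pval = q, len(hset) - 1, q_pval

    if len(hset) >= 3:
        eg = MREgger(hset).fit()
        result.estimates["egger"] = eg.estimate.with_names(*names)
        sens.egger_intercept = eg.intercept
        sens.intercept_se = eg.intercept_se
        sens.intercept_pval = eg.intercept_pval
        wm = WeightedMedian(hset).fit(
            n_boot=config.n_boot,
            seed=derive_seed(config.seed, "weighted_median", *names))
        result.estimates["weighted_median"] = wm.estimate.with_names(*names)
    else:
        result.eligibility_flags.append("too_few_for_egger")

    if len(hset) >= 4:
        pres = MRPresso(hset).fit(
            n_sim=config.n_presso_sim,
            seed=derive_seed(config.seed, "presso", *names))
        sens.presso_global_pval = pres.global_pval
        sens.presso_outliers = pres.outliers
        sens.presso_distortion_pval = pres.distortion_pval
        if pres.outliers:
            sens.presso_corrected = pres.corrected.with_names(*names)
            result.estimates["ivw_outlier_corrected"] = sens.presso_corrected

    result.sensitivity = sens
    primary = choose_primary_method(sens)
    if sens.intercept_pval is None:
        result.eligibility_flags.append("primary_defaulted_to_ivw")
    result.primary_method = primary
    result.significance = label_significance(
        result.estimates[primary].pval, config)
    return result


def run_matrix(exposures: dict[str, SummaryTable],
               outcomes: dict[str, SummaryTable],
               ld, confounders=None, config: AnalysisConfig | None = None,
               out_dir=None) -> list[PairResult]:
    """Every ordered exposure × outcome pair, both directions.

    Forward pairs take each entry of ``exposures`` as the exposure; the
    reverse direction re-selects instruments from the outcome trait's own
    table. Per-pair failures are recorded on the PairResult and do not
    abort the run. With ``out_dir`` set, one results TSV per direction and
    a sensitivity TSV are written.
    """
    config = config or AnalysisConfig()
    results: list[PairResult] = []
    plan = [("forward", e, o) for e in exposures for o in outcomes] + \
           [("reverse", o, e) for e in exposures for o in outcomes]
    tables = {**exposures, **outcomes}
    for direction, exp_name, out_name in plan:
        try:
            res = run_pair(tables[exp_name], tables[out_name], ld,
                           confounders, config, direction=direction)
        except Exception as exc:  # per-pair isolation
            logger.exception("pair %s -> %s failed", exp_name, out_name)
            res = PairResult(exposure=exp_name, outcome=out_name,
                             direction=direction, error=str(exc))
        results.append(res)
    if out_dir is not None:
        write_reports(results, out_dir)
    return results


def write_reports(results, out_dir) -> None:
    """One estimates TSV per direction plus a combined sensitivity TSV."""
    os.makedirs(out_dir, exist_ok=True)
    for direction in ("forward", "reverse"):
        rows = [est
                for r in results if r.direction == direction
                for est in r.estimates.values()]
        write_results_table(
            rows, os.path.join(out_dir, f"estimates_{direction}.tsv"))
    with open(os.path.join(out_dir, "sensitivity.tsv"), "w") as fh:
        fh.write("exposure\toutcome\tdirection\tcochran_q\tq_pval\t"
                 "egger_intercept\tintercept_pval\tpresso_global_pval\t"
                 "n_outliers\tdistortion_pval\tprimary_method\t"
                 "significance\tmrlap\tflags\terror\n")
        for r in results:
            s = r.sensitivity or SensitivityReport()

            def fmt(x):
                return "NA" if x is None else f"{x:.6g}"

            fh.write("\t".join([
                r.exposure, r.outcome, r.direction,
                fmt(s.q), fmt(s.q_pval), fmt(s.egger_intercept),
                fmt(s.intercept_pval), fmt(s.presso_global_pval),
                str(len(s.presso_outliers)), fmt(s.presso_distortion_pval),
                r.primary_method or "NA", r.significance or "NA",
                "NA",  # sample-overlap confirmation column, not computed
                ";".join(r.eligibility_flags) or "-",
                r.error or "-",
            ]) + "\n")
    with open(os.path.join(out_dir, "audit.tsv"), "w") as fh:
        fh.write("exposure\toutcome\tdirection\tvariant_id\tstage\treason\n")
        for r in results:
            for vid, stage, reason in r.audit:
                fh.write(f"{r.exposure}\t{r.outcome}\t{r.direction}\t"
                         f"{vid}\t{stage}\t{reason}\n")
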