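"""Synthetic GWAS summary statistics with known causal structure.

The generator works entirely at the summary level: per-variant effect/SE
pairs on the log-odds scale with SE(β) = 1/√(2·n·maf(1−maf)), the standard
large-sample approximation for a standardized trait or effective-n binary
trait. Instruments are drawn from a normal effect distribution and
rejection-sampled so their *true* effects pass genome-wide significance at
the exposure sample size; observed betas add sampling noise. Outcome betas
follow β_y = θ·β_x(true) + α + noise, where the per-SNP pleiotropy α can be
balanced (mean 0), directional (mean ≠ 0), or correlated with instrument
strength (InSIDE violation). Full table generation adds LD blocks
(attenuated satellite tags around each index instrument), null filler
variants, palindromic allele pairs and randomized outcome allele
orientation so that clumping and harmonization are genuinely exercised.

A mediation scenario plants an exposure → mediator → outcome chain
(effects a, b, plus a direct effect) together with decoy candidates
(a = 0, and a reverse-causal mediator) for the four-criterion screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ScenarioError
from .instruments import HarmonizedSet
from .sumstats import LDTable, SummaryTable, VariantAssociation

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_MIN_P = 1e-300  # floor to keep generated p-values representable


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth and design of one synthetic study.

    ``theta`` is the true causal effect (log-odds of outcome per SD of
    exposure liability); ``mu_alpha``/``sigma_alpha`` parameterize per-SNP
    pleiotropy; ``a_true``/``b_true``/``direct_true`` define the mediation
    chain. Sample sizes default to 100,000 per GWAS — large-biobank scale —
    and 50 instruments, the order of magnitude of a well-powered trait.
    """

    theta: float = 0.0
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    inside_violated: bool = False
    a_true: float = 0.0
    b_true: float = 0.0
    direct_true: float = 0.0
    n_snp: int = 50
    n_exp: int = 100_000
    n_out: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    sigma_x: float = 0.05          # SD of true instrument effects
    sig_threshold: float = 5e-8    # instruments pass this by construction
    block_size: int = 5            # variants per LD block (1 index + tags)
    n_filler: int = 100            # null non-instrument variants
    palindromic_frac: float = 0.16
    invalid_frac: float = 0.0      # fraction of instruments made pleiotropic
    invalid_alpha: float = 0.0     # fixed pleiotropy of invalid instruments
    n_outlier: int = 0             # instruments with an outlying ratio
    outlier_ratio_scale: float = 10.0
    outlier_se_scale: float = 0.7  # outliers are precisely measured

    def __post_init__(self):
        if self.n_snp < 1:
            raise ScenarioError("n_snp must be ≥ 1")
        if self.sigma_alpha < 0:
            raise ScenarioError("sigma_alpha must be ≥ 0")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ScenarioError("maf_range must be within (0, 0.5]")


def se_of_beta(n, maf):
    """SE(β) = 1/√(2·n·maf·(1−maf)) for an allele-count regression."""
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _pvals(beta, se):
    return np.maximum(2 * stats.norm.sf(np.abs(beta / se)), _MIN_P)


def draw_instrument_effects(truth: ScenarioTruth, rng: np.random.Generator):
    """Per-instrument truth and observed summary statistics.

    Returns a dict of arrays: ``maf, beta_true, beta_exp, se_exp, alpha,
    beta_out, se_out, invalid, outlier``.
    """
    k = truth.n_snp
    maf = rng.uniform(*truth.maf_range, size=k)
    se_exp = se_of_beta(truth.n_exp, maf)
    z_thresh = stats.norm.isf(truth.sig_threshold / 2)
    min_beta = z_thresh * se_exp
    accept = 2 * stats.norm.sf(min_beta / truth.sigma_x)
    if np.any(accept < 1e-6):
        raise ScenarioError(
            "rejection sampling infeasible: sigma_x too small for the "
            "significance threshold at this sample size")
    beta_true = np.zeros(k)
    todo = np.ones(k, bool)
    for _ in range(10_000):
        draws = rng.normal(0.0, truth.sigma_x, size=int(todo.sum()))
        beta_true[todo] = draws
        todo = np.abs(beta_true) <= min_beta
        if not todo.any():
            break
    else:  # pragma: no cover - guarded by the acceptance-probability check
        raise ScenarioError("rejection sampling did not converge")

    beta_exp = beta_true + rng.normal(0.0, se_exp)

    alpha = np.zeros(k)
    if truth.sigma_alpha > 0 or truth.mu_alpha != 0:
        if truth.inside_violated:
            strength = np.abs(beta_true)
            zs = (strength - strength.mean()) / (strength.std() or 1.0)
            eps = 0.7 * zs + np.sqrt(1 - 0.7 ** 2) * rng.normal(size=k)
        else:
            eps = rng.normal(size=k)
        # pleiotropy is defined on the exposure-increasing allele (allele
        # coding is arbitrary, so a directional mean must follow the
        # orientation MR-Egger uses or it would cancel)
        alpha = (truth.mu_alpha + truth.sigma_alpha * eps) \
            * np.sign(beta_true)

    se_out = se_of_beta(truth.n_out, maf)
    invalid = np.zeros(k, bool)
    if truth.invalid_frac > 0:
        n_invalid = int(round(truth.invalid_frac * k))
        # the weighted-median validity condition (valid instruments hold
        # a weight majority) is part of the scenario: redraw the invalid
        # subset if it would carry ≥ 50% of the IVW weight
        w = beta_exp ** 2 / se_out ** 2
        for _ in range(200):
            pick = rng.choice(k, size=n_invalid, replace=False)
            if w[pick].sum() / w.sum() < 0.5:
                break
        invalid[pick] = True
        # aligned with the instrument's sign so the ratio shift is
        # directional (a consistent upward pull on every invalid ratio)
        alpha = alpha + np.where(invalid,
                                 truth.invalid_alpha * np.sign(beta_true),
                                 0.0)

    theta_j = np.full(k, truth.theta)
    outlier = np.zeros(k, bool)
    if truth.n_outlier > 0:
        outlier[rng.choice(k, size=truth.n_outlier, replace=False)] = True
        theta_j = np.where(outlier, truth.theta * truth.outlier_ratio_scale,
                           theta_j)
        se_out = np.where(outlier, se_out * truth.outlier_se_scale, se_out)
    beta_out = theta_j * beta_true + alpha + rng.normal(0.0, se_out)
    return dict(maf=maf, beta_true=beta_true, beta_exp=beta_exp,
                se_exp=se_exp, alpha=alpha, beta_out=beta_out,
                se_out=se_out, invalid=invalid, outlier=outlier)


def generate_harmonized(truth: ScenarioTruth,
                        rng: np.random.Generator | None = None
                        ) -> tuple[HarmonizedSet, dict]:
    """Instrument-level view of a scenario: a ready HarmonizedSet.

    This bypasses table IO, clumping and allele alignment (those are
    exercised by :func:`generate_pair`) and is the fast path for estimator
    calibration studies.
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    eff = draw_instrument_effects(truth, rng)
    k = truth.n_snp
    rows = pd.DataFrame({
        "variant_id": [f"snp{j:05d}" for j in range(k)],
        "beta_exp": eff["beta_exp"],
        "se_exp": eff["se_exp"],
        "beta_out": eff["beta_out"],
        "se_out": eff["se_out"],
        "eaf_exp": eff["maf"],
        "eaf_out": eff["maf"],
    })
    hset = HarmonizedSet("synthetic_exposure", "synthetic_outcome", rows)
    return hset, eff


def _draw_alleles(rng, palindromic_frac):
    if rng.random() < palindromic_frac:
        return _PALINDROMIC[rng.integers(len(_PALINDROMIC))]
    return _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]


def _record(vid, chrom, pos, ea, oa, eaf, beta, se, n):
    return VariantAssociation(
        variant_id=vid, chrom=chrom, pos=int(pos), effect_allele=ea,
        other_allele=oa, eaf=float(np.clip(eaf, 1e-4, 1 - 1e-4)),
        beta=float(beta), se=float(se),
        pval=float(_pvals(np.array([beta]), np.array([se]))[0]), n=n)


def _present_outcome(rec: VariantAssociation, rng) -> VariantAssociation:
    """Re-express an outcome record with randomized allele orientation."""
    mode = rng.integers(4)
    ea, oa, beta, eaf = (rec.effect_allele, rec.other_allele, rec.beta,
                         rec.eaf)
    if mode % 2 == 1:  # swap allele roles
        ea, oa, beta, eaf = oa, ea, -beta, 1.0 - eaf
    if mode >= 2:      # report the other strand
        ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    return replace(rec, effect_allele=ea, other_allele=oa, beta=beta,
                   eaf=eaf, pval=rec.pval)


def generate_pair(truth: ScenarioTruth
                  ) -> tuple[SummaryTable, SummaryTable, LDTable, dict]:
    """Full exposure/outcome summary tables with LD blocks and fillers.

    Each planted instrument heads an LD block of ``block_size`` variants;
    its satellite tags carry attenuated signal (z scaled by √r² times a
    factor < 1) so clumping must pick the index variant. Filler variants
    are null. The outcome table re-expresses each variant's alleles in a
    random orientation (swapped / complemented / both) to exercise
    harmonization. Returns (exposure, outcome, ld, truth_info); truth_info
    lists the planted instrument ids and the per-instrument truth arrays.
    """
    rng = np.random.default_rng(truth.seed)
    eff = draw_instrument_effects(truth, rng)
    k = truth.n_snp
    ld = LDTable()
    exp_records: list[VariantAssociation] = []
    out_records: list[VariantAssociation] = []
    instrument_ids = []

    for j in range(k):
        chrom = str(j % 22 + 1)
        base = 1_000_000 + (j // 22) * 25_000_000
        vid = f"snp{j:05d}"
        instrument_ids.append(vid)
        ea, oa = _draw_alleles(rng, truth.palindromic_frac)
        eaf = eff["maf"][j] if rng.random() < 0.5 else 1 - eff["maf"][j]
        lead_exp = _record(vid, chrom, base, ea, oa, eaf,
                           eff["beta_exp"][j], eff["se_exp"][j], truth.n_exp)
        exp_records.append(lead_exp)
        eaf_out = eaf + rng.normal(0, 0.01)
        lead_out = _record(vid, chrom, base, ea, oa, eaf_out,
                           eff["beta_out"][j], eff["se_out"][j], truth.n_out)
        out_records.append(_present_outcome(lead_out, rng))

        # satellite tags in LD with the index variant
        sat_r2 = rng.uniform(0.2, 0.99, size=truth.block_size - 1)
        z_lead = eff["beta_exp"][j] / eff["se_exp"][j]
        z_out_lead = eff["beta_out"][j] / eff["se_out"][j]
        for s, r2 in enumerate(sat_r2):
            svid = f"snp{j:05d}_tag{s}"
            ld.set(vid, svid, float(r2))
            for s2 in range(s):
                ld.set(f"snp{j:05d}_tag{s2}", svid,
                       float(sat_r2[s2] * r2))
            maf_s = float(np.clip(eff["maf"][j] + rng.normal(0, 0.02),
                                  *truth.maf_range))
            se_s_exp = float(se_of_beta(truth.n_exp, maf_s))
            se_s_out = float(se_of_beta(truth.n_out, maf_s))
            atten = np.sqrt(r2) * rng.uniform(0.6, 0.95)
            sea, soa = _draw_alleles(rng, truth.palindromic_frac)
            eaf_s = maf_s if rng.random() < 0.5 else 1 - maf_s
            sat_exp = _record(svid, chrom, base + 10_000 * (s + 1), sea, soa,
                              eaf_s, z_lead * atten * se_s_exp, se_s_exp,
                              truth.n_exp)
            exp_records.append(sat_exp)
            sat_out = _record(svid, chrom, base + 10_000 * (s + 1), sea, soa,
                              eaf_s + rng.normal(0, 0.01),
                              z_out_lead * atten * se_s_out, se_s_out,
                              truth.n_out)
            out_records.append(_present_outcome(sat_out, rng))

    for f in range(truth.n_filler):
        vid = f"null{f:05d}"
        chrom = str(f % 22 + 1)
        pos = 500_000_000 + (f // 22) * 25_000_000
        maf_f = rng.uniform(*truth.maf_range)
        ea, oa = _draw_alleles(rng, truth.palindromic_frac)
        eaf = maf_f if rng.random() < 0.5 else 1 - maf_f
        se_f_exp = se_of_beta(truth.n_exp, maf_f)
        se_f_out = se_of_beta(truth.n_out, maf_f)
        exp_records.append(_record(vid, chrom, pos, ea, oa, eaf,
                                   rng.normal(0, se_f_exp), se_f_exp,
                                   truth.n_exp))
        out_rec = _record(vid, chrom, pos, ea, oa, eaf + rng.normal(0, 0.01),
                          rng.normal(0, se_f_out), se_f_out, truth.n_out)
        out_records.append(_present_outcome(out_rec, rng))

    exposure = SummaryTable("synthetic_exposure", "quantitative", exp_records)
    outcome = SummaryTable("synthetic_outcome", "binary", out_records)
    info = dict(eff, instrument_ids=instrument_ids, truth=truth)
    return exposure, outcome, ld, info


@dataclass
class MediationScenario:
    exposure: SummaryTable
    outcome: SummaryTable
    mediators: dict[str, SummaryTable]
    ld: LDTable
    truth: ScenarioTruth
    info: dict = field(default_factory=dict)

    @property
    def true_proportion(self) -> float:
        t = self.truth
        return t.a_true * t.b_true / (t.direct_true + t.a_true * t.b_true)


def _simple_records(ids, chroms, positions, betas, ses, mafs, n):
    """Instrument-level records with fixed, consistent allele coding."""
    recs = []
    for vid, ch, pos, b, s, m in zip(ids, chroms, positions, betas, ses,
                                     mafs):
        recs.append(VariantAssociation(
            variant_id=vid, chrom=ch, pos=int(pos), effect_allele="A",
            other_allele="G", eaf=float(m), beta=float(b), se=float(s),
            pval=float(_pvals(np.array([b]), np.array([s]))[0]), n=n))
    return recs


def generate_mediation_scenario(truth: ScenarioTruth,
                                with_decoys: bool = True,
                                reverse_effect: float = 0.1
                                ) -> MediationScenario:
    """Plant an exposure → mediator → outcome chain plus screen decoys.

    The outcome's genetic effects are ``(direct + a·b)·β_x`` at exposure
    instruments and ``b·β_m`` at mediator instruments, i.e. the total
    effect decomposes exactly as direct + a·b. Decoys: ``decoy_null_a``
    shares the b-path but is unaffected by the exposure (fails the
    exposure→mediator criterion); ``decoy_reverse`` additionally causes
    the exposure (fails the "not vice versa" clause). ``reverse_effect``
    is kept modest: the reverse UVMR detects it by aggregating all of the
    decoy's instruments, while each leaked per-SNP association stays far
    below the exposure's own selection threshold, so the planted total
    effect is not contaminated.
    """
    rng = np.random.default_rng(truth.seed)
    t = truth
    names = ["exposure_instruments", "mediator"]
    if with_decoys:
        names += ["decoy_null_a", "decoy_reverse"]

    # independent instrument sets, one block of ids/positions per trait
    sets = {}
    for i, name in enumerate(names):
        sub = replace(t, seed=int(rng.integers(2 ** 31)))
        eff = draw_instrument_effects(sub, np.random.default_rng(sub.seed))
        k = sub.n_snp
        ids = [f"t{i}snp{j:04d}" for j in range(k)]
        chroms = [str((i * 7 + j) % 22 + 1) for j in range(k)]
        positions = [1_000_000 + ((i * 7 + j) // 22) * 25_000_000 +
                     i * 1_000_000 for j in range(k)]
        sets[name] = dict(eff, ids=ids, chroms=chroms, positions=positions)

    def noisy(true_vals, ses):
        return true_vals + rng.normal(0.0, ses)

    exp = sets["exposure_instruments"]
    med = sets["mediator"]

    def table_for(trait_name, own, own_beta_obs, cross):
        """cross: list of (other_set, true effect array) rows to append."""
        recs = _simple_records(own["ids"], own["chroms"], own["positions"],
                               own_beta_obs, own["se_exp"], own["maf"],
                               t.n_exp)
        for other, effect in cross:
            recs += _simple_records(
                other["ids"], other["chroms"], other["positions"],
                noisy(effect, other["se_exp"]), other["se_exp"],
                other["maf"], t.n_exp)
        ttype = "binary" if trait_name == "outcome" else "quantitative"
        return SummaryTable(trait_name, ttype, recs)

    zeros = {n: np.zeros(t.n_snp) for n in names}

    # exposure: own instruments strong; others' instruments null unless a
    # reverse-causal decoy leaks its effects into the exposure
    cross_exp = [(med, zeros["mediator"])]
    if with_decoys:
        cross_exp += [(sets["decoy_null_a"], zeros["decoy_null_a"]),
                      (sets["decoy_reverse"],
                       reverse_effect * sets["decoy_reverse"]["beta_true"])]
    exposure_table = table_for("exposure", exp, exp["beta_exp"], cross_exp)

    mediator_table = table_for(
        "mediator", med, med["beta_exp"],
        [(exp, t.a_true * exp["beta_true"])])

    mediators = {"mediator": mediator_table}
    if with_decoys:
        mediators["decoy_null_a"] = table_for(
            "decoy_null_a", sets["decoy_null_a"],
            sets["decoy_null_a"]["beta_exp"],
            [(exp, zeros["exposure_instruments"])])
        mediators["decoy_reverse"] = table_for(
            "decoy_reverse", sets["decoy_reverse"],
            sets["decoy_reverse"]["beta_exp"],
            [(exp, t.a_true * exp["beta_true"])])

    # outcome: total = direct + a·b at exposure instruments; b at each
    # candidate's own instruments
    out_cross = [(exp, (t.direct_true + t.a_true * t.b_true)
                  * exp["beta_true"]),
                 (med, t.b_true * med["beta_true"])]
    if with_decoys:
        out_cross += [(sets["decoy_null_a"],
                       t.b_true * sets["decoy_null_a"]["beta_true"]),
                      (sets["decoy_reverse"],
                       t.b_true * sets["decoy_reverse"]["beta_true"])]
    out_recs = []
    for other, effect in out_cross:
        se_o = se_of_beta(t.n_out, other["maf"])
        out_recs += _simple_records(
            other["ids"], other["chroms"], other["positions"],
            noisy(effect, se_o), se_o, other["maf"], t.n_out)
    outcome_table = SummaryTable("outcome", "binary", out_recs)

    return MediationScenario(
        exposure=exposure_table, outcome=outcome_table, mediators=mediators,
        ld=LDTable(), truth=t,
        info={"instrument_ids": {n: sets[n]["ids"] for n in names}})


def generate_confounder_table(instruments, fraction: float,
                              seed: int) -> pd.DataFrame:
    """Mark a deterministic fraction of instruments as confounded.

    Returns the confounder-association table (variant_id, trait, pval) with
    ``round(fraction·k)`` instruments given p < 5e-8 hits; ``fraction=0``
    yields an empty table, matching a study where no confounder is found.
    """
    if not (0 <= fraction <= 1):
        raise ScenarioError("fraction must lie in [0, 1]")
    ids = [getattr(i, "variant_id", i) for i in instruments]
    rng = np.random.default_rng(seed)
    n_mark = int(round(fraction * len(ids)))
    marked = sorted(rng.choice(len(ids), size=n_mark, replace=False))
    return pd.DataFrame({
        "variant_id": [ids[i] for i in marked],
        "trait": "synthetic_confounder",
        "pval": 10.0 ** (-rng.uniform(8.5, 12, size=n_mark)),
    })


#: named study conditions used by the simulation CLI and the test harness
SCENARIOS: dict[str, ScenarioTruth] = {
    "null": ScenarioTruth(theta=0.0),
    "effect": ScenarioTruth(theta=0.3),
    "balanced_pleiotropy": ScenarioTruth(theta=0.1, sigma_alpha=0.003),
    "directional_pleiotropy": ScenarioTruth(theta=0.1, mu_alpha=0.003,
                                            sigma_alpha=0.002),
    "invalid40": ScenarioTruth(theta=0.1, n_snp=25, invalid_frac=0.4,
                               invalid_alpha=0.05),
    "outlier": ScenarioTruth(theta=0.3, n_snp=20, n_outlier=1,
                             outlier_ratio_scale=10.0),
    "mediation": ScenarioTruth(theta=0.0, a_true=0.2, b_true=0.4,
                               direct_true=0.32, n_snp=50),
}
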