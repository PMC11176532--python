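"""Two-sample MR estimators and sensitivity statistics.

Each estimator is a model object constructed from a
:class:`~mrkit.instruments.HarmonizedSet` whose ``fit()`` returns a results
object carrying the causal estimate, its uncertainty, diagnostics, and a
``summary()`` table:

* :class:`IVW` — random-effects inverse-variance-weighted estimate: the
  weighted regression of outcome betas on exposure betas through the origin
  (weights β_x²/SE_y², equivalently 1/SE_y² on the betas), with the SE
  inflated by √(Q/(k−1)) when Cochran's Q exceeds its degrees of freedom.
* :class:`MREgger` — the same regression with a free intercept; a nonzero
  intercept indicates directional pleiotropy and the slope is robust to it
  under the InSIDE assumption. Inference uses t with k−2 df.
* :class:`WeightedMedian` — the 50% point of the weight-ordered per-SNP
  ratio estimates; consistent when ≥50% of the weight is valid. SE by
  parametric bootstrap.
* :class:`MRPresso` — simulation-based global pleiotropy test, per-SNP
  outlier test, outlier-corrected estimate and distortion test.
* :class:`MultivariableIVW` — joint weighted regression on several
  exposures' betas, giving each exposure's direct effect.

Module-level functions (:func:`ivw`, :func:`egger`, ...) are thin wrappers
over the classes for pipeline use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import EstimationError, InsufficientInstrumentsError
from .instruments import HarmonizedSet, MultiHarmonizedSet

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the outcome scale.

    ``beta`` is log-odds per exposure unit when the outcome is binary; the
    odds-ratio fields are its exponentials and are meaningful only then.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    outcome_binary: bool = True
    exposure: str | None = None
    outcome: str | None = None

    @property
    def or_(self) -> float | None:
        return math.exp(self.beta) if self.outcome_binary else None

    @property
    def or_ci_low(self) -> float | None:
        return math.exp(self.ci_low) if self.outcome_binary else None

    @property
    def or_ci_high(self) -> float | None:
        return math.exp(self.ci_high) if self.outcome_binary else None

    def with_names(self, exposure: str, outcome: str) -> "MREstimate":
        return MREstimate(**{**self.__dict__, "exposure": exposure,
                             "outcome": outcome})


@dataclass
class SensitivityReport:
    """Heterogeneity/pleiotropy diagnostics attached to a trait pair."""

    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    presso_global_pval: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_corrected: MREstimate | None = None
    presso_distortion_pval: float | None = None


class _ResultsBase:
    """Common interface of estimator results (statsmodels-flavoured)."""

    method: str

    @property
    def estimate(self) -> MREstimate:
        raise NotImplementedError

    def summary(self) -> str:
        est = self.estimate
        lines = [
            f"{self.method} causal estimate ({est.n_snp} instruments)",
            "-" * 56,
            f"  beta      {est.beta: .6g}",
            f"  se        {est.se: .6g}",
            f"  95% CI    ({est.ci_low:.6g}, {est.ci_high:.6g})",
            f"  p-value   {est.pval:.4g}",
        ]
        if est.outcome_binary:
            lines.append(
                f"  OR        {est.or_:.4g} ({est.or_ci_low:.4g}, "
                f"{est.or_ci_high:.4g})")
        return "\n".join(lines)


def _as_arrays(data):
    if isinstance(data, HarmonizedSet):
        return (data.beta_exp, data.se_exp, data.beta_out, data.se_out,
                data.outcome_binary, data.variant_ids)
    bx, sx, by, sy = (np.asarray(a, float) for a in data)
    return bx, sx, by, sy, True, [str(i) for i in range(len(bx))]


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float,
               se_out: float, outcome_binary: bool = True) -> MREstimate:
    """Single-instrument causal estimate: β_y/β_x with first-order SE."""
    if beta_exp == 0:
        raise EstimationError("Wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    pval = 2 * stats.norm.sf(abs(beta) / se)
    return MREstimate("wald_ratio", beta, se, beta - Z95 * se,
                      beta + Z95 * se, float(pval), 1, outcome_binary)


class IVW:
    """Random-effects inverse-variance-weighted model.

    Parameters
    ----------
    data : HarmonizedSet or (beta_exp, se_exp, beta_out, se_out) arrays
    """

    min_instruments = 2

    def __init__(self, data):
        (self.beta_exp, self.se_exp, self.beta_out, self.se_out,
         self.outcome_binary, self.variant_ids) = _as_arrays(data)
        self.k = len(self.beta_exp)

    def fit(self) -> "IVWResults":
        if self.k < self.min_instruments:
            raise InsufficientInstrumentsError(
                f"IVW needs ≥ {self.min_instruments} instruments, got {self.k}")
        bx, by, sy = self.beta_exp, self.beta_out, self.se_out
        ratios = by / bx
        w = bx ** 2 / sy ** 2
        beta = float(np.sum(w * ratios) / np.sum(w))
        se_fixed = float(1.0 / math.sqrt(np.sum(w)))
        q = float(np.sum(w * (ratios - beta) ** 2))
        df = self.k - 1
        inflation = max(1.0, math.sqrt(q / df))
        se = se_fixed * inflation
        pval = float(2 * stats.norm.sf(abs(beta) / se))
        q_pval = float(stats.chi2.sf(q, df))
        return IVWResults(self, beta, se, se_fixed, pval, q, df, q_pval)


class IVWResults(_ResultsBase):
    method = "ivw"

    def __init__(self, model, beta, se, se_fixed, pval, q, q_df, q_pval):
        self.model = model
        self.beta = beta
        self.se = se
        self.se_fixed = se_fixed
        self.pval = pval
        self.q = q
        self.q_df = q_df
        self.q_pval = q_pval
        self.ci_low = beta - Z95 * se
        self.ci_high = beta + Z95 * se

    @property
    def estimate(self) -> MREstimate:
        return MREstimate("ivw", self.beta, self.se, self.ci_low,
                          self.ci_high, self.pval, self.model.k,
                          self.model.outcome_binary)

    def summary(self) -> str:
        return (super().summary()
                + f"\n  Cochran Q {self.q:.6g} (df {self.q_df}, "
                  f"p {self.q_pval:.4g})")


class MREgger:
    """MR-Egger regression: weighted fit of β_y on β_x with free intercept.

    Rows are first oriented so every exposure beta is non-negative (both
    betas negated where needed), making the intercept a directional
    pleiotropy test.
    """

    min_instruments = 3

    def __init__(self, data):
        (bx, sx, by, sy, self.outcome_binary,
         self.variant_ids) = _as_arrays(data)
        sign = np.where(bx < 0, -1.0, 1.0)
        self.beta_exp = bx * sign
        self.beta_out = by * sign
        self.se_exp = sx
        self.se_out = sy
        self.k = len(bx)

    def fit(self) -> "EggerResults":
        if self.k < self.min_instruments:
            raise InsufficientInstrumentsError(
                f"MR-Egger needs ≥ {self.min_instruments} instruments, "
                f"got {self.k}")
        bx, by, sy = self.beta_exp, self.beta_out, self.se_out
        w = 1.0 / sy ** 2
        X = np.column_stack([np.ones_like(bx), bx])
        XtW = X.T * w
        cov_unscaled = np.linalg.inv(XtW @ X)
        params = cov_unscaled @ (XtW @ by)
        resid = by - X @ params
        q = float(np.sum(w * resid ** 2))
        df = self.k - 2
        inflation = max(1.0, math.sqrt(q / df)) if df > 0 else 1.0
        ses = np.sqrt(np.diag(cov_unscaled)) * inflation
        tcrit = stats.t.ppf(0.975, df)
        pvals = 2 * stats.t.sf(np.abs(params / ses), df)
        q_pval = float(stats.chi2.sf(q, df))
        return EggerResults(
            self, slope=float(params[1]), slope_se=float(ses[1]),
            slope_pval=float(pvals[1]), intercept=float(params[0]),
            intercept_se=float(ses[0]), intercept_pval=float(pvals[0]),
            q=q, q_df=df, q_pval=q_pval, tcrit=float(tcrit))


class EggerResults(_ResultsBase):
    method = "egger"

    def __init__(self, model, slope, slope_se, slope_pval, intercept,
                 intercept_se, intercept_pval, q, q_df, q_pval, tcrit):
        self.model = model
        self.beta = slope
        self.se = slope_se
        self.pval = slope_pval
        self.intercept = intercept
        self.intercept_se = intercept_se
        self.intercept_pval = intercept_pval
        self.q = q
        self.q_df = q_df
        self.q_pval = q_pval
        self.ci_low = slope - tcrit * slope_se
        self.ci_high = slope + tcrit * slope_se

    @property
    def estimate(self) -> MREstimate:
        return MREstimate("egger", self.beta, self.se, self.ci_low,
                          self.ci_high, self.pval, self.model.k,
                          self.model.outcome_binary)

    def summary(self) -> str:
        return (super().summary()
                + f"\n  intercept {self.intercept:.6g} ± "
                  f"{self.intercept_se:.6g} (p {self.intercept_pval:.4g})"
                + f"\n  Cochran Q {self.q:.6g} (df {self.q_df}, "
                  f"p {self.q_pval:.4g})")


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray
                          ) -> np.ndarray:
    """Row-wise weighted median by linear interpolation at cumulative 0.5.

    ``ratios`` and ``weights`` are (n, k); weights need not be normalized.
    """
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    p = np.cumsum(w, axis=1) - w / 2.0
    # interpolate each row at 0.5
    idx = (p < 0.5).sum(axis=1)
    out = np.empty(len(r))
    low = idx == 0
    high = idx == r.shape[1]
    out[low] = r[low, 0]
    out[high] = r[high, -1]
    mid = ~(low | high)
    i = idx[mid]
    rows = np.nonzero(mid)[0]
    p0, p1 = p[rows, i - 1], p[rows, i]
    r0, r1 = r[rows, i - 1], r[rows, i]
    frac = (0.5 - p0) / (p1 - p0)
    out[mid] = r0 + frac * (r1 - r0)
    return out


class WeightedMedian:
    """Weighted-median estimator with parametric-bootstrap SE."""

    min_instruments = 3

    def __init__(self, data):
        (self.beta_exp, self.se_exp, self.beta_out, self.se_out,
         self.outcome_binary, self.variant_ids) = _as_arrays(data)
        self.k = len(self.beta_exp)

    def point_estimate(self) -> float:
        ratios = (self.beta_out / self.beta_exp)[None, :]
        weights = (self.beta_exp ** 2 / self.se_out ** 2)[None, :]
        return float(_weighted_median_rows(ratios, weights)[0])

    def fit(self, n_boot: int = 1000, seed: int | None = None
            ) -> "WeightedMedianResults":
        if self.k < self.min_instruments:
            raise InsufficientInstrumentsError(
                f"weighted median needs ≥ {self.min_instruments} "
                f"instruments, got {self.k}")
        if seed is None:
            raise EstimationError(
                "weighted median bootstrap requires an explicit seed")
        beta = self.point_estimate()
        rng = np.random.default_rng(seed)
        bx = rng.normal(self.beta_exp, self.se_exp, size=(n_boot, self.k))
        by = rng.normal(self.beta_out, self.se_out, size=(n_boot, self.k))
        # guard against resampled exposure betas crossing zero
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        boots = _weighted_median_rows(by / bx, bx ** 2 / self.se_out ** 2)
        se = float(np.std(boots, ddof=1))
        if se > 0:
            pval = float(2 * stats.norm.sf(abs(beta) / se))
        else:
            pval = 1.0 if beta == 0 else 0.0
        return WeightedMedianResults(self, beta, se, pval, n_boot, seed)


class WeightedMedianResults(_ResultsBase):
    method = "weighted_median"

    def __init__(self, model, beta, se, pval, n_boot, seed):
        self.model = model
        self.beta = beta
        self.se = se
        self.pval = pval
        self.n_boot = n_boot
        self.seed = seed
        self.ci_low = beta - Z95 * se
        self.ci_high = beta + Z95 * se

    @property
    def estimate(self) -> MREstimate:
        return MREstimate("weighted_median", self.beta, self.se, self.ci_low,
                          self.ci_high, self.pval, self.model.k,
                          self.model.outcome_binary)


def _loo_ivw(bx, by, sy):
    """Leave-one-out IVW point estimates, vectorized over the left-out SNP."""
    num = bx * by / sy ** 2
    den = bx ** 2 / sy ** 2
    return (num.sum() - num) / (den.sum() - den)


class MRPresso:
    """MR-PRESSO: pleiotropy residual sum of squares and outlier test.

    The observed weighted RSS uses leave-one-out IVW predictions; its null
    distribution is simulated by redrawing outcome betas around those
    predictions. The outlier test compares each SNP's observed weighted
    squared residual with its simulated distribution (Bonferroni across
    SNPs); the distortion test compares the outlier-removal displacement of
    the IVW estimate with displacements from removing random same-size
    subsets.
    """

    min_instruments = 4

    def __init__(self, data):
        (self.beta_exp, self.se_exp, self.beta_out, self.se_out,
         self.outcome_binary, self.variant_ids) = _as_arrays(data)
        self.k = len(self.beta_exp)

    @staticmethod
    def _outlier_pass(bx, by, sy, n_sim, rng):
        """One residual-simulation pass: global p, per-SNP p, observed
        per-SNP weighted squared residuals."""
        w = 1.0 / sy ** 2
        loo = _loo_ivw(bx, by, sy)
        rss_j_obs = w * (by - loo * bx) ** 2
        by_sim = rng.normal(loo * bx, sy, size=(n_sim, len(bx)))
        num_s = (bx * by_sim) / sy ** 2
        den = bx ** 2 / sy ** 2
        loo_s = (num_s.sum(axis=1, keepdims=True) - num_s) / \
                (den.sum() - den)
        rss_j_sim = w * (by_sim - loo_s * bx) ** 2
        global_pval = float(np.mean(rss_j_sim.sum(axis=1)
                                    >= rss_j_obs.sum()))
        p_snp = np.mean(rss_j_sim >= rss_j_obs, axis=0)
        return global_pval, p_snp, rss_j_obs

    def fit(self, n_sim: int = 1000, outlier_alpha: float = 0.05,
            seed: int | None = None) -> "PressoResults":
        if self.k < self.min_instruments:
            raise InsufficientInstrumentsError(
                f"MR-PRESSO needs ≥ {self.min_instruments} instruments, "
                f"got {self.k}")
        if seed is None:
            raise EstimationError("MR-PRESSO simulation requires a seed")
        rng = np.random.default_rng(seed)
        bx, by, sy = self.beta_exp, self.beta_out, self.se_out

        global_pval, p_snp, rss_j_obs = self._outlier_pass(
            bx, by, sy, n_sim, rng)
        p_adj = np.minimum(1.0, p_snp * self.k)
        out_mask = p_adj < outlier_alpha

        if out_mask.any() and self.k - out_mask.sum() < 2:
            # A dominating outlier corrupts every leave-one-out prediction
            # and the single-pass test flags (nearly) all SNPs. Peel
            # iteratively instead: drop the most extreme flagged SNP,
            # re-test the remainder, stop when nothing is flagged.
            active = np.ones(self.k, bool)
            peeled = []
            rss_cur, flags_cur = rss_j_obs, out_mask
            while flags_cur.any() and active.sum() > self.min_instruments:
                idx_active = np.nonzero(active)[0]
                worst_local = np.argmax(np.where(flags_cur, rss_cur,
                                                 -np.inf))
                worst = idx_active[worst_local]
                peeled.append(worst)
                active[worst] = False
                _, p_sub, rss_cur = self._outlier_pass(
                    bx[active], by[active], sy[active], n_sim, rng)
                flags_cur = (np.minimum(1.0, p_sub * active.sum())
                             < outlier_alpha)
            out_mask = np.zeros(self.k, bool)
            out_mask[peeled] = True
        outliers = [self.variant_ids[i] for i in np.nonzero(out_mask)[0]]

        raw = IVW((bx, self.se_exp, by, sy)).fit()
        raw_est = raw.estimate
        corrected, distortion_pval = raw_est, None
        if outliers and self.k - len(outliers) >= 2:
            keep = ~out_mask
            corr = IVW((bx[keep], self.se_exp[keep], by[keep],
                        sy[keep])).fit()
            corrected = corr.estimate
            disp_obs = corrected.beta - raw_est.beta
            n_out = int(out_mask.sum())
            disp_sim = np.empty(n_sim)
            for i in range(n_sim):
                drop = rng.choice(self.k, size=n_out, replace=False)
                m = np.ones(self.k, bool)
                m[drop] = False
                wr = bx[m] ** 2 / sy[m] ** 2
                disp_sim[i] = (np.sum(wr * (by[m] / bx[m])) / np.sum(wr)
                               - raw_est.beta)
            distortion_pval = float(np.mean(np.abs(disp_sim)
                                            >= abs(disp_obs)))
        return PressoResults(self, global_pval, outliers, raw_est,
                             corrected, distortion_pval, n_sim, seed)


class PressoResults:
    def __init__(self, model, global_pval, outliers, raw, corrected,
                 distortion_pval, n_sim, seed):
        self.model = model
        self.global_pval = global_pval
        self.outliers = outliers
        self.raw = raw
        self.corrected = corrected
        self.distortion_pval = distortion_pval
        self.n_sim = n_sim
        self.seed = seed

    def summary(self) -> str:
        lines = [
            f"MR-PRESSO ({self.model.k} instruments, {self.n_sim} simulations)",
            "-" * 56,
            f"  global test p       {self.global_pval:.4g}",
            f"  outliers            {len(self.outliers)}"
            + (f" ({', '.join(self.outliers)})" if self.outliers else ""),
        ]
        if self.outliers:
            lines.append(
                f"  corrected beta      {self.corrected.beta:.6g} "
                f"(raw {self.raw.beta:.6g})")
            lines.append(
                f"  distortion test p   {self.distortion_pval:.4g}")
        return "\n".join(lines)


class MultivariableIVW:
    """Multivariable MR: joint weighted regression on m exposures' betas.

    ``fit()`` estimates each exposure's direct effect on the outcome
    conditional on the others, with multiplicative overdispersion on the
    SEs and an Egger-style intercept diagnostic (rows oriented so the first
    exposure's betas are non-negative).
    """

    def __init__(self, data: MultiHarmonizedSet):
        self.data = data
        self.X = np.asarray(data.exposure_betas, float)
        self.by = np.asarray(data.beta_out, float)
        self.sy = np.asarray(data.se_out, float)
        self.k, self.m = self.X.shape

    def fit(self) -> "MultivariableIVWResults":
        if self.k < self.m + 1:
            raise InsufficientInstrumentsError(
                f"MVMR with {self.m} exposures needs ≥ {self.m + 1} "
                f"instruments, got {self.k}")
        w = 1.0 / self.sy ** 2
        XtW = self.X.T * w
        gram = XtW @ self.X
        if np.linalg.matrix_rank(gram) < self.m:
            raise EstimationError(
                "collinear exposure betas: "
                + ", ".join(self.data.exposure_names))
        cov_unscaled = np.linalg.inv(gram)
        params = cov_unscaled @ (XtW @ self.by)
        resid = self.by - self.X @ params
        q = float(np.sum(w * resid ** 2))
        df = self.k - self.m
        inflation = max(1.0, math.sqrt(q / df)) if df > 0 else 1.0
        ses = np.sqrt(np.diag(cov_unscaled)) * inflation
        pvals = 2 * stats.norm.sf(np.abs(params / ses))
        q_pval = float(stats.chi2.sf(q, df))

        # Egger-style intercept: same regression plus a constant, with rows
        # oriented to the first exposure positive
        intercept = intercept_se = intercept_pval = None
        if self.k >= self.m + 2:
            sign = np.where(self.X[:, 0] < 0, -1.0, 1.0)
            Xe = np.column_stack([np.ones(self.k), self.X * sign[:, None]])
            bye = self.by * sign
            XtWe = Xe.T * w
            grame = XtWe @ Xe
            if np.linalg.matrix_rank(grame) == self.m + 1:
                cove = np.linalg.inv(grame)
                pe = cove @ (XtWe @ bye)
                res_e = bye - Xe @ pe
                qe = float(np.sum(w * res_e ** 2))
                dfe = self.k - self.m - 1
                infl_e = max(1.0, math.sqrt(qe / dfe)) if dfe > 0 else 1.0
                se0 = math.sqrt(cove[0, 0]) * infl_e
                intercept = float(pe[0])
                intercept_se = float(se0)
                intercept_pval = float(
                    2 * stats.t.sf(abs(intercept / se0), dfe))
        return MultivariableIVWResults(
            self, params, ses, pvals, q, df, q_pval,
            intercept, intercept_se, intercept_pval)


class MultivariableIVWResults:
    method = "mvmr_ivw"

    def __init__(self, model, params, bse, pvalues, q, q_df, q_pval,
                 intercept, intercept_se, intercept_pval):
        self.model = model
        self.params = np.asarray(params)
        self.bse = np.asarray(bse)
        self.pvalues = np.asarray(pvalues)
        self.q = q
        self.q_df = q_df
        self.q_pval = q_pval
        self.intercept = intercept
        self.intercept_se = intercept_se
        self.intercept_pval = intercept_pval

    def estimates(self) -> list[MREstimate]:
        out = []
        for name, b, s, p in zip(self.model.data.exposure_names,
                                 self.params, self.bse, self.pvalues):
            out.append(MREstimate(
                "mvmr_ivw", float(b), float(s), float(b - Z95 * s),
                float(b + Z95 * s), float(p), self.model.k,
                self.model.data.outcome_binary, exposure=name,
                outcome=self.model.data.outcome_name))
        return out

    def estimate_for(self, exposure: str) -> MREstimate:
        idx = self.model.data.exposure_names.index(exposure)
        return self.estimates()[idx]

    def sensitivity(self) -> SensitivityReport:
        return SensitivityReport(
            q=self.q, q_df=self.q_df, q_pval=self.q_pval,
            egger_intercept=self.intercept,
            intercept_se=self.intercept_se,
            intercept_pval=self.intercept_pval)

    def summary(self) -> str:
        lines = [f"Multivariable IVW ({self.model.k} instruments, "
                 f"{self.model.m} exposures)", "-" * 56]
        for est in self.estimates():
            lines.append(
                f"  {est.exposure:<24s} beta {est.beta: .6g} "
                f"se {est.se:.6g} p {est.pval:.4g}")
        lines.append(f"  Cochran Q {self.q:.6g} (df {self.q_df}, "
                     f"p {self.q_pval:.4g})")
        if self.intercept is not None:
            lines.append(
                f"  intercept {self.intercept:.6g} ± {self.intercept_se:.6g}"
                f" (p {self.intercept_pval:.4g})")
        return "\n".join(lines)


def cochran_q(ratios, weights, center, df: int | None = None
              ) -> tuple[float, int, float]:
    """Cochran's heterogeneity statistic Q = Σ wⱼ (rⱼ − center)².

    ``df`` defaults to k − 1; the p-value is the upper chi-square tail.
    """
    r = np.asarray(ratios, float)
    w = np.asarray(weights, float)
    if len(r) < 2:
        raise EstimationError("Cochran's Q needs at least 2 ratios")
    q = float(np.sum(w * (r - center) ** 2))
    if df is None:
        df = len(r) - 1
    return q, df, float(stats.chi2.sf(q, df))


# ---------------------------------------------------------------------------
# functional wrappers

def ivw(hset) -> tuple[MREstimate, float, float]:
    """IVW estimate plus (Q, Q p-value); single-instrument sets fall back
    to the Wald ratio with Q undefined (NaN)."""
    model = IVW(hset)
    if model.k == 1:
        est = wald_ratio(model.beta_exp[0], model.se_exp[0],
                         model.beta_out[0], model.se_out[0],
                         model.outcome_binary)
        return est, float("nan"), float("nan")
    res = model.fit()
    return res.estimate, res.q, res.q_pval


def egger(hset):
    """MR-Egger slope estimate plus intercept diagnostics and Q."""
    res = MREgger(hset).fit()
    return (res.estimate, res.intercept, res.intercept_se,
            res.intercept_pval, res.q, res.q_pval)


def weighted_median(hset, n_boot: int = 1000, seed: int | None = None
                    ) -> MREstimate:
    return WeightedMedian(hset).fit(n_boot=n_boot, seed=seed).estimate


def mr_presso(hset, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int | None = None):
    res = MRPresso(hset).fit(n_sim=n_sim, outlier_alpha=outlier_alpha,
                             seed=seed)
    return res.global_pval, res.outliers, res.corrected, res.distortion_pval


def mvmr_ivw(multi_hset: MultiHarmonizedSet
             ) -> tuple[list[MREstimate], SensitivityReport]:
    res = MultivariableIVW(multi_hset).fit()
    return res.estimates(), res.sensitivity()
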