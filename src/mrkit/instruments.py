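"""Instrument selection, LD clumping, strength filtering and harmonization.

The selection pipeline mirrors standard two-sample MR practice: take
genome-wide-significant variants (p < 5e-8, or a relaxed 5e-6 for traits
with too few hits), clump them to approximate linkage independence
(r² < 0.001 within 10 Mb), drop weak instruments by the F > 10 rule, remove
variants with known confounder associations, and align exposure and outcome
effects to a common effect allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .sumstats import LDTable, SummaryTable, VariantAssociation

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: allele-frequency band within which a palindromic variant's strand cannot
#: be inferred from frequency (the de-facto standard window)
AMBIGUITY_WINDOW = (0.42, 0.58)


@dataclass(frozen=True)
class Instrument:
    """An exposure-side association together with its strength statistic."""

    association: VariantAssociation
    f_stat: float

    @property
    def variant_id(self) -> str:
        return self.association.variant_id


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to the exposure's effect allele.

    ``rows`` has columns ``variant_id, beta_exp, se_exp, beta_out, se_out,
    eaf_exp, eaf_out``; ``dropped`` records (variant_id, reason) for every
    instrument that could not be carried into the outcome.
    """

    exposure_name: str
    outcome_name: str
    rows: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)
    outcome_binary: bool = True

    def __post_init__(self) -> None:
        kept = set(self.rows["variant_id"])
        for vid, _ in self.dropped:
            if vid in kept:
                raise ValidationError(
                    f"variant {vid!r} both kept and dropped")
        if len(self.rows):
            if (self.rows["se_exp"] <= 0).any() or (self.rows["se_out"] <= 0).any():
                raise ValidationError("harmonized SEs must be positive")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.rows["beta_exp"].to_numpy(float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.rows["se_exp"].to_numpy(float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.rows["beta_out"].to_numpy(float)

    @property
    def se_out(self) -> np.ndarray:
        return self.rows["se_out"].to_numpy(float)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.rows["variant_id"])

    def drop_variants(self, variant_ids) -> "HarmonizedSet":
        """A copy without the named variants (used for outlier correction)."""
        drop = set(variant_ids)
        rows = self.rows[~self.rows["variant_id"].isin(drop)].reset_index(drop=True)
        return HarmonizedSet(self.exposure_name, self.outcome_name, rows,
                             list(self.dropped), self.outcome_binary)


def select_instruments(table: SummaryTable, p_threshold: float
                       ) -> list[VariantAssociation]:
    """All rows with p below the threshold, original order preserved."""
    if not (0 < p_threshold < 1):
        raise ValidationError(f"p_threshold must lie in (0,1), got {p_threshold}")
    return [r for r in table if r.pval < p_threshold]


def clump(candidates, ld: LDTable, r2_max: float = 0.001,
          window_bp: int = 10_000_000) -> list[VariantAssociation]:
    """Greedy LD clumping: keep index variants, discard their LD partners.

    Candidates are visited by ascending p (ties broken by variant_id); a
    candidate is accepted iff no already-accepted variant on the same
    chromosome within ``window_bp`` has r² ≥ ``r2_max`` with it. The
    accepted set is returned sorted by (chromosome, position).
    """
    order = sorted(candidates, key=lambda r: (r.pval, r.variant_id))
    accepted: list[VariantAssociation] = []
    for cand in order:
        clash = any(
            kept.chrom == cand.chrom
            and abs(kept.pos - cand.pos) <= window_bp
            and ld.r2(kept.variant_id, cand.variant_id) >= r2_max
            for kept in accepted
        )
        if not clash:
            accepted.append(cand)
    return sorted(accepted, key=lambda r: (r.chrom, r.pos))


def f_statistic(assoc: VariantAssociation) -> float:
    """Single-SNP instrument strength, the squared Wald z: (β/SE)²."""
    return (assoc.beta / assoc.se) ** 2


def make_instruments(associations) -> list[Instrument]:
    return [Instrument(a, f_statistic(a)) for a in associations]


def filter_weak(instruments, f_min: float = 10.0
                ) -> tuple[list[Instrument], float]:
    """Keep instruments with F above ``f_min``; also return the kept mean F.

    The caller applies the exposure-level rule: a trait whose instruments
    all fail (or whose mean F fails) is eligible only as an outcome.
    """
    kept = [i for i in instruments if i.f_stat > f_min]
    mean_f = float(np.mean([i.f_stat for i in kept])) if kept else float("nan")
    return kept, mean_f


def exclude_confounder_snps(instruments, confounder_table: pd.DataFrame | None,
                            p_threshold: float = 5e-8
                            ) -> tuple[list[Instrument], list[tuple[str, str]]]:
    """Drop instruments with any confounder association below ``p_threshold``.

    ``confounder_table`` holds one row per (variant_id, trait, pval); an
    empty or absent table leaves the instrument list unchanged. Returns
    (kept, removed) where removed pairs each variant with the confounder
    trait that triggered its removal.
    """
    if confounder_table is None or len(confounder_table) == 0:
        return list(instruments), []
    hits = confounder_table[confounder_table["pval"] < p_threshold]
    flagged = hits.groupby("variant_id")["trait"].first().to_dict()
    kept, removed = [], []
    for inst in instruments:
        trait = flagged.get(inst.variant_id)
        if trait is None:
            kept.append(inst)
        else:
            removed.append((inst.variant_id, f"confounder:{trait}"))
    return kept, removed


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return _COMPLEMENT[ea], _COMPLEMENT[oa]


def is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def _align_to(ref: VariantAssociation, rec: VariantAssociation,
              ambiguity_window=AMBIGUITY_WINDOW):
    """Align ``rec`` to ``ref``'s effect allele.

    Returns (beta, se, eaf) on success or a string drop-reason. Palindromic
    variants are oriented by allele frequency; if either frequency is
    missing or falls inside the ambiguity window, the variant is dropped.
    """
    ea, oa = ref.effect_allele, ref.other_allele
    rea, roa = rec.effect_allele, rec.other_allele
    lo, hi = ambiguity_window

    if is_palindromic(ea, oa):
        if (rea, roa) == (ea, oa):
            beta, eaf = rec.beta, rec.eaf
        elif (rea, roa) == (oa, ea):
            beta = -rec.beta
            eaf = None if rec.eaf is None else 1.0 - rec.eaf
        else:
            return "allele_mismatch"
        if ref.eaf is None or eaf is None:
            return "palindromic_ambiguous"
        if lo <= ref.eaf <= hi or lo <= eaf <= hi:
            return "palindromic_ambiguous"
        if (ref.eaf < 0.5) != (eaf < 0.5):
            # frequencies disagree on the minor allele: opposite strands
            beta, eaf = -beta, 1.0 - eaf
        return beta, rec.se, eaf

    if (rea, roa) == (ea, oa):
        return rec.beta, rec.se, rec.eaf
    if (rea, roa) == (oa, ea):
        return (-rec.beta, rec.se,
                None if rec.eaf is None else 1.0 - rec.eaf)
    crea, croa = _complement_pair(rea, roa)
    if (crea, croa) == (ea, oa):
        return rec.beta, rec.se, rec.eaf
    if (crea, croa) == (oa, ea):
        return (-rec.beta, rec.se,
                None if rec.eaf is None else 1.0 - rec.eaf)
    return "allele_mismatch"


def harmonize(exposure_rows, outcome_table: SummaryTable,
              exposure_name: str = "exposure",
              ambiguity_window=AMBIGUITY_WINDOW) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Rules, per instrument: matching alleles kept as-is; swapped alleles
    negate the outcome beta and flip its frequency; strand-complemented
    alleles are complemented first; palindromic (A/T, C/G) variants are
    oriented by allele frequency and dropped as ``palindromic_ambiguous``
    when either side's frequency is missing or near 0.5; instruments absent
    from the outcome are dropped as ``missing_in_outcome``. No proxy search
    is performed.
    """
    exposure_rows = [
        r.association if isinstance(r, Instrument) else r for r in exposure_rows
    ]
    rows, dropped = [], []
    for exp in exposure_rows:
        out = outcome_table.get(exp.variant_id)
        if out is None:
            dropped.append((exp.variant_id, "missing_in_outcome"))
            continue
        aligned = _align_to(exp, out, ambiguity_window)
        if isinstance(aligned, str):
            dropped.append((exp.variant_id, aligned))
            continue
        beta_out, se_out, eaf_out = aligned
        rows.append(
            (exp.variant_id, exp.beta, exp.se, beta_out, se_out,
             np.nan if exp.eaf is None else exp.eaf,
             np.nan if eaf_out is None else eaf_out))
    frame = pd.DataFrame(
        rows,
        columns=["variant_id", "beta_exp", "se_exp", "beta_out", "se_out",
                 "eaf_exp", "eaf_out"],
    )
    return HarmonizedSet(
        exposure_name=exposure_name,
        outcome_name=outcome_table.trait_name,
        rows=frame,
        dropped=dropped,
        outcome_binary=outcome_table.trait_type == "binary",
    )


@dataclass
class MultiHarmonizedSet:
    """Several exposures' effects jointly aligned with one outcome.

    ``exposure_betas`` is k × m (one column per exposure); rows are the
    union of the per-exposure instrument sets, complete-case across all
    exposure tables and the outcome.
    """

    exposure_names: list[str]
    outcome_name: str
    variant_ids: list[str]
    exposure_betas: np.ndarray
    exposure_ses: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)
    outcome_binary: bool = True

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return self.exposure_betas.shape[1]


def harmonize_multi(instrument_sets, exposure_tables, outcome_table,
                    ambiguity_window=AMBIGUITY_WINDOW) -> MultiHarmonizedSet:
    """Jointly harmonize several exposures with one outcome for MVMR.

    ``instrument_sets`` maps exposure name → its selected instruments
    (reference alleles come from the exposure that contributed the
    variant); ``exposure_tables`` maps exposure name → full SummaryTable so
    every exposure's effect at every union variant can be looked up.
    Variants missing or unalignable in any table are dropped complete-case
    with an audit reason.
    """
    names = list(exposure_tables)
    refs: dict[str, VariantAssociation] = {}
    for name in names:
        for inst in instrument_sets.get(name, []):
            assoc = inst.association if isinstance(inst, Instrument) else inst
            refs.setdefault(assoc.variant_id, assoc)

    kept_ids, X, SX, by, sy = [], [], [], [], []
    dropped: list[tuple[str, str]] = []
    for vid, ref in refs.items():
        out = outcome_table.get(vid)
        if out is None:
            dropped.append((vid, "missing_in_outcome"))
            continue
        out_aligned = _align_to(ref, out, ambiguity_window)
        if isinstance(out_aligned, str):
            dropped.append((vid, out_aligned))
            continue
        betas, ses, reason = [], [], None
        for name in names:
            rec = exposure_tables[name].get(vid)
            if rec is None:
                reason = f"missing_in_{name}"
                break
            aligned = _align_to(ref, rec, ambiguity_window)
            if isinstance(aligned, str):
                reason = aligned
                break
            betas.append(aligned[0])
            ses.append(aligned[1])
        if reason is not None:
            dropped.append((vid, reason))
            continue
        kept_ids.append(vid)
        X.append(betas)
        SX.append(ses)
        by.append(out_aligned[0])
        sy.append(out_aligned[1])

    return MultiHarmonizedSet(
        exposure_names=names,
        outcome_name=outcome_table.trait_name,
        variant_ids=kept_ids,
        exposure_betas=np.asarray(X, float).reshape(len(kept_ids), len(names)),
        exposure_ses=np.asarray(SX, float).reshape(len(kept_ids), len(names)),
        beta_out=np.asarray(by, float),
        se_out=np.asarray(sy, float),
        dropped=dropped,
        outcome_binary=outcome_table.trait_type == "binary",
    )
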