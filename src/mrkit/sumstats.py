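"""Reading, validation and writing of GWAS summary statistics and LD tables.

All formats are plain tab-separated text. Summary statistics follow a
GWAS-SSF-like default header (``variant_id``, ``chromosome``,
``base_pair_location``, ``effect_allele``, ``other_allele``,
``effect_allele_frequency``, ``beta``, ``standard_error``, ``p_value``,
``n``); other dialects are mapped in through ``column_map``. Positions are
1-based, alleles uppercase single nucleotides. LD is a long-format table
``id1 TAB id2 TAB r2`` with symmetric lookup; unlisted pairs are treated as
r² = 0 and a variant with itself as r² = 1.
"""

from __future__ import annotations

import math
import sys
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

VALID_ALLELES = frozenset("ACGT")

#: canonical column names, in file order
CANONICAL_COLUMNS = (
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
)

_REQUIRED = (
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
    "p_value",
)

_TINY_P = sys.float_info.min  # clamp for p-values that underflowed to 0


@dataclass(frozen=True)
class VariantAssociation:
    """One GWAS summary row: a variant's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` — log-odds units
    for binary traits, trait-SD units for quantitative traits. ``eaf`` and
    ``n`` may be missing (``None``); nothing imputes them.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float | None = None

    def validate(self, row: int | None = None) -> None:
        """Raise :class:`ValidationError` on the first violated invariant."""
        where = f" (row {row})" if row is not None else ""
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"invalid effect_allele {self.effect_allele!r}{where}",
                row=row, field="effect_allele")
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"invalid other_allele {self.other_allele!r}{where}",
                row=row, field="other_allele")
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"effect and other allele identical{where}",
                row=row, field="other_allele")
        if not math.isfinite(self.beta):
            raise ValidationError(f"non-finite beta{where}", row=row, field="beta")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(
                f"standard error must be > 0, got {self.se}{where}",
                row=row, field="se")
        if not (0 < self.pval <= 1):
            raise ValidationError(
                f"p-value must lie in (0, 1], got {self.pval}{where}",
                row=row, field="pval")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(
                f"eaf must lie in (0, 1), got {self.eaf}{where}",
                row=row, field="eaf")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def flipped(self) -> "VariantAssociation":
        """The same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class SummaryTable:
    """An ordered collection of :class:`VariantAssociation` for one trait."""

    trait_name: str
    trait_type: str  # "binary" or "quantitative"
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'quantitative', "
                f"got {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(v for v in ids if ids.count(v) > 1)
            raise ValidationError(
                f"duplicate variant_id {dup!r} in table {self.trait_name!r}")
        self._index = {r.variant_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self._index.get(variant_id)

    def to_frame(self) -> pd.DataFrame:
        """Canonical-column DataFrame view (missing values as NaN)."""
        return pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in self.records],
                "chromosome": [r.chrom for r in self.records],
                "base_pair_location": [r.pos for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "effect_allele_frequency": [
                    np.nan if r.eaf is None else r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "standard_error": [r.se for r in self.records],
                "p_value": [r.pval for r in self.records],
                "n": [np.nan if r.n is None else r.n for r in self.records],
            }
        )


class LDTable:
    """Pairwise LD lookup, symmetric in its arguments.

    ``r2(v, v)`` is 1 and absent pairs are 0, so a table listing only the
    correlated pairs is complete.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._pairs: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(f"r² must lie in [0, 1], got {r2}")
        if a != b:
            self._pairs[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._pairs)

    def items(self) -> Iterable[tuple[tuple[str, str], float]]:
        return self._pairs.items()


def _resolve_columns(header: list[str], column_map: Mapping[str, str] | None
                     ) -> dict[str, str]:
    """Map canonical names to actual file columns, erroring on gaps."""
    column_map = dict(column_map or {})
    resolved = {}
    for canon in CANONICAL_COLUMNS:
        actual = column_map.get(canon, canon)
        if actual in header:
            resolved[canon] = actual
    missing = [c for c in _REQUIRED if c not in resolved]
    if missing:
        raise ConfigurationError(
            f"required column(s) not found in header: {', '.join(missing)}; "
            f"header was {header}")
    return resolved


def _parse_float(raw, row: int, fieldname: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"non-numeric {fieldname} {raw!r} (row {row})",
            row=row, field=fieldname) from None


def read_summary_table(path, column_map: Mapping[str, str] | None = None,
                       trait_name: str | None = None,
                       trait_type: str = "binary") -> SummaryTable:
    """Read a TSV of GWAS summary statistics into a validated table.

    Rows violating a :class:`VariantAssociation` invariant raise a
    :class:`ValidationError` naming the 1-based data row. Input p-values of
    exactly 0 (underflowed exports) are clamped to the smallest positive
    float with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(df.columns), column_map)
    records = []
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, raw))

        def val(canon, default=None):
            v = rowd.get(cols[canon]) if canon in cols else None
            return default if v in (None, "", "NA", "nan", ".") else v

        pval = _parse_float(val("p_value"), i, "p_value")
        if pval == 0.0:
            warnings.warn(
                f"p-value of 0 at row {i} clamped to {_TINY_P:g}")
            pval = _TINY_P
        eaf = val("effect_allele_frequency")
        n = val("n")
        try:
            pos = int(float(val("base_pair_location")))
        except (TypeError, ValueError):
            raise ValidationError(
                f"non-numeric position (row {i})", row=i,
                field="base_pair_location") from None
        rec = VariantAssociation(
            variant_id=str(val("variant_id")),
            chrom=str(val("chromosome")),
            pos=pos,
            effect_allele=str(val("effect_allele")).upper(),
            other_allele=str(val("other_allele")).upper(),
            eaf=None if eaf is None else _parse_float(eaf, i, "eaf"),
            beta=_parse_float(val("beta"), i, "beta"),
            se=_parse_float(val("standard_error"), i, "se"),
            pval=pval,
            n=None if n is None else _parse_float(n, i, "n"),
        )
        rec.validate(row=i)
        records.append(rec)
    name = trait_name if trait_name is not None else str(path)
    return SummaryTable(trait_name=name, trait_type=trait_type,
                        records=records)


def write_summary_table(table: SummaryTable, path) -> None:
    """Write a summary table in the canonical TSV dialect."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format="%.10g")


def read_ld_table(path) -> LDTable:
    """Read a long-format LD table (``id1 TAB id2 TAB r2``)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str},
                     names=["id1", "id2", "r2"], header=None, skiprows=_sniff_header(path))
    ld = LDTable()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            r2 = float(row.r2)
        except (TypeError, ValueError):
            raise ValidationError(
                f"non-numeric r² {row.r2!r} (row {i})", row=i,
                field="r2") from None
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(
                f"r² must lie in [0, 1], got {r2} (row {i})", row=i,
                field="r2")
        ld.set(str(row.id1), str(row.id2), r2)
    return ld


def _sniff_header(path) -> int:
    """LD files may or may not carry a header line; skip one if present."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if len(first) >= 3:
        try:
            float(first[2])
            return 0
        except ValueError:
            return 1
    return 0


def write_ld_table(ld: LDTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("id1\tid2\tr2\n")
        for (a, b), r2 in sorted(ld.items()):
            fh.write(f"{a}\t{b}\t{r2:.10g}\n")


def read_confounder_table(path) -> pd.DataFrame:
    """Read a confounder-association table (``variant_id TAB trait TAB pval``)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["variant_id", "trait", "pval"]
    if list(df.columns)[:3] != expected:
        # headerless form
        df = pd.read_csv(path, sep="\t", header=None, names=expected)
    df["pval"] = df["pval"].astype(float)
    bad = df[(df["pval"] <= 0) | (df["pval"] > 1)]
    if len(bad):
        raise ValidationError(
            f"confounder p-value out of (0, 1] at row {bad.index[0] + 1}")
    return df


RESULTS_COLUMNS = (
    "exposure", "outcome", "method", "nsnp", "beta", "se",
    "ci_low", "ci_high", "pval", "or", "or_ci_low", "or_ci_high",
)


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_results_table(estimates, path) -> None:
    """Write causal estimates as a fixed-column TSV.

    Accepts any iterable of objects exposing the :class:`MREstimate`
    attributes. Odds-ratio columns are filled only for binary outcomes;
    numbers are printed at 6 significant digits.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(RESULTS_COLUMNS) + "\n")
        for est in estimates:
            binary = getattr(est, "outcome_binary", True)
            row = [
                _fmt(getattr(est, "exposure", None)),
                _fmt(getattr(est, "outcome", None)),
                est.method,
                str(est.n_snp),
                _fmt(est.beta),
                _fmt(est.se),
                _fmt(est.ci_low),
                _fmt(est.ci_high),
                _fmt(est.pval),
                _fmt(math.exp(est.beta) if binary else None),
                _fmt(math.exp(est.ci_low) if binary else None),
                _fmt(math.exp(est.ci_high) if binary else None),
            ]
            fh.write("\t".join(row) + "\n")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
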