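"""Cohort-level counting, aggregation and enrichment testing.

Works on per-cohort count rows rather than genotypes: published OCA cohorts
report how many individuals carry both S192Y and R402Q (so the cis haplotype
is *possible*), how many could be phased through relatives (the "informative
cohort"), and in how many of those the haplotype was confirmed in cis and in
trans to a pathogenic TYR variant.  The module aggregates those counts across
cohorts, computes the classic Pearson chi-squared test on the resulting 2x2
screening table (missing-heritability vs molecularly diagnosed), and builds a
structured enrichment report.

Two transcriptions of published per-cohort counts ship with the package
(``data/cohorts_haplotype_screen.tsv`` and
``data/cohorts_phase_informative.tsv``) and feed the ``reproduce-tables``
pipeline.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .core import DataError

__all__ = [
    "CohortGroup",
    "CohortRow",
    "AggregateResult",
    "EnrichmentResult",
    "read_cohort_table",
    "load_packaged_cohorts",
    "round_half_up",
    "aggregate_cohorts",
    "pearson_chi2_2x2",
    "enrichment_report",
]

#: Reporting floor used by the statistical software named in common methods
#: sections; p-values below it are displayed as "< 2.2e-16".
P_FLOOR = 2.2e-16


class CohortGroup(str, enum.Enum):
    MISSING_HERITABILITY = "MISSING_HERITABILITY"
    MOLECULARLY_DIAGNOSED = "MOLECULARLY_DIAGNOSED"
    CONTROL = "CONTROL"


@dataclass(frozen=True)
class CohortRow:
    """Counts for one cohort.

    ``n_hap_possible``: individuals hom or het for both S192Y and R402Q;
    ``n_informative``: of those, individuals whose phase could be determined
    through relatives; ``n_cis_in_trans``: informative individuals in whom the
    haplotype was in cis and in trans to the pathogenic variant.  The latter
    two are None when a study reports no phasing.
    """

    cohort_id: str
    group: CohortGroup
    n_total: int
    n_hap_possible: int
    n_informative: int | None = None
    n_cis_in_trans: int | None = None
    phenotype_desc: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.n_hap_possible <= self.n_total:
            raise DataError(
                f"cohort {self.cohort_id}: need 0 <= n_hap_possible ({self.n_hap_possible}) "
                f"<= n_total ({self.n_total})"
            )
        if self.n_informative is not None:
            if not 0 <= self.n_informative <= self.n_hap_possible:
                raise DataError(
                    f"cohort {self.cohort_id}: need 0 <= n_informative "
                    f"({self.n_informative}) <= n_hap_possible ({self.n_hap_possible})"
                )
            if self.n_cis_in_trans is not None and not (
                0 <= self.n_cis_in_trans <= self.n_informative
            ):
                raise DataError(
                    f"cohort {self.cohort_id}: need 0 <= n_cis_in_trans "
                    f"({self.n_cis_in_trans}) <= n_informative ({self.n_informative})"
                )


def read_cohort_table(path: str | Path) -> list[CohortRow]:
    """Read a cohort TSV: cohort_id, group, n_total, n_hap_possible
    [, n_informative, n_cis_in_trans, phenotype_desc]; NA allowed in the
    optional count columns."""
    df = pd.read_csv(path, sep="\t", dtype={"cohort_id": str}, na_values=["NA"])
    required = {"cohort_id", "group", "n_total", "n_hap_possible"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise DataError(f"{path}: missing columns {sorted(missing_cols)}")
    rows = []
    for rec in df.to_dict("records"):
        def opt(key):
            value = rec.get(key)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return None
            return int(value)

        try:
            group = CohortGroup(rec["group"])
        except ValueError as exc:
            raise DataError(f"{path}: unknown cohort group {rec['group']!r}") from exc
        rows.append(
            CohortRow(
                cohort_id=str(rec["cohort_id"]),
                group=group,
                n_total=int(rec["n_total"]),
                n_hap_possible=int(rec["n_hap_possible"]),
                n_informative=opt("n_informative"),
                n_cis_in_trans=opt("n_cis_in_trans"),
                phenotype_desc=str(rec.get("phenotype_desc", "") or ""),
            )
        )
    return rows


def load_packaged_cohorts() -> tuple[list[CohortRow], list[CohortRow]]:
    """The packaged (screen, phase-informative) cohort count tables."""
    base = resources.files("ocaphase").joinpath("data")
    with resources.as_file(base.joinpath("cohorts_haplotype_screen.tsv")) as p:
        screen = read_cohort_table(p)
    with resources.as_file(base.joinpath("cohorts_phase_informative.tsv")) as p:
        phase = read_cohort_table(p)
    return screen, phase


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (table-style: 25.45 -> 25.5, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AggregateResult:
    k: int
    n: int
    pct: float

    def as_dict(self) -> dict:
        return {"k": self.k, "n": self.n, "pct": self.pct}


def aggregate_cohorts(
    rows: Sequence[CohortRow],
    group: CohortGroup | None = None,
    numerator: str = "n_hap_possible",
    denominator: str = "n_total",
) -> AggregateResult:
    """Sum ``numerator``/``denominator`` over (optionally filtered) cohorts.

    Returns the combined count pair and the percentage rounded half-up to one
    decimal, matching published table formatting.  Rows with a missing (None)
    numerator are excluded with a warning; an empty selection is an error.
    """
    selected = [r for r in rows if group is None or r.group is group]
    if not selected:
        raise DataError(f"no cohort rows in group {group}")
    usable = []
    for row in selected:
        if getattr(row, numerator) is None or getattr(row, denominator) is None:
            warnings.warn(
                f"cohort {row.cohort_id}: {numerator}/{denominator} unavailable; excluded",
                stacklevel=2,
            )
        else:
            usable.append(row)
    if not usable:
        raise DataError(f"all cohort rows in group {group} lack {numerator}")
    k = sum(getattr(r, numerator) for r in usable)
    n = sum(getattr(r, denominator) for r in usable)
    pct = round_half_up(100.0 * k / n, 1) if n else 0.0
    return AggregateResult(k, n, pct)


@dataclass(frozen=True)
class EnrichmentResult:
    """Pearson chi-squared test on a 2x2 table of (hit, miss) per group."""

    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    df: int
    p: float
    correction: bool
    proportions: dict = field(default_factory=dict)

    @property
    def p_display(self) -> str:
        return f"< {P_FLOOR:g}" if self.p < P_FLOOR else f"{self.p:.4g}"

    def as_dict(self) -> dict:
        return {
            "table": [list(self.table[0]), list(self.table[1])],
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "p_display": self.p_display,
            "correction": self.correction,
            "proportions": self.proportions,
        }


def pearson_chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> EnrichmentResult:
    """Pearson chi-squared for the 2x2 table [[a, b], [c, d]] with df = 1.

    chi2 = N (|ad - bc| - corr)^2 / ((a+b)(c+d)(a+c)(b+d)), corr = N/2 when
    Yates' continuity correction is on (the conventional default for 2x2
    tables in mainstream statistical software) and 0 otherwise; the corrected
    |ad - bc| is clamped at zero.  The exact double-precision p-value is kept;
    ``p_display`` renders the conventional "< 2.2e-16" floor.
    """
    for name, value in zip("abcd", (a, b, c, d)):
        if value < 0:
            raise DataError(f"count {name} = {value} is negative")
    n = a + b + c + d
    margins = {"row1": a + b, "row2": c + d, "col1": a + c, "col2": b + d}
    degenerate = [name for name, m in margins.items() if m == 0]
    if degenerate:
        raise DataError(f"degenerate margin(s) {degenerate}: chi-squared is undefined")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff**2 / (margins["row1"] * margins["row2"] * margins["col1"] * margins["col2"])
    p = float(stats.chi2.sf(chi2, df=1))
    proportions = {
        "row1": {"k": a, "n": a + b, "pct": round_half_up(100.0 * a / (a + b), 1)},
        "row2": {"k": c, "n": c + d, "pct": round_half_up(100.0 * c / (c + d), 1)},
    }
    return EnrichmentResult(
        table=((a, b), (c, d)),
        chi2=float(chi2),
        df=1,
        p=p,
        correction=yates,
        proportions=proportions,
    )


def enrichment_report(
    screen_rows: Sequence[CohortRow],
    phase_rows: Sequence[CohortRow] | None = None,
    yates: bool = True,
) -> dict:
    """Structured report: combined proportions, pairwise tests, phasing summary.

    ``screen_rows`` must span at least two cohort groups.  When
    ``phase_rows`` (phase-informative counts, missing-heritability cohorts)
    are given, the report adds the combined informative-cohort cis-in-trans
    proportion and the cohort-level diagnostic-uplift proportion.
    """
    groups = sorted({r.group for r in screen_rows}, key=lambda g: g.value)
    if len(groups) < 2:
        raise DataError(f"enrichment report needs >=2 cohort groups, got {[g.value for g in groups]}")
    report: dict = {"schema_version": 1, "groups": {}, "per_cohort": [], "tests": {}}
    for g in groups:
        report["groups"][g.value] = aggregate_cohorts(screen_rows, group=g).as_dict()
    for row in screen_rows:
        report["per_cohort"].append(
            {
                "cohort_id": row.cohort_id,
                "group": row.group.value,
                "k": row.n_hap_possible,
                "n": row.n_total,
                "pct": round_half_up(100.0 * row.n_hap_possible / row.n_total, 1)
                if row.n_total
                else 0.0,
            }
        )
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            r1 = aggregate_cohorts(screen_rows, group=g1)
            r2 = aggregate_cohorts(screen_rows, group=g2)
            result = pearson_chi2_2x2(r1.k, r1.n - r1.k, r2.k, r2.n - r2.k, yates=yates)
            uncorrected = pearson_chi2_2x2(r1.k, r1.n - r1.k, r2.k, r2.n - r2.k, yates=False)
            report["tests"][f"{g1.value}_vs_{g2.value}"] = {
                "corrected": result.as_dict(),
                "uncorrected": uncorrected.as_dict(),
            }
    if phase_rows:
        informative = aggregate_cohorts(
            phase_rows, numerator="n_cis_in_trans", denominator="n_informative"
        )
        uplift = aggregate_cohorts(
            phase_rows, numerator="n_cis_in_trans", denominator="n_total"
        )
        report["informative_cis_in_trans"] = informative.as_dict()
        report["diagnostic_uplift"] = uplift.as_dict()
        report["per_cohort_uplift"] = [
            {
                "cohort_id": r.cohort_id,
                "k": r.n_cis_in_trans,
                "n": r.n_total,
                "pct": round_half_up(100.0 * r.n_cis_in_trans / r.n_total, 1)
                if r.n_cis_in_trans is not None and r.n_total
                else None,
            }
            for r in phase_rows
        ]
    return report
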