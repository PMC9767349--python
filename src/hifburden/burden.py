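"""Gene-level case-control burden testing by carrier collapsing.

For each gene, individuals are collapsed to a binary carrier status
(at least one qualifying variant) and a 2x2 contingency table of
carrier status against case/control status is tested with a two-sided
Fisher exact test.  Effect size is the unconditional cross-product odds
ratio with a Woolf (log-normal) confidence interval,

    exp( ln(ad/bc) +/- z * sqrt(1/a + 1/b + 1/c + 1/d) ),

with the Haldane-Anscombe +0.5 correction applied to every cell of a
table with a zero cell (for the OR/CI only, never for the exact p).
Significance is flagged at a nominal two-sided p < alpha; a
Benjamini-Hochberg adjusted column is reported for transparency but
does not drive the flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .observations import BURDEN, QualifyingCriteria, VariantObservation
from .prioritize import filter_qualifying
from .render import format_p, format_ratio


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier/non-carrier by case/control counts for one gene.

    a: case carriers, b: control carriers,
    c: case non-carriers, d: control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or cell != int(cell):
                raise ValueError(f"cells must be non-negative integers: {self}")

    @property
    def n_cases(self) -> int:
        return self.a + self.c

    @property
    def n_controls(self) -> int:
        return self.b + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Uses the minimum-likelihood convention: sum of hypergeometric point
    probabilities over all tables with the observed margins whose
    probability does not exceed the observed table's (with a small
    relative tolerance for floating-point ties).  A table with a zero
    margin carries no information and returns p = 1.
    """
    if table.total == 0:
        return 1.0
    if 0 in (table.a + table.b, table.c + table.d, table.n_cases, table.n_controls):
        return 1.0
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def odds_ratio(table: ContingencyTable2x2) -> float:
    """Unconditional cross-product odds ratio (a*d)/(b*c).

    Returns +inf when b*c == 0 with a*d > 0, and NaN (undefined) when
    both products are zero.
    """
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def woolf_ci(
    table: ContingencyTable2x2, level: float = 0.95
) -> tuple[float, float]:
    """Woolf log-normal confidence interval for the odds ratio.

    Tables with any zero cell receive the Haldane-Anscombe +0.5
    correction in every cell before the interval is computed.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    z = stats.norm.ppf(0.5 + level / 2.0)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def carrier_matrix(
    observations: Sequence[VariantObservation],
    individuals: Sequence[str],
    genes: Sequence[str],
) -> pd.DataFrame:
    """Per-individual, per-gene boolean carrier matrix.

    An individual is a carrier of a gene when it has at least one
    observation there; multiple variants in one gene still yield a
    single True.  Observations referencing individuals outside
    ``individuals`` are an error (they would silently distort margins).
    """
    known = set(individuals)
    mat = pd.DataFrame(False, index=list(individuals), columns=list(genes))
    for obs in observations:
        if obs.individual_id not in known:
            raise ValueError(
                f"observation references unknown individual {obs.individual_id!r}"
            )
        if obs.gene in mat.columns:
            mat.loc[obs.individual_id, obs.gene] = True
    return mat


def build_table(
    carriers: pd.Series, labels: Mapping[str, str]
) -> ContingencyTable2x2:
    """2x2 table from one gene's carrier vector and case/control labels."""
    unlabeled = [i for i in carriers.index if i not in labels]
    if unlabeled:
        raise ValueError(f"individuals without case/control label: {unlabeled[:5]}")
    is_case = pd.Series(
        [labels[i] == "case" for i in carriers.index], index=carriers.index
    )
    carr = carriers.astype(bool)
    return ContingencyTable2x2(
        a=int((carr & is_case).sum()),
        b=int((carr & ~is_case).sum()),
        c=int((~carr & is_case).sum()),
        d=int((~carr & ~is_case).sum()),
    )


@dataclass(frozen=True)
class BurdenResult:
    """Per-gene burden test output."""

    gene: str
    table: ContingencyTable2x2
    p_two_sided: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    significant: bool = False
    zero_cell_corrected: bool = False


def test_gene(
    gene: str, table: ContingencyTable2x2, alpha: float = 0.05
) -> BurdenResult:
    """Fisher p, cross-product OR and Woolf CI for one gene's table."""
    p = fisher_exact_two_sided(table)
    lo, hi = woolf_ci(table)
    return BurdenResult(
        gene=gene,
        table=table,
        p_two_sided=p,
        odds_ratio=odds_ratio(table),
        ci_low=lo,
        ci_high=hi,
        significant=p < alpha,
        zero_cell_corrected=0 in (table.a, table.b, table.c, table.d),
    )


def burden_scan(
    carriers: pd.DataFrame,
    labels: Mapping[str, str],
    genes: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> list[BurdenResult]:
    """Burden test every gene; deterministic order by (p, gene symbol)."""
    genes = list(genes) if genes is not None else list(carriers.columns)
    results = [
        test_gene(g, build_table(carriers[g], labels), alpha=alpha) for g in genes
    ]
    return sorted(results, key=lambda r: (r.p_two_sided, r.gene))


def results_frame(results: Sequence[BurdenResult]) -> pd.DataFrame:
    """Tabular burden results with a BH-adjusted p column appended."""
    rows = [
        {
            "gene": r.gene,
            "case_carriers": r.table.a,
            "control_carriers": r.table.b,
            "case_noncarriers": r.table.c,
            "control_noncarriers": r.table.d,
            "p": r.p_two_sided,
            "odds_ratio": r.odds_ratio,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "significant": r.significant,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_bh"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
    else:
        frame["p_bh"] = pd.Series(dtype=float)
    return frame


class BurdenModel:
    """Case-control carrier-collapsing burden model.

    Built either from qualifying variant observations plus case/control
    labels, from a prebuilt carrier matrix, or directly from per-gene
    2x2 counts.  ``fit`` runs the per-gene Fisher scan and returns a
    :class:`BurdenResults`.
    """

    def __init__(
        self,
        carriers: pd.DataFrame,
        labels: Mapping[str, str],
        tables: Optional[dict[str, ContingencyTable2x2]] = None,
    ):
        self.carriers = carriers
        self.labels = dict(labels)
        self._tables = tables

    @classmethod
    def from_observations(
        cls,
        observations: Sequence[VariantObservation],
        labels: Mapping[str, str],
        genes: Optional[Sequence[str]] = None,
        criteria: QualifyingCriteria = BURDEN,
    ) -> "BurdenModel":
        """Qualify observations, collapse carriers, and build the model."""
        qualifying = filter_qualifying(observations, criteria)
        if genes is None:
            genes = sorted({obs.gene for obs in qualifying})
        individuals = list(labels)
        return cls(carrier_matrix(qualifying, individuals, genes), labels)

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, tuple[int, int, int, int]]
    ) -> "BurdenModel":
        """Model directly from per-gene (a, b, c, d) carrier counts."""
        tables = {g: ContingencyTable2x2(*abcd) for g, abcd in counts.items()}
        return cls(carriers=pd.DataFrame(), labels={}, tables=tables)

    def fit(self, alpha: float = 0.05) -> "BurdenResults":
        if self._tables is not None:
            results = sorted(
                (test_gene(g, t, alpha=alpha) for g, t in self._tables.items()),
                key=lambda r: (r.p_two_sided, r.gene),
            )
        else:
            results = burden_scan(self.carriers, self.labels, alpha=alpha)
        return BurdenResults(self, results, alpha=alpha)


class BurdenResults:
    """Fitted burden scan: per-gene tables, p-values, ORs and CIs."""

    def __init__(self, model: BurdenModel, results: list[BurdenResult], alpha: float):
        self.model = model
        self.results = results
        self.alpha = alpha
        self.frame = results_frame(results)

    def __getitem__(self, gene: str) -> BurdenResult:
        for r in self.results:
            if r.gene == gene:
                return r
        raise KeyError(gene)

    @property
    def significant_genes(self) -> list[str]:
        return [r.gene for r in self.results if r.significant]

    def summary(self) -> str:
        lines = [
            "Gene-level burden scan (two-sided Fisher exact, "
            f"alpha={self.alpha:g}, Woolf 95% CI)",
            f"{'gene':<10}{'carriers':>14}{'p (FET)':>12}{'OR (95% CI)':>24}  sig",
        ]
        for r in self.results:
            carr = f"{r.table.a}/{r.table.n_cases} vs {r.table.b}/{r.table.n_controls}"
            or_ci = (
                f"{format_ratio(r.odds_ratio)} "
                f"({format_ratio(r.ci_low)} to {format_ratio(r.ci_high)})"
            )
            lines.append(
                f"{r.gene:<10}{carr:>14}{format_p(r.p_two_sided):>12}"
                f"{or_ci:>24}  {'*' if r.significant else ''}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
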