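"""Hypoxia-response differential expression and regulon-fraction analysis.

The analysis contrasts hypoxia against normoxia within a sample group,
requires a gene to reach significance under two independent
differential-expression tests, intersects the two calls (with direction
concordance), and then asks what fraction of the intersected DE genes
belongs to a HIF-1 regulon gene set.  Comparing that fraction between
proband and control cells quantifies how much of the hypoxia response
is HIF-1 mediated in each group.

The two tests are deliberately different in kind:

* method A — Welch two-sample t-test on log2(FPKM), an
  expression-level linear-model style test;
* method B — negative-binomial Wald test on raw counts with
  median-of-ratios size factors and method-of-moments dispersion,
  a count-model style test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .observations import GeneSet
from .render import format_percent, percent

#: pseudo-count added to raw counts before FPKM scaling so that zero
#: counts stay finite on the log scale
FPKM_OFFSET = 1e-4


@dataclass
class ExpressionExperiment:
    """Gene-by-sample count matrix with lengths and sample metadata.

    ``samples`` is indexed by sample id with columns ``group``
    (proband/control), ``condition`` (normoxia/hypoxia), ``individual``
    and ``replicate`` (biological/technical).
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.gene_lengths.index.equals(self.counts.index):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def sample_ids(self, group: str, condition: str) -> list[str]:
        meta = self.samples
        mask = (meta["group"] == group) & (meta["condition"] == condition)
        return [s for s in self.counts.columns if s in meta.index[mask]]

    def collapse_technical(self) -> "ExpressionExperiment":
        """Average technical replicates to one sample per individual
        and condition (rounded back to integer counts)."""
        meta = self.samples
        key = meta["individual"].astype(str) + ":" + meta["condition"].astype(str)
        grouped = {}
        newmeta = []
        for k in key.unique():
            ids = key.index[key == k]
            grouped[k] = self.counts[ids].mean(axis=1).round().astype(int)
            first = meta.loc[ids[0]]
            newmeta.append(
                {
                    "sample": k,
                    "group": first["group"],
                    "condition": first["condition"],
                    "individual": first["individual"],
                    "replicate": "biological",
                }
            )
        counts = pd.DataFrame(grouped)
        samples = pd.DataFrame(newmeta).set_index("sample")
        return ExpressionExperiment(counts, self.gene_lengths, samples)


def fpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, offset: float = FPKM_OFFSET
) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped reads.

    ``(count + offset) * 1e9 / (length * library_size)`` with the
    library size taken as the raw (un-offset) column total.  The small
    offset keeps zero counts strictly positive for log-scale testing.
    """
    libsize = counts.sum(axis=0).astype(float)
    if (libsize == 0).any():
        bad = list(libsize.index[libsize == 0])
        raise ValueError(f"zero library size for samples: {bad}")
    lengths = gene_lengths.reindex(counts.index).astype(float)
    scale = 1e9 / np.outer(lengths.to_numpy(), libsize.to_numpy())
    return pd.DataFrame(
        (counts.to_numpy() + offset) * scale,
        index=counts.index,
        columns=counts.columns,
    )


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def _finish_frame(genes: pd.Index, lfc: np.ndarray, p: np.ndarray) -> pd.DataFrame:
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "lfc": lfc,
            "p": p,
            "p_adj": _bh(p),
            "direction": np.sign(lfc).astype(int),
        },
        index=genes,
    )


def de_test_welch(
    experiment: ExpressionExperiment,
    test_samples: Sequence[str],
    ref_samples: Sequence[str],
) -> pd.DataFrame:
    """Method A: Welch t-test per gene on log2(FPKM).

    The log fold change is the difference of group means of
    log2(FPKM); genes with zero variance in both groups get p = 1.
    """
    if len(test_samples) < 2 or len(ref_samples) < 2:
        raise ValueError("need at least two samples on each side")
    values = np.log2(fpkm(experiment.counts, experiment.gene_lengths))
    x = values[list(test_samples)].to_numpy()
    y = values[list(ref_samples)].to_numpy()
    lfc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        p = np.asarray(res.pvalue)
    flat = (x.var(axis=1, ddof=1) == 0) & (y.var(axis=1, ddof=1) == 0)
    p = np.where(flat | ~np.isfinite(p), 1.0, p)
    return _finish_frame(experiment.genes, lfc, p)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes expressed everywhere."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    ref = np.exp(np.log(arr[positive]).mean(axis=1))
    sf = np.median(arr[positive] / ref[:, None], axis=0)
    return pd.Series(sf, index=counts.columns)


def de_test_nb(
    experiment: ExpressionExperiment,
    test_samples: Sequence[str],
    ref_samples: Sequence[str],
) -> pd.DataFrame:
    """Method B: negative-binomial Wald test per gene on raw counts.

    Counts are normalized by median-of-ratios size factors; the NB
    dispersion is a per-gene method-of-moments estimate pooled across
    the two groups (floored at 1e-8); the Wald statistic is the log
    mean ratio over its delta-method standard error.  Genes with zero
    counts throughout are excluded from testing and reported p = 1.
    """
    if len(test_samples) < 2 or len(ref_samples) < 2:
        raise ValueError("need at least two samples on each side")
    both = list(test_samples) + list(ref_samples)
    sub = experiment.counts[both]
    sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    n1, n0 = len(test_samples), len(ref_samples)
    x, y = norm[:, :n1], norm[:, n1:]

    mu1, mu0 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v0 = y.var(axis=1, ddof=1)
    df1, df0 = n1 - 1, n0 - 1
    num = df1 * (v1 - mu1) + df0 * (v0 - mu0)
    den = df1 * mu1**2 + df0 * mu0**2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    alpha = np.clip(alpha, 1e-8, None)

    all_zero = (mu1 == 0) & (mu0 == 0)
    m1 = np.clip(mu1, 1e-8, None)
    m0 = np.clip(mu0, 1e-8, None)
    lfc = np.log2(m1 / m0)
    se = np.sqrt((1.0 / m1 + alpha) / n1 + (1.0 / m0 + alpha) / n0)
    z = np.log(m1 / m0) / se
    # the moment dispersion estimate is noisy at small n; referring the
    # Wald statistic to t with the pooled residual df (rather than the
    # normal) keeps the test close to nominal size
    p = 2.0 * stats.t.sf(np.abs(z), df=n1 + n0 - 2)
    p = np.where(all_zero, 1.0, p)
    lfc = np.where(all_zero, 0.0, lfc)
    return _finish_frame(experiment.genes, lfc, p)


@dataclass(frozen=True)
class DEIntersection:
    """Genes significant under both methods with concordant direction."""

    genes: tuple[str, ...]
    n_up: int
    n_down: int
    n_discordant: int

    @property
    def total(self) -> int:
        return len(self.genes)


def intersect_de(
    result_a: pd.DataFrame,
    result_b: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    require_same_direction: bool = True,
) -> DEIntersection:
    """Two-method intersection of differential-expression calls.

    A gene is differentially expressed when it passes ``alpha`` under
    both methods (on BH-adjusted p by default) and, if required, both
    methods agree on the direction of change.  The up/down split is
    taken from method B's fold-change sign.
    """
    if set(result_a.index) != set(result_b.index):
        raise ValueError("the two results cover different gene universes")
    b = result_b.reindex(result_a.index)
    col = "p_adj" if use_adjusted else "p"
    sig = (result_a[col] < alpha) & (b[col] < alpha)
    concordant = (result_a["direction"] * b["direction"]) > 0
    n_discordant = int((sig & ~concordant).sum())
    if require_same_direction:
        sig = sig & concordant
    genes = tuple(sorted(result_a.index[sig]))
    up = int((b.loc[list(genes), "direction"] > 0).sum()) if genes else 0
    return DEIntersection(
        genes=genes, n_up=up, n_down=len(genes) - up, n_discordant=n_discordant
    )


@dataclass(frozen=True)
class FractionResult:
    """Overlap of a DE gene list with a regulon gene set."""

    n_de: int
    n_overlap: int
    universe_size: int
    regulon_size: int
    p_enrichment: float

    @property
    def fraction(self) -> float:
        if self.n_de == 0:
            return math.nan
        return self.n_overlap / self.n_de

    @property
    def as_percent(self) -> float:
        return percent(self.fraction) if self.n_de else math.nan

    def render(self) -> str:
        if self.n_de == 0:
            return "NA (no DE genes)"
        return f"{format_percent(self.fraction)} ({self.n_overlap}/{self.n_de})"


def regulon_fraction(
    de_genes: Sequence[str], regulon: GeneSet, universe: Sequence[str]
) -> FractionResult:
    """Fraction of DE genes in the regulon, with hypergeometric
    upper-tail enrichment p over the tested gene universe."""
    uni = set(universe)
    de = set(de_genes)
    if not de <= uni:
        raise ValueError("de_genes must be a subset of the universe")
    reg = regulon.members & uni
    k = len(de & reg)
    n_de = len(de)
    if n_de == 0:
        return FractionResult(0, 0, len(uni), len(reg), 1.0)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(reg), n_de))
    return FractionResult(n_de, k, len(uni), len(reg), min(p, 1.0))


@dataclass(frozen=True)
class FractionComparison:
    """Ratio of two regulon fractions with a two-proportion z test."""

    ratio: float
    p_value: float


def compare_fractions(
    fraction_test: FractionResult, fraction_ref: FractionResult
) -> FractionComparison:
    """Test fraction relative to reference fraction (ratio < 1 means the
    regulon is under-represented in the test DE set)."""
    if fraction_test.n_de == 0 or fraction_ref.n_de == 0:
        return FractionComparison(math.nan, 1.0)
    if fraction_ref.fraction == 0:
        return FractionComparison(math.nan, 1.0)
    ratio = fraction_test.fraction / fraction_ref.fraction
    counts = np.array([fraction_test.n_overlap, fraction_ref.n_overlap])
    nobs = np.array([fraction_test.n_de, fraction_ref.n_de])
    _, p = proportions_ztest(counts, nobs, alternative="two-sided")
    return FractionComparison(ratio, float(p))


def highfold_filter(
    results: pd.DataFrame, min_fold: float = 3.0, direction: str = "up"
) -> list[str]:
    """Genes with fold change strictly beyond ``min_fold``.

    Fold change is ``2**lfc``; ``direction='down'`` selects genes with
    fold change strictly below ``1/min_fold``.
    """
    if min_fold <= 0:
        raise ValueError("min_fold must be positive")
    threshold = math.log2(min_fold)
    if direction == "up":
        mask = results["lfc"] > threshold
    elif direction == "down":
        mask = results["lfc"] < -threshold
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    return sorted(results.index[mask])


class HypoxiaResponseModel:
    """Hypoxia-vs-normoxia response model for proband and control cells.

    ``fit`` runs both DE tests within each group, intersects the calls,
    computes each group's regulon fraction, and compares the fractions.
    """

    def __init__(
        self,
        experiment: ExpressionExperiment,
        regulon: GeneSet,
        alpha: float = 0.05,
        use_adjusted: bool = True,
        collapse_technical: bool = True,
    ):
        self.experiment = (
            experiment.collapse_technical() if collapse_technical else experiment
        )
        self.regulon = regulon
        self.alpha = alpha
        self.use_adjusted = use_adjusted

    def fit(self) -> "HypoxiaResponseResults":
        de: dict[tuple[str, str], pd.DataFrame] = {}
        intersections: dict[str, DEIntersection] = {}
        fractions: dict[str, FractionResult] = {}
        universe = list(self.experiment.genes)
        for group in ("control", "proband"):
            test = self.experiment.sample_ids(group, "hypoxia")
            ref = self.experiment.sample_ids(group, "normoxia")
            res_a = de_test_welch(self.experiment, test, ref)
            res_b = de_test_nb(self.experiment, test, ref)
            inter = intersect_de(
                res_a,
                res_b,
                alpha=self.alpha,
                use_adjusted=self.use_adjusted,
            )
            de[(group, "welch")] = res_a
            de[(group, "nb")] = res_b
            intersections[group] = inter
            fractions[group] = regulon_fraction(inter.genes, self.regulon, universe)
        comparison = compare_fractions(fractions["proband"], fractions["control"])
        return HypoxiaResponseResults(self, de, intersections, fractions, comparison)


class HypoxiaResponseResults:
    """Fitted hypoxia-response analysis."""

    def __init__(self, model, de, intersections, fractions, comparison):
        self.model = model
        self.de = de
        self.intersections = intersections
        self.fractions = fractions
        self.comparison = comparison

    @property
    def fraction_ratio(self) -> float:
        """Proband regulon fraction relative to control."""
        return self.comparison.ratio

    def high_fold_regulon_genes(
        self, group: str = "control", min_fold: float = 3.0, direction: str = "up"
    ) -> list[str]:
        """Regulon members with strong hypoxia response in one group
        (per the Welch log-FPKM fold change)."""
        strong = highfold_filter(
            self.de[(group, "welch")], min_fold=min_fold, direction=direction
        )
        return [g for g in strong if g in self.model.regulon]

    def summary(self) -> str:
        lines = ["Hypoxia response: two-method DE intersection and regulon fraction"]
        for group in ("control", "proband"):
            inter = self.intersections[group]
            frac = self.fractions[group]
            lines.append(
                f"  {group:<8} DE both methods: {inter.total} "
                f"({inter.n_up} up, {inter.n_down} down, "
                f"{inter.n_discordant} discordant dropped); "
                f"regulon fraction {frac.render()}, "
                f"enrichment p={frac.p_enrichment:.3g}"
            )
        lines.append(
            f"  proband/control fraction ratio: {self.comparison.ratio:.3f} "
            f"(two-proportion p={self.comparison.p_value:.3g})"
        )
        return "\n".join(lines)
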