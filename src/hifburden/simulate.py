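"""Synthetic cohorts and RNA-seq experiments for pipeline testing.

The study data this package analyses (controlled-access germline
sequencing and fibroblast RNA-seq) cannot be redistributed, so this
module generates synthetic inputs with the statistical structure the
analysis assumes: a case/control cohort with per-gene qualifying-variant
carrier rates and case enrichment, trio genotypes with injected de novo
and mosaic events, tumor-only somatic variants, and a hypoxia RNA-seq
experiment in which a HIF-1-style regulon responds to low oxygen with
an attenuated response in proband samples.

All randomness flows from a single ``numpy.random.Generator`` seeded in
the config; identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .expression import ExpressionExperiment
from .observations import (
    Consequence,
    GeneSet,
    Inheritance,
    SampleSource,
    VariantObservation,
    Zygosity,
)

_NUCLEOTIDES = np.array(list("ACGT"))

#: default per-class consequence mixture for simulated variants
DEFAULT_CONSEQUENCE_MIXTURE = {
    Consequence.MISSENSE: 0.55,
    Consequence.NONSENSE: 0.08,
    Consequence.STOP_LOSS: 0.02,
    Consequence.SPLICE_SITE_SNV: 0.05,
    Consequence.CODING_INDEL: 0.10,
    Consequence.SYNONYMOUS: 0.20,
}


def _round_sig(x: float, digits: int = 6) -> float:
    """Round to significant digits, as annotation pipelines print MAFs."""
    if x == 0:
        return 0.0
    return float(f"{x:.{digits}g}")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class GeneSpec:
    """Per-gene carrier model: control carrier probability and the
    multiplicative enrichment of that probability in cases."""

    name: str
    control_carrier_prob: float
    case_enrichment: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.control_carrier_prob <= 1.0):
            raise ConfigurationError(
                f"{self.name}: carrier probability must be in [0, 1]"
            )
        if self.case_enrichment < 1.0:
            raise ConfigurationError(f"{self.name}: enrichment must be >= 1")
        if self.control_carrier_prob * self.case_enrichment > 1.0:
            raise ConfigurationError(
                f"{self.name}: enrichment x carrier probability exceeds 1"
            )

    @property
    def case_carrier_prob(self) -> float:
        return self.control_carrier_prob * self.case_enrichment


#: default gene panel mirroring the carrier-count regimes of a
#: 94-case / 2,054-control enchondromatosis burden study: three genes
#: with strong case enrichment and three without a detectable excess
DEFAULT_GENES = (
    GeneSpec("HIF1A", 37 / 2054, (7 / 94) / (37 / 2054)),
    GeneSpec("VHL", 8 / 2054, (6 / 94) / (8 / 2054)),
    GeneSpec("IDH1", 11 / 2054, (3 / 94) / (11 / 2054)),
    GeneSpec("IDH2", 0.005, 2.0),
    GeneSpec("KDM4C", 0.005, 2.0),
    GeneSpec("CDKN2A", 0.005, 1.5),
)


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of the case/control cohort generator.

    Cohort sizes default to the study design this package emulates
    (94 cases, 2,054 sequenced controls).  Qualifying-variant MAFs are
    drawn log-uniformly inside ``rare_maf_bounds``; background
    (non-qualifying) records mix synonymous and common-MAF variants.
    Mosaic events carry binomially sampled alternate reads at
    ``mosaic_depth`` and ``mosaic_vaf``.
    """

    n_cases: int = 94
    n_controls: int = 2054
    genes: tuple[GeneSpec, ...] = DEFAULT_GENES
    rare_maf_bounds: tuple[float, float] = (1e-5, 5e-3)
    common_maf_bounds: tuple[float, float] = (0.02, 0.5)
    consequence_mixture: dict = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIXTURE)
    )
    background_rate: float = 0.5
    fraction_de_novo: float = 0.10
    fraction_mosaic: float = 0.05
    mosaic_vaf: float = 0.37
    mosaic_depth: int = 54
    fraction_tumor_only: float = 0.02
    fraction_trios: float = 68 / 94
    mean_depth: int = 80
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 0:
            raise ConfigurationError("cohort sizes must be positive")
        if self.mosaic_depth < 1:
            raise ConfigurationError("mosaic_depth must be >= 1")
        for frac_name in (
            "fraction_de_novo",
            "fraction_mosaic",
            "fraction_tumor_only",
            "fraction_trios",
            "mosaic_vaf",
        ):
            value = getattr(self, frac_name)
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{frac_name} must be in [0, 1]")
        total = sum(self.consequence_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"consequence mixture must sum to 1, got {total}"
            )
        if any(p < 0 for p in self.consequence_mixture.values()):
            raise ConfigurationError("mixture probabilities must be >= 0")
        lo, hi = self.rare_maf_bounds
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("rare_maf_bounds must satisfy 0 < lo <= hi < 1")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth emitted alongside a simulated cohort."""

    carriers: pd.DataFrame  # individuals x genes, bool
    variants: pd.DataFrame  # one row per injected variant


def _gene_locus(index: int) -> tuple[str, int]:
    chrom = f"chr{(index % 22) + 1}"
    return chrom, 1_000_000 * (index + 1)


def _draw_consequences(
    rng: np.random.Generator, mixture: dict, size: int, qualifying_only: bool
) -> list[Consequence]:
    classes = list(mixture)
    probs = np.array([mixture[c] for c in classes], dtype=float)
    if qualifying_only:
        keep = [
            i
            for i, c in enumerate(classes)
            if c
            in (
                Consequence.MISSENSE,
                Consequence.NONSENSE,
                Consequence.STOP_LOSS,
                Consequence.SPLICE_SITE_SNV,
            )
        ]
        classes = [classes[i] for i in keep]
        probs = probs[keep]
    probs = probs / probs.sum()
    idx = rng.choice(len(classes), size=size, p=probs)
    return [classes[i] for i in idx]


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[list[VariantObservation], pd.DataFrame, CohortTruth]:
    """Simulate an annotated case/control cohort.

    Returns ``(observations, metadata, truth)``.  Metadata has one row
    per individual (case/control status, disease label for cases, trio
    availability); the truth table records the per-individual carrier
    status for every configured gene and the intended classification of
    every injected qualifying variant.
    """
    rng = np.random.default_rng(config.seed)
    cases = [f"case{i + 1:04d}" for i in range(config.n_cases)]
    controls = [f"ctrl{i + 1:04d}" for i in range(config.n_controls)]
    individuals = cases + controls
    is_case = np.array([True] * config.n_cases + [False] * config.n_controls)

    # disease labels for cases mirror a 71:23 OD:MS cohort split
    n_od = int(round(config.n_cases * 71 / 94))
    diseases = ["OD"] * n_od + ["MS"] * (config.n_cases - n_od)
    has_parents = rng.random(config.n_cases) < config.fraction_trios
    metadata = pd.DataFrame(
        {
            "individual_id": individuals,
            "status": np.where(is_case, "case", "control"),
            "disease": diseases + ["NA"] * config.n_controls,
            "has_parents": list(has_parents) + [False] * config.n_controls,
        }
    ).set_index("individual_id")

    gene_names = [g.name for g in config.genes]
    carrier = np.zeros((len(individuals), len(gene_names)), dtype=bool)
    observations: list[VariantObservation] = []
    truth_rows: list[dict] = []

    for gi, spec in enumerate(config.genes):
        chrom, base = _gene_locus(gi)
        p = np.where(is_case, spec.case_carrier_prob, spec.control_carrier_prob)
        hit = rng.random(len(individuals)) < p
        carrier[:, gi] = hit
        n_hit = int(hit.sum())
        if n_hit == 0:
            continue
        offsets = rng.choice(500_000, size=n_hit, replace=False)
        mafs = np.exp(
            rng.uniform(
                np.log(config.rare_maf_bounds[0]),
                np.log(config.rare_maf_bounds[1]),
                size=n_hit,
            )
        )
        consequences = _draw_consequences(
            rng, config.consequence_mixture, n_hit, qualifying_only=True
        )
        for j, idx in enumerate(np.flatnonzero(hit)):
            ind = individuals[idx]
            ref, alt = rng.choice(_NUCLEOTIDES, size=2, replace=False)
            case_sample = bool(is_case[idx])
            classification = "germline"
            inheritance = Inheritance.UNKNOWN
            source = SampleSource.BLOOD
            total = int(rng.poisson(config.mean_depth)) + 1
            alt_reads = int(rng.binomial(total, 0.5))
            if case_sample:
                u = rng.random()
                if u < config.fraction_tumor_only:
                    classification = "tumor_only"
                    source = SampleSource.TUMOR
                    alt_reads = int(rng.binomial(total, 0.4))
                elif u < config.fraction_tumor_only + config.fraction_mosaic:
                    classification = "mosaic"
                    source = SampleSource.SALIVA
                    inheritance = Inheritance.DE_NOVO
                    total = config.mosaic_depth
                    alt_reads = int(rng.binomial(total, config.mosaic_vaf))
                elif metadata.loc[ind, "has_parents"]:
                    if rng.random() < config.fraction_de_novo:
                        classification = "de_novo"
                        inheritance = Inheritance.DE_NOVO
                    else:
                        inheritance = (
                            Inheritance.MATERNAL
                            if rng.random() < 0.5
                            else Inheritance.PATERNAL
                        )
            obs = VariantObservation(
                individual_id=ind,
                gene=spec.name,
                chrom=chrom,
                pos=base + int(offsets[j]),
                ref=str(ref),
                alt=str(alt),
                consequence=consequences[j],
                maf=_round_sig(float(mafs[j])),
                zygosity=Zygosity.HET,
                alt_reads=min(alt_reads, total),
                total_reads=total,
                sample_source=source,
                inheritance=inheritance,
            )
            observations.append(obs)
            truth_rows.append(
                {
                    "individual_id": ind,
                    "gene": spec.name,
                    "chrom": obs.chrom,
                    "pos": obs.pos,
                    "classification": classification,
                    "inheritance": inheritance.value,
                    "mother_carries": inheritance
                    in (Inheritance.MATERNAL, Inheritance.BIPARENTAL),
                    "father_carries": inheritance
                    in (Inheritance.PATERNAL, Inheritance.BIPARENTAL),
                    "qualifying": True,
                }
            )

    # background records are non-qualifying by construction (they must not
    # perturb the per-gene carrier truth): either synonymous, or a
    # functional consequence at common (>= 2%) population frequency
    n_background = rng.poisson(config.background_rate, size=len(individuals))
    for idx in np.flatnonzero(n_background):
        ind = individuals[idx]
        for _ in range(int(n_background[idx])):
            gi = int(rng.integers(len(gene_names)))
            chrom, base = _gene_locus(gi)
            synonymous = rng.random() < 0.5
            if synonymous:
                consequence = Consequence.SYNONYMOUS
                bounds = config.rare_maf_bounds
            else:
                consequence = _draw_consequences(
                    rng, config.consequence_mixture, 1, qualifying_only=True
                )[0]
                bounds = config.common_maf_bounds
            maf = float(np.exp(rng.uniform(np.log(bounds[0]), np.log(bounds[1]))))
            ref, alt = rng.choice(_NUCLEOTIDES, size=2, replace=False)
            alt_allele = str(alt)
            total = int(rng.poisson(config.mean_depth)) + 1
            observations.append(
                VariantObservation(
                    individual_id=ind,
                    gene=gene_names[gi],
                    chrom=chrom,
                    pos=base + 600_000 + int(rng.integers(100_000)),
                    ref=str(ref),
                    alt=alt_allele,
                    consequence=consequence,
                    maf=_round_sig(maf),
                    zygosity=Zygosity.HET,
                    alt_reads=int(rng.binomial(total, 0.5)),
                    total_reads=total,
                    sample_source=SampleSource.BLOOD,
                    inheritance=Inheritance.UNKNOWN,
                )
            )

    truth = CohortTruth(
        carriers=pd.DataFrame(carrier, index=individuals, columns=gene_names),
        variants=pd.DataFrame(
            truth_rows,
            columns=[
                "individual_id",
                "gene",
                "chrom",
                "pos",
                "classification",
                "inheritance",
                "mother_carries",
                "father_carries",
                "qualifying",
            ],
        ),
    )
    return observations, metadata, truth


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Configuration of the hypoxia RNA-seq generator.

    The layout mirrors the fibroblast experiment the analysis targets:
    control individuals contribute one biological replicate each,
    probands contribute ``n_technical_replicates`` technical replicates,
    and every culture is profiled at normoxia and at hypoxia.  Counts
    are negative binomial with a common dispersion; regulon genes carry
    a hypoxia log2 fold change drawn from a normal distribution, scaled
    by ``proband_attenuation`` in proband samples.
    """

    n_genes: int = 8000
    n_regulon_genes: int = 836
    n_control_individuals: int = 3
    n_proband_individuals: int = 4
    n_technical_replicates: int = 3
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.3
    dispersion: float = 0.05
    regulon_lfc_mean: float = 1.3
    regulon_lfc_sd: float = 1.0
    nonregulon_responsive_fraction: float = 0.30
    nonregulon_lfc_mean: float = 1.3
    nonregulon_lfc_sd: float = 1.0
    proband_attenuation: float = 0.5
    individual_baseline_sd: float = 0.1
    individual_lfc_sd: float = 0.1
    library_size_range: tuple[float, float] = (8e6, 1.2e7)
    gene_length_range: tuple[int, int] = (300, 10_000)
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_regulon_genes",
            "n_control_individuals",
            "n_proband_individuals",
            "n_technical_replicates",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_regulon_genes > self.n_genes:
            raise ConfigurationError("regulon cannot exceed the gene universe")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if not (0.0 <= self.proband_attenuation <= 1.0):
            raise ConfigurationError("proband_attenuation must be in [0, 1]")
        if not (0.0 <= self.nonregulon_responsive_fraction <= 1.0):
            raise ConfigurationError(
                "nonregulon_responsive_fraction must be in [0, 1]"
            )


def simulate_expression(
    config: ExpressionSimConfig,
) -> tuple[ExpressionExperiment, GeneSet, pd.DataFrame]:
    """Simulate a hypoxia/normoxia RNA-seq experiment.

    Returns ``(experiment, regulon, truth)`` where the truth table
    records every gene's true hypoxia log2 fold change per group; by
    construction the proband regulon effect equals the control effect
    times the attenuation multiplier.
    """
    rng = np.random.default_rng(config.seed)
    genes = pd.Index([f"G{i + 1:05d}" for i in range(config.n_genes)], name="gene")
    regulon_idx = rng.choice(config.n_genes, size=config.n_regulon_genes, replace=False)
    is_regulon = np.zeros(config.n_genes, dtype=bool)
    is_regulon[regulon_idx] = True

    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    )
    lengths = pd.Series(
        rng.integers(
            config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
        ),
        index=genes,
        name="length",
    )

    # regulon genes respond to hypoxia (mostly induced); the non-regulon
    # responsive pool draws from the same effect-size distribution by
    # default, so the regulon fraction of a detected DE list reflects
    # pool sizes and attenuation rather than direction- or power-biased
    # detection
    lfc_control = np.zeros(config.n_genes)
    lfc_control[is_regulon] = rng.normal(
        config.regulon_lfc_mean, config.regulon_lfc_sd, config.n_regulon_genes
    )
    nonreg = np.flatnonzero(~is_regulon)
    n_resp = int(round(config.nonregulon_responsive_fraction * len(nonreg)))
    responders = rng.choice(nonreg, size=n_resp, replace=False)
    lfc_control[responders] = rng.normal(
        config.nonregulon_lfc_mean, config.nonregulon_lfc_sd, n_resp
    )
    lfc_proband = lfc_control.copy()
    lfc_proband[is_regulon] = lfc_control[is_regulon] * config.proband_attenuation

    sample_rows = []
    for i in range(config.n_control_individuals):
        for condition in ("normoxia", "hypoxia"):
            sample_rows.append(
                (f"ctrl{i + 1}_{condition}", "control", condition, f"ctrl{i + 1}",
                 "biological")
            )
    for i in range(config.n_proband_individuals):
        for rep in range(config.n_technical_replicates):
            for condition in ("normoxia", "hypoxia"):
                sample_rows.append(
                    (
                        f"prob{i + 1}_r{rep + 1}_{condition}",
                        "proband",
                        condition,
                        f"prob{i + 1}",
                        "technical",
                    )
                )
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "group", "condition", "individual", "replicate"]
    ).set_index("sample")

    # per-individual biological state: each individual (cell line) has its
    # own baseline expression and its own realization of the hypoxia
    # response; technical replicates share that state and differ only by
    # library sampling noise
    individuals = samples["individual"].unique()
    ind_baseline = {}
    ind_lfc = {}
    for ind in individuals:
        group = samples.loc[samples["individual"] == ind, "group"].iloc[0]
        group_lfc = lfc_proband if group == "proband" else lfc_control
        ind_baseline[ind] = baseline * 2.0 ** rng.normal(
            0.0, config.individual_baseline_sd, config.n_genes
        )
        ind_lfc[ind] = group_lfc + rng.normal(
            0.0, config.individual_lfc_sd, config.n_genes
        )

    lib_sizes = rng.uniform(*config.library_size_range, size=len(samples))
    r = 1.0 / config.dispersion
    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    for s, (sample_id, row) in enumerate(samples.iterrows()):
        expected = ind_baseline[row["individual"]] * np.where(
            row["condition"] == "hypoxia", 2.0 ** ind_lfc[row["individual"]], 1.0
        )
        mu = expected / expected.sum() * lib_sizes[s]
        counts[:, s] = rng.negative_binomial(r, r / (r + mu))

    experiment = ExpressionExperiment(
        counts=pd.DataFrame(counts, index=genes, columns=samples.index),
        gene_lengths=lengths,
        samples=samples,
    )
    regulon = GeneSet.from_iterable("HIF1_regulon_synthetic", genes[is_regulon])
    truth = pd.DataFrame(
        {
            "is_regulon": is_regulon,
            "lfc_control": lfc_control,
            "lfc_proband": lfc_proband,
            "baseline_mean": baseline,
        },
        index=genes,
    )
    return experiment, regulon, truth
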