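"""Qualifying-variant prioritization workflow.

Implements the discovery pipeline applied to an annotated case cohort:

1. filter to rare functional ("qualifying") variants;
2. cross-check against a phenotype gene panel;
3. find genes recurrently hit across probands;
4. classify trio inheritance, variant allele fraction and mosaicism,
   and variant origin (germline / post-zygotic / tumor-only);
5. summarize the candidate set (genes, distinct variants, carriers).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from scipy import stats

from .observations import (
    GeneSet,
    Inheritance,
    MosaicStatus,
    QualifyingCriteria,
    SampleSource,
    VariantObservation,
    VariantOrigin,
)
from .render import percent, round_half_up


def filter_qualifying(
    observations: Sequence[VariantObservation],
    criteria: QualifyingCriteria,
) -> list[VariantObservation]:
    """Keep observations passing the consequence/MAF/SNV filter.

    The MAF bound is strict (``maf < max_maf``); input order is preserved.
    """
    return [obs for obs in observations if criteria.admits(obs)]


def crosscheck_panel(
    observations: Sequence[VariantObservation], panel: GeneSet
) -> list[VariantObservation]:
    """Restrict observations to genes in a phenotype panel."""
    if len(panel) == 0:
        raise ValueError("gene panel is empty")
    return [obs for obs in observations if obs.gene in panel]


def cohort_recurrence(
    observations: Sequence[VariantObservation], min_probands: int = 3
) -> list[tuple[str, int]]:
    """Genes hit in at least ``min_probands`` distinct individuals.

    Counts individuals, not observations: a proband carrying two
    variants in the same gene contributes one.  Sorted by carrier count
    descending, then gene symbol.
    """
    if min_probands < 1:
        raise ValueError(f"min_probands must be >= 1, got {min_probands}")
    carriers: dict[str, set[str]] = defaultdict(set)
    for obs in observations:
        carriers[obs.gene].add(obs.individual_id)
    hits = [(g, len(ids)) for g, ids in carriers.items() if len(ids) >= min_probands]
    return sorted(hits, key=lambda t: (-t[1], t[0]))


def classify_inheritance(
    proband_has_allele: bool,
    mother_has_allele: Optional[bool],
    father_has_allele: Optional[bool],
) -> Inheritance:
    """Trio segregation call from allele-presence indicators.

    Missing either parent yields ``unknown``; both parents negative
    yields ``de_novo``; both parents positive yields the ambiguous
    inherited label ``maternal+paternal``.
    """
    if not proband_has_allele:
        raise ValueError("proband does not carry the allele under test")
    if mother_has_allele is None or father_has_allele is None:
        return Inheritance.UNKNOWN
    if mother_has_allele and father_has_allele:
        return Inheritance.BIPARENTAL
    if mother_has_allele:
        return Inheritance.MATERNAL
    if father_has_allele:
        return Inheritance.PATERNAL
    return Inheritance.DE_NOVO


def compute_vaf(alt_reads: int, total_reads: int) -> tuple[float, str]:
    """Variant allele fraction and its rounded-percent rendering.

    Returns ``(alt/total, "NN%")`` with the percentage rounded half-up
    to the nearest integer (20/54 -> 0.370..., "37%").
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not (0 <= alt_reads <= total_reads):
        raise ValueError("alt_reads must be in [0, total_reads]")
    vaf = alt_reads / total_reads
    return vaf, f"{round_half_up(100.0 * vaf, 0):.0f}%"


def flag_mosaic(
    obs: VariantObservation,
    expected_het_vaf: float = 0.5,
    alpha: float = 0.01,
    max_mosaic_vaf: float = 0.45,
    min_depth: int = 20,
) -> MosaicStatus:
    """Classify a heterozygous call as constitutional or mosaic-candidate.

    A call is a mosaic candidate when the VAF is below
    ``max_mosaic_vaf`` AND an exact two-sided binomial test of the
    alternate-read count against the expected heterozygous fraction
    rejects at ``alpha``.  Calls without read support, or with depth
    below ``min_depth``, are ``insufficient_data``: at shallow depth the
    binomial test cannot distinguish mosaicism from sampling noise.
    """
    if obs.alt_reads is None or obs.total_reads is None:
        return MosaicStatus.INSUFFICIENT_DATA
    if obs.total_reads < min_depth:
        return MosaicStatus.INSUFFICIENT_DATA
    vaf = obs.alt_reads / obs.total_reads
    p = stats.binomtest(obs.alt_reads, obs.total_reads, expected_het_vaf).pvalue
    if vaf < max_mosaic_vaf and p < alpha:
        return MosaicStatus.MOSAIC_CANDIDATE
    return MosaicStatus.CONSISTENT_HET


def classify_origin(
    presence: Mapping[SampleSource, bool],
    mosaic_flag: MosaicStatus = MosaicStatus.CONSISTENT_HET,
) -> VariantOrigin:
    """Variant origin from per-sample-type presence and the mosaic flag.

    ``somatic_tumor_only`` when seen only in tumor tissue;
    ``post_zygotic_mosaic`` when present in a constitutional sample
    (blood/saliva) with a mosaic-candidate VAF; otherwise ``germline``.
    """
    present = {src for src, seen in presence.items() if seen}
    if not present:
        raise ValueError("variant is present in no sample")
    constitutional = present - {SampleSource.TUMOR}
    if not constitutional:
        return VariantOrigin.SOMATIC_TUMOR_ONLY
    if mosaic_flag is MosaicStatus.MOSAIC_CANDIDATE:
        return VariantOrigin.POST_ZYGOTIC_MOSAIC
    return VariantOrigin.GERMLINE


def variant_origins(
    observations: Sequence[VariantObservation],
) -> dict[tuple[str, tuple[str, int, str, str]], VariantOrigin]:
    """Origin call for every (individual, variant identity) pair.

    Presence maps are assembled from the observations themselves; the
    mosaic flag is taken from the constitutional record with the
    deepest coverage, if any.
    """
    groups: dict[tuple, list[VariantObservation]] = defaultdict(list)
    for obs in observations:
        groups[(obs.individual_id, obs.variant_id)].append(obs)
    origins = {}
    for key, group in groups.items():
        presence = {src: False for src in SampleSource}
        for obs in group:
            presence[obs.sample_source] = True
        constitutional = [
            o for o in group if o.sample_source is not SampleSource.TUMOR
        ]
        flag = MosaicStatus.CONSISTENT_HET
        if constitutional:
            with_reads = [o for o in constitutional if o.total_reads is not None]
            if with_reads:
                deepest = max(with_reads, key=lambda o: o.total_reads)
                flag = flag_mosaic(deepest)
        origins[key] = classify_origin(presence, flag)
    return origins


@dataclass(frozen=True)
class CandidateSummary:
    """Aggregate description of a candidate variant set.

    Tumor-only somatic records are excluded from variant counts; the
    germline/post-zygotic candidates define the proband carrier set.
    ``per_disease`` maps disease label to ``(n_carriers, percent)``
    where the percentage is over that disease's cohort size.
    """

    n_genes: int
    n_distinct_variants: int
    n_observations: int
    n_probands: int
    cohort_size: int
    per_disease: dict[str, tuple[int, float]]

    @property
    def percent_probands(self) -> float:
        if self.cohort_size == 0:
            return 0.0
        return percent(self.n_probands / self.cohort_size)


def summarize_candidates(
    observations: Sequence[VariantObservation],
    disease_labels: Mapping[str, str],
) -> CandidateSummary:
    """Summarize a candidate observation set against the full cohort.

    ``disease_labels`` maps every cohort individual (carrier or not) to
    its disease label, so per-disease denominators are cohort sizes.
    Distinct variants are genomic identities (chrom, pos, ref, alt);
    observations and distinct-variant counts exclude pairs classified
    ``somatic_tumor_only``.
    """
    origins = variant_origins(observations)
    kept = {
        key
        for key, origin in origins.items()
        if origin is not VariantOrigin.SOMATIC_TUMOR_ONLY
    }
    genes = set()
    variants = set()
    probands = set()
    for obs in observations:
        key = (obs.individual_id, obs.variant_id)
        if key not in kept:
            continue
        genes.add(obs.gene)
        variants.add(obs.variant_id)
        probands.add(obs.individual_id)

    cohort_by_disease: dict[str, int] = defaultdict(int)
    for disease in disease_labels.values():
        cohort_by_disease[disease] += 1
    per_disease = {}
    for disease in sorted(cohort_by_disease):
        n = sum(1 for p in probands if disease_labels.get(p) == disease)
        denom = cohort_by_disease[disease]
        per_disease[disease] = (n, percent(n / denom) if denom else 0.0)

    return CandidateSummary(
        n_genes=len(genes),
        n_distinct_variants=len(variants),
        n_observations=len(kept),
        n_probands=len(probands),
        cohort_size=len(disease_labels),
        per_disease=per_disease,
    )
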