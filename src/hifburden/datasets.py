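"""Packaged reference fixtures.

Small plain-text datasets encoding the published summary data of the
enchondromatosis (Ollier disease / Maffucci syndrome) germline study
that this package's pipeline reproduces:

* the 26 annotated candidate-variant observations across 21 probands
  (with trio inheritance, mosaic read support, and one tumor-only
  somatic call), plus case metadata for the full 94-proband cohort;
* the published per-gene carrier counts for the 94-case vs
  2,054-control burden comparison (HIF1A, VHL, IDH1);
* the six-gene enchondroma phenotype panel;
* a small illustrative HIF-1 regulated gene list.  The full curated
  836-gene HIF-1 regulon is not redistributable and must be supplied
  by the user (the synthetic generator produces a labelled stand-in).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .burden import ContingencyTable2x2
from .observations import GeneSet, VariantObservation
from .vcfio import frame_to_observations, read_gene_panel, read_gmt


def _data_path(name: str):
    return resources.files("hifburden.data") / name


def discovery_cohort() -> tuple[list[VariantObservation], pd.DataFrame]:
    """Candidate-variant observations and metadata for the 94-proband
    discovery cohort (21 carriers of 26 annotated observations)."""
    with resources.as_file(_data_path("discovery_observations.tsv")) as p:
        frame = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    observations = frame_to_observations(frame, path="discovery_observations.tsv")
    with resources.as_file(_data_path("discovery_metadata.tsv")) as p:
        metadata = pd.read_csv(p, sep="\t").set_index("individual_id")
    return observations, metadata


def burden_tables() -> dict[str, ContingencyTable2x2]:
    """Published carrier/non-carrier contingency counts per gene."""
    with resources.as_file(_data_path("burden_counts.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
    return {
        row["gene"]: ContingencyTable2x2(
            a=int(row["case_carriers"]),
            b=int(row["control_carriers"]),
            c=int(row["case_noncarriers"]),
            d=int(row["control_noncarriers"]),
        )
        for _, row in frame.iterrows()
    }


def enchondroma_panel() -> GeneSet:
    """Six genes associated with enchondroma phenotypes."""
    with resources.as_file(_data_path("enchondroma_panel.txt")) as p:
        return read_gene_panel(p, name="enchondroma_panel")


def hif1_illustrative_regulon() -> GeneSet:
    """Small illustrative HIF-1 regulated gene list (not the full
    curated 836-gene regulon, which is user-supplied)."""
    with resources.as_file(_data_path("hif1_illustrative.gmt")) as p:
        return read_gmt(p)["HIF1_ILLUSTRATIVE"]
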