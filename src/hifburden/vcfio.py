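"""Reading and writing annotated variant data and gene sets.

VCF 4.2 is the primary on-disk interchange format, with the annotation
carried in INFO keys:

    GENE      gene symbol (String)
    CSQ       consequence class (String, one of the Consequence values)
    GNOMAD_AF population minor allele frequency (Float; absent means 0)
    TRANSCRIPT, PCHANGE, CADD   optional annotations
    SRC       DNA source of the call (blood / saliva / tumor)
    INH       trio inheritance call

plus FORMAT GT:AD:DP for zygosity and read support.  A flat TSV with
one observation per row (columns named after VariantObservation fields)
is accepted as an equivalent input.  Gene panels are one symbol per
line; gene sets use the GMT format.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import pysam

from .observations import (
    Consequence,
    GeneSet,
    Inheritance,
    SampleSource,
    VariantObservation,
    Zygosity,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed record, with the offending file and locus named."""


_TSV_COLUMNS = [
    "individual_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "transcript",
    "protein_change",
    "consequence",
    "maf",
    "zygosity",
    "alt_reads",
    "total_reads",
    "sample_source",
    "inheritance",
    "cadd",
]


def _round_sig(x: float, digits: int = 6) -> float:
    if x == 0 or not math.isfinite(x):
        return float(x)
    return float(f"{x:.{digits}g}")


def _vcf_header(individual: str, contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig, length=300_000_000)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQ", 1, "String", "Functional consequence class")
    header.info.add("GNOMAD_AF", 1, "Float", "gnomAD minor allele frequency")
    header.info.add("TRANSCRIPT", 1, "String", "Transcript annotation")
    header.info.add("PCHANGE", 1, "String", "Protein change")
    header.info.add("CADD", 1, "Float", "CADD score (carried annotation)")
    header.info.add("SRC", 1, "String", "DNA source (blood/saliva/tumor)")
    header.info.add("INH", 1, "String", "Trio inheritance call")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(individual)
    return header


def write_cohort(
    observations: Sequence[VariantObservation],
    metadata: pd.DataFrame,
    out_dir: PathLike,
) -> list[Path]:
    """Write one VCF 4.2 per individual plus a ``metadata.tsv``.

    Every individual in ``metadata`` gets a VCF (possibly with zero
    records).  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_individual: dict[str, list[VariantObservation]] = {
        ind: [] for ind in metadata.index
    }
    for obs in observations:
        by_individual.setdefault(obs.individual_id, []).append(obs)

    paths = []
    for individual, group in by_individual.items():
        contigs = sorted({o.chrom for o in group})
        header = _vcf_header(individual, contigs)
        path = out / f"{individual}.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for obs in sorted(group, key=lambda o: (o.chrom, o.pos, o.ref, o.alt)):
                rec = vcf.new_record(
                    contig=obs.chrom,
                    start=obs.pos - 1,
                    alleles=(obs.ref, obs.alt),
                )
                rec.info["GENE"] = obs.gene
                rec.info["CSQ"] = obs.consequence.value
                if obs.maf > 0:
                    rec.info["GNOMAD_AF"] = obs.maf
                if obs.transcript:
                    rec.info["TRANSCRIPT"] = obs.transcript
                if obs.protein_change:
                    rec.info["PCHANGE"] = obs.protein_change
                if obs.cadd is not None:
                    rec.info["CADD"] = obs.cadd
                rec.info["SRC"] = obs.sample_source.value
                rec.info["INH"] = obs.inheritance.value
                sample = rec.samples[individual]
                sample["GT"] = (1, 1) if obs.zygosity is Zygosity.HOM else (0, 1)
                if obs.alt_reads is not None and obs.total_reads is not None:
                    sample["AD"] = (obs.total_reads - obs.alt_reads, obs.alt_reads)
                    sample["DP"] = obs.total_reads
                vcf.write(rec)
        paths.append(path)

    meta_path = out / "metadata.tsv"
    metadata.to_csv(meta_path, sep="\t")
    paths.append(meta_path)
    return paths


def _parse_enum(enum_cls, raw: str, path, locus, field_name):
    try:
        return enum_cls(raw)
    except ValueError:
        raise ParseError(
            f"{path}: {locus}: unknown {field_name} {raw!r}"
        ) from None


def parse_vcf(path: PathLike) -> list[VariantObservation]:
    """Parse one single-sample annotated VCF into observations."""
    path = Path(path)
    observations = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if len(sample_names) != 1:
            raise ParseError(f"{path}: expected exactly one sample per VCF")
        individual = sample_names[0]
        for rec in vcf:
            locus = f"{rec.chrom}:{rec.pos}"
            info = rec.info
            if "GENE" not in info or "CSQ" not in info:
                raise ParseError(f"{path}: {locus}: missing GENE/CSQ annotation")
            consequence = _parse_enum(
                Consequence, info["CSQ"], path, locus, "consequence"
            )
            source = _parse_enum(
                SampleSource, info.get("SRC", "blood"), path, locus, "sample source"
            )
            inheritance = _parse_enum(
                Inheritance, info.get("INH", "unknown"), path, locus, "inheritance"
            )
            sample = rec.samples[individual]
            gt = sample.get("GT")
            zygosity = Zygosity.HOM if gt == (1, 1) else Zygosity.HET
            alt_reads = total_reads = None
            ad = sample.get("AD")
            if ad is not None and ad[0] is not None:
                alt_reads = int(ad[1])
                dp = sample.get("DP")
                total_reads = int(dp) if dp is not None else int(ad[0]) + int(ad[1])
            maf = info.get("GNOMAD_AF", 0.0)
            cadd = info.get("CADD", None)
            if len(rec.alts or ()) != 1:
                raise ParseError(f"{path}: {locus}: expected a single ALT allele")
            observations.append(
                VariantObservation(
                    individual_id=individual,
                    gene=str(info["GENE"]),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    consequence=consequence,
                    maf=_round_sig(float(maf)),
                    zygosity=zygosity,
                    transcript=info.get("TRANSCRIPT", None),
                    protein_change=info.get("PCHANGE", None),
                    alt_reads=alt_reads,
                    total_reads=total_reads,
                    sample_source=source,
                    inheritance=inheritance,
                    cadd=_round_sig(float(cadd)) if cadd is not None else None,
                )
            )
    return observations


def parse_cohort(
    paths: Union[PathLike, Sequence[PathLike]],
) -> list[VariantObservation]:
    """Parse a cohort from VCF files, a directory of VCFs, or a TSV."""
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        if p.is_dir():
            paths = sorted(p.glob("*.vcf"))
        elif p.suffix in (".tsv", ".txt"):
            return read_observations_tsv(p)
        else:
            paths = [p]
    observations = []
    for path in paths:
        observations.extend(parse_vcf(path))
    return observations


def observations_to_frame(
    observations: Sequence[VariantObservation],
) -> pd.DataFrame:
    rows = []
    for o in observations:
        rows.append(
            {
                "individual_id": o.individual_id,
                "gene": o.gene,
                "chrom": o.chrom,
                "pos": o.pos,
                "ref": o.ref,
                "alt": o.alt,
                "transcript": o.transcript,
                "protein_change": o.protein_change,
                "consequence": o.consequence.value,
                "maf": o.maf,
                "zygosity": o.zygosity.value,
                "alt_reads": o.alt_reads,
                "total_reads": o.total_reads,
                "sample_source": o.sample_source.value,
                "inheritance": o.inheritance.value,
                "cadd": o.cadd,
            }
        )
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def frame_to_observations(frame: pd.DataFrame, path="<frame>") -> list[VariantObservation]:
    observations = []
    for i, row in frame.iterrows():
        locus = f"row {i}"

        def _opt(name, cast):
            value = row.get(name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return None
            if isinstance(value, str) and value in ("", "NA"):
                return None
            return cast(value)

        observations.append(
            VariantObservation(
                individual_id=str(row["individual_id"]),
                gene=str(row["gene"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                consequence=_parse_enum(
                    Consequence, str(row["consequence"]), path, locus, "consequence"
                ),
                maf=float(row["maf"]) if not pd.isna(row["maf"]) else 0.0,
                zygosity=_parse_enum(
                    Zygosity, str(row.get("zygosity", "het")), path, locus, "zygosity"
                ),
                transcript=_opt("transcript", str),
                protein_change=_opt("protein_change", str),
                alt_reads=_opt("alt_reads", lambda v: int(float(v))),
                total_reads=_opt("total_reads", lambda v: int(float(v))),
                sample_source=_parse_enum(
                    SampleSource,
                    str(row.get("sample_source", "blood")),
                    path,
                    locus,
                    "sample source",
                ),
                inheritance=_parse_enum(
                    Inheritance,
                    str(row.get("inheritance", "unknown")),
                    path,
                    locus,
                    "inheritance",
                ),
                cadd=_opt("cadd", float),
            )
        )
    return observations


def read_observations_tsv(path: PathLike) -> list[VariantObservation]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"individual_id", "gene", "chrom", "pos", "ref", "alt", "consequence"} - set(
        frame.columns
    )
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    return frame_to_observations(frame, path=path)


def write_observations_tsv(
    observations: Sequence[VariantObservation], path: PathLike
) -> None:
    observations_to_frame(observations).to_csv(path, sep="\t", index=False)


def read_metadata(path: PathLike) -> pd.DataFrame:
    # "NA" is a meaningful label (e.g. controls without a disease), not
    # a missing value
    meta = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    if "individual_id" not in meta.columns:
        raise ParseError(f"{path}: metadata needs an individual_id column")
    return meta.set_index("individual_id")


def read_gene_panel(path: PathLike, name: Optional[str] = None) -> GeneSet:
    """Gene panel: one symbol per line, blank lines and # comments skipped."""
    path = Path(path)
    genes = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return GeneSet.from_iterable(name or path.stem, genes)


def read_gmt(path: PathLike) -> dict[str, GeneSet]:
    """Read a GMT file: name <tab> description <tab> member genes."""
    sets = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: GMT needs >= 3 fields")
        name, _desc, *genes = fields
        sets[name] = GeneSet.from_iterable(name, [g for g in genes if g])
    return sets


def write_gmt(gene_sets: Iterable[GeneSet], path: PathLike, description: str = "-") -> None:
    lines = [
        "\t".join([gs.name, description, *sorted(gs.members)]) for gs in gene_sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
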