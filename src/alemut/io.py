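"""Readers and writers for every external format the pipeline touches.

Variant tables are TSV (one row per variant x sample observation) or a
minimal VCF 4.x subset; annotation is GFF3 plus operon/pathway membership
TSVs; references and protein alignments are FASTA; PSSMs, counts, designs
and reports are TSV; growth curves are CSV. All coordinates are 1-based
inclusive throughout.
"""

from __future__ import annotations

import csv
import math
import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AMINO_ACIDS,
    CallerClass,
    ConfidenceFlag,
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    GrowthCurve,
    ProfileModel,
    Role,
    SampleMeta,
    ValidationError,
    VariantCall,
    validate_cohort,
)


class ParseError(ValueError):
    """Raised for malformed input rows; message names the offending line."""


# ---------------------------------------------------------------------------
# sample metadata

SAMPLE_COLUMNS = ["sample_id", "role", "stage_index", "stage_label"]


def read_samples(path: str | os.PathLike) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    samples = []
    for i, row in df.iterrows():
        try:
            samples.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    role=Role(row["role"]),
                    stage_index=int(row["stage_index"]),
                    stage_label=row.get("stage_label", ""),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}, line {i + 2}: {exc}") from exc
    validate_cohort(samples)
    return samples


def write_samples(samples: Sequence[SampleMeta], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "role": s.role.value,
                "stage_index": s.stage_index,
                "stage_label": s.stage_label,
            }
            for s in samples
        ],
        columns=SAMPLE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant tables

VARIANT_COLUMNS = [
    "sample_id",
    "chrom",
    "position",
    "ref",
    "alt",
    "caller_class",
    "confidence_flag",
    "allele_frequency",
]


def read_variant_table(
    path: str | os.PathLike, samples: Sequence[SampleMeta]
) -> list[VariantCall]:
    """Read per-sample variant observations from TSV or minimal VCF.

    Files ending in ``.vcf`` go through the VCF path; anything else is read
    as TSV with header columns ``sample_id, position, ref, alt,
    caller_class, confidence_flag`` and optional ``chrom`` /
    ``allele_frequency``. Unknown sample ids are rejected.
    """
    if str(path).endswith(".vcf"):
        return _read_variant_vcf(path, samples)
    roles = {s.sample_id: s.role for s in samples}
    calls: list[VariantCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file, expected a header line")
        required = {"sample_id", "position", "ref", "alt", "caller_class", "confidence_flag"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                sid = row["sample_id"]
                if sid not in roles:
                    raise ValidationError(f"unknown sample_id {sid!r}")
                af_raw = (row.get("allele_frequency") or "").strip()
                af = float(af_raw) if af_raw else None
                calls.append(
                    VariantCall(
                        sample_id=sid,
                        chrom=row.get("chrom") or "ref",
                        position=int(row["position"]),
                        ref_allele=row["ref"],
                        alt_allele=row["alt"],
                        caller_class=CallerClass(row["caller_class"]),
                        confidence_flag=ConfidenceFlag(row["confidence_flag"]),
                        allele_frequency=af,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    return calls


def _read_variant_vcf(path: str | os.PathLike, samples: Sequence[SampleMeta]) -> list[VariantCall]:
    from cyvcf2 import VCF

    roles = {s.sample_id: s.role for s in samples}
    vcf = VCF(str(path))
    for sid in vcf.samples:
        if sid not in roles:
            raise ValidationError(f"VCF sample {sid!r} not in cohort metadata")
    calls: list[VariantCall] = []
    for rec in vcf:
        cls = CallerClass(rec.INFO.get("CLASS", "snp"))
        flag = ConfidenceFlag(rec.INFO.get("CONF", "hc"))
        afs = rec.format("AF")
        for i, sid in enumerate(vcf.samples):
            gt = rec.genotypes[i]
            if not any(a == 1 for a in gt[:-1]):
                continue
            af = None
            if afs is not None and not math.isnan(float(afs[i][0])):
                af = float(afs[i][0])
            # VCF encodes indels with an anchor base; convert to the
            # table convention ("-" on the empty side, position at the
            # first affected base).
            ref, alt, pos = rec.REF, rec.ALT[0], rec.POS
            if len(ref) > 1 and alt == ref[0]:
                ref, alt, pos = ref[1:], "-", pos + 1
            elif len(alt) > 1 and ref == alt[0]:
                ref, alt, pos = "-", alt[1:], pos + 1
            calls.append(
                VariantCall(
                    sample_id=sid,
                    chrom=rec.CHROM,
                    position=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    caller_class=cls,
                    confidence_flag=flag,
                    allele_frequency=af,
                )
            )
    return calls


def write_variant_table(calls: Sequence[VariantCall], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "position": c.position,
                "ref": c.ref_allele,
                "alt": c.alt_allele,
                "caller_class": c.caller_class.value,
                "confidence_flag": c.confidence_flag.value,
                "allele_frequency": "" if c.allele_frequency is None else repr(c.allele_frequency),
            }
            for c in calls
        ],
        columns=VARIANT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation

def read_annotation(
    gff_path: str | os.PathLike,
    operon_path: Optional[str | os.PathLike] = None,
    pathway_path: Optional[str | os.PathLike] = None,
) -> GenomeAnnotation:
    """Build a :class:`GenomeAnnotation` from GFF3 plus membership TSVs.

    Gene coordinates come from ``CDS`` features (falling back to ``gene``
    features that have no CDS child) carrying ``locus_tag`` attributes.
    Reference length is taken from the ``##sequence-region`` directive.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    reference_length = 0
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            reference_length = int(directive.split()[-1])
    genes: dict[str, Gene] = {}
    for ftype in ("CDS", "gene"):
        for feat in db.features_of_type(ftype):
            tag = feat.attributes.get("locus_tag", [feat.id])[0]
            if tag in genes:
                continue
            product = feat.attributes.get("product", [""])[0]
            genes[tag] = Gene(tag, feat.start, feat.end, feat.strand, product)
    operons = _read_membership(operon_path, ordered=True) if operon_path else {}
    pathways = (
        {k: set(v) for k, v in _read_membership(pathway_path, ordered=True).items()}
        if pathway_path
        else {}
    )
    return GenomeAnnotation(
        genes=list(genes.values()),
        operons=operons,
        pathways=pathways,
        reference_length=reference_length,
    )


def _read_membership(path: str | os.PathLike, ordered: bool) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("group_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}, line {lineno}: expected 2 columns, got {len(parts)}")
            groups.setdefault(parts[0], []).append(parts[1])
    return groups


def write_annotation(
    annotation: GenomeAnnotation,
    gff_path: str | os.PathLike,
    operon_path: Optional[str | os.PathLike] = None,
    pathway_path: Optional[str | os.PathLike] = None,
    chrom: str = "ref",
) -> None:
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom} 1 {annotation.reference_length}\n")
        for g in annotation.genes:
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag};product={g.product}"
            fh.write(
                f"{chrom}\talemut\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{chrom}\talemut\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID=cds-{g.locus_tag};Parent={g.locus_tag};locus_tag={g.locus_tag};"
                f"product={g.product}\n"
            )
    if operon_path is not None:
        _write_membership(annotation.operons, operon_path)
    if pathway_path is not None:
        _write_membership({k: sorted(v) for k, v in annotation.pathways.items()}, pathway_path)


def _write_membership(groups: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tlocus_tag\n")
        for gid in groups:
            for tag in groups[gid]:
                fh.write(f"{gid}\t{tag}\n")


# ---------------------------------------------------------------------------
# sequences

def read_reference(path: str | os.PathLike) -> tuple[str, str]:
    """Read a single-contig reference FASTA; returns (name, sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"expected a single-contig reference, found {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def write_reference(name: str, sequence: str, path: str | os.PathLike) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_msa(path: str | os.PathLike) -> MultipleSeqAlignment:
    return AlignIO.read(str(path), "fasta")


# ---------------------------------------------------------------------------
# PSSMs

def read_pssm(path: str | os.PathLike) -> ProfileModel:
    """Read a profile scoring matrix TSV.

    Leading ``#key=value`` comment lines carry model metadata (model_id,
    domain_locus, protein_start, protein_end); the table has one row per
    domain position and one column per residue.
    """
    meta: dict[str, str] = {}
    rows = []
    header: Optional[list[str]] = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
            elif header is None:
                header = line.split("\t")
            elif line:
                rows.append(line.split("\t"))
    if header is None:
        raise ParseError(f"{path}: no PSSM table found")
    df = pd.DataFrame(rows, columns=header)
    df = df.drop(columns=[c for c in df.columns if c == "position"])
    df = df.astype(float)
    return ProfileModel(
        model_id=meta.get("model_id", Path(path).stem),
        domain_locus=meta.get("domain_locus", ""),
        protein_start=int(meta.get("protein_start", 1)),
        protein_end=int(meta.get("protein_end", len(df))),
        pssm=df,
    )


def write_pssm(model: ProfileModel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#model_id={model.model_id}\n")
        fh.write(f"#domain_locus={model.domain_locus}\n")
        fh.write(f"#protein_start={model.protein_start}\n")
        fh.write(f"#protein_end={model.protein_end}\n")
        fh.write("position\t" + "\t".join(AMINO_ACIDS) + "\n")
        for pos, row in model.pssm.iterrows():
            fh.write(str(pos) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# expression

def read_counts(
    counts_path: str | os.PathLike, design_path: str | os.PathLike
) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", dtype={"sample": str, "condition": str})
    design["replicate"] = design["replicate"].astype(int)
    return ExpressionMatrix(counts=counts[list(design["sample"])], design=design)


def write_counts(
    matrix: ExpressionMatrix,
    counts_path: str | os.PathLike,
    design_path: str | os.PathLike,
) -> None:
    matrix.counts.rename_axis("locus_tag").to_csv(counts_path, sep="\t")
    matrix.design.to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# growth curves

def read_growth_csv(path: str | os.PathLike) -> GrowthCurve:
    """Read one growth curve CSV.

    ``#strain=`` / ``#condition=`` comment lines carry identity; columns are
    ``time``, ``od`` and optional ``product_<name>`` / ``substrate_<name>``.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, float_precision="round_trip")
    products = {
        c[len("product_"):]: df[c].to_numpy() for c in df.columns if c.startswith("product_")
    }
    substrates = {
        c[len("substrate_"):]: df[c].to_numpy() for c in df.columns if c.startswith("substrate_")
    }
    return GrowthCurve(
        strain=meta.get("strain", ""),
        condition=meta.get("condition", ""),
        times=df["time"].to_numpy(),
        od=df["od"].to_numpy(),
        products=products,
        substrates=substrates,
    )


def write_growth_csv(curve: GrowthCurve, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#strain={curve.strain}\n#condition={curve.condition}\n")
        cols = ["time", "od"]
        cols += [f"product_{n}" for n in curve.products]
        cols += [f"substrate_{n}" for n in curve.substrates]
        fh.write(",".join(cols) + "\n")
        for i in range(len(curve.times)):
            row = [repr(float(curve.times[i])), repr(float(curve.od[i]))]
            row += [repr(float(curve.products[n][i])) for n in curve.products]
            row += [repr(float(curve.substrates[n][i])) for n in curve.substrates]
            fh.write(",".join(row) + "\n")


# ---------------------------------------------------------------------------
# reports

def write_report(partition, hotspots, de_calls, growth_stats, outdir: str | os.PathLike) -> None:
    """Write machine-readable TSVs plus a human-readable summary.

    Accepts ``None`` for any section; re-running on the same inputs is
    byte-identical. ``partition`` is a
    :class:`~alemut.cohort.PanGenomePartition`, ``hotspots`` a list of
    :class:`~alemut.cohort.Hotspot`, ``de_calls`` a list of
    :class:`~alemut.expression.DECall`, ``growth_stats`` a list of
    :class:`~alemut.growth.AncovaResult`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: list[str] = ["mutation-cohort analysis report", ""]

    rows = []
    if partition is not None:
        for label in ("core", "shared", "unique", "discarded"):
            for vid in sorted(getattr(partition, label)):
                rows.append({"variant_id": vid, "class": label})
        summary.append(
            "pan-genome partition: "
            + ", ".join(
                f"{label}={len(getattr(partition, label))}"
                for label in ("core", "shared", "unique", "discarded")
            )
        )
    pd.DataFrame(rows, columns=["variant_id", "class"]).to_csv(
        outdir / "partition.tsv", sep="\t", index=False
    )

    rows = []
    if hotspots:
        for h in hotspots:
            per_gene = ";".join(
                f"{g}({sum(1 for v in h.member_variants if h.variant_genes[v] == g)})"
                for g in h.member_genes
            )
            rows.append(
                {
                    "hotspot_id": h.hotspot_id,
                    "n_mutations": len(h.member_variants),
                    "grouping_basis": h.grouping_basis,
                    "genes": per_gene,
                    "core_anchor": h.core_anchor,
                    "products": h.products,
                }
            )
        summary.append(f"hotspots: {len(hotspots)}")
    pd.DataFrame(
        rows,
        columns=["hotspot_id", "n_mutations", "grouping_basis", "genes", "core_anchor", "products"],
    ).to_csv(outdir / "hotspots.tsv", sep="\t", index=False)

    rows = []
    if de_calls:
        for d in de_calls:
            rows.append(
                {
                    "locus_tag": d.locus_tag,
                    "contrast": d.contrast,
                    "log2_diff": d.log2_diff,
                    "p_value": d.p_value,
                    "neg_log10_p": d.neg_log10_p,
                    "significant": d.significant,
                }
            )
        summary.append(
            f"differential expression: {sum(d.significant for d in de_calls)} significant "
            f"of {len(de_calls)} gene x contrast tests"
        )
    pd.DataFrame(
        rows,
        columns=["locus_tag", "contrast", "log2_diff", "p_value", "neg_log10_p", "significant"],
    ).to_csv(outdir / "de_calls.tsv", sep="\t", index=False)

    rows = []
    if growth_stats:
        for a in growth_stats:
            rows.append(
                {
                    "comparison": a.comparison,
                    "model_form": a.model_form,
                    "coefficient": a.coefficient,
                    "p_value": a.p_value,
                    "significant": a.significant,
                }
            )
        summary.append(f"growth comparisons: {len(growth_stats)}")
    pd.DataFrame(
        rows, columns=["comparison", "model_form", "coefficient", "p_value", "significant"]
    ).to_csv(outdir / "growth_comparisons.tsv", sep="\t", index=False)

    (outdir / "summary.txt").write_text("\n".join(summary) + "\n")
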