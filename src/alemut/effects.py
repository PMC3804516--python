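"""Coding-effect classification of mutations.

SNPs inside a CDS are classified by translating the reference and mutant
codons with the bacterial/archaeal genetic code (translation table 11):
synonymous (SYN), non-synonymous (NONSYN) or premature stop (STOP). Any
insertion or deletion is a single INDEL class regardless of frame
(frameshift status is kept as metadata only). Everything outside annotated
CDS is NONCODING, optionally assigned to the gene whose translation start
lies downstream within an upstream window — intergenic mutations often hit
promoters of the operon they precede.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .types import CallerClass, Gene, GenomeAnnotation, ValidationError, VariantCall

#: default upstream-assignment window (bp); wide enough for typical
#: promoter-proximal hits while excluding gene-desert mutations.
DEFAULT_UPSTREAM_WINDOW = 500


@dataclass(frozen=True)
class EffectAnnotation:
    """Predicted coding effect of one variant (per overlapping gene)."""

    variant_id: str
    effect: str  # SYN | NONSYN | STOP | INDEL | NONCODING
    locus_tag: Optional[str] = None
    codon_index: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    assigned_gene: Optional[str] = None
    frameshift: Optional[bool] = None  # metadata only, for INDELs inside a CDS


def _codon_change(
    variant: VariantCall, gene: Gene, reference: str
) -> tuple[int, str, str]:
    """Return (codon_index, ref_codon, alt_codon) on the coding strand."""
    pos0 = variant.position - 1
    if gene.strand == "+":
        cds_offset = variant.position - gene.start
        alt_base = variant.alt_allele
    else:
        cds_offset = gene.end - variant.position
        alt_base = str(Seq(variant.alt_allele).reverse_complement())
    codon_index = cds_offset // 3
    within = cds_offset % 3
    if gene.strand == "+":
        codon_start = gene.start - 1 + codon_index * 3
        ref_codon = reference[codon_start : codon_start + 3]
    else:
        codon_end = gene.end - codon_index * 3
        ref_codon = str(Seq(reference[codon_end - 3 : codon_end]).reverse_complement())
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    return codon_index + 1, ref_codon, alt_codon


def classify_effect(
    variant: VariantCall,
    annotation: GenomeAnnotation,
    reference: str,
    window: int = DEFAULT_UPSTREAM_WINDOW,
) -> list[EffectAnnotation]:
    """Classify one variant; one annotation per overlapping CDS.

    Returns a single-element list for the common case; variants overlapping
    two annotated CDS are reported once per gene. SNP reference alleles are
    checked against the reference sequence (data-integrity guard).
    """
    genes = annotation.genes_at(variant.position)
    is_snp = (
        variant.caller_class is CallerClass.SNP
        and len(variant.ref_allele) == 1
        and len(variant.alt_allele) == 1
        and variant.ref_allele != "-"
        and variant.alt_allele != "-"
    )
    if is_snp:
        actual = reference[variant.position - 1]
        if actual != variant.ref_allele:
            raise ValidationError(
                f"ref allele mismatch at {variant.position}: table says "
                f"{variant.ref_allele}, reference has {actual}"
            )
    if not genes:
        assigned = assign_noncoding(variant, annotation, window=window)
        return [
            EffectAnnotation(
                variant_id=variant.variant_id, effect="NONCODING", assigned_gene=assigned
            )
        ]
    out = []
    for gene in genes:
        if not is_snp:
            shift = None
            if variant.ref_allele == "-":
                shift = len(variant.alt_allele) % 3 != 0
            elif variant.alt_allele == "-":
                shift = len(variant.ref_allele) % 3 != 0
            out.append(
                EffectAnnotation(
                    variant_id=variant.variant_id,
                    effect="INDEL",
                    locus_tag=gene.locus_tag,
                    frameshift=shift,
                )
            )
            continue
        codon_index, ref_codon, alt_codon = _codon_change(variant, gene, reference)
        ref_aa = str(Seq(ref_codon).translate(table=11))
        alt_aa = str(Seq(alt_codon).translate(table=11))
        if alt_aa == "*" and ref_aa != "*":
            effect = "STOP"
        elif ref_aa == alt_aa:
            effect = "SYN"
        else:
            effect = "NONSYN"
        out.append(
            EffectAnnotation(
                variant_id=variant.variant_id,
                effect=effect,
                locus_tag=gene.locus_tag,
                codon_index=codon_index,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
            )
        )
    return out


def assign_noncoding(
    variant: VariantCall,
    annotation: GenomeAnnotation,
    window: int = DEFAULT_UPSTREAM_WINDOW,
) -> Optional[str]:
    """Assign an intergenic variant to the nearest downstream gene start.

    The candidate gene's translation start must lie downstream of the
    variant *on that gene's strand* within ``window`` bp; the nearest start
    wins. Returns ``None`` when no start is within the window. Calling this
    on a position inside a CDS is a precondition violation.
    """
    if annotation.genes_at(variant.position):
        raise ValidationError(
            f"position {variant.position} lies inside a CDS; upstream assignment undefined"
        )
    best: tuple[int, str] | None = None
    for g in annotation.genes:
        if g.strand == "+":
            dist = g.start - variant.position
        else:
            dist = variant.position - g.end
        if 0 < dist <= window and (best is None or dist < best[0]):
            best = (dist, g.locus_tag)
    return best[1] if best else None


def annotate_variants(
    variants: Sequence[VariantCall],
    annotation: GenomeAnnotation,
    reference: str,
    window: int = DEFAULT_UPSTREAM_WINDOW,
) -> list[EffectAnnotation]:
    """Annotate distinct variants (one pass per variant id, not per sample)."""
    seen: set[str] = set()
    out: list[EffectAnnotation] = []
    for v in variants:
        if v.variant_id in seen:
            continue
        seen.add(v.variant_id)
        out.extend(classify_effect(v, annotation, reference, window=window))
    return out


@dataclass
class EffectDistribution:
    """Counts per effect class with headline ratios."""

    counts: dict[str, int]
    fraction_noncoding: float
    nonsyn_to_syn_ratio: float

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def tabulate_effects(annotations: Sequence[EffectAnnotation]) -> EffectDistribution:
    """Distribution over distinct variants (first annotation per variant)."""
    primary: dict[str, str] = {}
    for a in annotations:
        primary.setdefault(a.variant_id, a.effect)
    counts = {k: 0 for k in ("SYN", "NONSYN", "STOP", "INDEL", "NONCODING")}
    for eff in primary.values():
        counts[eff] += 1
    n = len(primary)
    frac_nc = counts["NONCODING"] / n if n else 0.0
    ratio = counts["NONSYN"] / counts["SYN"] if counts["SYN"] else math.inf
    return EffectDistribution(
        counts=counts, fraction_noncoding=frac_nc, nonsyn_to_syn_ratio=ratio
    )


def write_effects(effects: Sequence[EffectAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "variant_id\teffect\tlocus_tag\tcodon_index\tref_aa\talt_aa\tassigned_gene\n"
        )
        for e in effects:
            fh.write(
                "\t".join(
                    "" if v is None else str(v)
                    for v in (
                        e.variant_id,
                        e.effect,
                        e.locus_tag,
                        e.codon_index,
                        e.ref_aa,
                        e.alt_aa,
                        e.assigned_gene,
                    )
                )
                + "\n"
            )
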