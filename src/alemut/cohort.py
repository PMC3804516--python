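"""Cohort-level analyses: presence, pan-genome partition, longitudinal
accumulation and mutational hotspot calling.

The pan-genome view partitions mutations by where they persist: *core*
(fixed in every single-colony isolate), *shared* (some but not all
isolates), *unique* (exactly one isolate) and *discarded* (seen in
population samples but in no isolate — lineages that were outcompeted
before the final population was plated). A *hotspot* is a group of >= 2
mutations concentrated in one gene, one operon or one pathway, anchored by
at least one gene carrying a core mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import Role, SampleMeta, ValidationError, VariantCall


@dataclass
class PresenceMatrix:
    """Boolean variant x sample presence under a frequency threshold.

    A population observation counts as *present* only if its allele
    frequency reaches ``threshold``; sub-threshold observations are mere
    detections and do not establish the mutation in the population.
    Wild-type and isolate observations are clonal, hence always present.
    """

    matrix: pd.DataFrame
    threshold: float

    def variants_of(self, sample_id: str) -> set[str]:
        col = self.matrix[sample_id]
        return set(col.index[col])


def build_presence(
    calls: Sequence[VariantCall],
    samples: Sequence[SampleMeta],
    threshold: float = 0.02,
) -> PresenceMatrix:
    """Tabulate presence of every observed variant in every sample."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError(f"threshold must lie in [0,1], got {threshold}")
    sample_ids = [s.sample_id for s in samples]
    variant_ids = list(dict.fromkeys(c.variant_id for c in calls))
    mat = pd.DataFrame(False, index=variant_ids, columns=sample_ids)
    for c in calls:
        present = c.allele_frequency is None or c.allele_frequency >= threshold
        if present:
            mat.loc[c.variant_id, c.sample_id] = True
    return PresenceMatrix(matrix=mat, threshold=threshold)


@dataclass
class PanGenomePartition:
    """Four-way mutation partition with fractions of the total."""

    core: set[str]
    shared: set[str]
    unique: set[str]
    discarded: set[str]
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.core) + len(self.shared) + len(self.unique) + len(self.discarded)


def partition_pan_genome(
    presence: PresenceMatrix, samples: Sequence[SampleMeta]
) -> PanGenomePartition:
    """Partition variants by their presence pattern across isolates.

    Variants present in no isolate fall in the *discarded* class (they were
    only ever population-borne). Requires at least one isolate.
    """
    isolates = [s.sample_id for s in samples if s.role is Role.ISOLATE]
    if not isolates:
        raise ValidationError("pan-genome partition requires >= 1 isolate")
    iso = presence.matrix[isolates]
    n_iso = iso.sum(axis=1)
    core = set(n_iso.index[n_iso == len(isolates)])
    unique = set(n_iso.index[n_iso == 1]) - (core if len(isolates) == 1 else set())
    shared = set(n_iso.index[(n_iso >= 2) & (n_iso < len(isolates))])
    discarded = set(n_iso.index[n_iso == 0])
    total = len(presence.matrix)
    fractions = {
        label: (len(s) / total if total else 0.0)
        for label, s in (
            ("core", core),
            ("shared", shared),
            ("unique", unique),
            ("discarded", discarded),
        )
    }
    return PanGenomePartition(
        core=core, shared=shared, unique=unique, discarded=discarded, fractions=fractions
    )


def isolate_burden(presence: PresenceMatrix, samples: Sequence[SampleMeta]) -> pd.Series:
    """Number of present mutations per isolate."""
    isolates = [s.sample_id for s in samples if s.role is Role.ISOLATE]
    return presence.matrix[isolates].sum(axis=0)


@dataclass
class LongitudinalProfile:
    """Mutation accumulation along the population time series.

    ``cumulative`` counts mutations present per population sample; deltas
    are consecutive differences starting from the wild type (zero
    mutations by definition). Two samples can carry equal counts while
    holding different mutations, so symmetric-difference sizes between
    consecutive sample variant sets are tracked as well.
    """

    sample_ids: list[str]
    cumulative: list[int]
    deltas: list[int]
    mean_delta: float
    sd_delta: float
    max_delta: int
    max_delta_pair: tuple[str, str]
    symmetric_differences: list[int]


def longitudinal_accumulation(
    presence: PresenceMatrix, samples: Sequence[SampleMeta]
) -> LongitudinalProfile:
    pops = sorted(
        (s for s in samples if s.role is Role.POPULATION), key=lambda s: s.stage_index
    )
    if len(pops) < 2:
        raise ValidationError("longitudinal analysis requires >= 2 population samples")
    idx = [s.stage_index for s in pops]
    if len(set(idx)) != len(idx):
        raise ValidationError(f"population stages not strictly ordered: {idx}")
    wt = next(s for s in samples if s.role is Role.WILD_TYPE)
    ids = [s.sample_id for s in pops]
    sets = [presence.variants_of(i) for i in ids]
    cumulative = [len(s) for s in sets]
    prev_counts = [0] + cumulative[:-1]
    deltas = [c - p for c, p in zip(cumulative, prev_counts)]
    prev_ids = [wt.sample_id] + ids[:-1]
    prev_sets = [presence.variants_of(wt.sample_id)] + sets[:-1]
    sym = [len(a ^ b) for a, b in zip(prev_sets, sets)]
    mean = float(np.mean(deltas))
    sd = float(np.std(deltas))  # population sd
    k = int(np.argmax(deltas))
    return LongitudinalProfile(
        sample_ids=ids,
        cumulative=cumulative,
        deltas=deltas,
        mean_delta=mean,
        sd_delta=sd,
        max_delta=deltas[k],
        max_delta_pair=(prev_ids[k], ids[k]),
        symmetric_differences=sym,
    )


# ---------------------------------------------------------------------------
# hotspots

@dataclass
class Hotspot:
    """A cluster of mutations sharing a gene, operon or pathway.

    ``core_anchor`` is one member gene carrying a core mutation (the rule's
    anchoring requirement); ``variant_genes`` records which gene each member
    mutation maps to.
    """

    hotspot_id: str
    member_genes: list[str]
    member_variants: set[str]
    grouping_basis: str  # same_gene | operon | pathway
    core_anchor: str
    variant_genes: dict[str, str] = field(default_factory=dict)
    products: str = ""


def call_hotspots(
    effects: Sequence["EffectAnnotation"],  # noqa: F821 - forward ref to alemut.effects
    annotation,
    core: set[str],
) -> list[Hotspot]:
    """Group mutations into hotspots at gene, operon and pathway level.

    Each mutation maps to a gene through its CDS locus or, for non-coding
    mutations, its upstream-assigned gene; unmapped mutations are skipped.
    Grouping is nested and non-redundant: operon groups absorb the
    single-gene clusters they contain, and pathway groups only merge genes
    not already merged by an operon. A group qualifies iff it holds >= 2
    mutations and >= 1 member gene carries a core mutation. A gene in two
    pathways may anchor two hotspots, so pathway hotspots can overlap.
    """
    gene_variants: dict[str, set[str]] = {}
    for e in effects:
        gene = e.locus_tag or e.assigned_gene
        if gene is None:
            continue
        gene_variants.setdefault(gene, set()).add(e.variant_id)
    core_genes = {g for g, vs in gene_variants.items() if vs & core}

    hotspots: list[Hotspot] = []
    consumed: set[str] = set()

    def emit(genes: list[str], basis: str) -> None:
        variants = set().union(*(gene_variants[g] for g in genes))
        anchors = sorted(g for g in genes if g in core_genes)
        if len(variants) < 2 or not anchors:
            return
        variant_gene = {}
        for g in genes:
            for v in sorted(gene_variants[g]):
                variant_gene[v] = g
        products = ""
        try:
            products = "; ".join(
                p for p in dict.fromkeys(annotation.gene(g).product for g in genes) if p
            )
        except KeyError:
            pass
        hotspots.append(
            Hotspot(
                hotspot_id=f"HS{len(hotspots) + 1}",
                member_genes=sorted(genes),
                member_variants=variants,
                grouping_basis=basis,
                core_anchor=anchors[0],
                variant_genes=variant_gene,
                products=products,
            )
        )

    # operon level: widest precedence, consumes its genes
    for oid in sorted(annotation.operons):
        members = [g for g in annotation.operons[oid] if g in gene_variants]
        if len(members) >= 1:
            variants = set().union(*(gene_variants[g] for g in members))
            if len(variants) >= 2 and any(g in core_genes for g in members):
                emit(members, "operon")
                consumed.update(members)

    # pathway level: only merges genes not already merged by an operon;
    # a group spanning a single gene is really a same-gene cluster and is
    # left to the gene level below
    in_pathway: set[str] = set()
    for pid in sorted(annotation.pathways):
        members = sorted(
            g for g in annotation.pathways[pid] if g in gene_variants and g not in consumed
        )
        if len(members) >= 2:
            variants = set().union(*(gene_variants[g] for g in members))
            if len(variants) >= 2 and any(g in core_genes for g in members):
                emit(members, "pathway")
                in_pathway.update(members)

    # gene level: remaining genes with >= 2 mutations of their own
    for g in sorted(gene_variants):
        if g in consumed or g in in_pathway:
            continue
        if len(gene_variants[g]) >= 2 and g in core_genes:
            emit([g], "same_gene")

    return hotspots
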