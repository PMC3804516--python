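"""Shared domain types for the mutation-cohort pipeline.

The experiment these types model is a serial-transfer adaptive laboratory
evolution (ALE) study: a wild-type ancestor, a handful of intermediate
*population* samples taken along the transfer history, and a set of
single-colony *isolates* picked from the final population.  Every stage of
the pipeline — filtering, effect annotation, pan-genome partitioning,
hotspot calling, expression linkage — consumes these containers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Canonical residue ordering used by every PSSM in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"


class Role(str, enum.Enum):
    """Role of a sequenced sample within the evolution experiment."""

    WILD_TYPE = "wild_type"
    POPULATION = "population"
    ISOLATE = "isolate"


class CallerClass(str, enum.Enum):
    SNP = "snp"
    INDEL = "indel"
    STRUCTURAL = "structural"


class ConfidenceFlag(str, enum.Enum):
    """Caller-provided confidence label.

    ``hc`` marks high-confidence differences; ``fp`` (false positive),
    ``ise`` (Illumina sequence-specific error) and ``sv`` (structural
    variant) are screened out by :mod:`alemut.filtering`.
    """

    HC = "hc"
    FP = "fp"
    ISE = "ise"
    SV = "sv"


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity and ordinal stage of one sequenced sample.

    ``stage_index`` is the ordinal position in the serial-transfer history
    (wild type = 0); isolates carry the final population's stage index.
    ``stage_label`` is free text, e.g. the hydrolysate concentration the
    population was adapted to when it was archived.
    """

    sample_id: str
    role: Role
    stage_index: int
    stage_label: str = ""

    def __post_init__(self) -> None:
        if self.stage_index < 0:
            raise ValidationError(f"stage_index must be >= 0, got {self.stage_index}")


def validate_cohort(samples: Sequence[SampleMeta]) -> None:
    """Check cohort-level invariants on a sample list.

    Exactly one wild type; population stage indices strictly increasing;
    isolates share the final population stage index.
    """
    wt = [s for s in samples if s.role is Role.WILD_TYPE]
    if len(wt) != 1:
        raise ValidationError(f"cohort must contain exactly one wild_type sample, found {len(wt)}")
    pops = sorted((s for s in samples if s.role is Role.POPULATION), key=lambda s: s.stage_index)
    idx = [s.stage_index for s in pops]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValidationError(f"population stage_index values must be strictly increasing: {idx}")
    if pops:
        final = pops[-1].stage_index
        for s in samples:
            if s.role is Role.ISOLATE and s.stage_index != final:
                raise ValidationError(
                    f"isolate {s.sample_id} has stage_index {s.stage_index}, "
                    f"expected final population stage {final}"
                )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_id in cohort")


@dataclass(frozen=True)
class VariantCall:
    """One mutation observation in one sample.

    ``ref_allele`` is ``-`` for insertions and ``alt_allele`` is ``-`` for
    deletions; both are forward-strand. ``allele_frequency`` is populated
    only for population samples (deep population sequencing reports the
    fraction of reads supporting the variant); wild-type and isolate
    observations are clonal and treated as fixed (frequency 1).
    """

    sample_id: str
    position: int
    ref_allele: str
    alt_allele: str
    caller_class: CallerClass
    confidence_flag: ConfidenceFlag
    allele_frequency: Optional[float] = None
    chrom: str = "ref"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"ref and alt alleles identical at {self.position}")
        if self.allele_frequency is not None and not (0.0 <= self.allele_frequency <= 1.0):
            raise ValidationError(f"allele_frequency outside [0,1]: {self.allele_frequency}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.position}:{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class Gene:
    """A CDS feature: 1-based inclusive coordinates on the reference."""

    locus_tag: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"bad interval for {self.locus_tag}: [{self.start},{self.end}]")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Genes plus operon and pathway memberships for one reference genome."""

    genes: list[Gene]
    operons: dict[str, list[str]] = field(default_factory=dict)
    pathways: dict[str, set[str]] = field(default_factory=dict)
    reference_length: int = 0

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        known = {g.locus_tag for g in self.genes}
        if len(known) != len(self.genes):
            raise ValidationError("duplicate locus_tag in annotation")
        if self.reference_length:
            for g in self.genes:
                if g.end > self.reference_length:
                    raise ValidationError(
                        f"gene {g.locus_tag} extends past reference length {self.reference_length}"
                    )
        for oid, members in self.operons.items():
            for lt in members:
                if lt not in known:
                    raise ValidationError(f"operon {oid} references unknown locus_tag {lt}")
        for pid, members in self.pathways.items():
            for lt in members:
                if lt not in known:
                    raise ValidationError(f"pathway {pid} references unknown locus_tag {lt}")
        self._by_tag = {g.locus_tag: g for g in self.genes}

    def gene(self, locus_tag: str) -> Gene:
        return self._by_tag[locus_tag]

    def genes_at(self, position: int) -> list[Gene]:
        """All genes whose CDS interval contains ``position`` (may be several)."""
        return [g for g in self.genes if g.start <= position <= g.end]

    def operon_of(self, locus_tag: str) -> Optional[str]:
        for oid, members in self.operons.items():
            if locus_tag in members:
                return oid
        return None


@dataclass
class ProfileModel:
    """A per-position residue scoring matrix over a protein domain.

    ``pssm`` is a DataFrame indexed by domain position (1-based, length
    ``protein_end - protein_start + 1``) with one column per residue in
    :data:`AMINO_ACIDS`. Scores are log-odds-like; only differences between
    residues at a position are meaningful to the function-change predictor.
    """

    model_id: str
    domain_locus: str
    protein_start: int
    protein_end: int
    pssm: pd.DataFrame

    def __post_init__(self) -> None:
        length = self.protein_end - self.protein_start + 1
        if len(self.pssm) != length:
            raise ValidationError(
                f"PSSM has {len(self.pssm)} rows but domain spans {length} positions"
            )
        missing = set(AMINO_ACIDS) - set(self.pssm.columns)
        if missing:
            raise ValidationError(f"PSSM missing residue columns: {sorted(missing)}")
        self.pssm = self.pssm[list(AMINO_ACIDS)]
        self.pssm.index = pd.RangeIndex(1, length + 1)

    @property
    def domain_length(self) -> int:
        return self.protein_end - self.protein_start + 1


@dataclass
class ExpressionMatrix:
    """Gene-level counts with a condition/replicate design.

    ``counts`` is genes x samples; ``design`` has one row per sample with
    columns ``sample``, ``condition``, ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design["sample"]):
            raise ValidationError("counts columns must match design sample order")
        if not self.normalized and (self.counts.to_numpy() < 0).any():
            raise ValidationError("raw counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.design["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        return list(self.design.loc[self.design["condition"] == condition, "sample"])


@dataclass
class GrowthCurve:
    """One OD600 fermentation time series, with optional metabolite series.

    OD readings are blank-referenced and may dip slightly below zero;
    log-phase fitting excludes non-positive points. ``products`` and
    ``substrates`` map metabolite names to g/L series aligned with ``times``.
    """

    strain: str
    condition: str
    times: np.ndarray
    od: np.ndarray
    products: dict[str, np.ndarray] = field(default_factory=dict)
    substrates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.times) != len(self.od) or len(self.times) < 3:
            raise ValidationError("need matching times/od arrays of length >= 3")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        for name, series in {**self.products, **self.substrates}.items():
            arr = np.asarray(series, dtype=float)
            if len(arr) != len(self.times):
                raise ValidationError(f"series {name} length mismatch")
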