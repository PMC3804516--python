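"""Synthetic study generator with planted ground truth.

Emulates the design of a serial-transfer ALE resequencing study: one wild
type, six intermediate population samples and seven single-colony isolates
from the final population. The lineage model is a single dominant lineage
(mutations that fix become *core*) with transient segregating
side-lineages (*discarded* mutations, present in population samples at
intermediate frequencies and lost before plating) plus isolate-private
*unique* and *shared* mutations. A set of wild-type-shared reference
artifacts and caller flag noise (fp/ise/sv) is planted on top, and a few
isolate mutations are given sub-threshold (< 2%) detections in the final
population to exercise the presence rule.

Default parameters are calibrated to the study design the pipeline was
built around: 224 raw variants = 73 high-confidence (22 core + 4 shared +
23 unique + 24 discarded) + 20 artifacts + 131 flagged; per-sample
mutation-count gains (8, 4, 0, 4, 5, 9) — mean 5, population sd 2.9,
maximum 9; 8 of the 73 non-coding; isolate burdens averaging exactly 27.

Everything is deterministic under ``CohortConfig.seed``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .types import (
    CallerClass,
    ConfidenceFlag,
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    GrowthCurve,
    Role,
    SampleMeta,
    ValidationError,
    VariantCall,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in _STOPS
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic evolution experiment.

    The per-epoch schedules (``core_gains``, ``discarded_births``,
    ``discarded_deaths``) determine the longitudinal mutation-count
    trajectory; class totals are derived from them. ``seed`` is mandatory.
    """

    seed: int
    n_populations: int = 6
    n_isolates: int = 7
    core_gains: tuple[int, ...] = (5, 3, 0, 3, 4, 7)
    discarded_births: tuple[int, ...] = (3, 4, 4, 4, 4, 5)
    discarded_deaths: tuple[int, ...] = (0, 3, 4, 3, 3, 3)
    shared_memberships: tuple[tuple[int, ...], ...] = (
        (0, 3),
        (0, 3),
        (0, 3),
        (0, 1, 2, 3, 4, 5),
    )
    unique_per_isolate: tuple[int, ...] = (2, 4, 4, 2, 4, 5, 2)
    n_subthreshold_detections: int = 4
    n_wt_artifacts: int = 20
    flag_noise: dict[str, int] = field(
        default_factory=lambda: {"fp": 120, "ise": 6, "sv": 5}
    )
    n_noncoding: int = 8
    n_noncoding_unassigned: int = 2
    n_syn: int = 10
    n_stop: int = 3
    n_indel: int = 12
    gene_codons: int = 300
    intergenic_bp: int = 250
    desert_bp: int = 4000
    n_decoy_genes: int = 10
    plant_hotspots: bool = True
    presence_threshold: float = 0.02

    # -- derived totals -----------------------------------------------------
    @property
    def n_core(self) -> int:
        return sum(self.core_gains)

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded_births)

    @property
    def n_shared(self) -> int:
        return len(self.shared_memberships)

    @property
    def n_unique(self) -> int:
        return sum(self.unique_per_isolate)

    @property
    def n_high_confidence(self) -> int:
        return self.n_core + self.n_shared + self.n_unique + self.n_discarded

    def validate(self) -> None:
        p = self.n_populations
        if not (len(self.core_gains) == len(self.discarded_births) == len(self.discarded_deaths) == p):
            raise ValidationError("epoch schedules must have n_populations entries")
        if len(self.unique_per_isolate) != self.n_isolates:
            raise ValidationError("unique_per_isolate must have n_isolates entries")
        alive = 0
        for e in range(p):
            if self.discarded_deaths[e] > alive:
                raise ValidationError(f"epoch {e + 1}: more deaths than alive side-lineages")
            alive += self.discarded_births[e] - self.discarded_deaths[e]
        for members in self.shared_memberships:
            if not (2 <= len(members) < self.n_isolates):
                raise ValidationError("shared mutations need 2..n_isolates-1 member isolates")
            if any(i >= self.n_isolates for i in members):
                raise ValidationError("shared membership references unknown isolate")
        n_hotspot = 6 if self.plant_hotspots else 0
        if self.plant_hotspots and (self.n_core < 5 or self.n_discarded < 1):
            raise ValidationError(
                "infeasible config: hotspot planting needs >= 5 core and >= 1 discarded mutation"
            )
        coding = self.n_high_confidence - self.n_noncoding
        if coding - self.n_syn - self.n_stop - self.n_indel - n_hotspot < 0:
            raise ValidationError("infeasible config: effect-class counts exceed coding variants")
        if self.n_noncoding_unassigned > self.n_noncoding:
            raise ValidationError("n_noncoding_unassigned exceeds n_noncoding")
        if self.n_subthreshold_detections > self.n_shared + self.n_unique:
            raise ValidationError("more sub-threshold detections than isolate mutations")
        if not (0 <= self.presence_threshold <= 1):
            raise ValidationError("presence_threshold outside [0,1]")


@dataclass
class PlantedTruth:
    """Ground-truth labels for one generated cohort."""

    labels: dict[str, str]  # variant_id -> core|shared|unique|discarded|wt_artifact|flag_noise
    effects: dict[str, str]  # hc variant_id -> SYN|NONSYN|STOP|INDEL|NONCODING
    variant_gene: dict[str, Optional[str]]  # hc variant_id -> locus_tag (assigned for NC)
    sample_variants: dict[str, set[str]]  # sample_id -> present hc variant ids
    epoch_gains: list[int]
    hotspot_groups: list[dict]  # planted hotspot structures

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _substitutions(codon: str) -> list[tuple[int, str, str]]:
    """All 9 single-base substitutions as (offset, alt_base, alt_codon)."""
    out = []
    for i, base in enumerate(codon):
        for alt in _BASES:
            if alt != base:
                out.append((i, alt, codon[:i] + alt + codon[i + 1 :]))
    return out


def _aa(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def _effect_of(ref_codon: str, alt_codon: str) -> str:
    ra, aa = _aa(ref_codon), _aa(alt_codon)
    if aa == "*" and ra != "*":
        return "STOP"
    return "SYN" if ra == aa else "NONSYN"


class _Genome:
    """Synthetic genome layout: genes on a grid with planted structure."""

    def __init__(self, config: CohortConfig, rng: np.random.Generator):
        c = config
        n_hot = 5 if c.plant_hotspots else 0
        n_coding = (
            c.n_high_confidence - c.n_noncoding - (6 if c.plant_hotspots else 0)
        )
        n_nc_assigned = c.n_noncoding - c.n_noncoding_unassigned
        self.n_hot = n_hot
        self.n_coding = n_coding
        self.n_nc_assigned = n_nc_assigned
        n_genes = n_hot + n_coding + n_nc_assigned + c.n_decoy_genes
        gene_len = 3 * c.gene_codons
        minus = set()
        if n_coding >= 4:  # a few reverse-strand genes exercise strand handling
            lo = n_hot + n_coding // 3
            minus = set(range(lo, min(lo + max(2, n_coding // 6), n_hot + n_coding)))
        parts: list[str] = []
        genes: list[Gene] = []
        self.cds: dict[str, str] = {}
        pos = 1
        self.desert: tuple[int, int] | None = None
        for i in range(n_genes):
            gap = c.desert_bp if i == n_hot + n_coding and c.n_noncoding_unassigned else c.intergenic_bp
            gap_seq = "".join(rng.choice(list(_BASES), size=gap))
            parts.append(gap_seq)
            if gap == c.desert_bp:
                self.desert = (pos, pos + gap - 1)
            pos += gap
            cds = _random_cds(rng, c.gene_codons)
            strand = "-" if i in minus else "+"
            seg = str(Seq(cds).reverse_complement()) if strand == "-" else cds
            parts.append(seg)
            tag = f"SYN_{i:04d}"
            genes.append(Gene(tag, pos, pos + gene_len - 1, strand, product=f"synthetic protein {i}"))
            self.cds[tag] = cds
            pos += gene_len
        tail = "".join(rng.choice(list(_BASES), size=c.intergenic_bp))
        parts.append(tail)
        self.sequence = "".join(parts)
        self.genes = genes
        operons: dict[str, list[str]] = {}
        pathways: dict[str, set[str]] = {}
        if c.plant_hotspots:
            operons["operon_hot"] = [genes[0].locus_tag, genes[1].locus_tag]
            pathways["pathway_hot"] = {genes[3].locus_tag, genes[4].locus_tag}
        if c.n_decoy_genes >= 8:
            decoys = genes[n_hot + n_coding + n_nc_assigned :]
            operons["operon_decoy"] = [g.locus_tag for g in decoys[:4]]
            pathways["pathway_decoy"] = {g.locus_tag for g in decoys[4:8]}
        self.annotation = GenomeAnnotation(
            genes=genes,
            operons=operons,
            pathways=pathways,
            reference_length=len(self.sequence),
        )
        # index ranges of the gene roles
        self.hot_genes = genes[:n_hot]
        self.coding_genes = genes[n_hot : n_hot + n_coding]
        self.nc_target_genes = genes[n_hot + n_coding : n_hot + n_coding + n_nc_assigned]


class _Placer:
    """Allocates non-colliding variant positions and alleles on the genome."""

    def __init__(self, genome: _Genome, rng: np.random.Generator):
        self.g = genome
        self.rng = rng
        self.used: set[int] = set()

    def _claim(self, positions: range | list[int]) -> bool:
        if any(p in self.used for p in positions):
            return False
        self.used.update(positions)
        return True

    def snp_in_gene(self, gene: Gene, effect: str) -> tuple[int, str, str, int]:
        """Plant a SNP with the requested coding effect; returns
        (position, ref, alt, codon_index) in forward-strand coordinates."""
        cds = self.g.cds[gene.locus_tag]
        n_codons = len(cds) // 3
        order = self.rng.permutation(np.arange(1, n_codons - 1))
        for ci in order:
            codon = cds[3 * ci : 3 * ci + 3]
            options = [
                (off, alt, alt_codon)
                for off, alt, alt_codon in _substitutions(codon)
                if _effect_of(codon, alt_codon) == effect
            ]
            self.rng.shuffle(options)
            for off, alt, _ in options:
                cds_offset = 3 * ci + off
                if gene.strand == "+":
                    pos = gene.start + cds_offset
                    ref_f, alt_f = codon[off], alt
                else:
                    pos = gene.end - cds_offset
                    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                    ref_f, alt_f = comp[codon[off]], comp[alt]
                if self._claim([pos]):
                    return pos, ref_f, alt_f, ci + 1
        raise ValidationError(
            f"could not plant a {effect} SNP in {gene.locus_tag}; gene too constrained"
        )

    def indel_in_gene(self, gene: Gene) -> tuple[int, str, str]:
        for _ in range(50):
            length = int(self.rng.integers(1, 7))
            lo = gene.start + 3
            hi = gene.end - 3 - length
            pos = int(self.rng.integers(lo, hi))
            if self.rng.random() < 0.5:  # deletion
                span = range(pos, pos + length)
                if self._claim(span):
                    ref = self.g.sequence[pos - 1 : pos - 1 + length]
                    return pos, ref, "-"
            else:  # insertion
                if self._claim([pos]):
                    ins = "".join(self.rng.choice(list(_BASES), size=length))
                    return pos, "-", ins
        raise ValidationError("could not place indel without collision")

    def noncoding_assigned(self, gene: Gene, window: int = 500) -> tuple[int, str, str]:
        for _ in range(50):
            dist = int(self.rng.integers(60, min(window - 20, 240)))
            pos = gene.start - dist
            if self._claim([pos]):
                ref = self.g.sequence[pos - 1]
                alt = self.rng.choice([b for b in _BASES if b != ref])
                return pos, ref, str(alt)
        raise ValidationError("could not place upstream non-coding variant")

    def noncoding_desert(self) -> tuple[int, str, str]:
        if self.g.desert is None:
            raise ValidationError("no gene desert in this layout")
        lo, hi = self.g.desert
        for _ in range(50):
            pos = int(self.rng.integers(lo + 50, hi - 600))
            if self._claim([pos]):
                ref = self.g.sequence[pos - 1]
                alt = self.rng.choice([b for b in _BASES if b != ref])
                return pos, ref, str(alt)
        raise ValidationError("could not place desert non-coding variant")

    def anywhere_snp(self) -> tuple[int, str, str]:
        n = len(self.g.sequence)
        for _ in range(200):
            pos = int(self.rng.integers(1, n + 1))
            if self._claim([pos]):
                ref = self.g.sequence[pos - 1]
                alt = self.rng.choice([b for b in _BASES if b != ref])
                return pos, ref, str(alt)
        raise ValidationError("genome saturated; cannot place more variants")


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[VariantCall], GenomeAnnotation, str, list[SampleMeta], PlantedTruth]:
    """Generate a complete synthetic resequencing cohort.

    Returns (variant observations, annotation, reference sequence, sample
    metadata, planted truth). Reproducible: the same config yields
    identical output.
    """
    config.validate()
    c = config
    rng = np.random.default_rng(c.seed)
    genome = _Genome(c, rng)
    placer = _Placer(genome, rng)

    pops = [f"P{e}" for e in range(1, c.n_populations + 1)]
    isos = [f"I{i}" for i in range(1, c.n_isolates + 1)]
    stage_labels = _stage_labels(c.n_populations)
    samples = (
        [SampleMeta("WT", Role.WILD_TYPE, 0, "ancestor")]
        + [
            SampleMeta(pops[e], Role.POPULATION, e + 1, stage_labels[e])
            for e in range(c.n_populations)
        ]
        + [SampleMeta(s, Role.ISOLATE, c.n_populations, "final isolate") for s in isos]
    )

    # --- plan the 73-ish high-confidence variants ---------------------------
    # (class, epochs-alive or isolate membership, effect, placement plan)
    plans: list[dict] = []
    hotspot_groups: list[dict] = []
    n_hot_core = 0
    if c.plant_hotspots:
        hg = genome.hot_genes
        plan_hot = [
            ("core", hg[0]),
            ("core", hg[1]),
            ("core", hg[2]),
            ("core", hg[2]),
            ("core", hg[3]),
            ("discarded", hg[4]),
        ]
        for label, gene in plan_hot:
            plans.append({"label": label, "effect": "NONSYN", "gene": gene, "kind": "cds"})
        n_hot_core = 5
        hotspot_groups = [
            {"basis": "operon", "genes": [hg[0].locus_tag, hg[1].locus_tag]},
            {"basis": "same_gene", "genes": [hg[2].locus_tag]},
            {"basis": "pathway", "genes": [hg[3].locus_tag, hg[4].locus_tag]},
        ]

    remaining_labels = (
        ["core"] * (c.n_core - n_hot_core)
        + ["discarded"] * (c.n_discarded - (1 if c.plant_hotspots else 0))
        + [f"shared:{k}" for k in range(c.n_shared)]
        + ["unique"] * c.n_unique
    )
    coding_total = c.n_high_confidence - c.n_noncoding
    n_nonsyn_rest = coding_total - c.n_syn - c.n_stop - c.n_indel - (6 if c.plant_hotspots else 0)
    effects_pool = (
        ["NONCODING"] * c.n_noncoding
        + ["SYN"] * c.n_syn
        + ["STOP"] * c.n_stop
        + ["INDEL"] * c.n_indel
        + ["NONSYN"] * n_nonsyn_rest
    )
    rng.shuffle(effects_pool)
    coding_genes = iter(genome.coding_genes)
    nc_targets = iter(genome.nc_target_genes)
    nc_assigned_left = c.n_noncoding - c.n_noncoding_unassigned
    for label, effect in zip(remaining_labels, effects_pool):
        if effect == "NONCODING":
            if nc_assigned_left > 0:
                nc_assigned_left -= 1
                plans.append(
                    {"label": label, "effect": effect, "gene": next(nc_targets), "kind": "nc_assigned"}
                )
            else:
                plans.append({"label": label, "effect": effect, "gene": None, "kind": "nc_desert"})
        elif effect == "INDEL":
            plans.append({"label": label, "effect": effect, "gene": next(coding_genes), "kind": "indel"})
        else:
            plans.append({"label": label, "effect": effect, "gene": next(coding_genes), "kind": "cds"})

    # --- realize positions/alleles ------------------------------------------
    for plan in plans:
        if plan["kind"] == "cds":
            pos, ref, alt, _ = placer.snp_in_gene(plan["gene"], plan["effect"])
            plan.update(position=pos, ref=ref, alt=alt, caller=CallerClass.SNP)
        elif plan["kind"] == "indel":
            pos, ref, alt = placer.indel_in_gene(plan["gene"])
            plan.update(position=pos, ref=ref, alt=alt, caller=CallerClass.INDEL)
        elif plan["kind"] == "nc_assigned":
            pos, ref, alt = placer.noncoding_assigned(plan["gene"])
            plan.update(position=pos, ref=ref, alt=alt, caller=CallerClass.SNP)
        else:
            pos, ref, alt = placer.noncoding_desert()
            plan.update(position=pos, ref=ref, alt=alt, caller=CallerClass.SNP)
        plan["variant_id"] = f"ref:{plan['position']}:{plan['ref']}>{plan['alt']}"

    # --- assign lineage history ---------------------------------------------
    core_plans = [p for p in plans if p["label"] == "core"]
    epoch_pool = [e + 1 for e, n in enumerate(c.core_gains) for _ in range(n)]
    rng.shuffle(epoch_pool)
    for plan, birth in zip(core_plans, epoch_pool):
        plan["pop_epochs"] = list(range(birth, c.n_populations + 1))
        plan["isolates"] = list(isos)

    discarded_plans = [p for p in plans if p["label"] == "discarded"]
    queue: list[dict] = []
    di = iter(discarded_plans)
    for e in range(1, c.n_populations + 1):
        for plan in queue[: c.discarded_deaths[e - 1]]:
            plan["_dead"] = True
        queue = [p for p in queue if not p.get("_dead")]
        for _ in range(c.discarded_births[e - 1]):
            plan = next(di)
            plan["pop_epochs"] = []
            queue.append(plan)
        for plan in queue:
            plan["pop_epochs"].append(e)
    for plan in discarded_plans:
        plan["isolates"] = []

    iso_plans = [p for p in plans if p["label"].startswith("shared") or p["label"] == "unique"]
    unique_iter = iter([p for p in plans if p["label"] == "unique"])
    for k, members in enumerate(c.shared_memberships):
        plan = next(p for p in plans if p["label"] == f"shared:{k}")
        plan["label"] = "shared"
        plan["isolates"] = [isos[i] for i in members]
        plan["pop_epochs"] = []
    for i, n_u in enumerate(c.unique_per_isolate):
        for _ in range(n_u):
            plan = next(unique_iter)
            plan["isolates"] = [isos[i]]
            plan["pop_epochs"] = []
    sub_idx = rng.choice(len(iso_plans), size=c.n_subthreshold_detections, replace=False)
    for k in sub_idx:
        iso_plans[k]["subthreshold"] = True

    # --- materialize observations -------------------------------------------
    calls: list[VariantCall] = []
    labels: dict[str, str] = {}
    effects: dict[str, str] = {}
    variant_gene: dict[str, Optional[str]] = {}
    sample_variants: dict[str, set[str]] = {s.sample_id: set() for s in samples}

    def obs(plan, sample_id, af=None, flag=ConfidenceFlag.HC):
        calls.append(
            VariantCall(
                sample_id=sample_id,
                position=plan["position"],
                ref_allele=plan["ref"],
                alt_allele=plan["alt"],
                caller_class=plan["caller"],
                confidence_flag=flag,
                allele_frequency=af,
            )
        )

    for plan in plans:
        vid = plan["variant_id"]
        labels[vid] = plan["label"]
        effects[vid] = plan["effect"]
        variant_gene[vid] = plan["gene"].locus_tag if plan["gene"] is not None else None
        for e in plan["pop_epochs"]:
            if plan["label"] == "core":
                af = float(rng.uniform(0.5, 1.0))
            else:
                af = float(rng.uniform(0.05, 0.5))
            obs(plan, pops[e - 1], af=af)
            sample_variants[pops[e - 1]].add(vid)
        for iso in plan["isolates"]:
            obs(plan, iso)
            sample_variants[iso].add(vid)
        if plan.get("subthreshold"):
            obs(plan, pops[-1], af=float(rng.uniform(0.004, c.presence_threshold * 0.95)))

    # --- artifacts and flag noise -------------------------------------------
    all_ids = [s.sample_id for s in samples]
    for _ in range(c.n_wt_artifacts):
        pos, ref, alt = placer.anywhere_snp()
        plan = {
            "position": pos,
            "ref": ref,
            "alt": alt,
            "caller": CallerClass.SNP,
        }
        vid = f"ref:{pos}:{ref}>{alt}"
        labels[vid] = "wt_artifact"
        for s in samples:
            af = float(rng.uniform(0.9, 1.0)) if s.role is Role.POPULATION else None
            obs(plan, s.sample_id, af=af)

    for flag_name in sorted(c.flag_noise):
        flag = ConfidenceFlag(flag_name)
        caller = CallerClass.STRUCTURAL if flag is ConfidenceFlag.SV else CallerClass.SNP
        for _ in range(c.flag_noise[flag_name]):
            pos, ref, alt = placer.anywhere_snp()
            plan = {"position": pos, "ref": ref, "alt": alt, "caller": caller}
            vid = f"ref:{pos}:{ref}>{alt}"
            labels[vid] = "flag_noise"
            n_obs = int(rng.integers(1, 6))
            chosen = rng.choice(all_ids, size=min(n_obs, len(all_ids) - 1), replace=False)
            for sid in chosen:
                role = next(s.role for s in samples if s.sample_id == sid)
                af = float(rng.uniform(0.05, 0.9)) if role is Role.POPULATION else None
                obs(plan, sid, af=af, flag=flag)

    truth = PlantedTruth(
        labels=labels,
        effects=effects,
        variant_gene=variant_gene,
        sample_variants=sample_variants,
        epoch_gains=_planted_gains(c),
        hotspot_groups=hotspot_groups,
    )
    return calls, genome.annotation, genome.sequence, samples, truth


def _planted_gains(c: CohortConfig) -> list[int]:
    gains = []
    prev = 0
    alive = 0
    cum_core = 0
    for e in range(c.n_populations):
        alive += c.discarded_births[e] - c.discarded_deaths[e]
        cum_core += c.core_gains[e]
        total = cum_core + alive
        gains.append(total - prev)
        prev = total
    return gains


def _stage_labels(n: int) -> list[str]:
    base = [
        "final 5% v/v",
        "final 10% v/v",
        "intermediate 15% v/v",
        "final 15% v/v",
        "intermediate 17.5% v/v",
        "final 17.5% v/v",
    ]
    if n <= len(base):
        return base[:n]
    return base + [f"stage {i}" for i in range(len(base) + 1, n + 1)]


def random_config(seed: int) -> CohortConfig:
    """A randomized, internally consistent small cohort configuration.

    Used for property testing: varies sample counts, schedules and class
    sizes while keeping the config feasible.
    """
    rng = np.random.default_rng(seed)
    n_pop = int(rng.integers(3, 7))
    n_iso = int(rng.integers(2, 8))
    core_gains = tuple(int(v) for v in rng.integers(0, 5, size=n_pop))
    core_gains = core_gains if sum(core_gains) >= 5 else (5,) + core_gains[1:]
    births, deaths, alive = [], [], 0
    for _ in range(n_pop):
        b = int(rng.integers(0, 4))
        k = int(rng.integers(0, alive + 1)) if alive else 0
        births.append(b)
        deaths.append(k)
        alive += b - k
    if sum(births) < 1:
        births[0] += 1
        alive += 1
    shared = []
    if n_iso >= 3:
        for _ in range(int(rng.integers(0, 4))):
            size = int(rng.integers(2, n_iso))
            shared.append(tuple(int(i) for i in rng.choice(n_iso, size=size, replace=False)))
    unique = tuple(int(v) for v in rng.integers(0, 4, size=n_iso))
    n_iso_muts = len(shared) + sum(unique)
    n_hc = sum(core_gains) + sum(births) + n_iso_muts
    n_nc = min(int(rng.integers(0, 4)), max(0, n_hc - 6 - 3))
    coding = n_hc - n_nc - 6
    n_syn = min(int(rng.integers(0, 4)), coding)
    n_stop = min(int(rng.integers(0, 2)), coding - n_syn)
    n_indel = min(int(rng.integers(0, 4)), coding - n_syn - n_stop)
    return CohortConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_populations=n_pop,
        n_isolates=n_iso,
        core_gains=core_gains,
        discarded_births=tuple(births),
        discarded_deaths=tuple(deaths),
        shared_memberships=tuple(shared),
        unique_per_isolate=unique,
        n_subthreshold_detections=min(2, n_iso_muts),
        n_wt_artifacts=int(rng.integers(0, 6)),
        flag_noise={"fp": int(rng.integers(0, 8)), "ise": int(rng.integers(0, 3)), "sv": int(rng.integers(0, 3))},
        n_noncoding=n_nc,
        n_noncoding_unassigned=min(1, n_nc),
        n_syn=n_syn,
        n_stop=n_stop,
        n_indel=n_indel,
        gene_codons=120,
        n_decoy_genes=4,
    )


# ---------------------------------------------------------------------------
# RNA-seq counts

@dataclass
class ExpressionTruth:
    is_de: np.ndarray
    log2_fold_change: np.ndarray
    baseline: str


def generate_counts(
    n_genes: int,
    design: pd.DataFrame,
    de_fraction: float = 0.1,
    log2_fold_change: float = 2.0,
    dispersion: float = 0.05,
    seed: int = 0,
    base_mean: float = 200.0,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Negative-binomial counts with planted fold changes.

    DE genes get their mean shifted by ±``log2_fold_change`` (random sign)
    in every non-baseline condition; the baseline is the design's first
    condition. Counts are gamma-Poisson with the given dispersion.
    """
    rng = np.random.default_rng(seed)
    baseline = design["condition"].iloc[0]
    mu0 = rng.lognormal(mean=np.log(base_mean), sigma=0.6, size=n_genes)
    n_de = int(round(de_fraction * n_genes))
    is_de = np.zeros(n_genes, dtype=bool)
    if n_de:
        is_de[rng.choice(n_genes, size=n_de, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    lfc = np.where(is_de, signs * log2_fold_change, 0.0)
    cols = {}
    for _, row in design.iterrows():
        mu = mu0 * np.power(2.0, lfc) if row["condition"] != baseline else mu0
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        else:
            lam = mu
        cols[row["sample"]] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=[f"GENE_{i:04d}" for i in range(n_genes)])
    matrix = ExpressionMatrix(counts=counts, design=design.copy())
    return matrix, ExpressionTruth(is_de=is_de, log2_fold_change=lfc, baseline=baseline)


def make_design(conditions: Sequence[str], n_replicates: int) -> pd.DataFrame:
    rows = [
        {"sample": f"{c}_r{r}", "condition": c, "replicate": r}
        for c in conditions
        for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# growth curves

@dataclass
class GrowthTruth:
    mu: float
    lag_h: float
    yields: dict[str, float]


def generate_growth_curves(
    mu: float = 0.35,
    lag_h: float = 4.0,
    od0: float = 0.1,
    k_stationary: float = 0.75,
    noise_sd: float = 0.01,
    yields: Optional[dict[str, float]] = None,
    substrate_g_l: float = 4.2,
    decline_rate: float = 0.05,
    t_end: float = 30.0,
    dt: float = 1.0,
    n_curves: int = 1,
    seed: int = 0,
    strain: str = "PM",
    condition: str = "0% v/v",
) -> tuple[list[GrowthCurve], GrowthTruth]:
    """Lag / exponential / stationary OD curves with consistent metabolites.

    OD stays at ``od0`` through the lag, grows exponentially at rate ``mu``
    (1/h) and plateaus at ``k_stationary``; Gaussian noise of sd
    ``noise_sd`` is added. Substrate utilization tracks biomass and each
    product accumulates at its planted yield (g product / g substrate).
    """
    if mu <= 0:
        raise ValidationError("mu must be positive")
    yields = yields if yields is not None else {"ethanol": 0.43}
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_end + dt / 2, dt)
    grow = np.where(times < lag_h, od0, od0 * np.exp(mu * (times - lag_h)))
    over = grow > k_stationary
    if over.any():
        onset = int(np.argmax(over))  # first sample past the ceiling
        peak_od = grow[onset - 1] if onset else od0
        clean = grow.copy()
        # slow post-peak decline so the OD maximum marks the end of
        # exponential growth, as in real batch fermentations
        clean[onset:] = peak_od * np.exp(-decline_rate * (times[onset:] - times[onset - 1]))
    else:
        clean = grow
        peak_od = grow[-1]
    utilized = np.maximum.accumulate(clean) - od0
    utilized = np.clip(utilized, 0.0, None) / (peak_od - od0) * substrate_g_l
    curves = []
    for _ in range(n_curves):
        od = clean + rng.normal(0.0, noise_sd, size=len(times))
        products = {
            name: y * utilized + rng.normal(0.0, noise_sd, size=len(times))
            for name, y in yields.items()
        }
        substrates = {
            "glucan": substrate_g_l - utilized + rng.normal(0.0, noise_sd, size=len(times))
        }
        curves.append(
            GrowthCurve(
                strain=strain,
                condition=condition,
                times=times.copy(),
                od=od,
                products=products,
                substrates=substrates,
            )
        )
    return curves, GrowthTruth(mu=mu, lag_h=lag_h, yields=dict(yields))


# ---------------------------------------------------------------------------
# study directory emission

def write_study(outdir, config: CohortConfig) -> PlantedTruth:
    """Emit a ready-to-run study directory in the pipeline's input formats."""
    from . import io as aio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls, annotation, reference, samples, truth = generate_cohort(config)
    aio.write_samples(samples, outdir / "samples.tsv")
    aio.write_variant_table(calls, outdir / "variants.tsv")
    aio.write_reference("ref", reference, outdir / "reference.fa")
    aio.write_annotation(
        annotation,
        outdir / "annotation.gff3",
        outdir / "operons.tsv",
        outdir / "pathways.tsv",
    )
    design = make_design(["WT_0pct", "PM_0pct", "PM_10pct"], 3)
    matrix, etruth = generate_counts(
        n_genes=len(annotation.genes), design=design, seed=config.seed + 1
    )
    matrix.counts.index = [g.locus_tag for g in annotation.genes]
    aio.write_counts(matrix, outdir / "counts.tsv", outdir / "design.tsv")
    for strain, condition, mu, lag in (
        ("WT", "0pct", 0.30, 4.0),
        ("PM", "0pct", 0.35, 4.0),
        ("PM", "10pct", 0.33, 6.0),
    ):
        curves, _ = generate_growth_curves(
            mu=mu, lag_h=lag, seed=config.seed + 2, strain=strain, condition=condition
        )
        aio.write_growth_csv(curves[0], outdir / f"growth_{strain}_{condition}.csv")
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "labels": truth.labels,
                "effects": truth.effects,
                "epoch_gains": truth.epoch_gains,
            },
            indent=1,
            sort_keys=True,
        )
    )
    return truth
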