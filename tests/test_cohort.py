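"""Presence logic, pan-genome partition, longitudinal profile, hotspots."""

import numpy as np
import pytest

from alemut.cohort import (
    build_presence,
    call_hotspots,
    isolate_burden,
    longitudinal_accumulation,
    partition_pan_genome,
)
from alemut.datasets import load_hotspot_example
from alemut.effects import EffectAnnotation
from alemut.filtering import screen_variants
from alemut.simulate import CohortConfig, generate_cohort, random_config
from alemut.types import (
    CallerClass,
    ConfidenceFlag,
    Gene,
    GenomeAnnotation,
    Role,
    SampleMeta,
    ValidationError,
    VariantCall,
)


def _samples(n_pop=2, n_iso=2):
    out = [SampleMeta("WT", Role.WILD_TYPE, 0)]
    out += [SampleMeta(f"P{i}", Role.POPULATION, i) for i in range(1, n_pop + 1)]
    out += [SampleMeta(f"I{i}", Role.ISOLATE, n_pop) for i in range(1, n_iso + 1)]
    return out


def _call(pos, sample, af=None):
    return VariantCall(
        sample_id=sample,
        position=pos,
        ref_allele="A",
        alt_allele="G",
        caller_class=CallerClass.SNP,
        confidence_flag=ConfidenceFlag.HC,
        allele_frequency=af,
    )


# ---------------------------------------------------------------------------
# presence

def test_subthreshold_population_call_is_detection_only():
    samples = _samples()
    calls = [_call(10, "P2", af=0.015), _call(10, "I1")]
    presence = build_presence(calls, samples, threshold=0.02)
    assert not presence.matrix.loc["ref:10:A>G", "P2"]
    assert presence.matrix.loc["ref:10:A>G", "I1"]
    # threshold 0: every observed call is present
    p0 = build_presence(calls, samples, threshold=0.0)
    assert p0.matrix.loc["ref:10:A>G", "P2"]


def test_presence_matches_elementwise_oracle():
    rng = np.random.default_rng(2)
    samples = _samples(3, 3)
    ids = [s.sample_id for s in samples]
    calls = []
    for pos in range(1, 30):
        for sid in rng.choice(ids, size=int(rng.integers(1, len(ids))), replace=False):
            af = float(rng.uniform(0, 0.1)) if sid.startswith("P") else None
            calls.append(_call(pos, sid, af=af))
    thr = 0.02
    presence = build_presence(calls, samples, threshold=thr)
    for c in calls:
        expected = c.allele_frequency is None or c.allele_frequency >= thr
        if expected:
            assert presence.matrix.loc[c.variant_id, c.sample_id]
    with pytest.raises(ValidationError):
        build_presence(calls, samples, threshold=1.5)


# ---------------------------------------------------------------------------
# partition

def test_single_isolate_partition_degenerates():
    samples = _samples(n_iso=1)
    calls = [_call(1, "I1"), _call(2, "P1", af=0.5)]
    part = partition_pan_genome(build_presence(calls, samples), samples)
    assert part.shared == set() and part.unique == set()
    assert part.core == {"ref:1:A>G"} and part.discarded == {"ref:2:A>G"}


def test_partition_requires_isolates():
    samples = [s for s in _samples() if s.role is not Role.ISOLATE]
    with pytest.raises(ValidationError):
        partition_pan_genome(build_presence([_call(1, "P1", af=0.5)], samples), samples)


def test_partition_recovers_planted_truth(default_cohort):
    calls, _, _, samples, truth = default_cohort
    hc, _ = screen_variants(calls, samples)
    part = partition_pan_genome(build_presence(hc, samples), samples)
    for label in ("core", "shared", "unique", "discarded"):
        assert getattr(part, label) == {
            v for v, lab in truth.labels.items() if lab == label
        }, label


def test_partition_exhaustive_and_disjoint_on_random_cohorts():
    for seed in range(25):
        cfg = random_config(seed)
        calls, _, _, samples, truth = generate_cohort(cfg)
        hc, _ = screen_variants(calls, samples, threshold=cfg.presence_threshold)
        presence = build_presence(hc, samples, threshold=cfg.presence_threshold)
        part = partition_pan_genome(presence, samples)
        sets = [part.core, part.shared, part.unique, part.discarded]
        assert sum(len(s) for s in sets) == len(presence.matrix)
        for i in range(4):
            for j in range(i + 1, 4):
                assert not (sets[i] & sets[j])
        assert sum(part.fractions.values()) == pytest.approx(1.0)


def test_adding_isolate_only_shrinks_core(default_cohort):
    calls, _, _, samples, _ = default_cohort
    hc, _ = screen_variants(calls, samples)
    sub = [s for s in samples if s.sample_id != "I7"]
    sub_calls = [c for c in hc if c.sample_id != "I7"]
    core_small = partition_pan_genome(build_presence(sub_calls, sub), sub).core
    core_full = partition_pan_genome(build_presence(hc, samples), samples).core
    assert core_full <= core_small


# ---------------------------------------------------------------------------
# longitudinal

def test_identical_consecutive_samples_zero_delta():
    samples = _samples(n_pop=2)
    calls = [_call(1, "P1", af=0.5), _call(1, "P2", af=0.5), _call(1, "I1")]
    prof = longitudinal_accumulation(build_presence(calls, samples), samples)
    assert prof.deltas == [1, 0]
    assert prof.symmetric_differences == [1, 0]


def test_planted_epoch_gains_recovered(default_cohort):
    calls, _, _, samples, truth = default_cohort
    hc, _ = screen_variants(calls, samples)
    prof = longitudinal_accumulation(build_presence(hc, samples), samples)
    assert prof.deltas == truth.epoch_gains
    assert prof.mean_delta == pytest.approx(np.mean(truth.epoch_gains))
    assert prof.sd_delta == pytest.approx(np.std(truth.epoch_gains))
    # equal counts but different members shows up in the symmetric difference
    zero_idx = prof.deltas.index(0)
    assert prof.symmetric_differences[zero_idx] > 0


def test_longitudinal_needs_two_populations():
    samples = _samples(n_pop=1)
    with pytest.raises(ValidationError):
        longitudinal_accumulation(build_presence([_call(1, "P1", af=0.5)], samples), samples)


def test_isolate_burden_counts(default_cohort, default_config):
    calls, _, _, samples, _ = default_cohort
    hc, _ = screen_variants(calls, samples)
    burden = isolate_burden(build_presence(hc, samples), samples)
    assert float(burden.mean()) == pytest.approx(27.0)
    c = default_config
    share_counts = [sum(1 for m in c.shared_memberships if i in m) for i in range(c.n_isolates)]
    expected = [
        c.n_core + u + s for u, s in zip(c.unique_per_isolate, share_counts)
    ]
    assert burden.tolist() == expected


# ---------------------------------------------------------------------------
# hotspots

def _brute_force_hotspots(effects, annotation, core):
    """Independent enumeration of the hotspot rule for small instances."""
    gene_vars = {}
    for e in effects:
        g = e.locus_tag or e.assigned_gene
        if g:
            gene_vars.setdefault(g, set()).add(e.variant_id)
    core_genes = {g for g, vs in gene_vars.items() if vs & core}

    found = []
    used_by_operon = set()
    for oid in sorted(annotation.operons):
        genes = [g for g in annotation.operons[oid] if g in gene_vars]
        variants = set().union(set(), *(gene_vars[g] for g in genes))
        if len(variants) >= 2 and any(g in core_genes for g in genes):
            found.append(("operon", frozenset(variants)))
            used_by_operon.update(genes)
    in_pathway = set()
    for pid in sorted(annotation.pathways):
        genes = [g for g in sorted(annotation.pathways[pid]) if g in gene_vars and g not in used_by_operon]
        if len(genes) < 2:
            continue
        variants = set().union(*(gene_vars[g] for g in genes))
        if len(variants) >= 2 and any(g in core_genes for g in genes):
            found.append(("pathway", frozenset(variants)))
            in_pathway.update(genes)
    for g in sorted(gene_vars):
        if g in used_by_operon or g in in_pathway:
            continue
        if len(gene_vars[g]) >= 2 and g in core_genes:
            found.append(("same_gene", frozenset(gene_vars[g])))
    return sorted(found)


def test_single_mutated_gene_without_partners_is_not_a_hotspot():
    genes = [Gene("a", 1, 300, "+"), Gene("b", 400, 700, "+")]
    ann = GenomeAnnotation(genes=genes, reference_length=1000)
    effects = [EffectAnnotation("v1", "NONSYN", locus_tag="a")]
    assert call_hotspots(effects, ann, core={"v1"}) == []


def test_two_mutations_one_core_gene_is_a_hotspot():
    ann = GenomeAnnotation(genes=[Gene("a", 1, 300, "+")], reference_length=500)
    effects = [
        EffectAnnotation("v1", "NONSYN", locus_tag="a"),
        EffectAnnotation("v2", "SYN", locus_tag="a"),
    ]
    [hs] = call_hotspots(effects, ann, core={"v1"})
    assert hs.grouping_basis == "same_gene" and hs.member_variants == {"v1", "v2"}
    # without a core anchor there is no hotspot
    assert call_hotspots(effects, ann, core=set()) == []


def test_hotspot_example_cohort():
    effects, ann, core = load_hotspot_example()
    hotspots = call_hotspots(effects, ann, core)
    assert len(hotspots) == 8
    counts = sorted((len(h.member_variants) for h in hotspots), reverse=True)
    assert counts == [5, 5, 4, 2, 2, 2, 2, 2]
    members = set().union(*(h.member_variants for h in hotspots))
    assert len(members) == 24 and len(members & core) == 14
    for h in hotspots:
        assert h.core_anchor in h.member_genes


def test_hotspots_match_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(60):
        n_genes = int(rng.integers(3, 21))
        genes = [Gene(f"g{i}", 1 + 400 * i, 300 + 400 * i, "+") for i in range(n_genes)]
        tags = [g.locus_tag for g in genes]
        operons, pathways = {}, {}
        pool = list(tags)
        rng.shuffle(pool)
        k = 0
        while len(pool) >= 2 and rng.random() < 0.6:
            size = int(rng.integers(2, min(5, len(pool)) + 1))
            operons[f"op{k}"] = [pool.pop() for _ in range(size)]
            k += 1
        for k in range(int(rng.integers(0, 3))):
            size = int(rng.integers(2, min(6, n_genes) + 1))
            pathways[f"pw{k}"] = set(rng.choice(tags, size=size, replace=False))
        ann = GenomeAnnotation(genes=genes, operons=operons, pathways=pathways,
                               reference_length=400 * n_genes + 400)
        n_mut = int(rng.integers(0, 31))
        effects, all_vids = [], []
        for v in range(n_mut):
            tag = tags[rng.integers(0, n_genes)]
            vid = f"v{v}"
            effects.append(EffectAnnotation(vid, "NONSYN", locus_tag=tag))
            all_vids.append(vid)
        core = set(rng.choice(all_vids, size=int(rng.integers(0, n_mut + 1)), replace=False)) if n_mut else set()
        got = sorted(
            (h.grouping_basis, frozenset(h.member_variants))
            for h in call_hotspots(effects, ann, core)
        )
        assert got == _brute_force_hotspots(effects, ann, core)


def test_planted_hotspots_recovered_exactly(default_cohort):
    from alemut.effects import annotate_variants

    calls, ann, ref, samples, truth = default_cohort
    hc, _ = screen_variants(calls, samples)
    effects = annotate_variants(hc, ann, ref)
    part = partition_pan_genome(build_presence(hc, samples), samples)
    hotspots = call_hotspots(effects, ann, part.core)
    got = sorted((h.grouping_basis, tuple(h.member_genes)) for h in hotspots)
    expected = sorted((g["basis"], tuple(sorted(g["genes"]))) for g in truth.hotspot_groups)
    assert got == expected


# ---------------------------------------------------------------------------
# property-based checks

from hypothesis import given, settings, strategies as st


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.data())
def test_partition_classes_follow_isolate_counts(data):
    """For arbitrary presence patterns, each variant's class is fully
    determined by the number of isolates carrying it."""
    n_pop = data.draw(st.integers(1, 4))
    n_iso = data.draw(st.integers(1, 6))
    samples = _samples(n_pop=n_pop, n_iso=n_iso)
    n_var = data.draw(st.integers(1, 12))
    calls = []
    for v in range(n_var):
        carriers = data.draw(
            st.sets(st.sampled_from([s.sample_id for s in samples if s.role is not Role.WILD_TYPE]), min_size=1)
        )
        for sid in carriers:
            af = 0.5 if sid.startswith("P") else None
            calls.append(_call(v + 1, sid, af=af))
    presence = build_presence(calls, samples)
    part = partition_pan_genome(presence, samples)
    iso_ids = [s.sample_id for s in samples if s.role is Role.ISOLATE]
    for vid in presence.matrix.index:
        k = int(presence.matrix.loc[vid, iso_ids].sum())
        if k == n_iso:
            assert vid in part.core
        elif k == 0:
            assert vid in part.discarded
        elif k == 1:
            assert vid in part.unique
        else:
            assert vid in part.shared
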