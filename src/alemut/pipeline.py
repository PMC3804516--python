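"""Stage orchestration over a study directory.

A *study directory* holds the pipeline inputs in the package's text
formats (``samples.tsv``, ``variants.tsv``, ``reference.fa``,
``annotation.gff3``, ``operons.tsv``, ``pathways.tsv`` and optionally
``counts.tsv``/``design.tsv``, ``growth_*.csv``, ``pssm_*.tsv``); stages
write their outputs into a results directory. Every stage is a thin
function over the library modules so they can be driven from the CLI or
called directly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import pandas as pd

from . import cohort as co
from . import effects as ef
from . import expression as ex
from . import filtering as fl
from . import growth as gr
from . import io as aio
from . import scoring as sc


@dataclasses.dataclass
class PipelineConfig:
    """Run-wide parameters; defaults mirror the printed study thresholds."""

    indir: Path
    outdir: Path
    presence_threshold: float = 0.02
    upstream_window: int = 500
    fdr: float = 0.05
    baseline: Optional[str] = None  # default: first condition in the design
    ancova_form: str = "main_effect"
    seed: int = 0

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        data["indir"] = Path(data["indir"])
        data["outdir"] = Path(data["outdir"])
        return cls(**data)


class MissingInputError(FileNotFoundError):
    pass


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingInputError(f"missing input artifact: {path}")
    return path


def _load_inputs(cfg: PipelineConfig):
    samples = aio.read_samples(_require(cfg.indir / "samples.tsv"))
    calls = aio.read_variant_table(_require(cfg.indir / "variants.tsv"), samples)
    return samples, calls


def _load_annotation(cfg: PipelineConfig):
    operons = cfg.indir / "operons.tsv"
    pathways = cfg.indir / "pathways.tsv"
    return aio.read_annotation(
        _require(cfg.indir / "annotation.gff3"),
        operons if operons.exists() else None,
        pathways if pathways.exists() else None,
    )


def stage_filter(cfg: PipelineConfig) -> list:
    """Artifact + confidence screen; writes the ledger and the hc table."""
    samples, calls = _load_inputs(cfg)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    hc, summary = fl.screen_variants(calls, samples, threshold=cfg.presence_threshold)
    fl.write_filter_summary(summary, cfg.outdir / "filter_summary.tsv")
    aio.write_variant_table(hc, cfg.outdir / "variants_hc.tsv")
    return hc


def _load_hc(cfg: PipelineConfig):
    samples = aio.read_samples(_require(cfg.indir / "samples.tsv"))
    hc_path = cfg.outdir / "variants_hc.tsv"
    if not hc_path.exists():
        return samples, stage_filter(cfg)
    return samples, aio.read_variant_table(hc_path, samples)


def stage_annotate(cfg: PipelineConfig) -> list:
    samples, hc = _load_hc(cfg)
    annotation = _load_annotation(cfg)
    _, reference = aio.read_reference(_require(cfg.indir / "reference.fa"))
    effects = ef.annotate_variants(hc, annotation, reference, window=cfg.upstream_window)
    ef.write_effects(effects, cfg.outdir / "effects.tsv")
    dist = ef.tabulate_effects(effects)
    with open(cfg.outdir / "effect_distribution.tsv", "w") as fh:
        fh.write("effect\tcount\n")
        for k in ("SYN", "NONSYN", "STOP", "INDEL", "NONCODING"):
            fh.write(f"{k}\t{dist.counts[k]}\n")
        fh.write(f"fraction_noncoding\t{dist.fraction_noncoding!r}\n")
        fh.write(f"nonsyn_to_syn_ratio\t{dist.nonsyn_to_syn_ratio!r}\n")
    return effects


def stage_pangenome(cfg: PipelineConfig):
    samples, hc = _load_hc(cfg)
    presence = co.build_presence(hc, samples, threshold=cfg.presence_threshold)
    partition = co.partition_pan_genome(presence, samples)
    burden = co.isolate_burden(presence, samples)
    burden.rename_axis("sample_id").rename("n_mutations").to_csv(
        cfg.outdir / "isolate_burden.tsv", sep="\t"
    )
    return presence, partition


def stage_longitudinal(cfg: PipelineConfig):
    samples, hc = _load_hc(cfg)
    presence = co.build_presence(hc, samples, threshold=cfg.presence_threshold)
    profile = co.longitudinal_accumulation(presence, samples)
    pd.DataFrame(
        {
            "sample_id": profile.sample_ids,
            "cumulative": profile.cumulative,
            "delta": profile.deltas,
            "symmetric_difference": profile.symmetric_differences,
        }
    ).to_csv(cfg.outdir / "longitudinal.tsv", sep="\t", index=False)
    return profile

def stage_hotspots(cfg: PipelineConfig):
    effects_path = cfg.outdir / "effects.tsv"
    effects = stage_annotate(cfg) if not effects_path.exists() else _read_effects(effects_path)
    _, partition = stage_pangenome(cfg)
    annotation = _load_annotation(cfg)
    hotspots = co.call_hotspots(effects, annotation, partition.core)
    return hotspots, partition


def _read_effects(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(
            ef.EffectAnnotation(
                variant_id=r["variant_id"],
                effect=r["effect"],
                locus_tag=r["locus_tag"] or None,
                codon_index=int(r["codon_index"]) if r["codon_index"] else None,
                ref_aa=r["ref_aa"] or None,
                alt_aa=r["alt_aa"] or None,
                assigned_gene=r["assigned_gene"] or None,
            )
        )
    return out


def stage_score(cfg: PipelineConfig) -> list:
    """Score NONSYN effects against any bundled domain profiles.

    Profiles are ``pssm_<locus_tag>.tsv`` files in the study directory;
    substitutions falling outside a profile's domain are skipped.
    """
    effects_path = cfg.outdir / "effects.tsv"
    effects = stage_annotate(cfg) if not effects_path.exists() else _read_effects(effects_path)
    scores = []
    for pssm_path in sorted(cfg.indir.glob("pssm_*.tsv")):
        model = aio.read_pssm(pssm_path)
        for e in effects:
            if e.effect != "NONSYN" or e.locus_tag != model.domain_locus:
                continue
            try:
                scores.append(
                    sc.score_function_change(
                        model, e.codon_index, e.ref_aa, e.alt_aa, variant_id=e.variant_id
                    )
                )
            except sc.OutOfDomainError:
                continue
    sc.write_scores(scores, cfg.outdir / "function_scores.tsv")
    return scores


def stage_expression(cfg: PipelineConfig) -> list:
    counts = cfg.indir / "counts.tsv"
    design = cfg.indir / "design.tsv"
    if not counts.exists():
        return []
    matrix = aio.read_counts(counts, _require(design))
    normalized = ex.normalize_counts(matrix)
    baseline = cfg.baseline or normalized.conditions[0]
    calls = ex.test_differential_expression(normalized, baseline=baseline, fdr=cfg.fdr)
    sig_genes = sorted({c.locus_tag for c in calls if c.significant})
    if len(sig_genes) >= 2:
        contrasts = sorted({c.contrast for c in calls})
        mat = pd.DataFrame(0.0, index=sig_genes, columns=contrasts)
        for c in calls:
            if c.locus_tag in mat.index:
                mat.loc[c.locus_tag, c.contrast] = c.log2_diff
        _, order, nwk = ex.cluster_de_genes(mat)
        (cfg.outdir / "de_dendrogram.nwk").write_text(nwk + "\n")
        (cfg.outdir / "de_gene_order.txt").write_text("\n".join(order) + "\n")
    return calls


def stage_growth(cfg: PipelineConfig):
    """Fit every growth curve and run pairwise ANCOVA on ln(OD) vs time."""
    import numpy as np

    curves = [aio.read_growth_csv(p) for p in sorted(cfg.indir.glob("growth_*.csv"))]
    fits, results = [], []
    for curve in curves:
        fits.append(gr.fit_growth_rate(curve))
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "strain": f.strain,
                "condition": f.condition,
                "lag_end_h": f.lag_end,
                "t_max_od_h": f.t_max_od,
                "mu_net_per_h": f.mu_net,
                "r_squared": f.r_squared,
            }
            for f in fits
        ]
    ).to_csv(cfg.outdir / "growth_fits.tsv", sep="\t", index=False)
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            a, b = curves[i], curves[j]
            sa = _ln_series(a)
            sb = _ln_series(b)
            label = f"{a.strain}/{a.condition} vs {b.strain}/{b.condition}"
            results.append(
                gr.ancova_compare(sa, sb, model_form=cfg.ancova_form, comparison=label)
            )
    return fits, results


def _ln_series(curve):
    import numpy as np

    mask = curve.od > 0
    return curve.times[mask], np.log(curve.od[mask])


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in dependency order and write the combined report."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    stage_filter(cfg)
    stage_annotate(cfg)
    presence, partition = stage_pangenome(cfg)
    samples = aio.read_samples(cfg.indir / "samples.tsv")
    profile = None
    if sum(1 for s in samples if s.role.value == "population") >= 2:
        profile = stage_longitudinal(cfg)
    hotspots, partition = stage_hotspots(cfg)
    scores = stage_score(cfg)
    de_calls = stage_expression(cfg)
    growth_stats = []
    if any(cfg.indir.glob("growth_*.csv")):
        _, growth_stats = stage_growth(cfg)
    aio.write_report(partition, hotspots, de_calls, growth_stats, cfg.outdir)
    return {
        "partition": partition,
        "longitudinal": profile,
        "hotspots": hotspots,
        "scores": scores,
        "de_calls": de_calls,
        "growth": growth_stats,
    }
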