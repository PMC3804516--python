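"""Linking mutations to expression changes.

Candidate genes are the union of four selection rules: a gene is a
candidate if it (1) is mutated, (2) sits downstream of or in an operon
with a mutated gene, (3) is another copy (paralog) of a mutated gene, or
(4) is under regulatory control of a mutated gene.

Counts are upper-quartile scaled and log2 transformed; per-gene one-way
ANOVA across conditions is combined with Benjamini-Hochberg FDR control
and dual effect-size thresholds (|log2 difference| > 1 and
-log10 p > 1.714) to call differential expression against a baseline
condition. Significant genes are ordered by average-linkage hierarchical
clustering of their log2 contrast profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .effects import EffectAnnotation
from .types import ExpressionMatrix, GenomeAnnotation, ValidationError

#: printed significance thresholds for a differential-expression call
LOG2_DIFF_THRESHOLD = 1.0
NEG_LOG10_P_THRESHOLD = 1.714


def normalize_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Upper-quartile scale then log2-transform a raw count matrix.

    Each sample is divided by the 75th percentile of its nonzero counts and
    multiplied by the geometric mean of all samples' factors (so values stay
    on a count-like scale); a +1 pseudocount precedes the log2.
    """
    if matrix.normalized:
        return matrix
    counts = matrix.counts.to_numpy(dtype=float)
    factors = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        col = counts[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValidationError(
                f"sample {matrix.counts.columns[j]!r} has all-zero counts"
            )
        factors[j] = np.percentile(nz, 75)
    scale = np.exp(np.mean(np.log(factors)))
    scaled = counts / factors * scale
    norm = np.log2(scaled + 1.0)
    return ExpressionMatrix(
        counts=pd.DataFrame(norm, index=matrix.counts.index, columns=matrix.counts.columns),
        design=matrix.design.copy(),
        normalized=True,
    )


def upper_quartile_factors(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-sample 75th percentiles of nonzero counts (the scale factors)."""
    counts = matrix.counts.to_numpy(dtype=float)
    return np.array(
        [np.percentile(col[col > 0], 75) for col in counts.T]
    )


# ---------------------------------------------------------------------------
# candidate genes

@dataclass
class CandidateGeneSet:
    """Selected genes with the reason(s) each was selected."""

    reasons: dict[str, set[str]] = field(default_factory=dict)

    def add(self, gene: str, reason: str) -> None:
        self.reasons.setdefault(gene, set()).add(reason)

    @property
    def genes(self) -> list[str]:
        return sorted(self.reasons)


def select_candidate_genes(
    effects: Sequence[EffectAnnotation],
    annotation: GenomeAnnotation,
    paralog_map: Optional[dict[str, list[str]]] = None,
    regulon_map: Optional[dict[str, list[str]]] = None,
) -> CandidateGeneSet:
    """Apply the four candidate-selection rules; reasons are recorded.

    "Downstream" means the next gene on the same strand after a mutated
    gene; operon co-membership covers whole transcription units.
    """
    paralog_map = paralog_map or {}
    regulon_map = regulon_map or {}
    out = CandidateGeneSet()
    mutated = sorted(
        {e.locus_tag or e.assigned_gene for e in effects if e.locus_tag or e.assigned_gene}
    )
    for g in mutated:
        out.add(g, "mutated")
    ordered = annotation.genes
    index_of = {g.locus_tag: i for i, g in enumerate(ordered)}
    for g in mutated:
        oid = annotation.operon_of(g)
        if oid is not None:
            for member in annotation.operons[oid]:
                if member != g:
                    out.add(member, "downstream_or_operon")
        i = index_of.get(g)
        if i is not None:
            strand = ordered[i].strand
            neighbor = i + 1 if strand == "+" else i - 1
            if 0 <= neighbor < len(ordered) and ordered[neighbor].strand == strand:
                out.add(ordered[neighbor].locus_tag, "downstream_or_operon")
        for copy in paralog_map.get(g, []):
            out.add(copy, "paralog_copy")
        for target in regulon_map.get(g, []):
            out.add(target, "regulatory_target")
    return out


# ---------------------------------------------------------------------------
# differential expression

@dataclass(frozen=True)
class DECall:
    locus_tag: str
    contrast: str
    log2_diff: float
    p_value: Optional[float]
    neg_log10_p: Optional[float]
    fdr_pass: bool
    significant: bool


def benjamini_hochberg(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejection decisions (wrapper kept as the single FDR entry point)."""
    reject, _, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return reject


def test_differential_expression(
    matrix: ExpressionMatrix,
    baseline: str,
    fdr: float = 0.05,
    genes: Optional[Sequence[str]] = None,
) -> list[DECall]:
    """Per-gene ANOVA across conditions with FDR control and dual thresholds.

    One DECall per gene per non-baseline condition; ``log2_diff`` is the
    mean normalized difference from baseline. A call is significant iff the
    gene survives BH-FDR on its ANOVA p-value AND |log2_diff| > 1 AND
    -log10 p > 1.714. With single-replicate conditions the ANOVA is not
    well-posed; the fallback keeps log2_diff and applies the fold-change
    threshold alone.
    """
    if not matrix.normalized:
        matrix = normalize_counts(matrix)
    conditions = matrix.conditions
    if baseline not in conditions:
        raise ValidationError(f"baseline condition {baseline!r} not in design")
    if len(conditions) < 2:
        raise ValidationError("differential expression needs >= 2 conditions")
    sub = matrix.counts.loc[list(genes)] if genes is not None else matrix.counts
    groups = [sub[matrix.samples_for(c)].to_numpy(dtype=float) for c in conditions]
    have_replicates = all(g.shape[1] >= 2 for g in groups)
    if have_replicates:
        with np.errstate(invalid="ignore"):
            _, pvals = stats.f_oneway(*groups, axis=1)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        fdr_pass = benjamini_hochberg(pvals, alpha=fdr)
    else:
        pvals = None
        fdr_pass = np.zeros(len(sub), dtype=bool)
    means = {c: g.mean(axis=1) for c, g in zip(conditions, groups)}
    calls: list[DECall] = []
    for ci, cond in enumerate(conditions):
        if cond == baseline:
            continue
        diffs = means[cond] - means[baseline]
        for gi, gene in enumerate(sub.index):
            if pvals is not None:
                p = float(pvals[gi])
                nlp = -math.log10(p)
                sig = (
                    bool(fdr_pass[gi])
                    and abs(diffs[gi]) > LOG2_DIFF_THRESHOLD
                    and nlp > NEG_LOG10_P_THRESHOLD
                )
                calls.append(
                    DECall(gene, f"{cond} vs {baseline}", float(diffs[gi]), p, nlp, bool(fdr_pass[gi]), sig)
                )
            else:
                sig = abs(diffs[gi]) > LOG2_DIFF_THRESHOLD
                calls.append(
                    DECall(gene, f"{cond} vs {baseline}", float(diffs[gi]), None, None, False, sig)
                )
    return calls


# ---------------------------------------------------------------------------
# clustering

def cluster_de_genes(de_matrix: pd.DataFrame) -> tuple[np.ndarray, list[str], str]:
    """Average-linkage hierarchical clustering of gene log2 profiles.

    ``de_matrix`` is genes x contrasts of log2 differences. Returns the
    scipy linkage matrix, the deterministic leaf-ordered gene list, and a
    Newick rendering of the dendrogram (merge heights as branch lengths).
    """
    genes = list(de_matrix.index)
    if len(genes) == 1:
        return np.empty((0, 4)), genes, f"{genes[0]};"
    link = hierarchy.linkage(de_matrix.to_numpy(dtype=float), method="average", metric="euclidean")
    order = [genes[i] for i in hierarchy.leaves_list(link)]
    tree = hierarchy.to_tree(link)

    def newick(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{genes[node.id]}:{length:g}"
        left = newick(node.get_left(), node.dist)
        right = newick(node.get_right(), node.dist)
        return f"({left},{right}):{length:g}"

    nwk = f"({newick(tree.get_left(), tree.dist)},{newick(tree.get_right(), tree.dist)});"
    return link, order, nwk
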