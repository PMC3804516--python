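"""High-confidence variant screening.

Raw resequencing reports contain three kinds of noise this stage removes:

1. *Reference artifacts* — putative differences present in every sample
   including the wild type. These are discrepancies between the ancestor
   actually used and the published reference genome, not mutations that
   arose during the evolution, and the whole variant is dropped.
2. *Flagged calls* — observations the caller labelled false positive
   (``fp``), Illumina sequence-specific error (``ise``) or structural
   variant (``sv``). Only ``hc`` (high-confidence) calls survive.

Counts are tracked per distinct variant, not per observation, so the ledger
mirrors the arithmetic of a study report (raw -> artifact-free -> hc).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .cohort import build_presence
from .types import ConfidenceFlag, Role, SampleMeta, ValidationError, VariantCall


@dataclass
class FilterSummary:
    """Ledger of the two screening steps, in distinct-variant units."""

    n_input: int = 0
    n_reference_artifacts: int = 0
    n_after_artifact_removal: int = 0
    n_dropped_by_flag: dict[str, int] = field(default_factory=dict)
    n_high_confidence: int = 0

    def validate(self) -> None:
        if self.n_input - self.n_reference_artifacts != self.n_after_artifact_removal:
            raise ValidationError("artifact arithmetic inconsistent")
        if self.n_after_artifact_removal - sum(self.n_dropped_by_flag.values()) != (
            self.n_high_confidence
        ):
            raise ValidationError("flag arithmetic inconsistent")


def remove_reference_artifacts(
    calls: Sequence[VariantCall],
    samples: Sequence[SampleMeta],
    threshold: float = 0.02,
) -> tuple[list[VariantCall], set[str]]:
    """Drop variants present in every sample including the wild type.

    Presence uses the same allele-frequency threshold rule as the cohort
    analyses, so one parameter governs both screens. Returns the retained
    observations and the removed variant ids.
    """
    if not any(s.role is Role.WILD_TYPE for s in samples):
        raise ValidationError("cohort has no wild_type sample; artifact screen undefined")
    if not calls:
        return [], set()
    presence = build_presence(calls, samples, threshold=threshold)
    everywhere = presence.matrix.all(axis=1)
    removed = set(everywhere.index[everywhere])
    kept = [c for c in calls if c.variant_id not in removed]
    return kept, removed


def filter_high_confidence(
    calls: Sequence[VariantCall],
) -> tuple[list[VariantCall], FilterSummary]:
    """Keep only ``hc``-flagged calls; ledger counts dropped flags.

    Flags are caller-provided and must agree across a variant's
    observations; mixed flags for one variant are a data-integrity error.
    """
    flags: dict[str, ConfidenceFlag] = {}
    for c in calls:
        prev = flags.setdefault(c.variant_id, c.confidence_flag)
        if prev is not c.confidence_flag:
            raise ValidationError(
                f"variant {c.variant_id} carries conflicting confidence flags "
                f"({prev.value} vs {c.confidence_flag.value})"
            )
    dropped: dict[str, int] = {}
    for flag in flags.values():
        if flag is not ConfidenceFlag.HC:
            dropped[flag.value] = dropped.get(flag.value, 0) + 1
    kept = [c for c in calls if c.confidence_flag is ConfidenceFlag.HC]
    summary = FilterSummary(
        n_input=len(flags),
        n_reference_artifacts=0,
        n_after_artifact_removal=len(flags),
        n_dropped_by_flag=dropped,
        n_high_confidence=sum(1 for f in flags.values() if f is ConfidenceFlag.HC),
    )
    summary.validate()
    return kept, summary


def screen_variants(
    calls: Sequence[VariantCall],
    samples: Sequence[SampleMeta],
    threshold: float = 0.02,
) -> tuple[list[VariantCall], FilterSummary]:
    """Full screen: artifact removal first, then confidence-flag filtering."""
    n_input = len({c.variant_id for c in calls})
    kept, removed = remove_reference_artifacts(calls, samples, threshold=threshold)
    hc, summary = filter_high_confidence(kept)
    summary.n_input = n_input
    summary.n_reference_artifacts = len(removed)
    summary.validate()
    return hc, summary


def write_filter_summary(summary: FilterSummary, path) -> None:
    """Serialize the ledger as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("metric\tcount\n")
        fh.write(f"input_variants\t{summary.n_input}\n")
        fh.write(f"reference_artifacts\t{summary.n_reference_artifacts}\n")
        fh.write(f"after_artifact_removal\t{summary.n_after_artifact_removal}\n")
        for flag in sorted(summary.n_dropped_by_flag):
            fh.write(f"dropped_{flag}\t{summary.n_dropped_by_flag[flag]}\n")
        fh.write(f"high_confidence\t{summary.n_high_confidence}\n")
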