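"""Function-change prediction for amino-acid substitutions.

A substitution inside a protein-family domain is scored as the difference
between the domain profile's score for the mutant residue and for the
reference residue at that position: a positive delta suggests a potential
gain of function, a negative delta a potential loss. Only the sign and
ordering of deltas are meaningful — absolute magnitudes depend on the
profile's scaling, which varies between toolkits.

A complementary, cruder classifier labels alignment columns by how
conserved the reference residue is across homologs: fully conserved
columns make any substitution suspect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment

from .types import AMINO_ACIDS, ProfileModel, ValidationError


class OutOfDomainError(ValueError):
    """Substitution position falls outside the profile's domain span."""


@dataclass(frozen=True)
class FunctionChangeScore:
    variant_id: str
    model_id: str
    domain_position: int
    ref_score: float
    alt_score: float
    delta: float
    verdict: str  # potential_gain | potential_loss | neutral


def score_function_change(
    model: ProfileModel,
    protein_position: int,
    ref_aa: str,
    alt_aa: str,
    variant_id: str = "",
) -> FunctionChangeScore:
    """Score one substitution against a domain profile.

    ``protein_position`` is 1-based on the protein; it must fall within
    ``[protein_start, protein_end]``. Stop codons are not scoreable here
    (they are handled upstream as STOP effects).
    """
    for aa, label in ((ref_aa, "ref"), (alt_aa, "alt")):
        if aa == "*":
            raise ValidationError("stop codons are not scored against domain profiles")
        if aa not in AMINO_ACIDS:
            raise ValidationError(f"{label}_aa {aa!r} is not a standard residue")
    if not (model.protein_start <= protein_position <= model.protein_end):
        raise OutOfDomainError(
            f"position {protein_position} outside domain "
            f"[{model.protein_start}, {model.protein_end}] of {model.model_id}"
        )
    dom_pos = protein_position - model.protein_start + 1
    ref_score = float(model.pssm.at[dom_pos, ref_aa])
    alt_score = float(model.pssm.at[dom_pos, alt_aa])
    delta = alt_score - ref_score
    if delta > 0:
        verdict = "potential_gain"
    elif delta < 0:
        verdict = "potential_loss"
    else:
        verdict = "neutral"
    return FunctionChangeScore(
        variant_id=variant_id,
        model_id=model.model_id,
        domain_position=dom_pos,
        ref_score=ref_score,
        alt_score=alt_score,
        delta=delta,
        verdict=verdict,
    )


@dataclass(frozen=True)
class ConservationCall:
    protein_id: str
    column_index: int
    call: str  # very_conserved | non_conserved | intermediate
    identity_fraction: float


def classify_conservation(
    msa: MultipleSeqAlignment,
    column_index: int,
    reference_row: int = 0,
    low_threshold: float = 0.5,
) -> ConservationCall:
    """Classify one alignment column by identity to the reference residue.

    ``column_index`` is 1-based. Identity is the fraction of non-gap
    residues matching the reference residue; 1.0 is ``very_conserved``,
    below ``low_threshold`` is ``non_conserved``, else ``intermediate``.
    """
    if not (1 <= column_index <= msa.get_alignment_length()):
        raise ValidationError(
            f"column {column_index} outside alignment width {msa.get_alignment_length()}"
        )
    column = [str(rec.seq[column_index - 1]).upper() for rec in msa]
    ref_res = column[reference_row]
    if ref_res == "-":
        raise ValidationError("reference row is gapped at the requested column")
    residues = [r for r in column if r != "-"]
    if not residues:
        raise ValidationError("all-gap column")
    identity = residues.count(ref_res) / len(residues)
    if identity == 1.0:
        call = "very_conserved"
    elif identity < low_threshold:
        call = "non_conserved"
    else:
        call = "intermediate"
    return ConservationCall(
        protein_id=msa[reference_row].id,
        column_index=column_index,
        call=call,
        identity_fraction=identity,
    )


def build_profile_from_msa(
    msa: MultipleSeqAlignment,
    pseudocount: float = 1.0,
    model_id: str = "msa_profile",
    domain_locus: str = "",
    protein_start: int = 1,
) -> ProfileModel:
    """Build a log-odds profile from an alignment (uniform background).

    Match columns are those with <= 50% gaps. Per match column the score of
    residue *a* is ``log2(((count_a + pc) / (N + 20 pc)) / (1/20))`` with
    ``N`` the number of non-gap residues in the column — a plain
    pseudocounted log-odds against the uniform background, sufficient for
    sign/ordering semantics.
    """
    n_seq = len(msa)
    if n_seq < 2:
        raise ValidationError("profile construction needs >= 2 sequences")
    width = msa.get_alignment_length()
    rows = []
    for j in range(width):
        column = [str(rec.seq[j]).upper() for rec in msa]
        non_gap = [r for r in column if r != "-"]
        if len(non_gap) < n_seq / 2:  # > 50% gaps: insert column, skipped
            continue
        n = len(non_gap)
        scores = {}
        for aa in AMINO_ACIDS:
            freq = (non_gap.count(aa) + pseudocount) / (n + 20 * pseudocount)
            scores[aa] = math.log2(freq * 20)
        rows.append(scores)
    if not rows:
        raise ValidationError("alignment has no match columns")
    pssm = pd.DataFrame(rows, columns=list(AMINO_ACIDS))
    return ProfileModel(
        model_id=model_id,
        domain_locus=domain_locus,
        protein_start=protein_start,
        protein_end=protein_start + len(rows) - 1,
        pssm=pssm,
    )


def write_scores(scores, path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tmodel_id\tdomain_position\tref_score\talt_score\tdelta\tverdict\n")
        for s in scores:
            fh.write(
                f"{s.variant_id}\t{s.model_id}\t{s.domain_position}\t"
                f"{s.ref_score!r}\t{s.alt_score!r}\t{s.delta!r}\t{s.verdict}\n"
            )
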