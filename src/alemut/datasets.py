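"""Bundled worked example for hotspot calling.

A curated mutation-to-gene assignment from a *Clostridium thermocellum*
hydrolysate-tolerance laboratory-evolution cohort: 18 mutated genes
carrying 24 mutations, with per-gene core-mutation flags, one
transcription unit (the eight-gene ATP-synthase operon Cthe_2602-2609)
and four pathway groupings (amino-acid production, the Rex/acetate
branch, homocysteine biosynthesis, glycoside hydrolases). Gene
coordinates are plausible placeholders; hotspot calling depends only on
the gene/operon/pathway structure, the mutation-to-gene map and the core
flags.

Running the hotspot caller on this cohort yields eight hotspots with
member-mutation counts {5, 5, 4, 2, 2, 2, 2, 2}: 24 member mutations of
which 14 are core.
"""

from __future__ import annotations

from .effects import EffectAnnotation
from .types import Gene, GenomeAnnotation

# (locus_tag, [(effect, is_core), ...], product)
# "NC" mutations are intergenic hits assigned upstream of the gene.
_GENE_MUTATIONS = [
    ("Cthe_0422", [("NONCODING", True), ("NONSYN", False)],
     "redox-sensing transcriptional repressor Rex"),
    ("Cthe_0948", [("NONSYN", True)], "dihydroorotate dehydrogenase PyrDII"),
    ("Cthe_0949", [("NONSYN", True)], "carbamoyl-phosphate synthase CarB"),
    ("Cthe_1020", [("NONSYN", True), ("NONSYN", False)],
     "extracellular solute-binding protein family 1"),
    ("Cthe_1028", [("INDEL", False)], "acetate kinase"),
    ("Cthe_1029", [("NONSYN", False)], "phosphotransacetylase"),
    ("Cthe_1202", [("NONCODING", True), ("NONSYN", True)],
     "major facilitator superfamily transporter MFS_1"),
    ("Cthe_1256", [("NONSYN", True)], "beta-glucosidase BglX"),
    ("Cthe_1569", [("STOP", True)], "O-acetylhomoserine sulfhydrylase MetY"),
    ("Cthe_1766", [("NONSYN", True)], "glutamate 5-kinase ProB"),
    ("Cthe_1842", [("NONSYN", True)], "O-acetylhomoserine sulfhydrylase MetY"),
    ("Cthe_1866", [("NONSYN", True)], "acetylornithine aminotransferase ArgD"),
    ("Cthe_2119", [("SYN", False)], "anti-sigma factor RsgI6"),
    ("Cthe_2529", [("NONSYN", False)], "pyridoxal-phosphate-dependent aminotransferase"),
    ("Cthe_2602", [("NONCODING", True), ("NONCODING", False)],
     "ATP synthase F1, epsilon subunit"),
    ("Cthe_2603", [("NONSYN", True), ("NONSYN", False)], "ATP synthase F1, beta subunit"),
    ("Cthe_2607", [("NONSYN", False)], "ATP synthase F0, B subunit"),
    ("Cthe_3087", [("NONSYN", True), ("NONSYN", False)],
     "sporulation transcriptional activator Spo0A"),
]

_OPERONS = {
    "TU_Cthe_2602_9": [f"Cthe_{n}" for n in range(2602, 2610)],
}

_PATHWAYS = {
    "amino_acid_production": {
        "Cthe_0948", "Cthe_0949", "Cthe_1766", "Cthe_1866", "Cthe_2529",
    },
    "rex_acetate_formation": {"Cthe_0422", "Cthe_1028", "Cthe_1029"},
    "homocysteine_biosynthesis": {"Cthe_1569", "Cthe_1842"},
    "glycoside_hydrolases": {"Cthe_1256", "Cthe_2119"},
}


def load_hotspot_example() -> tuple[list[EffectAnnotation], GenomeAnnotation, set[str]]:
    """The curated cohort as (effects, annotation, core variant ids).

    Feed the three return values straight to
    :func:`alemut.cohort.call_hotspots`.
    """
    tags = sorted({t for t, _, _ in _GENE_MUTATIONS} | {
        t for members in _OPERONS.values() for t in members
    })
    genes = []
    start = 1000
    products = {t: p for t, _, p in _GENE_MUTATIONS}
    for tag in tags:
        genes.append(Gene(tag, start, start + 899, "+", products.get(tag, "")))
        start += 1500
    annotation = GenomeAnnotation(
        genes=genes, operons=dict(_OPERONS), pathways=dict(_PATHWAYS), reference_length=start
    )
    effects: list[EffectAnnotation] = []
    core: set[str] = set()
    for tag, mutations, _ in _GENE_MUTATIONS:
        for k, (effect, is_core) in enumerate(mutations, start=1):
            vid = f"{tag}.m{k}"
            if effect == "NONCODING":
                effects.append(
                    EffectAnnotation(variant_id=vid, effect=effect, assigned_gene=tag)
                )
            else:
                effects.append(EffectAnnotation(variant_id=vid, effect=effect, locus_tag=tag))
            if is_core:
                core.add(vid)
    return effects, annotation, core
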