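"""Format readers/writers: round trips, dialects, and validation errors."""

import numpy as np
import pytest

from alemut import io as aio
from alemut.simulate import CohortConfig, generate_growth_curves, write_study
from alemut.types import (
    ConfidenceFlag,
    Gene,
    GenomeAnnotation,
    Role,
    SampleMeta,
    ValidationError,
    validate_cohort,
)

SAMPLES = [
    SampleMeta("WT", Role.WILD_TYPE, 0),
    SampleMeta("P1", Role.POPULATION, 1),
    SampleMeta("P2", Role.POPULATION, 2),
    SampleMeta("I1", Role.ISOLATE, 2),
]


def test_cohort_invariants_enforced():
    with pytest.raises(ValidationError):
        validate_cohort([SampleMeta("P1", Role.POPULATION, 1)])  # no wild type
    with pytest.raises(ValidationError):
        validate_cohort(
            [
                SampleMeta("WT", Role.WILD_TYPE, 0),
                SampleMeta("P2", Role.POPULATION, 2),
                SampleMeta("P1", Role.POPULATION, 2),  # stage collision
            ]
        )
    with pytest.raises(ValidationError):
        validate_cohort(
            [
                SampleMeta("WT", Role.WILD_TYPE, 0),
                SampleMeta("P1", Role.POPULATION, 3),
                SampleMeta("I1", Role.ISOLATE, 1),  # isolate not at final stage
            ]
        )


def test_empty_variant_table(tmp_path):
    path = tmp_path / "v.tsv"
    path.write_text("sample_id\tposition\tref\talt\tcaller_class\tconfidence_flag\n")
    assert aio.read_variant_table(path, SAMPLES) == []


def test_variant_table_parsing_and_flags(tmp_path):
    path = tmp_path / "v.tsv"
    path.write_text(
        "sample_id\tposition\tref\talt\tcaller_class\tconfidence_flag\tallele_frequency\n"
        "I1\t100\tA\tG\tsnp\thc\t\n"
        "P1\t200\tC\tT\tsnp\tfp\t0.4\n"
        "P2\t300\tG\tA\tsnp\thc\t0.015\n"
    )
    calls = aio.read_variant_table(path, SAMPLES)
    assert len(calls) == 3
    assert sum(c.confidence_flag is ConfidenceFlag.FP for c in calls) == 1
    # sub-2% population frequency parses as a detection-level observation
    assert calls[2].allele_frequency == pytest.approx(0.015)
    assert calls[0].allele_frequency is None


@pytest.mark.parametrize(
    "row,match",
    [
        ("I1\tnotint\tA\tG\tsnp\thc\t", "line 2"),
        ("I1\t100\tA\tG\tsnp\tweird\t", "line 2"),
        ("NOPE\t100\tA\tG\tsnp\thc\t", "line 2"),
    ],
)
def test_malformed_rows_name_line(tmp_path, row, match):
    path = tmp_path / "v.tsv"
    path.write_text(
        "sample_id\tposition\tref\talt\tcaller_class\tconfidence_flag\tallele_frequency\n"
        + row
        + "\n"
    )
    with pytest.raises(aio.ParseError, match=match):
        aio.read_variant_table(path, SAMPLES)


def test_variant_table_round_trip(tmp_path, default_cohort):
    calls, _, _, samples, _ = default_cohort
    path = tmp_path / "v.tsv"
    aio.write_variant_table(calls, path)
    back = aio.read_variant_table(path, samples)
    assert back == calls


def test_minimal_vcf_reading(tmp_path):
    path = tmp_path / "v.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="c">\n'
        '##INFO=<ID=CONF,Number=1,Type=String,Description="f">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="af">\n'
        "##contig=<ID=ref,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tWT\tP1\n"
        "ref\t100\t.\tA\tG\t.\tPASS\tCLASS=snp;CONF=hc\tGT:AF\t0/0:.\t1/1:0.35\n"
        "ref\t200\t.\tCTT\tC\t.\tPASS\tCLASS=indel;CONF=hc\tGT:AF\t0/0:.\t1/1:0.5\n"
    )
    calls = aio.read_variant_table(path, SAMPLES)
    assert len(calls) == 2
    assert calls[0].sample_id == "P1" and calls[0].allele_frequency == pytest.approx(0.35)
    # anchor-base deletion converts to the "-" convention at the first deleted base
    assert (calls[1].position, calls[1].ref_allele, calls[1].alt_allele) == (201, "TT", "-")


def test_annotation_gff_and_memberships(tmp_path):
    gff = tmp_path / "a.gff3"
    gff.write_text(
        "##gff-version 3\n##sequence-region ref 1 20000\n"
        + "".join(
            f"ref\tx\tCDS\t{1000 * i}\t{1000 * i + 299}\t.\t+\t0\t"
            f"ID=g{i};locus_tag=Cthe_{2600 + i};product=p{i}\n"
            for i in range(2, 12)
        )
    )
    ann = aio.read_annotation(gff)
    assert len(ann.genes) == 10 and ann.operons == {}
    assert ann.reference_length == 20000
    # the GFF interval of a 300 bp gene has length 300 (1-based inclusive)
    assert ann.genes[0].length == 300

    operons = tmp_path / "op.tsv"
    operons.write_text(
        "group_id\tlocus_tag\n"
        + "".join(f"TU_2602_9\tCthe_{n}\n" for n in range(2602, 2610))
    )
    pathways = tmp_path / "pw.tsv"
    pathways.write_text(
        "group_id\tlocus_tag\n" + "".join(f"aa_prod\tCthe_{n}\n" for n in range(2603, 2608))
    )
    ann = aio.read_annotation(gff, operons, pathways)
    assert len(ann.operons["TU_2602_9"]) == 8
    assert len(ann.pathways["aa_prod"]) == 5

    bad = tmp_path / "bad.tsv"
    bad.write_text("group_id\tlocus_tag\nTU\tCthe_9999\n")
    with pytest.raises(ValidationError):
        aio.read_annotation(gff, bad)


def test_annotation_round_trip(tmp_path, default_cohort):
    _, ann, ref, _, _ = default_cohort
    aio.write_annotation(ann, tmp_path / "a.gff3", tmp_path / "op.tsv", tmp_path / "pw.tsv")
    aio.write_reference("ref", ref, tmp_path / "ref.fa")
    back = aio.read_annotation(tmp_path / "a.gff3", tmp_path / "op.tsv", tmp_path / "pw.tsv")
    assert back.genes == ann.genes
    assert back.operons == ann.operons
    assert back.pathways == ann.pathways
    assert back.reference_length == ann.reference_length
    name, seq = aio.read_reference(tmp_path / "ref.fa")
    assert seq == ref


def test_growth_csv_round_trip(tmp_path):
    curves, _ = generate_growth_curves(seed=4, yields={"ethanol": 0.4, "acetate": 0.2})
    aio.write_growth_csv(curves[0], tmp_path / "g.csv")
    back = aio.read_growth_csv(tmp_path / "g.csv")
    assert back.strain == curves[0].strain and back.condition == curves[0].condition
    np.testing.assert_array_equal(back.times, curves[0].times)
    np.testing.assert_array_equal(back.od, curves[0].od)
    for k in curves[0].products:
        np.testing.assert_array_equal(back.products[k], curves[0].products[k])


def test_pssm_round_trip(tmp_path):
    import pandas as pd
    from alemut.types import AMINO_ACIDS, ProfileModel

    rng = np.random.default_rng(0)
    pssm = pd.DataFrame(rng.normal(size=(6, 20)), columns=list(AMINO_ACIDS))
    model = ProfileModel("m1", "Cthe_1866", 50, 55, pssm)
    aio.write_pssm(model, tmp_path / "p.tsv")
    back = aio.read_pssm(tmp_path / "p.tsv")
    assert back.model_id == "m1" and back.domain_locus == "Cthe_1866"
    assert (back.protein_start, back.protein_end) == (50, 55)
    np.testing.assert_array_equal(back.pssm.to_numpy(), model.pssm.to_numpy())


def test_write_report_empty_and_counts(tmp_path, default_cohort):
    aio.write_report(None, None, None, None, tmp_path / "empty")
    assert (tmp_path / "empty" / "summary.txt").exists()
    assert (tmp_path / "empty" / "partition.tsv").read_text().strip() == "variant_id\tclass"

    from alemut import cohort as co, filtering as fl

    calls, ann, ref, samples, _ = default_cohort
    hc, _ = fl.screen_variants(calls, samples)
    presence = co.build_presence(hc, samples)
    part = co.partition_pan_genome(presence, samples)
    aio.write_report(part, None, None, None, tmp_path / "r")
    rows = (tmp_path / "r" / "partition.tsv").read_text().strip().splitlines()
    assert len(rows) - 1 == part.total
    # deterministic re-run is byte-identical
    aio.write_report(part, None, None, None, tmp_path / "r2")
    assert (tmp_path / "r" / "partition.tsv").read_bytes() == (
        tmp_path / "r2" / "partition.tsv"
    ).read_bytes()


def test_written_study_passes_validators(tmp_path):
    write_study(tmp_path / "study", CohortConfig(seed=5))
    samples = aio.read_samples(tmp_path / "study" / "samples.tsv")
    validate_cohort(samples)
    calls = aio.read_variant_table(tmp_path / "study" / "variants.tsv", samples)
    assert calls
    matrix = aio.read_counts(tmp_path / "study" / "counts.tsv", tmp_path / "study" / "design.tsv")
    assert matrix.counts.shape[1] == len(matrix.design)
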