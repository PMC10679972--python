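"""Mutation table I/O, somatic filtering, partitions and biomarker grades."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatial_ith import variant_core as vc
from spatial_ith.synthetic_data import key_to_str


def _rec(**kw):
    base = dict(
        patient_id="P000",
        region="PT_sup",
        chrom="1",
        pos=100,
        ref="C",
        alt="T",
        gene="TP53",
        variant_class="missense",
        vaf=0.3,
        depth=120,
    )
    base.update(kw)
    return vc.MutationRecord(**base)


class TestMutationRecord:
    def test_invariants_enforced(self):
        with pytest.raises(vc.ValidationError):
            _rec(vaf=1.2)
        with pytest.raises(vc.ValidationError):
            _rec(depth=-1)
        with pytest.raises(vc.ValidationError):
            _rec(pos=0)
        with pytest.raises(vc.ValidationError):
            _rec(ref="C", alt="C")
        with pytest.raises(vc.ValidationError):
            _rec(tri_context="ATA")  # middle base must equal ref

    def test_key_and_snv(self):
        r = _rec()
        assert r.key == ("1", 100, "C", "T")
        assert r.is_snv
        assert not _rec(ref="CT", alt="C", variant_class="frameshift").is_snv


class TestReadMutationTable(object):
    def test_tsv_round_trip_preserves_rows(self, tmp_path):
        rows = [_rec(pos=p) for p in (10, 20, 30)]
        vc.records_to_frame(rows).to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        back = vc.read_mutation_table(tmp_path / "m.tsv")
        assert len(back) == 3
        assert [r.pos for r in back] == [10, 20, 30]
        assert back[0] == rows[0]

    def test_missing_column_named_in_error(self, tmp_path):
        df = vc.records_to_frame([_rec()]).drop(columns=["vaf"])
        df.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        with pytest.raises(vc.FormatError, match="vaf"):
            vc.read_mutation_table(tmp_path / "m.tsv")

    def test_out_of_range_vaf_reports_line(self, tmp_path):
        df = vc.records_to_frame([_rec(), _rec(pos=200)])
        df.loc[1, "vaf"] = 1.7
        df.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        with pytest.raises(vc.ValidationError, match="line 3"):
            vc.read_mutation_table(tmp_path / "m.tsv")

    def test_vcf_field_mapping(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##INFO=<ID=CLASS,Number=1,Type=String,Description="c">\n'
            '##FORMAT=<ID=AF,Number=1,Type=Float,Description="af">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1:PT_sup\n"
            "1\t100\t.\tC\tT\t.\t.\tGENE=TP53;CLASS=missense\tAF:DP\t0.25:100\n"
        )
        records = vc.read_mutation_table(vcf, dialect="vcf")
        assert len(records) == 1
        r = records[0]
        assert (r.vaf, r.depth) == (pytest.approx(0.25), 100)
        assert (r.patient_id, r.region, r.gene) == ("P1", "PT_sup", "TP53")


class TestFilterSomatic:
    def test_boundary_values_retained(self):
        kept, _ = vc.filter_somatic([_rec(vaf=0.02, depth=10)])
        assert len(kept) == 1

    def test_below_threshold_removed(self):
        kept, rep = vc.filter_somatic(
            [_rec(vaf=0.019, depth=200), _rec(vaf=0.3, depth=9)]
        )
        assert kept == []
        assert (rep.n_low_vaf, rep.n_low_depth) == (1, 1)

    def test_planted_low_quality_records_recovered(self, genomics_result):
        frame = genomics_result.mutations
        records = [
            vc._record_from_row(row, line=i) for i, row in enumerate(frame.to_dict("records"))
        ]
        kept, rep = vc.filter_somatic(records)
        planted = {
            k for per_patient in genomics_result.truth["low_quality"].values()
            for k in per_patient
        }
        removed = {key_to_str(r.key) for r in records} - {
            key_to_str(r.key) for r in kept
        }
        assert removed == planted
        assert rep.n_retained == rep.n_input - len(planted)

    def test_idempotent_and_gates_hold(self, genomics_result):
        frame = genomics_result.mutations
        records = [
            vc._record_from_row(row, line=i) for i, row in enumerate(frame.to_dict("records"))
        ]
        kept, _ = vc.filter_somatic(records)
        again, rep2 = vc.filter_somatic(kept)
        assert again == kept
        assert all(r.vaf >= 0.02 and r.depth >= 10 for r in kept)
        assert len(kept) <= len(records)


class TestPresenceMatrix:
    def test_trunk_row_pattern(self):
        recs = [_rec(region=r) for r in vc.REGIONS]
        m = vc.build_presence_matrix(recs)
        assert m.taxa == list(vc.REGIONS) + ["normal"]
        np.testing.assert_array_equal(m.values[:, 0], [1, 1, 1, 0])

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no mutations"):
            vc.build_presence_matrix([])

    def test_duplicates_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            m = vc.build_presence_matrix([_rec(), _rec()])
        assert m.values.sum() == 1

    def test_planted_trunk_and_private_structure(self):
        recs = [
            _rec(pos=p, region=r) for p in range(1, 11) for r in vc.REGIONS
        ] + [_rec(pos=p, region="PT_sup") for p in range(100, 105)]
        m = vc.build_presence_matrix(recs)
        tumor = m.values[:3, :]
        assert int((tumor.sum(axis=0) == 3).sum()) == 10
        assert int((tumor.sum(axis=0) == 1).sum()) == 5


class TestPartitionRegions:
    def test_small_example_fractions(self):
        recs = (
            [_rec(pos=1, region=r) for r in vc.REGIONS]
            + [_rec(pos=2, region=r) for r in vc.REGIONS]
            + [_rec(pos=3, region="PT_sup"), _rec(pos=4, region="LN_met")]
        )
        part = vc.partition_regions(vc.build_presence_matrix(recs))
        assert part.unique_fractions == {
            "PT_sup": pytest.approx(0.25),
            "LN_met": pytest.approx(0.25),
        }
        assert part.subset_counts[frozenset(vc.REGIONS)] == 2

    def test_single_shared_key(self):
        recs = [_rec(pos=1, region=r) for r in vc.REGIONS]
        part = vc.partition_regions(vc.build_presence_matrix(recs))
        assert part.unique_counts == {}
        assert part.subset_counts == {frozenset(vc.REGIONS): 1}

    def test_counts_match_bruteforce_tabulation(self, rng):
        n_keys = 200
        values = rng.integers(0, 2, size=(3, n_keys)).astype(np.uint8)
        values[:, values.sum(axis=0) == 0] = 1  # no absent mutations
        taxa = list(vc.REGIONS) + ["normal"]
        full = np.vstack([values, np.zeros((1, n_keys), dtype=np.uint8)])
        m = vc.BinaryCharacterMatrix(
            taxa=taxa,
            characters=[("1", i + 1, "C", "T") for i in range(n_keys)],
            values=full,
        )
        part = vc.partition_regions(m)
        # exhaustive per-key re-tabulation
        expected: dict[frozenset, int] = {}
        for j in range(n_keys):
            s = frozenset(t for i, t in enumerate(vc.REGIONS) if values[i, j])
            expected[s] = expected.get(s, 0) + 1
        assert part.subset_counts == expected
        assert sum(part.subset_counts.values()) == n_keys


class TestGeneFrequency:
    def test_fraction_and_rounding(self):
        recs = []
        for i in range(45):
            patient, region = f"P{i // 3}", vc.REGIONS[i % 3]
            if i < 42:
                recs.append(_rec(patient_id=patient, region=region, gene="TP53"))
            else:
                recs.append(
                    _rec(patient_id=patient, region=region, gene="OTHER")
                )
        freq = vc.gene_frequency(recs, top_n=5)
        tp53 = freq.set_index("gene").loc["TP53", "fraction"]
        assert round(tp53 * 100) == 93

    def test_silent_only_gene_not_listed(self):
        recs = [_rec(), _rec(pos=5, gene="SYN1", variant_class="silent")]
        freq = vc.gene_frequency(recs, top_n=10)
        assert "SYN1" not in set(freq["gene"])

    def test_planted_cohort_frequencies_recovered(self, genomics_result):
        frame = genomics_result.mutations
        records = [
            vc._record_from_row(row, line=i)
            for i, row in enumerate(frame.to_dict("records"))
        ]
        kept, _ = vc.filter_somatic(records)
        freq = vc.gene_frequency(kept, top_n=10_000).set_index("gene")["fraction"]
        for gene, expected in genomics_result.truth["gene_frequency"].items():
            assert freq[gene] == pytest.approx(expected)

    def test_extra_empty_sample_cannot_raise_fractions(self):
        recs = [_rec(patient_id="P0"), _rec(patient_id="P1", gene="TP53")]
        f1 = vc.gene_frequency(recs, 5).set_index("gene")["fraction"]
        recs_plus = recs + [
            _rec(patient_id="P2", gene="ZZZ", variant_class="silent")
        ]
        f2 = vc.gene_frequency(recs_plus, 5).set_index("gene")["fraction"]
        for gene in f1.index:
            assert f2.get(gene, 0) <= f1[gene]


class TestBiomarkers:
    @pytest.mark.parametrize(
        "n, mb, expected",
        [
            (50, 40, "TMB-L"),  # 1.25 / Mb
            (400, 40, "TMB-M"),  # exactly 10, closed upper bound
            (100, 40, "TMB-M"),  # exactly 2.5, closed lower bound
            (401, 40, "TMB-H"),
            (99, 40, "TMB-L"),
        ],
    )
    def test_tmb_grading(self, n, mb, expected):
        assert vc.classify_tmb(n, mb).tmb_class == expected

    @pytest.mark.parametrize(
        "tnb, expected",
        [(0.49, "TNB-L"), (0.5, "TNB-M"), (4.5, "TNB-M"), (5.0, "TNB-H")],
    )
    def test_tnb_grading(self, tnb, expected):
        assert vc.classify_tnb(int(tnb * 40), 40).tnb_class == expected

    @pytest.mark.parametrize(
        "score, expected", [(20.0, "MSI-H"), (19.9, "MSS"), (0.0, "MSS")]
    )
    def test_msi_grading(self, score, expected):
        assert vc.classify_msi(score) == expected

    def test_grading_total_on_random_values(self, rng):
        for _ in range(50):
            t = vc.classify_tmb(int(rng.integers(0, 2000)), 40)
            assert t.tmb_class in ("TMB-H", "TMB-M", "TMB-L")
        with pytest.raises(ValueError):
            vc.classify_tmb(10, 0)
        with pytest.raises(vc.ValidationError):
            vc.classify_msi(120)
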