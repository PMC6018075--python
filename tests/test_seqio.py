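import pytest

from gliadinscan import seqio
from gliadinscan.census_quant import CompositionSummary
from gliadinscan.seqio import (
    EpitopeDefinition,
    FastaError,
    CatalogError,
    ProteinRecord,
    SpotRecord,
)


class TestFasta:
    def test_single_entry(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1\nLQLQ\n")
        (rec,) = seqio.read_fasta(p)
        assert rec.id == "p1" and rec.sequence == "LQLQ"
        assert rec.maturity == "unknown"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fasta"
        p.write_text("")
        assert seqio.read_fasta(p) == []

    def test_lowercase_is_normalised(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1\nlqlq\n")
        assert seqio.read_fasta(p)[0].sequence == "LQLQ"

    def test_maturity_header_token(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1 maturity=mature\nLQLQ\n")
        assert seqio.read_fasta(p)[0].maturity == "mature"

    def test_malformed_names_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("LQLQ\n>p1\nLQLQ\n")
        with pytest.raises(FastaError, match="line 1"):
            seqio.read_fasta(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">p1\nLQLQ\n>p1\nQQQQ\n")
        with pytest.raises(FastaError, match="duplicate"):
            seqio.read_fasta(p)

    def test_invalid_residue_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">p1\nLQ1Q\n")
        with pytest.raises(FastaError, match="invalid residue"):
            seqio.read_fasta(p)

    def test_round_trip(self, tmp_path):
        records = [
            ProteinRecord(id="a", sequence="LQLQPFP", maturity="mature"),
            ProteinRecord(id="b", sequence="QQQQQQ", maturity="precursor"),
        ]
        p = tmp_path / "rt.fasta"
        seqio.write_fasta(records, p)
        back = seqio.read_fasta(p)
        assert [(r.id, r.sequence, r.maturity) for r in back] == [
            (r.id, r.sequence, r.maturity) for r in records
        ]


class TestEpitopeCatalog:
    def test_valid_entry(self):
        epi = EpitopeDefinition(
            name="DQ2.5-glia-α2",
            core_native="PQPQLPYPQ",
            core_deamidated="PQPELPYPQ",
            disease="CD",
            source_family="alpha",
        )
        assert epi.core_deamidated == "PQPELPYPQ"

    def test_wdeia_entry_without_deamidated_core(self):
        epi = EpitopeDefinition(name="WD-1", core_native="QQIPQQQ", disease="WDEIA",
                                source_family="omega")
        assert epi.core_deamidated is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(CatalogError, match="length"):
            EpitopeDefinition(name="x", core_native="PQPQ", core_deamidated="PQE")

    def test_non_q_substitution_rejected(self):
        # deamidation is Q->E only; a change at a P position is not deamidation
        with pytest.raises(CatalogError, match="only Q->E"):
            EpitopeDefinition(name="x", core_native="PQPQ", core_deamidated="AQPQ")

    def test_non_e_replacement_rejected(self):
        with pytest.raises(CatalogError):
            EpitopeDefinition(name="x", core_native="PQPQ", core_deamidated="PAPQ")

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "cat.yaml"
        p.write_text(
            "epitopes:\n"
            "  - {name: a, core_native: PQPQ}\n"
            "  - {name: a, core_native: QQQQ}\n"
        )
        with pytest.raises(CatalogError, match="duplicate"):
            seqio.read_epitope_catalog(p)

    def test_tsv_catalog(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text(
            "name\tcore_native\tcore_deamidated\tdisease\tsource_family\n"
            "WD-1\tQQIPQQQ\t-\tWDEIA\tomega\n"
        )
        (epi,) = seqio.read_epitope_catalog(p)
        assert epi.name == "WD-1" and epi.core_deamidated is None

    def test_default_catalog_contents(self, catalog):
        names = {e.name for e in catalog}
        assert {"DQ2.5-glia-α1a", "DQ2.5-glia-α2", "WD-1", "WD-2"} <= names
        by_name = {e.name: e for e in catalog}
        # cores fixed by the 33-mer decomposition and the omega-5 epitopes
        assert by_name["DQ2.5-glia-α1a"].core_native == "PFPQPQLPY"
        assert by_name["DQ2.5-glia-α2"].core_native == "PQPQLPYPQ"
        assert by_name["WD-1"].core_native == "QQIPQQQ"
        assert by_name["WD-2"].core_native == "QQFPQQQ"
        assert all(e.verified for e in catalog if e.name in
                   ("DQ2.5-glia-α1a", "DQ2.5-glia-α2", "WD-1", "WD-2"))


class TestSpotTable:
    def _write(self, tmp_path, body):
        p = tmp_path / "spots.tsv"
        p.write_text("spot_id\tvolume_norm\tprotein_id\tcategory\tminor_flag\n" + body)
        return p

    def test_toy_table(self, tmp_path):
        p = self._write(
            tmp_path,
            "1\t40.0\tA1\talpha\tfalse\n2\t35.0\tG1\tgamma\tfalse\n3\t25.0\t\tunknown\tfalse\n",
        )
        records = seqio.read_spot_table(p)
        assert len(records) == 3
        assert records[0].category == "alpha"

    def test_negative_volume_rejected(self, tmp_path):
        p = self._write(tmp_path, "1\t-1\tA1\talpha\tfalse\n")
        with pytest.raises(ValueError, match="negative volume"):
            seqio.read_spot_table(p)

    def test_unknown_category_rejected(self, tmp_path):
        p = self._write(tmp_path, "1\t1.0\tA1\tdelta\tfalse\n")
        with pytest.raises(ValueError, match="category"):
            seqio.read_spot_table(p)

    def test_duplicate_spot_id_rejected_when_unique(self, tmp_path):
        p = self._write(tmp_path, "1\t1.0\tA1\talpha\tfalse\n1\t2.0\tG1\tgamma\tfalse\n")
        with pytest.raises(ValueError, match="duplicate"):
            seqio.read_spot_table(p)
        assert len(seqio.read_spot_table(p, unique=False)) == 2

    def test_round_trip(self, tmp_path):
        records = [
            SpotRecord("1", 41.99, "A1", "alpha", False),
            SpotRecord("2", 0.0, "G1", "gamma", True),
        ]
        p = tmp_path / "rt.tsv"
        seqio.write_spot_table(records, p)
        assert seqio.read_spot_table(p, unique=False) == records

    def test_shipped_listings_cover_98_spots(self):
        listings = seqio.keumkang_spot_listings()
        assert len({r.spot_id for r in listings}) == 98


class TestReports:
    def test_empty_census_is_header_only(self, tmp_path):
        p = tmp_path / "census.tsv"
        seqio.write_census_report([], p)
        assert p.read_text().count("\n") == 1

    def test_census_round_trip(self, tmp_path, catalog):
        from gliadinscan import example_spec, generate_protein, profile_protein

        rec, _ = generate_protein(example_spec("alpha", seed=3))
        profile = profile_protein(rec, catalog)
        p = tmp_path / "census.tsv"
        seqio.write_census_report([profile], p)
        df = seqio.read_census_report(p)
        assert df.shape[0] == 1
        row = df.iloc[0]
        assert row["family"] == "alpha"
        assert row["cys_count"] == profile.cys_count
        assert bool(row["chain_terminator"]) == profile.chain_terminator
        for name, count in profile.epitope_counts.items():
            assert row[name] == count

    def test_summary_two_decimal_formatting(self, tmp_path):
        summary = CompositionSummary(
            rows=(("alpha", 2, 60.005), ("gamma", 1, 39.995)),
            total_spots=3,
            total_pct=100.0,
        )
        p = tmp_path / "summary.tsv"
        seqio.write_summary(summary, p)
        text = p.read_text()
        assert "60.00" in text or "60.01" in text
        df = seqio.read_summary(p)
        assert df[df.category == "total"].volume_pct.iloc[0] == pytest.approx(100.0)

    def test_summary_round_trip_at_printed_precision(self, tmp_path):
        summary = CompositionSummary(
            rows=(("alpha", 31, 41.99), ("gamma", 28, 24.84)),
            total_spots=59,
            total_pct=66.83,
        )
        p = tmp_path / "s.tsv"
        seqio.write_summary(summary, p)
        df = seqio.read_summary(p)
        assert list(df.volume_pct) == pytest.approx([41.99, 24.84, 66.83])
        assert list(df.n_spots) == [31, 28, 59]
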