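import numpy as np
import pytest

from gliadinscan import census_quant as cq
from gliadinscan import synthetic_data as sd
from gliadinscan.seqio import SpotRecord, keumkang_spot_listings

from oracles import group_sums


class TestBuildCensus:
    def test_planted_alpha_counts_recovered(self, catalog):
        spec = sd.example_spec("alpha", seed=13)
        spec = sd.SyntheticSpec(
            **{
                **spec.__dict__,
                "planted_epitopes": {"DQ2.5-glia-α1a": 1, "DQ2.5-glia-α2": 3},
            }
        )
        rec, _ = sd.generate_protein(spec, catalog)
        profiles, failures = cq.build_census([rec], catalog)
        assert failures == []
        (p,) = profiles
        assert p.epitope_counts["DQ2.5-glia-α1a"] == 1
        assert p.epitope_counts["DQ2.5-glia-α2"] == 3
        assert p.cys_count == 6 and p.chain_terminator is False

    def test_empty_collection(self, catalog):
        assert cq.build_census([], catalog) == ([], [])

    def test_omega5_wdeia_counts(self, catalog):
        spec = sd.example_spec("omega", "omega_5", seed=13)
        spec = sd.SyntheticSpec(
            **{**spec.__dict__, "planted_epitopes": {"WD-1": 4, "WD-2": 12}}
        )
        rec, _ = sd.generate_protein(spec, catalog)
        (p,), _ = cq.build_census([rec], catalog)
        assert p.epitope_counts["WD-1"] == 4
        assert p.epitope_counts["WD-2"] == 12
        assert (p.family, p.subtype) == ("omega", "omega_5")

    def test_failures_isolated(self, catalog, rng):
        good, _ = sd.generate_protein(sd.example_spec("gamma", seed=1), catalog)
        # an X-rich record passes input validation but cannot be aligned by
        # a panel restricted to another family; build_census must not raise
        profiles, failures = cq.build_census([good], catalog)
        assert len(profiles) == 1 and failures == []

    def test_genome_call_attached(self, catalog):
        panel = sd.make_reference_panel("omega", seed=2)
        rec, _ = sd.generate_protein(sd.example_spec("omega", "omega_5", seed=3), catalog)
        (p,), _ = cq.build_census([rec], catalog, panel=panel)
        assert p.genome_call is not None
        assert p.genome_call.genome == "B"  # SRLL- omega-5 rule


class TestSummarize:
    def test_table_like_six_categories(self):
        volumes = {
            "alpha": 41.99,
            "gamma": 24.84,
            "omega": 0.45,
            "lmw_gs": 11.95,
            "non_gluten": 6.28,
            "unknown": 14.49,
        }
        records = [
            SpotRecord(str(i), vol, category=cat)
            for i, (cat, vol) in enumerate(volumes.items())
        ]
        summary = cq.summarize_spots(records)
        assert summary.total_pct == pytest.approx(100.00, abs=1e-9)
        assert summary.total_spots == 6

    def test_single_spot(self):
        summary = cq.summarize_spots([SpotRecord("1", 100.0, category="alpha")])
        assert summary.rows == (("alpha", 1, 100.0),)
        assert summary.total_pct == 100.0

    def test_duplicate_spot_rejected(self):
        records = [SpotRecord("1", 1.0), SpotRecord("1", 2.0)]
        with pytest.raises(ValueError, match="duplicate"):
            cq.summarize_spots(records)

    def test_matches_group_sum_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 60))
            records, _ = sd.generate_spot_table(
                n, {"alpha": 3, "gamma": 2, "unknown": 1}, seed=int(rng.integers(1e6))
            )
            summary = cq.summarize_spots(records)
            oracle = group_sums(records)
            for category, n_spots, vol in summary.rows:
                o_n, o_v = oracle[category]
                assert n_spots == o_n
                assert vol == pytest.approx(o_v, abs=1e-9)
            assert summary.total_pct == pytest.approx(
                sum(r.volume_norm for r in records), abs=1e-9
            )


class TestPredominantSpots:
    def test_empty_table(self):
        assert cq.count_predominant_spots([], "alpha") == 0

    def test_all_minor_counts_zero(self):
        records = [SpotRecord("1", 0.0, category="alpha", minor_flag=True)]
        assert cq.count_predominant_spots(records, "alpha") == 0

    def test_minor_listing_does_not_shadow_predominant(self):
        records = [
            SpotRecord("43", 1.0, "BU-alpha3", "alpha", False),
            SpotRecord("43", 0.0, "ACI04085", "gamma", True),
        ]
        assert cq.count_predominant_spots(records, "alpha") == 1
        assert cq.count_predominant_spots(records, "gamma") == 0

    def test_conflicting_predominant_listings_rejected(self):
        records = [
            SpotRecord("1", 1.0, category="alpha"),
            SpotRecord("1", 1.0, category="gamma"),
        ]
        with pytest.raises(ValueError, match="conflicting"):
            cq.count_predominant_spots(records, "alpha")

    def test_sum_over_categories_counts_every_spot_once(self):
        listings = keumkang_spot_listings()
        total = sum(
            cq.count_predominant_spots(listings, cat)
            for cat in ("alpha", "gamma", "omega", "lmw_gs", "non_gluten", "unknown")
        )
        assert total == len({r.spot_id for r in listings}) == 98


class TestResolveListings:
    def test_published_listings_resolve_to_table_totals(self):
        summary = cq.summarize_spots(cq.resolve_listings(keumkang_spot_listings()))
        assert summary.total_spots == 98
        assert round(summary.volume_of("alpha"), 2) == 41.99
        assert round(summary.volume_of("gamma"), 2) == 24.84
        assert round(summary.volume_of("omega"), 2) == 0.45
        assert round(summary.total_pct, 2) == 100.00
        assert summary.spots_of("alpha") == 31
        assert summary.spots_of("gamma") == 28

    def test_spot_without_predominant_listing_rejected(self):
        with pytest.raises(ValueError, match="no predominant"):
            cq.resolve_listings([SpotRecord("1", 0.0, category="alpha", minor_flag=True)])


class TestGenomeShare:
    def _census_with_genomes(self, catalog, genomes):
        from dataclasses import replace
        from gliadinscan.census_quant import profile_protein
        from gliadinscan.genome_assigner import GenomeCall

        census = []
        for i, genome in enumerate(genomes):
            rec, _ = sd.generate_protein(sd.example_spec("alpha", seed=50 + i), catalog)
            prof = profile_protein(replace(rec, id=f"P{i}"), catalog)
            call = (
                None
                if genome is None
                else GenomeCall(f"P{i}", genome, "motif", evidence="planted")
            )
            census.append(replace(prof, protein_id=f"P{i}", genome_call=call))
        return census

    def test_planted_shares_recovered(self, catalog):
        census = self._census_with_genomes(catalog, ["A", "B", "D"])
        spots = [
            SpotRecord("1", 40.0, "P0", "alpha"),
            SpotRecord("2", 30.0, "P1", "alpha"),
            SpotRecord("3", 30.0, "P2", "alpha"),
        ]
        assert cq.genome_share(spots, census, "alpha") == {
            "A": 40.0,
            "B": 30.0,
            "D": 30.0,
        }

    def test_single_genome_gets_all_volume(self, catalog):
        census = self._census_with_genomes(catalog, ["D", "D"])
        spots = [
            SpotRecord("1", 60.0, "P0", "alpha"),
            SpotRecord("2", 40.0, "P1", "alpha"),
        ]
        assert cq.genome_share(spots, census, "alpha") == {"D": 100.0}

    def test_unknown_genome_bucket(self, catalog):
        census = self._census_with_genomes(catalog, ["A", None])
        spots = [
            SpotRecord("1", 70.0, "P0", "alpha"),
            SpotRecord("2", 30.0, "P1", "alpha"),
        ]
        shares = cq.genome_share(spots, census, "alpha")
        assert shares["unknown"] == 30.0
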