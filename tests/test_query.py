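"""Streaming annotators: lookup, overlap, same-variant, composition."""

import json
import random

import pytest

from tjkit import (
    TjsonError,
    annotate_pipeline,
    build_catalog,
    compress_and_index,
    lookup,
    overlap,
    same_variant,
    sort_catalog,
)
from tjkit.formats import drill_columns
from tjkit.tjson import extract_golden


def _variant_json(landmark, pos, ref, alts, end=None):
    obj = {
        "_landmark": landmark,
        "_minBP": pos,
        "_maxBP": end if end is not None else pos + len(ref) - 1,
        "_refAllele": ref,
        "_altAlleles": list(alts),
    }
    return json.dumps(obj, separators=(",", ":"))


class TestLookup:
    def test_hit_appends_payload(self, small_catalog):
        [out] = lookup(["rs7"], small_catalog, "_id")
        cols = out.split("\t")
        assert cols[0] == "rs7"
        assert json.loads(cols[1])["_id"] == "rs7"

    def test_miss_appends_empty_object(self, small_catalog):
        assert list(lookup(["rsNOPE"], small_catalog, "_id")) == ["rsNOPE\t{}"]

    def test_fan_out_in_catalog_order(self, small_catalog):
        out = list(lookup(["rs2"], small_catalog, "_id"))
        assert len(out) == 2
        alts = [json.loads(l.split("\t")[1])["_altAlleles"] for l in out]
        assert alts == [["A"], ["C"]]  # catalog (file) order

    def test_key_drilled_from_json_input_column(self, small_catalog):
        line = "x\t" + json.dumps({"_id": "rs7"})
        [out] = lookup([line], small_catalog, "_id")
        assert json.loads(out.split("\t")[-1])["_refAllele"] == "A"

    def test_headers_pass_through_first(self, small_catalog):
        out = list(lookup(["#h1", "rs7", "#h2"], small_catalog, "_id"))
        assert out[0] == "#h1" and "#h2" in out

    def test_no_line_is_dropped(self, fixture_set):
        rsids = fixture_set.rsids + ["rsNOPE"] * 3
        out = [l for l in lookup(rsids, fixture_set.dbsnp, "ID")]
        assert len(out) >= len(rsids)
        assert {l.split("\t")[0] for l in out} == set(rsids)


class TestOverlap:
    @pytest.fixture
    def gene_catalog(self, tmp_path, example_json):
        obj = json.loads(example_json)
        obj["_landmark"] = "chr1"
        line = "chr1\t10954\t11507\t" + json.dumps(obj, separators=(",", ":"))
        return compress_and_index([line], tmp_path / "gene")

    def _probe(self, lo, hi):
        return "probe\t" + json.dumps(
            {"_landmark": "chr1", "_minBP": lo, "_maxBP": hi}
        )

    def test_single_base_hit_on_interval_start(self, gene_catalog):
        [out] = overlap([self._probe(10954, 10954)], gene_catalog)
        assert json.loads(out.split("\t")[-1])["GeneID"] == "100506145"

    def test_adjacent_interval_does_not_overlap(self, gene_catalog):
        assert list(overlap([self._probe(11508, 11600)], gene_catalog)) == [
            self._probe(11508, 11600) + "\t{}"
        ]

    def test_containment_and_spanning_hit(self, gene_catalog):
        for lo, hi in [(11000, 11001), (10000, 12000), (11507, 11507)]:
            [out] = overlap([self._probe(lo, hi)], gene_catalog)
            assert out.endswith("}") and "{}" not in out.split("\t")[-1]

    def test_missing_coordinates_is_an_error(self, gene_catalog):
        with pytest.raises(TjsonError, match="no coordinates on line 1"):
            list(overlap(['x\t{"_id":"rs1"}'], gene_catalog))

    def test_upstream_miss_propagates(self, gene_catalog):
        assert list(overlap(["x\t{}"], gene_catalog)) == ["x\t{}\t{}"]

    def test_random_intervals_match_brute_force(self, tmp_path):
        rng = random.Random(13)
        lines = []
        for i in range(200):
            lo = rng.randint(1, 5000)
            hi = lo + rng.randint(0, 100)
            lines.append(
                f"chr1\t{lo}\t{hi}\t"
                + json.dumps({"_landmark": "chr1", "_minBP": lo, "_maxBP": hi, "_id": f"e{i}"})
            )
        catalog = compress_and_index(sort_catalog(lines), tmp_path / "iv")
        entries = list(catalog.iter_entries())
        for _ in range(500):
            qlo = rng.randint(1, 5200)
            qhi = qlo + rng.randint(0, 150)
            out = list(overlap([self._probe(qlo, qhi)], catalog))
            oracle = [
                e.json_text for e in entries if max(e.min_bp, qlo) <= min(e.max_bp, qhi)
            ]
            got = [l.split("\t")[-1] for l in out]
            assert got == (oracle or ["{}"])


class TestSameVariant:
    @pytest.fixture
    def kg_catalog(self, tmp_path):
        line = "chr1\t100\t100\t" + _variant_json("chr1", 100, "A", ["T", "C"])
        return compress_and_index([line], tmp_path / "kg")

    @pytest.mark.parametrize(
        "ref,alts,matches",
        [
            ("A", ["T"], True),  # shared alt
            ("A", ["C", "G"], True),  # intersection non-empty
            ("A", ["G"], False),  # disjoint alt sets
            ("G", ["T"], False),  # ref mismatch
            ("a", ["t"], True),  # case-insensitive alleles
        ],
    )
    def test_matching_rule(self, kg_catalog, ref, alts, matches):
        line = "v\t" + _variant_json("chr1", 100, ref, alts)
        [out] = same_variant([line], kg_catalog)
        assert (out.split("\t")[-1] != "{}") is matches

    def test_position_must_be_exactly_equal(self, tmp_path):
        # an entry spanning 100-102 overlaps position 101 but is not the same variant
        line = "chr1\t100\t102\t" + _variant_json("chr1", 100, "ATT", ["A"], end=102)
        catalog = compress_and_index([line], tmp_path / "span")
        probe = "v\t" + _variant_json("chr1", 101, "ATT", ["A"])
        [out] = same_variant([probe], catalog)
        assert out.endswith("\t{}")
        hit = list(overlap([probe], catalog))[0]
        assert not hit.endswith("\t{}")  # overlap does see it

    def test_incomplete_variant_is_an_error(self, kg_catalog):
        with pytest.raises(TjsonError, match="incomplete variant on line 1"):
            list(same_variant(['v\t{"_landmark":"chr1","_minBP":100}'], kg_catalog))

    def test_upstream_miss_propagates(self, kg_catalog):
        assert list(same_variant(["v\t{}"], kg_catalog)) == ["v\t{}\t{}"]

    def test_match_set_is_subset_of_overlap(self, fixture_set):
        probes = []
        for e in list(fixture_set.dbsnp.iter_entries())[:30]:
            probes.append("p\t" + e.json_text)
        for probe in probes:
            sv = {
                l.split("\t")[-1]
                for l in same_variant([probe], fixture_set.kgenomes)
            } - {"{}"}
            ov = {
                l.split("\t")[-1] for l in overlap([probe], fixture_set.kgenomes)
            } - {"{}"}
            assert sv <= ov

    def test_matches_brute_force_on_fixture(self, fixture_set):
        kg_entries = list(fixture_set.kgenomes.iter_entries())
        for e in fixture_set.dbsnp.iter_entries():
            g = extract_golden(e.json_text)
            oracle = [
                k.json_text
                for k in kg_entries
                if (kg := extract_golden(k.json_text)).landmark == g.landmark
                and kg.min_bp == g.min_bp
                and kg.ref_allele == g.ref_allele
                and kg.alt_alleles
                and not set(kg.alt_alleles).isdisjoint(g.alt_alleles or [])
            ]
            out = list(same_variant(["p\t" + e.json_text], fixture_set.kgenomes))
            got = [l.split("\t")[-1] for l in out]
            assert got == (oracle or ["{}"])


class TestPipeline:
    def test_composition_matches_staged_runs(self, fixture_set):
        rsids = fixture_set.rsids
        pipe = annotate_pipeline(
            [
                lambda s: lookup(s, fixture_set.dbsnp, "ID"),
                lambda s: same_variant(s, fixture_set.kgenomes),
                lambda s: drill_columns(s, -1, ["INFO.EUR_AF"], emit_header=False),
            ]
        )
        composed = list(pipe(rsids))
        staged = list(lookup(rsids, fixture_set.dbsnp, "ID"))
        staged = list(same_variant(staged, fixture_set.kgenomes))
        staged = list(drill_columns(staged, -1, ["INFO.EUR_AF"], emit_header=False))
        assert composed == staged

    def test_reproduces_ground_truth_pairs(self, fixture_set):
        pipe = annotate_pipeline(
            [
                lambda s: lookup(s, fixture_set.dbsnp, "ID"),
                lambda s: same_variant(s, fixture_set.kgenomes),
                lambda s: drill_columns(s, -1, ["INFO.EUR_AF"], emit_header=False),
            ]
        )
        out = list(pipe(fixture_set.rsids))
        pairs = [(l.split("\t")[0], l.split("\t")[2]) for l in out]
        assert pairs == fixture_set.truth_pairs()

    def test_empty_stream_preserves_header(self, fixture_set):
        pipe = annotate_pipeline([lambda s: lookup(s, fixture_set.dbsnp, "ID")])
        assert list(pipe(["#only-a-header"])) == ["#only-a-header"]


class TestStreamingLocality:
    def test_output_line_count_accounting(self, fixture_set):
        """Output lines = sum over inputs of max(1, matches): fan-out never
        drops or invents input lines."""
        rsids = fixture_set.rsids + ["rsNOPE", "rsNOPE2"]
        out = [l for l in lookup(rsids, fixture_set.dbsnp, "ID")]
        per_input = {}
        for line in out:
            per_input[line.split("\t")[0]] = per_input.get(line.split("\t")[0], 0) + 1
        assert set(per_input) == set(rsids)
        assert len(out) == sum(max(1, n) for n in per_input.values())
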