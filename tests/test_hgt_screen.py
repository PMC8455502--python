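import numpy as np
import pytest

from hgtsignal.hgt_screen import (
    BlastHit,
    CASCADE_STAGES,
    Gene,
    ScaffoldRecord,
    ScreenError,
    ScreenParams,
    SyntenyRecord,
    annotate_ledger,
    classify_duplicate_or_misassembly,
    dedupe_redundant,
    filter_hits,
    grubbs_outliers,
    grubbs_outliers_iterative,
    microsynteny,
    read_blast_tab,
    read_depth_tsv,
    read_gff_scaffolds,
    shine_dalgarno_scan,
    write_blast_tab,
    write_depth_tsv,
    write_gff_scaffolds,
)
from hgtsignal.synthetic_data import (
    ORF_START_IN_WINDOW,
    SimulationConfig,
    generate_screen_fixture,
)


def make_hit(hit_id="h1", scaffold="s1", start=100, end=400, evalue=1e-10,
             aa=100, bits=200.0, query="cdtB", strain="APSE-1"):
    return BlastHit(
        hit_id=hit_id, query_id=query, donor_strain=strain,
        subject_scaffold=scaffold, subject_start=start, subject_end=end,
        frame=1, evalue=evalue, hsp_len_aa=aa, pct_identity=55.0,
        bitscore=bits,
    )


@pytest.fixture
def fixture42():
    return generate_screen_fixture(SimulationConfig(seed=42))


class TestCascade:
    def test_empty_input(self):
        retained, ledger = filter_hits([], {}, {}, {})
        assert retained == [] and len(ledger) == 0

    def test_cascade_stops_at_first_failure(self):
        scaffolds = {"s1": ScaffoldRecord("s1", 50_000)}
        hit = make_hit(evalue=0.5)
        retained, ledger = filter_hits([hit], scaffolds, {"cdtB": 300}, {})
        assert retained == []
        row = ledger.iloc[0]
        assert row["verdict"] == "removed:evalue"
        # no later stage evaluated
        assert all(row[s] == "NA" for s in CASCADE_STAGES[1:])

    def test_unknown_scaffold_is_an_error(self):
        with pytest.raises(ScreenError):
            filter_hits([make_hit(scaffold="nope")], {}, {}, {})

    def test_missing_canonical_length_warns_and_retains(self):
        scaffolds = {"s1": ScaffoldRecord(
            "s1", 50_000,
            genes=[Gene("e1", 10, 500, is_bona_fide_eukaryotic=True)],
        )}
        retained, ledger = filter_hits([make_hit()], scaffolds, {}, {})
        assert len(retained) == 1
        row = ledger.iloc[0]
        assert row["canonical-fraction"] == "NA"
        assert row["warning"]
        assert row["verdict"] == "retained"

    def test_fixture_recovery_is_exact(self, fixture42):
        hits, scaffolds, _seqs, _depths, tophits, canonical, truth = fixture42
        retained, ledger = filter_hits(hits, scaffolds, canonical, tophits)
        assert sorted(h.hit_id for h in retained) == sorted(truth.planted_htg_ids)
        verdicts = dict(zip(ledger.candidate_id, ledger.verdict))
        assert verdicts == truth.expected_verdicts

    def test_ledger_covers_every_hit_once(self, fixture42):
        hits, scaffolds, _s, _d, tophits, canonical, _t = fixture42
        _, ledger = filter_hits(hits, scaffolds, canonical, tophits)
        assert sorted(ledger.candidate_id) == sorted(h.hit_id for h in hits)
        removed = ledger[ledger.verdict != "retained"]
        for _, row in removed.iterrows():
            stage = row["verdict"].split(":", 1)[1]
            assert row[stage] == "fail"
            fails = [s for s in CASCADE_STAGES if row[s] == "fail"]
            assert fails == [stage]

    @pytest.mark.parametrize(
        "relax",
        [
            {"evalue_max": 1.0},
            {"min_hsp_aa": 1},
            {"min_scaffold_bp": 1},
            {"min_fraction_of_canonical": 0.001},
            {"min_scaffold_no_euk_bp": 1},
            {"insect_tophit_count": 99},
        ],
    )
    def test_cascade_monotone_in_each_threshold(self, relax):
        for seed in range(5):
            hits, scaffolds, _s, _d, tophits, canonical, _t = (
                generate_screen_fixture(SimulationConfig(seed=seed))
            )
            base, _ = filter_hits(hits, scaffolds, canonical, tophits)
            loose, _ = filter_hits(
                hits, scaffolds, canonical, tophits, ScreenParams(**relax)
            )
            assert {h.hit_id for h in base} <= {h.hit_id for h in loose}

    def test_annotations_added(self, fixture42):
        hits, scaffolds, seqs, _d, tophits, canonical, truth = fixture42
        _, ledger = filter_hits(hits, scaffolds, canonical, tophits)
        sd = {
            hid: shine_dalgarno_scan(s, ORF_START_IN_WINDOW)["found"]
            for hid, s in seqs.items()
        }
        out = annotate_ledger(ledger, scaffolds, ["cont_scaffold_1"], sd)
        row = out[out.candidate_id == truth.planted_htg_ids[0]].iloc[0]
        assert row["shine-dalgarno"] == "no"
        assert row["depth-outlier"] == "no"
        assert row["introns"] != ""


class TestDedupe:
    def test_same_coordinates_keep_lowest_evalue(self):
        a = make_hit("a", evalue=1e-20, strain="APSE-1")
        b = make_hit("b", evalue=1e-10, strain="APSE-2")
        kept, rep = dedupe_redundant([a, b])
        assert [h.hit_id for h in kept] == ["a"]
        assert rep == {"a": "a", "b": "a"}

    def test_disjoint_hits_both_kept(self):
        a = make_hit("a", start=100, end=400)
        b = make_hit("b", start=1000, end=1300)
        kept, _ = dedupe_redundant([a, b])
        assert len(kept) == 2

    def test_single_linkage_chains_groups(self):
        # overlaps: a-b 60%, b-c 60%, a-c 10% -> one group of three
        a = make_hit("a", start=1, end=100, evalue=1e-30)
        b = make_hit("b", start=41, end=140, evalue=1e-20)
        c = make_hit("c", start=81, end=180, evalue=1e-10)
        kept, rep = dedupe_redundant([a, b, c])
        assert [h.hit_id for h in kept] == ["a"]
        assert set(rep.values()) == {"a"}

    def test_different_scaffolds_never_grouped(self):
        a = make_hit("a", scaffold="s1")
        b = make_hit("b", scaffold="s2")
        assert len(dedupe_redundant([a, b])[0]) == 2


class TestClassifyRedundant:
    def test_high_nt_identity_is_misassembly(self):
        assert classify_duplicate_or_misassembly(0.95) == "misassembly"

    def test_multiple_high_aa_ranges_is_duplication(self):
        out = classify_duplicate_or_misassembly(
            0.50, [((1, 100), 0.93), ((200, 300), 0.95)]
        )
        assert out == "duplication"

    def test_single_range_is_independent(self):
        out = classify_duplicate_or_misassembly(0.50, [((1, 100), 0.93)])
        assert out == "independent"

    def test_no_evidence_is_an_error(self):
        with pytest.raises(ScreenError):
            classify_duplicate_or_misassembly(None, None)


class TestGrubbs:
    def test_known_outlier_example(self):
        res = grubbs_outliers([10, 11, 12, 13, 100])
        assert res["G"] == pytest.approx(1.7880, abs=1e-3)
        assert res["critical"] == pytest.approx(1.715, abs=5e-3)
        assert res["outlier_indices"] == [4]

    def test_tight_sample_has_no_outlier(self):
        res = grubbs_outliers([10, 10.1, 9.9, 10.05])
        assert res["outlier_indices"] == []
        assert res["G"] < res["critical"]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ScreenError):
            grubbs_outliers([5.0, 5.0, 5.0])
        with pytest.raises(ScreenError):
            grubbs_outliers([1.0, 2.0])

    def test_gross_outlier_always_flagged(self, rng):
        for n in (5, 10, 30, 100):
            base = rng.normal(50, 5, size=n).tolist()
            spike = float(np.mean(base) + 10 * np.std(base, ddof=1))
            res = grubbs_outliers(base + [spike])
            assert res["outlier_indices"] == [n]

    def test_iterative_flags_all_inflated_scaffolds(self):
        hits, scaffolds, _s, depths, _t, _c, truth = generate_screen_fixture(
            SimulationConfig(seed=7, n_contaminants=2)
        )
        ids = list(depths)
        flagged = {ids[i] for i in grubbs_outliers_iterative(
            [depths[i] for i in ids]
        )}
        cont_scaffolds = {
            h.subject_scaffold
            for h in hits
            if h.hit_id in truth.planted_contaminant_ids
            and h.subject_scaffold.startswith("cont_")
        }
        assert cont_scaffolds <= flagged


class TestShineDalgarno:
    def test_exact_motif_in_window(self):
        seq = "A" * 40 + "AGGAGG" + "ACGTAC" + "ATGAAA"
        res = shine_dalgarno_scan(seq, 53)
        assert res["found"] and res["motif"] == "AGGAGG"

    def test_motif_far_upstream_not_found(self):
        seq = "AGGAGG" + "C" * 50 + "ATG"
        assert not shine_dalgarno_scan(seq, 57)["found"]

    def test_one_mismatch_found(self):
        seq = "C" * 38 + "AGGCGG" + "CT" * 4 + "ATGAAA"
        res = shine_dalgarno_scan(seq, 53)
        assert res["found"] and res["motif"] == "AGGCGG"

    def test_two_mismatches_not_found(self):
        seq = "C" * 38 + "ATTAGG" + "CT" * 4 + "ATGAAA"
        assert not shine_dalgarno_scan(seq, 53)["found"]

    def test_window_truncated_at_sequence_start(self):
        assert not shine_dalgarno_scan("CCATGAAA", 3)["found"]

    def test_bad_characters_rejected(self):
        with pytest.raises(ScreenError):
            shine_dalgarno_scan("ACGU" * 10, 20)


class TestMicrosynteny:
    RECORD = SyntenyRecord(
        htg_id="cdtB",
        neighbors=[(-1, "gA"), (1, "gB"), (2, "gC")],
        placements={
            "spB": {"gA": "scaf7", "gB": None, "gC": "scaf9"},
            "spC": {"gA": "scaf1", "gB": "scaf1", "gC": None},
        },
        htg_placement={"spB": "scaf7", "spC": "scaf2"},
    )

    def test_neighbor_on_same_scaffold_is_evidence(self):
        out = microsynteny(self.RECORD, "spB")
        assert out == {"evidence": True, "shared_neighbors": [-1]}

    def test_neighbors_elsewhere_is_no_evidence(self):
        assert not microsynteny(self.RECORD, "spC")["evidence"]

    def test_all_na_is_no_evidence(self):
        rec = SyntenyRecord(
            htg_id="x", neighbors=[(-1, "g")],
            placements={"spB": {"g": None}}, htg_placement={"spB": None},
        )
        assert not microsynteny(rec, "spB")["evidence"]

    def test_invalid_offsets_rejected(self):
        with pytest.raises(ScreenError):
            SyntenyRecord("x", [(0, "g")], {}, {})
        with pytest.raises(ScreenError):
            SyntenyRecord("x", [(1, "g"), (1, "h")], {}, {})


class TestTabularIO:
    def test_blast_round_trip(self, tmp_path, fixture42):
        hits = fixture42[0]
        path = tmp_path / "hits.tsv"
        write_blast_tab(hits, path)
        back = read_blast_tab(path)
        assert [h.hit_id for h in back] == [h.hit_id for h in hits]
        assert [h.subject_start for h in back] == [h.subject_start for h in hits]
        assert [h.query_id for h in back] == [h.query_id for h in hits]

    def test_gff_round_trip(self, tmp_path, fixture42):
        scaffolds = fixture42[1]
        path = tmp_path / "ann.gff"
        write_gff_scaffolds(scaffolds, path)
        back = read_gff_scaffolds(path)
        assert set(back) == set(scaffolds)
        sid = next(iter(scaffolds))
        assert back[sid].length_bp == scaffolds[sid].length_bp
        assert [g.gene_id for g in back[sid].genes] == [
            g.gene_id for g in scaffolds[sid].genes
        ]
        assert [g.is_bona_fide_eukaryotic for g in back[sid].genes] == [
            g.is_bona_fide_eukaryotic for g in scaffolds[sid].genes
        ]

    def test_depth_round_trip(self, tmp_path, fixture42):
        depths = fixture42[3]
        path = tmp_path / "depths.tsv"
        write_depth_tsv(depths, path)
        back = read_depth_tsv(path)
        assert set(back) == set(depths)
        for k in depths:
            assert back[k] == pytest.approx(depths[k], abs=1e-3)

    def test_gene_outside_scaffold_rejected(self):
        with pytest.raises(ScreenError):
            ScaffoldRecord("s", 100, genes=[Gene("g", 50, 200)])
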