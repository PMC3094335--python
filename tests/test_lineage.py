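"""Lineage conversion: resolution, replay, reports, release detection."""

import pytest

from wormtx import lineage, simulate
from wormtx.lineage import (
    BackwardConversionError,
    GeneRecord,
    LineageError,
    LineageEvent,
    NoDetectionError,
    ParseError,
    ReleaseHistory,
    ReleaseTag,
    UnsupportedFormatError,
    convert_list,
    convert_list_naive,
    detect_release,
    load_history,
    resolve_identifiers,
    write_history,
)


def full_span(history):
    return history.release_names[0], history.release_names[-1]


class TestEventValidation:
    def test_merge_with_single_source_rejected(self):
        with pytest.raises(LineageError, match="cardinality"):
            LineageEvent("WS150", "merge", ("WBGene1",), ("WBGene1",))

    def test_unknown_event_type_rejected(self):
        with pytest.raises(LineageError, match="unknown event_type"):
            LineageEvent("WS150", "fuse", ("a", "b"), ("a",))

    @pytest.mark.parametrize(
        "etype,sources,targets",
        [
            ("merge", ("a", "b"), ("a",)),
            ("split", ("a",), ("a", "b")),
            ("kill", ("a",), ()),
            ("create", (), ("a",)),
            ("rename", ("a",), ("a",)),
            ("resurrect", (), ("a",)),
        ],
    )
    def test_valid_cardinalities_accepted(self, etype, sources, targets):
        ev = LineageEvent("WS150", etype, sources, targets)
        assert ev.event_type == etype


class TestDocumentedMerges:
    """The two curated merge events recorded in the packaged history."""

    def test_r07e5_merge_ws150_to_ws210(self, mini_history):
        out, rep = convert_list(
            ["R07E5.12"], "WS150", "WS210", mini_history, "sequence_name"
        )
        assert out == ["R07E5.10"]
        assert list(rep.merged.values()) == ["WBGene90000010"]
        assert rep.killed == [] and rep.unresolved == []

    def test_c03b8_merge_ws216_to_ws220(self, mini_history):
        out, rep = convert_list(
            ["C03B8.1"], "WS216", "WS220", mini_history, "sequence_name"
        )
        assert out == ["C03B8.3"]
        assert len(rep.merged) == 1

    def test_merge_effective_release_boundary(self, mini_history):
        # before the merge becomes effective the gene is untouched
        out, rep = convert_list(["C03B8.1"], "WS210", "WS216", mini_history,
                                "sequence_name")
        assert out == ["C03B8.1"]
        assert rep.passthrough == ["C03B8.1"]


class TestResolution:
    def test_mixed_identifier_kinds_match_table_lookup(self, mini_history):
        table = mini_history.table("WS150")
        mixed = ["WBGene90000001", "R07E5.12", "nlp-29", "C03B8.1a"]
        pairs = resolve_identifiers(mixed, "WS150", mini_history)
        expected = {}
        for rec in table.values():
            expected[rec.wbid] = rec.wbid
            expected[rec.sequence_name] = rec.wbid
            if rec.public_name:
                expected[rec.public_name] = rec.wbid
            for t in rec.transcript_names:
                expected[t] = rec.wbid
        for ident, wbid in pairs:
            assert wbid == expected[ident]

    def test_unknown_identifier_reported_not_dropped(self, mini_history):
        pairs = resolve_identifiers(["no-such-gene-1"], "WS150", mini_history)
        assert pairs == [("no-such-gene-1", None)]

    def test_case_insensitive_fallback(self, mini_history):
        pairs = resolve_identifiers(["r07e5.12"], "WS150", mini_history)
        assert pairs[0][1] == "WBGene90000012"

    def test_empty_input_rejected(self, mini_history):
        with pytest.raises(LineageError):
            resolve_identifiers([], "WS150", mini_history)


class TestConvertContract:
    def test_identity_conversion(self, mini_history):
        ids = ["WBGene90000012", "WBGene90000001"]
        out, rep = convert_list(ids, "WS150", "WS150", mini_history)
        assert out == ids
        assert rep.merged == {} and rep.killed == [] and rep.split_added == []
        assert rep.passthrough == ids

    def test_backward_conversion_rejected(self, mini_history):
        with pytest.raises(BackwardConversionError):
            convert_list(["R07E5.12"], "WS210", "WS150", mini_history)

    def test_transcript_output_rejected(self, mini_history):
        with pytest.raises(UnsupportedFormatError):
            convert_list(["R07E5.12"], "WS150", "WS210", mini_history, "transcript")

    def test_unknown_release_rejected(self, mini_history):
        with pytest.raises(LineageError):
            convert_list(["R07E5.12"], "WS150", "WS999", mini_history)

    def test_killed_gene_omitted_and_reported(self):
        hist, truth = simulate.simulate_history(
            simulate.HistorySimConfig(n_genes=30, n_releases=4, kill_rate=4, seed=3)
        )
        a, b = full_span(hist)
        dead = sorted(g for g, fate in truth.items() if fate[0] == "dead")
        assert dead, "fixture must contain killed genes"
        out, rep = convert_list(dead, a, b, hist)
        assert out == []
        assert {rep.resolved[i] for i, _ in rep.killed} == set(dead)
        # oracle agrees
        out2, rep2 = convert_list_naive(dead, a, b, hist)
        assert out2 == out and rep2.to_dict() == rep.to_dict()


class TestReplayProperties:
    def test_oracle_equivalence_and_truth(self, random_histories):
        for hist, truth in random_histories:
            a, b = full_span(hist)
            ids = sorted(truth)
            out_f, rep_f = convert_list(ids, a, b, hist)
            out_n, rep_n = convert_list_naive(ids, a, b, hist)
            assert out_f == out_n
            assert rep_f.to_dict() == rep_n.to_dict()
            survivors = {f[1] for f in truth.values() if f[0] == "live"}
            assert set(out_f) - set(rep_f.split_added) == survivors

    def test_partition_accounting(self, random_histories):
        for hist, truth in random_histories:
            a, b = full_span(hist)
            ids = sorted(truth)
            _, rep = convert_list(ids, a, b, hist)
            n = (
                len(rep.unresolved)
                + len(rep.killed)
                + len(rep.merged)
                + len(rep.split_sources)
                + len(rep.passthrough)
            )
            assert n == len(ids)

    def test_outputs_live_in_target_release(self, random_histories):
        for hist, _ in random_histories:
            a, b = full_span(hist)
            ids = sorted(hist.table(a))
            out, _ = convert_list(ids, a, b, hist)
            table = hist.table(b)
            assert all(table[w].status == "live" for w in out)

    def test_composition_matches_direct_conversion(self, random_histories):
        for hist, _ in random_histories[:15]:
            names = hist.release_names
            a, mid, c = names[0], names[len(names) // 2], names[-1]
            ids = sorted(
                w for w, r in hist.table(a).items() if r.status == "live"
            )
            via_mid, rep1 = convert_list(ids, a, mid, hist)
            final_via, rep2 = convert_list(via_mid, mid, c, hist)
            direct, rep3 = convert_list(ids, a, c, hist)
            assert set(final_via) == set(direct)
            # inputs lost over the two steps = inputs lost directly
            id_after_step1 = {}
            for i in rep1.passthrough + rep1.split_sources:
                id_after_step1[i] = rep1.resolved[i]
            for i, w in rep1.resolved.items():
                if w in rep1.merged:
                    id_after_step1[i] = rep1.merged[w]
            killed_step2 = {rep2.resolved[i] for i, _ in rep2.killed}
            lost_two_step = {i for i, _ in rep1.killed} | {
                i for i, w in id_after_step1.items() if w in killed_step2
            }
            assert {i for i, _ in rep3.killed} == lost_two_step

    def test_monotone_loss(self, random_histories):
        for hist, _ in random_histories[:15]:
            names = hist.release_names
            a, mid, c = names[0], names[len(names) // 2], names[-1]
            ids = sorted(
                w for w, r in hist.table(a).items() if r.status == "live"
            )
            _, rep_ab = convert_list(ids, a, mid, hist)
            _, rep_ac = convert_list(ids, a, c, hist)
            killed_ab = {i for i, _ in rep_ab.killed}
            killed_ac = {i for i, _ in rep_ac.killed}
            # a gene dead by mid stays dead unless resurrected (no resurrects
            # in these fixtures)
            assert killed_ab <= killed_ac


class TestDetectRelease:
    def test_detects_release_of_obsolete_name(self, mini_history):
        # R07E5.12 is live only in WS150; nlp-29 everywhere
        tag, scores = detect_release(["R07E5.12", "nlp-29"], mini_history)
        assert tag.name == "WS150"
        assert scores["WS150"] == 1.0
        assert all(s < 1.0 for name, s in scores.items() if name != "WS150")

    def test_tie_broken_toward_most_recent(self, mini_history):
        tag, scores = detect_release(["nlp-29"], mini_history)
        assert tag.name == "WS220"
        assert len({round(s, 9) for s in scores.values()}) == 1

    def test_all_unresolvable_raises(self, mini_history):
        with pytest.raises(NoDetectionError):
            detect_release(["nope-1", "nope-2"], mini_history)

    def test_empty_list_raises(self, mini_history):
        with pytest.raises(LineageError):
            detect_release([], mini_history)


class TestLoadHistory:
    def test_roundtrip_write_load(self, tmp_path):
        hist, _ = simulate.simulate_history(
            simulate.HistorySimConfig(n_genes=20, n_releases=3, seed=7)
        )
        layout = write_history(hist, tmp_path)
        loaded = load_history(
            [(name, layout[name]) for name in hist.release_names],
            layout["events"],
        )
        assert loaded.release_names == hist.release_names
        assert loaded.inconsistencies == []
        a, b = full_span(hist)
        ids = sorted(hist.table(a))
        assert convert_list(ids, a, b, hist)[0] == convert_list(ids, a, b, loaded)[0]

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "corr.tsv"
        p.write_text(
            "wbid\tsequence_name\tpublic_name\ttranscript_names\tstatus\n"
            "WBGene1\tA1.1\t\tA1.1a\tlive\n"
            "WBGene2\tonly-two-fields\n"
        )
        ev = tmp_path / "events.tsv"
        ev.write_text("effective_release\tevent_type\tsource_wbids\ttarget_wbids\tnote\n")
        with pytest.raises(ParseError, match=r":3:"):
            load_history([("WS150", str(p))], str(ev))

    def test_unknown_event_type_in_log(self, tmp_path):
        p = tmp_path / "corr.tsv"
        p.write_text(
            "wbid\tsequence_name\tpublic_name\ttranscript_names\tstatus\n"
            "WBGene1\tA1.1\t\tA1.1a\tlive\n"
        )
        ev = tmp_path / "events.tsv"
        ev.write_text(
            "effective_release\tevent_type\tsource_wbids\ttarget_wbids\tnote\n"
            "WS150\texplode\tWBGene1\t\t\n"
        )
        with pytest.raises(LineageError, match="unknown event_type"):
            load_history([("WS150", str(p))], str(ev))

    def test_parentless_split_repaired_by_patch(self, tmp_path):
        """A split that drops its parent without a formal kill is an
        inconsistency; a patch declaring the implied kill repairs it."""
        header = "wbid\tsequence_name\tpublic_name\ttranscript_names\tstatus\n"
        (tmp_path / "ws150.tsv").write_text(
            header + "WBGene1\tA1.1\t\tA1.1a\tlive\n"
        )
        (tmp_path / "ws160.tsv").write_text(
            header
            + "WBGene1\tA1.1\t\t\tdead\n"
            + "WBGene2\tA1.2\t\tA1.2a\tlive\n"
            + "WBGene3\tA1.3\t\tA1.3a\tlive\n"
        )
        (tmp_path / "events.tsv").write_text(
            "effective_release\tevent_type\tsource_wbids\ttarget_wbids\tnote\n"
            "WS160\tsplit\tWBGene1\tWBGene2,WBGene3\tparent dropped\n"
        )
        (tmp_path / "patch.tsv").write_text(
            "effective_release\tevent_type\tsource_wbids\ttarget_wbids\tnote\n"
            "WS160\tkill\tWBGene1\t\timplied kill of split parent\n"
        )
        paths = [("WS150", str(tmp_path / "ws150.tsv")), ("WS160", str(tmp_path / "ws160.tsv"))]
        without_patch = load_history(paths, str(tmp_path / "events.tsv"))
        assert len(without_patch.inconsistencies) == 1
        patched = load_history(
            paths, str(tmp_path / "events.tsv"), str(tmp_path / "patch.tsv")
        )
        assert patched.inconsistencies == []
        assert len(patched.repaired) == 1
        out, rep = convert_list(["WBGene1"], "WS150", "WS160", patched)
        assert sorted(out) == ["WBGene2", "WBGene3"]
        assert len(rep.killed) == 1


class TestHistoryValidation:
    def test_duplicate_release_names_rejected(self):
        with pytest.raises(LineageError):
            ReleaseHistory(
                releases=[ReleaseTag(0, "WS150"), ReleaseTag(1, "WS150")],
                tables={"WS150": {}},
            )

    def test_event_referencing_unknown_release_rejected(self):
        with pytest.raises(LineageError):
            ReleaseHistory(
                releases=[ReleaseTag(0, "WS150")],
                tables={"WS150": {}},
                events=[LineageEvent("WS160", "kill", ("WBGene1",), ())],
            )
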