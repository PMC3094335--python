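"""Small packaged histories for demonstrations and worked examples."""

from __future__ import annotations

from .lineage import GeneRecord, LineageEvent, ReleaseHistory, ReleaseTag


def example_history() -> ReleaseHistory:
    """A mini release history encoding two documented WormBase merges.

    * R07E5.12 was merged into R07E5.10 in the WS152 release, the
      composite gene keeping the name R07E5.10;
    * C03B8.1 was merged into C03B8.3 effective from WS217.

    The WB IDs used here are synthetic placeholders: only the sequence
    names and the merge structure mirror the real record.  A stable
    bystander gene (nlp-29) is included so release detection has an
    anchor present everywhere.
    """
    releases = [
        ReleaseTag(0, "WS150"),
        ReleaseTag(1, "WS152"),
        ReleaseTag(2, "WS210"),
        ReleaseTag(3, "WS216"),
        ReleaseTag(4, "WS217"),
        ReleaseTag(5, "WS220"),
    ]
    r12 = "WBGene90000012"
    r10 = "WBGene90000010"
    c1 = "WBGene90000031"
    c3 = "WBGene90000033"
    stable = "WBGene90000001"

    def rec(wbid, seq, public="", dead=False):
        return GeneRecord(
            wbid=wbid,
            sequence_name=seq,
            public_name=public,
            transcript_names=() if dead else (seq + "a",),
            status="dead" if dead else "live",
        )

    base = {
        r10: rec(r10, "R07E5.10"),
        r12: rec(r12, "R07E5.12"),
        c1: rec(c1, "C03B8.1"),
        c3: rec(c3, "C03B8.3"),
        stable: rec(stable, "B0213.4", "nlp-29"),
    }
    after_152 = dict(base)
    after_152[r12] = rec(r12, "R07E5.12", dead=True)
    after_217 = dict(after_152)
    after_217[c1] = rec(c1, "C03B8.1", dead=True)

    tables = {
        "WS150": base,
        "WS152": after_152,
        "WS210": after_152,
        "WS216": after_152,
        "WS217": after_217,
        "WS220": after_217,
    }
    events = [
        LineageEvent("WS152", "merge", (r10, r12), (r10,),
                     note="R07E5.12 merged into R07E5.10"),
        LineageEvent("WS217", "merge", (c1, c3), (c3,),
                     note="C03B8.1 merged into C03B8.3"),
    ]
    return ReleaseHistory(releases=releases, tables=tables, events=events)
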