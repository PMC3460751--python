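"""Hamming-ball mapping semantics and the allopolyploid counting rules."""

import numpy as np
import pytest

from polytag import mapping, tags
from polytag.reference import ReferenceSet, RefRecord, revcomp
from polytag.tags import TagLibrary


def _lib(tag_counts, lane_id="E1"):
    lib = TagLibrary(lane_id=lane_id, species_label=lane_id[0], counts=dict(tag_counts))
    lib.total_reads_in = lib.total_tags
    return lib


def _pad(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


TAG1 = "GATC" + "ACGTACGTACGTACGT"
TAG2 = "GATC" + "TTGCATTGCATTGCAT"


def test_exact_hit_and_single_substitution():
    ref = ReferenceSet([RefRecord("s0", "g0", "single", _pad(30, 1) + TAG1 + _pad(30, 2))])
    lib = _lib({TAG1: 5})
    hits = mapping.map_tags(lib, ref, 0)[TAG1]
    assert len(hits) == 1 and hits[0].position == 30 and hits[0].mismatches == 0
    mutated = TAG1[:10] + ("A" if TAG1[10] != "A" else "C") + TAG1[11:]
    assert mapping.map_tags(_lib({mutated: 1}), ref, 0)[mutated] == []
    hit1 = mapping.map_tags(_lib({mutated: 1}), ref, 1)[mutated]
    assert len(hit1) == 1 and hit1[0].mismatches == 1


def test_reverse_strand_hit_reported_at_forward_coordinate():
    seq = _pad(20, 3) + revcomp(TAG1) + _pad(20, 4)
    ref = ReferenceSet([RefRecord("s0", "g0", "single", seq)])
    hits = mapping.map_tags(_lib({TAG1: 1}), ref, 0)[TAG1]
    assert len(hits) == 1 and hits[0].strand == "-" and hits[0].position == 20


@pytest.mark.parametrize("max_mm", [0, 1, 2])
def test_index_equals_bruteforce_oracle(small_sim, max_mm):
    """Hit sets equal an independent quadratic Hamming scan."""
    con, _, _, _ = small_sim
    sub = ReferenceSet(con.records[:20])
    rng = np.random.default_rng(42)
    from polytag.reference import enumerate_candidate_tags

    pool = list(enumerate_candidate_tags(sub))[:30]
    # add perturbed and random tags so mismatched and unmapped cases occur
    for t in pool[:10]:
        i = int(rng.integers(0, 20))
        pool.append(t[:i] + str(rng.choice([c for c in "ACGT" if c != t[i]])) + t[i + 1 :])
    pool += ["".join(rng.choice(list("ACGT"), 20)) for _ in range(10)]
    index = mapping.TagIndex(sub)
    for tag in pool:
        assert index.query(tag, max_mm) == mapping.brute_force_map(tag, sub, max_mm)


def test_mapped_and_ambiguous_monotone_in_mismatch(small_sim, small_lanes):
    con, _, _, _ = small_sim
    lane = small_lanes["E"][0]
    kept, nq, nl = tags.quality_filter(lane.to_seqrecords())
    lib = tags.build_tags(kept, lane_id=lane.lane_id, species_label="E")
    index = mapping.TagIndex(con)
    mapped, ambig = [], []
    for mm in (0, 1, 2):
        lc = mapping.classify_and_count(mapping.map_tags(lib, con, mm, index=index), lib, con)
        mapped.append(lc.report.tags_mapped)
        ambig.append(lc.report.tags_ambiguous)
        assert lc.report.tags_mapped == lc.report.tags_ambiguous + lc.report.tags_unambiguous
    assert mapped == sorted(mapped) and ambig == sorted(ambig)


def test_lane_count_conservation(small_sim, small_lanes):
    """Unambiguous + ambiguous + unmapped occurrences == library total."""
    con, _, _, _ = small_sim
    lane = small_lanes["F"][1]
    kept, *_ = tags.quality_filter(lane.to_seqrecords())
    lib = tags.build_tags(kept, lane_id=lane.lane_id)
    hits = mapping.map_tags(lib, con, 1)
    lc = mapping.classify_and_count(hits, lib, con)
    unmapped = sum(lib.counts[t] for t, h in hits.items() if not h)
    assert sum(lc.locus_counts.values()) + lc.report.tags_ambiguous + unmapped == lib.total_tags
    # locus = shared + sum of copy-specific, for every multi-copy locus
    for locus in con.multicopy_loci():
        if locus in lc.locus_counts:
            spec = sum(c for (l, _), c in lc.copy_specific.items() if l == locus)
            assert lc.locus_counts[locus] == lc.shared.get(locus, 0) + spec


def test_ambiguous_tag_between_two_loci_discarded():
    seq_a = _pad(10, 5) + TAG1 + _pad(10, 6)
    seq_b = _pad(12, 7) + TAG1 + _pad(8, 8)
    ref = ReferenceSet(
        [RefRecord("a", "gA", "single", seq_a), RefRecord("b", "gB", "single", seq_b)]
    )
    lib = _lib({TAG1: 7})
    lc = mapping.classify_and_count(mapping.map_tags(lib, ref, 0), lib, ref)
    assert lc.locus_counts == {}
    assert lc.report.tags_ambiguous == 7
    assert lc.report.classification[TAG1] == "ambiguous_discarded"


def test_tag_hitting_both_homeolog_copies_counted_once():
    ref = ReferenceSet(
        [
            RefRecord("a", "L1", "A", _pad(10, 9) + TAG1 + _pad(10, 10)),
            RefRecord("b", "L1", "B", _pad(14, 11) + TAG1 + _pad(6, 12)),
        ]
    )
    lib = _lib({TAG1: 4})
    lc = mapping.classify_and_count(mapping.map_tags(lib, ref, 0), lib, ref)
    assert lc.locus_counts == {"L1": 4}
    assert lc.shared == {"L1": 4} and lc.copy_specific == {}


def test_copy_specific_tag_recorded_for_its_copy():
    ref = ReferenceSet(
        [
            RefRecord("a", "L1", "A", _pad(10, 13) + TAG1 + _pad(10, 14)),
            RefRecord("b", "L1", "B", _pad(10, 15) + TAG2 + _pad(10, 16)),
        ]
    )
    lib = _lib({TAG1: 3, TAG2: 2})
    lc = mapping.classify_and_count(mapping.map_tags(lib, ref, 0), lib, ref)
    assert lc.locus_counts == {"L1": 5}
    assert lc.copy_specific == {("L1", "A"): 3, ("L1", "B"): 2}


def test_multiple_positions_within_one_gene_summed():
    seq = _pad(5, 17) + TAG1 + _pad(5, 18) + TAG2 + _pad(5, 19)
    ref = ReferenceSet([RefRecord("a", "g", "single", seq)])
    lib = _lib({TAG1: 5, TAG2: 3})
    lc = mapping.classify_and_count(mapping.map_tags(lib, ref, 0), lib, ref)
    assert lc.locus_counts == {"g": 8}


def test_tag_hitting_two_positions_of_one_gene_counted_once():
    seq = _pad(5, 20) + TAG1 + _pad(5, 21) + TAG1 + _pad(5, 22)
    ref = ReferenceSet([RefRecord("a", "g", "single", seq)])
    lib = _lib({TAG1: 6})
    hits = mapping.map_tags(lib, ref, 0)
    assert len(hits[TAG1]) == 2
    lc = mapping.classify_and_count(hits, lib, ref)
    # oracle: counting is per (tag, locus-set cardinality), not per hit
    assert lc.locus_counts == {"g": 6}


def test_forward_reverse_hits_merge_at_one_position():
    # palindromic-context window: tag and its revcomp both match at pos 10
    body = "ACGTACGTACGTACGT"
    window = "GATC" + body
    seq = _pad(10, 23) + window + _pad(10, 24)
    ref = ReferenceSet([RefRecord("a", "g", "single", seq)])
    lib = _lib({window: 2, revcomp(window): 3})
    hits = mapping.map_tags(lib, ref, 0)
    table = mapping.position_table(hits, lib)
    row = table[(table.sequence_id == "a") & (table.position == 10)]
    assert int(row["count"].iloc[0]) == 5  # both orientations combined


def test_contig_aggregation_rules():
    gene_seq = _pad(10, 25) + TAG1 + _pad(30, 26) + TAG2 + _pad(10, 27)
    # two overlapping contigs of one gene; TAG1 is in the overlap
    c1 = gene_seq[: 10 + 20 + 15]
    c2 = gene_seq[5:]
    other = _pad(10, 28) + "GATC" + "GGGGGGGGCCCCCCCC" + _pad(10, 29)
    ref = ReferenceSet(
        [
            RefRecord("c1", "c1", "single", c1),
            RefRecord("c2", "c2", "single", c2),
            RefRecord("c3", "c3", "single", other),
        ],
        kind="conspecific_contigs",
        contig_to_gene={"c1": "G1", "c2": "G1", "c3": "G2"},
    )
    tag3 = "GATCGGGGGGGGCCCCCCCC"
    lib = _lib({TAG1: 3, TAG2: 4, tag3: 2})
    hits = mapping.map_tags(lib, ref, 0)
    assert len({h.sequence_id for h in hits[TAG1]}) == 2  # hits both contigs
    lc = mapping.aggregate_contigs(hits, lib, ref)
    # overlap tag counted once; distinct tags on one gene summed
    assert lc.locus_counts == {"G1": 7, "G2": 2}


def test_contig_hits_on_two_genes_discarded():
    shared = TAG1
    ref = ReferenceSet(
        [
            RefRecord("c1", "c1", "single", _pad(8, 30) + shared + _pad(8, 31)),
            RefRecord("c2", "c2", "single", _pad(6, 32) + shared + _pad(10, 33)),
        ],
        contig_to_gene={"c1": "G1", "c2": "G2"},
    )
    lib = _lib({shared: 5})
    lc = mapping.aggregate_contigs(mapping.map_tags(lib, ref, 0), lib, ref)
    assert lc.locus_counts == {} and lc.report.tags_ambiguous == 5


def test_mapping_summary_percentages():
    rep = mapping.MappingReport("E1", tags_total=200, tags_mapped=60,
                                tags_ambiguous=4, tags_unambiguous=56)
    df = mapping.mapping_summary([rep])
    assert df.loc[0, "mapped_pct"] == 30.0
    assert df.loc[0, "unambiguous_pct"] == 28.0
    empty = mapping.MappingReport("E2", tags_total=100)
    assert mapping.mapping_summary([empty]).loc[0, "mapped_pct"] == 0.0


def test_heterospecific_reference_loses_information(small_sim, small_lanes):
    """At 0 mismatches, a ~10%-diverged reference maps far fewer tags."""
    con, het, _, _ = small_sim
    lane = small_lanes["F"][0]
    kept, *_ = tags.quality_filter(lane.to_seqrecords())
    lib = tags.build_tags(kept, lane_id=lane.lane_id)
    pct_con = mapping.classify_and_count(
        mapping.map_tags(lib, con, 0), lib, con
    ).report.percentages()["mapped_pct"]
    pct_het = mapping.classify_and_count(
        mapping.map_tags(lib, het, 0), lib, het
    ).report.percentages()["mapped_pct"]
    assert pct_het < 0.5 * pct_con
    assert pct_con > 80  # conspecific mapping is nearly lossless here
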