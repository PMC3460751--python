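"""Mismatch-tolerant tag mapping and allopolyploid-aware counting.

Tags are mapped against full reference sequences with pure Hamming
semantics: every window on either strand within the allowed mismatch
count (0-2) is a hit, no gaps. Counting then applies the locus rules:

* a tag hitting two or more distinct gene loci is ambiguous and discarded;
* a tag hitting both homeologous copies of one locus is counted once for
  the locus (it is "locus-specific" but cannot discriminate copies);
* a tag hitting exactly one copy of a multi-copy locus additionally counts
  as copy-specific for that copy;
* multiple hits within one locus (several positions, both strands) never
  double-count: counting is per (tag, locus), not per hit.

The index uses pigeonhole seeding: a 20-mer is split into three segments,
and any match with <=2 mismatches must match at least one segment exactly.
Candidates from the segment index are verified by direct Hamming distance,
so results are identical to a full quadratic scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .reference import ReferenceSet, revcomp, TAG_LENGTH
from .tags import TagLibrary

_SEGMENTS = ((0, 7), (7, 14), (14, TAG_LENGTH))  # pigeonhole split for <=2 mm


@dataclass(frozen=True)
class Hit:
    tag: str
    sequence_id: str
    position: int  # 0-based forward-strand start of the matched window
    strand: str  # "+" or "-"
    mismatches: int


class TagIndex:
    """Segment-seeded index of all fixed-length windows of a reference."""

    def __init__(self, ref: ReferenceSet, tag_length: int = TAG_LENGTH):
        self.ref = ref
        self.tag_length = tag_length
        self._seqs = [(r.sequence_id, r.seq) for r in ref.records]
        self._exact: dict[str, list[tuple[int, int]]] = {}
        self._seed: list[dict[str, list[tuple[int, int]]]] = [{} for _ in _SEGMENTS]
        for si, (_, seq) in enumerate(self._seqs):
            for pos in range(len(seq) - tag_length + 1):
                window = seq[pos : pos + tag_length]
                self._exact.setdefault(window, []).append((si, pos))
                for k, (a, b) in enumerate(_SEGMENTS):
                    self._seed[k].setdefault(window[a:b], []).append((si, pos))

    def _verify(self, query: str, max_mm: int) -> list[tuple[int, int, int]]:
        """All (seq_index, pos, mismatches) with Hamming(query, window) <= max_mm."""
        if max_mm == 0:
            return [(si, pos, 0) for si, pos in self._exact.get(query, [])]
        cand: set[tuple[int, int]] = set()
        for k, (a, b) in enumerate(_SEGMENTS):
            cand.update(self._seed[k].get(query[a:b], []))
        out = []
        L = self.tag_length
        for si, pos in cand:
            window = self._seqs[si][1][pos : pos + L]
            mm = 0
            for qc, wc in zip(query, window):
                if qc != wc or wc == "N":  # N never matches
                    mm += 1
                    if mm > max_mm:
                        break
            else:
                out.append((si, pos, mm))
        return out

    def query(self, tag: str, max_mismatch: int) -> list[Hit]:
        """Hits of ``tag`` on both strands, deduplicated by (seq, pos, strand)."""
        hits: dict[tuple[int, int, str], int] = {}
        for strand, q in (("+", tag), ("-", revcomp(tag))):
            for si, pos, mm in self._verify(q, max_mismatch):
                key = (si, pos, strand)
                if key not in hits or mm < hits[key]:
                    hits[key] = mm
        return [
            Hit(tag, self._seqs[si][0], pos, strand, mm)
            for (si, pos, strand), mm in sorted(hits.items())
        ]


def map_tags(
    library: TagLibrary,
    ref: ReferenceSet,
    max_mismatch: int,
    index: TagIndex | None = None,
) -> dict[str, list[Hit]]:
    """Map every unique tag of a lane; returns tag -> list of hits.

    ``max_mismatch`` must be 0, 1 or 2. A pre-built :class:`TagIndex` can
    be passed to amortize index construction across lanes.
    """
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    if index is None:
        index = TagIndex(ref)
    return {tag: index.query(tag, max_mismatch) for tag in library.counts}


@dataclass
class MappingReport:
    lane_id: str
    tags_total: int = 0  # read (tag occurrence) totals, not unique tags
    tags_mapped: int = 0
    tags_ambiguous: int = 0
    tags_unambiguous: int = 0
    unique_total: int = 0
    unique_mapped: int = 0
    unique_ambiguous: int = 0
    classification: dict[str, str] = field(default_factory=dict)

    def percentages(self) -> dict[str, float]:
        """Percentages relative to the lane's processed-read total."""
        tot = self.tags_total or 1
        return {
            "mapped_pct": 100.0 * self.tags_mapped / tot,
            "ambiguous_pct": 100.0 * self.tags_ambiguous / tot,
            "unambiguous_pct": 100.0 * self.tags_unambiguous / tot,
        }


@dataclass
class LaneCounts:
    """Per-locus (and per-copy) tag counts for one lane."""

    lane_id: str
    locus_counts: dict[str, int]
    copy_specific: dict[tuple[str, str], int]  # (locus, copy_label) -> count
    shared: dict[str, int]  # copy-unspecific counts per multi-copy locus
    report: MappingReport


def classify_and_count(
    hits_by_tag: dict[str, list[Hit]],
    library: TagLibrary,
    ref: ReferenceSet,
) -> LaneCounts:
    """Apply the ambiguity / homeolog counting rules to one lane's hits."""
    rep = MappingReport(lane_id=library.lane_id)
    rep.tags_total = library.total_tags
    rep.unique_total = library.unique_tags
    locus_counts: dict[str, int] = {}
    copy_specific: dict[tuple[str, str], int] = {}
    shared: dict[str, int] = {}
    by_id = {r.sequence_id: r for r in ref.records}
    for tag, hits in hits_by_tag.items():
        n = library.counts[tag]
        if not hits:
            rep.classification[tag] = "unmapped"
            continue
        rep.unique_mapped += 1
        rep.tags_mapped += n
        loci = {by_id[h.sequence_id].locus_id for h in hits}
        if len(loci) > 1:
            rep.unique_ambiguous += 1
            rep.tags_ambiguous += n
            rep.classification[tag] = "ambiguous_discarded"
            continue
        rep.tags_unambiguous += n
        locus = next(iter(loci))
        locus_counts[locus] = locus_counts.get(locus, 0) + n
        if len(ref.loci[locus]) > 1:
            copies = {by_id[h.sequence_id].copy_label for h in hits}
            if len(copies) == 1:
                copy = next(iter(copies))
                copy_specific[(locus, copy)] = copy_specific.get((locus, copy), 0) + n
                rep.classification[tag] = "copy_specific"
            else:
                shared[locus] = shared.get(locus, 0) + n
                rep.classification[tag] = "locus_specific"
        else:
            rep.classification[tag] = "locus_specific"
    return LaneCounts(library.lane_id, locus_counts, copy_specific, shared, rep)


def position_table(hits_by_tag: dict[str, list[Hit]], library: TagLibrary) -> pd.DataFrame:
    """Per-position tag counts with forward/reverse hits at one forward-strand
    coordinate merged into a single position key with combined counts."""
    rows: dict[tuple[str, int], int] = {}
    for tag, hits in hits_by_tag.items():
        n = library.counts[tag]
        for key in {(h.sequence_id, h.position) for h in hits}:
            rows[key] = rows.get(key, 0) + n
    df = pd.DataFrame(
        [(sid, pos, c) for (sid, pos), c in sorted(rows.items())],
        columns=["sequence_id", "position", "count"],
    )
    return df


def aggregate_contigs(
    hits_by_tag: dict[str, list[Hit]],
    library: TagLibrary,
    ref: ReferenceSet,
) -> LaneCounts:
    """Gene-level counting for partial-contig references.

    A tag counts iff all its contig hits resolve to exactly one gene; it
    then contributes once to that gene, no matter how many (possibly
    overlapping) contigs of the gene it hits. Contigs with no homology
    assignment count as their own "unannotated" pseudo-gene.
    """
    if ref.contig_to_gene is None:
        raise ValueError("reference has no contig_to_gene map")
    rep = MappingReport(lane_id=library.lane_id)
    rep.tags_total = library.total_tags
    rep.unique_total = library.unique_tags
    gene_counts: dict[str, int] = {}
    for tag, hits in hits_by_tag.items():
        n = library.counts[tag]
        if not hits:
            rep.classification[tag] = "unmapped"
            continue
        rep.unique_mapped += 1
        rep.tags_mapped += n
        genes = {
            ref.contig_to_gene.get(h.sequence_id, f"unannotated:{h.sequence_id}")
            for h in hits
        }
        if len(genes) > 1:
            rep.unique_ambiguous += 1
            rep.tags_ambiguous += n
            rep.classification[tag] = "ambiguous_discarded"
            continue
        rep.tags_unambiguous += n
        gene = next(iter(genes))
        gene_counts[gene] = gene_counts.get(gene, 0) + n
        rep.classification[tag] = "locus_specific"
    return LaneCounts(library.lane_id, gene_counts, {}, {}, rep)


def counts_matrix(lanes: list[LaneCounts], drop_unannotated: bool = True) -> pd.DataFrame:
    """Assemble per-lane locus counts into a loci x lanes integer matrix."""
    all_loci = sorted({l for lc in lanes for l in lc.locus_counts})
    if drop_unannotated:
        all_loci = [l for l in all_loci if not l.startswith("unannotated:")]
    df = pd.DataFrame(
        {lc.lane_id: [lc.locus_counts.get(l, 0) for l in all_loci] for lc in lanes},
        index=pd.Index(all_loci, name="locus"),
        dtype=int,
    )
    return df


def copy_counts_matrix(lanes: list[LaneCounts]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(copy-specific counts indexed by locus:copy, shared counts by locus)."""
    keys = sorted({k for lc in lanes for k in lc.copy_specific})
    spec = pd.DataFrame(
        {lc.lane_id: [lc.copy_specific.get(k, 0) for k in keys] for lc in lanes},
        index=pd.Index([f"{l}:{c}" for l, c in keys], name="copy"),
        dtype=int,
    )
    loci = sorted({l for lc in lanes for l in lc.shared})
    sh = pd.DataFrame(
        {lc.lane_id: [lc.shared.get(l, 0) for l in loci] for lc in lanes},
        index=pd.Index(loci, name="locus"),
        dtype=int,
    )
    return spec, sh


def mapping_summary(reports: list[MappingReport]) -> pd.DataFrame:
    """Per-lane accounting table: totals, mapped/ambiguous counts and
    percentages relative to the processed-read total."""
    rows = []
    for r in reports:
        pct = r.percentages()
        rows.append(
            {
                "lane_id": r.lane_id,
                "tags_total": r.tags_total,
                "tags_mapped": r.tags_mapped,
                "tags_ambiguous": r.tags_ambiguous,
                "tags_unambiguous": r.tags_unambiguous,
                **{k: round(v, 2) for k, v in pct.items()},
            }
        )
    return pd.DataFrame(rows)


def brute_force_map(
    tag: str, ref: ReferenceSet, max_mismatch: int
) -> list[Hit]:
    """Quadratic-scan oracle with the same contract as :meth:`TagIndex.query`.

    Intentionally naive; used in tests to verify the seeded index.
    """
    L = len(tag)
    hits = {}
    for r in ref.records:
        for strand, q in (("+", tag), ("-", revcomp(tag))):
            for pos in range(len(r.seq) - L + 1):
                window = r.seq[pos : pos + L]
                mm = sum(1 for a, b in zip(q, window) if a != b or b == "N")
                if mm <= max_mismatch:
                    key = (r.sequence_id, pos, strand)
                    if key not in hits or mm < hits[key]:
                        hits[key] = mm
    return [Hit(tag, s, p, st, mm) for (s, p, st), mm in sorted(hits.items())]


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
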