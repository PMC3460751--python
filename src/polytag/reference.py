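"""Reference transcriptomes: loading, indexing, and in-silico DpnII digestion.

A reference set groups transcript sequences into gene loci. In an
allopolyploid, one locus may be represented by two homeologous copies
(labelled ``A`` and ``B``) and occasionally a third, more diverged
paralogous copy (``C``); unduplicated loci carry the label ``single``.
Tag counting rules downstream depend on this grouping: a tag hitting both
copies of one locus is informative for the locus, a tag hitting two loci
is not informative at all.

Coordinates are 0-based, half-open, and always expressed on the forward
strand of the reference sequence, so that forward- and reverse-strand hits
at the same physical site share one position key.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

ENZYME_SITE = "GATC"  # DpnII recognition sequence; cleaves 5' of GATC
TAG_BODY = 16  # bases retained 3' of the restriction site
TAG_LENGTH = len(ENZYME_SITE) + TAG_BODY  # 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_KINDS = (
    "conspecific_full",
    "conspecific_contigs",
    "heterospecific_full",
    "heterospecific_all",
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RefRecord:
    sequence_id: str
    locus_id: str
    copy_label: str  # "A" | "B" | "C" | "single"
    seq: str


@dataclass
class ReferenceSet:
    """Ordered collection of reference sequences grouped into loci."""

    records: list[RefRecord]
    kind: str = "conspecific_full"
    contig_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown reference kind {self.kind!r}")
        ids = [r.sequence_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = [k for k, v in Counter(ids).items() if v > 1]
            raise ValueError(f"duplicate sequence ids: {dup[:5]}")
        by_locus: dict[str, list[RefRecord]] = {}
        for r in self.records:
            by_locus.setdefault(r.locus_id, []).append(r)
        for locus, recs in by_locus.items():
            if len(recs) > 1 and any(r.copy_label == "single" for r in recs):
                raise ValueError(
                    f"locus {locus} has multiple sequences but a 'single' copy label"
                )
        self._by_locus = by_locus

    def __len__(self) -> int:
        return len(self.records)

    @property
    def loci(self) -> dict[str, list[RefRecord]]:
        return self._by_locus

    def multicopy_loci(self) -> list[str]:
        return [l for l, recs in self._by_locus.items() if len(recs) > 1]

    def locus_of(self, sequence_id: str) -> str:
        return self._by_id[sequence_id].locus_id

    @property
    def _by_id(self) -> dict[str, RefRecord]:
        d = getattr(self, "_by_id_cache", None)
        if d is None:
            d = {r.sequence_id: r for r in self.records}
            object.__setattr__(self, "_by_id_cache", d)
        return d

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.sequence_id}\n")
                for i in range(0, len(r.seq), 70):
                    fh.write(r.seq[i : i + 70] + "\n")

    def write_locus_map(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence_id\tlocus_id\tcopy_label\n")
            for r in self.records:
                fh.write(f"{r.sequence_id}\t{r.locus_id}\t{r.copy_label}\n")


def load_reference(
    fasta_path: str | Path,
    locus_map_path: str | Path | None = None,
    kind: str = "conspecific_full",
    contig_map_path: str | Path | None = None,
) -> ReferenceSet:
    """Load a FASTA reference, optionally with a locus/copy map.

    The locus map is a 3-column TSV ``sequence_id  locus_id  copy_label``
    (header optional). Sequences absent from the map become their own
    single-copy locus. A contig map (``contig_id  gene_id``) attaches the
    contig-to-gene homology table used for partial-contig references.
    """
    locus_map: dict[str, tuple[str, str]] = {}
    if locus_map_path is not None:
        for ln, line in enumerate(Path(locus_map_path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "sequence_id":
                continue
            if len(parts) != 3:
                raise ValueError(f"{locus_map_path}: line {ln}: expected 3 columns")
            locus_map[parts[0]] = (parts[1], parts[2])

    records: list[RefRecord] = []
    n_parsed = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_parsed += 1
        if not rec.id:
            raise ValueError(f"{fasta_path}: record {n_parsed} has an empty header")
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{fasta_path}: record {n_parsed} ({rec.id}) has invalid residues {sorted(bad)}"
            )
        locus, copy = locus_map.get(rec.id, (rec.id, "single"))
        records.append(RefRecord(rec.id, locus, copy, seq))
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records found")

    contig_to_gene = None
    if contig_map_path is not None:
        contig_to_gene = {}
        for line in Path(contig_map_path).read_text().splitlines():
            if not line.strip() or line.startswith("contig_id\t"):
                continue
            cid, gid = line.rstrip("\n").split("\t")[:2]
            contig_to_gene[cid] = gid
    return ReferenceSet(records, kind=kind, contig_to_gene=contig_to_gene)


@dataclass
class SiteDistribution:
    """Per-sequence DpnII (GATC) site counts and their histogram."""

    site_counts: dict[str, int]
    histogram: dict[int, int] = field(init=False)
    siteless: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.histogram = dict(sorted(Counter(self.site_counts.values()).items()))
        self.siteless = [s for s, c in self.site_counts.items() if c == 0]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence_id\tn_sites\n")
            for sid, c in self.site_counts.items():
                fh.write(f"{sid}\t{c}\n")

    def write_histogram(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("n_sites\tn_sequences\n")
            for k, v in self.histogram.items():
                fh.write(f"{k}\t{v}\n")


def count_sites(seq: str, site: str = ENZYME_SITE) -> int:
    # GATC cannot overlap itself, so str.count is exact
    return seq.count(site)


def digest_in_silico(ref: ReferenceSet, site: str = ENZYME_SITE) -> SiteDistribution:
    """Count recognition sites per reference sequence.

    GATC is its own reverse complement, so the forward-strand scan covers
    both strands. Sequences with zero sites are flagged: no tag can ever
    be produced from them, so they are unsurveyable by the protocol.
    """
    return SiteDistribution({r.sequence_id: count_sites(r.seq, site) for r in ref.records})


def enumerate_candidate_tags(
    ref: ReferenceSet, site: str = ENZYME_SITE, tag_body: int = TAG_BODY
) -> dict[str, list[tuple[str, int, str]]]:
    """Enumerate every tag the protocol could emit from the reference.

    A candidate is the recognition site plus ``tag_body`` downstream bases,
    taken on either strand. Both orientations are keyed by the forward-strand
    start coordinate of the 20-mer window so forward/reverse candidates at
    one physical site share a position.
    """
    tag_len = len(site) + tag_body
    out: dict[str, list[tuple[str, int, str]]] = {}
    for r in ref.records:
        seq = r.seq
        start = seq.find(site)
        while start != -1:
            if start + tag_len <= len(seq):
                tag = seq[start : start + tag_len]
                out.setdefault(tag, []).append((r.sequence_id, start, "+"))
            # the same site read on the reverse strand: window ends at site end
            rc_start = start + len(site) - tag_len
            if rc_start >= 0:
                tag = revcomp(seq[rc_start : rc_start + tag_len])
                out.setdefault(tag, []).append((r.sequence_id, rc_start, "-"))
            start = seq.find(site, start + 1)
    return out
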