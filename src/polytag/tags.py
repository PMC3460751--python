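"""Raw 18-base reads -> quality-filtered, GATC-prefixed 20-mer tag libraries.

The sequencing protocol emits 18-base reads: 16 biological bases that lie
immediately 3' of a DpnII cut plus two artifactual bases appended by the
protocol. Processing clips the two junk bases and restores the GATC
recognition site at the front, giving one 20-base tag per read. Identical
tags are aggregated into counts; a lane's processed reads are its "tags",
the distinct ones its "unique tags".
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .reference import ENZYME_SITE, TAG_LENGTH

READ_LENGTH = 18
CLIP_BASES = 2
DEFAULT_MIN_QUALITY = 20


@dataclass
class TagLibrary:
    """One lane's unique 20-mer tags with occurrence counts."""

    lane_id: str
    species_label: str
    counts: dict[str, int] = field(default_factory=dict)
    total_reads_in: int = 0
    reads_discarded_quality: int = 0
    reads_discarded_length: int = 0
    reads_discarded_n: int = 0

    @property
    def total_tags(self) -> int:
        return sum(self.counts.values())

    @property
    def unique_tags(self) -> int:
        return len(self.counts)

    def validate(self) -> None:
        for t in self.counts:
            if len(t) != TAG_LENGTH or not t.startswith(ENZYME_SITE):
                raise ValueError(f"malformed tag {t!r}")
        kept = (
            self.total_reads_in
            - self.reads_discarded_quality
            - self.reads_discarded_length
            - self.reads_discarded_n
        )
        if self.total_tags != kept:
            raise ValueError("tag counts do not balance with read accounting")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tcount\n")
            for tag in sorted(self.counts):
                fh.write(f"{tag}\t{self.counts[tag]}\n")
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "lane_id": self.lane_id,
                    "species_label": self.species_label,
                    "total_reads_in": self.total_reads_in,
                    "reads_discarded_quality": self.reads_discarded_quality,
                    "reads_discarded_length": self.reads_discarded_length,
                    "reads_discarded_n": self.reads_discarded_n,
                },
                indent=1,
            )
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TagLibrary":
        counts: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("tag\t"):
                continue
            tag, c = line.split("\t")
            counts[tag] = int(c)
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        lib = cls(
            lane_id=meta.get("lane_id", Path(path).stem),
            species_label=meta.get("species_label", ""),
            counts=counts,
            total_reads_in=meta.get("total_reads_in", sum(counts.values())),
            reads_discarded_quality=meta.get("reads_discarded_quality", 0),
            reads_discarded_length=meta.get("reads_discarded_length", 0),
            reads_discarded_n=meta.get("reads_discarded_n", 0),
        )
        return lib


def quality_filter(
    reads, min_quality: int = DEFAULT_MIN_QUALITY
) -> tuple[list[str], int, int]:
    """Whole-read accept/reject on per-base Phred quality.

    Every tag here has the same fixed length, so trimming a read would only
    destroy it; a read is kept iff all 18 base qualities reach
    ``min_quality``. Returns (kept sequences, n discarded for quality,
    n discarded for wrong length).
    """
    kept: list[str] = []
    n_qual = 0
    n_len = 0
    for rec in reads:
        seq = str(rec.seq).upper()
        if len(seq) != READ_LENGTH:
            warnings.warn(f"read {rec.id}: length {len(seq)} != {READ_LENGTH}, skipped")
            n_len += 1
            continue
        quals = rec.letter_annotations["phred_quality"]
        if min(quals) >= min_quality:
            kept.append(seq)
        else:
            n_qual += 1
    return kept, n_qual, n_len


def build_tags(
    kept_reads: list[str],
    lane_id: str = "",
    species_label: str = "",
    total_reads_in: int | None = None,
    reads_discarded_quality: int = 0,
    reads_discarded_length: int = 0,
) -> TagLibrary:
    """Clip the 2 appended junk bases, prepend GATC, aggregate into counts.

    Reads still containing N after filtering cannot be counted as tags and
    are dropped (tracked in ``reads_discarded_n``).
    """
    counts: Counter[str] = Counter()
    n_dropped_n = 0
    for seq in kept_reads:
        body = seq[: READ_LENGTH - CLIP_BASES]
        if "N" in body:
            n_dropped_n += 1
            continue
        counts[ENZYME_SITE + body] += 1
    if total_reads_in is None:
        total_reads_in = len(kept_reads) + reads_discarded_quality + reads_discarded_length
    lib = TagLibrary(
        lane_id=lane_id,
        species_label=species_label,
        counts=dict(counts),
        total_reads_in=total_reads_in,
        reads_discarded_quality=reads_discarded_quality,
        reads_discarded_length=reads_discarded_length,
        reads_discarded_n=n_dropped_n,
    )
    lib.validate()
    return lib


def process_fastq(
    fastq_path: str | Path,
    lane_id: str | None = None,
    species_label: str = "",
    min_quality: int = DEFAULT_MIN_QUALITY,
) -> TagLibrary:
    """FASTQ lane (Phred+33) -> TagLibrary, the full per-lane pipeline."""
    reads = list(SeqIO.parse(str(fastq_path), "fastq"))
    kept, n_qual, n_len = quality_filter(reads, min_quality=min_quality)
    return build_tags(
        kept,
        lane_id=lane_id or Path(fastq_path).stem,
        species_label=species_label,
        total_reads_in=len(reads),
        reads_discarded_quality=n_qual,
        reads_discarded_length=n_len,
    )


def lane_overlap(libraries: list[TagLibrary]) -> dict:
    """Set-algebra report over per-lane unique-tag sets.

    Reports, per lane, how many unique tags are private to it and how many
    are shared with at least one other lane, plus the size of the all-lane
    intersection.
    """
    if len(libraries) < 2:
        raise ValueError("need at least two libraries to compare")
    sets = [set(lib.counts) for lib in libraries]
    inter = set.intersection(*sets)
    union = set.union(*sets)
    per_lane = {}
    for lib, s in zip(libraries, sets):
        others = set.union(*(o for o in sets if o is not s)) if len(sets) > 1 else set()
        per_lane[lib.lane_id] = {
            "unique_tags": len(s),
            "private": len(s - others),
            "shared": len(s & others),
        }
    return {
        "per_lane": per_lane,
        "intersection_all": len(inter),
        "union_all": len(union),
    }
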