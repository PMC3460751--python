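"""Copy-specific expression of homeologous (and paralogous) gene copies.

In an allopolyploid, each duplicated locus carries one copy from each
parental subgenome. Tags hitting only one copy ("copy-specific") can
attribute expression to that copy; tags hitting both ("copy-unspecific")
cannot. A locus is analysable for copy-specific expression only when the
copy-specific signal dominates: summed over lanes and copies, its
copy-specific tags must exceed five and be at least fivefold the
copy-unspecific tags. Per-copy differential expression between species
then uses copy-specific counts only, and each locus is classified into
one of six cross-species patterns (both copies up in one species, one up
with the other silent on the contrast, reciprocal, or no signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .mapping import LaneCounts
from . import detest

MIN_SPECIFIC = 5  # copy-specific tags must be > this
FOLD_OVER_SHARED = 5.0  # and >= this multiple of copy-unspecific tags

PATTERNS = (
    "all_up_E",
    "all_up_F",
    "one_up_E_other_null",
    "one_up_F_other_null",
    "reciprocal",
    "none",
)


@dataclass
class CopyRecord:
    locus_id: str
    copy_label: str
    copy_specific_counts: dict[str, int]  # lane -> count
    shared_counts: dict[str, int]  # locus-level copy-unspecific counts per lane

    @property
    def total_specific(self) -> int:
        return sum(self.copy_specific_counts.values())


def split_copy_counts(
    lanes: list[LaneCounts], locus_copies: dict[str, list[str]]
) -> dict[str, list[CopyRecord]]:
    """Separate copy-specific from shared counts, per multi-copy locus.

    ``locus_copies`` maps locus_id -> copy labels (>=2, else the locus is
    rejected: a single-copy locus has nothing to split).
    """
    out: dict[str, list[CopyRecord]] = {}
    for locus, labels in locus_copies.items():
        if len(labels) < 2:
            raise ValueError(f"locus {locus} has a single copy; nothing to split")
        shared = {lc.lane_id: lc.shared.get(locus, 0) for lc in lanes}
        out[locus] = [
            CopyRecord(
                locus,
                label,
                {lc.lane_id: lc.copy_specific.get((locus, label), 0) for lc in lanes},
                shared,
            )
            for label in labels
        ]
    return out


def filter_analysable_loci(
    records: dict[str, list[CopyRecord]],
    min_specific: int = MIN_SPECIFIC,
    fold: float = FOLD_OVER_SHARED,
    per_copy: bool = False,
) -> set[str]:
    """Loci whose copy-specific signal passes the >5 and >=5-fold filter.

    Default aggregation is locus-level: counts summed over lanes and
    copies. ``per_copy=True`` demands that every copy individually passes.
    """
    passing = set()
    for locus, recs in records.items():
        shared = sum(recs[0].shared_counts.values())
        if per_copy:
            ok = all(
                r.total_specific > min_specific and r.total_specific >= fold * shared
                for r in recs
            )
        else:
            spec = sum(r.total_specific for r in recs)
            ok = spec > min_specific and spec >= fold * shared
        if ok:
            passing.add(locus)
    return passing


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -2
        a.extend_gap_score = -1
        # free end gaps: partial sequences should not be penalized
        a.end_gap_score = 0
        _aligner = a
    return _aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identical sites from a global alignment with free end gaps.

    Identity = matches / aligned columns, end-gap columns excluded.
    """
    aln = _get_aligner().align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    # trim end-gap columns
    start = max(len(a) - len(a.lstrip("-")), len(b) - len(b.lstrip("-")))
    end = len(a) - max(len(a) - len(a.rstrip("-")), len(b) - len(b.rstrip("-")))
    cols = 0
    matches = 0
    for x, y in zip(a[start:end], b[start:end]):
        cols += 1
        if x == y and x != "-":
            matches += 1
    return 100.0 * matches / cols if cols else 0.0


def classify_copy_relationship(
    identities: dict[tuple[str, str], float],
    homeolog_max: float = 95.0,
    paralog_max: float = 90.0,
) -> dict[str, str]:
    """Label copies of one locus as homeolog / paralog / flagged.

    The two most similar copies below ``homeolog_max`` percent identity
    are the homeolog pair; a remaining copy below ``paralog_max`` to both
    is a putative paralog. Copies at or above ``homeolog_max`` to another
    copy are flagged as possible alleles or assembly artifacts.
    """
    labels_set: set[str] = set()
    for a, b in identities:
        labels_set.update((a, b))
    labels = sorted(labels_set)

    def ident(a: str, b: str) -> float:
        return identities.get((a, b), identities.get((b, a)))

    out = {l: "flagged" for l in labels}
    pairs = sorted(
        ((ident(a, b), a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]),
        reverse=True,
    )
    best = next((p for p in pairs if p[0] < homeolog_max), None)
    if best is None:
        return out  # everything suspiciously similar
    _, a, b = best
    out[a] = out[b] = "homeolog"
    for c in labels:
        if c in (a, b):
            continue
        if ident(c, a) < paralog_max and ident(c, b) < paralog_max:
            out[c] = "paralog"
    return out


def classify_pattern(calls: list[str]) -> str:
    """Locus-level pattern from the per-copy DE calls."""
    for c in calls:
        if c not in ("up_E", "up_F", "not_DE", "not_tested"):
            raise ValueError(f"unknown call {c!r}")
    n_e = sum(c == "up_E" for c in calls)
    n_f = sum(c == "up_F" for c in calls)
    if n_e and n_f:
        return "reciprocal"
    if n_e == len(calls):
        return "all_up_E"
    if n_f == len(calls):
        return "all_up_F"
    if n_e:
        return "one_up_E_other_null" if n_e == 1 else "all_up_E"
    if n_f:
        return "one_up_F_other_null" if n_f == 1 else "all_up_F"
    return "none"


def homeolog_de_analysis(
    copy_counts: pd.DataFrame,
    groups: pd.Series | dict,
    analysable: set[str] | None = None,
    m_threshold: float = detest.M_THRESHOLD_DEFAULT,
    alpha: float = detest.ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Per-copy exact-test DE plus per-locus pattern classification.

    ``copy_counts`` rows are indexed ``locus:copy`` (copy-specific counts
    only; shared tags cannot discriminate copies and are excluded).
    Returns the per-copy DE table with ``locus_id`` and ``pattern``
    columns attached.
    """
    if analysable is not None:
        keep = [i for i in copy_counts.index if i.split(":")[0] in analysable]
        copy_counts = copy_counts.loc[keep]
    if copy_counts.empty:
        return pd.DataFrame(
            columns=["locus_id", "copy_label", "M", "p_value", "adj_p", "call", "pattern"]
        )
    res, _ = detest.de_analysis(
        copy_counts, groups, m_threshold=m_threshold, alpha=alpha
    )
    res = res.copy()
    res["locus_id"] = [i.split(":")[0] for i in res.index]
    res["copy_label"] = [i.split(":")[1] for i in res.index]
    patterns = {
        locus: classify_pattern(list(sub["call"]))
        for locus, sub in res.groupby("locus_id")
    }
    res["pattern"] = res["locus_id"].map(patterns)
    return res
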