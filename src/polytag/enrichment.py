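"""Per-term Fisher enrichment and cluster enrichment scores.

Given a set of up-regulated genes and a background (here: the reference
genes that carry at least one DpnII site, i.e. the genes the protocol
could have surveyed), each annotation term is tested with a one-sided
Fisher exact test on the 2x2 table (in/out of the up set x has/lacks the
term). Term clusters (memberships supplied externally) are summarized by
the enrichment score -log10(geometric mean of the member p-values);
a score >= 1.3 corresponds to a geometric-mean p of 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

SCORE_CUTOFF = round(-math.log10(0.05), 1)  # 1.3


@dataclass
class AnnotationTable:
    gene_to_terms: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        extra = set(self.gene_to_terms) - self.background
        if extra:
            raise ValueError(
                f"{len(extra)} annotated genes are outside the background"
            )
        self.term_to_genes: dict[str, set[str]] = {}
        for g, terms in self.gene_to_terms.items():
            for t in terms:
                self.term_to_genes.setdefault(t, set()).add(g)


def term_fisher(term: str, up_set: set, annot: AnnotationTable) -> float:
    """One-sided (enrichment) Fisher exact p for one term."""
    if not up_set <= annot.background:
        raise ValueError("up_set must be a subset of the background")
    genes = annot.term_to_genes.get(term)
    if not genes:
        warnings.warn(f"term {term!r} absent from the background; p = 1")
        return 1.0
    k = len(genes & up_set)
    table = [
        [k, len(up_set) - k],
        [len(genes) - k, len(annot.background) - len(up_set) - (len(genes) - k)],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def enrich_all(up_set: set, annot: AnnotationTable) -> pd.DataFrame:
    rows = []
    for term in sorted(annot.term_to_genes):
        genes = annot.term_to_genes[term]
        rows.append(
            {
                "term": term,
                "n_term": len(genes),
                "n_up": len(genes & up_set),
                "p_value": term_fisher(term, up_set, annot),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ClusterScore:
    terms: list[str]
    p_values: list[float]
    score: float = field(init=False)
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if not self.p_values:
            raise ValueError("cluster must contain at least one p-value")
        if any(not (0 < p <= 1) for p in self.p_values):
            raise ValueError("p-values must lie in (0, 1]")
        log_gm = sum(math.log10(p) for p in self.p_values) / len(self.p_values)
        self.score = -log_gm
        self.significant = self.score >= SCORE_CUTOFF


def cluster_score(p_values: list[float], terms: list[str] | None = None) -> ClusterScore:
    """Enrichment score = -log10 of the geometric mean of member p-values."""
    return ClusterScore(terms or [], list(p_values))


def score_clusters(
    clusters: dict[str, list[str]], term_p: dict[str, float]
) -> pd.DataFrame:
    rows = []
    for name, terms in clusters.items():
        cs = cluster_score([term_p[t] for t in terms], terms)
        rows.append(
            {
                "cluster": name,
                "n_terms": len(terms),
                "score": cs.score,
                "significant": cs.significant,
            }
        )
    return pd.DataFrame(rows)


def load_annotation(gene_term_tsv, background: set[str] | None = None) -> AnnotationTable:
    """gene -> term TSV (two columns); background defaults to the annotated genes."""
    g2t: dict[str, set[str]] = {}
    from pathlib import Path

    for line in Path(gene_term_tsv).read_text().splitlines():
        if not line.strip() or line.startswith("gene_id\t"):
            continue
        gene, term = line.rstrip("\n").split("\t")[:2]
        g2t.setdefault(gene, set()).add(term)
    if background is None:
        background = set(g2t)
    return AnnotationTable(g2t, background)
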