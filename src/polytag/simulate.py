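"""Synthetic allopolyploid tag-profiling data.

Generates every input the pipeline consumes with the statistical structure
the analysis assumes, at desk scale:

* a conspecific reference transcriptome in which a configurable fraction of
  gene loci carry two homeologous copies (~10% diverged, mirroring the two
  parental subgenomes of an allopolyploid) and a small fraction a third,
  more diverged paralogous copy;
* a heterospecific ortholog set (~10% diverged from the conspecific
  sequences), standing in for a related model-species transcriptome;
* partial contigs fragmenting each conspecific transcript, with a
  contig-to-gene homology table;
* FASTQ tag lanes per species: per-gene lane counts are negative binomial
  around the gene's true proportion of the library, tags fall on
  GATC-anchored positions (the 3'-most site always cuts, upstream sites
  only in incompletely digested molecules), reads carry per-base
  sequencing error plus the protocol's two appended junk bases, and the
  second species' reads carry fixed interspecies SNPs;
* noisy DEG lists from two "platforms" over partially overlapping surveyed
  universes, for exercising the concordance analysis.

All randomness flows from a single seed; identical configs give
byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import RefRecord, ReferenceSet, ENZYME_SITE, TAG_LENGTH, count_sites

_BASES = np.frombuffer(b"ACGT", dtype="S1")
READ_LENGTH = 18
TAG_BODY = 16


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions emulated.

    Divergences default to 0.10 per site (homeologous copies and the
    heterospecific reference are each about 90% identical to the
    conspecific sequence) and interspecies SNPs to 0.02 (the two profiled
    species are about 98% identical). Three lanes per species match the
    flow-cell design. ``dispersion`` is the NB overdispersion phi
    (Var = mu + phi mu^2); 0 gives Poisson lanes.
    """

    n_loci: int = 300
    homeolog_fraction: float = 700 / 6428
    triplet_fraction: float = 5 / 700
    homeolog_divergence: float = 0.10
    paralog_divergence: float = 0.15
    heterospecific_divergence: float = 0.10
    interspecies_snp_rate: float = 0.02
    mean_length: int = 500
    dispersion: float = 0.1
    de_fraction: float = 0.10
    log2_fc: float = 2.0
    lanes_per_species: int = 3
    library_size: int = 50_000
    digestion_completeness: float = 0.5
    error_rate: float = 0.002
    bad_read_fraction: float = 0.08
    siteless_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = {
            "homeolog_fraction": self.homeolog_fraction,
            "triplet_fraction": self.triplet_fraction,
            "homeolog_divergence": self.homeolog_divergence,
            "paralog_divergence": self.paralog_divergence,
            "heterospecific_divergence": self.heterospecific_divergence,
            "interspecies_snp_rate": self.interspecies_snp_rate,
            "de_fraction": self.de_fraction,
            "digestion_completeness": self.digestion_completeness,
            "error_rate": self.error_rate,
            "bad_read_fraction": self.bad_read_fraction,
            "siteless_fraction": self.siteless_fraction,
        }
        for name, v in props.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_size <= 0 or self.n_loci <= 0 or self.lanes_per_species <= 0:
            raise ValueError("n_loci, library_size and lanes_per_species must be > 0")
        # every sequence must be able to host GATC plus a 16-base suffix
        if self.mean_length < 2 * TAG_LENGTH:
            raise ValueError(
                f"mean_length {self.mean_length} too short to host a GATC site "
                f"with a {TAG_BODY}-base suffix"
            )


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle checks downstream."""

    loci: pd.DataFrame  # locus_id, prop_E, prop_F, de (up_E/up_F/none), true_log2fc
    copies: pd.DataFrame  # sequence_id, locus_id, copy_label, share_E, share_F
    enysii_variants: dict[str, str] = field(repr=False, default_factory=dict)

    def de_loci(self, direction: str | None = None) -> set[str]:
        sel = self.loci["de"] != "none" if direction is None else self.loci["de"] == direction
        return set(self.loci.loc[sel, "locus_id"])

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        self.loci.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
        self.copies.to_csv(out / "truth_copies.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitutions at the given rate (always to a different base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _ensure_site(seq: str, rng: np.random.Generator) -> str:
    """Implant one GATC with a full 16-base suffix if none exists."""
    limit = len(seq) - TAG_LENGTH
    if ENZYME_SITE in seq[: limit + len(ENZYME_SITE)]:
        return seq
    pos = int(rng.integers(0, limit + 1))
    return seq[:pos] + ENZYME_SITE + seq[pos + 4 :]


def _strip_sites(seq: str) -> str:
    while ENZYME_SITE in seq:
        seq = seq.replace(ENZYME_SITE, "GATG")
    return seq


def simulate_reference(
    config: SimulationConfig,
) -> tuple[ReferenceSet, ReferenceSet, ReferenceSet, GroundTruth]:
    """Conspecific, heterospecific and partial-contig references + truth.

    Expression structure: species-F locus proportions are Dirichlet; DE
    loci get their species-E proportion multiplied by 2**(+-log2_fc) and
    the non-DE block is rescaled so species-E proportions still sum to 1 —
    so the |log2 fold change| of every DE locus is exactly ``log2_fc``
    while non-DE loci absorb a common (small) composition shift. Copy
    shares within multi-copy loci are independent Dirichlet draws per
    species, which lets reciprocal homeolog patterns arise naturally.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_loci
    lengths = rng.integers(
        max(2 * TAG_LENGTH, int(0.7 * config.mean_length)),
        int(1.3 * config.mean_length) + 1,
        size=n,
    )
    # exact counts: a homeolog_fraction of loci carry a second copy and a
    # triplet_fraction of those a third, so sequence totals are deterministic
    n_hom = int(round(config.homeolog_fraction * n))
    n_trip = int(round(config.triplet_fraction * n_hom))
    order = rng.permutation(n)
    is_homeolog = np.zeros(n, dtype=bool)
    is_homeolog[order[:n_hom]] = True
    is_triplet = np.zeros(n, dtype=bool)
    is_triplet[order[:n_trip]] = True
    is_siteless = rng.random(n) < config.siteless_fraction

    con_records: list[RefRecord] = []
    het_records: list[RefRecord] = []
    copy_rows = []
    for i in range(n):
        locus = f"L{i:05d}"
        seq = _random_seq(rng, int(lengths[i]))
        seq = _strip_sites(seq) if is_siteless[i] else _ensure_site(seq, rng)
        copies = [("A" if is_homeolog[i] else "single", seq)]
        if is_homeolog[i]:
            b = _mutate(seq, config.homeolog_divergence, rng)
            copies.append(("B", b if is_siteless[i] else _ensure_site(b, rng)))
            if is_triplet[i]:
                c = _mutate(seq, config.paralog_divergence, rng)
                copies.append(("C", c if is_siteless[i] else _ensure_site(c, rng)))
        shares_e = rng.dirichlet(np.ones(len(copies)))
        shares_f = rng.dirichlet(np.ones(len(copies)))
        for k, (label, cseq) in enumerate(copies):
            sid = locus if label == "single" else f"{locus}_{label}"
            con_records.append(RefRecord(sid, locus, label, cseq))
            copy_rows.append(
                {
                    "sequence_id": sid,
                    "locus_id": locus,
                    "copy_label": label,
                    "share_E": shares_e[k],
                    "share_F": shares_f[k],
                }
            )
        het = _mutate(seq, config.heterospecific_divergence, rng)
        het_records.append(RefRecord(f"{locus}_het", locus, "single", het))

    conspecific = ReferenceSet(con_records, kind="conspecific_full")
    heterospecific = ReferenceSet(het_records, kind="heterospecific_full")

    # partial contigs: fragment each conspecific sequence into >=1 pieces of
    # >=200 bases with a small overlap between neighbours
    contig_records: list[RefRecord] = []
    contig_to_gene: dict[str, str] = {}
    for r in con_records:
        L = len(r.seq)
        pieces: list[tuple[int, int]]
        if L < 450:
            pieces = [(0, L)]
        else:
            cut = int(rng.integers(200, L - 200 + 1))
            overlap = int(rng.integers(0, 31))
            pieces = [(0, min(L, cut + overlap)), (cut, L)]
        for j, (a, b) in enumerate(pieces):
            cid = f"{r.sequence_id}_ctg{j}"
            contig_records.append(RefRecord(cid, cid, "single", r.seq[a:b]))
            contig_to_gene[cid] = r.locus_id
    contigs = ReferenceSet(
        contig_records, kind="conspecific_contigs", contig_to_gene=contig_to_gene
    )

    # expression truth
    prop_f = rng.dirichlet(np.ones(n))
    de = np.array(["none"] * n, dtype=object)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    # assign directions greedily so the total mass moved up ~ mass moved
    # down: the compensating rescale of the non-DE block then stays near 1
    up_gain = 2.0**config.log2_fc - 1.0
    down_gain = 2.0**-config.log2_fc - 1.0
    imbalance = 0.0
    for i in de_idx:
        if abs(imbalance + prop_f[i] * up_gain) <= abs(imbalance + prop_f[i] * down_gain):
            de[i] = "up_E"
            imbalance += prop_f[i] * up_gain
        else:
            de[i] = "up_F"
            imbalance += prop_f[i] * down_gain
    factor = np.ones(n)
    factor[de == "up_E"] = 2.0**config.log2_fc
    factor[de == "up_F"] = 2.0**-config.log2_fc
    d_mass = float((prop_f * factor)[de != "none"].sum())
    nonde_mass = float(prop_f[de == "none"].sum())
    if d_mass >= 1.0 or nonde_mass <= 0:
        raise ValueError("DE mass exceeds the library; lower de_fraction or log2_fc")
    prop_e = prop_f * factor
    prop_e[de == "none"] *= (1.0 - d_mass) / nonde_mass
    true_fc = np.log2(prop_e) - np.log2(prop_f)

    loci_df = pd.DataFrame(
        {
            "locus_id": [f"L{i:05d}" for i in range(n)],
            "prop_E": prop_e,
            "prop_F": prop_f,
            "de": de,
            "true_log2fc": true_fc,
            "n_copies": [len(conspecific.loci[f"L{i:05d}"]) for i in range(n)],
        }
    )
    copies_df = pd.DataFrame(copy_rows)

    # the species-E allele of every conspecific transcript (fixed SNPs)
    snp_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    variants = {
        r.sequence_id: _mutate(r.seq, config.interspecies_snp_rate, snp_rng)
        for r in con_records
    }
    truth = GroundTruth(loci_df, copies_df, variants)
    return conspecific, heterospecific, contigs, truth


@dataclass
class Lane:
    lane_id: str
    species: str  # "E" or "F"
    reads: list[tuple[str, str]]  # (18-base sequence, Phred+33 quality string)

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (seq, qual) in enumerate(self.reads):
                fh.write(f"@{self.lane_id}:{i}\n{seq}\n+\n{qual}\n")

    def to_seqrecords(self):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        recs = []
        for i, (seq, qual) in enumerate(self.reads):
            r = SeqRecord(Seq(seq), id=f"{self.lane_id}:{i}", description="")
            r.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            recs.append(r)
        return recs


def _eligible_sites(seq: str, completeness: float, rng: np.random.Generator) -> list[int]:
    """GATC positions that can yield a tag: site needs a 16-base suffix;
    the 3'-most such site always cuts, upstream ones with the given
    probability (incomplete digestion)."""
    sites = []
    start = seq.find(ENZYME_SITE)
    while start != -1:
        if start + TAG_LENGTH <= len(seq):
            sites.append(start)
        start = seq.find(ENZYME_SITE, start + 1)
    if not sites:
        return []
    keep = [sites[-1]]
    for s in sites[:-1]:
        if rng.random() < completeness:
            keep.append(s)
    return sorted(keep)


def simulate_tag_lanes(
    reference: ReferenceSet, truth: GroundTruth, config: SimulationConfig
) -> dict[str, list[Lane]]:
    """FASTQ lanes per species ("E" and "F").

    Per-copy lane counts are Gamma-Poisson (i.e. NB with mean
    library_size * locus proportion * copy share and dispersion phi); each
    copy's tags are spread over its eligible GATC sites with geometrically
    decaying weight toward 5' (ratio 0.6); reads are the 16 bases 3' of
    the site plus two random junk bases, with substitution errors at
    ``error_rate``; species-E reads come from the SNP-carrying species-E
    allele of each transcript.
    """
    ss = np.random.SeedSequence(config.seed).spawn(10)
    out: dict[str, list[Lane]] = {"E": [], "F": []}
    copies = truth.copies
    site_rng = np.random.default_rng(ss[3])
    # eligibility is a property of the digested molecule pool per species
    seqs: dict[str, dict[str, str]] = {"E": {}, "F": {}}
    sites: dict[str, dict[str, list[int]]] = {"E": {}, "F": {}}
    for r in reference.records:
        seqs["F"][r.sequence_id] = r.seq
        seqs["E"][r.sequence_id] = truth.enysii_variants.get(r.sequence_id, r.seq)
    for sp in ("E", "F"):
        for sid, seq in seqs[sp].items():
            sites[sp][sid] = _eligible_sites(seq, config.digestion_completeness, site_rng)

    prop = truth.loci.set_index("locus_id")
    decay = 0.6
    # a lane yields ~library_size tags no matter what: copies whose transcript
    # has no usable GATC site (e.g. a species SNP destroyed it) drop out of
    # the pool and the remaining copies fill the lane
    base_mean: dict[str, np.ndarray] = {}
    for sp in ("E", "F"):
        raw = np.array(
            [
                prop.loc[row["locus_id"], f"prop_{sp}"] * row[f"share_{sp}"]
                if sites[sp][row["sequence_id"]]
                else 0.0
                for _, row in copies.iterrows()
            ]
        )
        if raw.sum() <= 0:
            raise ValueError("no simulated transcript carries a usable GATC site")
        base_mean[sp] = config.library_size * raw / raw.sum()
    for sp in ("E", "F"):
        for lane_no in range(config.lanes_per_species):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, 1000 + (0 if sp == "E" else 1), lane_no))
            )
            reads: list[tuple[str, str]] = []
            for ci, (_, row) in enumerate(copies.iterrows()):
                sid = row["sequence_id"]
                mean = base_mean[sp][ci]
                if mean == 0.0:
                    continue
                if config.dispersion > 0:
                    lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mean)
                else:
                    lam = mean
                count = int(rng.poisson(lam))
                if count == 0:
                    continue
                elig = sites[sp][sid]  # non-empty: zero-mean copies skipped above
                w = decay ** np.arange(len(elig))[::-1]  # 3'-most gets weight 1
                w = w / w.sum()
                per_site = rng.multinomial(count, w)
                seq = seqs[sp][sid]
                for s, c in zip(elig, per_site):
                    if c:
                        body = seq[s + 4 : s + 4 + TAG_BODY]
                        reads.extend(_make_reads(body, int(c), config, rng))
            rng.shuffle(reads)  # lanes are unsorted in reality
            lane = Lane(f"{sp}{lane_no + 1}", sp, reads)
            out[sp].append(lane)
    return out


def _make_reads(
    body: str, count: int, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """``count`` error-bearing reads from one 16-base tag body (vectorized)."""
    arr = np.tile(np.frombuffer(body.encode(), dtype="S1"), (count, 1))
    if config.error_rate > 0:
        err = rng.random(arr.shape) < config.error_rate
        if err.any():
            # shift by 1..3 positions in base order: always a different base
            idx = np.searchsorted(_BASES, arr[err])
            arr[err] = _BASES[(idx + rng.integers(1, 4, size=idx.size)) % 4]
    junk = rng.choice(_BASES, size=(count, 2))
    seqs = np.concatenate([arr, junk], axis=1)
    quals = rng.integers(30, 41, size=(count, READ_LENGTH))
    bad = rng.random(count) < config.bad_read_fraction
    n_bad = int(bad.sum())
    if n_bad:
        pos = rng.integers(0, READ_LENGTH, size=n_bad)
        quals[np.nonzero(bad)[0], pos] = rng.integers(2, 20, size=n_bad)
    qbytes = (quals + 33).astype(np.uint8)
    out = []
    for i in range(count):
        out.append((seqs[i].tobytes().decode(), qbytes[i].tobytes().decode()))
    return out


def simulate_count_matrix(
    truth: GroundTruth, config: SimulationConfig
) -> tuple["pd.DataFrame", "pd.Series"]:
    """The statistical layer alone: NB locus counts per lane, no sequencing.

    Draws the same Gamma-Poisson lane counts the FASTQ generator uses but
    skips digestion, errors and mapping, giving a clean gene x lane count
    matrix whose rows follow NB(library_size * proportion, phi) exactly.
    Returns (counts, lane -> species group labels).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 77)))
    loci = truth.loci
    cols = {}
    for sp in ("E", "F"):
        p = loci[f"prop_{sp}"].to_numpy()
        for lane_no in range(config.lanes_per_species):
            mu = config.library_size * p
            if config.dispersion > 0:
                lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
            else:
                lam = mu
            cols[f"{sp}{lane_no + 1}"] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=loci["locus_id"])
    counts.index.name = "locus"
    groups = pd.Series({c: c[0] for c in counts.columns})
    return counts, groups


def simulate_platform_lists(
    truth: GroundTruth,
    survey_overlap: float = 0.5,
    sensitivity: float = 0.8,
    false_positive_rate: float = 0.02,
    seed: int = 0,
) -> dict:
    """Two noisy DEG lists over partially overlapping surveyed universes.

    Each platform surveys an equal-sized subset of loci; the two universes
    share a ``survey_overlap`` fraction of their genes. True DE genes in a
    platform's universe enter its list with probability ``sensitivity``
    (with the true direction); surveyed non-DE genes enter with
    ``false_positive_rate`` (random direction).
    """
    if not (0 <= survey_overlap <= 1 and 0 <= sensitivity <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    loci = list(truth.loci["locus_id"])
    n = len(loci)
    size = int(n / (2 - survey_overlap))
    n_shared = int(round(survey_overlap * size))
    order = list(rng.permutation(loci))
    shared = order[:n_shared]
    priv_a = order[n_shared : size]
    priv_b = order[size : 2 * size - n_shared]
    universe_a = set(shared) | set(priv_a)
    universe_b = set(shared) | set(priv_b)

    de_dir = dict(zip(truth.loci["locus_id"], truth.loci["de"]))

    def make_list(universe: set) -> dict[str, set]:
        lists = {"up_E": set(), "up_F": set()}
        for g in universe:
            d = de_dir[g]
            if d != "none":
                if rng.random() < sensitivity:
                    lists[d].add(g)
            elif rng.random() < false_positive_rate:
                lists["up_E" if rng.random() < 0.5 else "up_F"].add(g)
        return lists

    return {
        "universe_a": universe_a,
        "universe_b": universe_b,
        "lists_a": make_list(universe_a),
        "lists_b": make_list(universe_b),
    }


def simulate_annotation(
    truth: GroundTruth, n_terms: int = 40, terms_per_gene: tuple[int, int] = (1, 5),
    seed: int = 0,
) -> dict[str, set[str]]:
    """Synthetic gene -> term map over the simulated loci."""
    rng = np.random.default_rng(seed)
    terms = [f"T:{i:07d}" for i in range(n_terms)]
    out = {}
    for g in truth.loci["locus_id"]:
        k = int(rng.integers(terms_per_gene[0], terms_per_gene[1] + 1))
        out[g] = set(rng.choice(terms, size=k, replace=False))
    return out


def write_simulation(out_dir: str | Path, config: SimulationConfig) -> dict:
    """Run the full generator and persist every artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    con, het, ctg, truth = simulate_reference(config)
    con.write_fasta(out / "conspecific.fa")
    con.write_locus_map(out / "conspecific_loci.tsv")
    het.write_fasta(out / "heterospecific.fa")
    ctg.write_fasta(out / "contigs.fa")
    with open(out / "contig_to_gene.tsv", "w") as fh:
        fh.write("contig_id\tgene_id\n")
        for cid, gid in ctg.contig_to_gene.items():
            fh.write(f"{cid}\t{gid}\n")
    truth.write(out)
    annot = simulate_annotation(truth, seed=config.seed)
    with open(out / "gene_to_term.tsv", "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for g in sorted(annot):
            for t in sorted(annot[g]):
                fh.write(f"{g}\t{t}\n")
    lanes = simulate_tag_lanes(con, truth, config)
    lane_paths = []
    for sp in ("E", "F"):
        for lane in lanes[sp]:
            p = out / f"lane_{lane.lane_id}.fastq"
            lane.write_fastq(p)
            lane_paths.append(str(p))
    import json

    (out / "sim_config.json").write_text(json.dumps(asdict(config), indent=1))
    return {"out_dir": str(out), "lanes": lane_paths, "n_loci": config.n_loci}
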