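"""End-to-end orchestration: simulate -> tags -> map -> test -> report.

A run is fully described by a :class:`RunConfig` (YAML-serializable):
which reference the tags are mapped against (conspecific full-length,
heterospecific ortholog, or partial contigs), the per-species mismatch
allowance (the asymmetric policy where only the second species' tags get
a mismatch budget against the conspecific reference), and the statistical
thresholds. Every stage writes TSV tables into the run directory and the
run ends with a manifest of content hashes, so identical configs yield
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import concordance, detest, enrichment, homeolog, mapping, simulate, tags
from .reference import ReferenceSet, load_reference, digest_in_silico

log = logging.getLogger("polytag")

REFERENCE_CHOICES = ("conspecific", "heterospecific", "contigs")


@dataclass
class RunConfig:
    out_dir: str = "polytag_run"
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    reference: str = "conspecific"
    mismatch_e: int = 0  # mismatch allowance for species-E tags
    mismatch_f: int = 0
    min_quality: int = tags.DEFAULT_MIN_QUALITY
    m_threshold: float = detest.M_THRESHOLD_DEFAULT
    alpha: float = detest.ALPHA_DEFAULT
    homeolog_min_specific: int = homeolog.MIN_SPECIFIC
    homeolog_fold: float = homeolog.FOLD_OVER_SHARED
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference not in REFERENCE_CHOICES:
            raise ValueError(f"reference must be one of {REFERENCE_CHOICES}")
        for mm in (self.mismatch_e, self.mismatch_f):
            if mm not in (0, 1, 2):
                raise ValueError("mismatch allowance must be 0, 1 or 2")
        if self.m_threshold <= 0 or not (0 < self.alpha < 1):
            raise ValueError("thresholds must be positive (alpha in (0,1))")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        sim_cfg = simulate.SimulationConfig(**{"seed": config.seed, **config.sim})
        sim_dir = out / "sim"
        simulate.write_simulation(sim_dir, sim_cfg)
        con = load_reference(sim_dir / "conspecific.fa", sim_dir / "conspecific_loci.tsv")
        het = load_reference(sim_dir / "heterospecific.fa", kind="heterospecific_full")
        ctg = load_reference(
            sim_dir / "contigs.fa",
            kind="conspecific_contigs",
            contig_map_path=sim_dir / "contig_to_gene.tsv",
        )
        truth_loci = pd.read_csv(sim_dir / "truth_loci.tsv", sep="\t")
        log.info("simulate: %d loci, %d conspecific sequences", sim_cfg.n_loci, len(con))

        stage = "tags"
        libs: list[tags.TagLibrary] = []
        for fq in sorted(sim_dir.glob("lane_*.fastq")):
            lane_id = fq.stem.replace("lane_", "")
            lib = tags.process_fastq(
                fq, lane_id=lane_id, species_label=lane_id[0],
                min_quality=config.min_quality,
            )
            lib.write_tsv(out / f"tags_{lane_id}.tsv")
            log.info(
                "tags %s: %d reads in, %d kept, %d unique",
                lane_id, lib.total_reads_in, lib.total_tags, lib.unique_tags,
            )
            libs.append(lib)

        stage = "map"
        ref: ReferenceSet = {"conspecific": con, "heterospecific": het, "contigs": ctg}[
            config.reference
        ]
        index = mapping.TagIndex(ref)
        lanes: list[mapping.LaneCounts] = []
        for lib in libs:
            mm = config.mismatch_e if lib.species_label == "E" else config.mismatch_f
            hits = mapping.map_tags(lib, ref, mm, index=index)
            if config.reference == "contigs":
                lc = mapping.aggregate_contigs(hits, lib, ref)
            else:
                lc = mapping.classify_and_count(hits, lib, ref)
            lanes.append(lc)
            pct = lc.report.percentages()
            log.info(
                "map %s (mm=%d): %.1f%% mapped, %.1f%% ambiguous",
                lib.lane_id, mm, pct["mapped_pct"], pct["ambiguous_pct"],
            )
        summary = mapping.mapping_summary([lc.report for lc in lanes])
        summary.to_csv(out / "mapping_summary.tsv", sep="\t", index=False)
        counts = mapping.counts_matrix(lanes)
        mapping.write_counts_tsv(counts, out / "counts.tsv")

        stage = "detest"
        groups = pd.Series({lc.lane_id: lc.lane_id[0] for lc in lanes})
        de_res, disp = detest.de_analysis(
            counts, groups, labels=["E", "F"],
            m_threshold=config.m_threshold, alpha=config.alpha,
        )
        de_res.to_csv(out / "de_results.tsv", sep="\t")
        n_up_e = int((de_res["call"] == "up_E").sum())
        n_up_f = int((de_res["call"] == "up_F").sum())
        log.info("detest: phi=%.4f, %d up_E, %d up_F", disp.phi, n_up_e, n_up_f)

        stage = "homeolog"
        homeo_res = pd.DataFrame()
        if config.reference == "conspecific":
            spec, shared = mapping.copy_counts_matrix(lanes)
            locus_copies = {
                l: [r.copy_label for r in recs]
                for l, recs in con.loci.items()
                if len(recs) > 1
            }
            records = homeolog.split_copy_counts(lanes, locus_copies)
            analysable = homeolog.filter_analysable_loci(
                records, config.homeolog_min_specific, config.homeolog_fold
            )
            if not spec.empty:
                homeo_res = homeolog.homeolog_de_analysis(
                    spec, groups, analysable,
                    m_threshold=config.m_threshold, alpha=config.alpha,
                )
            homeo_res.to_csv(out / "homeolog_results.tsv", sep="\t")
            log.info("homeolog: %d analysable loci", len(analysable))

        stage = "concord"
        universe_tags = set(de_res.index[de_res["call"] != "not_tested"].astype(str))
        platform = simulate.simulate_platform_lists(
            _truth_from_frame(truth_loci), seed=config.seed
        )
        concord = {}
        for direction in ("up_E", "up_F"):
            tag_list = set(de_res.index[de_res["call"] == direction].astype(str))
            tag_list &= universe_tags
            pair = concordance.DEGListPair(
                tag_list,
                platform["lists_b"][direction] & platform["universe_b"],
                universe_tags,
                platform["universe_b"],
            )
            concord[direction] = concordance.concordance_report(
                pair, reps=config.reps, seed=config.seed
            )
        (out / "concordance.json").write_text(json.dumps(concord, indent=1))

        stage = "enrich"
        annot_map = {}
        for line in (sim_dir / "gene_to_term.tsv").read_text().splitlines()[1:]:
            g, t = line.split("\t")
            annot_map.setdefault(g, set()).add(t)
        background = universe_tags
        annot = enrichment.AnnotationTable(
            {g: ts for g, ts in annot_map.items() if g in background}, background
        )
        up_e = set(de_res.index[de_res["call"] == "up_E"].astype(str)) & background
        term_table = enrichment.enrich_all(up_e, annot)
        term_table.to_csv(out / "enrichment_up_E.tsv", sep="\t", index=False)
        # cluster membership arrives as input; group terms into fives here
        terms = sorted(annot.term_to_genes)
        clusters = {
            f"cluster{i}": terms[i * 5 : (i + 1) * 5]
            for i in range((len(terms) + 4) // 5)
            if terms[i * 5 : (i + 1) * 5]
        }
        term_p = dict(zip(term_table["term"], term_table["p_value"]))
        cluster_table = enrichment.score_clusters(clusters, term_p)
        cluster_table.to_csv(out / "cluster_scores.tsv", sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    stage_counts = {
        "loci_simulated": int(sim_cfg.n_loci),
        "lanes": len(libs),
        "genes_with_counts": int(len(counts)),
        "degs_up_E": n_up_e,
        "degs_up_F": n_up_f,
        "homeolog_rows": int(len(homeo_res)),
    }
    config.to_yaml(out / "run_config.yaml")
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stage_counts": stage_counts,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _truth_from_frame(loci: pd.DataFrame) -> simulate.GroundTruth:
    return simulate.GroundTruth(loci, pd.DataFrame(), {})


def compare_datasets(run_dirs: list[str | Path], direction: str = "up_E") -> pd.DataFrame:
    """Pairwise survey-corrected DEG-overlap percentages across runs.

    Every run must provide ``de_results.tsv``; its surveyed universe is the
    set of tested genes and its DEG list the genes called in ``direction``.
    """
    if len(run_dirs) < 2:
        raise ValueError("need at least two run directories")
    data = []
    for d in run_dirs:
        df = pd.read_csv(Path(d) / "de_results.tsv", sep="\t", index_col=0)
        surveyed = set(df.index[df["call"] != "not_tested"].astype(str))
        deg = set(df.index[df["call"] == direction].astype(str))
        data.append((Path(d).name, deg, surveyed))
    names = [n for n, _, _ in data]
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            if not (data[i][2] & data[j][2]):
                raise ValueError(
                    f"runs {names[i]} and {names[j]} share no surveyed genes"
                )
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, (_, la, ua) in enumerate(data):
        for j, (_, lb, ub) in enumerate(data):
            pair = concordance.DEGListPair(la, lb, ua, ub)
            res = concordance.corrected_overlap(pair)
            mat.iloc[i, j] = res.percentage if res.percentage is not None else float("nan")
    return mat
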