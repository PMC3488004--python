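"""End-to-end orchestration: simulate -> scan -> footprint -> ARE -> stats.

The pipeline runs the whole analysis on synthetic data generated under
the study conditions: a manifest of 14 Early, 18 Middle and 11 Late
genes across four species (a human-like template plus chimp-, mouse- and
cattle-like orthologs at increasing divergence), 50 random background
sequences, and letter-shuffles of every template promoter.  Every stage
writes its artifacts into the run directory and all randomness derives
from one master seed, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import are as are_mod
from . import footprint as fp
from . import io as cio
from . import pwm as pwm_mod
from . import stats as stats_mod
from . import synthetic as syn

logger = logging.getLogger(__name__)

SPECIES = ("human", "chimp", "mouse", "cattle")
# per-site neutral substitution rates emulating increasing divergence
SPECIES_NEUTRAL_RATE = {"chimp": 0.03, "mouse": 0.25, "cattle": 0.30}

# group profiles: planted sites, placement mode, whether sites sit in
# slowly-evolving blocks, and mean planted ARE counts (class I, II, III)
GROUP_PROFILES: dict[str, dict] = {
    "Early": dict(n_sites=6, mode="clustered", conserved=True, are=(8, 3, 10)),
    "Middle_early_like": dict(n_sites=5, mode="clustered", conserved=True,
                              are=(5, 1, 8)),
    "Middle_late_like": dict(n_sites=2, mode="scattered", conserved=False,
                             are=(2, 0, 4)),
    "Late": dict(n_sites=2, mode="scattered", conserved=False, are=(1.5, 0, 2)),
}


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults are the study's stated settings."""

    threshold: float = 0.80
    window: int = 50
    cutoff: float = 0.40
    promoter_length: int = 1000
    n_background: int = 50
    offset_tol: int = 3
    are_min_len: int = 50
    are_u_frac: float = 0.60
    pseudocount: float = 0.8
    n_early: int = 14
    n_middle: int = 18
    n_late: int = 11
    utr_length: int = 4000
    sub_rate_conserved: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if not 0 < self.cutoff <= 1:
            raise ValueError(f"cutoff must be in (0, 1], got {self.cutoff}")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.promoter_length < 100:
            raise ValueError("promoter_length must be >= 100")
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if min(self.n_early, self.n_middle, self.n_late) < 2:
            raise ValueError("each gene group needs >= 2 genes")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data = {**data.get("defaults", {}), **{k: v for k, v in data.items()
                                               if k != "defaults"}}
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class Gene:
    gene_id: str
    group: str  # Early / Middle / Late
    profile: str  # key into GROUP_PROFILES
    promoters: dict[str, str] = field(default_factory=dict)
    truths: dict[str, syn.GroundTruth] = field(default_factory=dict)
    utr: str = ""
    utr_truth: syn.GroundTruth | None = None


def default_manifest(config: PipelineConfig) -> list[tuple[str, str, str]]:
    """(gene_id, group, profile) records; Middle genes split evenly into
    early-like and late-like profiles."""
    records = []
    for i in range(config.n_early):
        records.append((f"Early_{i + 1:02d}", "Early", "Early"))
    for i in range(config.n_middle):
        profile = ("Middle_early_like" if i < config.n_middle // 2
                   else "Middle_late_like")
        records.append((f"Middle_{i + 1:02d}", "Middle", profile))
    for i in range(config.n_late):
        records.append((f"Late_{i + 1:02d}", "Late", "Late"))
    return records


def simulate_genes(config: PipelineConfig,
                   pwms: list[pwm_mod.PWM]) -> list[Gene]:
    """Generate per-gene promoters (all species) and 3'UTRs."""
    master = np.random.default_rng(config.seed)
    genes = []
    for gene_id, group, profile in default_manifest(config):
        prof = GROUP_PROFILES[profile]
        gene = Gene(gene_id=gene_id, group=group, profile=profile)
        pspec = syn.PromoterSpec(
            length=config.promoter_length,
            n_planted_sites=prof["n_sites"],
            clustering_mode=prof["mode"],
            seed=int(master.integers(2**31)),
        )
        seq, truth = syn.generate_promoter(pspec, pwms)
        gene.promoters["human"] = seq
        gene.truths["human"] = truth
        blocks = tuple(pwm_mod.merge_loci(
            (max(0, s - 20), min(len(seq), e + 20))
            for _, s, e, _ in truth.planted_tfbs))
        for species, neutral in SPECIES_NEUTRAL_RATE.items():
            conserved_rate = (config.sub_rate_conserved if prof["conserved"]
                              else neutral)
            ospec = syn.OrthologSpec(
                sub_rate_neutral=neutral,
                sub_rate_conserved=min(conserved_rate, neutral),
                indel_rate=0.0,
                conserved_blocks=blocks,
                seed=int(master.integers(2**31)),
            )
            ortho, coord_map = syn.evolve_ortholog(seq, truth, ospec)
            gene.promoters[species] = ortho
            # planted sites carried over through the coordinate map
            otruth = syn.GroundTruth()
            for pwm_id, s, e, strand in truth.planted_tfbs:
                ns = int(coord_map[s])
                if ns >= 0:
                    otruth.planted_tfbs.append((pwm_id, ns, ns + (e - s), strand))
            gene.truths[species] = otruth
        lam1, lam2, lam3 = prof["are"]
        # Poisson counts truncated at twice the mean so every draw fits
        uspec = syn.UTRSpec(
            length=config.utr_length,
            n_class1=min(int(master.poisson(lam1)), int(2 * lam1)),
            n_class2=min(int(master.poisson(lam2)), max(int(2 * lam2), 1)),
            n_class3=min(int(master.poisson(lam3)), int(2 * lam3)),
            seed=int(master.integers(2**31)),
        )
        gene.utr, gene.utr_truth = syn.generate_utr(uspec)
        genes.append(gene)
    return genes


def make_table3_report(summaries: list[pwm_mod.GroupSummary],
                       family_order: list[str]) -> pd.DataFrame:
    """Per-group family totals and the per-sequence average, shaped like
    a participation table (one row per group, one column per family)."""
    if not summaries:
        raise ValueError("no group summaries")
    rows = []
    for s in summaries:
        row = {"group": s.group}
        for fam in family_order:
            row[fam] = s.per_family_totals.get(fam, 0)
        row["n_sequences"] = s.n_sequences
        row["avg_per_sequence"] = s.avg_per_sequence
        rows.append(row)
    return pd.DataFrame(rows)


def _footprint_gene(
    gene: Gene,
    hits: dict[str, list[pwm_mod.MotifHit]],
    config: PipelineConfig,
    species_pairs: list[tuple[str, str]],
) -> dict[tuple[str, str], list[fp.ConservedHitPair]]:
    """Conserved hit pairs for the requested ordered species pairs."""
    aln_cache: dict[frozenset, fp.PairwiseAlignment] = {}
    results = {}
    for a, b in species_pairs:
        key = frozenset((a, b))
        if key not in aln_cache:
            aln_cache[key] = fp.align_pair(gene.promoters[a], gene.promoters[b],
                                           seq_id_a=a, seq_id_b=b)
        aln = aln_cache[key]
        if aln.seq_id_a == a:
            aln_ab = aln
        else:  # reuse the alignment with roles swapped
            aln_ab = fp.PairwiseAlignment(
                seq_id_a=a, seq_id_b=b, gapped_a=aln.gapped_b,
                gapped_b=aln.gapped_a, score=aln.score,
            )
        profile = fp.conservation_profile(aln_ab, window=config.window)
        regions = fp.conserved_regions(profile, cutoff=config.cutoff)
        results[(a, b)] = fp.conserved_hits(
            hits[a], hits[b], aln_ab, regions, offset_tol=config.offset_tol
        )
    return results


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 pwms: list[pwm_mod.PWM] | None = None) -> dict:
    """Execute every stage and write all artifacts into ``outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if pwms is None:
        pwms = pwm_mod.bundled_nfkb_pwms()
    family_order = [p.id for p in pwms]
    chash = config.config_hash()
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config)))

    # --- stage 1: simulate -------------------------------------------------
    logger.info("stage simulate: generating %d genes",
                config.n_early + config.n_middle + config.n_late)
    genes = simulate_genes(config, pwms)
    rng = np.random.default_rng(config.seed + 1)
    backgrounds = syn.generate_background(
        config.n_background, config.promoter_length,
        seed=int(rng.integers(2**31)))
    shuffled = {g.gene_id: syn.shuffle_sequence(g.promoters["human"],
                                                seed=int(rng.integers(2**31)))
                for g in genes}
    cio.write_fasta({f"{g.gene_id}|{sp}": s for g in genes
                     for sp, s in g.promoters.items()},
                    outdir / "promoters.fa")
    cio.write_fasta({g.gene_id: g.utr for g in genes}, outdir / "utrs.fa")
    cio.write_fasta({f"bg_{i + 1:02d}": s for i, s in enumerate(backgrounds)},
                    outdir / "backgrounds.fa")
    cio.write_fasta(shuffled, outdir / "shuffled.fa")
    cio.write_ground_truth(
        {**{g.gene_id: g.truths["human"] for g in genes},
         **{f"{g.gene_id}|utr": g.utr_truth for g in genes}},
        outdir / "ground_truth.bed")
    manifest = pd.DataFrame(
        [(g.gene_id, g.group, g.profile) for g in genes],
        columns=["gene_id", "group", "profile"])
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    # --- stage 2: scan -----------------------------------------------------
    logger.info("stage scan: threshold %.2f", config.threshold)

    def _scan(seq: str, seq_id: str) -> list[pwm_mod.MotifHit]:
        return pwm_mod.scan_sequence(seq, pwms, threshold=config.threshold,
                                     seq_id=seq_id,
                                     pseudocount=config.pseudocount)

    gene_hits: dict[str, dict[str, list[pwm_mod.MotifHit]]] = {}
    scan_reports: dict[str, pwm_mod.ScanReport] = {}
    all_hits: list[pwm_mod.MotifHit] = []
    for g in genes:
        gene_hits[g.gene_id] = {}
        for sp, seq in g.promoters.items():
            hits = _scan(seq, f"{g.gene_id}|{sp}")
            gene_hits[g.gene_id][sp] = hits
            all_hits.extend(hits)
        scan_reports[g.gene_id] = pwm_mod.summarize_hits(
            gene_hits[g.gene_id]["human"], pwms, seq_id=g.gene_id)
    bg_reports = [pwm_mod.summarize_hits(_scan(s, f"bg_{i + 1:02d}"), pwms)
                  for i, s in enumerate(backgrounds)]
    sh_reports = [pwm_mod.summarize_hits(_scan(s, gid), pwms)
                  for gid, s in shuffled.items()]
    cio.write_hits_bed(all_hits, outdir / "hits.bed")
    cio.scan_reports_frame(list(scan_reports.values())).to_csv(
        outdir / "scan_reports.tsv", sep="\t", index=False)

    # --- stage 3: participation table + abundance tests --------------------
    group_of = {g.gene_id: g.group for g in genes}
    gene_reports = [scan_reports[g.gene_id] for g in genes]
    summaries = pwm_mod.aggregate_group(
        gene_reports, [g.group for g in genes])
    summaries += pwm_mod.aggregate_group(gene_reports, ["dataset"] * len(genes))
    summaries += pwm_mod.aggregate_group(bg_reports, ["random"] * len(bg_reports))
    summaries += pwm_mod.aggregate_group(sh_reports, ["shuffled"] * len(sh_reports))
    table3 = make_table3_report(summaries, family_order)
    with open(outdir / "table_participation.tsv", "w") as fh:
        fh.write(f"# config {chash}\n")
        table3.to_csv(fh, sep="\t", index=False)

    bg_distinct = [r.distinct_total for r in bg_reports]
    abundance_tests = {}
    for grp in ("Early", "Middle", "Late"):
        counts = [scan_reports[g.gene_id].distinct_total for g in genes
                  if g.group == grp]
        res = stats_mod.wilcoxon_rank_sum(counts, bg_distinct)
        abundance_tests[grp] = {"statistic": res.statistic,
                                "p_value": res.p_value,
                                "n": list(res.n_per_group)}
    (outdir / "abundance_tests.json").write_text(
        json.dumps(abundance_tests, indent=2))

    # --- stage 4: footprint ------------------------------------------------
    logger.info("stage footprint: window %d cutoff %.2f",
                config.window, config.cutoff)
    ordered_pairs_human = [("human", sp) for sp in SPECIES if sp != "human"]
    conserved_frac_rows = []
    for g in genes:
        res = _footprint_gene(g, gene_hits[g.gene_id], config,
                              ordered_pairs_human)
        n_human = len(gene_hits[g.gene_id]["human"])
        for (a, b), pairs in res.items():
            frac = 100.0 * len(pairs) / n_human if n_human else np.nan
            conserved_frac_rows.append(
                {"gene_id": g.gene_id, "group": g.group, "template": a,
                 "other": b, "n_template_hits": n_human,
                 "n_conserved": len(pairs), "pct_conserved": frac})
    cons_df = pd.DataFrame(conserved_frac_rows)
    cons_df.to_csv(outdir / "conserved_fractions.tsv", sep="\t", index=False)

    # full ordered-pair matrices for one representative Early and Late gene
    all_ordered = [(a, b) for a in SPECIES for b in SPECIES if a != b]
    for rep_gene in (genes[0], genes[-1]):
        res = _footprint_gene(rep_gene, gene_hits[rep_gene.gene_id], config,
                              all_ordered)
        mat = fp.conservation_matrix(gene_hits[rep_gene.gene_id], res)
        mat.to_csv(outdir / f"conservation_matrix_{rep_gene.gene_id}.tsv",
                   sep="\t")

    # --- stage 5: ARE ------------------------------------------------------
    are_reports = {
        g.gene_id: are_mod.are_report(g.utr, seq_id=g.gene_id,
                                      min_len=config.are_min_len,
                                      u_frac=config.are_u_frac)
        for g in genes
    }
    are_df = cio.are_reports_frame(list(are_reports.values()), group_of)
    are_df.to_csv(outdir / "are_reports.tsv", sep="\t", index=False)

    are_anova = {}
    for cls, attr in (("I", "count_class1"), ("II", "count_class2"),
                      ("III", "count_class3")):
        grouped = [
            [getattr(are_reports[g.gene_id], attr) for g in genes
             if g.group == grp]
            for grp in ("Early", "Middle", "Late")
        ]
        try:
            res = stats_mod.anova_oneway(grouped)
            are_anova[cls] = {"F": res.statistic, "p_value": res.p_value,
                              "group_means": list(res.group_means),
                              "ci_half_widths": list(res.ci_half_widths)}
        except ValueError as exc:
            are_anova[cls] = {"error": str(exc)}
    (outdir / "are_anova.json").write_text(json.dumps(are_anova, indent=2))

    # --- stage 6: clustering -----------------------------------------------
    features = stats_mod.build_features(
        scan_reports, are_reports, [(g.gene_id, g.group) for g in genes])
    dmat = stats_mod.feature_distance_matrix(features,
                                             metric="percent_disagreement")
    dendro = stats_mod.upgma(dmat, [f.gene_id for f in features])
    assignment = stats_mod.cut_clusters(dendro, k=4)
    (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    cluster_df = pd.DataFrame({
        "gene_id": [f.gene_id for f in features],
        "group": [f.group for f in features],
        "cluster": assignment,
    })
    cluster_df.to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    middle = [f for f in features if f.group == "Middle"]
    dmid = stats_mod.feature_distance_matrix(middle, metric="euclidean")
    mid_dendro = stats_mod.upgma(dmid, [f.gene_id for f in middle])
    mid_dendro.metric = "euclidean"
    mid_assign = stats_mod.cut_clusters(mid_dendro, k=min(3, len(middle)))
    (outdir / "middle_dendrogram.nwk").write_text(mid_dendro.to_newick() + "\n")

    # --- summary -----------------------------------------------------------
    dataset_summary = next(s for s in summaries if s.group == "dataset")
    random_summary = next(s for s in summaries if s.group == "random")
    by_group_pct = cons_df.groupby("group")["pct_conserved"].mean()
    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_genes": len(genes),
        "avg_distinct_per_gene": dataset_summary.avg_per_sequence,
        "avg_distinct_per_background": random_summary.avg_per_sequence,
        "abundance_p_values": {k: v["p_value"]
                               for k, v in abundance_tests.items()},
        "are_anova_p_values": {k: v.get("p_value")
                               for k, v in are_anova.items()},
        "mean_pct_conserved_by_group": {k: float(v)
                                        for k, v in by_group_pct.items()},
        "cluster_sizes": np.bincount(assignment, minlength=4).tolist(),
        "middle_cluster_sizes": np.bincount(mid_assign,
                                            minlength=3).tolist(),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
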