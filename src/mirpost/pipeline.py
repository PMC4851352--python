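"""Stage orchestration: discover → cluster → quantify → refgenes → diffexpr.

Each stage is a function reading and writing conventional file names inside
a working directory, so stages can be run standalone (the CLI exposes one
subcommand per stage) or chained with :func:`run_pipeline`.  Every decision
that removes or flags a record — a rejection, a tissue promotion, a
significance call — is written to the run log together with the rule that
triggered it.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from mirpost import io as mio
from mirpost.clusters import cluster_membership, detect_clusters
from mirpost.config import PipelineConfig
from mirpost.discovery import ClassificationConfig, classify_candidates, collapse_unique_matures
from mirpost.qpcr import analyze_differential_expression, bonferroni_alpha, delta_ct
from mirpost.quantify import (
    compute_rsd,
    count_perfect_matches,
    normalize_counts,
    screen_enriched_candidates,
    screen_reference_candidates,
)
from mirpost.stability import linearize_ct, normfinder_stability

log = logging.getLogger("mirpost")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _setup_logging(workdir: Path) -> None:
    if any(
        isinstance(h, logging.FileHandler)
        and Path(h.baseFilename) == workdir / "pipeline.log"
        for h in log.handlers
    ):
        return
    handler = logging.FileHandler(workdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(levelname)s\t%(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)


def stage_discover(workdir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Classify candidates; write ``classification.tsv`` and ``genes.gff3``."""
    workdir = Path(workdir)
    _setup_logging(workdir)
    candidates = mio.read_candidates(workdir)
    hits = mio.read_blast_tab(workdir / "blast.tsv")
    genes = classify_candidates(
        candidates,
        hits,
        ClassificationConfig(
            score_cutoff=config.score_cutoff,
            evalue=config.evalue,
            max_loci=config.max_loci,
            min_samples=config.min_samples,
            min_arm_reads=config.min_arm_reads,
            consistency_frac=config.consistency_frac,
        ),
    )
    for g in genes:
        if g.status == "rejected":
            log.info("discover\trejected\t%s\t%s", g.gene_id, g.rejection_reason)
        else:
            log.info("discover\taccepted\t%s\t%s", g.gene_id, g.status)
    report = mio.classification_report(genes)
    report.to_csv(workdir / "classification.tsv", sep="\t", index=False)
    mio.write_gff3(workdir / "genes.gff3", genes)

    accepted = [g for g in genes if g.status != "rejected"]
    uniques = collapse_unique_matures(accepted)
    pd.DataFrame(
        [
            {"mature_seq": seq, "n_genes": len(members),
             "members": ",".join(f"{gid}-{arm}" for gid, arm in members)}
            for seq, members in uniques.items()
        ]
    ).to_csv(workdir / "unique_matures.tsv", sep="\t", index=False)
    log.info(
        "discover\tsummary\t%d candidates -> %d conserved, %d novel, %d rejected; "
        "%d unique matures",
        len(genes),
        sum(g.status == "conserved" for g in genes),
        sum(g.status == "novel" for g in genes),
        sum(g.status == "rejected" for g in genes),
        len(uniques),
    )
    return report


def stage_cluster(workdir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Detect gene clusters among accepted genes; write cluster reports."""
    workdir = Path(workdir)
    _setup_logging(workdir)
    status = pd.read_csv(workdir / "classification.tsv", sep="\t", index_col=0)["status"]
    loci = [
        locus
        for locus in mio.gff3_to_loci(workdir / "genes.gff3")
        if status.get(locus.gene_id) != "rejected"
    ]
    clusters = detect_clusters(loci, max_gap=config.max_gap, gap_mode=config.gap_mode)
    for c in clusters:
        log.info("cluster\t%s\t%d genes\t%s", c.cluster_id, len(c), ",".join(c.member_ids))
    report = mio.cluster_report(clusters)
    report.to_csv(workdir / "clusters.tsv", sep="\t", index=False)
    membership = cluster_membership(clusters)
    pd.DataFrame(
        {"gene_id": list(membership), "cluster_id": list(membership.values())}
    ).to_csv(workdir / "cluster_membership.tsv", sep="\t", index=False)
    return report


def stage_quantify(workdir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Count, normalise and screen; write count/normalised/RSD tables."""
    workdir = Path(workdir)
    _setup_logging(workdir)
    reads = mio.read_reads(workdir / "reads.tsv")
    matures = pd.read_csv(workdir / "unique_matures.tsv", sep="\t")["mature_seq"].tolist()
    cm = count_perfect_matches(reads, matures, min_len=config.min_read_len)
    nm = normalize_counts(cm)
    rsd = compute_rsd(nm)
    mio.write_tsv_matrix(workdir / "counts.tsv", cm, "mature_seq")
    mio.write_tsv_matrix(workdir / "normalized.tsv", nm, "mature_seq")
    rsd.rename("rsd").to_frame().to_csv(workdir / "rsd.tsv", sep="\t", index_label="mature_seq")

    tissue_map_path = workdir / "tissue_map_seq.tsv"
    if tissue_map_path.exists():
        tissue_of_sample = mio.read_tissue_map(tissue_map_path)
        enriched = screen_enriched_candidates(
            nm, tissue_of_sample, totals=cm.sum(axis=0)
        )
        enriched.to_csv(workdir / "enriched_candidates.tsv", sep="\t", index_label="mature_seq")
        log.info("quantify\tenriched screen\t%d candidates", len(enriched))
    refs = screen_reference_candidates(rsd, k=5)
    pd.DataFrame({"mature_seq": refs}).to_csv(
        workdir / "reference_candidates.tsv", sep="\t", index=False
    )
    log.info("quantify\t%d matures counted; %d reference candidates", len(cm), len(refs))
    return nm


def stage_refgenes(workdir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """NormFinder-style stability ranking of the candidate reference genes.

    Reads ``ct_refs.tsv`` (candidate genes × samples) and the qPCR tissue
    map; writes per-gene stability values plus the best single gene and the
    best two-gene combination.
    """
    workdir = Path(workdir)
    _setup_logging(workdir)
    ct = mio.read_tsv_matrix(workdir / "ct_refs.tsv")
    groups = mio.read_tissue_map(workdir / "tissue_map_qpcr.tsv")
    result = normfinder_stability(linearize_ct(ct), groups)
    table = result.stability.rename("stability").to_frame()
    table["rank"] = table["stability"].rank(method="first").astype(int)
    table.sort_values("rank").to_csv(workdir / "stability.tsv", sep="\t", index_label="gene_id")
    summary = pd.DataFrame(
        [
            {"item": "best_single", "value": result.best_single,
             "stability": result.stability[result.best_single]},
            {"item": "best_pair", "value": "+".join(result.best_pair),
             "stability": result.pair_stability},
        ]
    )
    summary.to_csv(workdir / "stability_summary.tsv", sep="\t", index=False)
    log.info(
        "refgenes\tbest single %s (%.4f); best pair %s (%.4f)",
        result.best_single,
        result.stability[result.best_single],
        "+".join(result.best_pair),
        result.pair_stability,
    )
    return table


def stage_diffexpr(workdir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """ΔCt / ΔΔCt differential expression of the assayed miRNAs.

    Reads ``ct.tsv`` (all assayed genes × samples), the qPCR tissue map,
    ``de_targets.tsv`` (miRNA id → comma-separated initial target tissues)
    and the reference genes chosen by the refgenes stage.  The study design
    is mirrored per miRNA: all individuals from the target tissues, the
    first ``n_reference_individuals`` from each reference tissue.
    """
    workdir = Path(workdir)
    _setup_logging(workdir)
    ct = mio.read_tsv_matrix(workdir / "ct.tsv")
    tissue_of_sample = mio.read_tissue_map(workdir / "tissue_map_qpcr.tsv")
    targets_df = pd.read_csv(workdir / "de_targets.tsv", sep="\t", dtype=str)
    summary = pd.read_csv(workdir / "stability_summary.tsv", sep="\t")
    ref_genes = summary.loc[summary["item"] == "best_pair", "value"].iloc[0].split("+")
    missing = [g for g in ref_genes if g not in ct.index]
    if missing:
        raise StageError("diffexpr", KeyError(f"reference gene(s) not in ct.tsv: {missing}"))

    n_tests = config.n_tests or len(targets_df)
    threshold = bonferroni_alpha(config.alpha, n_tests)
    rows = []
    for row in targets_df.itertuples(index=False):
        mirna = row.mirna_id
        initial = set(str(row.initial_target).split(","))
        if mirna not in ct.index:
            log.warning("diffexpr\tskipped\t%s\tnot in ct.tsv", mirna)
            continue
        samples = _design_samples(ct.columns, tissue_of_sample, initial, config)
        dct = delta_ct(ct.loc[mirna, samples], ct.loc[ref_genes, samples])
        try:
            res = analyze_differential_expression(
                dct,
                tissue_of_sample,
                initial,
                mirna_id=mirna,
                alpha=config.alpha,
                n_tests=n_tests,
                promotion_rule=config.promotion_rule,
            )
        except ValueError as exc:
            log.warning("diffexpr\tuntestable\t%s\t%s", mirna, exc)
            continue
        promoted = res.target_tissues - initial
        if promoted:
            log.info("diffexpr\tpromoted\t%s\t%s", mirna, ",".join(sorted(promoted)))
        log.info(
            "diffexpr\t%s\tfold=%.2f\tp=%.3g\t%s (threshold %.2g)",
            mirna, res.fold, res.p,
            "significant" if res.significant else "not significant", threshold,
        )
        rows.append(
            {
                "mirna_id": mirna,
                "target_tissues": ",".join(sorted(res.target_tissues)),
                "n_target": res.n_target,
                "n_reference": res.n_reference,
                "ddct": res.ddct,
                "fold": res.fold,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "significant": res.significant,
            }
        )
    report = pd.DataFrame(rows)
    report.to_csv(workdir / "de_report.tsv", sep="\t", index=False)
    return report


def _design_samples(
    all_samples, tissue_of_sample, target_tissues: set[str], config: PipelineConfig
) -> list[str]:
    """All target-tissue samples plus n individuals per reference tissue."""
    per_tissue: dict[str, int] = {}
    chosen = []
    for s in all_samples:
        t = tissue_of_sample[s]
        if t in target_tissues:
            chosen.append(s)
        else:
            per_tissue[t] = per_tissue.get(t, 0) + 1
            if per_tissue[t] <= config.n_reference_individuals:
                chosen.append(s)
    return chosen


_STAGES = {
    "discover": stage_discover,
    "cluster": stage_cluster,
    "quantify": stage_quantify,
    "refgenes": stage_refgenes,
    "diffexpr": stage_diffexpr,
}


def run_pipeline(workdir: str | Path, config: Optional[PipelineConfig] = None) -> dict:
    """Run every stage in order on a prepared working directory."""
    config = config or PipelineConfig()
    outputs = {}
    for name, stage in _STAGES.items():
        try:
            outputs[name] = stage(workdir, config)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc
    return outputs
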