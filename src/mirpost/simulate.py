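"""Seeded synthetic data with the structure the analysis assumes.

The generator emulates the study design the pipeline targets: eight
deep-sequenced samples from different tissues of one individual, and an
RT-qPCR panel of nine tissues × eight individuals.  Three generators cover
the three input kinds:

* :func:`simulate_candidates` — candidate precursors with planted truth
  (conserved / novel / one specific rejection reason each), read stacks
  with controllable 5'-end consistency and arm coverage, and the matching
  BLAST hit tables;
* :func:`simulate_counts` — a mature-miRNA × sample count matrix from a
  negative-binomial model with planted tissue-enrichment folds and library
  sizes varying at least five-fold;
* :func:`simulate_ct` — Ct matrices with per-gene intra-group (individual)
  and inter-group (tissue) variance components and planted expression
  shifts, Gaussian on the cycle scale.

Everything is driven by a single integer seed: the same seed yields
byte-identical outputs.  Truth labels are returned alongside each dataset
so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from mirpost.discovery import BlastHit, CandidateRecord, ReadStack

#: Tissues of the eight deep-sequenced samples (one individual).
DEEPSEQ_TISSUES = (
    "head_kidney",
    "brain",
    "gills",
    "muscle",
    "liver",
    "spleen",
    "skin",
    "intestine",
)

#: Tissues of the 9-tissue × 8-individual qPCR design.
QPCR_TISSUES = DEEPSEQ_TISSUES + ("heart",)

_ALPHABET = np.array(list("ACGU"))

#: Planted candidate classes and their default counts (50 candidates total).
DEFAULT_CANDIDATE_CLASSES: dict[str, int] = {
    "conserved": 20,
    "novel": 10,
    "low_score": 5,
    "other_smallrna": 5,
    "repeat": 5,
    "insufficient_samples": 2,
    "insufficient_arm_reads": 2,
    "inconsistent_5p_end": 1,
}


@dataclass
class CtGeneSpec:
    """Variance components and planted effects for one simulated qPCR gene.

    ``tissue_sd`` is the inter-group spread (cycles) of random tissue
    effects; ``noise_sd`` the intra-group (between-individual) spread;
    ``target_shift`` lowers the Ct (raises expression) by that many cycles
    in ``target_tissues``.
    """

    gene_id: str
    baseline: float = 25.0
    tissue_sd: float = 0.0
    noise_sd: float = 0.5
    target_tissues: frozenset[str] = frozenset()
    target_shift: float = 0.0
    reference_candidate: bool = False


def _default_ct_panel() -> list[CtGeneSpec]:
    """Four reference-gene candidates of graded stability plus DE miRNAs.

    The DE genes carry a 5-cycle (≈32-fold) expression shift in one or two
    target tissues on top of σ = 0.5 cycles of individual noise, matching
    the magnitude of tissue enrichment the qPCR stage is meant to detect;
    ``null-*`` genes have no tissue effect at all.
    """
    refs = [
        CtGeneSpec("ref-a", 22.0, tissue_sd=0.05, noise_sd=0.15, reference_candidate=True),
        CtGeneSpec("ref-b", 24.0, tissue_sd=0.15, noise_sd=0.30, reference_candidate=True),
        CtGeneSpec("ref-c", 23.0, tissue_sd=0.40, noise_sd=0.40, reference_candidate=True),
        CtGeneSpec("ref-d", 25.0, tissue_sd=0.80, noise_sd=0.60, reference_candidate=True),
    ]
    de = [
        CtGeneSpec(
            f"de-{i:02d}",
            baseline=28.0,
            tissue_sd=0.2,
            noise_sd=0.5,
            target_tissues=frozenset({QPCR_TISSUES[i % len(QPCR_TISSUES)]}),
            target_shift=5.0,
        )
        for i in range(6)
    ]
    nulls = [
        CtGeneSpec(f"null-{i:02d}", baseline=27.0, tissue_sd=0.0, noise_sd=0.5)
        for i in range(4)
    ]
    return refs + de + nulls


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Defaults mirror the emulated design: 8 deep-sequencing samples, 9
    tissues × 8 individuals for qPCR, 50 candidate precursors with planted
    classes, negative-binomial counts with 5–25-fold library-size spread.
    """

    seed: int = 0
    n_samples: int = 8
    n_tissues: int = 9
    n_individuals: int = 8
    candidate_classes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CANDIDATE_CLASSES)
    )
    score_cutoff: float = 4.0
    n_family_pairs: int = 2
    n_cluster_pairs: int = 4
    # count simulation
    n_count_genes: int = 60
    n_enriched_genes: int = 12
    enrichment_fold: float = 8.0
    n_strong_enriched: int = 3
    strong_fold: float = 100.0
    base_mean: float = 200.0
    nb_dispersion: float = 5.0
    library_size_range: tuple[float, float] = (0.2, 5.0)
    # Ct simulation
    ct_genes: list[CtGeneSpec] = field(default_factory=_default_ct_panel)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if any(n < 0 for n in self.candidate_classes.values()):
            raise ValueError("candidate class counts must be non-negative")
        if self.enrichment_fold <= 0 or self.strong_fold <= 0:
            raise ValueError("enrichment folds must be positive")
        if any(g.noise_sd < 0 or g.tissue_sd < 0 for g in self.ct_genes):
            raise ValueError("variance components must be non-negative")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def _make_precursor(
    rng: np.random.Generator, mature5p: Optional[str] = None
) -> tuple[str, str, str, int, int]:
    """Random hairpin-like record: (precursor, mature5p, mature3p, off5p, off3p)."""
    m5 = mature5p or _random_seq(rng, 22)
    m3 = _random_seq(rng, 22)
    head = _random_seq(rng, 11)
    loop = _random_seq(rng, 8)
    tail = _random_seq(rng, 9)
    precursor = head + m5 + loop + m3 + tail
    return precursor, m5, m3, len(head), len(head) + len(m5) + len(loop)


def _good_stacks(
    rng: np.random.Generator,
    samples: Sequence[str],
    off5p: int,
    off3p: int,
    n_samples_expressed: int,
    dominant_5p: bool,
) -> list[ReadStack]:
    """Read stacks passing every novel-validation rule.

    >5 pooled reads per arm, ≥2 samples, modal 5' start carrying ≥95% of
    each arm's reads (a single off-by-one stack of 1 read is added on the
    dominant arm when counts allow).
    """
    chosen = list(rng.choice(samples, size=n_samples_expressed, replace=False))
    stacks: list[ReadStack] = []
    hi, lo = (30, 10) if dominant_5p else (10, 30)
    for sample in chosen:
        c5 = int(rng.integers(hi, hi * 3))
        c3 = int(rng.integers(lo, lo * 3))
        stacks.append(ReadStack(sample, "5p", off5p, 22, c5))
        stacks.append(ReadStack(sample, "3p", off3p, 22, c3))
    # rare off-by-one processing on the dominant arm, well under 5% of reads
    arm, off = ("5p", off5p) if dominant_5p else ("3p", off3p)
    stacks.append(ReadStack(chosen[0], arm, off + 1, 21, 1))
    return stacks


def simulate_candidates(
    cfg: SimConfig,
) -> tuple[list[CandidateRecord], list[BlastHit], pd.DataFrame]:
    """Generate candidate precursors, their BLAST hits and truth labels.

    Every candidate of a negative class violates exactly one classification
    rule; conserved candidates carry one significant stem-loop hit (and the
    annotation recorded in the truth table), novel candidates carry none
    but pass all read-evidence rules.  Conserved genes include
    ``n_family_pairs`` pairs sharing an identical 5p mature (gene families)
    and ``n_cluster_pairs`` pairs placed < 10 kb apart on a shared contig
    and strand (gene clusters).

    Returns ``(candidates, hits, truth)`` where ``truth`` has one row per
    candidate: ``status`` (conserved/novel/rejected), ``reason`` and
    ``family`` columns.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [f"sample{i + 1}" for i in range(cfg.n_samples)]
    candidates: list[CandidateRecord] = []
    hits: list[BlastHit] = []
    truth_rows: list[dict] = []

    classes: list[str] = []
    for cls, n in cfg.candidate_classes.items():
        classes.extend([cls] * n)

    # Genomic placement: clustered conserved pairs share a contig.
    n_conserved = cfg.candidate_classes.get("conserved", 0)
    cluster_pairs = min(cfg.n_cluster_pairs, n_conserved // 2)
    family_pairs = min(cfg.n_family_pairs, n_conserved // 2)
    conserved_seen = 0
    shared_m5: dict[int, str] = {}

    for i, cls in enumerate(classes):
        cid = f"cand-{i + 1:03d}"
        family_of = None
        mature5p = None
        if cls == "conserved":
            pair_idx = conserved_seen // 2
            if conserved_seen % 2 == 1 and pair_idx < family_pairs:
                mature5p = shared_m5.get(pair_idx)
        precursor, m5, m3, off5p, off3p = _make_precursor(rng, mature5p)
        if cls == "conserved" and conserved_seen % 2 == 0:
            shared_m5[conserved_seen // 2] = m5

        # location: clustered conserved pairs sit 2-8 kb apart, same strand
        if cls == "conserved" and (conserved_seen // 2) < cluster_pairs:
            contig = f"ctg{1 + conserved_seen // 2:04d}"
            strand = "+"
            start = 1000 if conserved_seen % 2 == 0 else int(rng.integers(3000, 9000))
        else:
            contig = f"ctg{100 + i:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(1_000, 500_000))
        end = start + len(precursor) - 1

        score = (
            float(rng.uniform(0.0, cfg.score_cutoff - 0.5))
            if cls == "low_score"
            else float(rng.uniform(cfg.score_cutoff + 1.0, cfg.score_cutoff + 50.0))
        )

        dominant_5p = bool(rng.random() < 0.7)
        if cls == "insufficient_samples":
            stacks = [
                s
                for s in _good_stacks(rng, samples, off5p, off3p, 2, dominant_5p)
                if s.sample_id == samples[0]
            ] or [
                ReadStack(samples[0], "5p", off5p, 22, 20),
                ReadStack(samples[0], "3p", off3p, 22, 20),
            ]
        elif cls == "insufficient_arm_reads":
            stacks = [
                ReadStack(samples[0], "5p", off5p, 22, 10),
                ReadStack(samples[1], "5p", off5p, 22, 10),
                ReadStack(samples[0], "3p", off3p, 22, 2),
                ReadStack(samples[1], "3p", off3p, 22, 3),  # 3p pooled = 5, not > 5
            ]
        elif cls == "inconsistent_5p_end":
            stacks = [
                ReadStack(samples[0], "5p", off5p, 22, 10),
                ReadStack(samples[0], "5p", off5p + 3, 20, 10),  # 50/50 split
                ReadStack(samples[1], "3p", off3p, 22, 12),
                ReadStack(samples[1], "5p", off5p, 22, 2),
            ]
        else:
            n_expr = int(rng.integers(2, min(5, cfg.n_samples) + 1))
            stacks = _good_stacks(rng, samples, off5p, off3p, n_expr, dominant_5p)

        candidates.append(
            CandidateRecord(
                candidate_id=cid,
                precursor_seq=precursor,
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                score=score,
                mature5p_seq=m5,
                mature3p_seq=m3,
                stacks=tuple(stacks),
            )
        )

        # BLAST evidence
        family = None
        if cls == "conserved":
            family = f"mir-{10 + conserved_seen // 2}"  # family pairs share a name
            hits.append(
                BlastHit(cid, family, "mirbase", float(10.0 ** -rng.integers(8, 20)), 120.0)
            )
            conserved_seen += 1
        elif rng.random() < 0.3:
            # occasional weak, non-significant stem-loop hit
            hits.append(BlastHit(cid, "mir-9999", "mirbase", 1e-3, 28.0))
        if cls == "other_smallrna":
            hits.append(BlastHit(cid, f"RF{rng.integers(1, 3000):05d}", "rfam", 1e-9, 95.0))
        # genome self-hit for everyone
        hits.append(
            BlastHit(cid, contig, "genome", 1e-30, 150.0, (contig, start, end, strand))
        )
        if cls == "repeat":
            n_loci = int(rng.integers(6, 60))
            for j in range(n_loci):
                c = f"rep{j:03d}"
                s = int(rng.integers(1_000, 900_000))
                hits.append(
                    BlastHit(cid, c, "genome", 1e-12, 110.0, (c, s, s + 70, "+"))
                )

        status = cls if cls in ("conserved", "novel") else "rejected"
        reason = None if status != "rejected" else cls
        truth_rows.append(
            {"candidate_id": cid, "status": status, "reason": reason, "family": family}
        )

    truth = pd.DataFrame(truth_rows).set_index("candidate_id")
    return candidates, hits, truth


@dataclass
class CountSim:
    """Synthetic count dataset: matrix, design, sequences and truth."""

    counts: pd.DataFrame  # matures × samples, integer
    tissue_of_sample: dict[str, str]
    mature_seqs: dict[str, str]
    truth: pd.DataFrame  # per gene: enrichment fold + target tissue


def simulate_counts(
    cfg: SimConfig,
    mature_ids: Optional[Sequence[str]] = None,
    mature_seqs: Optional[Mapping[str, str]] = None,
) -> CountSim:
    """Negative-binomial count matrix with planted tissue enrichment.

    Each of the 8 samples is one tissue of one individual.  Library-size
    factors span the configured range (≥5-fold by default); a subset of
    genes carries an ``enrichment_fold`` (default 8×) or ``strong_fold``
    (default 100×) elevated mean in one randomly chosen tissue.  Baseline
    means are log-uniform over roughly two decades so the matrix shows the
    strong count heterogeneity typical of small-RNA libraries.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if mature_ids is None:
        mature_ids = (
            list(mature_seqs)
            if mature_seqs is not None
            else [f"syn-mir-{i + 1:03d}" for i in range(cfg.n_count_genes)]
        )
    mature_ids = list(mature_ids)
    n_genes = len(mature_ids)
    samples = [f"sample{i + 1}" for i in range(cfg.n_samples)]
    tissue_of_sample = {
        s: DEEPSEQ_TISSUES[i % len(DEEPSEQ_TISSUES)] for i, s in enumerate(samples)
    }

    lib = rng.uniform(*cfg.library_size_range, size=cfg.n_samples)
    base = cfg.base_mean * 10 ** rng.uniform(-1.0, 1.0, size=n_genes)

    folds = np.ones(n_genes)
    targets = np.array([""] * n_genes, dtype=object)
    n_enriched = min(cfg.n_enriched_genes, n_genes)
    enriched_idx = rng.choice(n_genes, size=n_enriched, replace=False)
    for rank, gi in enumerate(enriched_idx):
        folds[gi] = cfg.strong_fold if rank < cfg.n_strong_enriched else cfg.enrichment_fold
        targets[gi] = DEEPSEQ_TISSUES[int(rng.integers(0, len(DEEPSEQ_TISSUES)))]

    counts = np.zeros((n_genes, cfg.n_samples), dtype=int)
    size = cfg.nb_dispersion
    for j, sample in enumerate(samples):
        tissue = tissue_of_sample[sample]
        mu = base * np.where(targets == tissue, folds, 1.0) * lib[j]
        p = size / (size + mu)
        counts[:, j] = rng.negative_binomial(size, p)

    if mature_seqs is None:
        mature_seqs = {gid: _random_seq(rng, 22) for gid in mature_ids}
    else:
        mature_seqs = dict(mature_seqs)
    truth = pd.DataFrame(
        {"fold": folds, "target_tissue": targets}, index=pd.Index(mature_ids, name="mirna")
    )
    return CountSim(
        counts=pd.DataFrame(counts, index=mature_ids, columns=samples),
        tissue_of_sample=tissue_of_sample,
        mature_seqs=mature_seqs,
        truth=truth,
    )


def reads_from_counts(
    sim: CountSim, rng: Optional[np.random.Generator] = None
) -> dict[str, list[tuple[str, int]]]:
    """Collapsed (sequence, count) reads reproducing a simulated count matrix.

    For every positive count one perfectly matching read stack is emitted;
    decoy reads (one-mismatch variants and <18 nt fragments) are added so
    exact-match counting is actually exercised.
    """
    rng = rng or np.random.default_rng(0)
    reads: dict[str, list[tuple[str, int]]] = {}
    for sample in sim.counts.columns:
        entries: list[tuple[str, int]] = []
        for gid, count in sim.counts[sample].items():
            if count <= 0:
                continue
            seq = sim.mature_seqs[gid]
            entries.append((seq, int(count)))
            if rng.random() < 0.3:  # mismatched decoy
                pos = int(rng.integers(0, len(seq)))
                alt = str(rng.choice([b for b in "ACGU" if b != seq[pos]]))
                entries.append((seq[:pos] + alt + seq[pos + 1 :], int(rng.integers(1, 5))))
            if rng.random() < 0.2:  # too-short decoy
                entries.append((seq[:17], int(rng.integers(1, 5))))
        reads[sample] = entries
    return reads


@dataclass
class CtSim:
    """Synthetic qPCR dataset: Ct matrix, design and truth components."""

    ct: pd.DataFrame  # genes × samples (cycles)
    tissue_of_sample: dict[str, str]
    truth: pd.DataFrame  # per gene: variance components and planted shift


def simulate_ct(cfg: SimConfig) -> CtSim:
    """Ct matrix over ``n_tissues`` × ``n_individuals`` samples.

    Ct(gene, tissue, individual) = baseline + tissue effect + noise, all on
    the cycle scale: the tissue effect is N(0, tissue_sd²) drawn once per
    (gene, tissue) minus ``target_shift`` in the gene's target tissues; the
    noise is i.i.d. N(0, noise_sd²) per measurement.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    tissues = list(QPCR_TISSUES[: cfg.n_tissues])
    if len(tissues) < cfg.n_tissues:
        tissues += [f"tissue{i + 1}" for i in range(cfg.n_tissues - len(tissues))]
    samples = [f"{t}_{i + 1}" for t in tissues for i in range(cfg.n_individuals)]
    tissue_of_sample = {s: s.rsplit("_", 1)[0] for s in samples}

    rows = []
    truth_rows = []
    for gene in cfg.ct_genes:
        effect = {t: rng.normal(0.0, gene.tissue_sd) for t in tissues}
        for t in gene.target_tissues:
            if t in effect:
                effect[t] -= gene.target_shift  # lower Ct = higher expression
        values = [
            gene.baseline + effect[tissue_of_sample[s]] + rng.normal(0.0, gene.noise_sd)
            for s in samples
        ]
        rows.append(pd.Series(values, index=samples, name=gene.gene_id))
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "baseline": gene.baseline,
                "tissue_sd": gene.tissue_sd,
                "noise_sd": gene.noise_sd,
                "target_shift": gene.target_shift,
                "target_tissues": ",".join(sorted(gene.target_tissues)),
                "reference_candidate": gene.reference_candidate,
            }
        )
    ct = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return CtSim(ct=ct, tissue_of_sample=tissue_of_sample, truth=truth)


def write_dataset(cfg: SimConfig, outdir) -> None:
    """Write a complete synthetic dataset in the formats the stages consume.

    Produces candidate files (FASTA + manifest + stacks + BLAST table),
    collapsed reads with their tissue map, Ct matrices (all genes, plus the
    reference-candidate panel used for stability testing), the per-miRNA
    initial target tissues for the DE stage, and one truth table per
    dataset.  Deterministic for a fixed config.
    """
    from pathlib import Path

    from mirpost import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    candidates, hits, cand_truth = simulate_candidates(cfg)
    mio.write_candidates(outdir, candidates)
    mio.write_blast_tab(outdir / "blast.tsv", hits)
    cand_truth.to_csv(outdir / "truth_candidates.tsv", sep="\t")

    # counts are simulated over the unique mature sequences of the planted
    # accepted candidates, so reads.tsv is consistent with the discovery
    # stage's unique_matures.tsv
    accepted = set(cand_truth.index[cand_truth["status"] != "rejected"])
    unique_seqs: dict[str, str] = {}
    for cand in candidates:
        if cand.candidate_id not in accepted:
            continue
        for arm, seq in (("5p", cand.mature5p_seq), ("3p", cand.mature3p_seq)):
            unique_seqs.setdefault(seq, f"{cand.candidate_id}-{arm}")
    mature_seqs = {gid: seq for seq, gid in unique_seqs.items()}
    count_sim = simulate_counts(cfg, mature_seqs=mature_seqs)
    rng = np.random.default_rng(cfg.seed + 3)
    reads = reads_from_counts(count_sim, rng)
    mio.write_reads(outdir / "reads.tsv", reads)
    mio.write_tissue_map(outdir / "tissue_map_seq.tsv", count_sim.tissue_of_sample)
    mio.write_fasta(outdir / "matures.fa", count_sim.mature_seqs)
    count_sim.truth.to_csv(outdir / "truth_counts.tsv", sep="\t")

    ct_sim = simulate_ct(cfg)
    mio.write_tsv_matrix(outdir / "ct.tsv", ct_sim.ct, "gene_id")
    refs = ct_sim.truth.index[ct_sim.truth["reference_candidate"]]
    mio.write_tsv_matrix(outdir / "ct_refs.tsv", ct_sim.ct.loc[refs], "gene_id")
    mio.write_tissue_map(outdir / "tissue_map_qpcr.tsv", ct_sim.tissue_of_sample)
    ct_sim.truth.to_csv(outdir / "truth_ct.tsv", sep="\t")
    de = ct_sim.truth[ct_sim.truth["target_shift"] > 0]
    rows = [
        {"mirna_id": gid, "initial_target": row["target_tissues"]}
        for gid, row in de.iterrows()
    ]
    pd.DataFrame(rows, columns=["mirna_id", "initial_target"]).to_csv(
        outdir / "de_targets.tsv", sep="\t", index=False
    )
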