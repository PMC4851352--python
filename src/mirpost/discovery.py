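"""Classification of candidate miRNA precursors.

Candidates produced by a hairpin-discovery tool (miRDeep2-style records:
precursor sequence, genomic location, score, per-sample read stacks) are
classified into

* ``conserved`` — the precursor has a significant homology hit (E-value
  ≤ 1e-6) against a miRBase-like stem-loop collection and is annotated as
  the ortholog of the best hit;
* ``novel`` — no stem-loop homology, no significant hit against other
  small-RNA families, not a multi-locus repeat, and supported by read
  evidence: detection in at least two independent samples, more than five
  perfectly matching reads on each arm, and consistent 5'-end processing;
* ``rejected`` — anything else, with the first failing rule recorded as the
  rejection reason.

All rules are pure functions of a single candidate plus its BLAST hits, so
classification is independent of input order.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import math

Arm = Literal["5p", "3p"]
Status = Literal["conserved", "novel", "rejected"]
RejectionReason = Literal[
    "low_score",
    "other_smallrna",
    "repeat",
    "insufficient_samples",
    "insufficient_arm_reads",
    "inconsistent_5p_end",
]

#: Significance threshold for all BLAST-based rules.
DEFAULT_EVALUE = 1e-6
#: Repeat rule: reject when significant genome hits cover more than this many loci.
DEFAULT_MAX_LOCI = 5
#: Novel validation: required number of distinct samples with reads.
DEFAULT_MIN_SAMPLES = 2
#: Novel validation: per-arm read sums must strictly exceed this.
DEFAULT_MIN_ARM_READS = 5
#: Novel validation: fraction of an arm's reads the modal 5' start must carry.
DEFAULT_CONSISTENCY_FRAC = 0.9


@dataclass(frozen=True)
class ReadStack:
    """A stack of identical read alignments on one precursor arm.

    ``start_offset`` is the 0-based offset of the read 5' end on the
    precursor sequence; ``count`` is the number of reads in the stack.
    """

    sample_id: str
    arm: Arm
    start_offset: int
    read_length: int
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative read count in stack for {self.sample_id}")
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")
        if self.start_offset < 0 or self.read_length <= 0:
            raise ValueError("start_offset must be >= 0 and read_length > 0")


@dataclass(frozen=True)
class CandidateRecord:
    """A putative miRNA precursor with location, score and read evidence."""

    candidate_id: str
    precursor_seq: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: Literal["+", "-"]
    score: float
    mature5p_seq: str
    mature3p_seq: str
    stacks: tuple[ReadStack, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.candidate_id}: start > end")
        if self.start < 1:
            raise ValueError(f"{self.candidate_id}: coordinates are 1-based")
        if not math.isfinite(self.score):
            raise ValueError(f"{self.candidate_id}: non-finite score")
        seq = self.precursor_seq.upper().replace("T", "U")
        for arm, mat in (("5p", self.mature5p_seq), ("3p", self.mature3p_seq)):
            if mat and mat.upper().replace("T", "U") not in seq:
                raise ValueError(
                    f"{self.candidate_id}: mature {arm} sequence not found in precursor"
                )
        for stack in self.stacks:
            if stack.start_offset + stack.read_length > len(self.precursor_seq):
                raise ValueError(
                    f"{self.candidate_id}: read stack exceeds precursor length"
                )
        object.__setattr__(self, "stacks", tuple(self.stacks))


@dataclass(frozen=True)
class BlastHit:
    """One tabular (outfmt-6 style) BLAST hit.

    ``subject_locus`` is only populated for genome hits, as
    (contig, start, end, strand) with 1-based inclusive coordinates.
    """

    query_id: str
    subject_id: str
    subject_db: Literal["mirbase", "rfam", "ntlike", "genome"]
    e_value: float
    bit_score: float
    subject_locus: Optional[tuple[str, int, int, str]] = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("E-value must be >= 0")


@dataclass(frozen=True)
class AnnotatedGene:
    """A classified miRNA gene."""

    gene_id: str
    status: Status
    contig: str
    start: int
    end: int
    strand: str
    mature5p_seq: str
    mature3p_seq: str
    rejection_reason: Optional[RejectionReason] = None
    family_annotation: Optional[str] = None
    arm_dominance: Optional[Literal["5p", "3p", "codominant"]] = None

    def __post_init__(self) -> None:
        if self.status == "conserved" and not self.family_annotation:
            raise ValueError(f"{self.gene_id}: conserved gene without annotation")
        if self.status == "rejected" and not self.rejection_reason:
            raise ValueError(f"{self.gene_id}: rejected gene without reason")


def apply_score_cutoff(
    candidates: Sequence[CandidateRecord], cutoff: float
) -> list[CandidateRecord]:
    """Keep candidates whose discovery score is strictly above ``cutoff``.

    The cutoff is normally chosen so that the discovery run reaches a target
    signal-to-noise ratio (30:1 in the originating study); only precursors
    with scores *above* that threshold are retained.
    """
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return [c for c in candidates if c.score > cutoff]


def _check_query(candidate: CandidateRecord, hits: Iterable[BlastHit], db: str) -> None:
    for h in hits:
        if h.query_id != candidate.candidate_id:
            raise ValueError(
                f"hit for query {h.query_id!r} passed with candidate "
                f"{candidate.candidate_id!r}"
            )
        if h.subject_db != db:
            raise ValueError(f"expected {db} hits, got {h.subject_db}")


def classify_conserved(
    candidate: CandidateRecord,
    hits: Sequence[BlastHit],
    evalue: float = DEFAULT_EVALUE,
) -> Optional[str]:
    """Return the family annotation if the candidate is evolutionarily conserved.

    A candidate is conserved when any stem-loop (miRBase-like) hit reaches
    E-value ≤ ``evalue`` (the boundary is included).  The annotation is the
    subject of the best hit: lowest E-value, ties broken by highest bit
    score, then lexicographically smallest subject id, so the result is
    deterministic.
    """
    _check_query(candidate, hits, "mirbase")
    significant = [h for h in hits if h.e_value <= evalue]
    if not significant:
        return None
    best = min(significant, key=lambda h: (h.e_value, -h.bit_score, h.subject_id))
    return best.subject_id


def filter_other_smallrna(
    candidate: CandidateRecord,
    hits: Sequence[BlastHit],
    evalue: float = DEFAULT_EVALUE,
) -> bool:
    """True if the candidate survives the other-small-RNA screen.

    Any significant hit (E-value ≤ ``evalue``) against an Rfam-like family
    collection marks the precursor as some other class of small RNA.
    """
    _check_query(candidate, hits, "rfam")
    return not any(h.e_value <= evalue for h in hits)


def _merged_locus_count(hits: Sequence[BlastHit]) -> int:
    """Count distinct genomic loci, merging overlapping hit intervals.

    Merging is per (contig, strand) so HSP fragments of a single locus are
    not double-counted.
    """
    by_region: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for h in hits:
        if h.subject_locus is None:
            # No coordinates: each subject id counts as one locus.
            by_region[(h.subject_id, ".")].append((0, 0))
            continue
        contig, start, end, strand = h.subject_locus
        lo, hi = min(start, end), max(start, end)
        by_region[(contig, strand)].append((lo, hi))
    n = 0
    for ivals in by_region.values():
        ivals.sort()
        cur_end = None
        for lo, hi in ivals:
            if cur_end is None or lo > cur_end:
                n += 1
                cur_end = hi
            else:
                cur_end = max(cur_end, hi)
    return n


def filter_repeats(
    candidate: CandidateRecord,
    hits: Sequence[BlastHit],
    max_loci: int = DEFAULT_MAX_LOCI,
    evalue: float = DEFAULT_EVALUE,
) -> bool:
    """True if the candidate survives the repeat-locus screen.

    A precursor hitting more than ``max_loci`` distinct loci in the genome
    (E-value ≤ ``evalue``) is treated as an interspersed or tandem repeat.
    Overlapping hit intervals on the same contig and strand are merged
    before counting.
    """
    if max_loci < 1:
        raise ValueError("max_loci must be >= 1")
    _check_query(candidate, hits, "genome")
    significant = [h for h in hits if h.e_value <= evalue]
    return _merged_locus_count(significant) <= max_loci


def validate_novel(
    candidate: CandidateRecord,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_arm_reads: int = DEFAULT_MIN_ARM_READS,
    consistency_frac: float = DEFAULT_CONSISTENCY_FRAC,
) -> Optional[RejectionReason]:
    """Validate a putative novel miRNA from its read evidence.

    Returns ``None`` when the candidate passes, otherwise the first failing
    criterion in order:

    1. ``insufficient_samples`` — reads present in fewer than ``min_samples``
       distinct samples;
    2. ``insufficient_arm_reads`` — pooled perfectly matching reads do not
       strictly exceed ``min_arm_reads`` on both the 5p and 3p arms;
    3. ``inconsistent_5p_end`` — on either arm, the modal read start offset
       carries less than ``consistency_frac`` of that arm's reads.

    Read counts are pooled across samples; "more than five reads" is a
    strict inequality.
    """
    stacks = [s for s in candidate.stacks if s.count > 0]
    samples = {s.sample_id for s in stacks}
    if len(samples) < min_samples:
        return "insufficient_samples"
    arm_counts = Counter()
    for s in stacks:
        arm_counts[s.arm] += s.count
    if arm_counts["5p"] <= min_arm_reads or arm_counts["3p"] <= min_arm_reads:
        return "insufficient_arm_reads"
    for arm in ("5p", "3p"):
        offsets: Counter[int] = Counter()
        for s in stacks:
            if s.arm == arm:
                offsets[s.start_offset] += s.count
        modal = max(offsets.values())
        if modal / arm_counts[arm] < consistency_frac:
            return "inconsistent_5p_end"
    return None


def call_arm_dominance(candidate: CandidateRecord) -> Literal["5p", "3p", "codominant"]:
    """Which precursor arm contributes the majority of sequenced reads.

    Counts are summed across all samples; exactly equal sums are called
    codominant.
    """
    if not candidate.stacks or all(s.count == 0 for s in candidate.stacks):
        raise ValueError(f"{candidate.candidate_id}: no reads to call arm dominance")
    totals = Counter()
    for s in candidate.stacks:
        totals[s.arm] += s.count
    if totals["5p"] > totals["3p"]:
        return "5p"
    if totals["3p"] > totals["5p"]:
        return "3p"
    return "codominant"


@dataclass
class ClassificationConfig:
    """Thresholds for the candidate classification chain."""

    score_cutoff: float = 4.0
    evalue: float = DEFAULT_EVALUE
    max_loci: int = DEFAULT_MAX_LOCI
    min_samples: int = DEFAULT_MIN_SAMPLES
    min_arm_reads: int = DEFAULT_MIN_ARM_READS
    consistency_frac: float = DEFAULT_CONSISTENCY_FRAC


def classify_candidates(
    candidates: Sequence[CandidateRecord],
    hits: Sequence[BlastHit],
    config: ClassificationConfig | None = None,
) -> list[AnnotatedGene]:
    """Run the full classification chain over a set of candidates.

    Order of rules per candidate: score cutoff → stem-loop homology
    (conserved) → other-small-RNA exclusion → repeat-locus exclusion →
    novel-candidate read validation.  Every input candidate yields exactly
    one :class:`AnnotatedGene` whose status is conserved, novel or rejected.
    """
    cfg = config or ClassificationConfig()
    hits_by_query: dict[tuple[str, str], list[BlastHit]] = defaultdict(list)
    for h in hits:
        hits_by_query[(h.query_id, h.subject_db)].append(h)

    out: list[AnnotatedGene] = []
    for cand in candidates:
        out.append(_classify_one(cand, hits_by_query, cfg))
    return out


def _classify_one(
    cand: CandidateRecord,
    hits_by_query: dict[tuple[str, str], list[BlastHit]],
    cfg: ClassificationConfig,
) -> AnnotatedGene:
    base = dict(
        gene_id=cand.candidate_id,
        contig=cand.contig,
        start=cand.start,
        end=cand.end,
        strand=cand.strand,
        mature5p_seq=cand.mature5p_seq,
        mature3p_seq=cand.mature3p_seq,
    )
    try:
        dominance = call_arm_dominance(cand)
    except ValueError:
        dominance = None

    if not apply_score_cutoff([cand], cfg.score_cutoff):
        return AnnotatedGene(status="rejected", rejection_reason="low_score", **base)

    annotation = classify_conserved(
        cand, hits_by_query.get((cand.candidate_id, "mirbase"), []), cfg.evalue
    )
    if annotation is not None:
        return AnnotatedGene(
            status="conserved",
            family_annotation=annotation,
            arm_dominance=dominance,
            **base,
        )

    rfam = hits_by_query.get((cand.candidate_id, "rfam"), [])
    if not filter_other_smallrna(cand, rfam, cfg.evalue):
        return AnnotatedGene(status="rejected", rejection_reason="other_smallrna", **base)

    genome = hits_by_query.get((cand.candidate_id, "genome"), [])
    if not filter_repeats(cand, genome, cfg.max_loci, cfg.evalue):
        return AnnotatedGene(status="rejected", rejection_reason="repeat", **base)

    reason = validate_novel(
        cand, cfg.min_samples, cfg.min_arm_reads, cfg.consistency_frac
    )
    if reason is not None:
        return AnnotatedGene(status="rejected", rejection_reason=reason, **base)
    return AnnotatedGene(status="novel", arm_dominance=dominance, **base)


def collapse_unique_matures(
    genes: Sequence[AnnotatedGene],
) -> dict[str, list[tuple[str, Arm]]]:
    """Collapse mature sequences to the unique set.

    Only *identical* mature sequences are merged (sequences are uppercased
    and T→U normalised first); the result maps each unique mature sequence
    to the (gene_id, arm) pairs carrying it.  The number of keys is the
    total number of unique mature miRNAs; it is at most twice the number of
    genes.
    """
    uniques: dict[str, list[tuple[str, Arm]]] = {}
    for gene in genes:
        for arm, seq in (("5p", gene.mature5p_seq), ("3p", gene.mature3p_seq)):
            if not seq:
                continue
            key = seq.upper().replace("T", "U")
            uniques.setdefault(key, []).append((gene.gene_id, arm))
    return uniques
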