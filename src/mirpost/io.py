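"""Readers and writers for the pipeline's on-disk formats.

All genomic coordinates on disk are 1-based inclusive (GFF3 convention).
Tables are plain TSV with stable column order so outputs can be diffed;
sequences travel as FASTA; BLAST hits as standard 12-column tabular
(outfmt-6) files with an optional 13th ``subject_db`` column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from mirpost.clusters import Cluster, GeneLocus
from mirpost.discovery import AnnotatedGene, BlastHit, CandidateRecord, ReadStack

MANIFEST_COLUMNS = ["candidate_id", "contig", "start", "end", "strand", "score"]
STACK_COLUMNS = ["candidate_id", "sample_id", "arm", "start_offset", "read_length", "count"]
BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id → sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- candidates

def write_candidates(
    directory: str | Path, candidates: Sequence[CandidateRecord]
) -> None:
    """Write candidates as precursor/mature FASTA + manifest + stack TSVs."""
    directory = Path(directory)
    seqs: dict[str, str] = {}
    manifest = []
    stacks = []
    for c in candidates:
        seqs[c.candidate_id] = c.precursor_seq
        if c.mature5p_seq:
            seqs[f"{c.candidate_id}-5p"] = c.mature5p_seq
        if c.mature3p_seq:
            seqs[f"{c.candidate_id}-3p"] = c.mature3p_seq
        manifest.append(
            [c.candidate_id, c.contig, c.start, c.end, c.strand, repr(c.score)]
        )
        for s in c.stacks:
            stacks.append(
                [c.candidate_id, s.sample_id, s.arm, s.start_offset, s.read_length, s.count]
            )
    write_fasta(directory / "candidates.fa", seqs)
    pd.DataFrame(manifest, columns=MANIFEST_COLUMNS).to_csv(
        directory / "candidates.tsv", sep="\t", index=False
    )
    pd.DataFrame(stacks, columns=STACK_COLUMNS).to_csv(
        directory / "stacks.tsv", sep="\t", index=False
    )


def read_candidates(directory: str | Path) -> list[CandidateRecord]:
    """Read candidates written by :func:`write_candidates`."""
    directory = Path(directory)
    seqs = read_fasta(directory / "candidates.fa")
    manifest = pd.read_csv(
        directory / "candidates.tsv",
        sep="\t",
        dtype={"contig": str},
        float_precision="round_trip",
    )
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"candidate manifest missing column(s): {missing}")
    stacks = pd.read_csv(directory / "stacks.tsv", sep="\t")
    stacks_by_id: dict[str, list[ReadStack]] = {}
    for i, row in enumerate(stacks.itertuples(index=False), start=2):
        try:
            stacks_by_id.setdefault(row.candidate_id, []).append(
                ReadStack(
                    sample_id=str(row.sample_id),
                    arm=row.arm,
                    start_offset=int(row.start_offset),
                    read_length=int(row.read_length),
                    count=int(row.count),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"stacks.tsv line {i}: {exc}") from exc
    out = []
    for i, row in enumerate(manifest.itertuples(index=False), start=2):
        cid = row.candidate_id
        if cid not in seqs:
            raise ValueError(f"candidates.tsv line {i}: no precursor sequence for {cid}")
        try:
            out.append(
                CandidateRecord(
                    candidate_id=cid,
                    precursor_seq=seqs[cid],
                    contig=str(row.contig),
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    score=float(row.score),
                    mature5p_seq=seqs.get(f"{cid}-5p", ""),
                    mature3p_seq=seqs.get(f"{cid}-3p", ""),
                    stacks=tuple(stacks_by_id.get(cid, [])),
                )
            )
        except ValueError as exc:
            raise ValueError(f"candidates.tsv line {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------- BLAST tabular

def read_blast_tab(
    path: str | Path, subject_db: Optional[str] = None
) -> list[BlastHit]:
    """Parse a 12-column outfmt-6 file (optional 13th ``subject_db`` column).

    For genome hits the subject locus is reconstructed from sseqid and
    sstart/send; reversed coordinates mean a minus-strand hit.
    """
    rows = pd.read_csv(str(path), sep="\t", header=None, comment="#", dtype=str)
    if rows.shape[1] == len(BLAST_COLUMNS):
        rows.columns = BLAST_COLUMNS
        if subject_db is None:
            raise ValueError(f"{path}: no subject_db column and none supplied")
        rows["subject_db"] = subject_db
    elif rows.shape[1] == len(BLAST_COLUMNS) + 1:
        rows.columns = BLAST_COLUMNS + ["subject_db"]
    else:
        raise ValueError(
            f"{path}: expected 12 or 13 tab-separated columns, got {rows.shape[1]}"
        )
    hits = []
    for i, row in enumerate(rows.itertuples(index=False), start=1):
        try:
            db = row.subject_db
            locus = None
            if db == "genome":
                s, e = int(row.sstart), int(row.send)
                strand = "+" if s <= e else "-"
                locus = (row.sseqid, min(s, e), max(s, e), strand)
            hits.append(
                BlastHit(
                    query_id=row.qseqid,
                    subject_id=row.sseqid,
                    subject_db=db,
                    e_value=float(row.evalue),
                    bit_score=float(row.bitscore),
                    subject_locus=locus,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return hits


def write_blast_tab(path: str | Path, hits: Sequence[BlastHit]) -> None:
    """Write hits as 13-column tabular (12 standard + subject_db)."""
    rows = []
    for h in hits:
        if h.subject_locus is not None:
            _, lo, hi, strand = h.subject_locus
            sstart, send = (lo, hi) if strand == "+" else (hi, lo)
        else:
            sstart, send = 1, 1
        rows.append(
            [h.query_id, h.subject_id, 100.0, 70, 0, 0, 1, 70, sstart, send,
             repr(h.e_value), h.bit_score, h.subject_db]
        )
    pd.DataFrame(rows, columns=BLAST_COLUMNS + ["subject_db"]).to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------- GFF3

def write_gff3(
    path: str | Path,
    genes: Sequence[AnnotatedGene],
    cluster_of: Optional[Mapping[str, str]] = None,
) -> None:
    """Write annotated genes as GFF3 ``miRNA_primary_transcript`` features.

    Accepted genes (conserved/novel) additionally get one child ``miRNA``
    feature per mature arm (located at the precursor span; per-arm genomic
    sub-coordinates are not tracked by the record type).  ``cluster_of``
    adds a ``cluster_id`` attribute where present.
    """
    cluster_of = cluster_of or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}", f"status={g.status}"]
            if g.family_annotation:
                attrs.append(f"family={g.family_annotation}")
            if g.rejection_reason:
                attrs.append(f"rejection_reason={g.rejection_reason}")
            if g.arm_dominance:
                attrs.append(f"arm_dominance={g.arm_dominance}")
            if g.gene_id in cluster_of:
                attrs.append(f"cluster_id={cluster_of[g.gene_id]}")
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        "mirpost",
                        "miRNA_primary_transcript",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            if g.status == "rejected":
                continue
            for arm, seq in (("5p", g.mature5p_seq), ("3p", g.mature3p_seq)):
                if not seq:
                    continue
                fh.write(
                    "\t".join(
                        [
                            g.contig,
                            "mirpost",
                            "miRNA",
                            str(g.start),
                            str(g.end),
                            ".",
                            g.strand,
                            ".",
                            f"ID={g.gene_id}-{arm};Parent={g.gene_id};arm={arm}",
                        ]
                    )
                    + "\n"
                )


def read_gff3(path: str | Path):
    """Parse a GFF3 file into gffutils Feature objects, validating coordinates."""
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"{path} line {lineno}: malformed GFF3 ({exc})") from exc
            if feat.start is None or feat.end is None or feat.start > feat.end:
                raise ValueError(f"{path} line {lineno}: invalid interval")
            if feat.start < 1:
                raise ValueError(f"{path} line {lineno}: coordinates are 1-based")
            features.append(feat)
    return features


def gff3_to_loci(path: str | Path, feature_type: str = "miRNA_primary_transcript") -> list[GeneLocus]:
    """Extract gene loci (for cluster detection) from a GFF3 file."""
    loci = []
    for feat in read_gff3(path):
        if feat.featuretype != feature_type:
            continue
        loci.append(
            GeneLocus(
                gene_id=feat.attributes["ID"][0],
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return loci


# ---------------------------------------------------------------- tables

def write_tsv_matrix(path: str | Path, matrix: pd.DataFrame, index_name: str = "id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", index_col=0)


def write_tissue_map(path: str | Path, tissue_of_sample: Mapping[str, str]) -> None:
    pd.DataFrame(
        {"sample": list(tissue_of_sample), "tissue": list(tissue_of_sample.values())}
    ).to_csv(path, sep="\t", index=False)


def read_tissue_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "tissue"]:
        raise ValueError(f"{path}: expected columns 'sample' and 'tissue'")
    return dict(zip(df["sample"], df["tissue"]))


def write_reads(path: str | Path, reads: Mapping[str, Iterable[tuple[str, int]]]) -> None:
    """Collapsed reads as a three-column TSV: sample, sequence, count."""
    rows = [
        [sample, seq, count]
        for sample, entries in reads.items()
        for seq, count in entries
    ]
    pd.DataFrame(rows, columns=["sample", "sequence", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_reads(path: str | Path) -> dict[str, list[tuple[str, int]]]:
    df = pd.read_csv(str(path), sep="\t", dtype={"sample": str, "sequence": str})
    out: dict[str, list[tuple[str, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample, []).append((row.sequence, int(row.count)))
    return out


# ---------------------------------------------------------------- reports

def classification_report(genes: Sequence[AnnotatedGene]) -> pd.DataFrame:
    """Tabular view of the classification outcome, one row per candidate."""
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "status": g.status,
                "rejection_reason": g.rejection_reason or "",
                "family": g.family_annotation or "",
                "arm_dominance": g.arm_dominance or "",
                "contig": g.contig,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
            for g in genes
        ]
    )


def cluster_report(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """One row per cluster: id, location, size and ordered members."""
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "contig": c.contig,
                "strand": c.strand,
                "span_start": c.span[0],
                "span_end": c.span[1],
                "n_genes": len(c),
                "members": ",".join(c.member_ids),
            }
            for c in clusters
        ]
    )
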