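"""Read counting, normalisation and cross-sample stability screens.

Counts are exact-match counts: a sequenced read contributes to a mature
miRNA's count only if it is identical to that mature sequence (reads shorter
than 18 nt are discarded up front).  Counts are normalised per sample to a
per-10^4 scale — each count is divided by the total number of miRNA-matching
reads in its sample and multiplied by 10^4 — which makes profiles comparable
across libraries of very different depth.

The relative standard deviation (RSD, the coefficient of variation) of a
mature miRNA's normalised profile across samples is a scale-free screen for
stably expressed genes; the enrichment ratio screen is the converse, ranking
miRNAs by how strongly their best tissue stands out from the rest.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

NORMALIZATION_SCALE = 1e4
DEFAULT_MIN_READ_LEN = 18


def count_perfect_matches(
    reads_per_sample: Mapping[str, Iterable[tuple[str, int]]],
    matures: Sequence[str],
    min_len: int = DEFAULT_MIN_READ_LEN,
) -> pd.DataFrame:
    """Count reads that perfectly match a mature miRNA, per sample.

    Parameters
    ----------
    reads_per_sample
        sample id → iterable of ``(sequence, count)`` pairs (collapsed
        reads).  Sequences are uppercased and T→U normalised before
        comparison, so DNA- and RNA-alphabet inputs agree.
    matures
        The unique mature miRNA sequences to count against.  Duplicates
        after normalisation are collapsed; a read increments exactly one
        unique mature.
    min_len
        Reads shorter than this are excluded before matching.

    Returns
    -------
    pandas.DataFrame
        matures × samples integer count matrix; reads matching no mature
        are ignored.
    """
    if not matures:
        raise ValueError("empty mature miRNA set")
    norm = [m.upper().replace("T", "U") for m in matures]
    index = list(dict.fromkeys(norm))  # unique, first-seen order
    lookup = {seq: seq for seq in index}
    samples = list(reads_per_sample)
    cm = pd.DataFrame(0, index=index, columns=samples, dtype=int)
    for sample, reads in reads_per_sample.items():
        for seq, count in reads:
            if count < 0:
                raise ValueError("negative read count")
            if len(seq) < min_len:
                continue
            key = lookup.get(seq.upper().replace("T", "U"))
            if key is not None:
                cm.loc[key, sample] += count
    return cm


def normalize_counts(cm: pd.DataFrame) -> pd.DataFrame:
    """Normalise a count matrix to the per-10^4 scale.

    Each entry is divided by its sample's total counted miRNA reads and
    multiplied by 10^4, so every column of the result sums to 10^4.
    """
    if (cm.to_numpy() < 0).any():
        raise ValueError("count matrix has negative entries")
    totals = cm.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total miRNA reads: {', '.join(map(str, zero.index))}"
        )
    return cm / totals * NORMALIZATION_SCALE


def compute_rsd(nm: pd.DataFrame) -> pd.Series:
    """Relative standard deviation of each miRNA across samples.

    RSD = sample standard deviation (n−1 denominator) / mean.  miRNAs with
    zero mean have no defined RSD and are reported as NaN.
    """
    if nm.shape[1] < 2:
        raise ValueError("RSD needs at least two samples")
    mean = nm.mean(axis=1)
    sd = nm.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = sd / mean
    rsd[mean == 0] = np.nan
    return rsd


def screen_reference_candidates(
    rsd: pd.Series,
    k: int,
    family: Optional[Mapping[str, str]] = None,
    cluster: Optional[Mapping[str, str]] = None,
) -> list[str]:
    """Greedy selection of reference-gene candidates by ascending RSD.

    Walks the RSD table from most to least stable, skipping any miRNA that
    shares a gene family or a gene cluster with an already selected one
    (family members carry identical or near-identical matures and clustered
    genes are often co-transcribed, so either would give redundant
    references).  Returns the first ``k`` ids; if fewer are eligible, all
    eligible ids are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    family = family or {}
    cluster = cluster or {}
    selected: list[str] = []
    used_families: set[str] = set()
    used_clusters: set[str] = set()
    for gene_id in rsd.dropna().sort_values(kind="stable").index:
        fam = family.get(gene_id)
        clu = cluster.get(gene_id)
        if (fam is not None and fam in used_families) or (
            clu is not None and clu in used_clusters
        ):
            continue
        selected.append(gene_id)
        if fam is not None:
            used_families.add(fam)
        if clu is not None:
            used_clusters.add(clu)
        if len(selected) == k:
            return selected
    warnings.warn(
        f"only {len(selected)} eligible reference candidates (requested {k})",
        stacklevel=2,
    )
    return selected


def screen_enriched_candidates(
    nm: pd.DataFrame,
    tissue_of_sample: Mapping[str, str],
    min_ratio: float = 4.0,
    totals: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Rank miRNAs by tissue enrichment of their normalised profile.

    For each miRNA the per-tissue mean normalised count is computed; the
    enrichment ratio is the highest tissue mean divided by the mean of the
    remaining tissues.  Zeros are smoothed by adding half a read on the
    count scale (0.5 × 10^4 / sample total when ``totals`` is given,
    otherwise a flat 0.5) so ratios stay finite.  miRNAs reaching
    ``min_ratio`` are returned ranked by descending ratio, with the top
    tissue attached — a screening aid for choosing qPCR candidates, not a
    significance test.
    """
    tissues = pd.Series({s: tissue_of_sample[s] for s in nm.columns})
    if tissues.nunique() < 2:
        raise ValueError("enrichment screen needs at least two tissues")
    if totals is not None:
        pseudo = 0.5 * NORMALIZATION_SCALE / totals.reindex(nm.columns)
    else:
        pseudo = pd.Series(0.5, index=nm.columns)
    smoothed = nm.add(pseudo, axis=1)
    tissue_means = smoothed.T.groupby(tissues).mean().T  # miRNAs × tissues
    top_tissue = tissue_means.idxmax(axis=1)
    top = tissue_means.max(axis=1)
    n_tissues = tissue_means.shape[1]
    rest = (tissue_means.sum(axis=1) - top) / (n_tissues - 1)
    ratio = top / rest
    out = pd.DataFrame(
        {"top_tissue": top_tissue, "enrichment_ratio": ratio}
    ).sort_values("enrichment_ratio", ascending=False, kind="stable")
    return out[out["enrichment_ratio"] >= min_ratio]
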