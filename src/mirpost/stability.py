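"""Model-based reference-gene stability ranking (NormFinder-style).

Candidate reference genes measured by RT-qPCR across tissue groups are
ranked by a *stability value*: a variance-decomposition score that is low
for genes whose expression is both homogeneous within tissues and constant
across tissues, and high otherwise.  The decomposition follows the
model-based approach of Andersen-type reference-gene selection:

1.  Measurements are analysed on the log2 scale.  Within each sample the
    per-gene values are centred on the sample's gene average, which removes
    global per-sample effects (input amount, RT efficiency) — stability is
    therefore always *relative* to the candidate panel.
2.  For gene *i* in tissue group *g* the centred values give a group
    difference estimate ``d_ig`` (how far the gene's level in that tissue
    sits from its own cross-tissue average) and an intra-group variance
    ``sigma2_ig``.  The raw within-group sample variance is biased by the
    per-sample centring; the standard unbiasing correction (factor
    ``k/(k−2)`` with the panel-average variance subtracted, for a panel of
    *k* genes) is applied, and negative method-of-moments estimates are
    clamped at zero.
3.  The inter-group variance of gene *i* is estimated from the spread of
    ``d_ig`` across groups with the sampling-error correction: the average
    ``sigma2_ig / n_g`` is subtracted (clamped at zero), because even a
    perfectly tissue-independent gene shows spread in ``d_ig`` from finite
    group sizes.
4.  The stability value combines both components,

    ``stability_i = sqrt( tau2_i + mean_g( sigma2_ig / n_g ) )``,

    i.e. the standard deviation of the error made when the gene's group
    level is used as a normaliser.  Lower is more stable.

The best two-gene combination averages the two genes' group differences
(systematic biases in opposite directions cancel) and propagates the
intra-group variances as the variance of the average, then applies the same
combination formula; all unordered pairs are scored and the minimiser
returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd


def linearize_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Transform a Ct matrix (genes × samples) to linear-scale expression.

    Uses ``2**(C − Ct)`` with ``C`` the maximum Ct in the matrix, so values
    are ≥ 1 and one cycle equals a two-fold change.  The constant ``C`` is a
    global scale factor; it cancels in every downstream stability value.
    """
    values = ct.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("Ct matrix contains non-finite values")
    return pd.DataFrame(
        np.exp2(values.max() - values), index=ct.index, columns=ct.columns
    )


@dataclass
class StabilityResult:
    """Output of the stability analysis.

    Attributes
    ----------
    stability : pandas.Series
        Per-gene stability value (lower = more stable).
    ranking : list of str
        Gene ids in ascending stability order.
    best_single : str
        The most stable single gene.
    best_pair : tuple of (str, str)
        The most stable two-gene combination.
    pair_stability : float
        Stability value of ``best_pair`` (comparable to single-gene values,
        but not guaranteed to be smaller than the best single's).
    group_differences, intra_variances : pandas.DataFrame
        Per gene × group estimates ``d_ig`` and ``sigma2_ig`` underlying the
        stability values.
    group_sizes : pandas.Series
        Samples per group.
    """

    stability: pd.Series
    ranking: list[str]
    best_single: str
    best_pair: tuple[str, str]
    pair_stability: float
    group_differences: pd.DataFrame
    intra_variances: pd.DataFrame
    group_sizes: pd.Series


def _combine(d: np.ndarray, sigma2: np.ndarray, n_g: np.ndarray) -> float:
    """Stability value from group differences and intra-group variances.

    ``d`` and ``sigma2`` are per-group vectors for one (possibly combined)
    gene; ``n_g`` the group sizes.
    """
    n_groups = d.size
    sampling = float(np.mean(sigma2 / n_g))
    tau2 = max(0.0, float(np.sum(d**2)) / (n_groups - 1) - sampling)
    return float(np.sqrt(tau2 + sampling))


def _decompose(
    mat: pd.DataFrame, groups: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Estimate ``d_ig`` and ``sigma2_ig`` from a linear-scale matrix."""
    n_genes = mat.shape[0]
    if n_genes < 3:
        raise ValueError("stability analysis needs at least 3 genes")
    missing = [s for s in mat.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing}")
    labels = pd.Series({s: groups[s] for s in mat.columns})
    group_names = sorted(labels.unique())
    if len(group_names) < 2:
        raise ValueError("stability analysis needs at least 2 groups")

    values = mat.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("linear-scale expression must be positive")
    y = np.log2(values)
    z = y - y.mean(axis=0, keepdims=True)  # remove per-sample level

    d = np.empty((n_genes, len(group_names)))
    sigma2 = np.empty_like(d)
    sizes = np.empty(len(group_names), dtype=int)
    for j, g in enumerate(group_names):
        cols = (labels == g).to_numpy()
        n = int(cols.sum())
        if n < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sizes[j] = n
        zg = z[:, cols]
        d[:, j] = zg.mean(axis=1)
        s2 = zg.var(axis=1, ddof=1)
        # Unbias for the per-sample centring across the k-gene panel.
        corr = s2.sum() / (n_genes * (n_genes - 1))
        sigma2[:, j] = np.maximum(0.0, n_genes / (n_genes - 2) * (s2 - corr))
    d -= d.mean(axis=1, keepdims=True)  # gene's own cross-group average

    idx = list(mat.index)
    return (
        pd.DataFrame(d, index=idx, columns=group_names),
        pd.DataFrame(sigma2, index=idx, columns=group_names),
        pd.Series(sizes, index=group_names),
    )


def normfinder_stability(
    linear: pd.DataFrame, groups: Mapping[str, str]
) -> StabilityResult:
    """Rank genes by model-based stability and find the best two-gene pair.

    Parameters
    ----------
    linear
        Linear-scale expression, genes × samples (e.g. from
        :func:`linearize_ct`).
    groups
        sample id → tissue group label; every group needs ≥ 2 samples.

    Returns
    -------
    StabilityResult
        Deterministic given the input; ties in the ranking are broken by
        gene id.
    """
    d, sigma2, sizes = _decompose(linear, groups)
    n_g = sizes.to_numpy(dtype=float)
    stability = pd.Series(
        {
            gene: _combine(d.loc[gene].to_numpy(), sigma2.loc[gene].to_numpy(), n_g)
            for gene in linear.index
        },
        name="stability",
    )
    ranking = list(stability.sort_values(kind="stable").index)
    pair, pair_value = _best_pair_from(d, sigma2, n_g)
    return StabilityResult(
        stability=stability,
        ranking=ranking,
        best_single=ranking[0],
        best_pair=pair,
        pair_stability=pair_value,
        group_differences=d,
        intra_variances=sigma2,
        group_sizes=sizes,
    )


def pair_stability(result: StabilityResult, gene_a: str, gene_b: str) -> float:
    """Stability value of an arbitrary two-gene combination."""
    d = result.group_differences
    s2 = result.intra_variances
    n_g = result.group_sizes.to_numpy(dtype=float)
    d_pair = (d.loc[gene_a].to_numpy() + d.loc[gene_b].to_numpy()) / 2.0
    s2_pair = (s2.loc[gene_a].to_numpy() + s2.loc[gene_b].to_numpy()) / 4.0
    return _combine(d_pair, s2_pair, n_g)


def _best_pair_from(
    d: pd.DataFrame, sigma2: pd.DataFrame, n_g: np.ndarray
) -> tuple[tuple[str, str], float]:
    genes = list(d.index)
    if len(genes) < 2:
        raise ValueError("best pair needs at least 2 genes")
    best: tuple[str, str] | None = None
    best_value = np.inf
    for a, b in combinations(genes, 2):
        d_pair = (d.loc[a].to_numpy() + d.loc[b].to_numpy()) / 2.0
        s2_pair = (sigma2.loc[a].to_numpy() + sigma2.loc[b].to_numpy()) / 4.0
        value = _combine(d_pair, s2_pair, n_g)
        if value < best_value:
            best, best_value = (a, b), value
    assert best is not None
    return best, float(best_value)


def best_pair(
    linear: pd.DataFrame, groups: Mapping[str, str]
) -> tuple[tuple[str, str], float]:
    """Exhaustively score all unordered gene pairs; return the minimiser."""
    result = normfinder_stability(linear, groups)
    return result.best_pair, result.pair_stability
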