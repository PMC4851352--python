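"""RT-qPCR differential expression by the comparative Ct (ΔΔCt) method.

Each assayed miRNA is measured across tissues together with the chosen
reference genes.  Per sample, ΔCt = target Ct − geometric mean of the
reference-gene Cts (lower ΔCt = higher expression).  Samples are split into
*target* tissues (where enrichment is hypothesised) and *reference* tissues;
tissues whose ΔCt values overlap the target range are promoted into the
target group before testing, mirroring the inspection step of the comparative
Ct workflow.  Welch's unequal-variance t-test compares the two groups, with
Bonferroni control across the battery of tests; the effect size is reported
as ΔΔCt = mean reference ΔCt − mean target ΔCt and fold change 2**ΔΔCt.

A deep-sequencing based fold estimate and a cross-platform correlation are
provided so qPCR fold changes can be validated against normalised read
counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def delta_ct(
    target_cts: pd.Series,
    ref_cts: pd.DataFrame,
    mode: Literal["geometric", "arithmetic"] = "geometric",
) -> pd.Series:
    """Normalise target Ct values by the reference genes, per sample.

    ΔCt_s = Ct_s − mean(reference Cts of sample s), where the mean is the
    geometric mean of the Ct values by default (``mode="arithmetic"`` is
    available since Ct is already a log-scale quantity).  Samples missing
    any reference Ct are dropped with a warning.
    """
    if ref_cts.shape[0] < 1:
        raise ValueError("at least one reference gene is required")
    common = [s for s in target_cts.index if s in ref_cts.columns]
    refs = ref_cts[common]
    complete = refs.columns[refs.notna().all(axis=0)]
    dropped = [s for s in common if s not in set(complete)] + [
        s for s in target_cts.index if s not in ref_cts.columns
    ]
    if dropped:
        warnings.warn(
            f"dropping sample(s) with missing reference Ct: {sorted(dropped)}",
            stacklevel=2,
        )
    refs = refs[complete]
    if (refs.to_numpy() <= 0).any() or (target_cts[complete] <= 0).any():
        raise ValueError("Ct values must be positive")
    if mode == "geometric":
        ref_mean = pd.Series(stats.gmean(refs, axis=0), index=complete)
    else:
        ref_mean = refs.mean(axis=0)
    return target_cts[complete] - ref_mean


def assign_target_tissues(
    dct: pd.Series,
    tissue_of_sample: Mapping[str, str],
    initial_target: set[str],
    rule: Literal["median_below_target_max", "median_below_target_median"] = (
        "median_below_target_max"
    ),
) -> set[str]:
    """Promote reference tissues whose expression overlaps the target range.

    Starting from the initially hypothesised target tissues, any reference
    tissue whose median ΔCt falls below the promotion threshold — the
    maximum (default) or median per-sample ΔCt observed in the current
    target group — is added to the target set; promotion is iterated to a
    fixed point.  (Lower ΔCt means higher expression, so "below" means
    "at least as highly expressed".)  If every tissue ends up promoted
    there is no reference group left and an error is raised.
    """
    if not initial_target:
        raise ValueError("initial_target must be non-empty")
    tissues = pd.Series({s: tissue_of_sample[s] for s in dct.index})
    all_tissues = set(tissues.unique())
    unknown = initial_target - all_tissues
    if unknown:
        raise ValueError(f"initial target tissue(s) not in data: {sorted(unknown)}")
    target = set(initial_target)
    while True:
        in_target = tissues.isin(target)
        if rule == "median_below_target_max":
            threshold = dct[in_target].max()
        else:
            threshold = dct[in_target].median()
        promoted = {
            t
            for t in all_tissues - target
            if dct[tissues == t].median() < threshold
        }
        if not promoted:
            break
        target |= promoted
    if target == all_tissues:
        raise ValueError("all tissues promoted to target: no reference group left")
    return target


def welch_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom.
    When both groups are constant: equal means give ``(0, df, 1)`` by
    convention, unequal means give an infinite statistic and ``p = 0``.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / x.size + vy / y.size
    diff = x.mean() - y.mean()
    if se2 == 0:
        df = float(x.size + y.size - 2)
        if diff == 0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / math.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test significance threshold controlling FWER over ``m`` tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def fold_change(mean_target: float, mean_reference: float) -> tuple[float, float]:
    """ΔΔCt and fold change between target and reference groups.

    ΔΔCt = mean reference ΔCt − mean target ΔCt, so higher expression in the
    target group gives a positive ΔΔCt; fold = 2**ΔΔCt assuming 100%
    amplification efficiency (one cycle per two-fold).
    """
    if not (math.isfinite(mean_target) and math.isfinite(mean_reference)):
        raise ValueError("group means must be finite")
    ddct = mean_reference - mean_target
    return ddct, 2.0**ddct


@dataclass
class DEResult:
    """Differential-expression call for one miRNA."""

    mirna_id: str
    target_tissues: set[str]
    n_target: int
    n_reference: int
    mean_dct_target: float
    mean_dct_reference: float
    ddct: float
    fold: float
    t: float
    df: float
    p: float
    significant: bool


def analyze_differential_expression(
    dct: pd.Series,
    tissue_of_sample: Mapping[str, str],
    initial_target: set[str],
    mirna_id: str = "",
    alpha: float = 0.05,
    n_tests: int = 1,
    promotion_rule: Literal[
        "median_below_target_max", "median_below_target_median", "none"
    ] = "median_below_target_max",
) -> DEResult:
    """Full per-miRNA DE analysis from a ΔCt table.

    Runs target-tissue promotion (``promotion_rule="none"`` keeps the
    initial target set), Welch's t-test of target vs reference ΔCts, the
    Bonferroni-adjusted significance call (strict ``p < alpha/m``) and the
    ΔΔCt fold change.
    """
    if promotion_rule == "none":
        final_target = set(initial_target)
    else:
        final_target = assign_target_tissues(
            dct, tissue_of_sample, initial_target, promotion_rule
        )
    tissues = pd.Series({s: tissue_of_sample[s] for s in dct.index})
    in_target = tissues.isin(final_target)
    target_vals = dct[in_target]
    ref_vals = dct[~in_target]
    t, df, p = welch_test(target_vals, ref_vals)
    ddct, fold = fold_change(float(target_vals.mean()), float(ref_vals.mean()))
    threshold = bonferroni_alpha(alpha, n_tests)
    return DEResult(
        mirna_id=mirna_id,
        target_tissues=final_target,
        n_target=int(in_target.sum()),
        n_reference=int((~in_target).sum()),
        mean_dct_target=float(target_vals.mean()),
        mean_dct_reference=float(ref_vals.mean()),
        ddct=ddct,
        fold=fold,
        t=t,
        df=df,
        p=p,
        significant=bool(p < threshold),
    )


def seq_fold_estimate(
    nm: pd.DataFrame,
    tissue_of_sample: Mapping[str, str],
    target_tissues: Mapping[str, set[str]],
) -> pd.Series:
    """Deep-sequencing fold estimate per miRNA: target over reference mean.

    Only miRNAs with a normalised count > 0 in *every* sample are estimated
    (others are excluded from cross-platform comparison); the value is the
    mean normalised count over target-tissue samples divided by the mean
    over the remaining samples.
    """
    tissues = pd.Series({s: tissue_of_sample[s] for s in nm.columns})
    out: dict[str, float] = {}
    for mirna, targets in target_tissues.items():
        if mirna not in nm.index:
            continue
        profile = nm.loc[mirna]
        if (profile <= 0).any():
            continue
        in_target = tissues.isin(targets)
        if not in_target.any() or in_target.all():
            raise ValueError(f"{mirna}: target tissues do not split the samples")
        out[mirna] = float(profile[in_target].mean() / profile[~in_target].mean())
    return pd.Series(out, dtype=float)


def correlate_platforms(
    qpcr_folds: pd.Series,
    seq_folds: pd.Series,
    method: Literal["log2_pearson", "pearson", "spearman"] = "log2_pearson",
) -> float:
    """Correlation between qPCR and deep-sequencing fold changes.

    Pairs the two series on their shared ids (≥ 3 required).  The default is
    the product-moment correlation of log2-transformed folds; raw-scale
    Pearson and Spearman rank correlation are available.  Returns NaN when
    either vector has zero variance.
    """
    common = qpcr_folds.index.intersection(seq_folds.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired fold estimates")
    x = qpcr_folds[common].to_numpy(dtype=float)
    y = seq_folds[common].to_numpy(dtype=float)
    if method == "log2_pearson":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("fold changes must be positive for the log2 option")
        x, y = np.log2(x), np.log2(y)
        method = "pearson"
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    return float(stats.spearmanr(x, y).statistic)
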