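"""Single-sample DUX4 activity score.

A sample expressing DUX4 should show the DUX4-upregulated target genes above
the DUX4-downregulated ones.  After placing every gene on a common scale
(row z-scores across samples), the default score of sample s is

    score_s = mean(z_{g,s} : g in up) - mean(z_{g,s} : g in down),

with a within-sample Welch t and a scaled rank-difference as variants.
Scores are therefore invariant under any gene-wise affine transform of the
raw matrix, and swapping the two lists negates every score exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SignatureSet, ValidationError, as_frame, samples_for

logger = logging.getLogger("duxent")


def zscore_rows(matrix) -> ExpressionMatrix:
    """Standardise each gene row to mean 0, SD 1 across samples.

    Uses the population SD (denominator n).  Zero-variance rows cannot be
    scaled and are dropped with a logged count.
    """
    df = as_frame(matrix)
    if df.shape[1] < 2:
        raise ValidationError("row z-scoring needs >= 2 samples")
    values = df.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.info("zscore_rows: dropped %d constant gene rows", int((~keep).sum()))
    values = values[keep]
    sd = sd[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(pd.DataFrame(z, index=df.index[keep], columns=df.columns))


def _signature_rows(z: pd.DataFrame, signature: SignatureSet):
    up = [g for g in signature.up_genes if g in z.index]
    down = [g for g in signature.down_genes if g in z.index]
    if not up or not down:
        raise ValidationError(
            "signature genes missing from matrix "
            f"(found {len(up)}/{len(signature.up_genes)} up, "
            f"{len(down)}/{len(signature.down_genes)} down)"
        )
    for label, found, total in (("up", len(up), len(signature.up_genes)),
                                ("down", len(down), len(signature.down_genes))):
        if found < 0.5 * total:
            logger.warning(
                "dux4_score: only %d/%d %s-signature genes found in matrix", found, total, label
            )
    return up, down


def dux4_score(matrix, signature: SignatureSet, statistic: str = "mean_diff") -> pd.DataFrame:
    """Score every sample for regulator activity.

    Returns a table indexed by sample with columns score, n_up_used,
    n_down_used.  Statistics: ``mean_diff`` (default), ``t_stat`` (within-
    sample Welch t between the two z-value sets) and ``rank_diff``
    (difference of mean within-sample ranks scaled to [-1, 1]).
    """
    z = as_frame(zscore_rows(matrix))
    up, down = _signature_rows(z, signature)
    zu = z.loc[up].to_numpy()
    zd = z.loc[down].to_numpy()
    if statistic == "mean_diff":
        score = zu.mean(axis=0) - zd.mean(axis=0)
    elif statistic == "t_stat":
        score = stats.ttest_ind(zu, zd, axis=0, equal_var=False).statistic
    elif statistic == "rank_diff":
        ranks = stats.rankdata(z.to_numpy(), axis=0)
        iu = z.index.get_indexer(up)
        idn = z.index.get_indexer(down)
        diff = ranks[iu].mean(axis=0) - ranks[idn].mean(axis=0)
        max_diff = z.shape[0] - (len(up) + len(down)) / 2.0
        score = diff / max_diff
    else:
        raise ValueError(f"unknown score statistic {statistic!r}")
    return pd.DataFrame(
        {"score": score, "n_up_used": len(up), "n_down_used": len(down)}, index=z.columns
    )


def compare_score_groups(
    scores: pd.DataFrame, metadata: pd.DataFrame, group_a: str, group_b: str
) -> tuple[float, float]:
    """Welch two-sample t-test of scores between two conditions.

    Returns (difference of mean scores a - b, two-sided p).
    """
    sa = scores.loc[samples_for(metadata, group_a), "score"].to_numpy()
    sb = scores.loc[samples_for(metadata, group_b), "score"].to_numpy()
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError("each group needs >= 2 samples")
    res = stats.ttest_ind(sa, sb, equal_var=False)
    return float(sa.mean() - sb.mean()), float(res.pvalue)


def score_auroc(scores_pos, scores_neg) -> float:
    """Area under the ROC curve for positive-class scores vs negative-class.

    Rank-based (equivalent to the Mann-Whitney U statistic scaled to [0, 1]).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))
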