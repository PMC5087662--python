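"""Two-group differential expression with empirical-Bayes variance moderation.

Each construct is contrasted against control independently.  Per gene g the
ordinary two-sample quantities are the difference of condition means
(``effect``), the pooled within-group variance ``s2`` on ``df = n1 + n2 - 2``
degrees of freedom.  The gene-wise variances are then shrunk towards a common
prior: with prior degrees of freedom d0 and prior variance s0^2,

    s2_tilde = (d0 * s0^2 + df * s2) / (d0 + df)
    t_mod    = effect / sqrt(s2_tilde * (1/n1 + 1/n2))

and the two-sided p-value comes from a Student t on d0 + df degrees of
freedom (standard normal when d0 is infinite).  The hyperparameters are
estimated by moment matching on e_g = log s2_g - digamma(df/2) + log(df/2),
whose theoretical variance under the scaled-inverse-chi-square prior is
trigamma(df/2) + trigamma(d0/2); solving

    trigamma(d0/2) = var(e) - trigamma(df/2)

for d0 by monotone Newton iteration and back-solving s0^2 from mean(e).
When the observed spread of e is no larger than the sampling component the
prior is degenerate and d0 = infinity with s0^2 = exp(mean(e)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError, as_frame, samples_for


@dataclass(frozen=True)
class EBHyperparams:
    """Empirical-Bayes prior: d0 degrees of freedom, s0_2 prior variance."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):  # d0 may be math.inf; NaN rejected
            raise ValidationError("d0 must be >= 0 or infinite")
        if not (self.s0_2 > 0):
            raise ValidationError("s0_2 must be > 0")


@dataclass
class ContrastFit:
    """Per-gene two-group statistics for one construct-vs-control contrast."""

    table: pd.DataFrame  # columns: effect, s2, df
    condition: str
    reference: str
    n_cond: int
    n_ref: int


def fit_contrast(matrix, metadata: pd.DataFrame, condition: str, reference: str = "control") -> ContrastFit:
    """Ordinary two-group fit of one condition against a reference condition."""
    df_expr = as_frame(matrix)
    cond_samples = samples_for(metadata, condition)
    ref_samples = samples_for(metadata, reference)
    if len(cond_samples) < 2 or len(ref_samples) < 2:
        raise ValidationError("each group needs >= 2 samples")
    missing = [s for s in cond_samples + ref_samples if s not in df_expr.columns]
    if missing:
        raise ValidationError(f"metadata samples absent from matrix: {missing[:5]}")
    a = df_expr[cond_samples].to_numpy(dtype=float)
    b = df_expr[ref_samples].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    effect = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    dof = n1 + n2 - 2
    s2 = ss / dof
    table = pd.DataFrame(
        {"effect": effect, "s2": s2, "df": float(dof)}, index=df_expr.index
    )
    return ContrastFit(table, condition, reference, n1, n2)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton with the standard start)."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += step
        if abs(step) / y < 1e-8:
            break
    return y


def estimate_eb(s2, df) -> EBHyperparams:
    """Moment-matching hyperparameter estimate from gene-wise variances."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValidationError("need >= 2 genes with positive s2 and df")
    if np.all(s2 == 0):
        raise ValidationError("degenerate variance distribution (all s2 == 0)")
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar <= 0:
        return EBHyperparams(math.inf, math.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return EBHyperparams(d0, s0_2)


def moderated_t(effect, s2, df, hyper: EBHyperparams, n_cond: int, n_ref: int):
    """Moderated t-statistics and two-sided p-values.

    d0 = 0 reduces to the ordinary pooled two-sample t; d0 = inf replaces
    every gene variance by the prior and uses a normal reference.
    """
    effect = np.asarray(effect, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    scale = 1.0 / n_cond + 1.0 / n_ref
    if math.isinf(hyper.d0):
        s2_tilde = np.full_like(effect, hyper.s0_2)
        t = effect / np.sqrt(s2_tilde * scale)
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        s2_tilde = (hyper.d0 * hyper.s0_2 + df * s2) / (hyper.d0 + df)
        t = effect / np.sqrt(s2_tilde * scale)
        p = 2.0 * stats.t.sf(np.abs(t), hyper.d0 + df)
    return t, p


def adjust_bh(p):
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    matrix,
    metadata: pd.DataFrame,
    condition: str,
    reference: str = "control",
    hyper: EBHyperparams | None = None,
) -> pd.DataFrame:
    """Full per-gene DE table for one contrast.

    Columns: effect, s2, df, t_mod, p, p_bh.  Hyperparameters are estimated
    from this contrast's variances unless supplied.
    """
    fit = fit_contrast(matrix, metadata, condition, reference)
    if hyper is None:
        hyper = estimate_eb(fit.table["s2"], fit.table["df"])
    t, p = moderated_t(
        fit.table["effect"], fit.table["s2"], fit.table["df"], hyper, fit.n_cond, fit.n_ref
    )
    out = fit.table.copy()
    out["t_mod"] = t
    out["p"] = p
    out["p_bh"] = adjust_bh(p)
    out.attrs["condition"] = condition
    out.attrs["reference"] = reference
    out.attrs["d0"] = hyper.d0
    out.attrs["s0_2"] = hyper.s0_2
    return out


def de_all_constructs(matrix, metadata: pd.DataFrame, reference: str = "control") -> dict[str, pd.DataFrame]:
    """One DE table per non-reference condition present in the metadata."""
    out = {}
    for cond in metadata["condition"].unique():
        if cond == reference:
            continue
        out[cond] = differential_expression(matrix, metadata, cond, reference)
    return out
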