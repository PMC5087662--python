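"""Cross-construct concordance: t-profile correlations and target signatures.

A gene is called a DUX4 target only when three independent perturbations
agree: significantly moved in the same direction by DUX4 and by the
constitutively activating tMALDUX4-VP16 fusion, and significantly moved in
the OPPOSITE direction by the dominant-negative tMALDUX4-ERD fusion.  DUX4c
targets require concordant significant movement under both DUX4c and the
truncated tMALDUX4.  "Upregulated" means t > 0 with two-sided p < alpha
(raw p by default; a flag switches to BH-adjusted p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SignatureSet, ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    construct_a: str
    construct_b: str
    r: float
    p: float
    n: int


def _shared_t(de_a: pd.DataFrame, de_b: pd.DataFrame):
    shared = de_a.index.intersection(de_b.index)
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared genes to correlate t-profiles")
    return de_a.loc[shared, "t_mod"].to_numpy(), de_b.loc[shared, "t_mod"].to_numpy(), len(shared)


def correlate_t_profiles(
    de_a: pd.DataFrame, de_b: pd.DataFrame, method: str = "pearson"
) -> CorrelationResult:
    """Correlate the moderated-t profiles of two contrasts over shared genes."""
    ta, tb, n = _shared_t(de_a, de_b)
    if method == "pearson":
        res = stats.pearsonr(ta, tb)
    elif method == "spearman":
        res = stats.spearmanr(ta, tb)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        de_a.attrs.get("condition", "a"),
        de_b.attrs.get("condition", "b"),
        float(res.statistic),
        float(res.pvalue),
        n,
    )


def pairwise_correlations(de_tables: dict[str, pd.DataFrame], method: str = "pearson") -> pd.DataFrame:
    """Symmetric matrix of pairwise t-profile correlations across constructs."""
    names = list(de_tables)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = correlate_t_profiles(de_tables[a], de_tables[b], method).r
            out.loc[a, b] = out.loc[b, a] = r
    return out


def _universe(*tables: pd.DataFrame) -> pd.Index:
    universe = tables[0].index
    for t in tables[1:]:
        universe = universe.intersection(t.index)
    if len(universe) == 0:
        raise ValidationError("empty shared gene universe across DE tables")
    return universe


def _calls(de: pd.DataFrame, genes: pd.Index, alpha: float, use_adjusted: bool):
    p = de.loc[genes, "p_bh" if use_adjusted else "p"].to_numpy()
    t = de.loc[genes, "t_mod"].to_numpy()
    sig = p < alpha  # ties at alpha excluded (strict inequality)
    return sig & (t > 0), sig & (t < 0)


def derive_dux4_signature(
    de_dux4: pd.DataFrame,
    de_vp16: pd.DataFrame,
    de_erd: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> SignatureSet:
    """Triple-concordance DUX4 target signature.

    up: significantly up under DUX4 and VP16, significantly down under ERD;
    down: the mirror image.
    """
    genes = _universe(de_dux4, de_vp16, de_erd)
    up_d, down_d = _calls(de_dux4, genes, alpha, use_adjusted)
    up_v, down_v = _calls(de_vp16, genes, alpha, use_adjusted)
    up_e, down_e = _calls(de_erd, genes, alpha, use_adjusted)
    up = genes[up_d & up_v & down_e]
    down = genes[down_d & down_v & up_e]
    return SignatureSet("DUX4", tuple(up), tuple(down))


def derive_dux4c_signature(
    de_tmal: pd.DataFrame,
    de_dux4c: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> SignatureSet:
    """Two-way concordance DUX4c target signature (DUX4c and tMALDUX4 agree)."""
    genes = _universe(de_tmal, de_dux4c)
    up_t, down_t = _calls(de_tmal, genes, alpha, use_adjusted)
    up_c, down_c = _calls(de_dux4c, genes, alpha, use_adjusted)
    return SignatureSet("DUX4c", tuple(genes[up_t & up_c]), tuple(genes[down_t & down_c]))


@dataclass
class JointPartition:
    """Set-algebra partition of the DUX4 and DUX4c signatures."""

    down_dux4_not_dux4c: tuple[str, ...]
    up_both: tuple[str, ...]
    up_dux4c_not_dux4: tuple[str, ...]
    down_dux4c_not_dux4: tuple[str, ...]
    down_both: tuple[str, ...]
    up_dux4_not_dux4c: tuple[str, ...]

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return {
            "down_dux4_not_dux4c": self.down_dux4_not_dux4c,
            "up_both": self.up_both,
            "up_dux4c_not_dux4": self.up_dux4c_not_dux4,
            "down_dux4c_not_dux4": self.down_dux4c_not_dux4,
            "down_both": self.down_both,
            "up_dux4_not_dux4c": self.up_dux4_not_dux4c,
        }


def partition_joint(sig_dux4: SignatureSet, sig_dux4c: SignatureSet, universe) -> JointPartition:
    """Partition the two signatures into the six joint categories."""
    universe = set(universe)
    for name, genes in (
        ("DUX4 up", sig_dux4.up_genes),
        ("DUX4 down", sig_dux4.down_genes),
        ("DUX4c up", sig_dux4c.up_genes),
        ("DUX4c down", sig_dux4c.down_genes),
    ):
        outside = set(genes) - universe
        if outside:
            raise ValidationError(f"{name} genes outside universe: {sorted(outside)[:5]}")

    def ordered(genes, keep):
        return tuple(g for g in genes if g in keep)

    up4, down4 = set(sig_dux4.up_genes), set(sig_dux4.down_genes)
    up4c, down4c = set(sig_dux4c.up_genes), set(sig_dux4c.down_genes)
    return JointPartition(
        down_dux4_not_dux4c=ordered(sig_dux4.down_genes, down4 - down4c),
        up_both=ordered(sig_dux4.up_genes, up4 & up4c),
        up_dux4c_not_dux4=ordered(sig_dux4c.up_genes, up4c - up4),
        down_dux4c_not_dux4=ordered(sig_dux4c.down_genes, down4c - down4),
        down_both=ordered(sig_dux4.down_genes, down4 & down4c),
        up_dux4_not_dux4c=ordered(sig_dux4.up_genes, up4 - up4c),
    )
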