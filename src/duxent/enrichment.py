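"""Gene-set enrichment by two-sided Fisher's exact test with BH correction.

For a query gene list Q inside a universe U, each annotation set A is tested
on the 2x2 table (a, b; c, d) = (|Q&A|, |Q\\A|; |A\\Q|, |U\\(Q|A)|).  The
two-sided p sums the hypergeometric probabilities of all tables with the
same margins that are no more probable than the observed one.  Sets are
flagged enriched when the BH-adjusted p falls below the threshold.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, ValidationError
from .diffexp import adjust_bh

logger = logging.getLogger("duxent")


def fisher_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (sample odds ratio a*d / b*c, with 0 and inf at the boundaries,
    and the two-sided p-value).
    """
    counts = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in counts):
        raise ValidationError("contingency counts must be non-negative integers")
    a, b, c, d = (int(x) for x in counts)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan  # 0/0: no association estimable
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    return odds, p


def enrich(
    query_genes,
    collection: GeneSetCollection,
    universe,
    alpha_bh: float = 0.05,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Test every annotation set for overlap with a query gene list.

    Sets with fewer than ``min_set_size`` members after intersection with the
    universe are skipped with a log entry.  Rows are sorted by raw p; the
    ``enriched`` flag marks BH-adjusted p < ``alpha_bh``.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValidationError("empty gene universe")
    uni = set(universe)
    query = set(query_genes)
    outside = query - uni
    if outside:
        raise ValidationError(f"query genes outside universe: {sorted(outside)[:5]}")
    rows = []
    n_skipped = 0
    for gene_set in collection:
        members = set(gene_set.members) & uni
        if len(members) < min_set_size:
            n_skipped += 1
            continue
        a = len(query & members)
        b = len(query - members)
        c = len(members - query)
        d = len(uni) - a - b - c
        odds, p = fisher_test(a, b, c, d)
        rows.append(
            {"set_name": gene_set.name, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": odds, "p": p}
        )
    if n_skipped:
        logger.info("enrich: skipped %d sets smaller than %d after universe intersection",
                    n_skipped, min_set_size)
    out = pd.DataFrame(rows, columns=["set_name", "a", "b", "c", "d", "odds_ratio", "p"])
    if len(out):
        out["p_bh"] = adjust_bh(out["p"].to_numpy())
        out["enriched"] = out["p_bh"] < alpha_bh
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["p_bh"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
    return out
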