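"""Right-tailed Fisher's exact gene-set enrichment over a fixed background.

For each gene set, a 2x2 table is formed from candidate membership and set
membership within the analysis background (the common-gene universe); the
right-tail p is the hypergeometric upper tail P(X >= overlap), the odds
ratio is the sample cross-product ratio, and Benjamini-Hochberg FDR is
applied across sets.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from emtint.de import bh_fdr
from emtint.io import GeneSetCollection


def fisher_enrichment(
    candidates: Iterable[str],
    background: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Enrichment of ``candidates`` in each gene set, tested on ``background``.

    Sets are intersected with the background before testing.  Returns one
    row per (restricted, non-empty) set, sorted by p-value then name, with
    columns: overlap, candidate_size, set_size_in_background,
    background_size, odds_ratio (NaN when the cross product has a zero
    cell), p_value, fdr, overlap_genes.
    """
    bg = set(background)
    cand = set(candidates)
    if not bg:
        raise ValueError("background gene set is empty")
    if not cand:
        raise ValueError("candidate gene set is empty")
    stray = cand - bg
    if stray:
        raise ValueError(f"candidates outside the background: {sorted(stray)[:5]}")
    restricted = collection.restrict(bg)
    N = len(bg)
    n = len(cand)
    rows = []
    for name, genes in restricted:
        K = len(genes)
        overlap_genes = sorted(cand & genes)
        a = len(overlap_genes)
        b = n - a            # candidates outside the set
        c = K - a            # set members not in candidates
        d = N - n - c        # everything else
        # right tail: P(X >= a) under Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(a - 1, N, K, n))
        odds = (a * d) / (b * c) if b * c > 0 else np.nan
        rows.append(
            {
                "set_name": name,
                "overlap": a,
                "candidate_size": n,
                "set_size_in_background": K,
                "background_size": N,
                "odds_ratio": odds,
                "p_value": min(p, 1.0),
                "overlap_genes": ",".join(overlap_genes),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap", "candidate_size", "set_size_in_background",
            "background_size", "odds_ratio", "p_value", "overlap_genes",
        ],
    )
    if table.empty:
        return table.assign(fdr=pd.Series(dtype=float))
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    table = table.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    return table[
        [
            "set_name", "overlap", "candidate_size", "set_size_in_background",
            "background_size", "odds_ratio", "p_value", "fdr", "overlap_genes",
        ]
    ]


def hypergeom_tail_bruteforce(a: int, N: int, K: int, n: int):
    """Exact right-tail P(X >= a) as a rational number, by term summation.

    Independent oracle for the enrichment p-value on small tables; uses
    exact integer binomials, so no floating error.
    """
    from fractions import Fraction
    from math import comb

    total = comb(N, n)
    upper = min(K, n)
    acc = sum(comb(K, x) * comb(N - K, n - x) for x in range(a, upper + 1))
    return Fraction(acc, total)
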