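"""Term enrichment by two-sided Fisher's exact test with BH adjustment.

Tests whether InterPro-style term IDs are over-represented in a
foreground gene set against a background, the classic route for asking
"what kind of genes are the CNV/PAP candidates?".  Multiple testing is
controlled with Benjamini-Hochberg adjusted values — a deterministic,
conservative upper bound on density-estimated q-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentRow:
    """One term's 2x2 table, odds ratio, p and adjusted q."""

    term_id: str
    a: int  # term & foreground
    b: int  # no term & foreground
    c: int  # term & background
    d: int  # no term & background
    odds_ratio: float
    p: float
    q: float = float("nan")


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a,b],[c,d]].

    Standard two-sided definition: the sum over all tables with the same
    margins whose hypergeometric probability does not exceed the observed
    table's.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d < 1:
        raise ValueError("empty table")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(foreground: set[str], background: set[str],
           term_table: dict[str, set[str]],
           bg_includes_fg: bool = False) -> list[EnrichmentRow]:
    """Fisher enrichment of every term observed in the background.

    ``foreground`` must be a subset of ``background``; ids missing from
    *term_table* count as term-free.  By default the foreground is
    excluded from the background cells (c, d); ``bg_includes_fg=True``
    keeps it in.  Rows are sorted by p, then term id.
    """
    if not foreground:
        raise ValueError("empty foreground")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    bg = set(background) if bg_includes_fg else set(background) - foreground
    terms = sorted({t for i in background for t in term_table.get(i, ())})
    n_fg, n_bg = len(foreground), len(bg)
    rows = []
    for term in terms:
        a = sum(1 for i in foreground if term in term_table.get(i, ()))
        c = sum(1 for i in bg if term in term_table.get(i, ()))
        b, d = n_fg - a, n_bg - c
        if b * c == 0:
            odds = math.inf if a * d > 0 else float("nan")
        else:
            odds = (a * d) / (b * c)
        rows.append(EnrichmentRow(term_id=term, a=a, b=b, c=c, d=d,
                                  odds_ratio=odds,
                                  p=fisher_two_sided(a, b, c, d)))
    q = adjust_bh([r.p for r in rows])
    for r, qv in zip(rows, q):
        r.q = float(qv)
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows
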