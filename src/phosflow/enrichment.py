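"""Term enrichment of differential protein lists by two-tailed Fisher exact
test against a supplied annotation table (GO/KEGG/domain/family — the
semantics belong to the caller).  Selection is on raw p < alpha; BH q-values
are reported alongside.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import AnnotationTable

logger = logging.getLogger("phosflow")

#: relative slack when comparing table probabilities for the two-tailed sum
_TIE_SLACK = 1.0 + 1e-7


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Exact two-tailed p for the 2x2 table [[a, b], [c, d]].

    Sums the probabilities of all tables with the same margins whose
    hypergeometric probability does not exceed the observed table's (with a
    small relative slack for floating-point ties).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero contingency table")
    row1, col1 = a + b, a + c
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(min(1.0, pmf[pmf <= p_obs * _TIE_SLACK].sum()))


def enrich(
    hits: Iterable[str],
    universe: Iterable[str],
    annotations: AnnotationTable,
    alpha: float = 0.05,
    namespace: str | None = None,
) -> pd.DataFrame:
    """Per-term enrichment of ``hits`` within ``universe``.

    Each term's 2x2 table is (hit & term, hit & not-term, non-hit & term,
    non-hit & not-term), with term membership intersected with the universe.
    Returns a frame sorted by ascending p (ties by term_id) with counts,
    fold-enrichment, p, BH q and the significance call at raw p < alpha.
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits:
        raise ValueError("empty hit list")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    members = annotations.term_members(namespace)
    names = annotations.term_names()
    n_hits, n_universe = len(hits), len(universe)
    rows = []
    for term_id in sorted(members):
        term = members[term_id] & universe
        if not term:
            continue
        a = len(hits & term)
        b = n_hits - a
        c = len(term) - a
        d = n_universe - n_hits - c
        expected = n_hits * len(term) / n_universe
        rows.append(
            {
                "term_id": term_id,
                "term_name": names.get(term_id, ""),
                "n_term": len(term),
                "n_hit": a,
                "fold_enrichment": a / expected if expected > 0 else np.nan,
                "p": fisher_two_tailed(a, b, c, d),
            }
        )
    if not rows:
        raise ValueError("no annotation terms overlap the universe")
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["p"] < alpha
    df = df.sort_values(["p", "term_id"]).reset_index(drop=True)
    logger.info(
        "enrichment: %d terms tested, %d significant at p<%.3g",
        len(df), int(df["significant"].sum()), alpha,
    )
    return df


def top_terms(result: pd.DataFrame, top_n: int = 20) -> pd.DataFrame:
    """The bubble-chart view: the ``top_n`` most significant terms."""
    return result.head(top_n).copy()
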