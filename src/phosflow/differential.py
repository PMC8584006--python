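"""Differential phosphosite / protein calling and dataset summary statistics.

Sites are tested per two-condition contrast with a two-sided Student's
t-test on log2 intensities (equal-variance by default, Welch optional) and
called up/down when the raw-scale fold change passes the ratio threshold
(default 1.5) and the raw p-value passes alpha (default 0.05).
Benjamini-Hochberg q-values are reported alongside but never used for
selection by default.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (
    ComparisonResult,
    PhosphoSite,
    QuantTable,
    STATUS_DOWN,
    STATUS_NS,
    STATUS_UP,
    percentage,
    round_half_up,
)

logger = logging.getLogger("phosflow")

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided two-sample t-test (a, b: n_items x n_reps).

    Zero-variance guard: when both groups are constant, p is 1 if the means
    agree and 0 otherwise (the limit of the test statistic).
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    diff = m1 - m2
    if equal_var:
        df = np.full(diff.shape, n1 + n2 - 2, dtype=float)
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    else:
        se2 = v1 / n1 + v2 / n2
        se = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = se == 0
    if zero.any():
        with np.errstate(invalid="ignore"):
            t = np.where(zero, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
        p = np.where(zero, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def log2_ratio_and_test(
    quant: QuantTable,
    comparison: tuple[str, str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-site log2 fold change and t-test p-value for (numerator,
    denominator) condition labels.

    log2fc = mean(log2 numerator) - mean(log2 denominator); p from a
    two-sided two-sample t-test on log2 intensities.
    """
    num, den = comparison
    s_num = quant.samples_for(num)
    s_den = quant.samples_for(den)
    for label, ss in ((num, s_num), (den, s_den)):
        if len(ss) < 2:
            raise ValueError(
                f"condition {label!r} has {len(ss)} replicate(s); at least 2 required"
            )
    log2 = quant.log2()
    a = log2[s_num].to_numpy()
    b = log2[s_den].to_numpy()
    t, p = _two_sample_t(a, b, equal_var=equal_var)
    return pd.DataFrame(
        {"log2fc": a.mean(axis=1) - b.mean(axis=1), "t": t, "p": p},
        index=log2.index,
    )


def classify(
    log2fc: float,
    p: float,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Status of a single site: up iff ratio >= fc_threshold and p < alpha,
    down iff ratio <= 1/fc_threshold and p < alpha, else ns.

    The ratio gate is applied on the log2 scale (|log2fc| >= log2(threshold))
    so the >= boundary is exact.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    log_thr = np.log2(fc_threshold)
    if p < alpha and log2fc >= log_thr:
        return STATUS_UP
    if p < alpha and log2fc <= -log_thr:
        return STATUS_DOWN
    return STATUS_NS


def compare(
    quant: QuantTable,
    comparison: tuple[str, str],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
) -> ComparisonResult:
    """Full differential call for one contrast: log2fc, ratio, p, BH q and
    up/down/ns status per site."""
    df = log2_ratio_and_test(quant, comparison, equal_var=equal_var)
    df["ratio"] = np.exp2(df["log2fc"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    log_thr = np.log2(fc_threshold)
    sig = df["p"] < alpha
    df["status"] = np.select(
        [sig & (df["log2fc"] >= log_thr), sig & (df["log2fc"] <= -log_thr)],
        [STATUS_UP, STATUS_DOWN],
        default=STATUS_NS,
    )
    result = ComparisonResult(tuple(comparison), df)
    counts = Counter(df["status"])
    logger.info(
        "comparison %s: %d sites, %d up, %d down (ratio>=%.3g, p<%.3g)",
        result.name, len(df), counts[STATUS_UP], counts[STATUS_DOWN],
        fc_threshold, alpha,
    )
    return result


def all_comparisons(
    quant: QuantTable, **kwargs
) -> list[ComparisonResult]:
    """Differential calls for every ordered pair of conditions, later
    condition as numerator (e.g. AC-B4/AC-MG for conditions listed
    MG-first)."""
    conds = quant.conditions
    return [
        compare(quant, (b, a), **kwargs)
        for a, b in itertools.combinations(conds, 2)
    ]


# ---------------------------------------------------------------------------
# dataset summaries


def residue_distribution(
    sites: Sequence[PhosphoSite],
) -> dict[str, dict[str, float]]:
    """Counts and integer-rounded percentages of pSer/pThr/pTyr sites."""
    if not sites:
        raise ValueError("empty site list")
    counts = Counter(s.residue for s in sites)
    total = len(sites)
    return {
        r: {
            "count": counts.get(r, 0),
            "percent": percentage(counts.get(r, 0), total, decimals=0),
        }
        for r in "STY"
    }


def sites_per_protein_histogram(
    sites: Sequence[PhosphoSite],
) -> dict[str, dict[str, float]]:
    """Counts and 1-decimal percentages of proteins with 1, 2, and >=3
    phosphosites; proteins with >=7 sites are reported additionally."""
    if not sites:
        raise ValueError("empty site list")
    per_protein = Counter(s.protein_id for s in sites)
    n_proteins = len(per_protein)
    n1 = sum(1 for c in per_protein.values() if c == 1)
    n2 = sum(1 for c in per_protein.values() if c == 2)
    n3 = sum(1 for c in per_protein.values() if c >= 3)
    n7 = sum(1 for c in per_protein.values() if c >= 7)
    return {
        bin_name: {"count": n, "percent": percentage(n, n_proteins, decimals=1)}
        for bin_name, n in (("1", n1), ("2", n2), (">=3", n3), (">=7", n7))
    }


def venn_counts(sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Exclusive Venn-cell counts for 2 or 3 named sets.

    Keys are frozensets of set names; e.g. for sets A, B, C the key
    frozenset({'A'}) counts items in A only, frozenset({'A','B','C'}) items
    in all three.
    """
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_counts needs 2 or 3 sets")
    universe = set().union(*sets.values())
    cells: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            cells[frozenset(combo)] = 0
    for item in universe:
        membership = frozenset(n for n in names if item in sets[n])
        cells[membership] += 1
    return cells


def overlap_counts(
    results: Sequence[ComparisonResult],
) -> dict[frozenset, int]:
    """Venn-cell counts of items significant (status != ns) in each
    comparison, keyed by frozensets of comparison names."""
    if len(results) not in (2, 3):
        raise ValueError("overlap_counts needs 2 or 3 comparisons")
    return venn_counts({r.name: r.significant() for r in results})


def union_size(n_a: int, n_b: int, n_shared: int) -> int:
    """|A u B| from |A|, |B| and |A n B| (inclusion-exclusion)."""
    if n_shared > min(n_a, n_b) or min(n_a, n_b, n_shared) < 0:
        raise ValueError(
            f"invalid overlap: n_shared={n_shared} exceeds min({n_a}, {n_b})"
        )
    return n_a + n_b - n_shared


def summary(
    sites: Sequence[PhosphoSite],
    results: Sequence[ComparisonResult] | None = None,
) -> dict:
    """JSON-ready dataset summary: residue distribution, sites-per-protein
    histogram and (when comparisons are given) Venn cells."""
    out: dict = {
        "n_sites": len(sites),
        "n_proteins": len({s.protein_id for s in sites}),
        "residue_distribution": residue_distribution(sites),
        "sites_per_protein": sites_per_protein_histogram(sites),
    }
    if results:
        out["venn"] = {
            "/".join(sorted(k)): v for k, v in overlap_counts(list(results)).items()
        }
    return out
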