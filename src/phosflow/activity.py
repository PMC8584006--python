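"""Kinase-activity inference by gene-set enrichment over ranked phosphosites.

A kinase's substrate sites form the gene set; sites are ranked either by
log2 fold change (comparison context) or by z-scored log2 intensity (single
sample context).  The enrichment score (ES) is the signed extremum of the
classic weighted Kolmogorov-Smirnov running sum: hits increment by
|value|^w / sum(|value|^w over hits), misses decrement by 1/(N - n_hits).
Significance comes from gene-set permutation (random same-size site sets);
the normalised enrichment score NES = ES / mean(|ES*|) over same-sign null
scores is the kinase-activity score, with NES >= +1 read as activated and
NES <= -1 as inhibited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ComparisonResult, QuantTable

logger = logging.getLogger("phosflow")

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_MIN_SET_SIZE = 3
DEFAULT_WEIGHT = 1.0

STATE_ACTIVATED = "activated"
STATE_INHIBITED = "inhibited"
STATE_INDETERMINATE = "indeterminate"


def rank_metric(
    source: ComparisonResult | QuantTable, context: str | None = None
) -> pd.Series:
    """Ranked site values, descending, ties broken by site_id.

    * ComparisonResult -> value = log2 fold change (context ignored).
    * QuantTable + sample name -> value = z-score of log2 intensity across
      sites in that sample.
    """
    if isinstance(source, ComparisonResult):
        values = source.table["log2fc"]
    else:
        if context is None or context not in source.samples:
            raise ValueError(f"sample {context!r} not in quant table")
        x = np.log2(source.intensities[context].to_numpy(dtype=float))
        values = pd.Series((x - x.mean()) / x.std(), index=source.intensities.index)
    df = pd.DataFrame(
        {"value": values.to_numpy(dtype=float), "site_id": list(values.index)}
    )
    df = df.sort_values(["value", "site_id"], ascending=[False, True])
    return pd.Series(df["value"].to_numpy(), index=df["site_id"], name="value")


def _hit_steps(values: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    """Per-position running-sum increments for one hit mask."""
    n = len(values)
    m = int(hits.sum())
    if m == 0:
        raise ValueError("substrate set has no overlap with the ranked list")
    w = np.abs(values[hits]) ** weight
    # sequential (cumsum) total so the score matches a plain running-sum
    # enumeration bit for bit
    total = float(np.cumsum(w)[-1])
    if total == 0:  # all hit values are exactly 0 -> unweighted fallback
        w = np.full(m, 1.0)
        total = float(m)
    steps = np.empty(n)
    if m == n:
        steps[:] = 0.0
        steps[hits] = w / total
    else:
        steps[~hits] = -1.0 / (n - m)
        steps[hits] = w / total
    return steps


def enrichment_score(
    ranked: pd.Series,
    substrate_set: Iterable[str],
    weight_exponent: float = DEFAULT_WEIGHT,
) -> tuple[float, np.ndarray]:
    """Classic GSEA enrichment score and the full running sum.

    ES is the running-sum value of largest magnitude (positive preferred on
    an exact magnitude tie).
    """
    hits = ranked.index.isin(set(substrate_set))
    steps = _hit_steps(ranked.to_numpy(dtype=float), hits, weight_exponent)
    running = np.cumsum(steps)
    top = float(running.max())
    bottom = float(running.min())
    es = top if top >= -bottom else bottom
    return es, running


def _null_scores(
    values: np.ndarray,
    set_size: int,
    n_permutations: int,
    rng: np.random.Generator,
    weight: float,
) -> np.ndarray:
    """Vectorised null ES for random same-size site sets.

    Uses the closed form of the running-sum extremum: between hits the sum
    decays linearly, so candidates are the values just after each hit (for
    the maximum) and just before each hit, or zero (for the minimum).
    Exactly equivalent to the cumulative-sum definition.
    """
    n = len(values)
    m = set_size
    if m >= n:
        return np.ones(n_permutations)
    keys = rng.random((n_permutations, n))
    positions = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)
    w = np.abs(values)[positions] ** weight
    cum = np.cumsum(w, axis=1)
    degenerate = cum[:, -1] == 0
    if degenerate.any():
        w[degenerate] = 1.0
        cum = np.cumsum(w, axis=1)
    hit_cum = cum / cum[:, -1:]
    miss = 1.0 / (n - m)
    i = np.arange(m)
    misses_before = (positions - i) * miss
    after = hit_cum - misses_before
    before = np.concatenate(
        [np.zeros((n_permutations, 1)), hit_cum[:, :-1]], axis=1
    ) - misses_before
    top = after.max(axis=1)
    bottom = np.minimum(before.min(axis=1), 0.0)
    return np.where(top >= -bottom, top, bottom)


@dataclass
class KinaseActivity:
    """Per-kinase activity in one context (comparison or sample)."""

    kinase_id: str
    context: str
    es: float
    nes: float
    p_perm: float
    n_substrates_in_rank: int
    state: str
    note: str = ""


def normalize_and_test(
    ranked: pd.Series,
    substrate_set: Iterable[str],
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    weight_exponent: float = DEFAULT_WEIGHT,
) -> tuple[float, float, float]:
    """(es, nes, p_perm) for one substrate set by gene-set permutation.

    The null re-draws random site sets of the same size from the ranked
    list.  NES = es / mean(|es*|) over null scores with the same sign as es;
    p = (1 + #{same-sign |es*| >= |es|}) / (1 + #same-sign).  Fully seeded.
    A kinase with no same-sign permutations gets nes = nan (flagged, not
    silently dropped).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    overlap = set(substrate_set) & set(ranked.index)
    es, _ = enrichment_score(ranked, overlap, weight_exponent)
    if es == 0:
        return 0.0, 0.0, 1.0
    null = _null_scores(
        ranked.to_numpy(dtype=float), len(overlap), n_permutations, rng,
        weight_exponent,
    )
    same_sign = null[np.sign(null) == np.sign(es)]
    if len(same_sign) == 0:
        return es, float("nan"), float("nan")
    nes = es / np.abs(same_sign).mean()
    p = (1.0 + np.count_nonzero(np.abs(same_sign) >= abs(es))) / (
        1.0 + len(same_sign)
    )
    return float(es), float(nes), float(p)


def classify_state(nes: float) -> str:
    """Activated iff NES >= +1, inhibited iff NES <= -1, else indeterminate
    (symmetric reading of the score > 1 / < 1 rule)."""
    if not np.isfinite(nes):
        return STATE_INDETERMINATE
    if nes >= 1.0:
        return STATE_ACTIVATED
    if nes <= -1.0:
        return STATE_INHIBITED
    return STATE_INDETERMINATE


def score_kinases(
    ranked: pd.Series,
    substrate_sets: Mapping[str, Iterable[str]],
    context: str,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    weight_exponent: float = DEFAULT_WEIGHT,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> list[KinaseActivity]:
    """Activity scores for a family of kinases against one ranked list.

    Each kinase gets an independent child seed derived from ``seed`` (stable
    under kinase-id order), so single-kinase reruns reproduce.  Kinases whose
    substrate overlap with the ranked list is below ``min_set_size`` are
    reported as skipped rather than dropped.
    """
    rank_ids = set(ranked.index)
    out: list[KinaseActivity] = []
    kin_ids = sorted(substrate_sets)
    seeds = np.random.SeedSequence(seed).spawn(len(kin_ids))
    for kid, ss in zip(kin_ids, seeds):
        overlap = set(substrate_sets[kid]) & rank_ids
        if len(overlap) < min_set_size:
            out.append(
                KinaseActivity(
                    kid, context, float("nan"), float("nan"), float("nan"),
                    len(overlap), STATE_INDETERMINATE,
                    note=f"skipped: {len(overlap)} substrates in rank "
                    f"(< {min_set_size})",
                )
            )
            continue
        es, nes, p = normalize_and_test(
            ranked, overlap, n_permutations, np.random.default_rng(ss),
            weight_exponent,
        )
        note = "" if np.isfinite(nes) else "no same-sign permutations"
        out.append(
            KinaseActivity(kid, context, es, nes, p, len(overlap),
                           classify_state(nes), note)
        )
    n_scored = sum(1 for a in out if not a.note.startswith("skipped"))
    logger.info("kinase activity in %s: %d scored, %d skipped",
                context, n_scored, len(out) - n_scored)
    return out


def activities_to_frame(activities: Sequence[KinaseActivity]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kinase_id": [a.kinase_id for a in activities],
            "context": [a.context for a in activities],
            "es": [a.es for a in activities],
            "nes": [a.nes for a in activities],
            "p_perm": [a.p_perm for a in activities],
            "n_substrates": [a.n_substrates_in_rank for a in activities],
            "state": [a.state for a in activities],
            "note": [a.note for a in activities],
        }
    )


def top_activities(
    activities: Sequence[KinaseActivity], top_k: int = 10
) -> pd.DataFrame:
    """Top-k activated and top-k inhibited kinases by NES (the per-context
    bar-chart view)."""
    df = activities_to_frame(activities)
    df = df[np.isfinite(df["nes"])]
    act = df[df["state"] == STATE_ACTIVATED].sort_values(
        ["nes", "kinase_id"], ascending=[False, True]
    ).head(top_k)
    inh = df[df["state"] == STATE_INHIBITED].sort_values(
        ["nes", "kinase_id"], ascending=[True, True]
    ).head(top_k)
    return pd.concat([act, inh], ignore_index=True)
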