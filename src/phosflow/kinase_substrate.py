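"""Kinase-substrate prediction by peptide-similarity scoring.

Each kinase is represented by exemplar substrate 13-mers; a candidate site
is scored as the mean, over exemplars, of the position-summed amino-acid
substitution similarity (BLOSUM62; '_' padding scores 0) between its window
and the exemplar.  Per-kinase score thresholds are calibrated to a target
false-positive rate on background windows of the kinase's central-residue
class (the "medium" setting corresponds to fpr = 0.05).  Predictions can be
filtered by protein-protein interaction evidence: the unordered (kinase
protein, substrate protein) pair must be a known edge (self-pairs always
pass).

Also houses the kinase/phosphatase census against an annotated catalogue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .model import PAD, PhosphoSite, ProteinRecord, extract_window, percentage
from .motifs import N_CODES, PAD_CODE, encode_windows

logger = logging.getLogger("phosflow")

DEFAULT_FPR = 0.05  # the "medium" stringency
MIN_BACKGROUND = 200


def _blosum62_lookup() -> np.ndarray:
    """(N_CODES x N_CODES) similarity table over the window alphabet;
    'X' uses BLOSUM62's X column and '_' scores 0 against everything."""
    mat = substitution_matrices.load("BLOSUM62")
    lut = np.zeros((N_CODES, N_CODES), dtype=float)
    alpha = "ACDEFGHIKLMNPQRSTVWY" + "X"
    for i, a in enumerate(alpha):
        for j, b in enumerate(alpha):
            lut[i, j] = mat[a][b]
    lut[PAD_CODE, :] = 0.0
    lut[:, PAD_CODE] = 0.0
    return lut


_BLOSUM62 = _blosum62_lookup()


@dataclass
class KinaseProfile:
    """One kinase's scoring model: exemplar substrate windows plus the
    calibrated score threshold."""

    kinase_id: str
    family: str
    exemplar_windows: tuple[str, ...]
    protein_id: str | None = None
    threshold: float | None = None
    calibration_fpr: float | None = None

    def __post_init__(self) -> None:
        if not self.exemplar_windows:
            raise ValueError(f"{self.kinase_id}: at least one exemplar window required")
        widths = {len(w) for w in self.exemplar_windows}
        if len(widths) != 1:
            raise ValueError(f"{self.kinase_id}: exemplar windows have mixed lengths")

    @property
    def central_residue(self) -> str:
        w = self.exemplar_windows[0]
        return w[len(w) // 2]


def score_windows(kinase: KinaseProfile, windows: Sequence[str]) -> np.ndarray:
    """Vectorised similarity scores of many windows against a kinase."""
    win = encode_windows(list(windows))
    ex = encode_windows(list(kinase.exemplar_windows))
    # (n_windows, n_exemplars, width) similarity, summed over positions,
    # averaged over exemplars
    sims = _BLOSUM62[win[:, None, :], ex[None, :, :]]
    return sims.sum(axis=2).mean(axis=1)


def score_site(kinase: KinaseProfile, window: str) -> float:
    """Similarity score of a single window (mean over exemplars of the
    position-summed BLOSUM62 similarity)."""
    return float(score_windows(kinase, [window])[0])


def calibrate_threshold(
    kinase: KinaseProfile,
    background_windows: Sequence[str],
    fpr: float = DEFAULT_FPR,
) -> float:
    """Set the kinase's threshold to the empirical (1 - fpr) quantile of its
    scores on background windows of the same central-residue class."""
    if not 0 < fpr <= 1:
        raise ValueError("fpr must be in (0, 1]")
    centre = kinase.central_residue
    flank = len(kinase.exemplar_windows[0]) // 2
    bg = [w for w in background_windows if w[flank] == centre]
    if len(bg) < MIN_BACKGROUND:
        raise ValueError(
            f"{kinase.kinase_id}: {len(bg)} background windows of class "
            f"{centre!r}; at least {MIN_BACKGROUND} required"
        )
    scores = score_windows(kinase, bg)
    # "higher" interpolation: fpr = 1 passes everything, fpr -> 0 converges
    # to the background maximum
    threshold = float(np.quantile(scores, 1.0 - fpr, method="higher"))
    kinase.threshold = threshold
    kinase.calibration_fpr = fpr
    return threshold


@dataclass(frozen=True)
class KSRelation:
    """A predicted kinase -> site regulatory relation."""

    kinase_id: str
    site_id: str
    score: float
    passed_ppi: bool


def predict_relations(
    kinases: Sequence[KinaseProfile],
    sites: Sequence[PhosphoSite],
    ppi_edges: Iterable[frozenset[str]] | None = None,
    require_ppi: bool = True,
) -> list[KSRelation]:
    """Emit (kinase, site) relations with score >= the kinase threshold.

    With ``require_ppi``, the unordered (kinase protein, site protein) pair
    must additionally be present in ``ppi_edges``; self-pairs always pass.
    Kinases must be calibrated first.
    """
    ppi = set(ppi_edges) if ppi_edges is not None else set()
    windows = [s.window for s in sites]
    relations: list[KSRelation] = []
    for kin in kinases:
        if kin.threshold is None:
            raise ValueError(f"{kin.kinase_id}: threshold not calibrated")
        scores = score_windows(kin, windows)
        for site, sc in zip(sites, scores):
            if sc < kin.threshold:
                continue
            if kin.protein_id is not None and site.protein_id == kin.protein_id:
                passed = True  # self-substrate
            else:
                passed = frozenset((kin.protein_id, site.protein_id)) in ppi
            if require_ppi and not passed:
                continue
            relations.append(KSRelation(kin.kinase_id, site.site_id, float(sc), passed))
    logger.info(
        "predicted %d kinase-substrate relations (%d kinases, %d sites, ppi=%s)",
        len(relations), len(kinases), len(sites), require_ppi,
    )
    return relations


def relations_to_frame(relations: Sequence[KSRelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kinase_id": [r.kinase_id for r in relations],
            "site_id": [r.site_id for r in relations],
            "score": [r.score for r in relations],
            "passed_ppi": [r.passed_ppi for r in relations],
        }
    )


def substrate_sets(relations: Sequence[KSRelation]) -> dict[str, set[str]]:
    """Group predicted relations into kinase -> substrate site_id sets."""
    out: dict[str, set[str]] = {}
    for r in relations:
        out.setdefault(r.kinase_id, set()).add(r.site_id)
    return out


# ---------------------------------------------------------------------------
# background windows and synthetic profiles


def proteome_windows(
    proteome: Sequence[ProteinRecord],
    residue: str,
    flank: int = 6,
    max_windows: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """All (or a random subsample of) windows centred on ``residue``
    extracted from the proteome — the default null population for motif
    discovery and threshold calibration."""
    windows = [
        extract_window(prot, i + 1, flank)
        for prot in proteome
        for i, c in enumerate(prot.sequence)
        if c == residue
    ]
    if max_windows is not None and len(windows) > max_windows:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(len(windows), size=max_windows, replace=False)
        windows = [windows[i] for i in sorted(idx)]
    return windows


def profiles_from_truth(
    sites: Sequence[PhosphoSite],
    truth,
    n_exemplars: int = 20,
    rng: np.random.Generator | None = None,
) -> list[KinaseProfile]:
    """Build kinase profiles from a synthetic study's ground truth by
    sampling exemplar windows among each kinase's substrate sites (the
    synthetic stand-in for a curated exemplar-substrate table)."""
    rng = rng or np.random.default_rng(0)
    window_of = {s.site_id: s.window for s in sites}
    profiles = []
    for kid in sorted(truth.substrates):
        sub = list(truth.substrates[kid])
        if not sub:
            continue
        take = min(n_exemplars, len(sub))
        idx = rng.choice(len(sub), size=take, replace=False)
        profiles.append(
            KinaseProfile(
                kinase_id=kid,
                family="synthetic",
                exemplar_windows=tuple(window_of[sub[i]] for i in sorted(idx)),
                protein_id=truth.kinase_proteins.get(kid),
            )
        )
    return profiles


def write_kinase_profiles(profiles: Sequence[KinaseProfile], path) -> None:
    """Exemplar TSV: one row per (kinase, exemplar window)."""
    rows = [
        {
            "kinase_id": k.kinase_id,
            "family": k.family,
            "protein_id": k.protein_id or "",
            "window": w,
        }
        for k in profiles
        for w in k.exemplar_windows
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_kinase_profiles(path) -> list[KinaseProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    profiles = []
    for kid, g in df.groupby("kinase_id", sort=True):
        pid = g["protein_id"].iloc[0]
        profiles.append(
            KinaseProfile(
                kinase_id=str(kid),
                family=str(g["family"].iloc[0]),
                exemplar_windows=tuple(g["window"]),
                protein_id=str(pid) if pid and not pd.isna(pid) else None,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# kinase / phosphatase census


def census(
    proteins_detected: Iterable[str],
    catalogue: Mapping[str, str],
    background_size: int | None = None,
) -> dict:
    """Census of detected catalogue members (kinases or phosphatases).

    ``catalogue`` maps protein_id -> family label.  Returns overall counts
    with percentages (detected/catalogue, and detected/background when a
    background size is given) plus a per-family table with the detected
    share of the catalogue (2 decimals) and each family's share of the
    detected set (1 decimal).
    """
    detected = set(proteins_detected)
    hits = {p for p in detected if p in catalogue}
    families = sorted(set(catalogue.values()))
    rows = []
    for fam in families:
        members = {p for p, f in catalogue.items() if f == fam}
        fam_hits = hits & members
        rows.append(
            {
                "family": fam,
                "n_catalogue": len(members),
                "n_detected": len(fam_hits),
                "pct_of_catalogue": percentage(len(fam_hits), len(members), 2)
                if members
                else 0.0,
                "share_of_detected": percentage(len(fam_hits), len(hits), 1)
                if hits
                else 0.0,
            }
        )
    out = {
        "n_catalogue": len(catalogue),
        "n_detected": len(hits),
        "pct_of_catalogue": percentage(len(hits), len(catalogue), 1)
        if catalogue
        else 0.0,
        "families": pd.DataFrame(rows),
    }
    if background_size:
        out["pct_of_background"] = percentage(len(hits), background_size, 1)
    return out
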