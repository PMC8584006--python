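"""Synthetic phosphoproteomics study generator.

Produces a fully specified study — proteome, phosphosites, kinase ground
truth and TMT-like intensities over three conditions — with the statistical
structure the downstream stages assume:

* S/T/Y site proportions near 83/12/5 and a sites-per-protein distribution
  dominated by single-site proteins (56.1% with one site, 21.7% with two);
* per-kinase consensus motifs planted into the flanking sequence of true
  substrate sites (e.g. proline-directed [SP], basophilic [RxxS], [GS]);
* lognormal TMT-like intensities (normal on the log2 scale) across
  conditions x replicates, with planted per-kinase activity shifts that
  propagate multiplicatively to substrate-site ratios.

Everything is deterministic under the config seed: the tuple (proteome,
sites, ground truth, intensities) is byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AA20,
    PhosphoSite,
    ProteinRecord,
    QuantTable,
    extract_window,
)
from .motifs import pattern_string

logger = logging.getLogger("phosflow")

# UniProt-average amino-acid frequencies (normalised to sum exactly to 1 below)
_RAW_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}
_TOTAL = sum(_RAW_AA_FREQUENCIES.values())
DEFAULT_AA_FREQUENCIES: dict[str, float] = {
    a: f / _TOTAL for a, f in _RAW_AA_FREQUENCIES.items()
}


@dataclass(frozen=True)
class KinaseMotif:
    """Consensus recognition motif of one synthetic kinase: the central
    phospho-residue plus fixed (offset, residue) flanking positions."""

    kinase_id: str
    central: str
    fixed: tuple[tuple[int, str], ...] = ()

    @property
    def pattern(self) -> str:
        return pattern_string(self.central, self.fixed)


# 13 Ser, 5 Thr and 2 Tyr kinases.  KIN01-KIN03 carry the field-classic
# single-position motifs [SP], [RxxS] and [GS]; the rest carry two-position
# consensi on distinct (offset, residue) pairs so their substrate windows are
# separable by similarity scoring without colliding in motif discovery.
DEFAULT_MOTIF_LIBRARY: tuple[KinaseMotif, ...] = (
    KinaseMotif("KIN01", "S", ((1, "P"),)),             # [SP]
    KinaseMotif("KIN02", "S", ((-3, "R"),)),            # [RxxS]
    KinaseMotif("KIN03", "S", ((-1, "G"),)),            # [GS]
    KinaseMotif("KIN04", "S", ((-3, "K"), (1, "D"))),
    KinaseMotif("KIN05", "S", ((-2, "P"), (2, "P"))),
    KinaseMotif("KIN06", "S", ((-4, "R"), (3, "L"))),
    KinaseMotif("KIN07", "S", ((-6, "K"), (1, "E"))),
    KinaseMotif("KIN08", "S", ((-2, "I"), (2, "F"))),
    KinaseMotif("KIN09", "S", ((-1, "D"), (4, "R"))),
    KinaseMotif("KIN10", "S", ((-3, "F"), (1, "G"))),
    KinaseMotif("KIN11", "S", ((-2, "R"), (2, "K"))),
    KinaseMotif("KIN12", "S", ((-1, "A"), (5, "P"))),
    KinaseMotif("KIN13", "S", ((-4, "L"), (1, "N"))),
    KinaseMotif("KIN14", "T", ((1, "P"),)),             # [TP]
    KinaseMotif("KIN15", "T", ((-2, "P"), (1, "P"))),   # [PxTP]
    KinaseMotif("KIN16", "T", ((-3, "R"),)),            # [RxxT]
    KinaseMotif("KIN17", "T", ((-1, "G"), (2, "R"))),
    KinaseMotif("KIN18", "T", ((-4, "K"), (1, "S"))),
    KinaseMotif("KIN19", "Y", ((-4, "R"),)),            # [RxxxY]
    KinaseMotif("KIN20", "Y", ((-5, "S"),)),            # [SxxxxY]
)

# five kinases with planted activity shifts on the ripening contrast:
# ratio > 1 -> activated in the numerator condition, < 1 -> inhibited
DEFAULT_PLANTED_ACTIVITIES: tuple[tuple[str, tuple[str, str], float], ...] = (
    ("KIN01", ("AC-B4", "AC-MG"), 2.0),
    ("KIN02", ("AC-B4", "AC-MG"), 0.5),
    ("KIN04", ("AC-B4", "AC-MG"), 1.8),
    ("KIN05", ("AC-B4", "AC-MG"), 0.55),
    ("KIN06", ("AC-B4", "AC-MG"), 1.6),
)


@dataclass
class SimConfig:
    """Full specification of a synthetic study.

    Defaults emulate the reference study design: three fruit-ripening
    conditions (wild-type mature-green and breaker+4, and the
    ripening-inhibitor mutant at breaker+4) with three replicates, ~2200
    sites over 1200 proteins, S/T/Y mix 83/12/5, and five kinases planted
    with >= 1.5-fold activity effects.
    """

    seed: int = 0
    n_proteins: int = 1200
    protein_length: tuple[float, float] = (400.0, 100.0)  # mean, sd
    min_protein_length: int = 50
    aa_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQUENCIES)
    )
    residue_mix: tuple[float, float, float] = (0.83, 0.12, 0.05)  # S, T, Y
    # P(k sites | protein), k = 1..len(pmf)
    sites_per_protein_pmf: tuple[float, ...] = (
        0.561, 0.217, 0.100, 0.060, 0.032, 0.020, 0.010
    )
    motif_library: tuple[KinaseMotif, ...] = DEFAULT_MOTIF_LIBRARY
    substrate_assignment_rate: float = 0.5
    conditions: tuple[str, ...] = ("AC-MG", "AC-B4", "rin-B4")
    replicates_per_condition: int = 3
    baseline_log_intensity: tuple[float, float] = (20.0, 1.5)  # log2 mean, sd
    noise_sd: float = 0.25  # log2 scale
    planted_activities: tuple[tuple[str, tuple[str, str], float], ...] = (
        DEFAULT_PLANTED_ACTIVITIES
    )
    strict_site_counts: bool = False  # error (vs truncate) when a protein
    # cannot host the drawn number of sites

    @property
    def n_kinases(self) -> int:
        return len(self.motif_library)

    def validate(self) -> None:
        for name, vec in (
            ("aa_frequencies", list(self.aa_frequencies.values())),
            ("residue_mix", list(self.residue_mix)),
            ("sites_per_protein_pmf", list(self.sites_per_protein_pmf)),
        ):
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(vec)!r})")
            if min(vec) < 0:
                raise ValueError(f"{name} has negative mass")
        if set(self.aa_frequencies) != set(AA20):
            raise ValueError("aa_frequencies must cover exactly the 20 standard residues")
        kin_ids = [k.kinase_id for k in self.motif_library]
        if len(set(kin_ids)) != len(kin_ids):
            raise ValueError("duplicate kinase ids in motif_library")
        for kid, comparison, ratio in self.planted_activities:
            if kid not in kin_ids:
                raise ValueError(f"planted activity for unknown kinase {kid!r}")
            if not all(c in self.conditions for c in comparison):
                raise ValueError(f"planted comparison {comparison} not in conditions")
            if ratio <= 0:
                raise ValueError("planted effects must be > 0")
        if not 0 <= self.substrate_assignment_rate <= 1:
            raise ValueError("substrate_assignment_rate must be in [0, 1]")
        if self.replicates_per_condition < 1:
            raise ValueError("need at least 1 replicate per condition")


@dataclass
class GroundTruth:
    """Planted truth of a synthetic study: kinase->site substrate edges,
    per-site condition effects (log2) and per-kinase planted state per
    comparison."""

    edges: tuple[tuple[str, str], ...]  # (kinase_id, site_id)
    substrates: dict[str, tuple[str, ...]]  # kinase_id -> site_ids
    kinase_proteins: dict[str, str]  # kinase_id -> protein_id
    condition_effects: dict[str, dict[str, float]]  # site_id -> cond -> log2
    kinase_states: dict[tuple[str, str], dict[str, str]]  # comparison -> kinase -> state

    def comparison_effect(self, site_id: str, comparison: tuple[str, str]) -> float:
        eff = self.condition_effects.get(site_id, {})
        return eff.get(comparison[0], 0.0) - eff.get(comparison[1], 0.0)

    def planted_kinases(self, comparison: tuple[str, str]) -> dict[str, str]:
        return dict(self.kinase_states.get(tuple(comparison), {}))


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    # deterministic per-stage generators derived from the single config seed
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


def simulate_proteome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[ProteinRecord]:
    """Generate the protein collection: i.i.d. residues from
    ``aa_frequencies``, lengths from a truncated normal (>= min length)."""
    config.validate()
    rng = rng or _stage_rng(config, 0)
    letters = np.array(list(AA20))
    freqs = np.array([config.aa_frequencies[a] for a in AA20], dtype=float)
    freqs = freqs / freqs.sum()
    mean, sd = config.protein_length
    lengths = np.maximum(
        np.rint(rng.normal(mean, sd, size=config.n_proteins)).astype(int),
        config.min_protein_length,
    )
    width = len(str(config.n_proteins))
    records = []
    for i, L in enumerate(lengths):
        seq = "".join(rng.choice(letters, size=L, p=freqs))
        records.append(ProteinRecord(f"P{i + 1:0{width}d}", seq))
    logger.info("simulated %d proteins, %d residues total", len(records), lengths.sum())
    return records


def plant_sites_and_motifs(
    config: SimConfig,
    proteome: list[ProteinRecord],
    rng: np.random.Generator | None = None,
    flank: int = 6,
) -> tuple[list[PhosphoSite], GroundTruth]:
    """Choose phosphosites and plant kinase consensus motifs.

    Per protein, a site count is drawn from ``sites_per_protein_pmf`` and
    positions are placed >= ``flank`` residues from either terminus with a
    minimum spacing of ``2*flank+1`` (so planted flanks never collide);
    central residues follow ``residue_mix``.  Each site becomes a true
    substrate of one kinase of its residue class with probability
    ``substrate_assignment_rate``; the kinase's fixed flanking residues are
    then written into the sequence.

    The passed ``proteome`` list is updated in place with the rewritten
    sequences so that site windows always match the returned proteins.
    """
    config.validate()
    rng = rng or _stage_rng(config, 1)
    pmf = np.asarray(config.sites_per_protein_pmf, dtype=float)
    pmf = pmf / pmf.sum()
    site_counts = rng.choice(np.arange(1, len(pmf) + 1), size=len(proteome), p=pmf)
    mix = np.asarray(config.residue_mix, dtype=float)
    mix = mix / mix.sum()

    seqs: dict[str, bytearray] = {}
    placed: list[tuple[str, int, str]] = []  # (protein_id, position, residue)
    spacing = 2 * flank + 1
    for prot, n_sites in zip(proteome, site_counts):
        L = len(prot.sequence)
        lo, hi = flank + 1, L - flank  # 1-based, full window inside sequence
        candidates = rng.permutation(np.arange(lo, hi + 1))
        chosen: list[int] = []
        for pos in candidates:
            if len(chosen) == n_sites:
                break
            if all(abs(pos - c) >= spacing for c in chosen):
                chosen.append(int(pos))
        if len(chosen) < n_sites:
            msg = (
                f"{prot.protein_id}: requested {n_sites} sites, placed {len(chosen)}"
            )
            if config.strict_site_counts:
                raise ValueError(msg)
            logger.warning("%s (truncated)", msg)
        residues = rng.choice(np.array(["S", "T", "Y"]), size=len(chosen), p=mix)
        seq = bytearray(prot.sequence.encode("ascii"))
        for pos, res in zip(sorted(chosen), residues):
            seq[pos - 1] = ord(res)
            placed.append((prot.protein_id, pos, str(res)))
        seqs[prot.protein_id] = seq

    # kinase assignment per residue class
    kinases_by_residue: dict[str, list[KinaseMotif]] = {}
    for k in config.motif_library:
        kinases_by_residue.setdefault(k.central, []).append(k)
    edges: list[tuple[str, str]] = []
    substrates: dict[str, list[str]] = {k.kinase_id: [] for k in config.motif_library}
    rate = config.substrate_assignment_rate
    for pid, pos, res in placed:
        pool = kinases_by_residue.get(res, [])
        if not pool or rng.random() >= rate:
            continue
        kin = pool[rng.integers(len(pool))]
        seq = seqs[pid]
        for off, aa in kin.fixed:
            seq[pos - 1 + off] = ord(aa)
        site_id = f"{pid}_{pos}{res}"
        edges.append((kin.kinase_id, site_id))
        substrates[kin.kinase_id].append(site_id)

    # rebuild proteome in place, then windows
    for i, prot in enumerate(proteome):
        proteome[i] = ProteinRecord(
            prot.protein_id, seqs[prot.protein_id].decode("ascii")
        )
    by_id = {p.protein_id: p for p in proteome}
    sites = [
        PhosphoSite(pid, pos, res, extract_window(by_id[pid], pos, flank))
        for pid, pos, res in placed
    ]

    # kinases are themselves proteins: assign each a distinct proteome entry
    kin_ids = [k.kinase_id for k in config.motif_library]
    host_ids = rng.choice(
        np.array([p.protein_id for p in proteome]), size=len(kin_ids), replace=False
    )
    kinase_proteins = dict(zip(kin_ids, (str(h) for h in host_ids)))

    # planted activity effects propagate to substrate-site condition effects
    condition_effects: dict[str, dict[str, float]] = {}
    kinase_states: dict[tuple[str, str], dict[str, str]] = {}
    for kid, comparison, ratio in config.planted_activities:
        comparison = tuple(comparison)
        state = "activated" if ratio > 1 else "inhibited"
        kinase_states.setdefault(comparison, {})[kid] = state
        for site_id in substrates[kid]:
            eff = condition_effects.setdefault(site_id, {})
            eff[comparison[0]] = eff.get(comparison[0], 0.0) + float(np.log2(ratio))

    truth = GroundTruth(
        edges=tuple(edges),
        substrates={k: tuple(v) for k, v in substrates.items()},
        kinase_proteins=kinase_proteins,
        condition_effects=condition_effects,
        kinase_states=kinase_states,
    )
    logger.info(
        "planted %d sites on %d proteins; %d substrate edges over %d kinases",
        len(sites), len({s.protein_id for s in sites}), len(edges), len(kin_ids),
    )
    return sites, truth


def simulate_intensities(
    config: SimConfig,
    sites: Sequence[PhosphoSite],
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> QuantTable:
    """TMT-like intensities: per site, log2 intensity = baseline +
    condition effect + N(0, noise_sd) per replicate, exponentiated to the
    raw intensity scale."""
    config.validate()
    rng = rng or _stage_rng(config, 2)
    n = len(sites)
    base_mean, base_sd = config.baseline_log_intensity
    baseline = rng.normal(base_mean, base_sd, size=n)
    samples: list[str] = []
    design: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}
    site_ids = [s.site_id for s in sites]
    effects = np.zeros((n, len(config.conditions)))
    for j, cond in enumerate(config.conditions):
        for i, sid in enumerate(site_ids):
            effects[i, j] = truth.condition_effects.get(sid, {}).get(cond, 0.0)
    for j, cond in enumerate(config.conditions):
        for r in range(config.replicates_per_condition):
            sample = f"{cond}.r{r + 1}"
            samples.append(sample)
            design[sample] = cond
            noise = (
                rng.normal(0.0, config.noise_sd, size=n)
                if config.noise_sd > 0
                else np.zeros(n)
            )
            columns[sample] = np.exp2(baseline + effects[:, j] + noise)
    quant = QuantTable(
        pd.DataFrame(columns, index=pd.Index(site_ids, name="site_id")), design
    )
    quant.validate()
    return quant


def synthetic_ppi(
    truth: GroundTruth,
    sites: Sequence[PhosphoSite],
    proteome: Sequence[ProteinRecord],
    extra_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
) -> set[frozenset[str]]:
    """Protein-protein interaction edges: every true (kinase protein,
    substrate protein) pair plus ``extra_fraction`` as many random pairs."""
    rng = rng or np.random.default_rng(0)
    protein_of = {s.site_id: s.protein_id for s in sites}
    edges = {
        frozenset((truth.kinase_proteins[k], protein_of[sid]))
        for k, sid in truth.edges
        if truth.kinase_proteins[k] != protein_of[sid]
    }
    ids = np.array([p.protein_id for p in proteome])
    n_extra = int(round(extra_fraction * len(edges)))
    while n_extra > 0:
        a, b = rng.choice(ids, size=2, replace=False)
        e = frozenset((str(a), str(b)))
        if e not in edges:
            edges.add(e)
            n_extra -= 1
    return edges


@dataclass
class SimStudy:
    """A complete simulated study bundle."""

    config: SimConfig
    proteome: list[ProteinRecord]
    sites: list[PhosphoSite]
    truth: GroundTruth
    quant: QuantTable
    ppi: set[frozenset[str]]


def simulate_study(config: SimConfig) -> SimStudy:
    """Run the three generator stages under the config seed and bundle the
    result; fully deterministic (seed fixed => byte-identical outputs)."""
    proteome = simulate_proteome(config)
    sites, truth = plant_sites_and_motifs(config, proteome)
    quant = simulate_intensities(config, sites, truth)
    ppi = synthetic_ppi(truth, sites, proteome, rng=_stage_rng(config, 3))
    return SimStudy(config, proteome, sites, truth, quant, ppi)
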