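"""Core domain types for site-level phosphoproteomics data.

The atomic unit of the pipeline is the :class:`PhosphoSite`: a serine,
threonine or tyrosine residue at a 1-based position in a protein, together
with its 13-mer flanking window (six residues either side, padded with
``'_'`` at protein termini).  Quantification lives in a :class:`QuantTable`
(site x sample intensity matrix plus a sample -> condition design), and each
two-condition contrast produces a :class:`ComparisonResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: the 20 standard amino-acid one-letter codes
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA20_SET = frozenset(AA20)

#: padding character for windows that overhang a protein terminus;
#: never matches any residue in motif matching
PAD = "_"

#: residues that can carry a phosphate group
PHOSPHO_RESIDUES = ("S", "T", "Y")

#: default flank length -> 13-mer windows
DEFAULT_FLANK = 6


class ParseError(ValueError):
    """Raised when an input file violates its grammar or an invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter alphabet (plus 'X' if the
    permissive reader mapped unknown characters)."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ParseError("protein_id must be non-empty")
        if len(self.sequence) < 1:
            raise ParseError(f"{self.protein_id}: empty sequence")

    def validate_alphabet(self) -> None:
        bad = set(self.sequence) - AA20_SET - {"X"}
        if bad:
            raise ParseError(
                f"{self.protein_id}: invalid characters {sorted(bad)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def extract_window(
    protein: "ProteinRecord | str", position: int, flank: int = DEFAULT_FLANK
) -> str:
    """Return the ``2*flank+1``-mer centred on ``position`` (1-based).

    Positions beyond either terminus are filled with '_'.  The centre
    character equals ``sequence[position - 1]``.
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not 1 <= position <= len(seq):
        raise IndexError(
            f"position {position} out of range 1..{len(seq)}"
        )
    i = position - 1
    left = seq[max(0, i - flank): i]
    right = seq[i + 1: i + 1 + flank]
    return PAD * (flank - len(left)) + left + seq[i] + right + PAD * (flank - len(right))


@dataclass(frozen=True)
class PhosphoSite:
    """One phosphorylation site with its flanking-sequence context.

    ``site_id`` is ``"<protein>_<position><residue>"``, e.g. ``"P1_97S"``.
    """

    protein_id: str
    position: int  # 1-based
    residue: str  # one of S, T, Y
    window: str  # length 2*flank+1, '_'-padded

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"residue must be one of {PHOSPHO_RESIDUES}, got {self.residue!r}")
        if len(self.window) % 2 == 0:
            raise ValueError("window length must be odd")
        centre = self.window[len(self.window) // 2]
        if centre != self.residue:
            raise ValueError(
                f"window centre {centre!r} does not match residue {self.residue!r}"
            )

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}_{self.position}{self.residue}"


def make_site(
    protein: ProteinRecord, position: int, flank: int = DEFAULT_FLANK
) -> PhosphoSite:
    """Build a PhosphoSite from a protein and a 1-based position."""
    window = extract_window(protein, position, flank)
    residue = protein.sequence[position - 1]
    if residue not in PHOSPHO_RESIDUES:
        raise ValueError(
            f"{protein.protein_id} position {position}: residue {residue!r} is not S/T/Y"
        )
    return PhosphoSite(protein.protein_id, position, residue, window)


@dataclass
class QuantTable:
    """Site x sample intensity matrix with its condition design.

    ``intensities`` is indexed by site_id with one column per sample;
    values are strictly positive raw-scale intensities.  ``design`` maps
    sample -> condition label.
    """

    intensities: pd.DataFrame
    design: dict[str, str]

    @property
    def sites(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.design[s], None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.design.get(s) == condition]

    def validate(self) -> None:
        missing = [s for s in self.samples if s not in self.design]
        if missing:
            raise ParseError(f"samples missing from design: {missing}")
        if not self.intensities.index.is_unique:
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise ParseError(f"duplicate site_id {dup!r}")
        vals = self.intensities.to_numpy()
        if np.isnan(vals).any():
            raise ParseError("missing intensities are not supported without an imputation policy")
        if (vals <= 0).any():
            raise ParseError("intensities must be strictly positive")

    def log2(self) -> pd.DataFrame:
        return np.log2(self.intensities)


#: differential status labels
STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"


@dataclass
class ComparisonResult:
    """Per-site differential statistics for one condition contrast.

    ``table`` is indexed by site_id (or protein_id for protein-level input)
    with columns log2fc, ratio, p, q, status.  ``comparison`` is the ordered
    (numerator, denominator) condition pair.
    """

    comparison: tuple[str, str]
    table: pd.DataFrame

    @property
    def name(self) -> str:
        return f"{self.comparison[0]}/{self.comparison[1]}"

    def significant(self) -> set[str]:
        """Items called up or down (status != ns)."""
        t = self.table
        return set(t.index[t["status"] != STATUS_NS])

    def up(self) -> set[str]:
        return set(self.table.index[self.table["status"] == STATUS_UP])

    def down(self) -> set[str]:
        return set(self.table.index[self.table["status"] == STATUS_DOWN])


@dataclass
class AnnotationTable:
    """Term -> protein membership used for Fisher-exact enrichment.

    Stored long-form: one row per (term, protein).  Namespaces (GO-BP,
    KEGG, family, ...) are free-text labels; populating the table is the
    caller's responsibility.
    """

    records: pd.DataFrame  # columns: term_id, term_name, namespace, protein_id

    REQUIRED = ("term_id", "term_name", "namespace", "protein_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ParseError(f"annotation table missing columns {missing}")

    def term_members(self, namespace: str | None = None) -> dict[str, set[str]]:
        recs = self.records
        if namespace is not None:
            recs = recs[recs["namespace"] == namespace]
        return {t: set(g["protein_id"]) for t, g in recs.groupby("term_id")}

    def term_names(self) -> dict[str, str]:
        return dict(zip(self.records["term_id"], self.records["term_name"]))


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention used for reported percentages)."""
    factor = 10.0 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def percentage(count: float, total: float, decimals: int = 1) -> float:
    """Percentage of ``count`` in ``total`` rounded half-up to ``decimals``."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_up(100.0 * count / total, decimals)
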