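"""Iterative phospho-motif discovery by position/residue binomial enrichment.

The algorithm is the classic motif-x scheme: starting from foreground and
background sets of 13-mer windows sharing a central residue, repeatedly find
the (offset, residue) pair whose foreground count is most improbably large
under the background frequency (binomial tail test), fix it, restrict both
sets to matching windows, and recurse.  A completed motif is accepted when
its final foreground support exceeds the occurrence threshold; its matching
foreground windows are then removed and the search restarts for the next
motif.

Thresholds default to a per-step p-value below 1e-6 and a final support
greater than 20 windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AA20, PAD

#: smallest p-value used when accumulating motif scores (avoids -log10(0))
_P_FLOOR = 1e-300


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Upper binomial tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError(f"require 0 < p0 < 1, got p0={p0}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


# ---------------------------------------------------------------------------
# window encoding

_CODE = np.full(256, -1, dtype=np.int16)
for _i, _a in enumerate(AA20):
    _CODE[ord(_a)] = _i
_CODE[ord("X")] = 20
_CODE[ord(PAD)] = 21
N_CODES = 22
PAD_CODE = 21


def encode_windows(windows: Sequence[str]) -> np.ndarray:
    """Encode equal-length windows as an (n, width) int16 matrix."""
    if len(windows) == 0:
        raise ValueError("empty window list")
    arr = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8)
    mat = _CODE[arr].reshape(len(windows), -1)
    if (mat < 0).any():
        raise ValueError("window contains a character outside the alphabet")
    return mat


@dataclass(frozen=True)
class Motif:
    """A fixed-position motif over a 13-mer window with its enrichment
    evidence.  ``steps`` records each accepted (offset, residue, k, n, p0, p)
    in discovery order; ``score`` is the sum of -log10(step p)."""

    central_residue: str
    fixed_positions: frozenset[tuple[int, str]]
    n_foreground_matches: int
    n_background_matches: int
    steps: tuple[tuple[int, str, int, int, float, float], ...]

    @property
    def pattern(self) -> str:
        return pattern_string(self.central_residue, self.fixed_positions)

    @property
    def score(self) -> float:
        return float(sum(-np.log10(max(s[5], _P_FLOOR)) for s in self.steps))

    def matches(self, window: str, flank: int = 6) -> bool:
        if window[flank] != self.central_residue:
            return False
        return all(window[flank + off] == res for off, res in self.fixed_positions)


def pattern_string(central: str, fixed: "frozenset[tuple[int, str]] | Sequence[tuple[int, str]]") -> str:
    """Compact pattern, e.g. {(-3,'R')} with central S -> ``"RxxS"``,
    {(+1,'P')} -> ``"SP"``.  Free positions are 'x'; flanking runs of free
    positions are trimmed."""
    fixed = dict(fixed)
    if not fixed:
        return central
    lo = min(min(fixed), 0)
    hi = max(max(fixed), 0)
    out = []
    for off in range(lo, hi + 1):
        if off == 0:
            out.append(central)
        else:
            out.append(fixed.get(off, "x"))
    return "".join(out)


def parse_pattern(pattern: str) -> tuple[str, frozenset[tuple[int, str]]]:
    """Inverse of :func:`pattern_string` for patterns with an S/T/Y centre."""
    centres = [i for i, c in enumerate(pattern) if c in "STY"]
    if not centres:
        raise ValueError(f"no S/T/Y centre in pattern {pattern!r}")
    # the centre is the unique S/T/Y position consistent with a compact
    # pattern; prefer the first (patterns like 'SP' or 'RxxS' are unambiguous
    # once flanking 'x' runs are trimmed)
    centre = centres[0]
    fixed = frozenset(
        (i - centre, c) for i, c in enumerate(pattern) if c != "x" and i != centre
    )
    return pattern[centre], fixed


# ---------------------------------------------------------------------------
# motif-x core


def _pair_counts(mat: np.ndarray, flank: int) -> np.ndarray:
    """Counts of each code at each offset: (n_codes, 2*flank+1)."""
    width = mat.shape[1]
    counts = np.zeros((N_CODES, width), dtype=np.int64)
    for j in range(width):
        counts[:, j] = np.bincount(mat[:, j], minlength=N_CODES)
    return counts


def _best_pair(
    fg: np.ndarray, bg: np.ndarray, flank: int
) -> tuple[float, int, str, int, int, float] | None:
    """Return (p, offset, residue, k, n, p0) for the most significant
    (offset, residue) pair, with the documented tie-break: smaller p, then
    larger foreground count, then smaller |offset|, then lexicographic
    residue.  Pairs whose background frequency is zero are skipped."""
    n_fg = fg.shape[0]
    fg_counts = _pair_counts(fg, flank)
    bg_counts = _pair_counts(bg, flank)
    width = fg.shape[1]
    # background denominators exclude '_' padding at each offset
    bg_valid = bg_counts[:20].sum(axis=0)

    best: tuple | None = None
    for j in range(width):
        off = j - flank
        if off == 0 or bg_valid[j] == 0:
            continue
        for code in range(20):
            k = int(fg_counts[code, j])
            nb = int(bg_counts[code, j])
            if nb == 0:
                continue  # p0 == 0: test undefined, pair skipped
            p0 = nb / bg_valid[j]
            if p0 >= 1.0:
                continue
            p = binomial_tail(k, n_fg, p0)
            key = (p, -k, abs(off), AA20[code])
            if best is None or key < best[0]:
                best = (key, off, AA20[code], k, n_fg, p0, p)
    if best is None:
        return None
    _, off, res, k, n, p0, p = best
    return (p, off, res, k, n, p0)


def motif_x(
    foreground: Sequence[str],
    background: Sequence[str],
    central_residue: str,
    p_threshold: float = 1e-6,
    min_occurrences: int = 20,
    min_inclusive: bool = False,
    flank: int = 6,
) -> list[Motif]:
    """Discover over-represented motifs among foreground windows.

    All windows must be length ``2*flank+1`` with ``central_residue`` at the
    centre.  A motif is accepted when at least one position was fixed and its
    final foreground support is ``> min_occurrences`` (``>=`` when
    ``min_inclusive``).  Accepted motifs' foreground windows are removed and
    the search restarts; motifs are returned in discovery order.
    """
    if len(foreground) == 0 or len(background) == 0:
        raise ValueError("foreground and background must be non-empty")
    width = 2 * flank + 1
    for w in list(foreground[:1]) + list(background[:1]):
        if len(w) != width:
            raise ValueError(f"windows must have length {width}")
    for name, group in (("foreground", foreground), ("background", background)):
        for w in group:
            if w[flank] != central_residue:
                raise ValueError(
                    f"{name} window {w!r} does not have centre {central_residue!r}"
                )

    fg_all = encode_windows(list(foreground))
    bg_all = encode_windows(list(background))
    motifs: list[Motif] = []

    def supported(count: int) -> bool:
        return count >= min_occurrences if min_inclusive else count > min_occurrences

    while fg_all.shape[0] > 0:
        fg, bg = fg_all, bg_all
        steps: list[tuple[int, str, int, int, float, float]] = []
        mask_all = np.ones(fg_all.shape[0], dtype=bool)
        while True:
            found = _best_pair(fg, bg, flank)
            if found is None:
                break
            p, off, res, k, n, p0 = found
            if p >= p_threshold:
                break
            steps.append((off, res, k, n, p0, p))
            code = _CODE[ord(res)]
            j = off + flank
            fg_keep = fg[:, j] == code
            fg = fg[fg_keep]
            bg = bg[bg[:, j] == code]
            sub = np.zeros_like(mask_all)
            sub[np.flatnonzero(mask_all)[fg_keep]] = True
            mask_all = sub
            if fg.shape[0] == 0 or bg.shape[0] == 0:
                break

        if not steps or not supported(fg.shape[0]):
            break
        motifs.append(
            Motif(
                central_residue=central_residue,
                fixed_positions=frozenset((s[0], s[1]) for s in steps),
                n_foreground_matches=int(fg.shape[0]),
                n_background_matches=int(bg.shape[0]),
                steps=tuple(steps),
            )
        )
        fg_all = fg_all[~mask_all]
    return motifs


def motifs_to_frame(motifs: Sequence[Motif]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pattern": [m.pattern for m in motifs],
            "central_residue": [m.central_residue for m in motifs],
            "n_foreground": [m.n_foreground_matches for m in motifs],
            "n_background": [m.n_background_matches for m in motifs],
            "score": [m.score for m in motifs],
            "step_p_values": [
                ";".join(f"{s[5]:.3e}" for s in m.steps) for m in motifs
            ],
        }
    )


# ---------------------------------------------------------------------------
# position-residue enrichment heatmap


def position_residue_heatmap(
    foreground: Sequence[str],
    background: Sequence[str],
    pseudo: float = 1e-4,
    mask_alpha: float | None = None,
    flank: int = 6,
) -> pd.DataFrame:
    """Log2 fold-enrichment of each residue at each non-central offset.

    Cell (a, o) = log2((fg_freq(a, o) + pseudo) / (bg_freq(a, o) + pseudo)).
    Frequencies exclude '_' padding from denominators.  When ``mask_alpha``
    is given, cells whose two-tailed binomial p exceeds it are set to 0.
    Returns a 20-residue x 12-offset DataFrame (offsets -flank..-1, +1..+flank).
    """
    fg = encode_windows(list(foreground))
    bg = encode_windows(list(background))
    fg_counts = _pair_counts(fg, flank)
    bg_counts = _pair_counts(bg, flank)
    fg_valid = fg_counts[:20].sum(axis=0).astype(float)
    bg_valid = bg_counts[:20].sum(axis=0).astype(float)

    offsets = [o for o in range(-flank, flank + 1) if o != 0]
    data = np.zeros((20, len(offsets)))
    for col, off in enumerate(offsets):
        j = off + flank
        if fg_valid[j] == 0 or bg_valid[j] == 0:
            continue
        f = fg_counts[:20, j] / fg_valid[j]
        b = bg_counts[:20, j] / bg_valid[j]
        cells = np.log2((f + pseudo) / (b + pseudo))
        if mask_alpha is not None:
            n = int(fg_valid[j])
            for code in range(20):
                p0 = b[code]
                if not 0 < p0 < 1:
                    cells[code] = 0.0
                    continue
                k = int(fg_counts[code, j])
                upper = float(stats.binom.sf(k - 1, n, p0)) if k > 0 else 1.0
                lower = float(stats.binom.cdf(k, n, p0))
                if min(1.0, 2 * min(upper, lower)) >= mask_alpha:
                    cells[code] = 0.0
        data[:, col] = cells
    return pd.DataFrame(data, index=list(AA20), columns=offsets)
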