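"""Iterative greedy extraction of independent linear motifs (motif-x style).

Starting from a foreground substrate set and the full-library background,
the most binomially over-represented (residue, position) cell is fixed when
its tail probability P(X >= k) falls at or below `alpha` and its foreground
support reaches `min_occurrence`; foreground and background are then reduced
to the matching sequences and the search repeats. When no cell qualifies the
accumulated fixed positions are emitted as one motif, its matching sequences
are removed from the remaining foreground, and the outer loop restarts.
Only over-representation is searched; conditional negative selection is not
describable by this procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AA_ALPHABET, CENTER_INDEX, PEPTIDE_LENGTH, POSITIONS, pos_to_index
from .specificity_stats import log10_binom_sf, residue_counts

DEFAULT_MIN_OCCURRENCE = 20
DEFAULT_ALPHA = 1e-6


@dataclass(frozen=True)
class Motif:
    """A linear motif: fixed (position -> residue) cells with their statistics.

    `p_chain` holds the binomial tail probability of each fixation step, in
    order; `support` is the number of foreground sequences matching all fixed
    positions.
    """

    fixed_positions: tuple[tuple[int, str], ...]
    support: int
    p_chain: tuple[float, ...]

    def matches(self, seq: str) -> bool:
        return all(seq[pos_to_index(pos)] == aa for pos, aa in self.fixed_positions)

    @property
    def pattern(self) -> str:
        """Serialized form, e.g. ``xxxxxx[L]Yx[P]xxxxx``."""
        out = []
        fixed = dict(self.fixed_positions)
        for i in range(PEPTIDE_LENGTH):
            pos = i - CENTER_INDEX
            if pos == 0:
                out.append("Y")
            elif pos in fixed:
                out.append(f"[{fixed[pos]}]")
            else:
                out.append("x")
        return "".join(out)


def _best_cell(
    foreground: list[str],
    background: list[str],
    fixed: dict[int, str],
    min_occurrence: int,
    log10_alpha: float,
) -> tuple[int, str, float, int] | None:
    """Most significant qualifying (position, residue) cell, or None.

    Ties on the tail probability break to the lower |position|, negative
    before positive, then alphabetical residue, so extraction is
    deterministic.
    """
    n = len(foreground)
    n_bg = len(background)
    fg_counts = residue_counts(foreground)
    bg_counts = residue_counts(background)
    best: tuple[float, int, int, str] | None = None  # sort key
    for pos in sorted(POSITIONS, key=lambda q: (abs(q), q)):
        if pos == 0 or pos in fixed:
            continue
        for aa in AA_ALPHABET:
            if aa == "Y":
                continue  # multi-tyrosine motifs are uninterpretable; never fixed
            k = int(fg_counts.at[aa, pos])
            if k < min_occurrence:
                continue
            p = bg_counts.at[aa, pos] / n_bg
            log10_tail = log10_binom_sf(k, n, float(p))
            if log10_tail > log10_alpha:
                continue
            key = (log10_tail, abs(pos), pos, aa)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    log10_tail, _, pos, aa = best
    k = int(fg_counts.at[aa, pos])
    return pos, aa, log10_tail, k


def extract_motifs(
    foreground: list[str],
    background: list[str],
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
    alpha: float = DEFAULT_ALPHA,
) -> list[Motif]:
    """Extract disjoint linear motifs from `foreground` against `background`.

    Greedy recursion with background re-filtering at each fixation step;
    sequences matching an emitted motif are removed from the foreground
    before the next motif is sought. Deterministic.
    """
    if not foreground or not background:
        raise ValueError("foreground and background must be non-empty")
    log10_alpha = float(np.log10(alpha))
    remaining = list(foreground)
    motifs: list[Motif] = []
    while remaining:
        fg = list(remaining)
        bg = list(background)
        fixed: dict[int, str] = {}
        p_chain: list[float] = []
        while True:
            cell = _best_cell(fg, bg, fixed, min_occurrence, log10_alpha)
            if cell is None:
                break
            pos, aa, log10_tail, _ = cell
            fixed[pos] = aa
            p_chain.append(10.0 ** log10_tail)
            idx = pos_to_index(pos)
            fg = [s for s in fg if s[idx] == aa]
            bg = [s for s in bg if s[idx] == aa]
        if not fixed:
            break
        motif = Motif(tuple(sorted(fixed.items())), len(fg), tuple(p_chain))
        motifs.append(motif)
        remaining = [s for s in remaining if not motif.matches(s)]
    return motifs


def motifs_to_rows(motifs: list[Motif]) -> list[dict]:
    """Flatten motifs for tabular output (one row per motif)."""
    return [
        {
            "pattern": m.pattern,
            "support": m.support,
            "n_fixed": len(m.fixed_positions),
            "p_chain": ";".join(f"{p:.3e}" for p in m.p_chain),
        }
        for m in motifs
    ]
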