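"""Enrichment and motif statistics around N-phosphosites.

Two questions are answered here. First, do phosphosites prefer a structural
category (exposure, secondary structure, order/disorder) relative to
non-phosphorylated H/K/R residues? That is quantified by the enrichment
ratio

    E-ratio = (m * N) / (M * n)

where m of M phosphosites and n of N non-phosphosites fall in the category,
with a 2x2 chi-squared test (no continuity correction) for significance.

Second, which sequence motifs surround the sites? A greedy motif-x-style
search repeatedly fixes the single (offset, residue) constraint whose
foreground frequency is most binomially surprising given the current
background frequency, reduces both sets to matching windows, and accepts the
accumulated motif when its score (sum of -log10 p over steps, base 10)
reaches the score floor and enough foreground windows remain. Accepted
motifs' windows are removed and the search repeats for further motifs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .seqio import CANONICAL_AA, PeptideWindow, SiteAnnotation

logger = logging.getLogger(__name__)

DEFAULT_MIN_OCC = 10
DEFAULT_MIN_SCORE = 5.0
DEFAULT_P_STEP = 1e-4  # per-step binomial cutoff, the motif-x convention

_P_FLOOR = 1e-300  # keeps -log10(p) finite when sf underflows


@dataclass(frozen=True)
class EnrichmentInput:
    m: int  # phosphosites in category
    M: int  # all phosphosites
    n: int  # non-phosphosites in category
    N: int  # all non-phosphosites

    def __post_init__(self) -> None:
        if not (0 <= self.m <= self.M and 0 <= self.n <= self.N):
            raise ValueError("category counts exceed their totals")
        if self.M <= 0 or self.N <= 0:
            raise ValueError("totals must be positive")


def e_ratio(x: EnrichmentInput) -> tuple[float, float]:
    """Enrichment ratio (m*N)/(M*n) and the chi-squared p-value of the 2x2
    table [[m, M-m], [n, N-n]] without continuity correction."""
    if x.n == 0:
        raise ZeroDivisionError("E-ratio undefined: no non-phosphosites in "
                                "category (n = 0)")
    ratio = (x.m * x.N) / (x.M * x.n)
    table = np.array([[x.m, x.M - x.m], [x.n, x.N - x.n]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ratio, math.nan
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ratio, float(p)


def propensity_table(sites: Sequence[SiteAnnotation],
                     background: Sequence[SiteAnnotation],
                     category_field: str) -> dict[str, dict[str, float]]:
    """Per-category enrichment of phosphosites vs background residues.

    ``category_field`` is one of ``exposure``, ``structure_class``,
    ``disorder``. Entries missing the field are excluded from the totals and
    reported under the ``_excluded`` key; categories absent from the
    background are skipped with a warning (the ratio is undefined there).
    """
    if category_field not in ("exposure", "structure_class", "disorder"):
        raise ValueError(f"unknown category field {category_field!r}")
    fg = [getattr(s, category_field) for s in sites]
    bg = [getattr(s, category_field) for s in background]
    fg_known = [v for v in fg if v is not None]
    bg_known = [v for v in bg if v is not None]
    M, N = len(fg_known), len(bg_known)
    if M == 0 or N == 0:
        raise ValueError("no annotated entries for field " + category_field)
    out: dict[str, dict[str, float]] = {
        "_excluded": {"sites": len(fg) - M, "background": len(bg) - N},
    }
    for level in sorted(set(fg_known) | set(bg_known)):
        m = fg_known.count(level)
        n = bg_known.count(level)
        if n == 0:
            logger.warning("category %s=%s absent from background; skipped",
                           category_field, level)
            continue
        ratio, p = e_ratio(EnrichmentInput(m=m, M=M, n=n, N=N))
        out[level] = {"m": m, "M": M, "n": n, "N": N,
                      "e_ratio": ratio, "p": p}
    return out


# ---------------------------------------------------------------------------
# motif-x style discovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifResult:
    """A discovered motif: fixed (offset, residue) constraints with the
    per-step binomial p-values, the total score sum(-log10 p), and the count
    of foreground windows matching every constraint."""

    steps: tuple[tuple[int, str, float], ...]
    score: float
    fg_occurrences: int
    center: str
    width: int

    @property
    def pattern(self) -> str:
        """Dot-padded window pattern, e.g. ``....S P....`` style string with
        the center residue in the middle."""
        half = self.width // 2
        chars = ["."] * self.width
        chars[half] = self.center
        for offset, residue, _ in self.steps:
            chars[half + offset] = residue
        return "".join(chars)

    def matches(self, window: PeptideWindow) -> bool:
        half = len(window) // 2
        return all(window.peptide[half + off] == res
                   for off, res, _ in self.steps)


def _binom_upper_tail(k: int, n: int, p: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p)."""
    return float(stats.binom.sf(k - 1, n, p))


def discover_motifs(fg: Sequence[PeptideWindow], bg: Sequence[PeptideWindow],
                    min_occ: int = DEFAULT_MIN_OCC,
                    min_score: float = DEFAULT_MIN_SCORE,
                    p_step: float = DEFAULT_P_STEP,
                    max_motifs: int = 50) -> list[MotifResult]:
    """Greedy iterative motif search over equal-length windows.

    Each step proposes the (offset, residue) pair with the smallest exact
    binomial upper-tail p-value of its foreground count given the current
    background frequency; only canonical residues at non-center offsets are
    proposed, and a step must keep at least ``min_occ`` foreground windows.
    Ties break by smaller offset magnitude, then alphabetical residue (and
    upstream before downstream at equal magnitude), so results are
    deterministic. A motif is emitted when its accumulated score reaches
    ``min_score`` with at least ``min_occ`` matching windows; its windows are
    then removed from the foreground and the search restarts.
    """
    if not fg or len(fg) < min_occ:
        return []
    width = len(fg[0])
    if any(len(w) != width for w in list(fg) + list(bg)):
        raise ValueError("foreground and background windows must share "
                         "one length")
    centers = {w.center_residue for w in fg}
    if len(centers) != 1:
        raise ValueError(f"foreground windows mix center residues {centers}")
    center = next(iter(centers))
    half = width // 2

    def to_matrix(windows):
        return np.array([list(w.peptide.encode("ascii")) for w in windows],
                        dtype=np.uint8)

    fg_mat = to_matrix(fg)
    bg_mat = to_matrix(bg)
    aa_codes = np.frombuffer(CANONICAL_AA.encode("ascii"), dtype=np.uint8)
    offsets = [o for o in range(-half, half + 1) if o != 0]
    # candidate order encodes the tie-break: |offset|, residue, upstream first
    order = sorted(
        ((off, i) for off in offsets for i in range(20)),
        key=lambda t: (abs(t[0]), CANONICAL_AA[t[1]], t[0] > 0),
    )

    results: list[MotifResult] = []
    remaining = fg_mat
    while len(remaining) >= min_occ and len(results) < max_motifs:
        cur_fg = remaining
        cur_bg = bg_mat
        steps: list[tuple[int, str, float]] = []
        fixed: set[int] = set()
        while True:
            n_fg, n_bg = len(cur_fg), len(cur_bg)
            if n_fg < min_occ or n_bg == 0:
                break
            best = None
            for off, aa_i in order:
                if off in fixed:
                    continue
                col = half + off
                k = int((cur_fg[:, col] == aa_codes[aa_i]).sum())
                if k < min_occ:
                    continue
                kb = int((cur_bg[:, col] == aa_codes[aa_i]).sum())
                p_bg = kb / n_bg if kb > 0 else 1.0 / (n_bg + 1.0)
                p = _binom_upper_tail(k, n_fg, p_bg)
                if p <= p_step and (best is None or p < best[0]):
                    best = (p, off, aa_i)
            if best is None:
                break
            p, off, aa_i = best
            residue = CANONICAL_AA[aa_i]
            steps.append((off, residue, max(p, _P_FLOOR)))
            fixed.add(off)
            col = half + off
            cur_fg = cur_fg[cur_fg[:, col] == aa_codes[aa_i]]
            cur_bg = cur_bg[cur_bg[:, col] == aa_codes[aa_i]]
        if not steps:
            break
        score = sum(-math.log10(p) for _, _, p in steps)
        if score < min_score or len(cur_fg) < min_occ:
            break
        motif = MotifResult(steps=tuple(steps), score=score,
                            fg_occurrences=int(len(cur_fg)), center=center,
                            width=width)
        results.append(motif)
        # remove matched windows from the foreground, restore full background
        mask = np.ones(len(remaining), dtype=bool)
        for off, residue, _ in steps:
            mask &= remaining[:, half + off] == ord(residue)
        remaining = remaining[~mask]
    return results


def write_motifs(motifs: Sequence[MotifResult], path) -> None:
    """Motif table: pattern, score, occurrences, and the ordered steps."""
    with open(path, "w") as fh:
        fh.write("pattern\tscore\tfg_occurrences\tsteps\n")
        for m in motifs:
            steps = ";".join(f"{off:+d}:{res}:{p:.3e}" for off, res, p in m.steps)
            fh.write(f"{m.pattern}\t{m.score:.4f}\t{m.fg_occurrences}\t{steps}\n")
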