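"""Peptide-window feature encodings: AAC, HQI8 and BLOSUM62 rows.

Three encodings of a 31-residue phosphosite-centered window are supported,
alone or concatenated (always in the fixed order AAC, HQI8, BLOSUM62):

* **AAC** — amino-acid composition: the frequency of each of the 20 canonical
  amino acids among the canonical residues of the window (length 20).
* **HQI8** — eight "high-quality" AAindex physicochemical property indices
  selected by fuzzy clustering of the full AAindex; each residue contributes
  an 8-long block, position-major (31 x 8 = 248).
* **BLOSUM62** — each residue contributes its 20-long BLOSUM62 substitution
  row, position-major (31 x 20 = 620); the pad character ``-`` uses the
  matrix's "any residue" (X) row, so terminal padding carries the neutral
  substitution profile rather than zeros.

The seven admissible combinations therefore have dimensions
20, 248, 620, 268 (AAC+HQI8), 640 (AAC+BLOSUM62), 868 (HQI8+BLOSUM62) and
888 (all three).

Pad and ambiguity letters are handled identically ("pad-equivalent"): zero
blocks for HQI8, the X row for BLOSUM62, and exclusion from the AAC
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import AMBIGUOUS_AA, CANONICAL_AA, PAD, PeptideWindow

ENCODERS = ("AAC", "HQI8", "BLOSUM62")

#: per-encoder vector length for a 31-residue window
ENCODER_DIMS = {"AAC": 20, "HQI8": 248, "BLOSUM62": 620}


class EncodingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# HQI8 table
# ---------------------------------------------------------------------------
# The eight AAindex entries of the published high-quality index set (HQI8),
# selected as fuzzy-cluster centres of the 500+ AAindex properties. Values
# transcribed from AAindex, amino acids in the order ACDEFGHIKLMNPQRSTVWY.
# Override with hqi8_from_table() to use a different property set.

HQI8_INDEX_IDS = (
    "BLAM930101",  # alpha-helix propensity (position 44, T4 lysozyme)
    "BIOV880101",  # information value for accessibility (35% cutoff)
    "MAXF760101",  # normalized frequency of alpha-helix
    "TSAJ990101",  # residue volume incl. crystallographic waters
    "NAKH920108",  # AA composition of membrane-spanning segments
    "CEDJ970104",  # AA composition of intracellular proteins (%)
    "LIFS790101",  # conformational preference for all-beta strands
    "MIYS990104",  # optimized relative partition energies
)

_HQI8_RAW = {
    #        BLAM9   BIOV8  MAXF7  TSAJ9   NAKH9  CEDJ9  LIFS7  MIYS9
    "A": ( 0.96,   16.0,  1.43,  89.3,   9.36,  7.9,  0.92, -0.04),
    "C": ( 0.42,  168.0,  0.94, 102.5,   2.56,  1.9,  1.16, -0.38),
    "D": ( 0.42,  -78.0,  0.92, 114.4,   0.94,  5.5,  0.48,  0.19),
    "E": ( 0.53, -106.0,  1.67, 138.8,   0.94,  7.1,  0.61,  0.23),
    "F": ( 0.59,  189.0,  1.19, 190.8,  10.99,  3.9,  1.25, -0.38),
    "G": ( 0.00,  -13.0,  0.46,  63.8,   6.17,  7.1,  0.61,  0.09),
    "H": ( 0.57,   50.0,  0.98, 157.5,   0.47,  2.1,  0.93, -0.04),
    "I": ( 0.84,  151.0,  1.04, 163.0,  13.73,  5.2,  1.81, -0.34),
    "K": ( 0.73, -141.0,  1.27, 165.1,   0.58,  6.7,  0.70,  0.33),
    "L": ( 0.92,  145.0,  1.36, 163.1,  16.64,  8.6,  1.30, -0.37),
    "M": ( 0.86,  124.0,  1.53, 165.8,   3.93,  2.4,  1.19, -0.30),
    "N": ( 0.39,  -74.0,  0.64, 122.4,   2.31,  4.0,  0.60,  0.13),
    "P": (-2.50,  -20.0,  0.49, 121.6,   1.96,  5.3,  0.40,  0.19),
    "Q": ( 0.80,  -73.0,  1.22, 146.9,   1.14,  4.4,  0.95,  0.14),
    "R": ( 0.77,  -70.0,  1.18, 190.3,   0.27,  4.9,  0.93,  0.07),
    "S": ( 0.53,  -70.0,  0.70,  94.2,   5.58,  6.6,  0.82,  0.12),
    "T": ( 0.54,  -38.0,  0.78, 119.6,   4.68,  5.3,  1.12,  0.03),
    "V": ( 0.63,  123.0,  0.98, 138.2,  12.43,  6.8,  1.81, -0.29),
    "W": ( 0.58,  145.0,  1.01, 226.4,   2.20,  1.2,  1.54, -0.33),
    "Y": ( 0.72,   53.0,  0.69, 194.6,   3.13,  3.1,  1.53, -0.29),
}


@dataclass(frozen=True)
class Hqi8Table:
    """Eight AAindex physicochemical properties per canonical amino acid."""

    indices: tuple[str, ...]
    values: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        if len(self.indices) != 8:
            raise EncodingError(f"HQI8 requires exactly 8 indices, "
                                f"got {len(self.indices)}")
        missing = set(CANONICAL_AA) - set(self.values)
        if missing:
            raise EncodingError(f"HQI8 table missing amino acids "
                                f"{sorted(missing)}")
        for aa in CANONICAL_AA:
            if len(self.values[aa]) != 8:
                raise EncodingError(f"HQI8 row for {aa} must have 8 entries")

    def as_array(self) -> np.ndarray:
        """(20, 8) array, rows in canonical alphabetical order."""
        return np.array([self.values[aa] for aa in CANONICAL_AA], dtype=float)


DEFAULT_HQI8 = Hqi8Table(indices=HQI8_INDEX_IDS, values=_HQI8_RAW)


def hqi8_from_table(path: str | Path) -> Hqi8Table:
    """Load an alternative 8-property table from TSV (header: ``aa`` then
    eight property-id columns; one row per amino acid)."""
    import csv

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = [c for c in (reader.fieldnames or []) if c != "aa"]
        values = {
            row["aa"]: tuple(float(row[c]) for c in cols) for row in reader
        }
    return Hqi8Table(indices=tuple(cols), values=values)


# ---------------------------------------------------------------------------
# BLOSUM62
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Blosum62Matrix:
    """21-row substitution matrix: the 20 canonical rows of BLOSUM62 plus a
    row for the pad/any character ``-`` (the matrix's X row by default).
    Columns are the canonical amino acids in alphabetical order."""

    rows: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        missing = (set(CANONICAL_AA) | {PAD}) - set(self.rows)
        if missing:
            raise EncodingError(f"BLOSUM62 table missing rows {sorted(missing)}")
        for letter, row in self.rows.items():
            if len(row) != 20:
                raise EncodingError(f"row {letter!r} must have 20 columns")

    def row(self, letter: str) -> tuple[float, ...]:
        if letter in AMBIGUOUS_AA:  # pad-equivalent
            letter = PAD
        try:
            return self.rows[letter]
        except KeyError:
            raise EncodingError(f"no BLOSUM62 row for letter {letter!r}") from None

    def as_array(self) -> np.ndarray:
        """(21, 20) array; rows ACDEFGHIKLMNPQRSTVWY then '-'."""
        order = list(CANONICAL_AA) + [PAD]
        return np.array([self.rows[ch] for ch in order], dtype=float)


def _matrix_to_blosum(mat) -> Blosum62Matrix:
    missing = sorted(set(CANONICAL_AA) - set(mat.alphabet))
    if missing:
        raise EncodingError(f"substitution matrix missing rows {missing}")
    rows: dict[str, tuple[float, ...]] = {}
    for m in CANONICAL_AA:
        rows[m] = tuple(float(mat[m, n]) for n in CANONICAL_AA)
    pad_source = "X" if "X" in mat.alphabet else "*"
    rows[PAD] = tuple(float(mat[pad_source, n]) for n in CANONICAL_AA)
    return Blosum62Matrix(rows=rows)


def load_blosum62(path: str | Path | None = None) -> Blosum62Matrix:
    """Load BLOSUM62 (or any NCBI-format substitution matrix file)."""
    if path is None:
        mat = substitution_matrices.load("BLOSUM62")
    else:
        mat = substitution_matrices.read(str(path))
    return _matrix_to_blosum(mat)


DEFAULT_BLOSUM62 = load_blosum62()


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]
    combo: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise EncodingError("values and names lengths differ")

    def __len__(self) -> int:
        return len(self.values)


def _canonical_codes(window: PeptideWindow) -> np.ndarray:
    """Integer codes 0..19 for canonical letters, -1 for pad/ambiguous."""
    return np.array([_AA_INDEX.get(c, -1) for c in window.peptide], dtype=int)


def encode_aac(window: PeptideWindow) -> FeatureVector:
    """Amino-acid composition over the window's canonical residues.

    Components sum to 1 whenever at least one canonical residue is present;
    an all-pad window has no composition and raises :class:`EncodingError`.
    """
    codes = _canonical_codes(window)
    canonical = codes[codes >= 0]
    if canonical.size == 0:
        raise EncodingError("cannot compute composition of an all-pad window")
    counts = np.bincount(canonical, minlength=20)
    values = counts / canonical.size
    names = tuple(f"AAC|{aa}" for aa in CANONICAL_AA)
    return FeatureVector(values=values, names=names, combo="AAC")


def encode_hqi8(window: PeptideWindow,
                table: Hqi8Table = DEFAULT_HQI8) -> FeatureVector:
    """Position-major HQI8 encoding: 8 property values per residue; pads and
    ambiguity letters contribute zero blocks."""
    w = len(window)
    codes = _canonical_codes(window)
    arr = table.as_array()
    out = np.zeros((w, 8), dtype=float)
    mask = codes >= 0
    out[mask] = arr[codes[mask]]
    half = w // 2
    names = tuple(
        f"HQI8|{idx}|pos{pos - half:+d}"
        for pos in range(w)
        for idx in table.indices
    )
    return FeatureVector(values=out.ravel(), names=names, combo="HQI8")


def encode_blosum62(window: PeptideWindow,
                    matrix: Blosum62Matrix = DEFAULT_BLOSUM62) -> FeatureVector:
    """Position-major BLOSUM62 row encoding: each residue contributes its
    20-long substitution row; pads (and ambiguity letters) use the '-' row."""
    w = len(window)
    out = np.array([matrix.row(c) for c in window.peptide], dtype=float)
    half = w // 2
    names = tuple(
        f"BLOSUM62|pos{pos - half:+d}|{aa}"
        for pos in range(w)
        for aa in CANONICAL_AA
    )
    return FeatureVector(values=out.ravel(), names=names, combo="BLOSUM62")


def normalize_combo(combo: Iterable[str] | str) -> tuple[str, ...]:
    """Canonicalize a feature combination to the fixed order AAC, HQI8,
    BLOSUM62. Accepts an iterable of encoder names or a '+'-joined string."""
    if isinstance(combo, str):
        parts = [p.strip() for p in combo.replace(",", "+").split("+") if p.strip()]
    else:
        parts = list(combo)
    chosen = {p.upper() for p in parts}
    unknown = chosen - set(ENCODERS)
    if unknown:
        raise ValueError(f"unknown encoders {sorted(unknown)}; "
                         f"choose from {ENCODERS}")
    if not chosen:
        raise ValueError("feature combination must name at least one encoder")
    return tuple(e for e in ENCODERS if e in chosen)


def combo_id(combo: Iterable[str] | str) -> str:
    return "+".join(normalize_combo(combo))


def combo_dim(combo: Iterable[str] | str, w: int = 31) -> int:
    dims = {"AAC": 20, "HQI8": 8 * w, "BLOSUM62": 20 * w}
    return sum(dims[e] for e in normalize_combo(combo))


def combine(window: PeptideWindow, combo: Iterable[str] | str,
            hqi8: Hqi8Table = DEFAULT_HQI8,
            blosum: Blosum62Matrix = DEFAULT_BLOSUM62) -> FeatureVector:
    """Concatenate the selected encodings in the fixed order AAC, HQI8,
    BLOSUM62."""
    encoders = normalize_combo(combo)
    parts = []
    for name in encoders:
        if name == "AAC":
            parts.append(encode_aac(window))
        elif name == "HQI8":
            parts.append(encode_hqi8(window, hqi8))
        else:
            parts.append(encode_blosum62(window, blosum))
    return FeatureVector(
        values=np.concatenate([p.values for p in parts]),
        names=tuple(n for p in parts for n in p.names),
        combo="+".join(encoders),
    )


def encode_windows(windows: Sequence[PeptideWindow],
                   combo: Iterable[str] | str,
                   hqi8: Hqi8Table = DEFAULT_HQI8,
                   blosum: Blosum62Matrix = DEFAULT_BLOSUM62,
                   ) -> tuple[np.ndarray, tuple[str, ...]]:
    """Vectorised encoding of many equal-length windows.

    Returns the (n_windows, dim) matrix and the feature names. Bit-identical
    to stacking :func:`combine` over the windows.
    """
    encoders = normalize_combo(combo)
    if not windows:
        return np.empty((0, combo_dim(encoders))), ()
    w = len(windows[0])
    if any(len(win) != w for win in windows):
        raise EncodingError("windows must share one length")
    codes = np.array(
        [[_AA_INDEX.get(c, -1) for c in win.peptide] for win in windows],
        dtype=int,
    )
    half = w // 2
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if "AAC" in encoders:
        n_canon = (codes >= 0).sum(axis=1)
        if np.any(n_canon == 0):
            raise EncodingError("cannot compute composition of an all-pad window")
        counts = np.stack([(codes == a).sum(axis=1) for a in range(20)], axis=1)
        blocks.append(counts / n_canon[:, None])
        names += [f"AAC|{aa}" for aa in CANONICAL_AA]
    if "HQI8" in encoders:
        lut = np.vstack([hqi8.as_array(), np.zeros((1, 8))])  # -1 -> zero row
        blocks.append(lut[codes].reshape(len(windows), -1))
        names += [f"HQI8|{idx}|pos{pos - half:+d}"
                  for pos in range(w) for idx in hqi8.indices]
    if "BLOSUM62" in encoders:
        lut = blosum.as_array()  # row 20 is the '-' row
        lookup = np.where(codes >= 0, codes, 20)
        blocks.append(lut[lookup].reshape(len(windows), -1))
        names += [f"BLOSUM62|pos{pos - half:+d}|{aa}"
                  for pos in range(w) for aa in CANONICAL_AA]
    return np.hstack(blocks), tuple(names)


def write_encoded_tsv(path: str | Path, windows: Sequence[PeptideWindow],
                      labels: Sequence[int], X: np.ndarray,
                      names: Sequence[str]) -> None:
    """One row per window: id, position, label, then named feature columns."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "position", "label", *names])
        for win, label, row in zip(windows, labels, X):
            writer.writerow([win.protein_id, win.position, label,
                             *(f"{v:.10g}" for v in row)])
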