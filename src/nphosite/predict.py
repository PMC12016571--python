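"""FASTA scanning with trained per-type models and graded site calls.

Every H/K/R residue of each query protein is windowed (31-mer, terminal
padding), encoded with the model's feature combination and scored. Sites
with predicted probability above 0.50 are reported, graded by reliability:
high (0.85 < p <= 1.00), middle (0.70 < p <= 0.85), low (0.50 < p <= 0.70).
Queries must have more than 16 residues. Proteome-wide scans use the
stricter 0.85 threshold and report per-type site and protein counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import features as _features
from .model import ModelBundle
from .seqio import SITE_TYPES, TYPE_RESIDUES, ProteinRecord, SiteAnnotation, \
    extract_window

#: the interactive service requires more than 16 residues per query
MIN_QUERY_LENGTH = 17

DEFAULT_REPORT_THRESHOLD = 0.50
PROTEOME_THRESHOLD = 0.85

GRADE_BINS = (
    ("high", 0.85, 1.00),
    ("middle", 0.70, 0.85),
    ("low", 0.50, 0.70),
)


class SequenceLengthError(ValueError):
    pass


class MissingModelError(KeyError):
    pass


def grade_probability(p: float) -> str | None:
    """Reliability grade for a predicted probability; None below 0.50.

    Bins are half-open on the left: high (0.85, 1.00], middle (0.70, 0.85],
    low (0.50, 0.70].
    """
    for name, lo, hi in GRADE_BINS:
        if lo < p <= hi:
            return name
    return None


@dataclass(frozen=True)
class PredictedSite:
    protein_id: str
    position: int
    residue: str
    site_type: str
    probability: float
    grade: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0,1]")


def _check_lengths(proteins: Sequence[ProteinRecord]) -> None:
    for p in proteins:
        if len(p) < MIN_QUERY_LENGTH:
            raise SequenceLengthError(
                f"query {p.id!r} has {len(p)} residues; all query sequences "
                f"must have more than 16 residues")


def predict_sites(proteins: Sequence[ProteinRecord],
                  bundles: Mapping[str, ModelBundle],
                  types: Iterable[str] | None = None,
                  report_threshold: float = DEFAULT_REPORT_THRESHOLD,
                  w: int = 31) -> list[PredictedSite]:
    """Score candidate residues of all proteins; emit sites with probability
    above ``report_threshold``, sorted by type, then input protein order,
    then ascending position."""
    requested = list(types) if types is not None else list(SITE_TYPES.values())
    for t in requested:
        if t not in TYPE_RESIDUES:
            raise MissingModelError(f"unknown site type {t!r}")
        if t not in bundles:
            raise MissingModelError(f"no trained model supplied for {t}")
    _check_lengths(proteins)
    order = {p.id: i for i, p in enumerate(proteins)}
    out: list[PredictedSite] = []
    for site_type in requested:
        bundle = bundles[site_type]
        letter = TYPE_RESIDUES[site_type]
        windows = []
        for protein in proteins:
            for pos0, ch in enumerate(protein.sequence):
                if ch == letter:
                    windows.append(extract_window(protein, pos0 + 1, w))
        if not windows:
            continue
        X, _ = _features.encode_windows(windows, bundle.combo)
        prob = bundle.predict_proba(X)
        for win, p in zip(windows, prob):
            if p > report_threshold:
                grade = grade_probability(float(p))
                out.append(PredictedSite(
                    protein_id=win.protein_id, position=win.position,
                    residue=letter, site_type=site_type,
                    probability=float(p),
                    grade=grade if grade is not None else "low",
                ))
    out.sort(key=lambda s: (s.site_type, order[s.protein_id], s.position))
    return out


# ---------------------------------------------------------------------------
# Proteome-wide scan and count/ratio reporters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanSummary:
    """Per-type counts from a proteome scan plus residue-usage ratios."""

    threshold: float
    site_counts: Mapping[str, int]
    protein_counts: Mapping[str, int]
    residue_totals: Mapping[str, int]

    @property
    def total_sites(self) -> int:
        return sum(self.site_counts.values())

    def modification_percentage(self, site_type: str) -> float:
        """Predicted sites as a percentage of all residues of that letter."""
        return modification_percentage(self.site_counts[site_type],
                                       self.residue_totals[site_type])


def total_sites(counts: Iterable[int]) -> int:
    """Sum of per-type site counts (e.g. curated pHis+pLys+pArg totals)."""
    return int(sum(counts))


def modification_percentage(n_sites: int, n_residues: int) -> float:
    """Sites per hundred candidate residues, to two decimals (the
    phosphorylation-ratio convention of proteome summary tables)."""
    if n_residues <= 0:
        raise ValueError("residue total must be positive")
    return round(100.0 * n_sites / n_residues, 2)


def mean_sites_per_protein(n_sites: int, n_proteins: int) -> float:
    """Average modification abundance per protein, to two decimals."""
    if n_proteins <= 0:
        raise ValueError("protein count must be positive")
    return round(n_sites / n_proteins, 2)


def proteome_scan(proteins: Sequence[ProteinRecord],
                  bundles: Mapping[str, ModelBundle],
                  threshold: float = PROTEOME_THRESHOLD,
                  types: Iterable[str] | None = None,
                  known_sites: Sequence[SiteAnnotation] | None = None,
                  w: int = 31) -> ScanSummary:
    """Count distinct predicted sites and proteins per type at a reliability
    threshold, excluding experimentally annotated positions when an
    annotation table is supplied."""
    requested = list(types) if types is not None else list(SITE_TYPES.values())
    known = {(s.protein_id, s.position) for s in (known_sites or ())}
    site_counts = {t: 0 for t in requested}
    protein_counts = {t: 0 for t in requested}
    residue_totals = {
        t: sum(p.sequence.count(TYPE_RESIDUES[t]) for p in proteins)
        for t in requested
    }
    if proteins:
        sites = [
            s for s in predict_sites(proteins, bundles, requested,
                                     report_threshold=threshold, w=w)
            if (s.protein_id, s.position) not in known
        ]
        for t in requested:
            sub = [s for s in sites if s.site_type == t]
            site_counts[t] = len({(s.protein_id, s.position) for s in sub})
            protein_counts[t] = len({s.protein_id for s in sub})
    return ScanSummary(threshold=threshold, site_counts=site_counts,
                       protein_counts=protein_counts,
                       residue_totals=residue_totals)


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_predictions(sites: Sequence[PredictedSite], tsv_path: str | Path,
                      txt_path: str | Path | None = None) -> None:
    """TSV with header plus an aligned plain-text mirror; probabilities to
    four decimals (grades were assigned on the full-precision values)."""
    with open(tsv_path, "w") as fh:
        fh.write("protein_id\tposition\tresidue\ttype\tprobability\tgrade\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.residue}\t"
                     f"{s.site_type}\t{s.probability:.4f}\t{s.grade}\n")
    if txt_path is not None:
        with open(txt_path, "w") as fh:
            fh.write(f"{'protein':<20}{'pos':>6} {'res':>4} {'type':>6} "
                     f"{'prob':>8} {'grade':>7}\n")
            for s in sites:
                fh.write(f"{s.protein_id:<20}{s.position:>6} {s.residue:>4} "
                         f"{s.site_type:>6} {s.probability:>8.4f} "
                         f"{s.grade:>7}\n")
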