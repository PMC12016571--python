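"""Benchmark construction: positives, RSA-constrained negatives, splits.

Positives are the experimentally annotated N-phosphosites, one 31-residue
window per distinct peptide string per site type (redundant peptides
collapsed). Negatives follow a four-step rule designed to yield confident
non-sites:

1. candidate H/K/R residues are drawn only from proteins that carry at least
   one annotated phosphosite of any type;
2. residues in exposed regions are excluded using per-letter relative
   solvent accessibility (RSA) ceilings — RSA <= 0.12 for His, 0.30 for Lys,
   0.20 for Arg — because genuine phosphosites are predominantly exposed;
3. the remaining residues are windowed exactly like positives;
4. candidates homologous to any positive are removed by an ungapped all-pairs
   identity scan at a 30% identity threshold, eliminating wrongly or
   ambiguously assigned negatives.

Identity between two equal-length windows is the number of positions with
identical non-pad letters divided by the window length, so at the default
threshold a 31-mer sharing 10 or more positions with any positive (10/31 ~
0.32) is removed while 9/31 (~0.29) survives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from . import features as _features
from .seqio import (
    PAD,
    SITE_TYPES,
    PeptideWindow,
    ProteinRecord,
    SiteAnnotation,
    extract_window,
    validate_sites,
)

logger = logging.getLogger(__name__)

#: RSA ceilings per candidate letter, chosen for per-letter dataset balance
DEFAULT_RSA_THRESHOLDS = {"H": 0.12, "K": 0.30, "R": 0.20}
DEFAULT_IDENTITY_THRESHOLD = 0.30

RsaMap = Mapping[str, Mapping[int, float]]


@dataclass(frozen=True)
class LabeledExample:
    """A peptide window with its binary phosphosite label and site type."""

    window: PeptideWindow
    label: int
    site_type: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.site_type not in SITE_TYPES.values():
            raise ValueError(f"unknown site type {self.site_type!r}")
        expected = {v: k for k, v in SITE_TYPES.items()}[self.site_type]
        center = self.window.center_residue
        if center != expected:
            raise ValueError(
                f"{self.site_type} example must be centered on {expected}, "
                f"got {center!r}"
            )


@dataclass(frozen=True)
class NegativeConfig:
    rsa_threshold: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RSA_THRESHOLDS))
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD

    def __post_init__(self) -> None:
        for letter, thr in self.rsa_threshold.items():
            if not 0.0 <= thr <= 1.0:
                raise ValueError(f"RSA threshold for {letter} not in [0,1]")
        if not 0.0 <= self.identity_threshold <= 1.0:
            raise ValueError("identity threshold must lie in [0,1]")


@dataclass(frozen=True)
class SplitPlan:
    """Repeated 80/20 evaluation splits plus per-training-set k-fold CV."""

    train_fraction: float = 0.8
    n_repeats: int = 5
    k_folds: int = 10
    cv_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must be in (0,1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_repeats < 1 or self.cv_repeats < 1:
            raise ValueError("repeat counts must be >= 1")


def derive_seeds(seed: int, n: int, salt: int = 0) -> list[int]:
    """Deterministic child seeds (< 2^31) from one top-level seed."""
    ss = np.random.SeedSequence([int(seed), int(salt)])
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Positives
# ---------------------------------------------------------------------------

def build_positives(sites: Sequence[SiteAnnotation],
                    proteins: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
                    w: int = 31) -> list[LabeledExample]:
    """Window every annotated site and collapse duplicate peptide strings
    within each site type. Sites are validated against their sequences first
    (a residue/sequence mismatch is a hard error naming the site)."""
    index = proteins if isinstance(proteins, Mapping) else {
        p.id: p for p in proteins
    }
    validate_sites(sites, index)
    seen: set[tuple[str, str]] = set()
    out: list[LabeledExample] = []
    for s in sites:
        win = extract_window(index[s.protein_id], s.position, w)
        key = (s.site_type, win.peptide)
        if key in seen:
            continue
        seen.add(key)
        out.append(LabeledExample(window=win, label=1, site_type=s.site_type))
    n_prot = len({e.window.protein_id for e in out})
    logger.info("positives: %d distinct windows from %d proteins (of %d sites)",
                len(out), n_prot, len(sites))
    return out


# ---------------------------------------------------------------------------
# Homology filter
# ---------------------------------------------------------------------------

def _window_matrix(examples: Sequence[LabeledExample]) -> np.ndarray:
    return np.array(
        [list(e.window.peptide.encode("ascii")) for e in examples],
        dtype=np.uint8,
    )


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped end-to-end identity: matching non-pad positions / length."""
    if len(a) != len(b):
        raise ValueError("windows must have equal length")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != PAD)
    return matches / len(a)


def homology_filter(candidates: Sequence[LabeledExample],
                    positives: Sequence[LabeledExample],
                    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                    ) -> list[LabeledExample]:
    """Drop every candidate whose identity to *some* positive reaches the
    threshold. Vectorised all-pairs scan; exact, no clustering heuristics."""
    if not candidates or not positives:
        return list(candidates)
    w = len(candidates[0].window)
    if any(len(p.window) != w for p in positives):
        raise ValueError("candidate and positive windows must share one length")
    cand = _window_matrix(candidates)
    pos = _window_matrix(positives)
    pad = ord(PAD)
    keep: list[LabeledExample] = []
    # chunked to bound the (n_cand x n_pos x w) intermediate
    chunk = max(1, int(4e7) // max(1, pos.shape[0] * w))
    min_matches = identity_threshold * w
    for start in range(0, len(cand), chunk):
        block = cand[start:start + chunk]
        eq = (block[:, None, :] == pos[None, :, :]) & (block[:, None, :] != pad)
        matches = eq.sum(axis=2)
        hom = (matches >= min_matches - 1e-9).any(axis=1)
        keep.extend(c for c, h in zip(candidates[start:start + chunk], hom)
                    if not h)
    return keep


# ---------------------------------------------------------------------------
# Negatives
# ---------------------------------------------------------------------------

def build_negatives(proteins: Sequence[ProteinRecord],
                    sites: Sequence[SiteAnnotation],
                    rsa: RsaMap,
                    cfg: NegativeConfig = NegativeConfig(),
                    w: int = 31,
                    positives: Sequence[LabeledExample] | None = None,
                    ) -> list[LabeledExample]:
    """Apply the four-step negative rule (see module docstring).

    ``rsa`` maps protein id -> {1-based position -> RSA}. Candidates without
    an RSA value are skipped (counted, not fatal): the RSA constraint is the
    defining feature of the rule, so imputation is deliberately avoided.
    """
    if positives is None:
        positives = build_positives(sites, proteins, w)
    annotated: set[tuple[str, int]] = {(s.protein_id, s.position) for s in sites}
    phospho_proteins = {s.protein_id for s in sites}
    index = {p.id: p for p in proteins}

    candidates: list[LabeledExample] = []
    n_missing_rsa = 0
    seen: set[tuple[str, str]] = set()
    for pid in sorted(phospho_proteins):
        protein = index.get(pid)
        if protein is None:
            continue
        protein_rsa = rsa.get(pid, {})
        for pos0, letter in enumerate(protein.sequence):
            if letter not in SITE_TYPES:
                continue
            position = pos0 + 1
            if (pid, position) in annotated:
                continue
            value = protein_rsa.get(position)
            if value is None:
                n_missing_rsa += 1
                continue
            if value > cfg.rsa_threshold.get(letter, 1.0):
                continue
            win = extract_window(protein, position, w)
            site_type = SITE_TYPES[letter]
            key = (site_type, win.peptide)
            if key in seen:
                continue
            seen.add(key)
            candidates.append(
                LabeledExample(window=win, label=0, site_type=site_type))
    if n_missing_rsa:
        logger.info("negatives: skipped %d candidates lacking RSA",
                    n_missing_rsa)

    out: list[LabeledExample] = []
    for site_type in SITE_TYPES.values():
        cand_t = [c for c in candidates if c.site_type == site_type]
        pos_t = [p for p in positives if p.site_type == site_type]
        kept = homology_filter(cand_t, pos_t, cfg.identity_threshold)
        logger.info("negatives[%s]: %d candidates -> %d after homology filter",
                    site_type, len(cand_t), len(kept))
        out.extend(kept)
    return out


def class_ratio(n_negative: int, n_positive: int) -> float:
    """Negative:positive ratio as reported for benchmark tables (e.g.
    6669 negatives vs 1945 positives -> 3.43)."""
    if n_positive <= 0:
        raise ValueError("positive count must be > 0")
    return round(n_negative / n_positive, 2)


def dataset_summary(examples: Sequence[LabeledExample]) -> dict:
    """Per-type positive/negative counts, protein counts and ratios."""
    out: dict = {}
    for site_type in SITE_TYPES.values():
        sub = [e for e in examples if e.site_type == site_type]
        n_pos = sum(e.label for e in sub)
        n_neg = len(sub) - n_pos
        if not sub:
            continue
        out[site_type] = {
            "n_positive": n_pos,
            "n_negative": n_neg,
            "n_proteins": len({e.window.protein_id for e in sub}),
            "ratio": class_ratio(n_neg, n_pos) if n_pos else None,
        }
    return out


# ---------------------------------------------------------------------------
# Encoded dataset container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabeledDataset:
    """Encoded feature matrix with labels and window provenance."""

    X: np.ndarray
    y: np.ndarray
    site_type: str
    combo: str
    feature_names: tuple[str, ...]
    provenance: tuple[tuple[str, int], ...]  # (protein_id, position) per row

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature name count does not match X columns")


def encode_examples(examples: Sequence[LabeledExample],
                    combo: Iterable[str] | str,
                    site_type: str | None = None,
                    **encoder_kwargs) -> LabeledDataset:
    """Encode labeled windows into a :class:`LabeledDataset`."""
    if site_type is not None:
        examples = [e for e in examples if e.site_type == site_type]
    else:
        types = {e.site_type for e in examples}
        if len(types) != 1:
            raise ValueError(
                f"examples mix site types {sorted(types)}; pass site_type")
        site_type = next(iter(types))
    windows = [e.window for e in examples]
    X, names = _features.encode_windows(windows, combo, **encoder_kwargs)
    return LabeledDataset(
        X=X,
        y=np.array([e.label for e in examples], dtype=int),
        site_type=site_type,
        combo=_features.combo_id(combo),
        feature_names=names,
        provenance=tuple((w.protein_id, w.position) for w in windows),
    )


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitResult:
    repeat: int
    seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    folds: tuple[np.ndarray, ...]  # validation indices into the full set


def split_dataset(examples_or_labels,
                  plan: SplitPlan) -> list[SplitResult]:
    """Produce ``plan.n_repeats`` independent stratified 80/20 splits, each
    with a stratified ``k_folds``-fold partition of its training set.

    Accepts a sequence of :class:`LabeledExample` or a label array. Class
    proportions are preserved within +-1 example per part; identical seeds
    reproduce identical index arrays.
    """
    if len(examples_or_labels) and isinstance(examples_or_labels[0],
                                              LabeledExample):
        y = np.array([e.label for e in examples_or_labels], dtype=int)
    else:
        y = np.asarray(examples_or_labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("stratified splitting needs both classes present")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    X_dummy = np.zeros((len(y), 1))
    seeds = derive_seeds(plan.seed, plan.n_repeats, salt=101)
    results: list[SplitResult] = []
    for rep, rep_seed in enumerate(seeds):
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=plan.train_fraction, random_state=rep_seed)
        train_idx, test_idx = next(splitter.split(X_dummy, y))
        train_idx = np.sort(train_idx)
        test_idx = np.sort(test_idx)
        kf = StratifiedKFold(n_splits=plan.k_folds, shuffle=True,
                             random_state=rep_seed)
        folds = tuple(
            train_idx[val] for _, val in kf.split(X_dummy[train_idx],
                                                  y[train_idx])
        )
        results.append(SplitResult(repeat=rep, seed=rep_seed,
                                   train_indices=train_idx,
                                   test_indices=test_idx, folds=folds))
    return results


# ---------------------------------------------------------------------------
# Benchmark IO (peptide FASTA + TSV labels, split indices as JSON)
# ---------------------------------------------------------------------------

def write_benchmark(examples: Sequence[LabeledExample], prefix: str | Path,
                    ) -> None:
    """Write per-site-type paired peptide FASTA + TSV label files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for site_type in sorted({e.site_type for e in examples}):
        sub = [e for e in examples if e.site_type == site_type]
        with open(f"{prefix}.{site_type}.peptides.fasta", "w") as fa, \
                open(f"{prefix}.{site_type}.labels.tsv", "w") as tsv:
            tsv.write("protein_id\tposition\tlabel\tsite_type\tpeptide\n")
            for i, e in enumerate(sub):
                header = f"{e.window.protein_id}|{e.window.position}|{e.label}"
                fa.write(f">{header}\n{e.window.peptide}\n")
                tsv.write(f"{e.window.protein_id}\t{e.window.position}\t"
                          f"{e.label}\t{e.site_type}\t{e.window.peptide}\n")


def read_benchmark(prefix: str | Path, site_type: str) -> list[LabeledExample]:
    import csv

    path = Path(f"{prefix}.{site_type}.labels.tsv")
    out: list[LabeledExample] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(LabeledExample(
                window=PeptideWindow(peptide=row["peptide"],
                                     protein_id=row["protein_id"],
                                     position=int(row["position"])),
                label=int(row["label"]),
                site_type=row["site_type"],
            ))
    return out


def write_splits(splits: Sequence[SplitResult], path: str | Path) -> None:
    payload = [
        {
            "repeat": s.repeat,
            "seed": s.seed,
            "train": s.train_indices.tolist(),
            "test": s.test_indices.tolist(),
            "folds": [f.tolist() for f in s.folds],
        }
        for s in splits
    ]
    Path(path).write_text(json.dumps(payload))


def read_splits(path: str | Path) -> list[SplitResult]:
    payload = json.loads(Path(path).read_text())
    return [
        SplitResult(
            repeat=p["repeat"], seed=p["seed"],
            train_indices=np.array(p["train"], dtype=int),
            test_indices=np.array(p["test"], dtype=int),
            folds=tuple(np.array(f, dtype=int) for f in p["folds"]),
        )
        for p in payload
    ]
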