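"""Seeded synthetic proteomes with planted N-phosphorylation signal.

The generator emulates the statistical structure the pipeline assumes so
every stage is testable without any download:

* proteins drawn residue-by-residue from a background composition
  (uniform 1/20 by default, so planted enrichment is analytically
  checkable; a UniProt-like human composition preset is included);
* planted positive sites whose flanking residues at type-specific signal
  offsets are resampled with an enrichment multiplier on the signal
  residues — K/E near pHis, S/P upstream of pLys, S/P at both flanks of
  pArg — mirroring the sequence preferences observed around real sites;
* per-residue relative solvent accessibility for every H/K/R residue:
  uniform on [0, 1] for background residues (so the negative-rule RSA
  filter has bite) and Beta(5, 5) (mean 0.5, mostly exposed) for planted
  sites.

A fixed seed makes every artifact byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dataset import LabeledExample, NegativeConfig, build_negatives, \
    build_positives, dataset_summary
from .seqio import CANONICAL_AA, SITE_TYPES, TYPE_RESIDUES, ProteinRecord, \
    SiteAnnotation

#: residues enriched around each site type
SIGNAL_RESIDUES: Mapping[str, str] = {
    "pHis": "KE",
    "pLys": "SP",
    "pArg": "SP",
}

#: window offsets (relative to the site) carrying the enrichment
SIGNAL_OFFSETS: Mapping[str, tuple[int, ...]] = {
    "pHis": tuple(o for o in range(-7, 8) if o != 0),
    "pLys": tuple(range(-6, 0)),
    "pArg": (-3, -2, -1, 1, 2, 3),
}

#: UniProt-like human amino-acid usage (order ACDEFGHIKLMNPQRSTVWY)
UNIPROT_LIKE_COMPOSITION = (
    0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0228, 0.0593, 0.0581,
    0.0966, 0.0241, 0.0406, 0.0472, 0.0394, 0.0553, 0.0660, 0.0535, 0.0687,
    0.0110, 0.0299,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic proteome.

    Defaults give ~2000 planted sites per type across 1000 proteins of mean
    length 500, with a 6x enrichment multiplier on the signal residues at the
    signal offsets.
    """

    n_proteins: int = 1000
    length_mean: float = 500.0
    length_sd: float = 100.0
    min_length: int = 40
    background: tuple[float, ...] = tuple([1.0 / 20] * 20)
    effect: Mapping[str, float] = field(
        default_factory=lambda: {"pHis": 6.0, "pLys": 6.0, "pArg": 6.0})
    sites_per_protein: Mapping[str, float] = field(
        default_factory=lambda: {"pHis": 2.0, "pLys": 2.0, "pArg": 2.0})
    rsa_site_beta: tuple[float, float] = (5.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.background) != 20 or \
                not np.isclose(sum(self.background), 1.0):
            raise ValueError("background composition must be 20 frequencies "
                             "summing to 1")
        if any(v < 1.0 for v in self.effect.values()):
            raise ValueError("effect multipliers must be >= 1")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


def signal_distribution(background: Sequence[float], residues: str,
                        effect: float) -> np.ndarray:
    """Background composition with the signal residues' probabilities
    multiplied by ``effect`` and the whole renormalized. ``effect`` = 1
    returns the background unchanged."""
    probs = np.asarray(background, dtype=float).copy()
    for r in residues:
        probs[CANONICAL_AA.index(r)] *= effect
    return probs / probs.sum()


_AA = np.array(list(CANONICAL_AA))


def generate_proteome(cfg: SimulationConfig,
                      ) -> tuple[list[ProteinRecord], list[SiteAnnotation],
                                 dict[str, dict[int, float]]]:
    """Sample proteins, plant positive sites and draw per-residue RSA.

    Returns proteins, the planted-site annotations (with RSA and an
    RSA-derived exposure label) and the RSA map covering every H/K/R
    residue — exactly the inputs the benchmark-construction rule needs.
    """
    rng = np.random.default_rng(cfg.seed)
    bg = np.asarray(cfg.background, dtype=float)
    tilted = {
        t: signal_distribution(bg, SIGNAL_RESIDUES[t], cfg.effect[t])
        for t in SITE_TYPES.values()
    }
    proteins: list[ProteinRecord] = []
    sites: list[SiteAnnotation] = []
    rsa_map: dict[str, dict[int, float]] = {}
    width = max(len(f"{cfg.n_proteins}"), 4)
    a, b = cfg.rsa_site_beta
    for i in range(cfg.n_proteins):
        length = max(cfg.min_length,
                     int(round(rng.normal(cfg.length_mean, cfg.length_sd))))
        seq = rng.choice(20, size=length, p=bg)
        pid = f"SYN{i:0{width}d}"
        planted: dict[int, str] = {}  # 0-based position -> site type
        for site_type in sorted(SITE_TYPES.values()):
            n_sites = rng.poisson(cfg.sites_per_protein[site_type])
            free = [p for p in range(length) if p not in planted]
            n_sites = min(n_sites, len(free))
            if n_sites == 0:
                continue
            for pos in rng.choice(len(free), size=n_sites, replace=False):
                planted[free[pos]] = site_type
        for pos0, site_type in sorted(planted.items()):
            seq[pos0] = CANONICAL_AA.index(TYPE_RESIDUES[site_type])
            dist = tilted[site_type]
            for off in SIGNAL_OFFSETS[site_type]:
                j = pos0 + off
                if 0 <= j < length and j not in planted:
                    seq[j] = rng.choice(20, p=dist)
        sequence = "".join(_AA[seq])
        proteins.append(ProteinRecord(id=pid, sequence=sequence))
        protein_rsa: dict[int, float] = {}
        for pos0, ch in enumerate(sequence):
            if ch not in SITE_TYPES:
                continue
            if pos0 in planted:
                protein_rsa[pos0 + 1] = float(rng.beta(a, b))
            else:
                protein_rsa[pos0 + 1] = float(rng.uniform())
        rsa_map[pid] = protein_rsa
        for pos0, site_type in sorted(planted.items()):
            rsa = protein_rsa[pos0 + 1]
            sites.append(SiteAnnotation(
                protein_id=pid, position=pos0 + 1,
                residue=TYPE_RESIDUES[site_type], rsa=rsa,
                exposure="exposed" if rsa > 0.25 else "buried",
            ))
    return proteins, sites, rsa_map


def make_benchmark(cfg: SimulationConfig,
                   negative_cfg: NegativeConfig = NegativeConfig(),
                   max_negative_ratio: float | None = 3.0,
                   w: int = 31,
                   ) -> tuple[dict[str, list[LabeledExample]], dict]:
    """Generate a proteome and build per-type labeled benchmarks through the
    real dataset rules (positives windowed and deduplicated; negatives via
    the four-step RSA + homology rule).

    ``max_negative_ratio`` caps negatives at that multiple of the positives
    per type by a seeded subsample, keeping the benchmark near the ~1:3
    class balance typical of curated sets; ``None`` keeps every negative.
    Returns the per-type examples and a summary with class counts/ratios.
    """
    proteins, site_annotations, rsa_map = generate_proteome(cfg)
    positives = build_positives(site_annotations, proteins, w)
    negatives = build_negatives(proteins, site_annotations, rsa_map,
                                negative_cfg, w, positives=positives)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    benchmark: dict[str, list[LabeledExample]] = {}
    for site_type in SITE_TYPES.values():
        pos_t = [e for e in positives if e.site_type == site_type]
        neg_t = [e for e in negatives if e.site_type == site_type]
        if max_negative_ratio is not None:
            cap = int(round(max_negative_ratio * len(pos_t)))
            if len(neg_t) > cap:
                idx = rng.choice(len(neg_t), size=cap, replace=False)
                neg_t = [neg_t[i] for i in sorted(idx)]
        benchmark[site_type] = pos_t + neg_t
    summary = dataset_summary([e for sub in benchmark.values() for e in sub])
    return benchmark, summary


def scaled(cfg: SimulationConfig, fraction: float) -> SimulationConfig:
    """A smaller copy of the study conditions: same laws and effects, fewer
    proteins. Useful for quick tests."""
    return replace(cfg, n_proteins=max(1, int(round(cfg.n_proteins * fraction))))
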