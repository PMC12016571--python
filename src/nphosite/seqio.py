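"""Sequence and site-annotation IO plus phosphosite-centered window extraction.

Protein N-phosphorylation occurs on histidine (pHis), lysine (pLys) and
arginine (pArg). All downstream analysis in this package operates on
fixed-length peptide windows centered on an H/K/R residue; the default window
spans 31 residues (15 up- and downstream of the site), the span over which
kinase-recognition signal around phosphosites is conserved. Windows that run
off a protein terminus are padded with the ``-`` character, which the feature
encoders treat as a dedicated 21st symbol.

Coordinates are 1-based and fully closed throughout, matching UniProt site
numbering; conversion to Python indices happens only inside this module.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: accepted on input but pad-equivalent for encoders (flagged on windows)
AMBIGUOUS_AA = "BZXUO"
PAD = "-"
ALLOWED_LETTERS = frozenset(CANONICAL_AA + AMBIGUOUS_AA)

#: residues that can carry an N-phosphate, and the site-type nomenclature
SITE_TYPES = {"H": "pHis", "K": "pLys", "R": "pArg"}
TYPE_RESIDUES = {v: k for k, v in SITE_TYPES.items()}

DEFAULT_WINDOW = 31

STRUCTURE_CLASSES = frozenset({"helix", "sheet", "coil"})
DISORDER_CLASSES = frozenset({"ordered", "disordered"})
EXPOSURE_CLASSES = frozenset({"exposed", "buried", "intermediate"})

SITE_TSV_COLUMNS = (
    "protein_id",
    "position",
    "residue",
    "rsa",
    "structure_class",
    "disorder",
    "exposure",
)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending record."""


class SiteValidationError(ValueError):
    """Raised when a site annotation contradicts its protein sequence."""


@dataclass(frozen=True)
class ProteinRecord:
    """An accession plus a validated uppercase amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or self.id != self.id.strip():
            raise FastaParseError(f"invalid protein id {self.id!r}")
        seq = self.sequence.upper()
        if not seq:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")
        bad = set(seq) - ALLOWED_LETTERS
        if bad:
            raise FastaParseError(
                f"record {self.id!r} contains illegal characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated H/K/R residue (1-based ``position``) with optional
    structural context (``rsa`` in [0, 1], secondary-structure class,
    order/disorder and exposure labels)."""

    protein_id: str
    position: int
    residue: str
    rsa: float | None = None
    structure_class: str | None = None
    disorder: str | None = None
    exposure: str | None = None

    def __post_init__(self) -> None:
        if self.residue not in SITE_TYPES:
            raise SiteValidationError(
                f"site {self.protein_id}:{self.position} residue must be one of "
                f"H/K/R, got {self.residue!r}"
            )
        if self.position < 1:
            raise SiteValidationError(
                f"site {self.protein_id}:{self.position}: positions are 1-based"
            )
        if self.rsa is not None and not 0.0 <= self.rsa <= 1.0:
            raise SiteValidationError(
                f"site {self.protein_id}:{self.position} RSA {self.rsa} not in [0,1]"
            )
        for value, allowed, name in (
            (self.structure_class, STRUCTURE_CLASSES, "structure_class"),
            (self.disorder, DISORDER_CLASSES, "disorder"),
            (self.exposure, EXPOSURE_CLASSES, "exposure"),
        ):
            if value is not None and value not in allowed:
                raise SiteValidationError(
                    f"site {self.protein_id}:{self.position} {name}={value!r} "
                    f"not in {sorted(allowed)}"
                )

    @property
    def site_type(self) -> str:
        return SITE_TYPES[self.residue]


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed odd-length peptide centered on a candidate phosphosite.

    ``peptide`` uses the 20 canonical letters plus ``-`` for terminal padding
    (and possibly ambiguity letters, which are flagged via
    :attr:`has_ambiguous` and treated as pad-equivalent by encoders). Pads may
    appear only as contiguous prefix/suffix runs.
    """

    peptide: str
    protein_id: str = ""
    position: int = 0

    def __post_init__(self) -> None:
        pep = self.peptide
        if len(pep) % 2 == 0 or not pep:
            raise ValueError(f"window length {len(pep)} must be odd")
        allowed = ALLOWED_LETTERS | {PAD}
        bad = set(pep) - allowed
        if bad:
            raise ValueError(f"window contains illegal characters {sorted(bad)!r}")
        core = pep.strip(PAD)
        if not core or PAD in core:
            raise ValueError(
                "pad characters must form contiguous terminal runs only"
            )

    def __len__(self) -> int:
        return len(self.peptide)

    @property
    def center_residue(self) -> str:
        return self.peptide[len(self.peptide) // 2]

    @property
    def has_ambiguous(self) -> bool:
        return any(c in AMBIGUOUS_AA for c in self.peptide)

    @property
    def n_pads(self) -> int:
        return self.peptide.count(PAD)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (wrapped or unwrapped) FASTA file into :class:`ProteinRecord` s.

    Raises :class:`FastaParseError` on empty sequences, illegal characters or
    duplicate identifiers, naming the offending record.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                wrap: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap or None)
    writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Site-annotation TSV
# ---------------------------------------------------------------------------

def read_sites(path: str | Path) -> list[SiteAnnotation]:
    """Read site annotations from TSV with the standard header; empty strings
    denote missing optional fields."""
    sites: list[SiteAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(SITE_TSV_COLUMNS[:3]) - set(reader.fieldnames or ())
        if missing:
            raise SiteValidationError(
                f"{path}: annotation table lacks columns {sorted(missing)}"
            )
        for row in reader:
            sites.append(
                SiteAnnotation(
                    protein_id=row["protein_id"],
                    position=int(row["position"]),
                    residue=row["residue"],
                    rsa=float(row["rsa"]) if row.get("rsa") else None,
                    structure_class=row.get("structure_class") or None,
                    disorder=row.get("disorder") or None,
                    exposure=row.get("exposure") or None,
                )
            )
    return sites


def write_sites(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_TSV_COLUMNS)
        for s in sites:
            writer.writerow([
                s.protein_id,
                s.position,
                s.residue,
                "" if s.rsa is None else f"{s.rsa:.6g}",
                s.structure_class or "",
                s.disorder or "",
                s.exposure or "",
            ])


def validate_sites(sites: Sequence[SiteAnnotation],
                   proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
                   ) -> None:
    """Check every site against its protein: the protein must exist, the
    position must be in range and the annotated residue must match the
    sequence letter. Raises :class:`SiteValidationError` naming the site."""
    index = proteins if isinstance(proteins, Mapping) else {
        p.id: p for p in proteins
    }
    for s in sites:
        protein = index.get(s.protein_id)
        if protein is None:
            raise SiteValidationError(f"site {s.protein_id}:{s.position}: "
                                      f"unknown protein {s.protein_id!r}")
        if s.position > len(protein):
            raise SiteValidationError(
                f"site {s.protein_id}:{s.position} beyond sequence length "
                f"{len(protein)}"
            )
        actual = protein.sequence[s.position - 1]
        if actual != s.residue:
            raise SiteValidationError(
                f"site {s.protein_id}:{s.position} annotated {s.residue} but "
                f"sequence has {actual}"
            )


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_window(protein: ProteinRecord, position: int,
                   w: int = DEFAULT_WINDOW) -> PeptideWindow:
    """Extract the ``w``-mer centered at 1-based ``position``; flanks beyond
    the termini are filled with ``-``.

    The number of pads equals ``max(0, h+1-position) + max(0, position+h-L)``
    for half-width ``h = (w-1)//2`` and protein length ``L``.
    """
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window width must be a positive odd integer, got {w}")
    if not 1 <= position <= len(protein):
        raise IndexError(
            f"position {position} out of range 1..{len(protein)} "
            f"for protein {protein.id!r}"
        )
    half = (w - 1) // 2
    start = position - 1 - half
    stop = position - 1 + half + 1
    left_pad = max(0, -start)
    right_pad = max(0, stop - len(protein))
    core = protein.sequence[max(0, start):min(len(protein), stop)]
    return PeptideWindow(
        peptide=PAD * left_pad + core + PAD * right_pad,
        protein_id=protein.id,
        position=position,
    )


def write_peptides(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    """Write windows as a peptide FASTA (``>protein_id|position`` headers)."""
    with open(path, "w") as fh:
        for win in windows:
            fh.write(f">{win.protein_id}|{win.position}\n{win.peptide}\n")


def read_peptides(path: str | Path) -> list[PeptideWindow]:
    """Read peptide windows from FASTA (``>id|position`` headers) or from
    plain one-peptide-per-line text."""
    text = Path(path).read_text()
    windows: list[PeptideWindow] = []
    if text.lstrip().startswith(">"):
        header = None
        chunks: list[str] = []
        lines = text.splitlines() + [">"]
        for line in lines:
            if line.startswith(">"):
                if header is not None:
                    pid, _, pos = header.partition("|")
                    windows.append(PeptideWindow(
                        peptide="".join(chunks).upper(),
                        protein_id=pid,
                        position=int(pos) if pos.isdigit() else 0,
                    ))
                header = line[1:].strip()
                chunks = []
            else:
                chunks.append(line.strip())
    else:
        for line in text.splitlines():
            line = line.strip().upper()
            if line:
                windows.append(PeptideWindow(peptide=line))
    return windows
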