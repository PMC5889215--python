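"""Construction of a phosphosite-derived surface-display peptide library.

Each library entry is a 15-residue window around an annotated tyrosine
phosphosite, padded with glycine where the window runs past a protein
terminus. Windows containing additional tyrosines get a second, Tyr->Ala
variant in which every non-central tyrosine is replaced with alanine, so the
central site can be read out in isolation. A small set of random control
triplets (central Y / F / A) is appended for qualitative QC; controls are
excluded from quantitative analysis downstream. Amino-acid sequences are
encoded as DNA with one fixed codon per residue and the scaffold-fusion
flanks appended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .constants import (
    AA_ALPHABET,
    CENTER_INDEX,
    ECOLI_PREFERRED_CODONS,
    FLANK_3,
    FLANK_5,
    PEPTIDE_LENGTH,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("wildtype", "tyr2ala_mutant", "control_Y", "control_F", "control_A")

#: Central residue implied by each category.
_CENTER_BY_CATEGORY = {
    "wildtype": "Y",
    "tyr2ala_mutant": "Y",
    "control_Y": "Y",
    "control_F": "F",
    "control_A": "A",
}


class InvalidSiteError(ValueError):
    """A phosphosite definition does not point at a tyrosine in range."""


class EncodingError(ValueError):
    """A peptide contains a residue absent from the codon table."""


class LibraryConfigError(ValueError):
    """The library violates a structural requirement (e.g. duplicate 15-mers)."""


@dataclass(frozen=True)
class PhosphoSite:
    """An annotated tyrosine phosphosite: protein, sequence, 1-based position."""

    protein_id: str
    protein_seq: str
    site_pos: int

    def __post_init__(self) -> None:
        if not 1 <= self.site_pos <= len(self.protein_seq):
            raise InvalidSiteError(
                f"{self.protein_id}: site {self.site_pos} outside protein "
                f"of length {len(self.protein_seq)}"
            )
        if self.protein_seq[self.site_pos - 1] != "Y":
            raise InvalidSiteError(
                f"{self.protein_id}: residue at {self.site_pos} is "
                f"'{self.protein_seq[self.site_pos - 1]}', expected 'Y'"
            )


@dataclass(frozen=True)
class PeptideEntry:
    """One library member: id, 15-mer, category, and its flanked DNA encoding."""

    peptide_id: str
    aa_seq: str
    category: str
    dna_seq: str = ""

    def __post_init__(self) -> None:
        if len(self.aa_seq) != PEPTIDE_LENGTH:
            raise LibraryConfigError(
                f"{self.peptide_id}: peptide length {len(self.aa_seq)} != {PEPTIDE_LENGTH}"
            )
        if self.category not in CATEGORIES:
            raise LibraryConfigError(f"{self.peptide_id}: unknown category {self.category}")
        center = self.aa_seq[CENTER_INDEX]
        expected = _CENTER_BY_CATEGORY[self.category]
        if center != expected:
            raise LibraryConfigError(
                f"{self.peptide_id}: central residue '{center}' != '{expected}' "
                f"required by category {self.category}"
            )
        if self.category == "tyr2ala_mutant" and self.aa_seq.count("Y") != 1:
            raise LibraryConfigError(
                f"{self.peptide_id}: Tyr->Ala variant must contain exactly one Y"
            )

    @property
    def is_control(self) -> bool:
        return self.category.startswith("control")


class PeptideLibrary:
    """Ordered collection of peptide entries; the universe all counts map to."""

    def __init__(self, entries: Iterable[PeptideEntry]):
        self.entries: list[PeptideEntry] = list(entries)
        self._by_id: dict[str, PeptideEntry] = {}
        for e in self.entries:
            if e.peptide_id in self._by_id:
                raise LibraryConfigError(f"duplicate peptide id {e.peptide_id}")
            self._by_id[e.peptide_id] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PeptideEntry]:
        return iter(self.entries)

    def __getitem__(self, peptide_id: str) -> PeptideEntry:
        return self._by_id[peptide_id]

    def __contains__(self, peptide_id: str) -> bool:
        return peptide_id in self._by_id

    @property
    def peptide_ids(self) -> list[str]:
        return [e.peptide_id for e in self.entries]

    @property
    def scored_entries(self) -> list[PeptideEntry]:
        """Entries that take part in quantitative analysis (controls excluded)."""
        return [e for e in self.entries if not e.is_control]

    def sequences(self, peptide_ids: Iterable[str] | None = None) -> list[str]:
        if peptide_ids is None:
            return [e.aa_seq for e in self.entries]
        return [self._by_id[p].aa_seq for p in peptide_ids]

    def seq_to_id(self) -> dict[str, str]:
        """Map 15-mer -> peptide id; error on duplicate 15-mers (ambiguous counting)."""
        mapping: dict[str, str] = {}
        for e in self.entries:
            if e.aa_seq in mapping:
                raise LibraryConfigError(
                    f"duplicate 15-mer shared by {mapping[e.aa_seq]} and {e.peptide_id}"
                )
            mapping[e.aa_seq] = e.peptide_id
        return mapping

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide_id": [e.peptide_id for e in self.entries],
                "category": [e.category for e in self.entries],
                "aa_seq": [e.aa_seq for e in self.entries],
                "dna_seq": [e.dna_seq for e in self.entries],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_dna_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.peptide_id}\n{e.dna_seq}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PeptideLibrary":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls(
            PeptideEntry(r.peptide_id, r.aa_seq, r.category, r.dna_seq)
            for r in df.itertuples()
        )


def extract_window(protein_seq: str, site_pos: int, protein_id: str = "?") -> str:
    """Cut the 15-mer window centred on a tyrosine, glycine-padded at termini.

    `site_pos` is 1-based; the returned window spans site_pos-7 .. site_pos+7
    with 'G' substituted for positions outside the protein.
    """
    if not 1 <= site_pos <= len(protein_seq):
        raise InvalidSiteError(f"{protein_id}: site {site_pos} out of range")
    if protein_seq[site_pos - 1] != "Y":
        raise InvalidSiteError(
            f"{protein_id}: residue at {site_pos} is "
            f"'{protein_seq[site_pos - 1]}', not 'Y'"
        )
    out = []
    for offset in range(-CENTER_INDEX, CENTER_INDEX + 1):
        i = site_pos - 1 + offset
        out.append(protein_seq[i] if 0 <= i < len(protein_seq) else "G")
    return "".join(out)


def generate_tyr_to_ala_variant(entry: PeptideEntry) -> PeptideEntry | None:
    """Return the Tyr->Ala variant of a multi-tyrosine wild-type window.

    Every tyrosine except the central one is replaced with alanine. Returns
    None for single-tyrosine windows, which need no variant.
    """
    if entry.category != "wildtype":
        raise ValueError("Tyr->Ala variants are generated from wild-type entries only")
    if entry.aa_seq.count("Y") <= 1:
        return None
    mutated = "".join(
        "A" if aa == "Y" and i != CENTER_INDEX else aa
        for i, aa in enumerate(entry.aa_seq)
    )
    return PeptideEntry(entry.peptide_id + "_m", mutated, "tyr2ala_mutant")


def make_control_sequences(n_controls: int = 12, seed: int = 0) -> list[PeptideEntry]:
    """Generate random control triplets with central Y / F / A.

    Each triplet shares the 14 flanking residues, drawn uniformly from the 19
    standard residues other than tyrosine (so each control carries at most one
    tyrosine), and differs only at the central position. Deterministic given
    the seed.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    rng = np.random.default_rng(seed)
    non_tyr = [aa for aa in AA_ALPHABET if aa != "Y"]
    entries: list[PeptideEntry] = []
    for i in range(1, n_controls + 1):
        flank = rng.choice(non_tyr, size=PEPTIDE_LENGTH - 1)
        for center in "YFA":
            aa_seq = "".join(flank[:CENTER_INDEX]) + center + "".join(flank[CENTER_INDEX:])
            entries.append(
                PeptideEntry(f"ctrl{i:02d}_ctrl{center}", aa_seq, f"control_{center}")
            )
    return entries


def encode_dna(aa_seq: str, codon_table: Mapping[str, str] | None = None) -> str:
    """Encode a 15-mer as flanked DNA using one fixed codon per residue."""
    table = ECOLI_PREFERRED_CODONS if codon_table is None else codon_table
    try:
        coding = "".join(table[aa] for aa in aa_seq)
    except KeyError as exc:
        raise EncodingError(f"no codon for residue {exc.args[0]!r}") from None
    return FLANK_5 + coding + FLANK_3


def strip_flanks(dna_seq: str) -> str:
    """Remove the scaffold flanks from an encoded sequence (exact match)."""
    if not (dna_seq.startswith(FLANK_5) and dna_seq.endswith(FLANK_3)):
        raise ValueError("sequence does not carry both scaffold flanks")
    return dna_seq[len(FLANK_5) : -len(FLANK_3)]


def build_library(
    sites: Iterable[PhosphoSite],
    n_controls: int = 12,
    seed: int = 0,
    codon_table: Mapping[str, str] | None = None,
) -> PeptideLibrary:
    """Assemble the full library from phosphosite definitions.

    Wild-type windows come first (duplicate 15-mers from distinct sites are
    dropped, keeping the first occurrence), then the Tyr->Ala variants, then
    the control triplets. All entries are DNA-encoded with the same codon
    table and flanks.
    """
    wildtype: list[PeptideEntry] = []
    seen: dict[str, str] = {}
    for site in sites:
        window = extract_window(site.protein_seq, site.site_pos, site.protein_id)
        peptide_id = f"{site.protein_id}_{site.site_pos}"
        if window in seen:
            logger.info(
                "dropping %s: identical 15-mer already present as %s",
                peptide_id,
                seen[window],
            )
            continue
        seen[window] = peptide_id
        wildtype.append(PeptideEntry(peptide_id, window, "wildtype"))

    mutants = [
        v for v in (generate_tyr_to_ala_variant(e) for e in wildtype) if v is not None
    ]
    controls = make_control_sequences(n_controls, seed=seed)

    encoded = [
        PeptideEntry(e.peptide_id, e.aa_seq, e.category, encode_dna(e.aa_seq, codon_table))
        for e in (*wildtype, *mutants, *controls)
    ]
    library = PeptideLibrary(encoded)
    library.seq_to_id()  # fail fast on duplicate 15-mers
    return library


def read_sites(
    sites_path: str | Path, fasta_path: str | Path | None = None
) -> list[PhosphoSite]:
    """Read phosphosite definitions from delimited text.

    With `fasta_path`, the site table needs columns (protein_id, site_pos) and
    sequences come from the FASTA. Without it, the table must carry a
    protein_seq column as well. Delimiter is sniffed from the extension
    (.csv -> comma, else tab).
    """
    sep = "," if str(sites_path).endswith(".csv") else "\t"
    df = pd.read_csv(sites_path, sep=sep)
    if fasta_path is not None:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        return [
            PhosphoSite(r.protein_id, seqs[r.protein_id], int(r.site_pos))
            for r in df.itertuples()
        ]
    return [
        PhosphoSite(r.protein_id, r.protein_seq, int(r.site_pos))
        for r in df.itertuples()
    ]


def translate_coding(coding: str) -> str:
    """Translate a coding region (no flanks) — convenience for round-trips."""
    return str(Seq(coding[: len(coding) - len(coding) % 3]).translate())
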