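"""Input/output for protein sequences, packaged motif fixtures and trees.

All coordinates in this package are 1-based and inclusive, following the
convention of the printed motif tables ("the numbers on the left of each motif
refer to the amino acid positions").

The packaged fixtures are verbatim transcriptions of the published motif
alignments (Arabidopsis and rice excised TPR motifs, plus the human Hop TPR2a
reference row) and of the Arabidopsis protein-property table. Typographic
markup in the source tables (bold = consensus clamp residue, bold-italic =
substitution) is carried as a parallel per-position flag string:
``C`` consensus, ``S`` substitution, ``.`` unmarked.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    EmptyInputError,
    FixtureIntegrityError,
    SerializationError,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Accepted residue alphabet: the 20 standard amino acids plus X (unknown).
ALPHABET = frozenset(AMINO_ACIDS + "X")

MOTIF_INDICES = ("I", "II", "III")

#: Reference rows (human Hop TPR2a) carry this placeholder locus id.
REFERENCE_LOCUS = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; the unit of motif scanning."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in ALPHABET:
                raise AlphabetError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifFixtureRow:
    """One excised TPR motif of one protein, as printed in the source table."""

    protein_name: str
    locus_id: str
    motif_index: str
    start: int
    motif_seq: str
    residue_markup: str

    def __post_init__(self) -> None:
        if self.motif_index not in MOTIF_INDICES:
            raise FixtureIntegrityError(
                f"{self.protein_name}: bad motif index {self.motif_index!r}"
            )
        if self.start < 1:
            raise FixtureIntegrityError(
                f"{self.protein_name} motif {self.motif_index}: start < 1"
            )
        if len(self.residue_markup) != len(self.motif_seq):
            raise FixtureIntegrityError(
                f"{self.protein_name} motif {self.motif_index}: "
                "markup does not align with motif sequence"
            )
        bad = set(self.motif_seq) - ALPHABET
        if bad:
            raise FixtureIntegrityError(
                f"{self.protein_name} motif {self.motif_index}: "
                f"illegal residues {sorted(bad)}"
            )

    @property
    def length_anomaly(self) -> bool:
        """True for rows whose printed motif is not the canonical 34 residues."""
        return len(self.motif_seq) != 34

    @property
    def is_reference(self) -> bool:
        return self.locus_id == REFERENCE_LOCUS


@dataclass(frozen=True)
class ProteinMeta:
    """Protein-level properties from the published Arabidopsis table."""

    locus_id: str
    name: str
    lengths: tuple[int, ...]
    additional_domains: tuple[str, ...]
    novel: bool
    n_tpr_domains: str  # "one" | "more_than_one"
    mrna_species: int

    def __post_init__(self) -> None:
        if self.mrna_species < 1:
            raise FixtureIntegrityError(f"{self.locus_id}: mrna_species < 1")
        if self.n_tpr_domains not in ("one", "more_than_one"):
            raise FixtureIntegrityError(
                f"{self.locus_id}: bad n_tpr_domains {self.n_tpr_domains!r}"
            )


# --------------------------------------------------------------------- FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file.

    The record id is the first whitespace-delimited word of the header; the
    remainder becomes the description. Sequences are uppercased and validated
    against the accepted alphabet.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                description=rec.description[len(rec.id):].strip(),
                sequence=str(rec.seq).upper(),
            )
        )
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FixtureIntegrityError(f"duplicate record ids in {path}: {dup}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seqs)


# ------------------------------------------------------------------ fixtures


def load_motif_fixture(path: str | Path) -> list[MotifFixtureRow]:
    """Load a motif fixture TSV and enforce its schema.

    Every protein must contribute exactly three motifs (I, II, III) with
    strictly increasing start coordinates.
    """
    rows: list[MotifFixtureRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_name", "locus_id", "motif_index", "start",
                    "motif_seq", "residue_markup"]
        if header != expected:
            raise FixtureIntegrityError(f"{path}: bad header {header}")
        for line in fh:
            if not line.strip():
                continue
            name, locus, mi, start, seq, markup = line.rstrip("\n").split("\t")
            rows.append(MotifFixtureRow(name, locus, mi, int(start), seq, markup))
    if not rows:
        raise EmptyInputError(f"no fixture rows in {path}")
    group_by_protein(rows)  # validates triplet structure
    return rows


def group_by_protein(
    rows: Iterable[MotifFixtureRow],
) -> dict[str, tuple[MotifFixtureRow, MotifFixtureRow, MotifFixtureRow]]:
    """Group fixture rows into ordered (I, II, III) triplets per protein.

    Raises :class:`FixtureIntegrityError` if any protein has a number of rows
    other than three, duplicate motif indices, or non-increasing starts.
    """
    grouped: dict[str, dict[str, MotifFixtureRow]] = {}
    for row in rows:
        slot = grouped.setdefault(row.protein_name, {})
        if row.motif_index in slot:
            raise FixtureIntegrityError(
                f"{row.protein_name}: duplicate motif {row.motif_index}"
            )
        slot[row.motif_index] = row
    out = {}
    for name, slot in grouped.items():
        if sorted(slot) != sorted(MOTIF_INDICES):
            raise FixtureIntegrityError(
                f"{name}: expected motifs I, II, III, got {sorted(slot)}"
            )
        triplet = tuple(slot[i] for i in MOTIF_INDICES)
        starts = [r.start for r in triplet]
        if not (starts[0] < starts[1] < starts[2]):
            raise FixtureIntegrityError(f"{name}: non-monotone starts {starts}")
        out[name] = triplet
    return out


def load_protein_metadata(path: str | Path) -> list[ProteinMeta]:
    """Load the protein-property table (Arabidopsis Table-1 schema) as TSV."""
    metas: list[ProteinMeta] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["locus_id", "name", "lengths", "additional_domains",
                    "novel", "n_tpr_domains", "mrna_species"]
        if header != expected:
            raise FixtureIntegrityError(f"{path}: bad header {header}")
        for line in fh:
            if not line.strip():
                continue
            locus, name, lengths, domains, novel, n_tpr, mrna = (
                line.rstrip("\n").split("\t")
            )
            if locus in seen:
                raise FixtureIntegrityError(f"duplicate locus_id {locus}")
            seen.add(locus)
            metas.append(
                ProteinMeta(
                    locus_id=locus,
                    name=name,
                    lengths=tuple(int(x) for x in lengths.split("/")),
                    additional_domains=tuple(
                        d for d in domains.split(";") if d
                    ) if domains else (),
                    novel={"true": True, "false": False}[novel],
                    n_tpr_domains=n_tpr,
                    mrna_species=int(mrna),
                )
            )
    if not metas:
        raise EmptyInputError(f"no metadata rows in {path}")
    return metas


def _packaged(name: str) -> Path:
    return Path(str(importlib.resources.files("cctpr").joinpath("data", name)))


def load_arabidopsis_motifs() -> list[MotifFixtureRow]:
    """Packaged Arabidopsis motif table (36 proteins + human Hop reference)."""
    return load_motif_fixture(_packaged("arabidopsis_motifs.tsv"))


def load_rice_motifs() -> list[MotifFixtureRow]:
    """Packaged rice motif table (35 proteins)."""
    return load_motif_fixture(_packaged("rice_motifs.tsv"))


def load_arabidopsis_metadata() -> list[ProteinMeta]:
    """Packaged Arabidopsis protein-property table (36 proteins)."""
    return load_protein_metadata(_packaged("arabidopsis_metadata.tsv"))


# -------------------------------------------------------------------- newick


def write_newick(tree, path: str | Path) -> None:
    """Serialize a :class:`cctpr.phylo.PhyloTree` to a Newick file.

    Branch lengths are written for all edges and integer bootstrap supports
    (when present) as internal node labels.
    """
    names = tree.leaf_names()
    if len(names) < 2:
        raise SerializationError("tree must have at least 2 leaves")
    if any(not n for n in names):
        raise SerializationError("tree has an unnamed leaf")
    Path(path).write_text(tree.to_newick())
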