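"""Second-search FASTA construction for lysine-restricted quantification.

In a heavy-lysine pulse experiment only lysine-containing peptides carry the
label, so quantification must be restricted to them.  Rather than filtering
search output, the trick is to make every lysine-free tryptic peptide
non-unique: all fully cleaved peptides without a lysine are concatenated into
"artificial proteins" appended to the search database.  A search engine set
to unique-peptides-only quantification then ignores them automatically,
because each occurs both in its real parent protein and in an artificial
entry.

Construction rules:

* digestion is trypsin/P — cleave after every K or R, no proline exception —
  with up to two missed cleavages and a minimum peptide length of seven;
* maximal runs of adjacent lysine-free fully-cleaved fragments are kept
  contiguous in the artificial entry, so in-silico digestion of the entry
  regenerates the missed-cleavage lysine-free variants as well;
* a run that ends at its protein's C-terminus closes its artificial entry,
  preserving the C-terminal position (such peptides need not end in K/R and
  would otherwise not be regenerated by digestion);
* entries are chunked at ~5000 residues with accessions ``ART_000001`` ...
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "Peptide",
    "ArtificialProteinDB",
    "UniquenessReport",
    "tryptic_digest",
    "build_artificial_db",
    "verify_quantification_uniqueness",
    "read_fasta",
    "write_fasta",
    "provenance_table",
]

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residues {sorted(bad)} "
                "(sequence must be uppercase amino acids or X)"
            )


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with provenance. Positions are 1-based inclusive."""

    sequence: str
    parent: str
    start: int
    end: int
    missed_cleavages: int
    has_lysine: bool
    is_protein_cterm: bool


def _cleavage_boundaries(sequence: str) -> list[int]:
    """Cut positions for trypsin/P: after every K/R, plus both termini."""
    bounds = [0]
    bounds += [i + 1 for i, aa in enumerate(sequence) if aa in "KR"]
    if bounds[-1] != len(sequence):
        bounds.append(len(sequence))
    return bounds


def tryptic_digest(
    protein: ProteinRecord, max_missed: int = 2, min_len: int = 7
) -> list[Peptide]:
    """All trypsin/P peptides of ``protein`` with <= ``max_missed`` missed
    cleavage sites, at least ``min_len`` residues long, in positional order."""
    seq = protein.sequence
    bounds = _cleavage_boundaries(seq)
    peptides: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(bounds))):
            start, end = bounds[i], bounds[j]
            if end - start < min_len:
                continue
            pep = seq[start:end]
            peptides.append(
                Peptide(
                    sequence=pep,
                    parent=protein.accession,
                    start=start + 1,
                    end=end,
                    missed_cleavages=j - i - 1,
                    has_lysine="K" in pep,
                    is_protein_cterm=(end == len(seq)),
                )
            )
    return peptides


@dataclass(frozen=True)
class ArtificialProteinDB:
    """Concatenations of lysine-free peptides with lossless provenance.

    ``entries`` maps each artificial accession to its sequence;
    ``provenance`` records, for every member peptide, its artificial entry,
    position inside it, and its origin in the source proteome.
    """

    entries: tuple[tuple[str, str], ...]
    provenance: tuple[dict, ...]

    def as_records(self) -> list[ProteinRecord]:
        return [ProteinRecord(acc, seq) for acc, seq in self.entries]


def build_artificial_db(
    proteome: Sequence[ProteinRecord],
    *,
    chunk: int = 5000,
    accession_fmt: str = "ART_{:06d}",
) -> ArtificialProteinDB:
    """Concatenate every lysine-free fully-cleaved tryptic fragment.

    No length filter is applied to the members: short lysine-free fragments
    must be present so that missed-cleavage combinations spanning them are
    regenerated when the artificial entries are digested in silico.
    A proteome without lysine-free fragments yields an empty (valid) DB.
    """
    # maximal runs of adjacent K-free fragments, per protein
    runs: list[list[Peptide]] = []
    for protein in proteome:
        fragments = [
            p for p in tryptic_digest(protein, max_missed=0, min_len=1)
        ]
        current: list[Peptide] = []
        for frag in fragments:
            if frag.has_lysine:
                if current:
                    runs.append(current)
                    current = []
            else:
                current.append(frag)
        if current:
            runs.append(current)

    entries: list[tuple[str, str]] = []
    provenance: list[dict] = []
    buffer: list[str] = []
    buffer_prov: list[dict] = []
    buffer_len = 0
    counter = 1

    def flush() -> None:
        nonlocal buffer, buffer_prov, buffer_len, counter
        if not buffer:
            return
        acc = accession_fmt.format(counter)
        counter += 1
        entries.append((acc, "".join(buffer)))
        for p in buffer_prov:
            p["artificial_accession"] = acc
        provenance.extend(buffer_prov)
        buffer, buffer_prov, buffer_len = [], [], 0

    for run in runs:
        run_seq = "".join(p.sequence for p in run)
        if buffer_len and buffer_len + len(run_seq) > chunk:
            flush()
        offset = buffer_len
        for p in run:
            buffer_prov.append(
                {
                    "artificial_accession": None,  # assigned at flush
                    "artificial_start": offset + 1,
                    "artificial_end": offset + len(p.sequence),
                    "peptide": p.sequence,
                    "parent": p.parent,
                    "parent_start": p.start,
                    "parent_end": p.end,
                    "is_protein_cterm": p.is_protein_cterm,
                }
            )
            offset += len(p.sequence)
        buffer.append(run_seq)
        buffer_len += len(run_seq)
        # a protein-C-terminal run must stay at the end of its entry
        if run[-1].is_protein_cterm or buffer_len >= chunk:
            flush()
    flush()
    return ArtificialProteinDB(entries=tuple(entries), provenance=tuple(provenance))


@dataclass(frozen=True)
class UniquenessReport:
    """Outcome of checking that lysine-free peptides lost their uniqueness."""

    n_kfree_peptides: int
    n_duplicated: int
    missing_kfree: tuple[str, ...]
    colliding_k_peptides: tuple[str, ...]

    @property
    def duplication_fraction(self) -> float:
        if self.n_kfree_peptides == 0:
            return 1.0
        return self.n_duplicated / self.n_kfree_peptides

    @property
    def ok(self) -> bool:
        return not self.missing_kfree and not self.colliding_k_peptides


def verify_quantification_uniqueness(
    original: Sequence[ProteinRecord],
    artificial: ArtificialProteinDB,
    *,
    max_missed: int = 2,
    min_len: int = 7,
) -> UniquenessReport:
    """Digest the union database and check the quantification premise.

    Every lysine-free peptide of the original proteome must occur in at
    least two entries of the union (so the search engine will not call it
    unique), and no lysine-containing peptide may occur in an artificial
    entry (it would corrupt real-protein quantification — a hard failure).
    """
    entry_sets: dict[str, set[str]] = {}
    for rec in list(original) + artificial.as_records():
        entry_sets[rec.accession] = {
            p.sequence for p in tryptic_digest(rec, max_missed=max_missed, min_len=min_len)
        }
    occurrences: dict[str, int] = {}
    for peptides in entry_sets.values():
        for pep in peptides:
            occurrences[pep] = occurrences.get(pep, 0) + 1

    original_peptides = {
        p.sequence
        for rec in original
        for p in tryptic_digest(rec, max_missed=max_missed, min_len=min_len)
    }
    kfree = sorted(p for p in original_peptides if "K" not in p)
    missing = tuple(p for p in kfree if occurrences.get(p, 0) < 2)

    artificial_accs = {acc for acc, _ in artificial.entries}
    k_peptides = {p for p in original_peptides if "K" in p}
    colliding = tuple(
        sorted(
            pep
            for pep in k_peptides
            if any(pep in entry_sets[acc] for acc in artificial_accs)
        )
    )
    if colliding:
        raise ValueError(
            "lysine-containing peptides collide with artificial entries: "
            f"{colliding[:5]}..."
        )
    return UniquenessReport(
        n_kfree_peptides=len(kfree),
        n_duplicated=len(kfree) - len(missing),
        missing_kfree=missing,
        colliding_k_peptides=colliding,
    )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(accession=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records],
        str(path),
        "fasta",
    )


def provenance_table(db: ArtificialProteinDB) -> pd.DataFrame:
    """Sidecar TSV-ready table mapping member peptides to their origins."""
    return pd.DataFrame(list(db.provenance))
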