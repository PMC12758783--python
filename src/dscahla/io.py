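"""Sequence, allele-registry and pair-table I/O plus the core record types.

Coordinates are 0-based half-open internally; user-facing reports print
1-based positions.  The residue alphabet is the 20 standard amino acids in
alphabetical one-letter order followed by 'X' (observed unknown residue) at
index 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + "X"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
CORE_LENGTH = 9
MAX_PEPTIDE_LENGTH = 64


class ParseError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class PeptideRecord:
    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence
        if not 1 <= len(seq) <= MAX_PEPTIDE_LENGTH:
            raise ValueError(f"peptide {self.id!r}: length {len(seq)} outside [1, {MAX_PEPTIDE_LENGTH}]")
        bad = set(seq) - set(ALPHABET)
        if bad:
            raise ValueError(f"peptide {self.id!r}: illegal residues {sorted(bad)}")

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class HLAAllele:
    """One HLA class II heterodimer: paired alpha- and beta-chain sequences."""

    name: str
    alpha_chain: str
    beta_chain: str

    def __post_init__(self):
        if not self.alpha_chain or not self.beta_chain:
            raise ValueError(f"allele {self.name!r}: both chains must be non-empty")


@dataclass(frozen=True)
class PairExample:
    """One labelled peptide-allele instance, optionally with a known 9-mer core offset."""

    peptide: PeptideRecord
    allele: str
    label: int
    core_start: int | None = None
    source: str = "measured"

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.core_start is not None:
            hi = len(self.peptide) - CORE_LENGTH
            if not 0 <= self.core_start <= hi:
                raise ValueError(
                    f"core_start {self.core_start} outside [0, {hi}] for peptide "
                    f"{self.peptide.id!r} of length {len(self.peptide)}")
        if self.source not in ("measured", "synthetic"):
            raise ValueError(f"source must be 'measured' or 'synthetic', got {self.source!r}")


def _clean_sequence(seq: str, map_unknown_to_x: bool, where: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set(ALPHABET)
    if bad:
        if not map_unknown_to_x:
            raise ParseError(f"{where}: illegal residues {sorted(bad)} "
                             f"(pass map_unknown_to_x=True to map them to 'X')")
        seq = "".join(c if c in AA_INDEX else "X" for c in seq)
    return seq


def read_fasta(path, map_unknown_to_x: bool = False) -> list[PeptideRecord]:
    """Read a FASTA file into peptide records; ids are headers up to first whitespace."""
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(entry.seq), map_unknown_to_x, f"entry {entry.id!r}")
        records.append(PeptideRecord(id=entry.id, sequence=seq))
    return records


def write_fasta(path, records: Iterable[PeptideRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def load_allele_registry(path, sep: str | None = None) -> dict[str, HLAAllele]:
    """Read an allele registry table (columns name, alpha_chain, beta_chain)."""
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"name", "alpha_chain", "beta_chain"} - set(df.columns)
    if missing:
        raise ParseError(f"allele registry missing column(s): {sorted(missing)}")
    registry: dict[str, HLAAllele] = {}
    for row in df.itertuples(index=False):
        if pd.isna(row.alpha_chain) or pd.isna(row.beta_chain) \
                or not row.alpha_chain or not row.beta_chain:
            raise ParseError(f"allele {row.name!r}: empty chain")
        if row.name in registry:
            raise ParseError(f"duplicate allele name {row.name!r}")
        registry[row.name] = HLAAllele(
            name=row.name,
            alpha_chain=_clean_sequence(row.alpha_chain, False, f"allele {row.name!r} alpha"),
            beta_chain=_clean_sequence(row.beta_chain, False, f"allele {row.name!r} beta"),
        )
    return registry


def write_allele_registry(path, registry: Mapping[str, HLAAllele]) -> None:
    pd.DataFrame(
        [(a.name, a.alpha_chain, a.beta_chain) for a in registry.values()],
        columns=["name", "alpha_chain", "beta_chain"],
    ).to_csv(path, index=False)


def read_pairs(path, registry: Mapping[str, HLAAllele], sep: str | None = None,
               map_unknown_to_x: bool = False) -> list[PairExample]:
    """Read a labelled pair table (peptide, allele, label[, core_start[, source]])."""
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"peptide": str, "allele": str})
    missing = {"peptide", "allele", "label"} - set(df.columns)
    if missing:
        raise ParseError(f"pair table missing column(s): {sorted(missing)}")
    unknown = sorted(set(df["allele"]) - set(registry))
    if unknown:
        raise ParseError(f"allele(s) not in registry: {unknown}")
    pairs: list[PairExample] = []
    for i, row in enumerate(df.itertuples(index=False)):
        label = row.label
        if label not in (0, 1):
            raise ParseError(f"row {i}: label {label!r} outside {{0, 1}}")
        core = getattr(row, "core_start", None)
        if core is not None and pd.isna(core):
            core = None
        source = getattr(row, "source", "measured")
        seq = _clean_sequence(row.peptide, map_unknown_to_x, f"row {i}")
        try:
            pairs.append(PairExample(
                peptide=PeptideRecord(id=f"p{i}", sequence=seq),
                allele=row.allele,
                label=int(label),
                core_start=None if core is None else int(core),
                source=source,
            ))
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
    return pairs


def write_pairs(path, pairs: Iterable[PairExample]) -> None:
    rows = [(p.peptide.sequence, p.allele, p.label,
             "" if p.core_start is None else p.core_start, p.source)
            for p in pairs]
    pd.DataFrame(rows, columns=["peptide", "allele", "label", "core_start", "source"]) \
        .to_csv(path, index=False)
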