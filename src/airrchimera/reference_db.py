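"""Aligned germline reference databases.

The chimera HMM is defined over a multiple sequence alignment (MSA) of
germline V (or J) alleles: every HMM reference state corresponds to one
allele row of the MSA, and query sequences are threaded into the MSA's
column space before evaluation.  This module loads such databases from
FASTA, validates them, and provides the genotype-manipulation operations
used by the simulator and by database-completeness diagnostics.

Sequences are normalized on input: case-folded to uppercase and IMGT-style
'.' gaps mapped to '-'.  The working alphabet is {A, C, G, T, -, N}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import (
    AlignmentError,
    DatabaseTooSmallError,
    InvalidCharacterError,
    ParameterError,
)

# Integer encoding shared with the HMM core: A,C,G,T are 0..3, '-' is 4, 'N' is 5.
ALPHABET = "ACGT-N"
GAP_CODE = 4
N_CODE = 5

_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _CODE_TABLE[ord(_c)] = _i

_DECODE = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map '.' to '-', and validate against {A,C,G,T,N,-}."""
    s = seq.upper().replace(".", "-")
    bad = set(s) - set(ALPHABET)
    if bad:
        raise InvalidCharacterError(
            f"{context} contains invalid characters: {sorted(bad)!r}"
        )
    return s


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a normalized sequence into uint8 codes (A=0..T=3, '-'=4, 'N'=5)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_TABLE[raw]
    if (codes == 255).any():
        raise InvalidCharacterError(f"cannot encode characters in {seq!r}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def gene_of(allele_name: str) -> str:
    """Gene name: the part of an allele identifier before '*' (IMGT convention)."""
    if "*" not in allele_name:
        raise ParameterError(
            f"allele name {allele_name!r} does not follow the gene*allele "
            "naming convention"
        )
    return allele_name.split("*", 1)[0]


def family_of(allele_name: str) -> str:
    """Gene-family label: the gene name up to the first '-', else the gene itself."""
    gene = gene_of(allele_name)
    return gene.split("-", 1)[0] if "-" in gene else gene


@dataclass(frozen=True)
class GermlineAllele:
    """One aligned germline allele (a row of the reference MSA)."""

    name: str
    aligned_seq: str

    @property
    def gene(self) -> str:
        return gene_of(self.name)

    @property
    def family(self) -> str:
        return family_of(self.name)

    @property
    def ungapped_seq(self) -> str:
        return self.aligned_seq.replace("-", "")

    @property
    def ungapped_length(self) -> int:
        return len(self.ungapped_seq)


class ReferenceMSA:
    """An ordered, validated set of equal-length aligned germline alleles.

    Attributes
    ----------
    alleles : list of GermlineAllele
    L : int
        Number of MSA columns.
    ungapped_to_column : dict[str, numpy.ndarray]
        Per allele, a vector mapping 1-based ungapped positions to 1-based
        MSA columns (``arr[p - 1]`` is the column of ungapped position p).
    """

    def __init__(self, alleles: Sequence[GermlineAllele]):
        alleles = list(alleles)
        if len(alleles) < 2:
            raise DatabaseTooSmallError(
                f"reference database needs at least 2 alleles, got {len(alleles)}"
            )
        L = len(alleles[0].aligned_seq)
        if L < 1:
            raise AlignmentError("reference alignment has zero columns")
        for a in alleles:
            if len(a.aligned_seq) != L:
                raise AlignmentError(
                    f"allele {a.name!r} has length {len(a.aligned_seq)}, "
                    f"expected {L}"
                )
        names = [a.name for a in alleles]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise AlignmentError(f"duplicate allele names: {dupes}")
        self.alleles = alleles
        self.L = L
        self._index = {a.name: i for i, a in enumerate(alleles)}
        self.ungapped_to_column = {
            a.name: np.flatnonzero(encode_sequence(a.aligned_seq) != GAP_CODE) + 1
            for a in alleles
        }
        self._codes: np.ndarray | None = None

    @property
    def G(self) -> int:
        return len(self.alleles)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.alleles]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return self.G

    def index(self, name: str) -> int:
        return self._index[name]

    def row(self, name: str) -> str:
        return self.alleles[self._index[name]].aligned_seq

    @property
    def codes(self) -> np.ndarray:
        """(G, L) uint8 encoding of the alignment; cached."""
        if self._codes is None:
            self._codes = np.vstack(
                [encode_sequence(a.aligned_seq) for a in self.alleles]
            )
        return self._codes


def read_reference_msa(path: str | Path) -> ReferenceMSA:
    """Read an aligned germline FASTA ('.' or '-' gaps, wrapped or not)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise DatabaseTooSmallError(
            f"{path}: reference database needs at least 2 records, "
            f"got {len(records)}"
        )
    alleles = []
    L = None
    for rec in records:
        seq = normalize_sequence(str(rec.seq), context=f"record {rec.id!r}")
        if L is None:
            L = len(seq)
        elif len(seq) != L:
            raise AlignmentError(
                f"{path}: record {rec.id!r} has length {len(seq)}, expected {L}; "
                "input is not an alignment"
            )
        alleles.append(GermlineAllele(name=rec.id, aligned_seq=seq))
    return ReferenceMSA(alleles)


def write_reference_msa(msa: ReferenceMSA, path: str | Path) -> None:
    """Write the alignment as unwrapped FASTA (round-trips exactly)."""
    with open(path, "w") as fh:
        for a in msa.alleles:
            fh.write(f">{a.name}\n{a.aligned_seq}\n")


def subsample_genotype(msa: ReferenceMSA, n_alleles: int, seed: int) -> ReferenceMSA:
    """Uniform subsample of alleles without replacement (columns untouched).

    Used to emulate incomplete reference databases; keeps input order.
    """
    if not (2 <= n_alleles <= msa.G):
        raise ParameterError(
            f"n_alleles must be in [2, {msa.G}], got {n_alleles}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(msa.G, size=n_alleles, replace=False))
    return ReferenceMSA([msa.alleles[i] for i in idx])


def sample_synthetic_genotype(allele_db: ReferenceMSA, seed: int) -> ReferenceMSA:
    """Sample a genotype: one allele per gene, uniformly, in database order."""
    groups: dict[str, list[int]] = {}
    for i, a in enumerate(allele_db.alleles):
        groups.setdefault(a.gene, []).append(i)
    rng = np.random.default_rng(seed)
    chosen = set()
    for gene, members in groups.items():
        chosen.add(members[int(rng.integers(len(members)))])
    picked = [allele_db.alleles[i] for i in sorted(chosen)]
    return ReferenceMSA(picked)
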