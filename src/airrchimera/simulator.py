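"""Synthetic repertoire simulation with ground-truth chimera labels.

The generator reproduces the study design used throughout the package's
evaluation: datasets of n sequences at a fixed chimerism rate (default
design point: 10,000 sequences, 5% chimeric).  Non-chimeric sequences are a
single genotype allele mutated uniformly per site; chimeric sequences join
two uniformly mutated alleles at a breakpoint drawn uniformly over columns
2..L, so each chimera carries at least one column from each parent.
Somatic hypermutation is modeled as uniform per-site substitution and
sequencing error as a flat per-site substitution applied after SHM and
joining; both are deliberate simplifications (no hot/cold-spot bias, no
read-position error profile) — see docs/methods.md.

Records are emitted as AIRR Rearrangement rows whose pairwise alignment
fields are synthesized directly in MSA coordinates against the assigned
allele (the genotype allele nearest by Hamming distance, mimicking an
aligner's best hit), so detection can thread them without any external
annotation tool and the threading round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DatabaseTooSmallError, ParameterError
from .reference_db import (
    GAP_CODE,
    GermlineAllele,
    ReferenceMSA,
    decode_sequence,
    encode_sequence,
    write_reference_msa,
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    genotype: ReferenceMSA
    n_sequences: int
    chimerism_rate: float = 0.05
    shm_rate: float = 0.0
    seq_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 1:
            raise ParameterError("n_sequences must be positive")
        if not (0 <= self.chimerism_rate <= 1):
            raise ParameterError("chimerism_rate must be in [0, 1]")
        if not (0 <= self.shm_rate < 0.5):
            raise ParameterError("shm_rate must be in [0, 0.5)")
        if not (0 <= self.seq_error_rate <= 0.1):
            raise ParameterError("seq_error_rate must be in [0, 0.1]")

    @property
    def n_chimeric(self) -> int:
        return int(round(self.n_sequences * self.chimerism_rate))


@dataclass
class SimulatedRecord:
    """One simulated sequence: its AIRR row plus the ground truth."""

    sequence_id: str
    row: dict
    msa_seq: str  # raw simulated sequence over all MSA columns
    threaded: str  # what threading against the assigned allele reproduces
    is_chimera: bool
    parent_alleles: list[str]
    breakpoint_column: int | None
    true_shm_rate: float


def mutate_uniform(aligned_seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each non-gap position independently with probability
    ``rate``; replacements are uniform over the three other bases.  Gaps are
    untouched, so the alignment structure is preserved."""
    if not (0 <= rate < 0.5):
        raise ParameterError(f"mutation rate must be in [0, 0.5), got {rate}")
    codes = encode_sequence(aligned_seq).copy()
    if rate == 0:
        return aligned_seq
    nucleotide = codes < 4
    hit = nucleotide & (rng.random(codes.size) < rate)
    # adding 1..3 mod 4 guarantees the replacement differs from the original
    offsets = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    codes[hit] = (codes[hit] + offsets) % 4
    return decode_sequence(codes)


def make_chimera(
    parent_a: GermlineAllele,
    parent_b: GermlineAllele,
    shm_rate: float,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Join two uniformly mutated parents at a breakpoint drawn uniformly
    from columns 2..L: output columns 1..bp-1 come from parent_a, bp..L from
    parent_b.  Returns (sequence, breakpoint_column)."""
    if parent_a.name == parent_b.name:
        raise ParameterError("chimera parents must be distinct alleles")
    if len(parent_a.aligned_seq) != len(parent_b.aligned_seq):
        raise ParameterError("chimera parents must have equal aligned length")
    L = len(parent_a.aligned_seq)
    ma = mutate_uniform(parent_a.aligned_seq, shm_rate, rng)
    mb = mutate_uniform(parent_b.aligned_seq, shm_rate, rng)
    bp = int(rng.integers(2, L + 1))
    return ma[: bp - 1] + mb[bp - 1:], bp


def nearest_allele(msa_seq: str, genotype: ReferenceMSA) -> str:
    """Genotype allele with the minimum Hamming distance over informative
    columns (both sides unambiguous nucleotides); ties go to database
    order.  Stands in for an aligner's best-hit assignment."""
    q = encode_sequence(msa_seq)
    ref = genotype.codes
    informative = (q[None, :] < 4) & (ref < 4)
    dist = ((q[None, :] != ref) & informative).sum(axis=1)
    return genotype.names[int(dist.argmin())]


def synthesize_airr_row(
    msa_seq: str, genotype: ReferenceMSA, sequence_id: str, *, v_call: str | None = None
) -> dict:
    """Build the AIRR alignment fields for a sequence given in MSA
    coordinates, pairwise-aligned against its assigned allele.

    Columns where both the allele and the sequence are gaps are dropped;
    columns where only the allele is gapped become query insertions.
    """
    allele = v_call or nearest_allele(msa_seq, genotype)
    a = encode_sequence(genotype.row(allele))
    c = encode_sequence(msa_seq)
    keep = ~((a == GAP_CODE) & (c == GAP_CODE))
    germ_aln = decode_sequence(a[keep])
    seq_aln = decode_sequence(c[keep])
    ungapped_len = int((a != GAP_CODE).sum())
    sequence = msa_seq.replace("-", "")
    return {
        "sequence_id": sequence_id,
        "sequence": sequence,
        "v_call": allele,
        "v_sequence_alignment": seq_aln,
        "v_germline_alignment": germ_aln,
        "v_germline_start": "1",
        "v_germline_end": str(ungapped_len),
    }


def truth_threaded(msa_seq: str, genotype: ReferenceMSA, allele: str) -> str:
    """The MSA-coordinate string that threading the synthesized AIRR row
    reproduces: the assigned allele's gap columns are never written and
    stay 'N'."""
    row = genotype.row(allele)
    return "".join(
        "N" if a == "-" else c for a, c in zip(row, msa_seq)
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[SimulatedRecord], pd.DataFrame]:
    """Generate a labeled dataset under the configured study conditions.

    Exactly round(n × chimerism_rate) records are chimeric; chimera labels
    are shuffled across positions.  Source alleles and parent pairs are
    drawn uniformly.  Deterministic given the seed.
    """
    geno = config.genotype
    if geno.G < 2:
        raise DatabaseTooSmallError("genotype needs at least 2 alleles")
    rng = np.random.default_rng(config.seed)
    n = config.n_sequences
    is_chim = np.zeros(n, dtype=bool)
    is_chim[: config.n_chimeric] = True
    rng.shuffle(is_chim)
    records: list[SimulatedRecord] = []
    truth_rows = []
    for i in range(n):
        sid = f"sim-{i + 1:06d}"
        if is_chim[i]:
            ia, ib = rng.choice(geno.G, size=2, replace=False)
            pa, pb = geno.alleles[int(ia)], geno.alleles[int(ib)]
            seq, bp = make_chimera(pa, pb, config.shm_rate, rng)
            parents = [pa.name, pb.name]
        else:
            src = geno.alleles[int(rng.integers(geno.G))]
            seq = mutate_uniform(src.aligned_seq, config.shm_rate, rng)
            parents = [src.name]
            bp = None
        if config.seq_error_rate > 0:
            seq = mutate_uniform(seq, config.seq_error_rate, rng)
        row = synthesize_airr_row(seq, geno, sid)
        records.append(
            SimulatedRecord(
                sequence_id=sid,
                row=row,
                msa_seq=seq,
                threaded=truth_threaded(seq, geno, row["v_call"]),
                is_chimera=bool(is_chim[i]),
                parent_alleles=parents,
                breakpoint_column=bp,
                true_shm_rate=config.shm_rate,
            )
        )
        truth_rows.append(
            {
                "sequence_id": sid,
                "is_chimera": "T" if is_chim[i] else "F",
                "parents": ",".join(parents),
                "breakpoint_column": "" if bp is None else str(bp),
                "true_shm_rate": f"{config.shm_rate:g}",
            }
        )
    return records, pd.DataFrame(truth_rows)


def simulate_to_files(config: SimulationConfig, out_prefix: str | Path) -> dict:
    """Write <prefix>.airr.tsv, <prefix>.truth.tsv and <prefix>.genotype.fasta.

    Output is byte-identical across reruns with the same config."""
    records, truth = simulate_dataset(config)
    prefix = str(out_prefix)
    airr_path = f"{prefix}.airr.tsv"
    cols = list(records[0].row.keys()) if records else [
        "sequence_id", "sequence", "v_call", "v_sequence_alignment",
        "v_germline_alignment", "v_germline_start", "v_germline_end",
    ]
    with open(airr_path, "w", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            fh.write("\t".join(str(rec.row[c]) for c in cols) + "\n")
    truth_path = f"{prefix}.truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, lineterminator="\n")
    geno_path = f"{prefix}.genotype.fasta"
    write_reference_msa(config.genotype, geno_path)
    return {"airr": airr_path, "truth": truth_path, "genotype": geno_path}


# ---------------------------------------------------------------------------
# synthetic germline databases


def synthetic_germline_database(
    n_genes: int,
    length: int = 296,
    seed: int = 0,
    *,
    n_families: int | None = None,
    max_alleles_per_gene: int = 3,
    family_divergence: float = 0.12,
    gene_divergence: float = 0.05,
    n_indel_sites: int = 3,
    locus: str = "SYNV",
) -> ReferenceMSA:
    """Generate an aligned synthetic germline V database.

    Mimics the hierarchical divergence structure of human V loci: gene
    families diverge ~12% from a common ancestor, genes ~5% within their
    family, and alleles of a gene differ by 1-4 substitutions.  A few
    columns carry family-correlated deletions so the alignment contains
    gaps.  Names follow the <locus><family>-<gene>*<allele> convention and
    are synthetic, not real gene names.
    """
    if n_genes < 2:
        raise ParameterError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    if n_families is None:
        n_families = max(2, int(round(np.sqrt(n_genes))))
    ancestor = rng.integers(0, 4, size=length, dtype=np.uint8)

    def _mutate(codes: np.ndarray, rate: float) -> np.ndarray:
        out = codes.copy()
        hit = rng.random(codes.size) < rate
        out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        return out

    indel_sites = rng.choice(length, size=min(n_indel_sites, length), replace=False)
    fam_seqs = [_mutate(ancestor, family_divergence) for _ in range(n_families)]
    fam_dels = [rng.random(len(indel_sites)) < 0.3 for _ in range(n_families)]
    alleles: list[GermlineAllele] = []
    seen: set[str] = set()
    for g in range(n_genes):
        fam = g % n_families
        gene_codes = _mutate(fam_seqs[fam], gene_divergence)
        n_alleles = int(rng.integers(1, max_alleles_per_gene + 1))
        base = None
        for a in range(n_alleles):
            for _attempt in range(100):
                if a == 0:
                    cand = gene_codes.copy()
                    base = cand
                else:
                    cand = base.copy()
                    k = int(rng.integers(1, 5))
                    pos = rng.choice(length, size=k, replace=False)
                    cand[pos] = (cand[pos] + rng.integers(1, 4, size=k)) % 4
                seq = decode_sequence(cand)
                # apply family-correlated deletions at the indel columns
                chars = list(seq)
                for site, deleted in zip(indel_sites, fam_dels[fam]):
                    if deleted:
                        chars[site] = "-"
                seq = "".join(chars)
                if seq not in seen:
                    seen.add(seq)
                    break
                if a == 0:
                    gene_codes = _mutate(fam_seqs[fam], gene_divergence)
            name = f"{locus}{fam + 1}-{g + 1}*{a + 1:02d}"
            alleles.append(GermlineAllele(name=name, aligned_seq=seq))
    return ReferenceMSA(alleles)
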