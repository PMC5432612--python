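"""Protein-guided pairwise codon alignment and NG86 Ks/Ka estimation.

Synonymous divergence (Ks) is estimated by Nei–Gojobori (1986) counting:
synonymous/nonsynonymous *sites* are fractional counts per codon position,
*differences* between codon pairs are averaged over all mutational pathways
(orders of the differing positions), excluding pathways that pass through a
stop codon, and the resulting proportions are corrected for multiple hits
with the one-parameter Jukes–Cantor formula

    d = -(3/4) * ln(1 - (4/3) p),    defined for p < 3/4.

A proportion at or beyond 3/4 is saturated and reported as a flag rather
than a number. The estimator is deliberately a counting method: it is fully
specifiable and adequate in the Ks < 2 regime that age-distribution
analyses retain; the module interface leaves room for an ML variant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io_formats import STOP_CODONS, FormatError, SequenceRecord, validate_cds

__all__ = [
    "CodonAlignment",
    "SubstitutionCounts",
    "PairDivergence",
    "SaturationError",
    "align_codons",
    "count_sites",
    "ng86",
    "jc_correct",
    "pair_divergence",
]

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid for the 61 sense codons of the standard code
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))


class SaturationError(ValueError):
    """A corrected distance does not exist (observed proportion ≥ 3/4)."""


@dataclass(frozen=True)
class CodonAlignment:
    """Two in-frame, gap-containing nucleotide rows of equal length."""

    gene_a: str
    gene_b: str
    row_a: str
    row_b: str

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows differ in length")
        if len(self.row_a) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    def codon_columns(self):
        for i in range(0, len(self.row_a), 3):
            yield self.row_a[i : i + 3], self.row_b[i : i + 3]


@dataclass(frozen=True)
class SubstitutionCounts:
    """NG86 site and difference counts for one aligned pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    codons_used: int


@dataclass(frozen=True)
class PairDivergence:
    """Corrected Ks/Ka for one gene pair; ``None`` marks saturation."""

    gene_a: str
    gene_b: str
    ks: float | None
    ka: float | None
    codons_used: int

    @property
    def saturated(self) -> bool:
        return self.ks is None or self.ka is None

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore[return-value]


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


def translate(cds: str) -> str:
    """Translate an in-frame, stop-free CDS with the standard code."""
    aa = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon not in GENETIC_CODE:
            raise FormatError(f"cannot translate codon {codon!r} at position {i}")
        aa.append(GENETIC_CODE[codon])
    return "".join(aa)


def align_codons(cds_a: SequenceRecord, cds_b: SequenceRecord) -> CodonAlignment:
    """Globally align two CDS via their proteins and back-map to codons.

    Affine-gap global protein alignment (BLOSUM62, gap open 10, extend 1,
    end gaps penalized), deterministic for fixed inputs; each protein gap
    becomes a codon gap of length 3.
    """
    a = validate_cds(cds_a)
    b = validate_cds(cds_b)
    prot_a, prot_b = translate(a.residues), translate(b.residues)
    aln = _aligner().align(prot_a, prot_b)[0]
    aligned_a = str(aln[0])
    aligned_b = str(aln[1])

    def back_map(aligned_protein: str, cds: str) -> str:
        chunks = []
        pos = 0
        for ch in aligned_protein:
            if ch == "-":
                chunks.append("---")
            else:
                chunks.append(cds[pos : pos + 3])
                pos += 3
        return "".join(chunks)

    return CodonAlignment(
        a.id, b.id, back_map(aligned_a, a.residues), back_map(aligned_b, b.residues)
    )


@lru_cache(maxsize=None)
def count_sites(codon: str) -> float:
    """Synonymous-site count of one sense codon (NG86), in [0, 3].

    For each of the three positions, the fraction of single-nucleotide
    changes that are synonymous, counting only sense-codon targets in the
    denominator. The nonsynonymous contribution is 3 minus this value.
    """
    if codon not in GENETIC_CODE:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = GENETIC_CODE[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        sense = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            sense += 1
            if GENETIC_CODE[mutant] == aa:
                syn += 1
        if sense:
            total += syn / sense
    return total


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) difference counts over pathways.

    Pathways through stop codons are excluded and the average renormalized;
    ``None`` if every pathway is blocked (the column is then skipped).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        syn = 0
        nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not blocked:
            syn_total += syn
            nonsyn_total += nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_total / n_paths, nonsyn_total / n_paths


def _usable(codon: str) -> bool:
    return codon in GENETIC_CODE  # excludes gaps, N-containing codons, stops


def ng86(aln: CodonAlignment) -> SubstitutionCounts:
    """NG86 site and difference counts over the usable codon columns.

    Sites S and N are averaged over the two sequences; columns containing a
    gap, ambiguity, or a stop codon are skipped, as are columns whose every
    mutational pathway passes through a stop.
    """
    S = N = Sd = Nd = 0.0
    used = 0
    for ca, cb in aln.codon_columns():
        if not (_usable(ca) and _usable(cb)):
            continue
        counts = _pathway_counts(ca, cb)
        if counts is None:
            continue
        s_col = (count_sites(ca) + count_sites(cb)) / 2.0
        S += s_col
        N += 3.0 - s_col
        Sd += counts[0]
        Nd += counts[1]
        used += 1
    if used == 0:
        raise ValueError(
            f"no usable codon columns in alignment {aln.gene_a} ~ {aln.gene_b}"
        )
    return SubstitutionCounts(S, N, Sd, Nd, used)


def jc_correct(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction; ``None`` flags saturation."""
    if p < 0:
        raise ValueError(f"proportion {p} is negative")
    if p >= 0.75:
        return None
    if p == 0:
        return 0.0
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def pair_divergence(aln: CodonAlignment) -> PairDivergence:
    """Corrected Ks and Ka of one aligned pair; symmetric in its inputs."""
    counts = ng86(aln)
    if counts.S == 0 or counts.N == 0:
        raise ValueError(
            f"pair {aln.gene_a} ~ {aln.gene_b}: zero synonymous or "
            f"nonsynonymous sites, divergence undefined"
        )
    ks = jc_correct(counts.Sd / counts.S)
    ka = jc_correct(counts.Nd / counts.N)
    return PairDivergence(aln.gene_a, aln.gene_b, ks, ka, counts.codons_used)


def pair_divergence_from_seqs(cds_a: SequenceRecord, cds_b: SequenceRecord) -> PairDivergence:
    """Convenience composition: align then estimate divergence."""
    return pair_divergence(align_codons(cds_a, cds_b))
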