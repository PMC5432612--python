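"""Rate-calibrated WGD dating via the molecular clock Ks = 2 T mu.

A mean ortholog-pair Ks distance matrix over the sampled species yields a
neighbor-joining Ks tree; an external calibration (a fossil-constrained
divergence age for one species pair) converts a Ks divergence into a
per-lineage synonymous rate mu = Ks / (2 * age). Inverting the clock at a
mixture-model peak then dates the WGD: T = peak_Ks / (2 * mu), with an
interval from the delta-method standard error of the peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .age_distribution import MixtureComponent
from .codonalign_ks import PairDivergence
from .gene_families import GeneFamily
from .io_formats import FormatError, parse_newick, species_of

__all__ = [
    "KsDistanceMatrix",
    "CalibrationConstraint",
    "RateEstimate",
    "WGDAgeEstimate",
    "ortholog_ks_matrix",
    "nj_tree",
    "estimate_rate",
    "date_wgd",
    "read_calibrations",
]


@dataclass
class KsDistanceMatrix:
    """Symmetric matrix of mean ortholog-pair Ks between species."""

    taxa: list[str]
    d: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        self.n_pairs = np.asarray(self.n_pairs, int)
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def ortholog_ks_matrix(
    orthogroups: list[GeneFamily],
    divergences: dict[tuple[str, str], PairDivergence],
) -> KsDistanceMatrix:
    """Mean Ks over single-copy ortholog pairs, per species pair.

    Saturated pairs are skipped (and not counted in ``n_pairs``); a species
    pair with no usable ortholog pair at all is an error.
    """
    taxa = sorted({species_of(g) for fam in orthogroups for g in fam.members})
    idx = {t: i for i, t in enumerate(taxa)}
    sums = np.zeros((len(taxa), len(taxa)))
    counts = np.zeros((len(taxa), len(taxa)), dtype=int)
    for fam in orthogroups:
        members = sorted(fam.members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                sa, sb = species_of(a), species_of(b)
                if sa == sb:
                    continue
                p = divergences.get((a, b)) or divergences.get((b, a))
                if p is None or p.ks is None:
                    continue
                ia, ib = idx[sa], idx[sb]
                sums[ia, ib] += p.ks
                sums[ib, ia] += p.ks
                counts[ia, ib] += 1
                counts[ib, ia] += 1
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            if counts[i, j] == 0:
                raise ValueError(
                    f"no usable ortholog pairs between {taxa[i]} and {taxa[j]}"
                )
    d = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return KsDistanceMatrix(taxa, d, counts)


def nj_tree(matrix: KsDistanceMatrix):
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion break lexicographically on the joined clusters'
    smallest leaf names. Negative branch lengths are clamped to zero with
    the deficit moved to the sibling branch. Returns an (unrooted, trifurcating
    at the root) dendropy tree with branch lengths in Ks units; exact for
    additive input matrices.
    """
    n0 = len(matrix.taxa)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # working state: cluster label -> newick fragment; distances in a dict
    labels = list(matrix.taxa)
    frags = {t: t for t in labels}
    sort_key = {t: t for t in labels}
    d = {
        frozenset((a, b)): float(matrix.d[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }

    def dist(a: str, b: str) -> float:
        return 0.0 if a == b else d[frozenset((a, b))]

    while len(labels) > 3:
        n = len(labels)
        r = {a: sum(dist(a, b) for b in labels) for a in labels}
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                key = tuple(sorted((sort_key[a], sort_key[b])))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        va = 0.5 * dist(a, b) + (r[a] - r[b]) / (2 * (n - 2))
        vb = dist(a, b) - va
        if va < 0:
            vb += va
            va = 0.0
        if vb < 0:
            va += vb
            vb = 0.0
        new = f"({frags[a]}:{va:.10g},{frags[b]}:{vb:.10g})"
        new_label = f"__join{len(frags)}"
        for c in labels:
            if c in (a, b):
                continue
            d[frozenset((new_label, c))] = 0.5 * (
                dist(a, c) + dist(b, c) - dist(a, b)
            )
        labels = [c for c in labels if c not in (a, b)] + [new_label]
        frags[new_label] = new
        sort_key[new_label] = min(sort_key[a], sort_key[b])
    a, b, c = sorted(labels, key=lambda t: sort_key[t])
    va = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    vb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    vc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    va, vb, vc = (max(v, 0.0) for v in (va, vb, vc))
    newick = (
        f"({frags[a]}:{va:.10g},{frags[b]}:{vb:.10g},{frags[c]}:{vc:.10g});"
    )
    return parse_newick(newick)


@dataclass(frozen=True)
class CalibrationConstraint:
    """A fossil-calibrated divergence age for one species pair."""

    taxon_a: str
    taxon_b: str
    age_min: float
    age_max: float
    age: float | None = None  # optional point age, Mya

    def __post_init__(self) -> None:
        if not 0 < self.age_min <= self.age_max:
            raise ValueError("need 0 < age_min ≤ age_max")

    @property
    def point_age(self) -> float:
        """Point age if given, else the interval midpoint (Mya)."""
        return self.age if self.age is not None else 0.5 * (self.age_min + self.age_max)


def read_calibrations(path: str | Path) -> list[CalibrationConstraint]:
    """TSV with header: taxon_a, taxon_b, age_min, age_max[, age]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["taxon_a", "taxon_b", "age_min", "age_max"]
        if header[:4] != required:
            raise FormatError(f"{path}: expected header starting {required}")
        has_age = len(header) > 4 and header[4] == "age"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                age = (
                    float(parts[4])
                    if has_age and len(parts) > 4 and parts[4] != ""
                    else None
                )
                out.append(
                    CalibrationConstraint(
                        parts[0], parts[1], float(parts[2]), float(parts[3]), age
                    )
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


@dataclass(frozen=True)
class RateEstimate:
    """Per-lineage synonymous substitution rate, per site per year."""

    lineage: str
    mu: float
    ks_divergence: float
    calibration_age_mya: float


def estimate_rate(ks_divergence: float, age_mya: float, lineage: str = "") -> RateEstimate:
    """mu = Ks / (2 * age): two lineages each accumulate Ks/2 over ``age``."""
    if ks_divergence <= 0 or age_mya <= 0:
        raise ValueError("ks_divergence and age must be positive")
    mu = ks_divergence / (2.0 * age_mya * 1e6)
    return RateEstimate(lineage, mu, ks_divergence, age_mya)


@dataclass(frozen=True)
class WGDAgeEstimate:
    species: str
    peak_ks: float
    mu: float
    t_mya: float
    interval_mya: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "peak_ks": self.peak_ks,
            "mu": self.mu,
            "t_mya": self.t_mya,
            "interval_low_mya": self.interval_mya[0],
            "interval_high_mya": self.interval_mya[1],
        }


def date_wgd(
    peak: MixtureComponent | float,
    mu: RateEstimate | float,
    species: str = "",
    z: float = 1.96,
) -> WGDAgeEstimate:
    """Invert the clock at a mixture peak: T = peak_Ks / (2 mu), in Mya.

    The interval maps peak_ks ± z * SE(peak_ks) through the same formula
    (delta-method propagation of the component mean's standard error); with
    a bare float peak the interval degenerates to the point estimate.
    """
    if isinstance(peak, MixtureComponent):
        peak_ks, se = peak.peak_ks, peak.peak_se
    else:
        peak_ks, se = float(peak), 0.0
    rate = mu.mu if isinstance(mu, RateEstimate) else float(mu)
    if peak_ks <= 0:
        raise ValueError("peak_ks must be positive (zero-age pairs are not a WGD)")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not np.isfinite(se):
        se = 0.0
    t = peak_ks / (2.0 * rate) / 1e6
    lo = max(peak_ks - z * se, 0.0) / (2.0 * rate) / 1e6
    hi = (peak_ks + z * se) / (2.0 * rate) / 1e6
    return WGDAgeEstimate(species, peak_ks, rate, t, (lo, hi))
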