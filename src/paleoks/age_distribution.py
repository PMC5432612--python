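"""Duplicate-pair Ks age distributions: filtering, node averaging,
normal-mixture modelling in log space, and SiZer feature maps.

The age distribution of retained duplicates mixes an L-shaped background of
continuous small-scale duplication with approximately Gaussian bursts left
by whole-genome duplications. The stage applies the four standard filters
(transposable-element pairs, Ks = 0 pairs, hierarchical node averaging of
multicopy families, Ks > 2 saturation cut), fits normal mixtures to ln(Ks)
by EM with BIC model selection, and maps significantly increasing /
decreasing density slopes across kernel bandwidths (SiZer) to confirm
peaks against stochastic wiggles in the background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.special import logsumexp
from scipy.stats import norm

from .codonalign_ks import PairDivergence

__all__ = [
    "KsSample",
    "MixtureComponent",
    "MixtureFit",
    "SiZerMap",
    "filter_pairs",
    "node_average",
    "build_ks_sample",
    "fit_mixture",
    "classify_wgd_components",
    "sizer",
]

KS_MAX = 2.0
ZERO_EPS = 1e-9
#: matrix placeholder for saturated pairs so they merge last and the
#: resulting node values fall to the saturation cut
_SATURATED_KS = 4.0

INCREASING, DECREASING, FLAT, SPARSE = 1, -1, 0, 9
_STATE_NAMES = {INCREASING: "INCREASING", DECREASING: "DECREASING", FLAT: "FLAT", SPARSE: "SPARSE"}


@dataclass
class KsSample:
    """Filtered, node-averaged Ks values for one species, with provenance."""

    species: str
    values: np.ndarray
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) and (self.values.min() <= 0 or self.values.max() > KS_MAX):
            raise ValueError("KsSample values must lie in (0, 2]")


def filter_pairs(
    pairs: list[PairDivergence],
    te_flags: set[str],
    ks_max: float = KS_MAX,
    zero_eps: float = ZERO_EPS,
) -> tuple[list[PairDivergence], dict[str, int]]:
    """Apply the pair-level filters in order TE → zero → saturation/max.

    Each pair is counted against exactly one rule. Returns the retained
    pairs and the per-rule removal counts.
    """
    retained = []
    prov = {"te_removed": 0, "zero_removed": 0, "saturated_removed": 0}
    for p in pairs:
        if p.gene_a in te_flags or p.gene_b in te_flags:
            prov["te_removed"] += 1
        elif p.ks is not None and p.ks <= zero_eps:
            prov["zero_removed"] += 1
        elif p.ks is None or p.ks > ks_max:
            prov["saturated_removed"] += 1
        else:
            retained.append(p)
    prov["retained"] = len(retained)
    return retained, prov


def node_average(matrix: np.ndarray) -> list[float]:
    """Collapse an m-member family's pairwise Ks matrix to m−1 node values.

    Average-linkage agglomerative clustering on the symmetric Ks matrix;
    each merge contributes the mean of all cross-cluster pairwise values at
    that merge (which is exactly the UPGMA merge height). Prevents a family
    of m near-identical duplicates from contributing C(m,2) copies of the
    same age.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("pairwise Ks matrix must be square")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("pairwise Ks matrix must be symmetric")
    m = matrix.shape[0]
    if m < 2:
        raise ValueError("need at least two family members")
    if m == 2:
        return [float(matrix[0, 1])]
    z = linkage(squareform(matrix, checks=False), method="average")
    return [float(h) for h in z[:, 2]]


def build_ks_sample(
    species: str,
    family_pairs: dict[str, dict[tuple[str, str], PairDivergence]],
    te_flags: set[str],
    ks_max: float = KS_MAX,
    zero_eps: float = ZERO_EPS,
) -> KsSample:
    """Compose the filters and node averaging into one species' KsSample.

    ``family_pairs`` maps family id → {(gene_a, gene_b): PairDivergence}
    over that family's within-species pairs. TE and zero-Ks removal act at
    the pair level (zero-Ks pairs collapse their genes, treating them as
    one assembly-split gene); node averaging then reduces each family to
    m−1 values, and the saturation cut drops node values above ``ks_max``.
    """
    prov = {"te_removed": 0, "zero_removed": 0, "saturated_removed": 0, "clustered_collapsed": 0}
    values: list[float] = []
    for fam_id, pairs in family_pairs.items():
        genes = sorted({g for key in pairs for g in key})
        kept_genes = [g for g in genes if g not in te_flags]
        n_te_pairs = len(pairs) - len(kept_genes) * (len(kept_genes) - 1) // 2
        prov["te_removed"] += n_te_pairs
        if len(kept_genes) < 2:
            continue
        # merge genes joined by zero-Ks pairs (identical transcripts)
        parent = {g: g for g in kept_genes}

        def find(g: str) -> str:
            while parent[g] != g:
                parent[g] = parent[parent[g]]
                g = parent[g]
            return g

        def lookup(a: str, b: str) -> PairDivergence | None:
            return pairs.get((a, b)) or pairs.get((b, a))

        for i, a in enumerate(kept_genes):
            for b in kept_genes[i + 1 :]:
                p = lookup(a, b)
                if p is not None and p.ks is not None and p.ks <= zero_eps:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[rb] = ra
                    prov["zero_removed"] += 1
        groups: dict[str, list[str]] = {}
        for g in kept_genes:
            groups.setdefault(find(g), []).append(g)
        reps = sorted(groups)
        n_pairs_in = sum(
            1
            for i, a in enumerate(kept_genes)
            for b in kept_genes[i + 1 :]
            if not (
                (p := lookup(a, b)) is not None
                and p.ks is not None
                and p.ks <= zero_eps
            )
        )
        if len(reps) < 2:
            prov["clustered_collapsed"] += n_pairs_in
            continue
        mat = np.zeros((len(reps), len(reps)))
        for i, ra in enumerate(reps):
            for j in range(i + 1, len(reps)):
                cell: list[float] = []
                for a in groups[ra]:
                    for b in groups[reps[j]]:
                        p = lookup(a, b)
                        if p is None:
                            continue
                        cell.append(_SATURATED_KS if p.ks is None else p.ks)
                d = float(np.mean(cell)) if cell else _SATURATED_KS
                mat[i, j] = mat[j, i] = d
        nodes = node_average(mat)
        prov["clustered_collapsed"] += n_pairs_in - len(nodes)
        for v in nodes:
            if v > ks_max or v <= zero_eps:
                prov["saturated_removed"] += 1
            else:
                values.append(v)
    prov["retained"] = len(values)
    return KsSample(species, np.array(values), prov)


@dataclass(frozen=True)
class MixtureComponent:
    """One normal component of the log-Ks mixture."""

    weight: float
    mu_log: float
    sigma_log: float
    n_eff: float  # weight * sample size, for the peak standard error

    @property
    def peak_ks(self) -> float:
        """Back-transformed peak (the log-normal median)."""
        return math.exp(self.mu_log)

    @property
    def peak_se(self) -> float:
        """Delta-method SE of peak_ks from the component mean's SE."""
        if self.n_eff <= 0:
            return float("nan")
        return self.peak_ks * self.sigma_log / math.sqrt(self.n_eff)


@dataclass(frozen=True)
class MixtureFit:
    k: int
    components: tuple[MixtureComponent, ...]
    loglik: float
    bic: float
    n: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "loglik": self.loglik,
            "bic": self.bic,
            "n": self.n,
            "seed": self.seed,
            "components": [
                {
                    "weight": c.weight,
                    "mu_log": c.mu_log,
                    "sigma_log": c.sigma_log,
                    "peak_ks": c.peak_ks,
                    "peak_se": c.peak_se,
                }
                for c in self.components
            ],
        }


SIGMA_FLOOR = 1e-4


def _em_once(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    tol: float = 1e-8,
    max_iter: int = 500,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """One EM run; returns (loglik, weights, means, sigmas).

    The log-likelihood is asserted non-decreasing across iterations.
    """
    n = len(x)
    if init is not None:
        weights, means, sigmas = (np.array(v, dtype=float) for v in init)
    else:
        # means at spread quantiles with jitter, pooled variance, equal weights
        qs = np.quantile(x, (np.arange(k) + 0.5) / k)
        spread = x.std() if x.std() > 0 else 1.0
        means = qs + rng.normal(0, 0.1 * spread / max(k, 1), size=k)
        sigmas = np.full(k, max(spread, SIGMA_FLOOR))
        weights = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    log_norm_const = -0.5 * math.log(2 * math.pi)
    xc = x[:, None]
    for _ in range(max_iter):
        z = (xc - means[None, :]) / sigmas[None, :]
        # weighted component densities, up to the 1/sqrt(2 pi) constant
        dens = (weights / sigmas)[None, :] * np.exp(-0.5 * z * z)
        total = dens.sum(axis=1)
        if np.any(total <= 0):  # far outliers underflowed: log-space fallback
            log_pdf = (
                np.log(weights / sigmas)[None, :] - 0.5 * z * z + log_norm_const
            )
            col = logsumexp(log_pdf, axis=1)
            ll = float(col.sum())
            resp = np.exp(log_pdf - col[:, None])
        else:
            ll = float(np.log(total).sum()) + n * log_norm_const
            resp = dens / total[:, None]
        assert ll >= prev_ll - 1e-7, "EM log-likelihood decreased"
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sigmas = np.sqrt(np.maximum(var, SIGMA_FLOOR**2))
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
    return prev_ll, weights, means, sigmas


def fit_mixture(
    ks_values: KsSample | np.ndarray,
    k_max: int = 5,
    restarts: int = 20,
    seed: int = 0,
) -> MixtureFit:
    """Fit normal mixtures to ln(Ks) for k = 1..k_max and select by BIC.

    BIC = -2 loglik + (3k - 1) ln n. Each k takes the best of ``restarts``
    seeded initializations; every restart is burned in for a short number
    of iterations and only the best continues to full convergence (the
    standard em-EM short-run strategy — restarts differ only in their
    initialization jitter, so the short runs rank them reliably).
    Requires n ≥ 30 and a non-degenerate sample.
    """
    values = ks_values.values if isinstance(ks_values, KsSample) else np.asarray(ks_values, float)
    n = len(values)
    if n < 30:
        raise ValueError(f"need at least 30 Ks values to fit a mixture, got {n}")
    if np.any(values <= 0):
        raise ValueError("Ks values must be positive to fit in log space")
    x = np.log(values)
    if x.std() < SIGMA_FLOOR:
        raise ValueError("degenerate sample: all Ks values (nearly) equal (variance floor)")
    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    for k in range(1, k_max + 1):
        best_ll = -np.inf
        best_params = None
        for _ in range(restarts):
            ll, w, mu, sig = _em_once(x, k, rng, max_iter=25)
            if ll > best_ll:
                best_ll, best_params = ll, (w, mu, sig)
        best_ll, w, mu, sig = _em_once(x, k, rng, init=best_params)
        bic = -2.0 * best_ll + (3 * k - 1) * math.log(n)
        order = np.argsort(mu)
        comps = tuple(
            MixtureComponent(float(w[i]), float(mu[i]), float(sig[i]), float(w[i]) * n)
            for i in order
        )
        fit = MixtureFit(k, comps, best_ll, bic, n, seed)
        if best is None or fit.bic < best.bic:
            best = fit
    return best


def classify_wgd_components(
    fit: MixtureFit,
    weight_min: float = 0.05,
    peak_range: tuple[float, float] = (0.1, KS_MAX),
) -> list[MixtureComponent]:
    """Components that qualify as WGD signatures.

    Components with back-transformed peak below 0.1 are the SSD-dominated
    initial peak and excluded; tiny-weight components are noise.
    """
    lo, hi = peak_range
    out = [
        c
        for c in fit.components
        if c.weight >= weight_min and lo < c.peak_ks <= hi
    ]
    return sorted(out, key=lambda c: c.peak_ks)


@dataclass
class SiZerMap:
    """Significance-of-slope map over (bandwidth, position) cells."""

    x_grid: np.ndarray
    bandwidths: np.ndarray
    states: np.ndarray  # shape (len(bandwidths), len(x_grid))
    alpha: float

    def state_name(self, i: int, j: int) -> str:
        return _STATE_NAMES[int(self.states[i, j])]

    def to_frame(self):
        import pandas as pd

        named = np.vectorize(_STATE_NAMES.get)(self.states)
        return pd.DataFrame(
            named,
            index=[f"h={h:.4f}" for h in self.bandwidths],
            columns=[f"{x:.2f}" for x in self.x_grid],
        )


def sizer_cell(
    values: np.ndarray, x: float, h: float, alpha: float = 0.05, ess_min: float = 5.0
) -> int:
    """Classify a single (h, x) cell; reference path for the map builder."""
    values = np.asarray(values, float)
    n = len(values)
    u = (x - values) / h
    kernel = norm.pdf(u)
    ess = kernel.sum() / norm.pdf(0.0)
    if ess < ess_min:
        return SPARSE
    terms = (x - values) / h**3 * -norm.pdf(u)
    deriv = terms.mean()
    se = terms.std(ddof=1) / math.sqrt(n)
    z = norm.ppf(1 - alpha / 2)
    if deriv - z * se > 0:
        return INCREASING
    if deriv + z * se < 0:
        return DECREASING
    return FLAT


def sizer(
    ks_values: KsSample | np.ndarray,
    x_grid: np.ndarray | None = None,
    bandwidths: np.ndarray | None = None,
    alpha: float = 0.05,
    ess_min: float = 5.0,
) -> SiZerMap:
    """SiZer map: significant zero crossings of the density derivative.

    For each bandwidth h and position x the Gaussian-kernel density
    derivative estimate is the mean of per-observation terms; a pointwise
    (1 - alpha) CI on it classifies the cell as INCREASING / DECREASING /
    FLAT, overridden by SPARSE where the effective sample size is below
    ``ess_min``.
    """
    values = ks_values.values if isinstance(ks_values, KsSample) else np.asarray(ks_values, float)
    n = len(values)
    if n < 30:
        raise ValueError(f"need at least 30 values for a SiZer map, got {n}")
    if x_grid is None:
        x_grid = np.round(np.arange(0.0, 2.0 + 1e-12, 0.02), 10)
    if bandwidths is None:
        bandwidths = np.logspace(math.log10(0.02), math.log10(0.5), 20)
    z = norm.ppf(1 - alpha / 2)
    phi0 = norm.pdf(0.0)
    states = np.empty((len(bandwidths), len(x_grid)), dtype=int)
    for i, h in enumerate(bandwidths):
        u = (x_grid[None, :] - values[:, None]) / h  # (n, nx)
        kern = norm.pdf(u)
        ess = kern.sum(axis=0) / phi0
        terms = -(x_grid[None, :] - values[:, None]) / h**3 * kern
        deriv = terms.mean(axis=0)
        se = terms.std(axis=0, ddof=1) / math.sqrt(n)
        row = np.full(len(x_grid), FLAT)
        row[deriv - z * se > 0] = INCREASING
        row[deriv + z * se < 0] = DECREASING
        row[ess < ess_min] = SPARSE
        states[i] = row
    return SiZerMap(np.asarray(x_grid, float), np.asarray(bandwidths, float), states, alpha)


def plot_sizer(map_: SiZerMap, path) -> None:
    """Render the SiZer map as a raster (red = decreasing, blue = increasing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    colormap = ListedColormap(["#d62728", "#7f4fc9", "#1f77b4", "#bfbfbf"])
    coded = np.select(
        [map_.states == DECREASING, map_.states == FLAT, map_.states == INCREASING],
        [0, 1, 2],
        default=3,
    )
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.imshow(
        coded,
        aspect="auto",
        origin="lower",
        cmap=colormap,
        vmin=-0.5,
        vmax=3.5,
        extent=(map_.x_grid[0], map_.x_grid[-1], 0, len(map_.bandwidths)),
    )
    ax.set_yticks(range(0, len(map_.bandwidths), 5))
    ax.set_yticklabels([f"{map_.bandwidths[i]:.3f}" for i in range(0, len(map_.bandwidths), 5)])
    ax.set_xlabel("Ks")
    ax.set_ylabel("bandwidth h")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
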