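"""Synthetic transcriptome-derived CDS sets with a planted duplication history.

The generator emulates what the real pipeline consumes: per-species CDS
FASTAs for several species descended from a common ancestor, carrying

* a shared whole-genome duplication (WGD) at a specified age, whose retained
  copies produce duplicate pairs of true synonymous divergence ``2 T mu``;
* a background of small-scale duplications (SSD) with an L-shaped
  (exponential) Ks age distribution;
* a fraction of transposable-element-like families (ordinary families
  carrying a flag — the TE filter downstream acts on annotation, not
  sequence); and
* multicopy families that exercise the node-averaging correction.

Sequence evolution places synonymous and nonsynonymous differences at
previously untouched positions until quotas drawn as
``Poisson(p * sites)`` are met, where ``p`` is the Jukes–Cantor inverse of
the target distance. By construction the NG86 + JC estimator applied to an
(ancestor, descendant) pair is then an approximately unbiased estimate of
the target Ks. Stop codons are never introduced; there are no indels.

Everything is deterministic under a fixed seed. A truth table records every
within-family gene pair with its event class (WGD / SSD / ORTHOLOG) and
true Ks, so downstream stages can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .codonalign_ks import GENETIC_CODE, SENSE_CODONS, count_sites
from .io_formats import (
    HitRecord,
    SequenceRecord,
    parse_newick,
    write_fasta,
    write_gene_list,
    write_hit_table,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_root_genes",
    "evolve_sequence",
    "simulate_dataset",
    "DEFAULT_SPECIES_TREE",
]

#: Five-taxon ultrametric species tree, branch lengths in Mya
#: (crown age 56.43, matching the divergence scenario the package targets).
DEFAULT_SPECIES_TREE = (
    "((((Kob:28.31,Cta:28.31):8.16,Rap:36.47):2.21,Bgy:38.68):17.75,Cbr:56.43);"
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults are the conditions the package's recovery analyses use: five
    species with the crown topology above, a shared WGD at 75 Mya with
    retention probability 0.25, lineage rate 2.5e-9 synonymous
    substitutions per site per year, a modest exponential SSD background,
    and 5% TE-like families.
    """

    seed: int = 0
    n_base_genes: int = 500
    species_tree: str = DEFAULT_SPECIES_TREE
    stem_age_mya: float = 110.0
    lineage_rate: float = 2.5e-9
    wgd_events: Sequence[tuple[float, float]] = ((75.0, 0.25),)
    ssd_rate: float = 1.0
    ssd_age_scale: float = 0.2
    te_family_fraction: float = 0.05
    gene_length_codons: tuple[int, int] = (100, 300)
    ka_ks_ratio: float = 0.2

    def __post_init__(self) -> None:
        if self.n_base_genes < 0:
            raise ValueError("n_base_genes must be nonnegative")
        if self.lineage_rate <= 0:
            raise ValueError("lineage_rate must be positive")
        if not 0.0 <= self.te_family_fraction <= 1.0:
            raise ValueError("te_family_fraction must lie in [0,1]")
        if self.ssd_rate < 0 or self.ssd_age_scale <= 0:
            raise ValueError("ssd_rate must be ≥ 0 and ssd_age_scale > 0")
        if not 0.0 < self.ka_ks_ratio <= 1.0:
            raise ValueError("ka_ks_ratio must lie in (0,1]")
        lo, hi = self.gene_length_codons
        if lo < 30 or hi < lo:
            raise ValueError("gene lengths must satisfy 30 ≤ min ≤ max codons")
        tree = parse_newick(self.species_tree)
        root_age = max(
            leaf.distance_from_root() for leaf in tree.leaf_node_iter()
        )
        if self.stem_age_mya < root_age:
            raise ValueError(
                f"stem_age_mya {self.stem_age_mya} is younger than the crown "
                f"age {root_age:.2f} of the species tree"
            )
        for age, p in self.wgd_events:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"WGD retention probability {p} not in [0,1]")
            if not 0.0 < age <= self.stem_age_mya:
                raise ValueError(
                    f"WGD age {age} outside (0, stem age {self.stem_age_mya}]"
                )

    @property
    def species(self) -> list[str]:
        tree = parse_newick(self.species_tree)
        return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


_SENSE = np.array(SENSE_CODONS)


def simulate_root_genes(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[SequenceRecord]:
    """Ancestral gene set: random in-frame sense codons, no stops."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.gene_length_codons
    records = []
    width = max(4, len(str(max(config.n_base_genes, 1))))
    for i in range(config.n_base_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        codons = _SENSE[rng.integers(0, len(_SENSE), size=n_codons)]
        records.append(SequenceRecord(f"g{i:0{width}d}", "".join(codons)))
    return records


def _jc_expected_p(d: float) -> float:
    """Expected observed difference proportion under JC at distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def evolve_sequence(
    seq: SequenceRecord | str,
    target_ks: float,
    omega: float,
    rng: np.random.Generator | int,
) -> str:
    """Evolve a CDS to an expected synonymous divergence of ``target_ks``.

    Returns the descendant residue string. Nonsynonymous divergence is
    scaled by ``omega`` (Ka = omega * Ks). Differences are placed at
    previously untouched positions so that the observed proportions match
    the JC inverse of the targets; stop codons are never created.
    """
    if target_ks < 0:
        raise ValueError("target_ks must be nonnegative")
    if not 0.0 < omega <= 1.0:
        raise ValueError("omega must lie in (0,1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if target_ks == 0:
        return residues
    codons = [residues[i : i + 3] for i in range(0, len(residues), 3)]
    s_sites = sum(count_sites(c) for c in codons)
    n_sites = 3.0 * len(codons) - s_sites
    need_syn = int(rng.poisson(_jc_expected_p(target_ks) * s_sites))
    need_non = int(rng.poisson(_jc_expected_p(omega * target_ks) * n_sites))
    touched: set[int] = set()
    bases = "ACGT"
    max_attempts = 400 * (need_syn + need_non + 10)
    attempts = 0
    while (need_syn > 0 or need_non > 0) and attempts < max_attempts:
        attempts += 1
        pos = int(rng.integers(0, 3 * len(codons)))
        if pos in touched:
            continue
        ci, off = divmod(pos, 3)
        codon = codons[ci]
        new_base = bases[int(rng.integers(0, 4))]
        if new_base == codon[off]:
            continue
        mutant = codon[:off] + new_base + codon[off + 1 :]
        if mutant not in GENETIC_CODE:  # stop codon — never introduced
            continue
        synonymous = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
        if synonymous and need_syn > 0:
            need_syn -= 1
        elif not synonymous and need_non > 0:
            need_non -= 1
        else:
            continue
        codons[ci] = mutant
        touched.add(pos)
    return "".join(codons)


@dataclass
class SimulatedDataset:
    """Output bundle of :func:`simulate_dataset`."""

    config: SimulationConfig
    species_seqs: dict[str, list[SequenceRecord]]
    hits: list[HitRecord]
    te_flags: set[str]
    truth: pd.DataFrame  # gene_a, gene_b, event, true_ks, te_flag, family
    families: dict[str, set[str]] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the external file dialects plus a seed-bearing manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sp, records in self.species_seqs.items():
            p = outdir / f"{sp}.cds.fasta"
            write_fasta(records, p)
            paths[f"fasta:{sp}"] = p
        write_hit_table(self.hits, outdir / "hits.tsv")
        paths["hits"] = outdir / "hits.tsv"
        write_gene_list(self.te_flags, outdir / "te_flags.txt")
        paths["te_flags"] = outdir / "te_flags.txt"
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        paths["truth"] = outdir / "truth.tsv"
        with open(outdir / "manifest.txt", "w") as fh:
            fh.write(f"seed: {self.config.seed}\n")
            fh.write(f"n_base_genes: {self.config.n_base_genes}\n")
            fh.write(f"species: {','.join(self.species_seqs)}\n")
        paths["manifest"] = outdir / "manifest.txt"
        return paths


class _Copy:
    """One gene-copy lineage descending through the species tree."""

    __slots__ = ("base", "seq", "chain")

    def __init__(self, base: int, seq: str, chain: tuple):
        self.base = base
        self.seq = seq
        self.chain = chain


def _node_ages(tree: dendropy.Tree) -> dict:
    """Age (Mya above the tips) of every node of an ultrametric tree."""
    ages = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(
                ages[c] + (c.edge.length or 0.0) for c in node.child_nodes()
            )
    return ages


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generative model and assemble the truth table."""
    rng = np.random.default_rng(config.seed)
    mu = config.lineage_rate
    tree = parse_newick(config.species_tree)
    ages = _node_ages(tree)
    root = tree.seed_node
    stem_age = config.stem_age_mya

    roots = simulate_root_genes(config, rng)
    n_te = int(round(config.te_family_fraction * config.n_base_genes))
    te_bases = set(
        int(i) for i in rng.choice(config.n_base_genes, size=n_te, replace=False)
    ) if n_te else set()

    events: list[tuple[float, str]] = []  # node registry: (age_mya, type)

    def new_event(age: float, kind: str) -> int:
        events.append((age, kind))
        return len(events) - 1

    def ks_of(delta_mya: float) -> float:
        return mu * delta_mya * 1e6

    wgds = sorted(config.wgd_events, key=lambda e: -e[0])

    def evolve_segment(copies: list[_Copy], t_hi: float, t_lo: float) -> list[_Copy]:
        """Evolve each copy from t_hi to t_lo, forking surviving SSD births.

        SSD births are a Poisson process along the lineage (rate ``ssd_rate``
        per gene per unit per-lineage Ks), thinned by survival probability
        exp(-age / ssd_age_scale) so retained duplicate ages are
        exponential — the L-shaped background of continuous small-scale
        duplication and loss.
        """
        if t_lo >= t_hi:
            return copies
        out = []
        for c in copies:
            seg_ks = ks_of(t_hi - t_lo)
            n_births = int(rng.poisson(config.ssd_rate * seg_ks))
            birth_times = sorted(
                (float(t) for t in rng.uniform(t_lo, t_hi, size=n_births)),
                reverse=True,
            )
            lineage = [c]
            t_now = t_hi
            for t_birth in birth_times:
                pair_ks_at_tip = 2.0 * ks_of(t_birth)
                if rng.random() >= math.exp(-pair_ks_at_tip / config.ssd_age_scale):
                    continue  # duplicate lost before the present
                for x in lineage:
                    x.seq = evolve_sequence(x.seq, ks_of(t_now - t_birth), config.ka_ks_ratio, rng)
                t_now = t_birth
                parent = lineage[int(rng.integers(0, len(lineage)))]
                ev = new_event(t_birth, "SSD")
                dup = _Copy(parent.base, parent.seq, parent.chain + ((ev, 1),))
                parent.chain = parent.chain + ((ev, 0),)
                lineage.append(dup)
            for x in lineage:
                x.seq = evolve_sequence(x.seq, ks_of(t_now - t_lo), config.ka_ks_ratio, rng)
            out.extend(lineage)
        return out

    def descend(node, copies: list[_Copy], t_top: float, is_stem: bool = False) -> dict[str, list[_Copy]]:
        """Evolve copies down the branch ending at ``node``; recurse."""
        t_bottom = ages[node]
        t_now = t_top
        for age, retention in wgds:
            on_branch = t_bottom <= age < t_top or (is_stem and age == t_top)
            if not on_branch:
                continue
            # evolve to the WGD time, then duplicate with retention prob
            if age < t_now:
                copies = evolve_segment(copies, t_now, age)
                t_now = age
            retained = rng.random(len(copies)) < retention
            new_copies = []
            for keep, c in zip(retained, copies):
                if keep:
                    ev = new_event(age, "WGD")
                    dup = _Copy(c.base, c.seq, c.chain + ((ev, 1),))
                    c.chain = c.chain + ((ev, 0),)
                    new_copies.append(dup)
            copies = copies + new_copies
        if t_bottom < t_now:
            copies = evolve_segment(copies, t_now, t_bottom)
        if node.is_leaf():
            return {node.taxon.label: copies}
        out: dict[str, list[_Copy]] = {}
        ev = new_event(t_bottom, "SPECIATION")
        for i, child in enumerate(node.child_nodes()):
            branch_copies = [
                _Copy(c.base, c.seq, c.chain + ((ev, i),)) for c in copies
            ]
            out.update(descend(child, branch_copies, t_bottom))
        return out

    start = [_Copy(i, r.residues, ()) for i, r in enumerate(roots)]
    tip_copies = descend(root, start, stem_age, is_stem=True)

    # finalize gene ids and families
    width = max(4, len(str(max(config.n_base_genes, 1))))
    species_seqs: dict[str, list[SequenceRecord]] = {}
    members: dict[int, list[tuple[str, _Copy]]] = {i: [] for i in range(config.n_base_genes)}
    te_flags: set[str] = set()
    for sp in sorted(tip_copies):
        serial: dict[int, int] = {}
        recs = []
        for c in tip_copies[sp]:
            k = serial.get(c.base, 0) + 1
            serial[c.base] = k
            gid = f"{sp}|g{c.base:0{width}d}.{k}"
            recs.append(SequenceRecord(gid, c.seq))
            members[c.base].append((gid, c))
            if c.base in te_bases:
                te_flags.add(gid)
        species_seqs[sp] = recs

    def divergence(a: _Copy, b: _Copy) -> tuple[str, float]:
        shared = 0
        for x, y in zip(a.chain, b.chain):
            if x != y:
                break
            shared += 1
        # the first differing element names the MRCA split event
        ev_id = a.chain[shared][0] if shared < len(a.chain) else b.chain[shared][0]
        age, kind = events[ev_id]
        event = {"SPECIATION": "ORTHOLOG"}.get(kind, kind)
        return event, 2.0 * mu * age * 1e6

    rows = []
    hits: list[HitRecord] = []
    families: dict[str, set[str]] = {}
    for base, mem in members.items():
        if not mem:
            continue
        fam_id = f"fam{base:0{width}d}"
        families[fam_id] = {gid for gid, _ in mem}
        te = base in te_bases
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                gid_a, ca = mem[i]
                gid_b, cb = mem[j]
                event, true_ks = divergence(ca, cb)
                rows.append((gid_a, gid_b, event, true_ks, te, fam_id))
                identity = max(45.0, 98.0 - 25.0 * min(true_ks, 2.0))
                bitscore = max(60.0, 600.0 - 200.0 * min(true_ks, 2.5))
                hits.append(HitRecord(gid_a, gid_b, identity, 1e-50, bitscore))
    truth = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "event", "true_ks", "te_flag", "family"]
    )
    return SimulatedDataset(config, species_seqs, hits, te_flags, truth, families)
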