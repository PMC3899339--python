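"""Synthetic multi-species essentiality corpora.

Generates labeled feature tables for a clade of microbial species with the
statistical structure that cross-species essentiality transfer rests on:

* one shared set of ortholog families whose latent *importance* ``z``
  evolves along a Yule time tree by Brownian motion, so which genes are
  essential drifts apart as species diverge;
* a per-species class-separation direction over the continuous features
  that drifts on the same tree, so the feature signature of essentiality
  decays in transferability with divergence time;
* growth-condition and lifestyle terms: a designated "biosynthesis" gene
  subset is pushed toward essentiality only under minimal medium, and a
  designated "energy" subset is keyed to the oxygen requirement; both tags
  also shift the class-separation direction on matched feature blocks, so
  species sharing a tag transfer better to each other;
* per-species label noise emulating assay quality (transposon screens vs
  systematic deletion collections);
* missing-completely-at-random feature dropout.

All randomness flows from a single integer seed through a fixed
``numpy.random.SeedSequence`` spawning order, so identical configurations
produce bit-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import DivergenceMatrix, FeatureSchema, SpeciesDataset, SpeciesMeta

__all__ = [
    "SimConfig",
    "PhyloTree",
    "simulate_divergence_tree",
    "simulate_multispecies",
    "apply_label_noise",
]

_OXYGEN_SIGN = {"aerobe": 1.0, "anaerobe": -1.0, "facultative": 0.0}


@dataclass
class SimConfig:
    """Parameters of the synthetic corpus generator.

    ``drift_sigma`` is the standard deviation of the root-to-tip Brownian
    displacement of a trait, in units of that trait's baseline scale (the
    latent importance has unit variance; the class-separation entries have
    baseline ``feature_separation``). ``condition_effect_size`` and
    ``lifestyle_effect_size`` are on the latent (unit-variance) scale and
    scale the matched feature-block shifts by ``feature_separation``.
    """

    n_species: int = 12
    n_genes_per_species: int = 500
    essential_fraction: float | Mapping[str, float] = 0.15
    n_features_cont: int = 13
    n_features_cat: int = 2
    feature_separation: float = 0.55
    drift_sigma: float = 0.5
    label_noise: Mapping[str, float] = field(default_factory=dict)
    condition: Mapping[str, str] = field(default_factory=dict)
    lifestyle: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    condition_effect_size: float = 1.5
    lifestyle_effect_size: float = 1.0
    conditional_gene_fraction: float = 0.15
    max_depth_my: float = 4000.0
    missing_rate: float = 0.05
    n_categorical_levels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        fracs = (
            [self.essential_fraction]
            if np.isscalar(self.essential_fraction)
            else list(self.essential_fraction.values())
        )
        for f in fracs:
            if not 0.0 < f < 1.0:
                raise ValueError(f"essential_fraction must be in (0,1), got {f}")
        for s, q in self.label_noise.items():
            if not 0.0 <= q <= 0.5:
                raise ValueError(f"label_noise[{s!r}] must be in [0,0.5], got {q}")
        if self.drift_sigma < 0:
            raise ValueError("drift_sigma must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        if self.max_depth_my <= 0:
            raise ValueError("max_depth_my must be positive")

    def pi(self, species_id: str) -> float:
        if np.isscalar(self.essential_fraction):
            return float(self.essential_fraction)  # type: ignore[arg-type]
        return float(self.essential_fraction[species_id])  # type: ignore[index]

    def noise(self, species_id: str) -> float:
        return float(self.label_noise.get(species_id, 0.0))

    def condition_of(self, species_id: str) -> str:
        return self.condition.get(species_id, "rich")

    def lifestyle_of(self, species_id: str) -> dict[str, str]:
        tags = dict(self.lifestyle.get(species_id, {}))
        tags.setdefault("gram", "neg")
        tags.setdefault("oxygen", "facultative")
        tags.setdefault("shape", "rod")
        return tags


class PhyloTree:
    """Rooted ultrametric time tree stored as parent/time arrays.

    Node times are depths from the root in My; tips all sit at
    ``max_depth_my``. Used both to report divergence times and to run
    Brownian-motion simulations of traits.
    """

    def __init__(self, parent: np.ndarray, time: np.ndarray, tip_ids: list[str], tip_nodes: np.ndarray):
        self.parent = parent
        self.time = time
        self.tip_ids = tip_ids
        self.tip_nodes = tip_nodes

    @property
    def depth(self) -> float:
        return float(self.time.max())

    def _ancestor_path(self, node: int) -> list[int]:
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(self.parent[path[-1]])
        return path

    def divergence_matrix(self) -> DivergenceMatrix:
        n = len(self.tip_ids)
        d = np.zeros((n, n))
        paths = [set(self._ancestor_path(int(t))) for t in self.tip_nodes]
        for i in range(n):
            for j in range(i + 1, n):
                shared = paths[i] & paths[j]
                mrca_time = max(self.time[k] for k in shared)
                d[i, j] = d[j, i] = self.depth - mrca_time
        return DivergenceMatrix(self.tip_ids, d)

    def brownian_tips(self, root_values: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
        """Brownian motion of a (k,)-trait vector down every branch.

        Per-branch variance is ``sigma**2 * branch_length / depth``, so the
        total root-to-tip displacement has standard deviation ``sigma``.
        Returns an array of shape (n_tips, k) in tip order.
        """
        n_nodes = len(self.parent)
        vals = np.empty((n_nodes,) + root_values.shape, dtype=float)
        order = np.argsort(self.time, kind="stable")  # parents precede children
        for node in order:
            p = self.parent[node]
            if p < 0:
                vals[node] = root_values
            else:
                bl = self.time[node] - self.time[p]
                sd = sigma * np.sqrt(max(bl, 0.0) / self.depth)
                vals[node] = vals[p] + rng.normal(0.0, sd, size=root_values.shape)
        return vals[self.tip_nodes]


def simulate_divergence_tree(
    n_species: int, max_depth_my: float, seed: int
) -> tuple[DivergenceMatrix, PhyloTree]:
    """Simulate a Yule (pure-birth) time tree and its divergence matrix.

    Branch lengths are rescaled so the root-to-tip depth equals
    ``max_depth_my``; divergence(i, j) is the time since the MRCA of tips
    i and j, making the matrix ultrametric.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if max_depth_my <= 0:
        raise ValueError("max_depth_my must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # root splits at t=0 into two lineages; each subsequent split picks a
    # uniform active lineage after an Exp(k) wait (k = current lineage count)
    parent = [-1, 0, 0]
    time = [0.0, np.inf, np.inf]  # tips provisionally open-ended
    active = [1, 2]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        time[node] = t
        for _ in range(2):
            parent.append(node)
            time.append(np.inf)
            active.append(len(parent) - 1)
    present = t + rng.exponential(1.0 / len(active))
    time = [present if np.isinf(x) else x for x in time]
    scale = max_depth_my / present
    time_arr = np.asarray(time) * scale
    parent_arr = np.asarray(parent, dtype=int)

    tip_nodes = np.asarray(sorted(active))
    width = max(2, len(str(n_species)))
    tip_ids = [f"S{i + 1:0{width}d}" for i in range(n_species)]
    tree = PhyloTree(parent_arr, time_arr, tip_ids, tip_nodes)
    return tree.divergence_matrix(), tree


def apply_label_noise(labels: np.ndarray, q: float, seed: int | np.random.Generator) -> np.ndarray:
    """Flip each binary label independently with probability ``q``."""
    if not 0.0 <= q <= 0.5:
        raise ValueError(f"label noise q must be in [0, 0.5], got {q}")
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flips = rng.random(labels.shape) < q
    return np.where(flips, 1 - labels, labels)


def _solve_threshold(u: np.ndarray, pi: float) -> tuple[float, np.ndarray]:
    """Threshold the latent scale so the realized essential fraction hits pi.

    Realized fraction must land within +/-2% (absolute) of pi; degenerate
    latent distributions (heavy ties from extreme effect sizes) that make
    this impossible raise instead of silently clipping.
    """
    n = len(u)
    k = int(round(pi * n))
    k = min(max(k, 1), n - 1)
    srt = np.sort(u)[::-1]
    thr = 0.5 * (srt[k - 1] + srt[k])
    y = u > thr
    realized = y.mean()
    if abs(realized - pi) > 0.02:
        raise ValueError(
            f"cannot realize essential fraction {pi:.3f} (got {realized:.3f}); "
            "latent distribution too discrete for this n or effect sizes"
        )
    return float(thr), y.astype(int)


def simulate_multispecies(
    config: SimConfig, tree: PhyloTree | None = None
) -> tuple[dict[str, SpeciesDataset], DivergenceMatrix]:
    """Generate one corpus of labeled species datasets on a shared tree.

    Returns the datasets keyed by species id plus the divergence matrix of
    the tree used. If ``tree`` is None a Yule tree is simulated from the
    config's own seed.
    """
    ss = np.random.SeedSequence(config.seed)
    # fixed spawning order: tree, z root, z drift, delta drift, subsets,
    # features, categorical noise, label flips, missingness
    (s_tree, s_zroot, s_zdrift, s_ddrift, s_subset,
     s_feat, s_cat, s_flip, s_miss) = ss.spawn(9)

    if tree is None:
        _, tree = simulate_divergence_tree(
            config.n_species, config.max_depth_my, seed=int(s_tree.generate_state(1)[0] % (2**31))
        )
    if len(tree.tip_ids) != config.n_species:
        raise ValueError(
            f"tree has {len(tree.tip_ids)} tips but config.n_species={config.n_species}"
        )
    divergence = tree.divergence_matrix()

    n = config.n_genes_per_species
    kc = config.n_features_cont
    km = config.n_features_cat
    species = tree.tip_ids

    rng_zroot = np.random.default_rng(s_zroot)
    rng_zdrift = np.random.default_rng(s_zdrift)
    rng_ddrift = np.random.default_rng(s_ddrift)
    rng_subset = np.random.default_rng(s_subset)
    rng_feat = np.random.default_rng(s_feat)
    rng_cat = np.random.default_rng(s_cat)
    rng_flip = np.random.default_rng(s_flip)
    rng_miss = np.random.default_rng(s_miss)

    # shared ortholog families: latent importance drifts on the tree
    z0 = rng_zroot.normal(size=n)
    z_tips = tree.brownian_tips(z0, config.drift_sigma, rng_zdrift)  # (n_species, n)

    # class-separation direction drifts on the tree; relative drift scale
    base_sep = np.full(kc, config.feature_separation)
    sep_sigma = config.drift_sigma * config.feature_separation
    delta_tips = tree.brownian_tips(base_sep, sep_sigma, rng_ddrift)  # (n_species, kc)

    # designated gene subsets (shared family indices) and feature blocks
    n_cond_genes = int(round(config.conditional_gene_fraction * n))
    perm = rng_subset.permutation(n)
    bio_genes = perm[:n_cond_genes]
    energy_genes = perm[n_cond_genes : 2 * n_cond_genes]
    block = max(1, kc // 5)
    bio_feats = np.arange(0, min(block, kc))
    energy_feats = np.arange(min(block, kc), min(2 * block, kc))

    cont_cols = [f"f{j + 1:02d}" for j in range(kc)]
    cat_cols = [f"c{j + 1:02d}" for j in range(km)]
    schema = FeatureSchema(continuous=tuple(cont_cols), categorical=tuple(cat_cols))

    datasets: dict[str, SpeciesDataset] = {}
    for si, sp in enumerate(species):
        cond = config.condition_of(sp)
        life = config.lifestyle_of(sp)
        oxy_sign = _OXYGEN_SIGN.get(life["oxygen"], 0.0)

        # latent essentiality propensity with condition/lifestyle terms
        u = z_tips[si].copy()
        if cond == "minimal":
            u[bio_genes] += config.condition_effect_size
        u[energy_genes] += oxy_sign * config.lifestyle_effect_size
        _, y = _solve_threshold(u, config.pi(sp))

        # species separation direction, shifted on matched feature blocks
        delta = delta_tips[si].copy()
        cond_sign = 1.0 if cond == "minimal" else -1.0
        delta[bio_feats] += cond_sign * config.condition_effect_size * config.feature_separation
        delta[energy_feats] += oxy_sign * config.lifestyle_effect_size * config.feature_separation

        # continuous features: class-conditional Gaussians, unit noise
        shift = np.where(y[:, None] == 1, 0.5, -0.5) * delta[None, :]
        x = shift + rng_feat.normal(size=(n, kc))

        # categorical features: quantile-binned noisy copies of z
        cats = np.empty((n, km), dtype=int)
        for j in range(km):
            noisy = z_tips[si] + rng_cat.normal(size=n)
            qs = np.quantile(noisy, np.linspace(0, 1, config.n_categorical_levels + 1)[1:-1])
            cats[:, j] = np.searchsorted(qs, noisy) + 1

        labels = apply_label_noise(y, config.noise(sp), rng_flip)

        gene_ids = [f"{sp}_g{i + 1:05d}" for i in range(n)]
        table = pd.DataFrame(x, columns=cont_cols, index=pd.Index(gene_ids, name="gene_id"))
        for j, c in enumerate(cat_cols):
            table[c] = cats[:, j].astype(float)
        if config.missing_rate > 0:
            mask = rng_miss.random(table.shape) < config.missing_rate
            table = table.mask(mask)
        table.insert(0, "species_id", sp)

        quality = "deletion"
        q = config.noise(sp)
        if q >= 0.25:
            quality = "inferred"
        elif q > 0.0:
            quality = "transposon"
        meta = SpeciesMeta(
            species_id=sp,
            quality_tier=quality,
            growth_condition=cond,
            gram=life["gram"],
            oxygen=life["oxygen"],
            shape=life["shape"],
        )
        datasets[sp] = SpeciesDataset(
            species_id=sp,
            features=table,
            labels=pd.Series(labels, index=table.index),
            schema=schema,
            meta=meta,
        )
    return datasets, divergence
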