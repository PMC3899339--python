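"""Training-set selection experiments.

Four suites built on the classifier and metrics:

* incomplete training sets — predictive accuracy as a function of the
  training-set size, as a fraction of the species' total genes;
* integrated training sets — full enumeration of k-species pools used as
  one concatenated training set;
* HASTS/LASTS grouping — splitting single-species training sets into
  high and low transfer-AUC groups and comparing their k-subset pools;
* rule-based selection — ranking candidate training species by label
  quality, growth-condition match, phylogenetic proximity, and lifestyle
  similarity, validated against a random-integration null distribution.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DivergenceMatrix, SpeciesDataset, SpeciesMeta, QUALITY_TIERS
from .evaluation import auc, ppv_at_k
from .nb import fit_nb, score_genes

__all__ = [
    "CurveResult",
    "incomplete_training_curve",
    "enumerate_integrated_sets",
    "IntegrationResult",
    "integrated_performance",
    "hasts_lasts_split",
    "partition_k_subsets",
    "group_comparison",
    "NullResult",
    "random_integration_pvalue",
    "rule_based_select",
    "welch_t_test",
]

log = logging.getLogger(__name__)

_QUALITY_SCORE = {tier: 1.0 - i / (len(QUALITY_TIERS) - 1) for i, tier in enumerate(QUALITY_TIERS)}


@dataclass
class CurveResult:
    """Accuracy vs training-set size (fractions of total genes)."""

    fractions: list[float]
    mean_auc: list[float]
    sd_auc: list[float]
    mean_ppv: list[float]
    sd_ppv: list[float]
    reps: int
    k_ppv: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "mean_auc": self.mean_auc,
                "sd_auc": self.sd_auc,
                "mean_ppv": self.mean_ppv,
                "sd_ppv": self.sd_ppv,
                "reps": self.reps,
            }
        )


def incomplete_training_curve(
    dataset: SpeciesDataset,
    fractions: Sequence[float] | None = None,
    reps: int = 1000,
    test_fraction: float = 0.2,
    k_ppv: int = 200,
    seed: int = 0,
    *,
    alpha: float = 1.0,
    normalization: str = "rank",
    max_retries: int = 20,
) -> CurveResult:
    """Within-species accuracy as the training set grows.

    Per replicate: hold out a class-stratified ``test_fraction`` of the
    labeled genes, then train on nested prefixes of a random permutation
    of the remainder, sized as the given fractions of the TOTAL labeled
    genes. A permutation whose smallest prefix is single-class is redrawn
    (bounded retries). AUC and PPV@k are aggregated as mean/sd per
    fraction over replicates, each replicate independently seeded.
    """
    if fractions is None:
        fractions = [round(f, 2) for f in list(np.arange(0.01, 0.11, 0.01)) + [0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]]
    fractions = list(fractions)
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be strictly increasing")
    if fractions[-1] > 1 - test_fraction + 1e-9:
        raise ValueError(f"fractions must not exceed 1 - test_fraction = {1 - test_fraction}")

    x_all, y_all = dataset.labeled_view()
    n = len(y_all)
    pos = np.flatnonzero(y_all == 1)
    neg = np.flatnonzero(y_all == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("dataset must contain both classes")
    n_test_pos = max(1, int(round(test_fraction * len(pos))))
    n_test_neg = max(1, int(round(test_fraction * len(neg))))
    sizes = [max(2, int(round(f * n))) for f in fractions]

    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    aucs = np.empty((reps, len(fractions)))
    ppvs = np.empty((reps, len(fractions)))
    k_eff = min(k_ppv, n_test_pos + n_test_neg)
    for r, cs in enumerate(child_seeds):
        rng = np.random.default_rng(cs)
        test_idx = np.concatenate(
            [rng.choice(pos, n_test_pos, replace=False), rng.choice(neg, n_test_neg, replace=False)]
        )
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test_idx] = True
        remainder = np.flatnonzero(~test_mask)
        perm = None
        for _ in range(max_retries):
            cand = rng.permutation(remainder)
            if len(set(y_all[cand[: sizes[0]]])) == 2:
                perm = cand
                break
        if perm is None:
            raise RuntimeError(
                f"could not draw a two-class training set of size {sizes[0]} in {max_retries} tries"
            )
        x_test = x_all.iloc[test_idx]
        y_test = y_all[test_idx]
        for fi, size in enumerate(sizes):
            train_rows = perm[: min(size, len(perm))]
            sub = SpeciesDataset(
                species_id=dataset.species_id,
                features=x_all.iloc[train_rows],
                labels=pd.Series(y_all[train_rows], index=x_all.index[train_rows]),
                schema=dataset.schema,
                meta=dataset.meta,
            )
            model = fit_nb(sub, alpha=alpha, normalization=normalization)
            s = score_genes(model, x_test).to_numpy()
            aucs[r, fi] = auc(s, y_test)
            ppvs[r, fi] = ppv_at_k(s, y_test, k=k_eff, gene_ids=x_test.index)
    return CurveResult(
        fractions=list(map(float, fractions)),
        mean_auc=aucs.mean(axis=0).tolist(),
        sd_auc=aucs.std(axis=0, ddof=1).tolist(),
        mean_ppv=ppvs.mean(axis=0).tolist(),
        sd_ppv=ppvs.std(axis=0, ddof=1).tolist(),
        reps=reps,
        k_ppv=k_eff,
    )


def enumerate_integrated_sets(pool: Iterable[str], k: int) -> list[tuple[str, ...]]:
    """All k-subsets of the species pool, in lexicographic order."""
    pool = sorted(pool)
    if not 1 <= k <= len(pool):
        raise ValueError(f"k must be in [1, {len(pool)}], got {k}")
    return list(itertools.combinations(pool, k))


@dataclass
class IntegrationResult:
    """AUCs of integrated (pooled) training sets against one test species."""

    test_species: str
    combos: list[tuple[str, ...]]
    aucs: np.ndarray
    groups: list[str] = field(default_factory=list)  # per-combo tag or empty

    def to_frame(self) -> pd.DataFrame:
        d = {"combo": ["+".join(c) for c in self.combos], "auc": self.aucs}
        if self.groups:
            d["group"] = self.groups
        return pd.DataFrame(d)


class _ComboScorer:
    """Caches the integrated AUC of each distinct species combination."""

    def __init__(
        self,
        datasets: Mapping[str, SpeciesDataset],
        test_species: str,
        alpha: float = 1.0,
        normalization: str = "rank",
    ):
        self.datasets = datasets
        self.test_species = test_species
        self.alpha = alpha
        self.normalization = normalization
        from .nb import normalize_features

        x, y = datasets[test_species].labeled_view()
        self._x_test = normalize_features(x, datasets[test_species].schema, normalization)
        self._y_test = y
        self._cache: dict[tuple[str, ...], float] = {}

    def auc_of(self, combo: Sequence[str]) -> float:
        key = tuple(sorted(combo))
        if self.test_species in key:
            raise ValueError(f"combo {key} contains the test species {self.test_species}")
        if key not in self._cache:
            model = fit_nb(
                [self.datasets[s] for s in key],
                alpha=self.alpha,
                normalization=self.normalization,
            )
            s = score_genes(model, self._x_test, assume_normalized=True).to_numpy()
            self._cache[key] = auc(s, self._y_test)
        return self._cache[key]


def integrated_performance(
    datasets: Mapping[str, SpeciesDataset],
    combos: Sequence[Sequence[str]],
    test_species: str,
    *,
    alpha: float = 1.0,
    normalization: str = "rank",
    scorer: _ComboScorer | None = None,
) -> IntegrationResult:
    """AUC of each combo's pooled training set on the test species.

    Pooling concatenates the member species' per-species-normalized
    labeled tables into one training set. A combo of a single species
    reduces to ordinary one-species transfer.
    """
    scorer = scorer or _ComboScorer(datasets, test_species, alpha, normalization)
    aucs = np.array([scorer.auc_of(c) for c in combos])
    return IntegrationResult(test_species, [tuple(c) for c in combos], aucs)


def hasts_lasts_split(
    single_set_aucs: Mapping[str, float]
) -> tuple[list[str], list[str], float]:
    """Split single-species training sets into high/low transfer groups.

    The top ceil(n * 9/19) by AUC form the high group (HASTS), the rest
    the low group (LASTS) — exactly 9 vs 10 for a pool of 19. The
    threshold is the midpoint between the boundary scores; score ties
    break by ascending species id.
    """
    if len(single_set_aucs) < 2:
        raise ValueError("need at least two training sets to split")
    order = sorted(single_set_aucs.items(), key=lambda kv: (-kv[1], kv[0]))
    n_high = math.ceil(len(order) * 9 / 19)
    hasts = [s for s, _ in order[:n_high]]
    lasts = [s for s, _ in order[n_high:]]
    threshold = 0.5 * (order[n_high - 1][1] + order[n_high][1])
    return hasts, lasts, float(threshold)


def partition_k_subsets(
    hasts: Sequence[str], lasts: Sequence[str], k: int
) -> tuple[list[tuple[str, ...]], list[str]]:
    """Tag every k-subset of HASTS+LASTS as high, low, or mixed.

    high = subsets drawn entirely from HASTS, low = entirely from LASTS,
    mixed = everything else. A group smaller than k simply contributes no
    subsets (flagged with a warning).
    """
    if set(hasts) & set(lasts):
        raise ValueError("HASTS and LASTS must be disjoint")
    pool = sorted(set(hasts) | set(lasts))
    high_set = set(enumerate_integrated_sets(hasts, k)) if len(hasts) >= k else set()
    low_set = set(enumerate_integrated_sets(lasts, k)) if len(lasts) >= k else set()
    if not high_set:
        log.warning("high group smaller than k=%d; empty distribution", k)
    if not low_set:
        log.warning("low group smaller than k=%d; empty distribution", k)
    combos = enumerate_integrated_sets(pool, k)
    groups = [
        "high" if c in high_set else "low" if c in low_set else "mixed" for c in combos
    ]
    return combos, groups


def group_comparison(
    datasets: Mapping[str, SpeciesDataset],
    hasts: Sequence[str],
    lasts: Sequence[str],
    test_species: str,
    k: int = 4,
    *,
    alpha: float = 1.0,
    normalization: str = "rank",
) -> IntegrationResult:
    """High / low / mixed k-subset AUC distributions (one tagged result)."""
    combos, groups = partition_k_subsets(hasts, lasts, k)
    scorer = _ComboScorer(datasets, test_species, alpha, normalization)
    aucs = np.array([scorer.auc_of(c) for c in combos])
    return IntegrationResult(test_species, combos, aucs, groups)


@dataclass
class NullResult:
    """Rule-based threshold AUC against a random-integration null."""

    threshold: float
    simulated: np.ndarray
    p_value: float
    n_sims: int
    mode: str

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "p_value": self.p_value,
            "n_sims": self.n_sims,
            "mode": self.mode,
        }


def random_integration_pvalue(
    datasets: Mapping[str, SpeciesDataset],
    test_species: str,
    rule_set: Sequence[str],
    k: int = 4,
    n_sims: int = 10000,
    mode: str = "sampled",
    seed: int = 0,
    *,
    pool: Sequence[str] | None = None,
    alpha: float = 1.0,
    normalization: str = "rank",
    scorer: _ComboScorer | None = None,
) -> NullResult:
    """P-value of the rule-selected training set under random integration.

    The threshold is the AUC of the rule set's integrated prediction.
    ``sampled`` draws k-subsets uniformly (with replacement over the
    combination space) and reports the proportion of draws whose AUC
    strictly exceeds the threshold; ``exact`` enumerates every k-subset
    and returns the exact exceedance proportion.
    """
    if mode not in ("sampled", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if test_species in rule_set:
        raise ValueError("rule_set must exclude the test species")
    pool = sorted(pool if pool is not None else (set(datasets) - {test_species}))
    scorer = scorer or _ComboScorer(datasets, test_species, alpha, normalization)
    threshold = scorer.auc_of(rule_set)
    combos = enumerate_integrated_sets(pool, k)
    if mode == "exact":
        sims = np.array([scorer.auc_of(c) for c in combos])
        p = float((sims > threshold).mean())
        return NullResult(threshold, sims, p, len(combos), "exact")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = rng.integers(0, len(combos), size=n_sims)
    sims = np.array([scorer.auc_of(combos[i]) for i in draws])
    p = float((sims > threshold).mean())
    return NullResult(threshold, sims, p, n_sims, "sampled")


_DEFAULT_WEIGHTS = {"quality": 0.25, "condition": 0.25, "proximity": 0.25, "lifestyle": 0.25}


def rule_based_select(
    metadata: Mapping[str, SpeciesMeta],
    divergence: DivergenceMatrix,
    target: str,
    n: int = 4,
    weights: Mapping[str, float] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Rank candidate training species by the four selection rules.

    Per-candidate subscores, each in [0, 1]: label quality tier
    (deletion 1.0 > transposon 0.5 > inferred 0.0), growth-condition
    match (0/1), phylogenetic proximity (1 - divergence / max divergence
    among candidates), and lifestyle similarity (fraction of matching
    gram/oxygen/shape tags). The total is the weighted sum; ties break by
    ascending species id. Candidates without metadata or divergence
    entries are excluded with a warning.
    """
    if target not in metadata:
        raise ValueError(f"no metadata for target species {target}")
    w = dict(_DEFAULT_WEIGHTS)
    if weights:
        unknown = set(weights) - set(w)
        if unknown:
            raise ValueError(f"unknown weight keys {sorted(unknown)}")
        w.update(weights)
    tgt = metadata[target]
    candidates = []
    for sp in sorted(metadata):
        if sp == target:
            continue
        if sp not in divergence.species:
            log.warning("candidate %s lacks a divergence entry; excluded", sp)
            continue
        candidates.append(sp)
    if len(candidates) < n:
        raise ValueError(f"only {len(candidates)} usable candidates for n={n}")
    max_d = max(divergence.distance(target, sp) for sp in candidates)
    rows = []
    for sp in candidates:
        m = metadata[sp]
        quality = _QUALITY_SCORE[m.quality_tier]
        condition = 1.0 if m.growth_condition == tgt.growth_condition else 0.0
        d = divergence.distance(target, sp)
        proximity = 1.0 - d / max_d if max_d > 0 else 1.0
        lifestyle = float(
            np.mean([m.gram == tgt.gram, m.oxygen == tgt.oxygen, m.shape == tgt.shape])
        )
        total = (
            w["quality"] * quality
            + w["condition"] * condition
            + w["proximity"] * proximity
            + w["lifestyle"] * lifestyle
        )
        rows.append(
            {"species": sp, "quality": quality, "condition": condition,
             "proximity": proximity, "lifestyle": lifestyle, "score": total}
        )
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["score", "species"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return ranking["species"].head(n).tolist(), ranking


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances); returns (t, p)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)
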