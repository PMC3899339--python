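"""Naive Bayes essentiality classifier for mixed feature tables.

Continuous features are modelled with class-conditional Gaussians,
categorical features with Laplace-smoothed multinomials. Missing values
are marginalized out: they contribute nothing at fit or score time, which
preserves the naive factorization without imputation. Scores are computed
in log space and returned as posterior probabilities of essentiality.

Because raw feature units (expression platforms, network sizes, genome
lengths) are not comparable across species, the default pipeline rank-
normalizes each species' continuous columns to (0, 1) before fitting or
scoring; the recipe travels with the fitted model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import FeatureSchema, SpeciesDataset

__all__ = ["NBModel", "normalize_features", "fit_nb", "score_genes"]

_NORM_METHODS = ("rank", "zscore", "none")
_PROB_FLOOR = 1e-12  # avoids -inf log-likelihoods when alpha = 0


def normalize_features(
    table: pd.DataFrame, schema: FeatureSchema, method: str = "rank"
) -> pd.DataFrame:
    """Normalize continuous columns per species; categorical untouched.

    ``rank`` maps non-missing values to rank/(n_valid+1) in (0, 1) with
    average ranks for ties (a constant column becomes all 0.5); ``zscore``
    standardizes (sample sd, zero when constant); ``none`` is identity.
    Missing values stay missing. If the table has a ``species_id`` column
    each species is normalized independently.
    """
    if method not in _NORM_METHODS:
        raise ValueError(f"unknown normalization {method!r}; choose from {_NORM_METHODS}")
    if method == "none":
        return table.copy()
    out = table.copy()
    if "species_id" in table.columns:
        groups = [idx for _, idx in table.groupby("species_id", sort=False).groups.items()]
    else:
        groups = [table.index]
    for idx in groups:
        for col in schema.continuous:
            x = out.loc[idx, col].to_numpy(dtype=float)
            valid = ~np.isnan(x)
            if valid.sum() == 0:
                continue
            if method == "rank":
                r = rankdata(x[valid], method="average")
                x[valid] = r / (valid.sum() + 1)
            else:
                mu = x[valid].mean()
                sd = x[valid].std(ddof=1) if valid.sum() > 1 else 0.0
                x[valid] = (x[valid] - mu) / sd if sd > 0 else 0.0
            out.loc[idx, col] = x
    return out


@dataclass
class NBModel:
    """Fitted class priors and per-feature class-conditional parameters."""

    schema: FeatureSchema
    log_prior: dict[str, float]  # keys "essential", "nonessential"
    continuous: dict[str, dict]  # mean/var per class, usable flag
    categorical: dict[str, dict]  # levels, per-class log-probs, smoothing
    normalization: str = "rank"
    meta: dict = field(default_factory=dict)

    SCHEMA_VERSION = 1

    def to_dict(self) -> dict:
        return {
            "schema_version": self.SCHEMA_VERSION,
            "continuous_features": list(self.schema.continuous),
            "categorical_features": list(self.schema.categorical),
            "log_prior": self.log_prior,
            "continuous": self.continuous,
            "categorical": self.categorical,
            "normalization": self.normalization,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NBModel":
        if d.get("schema_version") != cls.SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {d.get('schema_version')!r}")
        return cls(
            schema=FeatureSchema(
                continuous=tuple(d["continuous_features"]),
                categorical=tuple(d["categorical_features"]),
            ),
            log_prior=dict(d["log_prior"]),
            continuous={k: dict(v) for k, v in d["continuous"].items()},
            categorical={k: dict(v) for k, v in d["categorical"].items()},
            normalization=d["normalization"],
            meta=dict(d.get("meta", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "NBModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _pool_training(
    train: SpeciesDataset | Iterable[SpeciesDataset], normalization: str
) -> tuple[pd.DataFrame, np.ndarray, FeatureSchema, list[str]]:
    datasets = [train] if isinstance(train, SpeciesDataset) else list(train)
    if not datasets:
        raise ValueError("no training datasets given")
    schema = datasets[0].schema
    frames, labels, species = [], [], []
    for ds in datasets:
        if ds.schema != schema:
            raise ValueError("training datasets have inconsistent feature schemas")
        x, y = ds.labeled_view()
        frames.append(normalize_features(x, schema, normalization))
        labels.append(y)
        species.append(ds.species_id)
    pooled = pd.concat(frames, axis=0)
    return pooled, np.concatenate(labels), schema, species


def fit_nb(
    train: SpeciesDataset | Iterable[SpeciesDataset],
    *,
    alpha: float = 1.0,
    var_floor: float = 1e-9,
    normalization: str = "rank",
) -> NBModel:
    """Fit the classifier on one species or a pool of species.

    Pooling several species is plain concatenation of their (per-species
    normalized) labeled tables — an integrated training set. Priors are
    the pooled class frequencies. Gaussian parameters use maximum-
    likelihood variance with a floor; categorical tables get Laplace
    smoothing ``alpha`` over the levels observed in training. A feature
    with no observed value in one class is flagged unusable and skipped
    at scoring time.
    """
    pooled, y, schema, species = _pool_training(train, normalization)
    n_ess = int((y == 1).sum())
    n_non = int((y == 0).sum())
    if n_ess == 0 or n_non == 0:
        raise ValueError("training data must contain both essential and non-essential genes")
    n = n_ess + n_non
    log_prior = {"essential": float(np.log(n_ess / n)), "nonessential": float(np.log(n_non / n))}

    continuous: dict[str, dict] = {}
    for col in schema.continuous:
        x = pooled[col].to_numpy(dtype=float)
        entry: dict = {"usable": True}
        for cls_name, mask in (("essential", y == 1), ("nonessential", y == 0)):
            v = x[mask]
            v = v[~np.isnan(v)]
            if v.size == 0:
                entry["usable"] = False
                continue
            entry[cls_name] = {
                "mean": float(v.mean()),
                "var": float(max(v.var(ddof=0), var_floor)),
                "n": int(v.size),
            }
        continuous[col] = entry

    categorical: dict[str, dict] = {}
    for col in schema.categorical:
        x = pooled[col]
        valid = x.notna()
        levels = sorted({str(v) for v in x[valid]})
        entry = {"levels": levels, "alpha": float(alpha), "log_prob": {}, "n_class": {}}
        usable = True
        for cls_name, mask in (("essential", y == 1), ("nonessential", y == 0)):
            vals = x[mask & valid.to_numpy()].map(str)
            n_c = int(len(vals))
            if n_c == 0:
                usable = False
                continue
            counts = vals.value_counts()
            denom = n_c + alpha * len(levels)
            probs = [
                max((counts.get(lv, 0) + alpha) / denom, _PROB_FLOOR) if denom > 0 else _PROB_FLOOR
                for lv in levels
            ]
            entry["log_prob"][cls_name] = [float(np.log(p)) for p in probs]
            entry["n_class"][cls_name] = n_c
        entry["usable"] = usable and bool(levels)
        categorical[col] = entry

    return NBModel(
        schema=schema,
        log_prior=log_prior,
        continuous=continuous,
        categorical=categorical,
        normalization=normalization,
        meta={"species": species, "n_genes": n, "n_essential": n_ess},
    )


def score_genes(
    model: NBModel, table: pd.DataFrame | SpeciesDataset, *, assume_normalized: bool = False
) -> pd.Series:
    """Posterior probability of essentiality per gene, in [0, 1].

    Missing features contribute nothing; a categorical level unseen in
    training receives its smoothed pseudo-count mass; a gene with every
    feature missing scores at the prior. ``assume_normalized`` skips the
    model's normalization step for tables already normalized by the
    caller (an internal fast path for reciprocal matrices).
    """
    if isinstance(table, SpeciesDataset):
        table = table.features
    missing_cols = set(model.schema.columns) - set(table.columns)
    if missing_cols:
        raise ValueError(f"feature table lacks model columns {sorted(missing_cols)}")
    x = table if assume_normalized else normalize_features(table, model.schema, model.normalization)
    n = len(x)
    ll_e = np.full(n, model.log_prior["essential"])
    ll_n = np.full(n, model.log_prior["nonessential"])

    for col in model.schema.continuous:
        entry = model.continuous[col]
        if not entry.get("usable", False):
            continue
        v = x[col].to_numpy(dtype=float)
        valid = ~np.isnan(v)
        for cls_name, ll in (("essential", ll_e), ("nonessential", ll_n)):
            p = entry[cls_name]
            contrib = -0.5 * (np.log(2 * np.pi * p["var"]) + (v - p["mean"]) ** 2 / p["var"])
            ll += np.where(valid, contrib, 0.0)

    for col in model.schema.categorical:
        entry = model.categorical[col]
        if not entry.get("usable", False):
            continue
        levels = entry["levels"]
        lv_index = {lv: i for i, lv in enumerate(levels)}
        vals = table[col]
        valid = vals.notna().to_numpy()
        codes = np.array([lv_index.get(str(v), -1) if ok else -2
                          for v, ok in zip(vals, valid)])
        for cls_name, ll in (("essential", ll_e), ("nonessential", ll_n)):
            lp = np.asarray(entry["log_prob"][cls_name])
            n_c = entry["n_class"][cls_name]
            alpha = entry["alpha"]
            # unseen level: smoothed pseudo-count mass over K+1 cells
            if alpha > 0:
                unseen = float(np.log(max(alpha / (n_c + alpha * (len(levels) + 1)), _PROB_FLOOR)))
            else:
                unseen = 0.0  # alpha=0: no basis for a mass, skip the feature
            contrib = np.where(codes >= 0, lp[np.clip(codes, 0, None)],
                               np.where(codes == -1, unseen, 0.0))
            ll += contrib

    score = 1.0 / (1.0 + np.exp(np.clip(ll_n - ll_e, -700, 700)))
    return pd.Series(score, index=table.index, name="score")
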