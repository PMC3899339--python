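"""Core in-memory containers shared across the pipeline.

The pipeline moves per-species gene tables around: a feature table
(pandas DataFrame, one row per gene), a binary essentiality label vector,
species-level metadata used by the training-set selection rules, and a
symmetric matrix of pairwise divergence times in millions of years (My).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSchema",
    "SpeciesMeta",
    "SpeciesDataset",
    "DivergenceMatrix",
    "QUALITY_TIERS",
]

#: Label-quality tiers, ordered best -> worst. Genome-wide single-gene
#: deletion collections give the most reliable essentiality calls,
#: transposon-mutagenesis screens less so, and computationally inferred or
#: meta-analysed sets the least.
QUALITY_TIERS = ("deletion", "transposon", "inferred")


@dataclass(frozen=True)
class FeatureSchema:
    """Names of continuous and categorical feature columns in a table.

    Continuous columns are modelled as Gaussians by the classifier;
    categorical columns (e.g. domain type, phyletic age group) as
    multinomials.
    """

    continuous: tuple[str, ...]
    categorical: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.continuous) & set(self.categorical)
        if overlap:
            raise ValueError(f"columns listed as both continuous and categorical: {sorted(overlap)}")

    @property
    def columns(self) -> tuple[str, ...]:
        return self.continuous + self.categorical


#: Schema of the 15-feature table used for real per-species inputs.
FEATURE_TABLE_SCHEMA = FeatureSchema(
    continuous=(
        "mE", "mEF", "DoC", "DC", "CCo", "CC", "BC",
        "PL", "CAI", "NP", "NS", "NEH", "NNH",
    ),
    categorical=("Age", "DoT"),
)


@dataclass
class SpeciesMeta:
    """Species-level annotations driving the four selection rules."""

    species_id: str
    quality_tier: str = "deletion"
    growth_condition: str = "rich"
    gram: str = "neg"
    oxygen: str = "facultative"
    shape: str = "rod"

    def __post_init__(self) -> None:
        if self.quality_tier not in QUALITY_TIERS:
            raise ValueError(
                f"quality_tier must be one of {QUALITY_TIERS}, got {self.quality_tier!r}"
            )


@dataclass
class SpeciesDataset:
    """One species' feature table, labels, and metadata.

    ``features`` is indexed by gene_id; ``labels`` is an int series (0/1)
    aligned on the same index. ``labels`` may contain fewer genes than
    ``features`` (unlabeled genes are allowed at scoring time).
    """

    species_id: str
    features: pd.DataFrame
    labels: pd.Series
    schema: FeatureSchema
    meta: SpeciesMeta = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = SpeciesMeta(species_id=self.species_id)
        missing = set(self.schema.columns) - set(self.features.columns)
        if missing:
            raise ValueError(f"feature table for {self.species_id} lacks columns {sorted(missing)}")
        if self.features.index.has_duplicates:
            raise ValueError(f"duplicated gene_id in {self.species_id} feature table")
        lab = pd.Series(self.labels)
        bad = set(pd.unique(lab.dropna())) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, found {sorted(bad)}")
        extra = lab.index.difference(self.features.index)
        if len(extra):
            raise ValueError(f"labels for unknown genes in {self.species_id}: {list(extra[:5])}")
        self.labels = lab.astype(int)

    @property
    def n_genes(self) -> int:
        return len(self.features)

    def labeled_view(self) -> tuple[pd.DataFrame, np.ndarray]:
        """Features restricted to labeled genes, plus the label array."""
        x = self.features.loc[self.labels.index]
        return x, self.labels.to_numpy()


class DivergenceMatrix:
    """Symmetric, zero-diagonal matrix of pairwise divergence times (My)."""

    def __init__(self, species: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(species)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} species")
        if len(set(species)) != n:
            raise ValueError("duplicate species ids")
        if not np.allclose(values, values.T, atol=1e-8):
            raise ValueError("divergence matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-8):
            raise ValueError("divergence matrix diagonal is not zero")
        if (values < -1e-12).any():
            raise ValueError("negative divergence times")
        self.species = list(species)
        self.values = values
        self._idx = {s: i for i, s in enumerate(self.species)}

    def __len__(self) -> int:
        return len(self.species)

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._idx[a], self._idx[b]])

    def subset(self, species: list[str]) -> "DivergenceMatrix":
        idx = [self._idx[s] for s in species]
        return DivergenceMatrix(list(species), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DivergenceMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("row and column species ids differ")
        return cls(list(frame.index), frame.to_numpy(dtype=float))
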