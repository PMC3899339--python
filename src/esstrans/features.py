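"""Per-species gene features used to predict essentiality.

Fifteen features in six groups: domain properties (DoT, DoC), PPI network
centralities (DC, CCo, CC, BC), genomic sequence properties (PL, CAI),
homology properties (NP, NS, NEH, NNH), phyletic age (Age), and expression
statistics (mE, mEF). Each feature has its own small computation; the
table builder assembles them with NA where an input is absent.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .datatypes import FEATURE_TABLE_SCHEMA

__all__ = [
    "DomainHit",
    "cai_weights",
    "compute_cai",
    "compute_doc",
    "compute_dot",
    "graph_centralities",
    "paralog_count",
    "cross_species_homology_counts",
    "phyletic_age",
    "expression_stats",
    "build_feature_table",
]

log = logging.getLogger(__name__)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _synonym_families() -> dict[str, list[str]]:
    fam: dict[str, list[str]] = defaultdict(list)
    for codon, aa in _STANDARD_TABLE.forward_table.items():
        fam[aa].append(codon)
    return dict(fam)


#: Codons excluded from CAI: stops plus single-codon families (Met ATG,
#: Trp TGG), which carry no synonymous choice.
_EXCLUDED_CODONS = frozenset(_STANDARD_TABLE.stop_codons) | {
    c for codons in _synonym_families().values() if len(codons) == 1 for c in codons
}


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM hit of a protein domain on a gene."""

    gene_id: str
    domain_id: str
    bit_score: float
    domain_length: int

    def __post_init__(self) -> None:
        if self.domain_length < 1:
            raise ValueError(f"domain_length must be >= 1, got {self.domain_length}")
        if self.bit_score < 0:
            raise ValueError(f"bit_score must be >= 0, got {self.bit_score}")


def _as_codons(sequence: str | Sequence[str]) -> list[str]:
    if isinstance(sequence, str):
        seq = sequence.upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError(f"sequence length {len(seq)} not divisible by 3")
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return [c.upper().replace("U", "T") for c in sequence]


def cai_weights(reference_sequences: Iterable[str | Sequence[str]]) -> dict[str, float]:
    """Relative adaptiveness of each codon from a reference gene set.

    w(codon) = frequency / max synonymous frequency within the codon's
    amino-acid family. Codons never observed in the reference get a 0.5
    pseudo-count before normalization so every weight stays in (0, 1].
    """
    counts: dict[str, float] = {c: 0.0 for c in _STANDARD_TABLE.forward_table}
    for seq in reference_sequences:
        for codon in _as_codons(seq):
            if codon in counts:
                counts[codon] += 1.0
    for codon, c in counts.items():
        if c == 0.0:
            counts[codon] = 0.5
    weights: dict[str, float] = {}
    for codons in _synonym_families().values():
        mx = max(counts[c] for c in codons)
        for c in codons:
            weights[c] = counts[c] / mx
    return weights


def compute_cai(
    codon_sequence: str | Sequence[str], weights: Mapping[str, float]
) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Stop codons and single-codon families are skipped; any other codon
    missing from ``weights`` is an error naming the codon.
    """
    codons = _as_codons(codon_sequence)
    logs = []
    for codon in codons:
        if codon in _EXCLUDED_CODONS:
            continue
        if codon not in weights:
            raise ValueError(f"no relative-adaptiveness weight for codon {codon!r}")
        w = float(weights[codon])
        if not 0.0 < w <= 1.0:
            raise ValueError(f"weight for codon {codon!r} must be in (0,1], got {w}")
        logs.append(math.log(w))
    if not logs:
        raise ValueError("no codons usable for CAI after exclusions")
    return math.exp(sum(logs) / len(logs))


def compute_doc(hits: Sequence[DomainHit]) -> float:
    """Domain conservation: total bit score over total domain length.

    Aggregates all hits of the gene (sum of scores / sum of lengths);
    returns NaN when the gene has no domain hit.
    """
    if not hits:
        return float("nan")
    return sum(h.bit_score for h in hits) / sum(h.domain_length for h in hits)


def compute_dot(hits: Sequence[DomainHit]) -> str | None:
    """Domain type: the highest-scoring hit's domain id.

    Score ties break lexicographically on domain_id; no hits -> None.
    """
    if not hits:
        return None
    best = min(hits, key=lambda h: (-h.bit_score, h.domain_id))
    return best.domain_id


def graph_centralities(
    edges: Iterable[tuple[str, str]], nodes: Iterable[str]
) -> pd.DataFrame:
    """Four centralities (DC, CCo, CC, BC) of a PPI graph, all in [0, 1].

    The graph is simplified first (self-loops and duplicate edges dropped,
    counts logged). Closeness uses the disconnected-graph correction
    (within-component closeness scaled by the reachable fraction);
    betweenness is normalized by (n-1)(n-2)/2. Isolated nodes score 0 on
    all four.
    """
    universe = list(nodes)
    uset = set(universe)
    g = nx.Graph()
    g.add_nodes_from(universe)
    n_self = n_dup = 0
    for a, b in edges:
        if a not in uset or b not in uset:
            raise ValueError(f"edge ({a!r}, {b!r}) references a node outside the universe")
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    if n_self or n_dup:
        log.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
    dc = nx.degree_centrality(g) if len(g) > 1 else {v: 0.0 for v in g}
    cco = nx.clustering(g)
    cc = nx.closeness_centrality(g, wf_improved=True)
    bc = nx.betweenness_centrality(g, normalized=True)
    return pd.DataFrame(
        {"DC": dc, "CCo": cco, "CC": cc, "BC": bc}, index=pd.Index(universe, name="gene_id")
    ).astype(float)


def paralog_count(within_species_homology: Iterable[tuple[str, str]], gene: str) -> int:
    """NP: number of distinct within-species homology partners of a gene."""
    partners = set()
    for a, b in within_species_homology:
        if a == gene and b != gene:
            partners.add(b)
        elif b == gene and a != gene:
            partners.add(a)
    return len(partners)


def cross_species_homology_counts(
    ortholog_map: Iterable[tuple[str, str]],
    gene_species: Mapping[str, str],
    labels_by_species: Mapping[str, Mapping[str, int]],
    target: str,
) -> tuple[int, int, int]:
    """(NS, NEH, NNH) for a target gene from a cross-species ortholog map.

    NS counts distinct *other* species with at least one homolog of the
    target; NEH/NNH count homologous genes in other species labeled
    essential / non-essential. Homologs in unlabeled species contribute to
    NS only.
    """
    own_species = gene_species[target]
    homologs = set()
    for a, b in ortholog_map:
        if a == target and b != target:
            homologs.add(b)
        elif b == target and a != target:
            homologs.add(a)
    ns_species = set()
    neh = nnh = 0
    for h in homologs:
        sp = gene_species.get(h)
        if sp is None or sp == own_species:
            continue
        ns_species.add(sp)
        lab = labels_by_species.get(sp, {}).get(h)
        if lab == 1:
            neh += 1
        elif lab == 0:
            nnh += 1
    return len(ns_species), neh, nnh


def phyletic_age(
    presence_by_clade: Mapping[str, bool], clade_order: Sequence[str]
) -> int:
    """Ordinal gene age: index of the outermost clade holding a homolog.

    ``clade_order`` lists nested clades innermost -> outermost (index 1 is
    the species-typical group). A gene with no homolog beyond its own
    species gets age 1.
    """
    if not clade_order:
        raise ValueError("clade_order must be non-empty")
    age = 1
    for i, clade in enumerate(clade_order, start=1):
        if presence_by_clade.get(clade, False):
            age = i
    return age


def expression_stats(expression_row: Sequence[float]) -> tuple[float, float]:
    """(mE, mEF): mean expression and coefficient of variation.

    mEF uses the sample standard deviation (n-1 denominator) divided by
    the mean; it is NaN with fewer than two values or a non-positive mean.
    An all-missing row yields (NaN, NaN).
    """
    vals = np.asarray(expression_row, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), float("nan")
    m = float(vals.mean())
    if vals.size < 2 or m <= 0:
        return m, float("nan")
    return m, float(vals.std(ddof=1) / m)


def build_feature_table(
    species_id: str,
    gene_ids: Sequence[str],
    *,
    domain_hits: Mapping[str, Sequence[DomainHit]] | None = None,
    ppi_edges: Iterable[tuple[str, str]] | None = None,
    ppi_nodes: Iterable[str] | None = None,
    cdna: Mapping[str, str] | None = None,
    cai_reference: Sequence[str] | None = None,
    protein_lengths: Mapping[str, int] | None = None,
    within_species_homology: Iterable[tuple[str, str]] | None = None,
    ortholog_map: Iterable[tuple[str, str]] | None = None,
    gene_species: Mapping[str, str] | None = None,
    labels_by_species: Mapping[str, Mapping[str, int]] | None = None,
    clade_presence: Mapping[str, Mapping[str, bool]] | None = None,
    clade_order: Sequence[str] | None = None,
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the 15-feature table for one species.

    Every feature column is present in the output; genes missing from an
    input get NA for the corresponding features. Genes in the PPI node
    universe but with no edges get all-zero centralities; genes absent
    from the universe get NA. Missingness per feature is logged.
    """
    gene_ids = list(gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        dupes = pd.Index(gene_ids)
        raise ValueError(
            f"duplicated gene_id(s): {sorted(set(dupes[dupes.duplicated()]))[:5]}"
        )
    idx = pd.Index(gene_ids, name="gene_id")
    out = pd.DataFrame(index=idx)
    out["species_id"] = species_id
    for col in FEATURE_TABLE_SCHEMA.columns:
        out[col] = np.nan
    out["DoT"] = out["DoT"].astype(object)

    if expression is not None and len(expression.columns):
        for g in idx.intersection(expression.index):
            me, mef = expression_stats(expression.loc[g].to_numpy(dtype=float))
            out.loc[g, "mE"] = me
            out.loc[g, "mEF"] = mef

    if clade_presence is not None and clade_order is not None:
        for g in gene_ids:
            if g in clade_presence:
                out.loc[g, "Age"] = phyletic_age(clade_presence[g], clade_order)

    if domain_hits is not None:
        for g in gene_ids:
            hits = list(domain_hits.get(g, ()))
            if hits:
                out.loc[g, "DoC"] = compute_doc(hits)
                out.loc[g, "DoT"] = compute_dot(hits)

    if ppi_edges is not None or ppi_nodes is not None:
        universe = list(ppi_nodes) if ppi_nodes is not None else list(gene_ids)
        cent = graph_centralities(ppi_edges or [], universe)
        common = idx.intersection(cent.index)
        out.loc[common, ["DC", "CCo", "CC", "BC"]] = cent.loc[common].to_numpy()

    if protein_lengths is not None:
        for g in gene_ids:
            if g in protein_lengths:
                out.loc[g, "PL"] = protein_lengths[g]

    if cdna is not None:
        refs = cai_reference if cai_reference is not None else list(cdna)
        weights = cai_weights([cdna[g] for g in refs if g in cdna])
        for g in gene_ids:
            if g in cdna:
                out.loc[g, "CAI"] = compute_cai(cdna[g], weights)

    if within_species_homology is not None:
        edges = list(within_species_homology)
        for g in gene_ids:
            out.loc[g, "NP"] = paralog_count(edges, g)

    if ortholog_map is not None and gene_species is not None:
        edges = list(ortholog_map)
        labs = labels_by_species or {}
        for g in gene_ids:
            ns, neh, nnh = cross_species_homology_counts(edges, gene_species, labs, g)
            out.loc[g, "NS"] = ns
            out.loc[g, "NEH"] = neh
            out.loc[g, "NNH"] = nnh

    for col in FEATURE_TABLE_SCHEMA.columns:
        n_missing = int(out[col].isna().sum())
        if n_missing:
            log.info("%s: feature %s missing for %d/%d genes", species_id, col, n_missing, len(out))
    return out
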