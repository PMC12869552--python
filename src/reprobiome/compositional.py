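"""Compositional microbiome metrics: prevalence filtering, CLR,
Aitchison distance/similarity, ASV richness, taxonomy aggregation.

Count tables are pandas DataFrames (samples x taxa, non-negative
integers); the taxonomy map is a DataFrame indexed by taxon with
``family`` and ``phylum`` columns ("unidentified" allowed).  The
transform steps are sklearn transformers so they compose with pipelines;
the module-level functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CountTable", "PrevalenceFilter", "CLRTransformer", "AitchisonSimilarity",
    "filter_prevalence", "clr_transform", "aitchison_distance",
    "to_similarity", "asv_richness", "aggregate_taxonomy",
]


@dataclass
class CountTable:
    """Samples x taxa counts plus a taxonomy map.

    ``counts``: integer DataFrame (index sample_id, columns taxon ids).
    ``taxonomy``: DataFrame indexed by taxon with columns family, phylum.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.columns.difference(self.taxonomy.index)
        if len(missing):
            raise ValueError(f"taxonomy missing for taxa: {list(missing)[:5]}")

    @property
    def depth(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_taxa(self, taxa) -> "CountTable":
        return CountTable(self.counts[list(taxa)], self.taxonomy.loc[list(taxa)])


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Drop taxa below a prevalence threshold.

    Parameters
    ----------
    threshold : float in (0, 1)
        Fraction of samples in which a taxon must be present (count > 0).
    strict : bool
        If False (default), prevalence >= threshold retains the taxon
        ("20% or more"); if True, prevalence must strictly exceed it
        (the analysis-set 5% floor).
    """

    def __init__(self, threshold: float = 0.2, strict: bool = False):
        self.threshold = threshold
        self.strict = strict

    def fit(self, X: pd.DataFrame, y=None):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        prev = (X > 0).mean(axis=0)
        keep = prev > self.threshold if self.strict else prev >= self.threshold
        if not keep.any():
            raise ValueError(
                "prevalence filter removed every taxon; lower the threshold")
        self.prevalence_ = prev
        self.retained_taxa_ = X.columns[keep]
        self.n_retained_ = int(keep.sum())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "retained_taxa_")
        return X[self.retained_taxa_]


class CLRTransformer(BaseEstimator, TransformerMixin):
    """Centered log-ratio transform with a pseudocount.

    Row i, taxon j maps to ``ln((c_ij + pc) / g_i)`` with ``g_i`` the
    geometric mean of the pseudocounted row; each output row sums to 0.
    Scale-invariant per row, so raw counts and relative abundances give
    the same result when pc is scaled accordingly (pc=0 input already
    closed).
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.pseudocount < 0 or (
                self.pseudocount == 0 and (np.asarray(X) <= 0).any()):
            raise ValueError("pseudocount must be > 0 for tables with zeros")
        self.n_features_in_ = np.shape(X)[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        vals = np.asarray(X, dtype=float)
        if (vals < 0).any():
            raise ValueError("negative counts")
        vals = vals + self.pseudocount
        logv = np.log(vals)
        clr = logv - logv.mean(axis=1, keepdims=True)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(clr, index=X.index, columns=X.columns)
        return clr


class AitchisonSimilarity(BaseEstimator, TransformerMixin):
    """Rescale Aitchison distances to similarities in [0, 1].

    ``fit`` learns the maximum distance ``d_max_`` on the full analysis
    set; ``transform`` maps d -> 1 - d/d_max, so identical samples have
    similarity 1 and the most dissimilar observed pair has 0.  Fitting
    once and reusing d_max keeps similarities comparable across subsets.
    """

    def fit(self, D, y=None):
        arr = np.asarray(D, dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("distances must be finite")
        self.d_max_ = float(arr.max())
        if self.d_max_ == 0:
            warnings.warn("all distances are zero; similarities are all 1")
        return self

    def transform(self, D):
        check_is_fitted(self, "d_max_")
        arr = np.asarray(D, dtype=float)
        sim = np.ones_like(arr) if self.d_max_ == 0 else 1.0 - arr / self.d_max_
        if isinstance(D, pd.DataFrame):
            return pd.DataFrame(sim, index=D.index, columns=D.columns)
        return sim


# -- thin functional wrappers ----------------------------------------------

def filter_prevalence(table: CountTable, threshold: float = 0.2,
                      strict: bool = False) -> CountTable:
    filt = PrevalenceFilter(threshold=threshold, strict=strict).fit(table.counts)
    return table.subset_taxa(filt.retained_taxa_)


def clr_transform(counts: pd.DataFrame, pseudocount: float = 1.0
                  ) -> pd.DataFrame:
    return CLRTransformer(pseudocount).fit(counts).transform(counts)


def aitchison_distance(clr: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between CLR-transformed samples."""
    vals = np.asarray(clr, dtype=float)
    D = squareform(pdist(vals, metric="euclidean"))
    if isinstance(clr, pd.DataFrame):
        return pd.DataFrame(D, index=clr.index, columns=clr.index)
    return D


def to_similarity(dist: pd.DataFrame, d_max: float | None = None
                  ) -> pd.DataFrame:
    est = AitchisonSimilarity()
    if d_max is None:
        est.fit(dist)
    else:
        est.d_max_ = float(d_max)
    return est.transform(dist)


def asv_richness(counts: pd.DataFrame) -> pd.Series:
    """Number of taxa with count > 0 per sample."""
    rich = (counts > 0).sum(axis=1)
    if (rich == 0).any():
        warnings.warn(f"{int((rich == 0).sum())} all-zero sample(s)")
    return rich.rename("richness")


def aggregate_taxonomy(table: CountTable, rank: str) -> CountTable:
    """Sum counts within a taxonomic rank (family or phylum).

    Taxa with an "unidentified" family are binned per parent clade as
    ``unidentified:<phylum>`` rather than pooled into one global bin.
    Aggregation conserves per-sample totals.
    """
    if rank not in ("family", "phylum"):
        raise ValueError(f"unknown rank {rank!r}; use 'family' or 'phylum'")
    tax = table.taxonomy.loc[table.counts.columns]
    labels = tax[rank].astype(str).copy()
    if rank == "family":
        unid = labels.str.lower() == "unidentified"
        labels[unid] = "unidentified:" + tax.loc[unid, "phylum"].astype(str)
    agg = table.counts.T.groupby(labels.values).sum().T
    new_tax = pd.DataFrame(index=agg.columns)
    if rank == "family":
        fam2phy = (tax.assign(label=labels)
                   .groupby("label")["phylum"].first())
        new_tax["family"] = new_tax.index
        new_tax["phylum"] = fam2phy.reindex(new_tax.index)
    else:
        new_tax["family"] = "aggregated"
        new_tax["phylum"] = new_tax.index
    return CountTable(agg, new_tax)
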