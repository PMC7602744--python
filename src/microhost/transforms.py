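"""Compositional transforms: centered log-ratio and Bray-Curtis dissimilarity."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.spatial.distance import pdist, squareform
from skbio.stats.composition import clr as _clr

from .feature_table import FeatureTable


@dataclass
class ClrMatrix:
    """Samples x taxa CLR-transformed matrix; each row sums to zero."""

    values: pd.DataFrame
    pseudocount: float


def clr_transform(table: FeatureTable, pseudocount: float = 1) -> ClrMatrix:
    """Centered log-ratio transform of a count table.

    A pseudocount (in reads, default 1) is added before closure so that
    zeros have finite log-ratios; the CLR of a composition x is
    log(x_i) - mean_j log(x_j), mapping Aitchison geometry to real space.
    """
    if table.n_taxa < 2:
        raise ValueError("CLR needs at least 2 taxa")
    counts = table.counts.to_numpy(dtype=float)
    if pseudocount <= 0 and (counts == 0).any():
        raise ValueError("pseudocount must be positive when zeros are present")
    shifted = counts + pseudocount
    values = pd.DataFrame(_clr(shifted), index=table.counts.index, columns=table.counts.columns)
    return ClrMatrix(values=values, pseudocount=pseudocount)


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(u,v)) / (sum(u)+sum(v)) in [0,1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be non-negative")
    if u.sum() + v.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(u, v))


def pairwise_bray_curtis(table: FeatureTable, relative: bool = True) -> pd.DataFrame:
    """Square symmetric Bray-Curtis distance matrix between samples."""
    data = table.relative_abundance() if relative else table.counts.astype(float)
    dm = squareform(pdist(data.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(dm, index=data.index, columns=data.index)


def write_distance_matrix(dm: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dm.to_csv(path, sep="\t", index_label="sample_id")
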