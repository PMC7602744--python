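"""Chao1 richness with repeated fixed-depth subsampling.

Sequencing depth varies across studies, so richness is estimated on
repeated random subsamples of a fixed number of reads (default 5000,
drawn without replacement five times) and the Chao1 values are averaged.
The bias-corrected Chao1 estimator is used:

    S_chao1 = S_obs + F1 * (F1 - 1) / (2 * (F2 + 1))

where S_obs is the number of observed taxa, F1 the number of singleton
taxa (exactly one read) and F2 the number of doubletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_DEPTH = 5000
DEFAULT_REPS = 5


class InsufficientDepthError(ValueError):
    """Raised when a sample has fewer total reads than the subsampling depth."""


@dataclass(frozen=True)
class ChaoEstimate:
    """Mean Chao1 over subsampling replicates, with the per-replicate values."""

    value: float
    replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.replicates and not np.isclose(self.value, float(np.mean(self.replicates))):
            raise ValueError("value must be the mean of the replicates")


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness of a single count vector."""
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    s_obs = int((c > 0).sum())
    if s_obs == 0:
        raise ValueError("all-zero count vector has no defined richness")
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def subsample_counts(counts, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``depth`` reads without replacement (multivariate hypergeometric)."""
    c = np.asarray(counts, dtype=np.int64)
    total = int(c.sum())
    if total < depth:
        raise InsufficientDepthError(
            f"sample has {total} reads, fewer than the subsampling depth {depth}"
        )
    return rng.multivariate_hypergeometric(c, depth)


def rarefied_chao(
    counts,
    depth: int = DEFAULT_DEPTH,
    reps: int = DEFAULT_REPS,
    seed: int | np.random.Generator = 0,
) -> ChaoEstimate:
    """Mean Chao1 over ``reps`` independent subsamples of ``depth`` reads."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = np.asarray(counts, dtype=np.int64)
    values = tuple(chao1(subsample_counts(c, depth, rng)) for _ in range(reps))
    return ChaoEstimate(value=float(np.mean(values)), replicates=values)


def chao_column(
    table,
    depth: int = DEFAULT_DEPTH,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> pd.Series:
    """Mean rarefied Chao1 per sample of a feature table.

    Samples shallower than ``depth`` are dropped with a warning; the
    caller decides how to handle the reduced sample set.
    """
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    dropped: list[str] = []
    for sample_id, row in table.counts.iterrows():
        try:
            values[sample_id] = rarefied_chao(row.to_numpy(), depth, reps, rng).value
        except InsufficientDepthError:
            dropped.append(sample_id)
    if dropped:
        log.warning(
            "dropped %d samples with fewer than %d reads: %s",
            len(dropped), depth, dropped[:10],
        )
    return pd.Series(values, name="chao")
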