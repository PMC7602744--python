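"""Project-median Mann-Whitney testing with Holm and Benjamini-Hochberg control.

Samples within a study share a batch, so per-sample tests wildly overstate
the evidence for a host effect.  The unit of replication here is the
project: for each taxon, per-sample relative abundances are reduced to one
median per project, and a two-sided Mann-Whitney U test compares the pet
projects' medians against the human projects' medians.  With the study
design that is 12 pet values versus 10 human values per taxon.  Family-wise
error is controlled with Holm-Bonferroni, the false discovery rate with
Benjamini-Hochberg; the two rejection sets define the restricted feature
sets for the classifier ("MW-Holm" and "MW-FDR").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .feature_table import HOSTS, FeatureTable, align

#: Exact U distribution is used when both groups are at most this large
#: (and tie-free); covers the study's 12-vs-10 project design.
EXACT_CUTOFF = 12


@dataclass
class ProjectMedianMatrix:
    """Projects x taxa matrix of median relative abundances."""

    medians: pd.DataFrame  # index: project_id, columns: taxa
    project_hosts: pd.Series  # project_id -> host class

    def by_host(self, taxon: str) -> tuple[np.ndarray, np.ndarray]:
        """(pet medians, human medians) for one taxon."""
        pet = self.medians.loc[self.project_hosts == "pet", taxon].to_numpy()
        human = self.medians.loc[self.project_hosts == "human", taxon].to_numpy()
        return pet, human


@dataclass
class DifferentialAbundanceResult:
    """Per-taxon raw p-values and multiplicity-corrected decisions."""

    table: pd.DataFrame  # columns: level, p_value, holm, fdr, direction
    alpha: float
    level: str


def project_medians(table: FeatureTable, metadata: pd.DataFrame) -> ProjectMedianMatrix:
    """Median per-sample relative abundance of each taxon within each project."""
    align(table, metadata)
    md = metadata.loc[table.sample_ids]
    rel = table.relative_abundance()
    hosts = md.groupby("project_id")["host"].agg(set)
    mixed = hosts.index[hosts.map(len) > 1].tolist()
    if mixed:
        raise ValueError(f"projects spanning both host classes: {mixed}")
    medians = rel.groupby(md["project_id"], sort=True).median()
    project_hosts = hosts.map(lambda s: next(iter(s)))
    return ProjectMedianMatrix(medians=medians, project_hosts=project_hosts.loc[medians.index])


def mann_whitney_two_sided(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Uses the exact U null when both groups have at most EXACT_CUTOFF
    observations and the pooled data are tie-free; otherwise the
    tie-corrected normal approximation with continuity correction.
    Two identical constant vectors give p = 1 (no evidence).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return 1.0
    method = "exact" if (max(x.size, y.size) <= EXACT_CUTOFF and not has_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _check_pvals_alpha(pvals: np.ndarray, alpha: float) -> None:
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0,1]")


def holm_correction(pvals, alpha: float = 0.05) -> np.ndarray:
    """Holm-Bonferroni step-down rejection flags, in input order."""
    p = np.asarray(pvals, dtype=float)
    _check_pvals_alpha(p, alpha)
    return multipletests(p, alpha=alpha, method="holm")[0]


def bh_fdr(pvals, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags, in input order."""
    p = np.asarray(pvals, dtype=float)
    _check_pvals_alpha(p, alpha)
    return multipletests(p, alpha=alpha, method="fdr_bh")[0]


def run_differential_abundance(
    table: FeatureTable, metadata: pd.DataFrame, alpha: float = 0.05
) -> DifferentialAbundanceResult:
    """Project-median MW test for every taxon, with Holm and BH decisions."""
    pm = project_medians(table, metadata)
    records = []
    for taxon in pm.medians.columns:
        pet, human = pm.by_host(taxon)
        p = mann_whitney_two_sided(pet, human)
        direction = "human" if np.median(human) > np.median(pet) else "pet"
        records.append((taxon, p, direction))
    res = pd.DataFrame(records, columns=["taxon", "p_value", "direction"]).set_index("taxon")
    res.insert(0, "level", table.level)
    res["holm"] = holm_correction(res["p_value"].to_numpy(), alpha)
    res["fdr"] = bh_fdr(res["p_value"].to_numpy(), alpha)
    return DifferentialAbundanceResult(
        table=res[["level", "p_value", "holm", "fdr", "direction"]], alpha=alpha, level=table.level
    )


def select_features(result: DifferentialAbundanceResult, mode: str) -> list[str]:
    """Taxa significant under the chosen correction, in stable input order."""
    if mode not in ("holm", "fdr"):
        raise ValueError(f"mode must be 'holm' or 'fdr', got {mode!r}")
    return result.table.index[result.table[mode]].tolist()


def chao_host_test(chao: pd.Series, metadata: pd.DataFrame) -> float:
    """Project-median MW test of the Chao diversity column (reported separately;
    diversity never enters the MW feature sets)."""
    md = metadata.loc[chao.index]
    med = chao.groupby(md["project_id"]).median()
    host = md.groupby("project_id")["host"].first().loc[med.index]
    return mann_whitney_two_sided(med[host == "pet"], med[host == "human"])


def write_results(result: DifferentialAbundanceResult, path) -> None:
    result.table.to_csv(path, sep="\t", index_label="taxon")
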