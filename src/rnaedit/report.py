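"""Reporting utilities: PCA on editing-level matrices, cross-tissue set
intersections, and functional-category distributions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filtering import venn_regions


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray  # per component, sums to 1

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_on_dre(levels: pd.DataFrame) -> PCAResult:
    """PCA of a site x sample editing-level matrix.

    Missing levels are imputed by the site mean; sites constant across
    samples carry no information and are dropped; each site is centered and
    the sample scores come from the singular-value decomposition. Variance
    fractions are singular values squared over their total.
    """
    if levels.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    filled = levels.apply(lambda row: row.fillna(row.mean()), axis=1)
    filled = filled.dropna(how="any")  # all-missing sites cannot be imputed
    variable = filled.std(axis=1) > 1e-12  # tolerate fp noise in constants
    filled = filled[variable]
    if filled.shape[0] < 2:
        raise ValueError("need at least 2 non-constant sites for a PCA")
    centered = filled.sub(filled.mean(axis=1), axis=0)
    x = centered.to_numpy().T  # samples x sites
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(x.shape)
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=levels.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    total = float((s**2).sum())
    return PCAResult(scores=scores, variance_fraction=(s**2) / total)


def cross_tissue_intersection(dre_gene_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Venn region counts of differentially edited genes across tissues."""
    return venn_regions(dre_gene_sets)


def category_distribution(
    annotated: pd.DataFrame, dre_only: bool = False
) -> pd.Series:
    """Proportion of events per functional category (sums to 1).

    With ``dre_only`` the distribution is restricted to differentially
    edited events (requires an ``is_dre`` column).
    """
    frame = annotated
    if dre_only:
        frame = frame[frame["is_dre"]]
    if len(frame) == 0:
        raise ValueError("no events to summarize")
    counts = frame["category"].value_counts()
    return counts / counts.sum()
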