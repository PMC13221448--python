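"""Protein-signature scoring and marker-panel coverage.

Implements the signature-level read-outs of the pipeline: the 18-gene
tumor inflammation signature (TIS) score as the mean of per-protein
z-scored levels, the relative histology score (log2 adenocarcinoma
marker score minus log2 squamous marker score), identification coverage
of marker panels, cross-instrument score agreement, hierarchical
clustering of signature rows by Spearman correlation distance, and the
two-group tests used in the figures (Welch t, Wilcoxon rank-sum).
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DefinitionError, InsufficientDataError
from .io import SignatureDefinition
from .normalize import back_transform

logger = logging.getLogger(__name__)


def signature_score(
    scaled: pd.DataFrame, sig: SignatureDefinition, min_coverage: float = 0.5
) -> pd.DataFrame:
    """Per-sample mean of scaled (z-scored) levels over signature proteins.

    Missing member cells are excluded per sample (available-case mean).
    If the matrix carries fewer than ``min_coverage`` of the signature's
    proteins, all scores are reported missing — a score from one or two
    stray members is not a signature score.
    """
    members = [g for g in sig.genes if g in scaled.index]
    coverage = len(members) / len(sig.genes)
    if coverage < min_coverage or not members:
        logger.warning(
            "signature %s: coverage %.2f below min_coverage %.2f; scores set missing",
            sig.name, coverage, min_coverage,
        )
        return pd.DataFrame(
            {
                "sample_id": scaled.columns,
                "signature": sig.name,
                "score": np.nan,
                "n_used": 0,
                "coverage": coverage,
            }
        )
    sub = scaled.loc[members]
    return pd.DataFrame(
        {
            "sample_id": scaled.columns,
            "signature": sig.name,
            "score": sub.mean(axis=0, skipna=True).to_numpy(),
            "n_used": sub.notna().sum(axis=0).to_numpy(),
            "coverage": coverage,
        }
    )


def histology_score(
    norm: pd.DataFrame,
    ac_markers: SignatureDefinition,
    scc_markers: SignatureDefinition,
) -> pd.Series:
    """log2(mean AC-marker level) - log2(mean SCC-marker level) per sample.

    Marker means are taken on the median-normalized linear scale
    (back-transformed from log2), available-case per sample. Positive
    values favor adenocarcinoma, negative squamous histology. Samples
    where either marker class is entirely missing (or zero) get NaN.
    """
    linear = back_transform(norm)
    scores = {}
    for name, sig in (("AC", ac_markers), ("SCC", scc_markers)):
        members = [g for g in sig.genes if g in linear.index]
        if not members:
            raise DefinitionError(f"no {name} marker present in the matrix")
        scores[name] = linear.loc[members].mean(axis=0, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.log2(scores["AC"]) - np.log2(scores["SCC"])
    return rel.replace([np.inf, -np.inf], np.nan).rename("histology_score")


def list_coverage(
    matrix: pd.DataFrame, panel: SignatureDefinition
) -> tuple[float, pd.Series]:
    """Identification coverage of a marker panel, cohort-wide and per sample.

    Cohort percentage counts panel members identified in at least one
    sample of the (non-imputed) matrix; the per-sample series uses each
    sample's own non-missing rows. Both on the 0-100 scale.
    """
    panel_set = set(panel.genes)
    identified_any = set(matrix.index[matrix.notna().any(axis=1)])
    cohort_pct = 100.0 * len(panel_set & identified_any) / len(panel_set)
    members = [g for g in panel.genes if g in matrix.index]
    if members:
        per_sample = 100.0 * matrix.loc[members].notna().sum(axis=0) / len(panel_set)
    else:
        per_sample = pd.Series(0.0, index=matrix.columns)
    return cohort_pct, per_sample.rename(f"{panel.name}_pct")


def cross_dataset_agreement(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame
) -> tuple[float, int, float]:
    """Spearman agreement of one signature's scores between two datasets."""
    a = scores_a.set_index("sample_id")["score"].dropna()
    b = scores_b.set_index("sample_id")["score"].dropna()
    common = a.index.intersection(b.index)
    if len(common) < 5:
        raise InsufficientDataError(
            f"only {len(common)} common scored samples; need >= 5"
        )
    rho, p = stats.spearmanr(a.loc[common], b.loc[common])
    return float(rho), int(len(common)), float(p)


def cluster_signature_rows(
    scaled: pd.DataFrame,
    sig: SignatureDefinition,
    linkage: str = "average",
) -> tuple[list[str], np.ndarray]:
    """Order signature proteins by hierarchical clustering.

    Distance between protein profiles is 1 - Spearman rho across
    samples; linkage defaults to average. Proteins with constant
    profiles (undefined correlation) are placed last with a warning.
    Returns (leaf-ordered protein list, scipy linkage matrix).
    """
    members = [g for g in sig.genes if g in scaled.index]
    sub = scaled.loc[members].dropna(axis=0, how="any")
    constant = sub.index[sub.nunique(axis=1) < 2].tolist()
    if constant:
        logger.warning(
            "cluster_signature_rows: constant profile(s) placed last: %s", constant
        )
        sub = sub.drop(index=constant)
    if len(sub) < 2 or sub.shape[1] < 3:
        raise InsufficientDataError("clustering needs >= 2 proteins over >= 3 samples")
    rho = stats.spearmanr(sub.to_numpy(), axis=1)[0]
    if np.ndim(rho) == 0:  # scipy collapses the 2-profile case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    order = hierarchy.leaves_list(link)
    return [sub.index[i] for i in order] + constant, link


def group_compare(
    values: pd.Series,
    groups: pd.Series,
    test: Literal["welch", "wilcoxon"] = "welch",
) -> tuple[float, float]:
    """Two-sided two-group comparison: Welch t or Wilcoxon rank-sum."""
    joined = pd.concat([values, groups], axis=1, join="inner").dropna()
    labels = joined.iloc[:, 1].unique()
    if len(labels) != 2:
        raise InsufficientDataError(f"need exactly 2 groups, got {len(labels)}")
    a = joined.loc[joined.iloc[:, 1] == labels[0]].iloc[:, 0].to_numpy(float)
    b = joined.loc[joined.iloc[:, 1] == labels[1]].iloc[:, 0].to_numpy(float)
    if min(a.size, b.size) < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    if test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
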