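"""Per-sample quality control for single-slide FFPE DIA runs.

Metrics: identification counts, contaminant (skin-keratin / blood)
MS-signal fractions, top-N high-abundance signal fraction, total-ion-
chromatogram AUC, low-depth outlier flags (Tukey fence), and protein-
complex concordance (within-sample SD of centered MCM2-7 levels) — plus
Spearman correlations of each metric against analytical depth. High
contaminant load suppresses ionization of low-abundance peptides, so
these metrics are the first-line read-out of sample usability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DefinitionError,
    InsufficientDataError,
    SampleLookupError,
    UndefinedMetricError,
)
from .io import SignatureDefinition

OUTLIER_METHOD = "tukey_low_fence_1.5_iqr"


def id_count(matrix: pd.DataFrame, sample_id: str) -> int:
    """Number of proteins with a (non-missing) quantification in a sample."""
    if sample_id not in matrix.columns:
        raise SampleLookupError(f"sample {sample_id!r} not in matrix")
    return int(matrix[sample_id].notna().sum())


def id_counts(matrix: pd.DataFrame) -> pd.Series:
    """Per-sample identification counts (non-imputed matrix)."""
    return matrix.notna().sum(axis=0)


def signal_fraction(
    precursors: pd.DataFrame, sample_id: str, genes: SignatureDefinition
) -> float:
    """Fraction of a sample's total MS1 signal carried by a gene set."""
    sub = precursors.loc[precursors["sample_id"] == sample_id]
    if sub.empty:
        raise SampleLookupError(f"sample {sample_id!r} not in precursor table")
    total = float(sub["ms1_area"].sum())
    if total <= 0:
        raise UndefinedMetricError(f"sample {sample_id!r} has zero total MS1 signal")
    member = sub["protein"].str.upper().isin(set(genes.genes))
    return float(sub.loc[member, "ms1_area"].sum() / total)


def signal_fractions(precursors: pd.DataFrame, genes: SignatureDefinition) -> pd.Series:
    """Vectorized :func:`signal_fraction` over all samples."""
    total = precursors.groupby("sample_id")["ms1_area"].sum()
    if (total <= 0).any():
        bad = total.index[total <= 0][0]
        raise UndefinedMetricError(f"sample {bad!r} has zero total MS1 signal")
    member = precursors["protein"].str.upper().isin(set(genes.genes))
    part = precursors.loc[member].groupby("sample_id")["ms1_area"].sum()
    return (part.reindex(total.index).fillna(0.0) / total).rename("signal_fraction")


def top_n_fraction(precursors: pd.DataFrame, sample_id: str, n: int = 20) -> float:
    """Fraction of total MS1 signal from the sample's ``n`` most abundant
    proteins (per-protein summed MS1; ties broken by protein symbol)."""
    if n < 1:
        raise UndefinedMetricError("n must be >= 1")
    sub = precursors.loc[precursors["sample_id"] == sample_id]
    if sub.empty:
        raise SampleLookupError(f"sample {sample_id!r} not in precursor table")
    per_prot = sub.groupby("protein")["ms1_area"].sum()
    total = float(per_prot.sum())
    if total <= 0:
        raise UndefinedMetricError(f"sample {sample_id!r} has zero total MS1 signal")
    ranked = per_prot.sort_index().sort_values(ascending=False, kind="stable")
    return float(ranked.iloc[:n].sum() / total)


def tic_auc(trace: pd.DataFrame) -> float:
    """Area under a total-ion chromatogram by the composite trapezoid rule."""
    t = np.asarray(trace["time_min"], dtype=float)
    y = np.asarray(trace["intensity"], dtype=float)
    if t.size < 2:
        raise InsufficientDataError("TIC AUC needs >= 2 time points")
    return float(np.trapezoid(y, t))


def tic_aucs(tic: pd.DataFrame) -> pd.Series:
    return tic.groupby("sample_id", sort=True).apply(tic_auc, include_groups=False).rename("tic_auc")


def depth_outliers(counts: pd.Series) -> pd.Series:
    """Flag low-depth samples below the Tukey fence Q1 - 1.5*IQR.

    Only the low side is fenced: unusually deep runs are not a quality
    problem. The rule tag is :data:`OUTLIER_METHOD`.
    """
    if counts.size < 4:
        raise InsufficientDataError("outlier detection needs >= 4 samples")
    q1, q3 = counts.quantile([0.25, 0.75])
    fence = q1 - 1.5 * (q3 - q1)
    return (counts < fence).rename("depth_outlier")


def complex_concordance(
    log_matrix: pd.DataFrame, complex_def: SignatureDefinition
) -> pd.Series:
    """Per-sample SD of protein-centered log2 levels of complex members.

    The member block is double-centered: the per-sample member mean is
    removed first (so per-sample additive log-scale shifts, e.g. median
    normalization, cancel exactly even under missingness), then each
    member is centered on its cohort mean so constant stoichiometry
    offsets do not masquerade as disagreement. Samples with fewer than
    two observed members get a missing value.
    """
    members = [g for g in complex_def.genes if g in log_matrix.index]
    if len(members) < 2:
        raise DefinitionError(
            f"complex {complex_def.name!r}: fewer than 2 members in the matrix"
        )
    sub = log_matrix.loc[members]
    within = sub.sub(sub.mean(axis=0), axis=1)
    centered = within.sub(within.mean(axis=1), axis=0)
    n_obs = centered.notna().sum(axis=0)
    sd = centered.std(axis=0, ddof=1)
    sd[n_obs < 2] = np.nan
    return sd.rename(f"{complex_def.name}_sd")


def metric_depth_correlation(
    metric: pd.Series, counts: pd.Series
) -> tuple[float, float, str]:
    """Spearman rank correlation of a QC metric against identification depth."""
    joined = pd.concat([metric, counts], axis=1, join="inner").dropna()
    if len(joined) < 5:
        raise InsufficientDataError("correlation needs >= 5 paired observations")
    a, b = joined.iloc[:, 0], joined.iloc[:, 1]
    if a.nunique() < 2 or b.nunique() < 2:
        raise UndefinedMetricError("correlation undefined for constant input")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p), "spearman"


def qc_report(
    precursors: pd.DataFrame,
    matrix: pd.DataFrame,
    tic: pd.DataFrame,
    keratin_set: SignatureDefinition,
    complexes: list[SignatureDefinition] | None = None,
    top_n: int = 20,
) -> pd.DataFrame:
    """Assemble the per-sample QC table used by the pipeline report."""
    counts = id_counts(matrix)
    ker = signal_fractions(precursors, keratin_set)
    topn = pd.Series(
        {s: top_n_fraction(precursors, s, top_n) for s in counts.index},
        name=f"top{top_n}_fraction",
    )
    aucs = tic_aucs(tic)
    report = pd.DataFrame(
        {
            "id_count": counts,
            "keratin_fraction": ker.reindex(counts.index),
            f"top{top_n}_fraction": topn,
            "tic_auc": aucs.reindex(counts.index),
            "depth_outlier": depth_outliers(counts),
        }
    )
    log_matrix = np.log2(matrix)
    for cdef in complexes or []:
        report[f"{cdef.name}_sd"] = complex_concordance(log_matrix, cdef)
    report.index.name = "sample_id"
    return report
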