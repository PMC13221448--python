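"""Pre-ranked gene-set enrichment (weighted Kolmogorov-Smirnov statistic).

Proteins are ranked by a signed metric (here: moderated-test log2 fold
changes); for each gene set a running sum rises by |metric|^p at member
positions (normalized) and falls by 1/(N - N_hits) elsewhere. The
enrichment score (ES) is the signed maximum deviation of this walk; the
null is built from random same-size gene subsets, NES normalizes ES by
the mean |null ES| of matching sign, and the empirical p-value carries
a +1 continuity correction. BH adjustment is applied across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import bh_adjust
from .errors import DefinitionError, UndefinedMetricError
from .io import SignatureDefinition

DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 500


@dataclass(frozen=True)
class EnrichmentRow:
    name: str
    es: float
    nes: float
    p_value: float
    size: int
    leading_edge: tuple[str, ...]


def enrichment_score(
    ranked_genes: np.ndarray, metric: np.ndarray, member_mask: np.ndarray, weight: float
) -> tuple[float, int]:
    """ES of one set against a descending-ranked list.

    Returns the signed maximum of the running sum and the 0-based index
    of the extremum (for the leading edge).
    """
    n = member_mask.size
    n_hit = int(member_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise DefinitionError("gene set empty or equal to the whole universe")
    w = np.abs(metric) ** weight
    hit_w = np.where(member_mask, w, 0.0)
    denom = hit_w.sum()
    if denom <= 0:
        # all member metrics zero: fall back to unweighted hits
        hit_w = member_mask.astype(float)
        denom = hit_w.sum()
    step = hit_w / denom - (~member_mask) / float(n - n_hit)
    walk = np.cumsum(step)
    imax = int(np.argmax(np.abs(walk)))
    return float(walk[imax]), imax


def preranked_gsea(
    ranking: pd.Series,
    sets: list[SignatureDefinition],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> pd.DataFrame:
    """Permutation pre-ranked GSEA over a protein -> metric ranking.

    Sets are filtered to members present in the ranking; sets with fewer
    than ``min_size`` or more than ``max_size`` surviving members are
    discarded. The null permutes gene labels (random same-size subsets
    of the ranked universe), the standard scheme for a pre-ranked list.
    Ties in the metric are broken by protein name for determinism.
    """
    ranking = ranking.dropna()
    if ranking.index.has_duplicates:
        raise DefinitionError("ranking contains duplicate proteins")
    if ranking.nunique() < 2:
        raise UndefinedMetricError("ranking metric is constant; no ordering")
    frame = ranking.to_frame("metric").assign(gene=ranking.index.astype(str).str.upper())
    frame = frame.sort_values(["metric", "gene"], ascending=[False, True])
    genes = frame["gene"].to_numpy()
    metric = frame["metric"].to_numpy(float)
    n = genes.size
    pos = {g: i for i, g in enumerate(genes)}

    kept: list[tuple[SignatureDefinition, np.ndarray]] = []
    for sig in sets:
        idx = np.array(sorted(pos[g] for g in sig.genes if g in pos), dtype=int)
        if min_size <= idx.size <= max_size and idx.size < n:
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            kept.append((sig, mask))
    if not kept:
        raise DefinitionError("no gene set within size bounds after filtering")

    rng = np.random.default_rng(seed)
    rows = []
    for sig, mask in kept:
        es, imax = enrichment_score(genes, metric, mask, weight)
        size = int(mask.sum())
        null = np.empty(n_perm)
        for j in range(n_perm):
            rmask = np.zeros(n, dtype=bool)
            rmask[rng.choice(n, size=size, replace=False)] = True
            null[j], _ = enrichment_score(genes, metric, rmask, weight)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size:
            nes = es / np.mean(np.abs(same))
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size)
        else:
            nes, p = np.nan, 1.0 / (1.0 + n_perm)
        if es >= 0:
            leading = genes[: imax + 1][mask[: imax + 1]]
        else:
            leading = genes[imax:][mask[imax:]]
        rows.append(
            {
                "gene_set": sig.name,
                "es": es,
                "nes": nes,
                "p_value": p,
                "size": size,
                "leading_edge": ",".join(leading),
            }
        )
    out = pd.DataFrame(rows).set_index("gene_set")
    out["adj_p_value"] = bh_adjust(out["p_value"])
    return out
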