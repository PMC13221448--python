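#!/usr/bin/env python
"""PTPRC-tertile differential abundance and immune gene-set enrichment.

Stratifies the cohort into tertiles of PTPRC (CD45) abundance, runs the
count-moderated differential test between the high and low tertiles
(middle excluded), reports how identified immune-cell markers split
between significantly up and significantly down, and runs pre-ranked
GSEA of the immune hallmark-style sets on the fold-change ranking.
"""

from pathlib import Path

from slideproteo import normalize
from slideproteo.differential import (
    median_precursor_counts,
    moderated_test,
    stratify_tertiles,
    tertile_sizes,
)
from slideproteo.gsea import preranked_gsea
from slideproteo.io import packaged_signatures
from slideproteo.simulate import SimConfig, simulate_cohort

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sigs = packaged_signatures()
    cohort = simulate_cohort(SimConfig(seed=SEED))
    norm = normalize.median_normalize_log2(cohort.quant_imputed)

    labels = stratify_tertiles(norm.loc["PTPRC"])
    sizes = tertile_sizes(labels)
    print(f"PTPRC tertiles: {sizes}")

    counts = median_precursor_counts(cohort.precursors)
    diff = moderated_test(norm, labels, counts)
    print(f"moderated test: d0={diff['df_prior'].iloc[0]:.1f}, "
          f"{int((diff['adj_p_value'] < 0.05).sum())} of {len(diff)} proteins at BH<0.05")

    markers = [g for g in sigs["IMMUNE_CELL_MARKERS_SYNTHETIC"].genes if g in diff.index]
    sub = diff.loc[markers]
    up = 100 * ((sub["adj_p_value"] < 0.05) & (sub["logFC"] > 0)).mean()
    down = 100 * ((sub["adj_p_value"] < 0.05) & (sub["logFC"] < 0)).mean()
    print(f"immune markers identified: {len(markers)}; "
          f"{up:.0f}% significantly higher vs {down:.0f}% lower in PTPRC-high")

    RESULTS.mkdir(exist_ok=True)
    diff.sort_values("p_value").head(200).reset_index().to_csv(
        RESULTS / "05_differential_top200.tsv", sep="\t", index=False, float_format="%.6g"
    )

    enr = preranked_gsea(
        diff["logFC"].dropna(),
        [
            sigs["IFNG_RESPONSE_SYNTHETIC"],
            sigs["INFLAMMATORY_RESPONSE_SYNTHETIC"],
            sigs["IMMUNE_CELL_MARKERS_SYNTHETIC"],
        ],
        n_perm=1000,
        seed=SEED + 30,
    )
    enr.reset_index().to_csv(
        RESULTS / "05_gsea.tsv", sep="\t", index=False, float_format="%.6g"
    )
    for name, row in enr.iterrows():
        print(f"GSEA {name}: ES={row['es']:+.3f} NES={row['nes']:+.2f} "
              f"p={row['p_value']:.3g} adj={row['adj_p_value']:.3g}")
    print(f"wrote {RESULTS / '05_differential_top200.tsv'} and {RESULTS / '05_gsea.tsv'}")


if __name__ == "__main__":
    main()
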