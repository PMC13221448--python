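#!/usr/bin/env python
"""Signature-level read-outs: TIS, histology score, marker coverage.

Scores every sample for the 18-gene tumor inflammation signature (mean
of z-scored protein levels) and for the relative histology score
(log2 AC-marker mean minus log2 SCC-marker mean), checks both against
the simulator's ground truth, measures marker-panel identification
coverage, and quantifies cross-instrument agreement of the TIS score
for the same cohort measured on both configured instruments.
"""

from pathlib import Path

import pandas as pd
from scipy import stats

from slideproteo import normalize, signatures
from slideproteo.io import packaged_signatures
from slideproteo.simulate import SimConfig, simulate_two_instruments

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sigs = packaged_signatures()
    both = simulate_two_instruments(SimConfig(seed=SEED))
    cohort = both["astral"]
    truth = cohort.truth.samples

    norm = normalize.median_normalize_log2(cohort.quant_imputed)
    scaled = normalize.scale_per_protein(norm)

    tis = signatures.signature_score(scaled, sigs["TIS"]).set_index("sample_id")
    hist = signatures.histology_score(norm, sigs["AC_MARKERS"], sigs["SCC_MARKERS"])
    table = pd.DataFrame(
        {
            "tis_score": tis["score"],
            "histology_score": hist,
            "true_immune_fraction": truth["immune_fraction"],
            "histology": truth["histology"],
        }
    )
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "04_signature_scores.tsv"
    table.rename_axis("sample_id").reset_index().to_csv(
        out, sep="\t", index=False, float_format="%.6g"
    )

    rho = stats.spearmanr(table["tis_score"], table["true_immune_fraction"]).statistic
    print(f"TIS score vs true immune fraction: Spearman rho={rho:.3f}")
    p = stats.mannwhitneyu(
        table.loc[table["histology"] == "AC", "histology_score"].dropna(),
        table.loc[table["histology"] == "SCC", "histology_score"].dropna(),
    ).pvalue
    print(f"histology score AC vs SCC: Wilcoxon rank-sum p={p:.2e}")

    scores_b = signatures.signature_score(
        normalize.scale_per_protein(
            normalize.median_normalize_log2(both["timstof"].quant_imputed)
        ),
        sigs["TIS"],
    )
    arho, n, _ = signatures.cross_dataset_agreement(tis.reset_index(), scores_b)
    print(f"TIS agreement astral vs timstof: rho={arho:.3f} over {n} shared samples")

    cov_rows = []
    for panel in ("TIS", "LUNG_ACTIONABLE_MARKERS_SYNTHETIC", "IMMUNE_CELL_MARKERS_SYNTHETIC"):
        for instr, data in both.items():
            pct, _ = signatures.list_coverage(data.quant, sigs[panel])
            cov_rows.append({"panel": panel, "instrument": instr, "pct_identified": pct})
            print(f"{panel} coverage on {instr}: {pct:.0f}%")
    pd.DataFrame(cov_rows).to_csv(
        RESULTS / "04_marker_coverage.tsv", sep="\t", index=False, float_format="%.6g"
    )
    print(f"wrote {out} and {RESULTS / '04_marker_coverage.tsv'}")


if __name__ == "__main__":
    main()
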