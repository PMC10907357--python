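#!/usr/bin/env python
"""Synthesis: assimilation distribution, trait variability, correlations, PCA.

Runs the full pipeline on the moderate-density suite and reports the
within-plant assimilation split (top 40 cm vs below), per-depth trait
CVs, the trait × environment Pearson table, and the PCA variance
decomposition.  Tables land in results/traits/.
"""

import argparse
from pathlib import Path

from canopylight.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/simulated/moderate"))
    ap.add_argument("--out", type=Path, default=Path("results/traits"))
    args = ap.parse_args()

    sim = args.sim
    tables = run_pipeline(
        PipelineConfig(
            spectra=str(sim / "spectra.csv"),
            par=str(sim / "par.csv"),
            fluoro=str(sim / "fluoro.csv"),
            pigments=str(sim / "pigments.csv"),
            biomass=str(sim / "biomass.csv"),
            morpho=str(sim / "morpho.csv"),
            out_dir=str(args.out),
        )
    )

    assim = tables["assimilation"]
    share = assim.loc[assim["apical"], "percent"].sum()
    print("Potential assimilation (ETRmax × LA) by level:")
    print(assim[["depth_cm", "product", "percent"]].round(2).to_string(index=False))
    print(f"→ top 40 cm: {share:.1f}% vs deeper levels: {100 - share:.1f}%\n")

    cv = tables["trait_cv"]
    cv_med = cv.groupby("trait")["cv"].median().round(3)
    print("Median CV per trait across depths:")
    print(cv_med.to_string())

    corr = tables["correlations"]
    sig = corr[corr["significance"] != ""]
    print(f"\n{len(sig)}/{len(corr)} trait–environment correlations significant:")
    print(
        sig[["trait", "environment", "r", "p", "significance"]]
        .round(3)
        .to_string(index=False)
    )

    if "pca_variance" in tables:
        pv = tables["pca_variance"]
        print(
            f"\nPCA: axis 1 carries {pv.percent_variance.iloc[0]:.1f}% and axis 2 "
            f"{pv.percent_variance.iloc[1]:.1f}% of the standardized trait variance."
        )


if __name__ == "__main__":
    main()
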