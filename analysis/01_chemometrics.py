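"""Chemometric survey of the extraction campaign.

Computes the pairwise correlation structure of the 13 bioactivity
responses, a standardized PCA, and a raw-unit complete-linkage/City-block
cluster analysis of the 15 runs; writes all tables under
results/chemometrics/ and prints the headline numbers.
"""

from pathlib import Path

from uaeopt.pipeline import PipelineConfig, run

OUT = Path("results/chemometrics")


def main() -> None:
    artifacts = run(PipelineConfig(stages=["chemometrics"],
                                   output_dir=str(OUT)))
    r, p = artifacts["chemometrics"]["correlation"]
    print("strongest antioxidant-assay correlations:")
    print(f"  FRAP~CUPRAC r = {r.loc['FRAP', 'CUPRAC']:.4f}")
    print(f"  DPPH~FRAP   r = {r.loc['DPPH', 'FRAP']:.4f}")
    pct = artifacts["chemometrics"]["pca"].explained_pct
    print(f"PCA: PC1 {pct[0]:.2f}%, PC2 {pct[1]:.2f}% "
          f"(PC1+PC2 {pct[0] + pct[1]:.2f}%)")
    dendrogram = artifacts["chemometrics"]["dendrogram"]
    clusters = artifacts["chemometrics"]["clusters"]
    singletons = [s for s in clusters
                  if sum(v == clusters[s] for v in clusters.values()) == 1]
    print(f"HCA: final merge height {dendrogram.linkage[-1, 2]:.1f}; "
          f"k=3 singleton cluster(s): {singletons}")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
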