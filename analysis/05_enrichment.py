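#!/usr/bin/env python
"""Over-representation analysis of the recurrence arm's selected genes.

Builds a synthetic gene-set collection over the cohort's measured RNA
symbols (one set seeded with the planted differential genes, the rest
random), then scores the selected DEG/DEP symbols against it with the
hypergeometric upper tail and BH adjustment. The universe is the set of
measured gene/protein symbols, not the collection's union. Writes
results/enrichment/enrichment.tsv and the generated GMT.
"""

from pathlib import Path

import pandas as pd

from omicnet import LAYERS
from omicnet.enrichment import enrich
from omicnet.io import align_samples, read_clinical, read_layer, write_gmt
from omicnet.simulate import make_synthetic_gene_sets, read_truth


def main() -> None:
    base = Path("results/data/recurrence")
    layers = [read_layer(base / f"{n}.tsv", n) for n in LAYERS]
    clinical = read_clinical(base / "clinical.tsv")
    layers, clinical = align_samples(layers, clinical)
    truth = read_truth(base / "truth.txt")

    # rebuild a dataset shell so the generator can seed the planted set
    class _Shell:
        pass

    shell = _Shell()
    shell.layers = {ly.layer_name: ly for ly in layers}
    shell.truth = truth
    collection = make_synthetic_gene_sets(shell, seed=20240915)

    query = set()
    for name in ("rna", "protein"):
        rec = pd.read_csv(
            Path("results/differential/recurrence") / f"differential_{name}.tsv", sep="\t"
        )
        query |= set(rec.loc[rec["passes"], "symbol"].astype(str))
    universe = {
        str(s) for ly in layers if ly.layer_name in ("rna", "protein")
        for s in ly.feature_ids
    }

    out = Path("results/enrichment")
    out.mkdir(parents=True, exist_ok=True)
    write_gmt(collection, out / "synthetic_sets.gmt")
    results = enrich(query, collection, universe)
    results.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    print(f"query: {len(query)} selected symbols; universe: {len(universe)} measured")
    print(f"tested {len(results)} sets with nonzero overlap; top hits:")
    cols = ["set_name", "k_overlap", "K_set", "p_value", "adjusted_p", "odds_ratio"]
    print(results[cols].head(5).to_string(index=False))


if __name__ == "__main__":
    main()
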