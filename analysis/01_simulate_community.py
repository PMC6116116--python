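"""Generate the synthetic study community every later stage analyses.

Writes, under results/fixture/: sawfly and host species trees (Newick),
a barcode alignment (FASTA) with recorded true species, a metabolomic
feature table (CSV) and MS/MS spectra (MGF) for the hosts, an
incidence table with regional structure and sampling effort (CSV), and
the true variance components behind the incidence (JSON).

The incidence is drawn from the generative twin of the variance
partition model with a dominant defense-tracking component, so the
downstream analyses have a known answer to find.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cophylochem.chem_similarity import (build_compound_similarity,
                                         species_similarity_matrix, write_mgf)
from cophylochem.io_core import write_fasta, write_newick
from cophylochem.synthetic_data import (SimParams, sim_barcode_fixture,
                                        sim_bd_tree, sim_chem_profiles,
                                        sim_incidence)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/fixture"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    params = SimParams(seed=args.seed)

    saw = sim_bd_tree(params.n_parasite, params.birth, params.death,
                      seed=args.seed)
    host = sim_bd_tree(params.n_host, params.birth, params.death,
                       seed=args.seed + 1)
    write_newick(saw, out / "sawfly_tree.nwk")
    write_newick(host, out / "host_tree.nwk")

    barcodes = sim_barcode_fixture(
        n_species=8, n_per_species=4, intra_div=params.intra_div,
        inter_div=params.inter_div, kappa=params.kappa, seed=args.seed + 2,
        seq_len=params.seq_len)
    write_fasta(barcodes, out / "barcodes.fasta")
    pd.Series(barcodes.species_label, name="species").rename_axis("id") \
        .to_csv(out / "barcode_truth.csv")

    table, spectra = sim_chem_profiles(
        host, gain=params.compound_gain, loss=params.compound_loss,
        seed=args.seed + 3)
    table.df.rename_axis("compound").to_csv(out / "features.csv")
    write_mgf(spectra, out / "spectra.mgf")
    chem_S = species_similarity_matrix(table, build_compound_similarity(spectra))
    pd.DataFrame(chem_S.values, index=chem_S.names, columns=chem_S.names) \
        .to_csv(out / "chem_similarity.csv")

    components = {t: 0.01 for t in
                  ["region", "coevolution", "host_defense_interaction"]}
    components["defense_tracking"] = 1.0
    chem_df = pd.DataFrame(chem_S.values, index=host.tip_labels,
                           columns=host.tip_labels)
    sim = sim_incidence(saw, host, chem_df, components, seed=args.seed + 4)
    sim.table.records.to_csv(out / "incidence.csv", index=False)
    pd.DataFrame({"host": sim.cov.host_taxa,
                  "flushes_searched": sim.effort.astype(int)}) \
        .to_csv(out / "effort.csv", index=False)
    (out / "truth.json").write_text(json.dumps({
        "seed": args.seed,
        "variance_components": sim.sigma2_true,
        "threshold": sim.threshold,
        "prevalence": float(np.mean(sim.y)),
    }, indent=2))
    print(f"wrote fixture bundle to {out}/ "
          f"(prevalence {np.mean(sim.y):.3f}, "
          f"{len(table.compounds)} compounds, "
          f"{barcodes.n} barcodes)")


if __name__ == "__main__":
    main()
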