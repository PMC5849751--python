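"""Full-scale derivation from real membrane-protein databases (documented
walkthrough; requires downloaded structures, therefore not exercised by
the test suite).

The desk-scale examples in this directory run on synthetic fixtures.  To
reproduce database-level numbers — topology accuracy over hundreds of
chains, average pore-facing score fractions, per-protein embedding
heatmaps — you need membrane-oriented PDB files (PDBTM embedding,
reference in/out topology e.g. from OPM) and a manifest of the culled,
redundancy-reduced chain list:

1. Obtain oriented structures: download each chain's PDBTM-oriented PDB
   file into a directory, one file per entry, named <pdb_id>.pdb, with the
   membrane normal along z and the bilayer center at z = 0.
2. Cull chains externally (sequence-similarity reduction is out of scope
   here): resolution < 3 Å, R-factor < 0.3, 40-10,000 residues, no
   Cα-only or electron-microscopy entries.  `membpot.apply_curation`
   evaluates exactly these rules given per-chain metadata.
3. Write a tab-delimited manifest with columns
       pdb_id  chain  flip_flag  protein_class  resolution  r_factor
       length  method  ca_only
   setting flip_flag = 1 for entries whose PDBTM orientation disagrees
   with the reference in/out topology.
4. Run this script:  python examples/full_scale_pipeline.py \
       --manifest manifest.tsv --structures pdbs/ --protein-class alpha
"""

import argparse
import sys

import numpy as np

import membpot as mp


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--manifest")
    parser.add_argument("--structures")
    parser.add_argument("--protein-class", default="alpha",
                        choices=("alpha", "beta"))
    parser.add_argument("--out-table", default="potential.tsv")
    args = parser.parse_args()
    if not args.manifest or not args.structures:
        print(__doc__)
        sys.exit("provide --manifest and --structures (see docstring)")

    models = mp.assemble_dataset(args.manifest, args.structures,
                                 args.protein_class)
    for model in models:
        mp.classify_residues(model)
    pset = mp.derive_potential(models, protein_class=args.protein_class)
    mp.write_potential_table(pset, args.out_table)
    print(f"derived {args.protein_class} potential from {len(models)} "
          f"structures -> {args.out_table}")

    correct = 0
    fractions = []
    for model in models:
        pred = mp.predict_topology(model, pset)
        correct += pred.call == "native"
        bd = mp.score_structure(model, pset)
        if bd.total:
            fractions.append(bd.inaccessible_fraction)
    print(f"topology recovered for {correct}/{len(models)} structures "
          f"({correct / len(models):.1%})")
    print(f"mean lipid-inaccessible score fraction: "
          f"{np.mean(fractions):.2%}")


if __name__ == "__main__":
    main()
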