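# fwbench

Free–Wilson fragment benchmark for protein–ligand scoring functions (SFs).

The package counts medicinal-chemistry interaction fragments (hydrogen-bond
donors/acceptors, hydrophobic carbons, aromatic rings, cations, carboxylates,
halogens, fluorine) in ligands via SMARTS patterns, and uses regularized
linear models to quantify:

1. how experimental binding affinity (pK) correlates with fragment presence,
2. how each SF's predicted scores correlate with fragment presence, and
3. which fragments carry the *residual error* of each SF — a combined model
   regresses experimental pK on the standardized fragment matrix plus the
   raw SF prediction column; a coefficient near 1 on the SF column with
   near-zero fragment coefficients indicates a well-calibrated SF, while
   large fragment coefficients are the corrections that SF needs.

It also ships a minimal baseline scoring function: half the
solvent-accessible surface area (Shrake–Rupley) buried upon complex
formation, `(ligand_sasa + protein_sasa - complex_sasa) / 2`, with a 1.0 Å
probe.

A synthetic-data module generates fragment-count matrices, affinities, and
deliberately biased SF scores with known ground truth, so the whole pipeline
is testable offline.

## Layout

| module               | contents                                                                |
| -------------------- | ----------------------------------------------------------------------- |
| `fwbench.features`   | ligand I/O (SMILES/SDF/MOL2), charge-patch rules, SMARTS fragment counting |
| `fwbench.regression` | uncentered cosine correlation + filter, standardization, coordinate-descent Lasso with paths |
| `fwbench.benchmark`  | scoring power, the three regression schemes, full report builder        |
| `fwbench.sasa`       | Shrake–Rupley SASA, buried-surface score, PDB/MOL2 structure reading    |
| `fwbench.synthetic`  | ground-truth dataset generators, fixture molecules and toy 3D complexes |
| `fwbench.cli`        | `fwbench` command-line interface                                        |

Note on conventions: inter-feature "correlation" is the **uncentered cosine**
`a·b/(|a||b|)` on raw count vectors (a Pearson variant is available via a
flag), and the Lasso objective is `(1/N)‖y − β0·1 − Xβ‖² + λ‖β‖₁` — λ here is
twice the `alpha` of solvers using the 1/(2N) convention.

## CLI

```sh
# synthetic dataset (features.tsv, scores.tsv with one calibrated and one
# biased SF, toy_ligands.smi)
fwbench simulate --n 273 --seed 1 --out runs/sim

# count fragments in your own ligands
fwbench features --input ligands.smi --format smiles --out features.tsv

# scoring power + all three schemes for every SF column in scores.tsv
fwbench benchmark --features runs/sim/features.tsv \
                  --scores runs/sim/scores.tsv --out runs/report

# buried-surface baseline score for one complex
fwbench deltasas --ligand lig.mol2 --protein prot.pdb
```

`benchmark` writes `exclusions.tsv`, `scoring_power.tsv`, `scheme_ref.tsv`,
per-SF `scheme_sf_<SF>.tsv` / `scheme_combined_<SF>.tsv` (coefficient vs λ),
and a plain-text `summary.txt`. Score tables are TSV/CSV with header
`id, pk_ref, <SF>...`; use `--negate NAME` for score columns where more
negative means better (e.g. raw DSX output). Exit codes: 0 success, 2 config
error, 3 data error.

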