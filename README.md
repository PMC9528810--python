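# snarpred

Hybrid mechanistic/machine-learning prediction of activation free energies
for nucleophilic aromatic substitution (SNAr) reactions.

The package combines quantum-chemical ground-state and transition-state
descriptors (most importantly a DFT-computed barrier) with kinetic data to
train uncertainty-aware regression models, select them honestly, and use the
resulting barriers for absolute-rate and regio-/chemoselectivity prediction:

| module | what it does |
| --- | --- |
| `snarpred.reaction_data` | kinetic records, Eyring rate/barrier conversion, dataset summaries, seeded/grouped train-test splits |
| `snarpred.descriptors` | named feature sets (`X_full`, `X_noTS`, `X_small`, `X_trad`, `X_surf`), second-order polynomial expansion (PF2), Morgan reaction difference fingerprints, solvent principal components |
| `snarpred.model_zoo` | LR / ARD(+PF2) / RF / SVR / GPR (Matérn-3/2) plus raw and linearly corrected DFT baselines, prediction intervals, model archives |
| `snarpred.validation` | metrics (R², MAE, RMSE), bootstrap bias-corrected cross-validation (BBC-CV), learning curves, leave-one-group-out |
| `snarpred.interpretation` | Spearman correlation clustering, VIFs, bootstrapped permutation-importance ranking |
| `snarpred.applicability` | PLS DModX, integral accuracy averaging curves, interval coverage, categorical domain gates |
| `snarpred.selectivity` | lowest-barrier site prediction, regio/chemo top-1 accuracy |
| `snarpred.synthetic` | generators that emulate the statistical structure of the real data (correlated descriptor clusters, noisy DFT barrier, group structure, site competitions) |
| `snarpred.cli` | `snarpred` command-line workflow |

## CLI

All subcommands write artifacts plus a `run_manifest.json` (inputs hash,
seed, package version) into `--out`:

```bash
snarpred simulate --n-samples 300 --seed 1 --out runs/sim
snarpred summarize --reactions runs/sim/reactions.csv --out runs/summary
snarpred split --reactions runs/sim/reactions.csv --fraction-train 0.8 --seed 0 --out runs/split
snarpred train --reactions runs/sim/reactions.csv --descriptors runs/sim/descriptors.csv \
               --feature-set X_full --model GPR --out runs/model
snarpred evaluate --reactions runs/sim/reactions.csv --descriptors runs/sim/descriptors.csv \
                  --model-path runs/model/model.pkl --out runs/eval
snarpred bbc-cv --reactions runs/sim/reactions.csv --descriptors runs/sim/descriptors.csv \
                --model LR --model GPR --feature-set X_small --folds 10 --out runs/bbc
snarpred ad --reactions runs/sim/reactions.csv --descriptors runs/sim/descriptors.csv --out runs/ad
snarpred selectivity --sites sites.csv --out runs/sel
```

Input schemas (CSV): reaction table
(`rxn_id,reaction_smiles,nucleophile_class,leaving_class,electrophile_id,nucleophile_id,solvent,temperature_K,k_obs,dG_exp_kcal`),
descriptor table keyed by `rxn_id` (see
`src/snarpred/data/feature_sets.json` for the column manifest), solvent table
(`solvent,PC1..PC5`), and site table
(`substrate_id,site_label,halogen,dG_pred_kcal,dG_std_kcal,observed_major_flag`).

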