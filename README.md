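# coagsim

Quantitative-systems-pharmacology simulation of the human coagulation
network, predicting the clinical anticoagulation biomarkers **INR**
(warfarin, with phenprocoumon handled by dose conversion) and **aPTT**
(rivaroxaban) for virtual patients stratified by **CYP2C9** and **VKORC1**
genotype.

The pipeline chains two simulations per patient:

1. **In vivo** — a turnover / Michaelis-Menten clotting-factor network
   (hours time base) is initialized at its drug-free steady state and
   integrated through 20 days of once-daily oral dosing. Warfarin inhibits
   the vitamin-K-epoxide → vitamin-K regeneration step (Imax/IC50), which
   throttles production of the VK-dependent factors II, VII, IX, X, PC and
   PS; the VKORC1 genotype limits the vitamin K available to the system
   (GA −22%, AA −44%) and the CYP2C9 genotype reduces warfarin clearance
   (*2 −30%, *3 −80%). Rivaroxaban reversibly scales factor-Xa activity.
2. **In vitro** — the trough plasma state is handed to a closed-test-tube
   assay (seconds time base): PT adds 300 nM tissue factor; aPTT starts
   from the contact-activation split XIa = 0.148·XI(0), XI = 0.339·XI(0).
   Clot time is when the fibrin concentration–time AUC reaches 1500 nM·s,
   and INR = (PT_test/PT_standard)^ISI with ISI = 1.

Virtual populations sample genotypes at configurable frequencies and apply
20% log-normal inter-individual variability to designated factor
production rates and to the PK parameters. No residual error is added.

## The parameter table

All science lives in data: the network (species, turnover rates, reaction
constants), drug-action parameters, and PK defaults are defined in a
versioned TSV (`src/coagsim/data/default_network.tsv`, version
`coagsim-default-1.0`). The source publication reports a 56-compartment
model but prints neither the roster nor any rate constants, so the shipped
table is a documented reconstruction (33 species, 24 reactions) covering
the extrinsic, intrinsic and common pathways, the vitamin K cycle and
PC/PS, calibrated so that drug-free PT ≈ 11.8 s, drug-free aPTT ≈ 29.6 s,
the clot criterion corresponds to a ≈30% fibrinogen reduction in normal
plasma, and the population endpoint means land on their reported values.
Substitute your own table with the `table:` key of the run config;
`scripts/generate_default_table.py` regenerates the shipped one from its
calibration knobs.

## Command line

```sh
coagsim validate-table                  # check the shipped table, report PT/aPTT
coagsim run examples/example_config.yaml
coagsim summarize coagsim_out/results.csv --by-genotype
coagsim compare coagsim_out/results.csv observed.csv
```

`run` writes `results.csv` (patient_id, drug, dose_mg, cyp2c9, vkorc1,
endpoint, value, censored, failed), boxplot-style summaries
(median/quartiles/1.5·IQR whiskers), a genotype-stratified summary and a
log recording table version, seed and solver tolerances. Runs are
byte-deterministic for a fixed (config, seed, table version). The
observed-data CSV for `compare` uses columns
(patient_id, drug, dose_mg, cyp2c9, vkorc1, endpoint, value).

## Python API sketch

```python
from coagsim import (AssayConfig, DoseRegimen, PopulationSpec,
                     calibrate_standard, default_network, run_scenario)

net = default_network()
assay = calibrate_standard(net, AssayConfig())
spec = PopulationSpec(n=100, seed=1)
results = run_scenario(spec, DoseRegimen("warfarin", 5.0), assay, net)
```

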