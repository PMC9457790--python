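# nrfopart

Partitioning Fe(II) oxidation during nitrate-reducing Fe(II) oxidation
(NRFO) into its **enzymatic** and **chemodenitrification** contributions,
with a kinetic forward simulator for validating the estimator by parameter
recovery.

## The problem

In anoxic incubations of nitrate-reducing bacteria with Fe(II) and nitrate,
iron is oxidized by two entangled routes:

```
NO3- + 2 Fe2+ + 2 H+   ->  2 Fe3+ + NO2- + H2O          (enzymatic NRFO)
2 NO2- + 4 Fe2+ + 6 H+ ->  N2O + 4 Fe3+ + 3 H2O         (chemodenitrification)
```

The nitrite fueling the abiotic reaction is itself produced microbially, so
the observed Fe(II) drawdown alone cannot separate the two.  The
paired-control (delta-nitrate) mass balance can: running a companion setup
*without* Fe(II) (where reduction is fueled only by endogenous carbon
reserves) isolates the Fe-driven share of nitrate reduction,

```
ΔNO3 = NO3 consumed (with Fe) − NO3 consumed (without Fe)
enzymatic Fe = 2 · ΔNO3                     (2 Fe2+ per NO3-)
abiotic Fe   = total Fe oxidized − enzymatic Fe
```

with a built-in consistency check from the chemodenitrification N2O yield
(1 N2O per 4 Fe2+).  This package implements that estimator as a tested
pipeline — plus a seeded ODE model of the incubation (Monod kinetics,
endogenous-carbon limitation, encrustation-driven metabolic shutdown) so
the estimator's bias can be measured against known ground truths, including
scenarios that deliberately violate the paired-control assumption.

Intended users: biogeochemists and environmental microbiologists analysing
paired NRFO incubations, and method developers probing when the
delta-nitrate attribution is trustworthy.

## Worked example

The built-in demo reconstructs a published end-point mass balance for four
*Enterobacter* strains from its printed inputs (nitrate consumed
1.08–1.61 mM with Fe(II), 0.67–1.06 mM without, 3.80 mM total Fe(II)
oxidized) and runs the full estimator on both range endpoints:

```sh
$ nrfopart demo
quantity                            low endpoint  high endpoint
---------------------------------------------------------------
NO3- consumed with Fe(II) [mM]              1.08           1.61
NO3- consumed without Fe(II) [mM]           0.67           1.06
Fe-coupled delta NO3- [mM]                  0.41           0.55
enzymatic Fe(II) oxidized [mM]              0.82           1.10
total Fe(II) oxidized [mM]                  3.80           3.80
abiotic Fe(II) oxidized [mM]                2.98           2.70
enzymatic fraction [%]                        22             29
abiotic fraction [%]                          78             71
Fe-driven NO3- fraction [%]                   38             34
predicted chem N2O [mM]                     0.74           0.68
```

Reading: of the 3.80 mM Fe(II) oxidized, only 22–29% was coupled to
microbial nitrate reduction; the remaining 71–78% was oxidized abiotically
by biogenic nitrite, which predicts a 0.68–0.75 mM N2O excess in the
Fe-amended setups.

The same pipeline runs on your own data:

```sh
nrfopart simulate --out sim/ --seed 1          # or bring your own CSVs
nrfopart partition --with-fe sim/with_fe.csv --no-fe sim/no_fe.csv \
    --bootstrap 1000 --seed 1 --out est.json
nrfopart recover --reps 50 --seed 1 --out report.csv
```

Time courses are long-format CSV
(`setup_id,strain,replicate,time_h,analyte,value,unit`, analytes
Fe2/NO3/NO2/N2O, values in mM).  See `docs/methods.md` for the model, the
default parameter preset and its calibration, and known limitations.

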