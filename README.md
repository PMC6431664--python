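# memprobe

Membrane-probe analytics for small-molecule / lipid-bilayer interaction
studies. The package reduces three kinds of raw data to the quantities a
membrane-biophysics lab actually compares:

* **Fluorometry** — laurdan generalized polarization
  GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀) versus temperature, with sigmoidal
  melting-curve fitting for the main transition temperature Tm; and DPH
  fluorescence anisotropy r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) with the
  per-sample G-factor G = I_HV/I_HH.
* **Isothermal titration calorimetry** — fits cumulative heats of a
  lipid-into-solute titration to the partition isotherm
  Σδh = ΔH·V_cell·C_A⁰·K·C_L⁰/(1 + K·C_L⁰), with explicit handling of
  injection-volume dilution and the discarded priming injection, then
  decomposes ΔG = −RT·ln(55.5·K) and TΔS = ΔH − ΔG.
* **Bilayer structural observables** — per-carbon deuterium order
  parameters −S_CD with tetrahedral united-atom H reconstruction, atomic
  group z-profiles |z − z_COM|, and P–P bilayer thickness, from GRO-style
  coordinate frames or a simple multi-frame XYZ dialect with a JSON
  topology sidecar.

A seeded synthetic-data module generates inputs for every stage (melting
curves, polarized intensity quadruplets, thermograms, bead-chain bilayer
frames with tunable order), each constructed to be the exact inverse of
its analysis in the noiseless limit. See `docs/methods.md` for models,
conventions and limitations.

## Worked example

Simulate a titration of lipid vesicles into a sarmentine-like solute
(K = 1.69 mM⁻¹, ΔH = 1.47 kJ/mol, 75 µM solute, 5 mM lipid syringe,
2 µL + 28×10 µL schedule, 2 % heat noise) and fit it back:

```python
from memprobe import itc_partition as itc, synthetic_data as syn

exp = syn.gen_itc_thermogram(syn.ITCSpec(seed=42, K_mM=1.69, dH_kJ_mol=1.47,
                                         C_A0_uM=75.0, noise_sd=0.02))
fit = itc.fit_partition(exp)
th = itc.derive_thermodynamics(fit.K_mM, fit.dH_kJ_mol, exp.temperature_K)
print(f"K   = {fit.K_mM:.3f} +/- {fit.K_se:.3f} mM^-1")
print(f"dH  = {fit.dH_kJ_mol:.3f} +/- {fit.dH_se:.3f} kJ/mol")
print(f"dG  = {th.dG_kJ_mol:.2f} kJ/mol")
print(f"TdS = {th.TdS_kJ_mol:.2f} kJ/mol")
```

prints

```
K   = 1.671 +/- 0.004 mM^-1
dH  = 1.473 +/- 0.002 kJ/mol
dG  = -28.45 kJ/mol
TdS = 29.92 kJ/mol
```

The fitted partition constant and enthalpy recover the generator truth
within the injected noise; ΔG < 0 with |TΔS| ≫ |ΔH| says the transfer
into the bilayer is spontaneous and entropy-driven — the classical
hydrophobic-effect signature for an alkyl-tailed solute.

The same stages are available from the shell:

```bash
memprobe simulate itc --seed 4 --out demo/
memprobe itc-fit --config demo/itc_config.yaml --heats demo/heats.csv --out demo/fit.json
memprobe gp --in plate.csv --out gp.csv --tm-report tm.json
memprobe order --traj frames.gro --topo topology.json --chain palmitoyl --out order.csv
memprobe zprofile --traj frames.gro --topo topology.json --groups P,glycerol,polar --out z.csv
memprobe run --config run.yaml          # multi-stage pipeline with provenance
```

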