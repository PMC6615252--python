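# cspfit

Analysis of NMR chemical-shift-perturbation (CSP) titrations of
protein–peptide interactions: weighted CSP computation from HSQC peak
lists, per-residue dissociation-constant fitting under a 1:1
fast-exchange binding model with ligand depletion, differential CSP
comparison between protein constructs (e.g. a single domain versus the
same domain inside a tandem construct), ambiguous-interaction-restraint
(AIR) generation for data-guided docking, and mapping of CSP values onto
structures for visualisation.

The package was built around the binding behaviour of PDZ domains — the
second and third PDZ domains of the scaffolding phosphatase PTPN13
titrated with C-terminal peptides of APC and PRK2 — but every stage is
generic for weak (high-μM to mM K_D) 1:1 interactions followed by
¹H-¹⁵N HSQC titration.

## The model

In the fast-exchange regime an amide peak sits at the population-weighted
average of its free and bound positions, so its weighted perturbation at
ligand concentration L is

    Δδ_obs(L) = Δδ_max · f_b(P, L, K_D),
    Δδ_obs    = sqrt( Δδ(¹H_N)² + (Δδ(¹⁵N)/5)² )

with the bound fraction from exact mass balance in total concentrations
(ligand depletion is not negligible when K_D is comparable to the protein
concentration P):

    f_b = ((P + L + K_D) − sqrt((P + L + K_D)² − 4·P·L)) / (2·P)

Each significantly perturbed residue is fitted independently for
(K_D, Δδ_max) by bounded nonlinear least squares; the reported affinity is
the mean of the per-residue K_D estimates and its error is their sample
standard deviation. A partial-saturation flag marks titrations whose
endpoint bound fraction stays below 0.8 — very weak binders whose K_D is
correspondingly less well determined.

Raw titration peak lists for this class of experiment are rarely
deposited, so the package ships a synthetic titration generator
(`cspfit.synthetic`) that produces HSQC series with the structure the
analysis assumes — per-residue amplitudes with random signs, Gaussian
peak-position noise, missing prolines, partial-saturation designs — and
records the generating truth for parameter-recovery validation.

## Worked example

```python
import cspfit as cf

spec = cf.pdz_scenarios(seed=7)["pdz2_apc"]     # K_D truth: 286 uM
series, truth = cf.generate_series(spec)        # 7-point titration, 1:0 .. 1:30
model = cf.TitrationModel(series)               # quadratic isotherm, N-scale 5
results = model.fit()                           # mean + 1 SD residue selection
print(results.summary())
```

```
1:1 fast-exchange titration fit
================================================================
protein: PDZ2   ligand: KRHSGSYLVTSV
protein conc: 0.25 mM   points: 7   model: quadratic   N-scale: 5
----------------------------------------------------------------
 residue     K_D [uM]  dmax [ppm]  f_b(end)  conv
       4        263.4      0.2274     0.965  True
       9        292.4      0.2981     0.961  True
      22        288.8      0.2235     0.962  True
      42        322.4      0.2177     0.957  True
      49        284.6      0.2101     0.962  True
      64        281.9      0.3238     0.963  True
----------------------------------------------------------------
K_D = 289 ± 19 uM (n = 6 residues)
```

Six residues were selected by the endpoint-CSP threshold rule and fitted
independently; each row shows the per-residue dissociation constant, the
saturation amplitude of the weighted CSP, and the fraction of protein
bound at the final titration point. The aggregate line is the mean ± the
spread of the per-residue estimates — here recovering the generating
K_D of 286 μM within the noise (peak-position σ of 0.002 ppm in ¹H).

The same pipeline is scriptable from a shell:

```bash
cspfit simulate --scenario pdz2_apc --seed 7 --out dataset/
cspfit fit --manifest dataset/manifest.yaml --out fit/
cspfit diff --table-a single.csv --table-b tandem.csv --exclude G23 --out diff/
cspfit restraints --active-a T14,F15,E16,E18,N70,H94,L95 \
                  --active-b E17,V18,K19,L20,S98,L100 --out air.tbl
cspfit mass MFRDFDYIADWC          # -> 1580.64
```

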