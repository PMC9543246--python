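# mmnet

ODE modeling of the IRF4–MYC–PRDM1 regulatory network in multiple myeloma
(MM).

MM plasma cells are "addicted" to the transcription factor IRF4, which sits
in a mutual positive feedback loop with the oncogene MYC: MYC transactivates
*IRF4*, IRF4 transactivates *MYC* and its own promoter, and IRF4's target
PRDM1 (BLIMP1) represses *MYC* transcription. Drugs such as BET and
CBP/EP300 bromodomain inhibitors act on this axis by suppressing
transcription of MYC, IRF4, or both. `mmnet` is for systems biologists and
pharmacologists who want to simulate such perturbations, test which
drug-target hypothesis best explains measured mRNA/protein time courses, and
estimate protein half-lives from cycloheximide-chase experiments.

## The model

Each species X ∈ {MYC, IRF4, PRDM1} carries an mRNA and a protein variable
in dimensionless fold units, with two-stage kinetics:

```
d[mRNA_X]/dt    = k_m,X · drug_X(t) · Π_e g_e(protein_source(e)) − γ_m,X · mRNA_X
d[protein_X]/dt = k_p,X · mRNA_X − γ_p,X · protein_X
```

Degradation rates derive from half-lives, γ = ln2 / t<sub>½</sub>, and the
synthesis constants are fixed by the fold-change normalization
(k_m = γ_m, k_p = γ_p), so the unperturbed steady state is exactly 1 for
every variable. Regulatory edges enter as Hill-type multiplicative factors
g(x) on the target's transcription rate, each normalized so g(1) = 1 (with
defaults K = 1, h = 1, w = 2: activation g(x) = 2x/(1+x), repression
g(x) = 2/(1+x)). A drug multiplies targeted transcription by (1 − ε) from
its onset time. A cycloheximide chase sets all translation rates to zero,
so every protein decays as exp(−γ_p t) and its half-life can be recovered
by ordinary least squares of ln(signal) on time.

Model–data agreement is scored the same way the readouts are plotted: each
replicate series is divided by its own first timepoint (fold change), and
the per-timepoint squared distance (model − mean data)² is summed per
species/analyte and over the whole dataset to rank the three drug-target
scenarios (MYC, IRF4, MYC+IRF4).

Protein half-life presets (hours unless noted): `initial_model`
(MYC 30 min, IRF4 7), `updated_model` (IRF4 48), and per cell line
`KMS-12-BM` (IRF4 61, MYC 1 h), `NCI-H929` (IRF4 52, MYC 22 min),
`SKMM-1` (IRF4 33, MYC 30 min).

The package also ships a four-parameter-logistic (4PL) dose–response
fitter for IC50 extraction from viability tables, and a synthetic-data
module that generates treatment time courses (6 timepoints, 3 replicates,
multiplicative lognormal noise), chase decay series, and 4PL viability
curves for fully reproducible end-to-end testing.

## Worked example

```python
import numpy as np
from mmnet import (build_parameters, DrugPerturbation, simulate, simulate_chase,
                   estimate_half_life, gen_treatment_dataset, NoiseModel,
                   compare_scenarios)

params = build_parameters("updated_model")

# a drug blocking 80% of MYC transcription from t = 0
traj = simulate(params, DrugPerturbation.myc(0.8), t_max=72)
print(traj.at([0, 4, 8, 24, 48, 72]))

# in-silico cycloheximide chase -> half-life estimate
grid = np.array([0, 8, 24, 48, 72.0])
chase = simulate_chase(params, time_grid=grid)
est = estimate_half_life(grid, chase.series("IRF4", "protein"))
print(f"IRF4 half-life: {est.t_half_h:.1f} h (R^2 = {est.r_squared:.3f})")

# which drug-target hypothesis explains a (here: synthetic) dataset best?
ds = gen_treatment_dataset(params, DrugPerturbation.myc(0.8),
                           NoiseModel(cv=0.1, n_replicates=3, seed=1))
for r in compare_scenarios(params, ds):
    print(f"scenario {r.scenario:9s} total squared distance = {r.grand_total:.4f}")
```

This prints:

```
t(h)  MYC_mRNA  MYC_prot  IRF4_prot  PRDM1_mRNA
   0     1.000     1.000      1.000       1.000
   4     0.203     0.220      0.992       0.999
   8     0.197     0.198      0.965       0.991
  24     0.186     0.186      0.833       0.922
  48     0.173     0.173      0.667       0.813
  72     0.160     0.160      0.535       0.709

IRF4 half-life from chase: 48.0 h (R^2 = 1.000)
scenario MYC       total squared distance = 0.0309
scenario MYC+IRF4  total squared distance = 0.3348
scenario IRF4      total squared distance = 5.0132
```

MYC mRNA and protein collapse within hours of a MYC-transcription hit while
IRF4 protein declines only slowly — the long IRF4 half-life buffers it
against the loss of its activator — and scoring the three scenarios against
data generated under the MYC hit correctly ranks the MYC-only hypothesis
first.

The same workflows are available from the shell:

```sh
mmnet simulate --preset updated_model --drug myc --epsilon 0.8 --tmax 72 --out traj.csv
mmnet chase --preset KMS-12-BM --out chase.csv
mmnet gen-data chase --preset KMS-12-BM --cv 0 --out chase_tbl.csv
mmnet fit-halflife chase_tbl.csv --species IRF4 --out halflife.json
mmnet compare --data dataset.csv --preset updated_model --epsilon 0.8 --out report.json
mmnet fit-ic50 viability.csv --out ic50.csv
```

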