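# vulquant

Quantification pipeline for *C. elegans* vulval-induction imaging studies:
anchor-cell (AC) ligand polarity, AC-to-P6.p alignment, ERK biosensor
activity in the vulval precursor cells (VPCs), and vulval induction
statistics — with a synthetic-data generator that makes every stage
testable against known ground truth, without raw microscopy data.

## The problem

During vulval induction the AC secretes the EGF-like ligand LIN-3 toward
the six VPCs P3.p–P8.p; P6.p, the nearest VPC, receives the most ligand
and adopts the primary (1°) fate. Studies of this system quantify:

- **Dorso-ventral polarity index**
  `I_DV = mean ventral intensity / mean dorsal intensity`,
  measured on a summed z-projection of the AC after thresholding away
  non-AC pixels, with the halves split by a line through the AC nucleus
  centre. `I_DV > 1` means ventral enrichment (toward the VPCs).
- **AP polarity index** `I_AP`, analogous, with the halves proximal and
  distal to the nearest VPC.
- **Alignment index** `R = d(AC, P6.p) / d(P6.p, P5.p or P7.p)` — the
  AC-to-target distance normalized by the distance to the flanking
  reference VPC on the AC's side. `R = 0` means perfect alignment.
- **ERK-KTR biosensor activity** per VPC: the nuclear
  `mCherry::H2B / ERK-nKTR::mClover` (red/green) mean-intensity ratio in a
  summed projection of the five central slices, normalized per animal to
  the P4.p–P8.p mean (higher ratio = higher MPK-1/ERK activity).
- **Vulval induction index** `VI = total induced VPCs / animals scored`
  (3 in the wild type; `VI > 3` hyperinduced, `VI < 3` hypo-induced),
  with bootstrap SEM and 95% CI (10,000 resamples), and a battery of
  Welch/Student t, Mann–Whitney, F and Fisher exact tests.

`vulquant` implements this pipeline as a library plus a thin CLI, and
pairs it with generators for polarized ellipsoidal AC stacks, two-channel
biosensor nuclei rows, annotated animal geometries and scored cohorts, so
each measurement can be validated against the parameters that produced
the data.

## Worked example

```python
from vulquant import synthgen, polarity, geometry, stats

# A polarized AC with true ventral/dorsal ratio 1.5 at default SNR
params = synthgen.ACStackParams(rho_dv=1.5, rho_ap=1.2, seed=7)
stack, truth = synthgen.generate_ac_stack(params)
result = polarity.measure_polarity_stack(stack, params.ac_center)
print(f"true I_DV = {truth.i_dv:.3f}, measured I_DV = {result.i_dv:.3f}")
print(f"true I_AP = {truth.i_ap:.3f}, measured I_AP = {result.i_ap:.3f}")

# AC displaced 20 px anterior of P6.p
animal = synthgen.generate_animal(
    layout_params=synthgen.LayoutParams(ac_dx_px=-20.0), seed=7)
res = geometry.alignment_index(animal)
print(f"R = {res.r_index:.3f} ({geometry.classify_alignment(res)})")

# A mixed cohort: 80% wild-type, 20% hyperinduced
cohort = synthgen.generate_induction_cohort(synthgen.CohortParams(
    n_animals=60,
    fate_pattern_probs={"wild-type": 0.8, "hyperinduced": 0.2}, seed=7))
ic = stats.InductionCohort([
    stats.InductionRecord(a.animal_id, a.genotype, a.induced_count)
    for a in cohort])
boot = stats.bootstrap_mean(ic.counts, seed=7)
print(f"VI = {stats.vulval_index(ic):.3f}, sem = {boot.sem:.3f}, "
      f"95% CI = ({boot.ci95[0]:.3f}, {boot.ci95[1]:.3f})")
```

prints

```
true I_DV = 1.496, measured I_DV = 1.496
true I_AP = 1.190, measured I_AP = 1.193
R = 0.260 (pre-aligned)
VI = 3.258, sem = 0.074, 95% CI = (3.125, 3.417)
```

The measured polarity indices match the noiseless ground truth of the
generated stack (the random punctae shift the true ratio slightly off the
requested 1.5); the AC 20 px anterior of P6.p gives `R = 20/77 ≈ 0.26`,
past the `R > 0.09` pre-alignment boundary but below the `R > 0.4`
misalignment threshold; and the 20% hyperinduced admixture lifts the VI
above the wild-type value of 3.

The same pipeline is available from the shell:

```sh
vulquant all --n 20 --seed 1 --rho-dv 1.5 --outdir run1
```

which simulates a cohort, writes TIFF stacks with annotation sidecars,
and produces tidy `polarity.csv`, `alignment.csv` and `induction.csv`
tables plus run metadata with a config hash and all seeds.

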