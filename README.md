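# tgdrive

Quantitative machinery for **CRISPR homing gene drives**, both *full* drives
(Cas9 + gRNAs inserted as one element at the target locus) and
*trans-complementing* (split) drives, where a Cas9 transgene and a tandem-gRNA
transgene sit at two separate loci and each element copies itself only when
both are present in the same individual.

The package provides, as one consistent genetic engine:

* **Inheritance cubes** — for every (maternal genotype, paternal genotype)
  pair, the exact distribution over offspring genotype and sex, for six
  architectures: `full_GD`, `full_GDX`, `tGD_linked`, `tGDc`, `tGDX_linked`,
  `tGDXc` (autosomal / X-linked, linked / freely recombining).
* **A fly cross-outcome model** — F0 → F1 → F2 single-germline crosses with a
  two-phase cleavage-timing structure (zygotic maternal deposition vs late
  germline conversion), clonal pole-cell structure, and categorical
  resistant-allele (indel) identities.
* **Randomization statistics** — permutation tests for differences in means
  and in proportions, and the over/on/under-midline classification of paired
  inheritance rates.
* **A stochastic mosquito population model** — single-patch, daily-time-step,
  genotype-resolved stage-structured *Aedes aegypti* dynamics (egg, larva,
  pupa, adult; females mate once on emergence and store the mate's genotype),
  driven by the same inheritance cubes, for population replacement and
  suppression release scenarios.

## The model in brief

Each allele at a drive locus is in one of four states: `W` wild type, `T`
transgene, `R` in-frame (functional) resistant, `B` out-of-frame resistant.
In a germline carrying both a Cas9 source and a gRNA source, each wild-type
allele whose homolog carries the transgene is cleaved with probability *q*
and, given cleavage, converted (homing via homology-directed repair) with
probability *c*; failed conversions are repaired by end joining to `R` with
probability *ρ*, else to `B`.  A heterozygous parent therefore transmits the
transgene at rate

&nbsp;&nbsp;&nbsp;&nbsp;(1 + *q·c*) / 2,

so *q = c = 1* gives 100% transmission and *q* = 0 recovers Mendel's 50%.
Mothers carrying both components additionally deposit Cas9/gRNA into the egg:
each zygotic `W` allele is cleaved with probability *d* and repaired by end
joining **only** — deposition creates resistant alleles, never conversions,
which is why a drive inherited from a double-carrier mother collapses to ~50%
transmission with a single clonal indel per germline.

The population model follows the MGDrivE-style framework: daily time step,
stage durations *T<sub>E</sub>*, *T<sub>L</sub>*, *T<sub>P</sub>*, adult
mortality *μ<sub>M</sub>*, fecundity *β* per female per day, juvenile
mortality *μ<sub>J</sub>* calibrated to the daily growth rate *r*, and
Deredec-style density-dependent larval survival
(*α*/(*α*+*L*))<sup>1/*T<sub>L</sub>*</sup> calibrated so the deterministic
equilibrium holds *N* adults.  Defaults: *β* = 20, *T<sub>E</sub>* = 5,
*T<sub>L</sub>* = 6, *T<sub>P</sub>* = 4, *r* = 1.175, *μ<sub>M</sub>* = 0.090,
*N* = 10,000.

## Worked example

```python
import tgdrive as tg

# exact transmission from a trans-heterozygous female, q=1, c=0.9
cube = tg.build_cube("tGDX_linked", tg.CubeParams(q=1.0, c=0.9))
mother = tg.genotype_from_str("TA-WB/WA-TB|F", cube.architecture)
father = tg.genotype_from_str("WA-WB/Y|M", cube.architecture)
tg.transmission_rate(cube, mother, father, "T@A")   # 0.95  == (1 + 0.9)/2

# simulate 11 single-female vials of 50 scored F2 flies
scheme = tg.CrossScheme("father", "mother", False, "female", "tGDX_linked")
timing = tg.GermlineTimingParams(z=0.0, k=3, q_late=1.0, c_late=0.9,
                                 rho=1.0, spectra=tg.default_spectra())
table = tg.simulate_cross(scheme, timing=timing, n_vials=11,
                          n_offspring_per_vial=50, seed=1)
s = tg.inheritance_summary(table, "gfp")
print(s.mean, s.sd, s.n_vials, s.total_flies)
# 0.945 0.097 11 550          <- per-vial mean inheritance of the gRNA marker

fit = tg.fit_conversion(table, marker="gfp", n_boot=2000, seed=0)
print(fit.estimate["qc"], fit.ci["qc"])
# 0.891 (0.771, 1.0)          <- recovered q*c, 95% bootstrap CI over vials
```

The marker mean of 0.945 is the per-vial average (vials are averaged, not
flies) of the GFP-positive fraction; the fitted `q*c` of 0.89 recovers the
generating conversion efficiency 0.9 with the true value inside the CI.

A suppression release experiment at field scale (drive disrupts a gene
required in one copy for female fertility):

```python
df = tg.suppression_experiment(conversions=(1.0,), systems=("full_GD",),
                               replicates=10, seed=1, horizon=1095)
df["crash_day"].max()   # 542  -> adult females extinct 1.48 y after release
```

## Command line

`tgdrive` exposes `build-cube`, `simulate-cross`, `summarize`, `fit`,
`randtest`, `run-pop`, `experiment` and `make-fixtures`.  Every stochastic
subcommand takes `--seed` and prints it; validation failures exit with
code 2.  `run-pop` reads a JSON config, e.g.

```json
{
  "architecture": "full_GD",
  "cube_params": {"q": 1.0, "c": 0.95},
  "life_history": {"N": 10000},
  "sim_mode": "stochastic",
  "replicates": 10,
  "seed": 1,
  "horizon": 730,
  "burn_in": 50
}
```

Unknown keys are rejected.  Scoring tables are CSV with header
`experiment,vial,sex,dsred,gfp,body,eye,count,indel`;
`tgdrive.io.read_supplementary_xlsx` imports single-sheet spreadsheet exports
of per-vial scoring workbooks after a documented column mapping.

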