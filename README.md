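# equiloc

Bi-objective, capacitated location-allocation of drug-abuse **prevention**
and **mitigation** centers across a municipality network, for public-health
planners and operations-research analysts who need to decide *where to open
centers*, *how large to fund them*, and *which towns each center serves*
under fixed budgets — while trading off consumption **risk** against
geographic **equity**.

## The model

Each municipality *i* carries a composite risk index per intervention
*k* ∈ {1 = prevention, 2 = mitigation}

```
R¹_i = (α_i + ψ_i + γ_i) / 3        R²_i = R¹_i / 2
```

where α_i is the town's share of estimated substance consumers, ψ_i its
share of negative social-media posts about drug use, and γ_i its share of
crime incidents; and an equity index built multiplicatively from the
multidimensional poverty index and the rurality proportion

```
σ¹_i = RP_i · MPI_i                 σ²_i = σ¹_i / 2
```

The integer program decides patient flows Y^k_ij, funded capacity hours
C^k_j, and binary openings X_j, maximizing either

```
OF1 = δ Σ R^k_i Y^k_ij + (1−δ) Σ (−d_ij / D_max) Y^k_ij      (risk + proximity)
OF2 = π Σ σ^k_i Y^k_ij + (1−π) Σ (−d_ij / D_max) Y^k_ij      (equity + proximity)
```

subject to demand caps, per-intervention budgets (hourly cost F^k), a
minimum viable center size R_min, service-time capacity (L^k hours per
patient), big-M opening links, and a minimum-care floor of φ patients per
town. The Pareto frontier between OF1 and OF2 is traced with the
ε-constraint method, and the recommended compromise is the frontier point
nearest the ideal point in z-score-standardized objective space (the
"knee"). A population-ranked greedy heuristic provides the conventional
comparison baseline. Solving is exact branch-and-bound (HiGHS via
`scipy.optimize.milp`, relative gap 1e-4), and every solution is re-verified
against all constraints independently of the solver.

## Worked example

```python
from equiloc import (build_and_solve, coverage_report, epsilon_sweep,
                     population_heuristic)
from equiloc.synth import GeneratorConfig, generate_instance

profiles, inst = generate_instance(GeneratorConfig(seed=3, n_nodes=8))
s1 = build_and_solve(inst, "of1")          # risk-only optimum
front = epsilon_sweep(inst, n_points=8)    # Pareto frontier + knee
knee = front.knee_point
heur = population_heuristic(inst, profiles)
cov = coverage_report(inst, knee.solution, radius_km=40.0)
```

prints (via the formatting in the docstring example):

```
risk-only optimum:       OF1 = 1768.80, OF2 = 12.70, open sites = ['m00']
ideal point:             (1768.80, 261.13)
knee (best trade-off):   OF1 = 1187.41, OF2 = 190.16, open sites = ['m00']
population baseline:     OF1 = 1760.30, OF2 = 16.64, open sites = ['m00']
coverage within 40 km:   knee 23.37%  vs baseline 6.65%
```

Read it as: maximizing risk coverage alone and the population-ranked
baseline both concentrate service at the dominant city (`m00`), scoring
high on OF1 but poorly on equity; the knee solution gives up about a third
of OF1 to multiply the equity objective fifteen-fold, and more than triples
the share of demand served within a 40 km drive (23.37% vs 6.65%).

The same pipeline is scriptable from a shell:

```
equiloc synth  --config config.yaml --out out/
equiloc solve  --config config.yaml --out out/ --objective of1
equiloc pareto --config config.yaml --out out/ --n-points 20
equiloc report --config config.yaml --out out/
```

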