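# ifcr

Cross-ratio intuitionistic fuzzy values for multicriteria decision analysis.

An intuitionistic fuzzy value (IFV) is a pair `(membership, nonmembership)`
of degrees in the open unit interval with `membership + nonmembership <= 1`.
This package implements an algebra on such values in which **both**
components are handled through the odds (cross-ratio) transform
`x -> x / (1 - x)`:

* `oplus`, `otimes`, `scalar_mul`, `power` — addition, multiplication
  (the representable uninorm `xy / (xy + (1-x)(1-y))`, neutral element 0.5),
  scaling and powering, all linear or multiplicative in odds space;
* score / accuracy / hesitation functions and a two-stage comparison
  (score first, accuracy as tie-break);
* `icrwg` / `icrwgm` — the weighted geometric aggregation operator
  (componentwise weighted geometric mean of odds), plus two published
  baseline aggregators (`ifcr.aggregation.baseline`) kept for comparison;
* a bounded bipolar 0.1–0.9 rating scale with the classical 1–9 ratio-scale
  correspondence `r -> r/(1+r)`;
* intuitionistic preference relations (IPRs): validation (indifferent
  diagonal, complement-transposed reciprocity, rating band), row-wise local
  priorities, a seeded random generator, and a canonical text format;
* a two-level hierarchical decision procedure: per-criterion IPRs →
  decision matrix → weighted overall priorities → scores → ranking;
* an embedded reference case study (medical waste disposal method
  selection: 5 alternatives, 3 weighted criteria).

## CLI

```sh
ifcr demo mwdms                      # run the embedded case study
ifcr rank --problem problem.yaml [--score-variant geometric|eq4] [--format json|text]
ifcr validate matrix.ipr             # check an IPR file, exit 1 on violations
ifcr gen-ipr --n 5 --seed 42         # deterministic random valid IPR
ifcr scale convert --from saaty 3    # 1-9 scale <-> 0.1-0.9 scale
```

Problem files are YAML or JSON:

```yaml
alternatives: [x1, x2]
criteria:
  - {name: cost, weight: 0.6}
  - {name: risk, weight: 0.4}
relations:
  cost:
    - ["(0.5, 0.5)", "(5/8, 1/5)"]
    - ["(1/5, 5/8)", "(0.5, 0.5)"]
  risk:
    - ["(0.5, 0.5)", "(3/4, 1/8)"]
    - ["(1/8, 3/4)", "(0.5, 0.5)"]
```

Cell components may be decimals or exact fractions. JSON reports carry full
precision plus a 4-decimal `display` view under a versioned schema.

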