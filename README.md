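# fuzzcomfa

Multi-endpoint 3D-QSAR for drug safety design: fuzzy comprehensive
evaluation of adverse-drug-reaction (ADR) endpoints, CoMFA-style molecular
interaction fields with PLS regression, and the downstream derivative
design, environmental screening and risk arithmetic.

## The problem

Fluoroquinolone antibiotics share three common adverse reactions —
convulsive, gastrointestinal and cardiac toxicity — each of which can be
scored per compound (here by docking against the GABA receptor,
cyclooxygenase and the hERG channel). Classical QSAR models one endpoint at
a time. This package instead collapses the endpoint panel into a single
**comprehensive evaluation index (CEI)** with a weighted fuzzy membership
model and regresses *that* index against 3D molecular fields, so one model
captures the joint ADR burden and can steer substituent design toward
safer analogues.

## The model

**Fuzzy comprehensive evaluation.** For endpoint *i* and compound *j* with
raw score *c<sub>ij</sub>*, the large-scale membership function is the
per-endpoint min–max normalization

> r<sub>ij</sub> = (c<sub>ij</sub> − min<sub>j</sub> c<sub>ij</sub>) /
> (max<sub>j</sub> c<sub>ij</sub> − min<sub>j</sub> c<sub>ij</sub>)

and with endpoint weights **A** = (a₁, …, a<sub>m</sub>), Σaᵢ = 1 (here
0.50/0.40/0.10 by ADR incidence), the index is the weighted average
**C** = **A**·**R**, i.e. CEI<sub>j</sub> = Σᵢ aᵢ r<sub>ij</sub> ∈ [0, 1].

**Field/PLS engine.** Aligned molecules with partial charges are probed on
a shared lattice (2.0 Å spacing, 4.0 Å margin) by an sp³-carbon probe:
Lennard-Jones 6–12 steric energies truncated at +30 kcal/mol and Coulomb
electrostatic energies with distance-dependent dielectric ε(r) = r,
|E| ≤ 30 kcal/mol. Flattened, filtered and block-scaled lattice energies
form the design matrix for NIPALS PLS, validated by leave-one-out q²,
SEE/F, external Q²<sub>ext</sub>/r²<sub>pred</sub>/SEP, progressive
Y-scrambling (cSDEP, dq²/dr²yy′) and per-field contribution percentages.
stdev·coeff contour grids (80/20 favored/disfavored levels) export to
OpenDX for 3D viewers.

**Downstream arithmetic.** Substituent enumeration at two ring positions
(6 + 6 groups → 48 derivatives), CEI prediction and ranking; a three-stage
persistent-organic-pollutant screen on genotoxicity (pLOEC), photo-
degradability (log t½) and bioconcentration (log K<sub>ow</sub>);
single-factor consistency validation; EPA-style exposure dose (ADD),
hazard index (HI = ADD/RfD) and cancer risk (RI = ADD·SF); and substitution
thermochemistry (ΔG spontaneity, ΔE barrier ranking).

## Worked example

```python
import fuzzcomfa
from fuzzcomfa import fixtures

scores = fixtures.table1_fixture()[["3IP9", "3N8V", "2L0W"]]
result = fuzzcomfa.evaluate_table(scores, {"3IP9": 0.50, "3N8V": 0.40, "2L0W": 0.10})
print(result.loc[["Pazufloxacin", "Difloxacin", "Moxifloxacin"],
                 ["r_3IP9", "r_3N8V", "r_2L0W", "cei_display"]])
```

prints

```
                r_3IP9    r_3N8V    r_2L0W  cei_display
compound
Pazufloxacin  1.000000  0.862434  0.795963        0.925
Difloxacin    0.587841  0.924405  0.230799        0.687
Moxifloxacin  0.000000  0.269110  0.439943        0.152
```

Pazufloxacin tops every endpoint's membership and lands at CEI 0.925 — the
highest joint ADR burden of the 29-compound series, which is why it is the
derivatization template. The screening cascade then narrows its 48
derivatives:

```python
from fuzzcomfa.screening import pop_screen
res = pop_screen(fixtures.table5_fixture()[["ploec", "log_t_half", "log_kow"]])
print(res.cardinalities, res.stage3_bioconc)
# (28, 24, 3) ['Derivative-1', 'Derivative-2', 'Derivative-3']
```

i.e. the 1-methyl, 1-hydrogen and 1-ethyl analogues survive all three
environmental gates.

A command-line interface mirrors the library:
`fuzzcomfa cei`, `fields`, `screen`, `risk`, `thermo`, `synth`,
`fixtures` (see `fuzzcomfa --help`).

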