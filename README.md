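# lipidtraffic

**Lipid Traffic Analysis (LTA)** — network analysis of lipid metabolism
across tissue compartments.

Most lipidomics analyses compare one tissue at a time.  But lipids made in
the liver are distributed systemically — through the serum to the CNS
(structure), heart (fatty-acid oxidation) and adipose (storage) — so a
change in metabolism often shows up not as a change *within* a tissue but
as a change in *where* a lipid travels.  `lipidtraffic` is for lipidomics
practitioners who profile several compartments of the same organisms
(e.g. liver, serum, brain, heart, adipose in two phenotype groups) and
want to ask: which lipids moved, and which changed in amount?

## The method

Lipid variables (species at sum-composition resolution, e.g. `TG(52:5)`)
are first binarised per compartment: a variable is *present* when it has
signal > 0 in at least 50% of a group's samples.  On a star-shaped traffic
network (origin liver → hub serum → termini), each variable is categorised:

* **A** — present in *all* compartments;
* **B<sub>XY</sub>** — present at both endpoints of the axis X→Y (but not
  ubiquitous);
* **U** — present in one compartment and none of its neighbours.

**Switch Analysis.** For each axis the two phenotypes' variable lists
*X, Y* are compared with the Jaccard–Tanimoto coefficient
*J* = |X∩Y| / |X∪Y| and a p-value: the probability, when both lists are
redrawn as uniformly random subsets of X∪Y with the observed sizes, of a
*J* no larger than observed.  Variables that leave one hub axis in the
control group and appear on another hub axis in the experimental group are
reported as *re-routed*, with underground-map style routing diagrams
(DOT/GraphML).

**Abundance Analysis.** Per variable and compartment, the margin change
x̄_E − x̄_C is tested with a two-sample Student's t-test against a
dependent-variable-corrected threshold α/√N (N correlated lipid
variables; N = 586 at α = 0.05 gives 0.0021), and the effect size is the
error-normalised fold change

ENFC = log₁₀(x̄_E / x̄_C) / √((a² + b²)/2),

with *a*, *b* the group standard deviations.

Because multi-compartment lipidomics datasets are rarely public, the
package ships a seeded synthetic-data generator (`lipidtraffic.synthetic_data`)
that emulates the study design — two phenotypes, 6–8 samples per
compartment, several hundred log-normal lipid variables in per-mille
units — with plantable re-routings and fold changes recorded in a
ground-truth manifest.

## Worked example

Simulate an F1-neonate-shaped study (liver–serum–{brain, heart}) with one
planted re-route (`TG(52:2)` moved from the serum–heart axis to the
serum–brain axis in the experimental group) and one planted 10-fold liver
increase of `PC(34:1)`, then run both analysis strands:

```sh
lta simulate --preset F1N --seed 42 --n-samples 8 --dropout 0 \
    --reroute "TG(52:2)" SH SB --effect "PC(34:1)" liver 10 \
    --out sim --no-timestamp
lta report --input sim/dataset.csv --network F1N --out run --no-timestamp
```

The log prints, per axis, the variable counts for the two phenotypes with
*J* and *p*, and the abundance threshold actually applied:

```
INFO axis LS: 298:298 J=1 p=1
INFO axis SB: 293:294 J=0.997 p=1
INFO axis SH: 294:293 J=0.997 p=1
INFO corrected threshold: 0.002195 (sqrt over 519 variables, alpha 0.05)
INFO significant comparisons: 3
```

The SH and SB axes differ by exactly the moved variable (counts 294:293
and 293:294; *J* = 0.997 means 99.7% of the union is shared), and the
re-route is recovered programmatically:

```python
>>> import lipidtraffic as lt
>>> from lipidtraffic.dataset_io import read_table, signal_correct, detect_presence
>>> table = signal_correct(read_table("sim/dataset.csv"))
>>> net = lt.preset_network("F1N")
>>> report = lt.SwitchReport.build(detect_presence(table, net.nodes), net, "NP-NC", "LP-HC")
>>> sorted(lt.find_rerouted(report, "SH", "SB"))
['TG(52:2)']
```

In `run/abundance.csv` the planted effect is the top hit:

```
variable compartment  margin_change     t_pvalue     enfc  significant
PC(34:1)       liver       8.828378 4.966395e-07 0.484137         True
```

i.e. `PC(34:1)` gained 8.8 ‰ of total lipid signal in the experimental
livers, far below the 0.0022 threshold, with a positive ENFC (the fold
change is compressed on the per-mille scale because normalisation closes
the composition).  `run/` also contains the A/B/U categorisation, the
counts behind pie-chart summaries, the ENFC matrix for radar-style plots,
routing graphs and a `run_config.json` from which the run can be
reproduced byte-identically.

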