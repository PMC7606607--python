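# sibbn

Bayesian belief networks linking **sanitary-inspection (SI) data** to
**E. coli detection in household drinking water**.

In low- and middle-income settings, water quality is routinely assessed
through sanitary inspections — standardized observational checklists of
contamination risks at the water source (point of collection, POC) and in
the home (point of use, POU) — alongside microbial testing of stored
drinking water.  `sibbn` provides the modelling machinery to connect the
two: discrete belief networks whose structure follows the contamination
pathways (source water quality, household water treatment, storage
condition, surrounding hygiene), with cluster-summary nodes built from
additive SI risk scores, EM parameter learning that handles households
whose source was never sampled (an entire block of missing fields),
cross-validated AUC assessment, ΔP predictive inference to rank
influential nodes, and what-if scenario simulation.

The joint distribution factorizes by the chain rule,
P(x₁,…,x_d) = ∏ᵢ P(xᵢ | pa(xᵢ)), over categorical nodes.  Two intermediate
nodes carry deterministic CPTs derived from scored checklists: the storage
cluster (covered / uncracked / safely placed; totals 3, 2, 0–1 → low,
moderate, high chance of recontamination) and the environment–hygiene
cluster (six binary observations; totals 5–6, 3–4, 0–2 → low, moderate,
high).  Four structural variants are built in: model 1 conditions POC
water quality on the source type (piped/well/spring/river/other), model 2
on six well-SI observations; "B" variants add the storage-container
fullness level as an extra parent of the outcome.  The AUC is the
Mann–Whitney statistic P(s⁺ > s⁻) + ½P(tie).  A node's ΔP is the spread
(max − min) of the updated outcome probability across its states under
hard evidence.

Because field data of this kind are rarely deposited, the package includes
a fully specified synthetic generator (`sibbn.synthetic_data`) that
emulates the survey conditions — 328 households, 49 missing POC blocks,
published marginal frequencies, source-type-dependent contamination — so
the whole pipeline is testable end to end.  See `docs/methods.md` for the
model, defaults and limitations.

## Worked example

```python
import sibbn

bundle = sibbn.generate("1B", n=328, poc_missing=49, seed=7)
model  = sibbn.WaterQualityBBN(bundle.table.to_dataframe(), variant="1B")
res    = model.fit()

dp = res.delta_p()
print(f"baseline P(not_detected at POU) = {dp.baseline:.1f}%")
for node, val in dp.ranked()[:5]:
    print(f"  dP {node:<35} {val:5.1f}")

rep = model.cross_validate(k=10, seed=7)
print(rep.summary())
```

prints

```
baseline P(not_detected at POU) = 72.4%
  dP fullness_of_water_at_storage         21.5
  dP contamination_from_environment       21.2
  dP ecoli_poc                            20.2
  dP type_of_poc                          13.0
  dP contamination_from_storage           10.8
k-fold cross-validation: AUC = 0.621 (less accurate); 328 pooled records, 54 positive
```

Reading: with no evidence, 72.4% of households are expected to have no
E. coli in stored water.  The ΔP ranking says the fitted model is most
sensitive to storage fullness, the environment–hygiene cluster, and water
quality at the source — each can swing the outcome by ~20 percentage
points when set to its best vs worst state.  The cross-validated AUC of
0.62 ("less accurate" on Greiner's scale) is the honest out-of-sample
discrimination of this variant at this sample size.  `res.summary()`
prints the fitted marginal of every node, and `res.scenario()` evaluates
the combined best-case intervention against the baseline.

The same workflow is available from a shell:

```sh
sibbn simulate --variant 1B -n 328 --poc-missing 49 --seed 7
sibbn fit synthetic_survey.csv --variant 1B --out fitted.json
sibbn sweep fitted.json
sibbn scenario fitted.json --variant 1B
sibbn infer fitted.json ecoli_pou household_water_treatment=yes_treat
```

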