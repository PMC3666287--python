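# feedenergy

Summative total-digestible-nutrient (TDN) models for ruminant feed
evaluation: predict the energy value of forages and agro-industrial
byproducts from their chemical composition and ruminal NDF degradability,
discount it to production intake, and judge each model variant's
precision against an in vitro digestibility benchmark.

The package is aimed at animal nutritionists and feed-laboratory analysts
who have routine wet-chemistry results (CP, EE, NDF, ADF, lignin,
detergent-insoluble CP fractions) and, optionally, 48-h in vitro or in
situ degradability assays, and who need defensible TDN and metabolizable
energy (ME) figures for ration formulation — particularly for tropical
forages and salvage byproducts that sit poorly in temperate feed tables.

## The model

TDN at maintenance intake is the sum of the truly digestible nutrient
fractions minus a constant metabolic fecal loss (all % of DM):

```
TDN_1x = dCP + 2.25·dFA + dNFC + dNDF − 7

dCP  = CP·exp(−1.2·ADICP/CP)        (forages)
     = CP·(1 − 0.4·ADICP/CP)        (concentrates)
dFA  = max(0, EE − 1)
dNFC = FAP·0.98·NFC,  NFC = 100 − [CP + (NDF − NDICP) + EE + Ash]
```

Five variants differ only in the digestible-NDF term:

| variant | dNDF |
|---|---|
| `LSdNDF` | 0.75·((NDF−NDICP)−L)·(1 − (L/(NDF−NDICP))^0.667) — surface law, chemistry only |
| `0.75IVdNDF` | 0.75·(IVNDFD₄₈/100)·NDF |
| `IVdNDF` | (IVNDFD₄₈/100)·NDF |
| `ISdNDF` | (ISNDFD₄₈/100)·NDF |
| `Rocha-Junior` | 0.6232·((NDF−NDICP)−L)·(1 − (L/(NDF−NDICP))^1.2258) — surface law re-fit for tropical feeds |

At production intake (3× maintenance) faster passage depresses
digestibility: `TDN_3x = TDN_1x − (0.18·TDN_1x − 10.3)·2` when
`TDN_1x > 60`, unchanged otherwise, and `ME_3x = 0.036·TDN_3x` Mcal/kg DM.
Model precision is the R² of the ordinary least-squares regression of
each variant's predicted TDN (y) on observed 48-h in vitro true DM
digestibility (x) across feeds.

## Worked example

The package bundles a twelve-feed table (eight tropical forages, four
byproducts) with full chemistry and 48/72-h degradability:

```python
from feedenergy import SummativeTDN, load_example_feeds

results = SummativeTDN(load_example_feeds()).fit()
print(results.summary())
```

prints (abridged):

```
Predicted TDN at maintenance (% of DM)
method                             LSdNDF  0.75IVdNDF  IVdNDF  ISdNDF  Rocha-Junior
Discarded corn                       57.7        58.8    67.5    70.2          58.4
Citrus pulp                          71.2        78.7    83.9    86.9          72.3
Bermudagrass                         46.5        31.7    39.8    46.6          46.0
...

Precision: OLS of predicted TDN on observed IVTDMD-48
              intercept   slope  r_squared   n
LSdNDF           25.645  0.4162       0.41  12
0.75IVdNDF      -21.936  1.0335       0.90  12
IVdNDF          -16.134  1.0552       0.96  12
ISdNDF           -3.101  0.9226       0.91  12
Rocha-Junior     24.718  0.4368       0.42  12

NDFD calibration (in situ on in vitro, 48 h):
  y = +15.475 + 0.8313 x (R^2 = 0.94, n = 12)

Energy at production intake (IVdNDF basis)
                                   tdn_1x  tdn_3x  me_3x
Discarded corn                       67.5    63.8    2.3
Citrus pulp                          83.9    74.3    2.7
...
```

Reading the precision block: the chemistry-only surface-law models
explain only ~41–42 % of the variation in observed digestibility across
these feeds, while variants that inject a measured 48-h NDF degradability
explain 90–96 % — the unit-coefficient in vitro variant (`IVdNDF`) being
the most precise. The calibration line shows the in situ assay tracks
the in vitro one closely (R² = 0.94) but compresses its range.

The same analysis is available from the shell:

```
feedenergy predict  --example --out-dir out     # feeds × methods TDN table
feedenergy evaluate --example --out-dir out     # precision + calibration fits
feedenergy energy   --example --out-dir out     # TDN_3x and ME_3x
feedenergy simulate --seed 1 --n-feeds 12 --out-dir sim   # synthetic table
```

Synthetic tables (`feedenergy.simulate`) satisfy every structural
invariant by construction and can tie degradability to chemistry through
the surface law (exactly, or with observation noise), which makes
end-to-end pipeline tests possible without the bundled data.

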