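# herbmars

Selecting chemical markers for the quality control of herbal raw materials
with the **modified Herbal Chemical Marker Ranking System (Herb MaRS)**.

Herbal materials vary widely in composition, and most medicinal plants used
in African manufacturing have no pharmacopoeial monographs. Phytochemical
standardization therefore hinges on choosing *marker compounds* — ideally
bioactive constituents relevant to the product's therapeutic claim that can
actually be assayed. `herbmars` encodes the evidence behind that choice as
structured data and scores each candidate with a fully itemized 0–8 rubric,
so that every decision is reproducible and auditable.

The package is aimed at pharmacognosy and quality-assurance researchers who
curate evidence tables (bioactivities, concentration reports, vendor
listings of analytical standards, assay methods) and need a transparent,
deterministic ranking — plus an auditor that checks a scored table's
internal consistency against the rubric.

## The rubric

Each candidate marker in a given plant context receives

```
score = A + B + C + D + E + F ∈ [0, 8]
```

| component | meaning | points |
|---|---|---|
| A | documented constituent of the material | 0/1 |
| B | distinct indication symptoms the compound treats (1 / 2 / ≥3) | 0–3 |
| C | reported concentration ≥ 5 ppm (w/w) | 0/1 |
| D | reported concentration ≥ 50 ppm (implies C) | 0/1 |
| E | analytical reference standard commercially available | 0/1 |
| F | published assay method available | 0/1 |

Concentration reports in any dialect (`"0.50% of essential oil"`,
`"1.1-2.0 mg/g of rhizome"`, `"109-135ppm of gel"`, `"ND"`) are normalized
to ppm (1% = 10,000 ppm; 1 mg/g = 1,000 ppm), with ranges collapsed to
their midpoint. A compound is **suitable** iff its total is ≥ 5 *and* a
standard and a method exist; it gets a **quantitative** role at ≥ 50 ppm
and a **qualitative** (identity-only) role below. Toxic compounds carry a
mandatory-screening flag regardless of score, and *negative markers* (e.g.
aloin in oral aloe products) are checked against regulatory maxima
(ISC 10 ppm; EMA/FDA 0 ppm). Reference-standard practicality is summarized
as €/unit = pack price ÷ pack size, rounded to 1 decimal.

The case-study dataset — seven commonly used Ugandan medicinal plants
(*Eucalyptus globulus*, *Aloe vera*, *Albizia coriaria*, *Mangifera
indica*, *Warburgia ugandensis*, *Azadirachta indica*, *Zingiber
officinale*) with 35 candidate-marker dossiers and 37 vendor listings —
ships inside the package (`herbmars.load_reference_dataset()`), as JSON
with an identical CSV view and a published JSON-Schema.

## Worked example

```sh
herbmars fixture --out study.json
herbmars rank study.json --plant "Eucalyptus globulus" --no-header
```

```
Plant: Eucalyptus globulus
compound                 A B C D E F  /8 (A+B+C+D+E+F)  suitable  role          ppm        cost €/unit
------------------------------------------------------------------------------------------------------
1,8-cineol               1 3 1 1 1 1   8                yes       quantitative  973200     48.3
α-terpineol              1 3 1 1 1 1   8                yes       quantitative  5000       0.6
aromadendrine            1 2 1 1 1 1   7                yes       quantitative  200000     106.0/22.1/421.0
globulol                 1 1 1 1 1 1   6                yes       quantitative  105000     2.5

Markers for Eucalyptus globulus: 1,8-cineol, α-terpineol, aromadendrine, globulol
```

All four eucalyptus compounds clear the suitability bar (totals 8, 8, 7, 6
with standards and methods available); ties at 8 are broken
alphabetically. α-terpineol at 0.50% of essential oil (5,000 ppm) is a
quantitative marker costing €0.6 per mg of standard.

```sh
herbmars costs study.json
# n=37 min=0.6 (eg-terpineol) max=498.0 (ai-azadirachtin) mean=62.5 sd=101.5

herbmars audit study.json
# wu-polygodial: sum_mismatch on recorded_total (recorded 3, recomputed 4)
# zo-12-gingerol: derivation_mismatch on d (recorded 1, recomputed 0)
# ... 6 finding(s); 35 audited, 0 skipped
```

The auditor compares the dataset's *recorded* scores (as printed in the
source tables) with the rubric recomputed from the evidence: the
polygodial row's printed components sum to 4, not its printed total of 3,
and two ginger rows claim the 50 ppm point for 10–20 ppm concentrations.
Recorded values are never repaired — findings are data.

Synthetic datasets with known ground truth (and optionally planted
corruption for audit testing) come from
`herbmars simulate --n 100 --seed 42 --corrupt 5 --out sim.json`.

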