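# opswatch

Risk prioritization for organophosphorus pesticides (OPs) and their
environmental transformation products.

OPs are acetylcholinesterase-inhibiting agrochemicals regulated on three
lists — China's management list (banned / restricted / unrestricted), the
EPA register (yes / no) and the EU register (yes / no / not listed) — yet
many *unrestricted* compounds, and the hydrolysis/photolysis/microbial
products they degrade into, carry substantial toxicity. `opswatch`
implements a reproducible pipeline for deciding which of them deserve
regulatory attention:

1. **Descriptor reduction** — molecular-descriptor tables (PaDEL-style)
   are cleaned (columns with missing values or zero variance dropped) and
   pruned for redundancy by greedy Pearson correlation (retain a
   descriptor iff |r| < threshold against everything already retained,
   scanning by descending variance).
2. **Regulatory-status modelling** — eight classifier families (RF,
   XGBoost, complement naive Bayes, GBM, KNN, logistic regression, a
   single-hidden-layer perceptron, SVM) on a stratified 7:3 split, scored
   with a confusion matrix and support-weighted accuracy / precision /
   recall / F1, externally validated and applied to unlabelled molecules
   with per-class tallies.
3. **Composite toxicity** — 24 ADMET-style indicators (20 probability
   endpoints plus BCF, IGC₅₀, LC₅₀DM, LC₅₀FM) are orientation-normalized
   so larger always means more toxic, weighted objectively by Shannon
   entropy (wⱼ = (1−eⱼ)/Σ(1−eₖ), with eⱼ = −(1/ln n)·Σᵢ pᵢⱼ ln pᵢⱼ and
   pᵢⱼ the value shares), and ranked by TOPSIS closeness
   Cᵢ = D⁻ᵢ/(D⁺ᵢ+D⁻ᵢ) to the column-wise ideal-toxic point. Parents are
   combined with the average profile of their transformation products
   before scoring.
4. **Watch list** — composite scores are binned by mean-centred intervals
   of width 1.85δ (δ = population SD) into four attention levels:
   special (d ∈ (1.85δ, 3.7δ]), focus ((0, 1.85δ]), general
   ((−1.85δ, 0]), secondary ((−3.7δ, −1.85δ]).

Because the real inputs come from external services (PaDEL, ADMETlab,
EAWAG-BBD), the package ships (a) small fixture tables encoding the
published reference lists and scores and (b) a synthetic generator that
plants class-conditional descriptor signal, redundant descriptor blocks,
Beta/log-normal toxicity indicators and parent-correlated products, so
the whole pipeline is testable offline.

## Worked example

Score the 54 unrestricted OPs from the packaged composite-toxicity table
and bin them into attention levels:

```python
>>> from opswatch import load_paper_fixtures, assign_levels, compute_delta
>>> fx = load_paper_fixtures()
>>> scores = fx.composite_toxicity["composite_toxicity"]
>>> mean, delta = compute_delta(scores)
>>> (round(mean, 4), round(delta, 4))
(0.4228, 0.0458)
>>> wl = assign_levels(scores)
>>> wl.frame.head(4)
                   composite_toxicity  deviation                   level
name
Tetrachlorvinphos              0.5886    0.16583  AttentionLevel.SPECIAL
Chlorfenvinphos                0.5080    0.08523  AttentionLevel.SPECIAL
Propaphos                      0.5037    0.08093    AttentionLevel.FOCUS
Naftalofos                     0.4994    0.07663    AttentionLevel.FOCUS
>>> {k.value: v for k, v in wl.level_counts().items()}
{'special': 2, 'focus': 24, 'general': 26, 'secondary': 2}
```

The two compounds whose scores deviate more than 1.85 population standard
deviations above the mean — tetrachlorvinphos and chlorfenvinphos — are
flagged for special attention; malathion and phenthoate fall in the
secondary band at the other end.

The same stages run from the shell; `opswatch --help` lists the commands
(`simulate`, `select-features`, `train`, `apply`, `mcda`, `watchlist`,
`reproduce-paper`). For example:

```sh
opswatch simulate --seed 3 --out sim/
opswatch train --algo rf --descriptors sim/descriptors.csv \
    --labels sim/labels.csv --model-out rf.joblib --seed 3
opswatch mcda --toxicity sim/toxicity.csv --products sim/products.csv \
    --map sim/transformation_map.json --out scores.csv
opswatch watchlist --scores scores.csv --out watchlist.csv
```

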