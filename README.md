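# netrecon

Reconstruct a propagation network from observed spreading cascades.

In many systems the spreading results are observable but the underlying
contact structure is not: inter-bank risk propagates over confidential
lending relations, chemicals diffuse over synaptic connections that are
hard to map, rumors travel over unobserved social ties. `netrecon`
implements a local, similarity-based approach to this inverse problem:
simulate (or load) time-stamped SIR news cascades on a network of *N*
nodes and *E* links, record for every node *i* and news item *α* whether
it was received (*R*<sub>*iα*</sub> ∈ {0,1}) and when
(*T*<sub>*iα*</sub>, discrete steps), score every candidate node pair
from (*R*, *T*) alone, and take the *E* top-scoring pairs as the
inferred network.

## The method

Nodes that receive many of the same news items are likely neighbors.
The classic similarity indices count and normalise the common-news
overlap CN<sub>*ij*</sub> = Σ<sub>*α*</sub> *R*<sub>*iα*</sub>*R*<sub>*jα*</sub>:

| index | score *s*<sub>*ij*</sub> |
|---|---|
| CN | CN<sub>*ij*</sub> |
| Jaccard | CN<sub>*ij*</sub> / (*k*<sub>*i*</sub> + *k*<sub>*j*</sub> − CN<sub>*ij*</sub>) |
| RA | Σ<sub>*α* common</sub> 1/*d*<sub>*α*</sub> |
| LHN | CN<sub>*ij*</sub> / (*k*<sub>*i*</sub>·*k*<sub>*j*</sub>) |

with *k*<sub>*i*</sub> the number of news received by node *i* and
*d*<sub>*α*</sub> the audience size of news *α* (the extended set — Cos,
HDI, HPI, SSI, PA — is also provided). Each index has a **temporal**
version (TCN, TJac, TRA, TLHN, …) in which every common-news term is
weighted by *w*<sub>*α*</sub> = 1/|*T*<sub>*iα*</sub> − *T*<sub>*jα*</sub>|,
with *w*<sub>*α*</sub> = 0 when the times are equal — two nodes that
received a news at the same step cannot have passed it to one another.
The temporal weighting dramatically improves reconstruction when the
infection rate is large and cascades saturate the network.

Reconstructions are evaluated with a sampled AUC (probability that a
true link outscores a non-link, ties counted 0.5), top-*E* precision
*m*/*E*, the Pearson correlation between reconstructed and true node
degrees, and the random baseline *P*₀ = *E*/#candidate-pairs.

## Worked example

```python
import netrecon as nr

net = nr.generate_ws(500, 10, 0.1, seed=1)                  # small-world truth
rec = nr.run_spreading(net, nr.SimulationParams(            # f=0.5, mu=2/<k>
    submission_prob=0.5, infection_rate=0.2, seed=2))
est = nr.SimilarityReconstructor(metric="tjac", e_target=net.n_links)
est.fit(rec)
from netrecon.evaluate import evaluate_scores
report = evaluate_scores(est.score_table_, net, seed=3)
print(f"news={rec.n_news}  AUC={report.auc:.3f}  "
      f"precision={report.precision:.3f}  P0={report.p0:.3f}")
```

```
news=250  AUC=1.000  precision=0.941  P0=0.020
```

With 250 observed cascades at a high infection rate, the temporal
Jaccard index ranks essentially every true link above every non-link
(AUC ≈ 1.0) and recovers 94% of the 2500 links in its top-*E* set,
against a 2% random baseline. The same experiment with the classic
(time-blind) Jaccard index gives AUC ≈ 0.94 and precision ≈ 0.45 —
the time stamps carry most of the signal once cascades are large.

The same pipeline is available from the shell:

```bash
netrecon generate --model ws --n 500 --k 10 --p 0.1 --seed 1 --out net.txt
netrecon spread   --net net.txt --f 0.5 --mu 0.2 --seed 2 --out record/
netrecon score    --record record/ --metric tjac --out scores.tsv
netrecon evaluate --scores scores.tsv --truth net.txt --seed 3 --out report.json
netrecon sweep    --config sweep.yaml --out results/
```

`netrecon sweep` runs a full (μ, f) × metrics grid with realization
averaging and writes a tidy CSV;
`netrecon.experiments.special_range_report` flags the infection-rate
range in which degree-punishing metrics keep a high AUC while their
top-*E* precision collapses toward *P*₀.

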