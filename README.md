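# rmetnet

Response-distribution network analysis for four-alternative forced-choice
emotion-recognition tasks such as the Reading the Mind in the Eyes Test
(RMET).

Classical RMET scoring keeps only the correct answers. This package
analyzes the *whole* response distribution — including which wrong words
were chosen and when no choice was made at all — by turning each group's
responses into a directed graph: every item's correct answer is a target
node, every answer category (the four candidate words plus the
no-response condition) is a source node, and each observed choice adds
weight to an edge from source to target. Two indices summarize how
spread-out a group's choices are:

* **in-degree** of an item — distinct answer categories observed, from 1
  (full consensus) to 5 (everything, including timeouts);
* **density** — realized over potential connections, per item
  (denominator 10, the pairs of 5 candidate nodes) and for the whole
  directed network (`e / (n(n−1))`).

In-degree vectors are compared between groups with pooled two-sample
t-tests, overall and within negative/neutral/positive valence strata;
accuracy and reaction time with one-way ANOVA; and accuracy–trait
associations (AQ, ADI-R subscales) with Pearson correlation. A
Dirichlet-categorical cohort generator produces study-shaped synthetic
data (2×30 participants, 43 items, 19/15/9 valence split by default) so
the full pipeline is testable and its statistics can be validated by
parameter-recovery experiments. See `docs/methods.md` for the model and
its assumptions.

## Worked example

```bash
rmetnet simulate --seed 1 --out-dir data/
rmetnet build   --responses data/responses.csv --key data/answer_key.csv --out-dir nets/
rmetnet compare --responses data/responses.csv --key data/answer_key.csv \
                --traits data/traits.csv --out-dir report/
```

`build` logs one line per group:

```
INFO rmetnet: group A: 163 nodes, 178 edges, density 0.007
INFO rmetnet: group B: 154 nodes, 133 edges, density 0.006
```

Group A (the lower-accuracy, higher-diversity group) has more nodes and
edges than group B: its members' wrong answers land on more distinct
words. `report/report.txt` then contains, among other rows:

```
     in_degree_all 4.14 ± 0.83 3.09 ± 0.65         t 6.501644 84 5.389359e-09
in_degree_negative 4.37 ± 0.83 3.00 ± 0.58         t 5.896246 36 9.562839e-07
```

Read: group A's items collected on average 4.14 of the 5 possible answer
categories versus 3.09 for group B — a significant consensus difference
with the df structure this design implies (43+43 items → df 84; the 19
negative items → df 36) — and the gap is widest for negative-valence
words, which is exactly the pattern the generator's defaults encode. The
same run writes per-item tables (`items_A.csv`), network summaries, and
GEXF/GraphML/edge-list graph files loadable by standard graph tools.

The same API is available in Python:

```python
from rmetnet import (SimConfig, simulate_cohort, build_response_network,
                     in_degree_vector, two_sample_t)

responses, key, traits = simulate_cohort(SimConfig(seed=1))
net_a = build_response_network(responses, key, "A")
net_b = build_response_network(responses, key, "B")
print(two_sample_t(in_degree_vector(net_a, key),
                   in_degree_vector(net_b, key)).format())
# t(84) = 6.50, p = 0.000
```

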