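# herbbasket

Apriori association-rule mining for herbal co-prescription data, built
around a fully replicable case study: the 17 Chinese-herbal-bath-therapy
(CHBT) formulas used across randomized trials of whole-body herbal baths
for uremic pruritus (itching in advanced chronic kidney disease).

Multi-herb prescriptions are market baskets: each formula is a set of
items, and association rules A → B with

* **support** = P(A ∪ B) — fraction of transactions containing both sides,
* **confidence** = P(B | A) = support(A ∪ B) / support(A),
* **expected confidence** = P(B) — the consequent's baseline frequency,
* **lift** = confidence / expected confidence (1 under independence),

surface herb combinations that co-occur more often than chance. The miner
is a classic level-wise Apriori with exact integer support counting, a
brute-force enumeration oracle for verification, a rule engine computing
all four metrics, antecedent-based rule grouping for visualization, and a
seeded synthetic generator that plants known co-occurring itemsets in
noise so recovery can be checked exactly.

A peculiarity of the built-in case study, documented in
[docs/methods.md](docs/methods.md): the published rule metrics arise from
treating each **row** (within-formula rank) of the 17-column formula grid
as a transaction — 22 transactions, the length of the longest formula —
not each formula. Both encodings (`by_formula` and `by_rank`) are
first-class; replication mode uses `by_rank`.

## Worked example

```python
import herbbasket as hb

table = hb.builtin_paper_formulas()          # 17 formulas, 43 herbs
report = hb.herb_frequencies(table)
print(len(table), table.max_len, report.as_dict()["difuzi"])
# 17 22 15

rules = hb.replicate_paper_rules()           # by_rank + Apriori + 1->1 rules
print(len(rules), len(hb.group_by_antecedent(rules)))
# 19 9
r = rules[0]
print(r.label(), round(r.support, 8), r.confidence, round(r.lift, 6))
# {baixianpi} => {difuzi} 0.13636364 1.0 5.5
```

19 rules survive the thresholds (minimum support 5%, minimum confidence
90%); every one has confidence 1 (the antecedent herb never appears
without its consequent), only two support values occur (3/22 and 2/22),
and the rules fall into 9 groups by antecedent. The strongest pair,
chuanxiong ↔ dahuang, has lift 11: each occupies 2 of 22 rank-transactions
and always the same ones.

The same pipeline runs from the shell:

```sh
herbbasket replicate            # writes frequency.tsv, rules.tsv, grouping.json
herbbasket mine --input my.csv --min-support 0.1 --min-confidence 0.8
herbbasket synth --seed 7 --out synthetic.csv
```

`replicate` verifies every number against the embedded published tables
and exits nonzero on any mismatch.

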