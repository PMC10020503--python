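"""Co-prescription rule mining and the herb network.

A transaction is one patient-day of CHM dispensing.  Rules are ranked by
joint frequency; support, confidence and lift follow the market-basket
definitions on the percent scale; the antecedent is the product with the
smaller marginal frequency.  Connected components of the rule network
define herb clusters.
"""

from herbsurv import (
    build_graph,
    build_transactions,
    default_herb_catalog,
    default_planted_pairs,
    generate_transactions_only,
    rules_table,
    top_rules,
)

# a 10,000-transaction synthetic stream with the default planted structure
rx = generate_transactions_only(
    default_herb_catalog(), default_planted_pairs(), 10000, seed=1)
ts = build_transactions(rx)
rules = top_rules(ts, k=5)

print(f"{ts.n_total} transactions; top five co-prescription rules:")
print(rules_table(rules, rx).to_string(index=False))

graph = build_graph(rules, rx)
print("\nherb clusters (connected components of the rule network):")
for comp in graph.components():
    print("  cluster:", sorted(comp))

print("\nLift > 1 means the pair is co-prescribed more often than two")
print("independently drawn products would be; the planted pairs (e.g.")
print("HL->HQ, SZRT->YJT) should dominate the ranking and split into")
print("two separate clusters.")
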