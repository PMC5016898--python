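"""How leukocyte contamination dilutes drug-resistance gene readouts.

GAPDH-normalised bulk expression of a gene the leukocytes do not express
scales with the cancer-cell fraction of the pool.  The observed
fold-change between the ODEP-purified arm and the negative-selection-
only arm therefore encodes the purity of the unpurified arm.
"""

import odepsim as o

params = o.ExpressionParams()

print("measured MRP4 level vs pool purity (pure-cell level = 1):")
for p in (1.0, 0.5, 0.15, 0.103):
    r = o.mixture_relative_expression(o.MixtureSample(p), "MRP4", params)
    print(f"  purity {100 * p:5.1f} % -> relative expression {r:.3f}")

print("\nimplied purity of the unpurified arm from the printed folds:")
table = o.dilution_table({"MRP4": 9.69, "MRP5": 3.44})
for _, row in table.iterrows():
    print(f"  {row.gene}: {row.fold:.2f}-fold -> "
          f"{100 * row.implied_purity_unpurified:.1f} % purity")
print("\nThe MRP4 figure (10.3%) sits inside the 10-16% purity range")
print("reported for negative-selection-only CTC isolation; the MRP5")
print("figure disagrees (29.1%), a gene-specific discrepancy the model")
print("surfaces rather than averages away.")
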