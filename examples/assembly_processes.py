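"""Null-model partitioning of community assembly processes.

Computes pairwise bNTI and Raup-Crick for the bundled neutral and
environmental-filtering communities and partitions sample pairs into the
five assembly-process classes.
"""

from wetmicro import assembly_partition
from wetmicro.datasets import load_neutral_table, load_selection_table, load_tree

tree = load_tree()
for name, table in [("neutral", load_neutral_table()),
                    ("filtered", load_selection_table())]:
    part = assembly_partition(table, tree, n_null=299, seed=4)
    print(f"{name} communities ({len(part.pairs)} sample pairs):")
    for process, frac in part.fractions.items():
        if frac:
            print(f"  {process:25s} {100 * frac:5.1f}%")
    print()

print("homogeneous selection (bNTI < -2): consistent environmental")
print("filtering draws communities phylogenetically closer than the")
print("taxa-shuffle null; dispersal limitation (|bNTI| <= 2, RC > 0.95):")
print("compositional turnover beyond the stochastic expectation.")
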