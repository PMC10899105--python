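"""Run the experimental-data filter chain on a small UEI table.

Builds a toy per-concatemer UEI table (beacon id, target id, UEI barcode,
read count), then compares the two filtering strategies: a read-count filter
versus the indirect-path filter, each followed by the iterative <2-product
filter and largest-component selection.  The indirect-path filter targets
topologically implausible edges instead of low-coverage ones, so it can
remove artifacts while losing less data.
"""

import numpy as np
import pandas as pd

from minipath import UEITable, run_experimental_chain

rng = np.random.default_rng(9)
rows, k = [], 0
# two tight 4x4 blocks of polonies ...
for block, (us, vs) in enumerate([(range(4), range(4)), (range(4, 8), range(4, 8))]):
    for u in us:
        for v in vs:
            for _ in range(int(rng.integers(2, 5))):
                rows.append((f"b{u}", f"t{v}", f"uei{k}",
                             int(rng.integers(1, 6))))
                k += 1
# ... plus one low-support bridge between them (a crosslink-like artifact)
rows.append(("b0", "t4", f"uei{k}", 1))

table = UEITable(pd.DataFrame(
    rows, columns=["beacon_id", "target_id", "uei_id", "read_count"]))
print(f"input: {len(table)} UEIs over "
      f"{table.records[['beacon_id', 'target_id']].drop_duplicates().shape[0]} "
      "polony pairs")

for spec in ({"read_count": 2}, {"indirect_path": 1}):
    s = run_experimental_chain(table, spec)
    print(f"{spec}: {s['total_ueis']} UEIs, {s['n_edges']} edges, "
          f"{s['n_beacons']}+{s['n_targets']} polonies kept "
          f"(component fraction {s['component_fraction']:.2f})")
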