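#!/usr/bin/env python
"""The full recursive study replay: plant the reference wine design, run
the two-pass recursive identification, and compare what comes back.

Twelve wine runs (2 vineyards x 2 vintages x 3 replicates), three QC-pool
injections and an alkane ladder are simulated with the bundled
101-compound design as ground truth. The QC pool seeds the internal
library; samples are aligned against it with the RT trapezoid; leftovers
fall back to the RT-free external library; the 3-replicate rule produces
the group-level entity table. The script reports whether the recovered
presence matrix equals the planted one, entity by entity.
"""

from pathlib import Path

from wineomics.io_formats import export_cef, write_library
from wineomics.scenarios import scenario_table1_replay

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    result = scenario_table1_replay(seed=SEED)
    table = result.recovered_table
    out = table.entities.join(table.abundance)
    out.to_csv(RESULTS / "entities_by_group.csv")
    result.replicate_table.abundance.to_csv(RESULTS / "entities_by_injection.csv")
    export_cef(table, RESULTS / "entities.cef")
    print(f"recovered {len(table.entities)} entities "
          f"from {len(result.replicate_table.samples)} wine injections")
    print("planted  venn:", result.planted_venn)
    print("recovered venn:", result.recovered_venn)
    if result.exact_match:
        print("presence matrix recovered EXACTLY (no missed, no spurious entities)")
    else:
        print("presence mismatches:")
        print(result.mismatches.to_string())


if __name__ == "__main__":
    main()
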