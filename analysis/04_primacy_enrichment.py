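"""Do KCs integrate inputs from high-affinity (primacy) receptor sets?

Stage 2 on the simulated world: correlates OR-OR similarity in connectivity
with OR-OR similarity in primacy membership (p = 5), then tests enrichment
of claw/primacy-set overlaps for the top-k KCs per odorant (k = 1 is the
single "grandmother" KC; k = 10 and 50 are population readouts) against
degree-preserving shuffles, with BH-FDR across the p = 1..8 x degree grid.
Run 01 first.
"""

import json
from pathlib import Path

from primacyhull.cli import run_pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"
WORLD = ROOT / "world_fly"

if __name__ == "__main__":
    ac = run_pipeline(
        "affinity-compare",
        {
            "conn": str(WORLD / "connectivity_A.tsv"),
            "responses": str(WORLD / "affinity.tsv"),
            "p": 5,
            "n_perm": 999,
        },
        seed=4,
        out=ROOT / "affinity_compare",
    )
    print(
        f"connectivity vs primacy similarity: r = {ac['r']:.3f} "
        f"(p = {ac['p_value']:.3g}) over {ac['n_retained_odorants']} odorants"
    )

    for k in (1, 10, 50):
        res = run_pipeline(
            "enrich",
            {
                "conn": str(WORLD / "connectivity_A.tsv"),
                "responses": str(WORLD / "affinity.tsv"),
                "p_values": list(range(1, 9)),
                "k": k,
                "n_shuffles": 200,
            },
            seed=40 + k,
            out=ROOT / f"enrichment_k{k}",
        )
        print(
            f"k = {k:2d}: {res['n_significant_cells']} (p, degree) cells "
            f"enriched at FDR < 0.05"
        )
        if res["significant_cells"]:
            print(json.dumps(res["significant_cells"], indent=1))
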