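"""Cross-animal conservation of glomerulus->KC connectivity structure.

On the two simulated animals sharing a primacy hull: correlates their
glomerulus-glomerulus similarity matrices (with a degree-preserving shuffle
control), embeds the similarity profiles with PCA and Isomap, tests
per-dimension variance against the shuffle null, and reports the
Procrustes-aligned embedding RMSD between animals.  Run 01 first.
"""

import json
from pathlib import Path

from primacyhull.cli import run_pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"
WORLD = ROOT / "world_fly"

if __name__ == "__main__":
    summary = run_pipeline(
        "conn-compare",
        {
            "conn_a": str(WORLD / "connectivity_A.tsv"),
            "conn_b": str(WORLD / "connectivity_B.tsv"),
            "n_perm": 999,
            "n_shuffles": 100,
            "d": 2,
        },
        seed=3,
        out=ROOT / "connectivity_conservation",
    )
    print(json.dumps(summary, indent=1))
    print(
        f"similarity matrices correlate at r = {summary['offdiag_r']:.3f} "
        f"(permutation p = {summary['offdiag_p']:.3g}); after degree-preserving "
        f"shuffling r = {summary['offdiag_r_shuffled']:.3f} "
        f"(p = {summary['offdiag_p_shuffled']:.3g})."
    )
    for method in ("pca", "isomap"):
        m = summary[method]
        print(
            f"{method}: 2D RMSD between animals {m['rmsd']:.3f}; variance "
            f"explained {['%.3f' % v for v in m['variance_explained_a']]}; "
            f"dimension p-values {['%.3g' % v for v in m['dimension_p_values']]}"
        )
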