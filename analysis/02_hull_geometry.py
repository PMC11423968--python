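"""Primacy-hull geometry: face counts, membership, and an exact 2D sweep.

Reports (i) the subprime face-count table F(n, p) = C(p, n), including the
mouse-scale value F(8, 16) that matches the ~1e4 cells a single odor
activates in piriform cortex; (ii) an exact 2D hull for a small receptor
ensemble, with the receptors predicted to be pseudogenized (outside every
primacy set); (iii) hull membership at fly scale from the simulated world.
"""

import json
from pathlib import Path

import numpy as np

from primacyhull import io as phio
from primacyhull.hull import build_hull_exact_2d, face_count, hull_membership
from primacyhull.synth import sample_receptors

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    face_table = {
        "triangles_of_tetrahedron_F(3,4)": face_count(3, 4),
        "segments_of_tetrahedron_F(2,4)": face_count(2, 4),
        "mouse_scale_F(8,16)": face_count(8, 16),
    }
    print("subprime face counts:", json.dumps(face_table, indent=1))

    # exact 2D sweep on a small ensemble: which receptors join no primacy set?
    pts = sample_receptors(12, 2, seed=2)
    hull2d = build_hull_exact_2d(pts, p=2, cone="nonnegative_orthant")
    members, pseudo = hull_membership(hull2d)
    print(
        f"exact 2D sweep (12 receptors, p=2): {len(hull2d.simplices)} simplices, "
        f"{len(members)} hull members, predicted pseudogenized: {pseudo}"
    )

    summary = {
        "face_counts": face_table,
        "exact_2d": {
            "n_simplices": len(hull2d.simplices),
            "members": members,
            "predicted_pseudogenized": pseudo,
        },
    }

    world_hull_path = ROOT / "world_fly" / "hull.json"
    if world_hull_path.exists():
        hull = phio.read_hull(world_hull_path)
        members, pseudo = hull_membership(hull)
        print(
            f"fly-scale world hull: {len(hull.simplices)} simplices over "
            f"{len(members)}/{hull.n_receptors} receptors; "
            f"{len(pseudo)} outside the hull"
        )
        summary["fly_world"] = {
            "n_simplices": len(hull.simplices),
            "n_members": len(members),
            "n_pseudogenized": len(pseudo),
        }

    phio.write_json(ROOT / "hull_summary.json", summary)
    print(f"wrote {ROOT / 'hull_summary.json'}")
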