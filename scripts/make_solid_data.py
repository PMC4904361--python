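"""Maintainer script: construct all 123 reference solids and freeze their
vertex coordinates as packaged text data files plus a JSON manifest.

Run from the repository root:

    python scripts/make_solid_data.py [--only 84,88]

Each solid is validated (convexity, Euler's relation, regular faces for
the regular-faced families) before writing.  Coordinates are centered at
the vertex centroid and written with 12 significant digits, which
preserves the face combinatorics recovered by hull derivation with large
margin.
"""

import argparse
import json
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from polyclass import constructions as cons  # noqa: E402
from polyclass.geometry import derive_faces  # noqa: E402
from polyclass.library import _solid_filename, catalog  # noqa: E402

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "polyclass" / \
    "data"


def construct(sid: int, name: str, family: str) -> np.ndarray:
    if family == "Platonic":
        fn = getattr(cons, name.replace(" ", "_"))
        return fn()
    if family == "Archimedean":
        fn = dict(cons._ARCHIMEDEAN)[name]
        return fn()
    if family == "Catalan":
        idx = cons._CATALAN_NAMES.index(name)
        arch = cons._ARCHIMEDEAN[idx][1]()
        return cons.catalan_from(arch)
    jnum = int(name.split()[0][1:])
    return getattr(cons, f"j{jnum}")()


def main(argv=None):
    ap = argparse.ArgumentParser()
    ap.add_argument("--only", default=None,
                    help="comma-separated solid ids to regenerate")
    args = ap.parse_args(argv)
    only = None if args.only is None else {
        int(x) for x in args.only.split(",")}

    (DATA / "solids").mkdir(parents=True, exist_ok=True)
    manifest = []
    for sid, name, family in catalog():
        path = DATA / "solids" / _solid_filename(sid, name)
        if only is not None and sid not in only:
            if not path.exists():
                print(f"  [skip, missing] {sid:3d} {name}")
            continue
        pts = np.asarray(construct(sid, name, family), dtype=float)
        pts = pts - pts.mean(axis=0)
        if family in ("Platonic", "Archimedean", "Johnson"):
            pts = cons.normalize_edge(pts)
            cons.validate_regular_solid(pts, tol=1e-6)
        edges, faces = derive_faces(pts)
        lines = [f"# {name} | {family} | id {sid}"]
        for p in pts:
            lines.append("%.12g %.12g %.12g" % tuple(p))
        path.write_text("\n".join(lines) + "\n")
        print(f"  wrote {sid:3d} {name:45s} V={len(pts):3d} "
              f"E={len(edges):3d} F={len(faces):3d}")
    # manifest over everything present
    from polyclass.library import build_library, manifest as make_manifest
    build_library.cache_clear()
    lib = build_library()
    (DATA / "manifest.json").write_text(
        json.dumps(make_manifest(lib), indent=1) + "\n")
    print(f"manifest for {len(lib)} solids written")


if __name__ == "__main__":
    main()
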