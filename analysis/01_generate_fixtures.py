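#!/usr/bin/env python
"""Generate the standard synthetic fixture batch and record its manifest.

Writes results/fixtures_manifest.json: one entry per fixture with the
planted ground truth (rotation angles, axial shifts, kink angles/registers,
groove widenings, footprint walks, scaffold architectures).  Structure
files themselves are regenerated on demand from the seed; nothing binary is
kept.
"""

import json
import warnings
from pathlib import Path

import statewalk as sw

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fixtures = sw.synth.make_fixture_suite(seed=SEED)
    manifest = []
    for fx in fixtures:
        entry = {"name": fx["name"], "kind": fx["kind"], "truth": fx["truth"]}
        manifest.append(entry)
    path = OUT / "fixtures_manifest.json"
    path.write_text(json.dumps({"seed": SEED, "fixtures": manifest}, indent=2,
                               default=str))
    kinds = sorted({f["kind"] for f in fixtures})
    print(f"generated {len(fixtures)} fixtures (seed {SEED}) covering: {', '.join(kinds)}")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
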