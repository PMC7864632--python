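#!/usr/bin/env python
"""Track a buried-SASA interface across states with a planted maximum.

Three states place two Cα rods at closing separations (12, 6, 5 Å); the
interface area must grow monotonically and peak at the closest state —
the same measurement used to locate the state of maximal engagement
between a translocase module and a polymerase clamp.

Writes results/interface_track.csv.
"""

from pathlib import Path

import pandas as pd

import statewalk as sw
from statewalk.model import AtomSite, DomainRegistry, Selection, SelectionTerm, StructureModel

OUT = Path(__file__).resolve().parents[1] / "results"


def rods(label: str, separation: float) -> StructureModel:
    atoms = []
    for i in range(12):
        atoms.append(AtomSite("A", i + 1, "", "ALA", "CA", "C", [0.0, 0.0, 1.5 * i]))
        atoms.append(AtomSite("B", i + 1, "", "ALA", "CA", "C", [separation, 0.0, 1.5 * i]))
    return StructureModel(label, atoms)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    reg = DomainRegistry()
    reg.add(Selection("rod_a", [SelectionTerm("A")]), "synthetic")
    reg.add(Selection("rod_b", [SelectionTerm("B")]), "synthetic")
    separations = {"S1": 12.0, "S2": 6.0, "S3": 5.0}
    ens = sw.synth.make_ensemble(
        [(lab, rods(lab, sep), "ATP") for lab, sep in separations.items()], reg)
    reports, mean, peak, argmax = sw.interface_track(ens, "rod_a", "rod_b")
    rows = [{"state": lab, "separation_A": separations[lab],
             "interface_area_A2": r.interface_area}
            for lab, r in reports.items()]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "interface_track.csv", index=False)
    print(df.to_string(index=False))
    print(f"mean {mean:.1f} Å²; maximum {peak:.1f} Å² at state {argmax} "
          f"(planted closest approach)")


if __name__ == "__main__":
    main()
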