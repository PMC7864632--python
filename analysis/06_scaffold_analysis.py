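#!/usr/bin/env python
"""Sequence analysis of the shipped elongation-complex scaffold oligos.

Reports the RNA:t-strand 3'-hybrid length, the duplex/bubble segmentation
of the two 64-nt DNA strands, and the upstream duplex length.

Writes results/scaffold_report.txt and results/scaffold.json.
"""

from pathlib import Path

import statewalk as sw

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    s = sw.MFD_EC_SCAFFOLD
    ann = sw.annotate_scaffold(s["rna"], s["t_strand"], s["nt_strand"])
    text = sw.scaffold_report(ann)
    print(text)
    (OUT / "scaffold_report.txt").write_text(text + "\n")
    (OUT / "scaffold.json").write_text(ann.to_json())
    assert ann.hybrid_length == 9
    assert ann.upstream_duplex_length >= 40
    print("\nhybrid and upstream-duplex design features confirmed "
          f"({ann.hybrid_length} bp hybrid, {ann.upstream_duplex_length} bp upstream duplex)")


if __name__ == "__main__":
    main()
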