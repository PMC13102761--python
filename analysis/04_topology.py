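#!/usr/bin/env python
"""Tabulate node degrees and structural roles of the learned network.

Classifies every factor of the full learned network (02) as Parent, Child,
Intermediate, or Isolated from its in/out-degree, and checks degree
conservation against the edge count.

Writes: results/node_roles.tsv
"""

from pathlib import Path

from bedfallnet.netio import load_network
from bedfallnet.topology import node_roles

OUT = Path("results")


def main() -> None:
    net = load_network(OUT / "learned_network.json")
    frame = node_roles(net.dag)
    frame.to_csv(OUT / "node_roles.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    edges = len(net.dag.edges)
    assert frame["In-degree"].sum() == frame["Out-degree"].sum() == edges
    print(f"\ndegree conservation holds: total in = total out = {edges} edges")
    counts = frame["Role in network"].value_counts().to_dict()
    print(f"role counts: {counts}")


if __name__ == "__main__":
    main()
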