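"""Node-degree topology: classify each factor's structural role.

A node with outgoing edges only is a Parent node, incoming only a Child node,
both an Intermediate node, neither an Isolated node. Total in-degree equals
total out-degree equals the edge count.
"""

from __future__ import annotations

import pandas as pd

from bedfallnet.structure import Dag

ROLE_PARENT = "Parent node"
ROLE_CHILD = "Child node"
ROLE_INTERMEDIATE = "Intermediate node"
ROLE_ISOLATED = "Isolated node"


def _role(in_deg: int, out_deg: int) -> str:
    if in_deg == 0 and out_deg == 0:
        return ROLE_ISOLATED
    if in_deg == 0:
        return ROLE_PARENT
    if out_deg == 0:
        return ROLE_CHILD
    return ROLE_INTERMEDIATE


def node_roles(dag: Dag) -> pd.DataFrame:
    """Degree table with columns Variable, In-degree, Out-degree, Role in network."""
    rows = []
    for v in sorted(dag.nodes):
        i, o = dag.in_degree(v), dag.out_degree(v)
        rows.append(
            {
                "Variable": v,
                "In-degree": i,
                "Out-degree": o,
                "Role in network": _role(i, o),
            }
        )
    return pd.DataFrame(rows, columns=["Variable", "In-degree", "Out-degree", "Role in network"])
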