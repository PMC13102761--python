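"""Network serialization: JSON exchange format and DOT export.

JSON schema::

    {"nodes": [...],
     "edges": [["F", "G"], ...],
     "cpts": {"G": {"parents": ["F"], "table": {"0": [p0, p1], "1": [p0, p1]}}}}

Parent-configuration keys are little-endian binary indices over the ordered
parent list (first parent = least-significant bit). Probabilities round-trip
at full floating precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from bedfallnet.inference import BayesNet
from bedfallnet.parameters import Cpt
from bedfallnet.structure import Dag


def network_to_dict(net: BayesNet) -> dict:
    return {
        "nodes": list(net.dag.nodes),
        "edges": [list(e) for e in net.dag.sorted_edges()],
        "cpts": {
            v: {
                "parents": list(cpt.parents),
                "table": {str(j): [cpt.table[j, 0], cpt.table[j, 1]] for j in range(cpt.q)},
            }
            for v, cpt in sorted(net.cpts.items())
        },
    }


def network_from_dict(payload: dict) -> BayesNet:
    dag = Dag(tuple(payload["nodes"]), frozenset(map(tuple, payload["edges"])))
    cpts = {}
    for v, spec in payload["cpts"].items():
        parents = tuple(spec["parents"])
        q = 1 << len(parents)
        table = np.array([spec["table"][str(j)] for j in range(q)], dtype=np.float64)
        cpts[v] = Cpt(v, parents, table)
    return BayesNet(dag, cpts)


def dag_to_dot(dag: Dag, name: str = "bedfall") -> str:
    lines = [f"digraph {name} {{"]
    for v in dag.nodes:
        lines.append(f'  "{v}";')
    for u, v in dag.sorted_edges():
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_network(net: BayesNet, fmt: str, path: Optional[str | Path] = None) -> str:
    """Render the network as ``json`` or ``dot``; optionally write to path."""
    if fmt == "json":
        text = json.dumps(network_to_dict(net), indent=2) + "\n"
    elif fmt == "dot":
        text = dag_to_dot(net.dag)
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected 'json' or 'dot')")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def save_network(net: BayesNet, path) -> None:
    export_network(net, "json", path)


def load_network(path) -> BayesNet:
    with open(path, encoding="utf-8") as fh:
        return network_from_dict(json.load(fh))
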