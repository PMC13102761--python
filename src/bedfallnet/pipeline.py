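"""End-to-end orchestration: learn, bootstrap, retain, fit, analyse, report.

``run_full_pipeline`` executes the whole analysis on one incident matrix and
writes five artifacts to the output directory:

  network.json   stable structure + BDeu CPTs
  network.dot    DOT rendering of the stable structure
  edges.tsv      bootstrap edge frequencies (From, To, Frequency, Count)
  roles.tsv      node degrees and roles (Variable, In-degree, Out-degree, Role)
  scenarios.tsv  conditional scenarios and posteriors over ancestor-descendant
                 pairs of the stable network
  run_log.json   configuration, seed, config hash, stage shapes

Outputs are deterministic given input + config + seed (no timestamps inside
artifacts); every file embeds the config hash and seed. Scenario rows report
observational conditioning, not do-interventions: an edge direction within a
Markov-equivalence class is a tie-breaking artifact of the search.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd

from bedfallnet.bootstrap import BootstrapConfig, bootstrap_edge_frequencies, stable_network
from bedfallnet.data import IncidentMatrix, read_incident_matrix
from bedfallnet.inference import BayesNet, Evidence, posterior_cooccurrence, scenario_analysis
from bedfallnet.netio import dag_to_dot, network_to_dict
from bedfallnet.parameters import BdeuConfig, fit_cpts
from bedfallnet.structure import SearchConfig, hill_climb
from bedfallnet.topology import node_roles

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full pipeline run."""

    input_path: Optional[str] = None
    output_dir: str = "results"
    seed: int = 17
    search: SearchConfig = field(default_factory=SearchConfig)
    bootstrap_replicates: int = 200
    stability_threshold: float = 0.5
    ess: float = 1.0
    ci_replicates: int = 1000
    ci_level: float = 0.95
    verbosity: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (paths and verbosity are
        excluded so the same analysis hashes identically wherever it runs)."""
        payload = asdict(self)
        for key in ("input_path", "output_dir", "verbosity"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _fmt_p(p: float) -> str:
    return f"{p:.3f}"


def _fmt_ci(ci) -> str:
    return f"[{ci[0]:.3f}–{ci[1]:.3f}]" if ci else ""


def _fmt_pct(pct: Optional[float]) -> str:
    if pct is None:
        return "n/a"
    sign = "−" if pct < 0 else "+"
    return f"{sign}{abs(pct):.1f}%"


def _ancestor_descendant_pairs(dag) -> list[tuple[str, str]]:
    g = dag.to_networkx()
    pairs = []
    for u in sorted(dag.nodes):
        for v in sorted(nx.descendants(g, u)):
            pairs.append((u, v))
    return pairs


def scenario_table(
    net: BayesNet,
    matrix: IncidentMatrix,
    config: RunConfig,
) -> pd.DataFrame:
    """Scenario and posterior rows for every ancestor-descendant pair.

    Mirrors the published report layout: for ancestor u and descendant v, the
    scenario fixes u = 0 and tracks the target v; the companion posterior is
    P(u = 1 | v = 1). Probabilities are rendered at 3 decimals and percents at
    1 decimal; unrounded columns are kept alongside.
    """
    counts = {c: int(matrix.column(c).sum()) for c in matrix.column_codes}
    rows = []
    for u, v in _ancestor_descendant_pairs(net.dag):
        res = scenario_analysis(
            net,
            matrix,
            Evidence({u: 0}),
            v,
            ci_replicates=config.ci_replicates,
            ci_level=config.ci_level,
            seed=config.seed,
            bdeu=BdeuConfig(config.ess),
        )
        post = posterior_cooccurrence(net, Evidence({v: 1}), u)
        rows.append(
            {
                "Condition": f"{u} = 0",
                "Condition counts (n/SUM)": f"{matrix.n - counts[u]}/{matrix.n}",
                "Target": v,
                "Target counts (n/SUM)": f"{counts[v]}/{matrix.n}",
                "Baseline P(1) [95%CI]": f"{_fmt_p(res.baseline_p1)} {_fmt_ci(res.baseline_ci)}".strip(),
                "Conditional P(1) [95%CI]": f"{_fmt_p(res.conditional_p1)} {_fmt_ci(res.conditional_ci)}".strip(),
                "Absolute change": f"{'−' if res.absolute_change < 0 else '+'}{abs(res.absolute_change):.3f}",
                "Relative change": _fmt_pct(res.relative_change_pct),
                "Posterior P(cond=1 | target=1)": _fmt_p(post.posterior_p1),
                "baseline_raw": res.baseline_p1,
                "conditional_raw": res.conditional_p1,
                "posterior_raw": post.posterior_p1,
            }
        )
    return pd.DataFrame(rows)


def _write_tsv(frame: pd.DataFrame, path: Path, header_note: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header_note}\n")
        frame.to_csv(fh, sep="\t", index=False)


def run_full_pipeline(config: RunConfig, matrix: Optional[IncidentMatrix] = None) -> dict:
    """Execute learn -> bootstrap -> retain -> fit -> topology -> inference.

    Returns a report bundle mapping artifact names to paths plus the in-memory
    results. ``matrix`` may be passed directly; otherwise it is read from
    ``config.input_path``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    note = f"config_hash={config.config_hash()} seed={config.seed}"
    timings = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %-10s done in %.3fs", name, timings[name])
        return result

    try:
        if matrix is None:
            if config.input_path is None:
                raise ValueError("either matrix or config.input_path is required")
            matrix = stage("read", lambda: read_incident_matrix(config.input_path))
        logger.info("input matrix: n=%d records, p=%d factors", matrix.n, matrix.p)

        learned = stage("learn", lambda: hill_climb(matrix, config.search))
        boot_cfg = BootstrapConfig(
            replicates=config.bootstrap_replicates, seed=config.seed, search=config.search
        )
        freq = stage("bootstrap", lambda: bootstrap_edge_frequencies(matrix, boot_cfg))
        stable = stage(
            "stable",
            lambda: stable_network(freq, config.stability_threshold, nodes=matrix.column_codes),
        )
        cpts = stage("fit", lambda: fit_cpts(stable, matrix, BdeuConfig(config.ess)))
        net = BayesNet(stable, cpts)
        roles = stage("topology", lambda: node_roles(stable))
        scenarios = stage("inference", lambda: scenario_table(net, matrix, config))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {list(timings) and list(timings)[-1]}: {exc}") from exc

    payload = network_to_dict(net)
    payload["meta"] = {"config_hash": config.config_hash(), "seed": config.seed}
    (out / "network.json").write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    (out / "network.dot").write_text(f"// {note}\n" + dag_to_dot(stable), encoding="utf-8")
    _write_tsv(freq.to_frame(), out / "edges.tsv", note)
    _write_tsv(roles, out / "roles.tsv", note)
    _write_tsv(scenarios, out / "scenarios.tsv", note)
    from bedfallnet import __version__ as version

    run_log = {
        "version": version,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n": matrix.n,
        "p": matrix.p,
        "learned_edges": [list(e) for e in learned.sorted_edges()],
        "stable_edges": [list(e) for e in stable.sorted_edges()],
        "note": "conditioning is observational, not interventional; edge directions "
                "within a Markov-equivalence class are tie-breaking artifacts",
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n", encoding="utf-8")

    return {
        "paths": {
            name: str(out / name)
            for name in ("network.json", "network.dot", "edges.tsv", "roles.tsv", "scenarios.tsv", "run_log.json")
        },
        "learned": learned,
        "edge_frequencies": freq,
        "stable": stable,
        "net": net,
        "roles": roles,
        "scenarios": scenarios,
        "timings": timings,
    }
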