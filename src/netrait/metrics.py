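"""Binary-network measures: CPL, GCC, small-worldness, betweenness.

All measures operate on the binarized networks only. Definitions:

* CPL — mean shortest-path hop count over all *reachable* unordered node
  pairs (unreachable pairs are excluded, not treated as infinite).
* GCC — either the mean nodal clustering coefficient (``average_local``,
  the default: nodes of degree < 2 contribute 0) or the transitivity ratio
  3 * triangles / connected triples (``transitivity``). The two differ on
  most graphs; both are exposed because the literature uses both under the
  same name.
* SMW — (GCC_act / GCC_rand) / (CPL_act / CPL_rand), where X_rand is the
  mean of X over an ensemble of degree-preserving rewirings of the same
  network; values well above 1 indicate small-world organization.
* BET — unnormalized shortest-path betweenness, each unordered pair counted
  once, endpoints excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .threshold import BinaryNetwork, rewire_degree_preserving

GCC_METHODS = ("average_local", "transitivity")


@dataclass
class SubjectMetrics:
    subject_id: str
    cpl: float
    gcc: float
    smw: float                 # NaN when undefined (GCC_rand = 0)
    bet: np.ndarray
    gcc_method: str
    n_random_used: int
    smw_components: dict[str, float] | None = None


def characteristic_path_length(g: BinaryNetwork) -> float:
    """Mean shortest-path length over reachable unordered pairs."""
    if g.n_edges == 0:
        raise ValueError("CPL undefined for a graph with no edges")
    total = 0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(g.to_networkx()):
        for d in dists.values():
            if d >= 1:
                total += d
                count += 1
    # each unordered pair visited twice (once per endpoint)
    return total / count


def global_clustering(g: BinaryNetwork, method: str = "average_local") -> float:
    if method == "average_local":
        return float(nx.average_clustering(g.to_networkx(), count_zeros=True))
    if method == "transitivity":
        return float(nx.transitivity(g.to_networkx()))
    raise ValueError(f"unknown GCC method {method!r}")


def betweenness_all(g: BinaryNetwork, normalized: bool = False) -> np.ndarray:
    """Shortest-path betweenness per node (Brandes), unnormalized by
    default, each unordered pair counted once, endpoints excluded."""
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=normalized)
    return np.array([bc[v] for v in range(g.n_nodes)])


def small_worldness(g: BinaryNetwork, n_random: int,
                    rng: np.random.Generator | int | None = None,
                    gcc_method: str = "average_local",
                    swap_factor: float = 10.0,
                    ) -> tuple[float, dict[str, float]]:
    """SMW with its components (GCC_act, GCC_rand, CPL_act, CPL_rand).

    GCC_rand and CPL_rand are means over ``n_random`` degree-preserving
    rewirings of ``g`` itself. When GCC_rand = 0 the ratio is undefined and
    SMW is returned as NaN with a warning, never a silent infinity.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(rng)
    gcc_act = global_clustering(g, gcc_method)
    cpl_act = characteristic_path_length(g)
    gccs = np.empty(n_random)
    cpls = np.empty(n_random)
    for m in range(n_random):
        r = rewire_degree_preserving(g, swap_factor, rng)
        gccs[m] = global_clustering(r, gcc_method)
        cpls[m] = characteristic_path_length(r)
    comps = {"gcc_act": gcc_act, "gcc_rand": float(gccs.mean()),
             "cpl_act": cpl_act, "cpl_rand": float(cpls.mean())}
    if comps["gcc_rand"] == 0.0:
        warnings.warn("GCC_rand is 0; small-worldness undefined (NaN)")
        return float("nan"), comps
    smw = (gcc_act / comps["gcc_rand"]) / (cpl_act / comps["cpl_rand"])
    return smw, comps


def compute_cohort_metrics(cohort_nets: list[BinaryNetwork],
                           subject_ids: list[str] | None = None,
                           n_random: int = 500,
                           rng: np.random.Generator | int | None = None,
                           gcc_method: str = "average_local",
                           ) -> list[SubjectMetrics]:
    """Per-subject CPL, GCC, SMW and betweenness for a cohort of binarized
    networks; reproducible under a fixed seed."""
    if not cohort_nets:
        raise ValueError("empty cohort")
    n = cohort_nets[0].n_nodes
    if any(g.n_nodes != n for g in cohort_nets):
        raise ValueError("networks disagree on n_nodes")
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(len(cohort_nets))]
    rng = np.random.default_rng(rng)
    out = []
    for sid, g in zip(subject_ids, cohort_nets):
        smw, comps = small_worldness(g, n_random, rng, gcc_method)
        out.append(SubjectMetrics(
            subject_id=sid,
            cpl=characteristic_path_length(g),
            gcc=global_clustering(g, gcc_method),
            smw=smw,
            bet=betweenness_all(g),
            gcc_method=gcc_method,
            n_random_used=n_random,
            smw_components=comps,
        ))
    return out


def metrics_long_table(metrics: list[SubjectMetrics],
                       region_names: list[str]) -> pd.DataFrame:
    """Long-format table: one row per subject x node (betweenness), with the
    subject's global measures repeated on each row."""
    rows = []
    for m in metrics:
        for idx, name in enumerate(region_names):
            rows.append({"subject_id": m.subject_id, "node_index": idx,
                         "region_name": name, "bet": m.bet[idx],
                         "cpl": m.cpl, "gcc": m.gcc, "smw": m.smw,
                         "gcc_method": m.gcc_method})
    return pd.DataFrame(rows)


def metrics_from_long_table(df: pd.DataFrame) -> list[SubjectMetrics]:
    """Inverse of :func:`metrics_long_table` (for stage resumption)."""
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("node_index")
        out.append(SubjectMetrics(
            subject_id=str(sid),
            cpl=float(grp["cpl"].iloc[0]),
            gcc=float(grp["gcc"].iloc[0]),
            smw=float(grp["smw"].iloc[0]),
            bet=grp["bet"].to_numpy(dtype=float),
            gcc_method=str(grp["gcc_method"].iloc[0]),
            n_random_used=-1,
        ))
    return out
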