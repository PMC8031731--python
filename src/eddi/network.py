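"""Stage 6 — systems layer over the accepted dependency–predictor pairs.

* shared-DDP bipartite network: dependency nodes on one side, predictor
  genes appearing in >= 2 dependencies on the other, plus the weighted
  dependency–dependency projection (weight = number of shared DDPs);
* hierarchical clustering of dependencies and DDPs on their
  mode-of-expression profiles (categorical codes, Hamming distance,
  average linkage by default);
* tissue composition of each dependency's dependent cell lines, with
  per-tissue penetrance;
* hypergeometric over-representation of a query gene list against
  user-supplied gene sets (GMT format), BH-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .datatypes import CellAnnotation
from .labeling import DependentSet
from .modes import DDPRecord

__all__ = [
    "MODE_CODES",
    "DependencyNetwork",
    "EnrichmentResult",
    "build_network",
    "mode_matrix",
    "mode_profile_clustering",
    "ClusteringResult",
    "tissue_composition",
    "overrepresentation",
    "enrichment_to_frame",
    "read_gmt",
    "linkage_to_newick",
]

#: categorical codes for mode profiles (0 = pair absent); the integers
#: are labels only — distances are Hamming, never magnitude-based
MODE_CODES = {
    "absent": 0,
    "over": 1,
    "separable_over": 2,
    "under": 3,
    "separable_under": 4,
    "suppressed_under": 5,
    "SEE": 6,
    "SAW": 7,
}


def _record_code(r: DDPRecord) -> int:
    """Primary-label code of one record (SEESAW > suppressed > over/under)."""
    if r.seesaw is not None:
        return MODE_CODES[r.seesaw]
    if r.mode == "suppressed_under":
        return MODE_CODES["suppressed_under"]
    if r.mode == "over":
        return MODE_CODES["separable_over" if r.separable else "over"]
    if r.mode == "under":
        return MODE_CODES["separable_under" if r.separable else "under"]
    if r.separable:  # separable with no DE call: direction from the template
        return MODE_CODES["separable_over" if r.template_r >= 0 else "separable_under"]
    return MODE_CODES["absent"]


@dataclass(frozen=True)
class DependencyNetwork:
    dependency_nodes: frozenset
    ddp_nodes: frozenset  # predictors shared by >= 2 dependencies
    edges: tuple  # (dependency, predictor, mode-label) triples
    graph: nx.Graph = field(repr=False)  # bipartite
    projection: nx.Graph = field(repr=False)  # dependency-dependency, weighted

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edgelist(self, path) -> None:
        frame = pd.DataFrame(self.edges, columns=["dependency_id", "predictor_id", "label"])
        frame.to_csv(path, index=False)

    def write_projection(self, path) -> None:
        rows = [
            {"dependency_a": a, "dependency_b": b, "shared_ddps": d["weight"]}
            for a, b, d in sorted(self.projection.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["dependency_a", "dependency_b", "shared_ddps"]).to_csv(
            path, index=False
        )


def build_network(ddp_records: list[DDPRecord]) -> DependencyNetwork:
    """Bipartite shared-DDP network and its dependency projection.

    Only labeled records count; predictors seen in a single dependency
    are dropped (a "shared" DDP needs degree >= 2). Projection weights
    are exact pairwise intersection counts of the dependencies' shared-
    DDP sets.
    """
    labeled = [r for r in ddp_records if r.is_ddp]
    if not labeled:
        raise ValueError("no labeled DDP records to build a network from")
    by_predictor: dict[str, set[str]] = {}
    for r in labeled:
        by_predictor.setdefault(r.predictor_id, set()).add(r.dependency_id)
    shared = {g for g, deps in by_predictor.items() if len(deps) >= 2}

    graph = nx.Graph()
    edges = []
    for r in labeled:
        if r.predictor_id not in shared:
            continue
        graph.add_node(r.dependency_id, kind="dependency", bipartite=0)
        graph.add_node(r.predictor_id, kind="ddp", bipartite=1)
        graph.add_edge(r.dependency_id, r.predictor_id, label=r.label)
        edges.append((r.dependency_id, r.predictor_id, r.label))

    ddps_by_dep: dict[str, set[str]] = {}
    for g in shared:
        for d in by_predictor[g]:
            ddps_by_dep.setdefault(d, set()).add(g)
    projection = nx.Graph()
    projection.add_nodes_from(ddps_by_dep)
    for a, b in combinations(sorted(ddps_by_dep), 2):
        w = len(ddps_by_dep[a] & ddps_by_dep[b])
        if w > 0:
            projection.add_edge(a, b, weight=w)

    return DependencyNetwork(
        dependency_nodes=frozenset(ddps_by_dep),
        ddp_nodes=frozenset(shared),
        edges=tuple(sorted(edges)),
        graph=graph,
        projection=projection,
    )


def mode_matrix(ddp_records: list[DDPRecord], shared_only: bool = False) -> pd.DataFrame:
    """Dependency x predictor matrix of mode codes (0 = pair absent)."""
    labeled = [r for r in ddp_records if r.is_ddp]
    deps = sorted({r.dependency_id for r in labeled})
    if shared_only:
        counts: dict[str, set] = {}
        for r in labeled:
            counts.setdefault(r.predictor_id, set()).add(r.dependency_id)
        genes = sorted(g for g, d in counts.items() if len(d) >= 2)
    else:
        genes = sorted({r.predictor_id for r in labeled})
    mat = pd.DataFrame(0, index=deps, columns=genes, dtype=int)
    for r in labeled:
        if r.predictor_id in mat.columns:
            mat.loc[r.dependency_id, r.predictor_id] = _record_code(r)
    return mat


@dataclass(frozen=True)
class ClusteringResult:
    matrix: pd.DataFrame = field(repr=False)  # rows/cols in clustered order
    dependency_order: tuple
    ddp_order: tuple
    dependency_linkage: np.ndarray | None = field(default=None, repr=False)
    ddp_linkage: np.ndarray | None = field(default=None, repr=False)

    def newick(self, axis: str = "dependencies") -> str:
        if axis == "dependencies":
            link, labels = self.dependency_linkage, self.dependency_order
        else:
            link, labels = self.ddp_linkage, self.ddp_order
        if link is None:
            return "(" + ",".join(labels) + ");"
        # labels are in clustered order; linkage indexes the original order
        original = list(self.matrix.index if axis == "dependencies" else self.matrix.columns)
        reorder = sorted(original)  # linkage built on the sorted mode_matrix axes
        return linkage_to_newick(link, reorder)


def mode_profile_clustering(
    ddp_records: list[DDPRecord],
    linkage: str = "average",
    distance: str = "hamming",
    shared_only: bool = False,
) -> ClusteringResult:
    """Agglomerative clustering of both axes of the mode-code matrix."""
    mat = mode_matrix(ddp_records, shared_only=shared_only)

    def _cluster(frame: pd.DataFrame):
        if frame.shape[0] < 2:
            return None, tuple(frame.index)
        dists = pdist(frame.to_numpy(), metric=distance)
        link = hierarchy.linkage(dists, method=linkage)
        order = hierarchy.leaves_list(link)
        return link, tuple(frame.index[order])

    dep_link, dep_order = _cluster(mat)
    ddp_link, ddp_order = _cluster(mat.T)
    return ClusteringResult(
        matrix=mat.loc[list(dep_order), list(ddp_order)],
        dependency_order=dep_order,
        ddp_order=ddp_order,
        dependency_linkage=dep_link,
        ddp_linkage=ddp_link,
    )


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        return f"({left}:{node.dist / 2:g},{right}:{node.dist / 2:g})"

    return walk(tree) + ";"


def tissue_composition(
    dependent_sets: Iterable[DependentSet], ann: CellAnnotation
) -> pd.DataFrame:
    """Tissue make-up of each dependency's dependent cell lines.

    ``fraction`` is the share of the dependency's dependent cells from
    each tissue (sums to 1 per dependency); ``penetrance`` is dependent
    lines of the tissue / all annotated lines of that tissue.
    """
    tissue_totals = ann.tissues.value_counts()
    rows = []
    for ds in dependent_sets:
        cells = sorted(ds.dependent_cells)
        if not cells:
            continue
        tissues = pd.Series([ann.tissue_of(c) for c in cells])
        counts = tissues.value_counts()
        for tissue, n in counts.sort_index().items():
            rows.append(
                {
                    "dependency_id": ds.dependency_id,
                    "tissue": tissue,
                    "n_dependent": int(n),
                    "fraction": float(n / len(cells)),
                    "penetrance": float(n / tissue_totals[tissue]),
                }
            )
    return pd.DataFrame(
        rows, columns=["dependency_id", "tissue", "n_dependent", "fraction", "penetrance"]
    )


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    fdr: float
    enriched: bool


def overrepresentation(
    query: Iterable[str],
    gene_sets: dict[str, Iterable[str]],
    universe: Iterable[str],
    min_overlap: int = 5,
    fdr_cut: float = 0.25,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe first; p is the upper tail
    P(overlap >= observed), FDR is BH across all tested sets, and a set
    is flagged enriched when overlap >= ``min_overlap`` AND fdr <
    ``fdr_cut``. The full table is always returned.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query)
    if not query <= universe:
        raise ValueError(
            f"query genes outside the universe: {sorted(query - universe)[:5]}"
        )
    names, pvals, rows = [], [], []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        k = len(members & query)
        # P(X >= k), X ~ Hypergeom(M=|universe|, K=|set|, N=|query|)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        names.append(name)
        pvals.append(p)
        rows.append((name, k, len(members)))
    fdrs = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    return [
        EnrichmentResult(
            set_name=name,
            overlap=k,
            set_size=size,
            query_size=len(query),
            universe_size=len(universe),
            p=p,
            fdr=float(fdr),
            enriched=bool(k >= min_overlap and fdr < fdr_cut),
        )
        for (name, k, size), p, fdr in zip(rows, pvals, fdrs)
    ]


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "query_size": [r.query_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "enriched": [r.enriched for r in results],
        }
    )


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, members per line)."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
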