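"""Group-level connection-strength analysis over brain networks.

Subject feature matrices are averaged per diagnostic group, the mean
matrix is symmetrized (directionality ignored, keeping the larger of the
two directed strengths) and thresholded at 0.1, and the surviving
undirected edges are tallied per pair of the six canonical groupings:
sensorimotor cortex (SMC), visual cortex (VC), executive attention
network (EAN), default-mode network (DMN), subcortical nuclei (SN) and
cerebellum (Cereb). Edge lists are exported as plain text for external
connectome viewers; no 3-D rendering is done here.

The bundled AAL116 -> network assignment (data/aal116_networks.tsv) is an
editable reconstruction based on standard practice, not a canonical
ground truth; analyses depending on exact counts should review it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .features import ConnectivityFeatureMatrix

NETWORKS = ("SMC", "VC", "EAN", "DMN", "SN", "Cereb")


@dataclass
class NetworkMapping:
    """roi_id -> network label, with optional ROI names."""

    assignment: dict            # roi_id -> network
    roi_names: dict = None      # roi_id -> AAL name

    def __post_init__(self):
        bad = {v for v in self.assignment.values()} - set(NETWORKS)
        if bad:
            raise ValueError(f"unknown network labels {sorted(bad)}")
        if self.roi_names is None:
            self.roi_names = {}

    def network_of(self, roi_id) -> str:
        try:
            return self.assignment[roi_id]
        except KeyError:
            raise KeyError(f"ROI {roi_id} has no network assignment") from None


def load_network_mapping(path=None) -> NetworkMapping:
    """Load a mapping TSV (roi_id, roi_name, network); default = bundled AAL116."""
    if path is None:
        ref = resources.files("corrtf.data") / "aal116_networks.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return NetworkMapping(
        assignment=dict(zip(df["roi_id"].astype(int), df["network"])),
        roi_names=dict(zip(df["roi_id"].astype(int), df["roi_name"])),
    )


@dataclass(frozen=True)
class Edge:
    roi_a: int
    roi_b: int
    strength: float


@dataclass
class EdgeSet:
    """Undirected supra-threshold edges, roi_a < roi_b, no duplicates."""

    edges: frozenset
    threshold: float = 0.1

    def __post_init__(self):
        pairs = [(e.roi_a, e.roi_b) for e in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate ROI pairs in edge set")
        for e in self.edges:
            if e.roi_a >= e.roi_b:
                raise ValueError(f"edge ({e.roi_a}, {e.roi_b}) must satisfy roi_a < roi_b")

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(sorted(self.edges, key=lambda e: (e.roi_a, e.roi_b)))


def group_mean_matrix(subject_matrices) -> ConnectivityFeatureMatrix:
    """Elementwise mean of one diagnostic group's feature matrices."""
    mats = list(subject_matrices)
    if not mats:
        raise ValueError("need at least one subject matrix")
    roi_ids = mats[0].roi_ids
    for m in mats:
        if m.roi_ids != roi_ids:
            raise ValueError("subjects have mixed ROI orderings")
    stacked = np.stack([m.values for m in mats])
    return ConnectivityFeatureMatrix(stacked.mean(axis=0), roi_ids=list(roi_ids))


def threshold_edges(matrix: ConnectivityFeatureMatrix, threshold: float = 0.1) -> EdgeSet:
    """Undirected edges whose stronger direction reaches the threshold.

    Pair (i, j) is kept iff max(M[i,j], M[j,i]) >= threshold, with that
    max as the edge strength (boundary inclusive).
    """
    M = np.asarray(matrix.values, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("feature matrix contains non-finite entries")
    R = M.shape[0]
    edges = set()
    sym = np.maximum(M, M.T)
    for i in range(R):
        for j in range(i + 1, R):
            if sym[i, j] >= threshold:
                a, b = matrix.roi_ids[i], matrix.roi_ids[j]
                if a > b:
                    a, b = b, a
                edges.add(Edge(a, b, float(sym[i, j])))
    return EdgeSet(frozenset(edges), threshold=threshold)


def count_network_pairs(edges: EdgeSet, mapping: NetworkMapping) -> pd.DataFrame:
    """Symmetric 6x6 table of edge counts per network pair.

    Within-network edges are counted once, on the diagonal; the grand
    total (upper triangle incl. diagonal) equals the number of edges.
    """
    counts = pd.DataFrame(0, index=list(NETWORKS), columns=list(NETWORKS))
    for e in edges:
        p = mapping.network_of(e.roi_a)
        q = mapping.network_of(e.roi_b)
        counts.loc[p, q] += 1
        if p != q:
            counts.loc[q, p] += 1
    return counts


def export_edge_list(edges: EdgeSet, node_path, edge_path,
                     mapping: NetworkMapping = None, coordinates: dict = None) -> None:
    """Write viewer-ready node and edge text files.

    Node file columns: roi_id, network, optional x/y/z; edge file columns:
    roi_a, roi_b, strength. The pair round-trips via read_edge_list.
    """
    rois = sorted({e.roi_a for e in edges} | {e.roi_b for e in edges})
    rows = []
    for roi in rois:
        row = {"roi_id": roi}
        if mapping is not None:
            row["network"] = mapping.network_of(roi)
            row["roi_name"] = mapping.roi_names.get(roi, str(roi))
        if coordinates is not None:
            if roi not in coordinates:
                raise ValueError(f"coordinate table is missing ROI {roi}")
            row["x"], row["y"], row["z"] = coordinates[roi]
        rows.append(row)
    cols = ["roi_id"]
    if mapping is not None:
        cols += ["network", "roi_name"]
    if coordinates is not None:
        cols += ["x", "y", "z"]
    pd.DataFrame(rows, columns=cols).to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(
        [(e.roi_a, e.roi_b, e.strength) for e in edges],
        columns=["roi_a", "roi_b", "strength"],
    ).to_csv(edge_path, sep="\t", index=False)


def read_edge_list(edge_path, threshold: float = 0.1) -> EdgeSet:
    df = pd.read_csv(edge_path, sep="\t")
    edges = frozenset(
        Edge(int(r.roi_a), int(r.roi_b), float(r.strength)) for r in df.itertuples()
    )
    return EdgeSet(edges, threshold=threshold)
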