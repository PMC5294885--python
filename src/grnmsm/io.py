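"""Writers for the standard interchange formats used by the pipeline.

Sparse matrices go to Matrix Market, tables to TSV/CSV, MSM graphs to
GraphML and DOT.  Everything written here is plain text and diff-able.
"""

from __future__ import annotations

import csv
import json
import hashlib
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.io
import scipy.sparse as sp

__all__ = [
    "write_mtx",
    "write_table",
    "write_spectrum",
    "write_membership",
    "write_msm_graph",
    "write_manifest",
]


def write_mtx(path, matrix) -> None:
    scipy.io.mmwrite(str(path), sp.coo_matrix(matrix))


def write_table(path, rows, header, *, delimiter="\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(header)
        for row in rows:
            w.writerow(row)


def write_spectrum(path, spectral) -> None:
    write_table(
        path,
        spectral.to_table(),
        ("index", "re_lambda", "im_lambda", "mod_lambda", "timescale"),
    )


def write_membership(path, chi, labels) -> None:
    C = chi.shape[1]
    rows = (
        (i, *(f"{v:.8g}" for v in chi[i]), int(labels[i]))
        for i in range(chi.shape[0])
    )
    write_table(path, rows, ("state", *(f"chi_{j + 1}" for j in range(C)), "crisp"))


def write_msm_graph(path_graphml, path_dot, msm, *, edge_cut: float = 0.0) -> None:
    """MSM as a weighted digraph: node weight pi~, edge weight T~ entries."""
    G = nx.DiGraph()
    C = msm.n_macrostates
    for j in range(C):
        G.add_node(j + 1, stationary_probability=float(msm.pi_c[j]))
    for i in range(C):
        for j in range(C):
            if i != j and msm.T_c[i, j] > edge_cut:
                G.add_edge(i + 1, j + 1, probability=float(msm.T_c[i, j]))
    if path_graphml is not None:
        nx.write_graphml(G, str(path_graphml))
    if path_dot is not None:
        with open(path_dot, "w") as fh:
            fh.write("digraph msm {\n")
            for n, d in G.nodes(data=True):
                fh.write(f'  {n} [weight="{d["stationary_probability"]:.6g}"];\n')
            for a, b, d in G.edges(data=True):
                fh.write(f'  {a} -> {b} [weight="{d["probability"]:.6g}"];\n')
            fh.write("}\n")


def write_manifest(path, config: dict, *, seed=None, extra=None) -> None:
    """Reproducibility manifest: config hash, seeds, library versions."""
    import scipy as _scipy

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {"numpy": np.__version__, "scipy": _scipy.__version__},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
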