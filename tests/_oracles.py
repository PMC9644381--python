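"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's fast paths: distances enumerate all 27
periodic image translations explicitly, H-bond detection loops over candidate
pairs with the enumerated-image geometry, MSD averages origins directly, and
generation tracing delegates to networkx shortest paths.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

# all 27 lattice translations (fractional)
_SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def brute_force_min_image(p, q, box):
    """Min distance between p and the 27 images of q; also the displacement."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    box = np.asarray(box, float)
    candidates = q + _SHIFTS * box - p
    dists = np.linalg.norm(candidates, axis=1)
    k = int(np.argmin(dists))
    return float(dists[k]), candidates[k]


def brute_force_hbonds(frame, topology, d_cut=0.35, angle_cut=30.0, vertex="donor"):
    """O(N^2) H-bond detection with explicit 27-image enumeration.

    Returns a set of (donor_atom, hydrogen_atom, acceptor_atom) triples.
    """
    from asdkit.model import ROLE_ACCEPTOR

    box = frame.box
    acceptors = [a.atom_id for a in topology.atoms if ROLE_ACCEPTOR in a.roles]
    found = set()
    cos_cut = np.cos(np.deg2rad(angle_cut))
    for d, h in topology.donor_hydrogen_pairs:
        for a in acceptors:
            if a in (d, h):
                continue
            if topology.molecule_of_atom[d] == topology.molecule_of_atom[a]:
                continue
            dist, da = brute_force_min_image(
                frame.positions[d], frame.positions[a], box
            )
            if dist > d_cut:
                continue
            _, dh = brute_force_min_image(frame.positions[d], frame.positions[h], box)
            if vertex == "donor":
                u, v = dh, da
                cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                ok = cosang >= cos_cut - 1e-12
            else:
                u, v = -dh, da - dh
                cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                ok = cosang <= -cos_cut + 1e-12
            if ok:
                found.add((d, h, a))
    return found


def brute_force_msd(path):
    """Direct time-origin-averaged MSD for a single (F, 3) path."""
    n = len(path)
    msd = np.zeros(n)
    for lag in range(1, n):
        d = path[lag:] - path[:-lag]
        msd[lag] = (d * d).sum(axis=1).mean()
    return msd

def generation_oracle(protein_nodes, edges, drug_nodes):
    """Multi-source shortest-path depths via networkx."""
    g = nx.Graph()
    g.add_nodes_from(protein_nodes)
    g.add_nodes_from(drug_nodes)
    g.add_edges_from(edges)
    depth = nx.multi_source_dijkstra_path_length(g, set(protein_nodes)) if protein_nodes else {}
    return {n: (int(depth[n]) if n in depth else None) for n in drug_nodes}
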