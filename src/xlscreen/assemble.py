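"""Higher-order assembly inference from binary complex predictions.

Confidently predicted pairs (best ipTM strictly above a threshold, 0.65 by
default) form an undirected interaction graph.  Connected components with
three or more proteins are candidate higher-order complexes; components of
exactly three proteins — whether a path or a triangle — are candidate 1:1:1
trimers.  Binary models sharing a chain are merged into larger assemblies by
least-squares rigid superposition (Kabsch) of the shared chain, without any
refinement: the superposition RMSD and the Cα steric clash count are reported
so the user can judge each merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from xlscreen.model_io import Chain, ScoreRecord, StructureModel

__all__ = [
    "AssemblyModel",
    "GRAPH_THRESHOLD",
    "build_graph",
    "find_groups",
    "trimer_candidates",
    "superpose",
    "merge_models",
]

GRAPH_THRESHOLD = 0.65
CLASH_DISTANCE = 3.0  # Å between Cα of different source models


def build_graph(
    records: Iterable[ScoreRecord],
    threshold: float = GRAPH_THRESHOLD,
) -> nx.Graph:
    """Simple undirected PPI graph with an edge iff best ipTM > threshold.

    The inequality is strict; self-pairs never produce edges (the graph has
    no self-loops).  Edge weights carry the best ipTM.
    """
    g = nx.Graph(threshold=threshold)
    for rec in records:
        a, b = rec.members[0], rec.members[-1]
        if a == b:
            continue
        score = rec.best_iptm
        if score > threshold:
            if g.has_edge(a, b):
                score = max(score, g[a][b]["weight"])
            g.add_edge(a, b, weight=score)
    return g


def find_groups(g: nx.Graph) -> tuple[list[tuple[str, ...]], dict[int, int],
                                      list[tuple[str, str]]]:
    """Connected components with >= 3 proteins (candidate complexes).

    Returns (groups sorted by size then name, size histogram over the groups,
    isolated binary components reported separately).
    """
    groups, pairs = [], []
    for comp in nx.connected_components(g):
        members = tuple(sorted(comp))
        if len(members) >= 3:
            groups.append(members)
        elif len(members) == 2:
            pairs.append(members)
    groups.sort(key=lambda m: (-len(m), m))
    hist: dict[int, int] = {}
    for m in groups:
        hist[len(m)] = hist.get(len(m), 0) + 1
    return groups, hist, sorted(pairs)


def trimer_candidates(g: nx.Graph) -> list[tuple[str, str, str]]:
    """Components of exactly three proteins, path or triangle, sorted."""
    groups, _, _ = find_groups(g)
    return sorted(m for m in groups if len(m) == 3)


def superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of Q onto P (Kabsch).

    Returns (rotation, translation, rmsd) such that ``Q @ rotation.T +
    translation`` best fits P.  The rotation is proper (determinant +1);
    degenerate point sets never produce a reflection.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (N, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    rmsd = float(np.sqrt(np.mean(np.sum((Q @ R.T + t - P) ** 2, axis=1))))
    return R, t, rmsd


@dataclass
class AssemblyModel:
    """Multi-chain model merged from binary models sharing chains."""

    chains: list[Chain]
    provenance: list[str] = field(default_factory=list)  # source model ids
    chain_source: list[str] = field(default_factory=list)  # model id per chain
    merge_rmsd: list[float] = field(default_factory=list)  # one per merge step
    clash_counts: list[int] = field(default_factory=list)

    @classmethod
    def from_model(cls, model: StructureModel) -> "AssemblyModel":
        return cls(
            chains=list(model.chains),
            provenance=[model.model_id],
            chain_source=[model.model_id] * len(model.chains),
        )

    def chains_for(self, accession: str) -> list[Chain]:
        return [c for c in self.chains if c.accession == accession]

    def _next_chain_id(self) -> str:
        used = {c.chain_id for c in self.chains}
        for code in range(ord("A"), ord("Z") + 1):
            if chr(code) not in used:
                return chr(code)
        return str(len(self.chains))


def _common_residues(a: Chain, b: Chain) -> np.ndarray:
    return np.intersect1d(a.residue_numbers, b.residue_numbers)


def _coords_at(chain: Chain, residues: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(chain.residue_numbers, residues)
    return chain.coords[idx]


def merge_models(
    reference: StructureModel | AssemblyModel,
    incoming: StructureModel,
    shared_accession: str,
    clash_distance: float = CLASH_DISTANCE,
) -> AssemblyModel:
    """Merge a binary model into an assembly via their shared chain.

    The incoming model is rigidly transformed by superposing its copy of
    ``shared_accession`` onto the reference's copy (common resolved residues
    only); the incoming shared chain is then discarded and its partner chains
    are added.  When the shared accession occurs on several chains, the chain
    pair with the lowest superposition RMSD is used.  The merge RMSD and the
    count of inter-source Cα pairs closer than ``clash_distance`` are
    appended to the assembly's ledger.
    """
    asm = reference if isinstance(reference, AssemblyModel) \
        else AssemblyModel.from_model(reference)
    ref_chains = asm.chains_for(shared_accession)
    inc_chains = incoming.chains_for(shared_accession)
    if not ref_chains or not inc_chains:
        raise ValueError(f"no chain with accession {shared_accession!r} in both models")

    best = None
    for rc in ref_chains:
        for ic in inc_chains:
            common = _common_residues(rc, ic)
            if len(common) < 3:
                continue
            R, t, rmsd = superpose(_coords_at(rc, common), _coords_at(ic, common))
            if best is None or rmsd < best[0]:
                best = (rmsd, R, t, ic)
    if best is None:
        raise ValueError(
            f"fewer than 3 common resolved residues on {shared_accession!r}"
        )
    rmsd, R, t, shared_chain = best

    new_chains = []
    for chain in incoming.chains:
        if chain is shared_chain:
            continue
        new_chains.append(
            Chain(
                chain_id="?",
                accession=chain.accession,
                coords=chain.coords @ R.T + t,
                residue_numbers=chain.residue_numbers.copy(),
                length=chain.length,
                plddt=None if chain.plddt is None else chain.plddt.copy(),
            )
        )

    existing = np.vstack([c.coords for c in asm.chains])
    clashes = 0
    for chain in new_chains:
        clashes += int(np.sum(cdist(chain.coords, existing) < clash_distance))

    for chain in new_chains:
        chain.chain_id = asm._next_chain_id()
        asm.chains.append(chain)
        asm.chain_source.append(incoming.model_id)
    asm.provenance.append(incoming.model_id)
    asm.merge_rmsd.append(rmsd)
    asm.clash_counts.append(clashes)
    return asm
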