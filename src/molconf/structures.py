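"""Molecular-structure comparison: Tanimoto, MCES distance, 2D identity.

Two complementary dissimilarity notions are provided. The Tanimoto
coefficient (Jaccard index of two molecular-property sets) is cheap and
fingerprint-agnostic, but it saturates for highly similar molecules. For
near-identical structures the maximum-common-edge-subgraph (MCES) distance
is used instead: the minimum total number of edges that must be deleted
from the two hydrogen-free molecular graphs so the remainders become
isomorphic, with no connectivity requirement on the common subgraph. Node
element labels and bond multiplicities must match under the isomorphism.
The problem is NP-complete; the solver here is exact and intended for
small molecules only (it refuses inputs above a combined edge budget).

Hit correctness is judged on 2D structure: stereochemistry and charges are
not distinguished, so e.g. L- and D-threose count as identical.
"""

from __future__ import annotations

from itertools import combinations
from typing import FrozenSet, Iterable, Set

import networkx as nx
from networkx.algorithms import isomorphism as nx_iso

__all__ = [
    "tanimoto",
    "mol_graph_from_smiles",
    "mces_distance",
    "structures_identical_2d",
    "canonical_2d_key",
]


def tanimoto(a: Iterable[int], b: Iterable[int]) -> float:
    """Jaccard index of two molecular-property index sets, in [0, 1].

    Two empty fingerprints are defined as identical (1.0).
    """
    sa: FrozenSet = frozenset(a)
    sb: FrozenSet = frozenset(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def mol_graph_from_smiles(smiles: str) -> nx.Graph:
    """Hydrogen-free molecular graph from SMILES.

    Nodes carry an ``element`` attribute, edges an ``order`` (bond
    multiplicity as a float; aromatic bonds are 1.5). Connectivity is not
    required. Unparseable input raises ValueError.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES: {smiles!r}")
    mol = Chem.RemoveHs(mol)
    g = nx.Graph()
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "H":
            continue
        g.add_node(atom.GetIdx(), element=atom.GetSymbol())
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in g and j in g:
            g.add_edge(i, j, order=float(bond.GetBondTypeAsDouble()))
    return g


def _node_match(a, b) -> bool:
    return a.get("element") == b.get("element")


def _edge_match(a, b) -> bool:
    return a.get("order") == b.get("order")


def _edge_subgraph(g: nx.Graph, edges) -> nx.Graph:
    """Edge-induced subgraph without isolated vertices."""
    h = nx.Graph()
    for u, v in edges:
        h.add_node(u, **g.nodes[u])
        h.add_node(v, **g.nodes[v])
        h.add_edge(u, v, **g.edges[u, v])
    return h


def _embeds(h: nx.Graph, g: nx.Graph) -> bool:
    """Whether h maps injectively into g preserving labelled edges.

    A monomorphism suffices: extra edges of g among the mapped nodes do
    not matter, since only h's edges need to be common.
    """
    gm = nx_iso.GraphMatcher(g, h, node_match=_node_match, edge_match=_edge_match)
    return gm.subgraph_is_monomorphic()


def _isomorphic(a: nx.Graph, b: nx.Graph) -> bool:
    return nx.is_isomorphic(a, b, node_match=_node_match, edge_match=_edge_match)


def mces_distance(
    g1: nx.Graph | str, g2: nx.Graph | str, max_size: int = 30
) -> int:
    """Minimum total edge deletions making the two graphs isomorphic.

    Accepts molecular graphs or SMILES strings. Isolated vertices left
    behind by deletions are ignored (the common subgraph is edge-induced
    and need not be connected). Returns 0 iff the graphs are isomorphic;
    for non-isomorphic graphs with equal edge counts the distance is >= 2
    and even. Exact branch-and-bound over edge subsets of the smaller
    graph with monomorphism tests; inputs with more than ``max_size``
    combined edges are refused rather than solved heuristically.
    """
    if isinstance(g1, str):
        g1 = mol_graph_from_smiles(g1)
    if isinstance(g2, str):
        g2 = mol_graph_from_smiles(g2)
    e1, e2 = g1.number_of_edges(), g2.number_of_edges()
    if e1 + e2 > max_size:
        raise ValueError(
            f"combined edge count {e1 + e2} exceeds the exact-solver limit "
            f"({max_size}); MCES is NP-complete and no heuristic fallback is "
            "provided"
        )
    small, big = (g1, g2) if e1 <= e2 else (g2, g1)
    es, eb = small.number_of_edges(), big.number_of_edges()
    edges = list(small.edges())
    # largest common edge subgraph of size k gives distance (es - k) + (eb - k)
    for k in range(es, -1, -1):
        if k == 0:
            return es + eb
        for subset in combinations(edges, k):
            h = _edge_subgraph(small, subset)
            if _embeds(h, big):
                return (es - k) + (eb - k)
    return es + eb  # unreachable; k = 0 always embeds


def canonical_2d_key(smiles: str) -> str:
    """Canonical SMILES with stereochemistry (and isotopes) stripped.

    Serves as the 2D identity key: two inputs denote the same structure
    iff their keys are equal. Local canonicalization stands in for an
    external structure-standardization service.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    return Chem.MolToSmiles(mol, isomericSmiles=False, canonical=True)


def structures_identical_2d(smiles_a: str, smiles_b: str) -> bool:
    """Whether two structures are identical in 2D (stereo ignored)."""
    return canonical_2d_key(smiles_a) == canonical_2d_key(smiles_b)
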