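"""Structured-coalescent gene-tree simulation on species networks.

Simulates genealogies backwards in time under an n-taxon ultrametric
species tree (branch lengths in 2N generations, one haploid sample per
species) with instantaneous introgression pulses: at a pulse time each
lineage currently in the recipient population independently jumps to the
donor population with the pulse probability, after which the ordinary
multispecies coalescent continues.  Within a population k lineages
coalesce at rate k(k-1)/2 per 2N generations.  Each locus records which
pulses (if any) its lineages took, so downstream summaries can separate
loci that follow the species branching history from introgressed
histories.

The per-locus engine is a numba kernel operating on flat arrays; the
object layer (:class:`SpeciesNetwork`, :class:`GeneTree`) wraps it for
Newick I/O and validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Sequence, Tuple

import dendropy
import numpy as np
from numba import njit

__all__ = [
    "IntrogressionPulse",
    "SpeciesNetwork",
    "GeneTree",
    "simulate_gene_trees",
    "simulate_batch",
    "prune_to_focal_clade",
    "ULTRAMETRIC_TOL",
]

ULTRAMETRIC_TOL = 1e-6


class NetworkConfigError(ValueError):
    pass


@dataclass(frozen=True)
class IntrogressionPulse:
    """An instantaneous pulse: forward in time, genes flow donor -> recipient.

    ``donor`` and ``recipient`` name a tip whose ancestral lineage at
    ``time`` identifies the population; ``probability`` is the chance a
    lineage of the recipient follows the donor's history at this locus.
    """

    donor: str
    recipient: str
    time: float
    probability: float

    def __post_init__(self):
        if not 0 < self.probability <= 1:
            raise NetworkConfigError("pulse probability must be in (0, 1]")
        if self.time <= 0:
            raise NetworkConfigError("pulse time must be positive")


class SpeciesNetwork:
    """Rooted ultrametric species tree plus introgression pulses.

    Node ages are in units of 2N generations.  Internally the topology is
    held as parent/age arrays over node ids 0..2n-2 with tips 0..n-1 in
    taxon order; the branch above node ``i`` is population ``i``.
    """

    def __init__(self, taxa: Sequence[str], parent: np.ndarray, age: np.ndarray,
                 pulses: Sequence[IntrogressionPulse] = (), outgroup: str | None = None):
        self.taxa = tuple(taxa)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.age = np.asarray(age, dtype=np.float64)
        self.pulses = tuple(pulses)
        self.outgroup = outgroup
        self._validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, pulses: Sequence[IntrogressionPulse] = (),
                    outgroup: str | None = None) -> "SpeciesNetwork":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
        return cls.from_dendropy(tree, pulses=pulses, outgroup=outgroup)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, pulses: Sequence[IntrogressionPulse] = (),
                      outgroup: str | None = None) -> "SpeciesNetwork":
        tree = tree.clone(depth=1)
        tree.calc_node_ages(ultrametricity_precision=False)
        leaves = [lf for lf in tree.leaf_node_iter()]
        taxa = [lf.taxon.label for lf in leaves]
        n = len(taxa)
        internals = [nd for nd in tree.postorder_internal_node_iter()]
        if any(len(nd.child_nodes()) != 2 for nd in internals):
            raise NetworkConfigError("species tree must be binary and rooted")
        ids = {}
        for i, lf in enumerate(leaves):
            ids[lf] = i
        # internal ids in order of increasing age so children precede parents
        for j, nd in enumerate(sorted(internals, key=lambda nd: nd.age)):
            ids[nd] = n + j
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        age = np.zeros(2 * n - 1)
        for nd, i in ids.items():
            age[i] = nd.age if nd.age is not None else 0.0
            if nd.parent_node is not None:
                parent[i] = ids[nd.parent_node]
        age[:n] = 0.0
        return cls(taxa, parent, age, pulses=pulses, outgroup=outgroup)

    def to_newick(self) -> str:
        return _newick_from_arrays(self.parent, self.age, self.taxa) + ";"

    # -- validation --------------------------------------------------------
    def _validate(self):
        n = self.n_taxa
        if len(set(self.taxa)) != n:
            raise NetworkConfigError("duplicate taxon labels")
        if self.parent.shape[0] != 2 * n - 1:
            raise NetworkConfigError("malformed topology arrays")
        for i in range(2 * n - 2):
            p = self.parent[i]
            if p < 0:
                raise NetworkConfigError("non-root node without parent")
            if not self.age[p] > self.age[i]:
                raise NetworkConfigError("child age must be below parent age")
        # ultrametric: tips all at age 0 by construction; check input depths
        root = 2 * n - 2
        if self.age[root] <= 0:
            raise NetworkConfigError("root age must be positive")
        for pulse in self.pulses:
            for lab in (pulse.donor, pulse.recipient):
                if lab not in self.taxa:
                    raise NetworkConfigError(f"pulse taxon {lab!r} not in tree")
            db = self._branch_at(pulse.donor, pulse.time)
            rb = self._branch_at(pulse.recipient, pulse.time)
            if db == rb:
                raise NetworkConfigError(
                    f"pulse at t={pulse.time} lies above the divergence of "
                    f"{pulse.donor!r} and {pulse.recipient!r}"
                )
        if self.outgroup is not None and self.outgroup not in self.taxa:
            raise NetworkConfigError(f"outgroup {self.outgroup!r} not in tree")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def root_age(self) -> float:
        return float(self.age[2 * self.n_taxa - 2])

    def _branch_at(self, taxon: str, time: float) -> int:
        """Species-tree branch (node id) containing the taxon's lineage at a time."""
        i = self.taxa.index(taxon)
        while self.parent[i] >= 0 and self.age[self.parent[i]] <= time:
            i = self.parent[i]
        if time >= self.root_age:
            raise NetworkConfigError(f"time {time} is at or above the root")
        return i

    # -- event schedule for the kernel ------------------------------------
    def _event_arrays(self):
        n = self.n_taxa
        events = []  # (time, order, kind, i1, i2, i3, prob)
        children: dict[int, list[int]] = {}
        for i in range(2 * n - 2):
            children.setdefault(int(self.parent[i]), []).append(i)
        for node, chs in children.items():
            events.append((float(self.age[node]), 1, 0, chs[0], chs[1], node, 0.0))
        for k, pulse in enumerate(self.pulses):
            rb = self._branch_at(pulse.recipient, pulse.time)
            db = self._branch_at(pulse.donor, pulse.time)
            events.append((pulse.time, 0, 1, rb, db, k, pulse.probability))
        events.sort()
        ev_time = np.array([e[0] for e in events])
        ev_kind = np.array([e[2] for e in events], dtype=np.int64)
        ev_i = np.array([[e[3], e[4], e[5]] for e in events], dtype=np.int64)
        ev_p = np.array([e[6] for e in events])
        return ev_time, ev_kind, ev_i, ev_p


# ---------------------------------------------------------------------------
# numba kernel

@njit(cache=True)
def _simulate_kernel(n_loci, n, ev_time, ev_kind, ev_i, ev_p, seed,
                     out_parent, out_age, out_origin):  # pragma: no cover - jit
    np.random.seed(seed)
    n_ev = ev_time.shape[0]
    lin_node = np.empty(n, dtype=np.int64)
    lin_pop = np.empty(n, dtype=np.int64)
    for locus in range(n_loci):
        for i in range(n):
            lin_node[i] = i
            lin_pop[i] = i
            out_age[locus, i] = 0.0
        out_parent[locus, :] = -1
        origin = 0
        active = n
        next_node = n
        t = 0.0
        ei = 0
        while active > 1:
            t_event = ev_time[ei] if ei < n_ev else 1e300
            # coalesce until the next scheduled event
            while True:
                npairs = 0
                for i in range(active):
                    for j in range(i + 1, active):
                        if lin_pop[i] == lin_pop[j]:
                            npairs += 1
                if npairs == 0:
                    t = t_event
                    break
                dt = np.random.exponential(1.0 / npairs)
                if t + dt >= t_event:
                    t = t_event
                    break
                t = t + dt
                pick = np.random.randint(npairs)
                ii = -1
                jj = -1
                c = 0
                done = False
                for i in range(active):
                    if done:
                        break
                    for j in range(i + 1, active):
                        if lin_pop[i] == lin_pop[j]:
                            if c == pick:
                                ii = i
                                jj = j
                                done = True
                                break
                            c += 1
                node = next_node
                next_node += 1
                out_age[locus, node] = t
                out_parent[locus, lin_node[ii]] = node
                out_parent[locus, lin_node[jj]] = node
                lin_node[ii] = node
                lin_node[jj] = lin_node[active - 1]
                lin_pop[jj] = lin_pop[active - 1]
                active -= 1
                if active == 1:
                    break
            if active == 1:
                break
            if ei >= n_ev:
                # should be unreachable: all lineages share the root population
                break
            if ev_kind[ei] == 0:
                a = ev_i[ei, 0]
                b = ev_i[ei, 1]
                c2 = ev_i[ei, 2]
                for i in range(active):
                    if lin_pop[i] == a or lin_pop[i] == b:
                        lin_pop[i] = c2
            else:
                recip = ev_i[ei, 0]
                donor = ev_i[ei, 1]
                pidx = ev_i[ei, 2]
                for i in range(active):
                    if lin_pop[i] == recip:
                        if np.random.random() < ev_p[ei]:
                            lin_pop[i] = donor
                            origin |= 1 << pidx
            ei += 1
        out_origin[locus] = origin


def simulate_batch(net: SpeciesNetwork, n_trees: int, seed: int
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate ``n_trees`` genealogies; returns (parent, age, origin) arrays.

    ``parent`` is (n_trees, 2n-1) with -1 at the root, node ids assigned in
    coalescence order (tips 0..n-1 in ``net.taxa`` order); ``age`` holds
    node ages in 2N generations; ``origin`` is a bitmask of pulses taken
    (0 = species branching history).
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    n = net.n_taxa
    ev_time, ev_kind, ev_i, ev_p = net._event_arrays()
    parent = np.empty((n_trees, 2 * n - 1), dtype=np.int64)
    age = np.empty((n_trees, 2 * n - 1))
    origin = np.empty(n_trees, dtype=np.int64)
    _simulate_kernel(n_trees, n, ev_time, ev_kind, ev_i, ev_p,
                     int(seed) % (2 ** 32), parent, age, origin)
    return parent, age, origin


@dataclass
class GeneTree:
    """A simulated genealogy with branch lengths in 2N generations."""

    taxa: Tuple[str, ...]
    parent: np.ndarray  # (2n-1,), -1 at root
    age: np.ndarray
    origin: int = 0  # bitmask of pulses taken; 0 = species history

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def root_age(self) -> float:
        return float(self.age[-1])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        idx = np.arange(self.parent.shape[0] - 1)
        return self.age[self.parent[idx]] - self.age[idx]

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        return bool(np.all(np.abs(self.age[: self.n_taxa]) <= tol))

    def to_newick(self) -> str:
        return _newick_from_arrays(self.parent, self.age, self.taxa) + ";"


def simulate_gene_trees(net: SpeciesNetwork, n_trees: int, seed: int
                        ) -> Iterator[GeneTree]:
    """Stream :class:`GeneTree` objects; reproducible for a fixed seed."""
    parent, age, origin = simulate_batch(net, n_trees, seed)
    for k in range(n_trees):
        yield GeneTree(net.taxa, parent[k], age[k], int(origin[k]))


def _newick_from_arrays(parent: np.ndarray, age: np.ndarray,
                        taxa: Sequence[str]) -> str:
    n = len(taxa)
    nn = parent.shape[0]
    children: List[List[int]] = [[] for _ in range(nn)]
    root = -1
    for i in range(nn):
        if parent[i] >= 0:
            children[parent[i]].append(i)
        else:
            root = i

    def rec(i: int) -> str:
        if i < n:
            lab = taxa[i]
        else:
            lab = ""
        if children[i]:
            inner = ",".join(rec(c) for c in children[i])
            body = f"({inner}){lab}"
        else:
            body = lab
        if parent[i] >= 0:
            return f"{body}:{age[parent[i]] - age[i]:.10g}"
        return body

    return rec(root)


# ---------------------------------------------------------------------------
# pruning

def prune_to_focal_clade(net: SpeciesNetwork, derived_taxa: Iterable[str],
                         outgroup: str) -> SpeciesNetwork:
    """Smallest clade containing all derived taxa, plus the outgroup
    re-grafted at its original divergence time from that clade.

    Pulses touching dropped taxa are removed with a warning.
    """
    derived = set(derived_taxa)
    missing = derived - set(net.taxa)
    if missing:
        raise NetworkConfigError(f"derived taxa not in tree: {sorted(missing)}")
    if outgroup not in net.taxa:
        raise NetworkConfigError(f"outgroup {outgroup!r} not in tree")
    n = net.n_taxa
    # MRCA of derived taxa
    sets = {i: {i} for i in range(2 * n - 1)}
    for i in range(2 * n - 2):
        pass
    # tip sets bottom-up (ids ordered children-before-parents)
    tipsets: List[set] = [set() for _ in range(2 * n - 1)]
    for i in range(n):
        tipsets[i] = {net.taxa[i]}
    for i in range(2 * n - 2):
        tipsets[net.parent[i]] |= tipsets[i]
    mrca = min((i for i in range(2 * n - 1) if derived <= tipsets[i]),
               key=lambda i: net.age[i])
    if mrca == 2 * n - 2:
        # the derived taxa span the root: nothing to prune
        if outgroup in derived:
            raise NetworkConfigError(
                f"outgroup {outgroup!r} carries the derived state")
        return SpeciesNetwork(net.taxa, net.parent, net.age,
                              pulses=net.pulses, outgroup=outgroup)
    if outgroup in tipsets[mrca]:
        raise NetworkConfigError(
            f"outgroup {outgroup!r} lies inside the minimal derived clade")
    keep = set(tipsets[mrca]) | {outgroup}
    # outgroup divergence time from the focal lineage = age of MRCA(keep)
    mrca_all = min((i for i in range(2 * n - 1) if keep <= tipsets[i]),
                   key=lambda i: net.age[i])
    graft_age = float(net.age[mrca_all])

    kept_pulses = []
    for pulse in net.pulses:
        if pulse.donor in keep and pulse.recipient in keep and pulse.time < graft_age:
            kept_pulses.append(pulse)
        else:
            warnings.warn(
                f"dropping introgression pulse {pulse.donor}->{pulse.recipient} "
                f"at t={pulse.time}: outside the pruned clade")
    if keep == set(net.taxa):
        return SpeciesNetwork(net.taxa, net.parent, net.age,
                              pulses=kept_pulses, outgroup=outgroup)

    tree = dendropy.Tree.get(data=net.to_newick(), schema="newick",
                             preserve_underscores=True)
    taxa_to_keep = [t for t in tree.taxon_namespace if t.label in (keep - {outgroup})]
    sub = tree.extract_tree_with_taxa(taxa=taxa_to_keep)
    sub.purge_taxon_namespace()
    sub_newick = sub.as_string(schema="newick", suppress_rooting=True).strip()
    sub_net = SpeciesNetwork.from_newick(sub_newick)
    # graft outgroup: new root at graft_age
    new_newick = (
        f"({_newick_from_arrays(sub_net.parent, sub_net.age, sub_net.taxa)}"
        f":{graft_age - sub_net.root_age:.10g},{outgroup}:{graft_age:.10g});"
    )
    return SpeciesNetwork.from_newick(new_newick, pulses=kept_pulses,
                                      outgroup=outgroup)
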