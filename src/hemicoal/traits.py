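"""Binary-trait evolution along gene trees with explicit mutation events.

A single two-state character evolves along each genealogy: mutations are a
Poisson process at a constant symmetric rate (events per 2N generations)
independently on every branch, and each event flips the current state.
The root state is 0 (ancestral).  Optionally the ancestral state can be
anchored at a reference depth above the gene-tree root (``root_depth``),
in which case the stem from that depth down to the root is mutated too —
this matches the analytic model's ancestral branch.

Unlike a nucleotide-simulation pipeline, events are explicit, so mutation
counts, tip-vs-internal placement and forward-vs-reversal direction are
exact rather than inferred from site patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from numba import njit

from .simulate import GeneTree

__all__ = ["MutationEvent", "TraitRealization", "evolve_trait", "evolve_batch"]


@dataclass(frozen=True)
class MutationEvent:
    """A single state flip on a gene-tree branch.

    ``branch`` is the gene-tree node id below the branch (-1 for the stem
    above the root when the ancestral state is anchored at a reference
    depth); ``time`` is the age of the event in 2N generations.
    """

    branch: int
    time: float
    direction: Tuple[int, int]  # (0, 1) forward or (1, 0) reversal
    branch_class: str  # "tip" | "internal" | "stem"


@dataclass
class TraitRealization:
    """Tip states plus the ordered mutation events that produced them."""

    tree: GeneTree
    tip_states: Dict[str, int]
    events: List[MutationEvent] = field(default_factory=list)
    root_state: int = 0

    @property
    def n_events(self) -> int:
        return len(self.events)

    def derived_taxa(self) -> set:
        return {t for t, s in self.tip_states.items() if s == 1}


def evolve_trait(tree: GeneTree, rate: float, seed: int,
                 root_depth: float | None = None) -> TraitRealization:
    """Evolve one binary character along a gene tree.

    ``rate`` is the mutation rate per 2N generations per lineage.  Events
    flip the state; tip states therefore equal the parity of events on the
    root-to-tip path (XOR the stem parity when ``root_depth`` is given).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = tree.n_taxa
    nn = tree.parent.shape[0]
    events: List[MutationEvent] = []
    counts = np.zeros(nn + 1, dtype=np.int64)  # last slot: stem
    times: List[np.ndarray] = []
    for i in range(nn - 1):
        lo, hi = tree.age[i], tree.age[tree.parent[i]]
        k = rng.poisson(rate * (hi - lo)) if rate > 0 else 0
        counts[i] = k
        times.append(np.sort(rng.uniform(lo, hi, size=k))[::-1])  # old -> young
    stem_times = np.empty(0)
    if root_depth is not None and root_depth > tree.root_age:
        k = rng.poisson(rate * (root_depth - tree.root_age)) if rate > 0 else 0
        counts[nn] = k
        stem_times = np.sort(rng.uniform(tree.root_age, root_depth, size=k))[::-1]

    state = np.zeros(nn, dtype=np.int64)
    s = 0
    for t in stem_times:
        events.append(MutationEvent(-1, float(t), (s, 1 - s), "stem"))
        s = 1 - s
    state[nn - 1] = s
    for i in range(nn - 2, -1, -1):
        s = int(state[tree.parent[i]])
        for t in times[i]:
            events.append(
                MutationEvent(i, float(t), (s, 1 - s),
                              "tip" if i < n else "internal"))
            s = 1 - s
        state[i] = s
    events.sort(key=lambda e: -e.time)
    tip_states = {tree.taxa[i]: int(state[i]) for i in range(n)}
    return TraitRealization(tree=tree, tip_states=tip_states, events=events)


# ---------------------------------------------------------------------------
# batch kernel used by the pipeline

@njit(cache=True)
def _evolve_kernel(parent, age, n, rate, stem_depth, seed,
                   out_states, out_counts, out_tipmut, out_fwd,
                   out_branch):  # pragma: no cover
    np.random.seed(seed)
    n_loci, nn = parent.shape
    keep_branch = out_branch.shape[0] == n_loci
    state = np.empty(nn, dtype=np.int8)
    kbuf = np.empty(nn + 1, dtype=np.int64)
    for locus in range(n_loci):
        total = 0
        tipmut = 0
        for i in range(nn - 1):
            L = age[locus, parent[locus, i]] - age[locus, i]
            k = np.random.poisson(rate * L)
            kbuf[i] = k
            total += k
            if i < n:
                tipmut += k
        kstem = 0
        if stem_depth > 0 and stem_depth > age[locus, nn - 1]:
            kstem = np.random.poisson(rate * (stem_depth - age[locus, nn - 1]))
        total += kstem
        if keep_branch:
            for i in range(nn - 1):
                out_branch[locus, i] = kbuf[i]
            out_branch[locus, nn - 1] = kstem
        # propagate parity; count forward (0->1) mutations
        fwd = 0
        s = 0
        for _ in range(kstem):
            if s == 0:
                fwd += 1
            s = 1 - s
        state[nn - 1] = s
        for i in range(nn - 2, -1, -1):
            s = state[parent[locus, i]]
            k = kbuf[i]
            if k > 0:
                if s == 0:
                    fwd += (k + 1) // 2
                else:
                    fwd += k // 2
                if k % 2 == 1:
                    s = 1 - s
            state[i] = s
        for i in range(n):
            out_states[locus, i] = state[i]
        out_counts[locus] = total
        out_tipmut[locus] = tipmut
        out_fwd[locus] = fwd


def evolve_batch(parent: np.ndarray, age: np.ndarray, n_taxa: int, rate: float,
                 seed: int, root_depth: float | None = None,
                 return_branch_counts: bool = False):
    """Vectorized trait overlay for a batch of genealogies.

    Returns (tip_states, n_events, n_tip_events, n_forward); the reversal
    count is ``n_events - n_forward``.  With ``return_branch_counts`` a
    fifth array of per-branch event counts is appended (one column per
    non-root node, plus a final column for the stem above the root when
    the ancestral state is anchored at ``root_depth``).
    """
    n_loci, nn = parent.shape
    states = np.empty((n_loci, n_taxa), dtype=np.int8)
    counts = np.empty(n_loci, dtype=np.int64)
    tipmut = np.empty(n_loci, dtype=np.int64)
    fwd = np.empty(n_loci, dtype=np.int64)
    branch = np.empty((n_loci if return_branch_counts else 0, nn),
                      dtype=np.int64)
    _evolve_kernel(parent, age, n_taxa, float(rate),
                   -1.0 if root_depth is None else float(root_depth),
                   int(seed) % (2 ** 32), states, counts, tipmut, fwd, branch)
    if return_branch_counts:
        return states, counts, tipmut, fwd, branch
    return states, counts, tipmut, fwd
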