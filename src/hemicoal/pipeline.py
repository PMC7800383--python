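"""Hemiplasy inference by simulation: filter, count, classify, summarize.

The inference core: simulate a large number of gene trees from a species
network, evolve a binary trait along each, keep the "focal" loci whose tip
states exactly match the observed trait pattern, and summarize how many
mutations those loci required, where they fell, and whether the underlying
genealogies followed the species branching history or an introgressed one.
The species-tree Fitch parsimony score provides the homoplasy-only
baseline: a focal locus explained by fewer mutations than the Fitch score
must involve at least one transition on a branch that does not exist in
the species tree (hemiplasy).

Runs stream in chunks so very large simulations use constant memory;
multi-billion-tree runs are handled by invoking :func:`run` repeatedly
with distinct seeds and merging the returned summaries.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .simulate import GeneTree, SpeciesNetwork, simulate_batch
from .traits import TraitRealization, evolve_batch

__all__ = [
    "TraitPattern",
    "FocalSummary",
    "is_focal",
    "count_mutations",
    "classify",
    "fitch_parsimony",
    "derived_clade_count",
    "run",
]


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class TraitPattern:
    """Observed binary character states: which taxa carry the derived state."""

    derived_taxa: frozenset
    all_taxa: Tuple[str, ...]

    def __init__(self, derived_taxa: Iterable[str], all_taxa: Sequence[str]):
        object.__setattr__(self, "derived_taxa", frozenset(derived_taxa))
        object.__setattr__(self, "all_taxa", tuple(all_taxa))
        if not self.derived_taxa:
            raise PatternError("derived taxon set must be non-empty")
        if not self.derived_taxa < set(self.all_taxa):
            raise PatternError("derived taxa must be a proper subset of all taxa")


def is_focal(real: TraitRealization, pattern: TraitPattern) -> bool:
    """True iff the realized derived set equals the observed pattern exactly."""
    if set(real.tip_states) != set(pattern.all_taxa):
        raise PatternError("tip label sets differ between realization and pattern")
    return real.derived_taxa() == set(pattern.derived_taxa)


def count_mutations(real: TraitRealization) -> int:
    return real.n_events


def classify(real_or_count, fitch_score: int) -> str:
    """Label a focal locus relative to the species-tree parsimony baseline.

    One mutation is pure hemiplasy; more than one but fewer than the Fitch
    score is a hemiplasy/homoplasy mixture (at least one transition must
    sit on a discordant branch); at or above the Fitch score the locus is
    parsimony-equivalent.
    """
    count = real_or_count if isinstance(real_or_count, (int, np.integer)) \
        else count_mutations(real_or_count)
    if count < 1:
        raise PatternError("focal locus with a non-empty derived set but no events")
    if count == 1:
        return "hemiplasy-only"
    if count < fitch_score:
        return "mixed"
    return "parsimony-equivalent"


# ---------------------------------------------------------------------------
# Fitch parsimony on the species tree

def fitch_parsimony(net: SpeciesNetwork, pattern: TraitPattern) -> int:
    """Minimum number of state changes on the rooted binary species tree.

    Standard bottom-up pass over state sets; the score is the number of
    union operations.
    """
    n = net.n_taxa
    if set(pattern.all_taxa) != set(net.taxa):
        raise PatternError("pattern taxa do not match the tree")
    # state sets as bitmasks: 1 = {0}, 2 = {1}
    sets = np.zeros(2 * n - 1, dtype=np.int64)
    for i, tax in enumerate(net.taxa):
        sets[i] = 2 if tax in pattern.derived_taxa else 1
    children: Dict[int, list] = {}
    for i in range(2 * n - 2):
        children.setdefault(int(net.parent[i]), []).append(i)
    score = 0
    for node in range(n, 2 * n - 1):
        chs = children[node]
        if len(chs) != 2:
            raise PatternError("polytomy encountered: resolve the tree first")
        inter = sets[chs[0]] & sets[chs[1]]
        if inter:
            sets[node] = inter
        else:
            sets[node] = sets[chs[0]] | sets[chs[1]]
            score += 1
    return score


def derived_clade_count(tree: GeneTree, pattern: TraitPattern) -> int:
    """Number of maximal clades of derived taxa on a gene tree.

    Equals 1 when the derived taxa are monophyletic, and the number of
    separate derived groupings otherwise.
    """
    n = tree.n_taxa
    derived = np.array([t in pattern.derived_taxa for t in tree.taxa])
    all_der = np.ones(2 * n - 1, dtype=bool)
    all_der[:n] = derived
    for i in range(2 * n - 2):  # ids are children-before-parents
        all_der[tree.parent[i]] &= all_der[i]
    count = 0
    for i in range(2 * n - 1):
        if all_der[i] and (tree.parent[i] < 0 or not all_der[tree.parent[i]]):
            count += 1
    return count


# ---------------------------------------------------------------------------
# full run

@dataclass
class FocalSummary:
    """Summary of the focal (pattern-matching) loci of a simulation run."""

    n_simulated: int
    n_focal: int
    fitch_score: int
    mutation_count_distribution: Dict[int, float] = field(default_factory=dict)
    derived_clade_count_distribution: Dict[int, float] = field(default_factory=dict)
    tip_vs_internal: Tuple[int, int] = (0, 0)
    forward_vs_reversal: Tuple[int, int] = (0, 0)
    origin_distribution: Dict[str, float] = field(default_factory=dict)
    monophyly_fraction: float = float("nan")

    @property
    def hemiplasy_only_fraction(self) -> float:
        return self.mutation_count_distribution.get(1, 0.0)

    def classification(self) -> Dict[str, float]:
        out = {"hemiplasy-only": 0.0, "mixed": 0.0, "parsimony-equivalent": 0.0}
        for count, freq in self.mutation_count_distribution.items():
            out[classify(count, self.fitch_score)] += freq
        return out


def _derived_clades_batch(parent: np.ndarray, derived: np.ndarray) -> np.ndarray:
    """Vectorized derived-clade counts for a batch of gene trees."""
    n_loci, nn = parent.shape
    n = derived.shape[0]
    all_der = np.ones((n_loci, nn), dtype=bool)
    all_der[:, :n] = derived[None, :]
    rows = np.arange(n_loci)
    for i in range(nn - 1):
        np.logical_and.at(all_der, (rows, parent[:, i]), all_der[:, i])
    # a maximal derived clade is one whose parent clade is not all-derived
    counts = np.zeros(n_loci, dtype=np.int64)
    for i in range(nn):
        if i < nn - 1:
            maximal = all_der[:, i] & ~all_der[rows, parent[:, i]]
        else:
            maximal = all_der[:, i]
        counts += maximal
    return counts


def run(net: SpeciesNetwork, pattern: TraitPattern, rate: float, n_trees: int,
        seed: int, root_depth: float | None = None, chunk: int = 200_000,
        collect_records: bool = True) -> Tuple[FocalSummary, pd.DataFrame]:
    """Simulate, overlay the trait, filter to focal loci and summarize.

    ``rate`` is the trait mutation rate per 2N generations.  Deterministic
    for a fixed seed.  Returns the summary plus one record per focal tree
    (mutation count, origin bitmask, derived clade count, topology hash).
    """
    if set(pattern.all_taxa) != set(net.taxa):
        raise PatternError("pattern taxa do not match the network")
    n = net.n_taxa
    fitch = fitch_parsimony(net, pattern)
    derived = np.array([t in pattern.derived_taxa for t in net.taxa])
    target = derived.astype(np.int8)

    ss = np.random.SeedSequence(seed)
    counts_hist: Counter = Counter()
    clades_hist: Counter = Counter()
    origin_hist: Counter = Counter()
    tipmut_tot = 0
    intmut_tot = 0
    fwd_tot = 0
    rev_tot = 0
    mono = 0
    n_focal = 0
    records = []

    done = 0
    while done < n_trees:
        m = min(chunk, n_trees - done)
        s1, s2 = ss.spawn(2)
        parent, age, origin = simulate_batch(net, m, int(s1.generate_state(1)[0]))
        states, counts, tipmut, fwd = evolve_batch(
            parent, age, n, rate, int(s2.generate_state(1)[0]), root_depth)
        focal = np.all(states == target[None, :], axis=1)
        idx = np.nonzero(focal)[0]
        n_focal += idx.size
        if idx.size:
            fparent = parent[idx]
            cl = _derived_clades_batch(fparent, derived)
            for j, locus in enumerate(idx):
                c = int(counts[locus])
                counts_hist[c] += 1
                clades_hist[int(cl[j])] += 1
                origin_hist[int(origin[locus])] += 1
                if collect_records:
                    topo = hash(fparent[j].tobytes())
                    records.append((c, int(origin[locus]), int(cl[j]), topo))
            mono += int((cl == 1).sum())
            tipmut_tot += int(tipmut[idx].sum())
            intmut_tot += int((counts[idx] - tipmut[idx]).sum())
            fwd_tot += int(fwd[idx].sum())
            rev_tot += int((counts[idx] - fwd[idx]).sum())
        done += m

    if n_focal == 0:
        warnings.warn(
            "no simulated locus matched the trait pattern; increase n_trees "
            "or check the mutation rate / pattern polarization")

    def _freq(counter: Counter) -> Dict[int, float]:
        tot = sum(counter.values())
        return {k: v / tot for k, v in sorted(counter.items())} if tot else {}

    origin_named: Dict[str, float] = {}
    if n_focal:
        for mask, cnt in sorted(origin_hist.items()):
            if mask == 0:
                key = "species"
            else:
                key = "+".join(
                    f"pulse{i}" for i in range(64) if mask >> i & 1)
            origin_named[key] = cnt / n_focal

    summary = FocalSummary(
        n_simulated=n_trees,
        n_focal=n_focal,
        fitch_score=fitch,
        mutation_count_distribution=_freq(counts_hist),
        derived_clade_count_distribution=_freq(clades_hist),
        tip_vs_internal=(tipmut_tot, intmut_tot),
        forward_vs_reversal=(fwd_tot, rev_tot),
        origin_distribution=origin_named,
        monophyly_fraction=(mono / n_focal) if n_focal else float("nan"),
    )
    rec = pd.DataFrame(
        records, columns=["mutation_count", "origin", "clade_count", "topology_hash"])
    return summary, rec
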