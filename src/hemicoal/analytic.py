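"""Closed-form hemiplasy and homoplasy probabilities for three taxa.

The model: a rooted species tree ((A,B),C) with splits at ``t1`` (A/B) and
``t2`` (AB/C), both in coalescent units of 2N generations, plus a single
instantaneous introgression pulse between B and C at time ``tm < t1``.  A
locus follows the species history ("parent tree 1") with probability
1 - (delta2 + delta3), the C->B introgressed history (parent tree 2, B and
C sister from ``tm``, A joining at ``t2``) with probability ``delta2``, and
the B->C history (parent tree 3, B and C sister from ``tm``, A joining at
``t1``) with probability ``delta3``.  Within each parent tree gene trees
sort under the multispecies coalescent: the sister pair either coalesces
inside its internal interval (lineage sorting) or all three lineages reach
the ancestral population, where the first coalescing pair is uniform over
the three possibilities (incomplete lineage sorting).  That yields four
genealogy classes per parent tree, twelve in total.

A binary trait with derived state in B and C (A ancestral) mutates as a
symmetric Poisson process at per-lineage rate ``theta / 2`` per 2N
generations.  Hemiplasy is a single mutation on the internal branch of a
((B,C),A) genealogy; homoplasy is either parallel mutations on the B and C
tips or a mutation on the ancestral branch above the genealogy's root
followed by a reversal on the A tip.  Per-branch mutation probabilities
``nu`` are obtained by integrating P(at least one mutation) over the exact
coalescent distribution of each branch length, conditional on the class.

The ancestral state is anchored at a reference depth ``root_depth`` (think
of it as the divergence of a distant outgroup known to carry the ancestral
state); the ancestral branch of a genealogy runs from its root up to that
depth.  The default extent is calibrated so that the incomplete-lineage-
sorting-only model at the reference parameterization (t1=1, t2=3.5,
theta=0.002) yields the published baseline ratio P_e/P_o = 0.818.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "ThreeTaxonNetwork",
    "GeneTreeClass",
    "BranchMutationProfile",
    "CLASS_LABELS",
    "DEFAULT_ANCESTRAL_EXTENT",
    "parent_tree_probabilities",
    "gene_tree_class_probabilities",
    "branch_mutation_probabilities",
    "prob_hemiplasy",
    "prob_homoplasy",
    "hemiplasy_homoplasy_ratio",
    "grid_scan",
]

#: Extent of the ancestral branch above the species-tree root, in 2N
#: generations.  root_depth defaults to t2 + DEFAULT_ANCESTRAL_EXTENT.
#: Calibrated once against the published ILS-only baseline P_e/P_o = 0.818
#: at t1=1, t2=3.5, theta=0.002 (see docs/methods.md).
DEFAULT_ANCESTRAL_EXTENT = 13.4525

_BRANCHES = ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5")


class ParameterError(ValueError):
    """An invalid network parameterization, naming the violated invariant."""


@dataclass(frozen=True)
class ThreeTaxonNetwork:
    """Parameters of the three-taxon network model.

    Times are in coalescent units (2N generations); ``theta`` is the
    population-scaled trait mutation rate as conventionally printed (the
    per-lineage event rate used internally is ``theta / 2``).
    """

    t1: float
    t2: float
    tm: float = 0.5
    delta2: float = 0.0
    delta3: float = 0.0
    theta: float = 0.002
    root_depth: float | None = None

    def __post_init__(self):
        if not 0 < self.tm < self.t1 < self.t2:
            raise ParameterError(
                f"require 0 < tm < t1 < t2, got tm={self.tm}, t1={self.t1}, t2={self.t2}"
            )
        if self.delta2 < 0 or self.delta3 < 0:
            raise ParameterError("admixture proportions must be non-negative")
        if self.delta2 + self.delta3 > 1:
            raise ParameterError("delta2 + delta3 must not exceed 1")
        if not self.theta > 0:
            raise ParameterError("theta must be positive")
        if self.root_depth is None:
            object.__setattr__(self, "root_depth", self.t2 + DEFAULT_ANCESTRAL_EXTENT)
        elif self.root_depth <= self.t2:
            raise ParameterError("root_depth must exceed t2")

    @property
    def rate(self) -> float:
        """Per-lineage trait mutation rate per 2N generations."""
        return self.theta / 2.0


@dataclass(frozen=True)
class BranchMutationProfile:
    """Probability of >=1 trait mutation on each branch of a genealogy class.

    Branches follow the usual indexing: lambda1..lambda3 are the tips
    leading to A, B and C, lambda4 the internal branch, lambda5 the
    ancestral branch above the genealogy's root.
    """

    nu: Dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.nu[key]

    def as_array(self) -> np.ndarray:
        return np.array([self.nu[b] for b in _BRANCHES])


@dataclass(frozen=True)
class GeneTreeClass:
    """One of the twelve genealogy classes of the network model."""

    label: str
    parent_tree: int
    sisters: Tuple[str, str]
    lineage_sorting: bool
    probability: float  # conditional on the parent tree
    profile: BranchMutationProfile = field(repr=False)


# (label, parent_tree, sisters, lineage_sorting)
_CLASS_TABLE = [
    ("AB1_1", 1, ("A", "B"), True),
    ("AB2_1", 1, ("A", "B"), False),
    ("BC_1", 1, ("B", "C"), False),
    ("AC_1", 1, ("A", "C"), False),
    ("BC1_2", 2, ("B", "C"), True),
    ("BC2_2", 2, ("B", "C"), False),
    ("AB_2", 2, ("A", "B"), False),
    ("AC_2", 2, ("A", "C"), False),
    ("BC1_3", 3, ("B", "C"), True),
    ("BC2_3", 3, ("B", "C"), False),
    ("AB_3", 3, ("A", "B"), False),
    ("AC_3", 3, ("A", "C"), False),
]

CLASS_LABELS = tuple(row[0] for row in _CLASS_TABLE)

#: Aliases used in the literature for the parent-tree-1 classes.
_ALIASES = {"AB1": "AB1_1", "AB2": "AB2_1", "BC1": "BC_1", "AC1": "AC_1"}


def _bounds(net: ThreeTaxonNetwork, parent_tree: int) -> Tuple[float, float]:
    """Lower/upper coalescence bounds of a parent tree's internal interval."""
    if parent_tree == 1:
        return net.t1, net.t2
    if parent_tree == 2:
        return net.tm, net.t2
    if parent_tree == 3:
        return net.tm, net.t1
    raise ParameterError(f"unknown parent tree {parent_tree}")


# ---------------------------------------------------------------------------
# Laplace transforms E[exp(-r L)] of the coalescent branch-length laws.
# All accept numpy arrays and broadcast.

def _laplace_tip_ls(lo, hi, r):
    """Sister tip of a lineage-sorting class: T1 = lo + TruncExp(1, hi-lo)."""
    w = hi - lo
    return np.exp(-r * lo) * (1 - np.exp(-(1 + r) * w)) / ((1 + r) * (1 - np.exp(-w)))


def _laplace_tip_outer_ls(hi, r):
    """Outer tip of a lineage-sorting class: T2 = hi + Exp(1)."""
    return np.exp(-r * hi) / (1 + r)


def _laplace_internal_ls(lo, hi, r):
    """Internal branch of a lineage-sorting class: (hi - T1) + Exp(1)."""
    w = hi - lo
    part = np.exp(-r * w) * (1 - np.exp(-(1 - r) * w)) / ((1 - r) * (1 - np.exp(-w)))
    return part / (1 + r)


def _laplace_anc_ls(hi, r, root_depth):
    """Ancestral branch of a lineage-sorting class: max(0, root_depth - T2)."""
    s = root_depth - hi
    s = np.asarray(s, dtype=float)
    out = np.where(
        s > 0,
        np.exp(-r * s) * (1 - np.exp(-(1 - r) * np.maximum(s, 0.0))) / (1 - r)
        + np.exp(-np.maximum(s, 0.0)),
        1.0,
    )
    return out


def _laplace_tip_sister_ils(hi, r):
    """Sister tip of an ILS class: T1 = hi + Exp(3)."""
    return np.exp(-r * hi) * 3.0 / (3.0 + r)


def _laplace_tip_outer_ils(hi, r):
    """Outer tip of an ILS class: T2 = hi + Exp(3) + Exp(1)."""
    return np.exp(-r * hi) * 3.0 / ((3.0 + r) * (1.0 + r))


def _laplace_internal_ils(r):
    """Internal branch of an ILS class: Exp(1), whatever the parent tree."""
    return 1.0 / (1.0 + r)


def _laplace_anc_ils(hi, r, root_depth):
    """Ancestral branch of an ILS class: max(0, root_depth - hi - Exp(3) - Exp(1))."""
    s = np.asarray(root_depth - hi, dtype=float)
    sp = np.maximum(s, 0.0)
    e1 = np.exp(-r * sp) * (1 - np.exp(-(1 - r) * sp)) / (1 - r)
    e3 = np.exp(-r * sp) * (1 - np.exp(-(3 - r) * sp)) / (3 - r)
    tail = 1.5 * np.exp(-sp) - 0.5 * np.exp(-3 * sp)
    return np.where(s > 0, 1.5 * (e1 - e3) + tail, 1.0)


def _class_nu(net: ThreeTaxonNetwork, parent_tree: int, sisters: Tuple[str, str],
              lineage_sorting: bool) -> Dict[str, float]:
    """Per-branch mutation probabilities nu(lambda_i) for one class."""
    r = net.rate
    lo, hi = _bounds(net, parent_tree)
    if lineage_sorting:
        tip_sister = 1 - _laplace_tip_ls(lo, hi, r)
        tip_outer = 1 - _laplace_tip_outer_ls(hi, r)
        internal = 1 - _laplace_internal_ls(lo, hi, r)
        ancestral = 1 - _laplace_anc_ls(hi, r, net.root_depth)
    else:
        tip_sister = 1 - _laplace_tip_sister_ils(hi, r)
        tip_outer = 1 - _laplace_tip_outer_ils(hi, r)
        internal = 1 - _laplace_internal_ils(r)
        ancestral = 1 - _laplace_anc_ils(hi, r, net.root_depth)
    outer = ({"A", "B", "C"} - set(sisters)).pop()
    tips = {t: tip_sister for t in sisters}
    tips[outer] = tip_outer
    clip = lambda v: float(min(max(v, 0.0), 1.0))  # guard float cancellation
    return {
        "lambda1": clip(tips["A"]),
        "lambda2": clip(tips["B"]),
        "lambda3": clip(tips["C"]),
        "lambda4": clip(internal),
        "lambda5": clip(ancestral),
    }


# ---------------------------------------------------------------------------
# Joint no-mutation expectations.
#
# Within one genealogy class the five branch lengths are functions of the
# two coalescence times (T1, T2), so they are correlated: the sister tips
# share T1, and the ancestral branch max(0, root_depth - T2) shrinks as the
# outer tip T2 grows.  The probabilities of mutation configurations are
# therefore computed as exact joint expectations
#     E[ prod_{i in S} exp(-r lambda_i) ]
# over the coalescent law of (T1, T2), expanded by inclusion-exclusion,
# rather than as products of the marginal per-branch probabilities.  Every
# term has a closed form.  A subset S is summarized by
#     alpha = (#sister tips in S) - [l4 in S]   (coefficient of T1)
#     beta  = [outer tip in S] + [l4 in S]      (coefficient of T2)
#     gamma = [l5 in S]
# so that sum_{i in S} lambda_i = alpha T1 + beta T2 + gamma max(0, D - T2).


def _joint_ls(lo, hi, r, D, alpha, beta, gamma):
    """E[e^{-r(alpha T1 + beta T2 + gamma (D-T2)^+)}] for a lineage-sorting
    class: T1 = lo + TruncExp(1, hi-lo), T2 = hi + Exp(1), independent."""
    w = hi - lo
    a = r * alpha
    b = r * beta
    g = r * gamma
    t1_part = np.exp(-a * lo) * (1 - np.exp(-(1 + a) * w)) / ((1 + a) * (1 - np.exp(-w)))
    s = np.asarray(D - hi, dtype=float)
    sp = np.maximum(s, 0.0)
    inside = np.exp(-g * sp) * (1 - np.exp(-(1 + b - g) * sp)) / (1 + b - g)
    outside = np.exp(-(1 + b) * sp) / (1 + b)
    y_part = np.where(s > 0, inside + outside, 1.0 / (1 + b))
    return np.exp(-b * hi) * t1_part * y_part


def _joint_ils(hi, r, D, alpha, beta, gamma):
    """Same expectation for an ILS class: T1 = hi + U (U ~ Exp(3)),
    T2 = T1 + Y (Y ~ Exp(1))."""
    a = r * alpha
    b = r * beta
    g = r * gamma
    p = a + b + 3.0   # exponent of u (with density 3 e^{-3u})
    q = b + 1.0       # exponent of y (with density e^{-y})
    s = np.asarray(D - hi, dtype=float)
    sp = np.maximum(s, 0.0)
    p1 = p - g
    q1 = q - g
    # u + y <= s, with the gamma factor active
    i1 = 3.0 * np.exp(-g * sp) / q1 * (
        (1 - np.exp(-p1 * sp)) / p1
        - np.exp(-q1 * sp) * (1 - np.exp(-(p1 - q1) * sp)) / (p1 - q1)
    )
    # u + y > s: total mass minus the same triangle without the gamma factor
    tri = 3.0 / q * (
        (1 - np.exp(-p * sp)) / p
        - np.exp(-q * sp) * (1 - np.exp(-(p - q) * sp)) / (p - q)
    )
    i2 = 3.0 / (p * q) - tri
    total = np.where(s > 0, i1 + i2, 3.0 / (p * q))
    return np.exp(-(a + b) * hi) * total


def _joint_expectation(lo, hi, ils, r, D, n_sister, outer, l4, l5):
    alpha = n_sister - l4
    beta = outer + l4
    gamma = l5
    if ils:
        return _joint_ils(hi, r, D, alpha, beta, gamma)
    return _joint_ls(lo, hi, r, D, alpha, beta, gamma)


def _class_path_probabilities(net: ThreeTaxonNetwork, parent_tree: int,
                              sisters: Tuple[str, str], lineage_sorting: bool):
    """(hemiplasy, homoplasy) configuration probabilities for one class,
    conditional on the class, by exact joint integration."""
    r = net.rate
    lo, hi = _bounds(net, parent_tree)
    D = net.root_depth
    ils = not lineage_sorting

    def E(subset):
        """subset: set of roles among {'A','B','C','l4','l5'}."""
        n_sister = sum(1 for t in ("A", "B", "C")
                       if t in subset and t in sisters)
        outer = sum(1 for t in ("A", "B", "C")
                    if t in subset and t not in sisters)
        return _joint_expectation(lo, hi, ils, r, D, n_sister, outer,
                                  int("l4" in subset), int("l5" in subset))

    tips5 = {"A", "B", "C", "l5"}
    all5 = {"A", "B", "C", "l4", "l5"}
    hemi = E(tips5) - E(all5)
    parallel = (E({"A", "l4", "l5"}) - E({"A", "B", "l4", "l5"})
                - E({"A", "C", "l4", "l5"}) + E(all5))
    reversal = (E({"B", "C", "l4"}) - E({"A", "B", "C", "l4"})
                - E({"B", "C", "l4", "l5"}) + E(all5))
    return float(hemi), float(parallel + reversal)


# ---------------------------------------------------------------------------
# Public operations

def parent_tree_probabilities(net: ThreeTaxonNetwork) -> Tuple[float, float, float]:
    """Probabilities that a locus follows parent tree 1, 2 or 3."""
    return (1.0 - (net.delta2 + net.delta3), net.delta2, net.delta3)


def gene_tree_class_probabilities(net: ThreeTaxonNetwork) -> List[GeneTreeClass]:
    """The twelve genealogy classes with within-parent-tree probabilities.

    Lineage sorting in a parent tree with internal interval of length w has
    probability 1 - exp(-w); each of the three ILS classes has probability
    (1/3) exp(-w).
    """
    classes = []
    for label, pt, sisters, ls in _CLASS_TABLE:
        lo, hi = _bounds(net, pt)
        w = hi - lo
        p = (1.0 - np.exp(-w)) if ls else np.exp(-w) / 3.0
        classes.append(
            GeneTreeClass(
                label=label,
                parent_tree=pt,
                sisters=sisters,
                lineage_sorting=ls,
                probability=float(p),
                profile=BranchMutationProfile(_class_nu(net, pt, sisters, ls)),
            )
        )
    return classes


def branch_mutation_probabilities(net: ThreeTaxonNetwork, label: str) -> BranchMutationProfile:
    """nu(lambda_i) for i=1..5 of the named genealogy class."""
    label = _ALIASES.get(label, label)
    for row in _CLASS_TABLE:
        if row[0] == label:
            _, pt, sisters, ls = row
            return BranchMutationProfile(_class_nu(net, pt, sisters, ls))
    raise ParameterError(f"unknown genealogy class {label!r}")


def _hemi_homo(net: ThreeTaxonNetwork) -> Tuple[float, float]:
    weights = dict(zip((1, 2, 3), parent_tree_probabilities(net)))
    pe = 0.0
    po = 0.0
    for label, pt, sisters, ls in _CLASS_TABLE:
        lo, hi = _bounds(net, pt)
        w_int = hi - lo
        p = (1.0 - np.exp(-w_int)) if ls else np.exp(-w_int) / 3.0
        w = weights[pt] * p
        if w == 0.0:
            continue
        hemi, homo = _class_path_probabilities(net, pt, sisters, ls)
        if set(sisters) == {"B", "C"}:
            pe += w * hemi
        po += w * homo
    return pe, po


def prob_hemiplasy(net: ThreeTaxonNetwork) -> float:
    """P_e: a single internal-branch mutation yields the B,C-derived pattern.

    Sums the five ((B,C),A)-topology classes weighted by parent-tree
    probability; each term is (class probability) x nu(lambda4) x
    prod_{i != 4} (1 - nu(lambda_i)).
    """
    return _hemi_homo(net)[0]


def prob_homoplasy(net: ThreeTaxonNetwork) -> float:
    """P_o: two independent paths — parallel B,C tip mutations, or an
    ancestral-branch mutation reversed on the A tip — summed over all
    twelve classes weighted by p(tau)."""
    return _hemi_homo(net)[1]


def hemiplasy_homoplasy_ratio(net: ThreeTaxonNetwork) -> float:
    pe, po = _hemi_homo(net)
    return pe / po


def _split_deltas(delta: float, direction: str) -> Tuple[float, float]:
    if direction == "C->B":
        return delta, 0.0
    if direction == "B->C":
        return 0.0, delta
    if direction == "both-equal":
        return delta / 2.0, delta / 2.0
    raise ParameterError(f"unknown direction {direction!r}")


def grid_scan(
    tm_values: Sequence[float],
    delta_values: Sequence[float],
    direction: str = "C->B",
    t1: float = 1.0,
    t2: float = 3.5,
    theta: float = 0.002,
    root_depth: float | None = None,
) -> np.ndarray:
    """Matrix of P_e/P_o over introgression timings (rows) and total
    admixture proportions (columns) for one direction panel.

    ``direction`` is "C->B", "B->C" or "both-equal"; for the last the total
    admixture is split evenly, delta2 = delta3 = delta/2.  delta = 0 columns
    reduce to the ILS-only baseline.
    """
    out = np.empty((len(tm_values), len(delta_values)))
    for i, tm in enumerate(tm_values):
        for j, d in enumerate(delta_values):
            d2, d3 = _split_deltas(float(d), direction)
            net = ThreeTaxonNetwork(
                t1=t1, t2=t2, tm=float(tm), delta2=d2, delta3=d3,
                theta=theta, root_depth=root_depth,
            )
            out[i, j] = hemiplasy_homoplasy_ratio(net)
    return out
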