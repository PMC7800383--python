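"""Benchmark conditions, synthetic empirical fixtures, and input parsing.

The benchmark grid reproduces a four-taxon design with topology
(((4,3),2),1), derived state in species 4 and 2, and the root split fixed
at 8N generations (4 coalescent units):

* ILS1-ILS3 shrink the internal branch subtending (4,3) — 2N, 1.5N and N
  generations — with no introgression, raising the rate of incomplete
  lineage sorting.
* INT1-INT3 keep the ILS3 branch lengths and add a 2 -> 4 introgression
  pulse at 0.6N generations with probability 0.01, 0.05 and 0.1.
* INT4-INT6 hold the probability at 0.1 and make the pulse more recent:
  0.4N, 0.2N and 0.1N generations.
* CGF1-CGF5 (constant gene-tree frequency) jointly lengthen the internal
  branch (2N, 2.08N, 2.32N, 2.6N, 2.8N) while increasing the pulse
  probability (0, 0.01, 0.025, 0.04, 0.05) and recency (-, 0.4N, 0.3N,
  0.2N, 0.1N) so the frequency of the discordant (4,2) genealogy stays
  approximately constant while its expected internal branch grows.

Condition times are stated in N generations and divided by two once, at
construction, to give coalescent units (2N generations).  The
second-youngest split is held at 4N generations (2 coalescent units) and
the total height at 8N across all conditions; only the (4,3) split moves.

The empirical fixtures are synthetic reconstructions (no data files are
bundled): a 15-taxon lizard-like clade whose six green-blooded taxa fall
in four species-tree clades, and a Heliconius erato/sara-like clade whose
four inversion-bearing taxa fall in two clades connected by two
introgression pulses with total probability 0.201.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .pipeline import TraitPattern, run
from .simulate import IntrogressionPulse, SpeciesNetwork, simulate_batch

__all__ = [
    "BenchmarkCondition",
    "CONDITION_NAMES",
    "make_condition",
    "replicate_benchmark",
    "discordant_frequency",
    "lizard_like_network",
    "heliconius_like_network",
    "eight_taxon_test_tree",
    "parse_input",
]

_ROOT_CU = 4.0      # 8N generations
_MID_CU = 2.0       # (((4,3),2) ancestor at 4N generations
_DEFAULT_RATE = 0.05

# name -> (internal branch in N gen, pulse prob, pulse time in N gen)
_CONDITIONS: Dict[str, Tuple[float, float, float]] = {
    "ILS1": (2.0, 0.0, 0.0),
    "ILS2": (1.5, 0.0, 0.0),
    "ILS3": (1.0, 0.0, 0.0),
    "INT1": (1.0, 0.01, 0.6),
    "INT2": (1.0, 0.05, 0.6),
    "INT3": (1.0, 0.10, 0.6),
    "INT4": (1.0, 0.10, 0.4),
    "INT5": (1.0, 0.10, 0.2),
    "INT6": (1.0, 0.10, 0.1),
    "CGF1": (2.0, 0.0, 0.0),
    "CGF2": (2.08, 0.01, 0.4),
    "CGF3": (2.32, 0.025, 0.3),
    "CGF4": (2.6, 0.04, 0.2),
    "CGF5": (2.8, 0.05, 0.1),
}

CONDITION_NAMES = tuple(_CONDITIONS)


@dataclass(frozen=True)
class BenchmarkCondition:
    name: str
    network: SpeciesNetwork
    rate: float
    pattern: TraitPattern


def make_condition(name: str, rate: float = _DEFAULT_RATE) -> BenchmarkCondition:
    """Fully parameterized benchmark condition (times converted N -> 2N)."""
    if name not in _CONDITIONS:
        raise KeyError(f"unknown benchmark condition {name!r}")
    internal_n, prob, tm_n = _CONDITIONS[name]
    internal = internal_n / 2.0
    t43 = _MID_CU - internal
    newick = (f"((( '4':{t43},'3':{t43} ):{internal},'2':{_MID_CU} )"
              f":{_ROOT_CU - _MID_CU},'1':{_ROOT_CU});").replace(" ", "")
    pulses = []
    if prob > 0:
        pulses.append(IntrogressionPulse("2", "4", tm_n / 2.0, prob))
    net = SpeciesNetwork.from_newick(newick, pulses=pulses, outgroup="1")
    pattern = TraitPattern({"4", "2"}, net.taxa)
    return BenchmarkCondition(name=name, network=net, rate=rate, pattern=pattern)


def replicate_benchmark(condition: BenchmarkCondition, n_replicates: int,
                        n_trees: int, seed: int) -> pd.DataFrame:
    """Replicate runs of one condition; schema mirrors the benchmark table.

    ``hemi_count`` counts focal trees explained by a single mutation,
    ``homo_count`` those requiring two; conditional quantities are
    normalized by their sum, raw quantities by the number of simulated
    trees; ``pepo`` is cond_hemi / cond_homo.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        summary, _ = run(condition.network, condition.pattern, condition.rate,
                         n_trees, int(child.generate_state(1)[0]),
                         collect_records=False)
        dist = summary.mutation_count_distribution
        hemi = int(round(dist.get(1, 0.0) * summary.n_focal))
        homo = int(round(dist.get(2, 0.0) * summary.n_focal))
        both = hemi + homo
        rows.append({
            "condition": condition.name,
            "replicate": rep,
            "hemi_count": hemi,
            "homo_count": homo,
            "cond_hemi": hemi / both if both else np.nan,
            "raw_hemi": hemi / n_trees,
            "cond_homo": homo / both if both else np.nan,
            "raw_homo": homo / n_trees,
            "pepo": hemi / homo if homo else np.nan,
        })
    return pd.DataFrame(rows)


def discordant_frequency(condition: BenchmarkCondition, n_trees: int,
                         seed: int) -> float:
    """Frequency of gene trees in which taxa 4 and 2 form a cherry —
    the discordant genealogy on which hemiplasy of the {4,2} pattern
    arises via a single mutation."""
    net = condition.network
    parent, _, _ = simulate_batch(net, n_trees, seed)
    i4 = net.taxa.index("4")
    i2 = net.taxa.index("2")
    n = net.n_taxa
    cherry = (parent[:, i4] == parent[:, i2])
    # they form a cherry iff they share a parent node whose only tips they are
    return float(cherry.mean())


# ---------------------------------------------------------------------------
# synthetic empirical fixtures


def lizard_like_network() -> Tuple[SpeciesNetwork, TraitPattern]:
    """Synthetic 15-taxon reconstruction of the green-blooded lizard clade.

    Not the published input file: a stand-in built from the published
    description.  The six green-blooded taxa occupy four separate clades
    on the species tree — (prehensicauda, flavipes), (virens, sp_nov_2),
    semoni and sp_nov_1 — so Fitch parsimony requires four transitions,
    while short internal branches make discordance (and hemiplasy)
    rampant.  Branch lengths are in coalescent units.
    """
    newick = (
        "((((((P_prehensicauda:0.35,P_flavipes:0.35):0.15,"
        "(P_semoni:0.4,L_sp_A:0.4):0.1):0.1,"
        "(P_sp_nov_1:0.45,L_sp_B:0.45):0.15):0.2,"
        "((P_virens:0.3,P_sp_nov_2:0.3):0.25,L_sp_C:0.55):0.25):0.4,"
        "(((L_sp_D:0.5,L_sp_E:0.5):0.2,L_sp_F:0.7):0.3,"
        "(L_sp_G:0.6,L_sp_H:0.6):0.4):0.2):1.0,"
        "Scincella_lateralis:2.2);"
    )
    net = SpeciesNetwork.from_newick(newick, outgroup="Scincella_lateralis")
    green = {"P_prehensicauda", "P_flavipes", "P_semoni", "P_sp_nov_1",
             "P_virens", "P_sp_nov_2"}
    return net, TraitPattern(green, net.taxa)


def heliconius_like_network() -> Tuple[SpeciesNetwork, TraitPattern]:
    """Synthetic Heliconius erato/sara-like clade with the inversion in
    four taxa (two clades) and two introgression pulses between the
    inversion-bearing lineages (total probability 0.201).

    A stand-in for the published network, built from its description;
    branch lengths in coalescent units.
    """
    newick = (
        "((((H_erato:1.2,H_himera:1.2):0.9,"
        "(H_telesiphe:0.8,H_hecalesia:0.8):1.3):0.6,"
        "(H_sara:0.9,H_demeter:0.9):1.8):0.8,"
        "H_melpomene:3.5);"
    )
    pulses = [
        IntrogressionPulse("H_sara", "H_telesiphe", 1.0, 0.12),
        IntrogressionPulse("H_demeter", "H_hecalesia", 0.5, 0.081),
    ]
    net = SpeciesNetwork.from_newick(newick, pulses=pulses,
                                     outgroup="H_melpomene")
    derived = {"H_telesiphe", "H_hecalesia", "H_sara", "H_demeter"}
    return net, TraitPattern(derived, net.taxa)


def eight_taxon_test_tree() -> Tuple[SpeciesNetwork, TraitPattern]:
    """Known 8-taxon tree with three incongruent derived taxa, used for
    the end-to-end unit-conversion conservatism check."""
    newick = (
        "((((t4:0.4,t3:0.4):0.3,(t2:0.5,t5:0.5):0.2):0.5,"
        "(t6:0.8,t7:0.8):0.4):0.8,(t8:1.5,t1:1.5):0.5);"
    )
    net = SpeciesNetwork.from_newick(newick, outgroup="t1")
    return net, TraitPattern({"t4", "t2", "t6"}, net.taxa)


# ---------------------------------------------------------------------------
# input-file dialect

def parse_input(text: str) -> Dict[str, object]:
    """Parse the plain-text run description used by the command line.

    Lines: a Newick tree (bare or ``tree <newick>``), then directives
    ``introgression <donor> <recipient> <time> <probability>`` (one per
    pulse), ``derived <taxon> [<taxon> ...]``, ``outgroup <taxon>`` and
    optionally ``rate <mutations per 2N generations>``.  ``#`` starts a
    comment.
    """
    newick = None
    pulses = []
    derived: set = set()
    outgroup = None
    rate = None
    for raw in io.StringIO(text):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0].lower()
        if key == "tree":
            newick = line[len(parts[0]):].strip()
        elif key == "introgression":
            if len(parts) != 5:
                raise ValueError(f"malformed introgression line: {line!r}")
            pulses.append(IntrogressionPulse(parts[1], parts[2],
                                             float(parts[3]), float(parts[4])))
        elif key == "derived":
            derived.update(parts[1:])
        elif key == "outgroup":
            outgroup = parts[1]
        elif key == "rate":
            rate = float(parts[1])
        elif line.startswith("("):
            newick = line
        else:
            raise ValueError(f"unrecognized input line: {line!r}")
    if newick is None:
        raise ValueError("no species tree found in input")
    net = SpeciesNetwork.from_newick(newick, pulses=pulses, outgroup=outgroup)
    pattern = TraitPattern(derived, net.taxa) if derived else None
    return {"network": net, "pattern": pattern, "rate": rate,
            "outgroup": outgroup}
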