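"""Analytic oracles, summary statistics and unit conversions.

Holds the closed-form multispecies-coalescent results used to verify the
simulator (rooted-triplet gene-tree topology probabilities under incomplete
lineage sorting), topology tallies over collections of gene trees, the
conversion between mutation-scaled divergence times and calendar years, and
the through-origin regression used to compare parameter scales between
locus classes (e.g. coding vs noncoding divergence times).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .synthetic_data import GeneTree, TreeNode


def triplet_topology_probs(delta_tau: float, theta_anc: float) -> tuple[float, float, float]:
    """Rooted-triplet gene-tree topology probabilities under the MSC.

    For species tree ((A,B),C) with internal branch of length ``delta_tau``
    (expected substitutions/site) and ancestral population parameter
    ``theta_anc``, one lineage from each species: the two A-B lineages fail
    to coalesce within the internal branch with probability
    ``exp(-2*delta_tau/theta_anc)``, after which the three lineages pair up
    uniformly.  Returns ``(concordant, discordant_1, discordant_2)``.
    """
    if delta_tau < 0:
        raise ValueError("delta_tau must be >= 0")
    if theta_anc <= 0:
        raise ValueError("theta_anc must be > 0")
    p_no_coal = math.exp(-2.0 * delta_tau / theta_anc)
    discordant = p_no_coal / 3.0
    return (1.0 - 2.0 * discordant, discordant, discordant)


@dataclass
class TopologyFrequencyTable:
    taxa: tuple[str, ...]
    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0
    skipped: int = 0

    def frequencies(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {label: c / self.total for label, c in self.counts.items()}


def _induced_topology(node: TreeNode, keep: set[str]) -> TreeNode | None:
    """Prune a gene tree to a taxon subset, suppressing unary nodes."""
    if not node.children:
        return node if node.name in keep else None
    kept = [c for c in (_induced_topology(ch, keep) for ch in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return TreeNode(name=node.name, age=node.age, children=kept)


def _canonical_label(node: TreeNode) -> str:
    """Canonical rooted topology string: children sorted by smallest tip label."""
    if not node.children:
        return node.name
    parts = sorted(_canonical_label(c) for c in node.children)
    return "(" + ",".join(parts) + ")"


def topology_frequencies(trees: Iterable[GeneTree], taxa: Sequence[str]) -> TopologyFrequencyTable:
    """Tally induced rooted topologies of a taxon subset over gene trees.

    Trees missing any requested taxon are skipped and counted in
    ``skipped``.
    """
    keep = set(taxa)
    table = TopologyFrequencyTable(taxa=tuple(sorted(taxa)))
    for tree in trees:
        if not keep.issubset(tree.tip_names):
            table.skipped += 1
            continue
        pruned = _induced_topology(tree.root, keep)
        label = _canonical_label(pruned)
        table.counts[label] = table.counts.get(label, 0) + 1
        table.total += 1
    return table


# ---------------------------------------------------------------------------
# time scales

@dataclass(frozen=True)
class TimeScale:
    """Conversion constants between mutation units and calendar years."""

    mu: float  # mutations per site per generation
    gens_per_year: float

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.gens_per_year <= 0:
            raise ValueError("mu and gens_per_year must be > 0")


#: neutral mutation rate and generation time used for the worked example
HELICONIUS_SCALE = TimeScale(mu=2.9e-9, gens_per_year=4.0)


def mutation_scaled_to_years(tau: float, scale: TimeScale) -> float:
    """Convert a divergence time in expected substitutions/site to years."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return tau / (scale.mu * scale.gens_per_year)


def years_to_mutation_scaled(years: float, scale: TimeScale) -> float:
    if years < 0:
        raise ValueError("years must be >= 0")
    return years * scale.mu * scale.gens_per_year


# ---------------------------------------------------------------------------
# proportional (through-origin) regression

def proportional_regression(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Least-squares slope through the origin and its r-squared.

    ``slope = sum(x*y) / sum(x^2)``; the coefficient of determination for
    the through-origin fit is ``1 - RSS / sum(y^2)`` (conventions differ for
    regression without an intercept; this one compares against the zero
    function).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 2:
        raise ValueError("x and y must be equal-length vectors of length >= 2")
    sxx = float(np.sum(xa * xa))
    if sxx == 0.0:
        raise ValueError("x has no variation")
    slope = float(np.sum(xa * ya)) / sxx
    rss = float(np.sum((ya - slope * xa) ** 2))
    syy = float(np.sum(ya * ya))
    r2 = 1.0 - rss / syy if syy > 0 else float("nan")
    return slope, r2
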