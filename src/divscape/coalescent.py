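"""Single-locus coalescent simulation under simple demographies.

Each 5-kb analysis window is simulated as one non-recombining locus: a
genealogy of ``n_hap`` haploid lineages is drawn under the standard
coalescent with a time-varying population size, and infinite-sites
mutations are dropped on the branches at rate theta/2 per unit of
coalescent time (time in units of 2N generations, N the reference size
implied by theta).  Under a constant size this gives Watterson's classic
expectation E[S] = theta * sum_{i=1}^{n-1} 1/i.

Demographies are expressed as a backward-in-time relative size r(t):

* ``constant``   -- r(t) = 1.
* ``bottleneck`` -- r(t) = severity for t < t_event, 1 for t >= t_event.
  A recent contraction to a fraction ``severity`` of the ancestral size:
  trees are shortened near the tips and retain long internal branches,
  producing less diversity and positive Tajima's D.
* ``growth``     -- r(t) = exp(-growth_rate * t): exponential expansion
  up to the present, producing star-like trees and negative Tajima's D.

The pair-coalescence rate at time t with k lineages is C(k,2) / r(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["DemographyModel", "simulate_coalescent_window"]


@dataclass(frozen=True)
class DemographyModel:
    """Backward-time relative-size history of a single population.

    Parameters
    ----------
    kind : {"constant", "bottleneck", "growth"}
    N0 : float
        Current (reference) diploid effective size.  Only the shape of
        r(t) affects simulated data because time is already expressed in
        2N units; N0 is carried for bookkeeping and VCF/truth output.
    severity : float
        For ``bottleneck``: relative size during the recent epoch,
        0 < severity <= 1.
    t_event : float
        For ``bottleneck``: time of the contraction, in units of 2N
        generations.
    growth_rate : float
        For ``growth``: exponential rate per unit of 2N time (>= 0).
    """

    kind: str = "constant"
    N0: float = 1e6
    severity: float = 1.0
    t_event: float = 0.0
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "bottleneck", "growth"):
            raise ValueError(f"unknown demography kind {self.kind!r}")
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")
        if self.kind == "bottleneck" and not (0.0 < self.severity <= 1.0):
            raise ValueError("bottleneck severity must be in (0, 1]")
        if self.kind == "bottleneck" and self.t_event < 0:
            raise ValueError("t_event must be non-negative")
        if self.kind == "growth" and self.growth_rate < 0:
            raise ValueError("growth_rate must be non-negative")

    def waiting_time(self, t: float, k: int, rng: np.random.Generator) -> float:
        """Time from ``t`` until the next coalescence among k lineages."""
        base = k * (k - 1) / 2.0
        if self.kind == "constant" or (self.kind == "growth" and self.growth_rate == 0.0):
            return rng.exponential(1.0 / base)
        if self.kind == "growth":
            # rate(t) = base * exp(g t); invert the integrated hazard.
            g = self.growth_rate
            e = rng.exponential(1.0)
            return math.log1p(g * e / (base * math.exp(g * t))) / g
        # bottleneck: piecewise-constant epochs.
        t0 = t
        while True:
            size = self.severity if t < self.t_event else 1.0
            w = rng.exponential(size / base)
            if t >= self.t_event or t + w < self.t_event:
                return (t + w) - t0
            t = self.t_event  # crossed the epoch boundary; redraw


def _simulate_tree(n_hap: int, demography: DemographyModel, rng: np.random.Generator):
    """Draw a genealogy; return (branch lengths, leaf sets below each branch).

    Branches are indexed by their child node; leaf membership is a boolean
    matrix (branch x leaf).
    """
    n_nodes = 2 * n_hap - 1
    lengths = np.zeros(n_nodes)
    below = np.zeros((n_nodes, n_hap), dtype=bool)
    below[np.arange(n_hap), np.arange(n_hap)] = True

    active = list(range(n_hap))
    node_time = np.zeros(n_nodes)
    t = 0.0
    nxt = n_hap
    while len(active) > 1:
        k = len(active)
        t += demography.waiting_time(t, k, rng)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        node_time[nxt] = t
        lengths[a] = t - node_time[a]
        lengths[b] = t - node_time[b]
        below[nxt] = below[a] | below[b]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return lengths[: n_nodes - 1], below[: n_nodes - 1]  # root branch has no length


def simulate_coalescent_window(
    n_hap: int,
    theta: float,
    demography: DemographyModel,
    seed,
    window_size: int = 5000,
):
    """Simulate one window; return (haplotype 0/1 matrix, sorted positions).

    Mutations are Poisson with mean theta/2 times the total branch length
    and are placed on branches proportionally to length (infinite sites:
    each mutation creates a new biallelic site).  Positions are uniform
    integers in [0, window_size), distinct, returned sorted; the matrix is
    haplotypes x sites with the derived allele coded 1.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n_hap < 2:
        raise ValueError("need at least 2 haplotypes to coalesce")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lengths, below = _simulate_tree(n_hap, demography, rng)
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total) if theta > 0 else 0
    if n_mut == 0:
        return np.zeros((n_hap, 0), dtype=np.int8), np.zeros(0, dtype=np.int64)
    branch = rng.choice(len(lengths), size=n_mut, p=lengths / total)
    # distinct integer positions; windows are far sparser than 1 SNP/bp
    if n_mut <= window_size:
        pos = rng.choice(window_size, size=n_mut, replace=False)
    else:  # pathological theta: allow > window_size sites on a float grid
        pos = np.floor(rng.random(n_mut) * window_size).astype(np.int64)
    order = np.argsort(pos, kind="stable")
    geno = below[branch[order]].T.astype(np.int8)
    return geno, pos[order].astype(np.int64)
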