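"""Pedigree fixture generator: founders drawn from Balding-Nichols
population allele frequencies, descendants by independent-locus Mendelian
gene dropping, and exact pedigree kinship coefficients by recursion.

Gene dropping ignores linkage and recombination (no genetic map), which
gives unbiased expected kinship per pair but understates the between-pair
variance a linked genome would show; fixtures built here are therefore
asserted on means, never on IBD-sharing variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import NUCLEOTIDES, GenotypeDataset, MarkerTable, SampleTable


@dataclass
class PedigreeSpec:
    """Declarative cohort recipe.

    ``populations`` maps a population name to its Balding-Nichols F_ST
    against the shared ancestral frequencies (0 = the ancestral pool
    itself).  ``founders`` maps founder id -> population name.  ``matings``
    lists (child_id, parent1_id, parent2_id) triples; parents may themselves
    be children declared earlier.  ``observed`` selects which individuals
    enter the output dataset (default: everyone).
    """

    n_markers: int
    populations: dict
    founders: dict
    matings: list = field(default_factory=list)
    observed: list | None = None
    seed: int = 0
    ancestral_freq_range: tuple = (0.05, 0.95)


class Pedigree:
    """Parent bookkeeping plus exact kinship via the standard recursion."""

    def __init__(self, founders, matings):
        self.parents = {f: None for f in founders}
        order = list(founders)
        for child, p1, p2 in matings:
            if child in self.parents:
                raise ValueError(f"individual {child!r} declared twice")
            if p1 not in self.parents or p2 not in self.parents:
                raise ValueError(
                    f"parents of {child!r} must be declared before the child "
                    "(cyclic or out-of-order pedigree)"
                )
            self.parents[child] = (p1, p2)
            order.append(child)
        self.order = order
        self._depth = {}
        for ind in order:
            par = self.parents[ind]
            self._depth[ind] = 0 if par is None else 1 + max(
                self._depth[par[0]], self._depth[par[1]]
            )
        self._kin_cache: dict = {}

    def kinship(self, a, b) -> float:
        """Pedigree kinship coefficient phi(a, b) (phi(a, a) = (1+F_a)/2)."""
        key = (a, b) if a <= b else (b, a)
        if key in self._kin_cache:
            return self._kin_cache[key]
        if a == b:
            par = self.parents[a]
            F = self.kinship(*par) if par else 0.0
            val = 0.5 * (1.0 + F)
        else:
            # recurse through the individual deeper in the pedigree
            x, y = (a, b) if self._depth[a] >= self._depth[b] else (b, a)
            par = self.parents[x]
            if par is None:
                val = 0.0  # two founders are unrelated
            else:
                val = 0.5 * (self.kinship(par[0], y) + self.kinship(par[1], y))
        self._kin_cache[key] = val
        return val


def _random_marker_table(n_markers: int, rng) -> MarkerTable:
    nts = np.array(NUCLEOTIDES, dtype=object)
    major = nts[rng.integers(0, 4, size=n_markers)]
    shift = rng.integers(1, 4, size=n_markers)
    minor = nts[(np.searchsorted(nts, major) + shift) % 4]
    return MarkerTable.from_arrays(
        marker_id=[f"m{i + 1:07d}" for i in range(n_markers)],
        chromosome=["1"] * n_markers,
        position=np.arange(1, n_markers + 1) * 100,
        allele_major=major,
        allele_minor=minor,
    )


def generate_pedigree_cohort(spec: PedigreeSpec):
    """Simulate diploid genotypes down a pedigree.

    Returns ``(dataset, truth)``: the diploid GenotypeDataset of the observed
    individuals, and a DataFrame of every observed pair with nonzero
    pedigree kinship (columns sample1, sample2, kinship).
    """
    rng = np.random.default_rng(spec.seed)
    ped = Pedigree(spec.founders, spec.matings)
    m = spec.n_markers

    lo, hi = spec.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=m)
    pop_freqs = {}
    for pop, fst in spec.populations.items():
        if fst <= 0:
            pop_freqs[pop] = ancestral
        else:
            alpha = ancestral * (1.0 - fst) / fst
            beta = (1.0 - ancestral) * (1.0 - fst) / fst
            pop_freqs[pop] = np.clip(rng.beta(alpha, beta), 1e-4, 1.0 - 1e-4)

    # two allele columns per individual so transmission is allele-level
    haplos: dict = {}
    for ind in ped.order:
        par = ped.parents[ind]
        if par is None:
            pop = spec.founders[ind]
            pf = pop_freqs[pop]
            haplos[ind] = (
                (rng.random(m) < pf).astype(np.int8),
                (rng.random(m) < pf).astype(np.int8),
            )
        else:
            transmitted = []
            for p in par:
                h1, h2 = haplos[p]
                pick = rng.random(m) < 0.5
                transmitted.append(np.where(pick, h1, h2).astype(np.int8))
            haplos[ind] = tuple(transmitted)

    observed = spec.observed if spec.observed is not None else list(ped.order)
    unknown = [o for o in observed if o not in haplos]
    if unknown:
        raise ValueError(f"observed individuals not in pedigree: {unknown}")
    calls = np.empty((len(observed), m), dtype=np.int8)
    pops = []
    for i, ind in enumerate(observed):
        h1, h2 = haplos[ind]
        calls[i] = h1 + h2  # minor-allele dosage == state code for 0/1/2
        pops.append(spec.founders.get(ind, "pedigree"))

    markers = _random_marker_table(m, rng)
    samples = SampleTable.from_ids(observed, population_label=pops)
    ds = GenotypeDataset(markers, samples, calls, "diploid")

    rows = []
    for i, a in enumerate(observed):
        for b in observed[i + 1 :]:
            phi = ped.kinship(a, b)
            if phi > 0:
                rows.append({"sample1": a, "sample2": b, "kinship": phi})
    truth = pd.DataFrame(rows, columns=["sample1", "sample2", "kinship"])
    return ds, truth
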