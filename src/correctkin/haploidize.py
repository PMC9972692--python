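"""Random pseudo-haploidization (RPsH) of diploid genotype datasets.

Each heterozygous call is independently resolved to one of its two alleles
with probability 1/2, mimicking the single-read allele sampling used for
ancient samples; homozygous and missing states are untouched, so typed-marker
sets are invariant.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import HET, HOM_MAJOR, HOM_MINOR, GenotypeDataset

log = logging.getLogger(__name__)


def rpsh(ds: GenotypeDataset, seed: int) -> GenotypeDataset:
    """Randomly pseudo-haploidize a diploid dataset.

    Uses the counter-based Philox generator keyed by ``seed`` and drawing one
    uniform variate per (sample, marker) cell in a single vectorized pass, so
    the result is independent of traversal order. Identical seed, identical
    output.
    """
    if ds.ploidy_mode == "pseudo_haploid":
        log.warning("rpsh called on an already pseudo-haploid dataset; no-op")
        return ds.copy()
    rng = np.random.Generator(np.random.Philox(seed))
    u = rng.random(ds.calls.shape)
    calls = ds.calls.copy()
    het = ds.calls == HET
    calls[het] = np.where(u[het] < 0.5, HOM_MAJOR, HOM_MINOR)
    return GenotypeDataset(ds.markers, ds.samples, calls, "pseudo_haploid")


def rpsh_replicates(ds: GenotypeDataset, seeds) -> list[GenotypeDataset]:
    """One independent RPsH replicate per seed; duplicate seeds are an error."""
    seeds = list(seeds)
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds: RPsH replicates must be independent")
    return [rpsh(ds, s) for s in seeds]
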