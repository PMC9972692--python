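"""Degradation simulators for ancient-DNA conditions: pairwise marker
depletion, random per-individual depletion, and the three aDNA genotyping
error channels (post-mortem damage, exogenous and endogenous contamination).

All error sites are drawn without replacement among the typed sites of each
sample, and realized error counts equal ``round(rate x typed_count)``
exactly.  In mixed mode one combined site set is drawn and partitioned
across the channels (applied in the fixed order PMD, endogenous, exogenous),
so channels never collide on a site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import HOM_MAJOR, HOM_MINOR, MISSING, GenotypeDataset

log = logging.getLogger(__name__)

CHANNELS = ("pmd", "exogenous", "endogenous", "mixed")


@dataclass
class ErrorConfig:
    """aDNA genotyping-error scenario.

    Per-sample error rates are drawn uniformly on [0, max_rate] (dataset
    mean ~ max_rate/2, the "0-5% per sample, ~2.5% overall" condition);
    ``rate`` pins every sample to a fixed rate instead, which is what the
    deterministic unit tests use.  ``contaminant`` names the sample whose
    states the endogenous channel copies.
    """

    channel: str = "mixed"
    max_rate: float = 0.05
    rate: float | None = None
    contaminant: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown error channel {self.channel!r}")
        if self.channel in ("endogenous", "mixed") and self.contaminant is None:
            raise ValueError("endogenous contamination requires a contaminant sample id")


def deplete_markers(ds: GenotypeDataset, pair, target_f: float, seed: int) -> GenotypeDataset:
    """Deplete the overlap of one sample pair to an exact target fraction.

    Markers are removed from the pair's overlapping set until the overlap
    count equals ``round(target_f * M)`` exactly; each discarded marker is
    set MISSING in one randomly chosen member of the pair (keeping marginal
    typed counts realistic).  Other samples are untouched.
    """
    i = ds.sample_index(pair[0]) if isinstance(pair[0], str) else int(pair[0])
    j = ds.sample_index(pair[1]) if isinstance(pair[1], str) else int(pair[1])
    typed = ds.typed_mask()
    both = np.flatnonzero(typed[i] & typed[j])
    M = ds.n_markers
    n_target = int(round(target_f * M))
    if n_target > len(both):
        raise ValueError(
            f"target overlap {n_target} exceeds current overlap {len(both)}"
        )
    out = ds.copy()
    n_drop = len(both) - n_target
    if n_drop == 0:
        return out
    rng = np.random.default_rng(seed)
    drop = rng.choice(both, size=n_drop, replace=False)
    who = rng.integers(0, 2, size=n_drop)
    out.calls[i, drop[who == 0]] = MISSING
    out.calls[j, drop[who == 1]] = MISSING
    return out


def deplete_indivs(
    ds: GenotypeDataset,
    min_markers: int = 100_000,
    max_markers: int | None = None,
    seed: int = 0,
) -> GenotypeDataset:
    """Give every sample a random typed count uniform on [min, max].

    Markers to drop are chosen uniformly without replacement per sample.  A
    sample already typed below its drawn target (or below ``min_markers``)
    is left as-is with a warning.
    """
    M = ds.n_markers
    if max_markers is None:
        max_markers = M
    if not (0 <= min_markers <= max_markers <= M):
        raise ValueError("need 0 <= min_markers <= max_markers <= panel size")
    rng = np.random.default_rng(seed)
    out = ds.copy()
    typed = ds.typed_mask()
    targets = rng.integers(min_markers, max_markers + 1, size=ds.n_samples)
    for s in range(ds.n_samples):
        sites = np.flatnonzero(typed[s])
        if len(sites) < min_markers:
            log.warning(
                "sample %s typed at %d < min_markers=%d; left unchanged",
                ds.sample_ids[s],
                len(sites),
                min_markers,
            )
            continue
        target = min(int(targets[s]), len(sites))
        n_drop = len(sites) - target
        if n_drop > 0:
            drop = rng.choice(sites, size=n_drop, replace=False)
            out.calls[s, drop] = MISSING
    return out


def _pmd_marker_classes(markers):
    """Per-marker PMD fate: 'flip' for C/T- or G/A-alleled markers, 'missing'
    for other markers containing C or G (the damage product matches neither
    allele), 'immune' for A/T markers."""
    maj = markers.table["allele_major"].to_numpy(object)
    mnr = markers.table["allele_minor"].to_numpy(object)
    flip = np.zeros(len(maj), dtype=bool)
    immune = np.zeros(len(maj), dtype=bool)
    for k in range(len(maj)):
        pair = frozenset((maj[k], mnr[k]))
        if pair in (frozenset("CT"), frozenset("AG")):
            flip[k] = True
        elif "C" not in pair and "G" not in pair:
            immune[k] = True
    missing = ~flip & ~immune
    return flip, missing, immune


def apply_errors(ds: GenotypeDataset, cfg: ErrorConfig):
    """Inject aDNA-style genotyping errors into a pseudo-haploid dataset.

    Channel rules at a hit site:

    * ``pmd`` — markers whose alleles are C/T or G/A have their homozygous
      state flipped (deamination turns one allele into the other); markers
      containing C or G with any other partner become MISSING (the damage
      product is unrepresentable); A/T markers are immune (hit counted, no
      effect).
    * ``exogenous`` — the state is set to HOM_MAJOR regardless of the prior
      call (microbial DNA reads as the ancestral/major allele).
    * ``endogenous`` — the state is copied from the contaminant sample at
      the same marker (MISSING copies as MISSING).

    Returns ``(dataset, report)`` with per-sample requested rates and
    realized per-channel hit counts.
    """
    if ds.ploidy_mode != "pseudo_haploid":
        raise ValueError("apply_errors expects a pseudo-haploid dataset")
    rng = np.random.default_rng(cfg.seed)
    out = ds.copy()
    typed = ds.typed_mask()
    flip_class, missing_class, immune_class = _pmd_marker_classes(ds.markers)

    contaminant_idx = None
    if cfg.contaminant is not None:
        contaminant_idx = ds.sample_index(cfg.contaminant)
    contaminant_calls = None
    if contaminant_idx is not None:
        contaminant_calls = ds.calls[contaminant_idx].copy()

    rows = []
    for s in range(ds.n_samples):
        rate = cfg.rate if cfg.rate is not None else float(rng.uniform(0.0, cfg.max_rate))
        sites_typed = np.flatnonzero(typed[s])
        n_err = int(round(rate * len(sites_typed)))
        n_err = min(n_err, len(sites_typed))
        hits = rng.choice(sites_typed, size=n_err, replace=False) if n_err else np.array([], int)

        if cfg.channel == "mixed":
            thirds = np.array_split(hits, 3)
            parts = dict(zip(("pmd", "endogenous", "exogenous"), thirds))
        else:
            parts = {cfg.channel: hits}

        counts = {"pmd": 0, "endogenous": 0, "exogenous": 0}
        if "pmd" in parts:
            h = parts["pmd"]
            counts["pmd"] = len(h)
            hf = h[flip_class[h]]
            cur = out.calls[s, hf]
            flipped = np.where(cur == HOM_MAJOR, HOM_MINOR, np.where(cur == HOM_MINOR, HOM_MAJOR, cur))
            out.calls[s, hf] = flipped
            out.calls[s, h[missing_class[h]]] = MISSING
            # immune-class hits: counted, no effect
        if "endogenous" in parts and s != contaminant_idx:
            h = parts["endogenous"]
            counts["endogenous"] = len(h)
            out.calls[s, h] = contaminant_calls[h]
        if "exogenous" in parts:
            h = parts["exogenous"]
            counts["exogenous"] = len(h)
            out.calls[s, h] = HOM_MAJOR
        rows.append(
            {
                "sample_id": ds.sample_ids[s],
                "rate": rate,
                "n_typed": len(sites_typed),
                "n_hit": n_err,
                **{f"n_{k}": v for k, v in counts.items()},
            }
        )
    report = pd.DataFrame(rows)
    return out, report
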