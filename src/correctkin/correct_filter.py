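"""Overlap-fraction correction of kinship coefficients, the empirical
Z-score error model, relative filtering, degree classification and
kin-group construction.

The corrected coefficient phi* = phi / f divides the raw estimate by the
pair's overlapping-marker fraction, undoing the linear attenuation that
partial typing imposes on the mean-imputed estimator.  Because the variance
of phi* grows as the overlapping-marker count n shrinks, a single hard
threshold cannot separate relatives from unrelated pairs at every coverage;
instead an empirical error model of the unrelated-pair spread as a function
of n supports an N-sigma (default N = 6) decision rule with
coverage-independent specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .overlap import OverlapMatrix

log = logging.getLogger(__name__)

#: expected kinship coefficient per degree class
EXPECTED_KINSHIP = {
    "sample_match": 0.5,
    "first": 0.25,
    "second": 0.125,
    "third": 0.0625,
    "fourth": 0.03125,
}

#: arithmetic-midpoint class boundaries (upper-open); the 3rd/4th midpoint
#: 0.046875 doubles as the conventional hard filter threshold
DEGREE_BOUNDS = {
    "sample_match": (0.375, np.inf),
    "first": (0.1875, 0.375),
    "second": (0.09375, 0.1875),
    "third": (0.046875, 0.09375),
    "fourth": (0.0234375, 0.046875),
}

HARD_THRESHOLD_DEFAULT = (EXPECTED_KINSHIP["third"] + EXPECTED_KINSHIP["fourth"]) / 2.0

#: pairs below this overlapping-marker count are flagged low-confidence
#: (4th-degree calls become unreliable below ~17k overlapping markers)
LOW_CONFIDENCE_OVERLAP = 17_000


def correct_kinship(phi: np.ndarray, fraction: np.ndarray) -> np.ndarray:
    """Elementwise phi* = phi / f for off-diagonal pairs.

    Pairs with zero overlap are uncomputable and returned as NaN, never as a
    silent zero.  The diagonal (self-kinship) is returned as NaN: it is
    excluded from both model fitting and reporting.
    """
    phi = np.asarray(phi, dtype=float)
    fraction = np.asarray(fraction, dtype=float)
    if phi.shape != fraction.shape:
        raise ValueError("kinship and overlap-fraction matrices differ in shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = phi / fraction
    out[fraction == 0] = np.nan
    if out.ndim == 2 and out.shape[0] == out.shape[1]:
        np.fill_diagonal(out, np.nan)
    return out


def classify_degree(phi_star):
    """Nearest-expected-value degree class using arithmetic-midpoint bounds."""
    arr = np.asarray(phi_star, dtype=float)
    out = np.full(arr.shape, "distant", dtype=object)
    for name, (lo, hi) in DEGREE_BOUNDS.items():
        out[(arr >= lo) & (arr < hi)] = name
    if arr.ndim == 0:
        return str(out[()])
    return out


def _trimmed_sd_factor(trim: float) -> float:
    """Normal-consistency factor for a two-sided trimmed SD.

    Trimming a fraction ``trim`` from each tail shrinks the SD of a normal
    sample; dividing by this factor restores an unbiased scale so the
    Z-multiplier keeps its nominal meaning.
    """
    if trim <= 0:
        return 1.0
    a = stats.norm.ppf(1.0 - trim)
    mass = 1.0 - 2.0 * trim
    var = 1.0 - 2.0 * a * stats.norm.pdf(a) / mass
    return float(np.sqrt(var))


@dataclass
class ErrorModel:
    """Empirical mean/SD of corrected kinship among unrelated pairs vs
    overlapping-marker count, with an N-sigma threshold."""

    bin_n: np.ndarray  # geometric-mean overlap count per bin
    bin_mean: np.ndarray
    bin_sd: np.ndarray
    a: float  # sd(n) = a + b / sqrt(n)
    b: float
    Z: float = 6.0
    isotonic: bool = False
    _iso_sd: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def mean_curve(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return np.interp(np.log(n), np.log(self.bin_n), self.bin_mean)

    def sd_curve(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        if self.isotonic:
            sd = np.interp(np.log(n), np.log(self.bin_n), self._iso_sd)
        else:
            sd = self.a + self.b / np.sqrt(n)
        return np.maximum(sd, 1e-9)

    def threshold(self, n) -> np.ndarray:
        return self.mean_curve(n) + self.Z * self.sd_curve(n)

    def zscore(self, phi_star, n) -> np.ndarray:
        return (np.asarray(phi_star, dtype=float) - self.mean_curve(n)) / self.sd_curve(n)


def _extract_pairs(corrected, counts):
    corrected = np.asarray(corrected, dtype=float)
    counts = np.asarray(counts)
    if corrected.ndim == 2:
        iu = np.triu_indices(corrected.shape[0], k=1)
        phi = corrected[iu]
        n = counts[iu].astype(float)
    else:
        phi = corrected.ravel()
        n = counts.astype(float).ravel()
    ok = np.isfinite(phi) & (n > 0)
    return phi[ok], n[ok]


def fit_error_model(
    corrected,
    overlap_counts,
    Z: float = 6.0,
    hard_threshold: float = HARD_THRESHOLD_DEFAULT,
    n_bins: int = 10,
    min_per_bin: int = 20,
    trim: float = 0.05,
) -> ErrorModel:
    """Iterative robust fit of the unrelated-pair spread versus overlap count.

    (1) provisionally exclude pairs above ``hard_threshold``; (2) within
    log-spaced bins of n compute the trimmed mean and (consistency-corrected)
    trimmed SD; (3) fit sd(n) = a + b/sqrt(n) by least squares on the bin
    SDs; (4) re-exclude pairs above mean + Z*sd and refit once.  If the
    fitted curve is increasing in n (b < 0) the fit falls back to isotonic
    regression of the bin SDs, with a warning.

    Accepts full symmetric matrices (the upper triangle is used) or flat
    pair arrays.
    """
    phi_all, n_all = _extract_pairs(corrected, overlap_counts)
    if len(phi_all) < 50:
        raise ValueError(
            f"only {len(phi_all)} usable pairs; the error model needs >= 50 "
            "(add reference samples)"
        )
    factor = _trimmed_sd_factor(trim)
    include = phi_all <= hard_threshold

    bins_n = bins_mean = bins_sd = None
    a = b = 0.0
    isotonic = False
    iso_sd = None
    occupancy = []
    for _iteration in range(2):
        phi, n = phi_all[include], n_all[include]
        lo, hi = n.min(), n.max()
        if lo == hi:
            edges = np.array([lo, hi])
        else:
            edges = np.geomspace(lo, hi, n_bins + 1)
            edges[-1] = hi * (1 + 1e-12)
        which = np.clip(np.searchsorted(edges, n, side="right") - 1, 0, len(edges) - 2)
        # merge sparse bins upward (into the next higher-n bin)
        groups: list[np.ndarray] = []
        pending = np.array([], dtype=int)
        for bi in range(len(edges) - 1):
            idx = np.flatnonzero(which == bi)
            idx = np.concatenate([pending, idx])
            if len(idx) < min_per_bin:
                pending = idx
                continue
            groups.append(idx)
            pending = np.array([], dtype=int)
        if len(pending):
            if groups:
                groups[-1] = np.concatenate([groups[-1], pending])
            else:
                groups.append(pending)
        bins_n = np.array([np.exp(np.mean(np.log(n[g]))) for g in groups])
        bins_mean = np.array(
            [stats.trim_mean(phi[g], trim) if len(g) > 2 else phi[g].mean() for g in groups]
        )
        bins_sd = np.array(
            [
                stats.mstats.trimmed_std(phi[g], limits=(trim, trim)) / factor
                if len(g) > 2
                else phi[g].std()
                for g in groups
            ]
        )
        bins_sd = np.maximum(bins_sd, 1e-9)
        occupancy = [len(g) for g in groups]

        if len(groups) < 2:
            a, b = float(bins_sd[0]), 0.0
        else:
            A = np.column_stack([np.ones_like(bins_n), 1.0 / np.sqrt(bins_n)])
            w = np.sqrt(np.array(occupancy, dtype=float))
            coef, *_ = np.linalg.lstsq(A * w[:, None], bins_sd * w, rcond=None)
            a, b = float(coef[0]), float(coef[1])
        if b < 0:
            isotonic = True
            from sklearn.isotonic import IsotonicRegression

            iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
            iso_sd = iso.fit_transform(np.log(bins_n), bins_sd)
            iso_sd = np.maximum(iso_sd, 1e-9)
            log.warning(
                "sd(n) fit was increasing in n; falling back to isotonic regression"
            )

        model = ErrorModel(
            bin_n=bins_n,
            bin_mean=bins_mean,
            bin_sd=bins_sd,
            a=a,
            b=b,
            Z=Z,
            isotonic=isotonic,
            _iso_sd=iso_sd,
        )
        include = phi_all < model.threshold(n_all)
        if not include.any():  # pathological; keep previous fit
            break

    model.diagnostics = {
        "n_pairs_total": int(len(phi_all)),
        "n_pairs_used": int(include.sum()),
        "bin_occupancy": occupancy,
        "trim": trim,
        "sd_consistency_factor": factor,
    }
    return model


def filter_relatives(
    raw: np.ndarray,
    corrected: np.ndarray,
    overlap: OverlapMatrix,
    model: ErrorModel | None = None,
    hard_threshold: float | None = None,
) -> pd.DataFrame:
    """Report pairs exceeding the error model and/or a hard threshold.

    A pair is reported iff its Z score >= model.Z (error-model mode), its
    corrected coefficient >= hard_threshold (hard mode), or either when both
    criteria are supplied (combined mode, the default workflow behaviour).
    Output is sorted by corrected kinship descending; the ``criterion``
    column records which rule produced each call, and pairs with fewer than
    17,000 overlapping markers carry a low-confidence flag.
    """
    if model is None and hard_threshold is None:
        raise ValueError("supply an error model, a hard threshold, or both")
    corrected = np.asarray(corrected, dtype=float)
    n_samples = corrected.shape[0]
    ids = overlap.sample_ids
    iu, ju = np.triu_indices(n_samples, k=1)
    phi_star = corrected[iu, ju]
    raw_pair = np.asarray(raw, dtype=float)[iu, ju]
    n_pair = overlap.counts[iu, ju].astype(np.int64)
    f_pair = n_pair / float(overlap.panel_size)

    finite = np.isfinite(phi_star)
    z = np.full(len(phi_star), np.nan)
    by_z = np.zeros(len(phi_star), dtype=bool)
    if model is not None:
        ok = finite & (n_pair > 0)
        z[ok] = model.zscore(phi_star[ok], n_pair[ok])
        by_z[ok] = z[ok] >= model.Z
    by_hard = np.zeros(len(phi_star), dtype=bool)
    if hard_threshold is not None:
        by_hard[finite] = phi_star[finite] >= hard_threshold
    hit = by_z | by_hard

    criterion = np.where(
        by_z & by_hard, "both", np.where(by_z, "error_model", "hard")
    )
    sel = np.flatnonzero(hit)
    calls = pd.DataFrame(
        {
            "sample1": [ids[i] for i in iu[sel]],
            "sample2": [ids[j] for j in ju[sel]],
            "n_overlap": n_pair[sel],
            "f_overlap": f_pair[sel],
            "raw_kin": raw_pair[sel],
            "corrected_kin": phi_star[sel],
            "z": z[sel],
            "degree": classify_degree(phi_star[sel]),
            "criterion": criterion[sel],
            "low_confidence": n_pair[sel] < LOW_CONFIDENCE_OVERLAP,
        }
    )
    calls = calls.sort_values(
        ["corrected_kin", "sample1", "sample2"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return calls


def kin_groups(calls: pd.DataFrame) -> pd.DataFrame:
    """Label connected components of the relatives graph.

    Groups are numbered 1..G in order of their smallest member id, so labels
    are deterministic for a given call set.  Returns the calls with a
    ``kin_group`` column added.
    """
    calls = calls.copy()
    if calls.empty:
        calls["kin_group"] = pd.Series([], dtype=int)
        return calls
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for s1, s2 in zip(calls["sample1"], calls["sample2"]):
        union(s1, s2)
    members: dict = {}
    for node in parent:
        members.setdefault(find(node), []).append(node)
    groups = sorted(members.values(), key=lambda ms: min(str(m) for m in ms))
    label = {}
    for gid, ms in enumerate(groups, start=1):
        for mname in ms:
            label[mname] = gid
    calls["kin_group"] = [label[s] for s in calls["sample1"]]
    return calls
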