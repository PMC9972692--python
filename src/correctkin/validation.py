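"""Desk-scale validation experiments for the corrected-kinship workflow.

This module builds seeded synthetic cohorts (founders from population allele
frequencies plus gene-dropped pedigree descendants), degrades them to
aDNA-like sparsity and error, runs the full estimate-correct-filter path and
measures how well the known planted relationships are recovered.  The same
functions back the acceptance test suite and ``scripts/acceptance.py``.

It also carries two published worked-example tables of corrected-kinship
arithmetic from real ancient families (a medieval father-son pair sequenced
as five libraries of widely different coverage, and a Corded Ware Culture
kin group with 1st- to 4th-degree relations), used to check the correction
arithmetic against printed values.

Problem sizes: the overlap-fraction sweeps and expectation experiments use
20k-marker panels with ~200-sample reference cohorts; the filter-performance
experiment uses a 100k-marker panel with a 300-sample cohort.  Because the
statistical power of the Z-score filter depends on the ABSOLUTE
overlapping-marker count (sd(phi*) ~ c/sqrt(n)), relatives of 1st-3rd degree
are planted at typed fractions whose pairwise overlaps stay inside the
method's detection envelope, while 4th-degree pairs deliberately span the
full coverage range, including overlaps below the ~10% bound where
4th-degree detection is not expected.
"""

from __future__ import annotations

import io
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .correct_filter import correct_kinship, filter_relatives, fit_error_model
from .datatypes import GenotypeDataset, SampleTable
from .haploidize import rpsh
from .kinship import estimate_kinship
from .overlap import overlap_matrix
from .pedigree import PedigreeSpec, generate_pedigree_cohort
from .simulate import ErrorConfig, apply_errors, deplete_markers

log = logging.getLogger(__name__)

#: published corrected-kinship arithmetic, medieval father-son duo typed as
#: 3+2 independent libraries at 0.87-11.9x coverage (1240K panel, M=1150639)
REFERENCE_TABLE_MEDIEVAL = pd.read_csv(
    io.StringIO(
        """sample1\tsample2\tf\trelation\texpected\tuncorrected\tcorrected
Father_high\tChild_high\t0.933894\tfirst\t0.25\t0.22883\t0.24502
Father_high\tChild_low\t0.377769\tfirst\t0.25\t0.09179\t0.24297
Father_medium\tChild_high\t0.730011\tfirst\t0.25\t0.17604\t0.24114
Father_medium\tChild_low\t0.296127\tfirst\t0.25\t0.07150\t0.24144
Father_low\tChild_high\t0.511753\tfirst\t0.25\t0.12239\t0.23915
Father_low\tChild_low\t0.207545\tfirst\t0.25\t0.05014\t0.24160
Father_high\tFather_medium\t0.778247\tsample_match\t0.5\t0.38284\t0.49193
Father_high\tFather_low\t0.545866\tsample_match\t0.5\t0.27020\t0.49499
Father_medium\tFather_low\t0.427389\tsample_match\t0.5\t0.20863\t0.48814
Child_high\tChild_low\t0.354511\tsample_match\t0.5\t0.17286\t0.48761
"""
    ),
    sep="\t",
)

#: published corrected-kinship arithmetic, Corded Ware Culture kin group of
#: five males with 1st- to 4th-degree relations (0.12-4.18x coverage)
REFERENCE_TABLE_CWC = pd.read_csv(
    io.StringIO(
        """sample1\tsample2\tf\trelation\texpected\tuncorrected\tcorrected
I1538\tI1541\t0.039828\tfirst\t0.25\t0.01036\t0.26006
I1540\tI1541\t0.079863\tfirst\t0.25\t0.01959\t0.24534
I1534\tI1541\t0.047882\tsecond\t0.125\t0.00715\t0.14938
I1538\tI1534\t0.025735\tsecond\t0.125\t0.00335\t0.13003
I1538\tI1540\t0.042478\tsecond\t0.125\t0.00456\t0.10730
I1541\tI0104\t0.216185\tsecond\t0.125\t0.03394\t0.15700
I1534\tI1540\t0.049813\tthird\t0.0625\t0.00405\t0.08123
I1538\tI0104\t0.107634\tthird\t0.0625\t0.00846\t0.07864
I1540\tI0104\t0.22405\tthird\t0.0625\t0.01812\t0.08088
I1534\tI0104\t0.129456\tfourth\t0.03125\t0.00645\t0.04982
"""
    ),
    sep="\t",
)

#: full 1240K-style panel size and the typed counts behind the medieval table
REFERENCE_PANEL_SIZE = 1_150_639
REFERENCE_TYPED_COUNTS = {
    "Father_high": 1_148_973,
    "Father_medium": 896_623,
    "Father_low": 630_405,
    "Child_high": 1_075_845,
    "Child_low": 435_005,
}


def reference_tables() -> pd.DataFrame:
    """Both published worked-example tables concatenated."""
    return pd.concat(
        [REFERENCE_TABLE_MEDIEVAL, REFERENCE_TABLE_CWC], ignore_index=True
    )


# ---------------------------------------------------------------------------
# planted-family building blocks

def _family(degree: str, tag: str):
    """Founders/matings/observed/truth for one planted relative pair.

    Hidden connecting individuals (the unobserved parent of a parent-child
    pair, the shared grandparents of cousins, ...) are generated but not
    observed, so the output cohort contains exactly the two relatives.
    """
    f = lambda name: f"{tag}_{name}"
    if degree == "first":  # parent-child
        founders = [f("p1"), f("p2")]
        matings = [(f("c"), f("p1"), f("p2"))]
        observed = [f("p1"), f("c")]
        phi = 0.25
    elif degree == "second":  # half siblings
        founders = [f("p"), f("m1"), f("m2")]
        matings = [(f("c1"), f("p"), f("m1")), (f("c2"), f("p"), f("m2"))]
        observed = [f("c1"), f("c2")]
        phi = 0.125
    elif degree == "third":  # first cousins
        founders = [f("g1"), f("g2"), f("u1"), f("u2")]
        matings = [
            (f("s1"), f("g1"), f("g2")),
            (f("s2"), f("g1"), f("g2")),
            (f("c1"), f("s1"), f("u1")),
            (f("c2"), f("s2"), f("u2")),
        ]
        observed = [f("c1"), f("c2")]
        phi = 0.0625
    elif degree == "fourth":  # first cousins once removed
        founders = [f("g1"), f("g2"), f("u1"), f("u2"), f("u3")]
        matings = [
            (f("s1"), f("g1"), f("g2")),
            (f("s2"), f("g1"), f("g2")),
            (f("c1"), f("s1"), f("u1")),
            (f("c2"), f("s2"), f("u2")),
            (f("d1"), f("c1"), f("u3")),
        ]
        observed = [f("d1"), f("c2")]
        phi = 0.03125
    else:
        raise ValueError(f"unknown planted degree {degree!r}")
    pairs = [(observed[0], observed[1], degree, phi)]
    return founders, matings, observed, pairs


def _append_duplicate(ds: GenotypeDataset, sample_id: str, new_id: str) -> GenotypeDataset:
    """Append a second row with the same diploid genotypes (a sample match
    once the dataset is independently pseudo-haploidized)."""
    i = ds.sample_index(sample_id)
    table = ds.samples.table
    row = table.iloc[[i]].assign(sample_id=new_id)
    samples = SampleTable(pd.concat([table, row], ignore_index=True))
    calls = np.vstack([ds.calls, ds.calls[[i]]])
    return GenotypeDataset(ds.markers, samples, calls, ds.ploidy_mode)


def make_validation_cohort(
    n_reference: int,
    n_markers: int,
    degrees=("first", "second", "third", "fourth"),
    n_sample_match: int = 0,
    seed: int = 0,
    contaminant_fst: float | None = None,
):
    """Reference founders plus planted relative pairs, diploid.

    ``degrees`` may repeat entries to plant several pairs of one degree.
    Returns ``(dataset, truth)``; truth rows are (sample1, sample2, degree,
    kinship).  All reference and family founders come from one population
    (the own-reference-population setting); an optional divergent
    contaminant founder (sample id ``CONTAM``) supports the endogenous
    error channel.
    """
    populations = {"POP": 0.0}
    founders = {f"REF{i + 1:04d}": "POP" for i in range(n_reference)}
    matings: list = []
    observed = list(founders)
    truth: list = []
    for k, degree in enumerate(degrees):
        fam_founders, fam_matings, fam_observed, fam_pairs = _family(
            degree, tag=f"F{k + 1}{degree[:2].upper()}"
        )
        for name in fam_founders:
            founders[name] = "POP"
        matings.extend(fam_matings)
        observed.extend(fam_observed)
        truth.extend(fam_pairs)
    dup_sources = []
    for d in range(n_sample_match):
        name = f"DUP{d + 1}_a"
        founders[name] = "POP"
        observed.append(name)
        dup_sources.append(name)
    if contaminant_fst is not None:
        populations["CONT"] = contaminant_fst
        founders["CONTAM"] = "CONT"
        observed.append("CONTAM")

    spec = PedigreeSpec(
        n_markers=n_markers,
        populations=populations,
        founders=founders,
        matings=matings,
        observed=observed,
        seed=seed,
    )
    ds, _ = generate_pedigree_cohort(spec)
    for name in dup_sources:
        twin = name[:-2] + "_b"
        ds = _append_duplicate(ds, name, twin)
        truth.append((name, twin, "sample_match", 0.5))
    truth_df = pd.DataFrame(truth, columns=["sample1", "sample2", "degree", "kinship"])
    return ds, truth_df


def _pair_value(matrix, ds, s1, s2):
    return float(matrix[ds.sample_index(s1), ds.sample_index(s2)])


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# experiments

def linearity_sweep(
    seed: int,
    n_markers: int = 20_000,
    n_reference: int = 200,
    n_reps: int = 10,
    fractions=None,
) -> dict:
    """Raw kinship of a sample-match pair versus overlap fraction.

    The pair is depleted to each target fraction in 5% steps; each point
    averages ``n_reps`` independent pseudo-haploidization/depletion
    randomizations (the published sweep averages 100 randomizations per
    point).  Returns the regression of mean raw kinship on realized overlap
    fraction and the spread of the corrected coefficient across the sweep.
    """
    if fractions is None:
        fractions = np.round(np.arange(1, 21) * 0.05, 2)
    ds, _ = make_validation_cohort(
        n_reference, n_markers, degrees=(), n_sample_match=1, seed=seed
    )
    pair = ("DUP1_a", "DUP1_b")
    seeds = _child_seeds(seed, n_reps * (len(fractions) + 1)).reshape(
        n_reps, len(fractions) + 1
    )
    records = []
    for r in range(n_reps):
        hap = rpsh(ds, int(seeds[r, 0]))
        for k, f in enumerate(fractions):
            dep = deplete_markers(hap, pair, float(f), int(seeds[r, k + 1]))
            kin = estimate_kinship(dep)
            n_target = int(round(f * n_markers))
            phi = _pair_value(kin.phi, dep, *pair)
            records.append(
                {
                    "rep": r,
                    "target_f": float(f),
                    "realized_f": n_target / n_markers,
                    "phi_hat": phi,
                }
            )
    table = pd.DataFrame(records)
    means = table.groupby("realized_f", as_index=False)["phi_hat"].mean()
    fit = stats.linregress(means["realized_f"], means["phi_hat"])
    phi_star = means["phi_hat"] / means["realized_f"]
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "phi_star_mean": float(phi_star.mean()),
        "phi_star_range": float(phi_star.max() - phi_star.min()),
        "means": means.assign(phi_star=phi_star),
        "table": table,
        "n_markers": n_markers,
    }


def expectation_recovery(
    seed: int,
    n_reps: int = 20,
    n_markers: int = 20_000,
    n_reference: int = 200,
) -> pd.DataFrame:
    """Mean corrected kinship of fully typed planted pairs, per degree.

    One pair each of sample-match, 1st, 2nd, 3rd and 4th degree is planted
    in a fresh cohort per replicate; the dataset is pseudo-haploidized and
    the full estimate-correct path is run at full typing.
    """
    seeds = _child_seeds(seed, n_reps * 2).reshape(n_reps, 2)
    rows = []
    for r in range(n_reps):
        ds, truth = make_validation_cohort(
            n_reference,
            n_markers,
            degrees=("first", "second", "third", "fourth"),
            n_sample_match=1,
            seed=int(seeds[r, 0]),
        )
        hap = rpsh(ds, int(seeds[r, 1]))
        kin = estimate_kinship(hap)
        om = overlap_matrix(hap)
        corrected = correct_kinship(kin.phi, om.fraction)
        for t in truth.itertuples(index=False):
            rows.append(
                {
                    "rep": r,
                    "degree": t.degree,
                    "expected": t.kinship,
                    "corrected_kin": _pair_value(corrected, hap, t.sample1, t.sample2),
                }
            )
    per_pair = pd.DataFrame(rows)
    summary = (
        per_pair.groupby("degree", as_index=False)
        .agg(expected=("expected", "first"), mean_corrected=("corrected_kin", "mean"),
             sd_corrected=("corrected_kin", "std"))
    )
    summary["abs_error"] = (summary["mean_corrected"] - summary["expected"]).abs()
    return summary


def error_channel_effects(
    seed: int,
    n_reps: int = 20,
    n_markers: int = 20_000,
    n_reference: int = 100,
    max_rate: float = 0.05,
) -> pd.DataFrame:
    """Relative reduction of corrected kinship under each aDNA error channel.

    Plants a sample-match, a 1st- and a 2nd-degree pair; injects each error
    channel (and the equal three-way mix) at per-sample rates uniform on
    [0, max_rate]; reports the mean relative reduction of the planted pairs'
    corrected kinship versus the error-free dataset, in percent.
    """
    channels = ("pmd", "exogenous", "endogenous", "mixed")
    seeds = _child_seeds(seed, n_reps * (2 + len(channels))).reshape(n_reps, -1)
    rows = []
    for r in range(n_reps):
        ds, truth = make_validation_cohort(
            n_reference,
            n_markers,
            degrees=("first", "second"),
            n_sample_match=1,
            seed=int(seeds[r, 0]),
            contaminant_fst=0.15,
        )
        hap = rpsh(ds, int(seeds[r, 1]))
        om = overlap_matrix(hap)
        kin = estimate_kinship(hap)
        clean = correct_kinship(kin.phi, om.fraction)
        for c, channel in enumerate(channels):
            cfg = ErrorConfig(
                channel=channel,
                max_rate=max_rate,
                contaminant="CONTAM",
                seed=int(seeds[r, 2 + c]),
            )
            noisy, _ = apply_errors(hap, cfg)
            om_e = overlap_matrix(noisy)  # PMD can introduce new missingness
            kin_e = estimate_kinship(noisy)
            corr_e = correct_kinship(kin_e.phi, om_e.fraction)
            for t in truth.itertuples(index=False):
                v_clean = _pair_value(clean, hap, t.sample1, t.sample2)
                v_err = _pair_value(corr_e, noisy, t.sample1, t.sample2)
                rows.append(
                    {
                        "rep": r,
                        "channel": channel,
                        "degree": t.degree,
                        "clean": v_clean,
                        "with_errors": v_err,
                        "relative_reduction_pct": 100.0 * (v_clean - v_err) / v_clean,
                    }
                )
    per_pair = pd.DataFrame(rows)
    return (
        per_pair.groupby("channel", as_index=False)["relative_reduction_pct"]
        .mean()
        .set_index("channel")["relative_reduction_pct"]
        .to_frame()
    )


def _deplete_with_targets(ds, targets, seed):
    """Set each sample's typed count to its target by random marker removal."""
    rng = np.random.default_rng(seed)
    out = ds.copy()
    typed = ds.typed_mask()
    from .datatypes import MISSING

    for s, target in enumerate(targets):
        sites = np.flatnonzero(typed[s])
        n_drop = len(sites) - int(target)
        if n_drop > 0:
            out.calls[s, rng.choice(sites, size=n_drop, replace=False)] = MISSING
    return out


def filter_performance(
    seed: int,
    n_runs: int = 20,
    n_markers: int = 100_000,
    n_background: int = 284,
    Z: float = 6.0,
) -> dict:
    """Z-score filter sensitivity/specificity on depleted synthetic cohorts.

    Each run builds a 300-sample pseudo-haploid cohort: background samples
    with typed counts uniform on [scaled-100K, M] (the scaled analogue of
    the 100K-marker inclusion threshold on a 1.15M panel), two planted pairs
    each of 1st-3rd degree with typed counts uniform on [0.6M, M] (pairwise
    overlap inside the method's detection envelope), and two 4th-degree
    pairs spanning the full coverage range, some of which fall below the
    ~10%-overlap bound where 4th-degree detection is not expected.  The
    empirical error model is fitted per run and pairs at Z >= 6 reported.

    A run succeeds when every planted 1st-3rd-degree pair is reported and
    no unrelated pair is.  4th-degree recovery is tallied but not part of
    the success criterion.
    """
    degrees = ("first", "first", "second", "second", "third", "third", "fourth", "fourth")
    min_scaled = int(round(100_000 / REFERENCE_PANEL_SIZE * n_markers))
    seeds = _child_seeds(seed, n_runs * 3).reshape(n_runs, 3)
    runs = []
    for r in range(n_runs):
        ds, truth = make_validation_cohort(
            n_background, n_markers, degrees=degrees, seed=int(seeds[r, 0])
        )
        hap = rpsh(ds, int(seeds[r, 1]))
        rng = np.random.default_rng(int(seeds[r, 2]))
        planted_123 = set()
        for t in truth.itertuples(index=False):
            if t.degree in ("first", "second", "third"):
                planted_123.update((t.sample1, t.sample2))
        targets = np.empty(hap.n_samples, dtype=np.int64)
        for s, sid in enumerate(hap.sample_ids):
            if sid in planted_123:
                targets[s] = rng.integers(int(0.6 * n_markers), n_markers + 1)
            else:
                targets[s] = rng.integers(min_scaled, n_markers + 1)
        dep = _deplete_with_targets(hap, targets, int(seeds[r, 2]) + 1)

        om = overlap_matrix(dep)
        kin = estimate_kinship(dep)
        corrected = correct_kinship(kin.phi, om.fraction)
        model = fit_error_model(corrected, om.counts, Z=Z)
        calls = filter_relatives(kin.phi, corrected, om, model=model)

        called = {frozenset((a, b)) for a, b in zip(calls["sample1"], calls["sample2"])}
        truth_all = {
            frozenset((t.sample1, t.sample2)) for t in truth.itertuples(index=False)
        }
        want = {
            frozenset((t.sample1, t.sample2))
            for t in truth.itertuples(index=False)
            if t.degree in ("first", "second", "third")
        }
        fourth = truth_all - want
        false_pos = called - truth_all
        missed = want - called
        runs.append(
            {
                "run": r,
                "recovered_123": len(want) - len(missed),
                "n_123": len(want),
                "false_positives": len(false_pos),
                "fourth_recovered": len(fourth & called),
                "n_fourth": len(fourth),
                "success": (not missed) and (not false_pos),
            }
        )
    detail = pd.DataFrame(runs)
    return {
        "success_rate": float(detail["success"].mean()),
        "false_positive_total": int(detail["false_positives"].sum()),
        "fourth_recovery_rate": float(
            detail["fourth_recovered"].sum() / detail["n_fourth"].sum()
        ),
        "detail": detail,
        "n_markers": n_markers,
        "min_typed": min_scaled,
    }
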