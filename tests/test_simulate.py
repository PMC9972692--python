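"""Degradation simulators: exact depletion contracts, the three aDNA error
channels, and the pedigree gene-dropping generator."""

import numpy as np
import pytest
from scipy import stats

from correctkin.datatypes import HOM_MAJOR, HOM_MINOR, MISSING
from correctkin.overlap import overlap_matrix
from correctkin.pedigree import Pedigree, PedigreeSpec, generate_pedigree_cohort
from correctkin.simulate import (
    ErrorConfig,
    apply_errors,
    deplete_indivs,
    deplete_markers,
)

from conftest import dataset_from_matrix, random_dataset


class TestDepleteMarkers:
    def test_exact_target_count(self):
        ds = random_dataset(4, 1000, seed=1, missing_rate=0.0, mode="pseudo_haploid")
        out = deplete_markers(ds, (0, 1), 0.25, seed=9)
        om = overlap_matrix(out)
        assert om.counts[0, 1] == 250  # round(0.25 * 1000), exactly
        # other samples untouched
        np.testing.assert_array_equal(out.calls[2:], ds.calls[2:])

    def test_target_equal_to_current_is_noop(self):
        ds = random_dataset(3, 200, seed=2, missing_rate=0.1, mode="pseudo_haploid")
        cur = overlap_matrix(ds).pair(0, 1)[1]
        out = deplete_markers(ds, (0, 1), cur, seed=5)
        np.testing.assert_array_equal(out.calls, ds.calls)

    def test_target_above_current_overlap_errors(self):
        ds = random_dataset(2, 100, seed=3, missing_rate=0.5, mode="pseudo_haploid")
        with pytest.raises(ValueError, match="exceeds current overlap"):
            deplete_markers(ds, (0, 1), 0.99, seed=1)


class TestDepleteIndivs:
    def test_min_equal_max_equal_typed_is_noop(self):
        ds = random_dataset(5, 400, seed=4, missing_rate=0.0, mode="pseudo_haploid")
        out = deplete_indivs(ds, min_markers=400, max_markers=400, seed=1)
        np.testing.assert_array_equal(out.calls, ds.calls)

    def test_typed_counts_within_range_and_uniform(self):
        ds = random_dataset(100, 5000, seed=5, missing_rate=0.0, mode="pseudo_haploid")
        out = deplete_indivs(ds, min_markers=500, max_markers=5000, seed=7)
        counts = out.typed_counts()
        assert counts.min() >= 500 and counts.max() <= 5000
        ks = stats.kstest(counts, stats.uniform(loc=500, scale=4500).cdf)
        assert ks.pvalue > 0.01

    def test_sample_below_min_left_as_is(self, caplog):
        ds = random_dataset(2, 1000, seed=6, missing_rate=0.0, mode="pseudo_haploid")
        ds.calls[0, 100:] = MISSING  # typed at 100 < min
        with caplog.at_level("WARNING"):
            out = deplete_indivs(ds, min_markers=500, max_markers=1000, seed=2)
        assert out.typed_counts()[0] == 100
        assert "left unchanged" in caplog.text


class TestErrorChannels:
    def _ds(self):
        # four marker classes: C/T flip, A/C missing, C/G missing, A/T immune
        alleles = [("C", "T"), ("A", "C"), ("C", "G"), ("A", "T")] * 25
        calls = np.tile([HOM_MAJOR, HOM_MINOR], (3, 50)).astype(np.int8)
        return dataset_from_matrix(calls, mode="pseudo_haploid", alleles=alleles)

    def test_pmd_rules(self):
        ds = self._ds()
        cfg = ErrorConfig(channel="pmd", rate=1.0, seed=0)
        out, report = apply_errors(ds, cfg)
        flip = np.arange(0, 100, 4)  # C/T markers
        immune = np.arange(3, 100, 4)  # A/T markers
        other = np.setdiff1d(np.arange(100), np.concatenate([flip, immune]))
        # C/T markers: states flipped
        np.testing.assert_array_equal(
            out.calls[:, flip],
            np.where(ds.calls[:, flip] == HOM_MAJOR, HOM_MINOR, HOM_MAJOR),
        )
        # damage product matches neither allele -> missing
        assert np.all(out.calls[:, other] == MISSING)
        # A/T markers untouched (hit counted, no effect)
        np.testing.assert_array_equal(out.calls[:, immune], ds.calls[:, immune])
        assert report["n_hit"].tolist() == [100, 100, 100]

    def test_exogenous_sets_hom_major(self):
        ds = self._ds()
        out, _ = apply_errors(ds, ErrorConfig(channel="exogenous", rate=1.0, seed=0))
        assert np.all(out.calls == HOM_MAJOR)

    def test_endogenous_copies_contaminant_including_missing(self):
        ds = self._ds()
        ds.calls[2, 0] = MISSING  # contaminant missing at marker 0
        cfg = ErrorConfig(channel="endogenous", rate=1.0, contaminant="s3", seed=0)
        out, _ = apply_errors(ds, cfg)
        np.testing.assert_array_equal(out.calls[0], ds.calls[2])
        np.testing.assert_array_equal(out.calls[1], ds.calls[2])
        # the contaminant itself is never self-contaminated
        np.testing.assert_array_equal(out.calls[2], ds.calls[2])

    def test_endogenous_requires_contaminant(self):
        with pytest.raises(ValueError, match="contaminant"):
            ErrorConfig(channel="endogenous")

    def test_realized_counts_exact_and_mixed_rate(self):
        ds = random_dataset(40, 2000, seed=8, missing_rate=0.1, mode="pseudo_haploid")
        cfg = ErrorConfig(channel="mixed", max_rate=0.05, contaminant="s1", seed=3)
        out, report = apply_errors(ds, cfg)
        expected = np.round(report["rate"] * report["n_typed"]).astype(int)
        assert report["n_hit"].tolist() == expected.tolist()
        channel_sum = report[["n_pmd", "n_endogenous", "n_exogenous"]].sum(axis=1)
        contaminant_row = report["sample_id"] == "s1"
        assert (channel_sum[~contaminant_row] == report.loc[~contaminant_row, "n_hit"]).all()
        # dataset-mean realized rate ~ max_rate / 2
        assert report["rate"].mean() == pytest.approx(0.025, abs=0.01)

    def test_pmd_touches_only_markers_containing_c_or_g(self):
        alleles = [("A", "T")] * 200
        calls = np.tile([HOM_MAJOR, HOM_MINOR], (5, 100)).astype(np.int8)
        ds = dataset_from_matrix(calls, mode="pseudo_haploid", alleles=alleles)
        out, _ = apply_errors(ds, ErrorConfig(channel="pmd", rate=1.0, seed=1))
        np.testing.assert_array_equal(out.calls, ds.calls)

    def test_requires_pseudo_haploid(self):
        ds = random_dataset(3, 50, seed=9, mode="diploid", missing_rate=0.0)
        with pytest.raises(ValueError, match="pseudo-haploid"):
            apply_errors(ds, ErrorConfig(channel="pmd", rate=0.1))


class TestPedigree:
    def test_kinship_recursion_values(self):
        founders = ["g1", "g2", "u1", "u2", "u3", "m1"]
        matings = [
            ("s1", "g1", "g2"),
            ("s2", "g1", "g2"),
            ("c1", "s1", "u1"),
            ("c2", "s2", "u2"),
            ("d1", "c1", "u3"),
            ("h1", "g1", "m1"),
        ]
        ped = Pedigree(founders, matings)
        assert ped.kinship("g1", "s1") == 0.25  # parent-child
        assert ped.kinship("s1", "s2") == 0.25  # full sibs
        assert ped.kinship("s1", "h1") == 0.125  # half sibs
        assert ped.kinship("c1", "c2") == 0.0625  # first cousins
        assert ped.kinship("d1", "c2") == 0.03125  # cousins once removed
        assert ped.kinship("g1", "g1") == 0.5  # outbred self-kinship
        assert ped.kinship("g1", "g2") == 0.0

    def test_cyclic_or_out_of_order_pedigree_rejected(self):
        with pytest.raises(ValueError, match="before the child"):
            Pedigree(["a"], [("b", "a", "c"), ("c", "a", "b")])

    def test_generated_cohort_matches_truth_table(self):
        spec = PedigreeSpec(
            n_markers=500,
            populations={"P": 0.0},
            founders={"f1": "P", "f2": "P", "f3": "P"},
            matings=[("k1", "f1", "f2"), ("k2", "f1", "f3")],
            seed=4,
        )
        ds, truth = generate_pedigree_cohort(spec)
        assert ds.n_samples == 5 and ds.ploidy_mode == "diploid"
        pairs = {
            frozenset((t.sample1, t.sample2)): t.kinship
            for t in truth.itertuples(index=False)
        }
        assert pairs[frozenset(("f1", "k1"))] == 0.25
        assert pairs[frozenset(("k1", "k2"))] == 0.125  # half sibs
        assert frozenset(("f2", "f3")) not in pairs  # unrelated founders
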