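"""Core containers: marker panel, sample table and the genotype call matrix.

Genotype states are stored as a compact ``int8`` samples x markers matrix.
All operations in the package treat the minor-allele dosage convention:
``HOM_MAJOR`` carries 0 copies of the minor allele, ``HET`` one and
``HOM_MINOR`` two.  ``MISSING`` marks untyped sites and is the only state
excluded from overlap bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# genotype states (minor-allele dosage where defined)
HOM_MAJOR = np.int8(0)
HET = np.int8(1)
HOM_MINOR = np.int8(2)
MISSING = np.int8(3)

STATE_NAMES = {0: "HOM_MAJOR", 1: "HET", 2: "HOM_MINOR", 3: "MISSING"}

NUCLEOTIDES = ("A", "C", "G", "T")
AUTOSOMES = {str(i) for i in range(1, 23)}

#: numeric chromosome aliases as used by PLINK 1.9
_CHROM_ALIASES = {"23": "X", "24": "Y", "25": "XY", "26": "MT", "M": "MT"}


def normalize_chromosome(chrom) -> str:
    """Map PLINK numeric aliases (23-26) onto X/Y/XY/MT; pass others through."""
    c = str(chrom).strip()
    return _CHROM_ALIASES.get(c, c)


class FormatError(ValueError):
    """A genotype file violates its on-disk format contract."""


@dataclass
class MarkerTable:
    """The fixed biallelic marker panel used as the overlap denominator.

    ``table`` columns: marker_id, chromosome, position (1-based),
    allele_major, allele_minor.  Row count is the panel size M.
    """

    table: pd.DataFrame

    REQUIRED = ("marker_id", "chromosome", "position", "allele_major", "allele_minor")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        t = self.table
        for col in ("allele_major", "allele_minor"):
            bad = ~t[col].isin(NUCLEOTIDES)
            if bad.any():
                raise ValueError(
                    f"{col} contains non-ACGT values, e.g. {t.loc[bad, col].iloc[0]!r}"
                )
        if (t["allele_major"] == t["allele_minor"]).any():
            raise ValueError("monomorphic marker: allele_major == allele_minor")
        # positions strictly increasing within a chromosome
        for chrom, grp in t.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @classmethod
    def from_arrays(cls, marker_id, chromosome, position, allele_major, allele_minor):
        return cls(
            pd.DataFrame(
                {
                    "marker_id": np.asarray(marker_id, dtype=object),
                    "chromosome": [normalize_chromosome(c) for c in chromosome],
                    "position": np.asarray(position, dtype=np.int64),
                    "allele_major": np.asarray(allele_major, dtype=object),
                    "allele_minor": np.asarray(allele_minor, dtype=object),
                }
            )
        )

    @property
    def n(self) -> int:
        return len(self.table)

    def autosomal_mask(self) -> np.ndarray:
        return self.table["chromosome"].isin(AUTOSOMES).to_numpy()

    def subset(self, idx) -> "MarkerTable":
        return MarkerTable(self.table.iloc[np.asarray(idx)].reset_index(drop=True))


@dataclass
class SampleTable:
    """Sample metadata: unique id, population label and reference/test role."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if "sample_id" not in t.columns:
            raise ValueError("sample table requires a sample_id column")
        if "population_label" not in t.columns:
            t = t.assign(population_label="unknown")
        if "role" not in t.columns:
            t = t.assign(role="test")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_ids(cls, sample_ids, population_label="unknown", role="test"):
        n = len(sample_ids)
        pops = (
            [population_label] * n
            if isinstance(population_label, str)
            else list(population_label)
        )
        roles = [role] * n if isinstance(role, str) else list(role)
        return cls(
            pd.DataFrame(
                {"sample_id": list(sample_ids), "population_label": pops, "role": roles}
            )
        )

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list:
        return self.table["sample_id"].tolist()

    def subset(self, idx) -> "SampleTable":
        return SampleTable(self.table.iloc[np.asarray(idx)].reset_index(drop=True))


@dataclass
class GenotypeDataset:
    """Samples x markers genotype state matrix with its metadata.

    ``ploidy_mode`` is "diploid" or "pseudo_haploid"; pseudo-haploid data
    must not contain HET states (a single sampled allele is rendered as a
    homozygous call).
    """

    markers: MarkerTable
    samples: SampleTable
    calls: np.ndarray
    ploidy_mode: str = "diploid"

    def __post_init__(self) -> None:
        self.calls = np.ascontiguousarray(self.calls, dtype=np.int8)
        if self.calls.shape != (self.samples.n, self.markers.n):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{self.samples.n} samples x {self.markers.n} markers"
            )
        if self.ploidy_mode not in ("diploid", "pseudo_haploid"):
            raise ValueError(f"unknown ploidy_mode {self.ploidy_mode!r}")
        if self.ploidy_mode == "pseudo_haploid" and np.any(self.calls == HET):
            raise ValueError("pseudo_haploid dataset contains HET calls")
        if self.calls.size and (self.calls.min() < 0 or self.calls.max() > 3):
            raise ValueError("call matrix contains values outside the state codes 0..3")

    @property
    def n_samples(self) -> int:
        return self.samples.n

    @property
    def n_markers(self) -> int:
        return self.markers.n

    @property
    def sample_ids(self) -> list:
        return self.samples.ids

    def typed_mask(self) -> np.ndarray:
        """Boolean samples x markers matrix of genotyped (non-missing) sites."""
        return self.calls != MISSING

    def typed_counts(self) -> np.ndarray:
        return self.typed_mask().sum(axis=1)

    def dosage(self, dtype=np.float64) -> np.ndarray:
        """Minor-allele dosage in {0,1,2} with NaN at missing sites."""
        g = self.calls.astype(dtype)
        g[self.calls == MISSING] = np.nan
        return g

    def subset_samples(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx, dtype=np.int64)
        return GenotypeDataset(
            self.markers, self.samples.subset(idx), self.calls[idx], self.ploidy_mode
        )

    def subset_markers(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return GenotypeDataset(
            self.markers.subset(idx), self.samples, self.calls[:, idx], self.ploidy_mode
        )

    def restrict_autosomes(self) -> "GenotypeDataset":
        mask = self.markers.autosomal_mask()
        if mask.all():
            return self.copy()
        return self.subset_markers(np.flatnonzero(mask))

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            MarkerTable(self.markers.table.copy()),
            SampleTable(self.samples.table.copy()),
            self.calls.copy(),
            self.ploidy_mode,
        )

    def sample_index(self, sample_id) -> int:
        ids = self.samples.table["sample_id"]
        hit = ids[ids == sample_id].index
        if len(hit) == 0:
            raise KeyError(f"unknown sample {sample_id!r}")
        return int(hit[0])
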