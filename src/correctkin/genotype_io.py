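"""Bit-exact readers and writers for PLINK 1.9, EIGENSTRAT and
PACKEDANCESTRYMAP genotype filesets, plus import of haploid base-call tables.

Conventions
-----------
* PLINK bed: SNP-major, magic ``6C 1B 01``; two-bit codes per sample,
  little-endian within a byte (sample 0 in the low two bits).  Code meaning:
  ``00`` hom A1, ``01`` missing, ``10`` het, ``11`` hom A2.  On read we take
  A1 = minor, A2 = major (the PLINK 1.9 default); when a panel is supplied
  the bim alleles are matched against it and swapped markers are recoded,
  mismatching markers dropped with a counted warning (never strand-flipped).
* EIGENSTRAT text geno: one line per marker, digits ``0/1/2/9`` counting the
  allele written in .snp column 5 (this package writes the minor allele
  there), ``9`` = missing.
* PACKEDANCESTRYMAP: record length ``max(ceil(n/4), 48)``; ASCII header
  record ``GENO n_ind n_snp hash hash`` (hashes written as 0 and ignored on
  read); per-marker records pack two bits per sample, sample 0 in the MOST
  significant bits; values 0/1/2 count the column-5 allele, 3 = missing.
* Haploid base-call table: tab-separated with header ``chr pos major`` then
  one column per sample holding a single base or ``N``.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .datatypes import (
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
    FormatError,
    GenotypeDataset,
    MarkerTable,
    SampleTable,
    normalize_chromosome,
)

log = logging.getLogger(__name__)

_PLINK_MAGIC = bytes((0x6C, 0x1B))
_PLINK_SNP_MAJOR = 0x01

# PLINK two-bit code -> internal state, with A1 = minor / A2 = major
_PLINK_CODE_TO_STATE = np.array([HOM_MINOR, MISSING, HET, HOM_MAJOR], dtype=np.int8)
# internal state -> PLINK two-bit code
_STATE_TO_PLINK_CODE = np.array([3, 2, 0, 1], dtype=np.uint8)

# byte -> 4 states lookup table, built once
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _j in range(4):
        _BYTE_LUT[_b, _j] = _PLINK_CODE_TO_STATE[(_b >> (2 * _j)) & 3]


def _align_to_panel(ds: GenotypeDataset, panel: MarkerTable) -> GenotypeDataset:
    """Match dataset alleles against a fixed panel keyed by (chrom, pos).

    Markers whose alleles are swapped relative to the panel are recoded;
    markers whose alleles cannot be matched (or that are absent from the
    panel) are dropped with a counted warning.  No strand flipping, ever.
    """
    key = {}
    for i, row in enumerate(panel.table.itertuples(index=False)):
        key[(row.chromosome, row.position)] = (i, row.allele_major, row.allele_minor)
    keep, swap = [], []
    for i, row in enumerate(ds.markers.table.itertuples(index=False)):
        hit = key.get((row.chromosome, row.position))
        if hit is None:
            continue
        _, major, minor = hit
        if (row.allele_major, row.allele_minor) == (major, minor):
            keep.append((i, False))
        elif (row.allele_major, row.allele_minor) == (minor, major):
            keep.append((i, True))
            swap.append(i)
    dropped = ds.n_markers - len(keep)
    if dropped:
        log.warning("panel alignment dropped %d markers with mismatching alleles", dropped)
    idx = np.array([i for i, _ in keep], dtype=np.int64)
    calls = ds.calls[:, idx].copy()
    swapped = np.array([s for _, s in keep], dtype=bool)
    if swapped.any():
        sub = calls[:, swapped]
        flip = sub.copy()
        flip[sub == HOM_MAJOR] = HOM_MINOR
        flip[sub == HOM_MINOR] = HOM_MAJOR
        calls[:, swapped] = flip
    table = ds.markers.table.iloc[idx].copy()
    maj = table["allele_major"].to_numpy(object)
    mnr = table["allele_minor"].to_numpy(object)
    maj[swapped], mnr[swapped] = mnr[swapped].copy(), maj[swapped].copy()
    table["allele_major"], table["allele_minor"] = maj, mnr
    return GenotypeDataset(MarkerTable(table), ds.samples, calls, ds.ploidy_mode)


def read_plink(prefix: str, panel: MarkerTable | None = None) -> GenotypeDataset:
    """Read a PLINK 1.9 binary fileset ``prefix``.bed/.bim/.fam."""
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position", "a1", "a2"],
        dtype={"chromosome": str, "marker_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    n_samples, n_markers = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:2] != _PLINK_MAGIC:
        raise FormatError(
            f"not a PLINK bed file: magic bytes {raw[:2].hex()} != 6c1b"
        )
    if raw[2] != _PLINK_SNP_MAJOR:
        raise FormatError(
            f"unsupported bed mode byte 0x{raw[2]:02x}; only SNP-major (0x01) supported"
        )
    bpm = (n_samples + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != n_markers * bpm:
        raise FormatError(
            f"truncated bed: expected {n_markers * bpm} payload bytes, got {payload.size}"
        )
    states = _BYTE_LUT[payload.reshape(n_markers, bpm)].reshape(n_markers, bpm * 4)
    calls = np.ascontiguousarray(states[:, :n_samples].T)

    markers = MarkerTable.from_arrays(
        bim["marker_id"],
        bim["chromosome"].map(normalize_chromosome),
        bim["position"],
        allele_major=bim["a2"],
        allele_minor=bim["a1"],
    )
    samples = SampleTable(
        pd.DataFrame(
            {"sample_id": fam["iid"], "population_label": fam["fid"], "role": "test"}
        )
    )
    mode = "pseudo_haploid" if not np.any(calls == HET) else "diploid"
    ds = GenotypeDataset(markers, samples, calls, mode)
    if panel is not None:
        ds = _align_to_panel(ds, panel)
    return ds


def write_plink(ds: GenotypeDataset, prefix: str) -> None:
    """Write ``ds`` as a PLINK 1.9 binary fileset (SNP-major, pad bits zero)."""
    n, m = ds.n_samples, ds.n_markers
    bpm = (n + 3) // 4
    codes = _STATE_TO_PLINK_CODE[ds.calls.T]  # (m, n) uint8
    padded = np.zeros((m, bpm * 4), dtype=np.uint8)
    padded[:, :n] = codes
    padded = padded.reshape(m, bpm, 4)
    packed = (
        padded[:, :, 0]
        | (padded[:, :, 1] << 2)
        | (padded[:, :, 2] << 4)
        | (padded[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC + bytes([_PLINK_SNP_MAJOR]))
        fh.write(packed.tobytes())
    mt = ds.markers.table
    with open(prefix + ".bim", "w") as fh:
        for row in mt.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.marker_id}\t0\t{row.position}"
                f"\t{row.allele_minor}\t{row.allele_major}\n"
            )
    st = ds.samples.table
    with open(prefix + ".fam", "w") as fh:
        for row in st.itertuples(index=False):
            fh.write(f"{row.population_label}\t{row.sample_id}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------------
# EIGENSTRAT / PACKEDANCESTRYMAP

_DIGIT_TO_STATE = {ord("0"): HOM_MAJOR, ord("1"): HET, ord("2"): HOM_MINOR, ord("9"): MISSING}
_STATE_TO_DIGIT = np.array([ord("0"), ord("1"), ord("2"), ord("9")], dtype=np.uint8)
# packed values count the column-5 (minor) allele; 3 = missing
_PACKED_TO_STATE = np.array([HOM_MAJOR, HET, HOM_MINOR, MISSING], dtype=np.int8)
_STATE_TO_PACKED = np.array([0, 1, 2, 3], dtype=np.uint8)


def _read_snp_ind(prefix: str):
    snp = pd.read_csv(
        prefix + ".snp",
        sep=r"\s+",
        header=None,
        names=["marker_id", "chromosome", "gpos", "position", "a_minor", "a_major"],
        dtype={"marker_id": str, "chromosome": str, "a_minor": str, "a_major": str},
    )
    ind = pd.read_csv(
        prefix + ".ind",
        sep=r"\s+",
        header=None,
        names=["sample_id", "gender", "population_label"],
        dtype=str,
    )
    markers = MarkerTable.from_arrays(
        snp["marker_id"],
        snp["chromosome"].map(normalize_chromosome),
        snp["position"],
        allele_major=snp["a_major"],
        allele_minor=snp["a_minor"],
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": ind["sample_id"],
                "population_label": ind["population_label"],
                "role": "test",
            }
        )
    )
    return markers, samples


def read_eigenstrat(prefix: str, packed: bool = False) -> GenotypeDataset:
    """Read an EIGENSTRAT (text) or PACKEDANCESTRYMAP (binary) fileset."""
    markers, samples = _read_snp_ind(prefix)
    n, m = samples.n, markers.n
    if packed:
        with open(prefix + ".geno", "rb") as fh:
            raw = fh.read()
        if not raw.startswith(b"GENO"):
            raise FormatError("packed geno file does not start with GENO header")
        reclen = max((n + 3) // 4, 48)
        header = raw[:reclen].rstrip(b"\x00 ").split()
        if int(header[1]) != n or int(header[2]) != m:
            raise FormatError(
                f"packed geno header counts ({header[1]!r} ind, {header[2]!r} snp) "
                f"do not match .ind/.snp ({n}, {m})"
            )
        if len(raw) != reclen * (m + 1):
            raise FormatError("truncated packed geno file")
        body = np.frombuffer(raw, dtype=np.uint8, offset=reclen).reshape(m, reclen)
        shifts = np.array([6, 4, 2, 0], dtype=np.uint8)
        vals = (body[:, :, None] >> shifts[None, None, :]) & 3
        vals = vals.reshape(m, reclen * 4)[:, :n]
        calls = np.ascontiguousarray(_PACKED_TO_STATE[vals].T)
    else:
        with open(prefix + ".geno", "r") as fh:
            lines = fh.read().split()
        if len(lines) != m:
            raise FormatError(f"geno file has {len(lines)} lines, expected {m}")
        calls = np.empty((n, m), dtype=np.int8)
        for j, line in enumerate(lines):
            if len(line) != n:
                raise FormatError(
                    f"geno line {j + 1} has {len(line)} characters, expected {n}"
                )
            row = np.frombuffer(line.encode(), dtype=np.uint8)
            bad = ~np.isin(row, list(_DIGIT_TO_STATE))
            if bad.any():
                raise FormatError(
                    f"geno line {j + 1} contains invalid character "
                    f"{chr(row[bad][0])!r}"
                )
            states = np.empty(n, dtype=np.int8)
            for digit, state in _DIGIT_TO_STATE.items():
                states[row == digit] = state
            calls[:, j] = states
    mode = "pseudo_haploid" if not np.any(calls == HET) else "diploid"
    return GenotypeDataset(markers, samples, calls, mode)


def write_eigenstrat(ds: GenotypeDataset, prefix: str, packed: bool = False) -> None:
    n, m = ds.n_samples, ds.n_markers
    mt = ds.markers.table
    with open(prefix + ".snp", "w") as fh:
        for row in mt.itertuples(index=False):
            fh.write(
                f"{row.marker_id}\t{row.chromosome}\t0.0\t{row.position}"
                f"\t{row.allele_minor}\t{row.allele_major}\n"
            )
    with open(prefix + ".ind", "w") as fh:
        for row in ds.samples.table.itertuples(index=False):
            fh.write(f"{row.sample_id}\tU\t{row.population_label}\n")
    if packed:
        reclen = max((n + 3) // 4, 48)
        header = f"GENO {n} {m} 0 0".encode()
        vals = _STATE_TO_PACKED[ds.calls.T]  # (m, n)
        padded = np.full((m, reclen * 4), 3, dtype=np.uint8)
        padded[:, :n] = vals
        padded = padded.reshape(m, reclen, 4)
        body = (
            (padded[:, :, 0] << 6)
            | (padded[:, :, 1] << 4)
            | (padded[:, :, 2] << 2)
            | padded[:, :, 3]
        ).astype(np.uint8)
        with open(prefix + ".geno", "wb") as fh:
            fh.write(header + b"\x00" * (reclen - len(header)))
            fh.write(body.tobytes())
    else:
        digits = _STATE_TO_DIGIT[ds.calls.T]  # (m, n)
        with open(prefix + ".geno", "wb") as fh:
            newline = np.full((m, 1), ord("\n"), dtype=np.uint8)
            fh.write(np.hstack([digits, newline]).tobytes())


# ---------------------------------------------------------------------------
# haploid base-call import

def import_haplocall(path: str, panel: MarkerTable) -> GenotypeDataset:
    """Import a per-site haploid base-call table onto a fixed marker panel.

    Each called base equal to the panel's major allele becomes HOM_MAJOR,
    equal to the minor allele HOM_MINOR; ``N`` or any other base (a damage
    product or sequencing error is unrepresentable in a biallelic format)
    becomes MISSING, as do panel markers absent from the table.  Rows at
    positions outside the panel are skipped with a counted warning, as are
    rows whose stated major allele disagrees with the panel.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    lowered = {c.lower(): c for c in table.columns}
    for col in ("chr", "pos", "major"):
        if col not in lowered:
            raise FormatError(f"haploid call table missing required column {col!r}")
    sample_cols = [
        c for c in table.columns if c.lower() not in ("chr", "pos", "major")
    ]
    if not sample_cols:
        raise FormatError("haploid call table has no sample columns")
    try:
        positions = table[lowered["pos"]].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"malformed position column: {exc}") from None

    panel_index = {
        (row.chromosome, row.position): i
        for i, row in enumerate(panel.table.itertuples(index=False))
    }
    major = panel.table["allele_major"].to_numpy(object)
    minor = panel.table["allele_minor"].to_numpy(object)

    calls = np.full((len(sample_cols), panel.n), MISSING, dtype=np.int8)
    skipped = 0
    major_mismatch = 0
    chroms = table[lowered["chr"]].map(normalize_chromosome)
    stated_major = table[lowered["major"]]
    for r in range(len(table)):
        idx = panel_index.get((chroms.iloc[r], int(positions.iloc[r])))
        if idx is None:
            skipped += 1
            continue
        if stated_major.iloc[r] != major[idx]:
            major_mismatch += 1
        for s, col in enumerate(sample_cols):
            base = table[col].iloc[r]
            if base == major[idx]:
                calls[s, idx] = HOM_MAJOR
            elif base == minor[idx]:
                calls[s, idx] = HOM_MINOR
            # anything else (N, damage product, other base) stays MISSING
    if skipped:
        log.warning("import_haplocall skipped %d rows at positions outside the panel", skipped)
    if major_mismatch:
        log.warning(
            "import_haplocall: %d rows state a major allele different from the panel "
            "(panel definition used)",
            major_mismatch,
        )
    samples = SampleTable.from_ids(sample_cols)
    return GenotypeDataset(panel, samples, calls, "pseudo_haploid")


# ---------------------------------------------------------------------------
# format dispatch helpers used by the CLI

def read_dataset(prefix: str, fmt: str = "plink", panel: MarkerTable | None = None):
    if fmt == "plink":
        return read_plink(prefix, panel=panel)
    if fmt == "eigenstrat":
        return read_eigenstrat(prefix, packed=False)
    if fmt == "packedancestrymap":
        return read_eigenstrat(prefix, packed=True)
    raise ValueError(f"unknown format {fmt!r}")


def write_dataset(ds: GenotypeDataset, prefix: str, fmt: str = "plink"):
    if fmt == "plink":
        return write_plink(ds, prefix)
    if fmt == "eigenstrat":
        return write_eigenstrat(ds, prefix, packed=False)
    if fmt == "packedancestrymap":
        return write_eigenstrat(ds, prefix, packed=True)
    raise ValueError(f"unknown format {fmt!r}")
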