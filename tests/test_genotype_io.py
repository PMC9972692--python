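"""Format readers/writers: bit-exact round trips, hand-decoded oracles and
haploid base-call import."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from correctkin.datatypes import (
    HET,
    HOM_MAJOR,
    HOM_MINOR,
    MISSING,
    FormatError,
    MarkerTable,
)
from correctkin.genotype_io import (
    import_haplocall,
    read_eigenstrat,
    read_plink,
    write_eigenstrat,
    write_plink,
)

from conftest import dataset_from_matrix, random_dataset


def decode_bed_scalar(path, n_samples, n_markers):
    """Independent scalar PLINK bed decoder: plain python loops over bits."""
    with open(path, "rb") as fh:
        raw = fh.read()
    assert raw[0] == 0x6C and raw[1] == 0x1B and raw[2] == 0x01
    bpm = (n_samples + 3) // 4
    # plink code -> state with A1 = minor: 00 hom-minor, 01 missing, 10 het, 11 hom-major
    code_map = {0: HOM_MINOR, 1: MISSING, 2: HET, 3: HOM_MAJOR}
    calls = np.empty((n_samples, n_markers), dtype=np.int8)
    for j in range(n_markers):
        for i in range(n_samples):
            byte = raw[3 + j * bpm + i // 4]
            code = (byte >> (2 * (i % 4))) & 3
            calls[i, j] = code_map[code]
    return calls


def test_single_marker_byte_decodes_to_hom_major(tmp_path):
    """Payload byte 0b00000011 with A1=T, A2=C is a homozygous C/C call."""
    prefix = str(tmp_path / "one")
    with open(prefix + ".bed", "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01, 0b00000011]))
    with open(prefix + ".bim", "w") as fh:
        fh.write("1\trs1\t0\t100\tT\tC\n")
    with open(prefix + ".fam", "w") as fh:
        fh.write("FAM\tS1\t0\t0\t0\t-9\n")
    ds = read_plink(prefix)
    assert ds.calls[0, 0] == HOM_MAJOR
    assert ds.markers.table.loc[0, "allele_major"] == "C"
    assert ds.markers.table.loc[0, "allele_minor"] == "T"


def test_plink_roundtrip_is_byte_identical(tmp_path, tiny_diploid):
    p1, p2 = str(tmp_path / "a"), str(tmp_path / "b")
    write_plink(tiny_diploid, p1)
    ds = read_plink(p1)
    np.testing.assert_array_equal(ds.calls, tiny_diploid.calls)
    write_plink(ds, p2)
    for ext in (".bed", ".bim", ".fam"):
        assert open(p1 + ext, "rb").read() == open(p2 + ext, "rb").read()


def test_plink_decode_matches_scalar_oracle(tmp_path):
    ds = random_dataset(11, 23, seed=7)
    prefix = str(tmp_path / "rnd")
    write_plink(ds, prefix)
    expected = decode_bed_scalar(prefix + ".bed", 11, 23)
    got = read_plink(prefix)
    np.testing.assert_array_equal(got.calls, expected)
    np.testing.assert_array_equal(got.calls, ds.calls)


def test_plink_error_reporting(tmp_path):
    prefix = str(tmp_path / "bad")
    with open(prefix + ".bim", "w") as fh:
        fh.write("1\trs1\t0\t100\tT\tC\n")
    with open(prefix + ".fam", "w") as fh:
        fh.write("F\tS1\t0\t0\t0\t-9\n")
    with open(prefix + ".bed", "wb") as fh:
        fh.write(bytes([0x00, 0x1B, 0x01, 0x03]))
    with pytest.raises(FormatError, match="magic"):
        read_plink(prefix)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x00, 0x03]))
    with pytest.raises(FormatError, match="mode byte"):
        read_plink(prefix)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))  # no payload
    with pytest.raises(FormatError, match="truncated"):
        read_plink(prefix)


def test_empty_dataset_writes_valid_header(tmp_path):
    ds = random_dataset(1, 3, seed=0).subset_samples([])
    prefix = str(tmp_path / "empty")
    write_plink(ds, prefix)
    assert open(prefix + ".bed", "rb").read() == bytes([0x6C, 0x1B, 0x01])
    assert open(prefix + ".fam").read() == ""


def test_pseudo_haploid_bed_has_no_het_codes(tmp_path):
    ds = random_dataset(6, 9, seed=1, mode="pseudo_haploid")
    prefix = str(tmp_path / "hap")
    write_plink(ds, prefix)
    back = read_plink(prefix)
    assert back.ploidy_mode == "pseudo_haploid"
    assert not np.any(back.calls == HET)


def test_eigenstrat_digit_mapping(tmp_path):
    """Text geno line '0219': counted-allele dosages 0/2/1/9 map to states."""
    prefix = str(tmp_path / "es")
    with open(prefix + ".geno", "w") as fh:
        fh.write("0219\n")
    with open(prefix + ".snp", "w") as fh:
        fh.write("rs1\t1\t0.0\t100\tT\tC\n")
    with open(prefix + ".ind", "w") as fh:
        fh.write("s1\tU\tP\ns2\tU\tP\ns3\tU\tP\ns4\tU\tP\n")
    ds = read_eigenstrat(prefix)
    np.testing.assert_array_equal(
        ds.calls[:, 0], [HOM_MAJOR, HOM_MINOR, HET, MISSING]
    )


def test_eigenstrat_malformed_line_reports_position(tmp_path):
    prefix = str(tmp_path / "bad")
    with open(prefix + ".geno", "w") as fh:
        fh.write("021\n")  # 3 chars for 4 samples
    with open(prefix + ".snp", "w") as fh:
        fh.write("rs1\t1\t0.0\t100\tT\tC\n")
    with open(prefix + ".ind", "w") as fh:
        fh.write("s1\tU\tP\ns2\tU\tP\ns3\tU\tP\ns4\tU\tP\n")
    with pytest.raises(FormatError, match="line 1"):
        read_eigenstrat(prefix)


def test_text_and_packed_conversion_preserve_matrix(tmp_path, tiny_diploid):
    """5x7 fixture converted text->packed->text keeps the call matrix."""
    p_text, p_packed, p_back = (
        str(tmp_path / n) for n in ("text", "packed", "back")
    )
    write_eigenstrat(tiny_diploid, p_text, packed=False)
    ds1 = read_eigenstrat(p_text, packed=False)
    write_eigenstrat(ds1, p_packed, packed=True)
    ds2 = read_eigenstrat(p_packed, packed=True)
    write_eigenstrat(ds2, p_back, packed=False)
    ds3 = read_eigenstrat(p_back, packed=False)
    for ds in (ds1, ds2, ds3):
        np.testing.assert_array_equal(ds.calls, tiny_diploid.calls)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    n=st.integers(1, 6),
    m=st.integers(1, 8),
    seed=st.integers(0, 10_000),
)
def test_roundtrip_identity_all_formats(tmp_path_factory, n, m, seed):
    """Write->read reproduces the matrix exactly in every supported format,
    and the per-sample typed counts are invariant under conversion."""
    ds = random_dataset(n, m, seed=seed, missing_rate=0.3)
    tmp = tmp_path_factory.mktemp("rt")
    write_plink(ds, str(tmp / "p"))
    write_eigenstrat(ds, str(tmp / "e"), packed=False)
    write_eigenstrat(ds, str(tmp / "k"), packed=True)
    for back in (
        read_plink(str(tmp / "p")),
        read_eigenstrat(str(tmp / "e"), packed=False),
        read_eigenstrat(str(tmp / "k"), packed=True),
    ):
        np.testing.assert_array_equal(back.calls, ds.calls)
        np.testing.assert_array_equal(back.typed_counts(), ds.typed_counts())


def _toy_panel():
    return MarkerTable.from_arrays(
        marker_id=[f"m{i}" for i in range(1, 6)],
        chromosome=["1"] * 5,
        position=[100, 200, 300, 400, 500],
        allele_major=["C", "A", "G", "T", "C"],
        allele_minor=["T", "C", "A", "G", "G"],
    )


def test_import_haplocall_mapping_and_counts(tmp_path):
    """Bases matching an allele become homozygous calls; N, third alleles and
    off-panel rows become missing; per-sample typed counts match a hand count."""
    panel = _toy_panel()
    path = tmp_path / "calls.tsv"
    path.write_text(
        "chr\tpos\tmajor\ts1\ts2\ts3\n"
        "1\t100\tC\tC\tT\tG\n"  # s1 major, s2 minor, s3 unrepresentable
        "1\t200\tA\tA\tN\tC\n"  # s1 major, s2 N, s3 minor
        "1\t300\tG\tG\tG\tN\n"
        "1\t400\tT\tN\tG\tT\n"
        "1\t999\tC\tC\tC\tC\n"  # off-panel, skipped
    )
    ds = import_haplocall(str(path), panel)
    assert ds.ploidy_mode == "pseudo_haploid"
    assert ds.calls.shape == (3, 5)
    assert ds.calls[0, 0] == HOM_MAJOR
    assert ds.calls[1, 0] == HOM_MINOR
    assert ds.calls[2, 0] == MISSING  # G is neither C nor T
    # hand-counted typed markers: s1 -> 3 (m1,m2,m3), s2 -> 3 (m1,m3,m4),
    # s3 -> 2 (m2,m4)
    np.testing.assert_array_equal(ds.typed_counts(), [3, 3, 2])
    # marker 5 absent from the table -> missing everywhere
    assert np.all(ds.calls[:, 4] == MISSING)
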