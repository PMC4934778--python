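import numpy as np
import pytest

import msatland as m
from msatland.genotype_io import MISSING, GenotypeParseError

from conftest import matrix_from_indices

GENEPOP_SMALL = """title line
LocA
LocB, LocC
POP
ind1 , 101103 200200 150152
ind2 , 103103 200202 150150
POP
ind3 , 101101 202202 152152
ind4 , 101103 200202 000000
"""


def test_read_genepop_two_pops(tmp_path):
    p = tmp_path / "t.gen"
    p.write_text(GENEPOP_SMALL)
    gm = m.read_genepop(p)
    assert gm.n == 4 and gm.n_loci == 3
    assert gm.group_labels == ["POP1", "POP1", "POP2", "POP2"]
    assert tuple(gm.calls[0, 0]) == (101, 103)
    # "000000" decodes to missing
    assert tuple(gm.calls[3, 2]) == (MISSING, MISSING)


def test_read_genepop_two_digit_offset(tmp_path):
    p = tmp_path / "t.gen"
    p.write_text("t\nL1\nPOP\nind1 , 0101\n")
    gm = m.read_genepop(p, allele_offset=100)
    assert tuple(gm.calls[0, 0]) == (101, 101)


@pytest.mark.parametrize("body, msg", [
    ("t\nL1\nL2\nPOP\nind1 , 101101\n", "1 genotypes for 2"),
    ("t\nL1\nL2\nPOP\nind1 , 101101 0102\n", "mixed digit widths"),
    ("t\nL1\nPOP\nind1 , 1011x1\n", "bad genotype"),
    ("t\nL1\nind1 , 101101\n", "no POP"),
])
def test_read_genepop_malformed(tmp_path, body, msg):
    p = tmp_path / "bad.gen"
    p.write_text(body)
    with pytest.raises(GenotypeParseError, match=msg):
        m.read_genepop(p)


def test_genepop_round_trip(landscape, tmp_path):
    gm = landscape[0]
    m.write_genepop(gm, tmp_path / "rt.gen")
    back = m.read_genepop(tmp_path / "rt.gen")
    assert np.array_equal(back.calls, gm.calls)
    assert back.individual_ids == gm.individual_ids


def test_flat_table_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    calls = rng.integers(0, 8, size=(25, 6, 2))
    coords = rng.uniform(0, 100, size=(25, 2))
    gm = matrix_from_indices(calls, coords=coords)
    gm.calls[2, 1] = MISSING  # plant a missing genotype
    gm = m.GenotypeMatrix(gm.individual_ids, gm.loci, gm.calls,
                          coordinates=coords)
    layout = m.write_sample_table(gm, tmp_path / "s1.csv")
    back = m.read_sample_table(tmp_path / "s1.csv", layout)
    assert np.array_equal(back.calls, gm.calls)
    assert np.allclose(back.coordinates, gm.coordinates)
    assert back.individual_ids == gm.individual_ids


def test_sample_table_errors(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("id,A_a,A_b\nx,101,bad\n")
    layout = m.TableLayout(id_col="id", locus_columns={"A": ("A_a", "A_b")})
    with pytest.raises(GenotypeParseError, match="non-integer"):
        m.read_sample_table(p, layout)
    layout2 = m.TableLayout(id_col="id", locus_columns={"A": ("A_a", "Zz")})
    with pytest.raises(GenotypeParseError, match="missing mapped columns"):
        m.read_sample_table(p, layout2)


def test_sample_table_district_lookup(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("id,A_a,A_b,district\nx,101,103,north\ny,101,101,south\n")
    layout = m.TableLayout(
        id_col="id", locus_columns={"A": ("A_a", "A_b")},
        district_col="district",
        district_coordinates={"north": (10.0, 90.0), "south": (10.0, 5.0)})
    gm = m.read_sample_table(p, layout)
    assert np.allclose(gm.coordinates, [[10, 90], [10, 5]])


def test_spatial_ops_refuse_missing_coordinates(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("id,A_a,A_b,B_a,B_b\nx,101,103,140,142\ny,101,101,140,140\n")
    layout = m.TableLayout(id_col="id", locus_columns={
        "A": ("A_a", "A_b"), "B": ("B_a", "B_b")})
    gm = m.read_sample_table(p, layout)
    assert gm.coordinates is None
    with pytest.raises(ValueError, match="coordinates"):
        m.build_pairs(gm)


def test_exclude_loci(landscape):
    gm = landscape[0]
    out = m.exclude_loci(gm, ["L03"])
    assert out.n_loci == gm.n_loci - 1
    assert "L03" not in out.locus_names
    assert out.n == gm.n
    assert m.exclude_loci(gm, []).locus_names == gm.locus_names
    with pytest.raises(KeyError, match="FH2079"):
        m.exclude_loci(gm, ["FH2079"])
    with pytest.raises(ValueError, match="empty panel"):
        m.exclude_loci(gm, gm.locus_names)


def test_genotypes_stored_sorted_and_validated():
    calls = np.array([[[103, 101]], [[101, 101]]])
    gm = m.GenotypeMatrix(["a", "b"], [m.Locus("A")], calls)
    assert tuple(gm.calls[0, 0]) == (101, 103)
    with pytest.raises(GenotypeParseError, match="half-missing"):
        m.GenotypeMatrix(["a"], [m.Locus("A")],
                         np.array([[[101, MISSING]]]))
    with pytest.raises(GenotypeParseError, match="duplicate individual"):
        m.GenotypeMatrix(["a", "a"], [m.Locus("A")],
                         np.array([[[101, 101]], [[101, 101]]]))
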