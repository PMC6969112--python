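"""Inheritance-cube genetics: enumeration, transforms, cube construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tgdrive as tg
from tgdrive.genetics import (
    Genotype,
    make_genotype,
    genotype_from_str,
    genotype_to_str,
    wild_type_genotypes,
)

from _oracles import mendelian_offspring, oracle_offspring


def _g(code, arch):
    if isinstance(arch, str):
        arch = tg.architecture(arch)
    return genotype_from_str(code, arch)


def _cube_row_as_oracle_keys(cube, mother, father):
    """Convert a cube row to the oracle's {(sorted haps, sex): prob} keying."""
    dist = cube.offspring_distribution(mother, father)
    out = {}
    for g, p in zip(cube.offspring_index, dist):
        if p == 0.0:
            continue
        key = (tuple(sorted(g.haplotypes)), g.sex)
        out[key] = out.get(key, 0.0) + p
    return out


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "name,n_f,n_m",
    [
        ("full_GD", 10, 10),
        ("full_GDX", 10, 4),
        ("tGD_linked", 136, 136),
        ("tGDc", 136, 136),
        ("tGDX_linked", 136, 16),
        ("tGDXc", 136, 16),
    ],
)
def test_genotype_enumeration_counts(name, n_f, n_m):
    """4 states per locus: 10 unordered pairs (1 locus), 136 (2 loci);
    X-linked males are hemizygous over the plain haplotypes."""
    females, males = tg.enumerate_genotypes(tg.architecture(name))
    assert (len(females), len(males)) == (n_f, n_m)
    assert len(set(females)) == n_f and len(set(males)) == n_m


def test_enumeration_ordering_is_stable():
    f1, m1 = tg.enumerate_genotypes(tg.architecture("full_GD"))
    f2, m2 = tg.enumerate_genotypes(tg.architecture("full_GD"))
    assert f1 == f2 and m1 == m2
    assert genotype_to_str(f1[0]) == "W/W|F"  # W sorts first


def test_unknown_architecture_rejected():
    with pytest.raises(ValueError, match="unknown architecture"):
        tg.architecture("tGD_bogus")


# ---------------------------------------------------------------------------
# germline transform
# ---------------------------------------------------------------------------

def test_full_conversion_of_heterozygote(full_gd):
    g = _g("W/T|F", full_gd)
    dist = tg.germline_transform(g, tg.CubeParams(q=1, c=1), full_gd)
    assert dist == {_g("T/T|F", full_gd): 1.0}


def test_no_cleavage_is_identity(full_gd):
    params = tg.CubeParams(q=0.0)
    for code in ("W/T|F", "W/W|F", "T/R|F"):
        g = _g(code, full_gd)
        assert tg.germline_transform(g, params, full_gd) == {g: 1.0}


def test_transheterozygote_converts_both_loci():
    arch = tg.architecture("tGD_linked")
    g = _g("TA-WB/WA-TB|F", arch)
    dist = tg.germline_transform(g, tg.CubeParams(q=1, c=1), arch)
    assert dist == {_g("TA-TB/TA-TB|F", arch): 1.0}


def test_partial_conversion_branches(full_gd):
    g = _g("T/W|F", full_gd)
    dist = tg.germline_transform(g, tg.CubeParams(q=1, c=0.9, rho=1.0), full_gd)
    expected = {_g("T/T|F", full_gd): 0.9, _g("T/R|F", full_gd): 0.1}
    assert dist.keys() == expected.keys()
    for k in expected:
        assert dist[k] == pytest.approx(expected[k], abs=1e-15)


def test_hemizygous_male_cannot_convert(full_gdx):
    g = _g("T/Y|M", full_gdx)
    assert tg.germline_transform(g, tg.CubeParams(q=1, c=1), full_gdx) == {g: 1.0}


def test_machinery_requires_both_components():
    """A lone Cas9 (or lone gRNA) carrier never cleaves."""
    arch = tg.architecture("tGD_linked")
    params = tg.CubeParams(q=1, c=1)
    for code in ("TA-WB/WA-WB|F", "WA-TB/WA-WB|F"):
        g = _g(code, arch)
        assert tg.germline_transform(g, params, arch) == {g: 1.0}


def test_invalid_probability_rejected(full_gd):
    with pytest.raises(ValueError):
        tg.build_cube(full_gd, tg.CubeParams(q=1.2))
    with pytest.raises(ValueError):
        tg.build_cube(full_gd, tg.CubeParams(rho=-0.1))


# ---------------------------------------------------------------------------
# gametes
# ---------------------------------------------------------------------------

def test_gamete_heterozygote(full_gd):
    g = _g("W/T|F", full_gd)
    assert tg.gamete_distribution(g, full_gd) == {("T",): 0.5, ("W",): 0.5}


@pytest.mark.parametrize(
    "recomb,expected_n,expected_p",
    [(0.0, 2, 0.5), (0.5, 4, 0.25)],
)
def test_gamete_two_locus_recombination(recomb, expected_n, expected_p):
    arch = tg.architecture("tGD_linked", recomb_fraction=recomb)
    g = _g("TA-WB/WA-TB|F", arch)
    dist = tg.gamete_distribution(g, arch)
    assert len(dist) == expected_n
    assert all(p == pytest.approx(expected_p) for p in dist.values())


def test_gamete_hemizygous_male_transmits_y(full_gdx):
    g = _g("T/Y|M", full_gdx)
    dist = tg.gamete_distribution(g, full_gdx)
    assert dist == {("T",): 0.5, "Y": 0.5}


# ---------------------------------------------------------------------------
# deposition
# ---------------------------------------------------------------------------

def test_deposition_inactive_without_full_machinery():
    arch = tg.architecture("tGD_linked")
    zygote = _g("WA-WB/WA-WB|F", arch)
    mother = _g("TA-WB/WA-WB|F", arch)  # Cas9 but no gRNA
    params = tg.CubeParams(d=1.0)
    assert tg.deposition_transform(zygote, mother, params, arch) == {zygote: 1.0}


def test_deposition_cleaves_all_wild_type():
    arch = tg.architecture("tGD_linked")
    mother = _g("TA-TB/WA-WB|F", arch)
    zygote = _g("TA-TB/WA-WB|F", arch)
    dist = tg.deposition_transform(zygote, mother, tg.CubeParams(d=1.0, rho=1.0), arch)
    assert dist == {_g("TA-TB/RA-RB|F", arch): 1.0}


def test_deposition_identity_without_targets(full_gd):
    mother = _g("T/T|F", full_gd)
    zygote = _g("T/R|F", full_gd)
    params = tg.CubeParams(d=1.0)
    assert tg.deposition_transform(zygote, mother, params, full_gd) == {zygote: 1.0}


# ---------------------------------------------------------------------------
# cube construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", tg.ARCHITECTURE_NAMES)
def test_cube_rows_sum_to_one_and_nonnegative(name):
    cube = tg.build_cube(name, tg.CubeParams(q=0.8, c=0.7, d=0.3, rho=0.6))
    assert np.all(cube.table >= 0)
    np.testing.assert_allclose(cube.table.sum(axis=2), 1.0, atol=1e-12)


@pytest.mark.parametrize("name", tg.ARCHITECTURE_NAMES)
def test_autosomal_sex_marginal_is_half(name):
    cube = tg.build_cube(name, tg.CubeParams(q=0.9, c=0.8, d=0.2, rho=0.5))
    son_mass = cube.table[:, :, cube.n_f :].sum(axis=2)
    np.testing.assert_allclose(son_mass, 0.5, atol=1e-12)


@pytest.mark.parametrize("name", tg.ARCHITECTURE_NAMES)
def test_mendelian_reduction(name):
    """q = 0 and d = 0 collapses every architecture to plain Mendelian
    segregation, checked against direct combinatorics."""
    arch = tg.architecture(name)
    cube = tg.build_cube(arch, tg.CubeParams(q=0.0, c=0.9, d=0.0))
    rng = np.random.default_rng(7)
    mothers = rng.choice(len(cube.female_genotypes), size=6, replace=False)
    fathers = rng.choice(len(cube.male_genotypes), size=min(4, cube.n_m), replace=False)
    for i in mothers:
        for j in fathers:
            mother = cube.female_genotypes[i]
            father = cube.male_genotypes[j]
            expected = mendelian_offspring(
                mother.haplotypes, father.haplotypes, arch
            )
            got = _cube_row_as_oracle_keys(cube, mother, father)
            assert set(got) == {k for k, v in expected.items() if v > 0}
            for k, v in got.items():
                assert v == pytest.approx(expected[k], abs=1e-12)


def test_full_drive_all_offspring_carry_transgene(full_gd):
    cube = tg.build_cube(full_gd, tg.CubeParams(q=1, c=1, d=0))
    fwt, mwt = wild_type_genotypes(full_gd)
    assert tg.transmission_rate(cube, _g("T/W|F", full_gd), mwt, "T") == 1.0


@pytest.mark.parametrize("arch_name", ["full_GD", "tGDc"])
def test_cube_matches_symbolic_oracle(arch_name):
    """build_cube agrees with an independent recursive symbolic expansion on
    random parameter vectors, to 1e-12."""
    arch = tg.architecture(arch_name)
    rng = np.random.default_rng(99)
    n_loci = arch.n_loci
    for trial in range(20):
        q = rng.random((n_loci, 2))
        c = rng.random((n_loci, 2))
        d = rng.random(n_loci)
        rho = float(rng.random())
        cube = tg.build_cube(arch, tg.CubeParams(q=q, c=c, d=d, rho=rho))
        n_pairs = cube.n_f * cube.n_m
        # full cube for the small system; random parental pairs for the big one
        if n_pairs <= 100:
            pairs = list(itertools.product(range(cube.n_f), range(cube.n_m)))
        else:
            pairs = [
                (int(rng.integers(cube.n_f)), int(rng.integers(cube.n_m)))
                for _ in range(10)
            ]
        q_l = [tuple(q[l]) for l in range(n_loci)]
        c_l = [tuple(c[l]) for l in range(n_loci)]
        for i, j in pairs:
            mother = cube.female_genotypes[i]
            father = cube.male_genotypes[j]
            expected = oracle_offspring(
                mother.haplotypes, father.haplotypes, arch, q_l, c_l, list(d), rho
            )
            got = _cube_row_as_oracle_keys(cube, mother, father)
            for k in set(expected) | set(got):
                assert got.get(k, 0.0) == pytest.approx(
                    expected.get(k, 0.0), abs=1e-12
                )


# ---------------------------------------------------------------------------
# transmission rate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("qc", [0.0, 0.3, 0.92, 1.0])
def test_transmission_closed_form(full_gd, qc):
    """Single-locus heterozygous mother x wild father: (1 + q c) / 2."""
    cube = tg.build_cube(full_gd, tg.CubeParams(q=1.0, c=qc, d=0.0))
    _, mwt = wild_type_genotypes(full_gd)
    rate = tg.transmission_rate(cube, _g("T/W|F", full_gd), mwt, "T")
    assert rate == pytest.approx((1 + qc) / 2, abs=1e-12)


def test_transmission_monotone_in_conversion(full_gd):
    _, mwt = wild_type_genotypes(full_gd)
    rates = []
    for c in np.linspace(0, 1, 11):
        cube = tg.build_cube(full_gd, tg.CubeParams(q=0.8, c=c))
        rates.append(tg.transmission_rate(cube, _g("T/W|F", full_gd), mwt, "T"))
    assert np.all(np.diff(rates) >= -1e-15)


def test_x_linked_male_transmission(full_gdx):
    """A hemizygous drive male transmits to exactly half of all offspring and
    to every daughter."""
    cube = tg.build_cube(full_gdx, tg.CubeParams(q=1, c=1))
    fwt, _ = wild_type_genotypes(full_gdx)
    male = _g("T/Y|M", full_gdx)
    assert tg.transmission_rate(cube, fwt, male, "T") == 0.5
    assert tg.transmission_rate(cube, fwt, male, "T", restrict_sex="F") == 1.0
    assert tg.transmission_rate(cube, fwt, male, "T", restrict_sex="M") == 0.0


def test_allele_query_validation(mendelian_full_gd):
    fwt, mwt = wild_type_genotypes(mendelian_full_gd.architecture)
    with pytest.raises(ValueError, match="allele class"):
        tg.transmission_rate(mendelian_full_gd, fwt, mwt, "Z")
    with pytest.raises(ValueError, match="locus"):
        tg.transmission_rate(mendelian_full_gd, fwt, mwt, "T@B")


# ---------------------------------------------------------------------------
# allele-state conservation & string codes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", ["tGDc", "full_GDX"])
def test_allele_state_conservation(name):
    """Offspring genotypes always carry exactly ploidy alleles per locus,
    all from {W, T, R, B}."""
    cube = tg.build_cube(name, tg.CubeParams(q=0.7, c=0.6, d=0.4, rho=0.3))
    arch = cube.architecture
    for g in cube.offspring_index:
        ploidy = 1 if g.hemizygous else 2
        for locus in range(arch.n_loci):
            total = sum(g.count_state(s, locus) for s in ("W", "T", "R", "B"))
            assert total == ploidy


@st.composite
def genotypes(draw):
    name = draw(st.sampled_from(tg.ARCHITECTURE_NAMES))
    arch = tg.architecture(name)
    females, males = tg.enumerate_genotypes(arch)
    g = draw(st.sampled_from(females + males))
    return arch, g


@given(genotypes())
@settings(max_examples=60, derandomize=True)
def test_genotype_string_roundtrip(arch_g):
    arch, g = arch_g
    assert genotype_from_str(genotype_to_str(g), arch) == g


def test_cube_csv_roundtrip(tmp_path):
    from tgdrive.io import export_cube_csv, import_cube_csv

    cube = tg.build_cube("full_GDX", tg.CubeParams(q=0.85, c=0.77, d=0.21, rho=0.4))
    path = tmp_path / "cube.csv"
    export_cube_csv(cube, path)
    back = import_cube_csv(path)
    assert back.architecture.name == "full_GDX"
    np.testing.assert_array_equal(back.table, cube.table)
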