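"""Lipid shorthand parsing, formatting, and acyl-multiplicity accounting."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidtiers.nomenclature import (
    ESTER,
    ETHER,
    MOLECULAR_SPECIES,
    SUM_COMPOSITION,
    AcylChain,
    LipidNameError,
    SphingoidBase,
    acyl_multiplicity,
    default_registry,
    format_lipid_name,
    parse_lipid_name,
)


class TestParse:
    def test_molecular_species_with_header(self):
        sp = parse_lipid_name("DG 36:3(18:2_18:1)")
        assert sp.lipid_class.code == "DG"
        assert sp.level == MOLECULAR_SPECIES
        assert (sp.total_carbons, sp.total_double_bonds) == (36, 3)
        assert [(c.carbons, c.double_bonds) for c in sp.acyls] == [(18, 2), (18, 1)]

    def test_single_chain_free_acid(self):
        sp = parse_lipid_name("FA 16:0")
        assert sp.level == MOLECULAR_SPECIES
        assert len(sp.acyls) == 1
        assert sp.acyls[0] == AcylChain(16, 0)

    def test_ether_species_counts_prefixed_chain_in_totals(self):
        sp = parse_lipid_name("PE O-38:6(O-18:2_20:4)")
        assert sp.lipid_class.code == "PE"
        first, second = sp.acyls
        assert first.linkage == ETHER and (first.carbons, first.double_bonds) == (18, 2)
        assert second.linkage == ESTER and (second.carbons, second.double_bonds) == (20, 4)
        # header totals are the plain chain sums: 18+20 and 2+4
        assert (sp.total_carbons, sp.total_double_bonds) == (38, 6)

    def test_sum_composition(self):
        sp = parse_lipid_name("TG 52:3")
        assert sp.level == SUM_COMPOSITION
        assert (sp.total_carbons, sp.total_double_bonds) == (52, 3)
        assert sp.acyls == ()

    def test_sphingolipid_sum_composition_with_oxygenation(self):
        sp = parse_lipid_name("SM 33:1;O2")
        assert sp.level == SUM_COMPOSITION
        assert sp.total_oxygenation == 2

    def test_sphingoid_base_slash_dialect(self):
        sp = parse_lipid_name("Cer d18:1/17:0")
        assert sp.level == MOLECULAR_SPECIES
        base, nacyl = sp.acyls
        assert isinstance(base, SphingoidBase)
        assert (base.carbons, base.double_bonds) == (18, 1)
        assert nacyl == AcylChain(17, 0)
        assert sp.separator == "/"

    def test_whitespace_before_parenthesis_optional(self):
        with_space = parse_lipid_name("DG 36:3 (18:2_18:1)")
        without = parse_lipid_name("DG 36:3(18:2_18:1)")
        assert format_lipid_name(with_space) == format_lipid_name(without)

    def test_omega_suffix_on_free_acid(self):
        sp = parse_lipid_name("FA 18:3 n-3")
        assert sp.acyls[0].omega_class == "n-3"
        assert format_lipid_name(sp) == "FA 18:3 n-3"

    @pytest.mark.parametrize(
        "bad, match",
        [
            ("XX 34:1", "unrecognized class"),
            ("DG 36:4(18:2_18:1)", "inconsistent composition"),
            ("DG 37:3(18:2_18:1)", "inconsistent composition"),
            ("PC 34:1(16:0_18:1_18:1)", "inconsistent composition"),
            ("DG 36:3(18:2_", "parse error"),
            ("PC", "parse error"),
            ("", "parse error"),
            ("PC abc", "parse error"),
        ],
    )
    def test_errors(self, bad, match):
        with pytest.raises(LipidNameError, match=match):
            parse_lipid_name(bad)

    def test_error_carries_position(self):
        with pytest.raises(LipidNameError) as exc:
            parse_lipid_name("XX 34:1")
        assert exc.value.position == 0


class TestFormat:
    @pytest.mark.parametrize(
        "name",
        [
            "DG 36:3(18:2_18:1)",
            "FA 16:0",
            "PE O-38:6(O-18:2_20:4)",
            "TG 52:3",
            "SM 33:1;O2",
            "PI 36:3(18:2_18:1)",
            "Cer d18:1/17:0",
            "PE 17:0/17:0",
            "CL 14:0/14:0/14:0/14:0",
            "BMP 14:0/14:0",
            "PC O-34:1",
            "TG 54:3(18:1_18:1_18:1)",
            "LPC 17:0",
            "FA 20:4 n-6",
        ],
    )
    def test_round_trip(self, name):
        canonical = format_lipid_name(parse_lipid_name(name))
        assert format_lipid_name(parse_lipid_name(canonical)) == canonical

    def test_canonical_form_drops_space_before_parenthesis(self):
        sp = parse_lipid_name("DG 36:3 (18:2_18:1)")
        assert format_lipid_name(sp) == "DG 36:3(18:2_18:1)"

    def test_separator_preserved(self):
        assert "/" in format_lipid_name(parse_lipid_name("PE 17:0/17:0"))
        assert "_" in format_lipid_name(parse_lipid_name("DG 36:3(18:2_18:1)"))


class TestMultiplicity:
    def test_single_match(self):
        sp = parse_lipid_name("DG 36:3(18:2_18:1)")
        assert acyl_multiplicity(sp, AcylChain(18, 1)) == 1
        assert acyl_multiplicity(sp, AcylChain(18, 2)) == 1
        assert acyl_multiplicity(sp, AcylChain(16, 0)) == 0

    def test_homotriacyl_counts_three(self):
        sp = parse_lipid_name("TG 54:3(18:1_18:1_18:1)")
        assert acyl_multiplicity(sp, AcylChain(18, 1)) == 3

    def test_sphingolipid_n_acyl_not_saponifiable(self):
        assert acyl_multiplicity(parse_lipid_name("SM 33:1;O2"), AcylChain(15, 0)) == 0
        cer = parse_lipid_name("Cer d18:1/17:0")
        assert acyl_multiplicity(cer, AcylChain(17, 0)) == 0
        assert acyl_multiplicity(cer, AcylChain(17, 0), saponifiable_only=False) == 1

    def test_ether_chain_never_matches_ester_query(self):
        sp = parse_lipid_name("PE O-38:6(O-18:2_20:4)")
        assert acyl_multiplicity(sp, AcylChain(18, 2)) == 0
        # nor does an ether query count as saponifiable
        ether_query = AcylChain(18, 2, linkage=ETHER)
        assert acyl_multiplicity(sp, ether_query) == 0
        assert acyl_multiplicity(sp, ether_query, saponifiable_only=False) == 1

    def test_sum_composition_returns_zero_and_is_marked_unresolved(self):
        sp = parse_lipid_name("TG 52:3")
        assert not sp.resolved
        assert acyl_multiplicity(sp, AcylChain(18, 1)) == 0

    def test_multiplicities_sum_to_resolved_slots(self):
        sp = parse_lipid_name("TG 52:2(16:0_18:1_18:1)")
        distinct = {(c.carbons, c.double_bonds) for c in sp.fatty_acyls}
        total = sum(acyl_multiplicity(sp, AcylChain(*cd)) for cd in distinct)
        assert total == len(sp.fatty_acyls) == 3


# --- randomized round-trip ---------------------------------------------------

_REGISTRY = default_registry()
_GLYCERO = [c for c in _REGISTRY if c.saponifiable_slots == c.acyl_slots > 0]
_SPHINGO = [c for c in _REGISTRY if c.has_sphingoid_base]


@st.composite
def molecular_species_names(draw):
    cls = draw(st.sampled_from(_GLYCERO))
    n = cls.acyl_slots
    chains = []
    for i in range(n):
        carbons = draw(st.integers(2, 26))
        dbs = draw(st.integers(0, min(6, carbons - 1)))
        linkage = "ester"
        if i == 0 and n > 1 and draw(st.booleans()) and draw(st.booleans()):
            linkage = draw(st.sampled_from(["ether", "vinyl-ether"]))
        chains.append(AcylChain(carbons, dbs, linkage=linkage))
    sep = draw(st.sampled_from(["_", "/"])) if n > 1 else "_"
    chain_txt = sep.join(c.shorthand() for c in chains)
    if n == 1:
        return f"{cls.code} {chain_txt}"
    tot_c = sum(c.carbons for c in chains)
    tot_d = sum(c.double_bonds for c in chains)
    n_eth = sum(c.linkage == "ether" for c in chains)
    n_vin = sum(c.linkage == "vinyl-ether" for c in chains)
    prefix = "O-" if n_eth else ("P-" if n_vin else "")
    return f"{cls.code} {prefix}{tot_c}:{tot_d}({chain_txt})"


@st.composite
def sum_composition_names(draw):
    cls = draw(st.sampled_from(list(_REGISTRY)))
    carbons = draw(st.integers(20, 70))
    dbs = draw(st.integers(0, 12))
    oxy = draw(st.sampled_from(["", ";O", ";O2"])) if cls.has_sphingoid_base else ""
    return f"{cls.code} {carbons}:{dbs}{oxy}"


@st.composite
def sphingo_species_names(draw):
    cls = draw(st.sampled_from(_SPHINGO))
    base = SphingoidBase(
        draw(st.integers(14, 20)), draw(st.integers(0, 2)),
        hydroxyls=draw(st.sampled_from([2, 3])),
    )
    carbons = draw(st.integers(8, 26))
    nacyl = AcylChain(carbons, draw(st.integers(0, min(2, carbons - 1))))
    return f"{cls.code} {base.shorthand()}/{nacyl.shorthand()}"


@given(
    st.one_of(molecular_species_names(), sum_composition_names(), sphingo_species_names())
)
def test_round_trip_on_fuzzed_valid_names(name):
    """parse-format-parse is the identity on randomized valid species."""
    sp = parse_lipid_name(name)
    canonical = format_lipid_name(sp)
    sp2 = parse_lipid_name(canonical)
    assert format_lipid_name(sp2) == canonical
    assert sp2.level == sp.level
    assert (sp2.total_carbons, sp2.total_double_bonds) == (
        sp.total_carbons,
        sp.total_double_bonds,
    )
    assert sp2.acyls == sp.acyls


@given(st.one_of(molecular_species_names(), sphingo_species_names()))
def test_composition_conservation_on_fuzzed_parses(name):
    """Chain sums always equal header totals after parsing."""
    sp = parse_lipid_name(name)
    assert sum(c.carbons for c in sp.acyls) == sp.total_carbons
    assert sum(c.double_bonds for c in sp.acyls) == sp.total_double_bonds
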