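"""Enzyme rewrite rules: worked digestions, conservation, protection, inference."""

import pytest

from glycotrim import (
    GlycanComposition,
    NotASubstrate,
    apply_endoM,
    apply_gcs1,
    apply_gcs2,
    apply_mns45,
    apply_uggt,
    build_canonical,
    composition_of,
    infer_isomer,
    jbm_digest,
    parse_structure,
    reachable_structures,
)
from glycotrim.enzymes import A12_MANNOSIDASE, ER_RULESET, MNS45_B, MNS45_C, RULES


def comp(label: str) -> GlycanComposition:
    return GlycanComposition.from_label(label)


# -- glucosidases -----------------------------------------------------------


def test_gcs1_removes_outermost_alpha12_glucose():
    res = apply_gcs1(build_canonical("Glc3Man9GlcNAc2"))
    assert composition_of(res.product).label == "Hex11HexNAc2"
    assert res.released_composition == comp("Hex1")


@pytest.mark.parametrize("name", ["Man9GlcNAc2", "Glc1Man9GlcNAc2"])
def test_gcs1_requires_terminal_alpha12_glucose(name):
    with pytest.raises(NotASubstrate):
        apply_gcs1(build_canonical(name))


def test_gcs2_stepwise_deglucosylation():
    glc2 = build_canonical("Glc2Man9GlcNAc2")
    glc1 = apply_gcs2(glc2).product
    assert glc1 == build_canonical("Glc1Man9GlcNAc2")
    assert apply_gcs2(glc1).product == build_canonical("Man9GlcNAc2")


def test_gcs2_ignores_alpha12_capped_precursor():
    with pytest.raises(NotASubstrate):
        apply_gcs2(build_canonical("Glc3Man9GlcNAc2"))


# -- UGGT reglucosylation ---------------------------------------------------


def test_uggt_reglucosylates_glucose_free_glycan():
    res = apply_uggt(build_canonical("Man9GlcNAc2"))
    assert res.product == build_canonical("Glc1Man9GlcNAc2")
    assert res.released == ()


def test_uggt_rejects_already_glucosylated():
    with pytest.raises(NotASubstrate):
        apply_uggt(build_canonical("Glc1Man9GlcNAc2"))


def test_uggt_rejects_trimmed_a_branch():
    """EndoM removes the acceptor mannose, making reglucosylation impossible."""
    man8a = apply_endoM(build_canonical("Glc1Man9GlcNAc2")).product
    with pytest.raises(NotASubstrate):
        apply_uggt(man8a)


# -- MNS4/MNS5 --------------------------------------------------------------


def test_mns45_trims_c_branch_and_exposes_os9_signal():
    glc1man9 = build_canonical("Glc1Man9GlcNAc2")
    assert not glc1man9.os9_signal_exposed
    res = apply_mns45(glc1man9)
    assert composition_of(res.product).label == "Hex9HexNAc2"
    assert res.product == build_canonical("Glc1Man8GlcNAc2")
    assert res.product.os9_signal_exposed


def test_mns45_extended_also_trims_b_tip():
    res = apply_mns45(build_canonical("Glc1Man9GlcNAc2"), extended=True)
    assert composition_of(res.product).label == "Hex8HexNAc2"
    assert res.product == build_canonical("Glc1Man7GlcNAc2")


def test_mns45_requires_c_tip():
    with pytest.raises(NotASubstrate):
        apply_mns45(build_canonical("Glc1Man7GlcNAc2"))


# -- EndoM ------------------------------------------------------------------


def test_endoM_releases_glc_man_disaccharide():
    res = apply_endoM(build_canonical("Glc1Man9GlcNAc2"))
    assert composition_of(res.product).label == "Hex8HexNAc2"
    assert res.product == build_canonical("Man8GlcNAc2-A")
    assert res.released == (comp("Hex2"),)


def test_endoM_on_processed_monoglucosylated():
    res = apply_endoM(build_canonical("Glc1Man7GlcNAc2"))
    assert composition_of(res.product).label == "Hex6HexNAc2"


@pytest.mark.parametrize("name", ["Man9GlcNAc2", "Glc2Man9GlcNAc2", "Glc3Man9GlcNAc2"])
def test_endoM_requires_exactly_one_glucose(name):
    with pytest.raises(NotASubstrate):
        apply_endoM(build_canonical(name))


# -- jack bean alpha-mannosidase -------------------------------------------


@pytest.mark.parametrize("name,limit", [
    ("Man9GlcNAc2", "Hex1HexNAc2"),
    ("Man8GlcNAc2-A", "Hex1HexNAc2"),
    ("Glc1Man7GlcNAc2", "Hex5HexNAc2"),
    ("Glc1Man9GlcNAc2", "Hex5HexNAc2"),
])
def test_jbm_limit_digest(name, limit):
    assert composition_of(jbm_digest(build_canonical(name)).product).label == limit


def test_jbm_beta_mannose_is_not_a_substrate():
    core = parse_structure("Man(b1-4)GlcNAc(b1-4)GlcNAc")
    res = jbm_digest(core)
    assert res.product == core
    assert res.released == ()


def test_jbm_partial_digestion_series_is_monotone():
    """Iterations 0..limit walk the Hex10 -> Hex5 trimming series."""
    start = build_canonical("Glc1Man9GlcNAc2")
    seen = [composition_of(jbm_digest(start, iterations=k).product).hex
            for k in range(5)]
    assert seen == [10, 8, 6, 5, 5]


def test_jbm_limit_is_idempotent(registry):
    for tree in registry.values():
        once = jbm_digest(tree).product
        assert jbm_digest(once).product == once


def test_jbm_protects_glucose_capped_a_branch(registry):
    """Glc count and the A-arm mannoses under the cap survive any JBM digest."""
    for name, tree in registry.items():
        glc_before = len(tree.find(sugar="Glc"))
        if glc_before == 0:
            continue
        product = jbm_digest(tree).product
        assert len(product.find(sugar="Glc")) == glc_before
        capped_a = {r.residue_id for r in tree.find(sugar="Man", branch="A")
                    if not tree.is_terminal(r.residue_id)}
        surviving = {r.residue_id for r in product.find(sugar="Man", branch="A")}
        assert capped_a <= surviving, name


# -- conservation and monotonicity -----------------------------------------


def test_every_rule_conserves_residues(registry):
    for name, tree in registry.items():
        before = composition_of(tree)
        for rule in RULES.values():
            for res in rule.applications(tree):
                after = composition_of(res.product) + res.released_composition
                if rule.name == "UGGT":  # transferase: one hexose gained, none released
                    assert res.released == ()
                    assert after == before + comp("Hex1"), name
                else:
                    assert after == before, (name, rule.name)
        res = jbm_digest(tree)
        assert composition_of(res.product) + res.released_composition == before


def test_rule_changes_residue_count_by_declared_amount(registry):
    expected = {"GCSI": -1, "GCSII": -1, "MNS45-C": -1, "MNS45-B": -1,
                "generic-a12-mannosidase": -1, "EndoM": -2, "UGGT": +1}
    for tree in registry.values():
        for rname, delta in expected.items():
            for res in RULES[rname].applications(tree):
                assert len(res.product) - len(tree) == delta


def test_no_degradative_rule_increases_hexoses(registry):
    degradative = [r for n, r in RULES.items() if n != "UGGT"]
    for tree in reachable_structures(registry["Glc3Man9GlcNAc2"], degradative):
        hex_before = composition_of(tree).hex
        for rule in degradative:
            for res in rule.applications(tree):
                assert composition_of(res.product).hex < hex_before


def test_os9_signal_iff_c_stem_terminal(registry):
    for tree in reachable_structures(registry["Glc3Man9GlcNAc2"], ER_RULESET):
        stems = tree.find(sugar="Man", linkage="a1-6", branch="C")
        exposed = any(tree.is_terminal(r.residue_id) for r in stems)
        assert tree.os9_signal_exposed == exposed


# -- reachable-structure enumeration ----------------------------------------


def brute_force_reachable(start, rules, max_steps):
    """Independent recursive enumeration used as the search oracle.

    Tracks the best (shortest) depth per state and re-expands on improvement,
    so the depth limit cannot hide states first met via a longer path."""
    best = {start.canonical(): 0}
    trees = {start.canonical(): start}

    def walk(tree, depth):
        if depth == max_steps:
            return
        for rule in rules:
            for res in rule.applications(tree):
                key = res.product.canonical()
                if key not in best or best[key] > depth + 1:
                    best[key] = depth + 1
                    trees[key] = res.product
                    walk(res.product, depth + 1)

    walk(start, 0)
    return set(trees.values())


def test_zero_steps_returns_start(registry):
    start = registry["Man9GlcNAc2"]
    assert reachable_structures(start, ER_RULESET, max_steps=0) == {start}


def test_man9_has_three_man8_isomers():
    start = build_canonical("Man9GlcNAc2")
    step1 = reachable_structures(start, [A12_MANNOSIDASE], max_steps=1)
    man8 = {t for t in step1 if composition_of(t).label == "Hex8HexNAc2"}
    assert len(man8) == 3
    assert man8 == {build_canonical(f"Man8GlcNAc2-{b}") for b in "ABC"}


def test_deglucosylation_chain():
    chain = reachable_structures(build_canonical("Glc3Man9GlcNAc2"),
                                 ["GCSI", "GCSII"])
    assert chain == {build_canonical(n) for n in [
        "Glc3Man9GlcNAc2", "Glc2Man9GlcNAc2", "Glc1Man9GlcNAc2", "Man9GlcNAc2"]}


@pytest.mark.parametrize("start", ["Glc3Man9GlcNAc2", "Glc1Man9GlcNAc2",
                                   "Man9GlcNAc2", "Glc1Man7GlcNAc2"])
@pytest.mark.parametrize("max_steps", [1, 2, 4])
def test_bfs_matches_brute_force(start, max_steps):
    rules = [RULES[r] for r in ER_RULESET]
    tree = build_canonical(start)
    assert (reachable_structures(tree, rules, max_steps)
            == brute_force_reachable(tree, rules, max_steps))


# -- isobaric-structure inference -------------------------------------------


def test_infer_hex8_with_protected_jbm_limit_is_monoglucosylated():
    result = infer_isomer(comp("Hex8HexNAc2"), jbm_limit=comp("Hex5HexNAc2"))
    assert [c.name for c in result] == ["Glc1Man7GlcNAc2"]


def test_infer_hex8_fully_trimmed_gives_man8_isomers():
    result = infer_isomer(comp("Hex8HexNAc2"), jbm_limit=comp("Hex1HexNAc2"))
    assert [c.name for c in result] == [
        "Man8GlcNAc2-A", "Man8GlcNAc2-B", "Man8GlcNAc2-C"]
    assert all(c.glc_count == 0 for c in result)


def test_infer_hex9_without_evidence_is_ambiguous():
    names = [c.name for c in infer_isomer(comp("Hex9HexNAc2"))]
    assert "Glc1Man8GlcNAc2" in names
    assert "Man9GlcNAc2" in names
    # glucosylated candidates rank first
    assert names[0].startswith("Glc1")


def test_infer_orders_glucosylated_first_when_off_standard():
    result = infer_isomer(comp("Hex9HexNAc2"), elutes_off_standard=True)
    assert result.candidates[0].glc_count == 1


def test_infer_contradictory_evidence_yields_diagnostic():
    result = infer_isomer(comp("Hex8HexNAc2"), jbm_limit=comp("Hex9HexNAc2"))
    assert len(result) == 0
    assert "no ER-reachable structure" in result.diagnostic


def test_infer_requires_two_hexnac():
    with pytest.raises(ValueError):
        infer_isomer(GlycanComposition(hexnac=1, hex=3))


def test_infer_endoM_evidence_separates_glucosylated():
    sensitive = infer_isomer(comp("Hex8HexNAc2"), endoM_sensitive=True)
    assert [c.name for c in sensitive] == ["Glc1Man7GlcNAc2"]
    resistant = infer_isomer(comp("Hex8HexNAc2"), endoM_sensitive=False)
    assert all(c.glc_count == 0 for c in resistant)
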