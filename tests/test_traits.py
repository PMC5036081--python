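import numpy as np
import pytest
from scipy.optimize import minimize

import cladistron as cl
from cladistron.data import measurement_table, ratio_claims
from cladistron.traits import (
    MeasurementTable,
    TraitTable,
    body_size_proxy,
    map_continuous,
    map_discrete,
    ratio,
    verify_ratios,
)


# ---------------------------------------------------------------------------
# ratios


def test_printed_skull_ratios():
    assert ratio(119, 290) == 0.41  # temporal fossa / neurocranium
    assert ratio(330, 798) == 0.41  # symphysis / rostrum length
    assert ratio(5, 5) == 1.00


def test_ratio_digits_respected():
    assert ratio(1, 3, digits=4) == 0.3333
    assert ratio(2, 3, digits=1) == 0.7


def test_ratio_half_up_rounding():
    assert ratio(1, 8) == 0.13  # 0.125 rounds up, not to even
    assert ratio(135, 1000, digits=2) == 0.14


def test_ratio_inverse_consistency():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a, b = rng.uniform(10, 500, size=2)
        prod = ratio(a, b, digits=6) * ratio(b, a, digits=6)
        assert prod == pytest.approx(1.0, abs=1e-4)


def test_ratio_rejects_bad_denominator():
    with pytest.raises(ValueError):
        ratio(1, 0)
    with pytest.raises(ValueError):
        ratio(1, -2)


def test_verify_ratios_surfaces_discrepancy():
    report = verify_ratios(ratio_claims())
    disagreements = [r["name"] for r in report if not r["agrees"]]
    # the left/right premaxillary-fossa ratio is printed 0.82 but its own
    # table values give 44/53 = 0.83; everything else reproduces exactly
    assert disagreements == ["MUSM 2538 left / right premaxillary sac fossa"]


# ---------------------------------------------------------------------------
# measurement tables


def test_measurement_flags_parsed():
    t1 = measurement_table("table1_musm2538")
    m = t1.data["MUSM 2538"]
    assert m["Condylobasal length"].value == 468
    assert m["Condylobasal length"].preserved
    assert m["Postorbital width of skull"].estimated
    assert not m["Length of neurocranium"].preserved


def test_comparison_table_ratios_reproduce():
    t3 = measurement_table("table3_comparison")
    a = t3.get("MUSM 1609", "Length of rostrum (A)")
    b = t3.get("MUSM 1609", "Width of rostrum base at level antorbital notch (B)")
    c = t3.get("MUSM 1609", "Width of rostrum at midlength (C)")
    d = t3.get("MUSM 1609", "Length of symphyseal portion of mandible (D)")
    assert (ratio(b, a), ratio(c, a), ratio(d, a)) == (0.27, 0.07, 0.41)
    a2 = t3.get("MUSM 1037", "Length of rostrum (A)")
    assert (
        ratio(t3.get("MUSM 1037", "Width of rostrum base at level antorbital notch (B)"), a2),
        ratio(t3.get("MUSM 1037", "Width of rostrum at midlength (C)"), a2),
        ratio(t3.get("MUSM 1037", "Length of symphyseal portion of mandible (D)"), a2),
    ) == (0.26, 0.08, 0.46)


def test_measurement_csv_rejects_nonpositive(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("measurement,X\nLength,0\n")
    with pytest.raises(ValueError, match="non-positive"):
        MeasurementTable.from_csv(p)


# ---------------------------------------------------------------------------
# discrete mapping


def test_uniform_trait_maps_with_zero_changes():
    t = cl.Tree.from_newick("((A,B),(C,D));")
    rec = map_discrete(t, {"A": "B", "B": "B", "C": "B", "D": "B"})
    assert rec.n_changes == 0
    for n in rec.tree.postorder():
        assert n.annotations["state_set"] == frozenset(["B"])


def test_two_clade_trait_needs_one_change():
    t = cl.Tree.from_newick("((A,B),(C,D));")
    rec = map_discrete(t, {"A": "A", "B": "A", "C": "B", "D": "B"})
    assert rec.n_changes == 1


def test_missing_tip_warns_and_uses_full_alphabet():
    t = cl.Tree.from_newick("((A,B),(C,D));")
    with pytest.warns(UserWarning, match="unknown"):
        rec = map_discrete(t, {"A": "A", "B": "A", "C": "B"})
    assert rec.n_changes == 1


@pytest.mark.parametrize("seed", range(10))
def test_change_count_equals_fitch_steps(seed):
    rng = np.random.default_rng(seed)
    t = cl.simulate_tree(8, seed=seed)
    labels = t.leaf_labels()
    states = "WXYZ"
    trait = {lab: states[int(rng.integers(3))] for lab in labels}
    rec = map_discrete(t, trait)
    column = {lab: {states.index(v)} for lab, v in trait.items()}
    assert rec.n_changes == cl.fitch_steps(t, column)


# ---------------------------------------------------------------------------
# continuous mapping


def test_constant_trait_reconstructs_constant():
    t = cl.Tree.from_newick("((A,B),(C,D));")
    rec = map_continuous(t, {lab: 2.5 for lab in "ABCD"})
    for n in rec.tree.postorder():
        assert n.annotations["value"] == pytest.approx(2.5)
    assert rec.sum_squared_change == pytest.approx(0.0)


def test_star_center_is_the_mean():
    t = cl.Tree.from_newick("(A,B,C);")
    rec = map_continuous(t, {"A": 0.0, "B": 0.0, "C": 3.0})
    assert rec.tree.root.annotations["value"] == pytest.approx(1.0)


def test_root_value_within_tip_span():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        t = cl.simulate_tree(9, seed=seed)
        vals = {lab: float(rng.uniform(0, 10)) for lab in t.leaf_labels()}
        rec = map_continuous(t, vals)
        lo, hi = min(vals.values()), max(vals.values())
        for n in rec.tree.postorder():
            assert lo - 1e-9 <= n.annotations["value"] <= hi + 1e-9


@pytest.mark.parametrize("seed", range(8))
def test_squared_change_matches_black_box_optimizer(seed):
    rng = np.random.default_rng(seed)
    t = cl.simulate_tree(int(rng.integers(5, 9)), seed=seed)
    vals = {lab: float(rng.normal(0, 5)) for lab in t.leaf_labels()}
    rec = map_continuous(t, vals)

    internal = [n for n in rec.tree.postorder() if not n.is_leaf]

    def objective(x):
        assign = {id(n): xi for n, xi in zip(internal, x)}
        total = 0.0
        for n in rec.tree.postorder():
            if n.parent is None:
                continue
            a = assign.get(id(n), vals.get(n.label))
            b = assign.get(id(n.parent))
            total += (a - b) ** 2
        return total

    x0 = np.zeros(len(internal))
    opt = minimize(objective, x0, method="BFGS", tol=1e-12)
    assert rec.sum_squared_change == pytest.approx(opt.fun, abs=1e-8)


def test_pruned_and_underdetermined_cases():
    t = cl.Tree.from_newick("((A,B),(C,D));")
    with pytest.warns(UserWarning, match="pruned"):
        rec = map_continuous(t, {"A": 1.0, "B": 3.0, "C": 2.0})
    assert rec.tree.root.annotations["value"] <= 3.0
    with pytest.raises(ValueError, match="two valued tips"):
        map_continuous(t, {"A": 1.0})


def test_polytomy_handled_in_continuous_map():
    t = cl.Tree.from_newick("((A,B,C),(D,E));")
    rec = map_continuous(t, {"A": 1.0, "B": 1.0, "C": 1.0, "D": 5.0, "E": 5.0})
    vals = [n.annotations["value"] for n in rec.tree.postorder() if not n.is_leaf]
    assert all(1.0 <= v <= 5.0 for v in vals)


# ---------------------------------------------------------------------------
# body-size proxy


def test_body_size_proxy_identity_maps_postorbital_width():
    t1 = measurement_table("table1_musm2538")
    t2 = measurement_table("table2_musm2548")
    assert body_size_proxy(t1).values["MUSM 2538"] == 350
    assert body_size_proxy(t2).values["MUSM 2548"] == 240


def test_body_size_proxy_linear_transform():
    t1 = measurement_table("table1_musm2538")
    ident = body_size_proxy(t1, regression=(0.0, 1.0))
    assert ident.values == body_size_proxy(t1).values
    scaled = body_size_proxy(t1, regression=(100.0, 2.0))
    assert scaled.values["MUSM 2538"] == 100 + 2 * 350


def test_body_size_proxy_warns_on_missing_measurement():
    t3 = measurement_table("table3_comparison")  # has no postorbital widths
    with pytest.warns(UserWarning, match="excluded"):
        out = body_size_proxy(t3)
    assert out.values == {}


def test_trait_table_csv(tmp_path):
    p = tmp_path / "trait.csv"
    p.write_text("taxon,area\nA,B\nB,?\nC,D\n")
    t = TraitTable.from_csv(p)
    assert t.values == {"A": "B", "C": "D"}
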