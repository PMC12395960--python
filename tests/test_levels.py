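import numpy as np
import pandas as pd
import pytest

from spinefe import levels


def make_records(strengths: dict, fractured: set = frozenset(), sex: dict = None):
    """strengths: {subject: {level: value}} -> record list."""
    rows = []
    for subj, per_level in strengths.items():
        for lv, val in per_level.items():
            rows.append({
                "subject": subj, "level": lv, "value": val,
                "fractured": (subj, lv) in fractured,
                "sex": (sex or {}).get(subj, "F"),
            })
    return pd.DataFrame(rows)


def test_adjacent_ratio_graph_constructed_ratios():
    recs = make_records({
        "S0": {"T12": 0.95, "L1": 1.00, "L2": 1.10},
        "S1": {"T12": 1.90, "L1": 2.00, "L2": 2.20},
    })
    g = levels.adjacent_ratio_graph(recs)
    assert np.isclose(g.edge_mean_ratio[("T12", "L1")], 0.95)
    assert np.isclose(g.edge_mean_ratio[("L1", "L2")], 1 / 1.10)
    assert np.isclose(g.cumulative_pct_vs_ref["L2"], 10.0)
    assert np.isclose(g.cumulative_pct_vs_ref["T12"], -5.0)
    assert g.cumulative_pct_vs_ref["L1"] == 0.0
    assert g.edge_n[("L1", "L2")] == 2
    assert g.unreachable == []


def test_graph_chain_accumulation_multiplies():
    recs = make_records({"S0": {"T11": 0.81, "T12": 0.90, "L1": 1.00,
                                "L2": 1.10, "L3": 1.21}})
    g = levels.adjacent_ratio_graph(recs)
    assert np.isclose(g.cumulative_pct_vs_ref["L3"], 21.0)
    assert np.isclose(g.cumulative_pct_vs_ref["T11"], -19.0)


def test_graph_geometric_mean_option():
    recs = make_records({
        "S0": {"L1": 1.0, "L2": 2.0},
        "S1": {"L1": 1.0, "L2": 0.5},
    })
    g = levels.adjacent_ratio_graph(recs, mean="geometric")
    # ratios upper/lower are 0.5 and 2.0 -> geometric mean exactly 1
    assert np.isclose(g.edge_mean_ratio[("L1", "L2")], 1.0)
    ga = levels.adjacent_ratio_graph(recs, mean="arithmetic")
    assert np.isclose(ga.edge_mean_ratio[("L1", "L2")], 1.25)


def test_fracture_exclusion_per_pair():
    recs = make_records(
        {
            "S0": {"L1": 1.0, "L2": 1.5},
            "S1": {"L1": 1.0, "L2": 9.0},   # fractured L2: pair dropped
            "S2": {"L1": 1.0, "L2": 1.5},
        },
        fractured={("S1", "L2")},
    )
    g = levels.adjacent_ratio_graph(recs)
    assert g.edge_n[("L1", "L2")] == 2
    assert np.isclose(g.edge_mean_ratio[("L1", "L2")], 1 / 1.5)
    # brute-force count of usable pairs
    usable = sum(1 for s in ("S0", "S1", "S2")
                 if not (s, "L1") in {("S1", "L2")} and not (s, "L2") in {("S1", "L2")})
    assert g.edge_n[("L1", "L2")] == usable


def test_graph_unreachable_levels():
    recs = make_records({"S0": {"T11": 0.9, "L1": 1.0, "L2": 1.1}})  # T12 missing
    g = levels.adjacent_ratio_graph(recs)
    assert "T11" in g.unreachable
    assert "T11" not in g.cumulative_pct_vs_ref
    assert np.isclose(g.cumulative_pct_vs_ref["L2"], 10.0)


def test_graph_requires_reference():
    recs = make_records({"S0": {"L2": 1.1, "L3": 1.2}})
    with pytest.raises(ValueError):
        levels.adjacent_ratio_graph(recs, reference="L1")


def test_population_relative_to_l1():
    recs = make_records({
        "S0": {"L1": 1.0, "L2": 1.2},
        "S1": {"L1": 3.0, "L2": 3.2},
    })
    pop = levels.population_relative_to_l1(recs)
    assert np.isclose(pop["L1"], 0.0)
    assert np.isclose(pop["L2"], (2.2 / 2.0 - 1) * 100)


def test_graph_and_population_coincide_for_identical_subjects():
    per = {"T12": 0.9, "L1": 1.0, "L2": 1.1}
    recs = make_records({f"S{i}": dict(per) for i in range(4)})
    g = levels.adjacent_ratio_graph(recs)
    pop = levels.population_relative_to_l1(recs)
    for lv in per:
        assert np.isclose(g.cumulative_pct_vs_ref[lv], pop[lv])


def test_stratify_by_sex():
    recs = make_records(
        {
            "S0": {"L1": 1.0, "L2": 1.2},
            "S1": {"L1": 1.0, "L2": 1.2},
            "S2": {"L1": 2.0, "L2": 2.2},
        },
        sex={"S0": "M", "S1": "M", "S2": "F"},
    )
    out = levels.stratify(recs, by="sex")
    assert set(out) == {"M", "F"}
    assert out["M"]["n_subjects"] == 2
    assert out["F"]["small_sample"]
    assert np.isclose(out["M"]["graph"].cumulative_pct_vs_ref["L2"], 20.0)
    assert np.isclose(out["F"]["graph"].cumulative_pct_vs_ref["L2"], 10.0)


def test_stratify_exclude_fracture_subjects():
    recs = make_records(
        {
            "S0": {"L1": 1.0, "L2": 1.2},
            "S1": {"L1": 1.0, "L2": 5.0},
        },
        fractured={("S1", "L1")},
    )
    out = levels.stratify(recs, by="sex", exclude_fractures=True)
    # S1 removed entirely (any fractured vertebra excludes the subject)
    assert out["F"]["n_subjects"] == 1
    assert np.isclose(out["F"]["graph"].cumulative_pct_vs_ref["L2"], 20.0)


def test_fracture_group_test_separated_groups():
    frac = [1.0, 1.1, 1.2]
    ctrl = [2.0, 2.1, 2.2, 2.3]
    res = levels.fracture_group_test(frac, ctrl)
    assert res["p"] < 0.05
    assert not res["tie_warning"]
    # reversed direction is not significant for "less"
    res_rev = levels.fracture_group_test(ctrl, frac)
    assert res_rev["p"] > 0.9


def test_fracture_group_test_all_tied_warns():
    with pytest.warns(UserWarning):
        res = levels.fracture_group_test([1.0, 1.0], [1.0, 1.0])
    assert res["p"] == 0.5
    assert res["tie_warning"]


def test_fracture_group_test_exact_vs_asymptotic():
    rng = np.random.default_rng(2)
    frac = rng.normal(1.0, 0.1, 12)
    ctrl = rng.normal(1.5, 0.1, 12)
    res = levels.fracture_group_test(frac, ctrl)  # n > 8 -> asymptotic
    assert res["p"] < 1e-3


def test_records_frame_validation():
    with pytest.raises(ValueError):
        levels.records_frame(pd.DataFrame({"subject": ["a"], "level": ["L1"]}))
    with pytest.raises(ValueError):
        levels.adjacent_ratio_graph(make_records({"S0": {"L1": 1.0}}).assign(level="X9"))
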