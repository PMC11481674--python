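import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cortiquant import (
    aggregate,
    condition_summary,
    levene,
    one_way_anova,
    run_battery,
    shapiro_wilk,
    significance_stars,
    tukey_hsd,
)

# Frozen independent-reference values (R 4.3.3: shapiro.test, TukeyHSD(aov),
# one-way ANOVA on absolute deviations for Levene), computed before the
# implementation was written.
SHAPIRO_SAMPLE = [0.1, 0.5, 0.9, 1.3, 1.7]
SHAPIRO_W_REF = 0.98676216
SHAPIRO_P_REF = 0.96717394
TUKEY_GROUPS = ([1.1, 2.3, 1.9], [3.2, 2.8, 4.1, 3.6], [5.0, 4.4, 5.9])
TUKEY_P_REF = {("group1", "group2"): 0.0262895,
               ("group1", "group3"): 0.0008893,
               ("group2", "group3"): 0.0251264}
LEVENE_GROUPS = ([1, 2, 3], [10, 20, 30])
LEVENE_STAT_REF = 3.2079208


def _measurements(ratios, condition="wt", replicate=1):
    return pd.DataFrame({
        "field_id": "f0", "cell_label": np.arange(len(ratios)) + 1,
        "channel": "GFP", "condition": condition, "replicate": replicate,
        "pm_cytosol_ratio": ratios, "area_um2": 20.0, "degenerate": False,
    })


def test_aggregate_single_replicate_mean():
    reps = aggregate(_measurements([1.0, 2.0, 3.0]))
    assert len(reps) == 1
    assert reps["mean_ratio"][0] == pytest.approx(2.0)
    assert reps["n_cells"][0] == 3


def test_aggregate_hierarchy_replicates_not_cells():
    df = pd.concat([_measurements([1.0, 1.0], replicate=1),
                    _measurements([3.0], replicate=2)], ignore_index=True)
    reps = aggregate(df)
    cond = condition_summary(reps)
    assert cond["mean_ratio"][0] == pytest.approx(2.0)   # not 5/3


def test_aggregate_excludes_infinite_sentinels(caplog):
    ratios = [1.0] * 9 + [float("inf")]
    reps = aggregate(_measurements(ratios))
    assert reps["n_cells"][0] == 9


def test_aggregate_via_annotations():
    df = _measurements([1.0, 2.0]).drop(columns=["condition", "replicate"])
    ann = pd.DataFrame({"field_id": ["f0"], "condition": ["wt"],
                        "replicate": [1]})
    reps = aggregate(df, ann)
    assert reps["condition"][0] == "wt"


def test_shapiro_matches_reference():
    rep = shapiro_wilk(SHAPIRO_SAMPLE)
    assert rep.statistic == pytest.approx(SHAPIRO_W_REF, abs=1e-3)
    assert rep.pvalue == pytest.approx(SHAPIRO_P_REF, abs=1e-3)


@pytest.mark.parametrize("n", [2, 51])
def test_shapiro_sample_size_contract(n):
    with pytest.raises(ValueError):
        shapiro_wilk(np.linspace(0, 1, n))


def test_shapiro_accepts_normal_samples():
    rng = np.random.default_rng(0)
    hits = sum(shapiro_wilk(rng.normal(size=30)).pvalue > 0.05
               for _ in range(100))
    assert hits >= 90


def test_levene_identical_groups():
    rep = levene([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert rep.statistic == pytest.approx(0.0, abs=1e-12)
    assert rep.pvalue == pytest.approx(1.0)


def test_levene_matches_anova_on_absolute_deviations():
    rep = levene(LEVENE_GROUPS, center="mean")
    assert rep.statistic == pytest.approx(LEVENE_STAT_REF, abs=1e-6)
    # brute-force oracle: one-way ANOVA on |x - group mean|
    devs = [np.abs(np.asarray(g, float) - np.mean(g)) for g in LEVENE_GROUPS]
    f_ref = sps.f_oneway(*devs)
    assert rep.statistic == pytest.approx(f_ref.statistic, abs=1e-10)
    assert rep.pvalue == pytest.approx(f_ref.pvalue, abs=1e-10)


def test_levene_undersized_groups_raise():
    with pytest.raises(ValueError):
        levene([[1.0], [2.0, 3.0]])


def test_anova_hand_computed_example():
    # SSB = 16 (df 2), SSW = 1.5 (df 3) -> F = 8 / 0.5 = 16
    rep = one_way_anova([[1, 2], [3, 4], [5, 6]])
    assert rep.statistic == pytest.approx(16.0, abs=1e-10)
    assert rep.df == (2, 3)


def test_anova_identical_constant_groups():
    rep = one_way_anova([[5.0, 5.0], [5.0, 5.0]])
    assert rep.statistic == 0.0 and rep.pvalue == 1.0


def test_anova_affine_invariance():
    groups = [[1.2, 2.1, 1.7], [2.9, 3.3, 3.1], [4.0, 4.4, 3.9]]
    f0 = one_way_anova(groups).statistic
    shifted = [[x + 10 for x in g] for g in groups]
    scaled = [[x * 3.5 for x in g] for g in groups]
    assert one_way_anova(shifted).statistic == pytest.approx(f0, rel=1e-9)
    assert one_way_anova(scaled).statistic == pytest.approx(f0, rel=1e-9)


def test_tukey_two_groups_reduces_to_pooled_t():
    rng = np.random.default_rng(3)
    for _ in range(50):
        g1 = rng.normal(size=rng.integers(3, 8))
        g2 = rng.normal(loc=rng.uniform(0, 2), size=rng.integers(3, 8))
        rep = tukey_hsd([g1, g2])
        t = sps.ttest_ind(g1, g2, equal_var=True)
        assert rep.pairwise["p_adj"][0] == pytest.approx(t.pvalue, abs=1e-6)


def test_tukey_matches_reference():
    rep = tukey_hsd(list(TUKEY_GROUPS))
    for _, row in rep.pairwise.iterrows():
        ref = TUKEY_P_REF[(row["group_a"], row["group_b"])]
        assert row["p_adj"] == pytest.approx(ref, abs=1e-3)


def test_tukey_identical_groups_p_one():
    rep = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert rep.pairwise["p_adj"][0] == pytest.approx(1.0)


@pytest.mark.parametrize("p,label", [
    (0.00005, "****"), (0.0001, "****"), (0.0005, "***"), (0.001, "***"),
    (0.005, "**"), (0.01, "**"), (0.03, "*"), (0.05, "*"), (0.2, "ns"),
])
def test_significance_star_mapping(p, label):
    assert significance_stars(p) == label


@pytest.mark.parametrize("p", [-0.1, 1.5])
def test_stars_reject_invalid_p(p):
    with pytest.raises(ValueError):
        significance_stars(p)


def test_battery_reports_gate_warnings():
    rng = np.random.default_rng(5)
    rows = []
    for cond, scale in (("a", 0.1), ("b", 5.0), ("c", 0.1)):
        for rep in range(1, 6):
            rows.append({"condition": cond, "replicate": rep,
                         "mean_ratio": rng.normal(1.0, scale)})
    reps = pd.DataFrame(rows)
    reports = run_battery(reps)
    anova = next(r for r in reports if r.name == "one-way-anova")
    assert any("variance" in n for n in anova.notes)
    tukey = next(r for r in reports if r.name == "tukey-hsd")
    assert len(tukey.pairwise) == 3
    assert set(tukey.pairwise["stars"]).issubset(
        {"ns", "*", "**", "***", "****"})
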