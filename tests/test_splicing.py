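"""PSI computation, pooled binomial LRT, event filters, quartile groups."""
import numpy as np
import pandas as pd
import pytest

from oracles import binomial_lrt_loglik
from ubnexus.splicing import (SpliceEventTable, compute_psi, event_test,
                              filter_events, quartile_groups)


def test_psi_direct_values():
    assert compute_psi(30, 10) == pytest.approx(0.75)
    assert compute_psi(0, 10) == 0.0
    assert np.isnan(compute_psi(0, 0))


def test_length_normalized_psi_matches_oracle(rng):
    for _ in range(20):
        i, s = rng.integers(0, 100, 2)
        li, ls = rng.integers(1, 5, 2)
        if i + s == 0:
            continue
        got = compute_psi(i, s, li, ls, length_normalize=True)
        ref = (i / li) / ((i / li) + (s / ls))
        assert got == pytest.approx(ref, rel=1e-12)


def test_psi_swap_complement(rng):
    i = rng.integers(1, 50, 10)
    s = rng.integers(1, 50, 10)
    assert np.allclose(compute_psi(i, s), 1.0 - compute_psi(s, i))


def _toy_table(inc, skp, samples):
    n = len(inc)
    ids = pd.Index([f"E{k}" for k in range(n)], name="event_id")
    meta = pd.DataFrame({"gene": ["G"] * n,
                         "event_type": ["SE"] * n,
                         "len_inclusion": 2, "len_skipping": 1}, index=ids)
    return SpliceEventTable(
        meta=meta,
        inclusion=pd.DataFrame(inc, index=ids, columns=samples),
        skipping=pd.DataFrame(skp, index=ids, columns=samples),
    )


def test_identical_pooled_proportions_give_null():
    t = _toy_table([[30, 30, 30, 30]], [[10, 10, 10, 10]], list("abcd"))
    res = event_test(t, ["a", "b"], ["c", "d"])
    assert res["lr_statistic"].iloc[0] == 0.0
    assert res["p_value"].iloc[0] == 1.0
    assert res["delta_psi"].iloc[0] == 0.0


def test_lrt_matches_likelihood_oracle(rng):
    for _ in range(25):
        i1, i2 = rng.integers(1, 200, 2)
        s1, s2 = rng.integers(1, 200, 2)
        t2 = _toy_table([[i1, i2]], [[s1, s2]], ["x", "y"])
        res = event_test(t2, ["x"], ["y"])
        g_ref, p_ref = binomial_lrt_loglik(i1, s1, i2, s2)
        assert res["lr_statistic"].iloc[0] == pytest.approx(g_ref, rel=1e-9, abs=1e-9)
        assert res["p_value"].iloc[0] == pytest.approx(p_ref, rel=1e-9, abs=1e-12)


def test_group_swap_negates_dpsi_keeps_p(rng):
    inc = rng.integers(0, 60, size=(10, 6))
    skp = rng.integers(1, 60, size=(10, 6))
    samples = [f"s{i}" for i in range(6)]
    t = _toy_table(inc, skp, samples)
    fwd = event_test(t, samples[:3], samples[3:])
    rev = event_test(t, samples[3:], samples[:3])
    assert np.allclose(fwd["delta_psi"], -rev["delta_psi"], equal_nan=True)
    assert np.allclose(fwd["p_value"], rev["p_value"], equal_nan=True)


def test_no_coverage_group_skipped():
    t = _toy_table([[0, 5]], [[0, 5]], ["x", "y"])
    res = event_test(t, ["x"], ["y"])
    assert res["skipped_reason"].iloc[0] == "no_coverage_in_group"
    assert not res["passes"].iloc[0]


def test_filter_counts_and_monotonicity(rng):
    inc = rng.integers(0, 200, size=(10, 8))
    skp = rng.integers(1, 200, size=(10, 8))
    samples = [f"s{i}" for i in range(8)]
    t = _toy_table(inc, skp, samples)
    t.meta["event_type"] = (["SE"] * 4 + ["RI"] * 3 + ["A3SS"] * 3)
    res = event_test(t, samples[:4], samples[4:])
    ids, counts = filter_events(res)
    # manual tally
    manual = res[res["passes"]].groupby("event_type").size()
    for etype in counts.index:
        assert counts[etype] == manual.get(etype, 0)
    # tightening the dPSI cutoff never adds events
    tighter = event_test(t, samples[:4], samples[4:], dpsi_cutoff=0.4)
    ids_t, _ = filter_events(tighter)
    assert ids_t <= ids


def test_empty_results_give_zero_counts():
    res = pd.DataFrame({"event_type": pd.Series(dtype=str),
                        "passes": pd.Series(dtype=bool)})
    ids, counts = filter_events(res)
    assert ids == set()
    assert counts.sum() == 0


def test_quartile_groups_eight_distinct_values():
    expr = pd.Series(np.arange(1.0, 9.0), index=[f"s{i}" for i in range(8)])
    g = quartile_groups(expr)
    assert set(g.high) == {"s6", "s7"}
    assert set(g.low) == {"s0", "s1"}
    assert not g.degenerate
    assert set(g.high).isdisjoint(g.low)


def test_quartile_groups_all_equal_degenerate():
    g = quartile_groups(pd.Series([5.0] * 8, index=[f"s{i}" for i in range(8)]))
    assert g.degenerate and g.high == [] and g.low == []


def test_quartile_groups_match_percentile_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(4, 40))
        expr = pd.Series(rng.normal(0, 1, n), index=[f"s{i}" for i in range(n)])
        g = quartile_groups(expr)
        q25, q75 = np.percentile(expr.to_numpy(), [25, 75])
        assert set(g.high) == set(expr.index[expr >= q75])
        assert set(g.low) == set(expr.index[expr <= q25])
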