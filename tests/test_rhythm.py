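"""Rhythm detection: the three ensemble members, Fisher integration, the
replicate-trial scheme and phase windows."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apaclock import rhythm, sim
from conftest import nb_draws

T6 = np.array([2, 6, 10, 14, 18, 22], dtype=float)


def cosine(t, mesor=5.0, amp=2.0, phase=18.0, period=24.0):
    return mesor + amp * np.cos(2 * np.pi * (t - phase) / period)


# ---------------------------------------------------------------------------
# Lomb-Scargle


def test_ls_pure_cosine_is_significant():
    assert rhythm.lomb_scargle_p(T6, cosine(T6), 24.0) < 1e-3


def test_ls_constant_series():
    assert rhythm.lomb_scargle_p(T6, np.full(6, 3.0), 24.0) == 1.0


def test_ls_null_p_is_uniform():
    rng = np.random.default_rng(0)
    ps = [rhythm.lomb_scargle_p(T6, rng.normal(size=6), 24.0)
          for _ in range(3000)]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# JTK


def test_jtk_perfect_concordance_minimal_p():
    p, phase = rhythm.jtk_p(T6, cosine(T6), 24.0)
    assert phase == 18.0
    # minimal attainable two-sided p for n=6 with 6 references tested
    assert p == pytest.approx(6 * 2 / 720)


def test_jtk_antiphase_symmetry():
    p1, ph1 = rhythm.jtk_p(T6, cosine(T6), 24.0)
    p2, ph2 = rhythm.jtk_p(T6, -cosine(T6), 24.0)
    assert p1 == p2
    assert (ph2 - ph1) % 24 == pytest.approx(12.0)


def test_jtk_all_tied_series():
    assert rhythm.jtk_p(T6, np.full(6, 7.0), 24.0) == (1.0, 0.0)


def naive_jtk_oracle(t, y, period):
    """Independent JTK p: naive pair counting over every permutation."""
    from itertools import permutations

    offsets = np.unique(t % period)
    n = len(y)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def tau_b(a, b):
        s = t_a = t_b = 0
        for i, j in pairs:
            da, db = np.sign(a[j] - a[i]), np.sign(b[j] - b[i])
            s += da * db
            t_a += da == 0
            t_b += db == 0
        denom = np.sqrt((len(pairs) - t_a) * (len(pairs) - t_b))
        return s / denom if denom > 0 else 0.0

    refs = [np.cos(2 * np.pi * (t - off) / period) for off in offsets]
    taus = [tau_b(y, r) for r in refs]
    k = int(np.argmax(np.abs(taus)))
    best = abs(taus[k])
    null = [abs(tau_b(np.array(pm), refs[k])) for pm in permutations(y)]
    p_one = np.mean(np.asarray(null) >= best - 1e-9)
    return min(1.0, p_one * len(offsets))


def test_jtk_matches_permutation_oracle():
    rng = np.random.default_rng(5)
    for _ in range(15):
        y = rng.normal(size=6)
        p_impl, _ = rhythm.jtk_p(T6, y, 24.0)
        assert p_impl == pytest.approx(naive_jtk_oracle(T6, y, 24.0), abs=1e-12)


# ---------------------------------------------------------------------------
# Cosinor


def test_harmonic_exact_recovery():
    p, phase, amp = rhythm.harmonic_p(T6, cosine(T6), 24.0)
    assert p < 1e-10
    assert phase == pytest.approx(18.0, abs=1e-8)
    assert amp == pytest.approx(2.0, abs=1e-8)


def test_harmonic_constant_series():
    p, _, amp = rhythm.harmonic_p(T6, np.full(6, 4.0), 24.0)
    assert p == 1.0 and amp == 0.0


def test_harmonic_null_type_I():
    rng = np.random.default_rng(1)
    ps = np.array(
        [rhythm.harmonic_p(T6, rng.normal(size=6), 24.0)[0]
         for _ in range(4000)]
    )
    assert abs((ps < 0.05).mean() - 0.05) < 0.015


@pytest.mark.parametrize("method", ["lomb_scargle", "jtk", "harmonic"])
def test_affine_invariance(method):
    rng = np.random.default_rng(3)
    y = rng.normal(size=6)
    f = {
        "lomb_scargle": lambda v: rhythm.lomb_scargle_p(T6, v, 24.0),
        "jtk": lambda v: rhythm.jtk_p(T6, v, 24.0)[0],
        "harmonic": lambda v: rhythm.harmonic_p(T6, v, 24.0)[0],
    }[method]
    assert f(3.5 * y + 10.0) == pytest.approx(f(y), rel=1e-9)


# ---------------------------------------------------------------------------
# Integration


def test_meta_single_method_identity():
    p, _, _ = rhythm.integrate_meta({"m": 0.037}, {}, {}, 24.0)
    assert p == pytest.approx(0.037)


def test_meta_fisher_example():
    p, _, _ = rhythm.integrate_meta({"a": 0.5, "b": 0.5}, {}, {}, 24.0)
    # -2(ln .5 + ln .5) = 2.7726 against chi2(4)
    assert p == pytest.approx(0.5966, abs=1e-3)


def test_meta_identical_phases_survive_weighting():
    p, phase, _ = rhythm.integrate_meta(
        {"a": 0.01, "b": 0.2}, {"a": 7.25, "b": 7.25}, {}, 24.0
    )
    assert phase == pytest.approx(7.25)


def test_meta_zero_p_is_floored():
    p, _, _ = rhythm.integrate_meta({"a": 0.0, "b": 0.5}, {}, {}, 24.0)
    assert 0.0 <= p < 1e-100


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(8)
    p = rng.uniform(size=200)
    ours = rhythm.bh_adjust(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, theirs)


# ---------------------------------------------------------------------------
# Trials


@pytest.fixture(scope="module")
def trial_run(design_table):
    rng = np.random.default_rng(17)
    zts = {r.sample_id: r.zt_h for r in design_table.rows}
    cols = design_table.sample_ids
    rows, kinds, phases = [], [], []
    for _ in range(12):  # strong planted rhythms
        ph = float(rng.uniform(0, 24))
        mu = np.array([800 * (1 + 0.9 * np.cos(2 * np.pi * (zts[c] - ph) / 24))
                       for c in cols])
        rows.append([nb_draws(rng, m, 1, 0.02)[0] for m in mu])
        kinds.append("rhythmic")
        phases.append(ph)
    for _ in range(40):
        rows.append(list(nb_draws(rng, np.full(len(cols), 500.0), len(cols), 0.05)))
        kinds.append("null")
        phases.append(np.nan)
    mat = pd.DataFrame(rows, columns=cols)
    cfg = rhythm.RhythmConfig(period_h=24.0)
    res = rhythm.run_trials(mat, design_table, cfg)
    return res, kinds, phases, cfg


def test_run_trials_significance_is_all_trials(trial_run):
    res, *_ , cfg = trial_run
    pcols = [c for c in res.columns if c.startswith("trial") and c.endswith("_p")]
    want = (res[pcols] < cfg.alpha).all(axis=1)
    assert (res["significant"] == want).all()
    assert res["median_p"].equals(res[pcols].median(axis=1))


def test_run_trials_recovers_strong_rhythms(trial_run):
    res, kinds, phases, _ = trial_run
    planted = [k == "rhythmic" for k in kinds]
    sig = res["significant"].to_numpy()
    assert sig[np.array(planted)].mean() >= 0.8
    # circular phase error among recovered planted sites
    est = res["avg_phase_h"].to_numpy()
    err = []
    for i, (is_p, ph) in enumerate(zip(planted, phases)):
        if is_p and sig[i]:
            err.append((est[i] - ph + 12) % 24 - 12)
    assert np.sqrt(np.mean(np.square(err))) <= 1.5


def test_run_trials_null_rarely_called(trial_run):
    res, kinds, *_ = trial_run
    nulls = np.array([k == "null" for k in kinds])
    assert res["significant"].to_numpy()[nulls].mean() <= 0.05


def test_rotation_assignments_are_disjoint(design_table):
    cfg = rhythm.RhythmConfig()
    a = rhythm.trial_assignments(design_table, cfg)
    assert len(a) == 5
    flat = [s for trial in a for s in trial]
    assert len(set(flat)) == 30  # every diurnal library used exactly once


def test_random_assignment_seeded(design_table):
    cfg = rhythm.RhythmConfig(assignment="random", seed=42)
    a = rhythm.trial_assignments(design_table, cfg)
    b = rhythm.trial_assignments(design_table, cfg)
    assert a == b
    flat = [s for trial in a for s in trial]
    assert len(set(flat)) == 30  # without replacement across trials


def test_missing_replicate_slot_errors(design_table):
    cfg = rhythm.RhythmConfig(n_trials=6)
    with pytest.raises(ValueError, match="replicates"):
        rhythm.trial_assignments(design_table, cfg)


# ---------------------------------------------------------------------------
# Phase windows


def make_results(phases, significant=True):
    return pd.DataFrame(
        {"avg_phase_h": phases, "significant": [significant] * len(phases)}
    )


def test_phase_window_zt6_interval():
    res = make_results([3.5, 8.4, 8.5])
    win = rhythm.phase_windows(res)
    assert win[6.0] == [0, 1]          # [3.5, 8.5): 8.5 excluded


def test_phase_window_wraparound():
    res = make_results([23.9])
    win = rhythm.phase_windows(res)
    assert win[2.0] == [0]             # ZT2 window spans [23.5, 4.5)


def test_phase_window_overlap_membership():
    res = make_results([8.0])
    win = rhythm.phase_windows(res)
    assert win[6.0] == [0] and win[10.0] == [0]


def test_phase_window_ignores_nonsignificant():
    res = make_results([6.0], significant=False)
    win = rhythm.phase_windows(res)
    assert all(len(v) == 0 for v in win.values())
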