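"""Diurnal (24 h) and ultradian (12 h) rhythm detection.

Three detectors are combined per series — a single-frequency
Lomb-Scargle test, a JTK-style Kendall-tau concordance test against
phase-shifted cosine references, and cosinor harmonic regression — and
their p-values are merged by Fisher's method, in the spirit of ensemble
rhythm callers.  The ensemble is run once per replicate *trial*: trial r
builds one series per PAS from replicate r at every timepoint, and a PAS
is called significant only when the integrated p-value clears alpha in
every trial.  This conjunction over trials is what controls the
anti-conservative independence assumption of the Fisher combination.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as ssig
from scipy import stats

from .io import DesignTable

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class RhythmConfig:
    period_h: float = 24.0
    timepoints_h: tuple[float, ...] = (2, 6, 10, 14, 18, 22)
    n_trials: int = 5
    alpha: float = 0.05
    methods: tuple[str, ...] = ("lomb_scargle", "jtk", "harmonic")
    assignment: str = "rotation"     # rotation | random
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        bad = set(self.methods) - {"lomb_scargle", "jtk", "harmonic"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Lomb-Scargle


def lomb_scargle_p(t_h: Sequence[float], y: Sequence[float],
                   period_h: float) -> float:
    """P-value for periodicity at a single tested frequency.

    The periodogram power at 1/period is normalized by the sample
    variance; under Gaussian noise the variance-normalized power z of an
    n-point series has the exact null tail
    P(Z > z) = (1 - 2z/(n-1))^((n-3)/2), which is the finite-sample form
    whose large-n limit is the familiar exp(-z) tail.  A constant series
    returns p = 1.
    """
    t = np.asarray(t_h, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 6:
        raise ValueError("need >= 6 observations")
    var = y.var(ddof=1)
    if var <= 0:
        return 1.0
    omega = 2 * np.pi / period_h
    power = float(
        np.atleast_1d(ssig.lombscargle(t, y - y.mean(), np.array([omega])))[0]
    )
    z = power / var
    zmax = (n - 1) / 2.0
    z = min(max(z, 0.0), zmax)
    return float((1.0 - 2.0 * z / (n - 1)) ** ((n - 3) / 2.0))


# ---------------------------------------------------------------------------
# JTK (Kendall tau vs. cosine references)


def _reference_offsets(timepoints: Sequence[float], period_h: float) -> np.ndarray:
    """Candidate acrophases: the sampling times folded into one period."""
    return np.unique(np.asarray(timepoints, dtype=float) % period_h)


def _tau_b(x: np.ndarray, y: np.ndarray) -> float:
    tau = stats.kendalltau(x, y).statistic
    return 0.0 if np.isnan(tau) else float(tau)


@lru_cache(maxsize=256)
def _exact_abs_tau_null(ref_ranks: tuple, y_pattern: tuple) -> np.ndarray:
    """Exact permutation null of |tau-b| for small n.

    ``ref_ranks`` is the reference's value pattern, ``y_pattern`` the
    observed series' value pattern (rank multiset), so ties on either
    side enter the enumeration.  Returns the sorted |tau| over all
    permutations of the observed values.
    """
    ref = np.asarray(ref_ranks, dtype=float)
    yv = np.asarray(y_pattern, dtype=float)
    n = len(ref)
    ii, jj = np.triu_indices(n, k=1)
    sign_r = np.sign(ref[jj] - ref[ii])
    perms = np.array(list(itertools.permutations(yv)))
    sign_y = np.sign(perms[:, jj] - perms[:, ii])
    s = sign_y @ sign_r
    n_pairs = len(ii)
    t_y = n_pairs - np.count_nonzero(sign_y, axis=1)   # tied pairs in y
    t_r = n_pairs - np.count_nonzero(sign_r)
    denom = np.sqrt((n_pairs - t_y) * (n_pairs - t_r))
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(denom > 0, s / denom, 0.0)
    return np.sort(np.abs(tau))


def jtk_p(t_h: Sequence[float], y: Sequence[float],
          period_h: float) -> tuple[float, float]:
    """(p-value, best phase) from Kendall concordance with cosine references.

    References are cosines peaking at each sampling offset within one
    period; the best phase maximizes tau-b.  For n <= 8 the p-value is
    the exact two-sided permutation tail; above that a normal
    approximation is used.  The result is Bonferroni-adjusted for the
    number of reference phases tested.  An all-tied series returns p = 1.
    """
    t = np.asarray(t_h, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 6:
        raise ValueError("need >= 6 observations")
    if np.all(y == y[0]):
        return 1.0, 0.0
    offsets = _reference_offsets(t, period_h)
    taus = []
    refs = []
    for off in offsets:
        ref = np.cos(2 * np.pi * (t - off) / period_h)
        refs.append(ref)
        taus.append(_tau_b(y, ref))
    best = int(np.argmax(taus))
    # two-sided: the most extreme |tau| over references decides
    abs_best = float(np.max(np.abs(taus)))
    k = int(np.argmax(np.abs(taus)))
    if n <= 8:
        ref_ranks = tuple(stats.rankdata(refs[k]))
        y_pattern = tuple(np.sort(stats.rankdata(y)))
        null = _exact_abs_tau_null(ref_ranks, y_pattern)
        p_one = float(np.mean(null >= abs_best - 1e-9))
    else:
        p_one = stats.kendalltau(y, refs[k]).pvalue
        if np.isnan(p_one):
            p_one = 1.0
    p = min(1.0, p_one * len(offsets))
    return p, float(offsets[best] % period_h)


# ---------------------------------------------------------------------------
# Cosinor harmonic regression


def harmonic_p(t_h: Sequence[float], y: Sequence[float],
               period_h: float) -> tuple[float, float, float]:
    """(p, acrophase, amplitude) from least-squares cosinor fit.

    Fits y ~ m + a*cos(2*pi*t/T) + b*sin(2*pi*t/T); the F-test compares
    against the intercept-only model; amplitude is sqrt(a^2+b^2) (half
    the fitted peak-to-trough) and the acrophase is the time of the
    fitted maximum in [0, T).
    """
    t = np.asarray(t_h, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("need >= 4 observations")
    omega = 2 * np.pi / period_h
    X = np.column_stack([np.ones(n), np.cos(omega * t), np.sin(omega * t)])
    if np.linalg.matrix_rank(X) < 3:
        warnings.warn("rank-deficient cosinor design")
        return 1.0, 0.0, 0.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss1 = float(resid @ resid)
    ss0 = float(((y - y.mean()) ** 2).sum())
    a, b = beta[1], beta[2]
    amp = float(np.hypot(a, b))
    phase = float((math.atan2(b, a) / omega) % period_h)
    if ss0 <= 0:
        return 1.0, phase, 0.0
    df2 = n - 3
    if ss1 <= 1e-12 * ss0:
        return 0.0, phase, amp
    f = ((ss0 - ss1) / 2.0) / (ss1 / df2)
    p = float(stats.f.sf(f, 2, df2))
    return p, phase, amp


# ---------------------------------------------------------------------------
# Meta integration


def circular_mean(phases: Sequence[float], period: float,
                  weights: Sequence[float] | None = None) -> float:
    ang = 2 * np.pi * np.asarray(phases, dtype=float) / period
    w = np.ones(len(ang)) if weights is None else np.asarray(weights, float)
    if w.sum() <= 0:
        w = np.ones(len(ang))
    x = float(np.sum(w * np.cos(ang)))
    y = float(np.sum(w * np.sin(ang)))
    if x == 0 and y == 0:
        return 0.0
    return float((math.atan2(y, x) * period / (2 * np.pi)) % period)


def integrate_meta(
    pvals: Mapping[str, float],
    phases: Mapping[str, float],
    amps: Mapping[str, float],
    period_h: float,
) -> tuple[float, float, float]:
    """Combine per-method results into one (p, phase, amplitude).

    P-values merge by Fisher's method (-2*sum(log p) ~ chi2 with 2k df,
    p floored at 1e-300); the phase is the circular mean of method
    phases weighted by -log p; the amplitude is the arithmetic mean.
    """
    if not pvals:
        raise ValueError("need at least one method p-value")
    ps = np.array([max(p, _P_FLOOR) for p in pvals.values()])
    stat = -2.0 * np.log(ps).sum()
    p = float(stats.chi2.sf(stat, 2 * len(ps)))
    if phases:
        w = [-math.log(max(pvals.get(m, 1.0), _P_FLOOR)) for m in phases]
        phase = circular_mean(list(phases.values()), period_h, w)
    else:
        phase = 0.0
    amp = float(np.mean(list(amps.values()))) if amps else 0.0
    return p, phase, amp


def series_stats(t_h: Sequence[float], y: Sequence[float],
                 cfg: RhythmConfig) -> tuple[float, float, float]:
    """(integrated p, phase, amplitude) of one series under ``cfg``."""
    pvals: dict[str, float] = {}
    phases: dict[str, float] = {}
    amps: dict[str, float] = {}
    if "lomb_scargle" in cfg.methods:
        pvals["lomb_scargle"] = lomb_scargle_p(t_h, y, cfg.period_h)
    if "jtk" in cfg.methods:
        p, ph = jtk_p(t_h, y, cfg.period_h)
        pvals["jtk"], phases["jtk"] = p, ph
    if "harmonic" in cfg.methods:
        p, ph, a = harmonic_p(t_h, y, cfg.period_h)
        pvals["harmonic"], phases["harmonic"], amps["harmonic"] = p, ph, a
    return integrate_meta(pvals, phases, amps, cfg.period_h)


# ---------------------------------------------------------------------------
# Trials


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def trial_assignments(design: DesignTable, cfg: RhythmConfig) -> list[list[str]]:
    """Sample ids filling each timepoint slot, one list per trial.

    Rotation (default) places replicate r at every timepoint in trial r;
    random mode shuffles each timepoint's replicates once under the run
    seed, so trials still draw without replacement.  Only diurnal
    timecourse samples (group ZT<t> at a configured timepoint) are used.
    """
    rng = (np.random.default_rng(cfg.seed)
           if cfg.assignment == "random" else None)
    if cfg.assignment not in ("rotation", "random"):
        raise ValueError("assignment must be 'rotation' or 'random'")
    per_tp: list[list[str]] = []
    for tp in cfg.timepoints_h:
        reps = sorted(
            (r for r in design.rows
             if r.zt_h == tp and r.group == f"ZT{tp:g}"),
            key=lambda r: r.replicate,
        )
        if len(reps) < cfg.n_trials:
            raise ValueError(
                f"timepoint ZT{tp:g} has {len(reps)} replicates, "
                f"need {cfg.n_trials}"
            )
        ids = [r.sample_id for r in reps]
        if rng is not None:
            ids = [ids[k] for k in rng.permutation(len(ids))]
        per_tp.append(ids)
    return [[ids[trial] for ids in per_tp] for trial in range(cfg.n_trials)]


def run_trials(matrix: pd.DataFrame, design: DesignTable,
               cfg: RhythmConfig) -> pd.DataFrame:
    """Per-PAS rhythm results under the replicate-trial scheme.

    ``matrix`` holds normalized counts (PAS x sample).  Each of the
    ``n_trials`` trials tests one replicate series per PAS; BH adjustment
    is computed within each trial across all PASs.  The output carries
    per-trial p-values, their median, the median BH.Q, the circular-mean
    phase, mean amplitude, mean relative amplitude, and the all-trials
    significance call.
    """
    t = np.array(cfg.timepoints_h, dtype=float)
    assignments = trial_assignments(design, cfg)
    n_pas = len(matrix)
    trial_p = np.empty((n_pas, cfg.n_trials))
    trial_q = np.empty((n_pas, cfg.n_trials))
    trial_phase = np.empty((n_pas, cfg.n_trials))
    trial_amp = np.empty((n_pas, cfg.n_trials))
    trial_mean = np.empty((n_pas, cfg.n_trials))
    for trial in range(1, cfg.n_trials + 1):
        cols = assignments[trial - 1]
        Y = matrix[cols].to_numpy(dtype=float)
        for i in range(n_pas):
            p, ph, a = series_stats(t, Y[i], cfg)
            trial_p[i, trial - 1] = p
            trial_phase[i, trial - 1] = ph
            trial_amp[i, trial - 1] = a
        trial_mean[:, trial - 1] = Y.mean(axis=1)
        trial_q[:, trial - 1] = bh_adjust(trial_p[:, trial - 1])

    med_p = np.median(trial_p, axis=1)
    med_q = np.median(trial_q, axis=1)
    avg_phase = np.array(
        [circular_mean(trial_phase[i], cfg.period_h) for i in range(n_pas)]
    )
    avg_amp = trial_amp.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ramp = np.where(trial_mean > 0, trial_amp / trial_mean, 0.0)
    avg_ramp = ramp.mean(axis=1)
    significant = (trial_p < cfg.alpha).all(axis=1)

    out = pd.DataFrame(
        {
            **{f"trial{r}_p": trial_p[:, r - 1]
               for r in range(1, cfg.n_trials + 1)},
            "median_p": med_p,
            "median_bhq": med_q,
            "avg_phase_h": avg_phase,
            "avg_amp": avg_amp,
            "avg_ramp": avg_ramp,
            "significant": significant,
            "period_h": cfg.period_h,
        },
        index=matrix.index,
    )
    return out


# ---------------------------------------------------------------------------
# Phase windows


def phase_windows(
    results: pd.DataFrame,
    centers: Sequence[float] = (2, 6, 10, 14, 18, 22),
    width_h: float = 5.0,
    period_h: float = 24.0,
) -> dict[float, list]:
    """Group significant PASs by sliding phase windows.

    A PAS joins window c iff its average phase lies in
    [c - width/2, c + width/2) modulo the period; with 4 h centers and a
    5 h width, adjacent windows overlap by 1 h and a PAS in the overlap
    is reported in both.
    """
    half = width_h / 2.0
    sig = results[results["significant"]]
    out: dict[float, list] = {float(c): [] for c in centers}
    for pas_id, phase in sig["avg_phase_h"].items():
        for c in centers:
            d = (phase - c + period_h / 2) % period_h - period_h / 2
            if -half <= d < half:
                out[float(c)].append(pas_id)
    return out
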