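"""Step-2 evaluation: do AddHRVr triggers predict objective stress increases?

Each qualifying stress transition is one binary observation: outcome
``direction`` (1 = increase of objective stress), predictor
``trigger_present`` (1 = a trigger fired within the follow window),
grouped by participant.  The model is a random-intercept logistic
regression

    logit P(direction_ij = 1) = beta0 + beta1 * trigger_ij + b_i,
    b_i ~ N(0, sigma_b^2),

whose marginal likelihood is integrated per cluster with Gauss-Hermite
quadrature and maximised numerically.  Effects are reported as the
percentage change in odds, (OR - 1) * 100, for trigger presence.

Statistical power of a given algorithm setting is estimated by a cluster
bootstrap: per iteration the participants are resampled with replacement,
their (precomputed, deterministic) events pooled, and the model refitted;
power is the fraction of valid iterations with p < 0.05.  Iterations are
invalid on non-convergence, complete separation (a zero cell in the pooled
2x2 table), or a resample in which all events share one direction or one
predictor value.  Resampled participants entering an iteration more than
once are treated as distinct grouping units, the standard cluster
bootstrap convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from .calibration import CalibrationModel
from .stress_labeling import EventRecord, detect_transitions, match_triggers
from .timeseries_io import ParticipantSeries
from .trigger_engine import (
    AlgorithmSettings,
    enumerate_settings,
    run_algorithm,
)

P_SIGNIFICANT = 0.05
N_QUAD = 25  # Gauss-Hermite nodes for the random-intercept integral
_LOG_SIGMA_BOUNDS = (-6.0, 3.0)


@dataclass(frozen=True)
class ModelFit:
    """Wald summary of the trigger coefficient in one fitted model."""

    beta_trigger: float
    se: float
    p_value: float
    odds_ratio: float
    converged: bool
    beta_intercept: float = float("nan")
    sigma_b: float = float("nan")

    @classmethod
    def failed(cls) -> "ModelFit":
        nan = float("nan")
        return cls(nan, nan, nan, nan, converged=False)


@dataclass(frozen=True)
class ParticipantData:
    """One participant's precomputed step-2 inputs for one setting."""

    participant_id: str
    directions: np.ndarray  # 0/1 per transition
    triggers_present: np.ndarray  # 0/1 per transition
    n_triggers: int  # total triggers delivered over the whole day


@dataclass(frozen=True)
class SettingResult:
    """Bootstrap summary of one algorithm setting (one table row)."""

    settings: AlgorithmSettings
    power: float
    mean_pct_odds: float
    ci_low: float
    ci_high: float
    total_triggers: int
    triggered_increases: float
    triggered_decreases: float
    n_valid_iters: int
    unreliable: bool = False


# ---------------------------------------------------------------------------
# random-intercept logistic likelihood
# ---------------------------------------------------------------------------

def _cluster_loglik(y, x, group_bounds, params, z_nodes, log_w):
    """Sum over clusters of the GH-approximated marginal log-likelihood."""
    b0, b1, log_sigma = params
    sigma = math.exp(log_sigma)
    eta = b0 + b1 * x
    sgn = 2.0 * y - 1.0
    # per-event log-likelihood at each shifted node: (n_nodes, n_events)
    shift = math.sqrt(2.0) * sigma * z_nodes[:, None]
    ll_events = -np.logaddexp(0.0, -sgn[None, :] * (eta[None, :] + shift))
    # per-cluster sums at each node
    ll_clusters = np.add.reduceat(ll_events, group_bounds, axis=1)
    from scipy.special import logsumexp

    return float(np.sum(logsumexp(log_w[:, None] + ll_clusters, axis=0)))


def _plain_loglik(y, x, params):
    b0, b1 = params
    sgn = 2.0 * y - 1.0
    return float(np.sum(-np.logaddexp(0.0, -sgn * (b0 + b1 * x))))


def _prepare_groups(groups):
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    bounds = np.concatenate(
        ([0], np.flatnonzero(sorted_groups[1:] != sorted_groups[:-1]) + 1)
    )
    return order, bounds


def events_table(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pooled 2x2 table [[n00, n01], [n10, n11]] indexed [x][y]."""
    t = np.zeros((2, 2))
    for xi in (0, 1):
        for yi in (0, 1):
            t[xi, yi] = np.sum((x == xi) & (y == yi))
    return t


def _degenerate(y: np.ndarray, x: np.ndarray, groups: np.ndarray) -> bool:
    if len(y) == 0 or len(np.unique(y)) < 2 or len(np.unique(x)) < 2:
        return True
    # a zero cell makes the trigger odds ratio 0 or infinite (separation)
    return bool(np.any(events_table(y, x) == 0))


def fit_logistic_arrays(
    y,
    x,
    groups,
    random_intercept: bool = True,
    p_method: str = "wald",
    n_quad: int = N_QUAD,
) -> ModelFit:
    """Maximum-likelihood fit of the (random-intercept) logistic model.

    ``random_intercept=False`` constrains sigma_b = 0, collapsing to plain
    logistic regression; ``p_method`` is ``"wald"`` (default, the z-test on
    the trigger coefficient) or ``"lr"`` (likelihood ratio against the
    trigger-free model).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if _degenerate(y, x, groups):
        return ModelFit.failed()

    # starting values from the pooled 2x2 table
    t = events_table(y, x)
    b0_start = math.log(t[0, 1] / t[0, 0])
    b1_start = math.log(t[1, 1] * t[0, 0] / (t[1, 0] * t[0, 1]))

    if random_intercept:
        order, bounds = _prepare_groups(groups)
        ys, xs = y[order], x[order]
        z_nodes, w = np.polynomial.hermite.hermgauss(n_quad)
        log_w = np.log(w) - 0.5 * math.log(math.pi)

        def nll(p):
            return -_cluster_loglik(ys, xs, bounds, p, z_nodes, log_w)

        start = np.array([b0_start, b1_start, math.log(0.5)])
        res = optimize.minimize(
            nll,
            start,
            method="L-BFGS-B",
            bounds=[(None, None), (None, None), _LOG_SIGMA_BOUNDS],
        )
        if not res.success or not np.all(np.isfinite(res.x)):
            return ModelFit.failed()
        beta0, beta1, log_sigma = res.x
        sigma_b = math.exp(log_sigma)
        hess = numdiff.approx_hess(res.x, nll)
        free = hess[:2, :2] if log_sigma <= _LOG_SIGMA_BOUNDS[0] + 1e-6 else hess
        try:
            cov = np.linalg.inv(free)
        except np.linalg.LinAlgError:
            return ModelFit.failed()
        se = float(np.sqrt(cov[1, 1])) if cov[1, 1] > 0 else float("nan")
        final_nll = res.fun
    else:

        def nll(p):
            return -_plain_loglik(y, x, p)

        res = optimize.minimize(nll, np.array([b0_start, b1_start]), method="BFGS")
        if not res.success or not np.all(np.isfinite(res.x)):
            return ModelFit.failed()
        beta0, beta1 = res.x
        sigma_b = 0.0
        hess = numdiff.approx_hess(res.x, nll)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return ModelFit.failed()
        se = float(np.sqrt(cov[1, 1])) if cov[1, 1] > 0 else float("nan")
        final_nll = res.fun

    if not np.isfinite(se):
        return ModelFit.failed()

    if p_method == "lr":
        p_value = _lr_pvalue(y, x, groups, random_intercept, n_quad, final_nll)
    else:
        z = beta1 / se
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    return ModelFit(
        beta_trigger=float(beta1),
        se=se,
        p_value=p_value,
        odds_ratio=float(math.exp(beta1)),
        converged=True,
        beta_intercept=float(beta0),
        sigma_b=sigma_b,
    )


def _lr_pvalue(y, x, groups, random_intercept, n_quad, full_nll):
    """Likelihood-ratio p for the trigger coefficient (1 df)."""
    if random_intercept:
        order, bounds = _prepare_groups(groups)
        ys, xs = y[order], x[order]
        z_nodes, w = np.polynomial.hermite.hermgauss(n_quad)
        log_w = np.log(w) - 0.5 * math.log(math.pi)

        def nll0(p):
            return -_cluster_loglik(
                ys, xs, bounds, (p[0], 0.0, p[1]), z_nodes, log_w
            )

        res0 = optimize.minimize(
            nll0,
            np.array([0.0, math.log(0.5)]),
            method="L-BFGS-B",
            bounds=[(None, None), _LOG_SIGMA_BOUNDS],
        )
    else:

        def nll0(p):
            return -_plain_loglik(y, x, (p[0], 0.0))

        res0 = optimize.minimize(nll0, np.array([0.0]), method="BFGS")
    lr = 2.0 * (res0.fun - full_nll)
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def fit_random_intercept_logistic(
    events: Sequence[EventRecord],
    random_intercept: bool = True,
    p_method: str = "wald",
) -> ModelFit:
    """Fit the step-2 model to a pooled set of transition events."""
    y = np.array([e.transition.direction for e in events], dtype=float)
    x = np.array([e.trigger_present for e in events], dtype=float)
    groups = np.array([e.transition.participant_id for e in events])
    return fit_logistic_arrays(
        y, x, groups, random_intercept=random_intercept, p_method=p_method
    )


# ---------------------------------------------------------------------------
# step-2 inputs and the cluster bootstrap
# ---------------------------------------------------------------------------

def participant_events(
    series: ParticipantSeries,
    model: CalibrationModel,
    settings: AlgorithmSettings,
    follow_window: int = 20,
    min_duration: int = 20,
) -> ParticipantData:
    """Run the trigger engine and match triggers with transitions for one day."""
    train = run_algorithm(series, model, settings)
    transitions = detect_transitions(series, min_duration=min_duration)
    matched = match_triggers(transitions, train, follow_window=follow_window)
    return ParticipantData(
        participant_id=series.participant_id,
        directions=np.array([e.transition.direction for e in matched.events], dtype=int),
        triggers_present=np.array(
            [e.trigger_present for e in matched.events], dtype=int
        ),
        n_triggers=train.n_triggers,
    )


def bootstrap_setting(
    cohort: Sequence[ParticipantData],
    settings: AlgorithmSettings,
    iters: int = 500,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    n_participants: Optional[int] = None,
    p_method: str = "wald",
) -> SettingResult:
    """Cluster-bootstrapped evaluation of one algorithm setting.

    Per iteration ``n_participants`` participants (default: the cohort
    size) are drawn with replacement, their precomputed events pooled and
    the random-intercept logistic model refitted.  Power is the share of
    valid iterations with p < 0.05; the effect estimate is the mean over
    valid iterations of (OR - 1) * 100 with 2.5/97.5 percentile bounds.
    Reproducible: a pure function of (cohort, settings, iters, seed).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(cohort) if n_participants is None else int(n_participants)
    n_sig = 0
    pct_odds: list[float] = []
    inc_counts: list[int] = []
    dec_counts: list[int] = []
    for _ in range(iters):
        idx = rng.integers(0, len(cohort), size=n)
        ys, xs, gs = [], [], []
        for j, i in enumerate(idx):
            p = cohort[i]
            if len(p.directions) == 0:
                continue
            ys.append(p.directions)
            xs.append(p.triggers_present)
            gs.append(np.full(len(p.directions), j))  # fresh label per draw
        if not ys:
            continue
        y = np.concatenate(ys).astype(float)
        x = np.concatenate(xs).astype(float)
        g = np.concatenate(gs)
        fit = fit_logistic_arrays(y, x, g, p_method=p_method)
        if not fit.converged or not np.isfinite(fit.p_value):
            continue
        if fit.p_value < P_SIGNIFICANT:
            n_sig += 1
        pct_odds.append((fit.odds_ratio - 1.0) * 100.0)
        inc_counts.append(int(np.sum((y == 1) & (x == 1))))
        dec_counts.append(int(np.sum((y == 0) & (x == 1))))
    n_valid = len(pct_odds)
    total_triggers = int(sum(p.n_triggers for p in cohort))
    if n_valid == 0:
        nan = float("nan")
        return SettingResult(
            settings, nan, nan, nan, nan, total_triggers, nan, nan, 0, True
        )
    pct = np.asarray(pct_odds)
    return SettingResult(
        settings=settings,
        power=n_sig / n_valid,
        mean_pct_odds=float(np.mean(pct)),
        ci_low=float(np.percentile(pct, 2.5)),
        ci_high=float(np.percentile(pct, 97.5)),
        total_triggers=total_triggers,
        triggered_increases=float(np.mean(inc_counts)),
        triggered_decreases=float(np.mean(dec_counts)),
        n_valid_iters=n_valid,
        unreliable=n_valid < iters / 2,
    )


def sweep_grid(
    cohort: Sequence[tuple[ParticipantSeries, CalibrationModel]],
    variant: str = "static",
    silent_min: int = 20,
    follow_window: int = 20,
    min_duration: int = 20,
    iters: int = 500,
    seed: int = 0,
    min_len: int = 2,
    max_len: int = 30,
    decrease_mult: float = 0.5,
    skip: Optional[set] = None,
) -> list[SettingResult]:
    """Bootstrap every (window_length, window_threshold) adjustment.

    One SettingResult per pair from :func:`enumerate_settings`, each with
    its own deterministic child seed so restricting the grid or skipping
    already-computed pairs (``skip``) does not change any individual result.
    """
    pairs = enumerate_settings(min_len, max_len)
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    results = []
    for (n, k), child in zip(pairs, children):
        if skip and (n, k) in skip:
            continue
        settings = AlgorithmSettings(
            variant=variant,
            window_length=n,
            window_threshold=k,
            silent_min=silent_min,
            decrease_mult=decrease_mult,
        )
        data = [
            participant_events(
                s, m, settings, follow_window=follow_window, min_duration=min_duration
            )
            for s, m in cohort
        ]
        results.append(
            bootstrap_setting(
                data,
                settings,
                iters=iters,
                rng=np.random.default_rng(child),
            )
        )
    return results


def power_curve(
    cohort: Sequence[ParticipantData],
    settings: AlgorithmSettings,
    n_values: Sequence[int],
    iters: int = 500,
    seed: int = 0,
    thresholds: Sequence[float] = (0.70, 0.80, 0.90),
) -> tuple[pd.DataFrame, dict[float, Optional[int]]]:
    """Bootstrap power as a function of the number of sampled participants.

    Sampling is always with replacement, so ``n`` may exceed the cohort
    size.  Returns the (n, power) table and, per requested threshold, the
    smallest n whose estimated power crosses it (None if never crossed).
    """
    if len(n_values) < 2:
        raise ValueError("need at least 2 sample sizes")
    children = np.random.SeedSequence(seed).spawn(len(n_values))
    rows = []
    for n, child in zip(n_values, children):
        res = bootstrap_setting(
            cohort,
            settings,
            iters=iters,
            rng=np.random.default_rng(child),
            n_participants=n,
        )
        rows.append({"n": int(n), "power": res.power,
                     "mean_pct_odds": res.mean_pct_odds,
                     "n_valid_iters": res.n_valid_iters})
    frame = pd.DataFrame(rows).sort_values("n").reset_index(drop=True)
    crossings: dict[float, Optional[int]] = {}
    for thr in thresholds:
        above = frame[frame["power"] >= thr]
        crossings[thr] = int(above["n"].iloc[0]) if len(above) else None
    return frame, crossings


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def results_to_frame(results: Sequence[SettingResult]) -> pd.DataFrame:
    """Settings table ordered by power (descending), report-style columns."""
    frame = pd.DataFrame(
        {
            "window_length": [r.settings.window_length for r in results],
            "window_threshold": [r.settings.window_threshold for r in results],
            "power": [r.power for r in results],
            "effect_estimate_pct": [r.mean_pct_odds for r in results],
            "ci_low_2.5": [r.ci_low for r in results],
            "ci_high_97.5": [r.ci_high for r in results],
            "total_triggers": [r.total_triggers for r in results],
            "triggered_increases": [r.triggered_increases for r in results],
            "triggered_decreases": [r.triggered_decreases for r in results],
            "n_valid_iters": [r.n_valid_iters for r in results],
            "unreliable": [r.unreliable for r in results],
        }
    )
    return frame.sort_values("power", ascending=False).reset_index(drop=True)


def power_matrix(results: Sequence[SettingResult]) -> pd.DataFrame:
    """Long-format (window_length, window_threshold, power, pct_odds) export."""
    return pd.DataFrame(
        {
            "window_length": [r.settings.window_length for r in results],
            "window_threshold": [r.settings.window_threshold for r in results],
            "power": [r.power for r in results],
            "pct_odds": [r.mean_pct_odds for r in results],
        }
    )
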