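"""Hyperparameter optimisation and design-of-experiments effect analysis.

The tuning objective balances validation accuracy against overfitting:

    F = JT_val * (1 - |JT_train - JT_val|)

where JT_train / JT_val are mean Jaccard–Tanimoto similarities on the
training and validation sets.  F is maximised with a Tree-structured Parzen
Estimator: after a random start-up phase, past trials are split at a
quantile of F into good/bad groups, one-dimensional Parzen densities
l(x) and g(x) are built over each group, and the candidate maximising
l(x)/g(x) is evaluated next.

The contribution of each hyperparameter to F is estimated afterwards by
regressing the standardised response on standardised (min-max scaled or
one-hot) predictors and reading off the coefficients with their 95%
confidence intervals.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def objective(jt_train: float, jt_val: float) -> float:
    """Overfitting-penalised validation similarity F (to be maximised)."""
    if not (0 <= jt_train <= 1 and 0 <= jt_val <= 1):
        raise ValueError("JT values must lie in [0, 1]")
    return jt_val * (1.0 - abs(jt_train - jt_val))


# --------------------------------------------------------------------------
# search space


@dataclass(frozen=True)
class Dimension:
    """One search dimension: float/int (optionally log-scaled) or categorical."""

    name: str
    kind: str  # {"float", "int", "cat"}
    low: Optional[float] = None
    high: Optional[float] = None
    log: bool = False
    choices: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind in ("float", "int"):
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError(f"{self.name}: need low < high")
        elif self.kind == "cat":
            if not self.choices:
                raise ValueError(f"{self.name}: categorical needs choices")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    def _to_internal(self, x):
        return math.log(x) if self.log else x

    def _from_internal(self, u):
        x = math.exp(u) if self.log else u
        if self.kind == "int":
            x = int(round(x))
            x = min(max(x, int(self.low)), int(self.high))
        return x

    def sample(self, rng: np.random.Generator):
        if self.kind == "cat":
            return self.choices[rng.integers(len(self.choices))]
        lo, hi = self._to_internal(self.low), self._to_internal(self.high)
        return self._from_internal(rng.uniform(lo, hi))


def default_space(n_train: Optional[int] = None) -> list[Dimension]:
    """The eight-dimensional network search space.

    Bounds follow the published tuning table (shared neurons 50–100,
    task-specific neurons 250–500, learning rate 1e-4–1e-2 log-scaled,
    dropout 0–0.5, batch size 2000–4000, patience 50–150).  For small
    datasets the batch-size upper bound is capped at n_train / 4 so several
    updates happen per epoch.
    """
    bs_high = 4000
    bs_low = 2000
    if n_train is not None:
        bs_high = max(2, min(bs_high, n_train // 4))
        bs_low = min(bs_low, max(2, bs_high // 2))
    return [
        Dimension("n_neurons", "int", 50, 100),
        Dimension("n_task_specific", "int", 250, 500),
        Dimension("learning_rate", "float", 1e-4, 1e-2, log=True),
        Dimension("activation", "cat", choices=("sigmoid", "relu")),
        Dimension("dropout", "float", 0.0, 0.5),
        Dimension("batch_size", "int", bs_low, max(bs_low + 1, bs_high)),
        Dimension("patience", "int", 50, 150),
        Dimension("optimizer", "cat", choices=("adam", "sgd", "rmsprop")),
    ]


# --------------------------------------------------------------------------
# TPE


@dataclass
class TuningTrial:
    """One evaluated configuration with its scores."""

    index: int
    params: dict
    jt_train: float = np.nan
    jt_val: float = np.nan
    F: float = np.nan
    failed: bool = False
    error: Optional[str] = None


def _parzen_logpdf(u: np.ndarray, obs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Log-density of a 1-D Parzen (Gaussian-mixture) estimator over [lo, hi].

    Bandwidth: Scott's rule with a floor of 1/20 of the range so the density
    never collapses onto the observations.
    """
    if obs.size == 0:
        return np.full(u.shape, -np.log(hi - lo))
    span = hi - lo
    sd = np.std(obs) if obs.size > 1 else span / 4
    bw = max(1.06 * sd * obs.size ** (-0.2), span / 20.0)
    diff = (u[:, None] - obs[None, :]) / bw
    log_k = -0.5 * diff**2 - 0.5 * np.log(2 * np.pi) - np.log(bw)
    return np.logaddexp.reduce(log_k, axis=1) - np.log(obs.size)


class TPESampler:
    """Minimal independent-dimension Tree-structured Parzen Estimator."""

    def __init__(
        self,
        space: Sequence[Dimension],
        seed: int = 0,
        n_startup: int = 10,
        gamma: float = 0.25,
        n_candidates: int = 24,
    ):
        self.space = list(space)
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    def suggest(self, trials: Sequence[TuningTrial]) -> dict:
        done = [t for t in trials if not t.failed and np.isfinite(t.F)]
        if len(done) < self.n_startup:
            return {d.name: d.sample(self.rng) for d in self.space}
        scores = np.array([t.F for t in done])
        n_good = max(1, int(np.ceil(self.gamma * len(done))))
        good_idx = np.argsort(-scores)[:n_good]
        good = set(good_idx.tolist())
        params: dict = {}
        for d in self.space:
            good_obs = [done[i].params[d.name] for i in range(len(done)) if i in good]
            bad_obs = [done[i].params[d.name] for i in range(len(done)) if i not in good]
            if d.kind == "cat":
                params[d.name] = self._suggest_cat(d, good_obs, bad_obs)
            else:
                params[d.name] = self._suggest_numeric(d, good_obs, bad_obs)
        return params

    def _suggest_cat(self, d: Dimension, good_obs, bad_obs):
        def probs(obs):
            counts = np.array(
                [1.0 + sum(o == c for o in obs) for c in d.choices]
            )  # add-one smoothing
            return counts / counts.sum()

        ratio = probs(good_obs) / probs(bad_obs)
        # sample candidates from the good density, keep best l/g ratio
        pg = probs(good_obs)
        cand = self.rng.choice(len(d.choices), size=self.n_candidates, p=pg)
        best = cand[np.argmax(ratio[cand])]
        return d.choices[int(best)]

    def _suggest_numeric(self, d: Dimension, good_obs, bad_obs):
        lo, hi = d._to_internal(d.low), d._to_internal(d.high)
        g = np.array([d._to_internal(x) for x in good_obs], dtype=float)
        b = np.array([d._to_internal(x) for x in bad_obs], dtype=float)
        # draw candidates from the good mixture (resample outside bounds)
        if g.size:
            centers = self.rng.choice(g, size=self.n_candidates)
            span = hi - lo
            sd = np.std(g) if g.size > 1 else span / 4
            bw = max(1.06 * sd * g.size ** (-0.2), span / 20.0)
            cand = centers + self.rng.normal(0, bw, size=self.n_candidates)
            cand = np.clip(cand, lo, hi)
        else:
            cand = self.rng.uniform(lo, hi, size=self.n_candidates)
        score = _parzen_logpdf(cand, g, lo, hi) - _parzen_logpdf(cand, b, lo, hi)
        return d._from_internal(float(cand[np.argmax(score)]))


def tpe_search(
    evaluate: Callable[[dict], tuple[float, float]],
    space: Sequence[Dimension],
    n_trials: int = 100,
    base_seed: int = 0,
    sampler_kwargs: Optional[dict] = None,
    trials: Optional[list[TuningTrial]] = None,
) -> tuple[TuningTrial, list[TuningTrial]]:
    """Maximise F over the space with TPE.

    ``evaluate`` maps a parameter dict to (jt_train, jt_val); a crashing
    trial is recorded as failed and the search continues.  Passing an
    existing trial log resumes it (trial numbering continues).  Reproducible
    under ``base_seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    sampler = TPESampler(space, seed=base_seed, **(sampler_kwargs or {}))
    trials = trials if trials is not None else []
    start = len(trials)
    for i in range(start, start + n_trials):
        params = sampler.suggest(trials)
        trial = TuningTrial(index=i, params=params)
        try:
            jt_train, jt_val = evaluate(params)
            trial.jt_train = jt_train
            trial.jt_val = jt_val
            trial.F = objective(jt_train, jt_val)
        except Exception as exc:  # noqa: BLE001 — a bad config must not kill the search
            trial.failed = True
            trial.error = f"{type(exc).__name__}: {exc}"
            logger.warning("trial %d failed: %s", i, trial.error)
        trials.append(trial)
    done = [t for t in trials if not t.failed and np.isfinite(t.F)]
    if not done:
        raise RuntimeError("every trial failed")
    best = max(done, key=lambda t: t.F)
    return best, trials


def trials_to_frame(trials: Sequence[TuningTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        row = {"trial": t.index, **t.params, "jt_train": t.jt_train,
               "jt_val": t.jt_val, "F": t.F, "failed": t.failed}
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# DoE-style effect analysis


def effect_analysis(
    trials: Sequence[TuningTrial] | pd.DataFrame,
    response: str = "F",
) -> pd.DataFrame:
    """Standardised regression coefficients of F on the hyperparameters.

    Numeric settings are min-max scaled, categorical ones one-hot encoded
    against a reference level; predictors and response are then z-scored and
    the response regressed on them by ordinary least squares.  Returns a
    frame with coefficients and 95% confidence intervals, ordered by
    absolute effect size.  Aliased (perfectly collinear) columns are dropped
    with a warning.
    """
    import statsmodels.api as sm

    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    df = df[~df.get("failed", pd.Series(False, index=df.index)).astype(bool)]
    hp_cols = [c for c in df.columns if c not in ("trial", "jt_train", "jt_val", "failed", response)]
    if len(df) < 2 * len(hp_cols):
        raise ValueError(
            f"need at least {2 * len(hp_cols)} trials for {len(hp_cols)} hyperparameters"
        )
    X = pd.DataFrame(index=df.index)
    for c in hp_cols:
        col = df[c]
        if pd.api.types.is_numeric_dtype(col):
            rng_ = col.max() - col.min()
            X[c] = 0.0 if rng_ == 0 else (col - col.min()) / rng_
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    # z-score predictors and response; constant columns stay zero
    y = df[response].astype(float)
    y_sd = y.std(ddof=0)
    y_std = (y - y.mean()) / y_sd if y_sd > 0 else y * 0.0
    for c in X.columns:
        sd = X[c].std(ddof=0)
        X[c] = (X[c] - X[c].mean()) / sd if sd > 0 else 0.0
    # drop aliased columns (exact collinearity with earlier columns)
    keep: list[str] = []
    dropped: list[str] = []
    M = np.empty((len(X), 0))
    for c in X.columns:
        v = X[c].to_numpy()[:, None]
        cand = np.hstack([M, v])
        if np.linalg.matrix_rank(cand, tol=1e-8) > M.shape[1]:
            keep.append(c)
            M = cand
        else:
            dropped.append(c)
    if dropped:
        warnings.warn(f"dropping aliased columns: {dropped}", stacklevel=2)
    design = sm.add_constant(X[keep])
    fit = sm.OLS(y_std, design).fit()
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "coefficient": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    ).drop(index="const", errors="ignore")
    return out.reindex(out["coefficient"].abs().sort_values(ascending=False).index)
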