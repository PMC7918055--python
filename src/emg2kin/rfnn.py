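"""Recurrent fuzzy neural network (RFNN) regression.

The network has four layers. Layer 1 passes the (normalized) inputs
through. Layer 2 fuzzifies each input i against each rule j with a Gaussian
membership ``exp(-(x_i - m_ij)^2 / sigma_ij^2)``. Layer 3 combines the
memberships of a rule with a product (fuzzy AND) into a spatial firing
strength ``s_j``, then feeds it through a per-rule internal feedback loop

    u_j(t) = lambda_j * s_j(t) + (1 - lambda_j) * u_j(t-1),

where ``lambda_j`` in [0, 1] balances current against past activation —
this is what lets the network model time-varying input-output maps. Layer 4
defuzzifies with a firing-strength-weighted average of per-rule output
weights, ``y_o = sum_j u_j w_jo / sum_j u_j``.

Structure is initialised by k-means clustering of the training inputs (one
rule per cluster) and adapted online: a rule is added when no existing rule
fires above a threshold, and rules whose mean firing over an epoch falls
below a prune threshold are removed. All four parameter families (centers,
widths, recurrent parameters, output weights) are trained by per-sample
gradient descent on the squared error; the recurrent state one step back is
treated as a constant in the gradient (depth-1 truncation), matching
real-time per-iteration updates rather than full backpropagation through
time.

The public surface follows the statsmodels idiom:
:class:`RecurrentFuzzyRegression` is built from data and ``fit()`` returns
an :class:`RFNNResults` carrying the fitted parameters, training
diagnostics, ``predict()`` and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from statsmodels.iolib.table import SimpleTable

EPS_ACTIVATION = 1e-12

__all__ = [
    "LearningConfig",
    "RfnnParams",
    "RecurrentFuzzyRegression",
    "RFNNResults",
    "ZeroActivationError",
    "fuzzify",
    "rule_strength",
    "recurrent_update",
    "defuzzify",
    "forward_sequence",
    "sample_loss",
    "gradients",
    "grad_step",
    "structure_init",
    "structure_adapt",
]


class ZeroActivationError(ArithmeticError):
    """Total rule activation vanished; the defuzzified output is undefined."""


@dataclass(frozen=True)
class LearningConfig:
    """Training hyper-parameters.

    Learning rates are per parameter family (centers, widths, recurrent
    parameters, output weights). ``n_rules`` is the initial rule count;
    structure adaptation may add (firing below ``add_threshold``) or prune
    (epoch-mean firing below ``prune_threshold``) rules. ``sigma_min``
    floors the Gaussian widths; ``tol`` stops training early when the
    per-epoch loss improvement falls below it.
    """

    lr_center: float = 0.01
    lr_width: float = 0.01
    lr_lambda: float = 0.01
    lr_weight: float = 0.01
    epochs: int = 50
    n_rules: int = 10
    sigma_min: float = 1e-3
    add_threshold: float = 0.1
    prune_threshold: float = 1e-4
    adapt_structure: bool = True
    tol: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.lr_center, self.lr_width, self.lr_lambda, self.lr_weight):
            if r <= 0:
                raise ValueError("learning rates must be positive")
        if not (0 < self.add_threshold < 1 and 0 < self.prune_threshold < 1):
            raise ValueError("firing thresholds must lie in (0, 1)")


@dataclass
class RfnnParams:
    """All trainable parameters plus the input/output normalizers.

    ``centers`` and ``widths`` are (n_inputs, n_rules); ``lambdas`` is
    (n_rules,) in [0, 1]; ``weights`` is (n_rules, n_outputs). Inputs and
    outputs are min-max normalized to [0, 1] (ranges stored here), keeping
    the Gaussian operands bounded; a zero range is replaced by 1 so constant
    dimensions normalize to 0 and denormalize exactly.
    """

    centers: np.ndarray
    widths: np.ndarray
    lambdas: np.ndarray
    weights: np.ndarray
    x_min: np.ndarray
    x_range: np.ndarray
    y_min: np.ndarray
    y_range: np.ndarray
    sigma_min: float = 1e-3

    def __post_init__(self):
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")
        if np.any((self.lambdas < 0) | (self.lambdas > 1)):
            raise ValueError("lambdas must lie in [0, 1]")

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[0]

    @property
    def n_rules(self) -> int:
        return self.centers.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[1]

    def normalize_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_min) / self.x_range

    def normalize_y(self, Y: np.ndarray) -> np.ndarray:
        return (np.asarray(Y, dtype=float) - self.y_min) / self.y_range

    def denormalize_y(self, Yn: np.ndarray) -> np.ndarray:
        return Yn * self.y_range + self.y_min

    def copy(self) -> "RfnnParams":
        return RfnnParams(
            centers=self.centers.copy(), widths=self.widths.copy(),
            lambdas=self.lambdas.copy(), weights=self.weights.copy(),
            x_min=self.x_min.copy(), x_range=self.x_range.copy(),
            y_min=self.y_min.copy(), y_range=self.y_range.copy(),
            sigma_min=self.sigma_min,
        )

    def to_json(self, path) -> None:
        payload = {
            k: np.asarray(getattr(self, k)).tolist()
            for k in ("centers", "widths", "lambdas", "weights",
                      "x_min", "x_range", "y_min", "y_range")
        }
        payload["sigma_min"] = self.sigma_min
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RfnnParams":
        with open(path) as fh:
            payload = json.load(fh)
        sigma_min = payload.pop("sigma_min")
        arrays = {k: np.asarray(v, dtype=float) for k, v in payload.items()}
        return cls(sigma_min=sigma_min, **arrays)


# ---------------------------------------------------------------------------
# layer operations (normalized domain)
# ---------------------------------------------------------------------------

def fuzzify(x: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Layer-2 Gaussian memberships, shape (n_inputs, n_rules), in (0, 1]."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != centers.shape[0]:
        raise ValueError("input dimension does not match the rule grid")
    z = ((x[:, None] - centers) / widths) ** 2
    return np.exp(-z)


def rule_strength(a2: np.ndarray) -> np.ndarray:
    """Layer-3 fuzzy AND: product of a rule's memberships over the inputs."""
    return np.prod(a2, axis=0)


def recurrent_update(
    s: np.ndarray, u_prev: np.ndarray, lambdas: np.ndarray
) -> np.ndarray:
    """Internal feedback: convex mix of current firing and previous state."""
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any((lambdas < 0) | (lambdas > 1)):
        raise ValueError("lambda must lie in [0, 1]")
    return lambdas * s + (1.0 - lambdas) * u_prev


def defuzzify(u: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Layer-4 output: activation-weighted average of the rule weights."""
    total = u.sum()
    if total <= EPS_ACTIVATION:
        raise ZeroActivationError("total rule activation is zero")
    return (u @ weights) / total


def _forward_step(params: RfnnParams, u_prev: np.ndarray, x_norm: np.ndarray):
    """One time step; returns (y_norm, cache) with all layer intermediates."""
    a2 = fuzzify(x_norm, params.centers, params.widths)
    s = rule_strength(a2)
    u = recurrent_update(s, u_prev, params.lambdas)
    total = u.sum()
    y = None if total <= EPS_ACTIVATION else (u @ params.weights) / total
    return y, {"a2": a2, "s": s, "u": u, "total": total, "x": x_norm}


def forward_sequence(params: RfnnParams, X: np.ndarray) -> np.ndarray:
    """Run the network over a (T, n_inputs) sequence of raw inputs.

    The recurrent state starts at zero. If the total activation underflows
    at some step the previous output is held (at t = 0, the mean rule
    weight). Outputs are returned on the original (denormalized) scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xn = params.normalize_x(X)
    u = np.zeros(params.n_rules)
    y_hold = params.weights.mean(axis=0)
    out = np.empty((X.shape[0], params.n_outputs))
    for t in range(X.shape[0]):
        y, cache = _forward_step(params, u, Xn[t])
        u = cache["u"]
        if y is None:
            y = y_hold
        y_hold = y
        out[t] = y
    return params.denormalize_y(out)


# ---------------------------------------------------------------------------
# learning
# ---------------------------------------------------------------------------

def sample_loss(
    params: RfnnParams, u_prev: np.ndarray, x_norm: np.ndarray,
    y_norm_target: np.ndarray,
) -> float:
    """Squared-error cost 0.5 * sum_o (y_o - yhat_o)^2 for one step."""
    y, _ = _forward_step(params, u_prev, x_norm)
    if y is None:
        raise ZeroActivationError("total rule activation is zero")
    return 0.5 * float(np.sum((y - y_norm_target) ** 2))


def gradients(
    params: RfnnParams, u_prev: np.ndarray, x_norm: np.ndarray,
    y_norm_target: np.ndarray,
):
    """Analytic per-sample gradients of the cost w.r.t. all parameters.

    ``u_prev`` (the recurrent state one step back) is held constant — the
    depth-1 truncation under which the per-iteration update rules are
    exact. Returns ``(grads, cache)`` where grads has keys ``centers``,
    ``widths``, ``lambdas``, ``weights``.
    """
    y, cache = _forward_step(params, u_prev, x_norm)
    if y is None:
        raise ZeroActivationError("total rule activation is zero")
    a2, s, u, total = cache["a2"], cache["s"], cache["u"], cache["total"]
    err = y - y_norm_target  # (n_outputs,)

    g_w = np.outer(u / total, err)  # dE/dw_jo
    # dE/du_j through the normalized weighted average
    g_u = ((params.weights - y) @ err) / total  # (n_rules,)
    g_lam = g_u * (s - u_prev)
    g_s = g_u * params.lambdas  # dE/ds_j
    # dE/dm and dE/dsigma via g_s * s = dE/da2 * a2 (no division by a2)
    diff = cache["x"][:, None] - params.centers  # (n_inputs, n_rules)
    common = (g_s * s) * 2.0 * diff / params.widths**2
    g_m = common
    g_sg = (g_s * s) * 2.0 * diff**2 / params.widths**3

    grads = {"centers": g_m, "widths": g_sg, "lambdas": g_lam, "weights": g_w}
    if not all(np.all(np.isfinite(g)) for g in grads.values()):
        raise FloatingPointError("non-finite gradient encountered")
    cache["y"] = y
    cache["err"] = err
    return grads, cache


def grad_step(
    params: RfnnParams, u_prev: np.ndarray, x_norm: np.ndarray,
    y_norm_target: np.ndarray, cfg: LearningConfig,
):
    """One in-place gradient-descent update; returns the forward cache.

    Constraints are re-imposed after the update: lambdas clipped to [0, 1],
    widths floored at ``sigma_min``.
    """
    grads, cache = gradients(params, u_prev, x_norm, y_norm_target)
    params.centers -= cfg.lr_center * grads["centers"]
    params.widths -= cfg.lr_width * grads["widths"]
    params.lambdas -= cfg.lr_lambda * grads["lambdas"]
    params.weights -= cfg.lr_weight * grads["weights"]
    np.clip(params.lambdas, 0.0, 1.0, out=params.lambdas)
    np.maximum(params.widths, params.sigma_min, out=params.widths)
    return cache


def _minmax(A: np.ndarray):
    lo = A.min(axis=0)
    rng = A.max(axis=0) - lo
    rng = np.where(rng > 0, rng, 1.0)
    return lo, rng


def structure_init(
    X: np.ndarray, Y: np.ndarray, n_rules: int, seed: int = 0,
    sigma_min: float = 1e-3,
) -> RfnnParams:
    """Generate the initial rule base by k-means clustering.

    Inputs and targets are min-max normalized; each cluster becomes one
    rule with center at the cluster mean, width proportional to the
    per-dimension cluster standard deviation (floored at ``sigma_min``),
    output weights the mean normalized target of the cluster, and
    lambda = 0.5 (neutral memory).

    Widths are scaled by kappa = sqrt(n_inputs): the product AND multiplies
    one membership per input, so a point one cluster-SD away in every
    dimension then fires at e^-1 regardless of dimensionality. Without this
    calibration, firing strengths collapse exponentially with the input
    count (e^-12 for 12 features) and the add/prune thresholds, which are
    O(0.1) quantities, lose meaning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if not 1 <= n_rules <= X.shape[0]:
        raise ValueError("need 1 <= n_rules <= n_samples")
    x_min, x_range = _minmax(X)
    y_min, y_range = _minmax(Y)
    Xn = (X - x_min) / x_range
    Yn = (Y - y_min) / y_range

    if n_rules == 1:
        labels = np.zeros(X.shape[0], dtype=int)
        centers = Xn.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=n_rules, n_init=5, random_state=seed)
        labels = km.fit_predict(Xn)
        centers = km.cluster_centers_

    n_in, n_out = X.shape[1], Y.shape[1]
    m = np.empty((n_in, n_rules))
    sg = np.empty((n_in, n_rules))
    w = np.empty((n_rules, n_out))
    for j in range(n_rules):
        members = Xn[labels == j]
        m[:, j] = centers[j]
        sg[:, j] = np.maximum(
            members.std(axis=0) if len(members) else 0.0, sigma_min
        )
        w[j] = Yn[labels == j].mean(axis=0) if np.any(labels == j) else Yn.mean(axis=0)
    # widths below ~5% of the normalized range make rules needle-thin;
    # kappa compensates the product AND for the input dimensionality
    kappa = np.sqrt(n_in)
    sg = np.maximum(sg, 0.05) * kappa
    return RfnnParams(
        centers=m, widths=sg, lambdas=np.full(n_rules, 0.5), weights=w,
        x_min=x_min, x_range=x_range, y_min=y_min, y_range=y_range,
        sigma_min=sigma_min,
    )


def structure_adapt(
    params: RfnnParams, x_norm: np.ndarray, y_pred_norm: np.ndarray,
    add_threshold: float,
) -> bool:
    """Add a rule at ``x_norm`` if no existing rule fires above threshold.

    The new rule's widths come from the per-dimension distance to the
    nearest existing center (floored at 5% of the normalized range and
    scaled by sqrt(n_inputs), the same product-AND calibration as in
    :func:`structure_init`), its weights from the current prediction, and
    its lambda starts neutral at 0.5. Returns True when a rule was added.
    Pruning is handled at epoch boundaries by the trainer.
    """
    s = rule_strength(fuzzify(x_norm, params.centers, params.widths))
    if s.max() >= add_threshold:
        return False
    dist = np.abs(x_norm[:, None] - params.centers)
    nearest = np.argmin(dist.max(axis=0))
    kappa = np.sqrt(params.n_inputs)
    new_sigma = np.maximum(kappa * np.maximum(dist[:, nearest], 0.05), 0.05)
    params.centers = np.column_stack([params.centers, x_norm])
    params.widths = np.column_stack([params.widths, new_sigma])
    params.lambdas = np.append(params.lambdas, 0.5)
    params.weights = np.vstack([params.weights, y_pred_norm])
    return True


def _as_sequences(A) -> list:
    if isinstance(A, (list, tuple)):
        return [np.atleast_2d(np.asarray(a, dtype=float)) for a in A]
    return [np.atleast_2d(np.asarray(A, dtype=float))]


class RecurrentFuzzyRegression:
    """Multi-output RFNN regression model built from aligned data.

    Parameters
    ----------
    endog : array or list of arrays
        Targets, (T, n_outputs) — e.g. 3-D hand position in cm. A list is
        treated as independent sequences: the recurrent state resets at
        each sequence start (one sequence per movement segment).
    exog : array or list of arrays
        Inputs, (T, n_inputs) — e.g. the 12-column EMG feature matrix.

    Examples
    --------
    >>> model = RecurrentFuzzyRegression(positions, features)
    >>> res = model.fit(LearningConfig(epochs=30, seed=1))
    >>> y_hat = res.predict(features_test)
    """

    def __init__(self, endog, exog):
        self.endog = _as_sequences(endog)
        self.exog = _as_sequences(exog)
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog sequence counts differ")
        for Y, X in zip(self.endog, self.exog):
            if Y.shape[0] != X.shape[0]:
                raise ValueError("unaligned sequence lengths")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, target_cols, feature_cols, sequence_col=None
    ) -> "RecurrentFuzzyRegression":
        """Build from a tidy frame, optionally splitting on a sequence id."""
        if sequence_col is None:
            return cls(df[list(target_cols)].values, df[list(feature_cols)].values)
        groups = [g for _, g in df.groupby(sequence_col, sort=False)]
        return cls(
            [g[list(target_cols)].values for g in groups],
            [g[list(feature_cols)].values for g in groups],
        )

    def fit(self, cfg: LearningConfig | None = None) -> "RFNNResults":
        """Train by structure learning plus per-sample gradient descent.

        k-means structure initialisation, then per epoch: the recurrent
        state is reset at each sequence start, every sample takes one
        truncated-gradient step followed by a rule-addition check, and
        rules whose epoch-mean firing falls below the prune threshold are
        removed at the epoch boundary (never below one rule).
        """
        cfg = cfg or LearningConfig()
        Xc = np.vstack(self.exog)
        Yc = np.vstack(self.endog)
        params = structure_init(Xc, Yc, cfg.n_rules, cfg.seed, cfg.sigma_min)
        Xn = [params.normalize_x(X) for X in self.exog]
        Yn = [params.normalize_y(Y) for Y in self.endog]

        loss_history = []
        rules_history = []
        for epoch in range(cfg.epochs):
            sse = 0.0
            n_steps = 0
            fire_sum = np.zeros(params.n_rules)
            for Xs, Ys in zip(Xn, Yn):
                u = np.zeros(params.n_rules)
                y_hold = params.weights.mean(axis=0)
                for t in range(Xs.shape[0]):
                    x, yt = Xs[t], Ys[t]
                    try:
                        cache = grad_step(params, u, x, yt, cfg)
                        u = cache["u"]
                        y_hold = cache["y"]
                        sse += float(np.sum(cache["err"] ** 2))
                        s_now = cache["s"]
                    except ZeroActivationError:
                        # undefined output: hold the prediction and recover
                        # the dead state — add a rule at x, or (if one
                        # already covers x but its memory froze at zero)
                        # restart the recurrence from the current firing
                        if structure_adapt(params, x, y_hold, 1.0):
                            u = np.append(u, 0.5)
                            fire_sum = np.append(fire_sum, 0.0)
                        s_now = rule_strength(
                            fuzzify(x, params.centers, params.widths)
                        )
                        u = np.maximum(u, s_now)
                    fire_sum[: len(s_now)] += s_now
                    n_steps += 1
                    if (
                        cfg.adapt_structure
                        and s_now.max() < cfg.add_threshold
                        and structure_adapt(params, x, y_hold, cfg.add_threshold)
                    ):
                        u = np.append(u, 0.5 * 1.0)  # lambda * s at own center
                        fire_sum = np.append(fire_sum, 1.0)
            # epoch-boundary pruning of rules that essentially never fired
            if cfg.adapt_structure and params.n_rules > 1:
                mean_fire = fire_sum / max(n_steps, 1)
                keep = mean_fire >= cfg.prune_threshold
                if not keep.any():
                    keep[np.argmax(mean_fire)] = True
                if not keep.all():
                    params.centers = params.centers[:, keep]
                    params.widths = params.widths[:, keep]
                    params.lambdas = params.lambdas[keep]
                    params.weights = params.weights[keep]
            loss_history.append(sse / (2.0 * max(n_steps, 1)))
            rules_history.append(params.n_rules)
            if (
                cfg.tol > 0 and epoch > 0
                and loss_history[-2] - loss_history[-1] < cfg.tol
            ):
                break
        return RFNNResults(self, params, cfg, loss_history, rules_history)


class RFNNResults:
    """Fitted-RFNN container: parameters, diagnostics, prediction, summary."""

    def __init__(self, model, params, cfg, loss_history, rules_history):
        self.model = model
        self.params = params
        self.config = cfg
        self.loss_history = list(loss_history)
        self.rules_history = list(rules_history)

    @property
    def n_rules(self) -> int:
        return self.params.n_rules

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]

    def predict(self, exog):
        """Predict targets for raw inputs; lists map to per-sequence outputs
        with the recurrent state reset at each sequence start."""
        if isinstance(exog, (list, tuple)):
            return [forward_sequence(self.params, X) for X in exog]
        return forward_sequence(self.params, np.asarray(exog, dtype=float))

    @property
    def fittedvalues(self):
        return self.predict(self.model.exog)

    def save(self, path) -> None:
        self.params.to_json(path)

    def summary(self) -> SimpleTable:
        p = self.params
        rows = [
            ("No. inputs", p.n_inputs),
            ("No. outputs", p.n_outputs),
            ("No. rules", p.n_rules),
            ("Epochs run", len(self.loss_history)),
            ("Final loss (norm. MSE/2)", f"{self.final_loss:.6g}"),
            ("lambda range", f"[{p.lambdas.min():.3f}, {p.lambdas.max():.3f}]"),
            ("width range", f"[{p.widths.min():.3f}, {p.widths.max():.3f}]"),
        ]
        return SimpleTable(
            [[str(v)] for _, v in rows],
            headers=["value"],
            stubs=[k for k, _ in rows],
            title="Recurrent Fuzzy Neural Network Results",
        )

    def plot_prediction(self, actual, predicted=None, ax=None):
        """Overlay predicted vs actual trajectories per output axis."""
        import matplotlib.pyplot as plt

        actual = np.atleast_2d(np.asarray(actual, dtype=float))
        if predicted is None:
            raise ValueError("pass the predicted array to plot")
        n_out = actual.shape[1]
        if ax is None:
            _, ax = plt.subplots(n_out, 1, sharex=True, squeeze=False)
            ax = ax[:, 0]
        for o, a in enumerate(np.atleast_1d(ax)):
            a.plot(actual[:, o], label="actual")
            a.plot(predicted[:, o], "--", label="predicted")
            a.set_ylabel(f"axis {o}")
        np.atleast_1d(ax)[0].legend(loc="best")
        return ax
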