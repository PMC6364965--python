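"""Single-layer LSTM sequence regressor with masked loss, plus a static baseline.

The network maps a monthly predictor sequence (seven reflectance bands + four
climate drivers, D=11) to monthly NEE.  The loss is computed only at months
where a quality-controlled NEE observation exists, so the recurrence runs over
the full predictor record while gradients flow only from observed months.

The forward/backward passes are written directly in numpy (exact analytic
BPTT) and are vectorized over a leading ensemble-member axis and a site axis,
so an ensemble of M random initializations trains in one set of stacked
3-D matmuls.  Optimization is full-batch Adam with site-wise early stopping
on a held-out evaluation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor

PREDICTORS = [
    "blue", "green", "red", "nir", "swir1", "swir2", "tir",
    "tair", "precip", "rg", "vpd",
]
N_PREDICTORS = len(PREDICTORS)


class DimensionError(ValueError):
    pass


class UndefinedLossError(ValueError):
    pass


class DivergenceError(RuntimeError):
    def __init__(self, iteration: int):
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration


@dataclass
class SequenceSample:
    """One site's aligned (predictors, target, observation mask) triple."""

    site_id: str
    X: np.ndarray      # (T, D) complete predictor matrix
    y: np.ndarray      # (T,) NEE, NaN where unobserved
    mask: np.ndarray   # (T,) bool, True where NEE observed post-QC


@dataclass
class Hyperparams:
    """Training knobs; the default grid is lr {0.1, 0.01} x hidden {10, 20, 30}
    x dropout {0, 0.5} with 500-iteration early-stopping patience."""

    learning_rate: float = 0.01
    hidden_units: int = 10
    dropout: float = 0.0
    patience: int = 500
    max_iterations: int = 5000
    eval_frac: float = 0.2


DEFAULT_GRID = [
    Hyperparams(learning_rate=lr, hidden_units=h, dropout=d)
    for h in (10, 20, 30)
    for lr in (0.01, 0.1)
    for d in (0.0, 0.5)
]


@dataclass
class LSTMWeights:
    """Gate weights in a single (D+H) x 4H block layout; gate order i, f, g, o."""

    wx: np.ndarray      # (D, 4H)
    wh: np.ndarray      # (H, 4H)
    b: np.ndarray       # (4H,)
    w_out: np.ndarray   # (H,)
    b_out: float
    init_seed: int = 0

    @property
    def hidden_units(self) -> int:
        return self.wh.shape[0]


@dataclass
class Standardizer:
    """Z-scaling fitted on training folds only; target stats use observed months."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float

    @classmethod
    def fit(cls, samples: Sequence[SequenceSample]) -> "Standardizer":
        X = np.concatenate([s.X for s in samples], axis=0)
        yobs = np.concatenate([s.y[s.mask] for s in samples])
        x_sd = X.std(axis=0)
        x_sd[x_sd == 0] = 1.0
        y_sd = yobs.std()
        return cls(X.mean(axis=0), x_sd, float(yobs.mean()), float(y_sd if y_sd > 0 else 1.0))

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_sd

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_sd

    def inverse_y(self, y_std: np.ndarray) -> np.ndarray:
        return y_std * self.y_sd + self.y_mean


# ---------------------------------------------------------------------------
# stacked LSTM core: member axis M, site axis S, time axis T


def _init_stacked(n_members: int, d: int, h: int, seeds: Sequence[int]) -> dict:
    wx = np.empty((n_members, d, 4 * h))
    wh = np.empty((n_members, h, 4 * h))
    b = np.zeros((n_members, 4 * h))
    w_out = np.empty((n_members, h))
    b_out = np.zeros(n_members)
    for m, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        lim_x = 1.0 / np.sqrt(d)
        lim_h = 1.0 / np.sqrt(h)
        wx[m] = rng.uniform(-lim_x, lim_x, (d, 4 * h))
        wh[m] = rng.uniform(-lim_h, lim_h, (h, 4 * h))
        w_out[m] = rng.uniform(-lim_h, lim_h, h)
        b[m, h : 2 * h] = 1.0  # forget-gate bias
    return {"wx": wx, "wh": wh, "b": b, "w_out": w_out, "b_out": b_out}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _forward_stacked(X: np.ndarray, p: dict, drop_mask: Optional[np.ndarray] = None):
    """X: (S, T, D); params stacked over M.  Returns yhat (M, S, T) and cache."""
    S, T, D = X.shape
    M = p["wx"].shape[0]
    H = p["wh"].shape[1]
    # input contribution for all timesteps at once: (M, S*T, 4H)
    xp = np.matmul(X.reshape(1, S * T, D), p["wx"]).reshape(M, S, T, 4 * H)
    xp += p["b"][:, None, None, :]

    gates = np.empty((M, S, T, 4 * H))
    cs = np.empty((M, S, T, H))
    hs = np.empty((M, S, T, H))
    h = np.zeros((M, S, H))
    c = np.zeros((M, S, H))
    for t in range(T):
        z = xp[:, :, t, :] + np.matmul(h, p["wh"])
        i = _sigmoid(z[..., 0 * H : 1 * H])
        f = _sigmoid(z[..., 1 * H : 2 * H])
        g = np.tanh(z[..., 2 * H : 3 * H])
        o = _sigmoid(z[..., 3 * H : 4 * H])
        c = f * c + i * g
        h = o * np.tanh(c)
        gates[:, :, t, 0 * H : 1 * H] = i
        gates[:, :, t, 1 * H : 2 * H] = f
        gates[:, :, t, 2 * H : 3 * H] = g
        gates[:, :, t, 3 * H : 4 * H] = o
        cs[:, :, t, :] = c
        hs[:, :, t, :] = h

    h_eff = hs if drop_mask is None else hs * drop_mask[:, None, None, :]
    yhat = np.einsum("msth,mh->mst", h_eff, p["w_out"]) + p["b_out"][:, None, None]
    cache = {"X": X, "gates": gates, "cs": cs, "hs": hs, "drop_mask": drop_mask, "p": p}
    return yhat, cache


def _backward_stacked(cache: dict, dY: np.ndarray) -> dict:
    """Exact gradients of sum(dY * yhat) w.r.t. all stacked parameters."""
    X, gates, cs, hs, p = cache["X"], cache["gates"], cache["cs"], cache["hs"], cache["p"]
    drop_mask = cache["drop_mask"]
    S, T, D = X.shape
    M, _, H4 = p["wx"].shape
    H = H4 // 4

    h_eff = hs if drop_mask is None else hs * drop_mask[:, None, None, :]
    d_wout = np.einsum("mst,msth->mh", dY, h_eff)
    d_bout = dY.sum(axis=(1, 2))
    dH_out = dY[..., None] * p["w_out"][:, None, None, :]
    if drop_mask is not None:
        dH_out = dH_out * drop_mask[:, None, None, :]

    dZ = np.empty((M, S, T, 4 * H))
    dh_next = np.zeros((M, S, H))
    dc_next = np.zeros((M, S, H))
    whT = np.swapaxes(p["wh"], 1, 2)
    for t in range(T - 1, -1, -1):
        i = gates[:, :, t, 0 * H : 1 * H]
        f = gates[:, :, t, 1 * H : 2 * H]
        g = gates[:, :, t, 2 * H : 3 * H]
        o = gates[:, :, t, 3 * H : 4 * H]
        c = cs[:, :, t, :]
        c_prev = cs[:, :, t - 1, :] if t > 0 else np.zeros((M, S, H))
        tanh_c = np.tanh(c)

        dh = dH_out[:, :, t, :] + dh_next
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c**2) + dc_next
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f

        dzi = di * i * (1.0 - i)
        dzf = df * f * (1.0 - f)
        dzg = dg * (1.0 - g**2)
        dzo = do * o * (1.0 - o)
        dz = np.concatenate([dzi, dzf, dzg, dzo], axis=-1)
        dZ[:, :, t, :] = dz
        dh_next = np.matmul(dz, whT)

    d_wx = np.einsum("std,mstk->mdk", X, dZ)
    h_prev = np.concatenate([np.zeros((M, S, 1, H)), hs[:, :, :-1, :]], axis=2)
    d_wh = np.einsum("msth,mstk->mhk", h_prev, dZ)
    d_b = dZ.sum(axis=(1, 2))
    return {"wx": d_wx, "wh": d_wh, "b": d_b, "w_out": d_wout, "b_out": d_bout}


def _stack_single(w: LSTMWeights) -> dict:
    return {
        "wx": w.wx[None], "wh": w.wh[None], "b": w.b[None],
        "w_out": w.w_out[None], "b_out": np.array([w.b_out]),
    }


def lstm_forward(X: np.ndarray, weights: LSTMWeights) -> np.ndarray:
    """Run the LSTM recurrences over one sequence; returns (T,) predictions.

    Initial hidden and cell states are zero; the hidden state at each month is
    mapped to a scalar prediction by the linear output layer.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != weights.wx.shape[0]:
        raise DimensionError(
            f"X must be (T, {weights.wx.shape[0]}); got {X.shape}"
        )
    yhat, _ = _forward_stacked(X[None], _stack_single(weights))
    return yhat[0, 0]


def masked_mse(pred: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over observed months only."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise UndefinedLossError("loss undefined: no observed months in mask")
    d = np.asarray(pred)[mask] - np.asarray(y)[mask]
    return float(np.mean(d * d))


def loss_and_grads(
    X: np.ndarray, y: np.ndarray, mask: np.ndarray, weights: LSTMWeights
) -> tuple[float, LSTMWeights]:
    """Masked MSE and its exact analytic gradient for one sequence.

    Used directly by the finite-difference gradient check; training uses the
    same stacked kernels internally.
    """
    p = _stack_single(weights)
    yhat, cache = _forward_stacked(np.asarray(X, dtype=float)[None], p)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise UndefinedLossError("loss undefined: no observed months in mask")
    y0 = np.where(mask, y, 0.0)
    resid = (yhat[0, 0] - y0) * mask
    loss = float(np.sum(resid**2) / mask.sum())
    dY = (2.0 * resid / mask.sum())[None, None, :]
    g = _backward_stacked(cache, dY)
    grad = LSTMWeights(
        wx=g["wx"][0], wh=g["wh"][0], b=g["b"][0],
        w_out=g["w_out"][0], b_out=float(g["b_out"][0]),
        init_seed=weights.init_seed,
    )
    return loss, grad


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingHistory:
    train_loss: np.ndarray      # (n_iter, M)
    eval_loss: np.ndarray       # (n_iter, M)
    best_iteration: np.ndarray  # (M,)
    eval_sites: list[str] = field(default_factory=list)


@dataclass
class TrainedEnsemble:
    """Fitted members (differing only in init seed) plus shared metadata."""

    members: list[LSTMWeights]
    hp: Hyperparams
    standardizer: Standardizer
    history: TrainingHistory

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict(self, samples: Sequence[SequenceSample]) -> np.ndarray:
        """Member predictions on the NEE scale: (M, S, T)."""
        X = np.stack([self.standardizer.transform_x(s.X) for s in samples])
        p = _stack_members(self.members)
        yhat, _ = _forward_stacked(X, p)
        return self.standardizer.inverse_y(yhat)


def _stack_members(members: Sequence[LSTMWeights]) -> dict:
    return {
        "wx": np.stack([w.wx for w in members]),
        "wh": np.stack([w.wh for w in members]),
        "b": np.stack([w.b for w in members]),
        "w_out": np.stack([w.w_out for w in members]),
        "b_out": np.array([w.b_out for w in members]),
    }


def _unstack_members(p: dict, seeds: Sequence[int]) -> list[LSTMWeights]:
    return [
        LSTMWeights(
            wx=p["wx"][m].copy(), wh=p["wh"][m].copy(), b=p["b"][m].copy(),
            w_out=p["w_out"][m].copy(), b_out=float(p["b_out"][m]),
            init_seed=int(seeds[m]),
        )
        for m in range(p["wx"].shape[0])
    ]


def _site_split(samples: Sequence[SequenceSample], eval_frac: float, rng: np.random.Generator):
    """Site-wise split: whole sites held out of gradient updates."""
    n = len(samples)
    n_eval = max(1, int(round(eval_frac * n))) if n > 1 else 0
    order = rng.permutation(n)
    eval_idx = set(order[:n_eval].tolist())
    train = [s for i, s in enumerate(samples) if i not in eval_idx]
    evals = [s for i, s in enumerate(samples) if i in eval_idx]
    return train, evals


def _masked_batch(samples: Sequence[SequenceSample], std: Standardizer):
    X = np.stack([std.transform_x(s.X) for s in samples])
    mask = np.stack([s.mask for s in samples]).astype(bool)
    y = np.stack([np.where(s.mask, std.transform_y(np.where(s.mask, s.y, 0.0)), 0.0) for s in samples])
    return X, y, mask


def _train_members(
    samples: Sequence[SequenceSample],
    hp: Hyperparams,
    n_members: int,
    seed: int,
    standardizer: Optional[Standardizer] = None,
) -> TrainedEnsemble:
    if len(samples) < 2:
        raise ValueError("training requires at least 2 sites")
    master = np.random.SeedSequence(seed)
    split_seed, drop_seed, *member_seeds = master.generate_state(2 + n_members)
    rng_split = np.random.default_rng(split_seed)
    rng_drop = np.random.default_rng(drop_seed)

    train, evals = _site_split(samples, hp.eval_frac, rng_split)
    std = standardizer if standardizer is not None else Standardizer.fit(train)
    Xt, yt, mt = _masked_batch(train, std)
    Xe, ye, me = _masked_batch(evals, std) if evals else (None, None, None)
    n_train_obs = mt.sum()
    if n_train_obs == 0:
        raise UndefinedLossError("no observed months in training split")

    D = Xt.shape[2]
    H = hp.hidden_units
    p = _init_stacked(n_members, D, H, member_seeds)
    m1 = {k: np.zeros_like(v) for k, v in p.items()}
    m2 = {k: np.zeros_like(v) for k, v in p.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8

    best_loss = np.full(n_members, np.inf)
    best_iter = np.zeros(n_members, dtype=int)
    best_p = {k: v.copy() for k, v in p.items()}
    bad = np.zeros(n_members, dtype=int)
    active = np.ones(n_members, dtype=bool)
    tr_hist, ev_hist = [], []

    for it in range(1, hp.max_iterations + 1):
        drop_mask = None
        if hp.dropout > 0:
            drop_mask = (rng_drop.random((n_members, H)) >= hp.dropout) / (1.0 - hp.dropout)
        yhat, cache = _forward_stacked(Xt, p, drop_mask=drop_mask)
        resid = (yhat - yt[None]) * mt[None]
        train_loss = (resid**2).sum(axis=(1, 2)) / n_train_obs
        if not np.all(np.isfinite(train_loss[active])):
            raise DivergenceError(it)
        dY = 2.0 * resid / n_train_obs
        g = _backward_stacked(cache, dY)

        # Adam step (frozen members keep their parameters)
        act = active.astype(float)
        for k in p:
            sl = (slice(None),) + (None,) * (p[k].ndim - 1)
            m1[k] = b1 * m1[k] + (1 - b1) * g[k]
            m2[k] = b2 * m2[k] + (1 - b2) * g[k] ** 2
            mhat = m1[k] / (1 - b1**it)
            vhat = m2[k] / (1 - b2**it)
            p[k] = p[k] - hp.learning_rate * act[sl] * mhat / (np.sqrt(vhat) + eps)

        if Xe is not None:
            ye_hat, _ = _forward_stacked(Xe, p)
            eresid = (ye_hat - ye[None]) * me[None]
            eval_loss = (eresid**2).sum(axis=(1, 2)) / max(me.sum(), 1)
        else:
            eval_loss = train_loss
        if not np.all(np.isfinite(eval_loss[active])):
            raise DivergenceError(it)
        tr_hist.append(train_loss.copy())
        ev_hist.append(eval_loss.copy())

        improved = active & (eval_loss < best_loss)
        for m in np.flatnonzero(improved):
            best_loss[m] = eval_loss[m]
            best_iter[m] = it
            for k in p:
                best_p[k][m] = p[k][m]
            bad[m] = 0
        bad[active & ~improved] += 1
        active &= bad <= hp.patience
        if not active.any():
            break

    history = TrainingHistory(
        train_loss=np.array(tr_hist), eval_loss=np.array(ev_hist),
        best_iteration=best_iter, eval_sites=[s.site_id for s in evals],
    )
    return TrainedEnsemble(
        members=_unstack_members(best_p, member_seeds), hp=hp,
        standardizer=std, history=history,
    )


def train_lstm(
    samples: Sequence[SequenceSample],
    hp: Hyperparams,
    seed: int,
    standardizer: Optional[Standardizer] = None,
) -> tuple[LSTMWeights, TrainingHistory]:
    """Train a single LSTM with Adam, masked loss and site-wise early stopping.

    An iteration is one full pass over the training sites (full batch);
    training stops when the evaluation loss has not improved for ``patience``
    consecutive iterations, and the best-iteration weights are returned.
    """
    ens = _train_members(samples, hp, n_members=1, seed=seed, standardizer=standardizer)
    return ens.members[0], ens.history


def fit_ensemble(
    samples: Sequence[SequenceSample],
    hp: Hyperparams,
    n_members: int,
    seed: int,
    standardizer: Optional[Standardizer] = None,
) -> TrainedEnsemble:
    """Train ``n_members`` LSTMs differing only in weight-initialization seed."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    return _train_members(samples, hp, n_members=n_members, seed=seed, standardizer=standardizer)


def grid_search(
    samples: Sequence[SequenceSample],
    grid: Sequence[Hyperparams],
    seed: int,
) -> Hyperparams:
    """Pick the hyperparameters with the lowest final evaluation loss.

    Ties break toward the smaller network: (hidden_units, learning_rate,
    dropout) ascending.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    scored = []
    for j, hp in enumerate(grid):
        _, hist = train_lstm(samples, hp, seed=seed)
        best = float(np.min(hist.eval_loss[:, 0]))
        scored.append((best, hp.hidden_units, hp.learning_rate, hp.dropout, j, hp))
    scored.sort(key=lambda r: r[:4])
    return scored[0][5]


def train_static_baseline(
    X: np.ndarray, y: np.ndarray, seed: int, n_estimators: int = 200
) -> RandomForestRegressor:
    """Random-forest regression on instantaneous predictor rows (no memory).

    Rows must come from observed months only; predictions are month-by-month.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("training rows must be a non-empty 2-D array")
    # canonical row order: bootstrap draws depend on row positions, so sorting
    # makes the fit invariant to the order rows were collected in
    order = np.lexsort(np.vstack([X.T, y[None]]))
    rf = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    rf.fit(X[order], y[order])
    return rf


def build_samples(
    panels: dict[str, "pd.DataFrame"],
    qc_threshold: float = 0.8,
) -> list[SequenceSample]:
    """Assemble SequenceSamples from preprocessed panels.

    NEE is masked where quality <= threshold (strict) or missing; predictor
    rows must be complete (reflectance gap-filled beforehand).
    """
    from .preprocess import qc_filter

    samples = []
    for sid, panel in panels.items():
        filtered = qc_filter(panel, threshold=qc_threshold)
        X = filtered[PREDICTORS].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError(f"site {sid}: predictor matrix has gaps; gap-fill first")
        y = filtered["nee"].to_numpy(dtype=float)
        mask = ~np.isnan(y)
        samples.append(SequenceSample(site_id=sid, X=X, y=y, mask=mask))
    return samples
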