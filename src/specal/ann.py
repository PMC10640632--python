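"""Linear feed-forward network calibration.

A three-layer network (spectral inputs -> hidden -> component outputs) with
identity ("purelin") transfer functions throughout, trained by full-batch
gradient descent on mean squared error. With linear transfer the network is
exactly an affine map whose effective rank is bounded by the hidden width;
it is kept here because such shallow linear networks are the classical
neural treatment of multicomponent UV calibration.

Two presets are provided:

``legacy``
    4 hidden units, learning rate 0.1, 50 epochs — the historically used
    toolbox configuration for this assay.
``accuracy``
    5 hidden units (one per analyte, so the affine map can reach full rank)
    and training to convergence; used when near-exact recovery on clean
    linear data is required.

Inputs are mean-centered and scaled by the pooled standard deviation of the
calibration absorbances; targets are scaled per component to [-1, 1] from
the calibration min/max. Without such scaling, gradient descent at learning
rate 0.1 on raw AU x ug/mL scales diverges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PRESETS: dict[str, dict] = {
    "legacy": {"n_hidden": 4, "lr": 0.1, "epochs": 50, "tol": None},
    "accuracy": {"n_hidden": 5, "lr": 0.05, "epochs": 30000, "tol": 1e-14},
}


@dataclass(frozen=True)
class AnnScaler:
    """Input standardization and per-target [-1, 1] range scaling."""

    x_mean: np.ndarray
    x_scale: float
    y_min: np.ndarray
    y_max: np.ndarray

    def scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_scale

    def scale_y(self, Y: np.ndarray) -> np.ndarray:
        return 2.0 * (Y - self.y_min) / (self.y_max - self.y_min) - 1.0

    def unscale_y(self, Ys: np.ndarray) -> np.ndarray:
        return (Ys + 1.0) / 2.0 * (self.y_max - self.y_min) + self.y_min


def fit_scaler(X: np.ndarray, Y: np.ndarray) -> AnnScaler:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    spread = Y.max(axis=0) - Y.min(axis=0)
    if np.any(spread <= 0):
        raise ValueError("every target column needs a positive range for scaling")
    scale = X.std()
    if scale == 0:
        raise ValueError("calibration spectra have zero variance")
    return AnnScaler(x_mean=X.mean(axis=0), x_scale=float(scale),
                     y_min=Y.min(axis=0), y_max=Y.max(axis=0))


@dataclass(frozen=True)
class AnnModel:
    """Weights, biases, scaler and training configuration."""

    W1: np.ndarray  # hidden x inputs
    b1: np.ndarray  # hidden
    W2: np.ndarray  # outputs x hidden
    b2: np.ndarray  # outputs
    scaler: AnnScaler | None
    config: dict = field(default_factory=dict)

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_out(self) -> int:
        return self.W2.shape[0]

    def forward_scaled(self, Xs: np.ndarray) -> np.ndarray:
        """Layered forward pass on already-scaled inputs."""
        H = Xs @ self.W1.T + self.b1
        return H @ self.W2.T + self.b2

    def as_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Collapse the purelin network to a single affine map (A, c)."""
        A = self.W2 @ self.W1
        c = self.W2 @ self.b1 + self.b2
        return A, c


def init_ann(n_in: int, n_hidden: int = 4, n_out: int = 5, seed: int = 0) -> AnnModel:
    """Seeded symmetric small-weight initialization; biases zero."""
    if min(n_in, n_hidden, n_out) < 1:
        raise ValueError("all layer sizes must be positive")
    rng = np.random.default_rng(seed)
    s1 = 1.0 / np.sqrt(n_in)
    s2 = 1.0 / np.sqrt(n_hidden)
    return AnnModel(
        W1=rng.uniform(-s1, s1, size=(n_hidden, n_in)),
        b1=np.zeros(n_hidden),
        W2=rng.uniform(-s2, s2, size=(n_out, n_hidden)),
        b2=np.zeros(n_out),
        scaler=None,
        config={"seed": seed, "n_hidden": n_hidden},
    )


def _loss_and_grads(model: AnnModel, Xs: np.ndarray, Ys: np.ndarray):
    n, m = Ys.shape
    with np.errstate(over="ignore", invalid="ignore"):  # divergence handled upstream
        H = Xs @ model.W1.T + model.b1
        E = H @ model.W2.T + model.b2 - Ys
        loss = float(np.mean(E**2))
        dY = 2.0 * E / (n * m)
        gW2 = dY.T @ H
        gb2 = dY.sum(axis=0)
        dH = dY @ model.W2
        gW1 = dH.T @ Xs
        gb1 = dH.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def train_ann(
    model: AnnModel,
    X: np.ndarray,
    Y: np.ndarray,
    epochs: int = 50,
    lr: float = 0.1,
    tol: float | None = None,
) -> tuple[AnnModel, np.ndarray]:
    """Full-batch gradient descent on MSE; returns (model, loss trace).

    X, Y are raw calibration matrices; the scaler is fitted here and stored.
    The loss trace holds one entry per completed epoch (fewer if ``tol``
    stops training early). Raises if the loss diverges to non-finite values,
    which on these problems indicates unscaled data or too large a rate.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    scaler = fit_scaler(X, Y)
    Xs = scaler.scale_x(X)
    Ys = scaler.scale_y(Y)
    cur = replace(model, scaler=scaler)
    trace = []
    for _ in range(epochs):
        loss, (gW1, gb1, gW2, gb2) = _loss_and_grads(cur, Xs, Ys)
        if not np.isfinite(loss):
            raise FloatingPointError(
                "training diverged (non-finite loss); check input/target "
                "scaling or reduce the learning rate"
            )
        cur = replace(
            cur,
            W1=cur.W1 - lr * gW1,
            b1=cur.b1 - lr * gb1,
            W2=cur.W2 - lr * gW2,
            b2=cur.b2 - lr * gb2,
        )
        trace.append(_loss_and_grads(cur, Xs, Ys)[0])
        if tol is not None and trace[-1] <= tol:
            break
    cfg = dict(model.config)
    cfg.update({"lr": lr, "epochs": epochs, "tol": tol})
    return replace(cur, config=cfg), np.asarray(trace)


def train_preset(
    X: np.ndarray,
    Y: np.ndarray,
    preset: str = "legacy",
    seed: int = 0,
) -> tuple[AnnModel, np.ndarray]:
    """Initialize and train with a named preset configuration."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    model = init_ann(X.shape[1], n_hidden=cfg["n_hidden"], n_out=Y.shape[1], seed=seed)
    trained, trace = train_ann(
        model, X, Y, epochs=cfg["epochs"], lr=cfg["lr"], tol=cfg["tol"]
    )
    trained = replace(trained, config={**trained.config, "preset": preset})
    return trained, trace


def predict_ann(model: AnnModel, X_new: np.ndarray) -> np.ndarray:
    """Scale, forward, unscale: predictions in original units (ug/mL)."""
    if model.scaler is None:
        raise ValueError("model is untrained (no scaler); call train_ann first")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_in:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_in}"
        )
    return model.scaler.unscale_y(model.forward_scaled(model.scaler.scale_x(X_new)))


def hidden_size_scan(
    X: np.ndarray,
    Y: np.ndarray,
    hidden_sizes=range(1, 9),
    epochs: int = 50,
    lr: float = 0.1,
    seed: int = 0,
) -> dict[int, float]:
    """Calibration RMSEC (ug/mL) per hidden-layer width.

    Mirrors the usual hidden-size search: train at each width and report the
    calibration-set root mean squared error.
    """
    out = {}
    for h in hidden_sizes:
        model = init_ann(np.atleast_2d(X).shape[1], n_hidden=h,
                         n_out=np.atleast_2d(Y).shape[1], seed=seed)
        trained, _ = train_ann(model, X, Y, epochs=epochs, lr=lr)
        resid = predict_ann(trained, X) - Y
        out[h] = float(np.sqrt(np.mean(resid**2)))
    return out
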