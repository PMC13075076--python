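"""Shallow softmax neural network trained by scaled conjugate gradients.

A single-hidden-layer (default 10 tanh units) feedforward classifier
with a softmax output and cross-entropy loss, trained full-batch with
Møller's scaled conjugate gradient (SCG) algorithm and Nguyen–Widrow
weight initialization.  Early stopping monitors a held-out validation
split of the training data and stops after a fixed number of
consecutive validation failures (epochs without improvement), restoring
the best weights; training also stops when the gradient infinity norm
falls below ``min_gradient`` or after ``max_epochs`` iterations.

No installed library offers this exact training regime (scikit-learn's
MLP has neither SCG nor Nguyen–Widrow), so it is implemented here with
the scikit-learn estimator API so it can slot into pipelines and
cross-validation unchanged.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted


def nguyen_widrow_init(rng: np.random.Generator, n_in: int, n_hidden: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Hidden-layer weights/biases per Nguyen & Widrow.

    Weight rows get random directions scaled to magnitude
    ``beta = 0.7 * H**(1/d)``; biases are spread linearly over
    ``[-beta, beta]`` with the sign of each row's first weight, which
    distributes the tanh active regions across the input space
    (assumed standardized).
    """
    beta = 0.7 * n_hidden ** (1.0 / n_in)
    w = rng.uniform(-1.0, 1.0, size=(n_hidden, n_in))
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    w = beta * w / norms
    if n_hidden == 1:
        b = np.zeros(1)
    else:
        b = beta * np.linspace(-1.0, 1.0, n_hidden) * np.sign(w[:, 0])
    return w, b


class _Net:
    """Parameter pack / forward / gradient for the 1-hidden-layer net."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int):
        self.shapes = [(n_hidden, n_in), (n_hidden,),
                       (n_out, n_hidden), (n_out,)]
        self.sizes = [int(np.prod(s)) for s in self.shapes]

    def unpack(self, theta: np.ndarray):
        parts, i = [], 0
        for size, shape in zip(self.sizes, self.shapes):
            parts.append(theta[i:i + size].reshape(shape))
            i += size
        return parts  # W1, b1, W2, b2

    def forward(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray:
        W1, b1, W2, b2 = self.unpack(theta)
        hidden = np.tanh(X @ W1.T + b1)
        logits = hidden @ W2.T + b2
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        return expz / expz.sum(axis=1, keepdims=True)

    def loss(self, theta: np.ndarray, X: np.ndarray,
             Y: np.ndarray) -> float:
        proba = self.forward(theta, X)
        return float(-np.mean(np.sum(Y * np.log(proba + 1e-12), axis=1)))

    def loss_grad(self, theta: np.ndarray, X: np.ndarray,
                  Y: np.ndarray) -> tuple[float, np.ndarray]:
        W1, b1, W2, b2 = self.unpack(theta)
        hidden = np.tanh(X @ W1.T + b1)
        logits = hidden @ W2.T + b2
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        proba = expz / expz.sum(axis=1, keepdims=True)
        n = X.shape[0]
        loss = float(-np.mean(np.sum(Y * np.log(proba + 1e-12), axis=1)))
        dlogits = (proba - Y) / n
        gW2 = dlogits.T @ hidden
        gb2 = dlogits.sum(axis=0)
        dhidden = (dlogits @ W2) * (1.0 - hidden ** 2)
        gW1 = dhidden.T @ X
        gb1 = dhidden.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
        return loss, grad


def scg_minimize(fun_grad, theta0: np.ndarray, *, max_iter: int = 1000,
                 min_gradient: float = 1e-7, callback=None) -> np.ndarray:
    """Møller's scaled conjugate gradient minimizer.

    ``fun_grad(theta) -> (loss, grad)``.  ``callback(theta)`` is invoked
    after every successful weight update and may return True to stop
    (used for validation-based early stopping).
    """
    sigma0, lam, lam_bar = 5e-5, 5e-7, 0.0
    theta = theta0.copy()
    f, grad = fun_grad(theta)
    r = -grad
    p = r.copy()
    success = True
    n_params = theta.size
    delta = 0.0

    for k in range(1, max_iter + 1):
        p_sq = float(p @ p)
        if p_sq == 0.0:
            break
        if success:
            sigma = sigma0 / np.sqrt(p_sq)
            _, grad_s = fun_grad(theta + sigma * p)
            s = (grad_s - grad) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * p_sq
        if delta <= 0:  # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta / p_sq)
            delta = -delta + lam * p_sq
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, grad_new = fun_grad(theta + alpha * p)
        comparison = 2.0 * delta * (f - f_new) / mu ** 2

        if comparison >= 0:  # successful step
            theta = theta + alpha * p
            f = f_new
            grad = grad_new
            r_new = -grad
            lam_bar = 0.0
            success = True
            if k % n_params == 0:
                p = r_new.copy()  # periodic restart
            else:
                beta = float((r_new @ r_new - r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam *= 0.25
            if callback is not None and callback(theta):
                break
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / p_sq
        if np.max(np.abs(r)) < min_gradient:
            break
    return theta


class ScgMlpClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-compatible shallow ANN (tanh hidden layer, softmax).

    Parameters mirror the classical shallow-network training recipe:
    ``hidden_units=10``, SCG optimizer, Nguyen–Widrow init, at most
    1000 epochs, early stopping after 6 consecutive validation
    failures on a seeded ``validation_fraction`` split, minimum
    gradient 1e-7.  ``class_order`` fixes ``classes_`` (and thereby the
    argmax tie-break) instead of sorted label order.
    """

    def __init__(self, hidden_units: int = 10, max_epochs: int = 1000,
                 patience: int = 6, min_gradient: float = 1e-7,
                 validation_fraction: float = 0.15,
                 random_state: int | None = None,
                 class_order: tuple[str, ...] | None = None):
        self.hidden_units = hidden_units
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_gradient = min_gradient
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.class_order = class_order

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if not 0.0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5)")
        present = list(dict.fromkeys(y.tolist()))
        if self.class_order is not None:
            classes = [c for c in self.class_order if c in present]
            extra = [c for c in present if c not in classes]
            classes += extra
        else:
            classes = sorted(present)
        self.classes_ = np.asarray(classes)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        class_idx = {c: i for i, c in enumerate(classes)}
        Y = np.zeros((len(y), len(classes)))
        Y[np.arange(len(y)), [class_idx[c] for c in y]] = 1.0

        rng = np.random.default_rng(self.random_state)
        # seeded stratified validation split for early stopping
        idx_train, idx_val = train_test_split(
            np.arange(len(y)), test_size=self.validation_fraction,
            stratify=y,
            random_state=int(rng.integers(0, 2 ** 31 - 1)))
        Xt, Yt = X[idx_train], Y[idx_train]
        Xv, Yv = X[idx_val], Y[idx_val]

        net = _Net(X.shape[1], self.hidden_units, len(classes))
        W1, b1 = nguyen_widrow_init(rng, X.shape[1], self.hidden_units)
        W2 = rng.uniform(-0.5, 0.5, size=(len(classes), self.hidden_units))
        b2 = np.zeros(len(classes))
        theta0 = np.concatenate([W1.ravel(), b1, W2.ravel(), b2])

        state = {"best_loss": np.inf, "best_theta": theta0.copy(),
                 "fails": 0}

        def callback(theta):
            val_loss = net.loss(theta, Xv, Yv)
            if val_loss < state["best_loss"]:
                state["best_loss"] = val_loss
                state["best_theta"] = theta.copy()
                state["fails"] = 0
            else:
                state["fails"] += 1
            return state["fails"] >= self.patience

        theta = scg_minimize(
            lambda t: net.loss_grad(t, Xt, Yt), theta0,
            max_iter=self.max_epochs, min_gradient=self.min_gradient,
            callback=callback)
        if net.loss(theta, Xv, Yv) > state["best_loss"]:
            theta = state["best_theta"]
        self._net = net
        self.theta_ = theta
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "theta_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return self._net.forward(self.theta_, X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
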