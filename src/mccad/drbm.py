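"""Discriminative restricted Boltzmann machine over raw image patches.

The model couples binary hidden units h with real-valued visible units x
(patch intensities scaled to [0, 1]) and a one-hot class unit y through the
energy

    E(y, x, h) = -h'Wx - b'x - c'h - d_y - h'U[:, y].

Because the hidden units are conditionally independent, p(y | x) is exact
and tractable through the free energy

    F_y(x) = d_y + sum_j softplus(c_j + U[j, y] + W[j] . x),
    p(y | x) = softmax over y of F_y(x),

which is what classification uses.  Training defaults to contrastive
divergence on the joint (y, x): the positive phase clamps the data with
mean-field hidden activations; the negative phase alternates hidden
sampling with mean-field visible reconstruction and a resampled class unit.
The exact gradient of the discriminative objective
``-sum_i log p(y_i | x_i)`` is also implemented, both as an alternative
trainer and as the hook for finite-difference verification.

Visible units are treated as Bernoulli means: real inputs in [0, 1] are
used directly as activations, with no stochastic binarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .io import DetectionRecord, MammogramImage

_FORMAT_VERSION = 1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


@dataclass
class DRBMTrainConfig:
    learning_rate: float = 0.02
    n_epochs: int = 100
    batch_size: int = 64
    cd_steps: int = 1
    seed: int = 0
    patch_side: int = 15

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")
        if self.patch_side % 2 != 1:
            raise ValueError("patch_side must be odd so a center pixel exists")


class DRBM:
    """Two-class discriminative RBM; parameters W (h x v), U (h x 2),
    b (v), c (h), d (2)."""

    n_classes = 2

    def __init__(self, n_visible: int, n_hidden: int, seed: int = 0, init_scale: float = 0.01):
        rng = np.random.default_rng(seed)
        self.n_visible = int(n_visible)
        self.n_hidden = int(n_hidden)
        self.W = rng.normal(0.0, init_scale, size=(n_hidden, n_visible))
        self.U = rng.normal(0.0, init_scale, size=(n_hidden, self.n_classes))
        self.b = np.zeros(n_visible)
        self.c = np.zeros(n_hidden)
        self.d = np.zeros(self.n_classes)

    # -- energy / inference -------------------------------------------------

    def energy(self, y: int, x: np.ndarray, h: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        h = np.asarray(h, dtype=float)
        if x.shape != (self.n_visible,) or h.shape != (self.n_hidden,):
            raise ValueError("dimension mismatch in energy()")
        return float(
            -h @ self.W @ x - self.b @ x - self.c @ h - self.d[y] - h @ self.U[:, y]
        )

    def free_energy(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) matrix of F_y(x); p(y|x) is its row-softmax."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_visible:
            raise ValueError("dimension mismatch in free_energy()")
        act = X @ self.W.T + self.c  # (n, h)
        F = np.empty((len(X), self.n_classes))
        for y in range(self.n_classes):
            F[:, y] = self.d[y] + _softplus(act + self.U[:, y]).sum(axis=1)
        return F

    def conditional_prob(self, X: np.ndarray) -> np.ndarray:
        """p(y | x) rows (n, 2), computed in log-space with max
        subtraction; each row sums to 1."""
        if not (np.isfinite(self.W).all() and np.isfinite(self.U).all()
                and np.isfinite(self.b).all() and np.isfinite(self.c).all()
                and np.isfinite(self.d).all()):
            raise ValueError("model parameters are not finite")
        F = self.free_energy(X)
        F -= F.max(axis=1, keepdims=True)
        e = np.exp(F)
        return e / e.sum(axis=1, keepdims=True)

    def sample_hidden(self, y: np.ndarray, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One Bernoulli draw per hidden unit given the clamped (y, x)."""
        means = self.hidden_means(y, X)
        return (rng.uniform(size=means.shape) < means).astype(float)

    def hidden_means(self, y: np.ndarray, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=int))
        return _sigmoid(X @ self.W.T + self.c + self.U[:, y].T)

    # -- training -----------------------------------------------------------

    def cd_update(
        self,
        X: np.ndarray,
        y: np.ndarray,
        learning_rate: float,
        cd_steps: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        """One contrastive-divergence parameter update on a mini-batch."""
        rng = rng if rng is not None else np.random.default_rng()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=int))
        n = len(X)
        Y0 = np.eye(self.n_classes)[y]  # (n, 2) one-hot
        H0 = self.hidden_means(y, X)

        Xk, yk = X, y
        Hmeans = H0
        for _ in range(cd_steps):
            Hs = (rng.uniform(size=Hmeans.shape) < Hmeans).astype(float)
            Xk = _sigmoid(Hs @ self.W + self.b)  # visible means, not sampled
            class_logits = Hs @ self.U + self.d
            class_logits -= class_logits.max(axis=1, keepdims=True)
            p_y = np.exp(class_logits)
            p_y /= p_y.sum(axis=1, keepdims=True)
            yk = (rng.uniform(size=n) < p_y[:, 1]).astype(int)  # resample class
            Hmeans = self.hidden_means(yk, Xk)
        Yk = np.eye(self.n_classes)[yk]
        Hk = Hmeans

        lr = learning_rate
        self.W += lr * (H0.T @ X - Hk.T @ Xk) / n
        self.U += lr * (H0.T @ Y0 - Hk.T @ Yk) / n
        self.b += lr * (X - Xk).mean(axis=0)
        self.c += lr * (H0 - Hk).mean(axis=0)
        self.d += lr * (Y0 - Yk).mean(axis=0)

    def discriminative_gradient(
        self, X: np.ndarray, y: np.ndarray
    ) -> dict[str, np.ndarray]:
        """Exact gradient of ``-sum_i log p(y_i | x_i)`` w.r.t. the
        parameters (summed over the batch, not averaged)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=int))
        n = len(X)
        p = self.conditional_prob(X)  # (n, 2)
        act = X @ self.W.T + self.c  # (n, h)
        gW = np.zeros_like(self.W)
        gU = np.zeros_like(self.U)
        gc = np.zeros_like(self.c)
        gd = np.zeros_like(self.d)
        s_data = np.empty((n, self.n_hidden))
        for cls in range(self.n_classes):
            s = _sigmoid(act + self.U[:, cls])  # (n, h)
            w = p[:, cls][:, None]  # model expectation weight
            gW += (w * s).T @ X
            gU[:, cls] += (w * s).sum(axis=0)
            gc += (w * s).sum(axis=0)
            gd[cls] += p[:, cls].sum()
            data_rows = y == cls
            if data_rows.any():
                gW -= s[data_rows].T @ X[data_rows]
                gU[:, cls] -= s[data_rows].sum(axis=0)
                gc -= s[data_rows].sum(axis=0)
                gd[cls] -= float(data_rows.sum())
        return {"W": gW, "U": gU, "b": np.zeros_like(self.b), "c": gc, "d": gd}

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: DRBMTrainConfig,
        method: str = "cd",
        log: list | None = None,
    ) -> "DRBM":
        """Mini-batch training; ``method`` is "cd" (default) or "disc"
        (exact discriminative gradient descent)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=int))
        rng = np.random.default_rng(config.seed)
        n = len(X)
        for epoch in range(config.n_epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                batch = order[start : start + config.batch_size]
                if method == "cd":
                    self.cd_update(
                        X[batch], y[batch], config.learning_rate, config.cd_steps, rng
                    )
                elif method == "disc":
                    g = self.discriminative_gradient(X[batch], y[batch])
                    m = len(batch)
                    self.W -= config.learning_rate * g["W"] / m
                    self.U -= config.learning_rate * g["U"] / m
                    self.c -= config.learning_rate * g["c"] / m
                    self.d -= config.learning_rate * g["d"] / m
                else:
                    raise ValueError(f"unknown training method {method!r}")
            if log is not None:
                log.append((epoch, self.nll(X, y)))
        return self

    def nll(self, X: np.ndarray, y: np.ndarray) -> float:
        """Negative conditional log-likelihood of the data."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=int))
        if len(X) == 0:
            raise ValueError("nll of empty data")
        p = self.conditional_prob(X)
        return float(-np.log(p[np.arange(len(y)), y]).sum())

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": _FORMAT_VERSION,
            "n_visible": self.n_visible,
            "n_hidden": self.n_hidden,
            "W": self.W.tolist(),
            "U": self.U.tolist(),
            "b": self.b.tolist(),
            "c": self.c.tolist(),
            "d": self.d.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "DRBM":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported DRBM file version")
        model = cls(payload["n_visible"], payload["n_hidden"])
        model.W = np.asarray(payload["W"], dtype=float)
        model.U = np.asarray(payload["U"], dtype=float)
        model.b = np.asarray(payload["b"], dtype=float)
        model.c = np.asarray(payload["c"], dtype=float)
        model.d = np.asarray(payload["d"], dtype=float)
        return model


# ---------------------------------------------------------------------------
# patches


def extract_patch(
    image: MammogramImage, center: tuple[int, int], patch_side: int
) -> np.ndarray:
    """Flattened (row-major) ``patch_side x patch_side`` window centered on
    ``center``, intensities divided by the full bit-depth range so every
    component lies in [0, 1]; borders are reflect-padded."""
    if patch_side % 2 != 1:
        raise ValueError("patch_side must be odd")
    if patch_side > min(image.shape):
        raise ValueError("patch larger than image")
    half = patch_side // 2
    padded = np.pad(image.pixels, half, mode="symmetric")
    r, c = center
    win = padded[r : r + patch_side, c : c + patch_side]
    return win.ravel() / image.max_intensity


def classify_patches(
    model: DRBM,
    candidates: list[tuple[int, int]],
    image: MammogramImage,
    theta_drbm: float,
    patch_side: int,
    image_id: str = "",
) -> list[DetectionRecord]:
    """Score each candidate with p(microcalcification | patch) and retain
    those with score >= theta_drbm."""
    if not 0.0 <= theta_drbm <= 1.0:
        raise ValueError("theta_drbm must be in [0, 1]")
    if not candidates:
        return []
    X = np.stack([extract_patch(image, c, patch_side) for c in candidates])
    scores = model.conditional_prob(X)[:, 1]
    return [
        DetectionRecord(point=(int(r), int(c)), score=float(s), stage="drbm", image_id=image_id)
        for (r, c), s in zip(candidates, scores)
        if s >= theta_drbm
    ]
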