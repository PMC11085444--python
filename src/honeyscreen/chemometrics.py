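"""Latent-variable engine: NIPALS PCA/PLS1, cross-validation, Hotelling T2.

Everything is computed from scratch on top of numpy so that the model state
(weights, loadings, scores, regression vector, diagnostics) is fully
inspectable and serialisable.  Conventions:

* variables are centred, and under unit-variance (UV) scaling divided by
  their sample SD (ddof=1); zero-variance variables keep scale 1 and are
  flagged (they are inert after centring);
* PLS1 weight vectors ``W`` have unit norm and score vectors are mutually
  orthogonal; predictions use the direct regression vector
  ``B = W (P'W)^-1 q`` in scaled-X space;
* the sign of each component is fixed so its largest-|loading| element is
  positive, for reproducible score plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist

__all__ = [
    "ScalingState",
    "LatentModel",
    "CVResult",
    "fit_scaling",
    "fit_pca",
    "fit_pls",
    "fit_plsda",
    "predict_y",
    "project_scores",
    "cross_validate",
    "hotelling_limit",
    "hotelling_t2",
]

_EPS = 1e-12


@dataclass
class ScalingState:
    """Per-variable centring/scaling learned from training data."""

    means: np.ndarray
    scales: np.ndarray
    mode: str = "center"  # center | uv
    zero_variance: np.ndarray = field(default=None)  # bool mask

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means.size:
            raise ValueError(
                f"expected {self.means.size} variables, got {X.shape[1]}"
            )
        return (X - self.means) / self.scales

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.atleast_2d(Z) * self.scales + self.means


def fit_scaling(X: np.ndarray, mode: str = "center") -> ScalingState:
    """Column means and divisors (1 for centre-only, SD with n-1 for UV).

    Columns with SD below tolerance are flagged and keep scale 1, so after
    centring they contribute nothing to any model.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("scaling needs a 2-D matrix with at least 2 rows")
    if mode not in ("center", "uv"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    means = X.mean(axis=0)
    if mode == "uv":
        sd = X.std(axis=0, ddof=1)
        zero = sd <= _EPS * (1.0 + np.abs(means))
        scales = np.where(zero, 1.0, sd)
    else:
        zero = X.std(axis=0, ddof=1) <= _EPS * (1.0 + np.abs(means))
        scales = np.ones_like(means)
    return ScalingState(means=means, scales=scales, mode=mode, zero_variance=zero)


@dataclass
class LatentModel:
    """Fitted PCA / PLS / PLS-DA state."""

    kind: str  # pca | pls | plsda
    A: int
    scaling: ScalingState
    W: np.ndarray | None  # (p, A) unit-norm weights (PLS) / None for PCA
    P: np.ndarray  # (p, A) x-loadings
    q: np.ndarray | None  # (A,) y-loadings (PLS)
    T: np.ndarray  # (n, A) training scores
    B: np.ndarray | None  # (p,) regression vector in scaled-X space (PLS)
    y_mean: float = 0.0
    classes: tuple | None = None  # (class0, class1) for plsda; y = 1(class1)
    diagnostics: dict = field(default_factory=dict)

    @property
    def R(self) -> np.ndarray:
        """Projection matrix R = W (P'W)^-1 mapping scaled X to scores."""
        if self.W is None:
            return self.P  # PCA loadings are orthonormal
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "kind": self.kind,
            "A": self.A,
            "scaling": {
                "means": arr(self.scaling.means),
                "scales": arr(self.scaling.scales),
                "mode": self.scaling.mode,
                "zero_variance": arr(self.scaling.zero_variance),
            },
            "W": arr(self.W),
            "P": arr(self.P),
            "q": arr(self.q),
            "T": arr(self.T),
            "B": arr(self.B),
            "y_mean": self.y_mean,
            "classes": list(self.classes) if self.classes else None,
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatentModel":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        s = d["scaling"]
        scaling = ScalingState(
            means=arr(s["means"]),
            scales=arr(s["scales"]),
            mode=s["mode"],
            zero_variance=np.asarray(s["zero_variance"], dtype=bool),
        )
        return cls(
            kind=d["kind"],
            A=d["A"],
            scaling=scaling,
            W=arr(d["W"]),
            P=arr(d["P"]),
            q=arr(d["q"]),
            T=arr(d["T"]),
            B=arr(d["B"]),
            y_mean=d["y_mean"],
            classes=tuple(d["classes"]) if d["classes"] else None,
            diagnostics=d["diagnostics"],
        )


def _fix_sign(p: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    j = int(np.argmax(np.abs(p)))
    if p[j] < 0:
        return -p, -t
    return p, t


def fit_pca(
    X: np.ndarray,
    A: int,
    scaling: str = "center",
    max_iter: int = 20000,
    tol: float = 1e-13,
) -> LatentModel:
    """NIPALS principal component analysis.

    Loadings are orthonormal; per-component explained variance shares are
    reported in ``diagnostics["r2x_per_component"]``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A={A} out of range for {n}x{p} data")
    state = fit_scaling(X, scaling)
    Z = state.transform(X)
    ss_total = float((Z**2).sum())
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    r2x = []
    for a in range(A):
        t = Z[:, int(np.argmax(Z.var(axis=0)))].copy()
        if float(t @ t) <= _EPS:
            raise ValueError("matrix rank lower than requested components")
        for _ in range(max_iter):
            pl = Z.T @ t / float(t @ t)
            pl /= np.linalg.norm(pl)
            t_new = Z @ pl
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        pl, t = _fix_sign(pl, t)
        T[:, a] = t
        P[:, a] = pl
        Z = Z - np.outer(t, pl)
        r2x.append(float(t @ t) / ss_total if ss_total > 0 else 0.0)
    eig = (T**2).sum(axis=0) / max(n - 1, 1)
    return LatentModel(
        kind="pca",
        A=A,
        scaling=state,
        W=None,
        P=P,
        q=None,
        T=T,
        B=None,
        diagnostics={
            "r2x_per_component": r2x,
            "R2X": float(np.sum(r2x)),
            "eigenvalues": eig.tolist(),
        },
    )


def _pls_components(Z: np.ndarray, y0: np.ndarray, A: int, allow_early_stop: bool = False):
    """NIPALS PLS1 with X- and y-deflation on pre-scaled data.

    With ``allow_early_stop`` the extraction stops once the y residual is
    exhausted (perfect fit) and the arrays are truncated to the components
    actually extracted.
    """
    n, p = Z.shape
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    Zd, yd = Z.copy(), y0.copy()
    scale_y = max(float(np.linalg.norm(y0)), 1.0)
    for a in range(A):
        w = Zd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-10 * scale_y:
            if allow_early_stop and a >= 1:
                return W[:, :a], P[:, :a], q[:a], T[:, :a]
            raise ValueError(
                f"y residual uncorrelated with X at component {a + 1}; "
                "reduce the number of components"
            )
        w /= nw
        t = Zd @ w
        tt = float(t @ t)
        if tt <= _EPS:
            raise ValueError(f"degenerate score vector at component {a + 1}")
        pl = Zd.T @ t / tt
        # Sign convention on the loading; w and t flip together with it.
        j = int(np.argmax(np.abs(pl)))
        if pl[j] < 0:
            w, t, pl = -w, -t, -pl
        qa = float(yd @ t) / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, pl, qa, t
        Zd = Zd - np.outer(t, pl)
        yd = yd - qa * t
    return W, P, q, T


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


def fit_pls(
    X: np.ndarray, y: np.ndarray, A: int, scaling: str = "center"
) -> LatentModel:
    """NIPALS PLS1 regression of a single response on X."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y length mismatch")
    if n < A + 1:
        raise ValueError(f"need at least A+1={A + 1} samples, got {n}")
    if np.std(y) <= _EPS * (1.0 + abs(float(np.mean(y)))):
        raise ValueError("response has zero variance")
    state = fit_scaling(X, scaling)
    Z = state.transform(X)
    y_mean = float(y.mean())
    y0 = y - y_mean
    W, P, q, T = _pls_components(Z, y0, A)
    B = _coefficients(W, P, q, A)
    fitted = y_mean + Z @ B
    rss = float(((y - fitted) ** 2).sum())
    ss = float((y0**2).sum())
    ssz = float((Z**2).sum())
    r2x = [float(T[:, a] @ T[:, a]) * float(P[:, a] @ P[:, a]) / ssz for a in range(A)]
    dof = max(n - A - 1, 1)
    model = LatentModel(
        kind="pls",
        A=A,
        scaling=state,
        W=W,
        P=P,
        q=q,
        T=T,
        B=B,
        y_mean=y_mean,
        diagnostics={
            "R2Y": 1.0 - rss / ss,
            "R2X": float(np.sum(r2x)),
            "r2x_per_component": r2x,
            "RMSEE": float(np.sqrt(rss / dof)),
        },
    )
    return model


def fit_plsda(
    X: np.ndarray, labels, A: int, scaling: str = "uv", positive=None
) -> LatentModel:
    """PLS-DA: PLS1 on a 0/1 dummy response.

    ``positive`` names the class coded 1 (default: the lexically larger of
    the two labels).  Predicted Y for new samples comes from
    :func:`predict_y`; values are not clipped to [0, 1].
    """
    labels = np.asarray(labels)
    uniq = sorted(np.unique(labels).tolist())
    if len(uniq) != 2:
        raise ValueError(f"PLS-DA needs exactly two classes, got {uniq}")
    if positive is None:
        positive = uniq[1]
    if positive not in uniq:
        raise ValueError(f"positive class {positive!r} not among labels {uniq}")
    negative = uniq[0] if positive == uniq[1] else uniq[1]
    y = (labels == positive).astype(float)
    model = fit_pls(X, y, A, scaling=scaling)
    model.kind = "plsda"
    model.classes = (negative, positive)
    return model


def predict_y(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted response (YPredPS for PLS-DA) for new samples."""
    if model.B is None:
        raise ValueError("model has no regression vector (PCA?)")
    Z = model.scaling.transform(X_new)
    return model.y_mean + Z @ model.B


def project_scores(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    """Score coordinates of new samples, consistent with NIPALS deflation."""
    Z = model.scaling.transform(X_new)
    return Z @ model.R


@dataclass
class CVResult:
    """Cross-validation diagnostics per candidate component count."""

    scheme: str
    rmsecv: np.ndarray  # index a-1 -> RMSECV with a components
    q2: np.ndarray
    chosen_A: int

    @property
    def min_rmsecv(self) -> float:
        return float(self.rmsecv.min())


def _folds(y: np.ndarray, scheme: str, n_folds: int) -> list[np.ndarray]:
    n = y.size
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if scheme != "venetian":
        raise ValueError(f"unknown CV scheme {scheme!r}")
    order = np.argsort(y, kind="stable")
    folds = [order[k::n_folds] for k in range(n_folds)]
    return [f for f in folds if f.size]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int,
    scheme: str = "venetian",
    n_folds: int = 7,
    scaling: str = "center",
) -> CVResult:
    """RMSECV and Q2 for 1..A_max PLS components.

    Default scheme: 7 interleaved ("venetian blind") folds ordered by y.
    Scaling is refit inside each training fold.  The chosen component count
    minimises RMSECV (ties break to the smaller A).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if scheme == "venetian" and (n_folds < 2 or n < n_folds):
        raise ValueError(f"need n >= folds >= 2, got n={n}, folds={n_folds}")
    folds = _folds(y, scheme, n_folds)
    press = np.zeros(A_max)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        state = fit_scaling(X[train_idx], scaling)
        Z = state.transform(X[train_idx])
        y_mean = float(y[train_idx].mean())
        W, P, q, _ = _pls_components(
            Z, y[train_idx] - y_mean, A_max, allow_early_stop=True
        )
        a_eff = q.size  # may be < A_max when the fold fits y exactly
        Znew = state.transform(X[test_idx])
        for a in range(1, A_max + 1):
            pred = y_mean + Znew @ _coefficients(W, P, q, min(a, a_eff))
            press[a - 1] += float(((y[test_idx] - pred) ** 2).sum())
    rmsecv = np.sqrt(press / n)
    ss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / ss
    chosen = int(np.argmin(rmsecv)) + 1
    name = "loo" if scheme == "loo" else f"venetian-{n_folds}"
    return CVResult(scheme=name, rmsecv=rmsecv, q2=q2, chosen_A=chosen)


def hotelling_limit(n: int, A: int, alpha: float = 0.05) -> float:
    """Critical Hotelling T2 at confidence 1-alpha for A scores, n samples.

    T2_crit = A (n-1)(n+1) / (n (n-A)) * F_{1-alpha}(A, n-A).
    """
    if not (n > A >= 1):
        raise ValueError(f"need n > A >= 1, got n={n}, A={A}")
    factor = A * (n - 1) * (n + 1) / (n * (n - A))
    return float(factor * f_dist.ppf(1.0 - alpha, A, n - A))


def hotelling_t2(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    """T2 of new samples in score space, scaled by training score SDs."""
    t = project_scores(model, X_new)
    sd = model.T.std(axis=0, ddof=1)
    return ((t / sd) ** 2).sum(axis=1)
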