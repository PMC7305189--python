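"""Pseudolikelihood Potts-model fitting, APC-corrected coupling scores, and
calibrated contact probabilities.

The model is a Markov random field over alignment columns on a 21-state
alphabet (20 amino acids + gap).  Fitting minimizes the weighted negative
log-pseudolikelihood

    sum_s w_s sum_i -log P(x_i^s | x_{-i}^s),
    P ~ softmax_a( fields[i, a] + sum_{j != i} couplings[i, j, a, x_j^s] )

with L2 penalties on fields and couplings.  Couplings are fitted
asymmetrically (one conditional per site) and symmetrized afterwards,
the standard pseudolikelihood-maximization scheme for direct-coupling
analysis.  Scores are Frobenius norms over the 20x20 amino-acid block,
background-corrected with the average product correction (APC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from . import Q
from .msa import Alignment

log = logging.getLogger(__name__)

__all__ = [
    "PottsModel",
    "ContactPrediction",
    "FitTrace",
    "fit_potts",
    "coupling_scores",
    "apc_correct",
    "calibrate_probabilities",
    "write_rr",
    "read_rr",
    "write_predictions_tsv",
    "save_model",
    "load_model",
    "CALIBRATION_COEFFS",
]

# Logistic calibration p = expit(a*z + b*log(nf) + c) in the normalized APC
# score z and log effective-depth nf.  Coefficients were fit by logistic
# regression on a synthetic planted-contact benchmark (toy complexes sampled
# at depths 300-3000 across seeds; see tests/test_coevolution.py) and frozen.
CALIBRATION_COEFFS = {"a": 14.6, "b": 0.23, "c": -5.4}


@dataclass
class PottsModel:
    """Fields (L, 21) and symmetric couplings (L, L, 21, 21)."""

    fields: np.ndarray
    couplings: np.ndarray
    lambda_field: float
    lambda_coupling: float

    def __post_init__(self) -> None:
        L = self.fields.shape[0]
        if self.fields.shape != (L, Q):
            raise ValueError(f"fields must be (L, {Q})")
        if self.couplings.shape != (L, L, Q, Q):
            raise ValueError(f"couplings must be (L, L, {Q}, {Q})")
        if self.lambda_field < 0 or self.lambda_coupling < 0:
            raise ValueError("regularization strengths must be non-negative")

    @property
    def ncols(self) -> int:
        return self.fields.shape[0]

    def symmetrize(self) -> "PottsModel":
        J = 0.5 * (self.couplings + self.couplings.transpose(1, 0, 3, 2))
        idx = np.arange(self.ncols)
        J[idx, idx] = 0.0
        return PottsModel(self.fields, J, self.lambda_field, self.lambda_coupling)


@dataclass(frozen=True)
class ContactPrediction:
    """One scored residue pair (0-based columns, i < j)."""

    i: int
    j: int
    raw_score: float
    apc_score: float
    probability: float


@dataclass
class FitTrace:
    """Objective values logged across optimizer iterations."""

    objective: list[float] = field(default_factory=list)
    grad_norm: float = float("nan")
    converged: bool = False
    n_iter: int = 0


class FitConvergenceError(RuntimeError):
    def __init__(self, grad_norm: float, n_iter: int):
        super().__init__(
            f"pseudolikelihood fit did not converge within {n_iter} iterations "
            f"(final gradient norm {grad_norm:.3e})"
        )
        self.grad_norm = grad_norm


def _one_hot(states: np.ndarray) -> np.ndarray:
    N, L = states.shape
    oh = np.zeros((N, L, Q), dtype=np.float64)
    oh[np.arange(N)[:, None], np.arange(L)[None, :], states] = 1.0
    return oh


def _pseudolikelihood_objective(
    states: np.ndarray,
    w: np.ndarray,
    lambda_field: float,
    lambda_coupling: float,
):
    """Build the weighted negative log-pseudolikelihood closure.

    Parameters are packed as (fields, asymmetric couplings); the closure
    returns (value, gradient).  The NLL is normalized by the weight sum.
    Diagonal coupling blocks start at zero and their gradient components are
    zeroed, so optimizers never move them.
    """
    N, L = states.shape
    neff = float(w.sum())
    X = _one_hot(states)
    Xf = X.reshape(N, L * Q)
    wcol = w[:, None, None]
    nf_params = L * Q
    diag = np.arange(L)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        f = theta[:nf_params].reshape(L, Q)
        J = theta[nf_params:].reshape(L, Q, L, Q)
        # logits[s, i, a] = f[i, a] + sum_{j,b} J[i, a, j, b] x[s, j, b]
        logits = (Xf @ J.reshape(L * Q, L * Q).T).reshape(N, L, Q) + f
        lse = logsumexp(logits, axis=2)
        obs = np.einsum("nia,nia->ni", logits, X)
        nll = float((w[:, None] * (lse - obs)).sum()) / neff
        P = np.exp(logits - lse[:, :, None])
        D = (wcol * (P - X)).reshape(N, L * Q) / neff
        grad_f = D.reshape(N, L, Q).sum(axis=0) + 2.0 * lambda_field * f
        grad_J = (D.T @ Xf).reshape(L, Q, L, Q) + 2.0 * lambda_coupling * J
        grad_J[diag, :, diag, :] = 0.0
        reg = lambda_field * float((f * f).sum()) + lambda_coupling * float(
            (J * J).sum()
        )
        return nll + reg, np.concatenate([grad_f.ravel(), grad_J.ravel()])

    return objective, nf_params


def fit_potts(
    aln: Alignment,
    lambda_field: float = 0.01,
    lambda_coupling: float | None = None,
    max_iter: int = 500,
    gtol: float = 1e-5,
    trace: FitTrace | None = None,
    strict_convergence: bool = False,
) -> PottsModel:
    """Fit a Potts model by weighted pseudolikelihood maximization.

    The weighted NLL is normalized by the weight sum (Neff), so the
    penalties act per effective sequence; ``lambda_coupling`` defaults to
    ``0.01 * (ncols - 1) / neff``, the conventional plmDCA-style scaling.
    Deterministic: zero initialization, L-BFGS-B.

    With ``strict_convergence`` a failure to reach ``gtol`` within
    ``max_iter`` iterations raises :class:`FitConvergenceError`; by default
    it is logged and the current iterate is returned.
    """
    if aln.ncols < 1:
        raise ValueError("alignment has no columns")
    states = aln.to_states()
    N, L = states.shape
    w = (
        np.asarray(aln.weights, dtype=float)
        if aln.weights is not None
        else np.ones(N)
    )
    neff = float(w.sum())
    if lambda_coupling is None:
        lambda_coupling = 0.01 * (L - 1) / neff

    raw_objective, nf_params = _pseudolikelihood_objective(
        states, w, lambda_field, lambda_coupling
    )
    nJ_params = (L * Q) ** 2
    diag = np.arange(L)

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = theta[:nf_params].reshape(L, Q)
        J = theta[nf_params:].reshape(L, Q, L, Q)
        return f, J

    last_val = [np.inf]

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        val, grad = raw_objective(theta)
        last_val[0] = val
        return val, grad

    # the line search's final evaluation is at the accepted iterate, so
    # last_val holds the per-iteration objective when the callback fires
    callback = None
    if trace is not None:
        callback = lambda xk: trace.objective.append(last_val[0])  # noqa: E731

    theta0 = np.zeros(nf_params + nJ_params)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12, "maxcor": 8},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    if trace is not None:
        trace.grad_norm = gnorm
        trace.converged = bool(res.success)
        trace.n_iter = int(res.nit)
    if not res.success and gnorm > gtol:
        if strict_convergence:
            raise FitConvergenceError(gnorm, int(res.nit))
        log.warning(
            "fit stopped after %d iterations (grad norm %.3e); using final iterate",
            res.nit, gnorm,
        )
    f, J = unpack(res.x)
    J[diag, :, diag, :] = 0.0
    model = PottsModel(
        fields=f,
        couplings=J.transpose(0, 2, 1, 3).copy(),  # (L, L, Q, Q)
        lambda_field=lambda_field,
        lambda_coupling=lambda_coupling,
    )
    return model.symmetrize()


def coupling_scores(model: PottsModel, exclude_gap: bool = True) -> np.ndarray:
    """Frobenius norm per column pair; gap states excluded by default.

    The L2 penalty already pins the coupling gauge, so the norm is taken
    over the raw 20x20 amino-acid block.
    """
    k = Q - 1 if exclude_gap else Q
    J = model.couplings[:, :, :k, :k]
    S = np.sqrt((J**2).sum(axis=(2, 3)))
    np.fill_diagonal(S, 0.0)
    return 0.5 * (S + S.T)


def apc_correct(S: np.ndarray) -> np.ndarray:
    """Average product correction: S'_ij = S_ij - mean_i * mean_j / mean_all.

    Means exclude the diagonal.  An all-zero matrix is returned unchanged.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("score matrix must be square")
    if not np.allclose(S, S.T):
        raise ValueError("score matrix must be symmetric")
    L = S.shape[0]
    if L < 2 or not S.any():
        return np.zeros_like(S)
    off = ~np.eye(L, dtype=bool)
    mean_all = S[off].mean()
    if mean_all == 0:
        return np.zeros_like(S)
    row_mean = S.sum(axis=1) / (L - 1)
    corrected = S - np.outer(row_mean, row_mean) / mean_all
    np.fill_diagonal(corrected, 0.0)
    return corrected


def _candidate_pairs(
    L: int, min_sep: int, boundary: int | None
) -> list[tuple[int, int]]:
    pairs = []
    for i in range(L):
        for j in range(i + 1, L):
            cross = boundary is not None and i < boundary <= j
            if cross or j - i >= min_sep:
                pairs.append((i, j))
    return pairs


def calibrate_probabilities(
    scores: np.ndarray,
    neff: float,
    ncols: int,
    min_sep: int = 6,
    boundary: int | None = None,
    coeffs: dict | None = None,
) -> list[ContactPrediction]:
    """Turn APC-corrected scores into ranked contact probabilities.

    Scores are normalized by the mean of the top-``ncols`` candidate scores
    (z); probability = logistic(a*z + b*log(nf) + c) with nf = neff/sqrt(ncols).
    Intra-chain pairs with separation < ``min_sep`` are dropped; pairs
    straddling ``boundary`` are exempt from the separation rule.
    """
    if neff <= 0:
        raise ValueError(f"neff must be positive, got {neff}")
    c = dict(CALIBRATION_COEFFS if coeffs is None else coeffs)
    L = scores.shape[0]
    pairs = _candidate_pairs(L, min_sep, boundary)
    if not pairs:
        return []
    vals = np.array([scores[i, j] for i, j in pairs])
    top = np.sort(vals)[::-1][: min(ncols, len(vals))]
    norm = top.mean()
    if norm <= 0:
        norm = 1.0
    nf = neff / np.sqrt(ncols)
    z = vals / norm
    probs = expit(c["a"] * z + c["b"] * np.log(nf) + c["c"])
    preds = [
        ContactPrediction(i, j, float(scores[i, j]), float(scores[i, j]), float(p))
        for (i, j), p in zip(pairs, probs)
    ]
    preds.sort(key=lambda p: (-p.probability, p.i, p.j))
    return preds


# ---------------------------------------------------------------------------
# I/O

def write_rr(preds: list[ContactPrediction], path: str | Path) -> None:
    """CASP-RR style text: 1-based i, j, 0, 8, probability."""
    with open(path, "w") as fh:
        for p in preds:
            fh.write(f"{p.i + 1} {p.j + 1} 0 8 {p.probability:.6f}\n")


def read_rr(path: str | Path) -> list[ContactPrediction]:
    preds = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 5:
                continue
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            p = float(parts[4])
            preds.append(ContactPrediction(i, j, float("nan"), float("nan"), p))
    return preds


def write_predictions_tsv(
    preds: list[ContactPrediction], path: str | Path, boundary: int | None = None
) -> None:
    """TSV with chain labels: pair columns are labelled A or B by ``boundary``."""

    def label(col: int) -> str:
        if boundary is None:
            return "A"
        return "A" if col < boundary else "B"

    def local(col: int) -> int:
        if boundary is None or col < boundary:
            return col + 1
        return col - boundary + 1

    with open(path, "w") as fh:
        fh.write("chain_i\tres_i\tchain_j\tres_j\traw\tapc\tprobability\n")
        for p in preds:
            fh.write(
                f"{label(p.i)}\t{local(p.i)}\t{label(p.j)}\t{local(p.j)}\t"
                f"{p.raw_score:.6g}\t{p.apc_score:.6g}\t{p.probability:.6f}\n"
            )


_MODEL_FORMAT_VERSION = 1


def save_model(model: PottsModel, path: str | Path) -> None:
    """Serialize to a versioned NPZ container."""
    np.savez_compressed(
        path,
        format_version=_MODEL_FORMAT_VERSION,
        fields=model.fields,
        couplings=model.couplings,
        lambda_field=model.lambda_field,
        lambda_coupling=model.lambda_coupling,
    )


def load_model(path: str | Path) -> PottsModel:
    with np.load(path) as data:
        version = int(data["format_version"])
        if version != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        return PottsModel(
            fields=data["fields"],
            couplings=data["couplings"],
            lambda_field=float(data["lambda_field"]),
            lambda_coupling=float(data["lambda_coupling"]),
        )
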