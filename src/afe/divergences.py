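"""f-divergences between discrete class-posterior distributions.

Active feature elicitation scores a candidate example by how far the
posterior of the observed-features model lies from the posteriors of the
full-features model. All four divergences used for that scoring are
instances of the Csiszar f-divergence

    D_f(p || q) = sum_i q_i * f(p_i / q_i),    f convex, f(1) = 0,

and :func:`f_divergence` evaluates that generic form directly so it can
serve as an independent oracle for the closed forms.

Closed forms implemented:

================  ======================  =========================
name              generator f(x)          closed form
================  ======================  =========================
kl                x log x                 sum p_i log(p_i/q_i)
hellinger         (sqrt(x)-1)^2           (1/2) sum (sqrt p - sqrt q)^2
total_variation   |x-1|/2                 (1/2) ||p - q||_1
neyman_chi2       (x-1)^2                 sum (p_i-q_i)^2 / q_i
================  ======================  =========================

Note on the Hellinger constant: the generator (sqrt(x)-1)^2 integrates to
sum (sqrt p - sqrt q)^2, which is exactly twice the bounded-by-one closed
form implemented here. We keep the 1/2 so the value lies in [0, 1];
example ranking is unaffected by a positive constant.

KL and the Neyman chi-square ratio are undefined when q has zeros, which
happens routinely with confident classifiers, so the denominator
distribution is floored at ``clamp_eps`` and renormalised before any
ratio is taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "DIVERGENCE_NAMES",
    "DivergenceSpec",
    "as_probability_vector",
    "kl_divergence",
    "hellinger_distance",
    "total_variation",
    "neyman_chi2",
    "f_divergence",
    "get_divergence",
    "pairwise_divergence_matrix",
]

DIVERGENCE_NAMES = ("kl", "hellinger", "total_variation", "neyman_chi2")

DEFAULT_CLAMP_EPS = 1e-10


class DimensionError(ValueError):
    """p and q have different lengths."""


class ValidationError(ValueError):
    """A vector is not a probability distribution."""


@dataclass(frozen=True)
class DivergenceSpec:
    """Choice of divergence plus the zero-probability floor.

    Parameters
    ----------
    name
        One of ``kl``, ``hellinger``, ``total_variation``, ``neyman_chi2``.
    clamp_eps
        Floor applied to the denominator distribution (and to p inside
        ``p log p`` terms) before ratio-based divergences; must lie in
        (0, 1e-4].
    """

    name: str = "kl"
    clamp_eps: float = DEFAULT_CLAMP_EPS

    def __post_init__(self) -> None:
        if self.name not in DIVERGENCE_NAMES:
            raise ValidationError(
                f"unknown divergence {self.name!r}; expected one of {DIVERGENCE_NAMES}"
            )
        if not (0.0 < self.clamp_eps <= 1e-4):
            raise ValidationError("clamp_eps must lie in (0, 1e-4]")

    def __call__(self, p: np.ndarray, q: np.ndarray) -> float:
        return get_divergence(self.name)(p, q, clamp_eps=self.clamp_eps)


def as_probability_vector(p, *, atol: float = 1e-9) -> np.ndarray:
    """Validate and return ``p`` as a 1-d probability vector.

    Entries must be nonnegative and sum to one within ``atol``; at least
    two classes are required.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError("probability vector must be 1-d with K >= 2 entries")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("probability vector has non-finite entries")
    if np.any(arr < 0):
        raise ValidationError("probability vector has negative entries")
    if abs(arr.sum() - 1.0) > atol:
        raise ValidationError(f"probabilities sum to {arr.sum():.12g}, not 1")
    return arr


def _check_pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = as_probability_vector(p)
    q = as_probability_vector(q)
    if p.shape != q.shape:
        raise DimensionError(f"length mismatch: {p.size} vs {q.size}")
    return p, q


def _clamp(v: np.ndarray, eps: float) -> np.ndarray:
    """Floor at eps and renormalise; keeps ratios finite near zero.

    Left bitwise untouched when no entry is below the floor, so identical
    arguments give exactly zero divergence.
    """
    if np.all(v >= eps):
        return v
    v = np.maximum(v, eps)
    return v / v.sum()


def kl_divergence(p, q, *, clamp_eps: float = DEFAULT_CLAMP_EPS) -> float:
    """Kullback-Leibler divergence sum p_i log(p_i/q_i), in nats.

    Asymmetric. Zero terms of p contribute 0 (the 0 log 0 convention);
    q is floored at ``clamp_eps`` and renormalised so the ratio is finite.
    """
    p, q = _check_pair(p, q)
    q = _clamp(q, clamp_eps)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def hellinger_distance(p, q, *, clamp_eps: float = DEFAULT_CLAMP_EPS) -> float:
    """Squared Hellinger distance (1/2) sum (sqrt p_i - sqrt q_i)^2, in [0, 1].

    Symmetric; no clamping needed (square roots are defined at zero).
    """
    p, q = _check_pair(p, q)
    return float(0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))


def total_variation(p, q, *, clamp_eps: float = DEFAULT_CLAMP_EPS) -> float:
    """Total-variation distance (1/2) ||p - q||_1, in [0, 1]. Symmetric."""
    p, q = _check_pair(p, q)
    return float(0.5 * np.sum(np.abs(p - q)))


def neyman_chi2(p, q, *, clamp_eps: float = DEFAULT_CLAMP_EPS) -> float:
    """Chi-square divergence sum (p_i - q_i)^2 / q_i.

    Asymmetric; q is floored at ``clamp_eps`` and renormalised.
    """
    p, q = _check_pair(p, q)
    q = _clamp(q, clamp_eps)
    return float(np.sum((p - q) ** 2 / q))


def f_divergence(
    f: Callable[[np.ndarray], np.ndarray],
    p,
    q,
    *,
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> float:
    """Generic f-divergence sum_i q_i f(p_i / q_i) for convex f, f(1) = 0.

    Brute-force evaluation of the defining form; used as the correctness
    oracle for the closed-form divergences above. q is floored and
    renormalised so the ratio is always finite.
    """
    p, q = _check_pair(p, q)
    q = _clamp(q, clamp_eps)
    vals = q * np.asarray(f(p / q), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError("f produced non-finite values on p/q ratios")
    return float(np.sum(vals))


_CLOSED_FORMS = {
    "kl": kl_divergence,
    "hellinger": hellinger_distance,
    "total_variation": total_variation,
    "neyman_chi2": neyman_chi2,
}


def get_divergence(name: str):
    """Return the closed-form divergence function registered under ``name``."""
    try:
        return _CLOSED_FORMS[name]
    except KeyError:
        raise ValidationError(
            f"unknown divergence {name!r}; expected one of {DIVERGENCE_NAMES}"
        ) from None


def pairwise_divergence_matrix(
    P: np.ndarray, Q: np.ndarray, spec: DivergenceSpec
) -> np.ndarray:
    """All divergences D[a, b] = Div(P[a] || Q[b]) between two posterior stacks.

    Vectorised over the (|P| x |Q|) grid; rows of ``P`` and ``Q`` are
    length-K probability vectors. Used by the elicitation loop so scoring
    costs O(|E_u| * |E_o|) array work on cached posteriors rather than
    per-pair Python calls.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.ndim != 2 or Q.ndim != 2 or P.shape[1] != Q.shape[1]:
        raise DimensionError("P and Q must be 2-d with a shared class dimension")
    eps = spec.clamp_eps
    if np.all(Q >= eps):
        Qc = Q
    else:
        Qc = np.maximum(Q, eps)
        Qc = Qc / Qc.sum(axis=1, keepdims=True)
    Pb = P[:, None, :]  # (a, 1, K)
    Qb = Qc[None, :, :]  # (1, b, K)
    if spec.name == "kl":
        ratio = np.where(Pb > 0, Pb / Qb, 1.0)
        return np.sum(np.where(Pb > 0, Pb * np.log(ratio), 0.0), axis=2)
    if spec.name == "hellinger":
        return 0.5 * np.sum((np.sqrt(P[:, None, :]) - np.sqrt(Q[None, :, :])) ** 2, axis=2)
    if spec.name == "total_variation":
        return 0.5 * np.sum(np.abs(P[:, None, :] - Q[None, :, :]), axis=2)
    if spec.name == "neyman_chi2":
        return np.sum((Pb - Qb) ** 2 / Qb, axis=2)
    raise ValidationError(f"unknown divergence {spec.name!r}")
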