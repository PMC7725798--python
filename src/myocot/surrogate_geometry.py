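"""Polynomial surrogates of muscle-tendon length and moment arms.

Each muscle's muscle-tendon length is modeled as a multivariate polynomial
in the joint angles it spans.  The moment arm about DOF j is, by the
principle of virtual work, the negative partial derivative of muscle-tendon
length with respect to angle j; the surrogate enforces this by construction:
moment-arm rows in the regression use the (negated) analytic derivatives of
the same monomial basis, so length and moment arms share one coefficient
vector.  Muscle-tendon velocity is the total time derivative,
v_mt = sum_j (dl/dq_j) qdot_j.

Joint-angle workspaces are sampled with a Latin hypercube design so every
equal-width stratum of each DOF receives exactly one sample.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

__all__ = [
    "GeometrySampleSet",
    "SurrogatePolynomial",
    "latin_hypercube",
    "monomial_exponents",
    "fit_surrogate",
]


def monomial_exponents(n_dofs: int, degree: int) -> list[tuple[int, ...]]:
    """All exponent tuples over ``n_dofs`` variables with total degree <= degree."""
    exps = [
        e
        for e in itertools.product(range(degree + 1), repeat=n_dofs)
        if sum(e) <= degree
    ]
    exps.sort(key=lambda e: (sum(e), e))
    return exps


def _basis(q: np.ndarray, exps: list[tuple[int, ...]]) -> np.ndarray:
    """Design matrix of monomials at sample points q (n_samples x n_dofs)."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    cols = [np.prod(q**np.asarray(e), axis=1) for e in exps]
    return np.column_stack(cols)


def _basis_deriv(q: np.ndarray, exps: list[tuple[int, ...]], j: int) -> np.ndarray:
    """Partial derivative of the monomial basis with respect to variable j."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    cols = []
    for e in exps:
        if e[j] == 0:
            cols.append(np.zeros(q.shape[0]))
        else:
            de = list(e)
            de[j] -= 1
            cols.append(e[j] * np.prod(q**np.asarray(de), axis=1))
    return np.column_stack(cols)


@dataclass
class GeometrySampleSet:
    """Sampled geometry of one muscle: lengths + moment arms over joint angles."""

    muscle: str
    spanned_dofs: list[str]
    joint_angles: np.ndarray  # (n_samples, n_dofs), rad
    lengths: np.ndarray  # (n_samples,), m
    moment_arms: np.ndarray  # (n_samples, n_dofs), m

    def __post_init__(self) -> None:
        self.joint_angles = np.atleast_2d(np.asarray(self.joint_angles, float))
        self.lengths = np.asarray(self.lengths, float)
        self.moment_arms = np.atleast_2d(np.asarray(self.moment_arms, float))
        n, d = self.joint_angles.shape
        if d != len(self.spanned_dofs):
            raise ValueError("angle columns do not match spanned_dofs")
        if self.lengths.shape != (n,) or self.moment_arms.shape != (n, d):
            raise ValueError("inconsistent sample-set shapes")


@dataclass
class SurrogatePolynomial:
    """Fitted length polynomial; moment arms are its negated partials."""

    muscle: str
    spanned_dofs: list[str]
    degree: int
    coefficients: np.ndarray
    fit_rmse_length: float = 0.0
    fit_rmse_momentarm: float = 0.0
    angle_ranges: np.ndarray | None = None  # (n_dofs, 2), fitted workspace

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        self._exps = monomial_exponents(len(self.spanned_dofs), self.degree)
        if self.coefficients.shape[0] != len(self._exps):
            raise ValueError(
                f"{len(self._exps)} coefficients expected for degree "
                f"{self.degree} over {len(self.spanned_dofs)} DOFs"
            )

    def length(self, q: np.ndarray) -> np.ndarray:
        """Muscle-tendon length (m) at joint angles q."""
        return _basis(q, self._exps) @ self.coefficients

    def moment_arms(self, q: np.ndarray) -> np.ndarray:
        """Moment arms (m), one column per spanned DOF: r_j = -dl/dq_j."""
        q2 = np.atleast_2d(np.asarray(q, float))
        out = np.column_stack(
            [
                -(_basis_deriv(q2, self._exps, j) @ self.coefficients)
                for j in range(len(self.spanned_dofs))
            ]
        )
        return out

    def evaluate(
        self, q: np.ndarray, qdot: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(l_mt, v_mt, moment_arms) along a trajectory.

        v_mt is the chain-rule total time derivative sum_j (dl/dq_j) qdot_j
        = -sum_j r_j qdot_j.  Extrapolates (with a warning suppressed to the
        caller's discretion) outside the fitted angle ranges.
        """
        q2 = np.atleast_2d(np.asarray(q, float))
        qd2 = np.atleast_2d(np.asarray(qdot, float))
        l_mt = self.length(q2)
        r = self.moment_arms(q2)
        v_mt = -np.sum(r * qd2, axis=1)
        return l_mt, v_mt, r

    def to_dict(self) -> dict:
        return {
            "muscle": self.muscle,
            "spanned_dofs": list(self.spanned_dofs),
            "degree": self.degree,
            "coefficients": self.coefficients.tolist(),
            "fit_rmse_length": self.fit_rmse_length,
            "fit_rmse_momentarm": self.fit_rmse_momentarm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogatePolynomial":
        return cls(
            muscle=d["muscle"],
            spanned_dofs=list(d["spanned_dofs"]),
            degree=int(d["degree"]),
            coefficients=np.asarray(d["coefficients"], float),
            fit_rmse_length=float(d.get("fit_rmse_length", 0.0)),
            fit_rmse_momentarm=float(d.get("fit_rmse_momentarm", 0.0)),
        )


def save_surrogates(surrogates: dict[str, SurrogatePolynomial], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: s.to_dict() for k, s in surrogates.items()}, fh, indent=1)


def load_surrogates(path) -> dict[str, SurrogatePolynomial]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: SurrogatePolynomial.from_dict(d) for k, d in raw.items()}


def latin_hypercube(
    ranges: np.ndarray, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Latin hypercube sample of joint angles.

    ranges: (n_dofs, 2) array of [lo, hi] per DOF (rad).  Exactly one sample
    falls in each of the n equal-width strata of every DOF; reproducible
    under a fixed seed.
    """
    ranges = np.atleast_2d(np.asarray(ranges, float))
    if n < 1:
        raise ValueError("n must be >= 1")
    if np.any(ranges[:, 1] <= ranges[:, 0]):
        raise ValueError("each range must satisfy lo < hi")
    sampler = qmc.LatinHypercube(d=ranges.shape[0], seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, ranges[:, 0], ranges[:, 1])


def fit_surrogate(
    samples: GeometrySampleSet,
    degree: int = 4,
    momentarm_weight: float = 1.0,
) -> SurrogatePolynomial:
    """Fit length and moment arms simultaneously by stacked least squares.

    Length rows use the monomial basis; moment-arm rows for DOF j use the
    negated analytic partial derivative of the basis with respect to q_j.
    One solve yields the shared coefficient vector, so derivative
    consistency is exact by construction.
    """
    exps = monomial_exponents(len(samples.spanned_dofs), degree)
    n, d = samples.joint_angles.shape
    n_rows = n * (1 + d)
    if n_rows < 10 * len(exps):
        raise ValueError(
            f"{n} samples give {n_rows} equations for {len(exps)} coefficients; "
            "need >= 10x (add samples or lower the degree)"
        )
    blocks = [_basis(samples.joint_angles, exps)]
    rhs = [samples.lengths]
    w = np.sqrt(momentarm_weight)
    for j in range(d):
        blocks.append(-w * _basis_deriv(samples.joint_angles, exps, j))
        rhs.append(w * samples.moment_arms[:, j])
    A = np.vstack(blocks)
    b = np.concatenate(rhs)
    coeffs, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < len(exps):
        raise ValueError(
            f"rank-deficient design ({rank} < {len(exps)}); lower the degree "
            "or widen/add samples"
        )
    surr = SurrogatePolynomial(
        muscle=samples.muscle,
        spanned_dofs=list(samples.spanned_dofs),
        degree=degree,
        coefficients=coeffs,
        angle_ranges=np.column_stack(
            [samples.joint_angles.min(axis=0), samples.joint_angles.max(axis=0)]
        ),
    )
    surr.fit_rmse_length = float(
        np.sqrt(np.mean((surr.length(samples.joint_angles) - samples.lengths) ** 2))
    )
    surr.fit_rmse_momentarm = float(
        np.sqrt(
            np.mean((surr.moment_arms(samples.joint_angles) - samples.moment_arms) ** 2)
        )
    )
    return surr
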