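"""Parameter-uncertainty distributions for the probabilistic analysis.

Cost inputs follow gamma distributions, utilities and utilization
probabilities follow beta distributions (both moment-matched to the
stated mean and standard deviation), and transition-probability rows
are drawn from a Dirichlet whose concentration is calibrated so the
row's largest cell has approximately the stated standard deviation.
A standard deviation of zero always degenerates to a point mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistributionSpec",
    "moment_match_beta",
    "moment_match_gamma",
    "sample_beta",
    "sample_gamma",
    "sample_transition_row",
]

#: Smallest Dirichlet concentration allowed for any cell.
_ALPHA_FLOOR = 1e-3


@dataclass(frozen=True)
class DistributionSpec:
    """Tagged distribution for one uncertain parameter.

    ``kind`` is one of ``gamma``, ``beta``, ``dirichlet-row`` or
    ``fixed``.  ``mean`` is a scalar for the scalar kinds and a
    probability row for ``dirichlet-row``.
    """

    kind: str
    mean: float | np.ndarray
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "beta", "dirichlet-row", "fixed"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.kind == "gamma" and self.sd > 0 and self.mean <= 0:
            raise ValueError("gamma requires mean > 0")
        if self.kind == "beta" and not (0 < self.mean < 1) and self.sd > 0:
            raise ValueError("beta requires mean in (0, 1)")
        if self.kind == "dirichlet-row":
            row = np.asarray(self.mean, dtype=float)
            if np.any(row < 0) or row.sum() <= 0:
                raise ValueError("dirichlet-row means must be non-negative with positive sum")
            object.__setattr__(self, "mean", row / row.sum())

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.kind == "fixed" or self.sd == 0:
            if self.kind == "dirichlet-row":
                row = np.asarray(self.mean, dtype=float)
                return np.broadcast_to(row, (size, row.size)).copy() if size else row.copy()
            return np.full(size, float(self.mean)) if size else float(self.mean)
        if self.kind == "gamma":
            return sample_gamma(self.mean, self.sd, rng, size)
        if self.kind == "beta":
            return sample_beta(self.mean, self.sd, rng, size)
        return sample_transition_row(self.mean, self.sd, rng, size)


def moment_match_beta(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters reproducing a given mean and sd exactly.

    With ``nu = mean(1-mean)/sd^2 - 1``, the shapes are
    ``alpha = mean * nu`` and ``beta = (1-mean) * nu``.

    Raises
    ------
    ValueError
        If the sd is infeasible for a beta distribution, i.e.
        ``sd^2 >= mean(1-mean)``; the message reports the feasible bound.
    """
    if not 0 < mean < 1:
        raise ValueError("beta mean must lie strictly in (0, 1)")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    bound = np.sqrt(mean * (1.0 - mean))
    if sd >= bound:
        raise ValueError(
            f"infeasible beta sd {sd}: must be < sqrt(mean*(1-mean)) = {bound:.6g}"
        )
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def moment_match_gamma(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) reproducing a given mean and sd exactly.

    shape = mean^2 / sd^2, scale = sd^2 / mean.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma moment matching requires mean > 0 and sd > 0")
    return mean**2 / sd**2, sd**2 / mean


def sample_beta(mean, sd, rng: np.random.Generator, size=None):
    """Beta draw(s) moment-matched to (mean, sd); sd = 0 is a point mass."""
    if sd == 0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    a, b = moment_match_beta(mean, sd)
    out = rng.beta(a, b, size=size)
    return out if size is not None else float(out)


def sample_gamma(mean, sd, rng: np.random.Generator, size=None):
    """Gamma draw(s) moment-matched to (mean, sd); sd = 0 is a point mass."""
    if mean == 0 and sd == 0:
        return np.zeros(size) if size is not None else 0.0
    if sd == 0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    shape, scale = moment_match_gamma(mean, sd)
    out = rng.gamma(shape, scale, size=size)
    return out if size is not None else float(out)


def dirichlet_concentration(means: np.ndarray, sd: float) -> np.ndarray:
    """Concentration vector for a transition-row Dirichlet.

    The total concentration ``c`` is chosen so the cell with the largest
    mean ``p*`` has standard deviation ``sd``:
    ``sqrt(p*(1-p*)/(c+1)) = sd  =>  c = p*(1-p*)/sd^2 - 1``.
    Zero-mean cells receive zero concentration mass (they are excluded
    from the draw entirely); every retained concentration is floored at
    a small positive value.
    """
    means = np.asarray(means, dtype=float)
    nz = means[means > 0]
    pmax = nz.max()
    c = pmax * (1.0 - pmax) / sd**2 - 1.0
    alpha = np.maximum(np.maximum(c, _ALPHA_FLOOR) * nz, _ALPHA_FLOOR)
    return alpha

def sample_transition_row(means, sd: float, rng: np.random.Generator, size=None):
    """Sample a probability row that sums to 1, preserving zero cells.

    With ``sd = 0`` the means are returned unchanged.  Otherwise the
    non-zero cells are drawn from a Dirichlet calibrated so the largest
    cell's sd is approximately ``sd`` (see :func:`dirichlet_concentration`);
    zero-mean cells return exactly 0 in every draw.
    """
    means = np.asarray(means, dtype=float)
    if np.any(means < 0) or means.sum() <= 0:
        raise ValueError("means must be non-negative with positive sum")
    means = means / means.sum()
    nz_mask = means > 0
    if sd == 0 or nz_mask.sum() == 1:
        if size is not None:
            return np.broadcast_to(means, (size, means.size)).copy()
        return means.copy()
    alpha = dirichlet_concentration(means, sd)
    if size is not None:
        out = np.zeros((size, means.size))
        out[:, nz_mask] = rng.dirichlet(alpha, size=size)
        return out
    out = np.zeros_like(means)
    out[nz_mask] = rng.dirichlet(alpha)
    return out
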