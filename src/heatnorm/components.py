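"""Variance-component containers and sampler priors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_RESIDUAL_CLASSES = 5

#: Column names used for variance-component draws in posterior chains.
VARCOMP_COLUMNS = (
    "sigma2_a0",
    "sigma_a01",
    "sigma2_a1",
    "sigma2_pe",
    "sigma2_e1",
    "sigma2_e2",
    "sigma2_e3",
    "sigma2_e4",
    "sigma2_e5",
)


@dataclass
class VarianceComponents:
    """(Co)variance components of the reaction-norm model.

    Attributes
    ----------
    G : (2, 2) ndarray
        Additive-genetic covariance matrix of the random intercept and
        slope: ``[[sigma2_a0, sigma_a01], [sigma_a01, sigma2_a1]]``.
    sigma2_pe : float
        Sow permanent-environment variance (repeated across parities).
    sigma2_e : (5,) ndarray
        Residual variance per environmental class (class 1 = most
        comfortable gradient, class 5 = most extreme).
    """

    G: np.ndarray
    sigma2_pe: float
    sigma2_e: np.ndarray = field(
        default_factory=lambda: np.ones(N_RESIDUAL_CLASSES)
    )

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        self.sigma2_e = np.asarray(self.sigma2_e, dtype=float)
        if self.G.shape != (2, 2):
            raise ValueError("G must be 2x2")
        if not np.allclose(self.G, self.G.T):
            raise ValueError("G must be symmetric")
        if np.linalg.eigvalsh(self.G).min() < -1e-10:
            raise ValueError("G must be positive semidefinite")
        if self.sigma2_pe < 0:
            raise ValueError("sigma2_pe must be >= 0")
        if self.sigma2_e.shape != (N_RESIDUAL_CLASSES,) or np.any(self.sigma2_e < 0):
            raise ValueError(
                f"sigma2_e must be {N_RESIDUAL_CLASSES} non-negative values"
            )

    def as_array(self) -> np.ndarray:
        """Flatten to the 9 scalars in :data:`VARCOMP_COLUMNS` order."""
        return np.concatenate(
            [[self.G[0, 0], self.G[0, 1], self.G[1, 1], self.sigma2_pe], self.sigma2_e]
        )

    @classmethod
    def from_array(cls, v) -> "VarianceComponents":
        v = np.asarray(v, dtype=float)
        return cls(
            G=np.array([[v[0], v[1]], [v[1], v[2]]]),
            sigma2_pe=float(v[3]),
            sigma2_e=v[4:9].copy(),
        )


@dataclass
class Priors:
    """Weakly-informative conjugate priors for the Gibbs sampler.

    Fixed effects get a flat prior.  ``G`` gets an inverse-Wishart prior
    with ``nu_g`` degrees of freedom and scale ``S_g``; the scalar
    variances get scaled inverse-chi-square priors with ``nu_s`` degrees
    of freedom and scale ``s2_*``.  Defaults are proper but carry almost
    no weight next to even a few hundred records.
    """

    nu_g: float = 4.0
    S_g: np.ndarray = field(default_factory=lambda: np.eye(2))
    nu_s: float = 4.0
    s2_pe: float = 1.0
    s2_e: float = 1.0

    def __post_init__(self):
        self.S_g = np.asarray(self.S_g, dtype=float)
        if self.nu_g <= 3 or self.nu_s <= 2:
            raise ValueError("prior degrees of freedom too small for proper moments")

    @classmethod
    def scaled(cls, var_y: float, frac: float = 0.1) -> "Priors":
        """Priors with mean ``frac * var_y`` per variance component.

        A unit prior scale is far from weakly informative for variance
        components whose likelihood is flat along a confounding ridge
        (the intercept-genetic vs permanent-environment direction in
        particular): with inverse-Wishart degrees of freedom ``nu_g = 4``
        the prior mean equals the scale matrix, so an identity scale
        quietly pulls weakly-identified variances toward 1.  Scaling the
        prior mean to a fraction of the phenotypic variance keeps the
        prior proper and mild at any measurement scale.
        """
        if var_y <= 0:
            raise ValueError("phenotypic variance must be positive")
        s = frac * var_y
        return cls(nu_g=4.0, S_g=s * np.eye(2), nu_s=4.0, s2_pe=s, s2_e=s)
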