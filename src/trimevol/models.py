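"""Site-class selection regimes (M0, M1a, M2a, M7, M8).

A regime is the generative description shared by the simulator and the
maximum-likelihood fitter: a set of dN/dS classes with probabilities, plus
the transition/transversion ratio kappa.  M7 and M8 draw their omega classes
from a beta(p, q) distribution on (0, 1), discretised into equal-probability
categories represented by their category means (the conventional treatment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betainc, betaincinv

MODEL_IDS = ("M0", "M1a", "M2a", "M7", "M8")

#: number of free parameters beyond branch lengths/scale (kappa included)
FREE_PARAMS = {"M0": 2, "M1a": 3, "M2a": 5, "M7": 3, "M8": 5}

DEFAULT_BETA_NCAT = 10


def discretize_beta(p: float, q: float, ncat: int = DEFAULT_BETA_NCAT) -> np.ndarray:
    """Means of ``ncat`` equal-probability categories of Beta(p, q).

    The conditional mean on quantile bin (x_lo, x_hi) is
    ``p/(p+q) * (I_{x_hi}(p+1, q) - I_{x_lo}(p+1, q)) / (1/ncat)`` with I the
    regularised incomplete beta function.
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be positive")
    edges = betaincinv(p, q, np.linspace(0.0, 1.0, ncat + 1))
    upper = betainc(p + 1.0, q, edges)
    means = (p / (p + q)) * np.diff(upper) * ncat
    return np.clip(means, 0.0, 1.0)


@dataclass(frozen=True)
class SelectionRegime:
    """One mixture-omega selection regime.

    ``omegas`` and ``proportions`` enumerate the site classes; ``beta_p`` /
    ``beta_q`` record the generating beta shape for M7/M8 and ``omega_pos``
    the extra positively selected class of M2a/M8.
    """

    model_id: str
    kappa: float
    omegas: tuple = ()
    proportions: tuple = ()
    beta_p: float | None = None
    beta_q: float | None = None
    omega_pos: float | None = None

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        om = np.asarray(self.omegas, dtype=float)
        pr = np.asarray(self.proportions, dtype=float)
        if om.shape != pr.shape or om.ndim != 1 or om.size == 0:
            raise ValueError("omegas and proportions must be equal-length vectors")
        if np.any(om < 0):
            raise ValueError("omega values must be non-negative")
        if np.any(pr < 0) or abs(pr.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must be non-negative and sum to 1")
        if self.model_id == "M1a":
            if om.size != 2 or om[0] >= 1 or abs(om[1] - 1.0) > 1e-12:
                raise ValueError("M1a requires omegas = [omega0 < 1, 1]")
        if self.model_id == "M2a":
            if om.size != 3 or om[0] >= 1 or abs(om[1] - 1.0) > 1e-12 or om[2] < 1:
                raise ValueError("M2a requires omegas = [omega0 < 1, 1, omega2 >= 1]")
        if self.model_id in ("M2a", "M8") and self.omega_pos is not None:
            if self.omega_pos < 1:
                raise ValueError("omega_pos must be >= 1")
        if self.model_id in ("M7", "M8"):
            if self.beta_p is None or self.beta_q is None:
                raise ValueError(f"{self.model_id} requires beta_p and beta_q")
            if self.beta_p <= 0 or self.beta_q <= 0:
                raise ValueError("beta shape parameters must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.omegas)

    @property
    def positive_class(self) -> int | None:
        """Index of the omega >= 1 'extra' class (M2a/M8), else None."""
        if self.model_id == "M2a":
            return 2
        if self.model_id == "M8":
            return len(self.omegas) - 1
        return None

    # -- factories ------------------------------------------------------

    @classmethod
    def m0(cls, omega: float, kappa: float = 2.0) -> "SelectionRegime":
        return cls("M0", kappa, (omega,), (1.0,))

    @classmethod
    def m1a(cls, p0: float, omega0: float, kappa: float = 2.0) -> "SelectionRegime":
        return cls("M1a", kappa, (omega0, 1.0), (p0, 1.0 - p0))

    @classmethod
    def m2a(
        cls,
        p0: float,
        p1: float,
        omega0: float,
        omega_pos: float,
        kappa: float = 2.0,
    ) -> "SelectionRegime":
        p2 = 1.0 - p0 - p1
        return cls(
            "M2a",
            kappa,
            (omega0, 1.0, omega_pos),
            (p0, p1, p2),
            omega_pos=omega_pos,
        )

    @classmethod
    def m7(
        cls, p: float, q: float, kappa: float = 2.0, ncat: int = DEFAULT_BETA_NCAT
    ) -> "SelectionRegime":
        om = discretize_beta(p, q, ncat)
        pr = np.full(ncat, 1.0 / ncat)
        return cls("M7", kappa, tuple(om), tuple(pr), beta_p=p, beta_q=q)

    @classmethod
    def m8(
        cls,
        p0: float,
        p: float,
        q: float,
        omega_pos: float,
        kappa: float = 2.0,
        ncat: int = DEFAULT_BETA_NCAT,
    ) -> "SelectionRegime":
        om = tuple(discretize_beta(p, q, ncat)) + (omega_pos,)
        pr = tuple(np.full(ncat, p0 / ncat)) + (1.0 - p0,)
        return cls(
            "M8", kappa, om, pr, beta_p=p, beta_q=q, omega_pos=omega_pos
        )
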