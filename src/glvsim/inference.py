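"""Ridge-regression inference of gLV parameters from abundance timecourses.

Dividing the gLV equation by ``z`` gives ``d(ln z)/dt = g + M z + u b``, which
is linear in the parameters.  The fit therefore regresses the matrix ``F`` of
time-scaled log-abundance increments on a design stacking the abundances, a
row of ones (for the growth rates) and the intervention magnitude series:

    (M, g, b) = F^T Ydes^T (Ydes Ydes^T + lambda I)^{-1}

solved as a linear system, never via an explicit inverse.  The method assumes
absolute abundances are observed, wants densely sampled data, and is noise
sensitive; zeros are offset by a small pseudocount before taking logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .exceptions import ConfigurationError, DomainError, InferenceError
from .types import Timecourse

__all__ = ["DesignPair", "GlvFit", "build_design", "concat_designs", "infer_glv_ridge", "fit_timecourses"]

DEFAULT_PSEUDOCOUNT_SCALE = 1e-6  # times the mean positive abundance


@dataclass
class DesignPair:
    """Response/design matrices for the ridge fit.

    ``F`` is ``(T-1) x D``: row ``t`` holds the per-unit-time changes between
    successive samples.  ``Ydes`` is ``(D + 1 + n_interventions) x (T-1)``:
    abundance rows, a row of ones, then intervention magnitude rows.
    """

    F: np.ndarray
    Ydes: np.ndarray

    def __post_init__(self) -> None:
        if self.F.shape[0] != self.Ydes.shape[1]:
            raise ConfigurationError(
                f"F has {self.F.shape[0]} rows but Ydes has {self.Ydes.shape[1]} columns"
            )


@dataclass
class GlvFit:
    """Inferred gLV parameters.

    ``M_hat`` is D x D (per-unit-time per unit abundance), ``g_hat`` length D,
    ``b_hat`` D x n_interventions, and ``lam`` the ridge penalty used.
    """

    M_hat: np.ndarray
    g_hat: np.ndarray
    b_hat: np.ndarray
    lam: float


def build_design(
    Z: np.ndarray,
    times: np.ndarray,
    interventions_u: np.ndarray | None = None,
    pseudocount: float | None = None,
    mode: str = "log",
) -> DesignPair:
    """Assemble the regression pair from one abundance timecourse.

    ``mode="log"`` (default) uses log-increments
    ``(ln(Z[t+1]+c) - ln(Z[t]+c)) / dt``, the transform under which the gLV
    parameters enter linearly; ``mode="linear"`` uses raw increments divided
    by the current abundance, ``(Z[t+1]-Z[t]) / dt / (Z[t]+c)``.  The
    pseudocount ``c`` defaults to 1e-6 times the mean positive abundance.

    ``interventions_u``: optional ``T x n_interventions`` (or length-T)
    magnitude series, truncated to the first T-1 points in the design.
    """
    Z = np.asarray(Z, dtype=float)
    times = np.asarray(times, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise DomainError("Z must be 2-D with at least 2 time points")
    if times.shape != (Z.shape[0],):
        raise DomainError("times must have one entry per row of Z")
    dts = np.diff(times)
    if np.any(dts <= 0):
        raise DomainError("times must be strictly increasing")
    if mode not in ("log", "linear"):
        raise ConfigurationError(f"mode must be 'log' or 'linear', got {mode!r}")

    if pseudocount is None:
        positive = Z[Z > 0]
        pseudocount = DEFAULT_PSEUDOCOUNT_SCALE * (positive.mean() if positive.size else 1.0)
    if pseudocount <= 0:
        raise DomainError("pseudocount must be > 0")

    if mode == "log":
        logZ = np.log(Z + pseudocount)
        F = np.diff(logZ, axis=0) / dts[:, None]
    else:
        F = np.diff(Z, axis=0) / dts[:, None] / (Z[:-1] + pseudocount)

    rows = [Z[:-1].T, np.ones((1, Z.shape[0] - 1))]
    if interventions_u is not None:
        U = np.asarray(interventions_u, dtype=float)
        if U.ndim == 1:
            U = U[:, None]
        if U.shape[0] != Z.shape[0]:
            raise DomainError("interventions_u must have one row per time point")
        rows.append(U[:-1].T)
    return DesignPair(F=F, Ydes=np.vstack(rows))


def concat_designs(designs: list[DesignPair]) -> DesignPair:
    """Pool designs from several individuals into one regression problem."""
    if not designs:
        raise DomainError("need at least one design")
    widths = {d.Ydes.shape[0] for d in designs}
    if len(widths) > 1:
        raise DomainError("designs have inconsistent numbers of predictor rows")
    return DesignPair(
        F=np.vstack([d.F for d in designs]),
        Ydes=np.hstack([d.Ydes for d in designs]),
    )


def infer_glv_ridge(design: DesignPair, lam: float = 1e-6) -> GlvFit:
    """Solve the ridge normal equations and unpack (M, g, b).

    The regularizer is ``lam`` times the identity on all coefficients.  At
    ``lam=0`` a singular system raises an error advising a positive penalty.
    """
    if lam < 0:
        raise ConfigurationError("lambda must be >= 0")
    F, Ydes = design.F, design.Ydes
    D = F.shape[1]
    p = Ydes.shape[0]
    n_interventions = p - D - 1
    if n_interventions < 0:
        raise ConfigurationError(
            f"design has {p} predictor rows, fewer than D + 1 = {D + 1}"
        )
    A = Ydes @ Ydes.T + lam * np.eye(p)
    B = Ydes @ F  # p x D
    try:
        coeffs = scipy.linalg.solve(A, B, assume_a="pos")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        raise InferenceError(
            "normal matrix is singular; use lambda > 0 (ridge) or more time points"
        ) from None
    theta = coeffs.T  # D x p
    return GlvFit(
        M_hat=theta[:, :D],
        g_hat=theta[:, D],
        b_hat=theta[:, D + 1 :],
        lam=lam,
    )


def fit_timecourses(
    timecourses: list[Timecourse],
    lam: float = 1e-6,
    interventions_u: list[np.ndarray] | None = None,
    pseudocount: float | None = None,
    mode: str = "log",
) -> GlvFit:
    """Convenience: build designs from each individual's Z and fit jointly."""
    us = interventions_u or [None] * len(timecourses)
    if len(us) != len(timecourses):
        raise DomainError("interventions_u must match the number of timecourses")
    designs = [
        build_design(tc.Z, tc.times, u, pseudocount=pseudocount, mode=mode)
        for tc, u in zip(timecourses, us)
    ]
    return infer_glv_ridge(concat_designs(designs), lam=lam)
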