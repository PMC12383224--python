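"""The four measurement frameworks for moral-dilemma responses.

Given a participant's four per-category response summaries (PB, PC, AB, AC;
see :mod:`moraldm.dilemma`), this module computes:

* **traditional score** — acceptance rate in the PB cell only (the trolley
  cell, norm-prohibited with benefits > costs); higher = more utilitarian.
* **process dissociation (PD)** — U (utilitarian-driven) and D
  (deontology-driven) parameters from the rejection rates of the two
  norm-prohibited cells.  The forward model is
  ``P(reject | congruent PC) = U + (1-U)·D`` and
  ``P(reject | incongruent PB) = (1-U)·D``; with two observations and two
  parameters the inversion is exact.
* **CNI multinomial processing tree** — a sequential three-branch tree:
  with probability C the response follows consequences; otherwise with
  probability N it follows the norm; otherwise with probability I the
  participant prefers inaction.  Action probabilities per cell:

      p_PB = C + (1-C)(1-N)(1-I)
      p_PC =     (1-C)(1-N)(1-I)
      p_AB = C + (1-C)N + (1-C)(1-N)(1-I)
      p_AC =     (1-C)N + (1-C)(1-N)(1-I)

  Parameters are estimated by product-binomial maximum likelihood with a
  G² goodness-of-fit statistic on 1 df (4 cells, 3 parameters).
* **CAN algebraic decomposition** — linear contrasts of the four cell values
  v_t (acceptance proportions, or mean 1-6 ratings in continuous mode):

      C = ((v_PB + v_AB) - (v_PC + v_AC)) / 2     consequence sensitivity
      N = ((v_AB + v_AC) - (v_PB + v_PC)) / 2     norm sensitivity
      A = (v_PB + v_PC + v_AB + v_AC) / 4         overall action bias

  For noise-free data generated by the CNI tree the two parameterizations
  bridge exactly: CAN C = C, CAN N = (1-C)·N, and
  CAN A = C/2 + (1-C)N/2 + (1-C)(1-N)(1-I).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dilemma import CATEGORIES, CategoryProfile

__all__ = [
    "PDParams",
    "CNIParams",
    "CANParams",
    "CNIFitError",
    "traditional_score",
    "pd_forward",
    "pd_params",
    "cni_predict",
    "cni_invert",
    "cni_loglik",
    "cni_gsq",
    "cni_fit",
    "can_params",
    "estimate_all",
]

_PCLIP = 1e-9
_BOUNDARY_TOL = 1e-6


@dataclass
class PDParams:
    """Process-dissociation parameters; ``D`` is undefined (NaN) when U = 1."""

    U: float
    D: float
    defined: bool = True


@dataclass
class CNIParams:
    C: float
    N: float
    I: float
    gsq: float
    df: int
    fit_p: float
    excluded: bool
    loglik: float
    boundary: tuple[str, ...] = ()
    unidentified: tuple[str, ...] = ()
    converged: bool = True


@dataclass
class CANParams:
    C: float
    A: float
    N: float
    scale: str  # "binary" | "continuous"


class CNIFitError(RuntimeError):
    """Raised when the CNI optimizer fails on every restart."""


def _values_array(profile) -> np.ndarray:
    if isinstance(profile, CategoryProfile):
        return profile.as_array()
    if isinstance(profile, Mapping):
        return np.array([profile[c] for c in CATEGORIES], dtype=float)
    arr = np.asarray(profile, dtype=float)
    if arr.shape[-1] != 4:
        raise ValueError("expected four per-category values in PB, PC, AB, AC order")
    return arr


def traditional_score(profile) -> float:
    """Acceptance proportion in the norm-prohibited benefits>costs (PB) cell.

    Defined on accept/reject data only; a continuous-mode profile is
    rejected because the traditional analysis counts approvals.
    """
    if isinstance(profile, CategoryProfile):
        if profile.mode != "binary":
            raise ValueError("traditional analysis requires a binary-mode profile")
        return float(profile.values["PB"])
    vals = _values_array(profile)
    p = float(vals[..., 0])
    if not 0.0 <= p <= 1.0:
        raise ValueError("PB value outside [0, 1]; is this continuous-mode data?")
    return p


def pd_forward(U: float, D: float) -> tuple[float, float]:
    """PD forward model: rejection probabilities for (congruent, incongruent) cells."""
    return U + (1 - U) * D, (1 - U) * D


def pd_params(p_reject_congruent: float, p_reject_incongruent: float) -> PDParams:
    """Invert the PD forward model from the two prohibited-cell rejection rates.

    ``U = p_reject_congruent - p_reject_incongruent`` and
    ``D = p_reject_incongruent / (1 - U)``; the inversion reproduces both
    inputs exactly.  When U = 1 the D parameter is undefined and flagged.
    """
    for name, p in (("congruent", p_reject_congruent), ("incongruent", p_reject_incongruent)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_reject_{name} must be in [0, 1]")
    U = p_reject_congruent - p_reject_incongruent
    if U >= 1.0:
        return PDParams(U=1.0, D=math.nan, defined=False)
    D = p_reject_incongruent / (1.0 - U)
    return PDParams(U=U, D=D)


def cni_predict(C, N, I) -> np.ndarray:
    """Action probabilities (p_PB, p_PC, p_AB, p_AC) under the CNI tree.

    Broadcasts over array parameters; output has shape ``(..., 4)``.
    """
    C, N, I = np.broadcast_arrays(np.asarray(C, float), np.asarray(N, float), np.asarray(I, float))
    if np.any((C < 0) | (C > 1) | (N < 0) | (N > 1) | (I < 0) | (I > 1)):
        raise ValueError("C, N, I must lie in [0, 1]")
    base = (1 - C) * (1 - N) * (1 - I)  # neither consequences nor norms drive; acts
    norm = (1 - C) * N
    # mathematically in [0, 1]; clip floating-point overshoot at the corners
    return np.clip(np.stack([C + base, base, C + norm + base, norm + base], axis=-1), 0.0, 1.0)


def cni_invert(probs, tol: float = 1e-9):
    """Algebraically invert four cell probabilities to (C, N, I), if possible.

    Uses the closed-form contrasts
    ``C = ((p_PB - p_PC) + (p_AB - p_AC)) / 2``,
    ``N = ((p_AB - p_PB) + (p_AC - p_PC)) / (2(1-C))`` and
    ``I = 1 - p_PC / ((1-C)(1-N))``.  Returns ``None`` (infeasible) when any
    parameter leaves [0, 1], a division degenerates, or the candidate does
    not reproduce the inputs (the tree imposes
    ``p_AB - p_PB = p_AC - p_PC``, so not every quadruple is attainable).
    Never raises on degenerate branches.
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (4,):
        raise ValueError("expected four probabilities (PB, PC, AB, AC)")
    if np.any((p < 0) | (p > 1)):
        return None
    p_pb, p_pc, p_ab, p_ac = p
    C = ((p_pb - p_pc) + (p_ab - p_ac)) / 2.0
    if not -tol <= C <= 1 + tol:
        return None
    C = min(max(C, 0.0), 1.0)
    if C >= 1.0 - tol:
        # Saturating consequence branch: N, I unconstrained; feasible only if
        # the cells actually look like (1, 0, 1, 0).
        cand = (1.0, 0.5, 0.5)
        return cand if np.allclose(cni_predict(*cand), p, atol=max(tol, 1e-8)) else None
    N = ((p_ab - p_pb) + (p_ac - p_pc)) / (2.0 * (1.0 - C))
    if not -tol <= N <= 1 + tol:
        return None
    N = min(max(N, 0.0), 1.0)
    denom = (1.0 - C) * (1.0 - N)
    if denom <= tol:
        I = 0.5  # inaction branch never reached; unconstrained
    else:
        I = 1.0 - p_pc / denom
        if not -tol <= I <= 1 + tol:
            return None
        I = min(max(I, 0.0), 1.0)
    cand = (float(C), float(N), float(I))
    if not np.allclose(cni_predict(*cand), p, atol=max(tol, 1e-8)):
        return None
    return cand


def cni_loglik(k, n, params) -> float:
    """Product-binomial log-likelihood kernel of (C, N, I) given cell counts."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(cni_predict(*params), _PCLIP, 1 - _PCLIP)
    return float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))


def _saturated_loglik(k: np.ndarray, n: np.ndarray) -> float:
    ph = k / n
    # xlogy gives the 0·ln 0 ≡ 0 convention; k > 0 implies ph > 0 and vice versa
    return float(np.sum(special.xlogy(k, ph) + special.xlogy(n - k, 1 - ph)))


def cni_gsq(k, n, params) -> float:
    """Likelihood-ratio goodness-of-fit statistic G² (0·ln 0 ≡ 0)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    return max(0.0, 2.0 * (_saturated_loglik(k, n) - cni_loglik(k, n, params)))


def _flags(params: Sequence[float]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    names = ("C", "N", "I")
    boundary = tuple(
        nm for nm, v in zip(names, params) if v < _BOUNDARY_TOL or v > 1 - _BOUNDARY_TOL
    )
    unidentified: list[str] = []
    C, N, _ = params
    if C > 1 - _BOUNDARY_TOL:
        unidentified += ["N", "I"]  # later branches never reached
    elif N > 1 - _BOUNDARY_TOL:
        unidentified += ["I"]
    return boundary, tuple(unidentified)


def cni_fit(
    k,
    n,
    n_restarts: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
) -> CNIParams:
    """Maximum-likelihood CNI fit to per-category accept counts.

    Parameters
    ----------
    k, n
        Accepts and trials for the four cells in (PB, PC, AB, AC) order.
    n_restarts
        Uniform random restarts added to the algebraic initializer.
    alpha
        Misfit threshold: participants with ``fit_p < alpha`` are flagged
        ``excluded`` (a small goodness-of-fit p indicates the tree does not
        describe their responses).

    Notes
    -----
    When the observed proportions invert algebraically the inverse is the
    (saturated) MLE and G² = 0 exactly; otherwise L-BFGS-B maximizes the
    likelihood over the unit cube from multiple starts.  Estimates within
    1e-6 of a bound are flagged ``boundary``; parameters downstream of a
    saturating branch are flagged ``unidentified``.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if k.shape != (4,) or n.shape != (4,):
        raise ValueError("k and n must each give four cells (PB, PC, AB, AC)")
    if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n with n >= 1 in every cell")

    obs = k / n
    inv = cni_invert(obs)
    if inv is not None:
        ll = cni_loglik(k, n, inv)
        boundary, unidentified = _flags(inv)
        return CNIParams(
            C=inv[0], N=inv[1], I=inv[2],
            gsq=0.0, df=1, fit_p=1.0, excluded=False,
            loglik=ll, boundary=boundary, unidentified=unidentified,
        )

    rng = np.random.default_rng(seed)
    starts = [np.array([0.5, 0.5, 0.5])]
    # partial algebraic initialization: clamp the raw contrasts into the cube
    c0 = np.clip(((obs[0] - obs[1]) + (obs[2] - obs[3])) / 2, 0.0, 1.0)
    if c0 < 1:
        n0 = np.clip(((obs[2] - obs[0]) + (obs[3] - obs[1])) / (2 * (1 - c0)), 0.0, 1.0)
    else:
        n0 = 0.5
    denom = (1 - c0) * (1 - n0)
    i0 = np.clip(1 - obs[1] / denom, 0.0, 1.0) if denom > 1e-9 else 0.5
    starts.append(np.array([c0, n0, i0]))
    starts.extend(rng.uniform(size=(n_restarts, 3)))

    def nll_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        C, N, I = theta
        p = np.clip(cni_predict(C, N, I), _PCLIP, 1 - _PCLIP)
        ll = float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))
        w = k / p - (n - k) / (1 - p)  # d ll / d p_t
        b_c, b_n, b_i = (1 - N) * (1 - I), (1 - C) * (1 - I), (1 - C) * (1 - N)
        # rows: cells (PB, PC, AB, AC); cols: d p / d (C, N, I)
        jac = np.array(
            [
                [1 - b_c, -b_n, -b_i],
                [-b_c, -b_n, -b_i],
                [1 - N - b_c, (1 - C) * I, -b_i],
                [-N - b_c, (1 - C) * I, -b_i],
            ]
        )
        return -ll, -(w @ jac)

    best = None
    any_converged = False
    for s in starts:
        res = optimize.minimize(
            nll_grad, s, method="L-BFGS-B", jac=True, bounds=[(0.0, 1.0)] * 3,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not any_converged:
        raise CNIFitError(
            f"CNI optimizer failed to converge from {len(starts)} starts; counts k={k}, n={n}"
        )
    theta = np.clip(best.x, 0.0, 1.0)
    ll = cni_loglik(k, n, theta)
    gsq = cni_gsq(k, n, theta)
    fit_p = float(stats.chi2.sf(gsq, df=1))
    boundary, unidentified = _flags(theta)
    return CNIParams(
        C=float(theta[0]), N=float(theta[1]), I=float(theta[2]),
        gsq=gsq, df=1, fit_p=fit_p, excluded=bool(fit_p < alpha),
        loglik=ll, boundary=boundary, unidentified=unidentified,
        converged=bool(any_converged),
    )


def can_params(profile, mode: str | None = None) -> CANParams:
    """Algebraic CAN decomposition of the four per-category values.

    Binary mode consumes acceptance proportions (C, N in [-1, 1]; A in
    [0, 1]); continuous mode consumes mean 1-6 ratings in raw rating units
    (C, N in [-5, 5]; A in [1, 6]) so that A sits near the 3.5 scale
    midpoint for neutral responding.
    """
    if isinstance(profile, CategoryProfile):
        mode = profile.mode
    if mode not in ("binary", "continuous"):
        raise ValueError("mode must be 'binary' or 'continuous'")
    v = _values_array(profile)
    lo, hi = (0.0, 1.0) if mode == "binary" else (1.0, 6.0)
    if np.any((v < lo) | (v > hi)):
        raise ValueError(f"{mode} values must lie in [{lo}, {hi}]")
    v_pb, v_pc, v_ab, v_ac = v
    C = ((v_pb + v_ab) - (v_pc + v_ac)) / 2.0
    N = ((v_ab + v_ac) - (v_pb + v_pc)) / 2.0
    A = (v_pb + v_pc + v_ab + v_ac) / 4.0
    return CANParams(C=float(C), A=float(A), N=float(N), scale=mode)


def can_params_arrays(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized CAN contrasts for a (participants x 4) value matrix.

    Returns (C, A, N) arrays; used by the simulation studies where the
    per-participant dataclass wrapper would dominate runtime.
    """
    v = np.asarray(values, dtype=float)
    C = ((v[..., 0] + v[..., 2]) - (v[..., 1] + v[..., 3])) / 2.0
    N = ((v[..., 2] + v[..., 3]) - (v[..., 0] + v[..., 1])) / 2.0
    A = v.mean(axis=-1)
    return C, A, N


def estimate_all(
    profiles_binary: pd.DataFrame,
    profiles_continuous: pd.DataFrame | None = None,
    cni_restarts: int = 20,
    cni_seed: int = 0,
) -> pd.DataFrame:
    """Run every framework on a cohort of per-participant category profiles.

    ``profiles_binary`` (and optionally ``profiles_continuous``) are frames
    as produced by :func:`moraldm.dilemma.aggregate_profiles`.  Returns one
    tidy row per participant with the cell proportions, the traditional
    score, PD U/D, CNI parameters with fit diagnostics, and CAN parameters
    on each available scale.
    """
    rows = []
    for pid, row in profiles_binary.iterrows():
        vals = row[list(CATEGORIES)].to_numpy(dtype=float)
        counts = row[[f"n_{c}" for c in CATEGORIES]].to_numpy(dtype=float)
        pd_est = pd_params(1.0 - vals[1], 1.0 - vals[0])
        k = np.rint(vals * counts)
        cni = cni_fit(k, counts, n_restarts=cni_restarts, seed=cni_seed)
        can_b = can_params(vals, mode="binary")
        rec = {
            "participant_id": pid,
            "p_PB": vals[0], "p_PC": vals[1], "p_AB": vals[2], "p_AC": vals[3],
            "trad_p_action": traditional_score(vals),
            "U": pd_est.U, "D": pd_est.D, "pd_defined": pd_est.defined,
            "C_cni": cni.C, "N_cni": cni.N, "I_cni": cni.I,
            "gsq": cni.gsq, "fit_p": cni.fit_p, "excluded": cni.excluded,
            "C_can": can_b.C, "A_can": can_b.A, "N_can": can_b.N, "scale": "binary",
        }
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("participant_id")
    if profiles_continuous is not None:
        cont = profiles_continuous.loc[out.index]
        C, A, N = can_params_arrays(cont[list(CATEGORIES)].to_numpy(dtype=float))
        out["C_can_cont"] = C
        out["A_can_cont"] = A
        out["N_can_cont"] = N
    return out
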