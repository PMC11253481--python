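"""Linear-programming preselection of catalogue haplotypes.

Evaluating the exact posterior over all combinations of catalogue
haplotypes is exponential in the catalogue size, so haplotypes that
cannot plausibly contribute to the observed allele frequencies are
discarded upfront.  A linear program finds the fraction vector psi on
the simplex minimising the total absolute deviation between the induced
allele frequencies ``sum_i psi_i V[i, j]`` and the maximum a posteriori
estimates ``theta_hat_j``, restricted to variants covered by every
considered haplotype (so the induced-frequency denominator is 1 and the
objective stays linear).  Haplotypes with ``psi_i >= t`` are kept, and
the kept set is extended by haplotypes whose variant pattern differs
from a kept one by at most ``m`` variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .catalog import VariantMatrix

logger = logging.getLogger(__name__)

DEFAULT_T = 0.01
DEFAULT_M = 0


class EmptyCommonSetError(ValueError):
    """No variant is covered by all considered haplotypes; skip pruning."""


@dataclass
class LpResult:
    fractions: np.ndarray  # psi*, on the simplex
    objective: float  # total absolute deviation at the optimum
    retained: list[int] | None = None  # filled in by prune()


def common_variant_indices(
    matrix: VariantMatrix, candidate_rows: list[int] | None = None
) -> list[int]:
    """Variant columns covered by every considered haplotype (the set W)."""
    rows = list(range(matrix.n_haplotypes)) if candidate_rows is None else list(candidate_rows)
    if not rows:
        raise ValueError("candidate_rows must be nonempty")
    if matrix.n_variants == 0:
        return []
    mask = matrix.Cov[rows, :].all(axis=0)
    return [int(j) for j in np.flatnonzero(mask)]


def lp_fit(V_W: np.ndarray, theta_hat: np.ndarray) -> LpResult:
    """Solve min sum_j |sum_i psi_i V[i,j] - theta_hat_j| on the simplex.

    Linearised with one auxiliary deviation variable per variant
    (``d_j >= +-(V^T psi - theta_hat)_j``) and solved exactly with the
    HiGHS simplex method, so results are deterministic.
    """
    V_W = np.asarray(V_W, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    n, w = V_W.shape
    if w == 0:
        raise EmptyCommonSetError(
            "no variant covered by all haplotypes; skip LP preselection"
        )
    if np.any((theta_hat < 0) | (theta_hat > 1)):
        raise ValueError("theta_hat entries must lie in [0,1]")
    # variables: psi (n), d (w); minimise sum d
    c = np.concatenate([np.zeros(n), np.ones(w)])
    # V^T psi - d <= theta_hat  and  -V^T psi - d <= -theta_hat
    A_ub = np.block(
        [[V_W.T, -np.eye(w)], [-V_W.T, -np.eye(w)]]
    )
    b_ub = np.concatenate([theta_hat, -theta_hat])
    A_eq = np.concatenate([np.ones(n), np.zeros(w)])[None, :]
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=[1.0],
        bounds=[(0.0, 1.0)] * n + [(0.0, None)] * w,
        method="highs",
    )
    if not res.success:  # simplex constraint is always feasible
        raise RuntimeError(f"LP solver failed unexpectedly: {res.message}")
    psi = np.clip(res.x[:n], 0.0, 1.0)
    return LpResult(fractions=psi, objective=float(res.fun))


def prune(
    lp: LpResult,
    matrix: VariantMatrix,
    t: float = DEFAULT_T,
    m: int = DEFAULT_M,
) -> list[int]:
    """Keep haplotypes with psi* >= t, extended by near-identical patterns.

    The extension adds every haplotype whose variant set differs from
    some kept haplotype by at most ``m`` variants (symmetric difference
    over all V columns); at ``m = 0`` this admits exactly the haplotypes
    with an identical variant pattern.  Never returns an empty set: if no
    fraction reaches ``t`` the single largest-fraction haplotype is kept.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must be in [0,1], got {t}")
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    psi = lp.fractions
    base = [int(i) for i in np.flatnonzero(psi >= t)]
    if not base:
        base = [int(np.argmax(psi))]
    V = matrix.V.astype(np.int16)
    keep = set(base)
    for i in range(matrix.n_haplotypes):
        if i in keep:
            continue
        diffs = np.abs(V[i] - V[base]).sum(axis=1)
        if diffs.min() <= m:
            keep.add(i)
    retained = sorted(keep)
    lp.retained = retained
    return retained


def preselect_haplotypes(
    matrix: VariantMatrix,
    theta_hat_all: np.ndarray,
    t: float = DEFAULT_T,
    m: int = DEFAULT_M,
) -> tuple[list[int], LpResult | None]:
    """Full preselection: common variants, LP fit, threshold-and-extend.

    ``theta_hat_all`` holds one MAP allele-frequency estimate per matrix
    column.  When no variant is covered by all haplotypes the LP would be
    ill-defined, so pruning is skipped with a warning and every haplotype
    is retained.
    """
    W = common_variant_indices(matrix)
    if not W:
        logger.warning(
            "no variant covered by all haplotypes; skipping LP preselection"
        )
        return list(range(matrix.n_haplotypes)), None
    theta_hat_all = np.asarray(theta_hat_all, dtype=float)
    if theta_hat_all.shape != (matrix.n_variants,):
        raise ValueError("need one theta_hat per variant column")
    lp = lp_fit(matrix.V[:, W], theta_hat_all[W])
    retained = prune(lp, matrix, t=t, m=m)
    return retained, lp
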