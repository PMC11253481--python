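"""Independent reference implementations used only to check the package.

Everything here is deliberately naive: exhaustive enumeration and plain
linear-space arithmetic, no log-sum-exp, no vectorisation, no reuse of
the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Alignment: exhaustive search over all global alignments of two short strings
# ---------------------------------------------------------------------------

def brute_force_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -4.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
):
    """Best affine-gap score and op string over ALL global alignments.

    ``a`` is the reference, ``b`` the query.  An alignment is a path of
    moves D (consume both), U (consume a only: deletion from b), L
    (consume b only: insertion into b).  A gap of length L scores
    gap_open + (L-1) * gap_extend.  Returns (score, ops) with ops a list
    of (op, length) runs using the package's op names.
    """
    best_score = -math.inf
    best_moves: list[list[str]] = []

    def walk(i: int, j: int, moves: list[str], score: float, last: str) -> None:
        nonlocal best_score, best_moves
        if i == len(a) and j == len(b):
            if score > best_score + 1e-9:
                best_score = score
                best_moves = [list(moves)]
            elif abs(score - best_score) <= 1e-9:
                best_moves.append(list(moves))
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            moves.append("D")
            walk(i + 1, j + 1, moves, score + s, "D")
            moves.pop()
        if i < len(a):
            s = gap_extend if last == "U" else gap_open
            moves.append("U")
            walk(i + 1, j, moves, score + s, "U")
            moves.pop()
        if j < len(b):
            s = gap_extend if last == "L" else gap_open
            moves.append("L")
            walk(i, j + 1, moves, score + s, "L")
            moves.pop()

    walk(0, 0, [], 0.0, "")

    def to_ops(moves: list[str]):
        ops = []
        i = j = 0
        for mv, group in itertools.groupby(moves):
            length = len(list(group))
            if mv == "D":
                for t in range(length):
                    kind = "match" if a[i + t] == b[j + t] else "mismatch"
                    if ops and ops[-1][0] == kind:
                        ops[-1] = (kind, ops[-1][1] + 1)
                    else:
                        ops.append((kind, 1))
                i += length
                j += length
            elif mv == "U":
                ops.append(("deletion", length))
                i += length
            else:
                ops.append(("insertion", length))
                j += length
        return tuple(ops)

    return best_score, {to_ops(m) for m in best_moves}


# ---------------------------------------------------------------------------
# Posterior: explicit loops in plain linear-space arithmetic
# ---------------------------------------------------------------------------

def naive_posterior(candidates, V, Cov, observations):
    """Posterior probabilities by direct enumeration, no log-space tricks.

    ``candidates``: list of fraction tuples; ``V``/``Cov``: plain 0/1
    nested lists (n x k); ``observations``: list of
    (variant_index, pi, loglik_alt, loglik_ref, tau) tuples.  Returns a
    list of normalised probabilities, one per candidate, in order.
    """
    n = len(V)
    k = len(V[0]) if n else 0
    likelihoods = []
    for psi in candidates:
        prob = 1.0
        for j in range(k):
            den = sum(Cov[i][j] * psi[i] for i in range(n))
            if den <= 0.0:
                continue  # uncovered: skipped
            num = sum(V[i][j] * psi[i] for i in range(n))
            theta = num / den
            for (vj, pi, la, lr, tau) in observations:
                if vj != j:
                    continue
                p_alt = theta * tau
                mapped = p_alt * math.exp(la) + (1.0 - p_alt) * math.exp(lr)
                background = 0.5 * (math.exp(la) + math.exp(lr))
                prob *= pi * mapped + (1.0 - pi) * background
        likelihoods.append(prob)
    total = math.fsum(likelihoods)
    return [p / total for p in likelihoods]


# ---------------------------------------------------------------------------
# LP: simplex-grid brute force and exact active-set vertex enumeration
# ---------------------------------------------------------------------------

def _objective(psi: np.ndarray, V: np.ndarray, theta: np.ndarray) -> float:
    return float(np.abs(V.T @ psi - theta).sum())


def grid_min_objective(V: np.ndarray, theta: np.ndarray, step: float = 0.01) -> float:
    """Minimum total absolute deviation over the simplex grid.

    Grid points are enumerated via the stars-and-bars bijection
    (divider positions -> compositions) and evaluated in one vectorised
    pass.
    """
    n = V.shape[0]
    units = round(1.0 / step)
    if n == 1:
        return _objective(np.array([1.0]), V, theta)
    dividers = np.fromiter(
        itertools.chain.from_iterable(
            itertools.combinations(range(units + n - 1), n - 1)
        ),
        dtype=np.int64,
    ).reshape(-1, n - 1)
    bounded = np.hstack(
        [
            np.full((len(dividers), 1), -1),
            dividers,
            np.full((len(dividers), 1), units + n - 1),
        ]
    )
    counts = np.diff(bounded, axis=1) - 1  # compositions of `units` into n parts
    psi = counts / units
    dev = np.abs(psi @ V.astype(float) - theta[None, :]).sum(axis=1)
    return float(dev.min())


def identifiable_diploid_instance(
    V: np.ndarray, pair: tuple[int, int], t: float = 0.01
) -> bool:
    """True when every exact-fit mixture keeps mass >= t on both true haplotypes.

    The zero-deviation polytope is {psi >= 0, sum psi = 1, V^T psi = theta}
    with theta induced by the true pair.  If some solution can push a true
    haplotype's fraction below t, an LP vertex dropping it is a valid
    optimum and no method working from theta alone can be required to
    retain the truth.
    """
    from scipy.optimize import linprog

    n, k = V.shape
    a, b = pair
    theta = (V[a] + V[b]) / 2.0
    A_eq = np.vstack([V.T.astype(float), np.ones(n)])
    b_eq = np.concatenate([theta, [1.0]])
    for idx in (a, b):
        c = np.zeros(n)
        c[idx] = 1.0
        res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=[(0, 1)] * n, method="highs")
        if res.success and res.fun < t - 1e-9:
            return False
    return True


def exact_min_objective(V: np.ndarray, theta: np.ndarray) -> float:
    """Exact continuous minimum via enumeration of basic points.

    The objective is convex piecewise linear on the simplex, so a
    minimiser exists where n constraints from {psi_i = 0, psi_i = 1,
    (V^T psi)_j = theta_j, sum psi = 1} are active with full rank.  All
    (n-1)-subsets on top of the simplex equality are enumerated.
    """
    n, k = V.shape
    rows = [(np.eye(n)[i], 0.0) for i in range(n)]
    rows += [(np.eye(n)[i], 1.0) for i in range(n)]
    rows += [(V[:, j].astype(float), float(theta[j])) for j in range(k)]
    ones = np.ones(n)
    best = math.inf
    if n == 1:
        return _objective(np.array([1.0]), V, theta)
    for subset in itertools.combinations(range(len(rows)), n - 1):
        A = np.vstack([ones] + [rows[s][0] for s in subset])
        b = np.array([1.0] + [rows[s][1] for s in subset])
        try:
            psi = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        if np.any(psi < -1e-9) or np.any(psi > 1 + 1e-9):
            continue
        val = _objective(np.clip(psi, 0, 1), V, theta)
        if val < best:
            best = val
    return best


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def weak_composition_count(total_units: int, parts: int) -> int:
    """Number of ways to write total_units as an ordered sum of `parts` >= 0."""
    return math.comb(total_units + parts - 1, parts - 1)
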