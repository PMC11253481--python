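"""Bayesian core: induced allele frequencies and the exact posterior.

The latent quantity is a fraction vector psi on the simplex over the
retained haplotypes.  Under the assumption that the catalogue captures
all variation at the locus, the allele frequency of variant j induced by
psi is

    theta_j = sum_i V[i, j] psi_i / sum_i Cov[i, j] psi_i,

i.e. the mixture weight of carrier haplotypes among those whose
alignment spans the locus.  The joint log-likelihood of psi is the sum
of the per-variant likelihood curves evaluated at the induced
frequencies, and the posterior over an enumerated fraction universe
(diploid {0, 1/2, 1} or a regular simplex grid) follows by exact
normalisation — no sampling is involved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .catalog import VariantMatrix
from .evidence import VafLikelihood

#: relative tolerance under which two log-posteriors count as tied
TIE_RTOL = 1e-9
#: refuse to enumerate continuous-universe grids larger than this
DEFAULT_GRID_BUDGET = 2_000_000


@dataclass(frozen=True)
class FractionUniverse:
    """The admissible per-haplotype fraction values.

    ``discrete`` universes enumerate a finite value set (diploid:
    {0, 0.5, 1}); ``continuous`` universes are approximated by a regular
    simplex grid with ``q`` points per axis, interpreted as a quadrature
    of the continuous posterior.
    """

    kind: str  # "discrete" | "continuous"
    values: tuple[float, ...] = (0.0, 0.5, 1.0)
    q: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise ValueError(f"unknown universe kind {self.kind!r}")
        if self.kind == "discrete":
            if 0.0 not in self.values or any(not 0 <= v <= 1 for v in self.values):
                raise ValueError("discrete universe must contain 0 and lie in [0,1]")
        elif self.q < 2:
            raise ValueError("continuous universe needs q >= 2 grid points")


DIPLOID = FractionUniverse(kind="discrete", values=(0.0, 0.5, 1.0))


@dataclass(frozen=True)
class FractionVector:
    """A point on the haplotype simplex, tagged with its universe."""

    fractions: tuple[float, ...]
    universe: FractionUniverse

    def __post_init__(self) -> None:
        s = math.fsum(self.fractions)
        tol = 0.0 if self.universe.kind == "discrete" else 1e-9
        if abs(s - 1.0) > max(tol, 1e-9):
            raise ValueError(f"fractions sum to {s}, not 1")

    @property
    def support(self) -> tuple[int, ...]:
        return tuple(i for i, f in enumerate(self.fractions) if f > 0)


def induced_vaf(
    psi: Sequence[float], matrix: VariantMatrix, j: int
) -> float | None:
    """Allele frequency of variant j induced by fraction vector psi.

    Returns None when no spanning haplotype has positive fraction (the
    variant is uncovered under psi and must be skipped by the caller).
    Because the coverage matrix includes carriers, the result is always
    in [0, 1].
    """
    psi = np.asarray(psi, dtype=float)
    den = float(matrix.Cov[:, j] @ psi)
    if den <= 0.0:
        return None
    num = float(matrix.V[:, j] @ psi)
    return min(max(num / den, 0.0), 1.0)


def joint_loglik(
    psi: Sequence[float],
    matrix: VariantMatrix,
    likelihoods: Sequence[VafLikelihood],
    return_skipped: bool = False,
):
    """Sum of per-variant likelihood curves at the induced frequencies.

    Variants uncovered under ``psi`` (zero denominator) contribute
    nothing; their count is available via ``return_skipped``.
    """
    total = 0.0
    skipped = 0
    for vl in likelihoods:
        theta = induced_vaf(psi, matrix, vl.variant_index)
        if theta is None:
            skipped += 1
            continue
        total += vl(theta)
    return (total, skipped) if return_skipped else total


def restrict_to_haplotypes(
    matrix: VariantMatrix,
    likelihoods: Sequence[VafLikelihood],
    indices: Sequence[int],
) -> tuple[VariantMatrix, list[VafLikelihood]]:
    """Subset the matrix to retained haplotypes, re-indexing the curves.

    Variant columns that lose their last carrier are dropped; the
    surviving likelihood curves are renumbered to the new column order.
    """
    from .evidence import VafLikelihood as _VL

    sub = matrix.subset_haplotypes(indices)
    col_of = {v: j for j, v in enumerate(sub.variants)}
    out: list[VafLikelihood] = [None] * sub.n_variants  # type: ignore[list-item]
    for old_j, v in enumerate(matrix.variants):
        new_j = col_of.get(v)
        if new_j is not None:
            vl = likelihoods[old_j]
            out[new_j] = _VL(new_j, vl.grid, vl.values, vl.n_fragments)
    return sub, out


def enumerate_diploid(n_retained: int) -> list[FractionVector]:
    """All unordered diploid genotypes over n haplotypes.

    Homozygous i/i gives psi_i = 1; heterozygous i/i' gives
    psi_i = psi_i' = 0.5.  Count: n(n+1)/2, in lexicographic index-pair
    order.
    """
    if n_retained < 1:
        raise ValueError("need at least one haplotype")
    out = []
    for i, i2 in combinations_with_replacement(range(n_retained), 2):
        psi = [0.0] * n_retained
        if i == i2:
            psi[i] = 1.0
        else:
            psi[i] = psi[i2] = 0.5
        out.append(FractionVector(tuple(psi), DIPLOID))
    return out


def grid_candidate_count(n_retained: int, q: int) -> int:
    """Number of simplex grid points: weak compositions of q-1 into n parts."""
    return math.comb(q - 1 + n_retained - 1, n_retained - 1)


def enumerate_grid(
    n_retained: int, q: int, budget: int = DEFAULT_GRID_BUDGET
) -> list[FractionVector]:
    """All fraction vectors on the regular simplex grid with step 1/(q-1).

    Enumeration cost grows as O(q^n); when the candidate count exceeds
    ``budget`` an error advises stronger preselection instead of silently
    attempting the enumeration.
    """
    if n_retained < 1:
        raise ValueError("need at least one haplotype")
    if q < 2:
        raise ValueError("q must be >= 2")
    count = grid_candidate_count(n_retained, q)
    if count > budget:
        raise ValueError(
            f"grid universe would enumerate {count} candidates (> budget "
            f"{budget}); prune the catalogue harder or lower q"
        )
    universe = FractionUniverse(kind="continuous", q=q)
    step_den = q - 1
    out = []

    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            vec = prefix + [remaining]
            out.append(
                FractionVector(tuple(a / step_den for a in vec), universe)
            )
            return
        for a in range(remaining + 1):
            rec(prefix + [a], remaining - a, slots - 1)

    rec([], step_den, n_retained)
    return out


@dataclass
class SolutionSet:
    """Ranked candidate fraction vectors with normalised posteriors.

    ``solutions[r]`` is the rank-r candidate as a tuple of
    ``(haplotype_name, fraction)`` pairs over its support, sorted by
    name; ``log_posteriors[r]`` is its normalised log posterior
    (probability for discrete universes, quadrature mass for grids).
    """

    solutions: list[tuple[tuple[str, float], ...]]
    log_posteriors: np.ndarray
    universe: FractionUniverse
    fraction_vectors: list[FractionVector] | None = None
    haplotype_names: list[str] | None = None
    skipped_variants: list[int] = field(default_factory=list)

    @property
    def probabilities(self) -> np.ndarray:
        return np.exp(self.log_posteriors)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rank, (sol, lp) in enumerate(zip(self.solutions, self.log_posteriors)):
            rows.append(
                {
                    "rank": rank,
                    "solution": ";".join(f"{n}={f:g}" for n, f in sol),
                    "log_posterior": lp,
                    "probability": math.exp(lp),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "universe": self.universe.kind,
                "solutions": [
                    {
                        "haplotypes": {n: f for n, f in sol},
                        "log_posterior": float(lp),
                        "probability": float(math.exp(lp)),
                    }
                    for sol, lp in zip(self.solutions, self.log_posteriors)
                ],
            },
            indent=2,
        )


def _solution_key(sol: tuple[tuple[str, float], ...]) -> tuple:
    return tuple((name, -frac) for name, frac in sol)


def solution_from_psi(
    psi: Sequence[float], haplotype_names: Sequence[str]
) -> tuple[tuple[str, float], ...]:
    pairs = [
        (haplotype_names[i], float(f)) for i, f in enumerate(psi) if f > 0
    ]
    return tuple(sorted(pairs))


def posterior(
    candidates: Sequence[FractionVector],
    matrix: VariantMatrix,
    likelihoods: Sequence[VafLikelihood],
    haplotype_names: Sequence[str] | None = None,
    log_prior: Callable[[FractionVector], float] | None = None,
) -> SolutionSet:
    """Exact posterior over an enumerated candidate set.

    ``log_prior`` maps a candidate to its unnormalised log prior weight
    (default: uniform).  The marginal likelihood is the log-sum-exp over
    all candidates, so discrete posteriors sum to exactly 1; for grid
    universes the same normalisation acts as a regular-grid quadrature
    of the continuous posterior (uniform cell volumes cancel).
    Candidates are ranked by descending posterior, ties broken
    lexicographically by haplotype name.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if haplotype_names is None:
        haplotype_names = matrix.haplotype_names
    n = len(candidates[0].fractions)
    if n != len(haplotype_names) or n != matrix.n_haplotypes:
        raise ValueError("candidate length, names and matrix rows must agree")
    scores = np.empty(len(candidates))
    skipped = []
    for c, cand in enumerate(candidates):
        ll, sk = joint_loglik(
            cand.fractions, matrix, likelihoods, return_skipped=True
        )
        prior = 0.0 if log_prior is None else log_prior(cand)
        scores[c] = prior + ll
        skipped.append(sk)
    if np.all(np.isneginf(scores)):
        raise ValueError("no candidate explains the data (all posteriors zero)")
    log_post = scores - logsumexp(scores)
    sols = [
        solution_from_psi(cand.fractions, haplotype_names) for cand in candidates
    ]
    order = sorted(
        range(len(candidates)),
        key=lambda c: (-log_post[c], _solution_key(sols[c])),
    )
    return SolutionSet(
        solutions=[sols[c] for c in order],
        log_posteriors=log_post[order],
        universe=candidates[0].universe,
        fraction_vectors=[candidates[c] for c in order],
        haplotype_names=list(haplotype_names),
        skipped_variants=[skipped[c] for c in order],
    )
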