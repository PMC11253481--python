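"""Result reporting: field collapsing, call filter, contribution tables.

Haplotype names in HLA-style nomenclature carry colon-separated fields
of increasing resolution; solutions that agree after truncation to two
or three fields can be merged, summing their posterior mass.  A
prediction is only *called* when the group of rank-1 solutions of equal
posterior probability is small (at most ``max_solutions``) and carries
most of the mass (more than ``min_mass``); otherwise the full ranked
solution list is reported as an uncertain result.  The contribution
table makes the model decision transparent by juxtaposing, per variant,
the observed MAP allele frequency with the fraction contributions of the
winning solution's haplotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import catalog as _catalog
from . import evidence as _evidence
from . import model as _model
from . import preselect as _preselect
from .catalog import VariantMatrix
from .model import SolutionSet, FractionVector, TIE_RTOL

logger = logging.getLogger(__name__)

DEFAULT_MAX_SOLUTIONS = 5
DEFAULT_MIN_MASS = 0.7


@dataclass
class CallResult:
    solutions: SolutionSet
    called: bool
    top_group: list[tuple[tuple[str, float], ...]]
    top_group_mass: float


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def truncate_name(name: str, n_fields: int) -> str:
    """Truncate an allele name to its first ``n_fields`` colon-separated fields.

    Names without colons (or with fewer fields) pass through unchanged;
    a ``*``-separated gene prefix (e.g. ``A*01:01:01``) is preserved.
    """
    return ":".join(name.split(":")[:n_fields])


def collapse_solutions(ss: SolutionSet, n_fields: int) -> SolutionSet:
    """Merge solutions indistinguishable at a coarser name resolution.

    Each haplotype name is truncated to ``n_fields`` fields; solutions
    mapping to the same multiset of (truncated name, fraction) pairs are
    merged with their probabilities summed.  Total mass is conserved.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    groups: dict[tuple, list[int]] = {}
    for idx, sol in enumerate(ss.solutions):
        collapsed = tuple(
            sorted((truncate_name(n, n_fields), f) for n, f in sol)
        )
        groups.setdefault(collapsed, []).append(idx)
    sols, log_posts = [], []
    for collapsed, idxs in groups.items():
        sols.append(collapsed)
        log_posts.append(logsumexp(ss.log_posteriors[idxs]))
    order = sorted(
        range(len(sols)),
        key=lambda c: (-log_posts[c], _model._solution_key(sols[c])),
    )
    return SolutionSet(
        solutions=[sols[c] for c in order],
        log_posteriors=np.array([log_posts[c] for c in order]),
        universe=ss.universe,
        haplotype_names=ss.haplotype_names,
    )


def apply_call_filter(
    ss: SolutionSet,
    max_solutions: int = DEFAULT_MAX_SOLUTIONS,
    min_mass: float = DEFAULT_MIN_MASS,
) -> CallResult:
    """Decide whether the top equal-probability group warrants a call.

    The top group is the maximal prefix of rank-1 solutions whose log
    posteriors tie with the best (relative tolerance 1e-9, matching the
    ranking tie-break).  A call is made iff the group has at most
    ``max_solutions`` members and its cumulative mass exceeds
    ``min_mass``.
    """
    if not ss.solutions:
        raise ValueError("empty solution set")
    lp = ss.log_posteriors
    best = lp[0]
    group = [0]
    for r in range(1, len(ss.solutions)):
        if math.isclose(lp[r], best, rel_tol=TIE_RTOL, abs_tol=1e-12):
            group.append(r)
        else:
            break
    mass = float(np.exp(lp[group]).sum())
    called = len(group) <= max_solutions and mass > min_mass
    return CallResult(
        solutions=ss,
        called=called,
        top_group=[ss.solutions[r] for r in group],
        top_group_mass=mass,
    )


def contribution_table(
    winning: FractionVector,
    matrix: VariantMatrix,
    theta_hats: Sequence[float],
) -> pd.DataFrame:
    """Per-variant breakdown of the winning solution's induced frequencies.

    One row per variant: the observed MAP allele frequency, one
    contribution column ``psi_i * V[i, j]`` per retained haplotype with
    positive fraction, the induced frequency, and an ``uncovered`` flag
    when no spanning haplotype has positive fraction (suitable for a
    stacked-bar rendering).
    """
    psi = np.asarray(winning.fractions, dtype=float)
    active = [i for i in range(matrix.n_haplotypes) if psi[i] > 0]
    rows = []
    for j, v in enumerate(matrix.variants):
        theta = _model.induced_vaf(psi, matrix, j)
        row: dict = {
            "variant": v.id,
            "theta_hat": float(theta_hats[j]),
            "induced_theta": np.nan if theta is None else theta,
            "uncovered": theta is None,
        }
        for i in active:
            row[f"contrib[{matrix.haplotype_names[i]}]"] = float(
                psi[i] * matrix.V[i, j]
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Inputs and thresholds for the full quantification pipeline.

    Either ``candidates_vcf`` or (``haplotypes_fasta``, ``reference_fasta``)
    must be given, and either ``bam`` or ``observations_tsv``.
    """

    candidates_vcf: str | None = None
    haplotypes_fasta: str | None = None
    reference_fasta: str | None = None
    region: tuple[str, int, int] | None = None
    bam: str | None = None
    observations_tsv: str | None = None
    universe: str = "diploid"  # "diploid" or "grid:<q>"
    t: float = _preselect.DEFAULT_T
    m: int = _preselect.DEFAULT_M
    max_solutions: int = DEFAULT_MAX_SOLUTIONS
    min_mass: float = DEFAULT_MIN_MASS
    n_fields: int = 0  # 0 = no collapsing
    out_prefix: str | None = None


def _read_fasta(path: str) -> list[_catalog.HaplotypeSeq]:
    from Bio import SeqIO

    return [
        _catalog.HaplotypeSeq(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> CallResult:
    """Run candidates -> evidence -> preselection -> posterior -> call."""
    with _stage("candidates"):
        if config.candidates_vcf:
            matrix = _catalog.read_candidates(config.candidates_vcf)
        elif config.haplotypes_fasta and config.reference_fasta:
            haps = _read_fasta(config.haplotypes_fasta)
            refs = _read_fasta(config.reference_fasta)
            if len(refs) != 1:
                raise ValueError("reference FASTA must hold exactly one sequence")
            matrix = _catalog.build_catalog(
                haps, refs[0].sequence, chrom=refs[0].name
            )
        else:
            raise ValueError(
                "config needs candidates_vcf or haplotypes_fasta+reference_fasta"
            )
        if config.region is not None:
            matrix = _catalog.restrict_to_region(matrix, *config.region)

    with _stage("evidence"):
        if config.bam:
            observations = _evidence.extract_observations(config.bam, matrix)
        elif config.observations_tsv:
            observations = _evidence.read_observations_tsv(
                config.observations_tsv, matrix
            )
        else:
            raise ValueError("config needs bam or observations_tsv")
        likelihoods = _evidence.likelihoods_from_observations(observations, matrix)
        theta_hats = np.array([_evidence.map_vaf(vl) for vl in likelihoods])

    with _stage("preselect"):
        retained, lp = _preselect.preselect_haplotypes(
            matrix, theta_hats, t=config.t, m=config.m
        )
        sub, sub_likelihoods = _model.restrict_to_haplotypes(
            matrix, likelihoods, retained
        )
        kept = {v: j for j, v in enumerate(matrix.variants)}
        sub_theta = theta_hats[[kept[v] for v in sub.variants]]

    with _stage("model"):
        if config.universe == "diploid":
            candidates = _model.enumerate_diploid(sub.n_haplotypes)
        elif config.universe.startswith("grid:"):
            q = int(config.universe.split(":", 1)[1])
            candidates = _model.enumerate_grid(sub.n_haplotypes, q)
        else:
            raise ValueError(f"unknown universe {config.universe!r}")
        ss = _model.posterior(candidates, sub, sub_likelihoods)

    with _stage("reporting"):
        reported = (
            collapse_solutions(ss, config.n_fields) if config.n_fields else ss
        )
        result = apply_call_filter(
            reported, config.max_solutions, config.min_mass
        )
        if config.out_prefix:
            prefix = Path(config.out_prefix)
            prefix.parent.mkdir(parents=True, exist_ok=True)
            reported.to_dataframe().to_csv(
                f"{prefix}.solutions.tsv", sep="\t", index=False
            )
            Path(f"{prefix}.solutions.json").write_text(reported.to_json())
            if ss.fraction_vectors:
                contribution_table(
                    ss.fraction_vectors[0], sub, sub_theta
                ).to_csv(f"{prefix}.contributions.tsv", sep="\t", index=False)
    return result
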