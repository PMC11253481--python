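"""Fragment-level read evidence and per-variant allele-frequency likelihoods.

Every fragment overlapping a candidate variant contributes one
observation summarising (i) the probability that the fragment is mapped
to the right locus (from MAPQ), (ii) the likelihood of its base calls
under the ref and alt alleles (from base qualities), and (iii) the
probability ``tau`` that a fragment from the variant-carrying copy
covers the variant at all.

The per-fragment likelihood as a function of the variant allele
frequency theta is a two-component mixture:

    Pr(Z | theta) = pi * [ theta*tau * Pr(Z|alt) + (1 - theta*tau) * Pr(Z|ref) ]
                  + (1 - pi) * Pr(Z | mis-mapped)

where the mis-mapped background is the uninformative equal mixture of the
two allele likelihoods, so a mis-mapped fragment pulls toward no theta.
Summing fragment log-likelihoods per variant gives the likelihood curve
over theta in [0, 1], tabulated on a regular grid and interpolated
linearly in between.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .catalog import VariantMatrix, VariantRecord

logger = logging.getLogger(__name__)

LOG_QUARTER = math.log(0.25)
LIKELIHOOD_FLOOR = math.log(1e-10)
#: mapping probability assumed when MAPQ is reported as 255 ("unavailable")
DEFAULT_PI_UNAVAILABLE = 0.99
#: error rate of the CIGAR-concordance indel evidence model
DEFAULT_INDEL_EPSILON = 0.01
#: number of grid intervals for the likelihood curve (step 0.01)
DEFAULT_GRID_SIZE = 100

MAPQ_UNAVAILABLE = 255


def mapq_to_prob(
    mapq: int, unavailable_prob: float = DEFAULT_PI_UNAVAILABLE
) -> float:
    """Convert a Phred-scaled MAPQ into the probability of correct mapping.

    MAPQ encodes the posterior probability that the reported locus is
    wrong; the complement ``pi = 1 - 10**(-mapq/10)`` enters the fragment
    likelihood.  MAPQ 255 means "unavailable" and maps to a configurable
    default.
    """
    if mapq < 0:
        raise ValueError(f"MAPQ must be >= 0, got {mapq}")
    if mapq == MAPQ_UNAVAILABLE:
        return unavailable_prob
    return 1.0 - 10.0 ** (-mapq / 10.0)


def allele_likelihoods(
    observed: str, base_qual: int | Sequence[int], variant: VariantRecord
) -> tuple[float, float]:
    """Log-likelihoods of the observed base(s) under the ref and alt alleles.

    With per-base error probability ``eps = 10**(-Q/10)``, a base matching
    the allele has likelihood ``1 - eps`` and a non-matching base
    ``eps / 3``; positions of an MNV multiply (log-likelihoods add).
    Non-ACGT observed bases contribute the uninformative 1/4 to both
    alleles.  Returns ``(loglik_ref, loglik_alt)``, floored at log(1e-10).
    """
    if variant.kind not in ("SNV", "MNV"):
        raise ValueError("allele_likelihoods applies to SNV/MNV variants only")
    observed = observed.upper()
    npos = len(variant.ref_allele)
    if len(observed) != npos:
        raise ValueError(
            f"observed {observed!r} length != variant length {npos}"
        )
    quals = [base_qual] * npos if isinstance(base_qual, int) else list(base_qual)
    if len(quals) != npos:
        raise ValueError("one base quality per variant position required")
    ll_ref = ll_alt = 0.0
    for b, q, r, a in zip(observed, quals, variant.ref_allele, variant.alt_allele):
        if b not in "ACGT":
            logger.warning("non-ACGT base %r observed; treating as uninformative", b)
            ll_ref += LOG_QUARTER
            ll_alt += LOG_QUARTER
            continue
        eps = 10.0 ** (-q / 10.0)
        match_ll = math.log1p(-eps) if eps < 1.0 else LIKELIHOOD_FLOOR
        mismatch_ll = math.log(eps / 3.0) if eps > 0.0 else LIKELIHOOD_FLOOR
        ll_ref += match_ll if b == r else mismatch_ll
        ll_alt += match_ll if b == a else mismatch_ll
    return max(ll_ref, LIKELIHOOD_FLOOR), max(ll_alt, LIKELIHOOD_FLOOR)


@dataclass(frozen=True)
class FragmentObservation:
    """One fragment's evidence at one candidate variant."""

    variant_index: int
    prob_mapped: float  # pi, complement of the MAPQ mis-mapping probability
    loglik_alt: float
    loglik_ref: float
    tau: float = 1.0  # Pr(fragment from the variant copy covers the variant)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_mapped <= 1.0:
            raise ValueError(f"prob_mapped {self.prob_mapped} outside [0,1]")
        if self.loglik_alt > 1e-12 or self.loglik_ref > 1e-12:
            raise ValueError("allele log-likelihoods must be <= 0")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError(f"tau {self.tau} outside (0,1]")


def fragment_loglik(obs: FragmentObservation, theta: float) -> float:
    """Log-likelihood of one fragment at allele frequency ``theta``.

    Marginalises the two Bernoulli latent variables: whether the fragment
    stems from the locus (probability ``pi``) and whether it was sampled
    from the variant allele (probability ``theta * tau``).
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta {theta} outside [0,1]")
    la, lr = obs.loglik_alt, obs.loglik_ref
    p_alt = theta * obs.tau
    # log of the mapped mixture theta*tau*e^la + (1-theta*tau)*e^lr
    if p_alt <= 0.0:
        mapped = lr
    elif p_alt >= 1.0:
        mapped = la
    else:
        mapped = np.logaddexp(math.log(p_alt) + la, math.log1p(-p_alt) + lr)
    background = math.log(0.5) + np.logaddexp(la, lr)
    pi = obs.prob_mapped
    if pi >= 1.0:
        return float(mapped)
    if pi <= 0.0:
        return float(background)
    return float(
        np.logaddexp(math.log(pi) + mapped, math.log1p(-pi) + background)
    )


@dataclass
class VafLikelihood:
    """Per-variant log-likelihood curve over theta in [0, 1].

    Tabulated at ``grid_size + 1`` equally spaced support points; values
    at grid points equal the exact sum of fragment log-likelihoods, and
    evaluation between grid points interpolates linearly.
    """

    variant_index: int
    grid: np.ndarray
    values: np.ndarray
    n_fragments: int

    def __call__(self, theta: float) -> float:
        if not 0.0 <= theta <= 1.0:
            raise ValueError(f"theta {theta} outside [0,1]")
        return float(np.interp(theta, self.grid, self.values))


def variant_likelihood(
    observations: Iterable[FragmentObservation],
    grid_size: int = DEFAULT_GRID_SIZE,
) -> VafLikelihood:
    """Tabulate the summed fragment log-likelihood for one variant.

    All observations must share a variant index; an empty observation
    list yields the constant-zero curve (no evidence).
    """
    obs = list(observations)
    grid = np.linspace(0.0, 1.0, grid_size + 1)
    if not obs:
        return VafLikelihood(-1, grid, np.zeros(grid_size + 1), 0)
    indices = {o.variant_index for o in obs}
    if len(indices) != 1:
        raise ValueError(f"mixed variant indices in observation set: {indices}")
    la = np.array([o.loglik_alt for o in obs])[:, None]
    lr = np.array([o.loglik_ref for o in obs])[:, None]
    pi = np.array([o.prob_mapped for o in obs])[:, None]
    tau = np.array([o.tau for o in obs])[:, None]
    p_alt = np.clip(tau * grid[None, :], 0.0, 1.0)
    with np.errstate(divide="ignore"):
        mapped = np.logaddexp(np.log(p_alt) + la, np.log1p(-p_alt) + lr)
        background = math.log(0.5) + np.logaddexp(la, lr)
        per_frag = np.logaddexp(
            np.log(pi) + mapped, np.log1p(-pi) + background
        )
    values = per_frag.sum(axis=0)
    return VafLikelihood(indices.pop(), grid, values, len(obs))


def map_vaf(vl: VafLikelihood) -> float:
    """Maximum-likelihood allele frequency on the grid (flat prior).

    Ties break toward the smaller theta.
    """
    return float(vl.grid[int(np.argmax(vl.values))])


# ---------------------------------------------------------------------------
# Observation I/O: TSV dialect and BAM extraction
# ---------------------------------------------------------------------------

OBS_COLUMNS = ["variant_index", "mapq", "allele_call", "base_qual"]


def observations_from_table(
    table: pd.DataFrame,
    matrix: VariantMatrix,
    unavailable_prob: float = DEFAULT_PI_UNAVAILABLE,
    tau: float = 1.0,
) -> list[FragmentObservation]:
    """Build observations from the tabular dialect.

    Columns: ``variant_index`` (0-based column in the matrix), ``mapq``,
    ``allele_call`` in {ref, alt, other}, ``base_qual``.  ``other`` means
    the observed base matched neither allele, so both allele likelihoods
    get the mismatch term.
    """
    missing = set(OBS_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"observation table lacks columns {sorted(missing)}")
    out = []
    for row in table.itertuples(index=False):
        j = int(row.variant_index)
        if not 0 <= j < matrix.n_variants:
            raise ValueError(f"variant_index {j} outside matrix (k={matrix.n_variants})")
        eps = 10.0 ** (-float(row.base_qual) / 10.0)
        match_ll = math.log1p(-eps) if eps < 1.0 else LIKELIHOOD_FLOOR
        mismatch_ll = max(math.log(eps / 3.0), LIKELIHOOD_FLOOR) if eps > 0 else LIKELIHOOD_FLOOR
        call = str(row.allele_call)
        if call == "alt":
            lr, la = mismatch_ll, match_ll
        elif call == "ref":
            lr, la = match_ll, mismatch_ll
        elif call == "other":
            lr = la = mismatch_ll
        else:
            raise ValueError(f"allele_call must be ref/alt/other, got {call!r}")
        out.append(
            FragmentObservation(
                variant_index=j,
                prob_mapped=mapq_to_prob(int(row.mapq), unavailable_prob),
                loglik_alt=max(la, LIKELIHOOD_FLOOR),
                loglik_ref=max(lr, LIKELIHOOD_FLOOR),
                tau=tau,
            )
        )
    return out


def read_observations_tsv(
    path: str, matrix: VariantMatrix, **kwargs
) -> list[FragmentObservation]:
    table = pd.read_csv(path, sep="\t")
    return observations_from_table(table, matrix, **kwargs)


def write_observations_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, columns=OBS_COLUMNS)


def likelihoods_from_observations(
    observations: Iterable[FragmentObservation],
    matrix: VariantMatrix,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> list[VafLikelihood]:
    """Group observations by variant and tabulate one curve per variant.

    Variants without observations get the constant-zero (uninformative)
    curve so downstream indexing stays aligned with the matrix columns.
    """
    by_variant: dict[int, list[FragmentObservation]] = {}
    for o in observations:
        by_variant.setdefault(o.variant_index, []).append(o)
    out = []
    for j in range(matrix.n_variants):
        vl = variant_likelihood(by_variant.get(j, []), grid_size=grid_size)
        vl.variant_index = j
        out.append(vl)
    return out


@dataclass
class ExtractionStats:
    n_observations: int = 0
    n_skipped_ambiguous: int = 0
    merged_pairs: int = 0


def extract_observations(
    bam_path: str,
    matrix: VariantMatrix,
    unavailable_prob: float = DEFAULT_PI_UNAVAILABLE,
    indel_epsilon: float = DEFAULT_INDEL_EPSILON,
    tau_indel: dict[int, float] | None = None,
    stats: ExtractionStats | None = None,
) -> list[FragmentObservation]:
    """Extract per-fragment observations from a coordinate-sorted BAM.

    For SNV/MNVs the observed bases and qualities at the variant site are
    read off the alignment; for indels a CIGAR-concordance model is used
    (the fragment supports the alt allele when its CIGAR shows the
    expected gap at the locus, with error rate ``indel_epsilon``).  Read
    pairs spanning the same variant merge into one observation by adding
    allele log-likelihoods and keeping the less confident mapping
    probability.  Fragments with ambiguous placement (clipped or deleted
    at an SNV site) are skipped and counted.
    """
    if stats is None:
        stats = ExtractionStats()
    tau_indel = tau_indel or {}
    try:
        bam = pysam.AlignmentFile(bam_path, "rb")
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot open BAM {bam_path}: {exc}") from exc
    with bam:
        if not bam.has_index():
            raise ValueError(f"BAM {bam_path} is not indexed (coordinate-sorted, indexed BAM required)")
        refs = set(bam.references)
        chroms = {v.chrom for v in matrix.variants}
        if chroms - refs:
            raise ValueError(
                f"BAM {bam_path} lacks reference(s) {sorted(chroms - refs)}"
            )
        # fragment (query name) -> partial evidence per variant
        merged: dict[tuple[str, int], dict] = {}
        for j, v in enumerate(matrix.variants):
            for read in bam.fetch(v.chrom, v.pos - 1, v.end):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                ):
                    continue
                ev = _read_evidence_at(read, v, indel_epsilon)
                if ev is None:
                    stats.n_skipped_ambiguous += 1
                    continue
                lr, la = ev
                pi = mapq_to_prob(read.mapping_quality, unavailable_prob)
                key = (read.query_name, j)
                if key in merged:
                    rec = merged[key]
                    rec["lr"] += lr
                    rec["la"] += la
                    rec["pi"] = min(rec["pi"], pi)
                    stats.merged_pairs += 1
                else:
                    merged[key] = {"j": j, "lr": lr, "la": la, "pi": pi}
    out = []
    for rec in merged.values():
        j = rec["j"]
        out.append(
            FragmentObservation(
                variant_index=j,
                prob_mapped=rec["pi"],
                loglik_alt=max(rec["la"], LIKELIHOOD_FLOOR),
                loglik_ref=max(rec["lr"], LIKELIHOOD_FLOOR),
                tau=tau_indel.get(j, 1.0),
            )
        )
    stats.n_observations = len(out)
    return out


def _read_evidence_at(
    read: pysam.AlignedSegment, variant: VariantRecord, indel_epsilon: float
) -> tuple[float, float] | None:
    """(loglik_ref, loglik_alt) for one read at one variant, or None if ambiguous."""
    if variant.kind in ("SNV", "MNV"):
        pos_map = {
            rpos: qpos
            for qpos, rpos in read.get_aligned_pairs(matches_only=True)
            if rpos is not None
        }
        bases, quals = [], []
        for rpos in range(variant.pos - 1, variant.end):
            qpos = pos_map.get(rpos)
            if qpos is None:
                return None  # deleted/clipped at the site: ambiguous
            bases.append(read.query_sequence[qpos])
            quals.append(read.query_qualities[qpos])
        return allele_likelihoods("".join(bases), quals, variant)

    # Indel: CIGAR concordance at the locus.
    match_ll = math.log1p(-indel_epsilon)
    mismatch_ll = math.log(indel_epsilon)
    start, end = read.reference_start, read.reference_end  # 0-based half-open
    anchor0 = variant.pos - 1  # 0-based anchor base
    if start > anchor0 or end < variant.end + 1:
        return None  # does not fully span the locus plus one base
    has_gap = False
    ref_cursor = start
    expected_len = abs(len(variant.alt_allele) - len(variant.ref_allele))
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M/=/X consume both
            ref_cursor += length
        elif op == 2:  # D consumes reference
            if (
                variant.kind == "deletion"
                and ref_cursor == anchor0 + 1
                and length == expected_len
            ):
                has_gap = True
            ref_cursor += length
        elif op == 1:  # I consumes query only
            if (
                variant.kind == "insertion"
                and ref_cursor == anchor0 + 1
                and length == expected_len
            ):
                has_gap = True
        # S/H/N/P do not affect the locus check here
    if has_gap:
        return (mismatch_ll, match_ll)
    return (match_ll, mismatch_ll)
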