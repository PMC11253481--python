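"""Seeded synthetic-data generation for end-to-end testing and calibration.

The generator emulates the model's own generative story: a random
reference, a catalogue of haplotypes defined by distinct planted variant
patterns, a latent fraction vector, and per-variant fragment
observations with Phred-scaled base-call noise and MAPQ-encoded
mis-mapping.  It emits in-memory objects and, on request, plain-text
artifacts (FASTA pair, candidates VCF, observation and truth TSVs).

What it does *not* emulate: read-level sequences and alignment, indel
realignment ambiguity, non-uniform error profiles, or coverage biases —
fragment counts per variant are simply Poisson around the target depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import catalog as _catalog
from . import evidence as _evidence
from . import model as _model
from . import preselect as _preselect
from . import reporting as _reporting
from .catalog import HaplotypeSeq, VariantMatrix, VariantRecord

BASES = "ACGT"
#: minimum spacing between planted variant anchor positions
MIN_SPACING = 10


@dataclass
class Catalogue:
    """A simulated reference + haplotype catalogue with known truth."""

    reference: str
    chrom: str
    haplotypes: list[HaplotypeSeq]
    matrix: VariantMatrix  # exact planted V/Cov (full-length haplotypes)
    planted: dict[str, list[VariantRecord]]

    def save(self, out_dir: str) -> dict[str, str]:
        """Write reference FASTA, haplotype FASTA, candidates VCF, truth TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": str(out / "reference.fasta"),
            "haplotypes": str(out / "haplotypes.fasta"),
            "candidates": str(out / "candidates.vcf"),
            "truth": str(out / "truth.tsv"),
        }
        _write_fasta(paths["reference"], [(self.chrom, self.reference)])
        _write_fasta(
            paths["haplotypes"],
            [(h.name, h.sequence) for h in self.haplotypes],
        )
        _catalog.write_candidates(self.matrix, paths["candidates"])
        rows = [
            {"haplotype": name, "variant": v.id}
            for name, vs in self.planted.items()
            for v in vs
        ]
        pd.DataFrame(rows, columns=["haplotype", "variant"]).to_csv(
            paths["truth"], sep="\t", index=False
        )
        return paths


def _write_fasta(path: str, records: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _apply_variants(reference: str, variants: list[VariantRecord]) -> str:
    """Apply non-overlapping variants (sorted by pos) right-to-left."""
    seq = reference
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        start = v.pos - 1
        assert seq[start : start + len(v.ref_allele)] == v.ref_allele
        seq = seq[:start] + v.alt_allele + seq[start + len(v.ref_allele) :]
    return seq


def make_catalogue(
    n_haplotypes: int,
    n_variants: int,
    ref_length: int = 400,
    seed: int = 0,
    chrom: str = "ref",
    mnv_fraction: float = 0.0,
    indel_fraction: float = 0.0,
    max_indel_len: int = 3,
) -> Catalogue:
    """Plant distinct variant patterns into a random reference.

    Variant sites are spaced at least 10 bp apart and away from the
    sequence ends; alleles are SNVs by default, with optional MNV and
    indel quotas.  Every haplotype receives a distinct binary carrier
    pattern and every variant has at least one carrier.  Fully
    reproducible from ``seed``.
    """
    if n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    if n_variants > ref_length // MIN_SPACING:
        raise ValueError(
            f"{n_variants} variants do not fit in ref_length {ref_length} "
            f"at {MIN_SPACING} bp spacing"
        )
    if n_variants and 2**n_variants < n_haplotypes:
        raise ValueError(
            f"cannot give {n_haplotypes} haplotypes distinct patterns over "
            f"{n_variants} variants"
        )
    rng = np.random.default_rng(seed)
    reference = "".join(rng.choice(list(BASES), size=ref_length))

    # Spaced anchor positions, keeping 5 bp clear of both ends.
    lo, hi = 6, ref_length - 5 - max_indel_len
    positions = []
    candidates_pos = np.arange(lo, hi)
    rng.shuffle(candidates_pos)
    for p in candidates_pos:
        if len(positions) == n_variants:
            break
        if all(abs(p - q) >= MIN_SPACING for q in positions):
            positions.append(int(p))
    if len(positions) < n_variants:
        raise ValueError("could not place variants with required spacing")
    positions.sort()

    variants: list[VariantRecord] = []
    for p in positions:
        u = rng.random()
        ref_base = reference[p - 1]
        if u < indel_fraction:
            length = int(rng.integers(1, max_indel_len + 1))
            if rng.random() < 0.5:  # insertion after the anchor
                ins = "".join(rng.choice(list(BASES), size=length))
                raw = VariantRecord(chrom, p, ref_base, ref_base + ins)
            else:  # deletion of the bases following the anchor
                deleted = reference[p : p + length]
                raw = VariantRecord(chrom, p, ref_base + deleted, ref_base)
            # store the left-aligned (VCF-normalised) representation; if a
            # repeat run would shift it into the previous variant's buffer,
            # plant a plain SNV instead
            norm = _catalog._left_align_indel(
                chrom, raw.pos, raw.ref_allele, raw.alt_allele, reference
            )
            if norm.pos >= p - 3:
                variants.append(norm)
            else:
                alt = rng.choice([b for b in BASES if b != ref_base])
                variants.append(VariantRecord(chrom, p, ref_base, str(alt)))
        elif u < indel_fraction + mnv_fraction:
            ref_run = reference[p - 1 : p + 1]
            alt_run = "".join(
                rng.choice([b for b in BASES if b != r]) for r in ref_run
            )
            variants.append(VariantRecord(chrom, p, ref_run, alt_run))
        else:
            alt = rng.choice([b for b in BASES if b != ref_base])
            variants.append(VariantRecord(chrom, p, ref_base, str(alt)))

    # Distinct carrier patterns with every variant column nonzero.
    k = len(variants)
    patterns: list[tuple[int, ...]] = []
    if k:
        seen = set()
        guard = 0
        while len(patterns) < n_haplotypes:
            pat = tuple(int(b) for b in rng.integers(0, 2, size=k))
            if pat not in seen:
                seen.add(pat)
                patterns.append(pat)
            guard += 1
            if guard > 10000 * n_haplotypes:  # pragma: no cover
                raise RuntimeError("pattern sampling stalled")
        V = np.array(patterns, dtype=np.int8)
        for j in np.flatnonzero(V.sum(axis=0) == 0):
            # give an uncarried variant to the haplotype whose pattern
            # stays unique after the flip (deterministic scan)
            for i in range(n_haplotypes):
                trial = V.copy()
                trial[i, j] = 1
                rows = {tuple(r) for r in trial.tolist()}
                if len(rows) == n_haplotypes:
                    V = trial
                    break
            else:  # pragma: no cover
                raise RuntimeError("cannot repair uncarried variant")
        patterns = [tuple(row) for row in V.tolist()]
    else:
        V = np.zeros((n_haplotypes, 0), dtype=np.int8)

    names = [f"H*{i + 1:02d}:01:01" for i in range(n_haplotypes)]
    planted: dict[str, list[VariantRecord]] = {}
    haplotypes = []
    for i, name in enumerate(names):
        mine = [v for j, v in enumerate(variants) if k and V[i, j]]
        planted[name] = mine
        haplotypes.append(HaplotypeSeq(name, _apply_variants(reference, mine)))
    Cov = np.ones_like(V)  # full-length haplotypes span every locus
    matrix = VariantMatrix(
        names, list(variants), V, Cov, {chrom: ref_length}
    )
    return Catalogue(reference, chrom, haplotypes, matrix, planted)


@dataclass
class SimulationTruth:
    """Ground truth and noise parameters of one simulated sample."""

    seed: int
    catalogue: Catalogue
    true_fractions: _model.FractionVector
    depth: float = 30.0
    base_error_q: int = 30
    mapq: int = 60
    mismap_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def simulate_observations(truth: SimulationTruth) -> pd.DataFrame:
    """Draw per-variant fragment observations from the generative model.

    Per variant: a Poisson(depth) number of fragments, each sampled from
    a spanning haplotype with probability proportional to its fraction.
    The fragment reports the haplotype's allele, flipped to a uniformly
    chosen wrong base with probability ``10**(-Q/10)``; with probability
    ``mismap_rate`` the fragment is mis-mapped — its MAPQ drops to 0 and
    its base is uniform over all four.  Returns the tabular observation
    dialect (variant_index, mapq, allele_call, base_qual).
    """
    cat = truth.catalogue
    matrix = cat.matrix
    psi = np.asarray(truth.true_fractions.fractions, dtype=float)
    rng = np.random.default_rng(truth.seed)
    eps = 10.0 ** (-truth.base_error_q / 10.0)
    rows = []
    for j, v in enumerate(matrix.variants):
        spanning = np.flatnonzero(matrix.Cov[:, j])
        weights = psi[spanning]
        total = weights.sum()
        if total <= 0:
            continue  # variant uncovered under the truth
        weights = weights / total
        count = rng.poisson(truth.depth)
        for _ in range(count):
            hap = int(rng.choice(spanning, p=weights))
            carries = bool(matrix.V[hap, j])
            mapq = truth.mapq
            if rng.random() < truth.mismap_rate:
                mapq = 0
                call = str(rng.choice(["ref", "alt", "other", "other"]))
            else:
                call = _noisy_call(carries, v, eps, rng)
            rows.append(
                {
                    "variant_index": j,
                    "mapq": mapq,
                    "allele_call": call,
                    "base_qual": truth.base_error_q,
                }
            )
    return pd.DataFrame(rows, columns=_evidence.OBS_COLUMNS)


def _noisy_call(carries: bool, v: VariantRecord, eps: float, rng) -> str:
    """Sequencing-noise channel for one fragment's allele call."""
    if v.kind in ("SNV",):
        true_base = v.alt_allele if carries else v.ref_allele
        if rng.random() < eps:
            base = str(rng.choice([b for b in BASES if b != true_base]))
        else:
            base = true_base
        if base == v.alt_allele:
            return "alt"
        if base == v.ref_allele:
            return "ref"
        return "other"
    # MNV/indel: per-fragment misclassification with probability eps
    truth_call = "alt" if carries else "ref"
    if rng.random() < eps:
        return "ref" if truth_call == "alt" else "alt"
    return truth_call


def random_diploid_truth(
    n_haplotypes: int, rng: np.random.Generator
) -> _model.FractionVector:
    """Uniformly random unordered diploid genotype over the catalogue."""
    candidates = _model.enumerate_diploid(n_haplotypes)
    return candidates[int(rng.integers(len(candidates)))]


def identifiable_diploid_truths(matrix: VariantMatrix) -> list[_model.FractionVector]:
    """Diploid genotypes whose induced frequency vector is unique.

    Two unordered pairs whose carrier-pattern sums coincide induce the
    same allele frequencies at every variant and are indistinguishable
    from fragment data by any method; a recovery study is only
    well-posed on the identifiable genotypes.
    """
    candidates = _model.enumerate_diploid(matrix.n_haplotypes)
    signatures = []
    for cand in candidates:
        sig = tuple(
            -1.0 if (t := _model.induced_vaf(cand.fractions, matrix, j)) is None else round(t, 9)
            for j in range(matrix.n_variants)
        )
        signatures.append(sig)
    counts: dict[tuple, int] = {}
    for sig in signatures:
        counts[sig] = counts.get(sig, 0) + 1
    return [c for c, sig in zip(candidates, signatures) if counts[sig] == 1]


@dataclass
class RecoveryConfig:
    n_haplotypes: int = 10
    n_variants: int = 6
    ref_length: int = 400
    depth: float = 30.0
    base_error_q: int = 30
    mapq: int = 60
    mismap_rate: float = 0.01
    t: float = _preselect.DEFAULT_T
    m: int = _preselect.DEFAULT_M
    max_solutions: int = _reporting.DEFAULT_MAX_SOLUTIONS
    min_mass: float = _reporting.DEFAULT_MIN_MASS


def run_replicate(
    seed: int, config: RecoveryConfig
) -> dict:
    """One simulate-and-recover replicate of the full calling path."""
    cat = make_catalogue(
        config.n_haplotypes,
        config.n_variants,
        ref_length=config.ref_length,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    # condition on identifiable truths: pairs sharing their pattern sum
    # with another pair are indistinguishable from fragment data
    identifiable = identifiable_diploid_truths(cat.matrix)
    if identifiable:
        truth_vec = identifiable[int(rng.integers(len(identifiable)))]
    else:  # pragma: no cover - tiny catalogues only
        truth_vec = random_diploid_truth(config.n_haplotypes, rng)
    truth = SimulationTruth(
        seed=seed + 2,
        catalogue=cat,
        true_fractions=truth_vec,
        depth=config.depth,
        base_error_q=config.base_error_q,
        mapq=config.mapq,
        mismap_rate=config.mismap_rate,
    )
    obs_table = simulate_observations(truth)
    observations = _evidence.observations_from_table(obs_table, cat.matrix)
    likelihoods = _evidence.likelihoods_from_observations(observations, cat.matrix)
    theta_hats = np.array([_evidence.map_vaf(vl) for vl in likelihoods])

    retained, _lp = _preselect.preselect_haplotypes(
        cat.matrix, theta_hats, t=config.t, m=config.m
    )
    sub, sub_likelihoods = _model.restrict_to_haplotypes(
        cat.matrix, likelihoods, retained
    )
    candidates = _model.enumerate_diploid(sub.n_haplotypes)
    ss = _model.posterior(candidates, sub, sub_likelihoods)
    call = _reporting.apply_call_filter(
        ss, config.max_solutions, config.min_mass
    )

    truth_sol = _model.solution_from_psi(
        truth_vec.fractions, cat.matrix.haplotype_names
    )
    truth_retained = all(
        i in retained for i in truth_vec.support
    )
    correct = truth_sol in call.top_group
    return {
        "seed": seed,
        "truth": ";".join(f"{n}={f:g}" for n, f in truth_sol),
        "top": ";".join(f"{n}={f:g}" for n, f in ss.solutions[0]),
        "correct": bool(correct),
        "called": bool(call.called),
        "truth_retained": bool(truth_retained),
        "n_retained": len(retained),
        "top_probability": float(np.exp(ss.log_posteriors[0])),
        "top_group_mass": float(call.top_group_mass),
    }


def recovery_experiment(
    n_reps: int, config: RecoveryConfig | None = None, master_seed: int = 0
) -> pd.DataFrame:
    """Run repeated simulate-and-recover replicates; one summary row each."""
    config = config or RecoveryConfig()
    rows = [
        run_replicate(master_seed + 10 * r, config) for r in range(n_reps)
    ]
    return pd.DataFrame(rows)


def summarize_recovery(table: pd.DataFrame) -> dict:
    """Aggregate a recovery experiment: mode accuracy and call rate."""
    n = len(table)
    called = table["called"]
    return {
        "n_reps": n,
        "mode_accuracy": float(table["correct"].mean()) if n else float("nan"),
        "call_rate": float(called.mean()) if n else float("nan"),
        "accuracy_among_called": float(table.loc[called, "correct"].mean())
        if called.any()
        else float("nan"),
        "wrong_called": int((called & ~table["correct"]).sum()),
    }
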