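"""Candidate-variant catalogue construction.

A haplotype catalogue (e.g. the known alleles of an HLA locus) is turned
into a set of candidate variants by aligning every haplotype sequence
against a common reference and extracting the differences.  The catalogue
is then summarised by two binary haplotype-by-variant matrices:

* ``V[i, j] = 1`` — haplotype *i* carries variant *j*;
* ``Cov[i, j] = 1`` — haplotype *i*'s alignment spans the locus of
  variant *j* (inclusive of carriers, so ``V <= Cov`` elementwise).

``Cov`` is the denominator matrix of the induced variant allele frequency
(see :mod:`haploquant.model`); storing it inclusively guarantees induced
frequencies stay within [0, 1].

The matrices are serialised to a multi-sample VCF 4.2 with one sample
column per haplotype and FORMAT fields ``GT`` (the V entry) and ``C``
(the Cov entry).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


class CatalogError(ValueError):
    """Invalid catalogue input (sequences, matrices or regions)."""


class VcfParseError(ValueError):
    """A candidates VCF could not be parsed; the message names the line."""


@dataclass(frozen=True)
class HaplotypeSeq:
    """A named haplotype sequence over the alphabet {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise CatalogError("haplotype name must be nonempty")
        if not self.sequence:
            raise CatalogError(f"haplotype {self.name!r}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise CatalogError(
                f"haplotype {self.name!r}: invalid bases {sorted(bad)}"
            )


@dataclass(frozen=True, order=True)
class VariantRecord:
    """One candidate variant in VCF-style left-anchored representation.

    ``pos`` is the 1-based reference coordinate of the first affected base
    (for indels: of the shared one-base left anchor).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CatalogError(f"variant position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise CatalogError("ref and alt alleles must differ")
        if not self.ref_allele or not self.alt_allele:
            raise CatalogError("alleles must be nonempty")

    @property
    def kind(self) -> str:
        nr, na = len(self.ref_allele), len(self.alt_allele)
        if nr == na == 1:
            return "SNV"
        if nr == na:
            return "MNV"
        return "insertion" if na > nr else "deletion"

    @property
    def end(self) -> int:
        """1-based inclusive last reference base of the variant locus."""
        return self.pos + len(self.ref_allele) - 1

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


# Alignment operation codes.
MATCH = "match"
MISMATCH = "mismatch"
INSERTION = "insertion"  # bases present in the haplotype, absent from the reference
DELETION = "deletion"  # reference bases absent from the haplotype


@dataclass(frozen=True)
class AlignOp:
    op: str
    length: int
    hap_subseq: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise CatalogError("alignment op length must be >= 1")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of one haplotype against (a window of) the reference.

    Terminal gap operations are trimmed, so ``ref_start`` points at the
    first reference base aligned to a haplotype base and the consumed
    reference length equals the aligned span.
    """

    hap_name: str
    ref_start: int  # 1-based inclusive
    ops: tuple[AlignOp, ...]

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based closed interval of reference coordinates covered."""
        consumed = sum(o.length for o in self.ops if o.op != INSERTION)
        return self.ref_start, self.ref_start + consumed - 1


def _make_aligner(
    match: float = 1.0,
    mismatch: float = -4.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    # N scores as a mismatch against everything, including itself.
    m = np.full((5, 5), mismatch)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch
    m[:, 4] = mismatch
    aligner.substitution_matrix = substitution_matrices.Array(
        "ACGTN", dims=2, data=m
    )
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.mode = "global"
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def pairwise_align(
    hap: HaplotypeSeq,
    ref: str,
    window: tuple[int, int] | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> PairwiseAlignment:
    """Globally align a haplotype against the reference with affine gaps.

    Scoring defaults: match +1, mismatch -4, gap open -6, gap extend -1
    (a length-L gap scores -6 - (L-1)).  ``window`` restricts the
    reference to a 1-based closed interval; coordinates in the result are
    always on the full reference.  Deterministic: among co-optimal
    alignments the aligner's first reported one is used.
    """
    if not ref:
        raise CatalogError("reference sequence is empty")
    offset = 0
    if window is not None:
        lo, hi = window
        if lo < 1 or hi > len(ref) or lo > hi:
            raise CatalogError(f"window {window} outside reference bounds")
        ref = ref[lo - 1 : hi]
        offset = lo - 1
    ref = ref.upper()
    hap_seq = hap.sequence.upper()
    if aligner is None:
        aligner = _DEFAULT_ALIGNER
    aln = aligner.align(ref, hap_seq)[0]

    ops: list[AlignOp] = []
    coords = aln.coordinates
    ref_aln_start: int | None = None
    ref_pos = 0
    for c in range(coords.shape[1] - 1):
        r0, r1 = int(coords[0, c]), int(coords[0, c + 1])
        q0, q1 = int(coords[1, c]), int(coords[1, c + 1])
        if r1 > r0 and q1 > q0:
            if ref_aln_start is None:
                ref_aln_start = r0
            # Aligned block: split into maximal match/mismatch runs.
            run_op: str | None = None
            run_start = 0
            block_r, block_q = ref[r0:r1], hap_seq[q0:q1]
            for t in range(len(block_r)):
                same = block_r[t] == block_q[t] and block_r[t] != "N"
                op = MATCH if same else MISMATCH
                if op != run_op:
                    if run_op is not None:
                        ops.append(
                            AlignOp(run_op, t - run_start, block_q[run_start:t])
                        )
                    run_op, run_start = op, t
            ops.append(AlignOp(run_op, len(block_r) - run_start, block_q[run_start:]))
        elif r1 > r0:
            ops.append(AlignOp(DELETION, r1 - r0))
        else:
            ops.append(AlignOp(INSERTION, q1 - q0, hap_seq[q0:q1]))
        ref_pos = r1

    # Trim terminal gap ops: they reflect length differences between the
    # haplotype and the reference window, not variants.
    while ops and ops[0].op in (INSERTION, DELETION):
        if ops[0].op == DELETION:
            ref_aln_start = (ref_aln_start or 0)
        ops.pop(0)
    while ops and ops[-1].op in (INSERTION, DELETION):
        ops.pop()
    if not ops:
        raise CatalogError(
            f"haplotype {hap.name!r}: alignment has no aligned bases"
        )
    if ref_aln_start is None:
        ref_aln_start = 0
    return PairwiseAlignment(
        hap_name=hap.name, ref_start=offset + ref_aln_start + 1, ops=tuple(ops)
    )


def _left_align_indel(
    chrom: str, pos: int, ref_allele: str, alt_allele: str, ref: str
) -> VariantRecord:
    """Shift a left-anchored indel left through repeats (VCF normalisation)."""
    ref_a, alt_a = ref_allele, alt_allele
    while (
        pos > 1
        and len(ref_a) != len(alt_a)
        and ref_a[-1] == alt_a[-1]
        and ref_a[0] == alt_a[0]
    ):
        prev = ref[pos - 2].upper()
        ref_a = prev + ref_a[:-1]
        alt_a = prev + alt_a[:-1]
        pos -= 1
    return VariantRecord(chrom, pos, ref_a, alt_a)


def extract_variants(
    aln: PairwiseAlignment, ref: str, chrom: str = "ref"
) -> list[VariantRecord]:
    """Extract SNV/MNV/indel records from a pairwise alignment.

    Each maximal run of adjacent mismatches yields one record (length 1:
    SNV, length >= 2: MNV); each gap yields one left-anchored, left-aligned
    indel.  Records containing N in either allele are dropped with a
    warning.  Records are returned sorted by position.
    """
    ref = ref.upper()
    out: list[VariantRecord] = []
    pos = aln.ref_start  # 1-based position of next reference base
    for op in aln.ops:
        if op.op == MATCH:
            pos += op.length
        elif op.op == MISMATCH:
            ref_run = ref[pos - 1 : pos - 1 + op.length]
            out.append(VariantRecord(chrom, pos, ref_run, op.hap_subseq.upper()))
            pos += op.length
        elif op.op == DELETION:
            if pos == aln.ref_start:
                raise CatalogError("gap op at alignment start (no left anchor)")
            anchor = ref[pos - 2]
            deleted = ref[pos - 1 : pos - 1 + op.length]
            out.append(
                _left_align_indel(chrom, pos - 1, anchor + deleted, anchor, ref)
            )
            pos += op.length
        elif op.op == INSERTION:
            if pos == aln.ref_start:
                raise CatalogError("gap op at alignment start (no left anchor)")
            anchor = ref[pos - 2]
            out.append(
                _left_align_indel(
                    chrom, pos - 1, anchor, anchor + op.hap_subseq.upper(), ref
                )
            )
        else:  # pragma: no cover - exhaustive
            raise CatalogError(f"unknown op {op.op!r}")
    kept = []
    for v in out:
        if "N" in v.ref_allele or "N" in v.alt_allele:
            warnings.warn(f"dropping variant {v.id} containing N")
            continue
        kept.append(v)
    return sorted(kept, key=lambda v: (v.chrom, v.pos, v.ref_allele, v.alt_allele))


@dataclass
class VariantMatrix:
    """Binary haplotype-by-variant matrices V (carries) and Cov (spans).

    Invariants: ``V[i, j] = 1`` implies ``Cov[i, j] = 1``; every variant
    column of V has at least one carrier.
    """

    haplotype_names: list[str]
    variants: list[VariantRecord]
    V: np.ndarray
    Cov: np.ndarray
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, k = len(self.haplotype_names), len(self.variants)
        self.V = np.asarray(self.V, dtype=np.int8).reshape(n, k)
        self.Cov = np.asarray(self.Cov, dtype=np.int8).reshape(n, k)
        if len(set(self.haplotype_names)) != n:
            raise CatalogError("duplicate haplotype names")
        if np.any(self.V > self.Cov):
            raise CatalogError("V=1 entry without coverage (V must imply Cov)")
        if k and not np.all(self.V.sum(axis=0) >= 1):
            raise CatalogError("variant column with no carrier")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_names)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_haplotypes(self, indices: Sequence[int]) -> "VariantMatrix":
        """Row subset; drops variant columns that lose all carriers."""
        idx = list(indices)
        names = [self.haplotype_names[i] for i in idx]
        V, Cov = self.V[idx, :], self.Cov[idx, :]
        keep = np.flatnonzero(V.sum(axis=0) >= 1) if self.n_variants else []
        return VariantMatrix(
            names,
            [self.variants[j] for j in keep],
            V[:, keep] if self.n_variants else V,
            Cov[:, keep] if self.n_variants else Cov,
            dict(self.contig_lengths),
        )


def build_matrices(
    per_haplotype: Mapping[str, tuple[Iterable[VariantRecord], tuple[str, int, int]]],
    contig_lengths: Mapping[str, int] | None = None,
) -> VariantMatrix:
    """Assemble V/Cov from per-haplotype variant lists and aligned spans.

    ``per_haplotype`` maps each haplotype name to its extracted variants
    and its aligned reference span ``(chrom, start, end)`` (1-based
    closed).  Variant columns are the sorted union by
    (chrom, pos, ref, alt); coverage is 1 when the whole variant locus
    lies inside the haplotype's span, so carriers are always covered.
    """
    names = list(per_haplotype)
    if len(set(names)) != len(names):
        raise CatalogError("duplicate haplotype names")
    union: set[VariantRecord] = set()
    for vlist, _span in per_haplotype.values():
        union.update(vlist)
    variants = sorted(union, key=lambda v: (v.chrom, v.pos, v.ref_allele, v.alt_allele))
    col = {v: j for j, v in enumerate(variants)}
    n, k = len(names), len(variants)
    V = np.zeros((n, k), dtype=np.int8)
    Cov = np.zeros((n, k), dtype=np.int8)
    for i, name in enumerate(names):
        vlist, (chrom, start, end) = per_haplotype[name]
        for j, v in enumerate(variants):
            if v.chrom == chrom and start <= v.pos and v.end <= end:
                Cov[i, j] = 1
        for v in vlist:
            V[i, col[v]] = 1
            Cov[i, col[v]] = 1  # carriers are covered by definition
    return VariantMatrix(names, variants, V, Cov, dict(contig_lengths or {}))


def build_catalog(
    haplotypes: Sequence[HaplotypeSeq],
    reference: str,
    chrom: str = "ref",
    window: tuple[int, int] | None = None,
) -> VariantMatrix:
    """Convenience: align every haplotype, extract variants, build matrices."""
    per_hap = {}
    for hap in haplotypes:
        aln = pairwise_align(hap, reference, window=window)
        variants = extract_variants(aln, reference, chrom=chrom)
        lo, hi = aln.ref_span
        per_hap[hap.name] = (variants, (chrom, lo, hi))
    return build_matrices(per_hap, contig_lengths={chrom: len(reference)})


def restrict_to_region(
    matrix: VariantMatrix, chrom: str, start: int, end: int
) -> VariantMatrix:
    """Keep only variant columns with ``pos`` inside a 1-based closed interval.

    Columns whose V becomes all-zero cannot occur (restriction keeps whole
    columns), but columns outside the region are dropped with their Cov.
    """
    if start > end:
        raise CatalogError(f"inverted interval {start}-{end}")
    keep = [
        j
        for j, v in enumerate(matrix.variants)
        if v.chrom == chrom and start <= v.pos <= end
    ]
    dropped = matrix.n_variants - len(keep)
    if dropped:
        logger.warning("restrict_to_region: dropped %d variant(s)", dropped)
    return VariantMatrix(
        list(matrix.haplotype_names),
        [matrix.variants[j] for j in keep],
        matrix.V[:, keep],
        matrix.Cov[:, keep],
        dict(matrix.contig_lengths),
    )


_VCF_FORMAT_LINES = (
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haplotype carries the variant (1) or not (0)">',
    '##FORMAT=<ID=C,Number=1,Type=Integer,Description="Haplotype alignment spans the variant locus (carriers included)">',
)


def write_candidates(matrix: VariantMatrix, path: str) -> None:
    """Serialise a VariantMatrix to a VCF 4.2 candidates file.

    One sample column per haplotype; FORMAT ``GT`` holds the V entry as a
    single unphased allele and FORMAT ``C`` holds the Cov entry.
    """
    header = pysam.VariantHeader()
    chroms = sorted({v.chrom for v in matrix.variants})
    for chrom in chroms:
        length = matrix.contig_lengths.get(chrom)
        if length:
            header.add_line(f"##contig=<ID={chrom},length={length}>")
        else:
            header.add_line(f"##contig=<ID={chrom}>")
    for line in _VCF_FORMAT_LINES:
        header.add_line(line)
    for name in matrix.haplotype_names:
        header.add_sample(name)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for j, v in enumerate(matrix.variants):
            rec = vf.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref_allele),
                alleles=(v.ref_allele, v.alt_allele),
            )
            for i, name in enumerate(matrix.haplotype_names):
                rec.samples[name]["GT"] = (int(matrix.V[i, j]),)
                rec.samples[name]["C"] = int(matrix.Cov[i, j])
            vf.write(rec)


def read_candidates(path: str) -> VariantMatrix:
    """Parse a candidates VCF back into a VariantMatrix (inverse of write)."""
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vf:
        if "C" not in vf.header.formats:
            raise VcfParseError(
                f"{path}: missing FORMAT=C header line (coverage matrix field)"
            )
        if "GT" not in vf.header.formats:
            raise VcfParseError(f"{path}: missing FORMAT=GT header line")
        names = list(vf.header.samples)
        contig_lengths = {
            c.name: c.length for c in vf.header.contigs.values() if c.length
        }
        variants: list[VariantRecord] = []
        V_rows: list[list[int]] = []
        C_rows: list[list[int]] = []
        for rec in vf:
            line = f"{rec.chrom}:{rec.pos}"
            if rec.alts is None or len(rec.alts) != 1:
                raise VcfParseError(
                    f"{path}: record {line}: exactly one ALT allele required"
                )
            variants.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alts[0])
            )
            v_col, c_col = [], []
            for name in names:
                s = rec.samples[name]
                gt = s.get("GT")
                c = s.get("C")
                if gt is None or gt[0] is None or c is None:
                    raise VcfParseError(
                        f"{path}: record {line}: sample {name} lacks GT or C"
                    )
                v_col.append(int(gt[0]))
                c_col.append(int(c))
            V_rows.append(v_col)
            C_rows.append(c_col)
    n, k = len(names), len(variants)
    V = np.array(V_rows, dtype=np.int8).T if k else np.zeros((n, 0), dtype=np.int8)
    C = np.array(C_rows, dtype=np.int8).T if k else np.zeros((n, 0), dtype=np.int8)
    return VariantMatrix(names, variants, V, C, contig_lengths)
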