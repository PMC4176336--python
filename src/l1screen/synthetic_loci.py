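"""Synthetic L1 locus cohorts with known ground truth.

The screen's statistical premise is that genomic full-length L1 copies are
reference-like sequences carrying point substitutions, nonsense mutations,
indels and 5' truncations.  This module generates exactly that structure so
every downstream stage can be tested against labels that are true by
construction: each locus is the reference element plus a background
substitution process plus zero or more injected, recorded mutations.

Background substitutions are by default *constrained*: a proposed
substitution that would create a stop codon inside either ORF, or touch an
ORF start codon, is re-drawn or dropped.  This keeps the ground-truth labels
exact (background noise never silently converts a locus into a screen hit);
an unconstrained mode lifts the restriction for stress testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, MutationSpecError
from .reference_models import (
    AA_TO_CODONS,
    STOP_CODONS,
    ReferenceModel,
    translate_cds,
)

LOCUS_CLASSES = (
    "screen_hit",
    "intact_both_orfs",
    "orf1_broken",
    "orf2_frameshift",
    "orf2_gap",
    "truncated_5p",
)

#: default cohort composition (fractions by class)
DEFAULT_CLASS_MIX = {
    "screen_hit": 0.25,
    "intact_both_orfs": 0.15,
    "orf1_broken": 0.20,
    "orf2_frameshift": 0.15,
    "orf2_gap": 0.10,
    "truncated_5p": 0.15,
}

#: default per-site background substitution rate
DEFAULT_BACKGROUND_RATE = 0.02

MUTATION_KINDS = (
    "substitution",
    "nonsense",
    "missense_at",
    "frameshift_indel",
    "inframe_indel",
    "five_prime_truncation",
)


@dataclass(frozen=True)
class LocusRecord:
    """One candidate L1 locus on its element-sense strand."""

    locus_id: str
    sequence: str
    source: tuple[str, int, int, str] | None = None  # (chrom, start, end, strand)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"{self.locus_id}: empty sequence")
        if set(self.sequence.upper()) - set("ACGTN"):
            bad = sorted(set(self.sequence.upper()) - set("ACGTN"))
            raise InputError(f"{self.locus_id}: invalid characters {bad}")


@dataclass(frozen=True)
class MutationSpec:
    """One injected mutation, positioned in reference coordinates.

    ``position`` is a 1-based amino-acid coordinate for ``nonsense`` and
    ``missense_at`` (within the ORF selected by ``orf``) and a 1-based
    nucleotide coordinate on the reference element for every other kind.
    For indels, a set ``payload`` means insertion (after ``position``) and
    an unset payload means deletion of ``length`` nt starting at
    ``position``.
    """

    kind: str
    position: int = 0
    payload: str | None = None
    length: int = 0
    orf: int = 2

    def __post_init__(self) -> None:
        if self.kind not in MUTATION_KINDS:
            raise MutationSpecError(f"unknown mutation kind {self.kind!r}")
        if self.kind == "frameshift_indel" and self.length % 3 == 0:
            raise MutationSpecError("frameshift_indel length must not be divisible by 3")
        if self.kind == "inframe_indel" and self.length % 3 != 0:
            raise MutationSpecError("inframe_indel length must be divisible by 3")

    def describe(self) -> str:
        parts = [f"{self.kind}@{self.position}"]
        if self.length:
            parts.append(f"len={self.length}")
        if self.payload:
            parts.append(f"payload={self.payload}")
        if self.kind in ("nonsense", "missense_at"):
            parts.append(f"orf={self.orf}")
        return ",".join(parts)


@dataclass(frozen=True)
class GroundTruth:
    """Generator label for one synthetic locus."""

    locus_class: str
    true_first_stop_aa: int | None
    injected_mutations: tuple[MutationSpec, ...]
    background_rate: float


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# single mutations


def _replace_codon(seq: list[str], reference: ReferenceModel, spec_orf: int,
                   aa_pos: int, codon: str) -> None:
    lo, hi = reference.codon_nt_span(aa_pos, which_orf=spec_orf)
    seq[lo - 1 : hi] = list(codon)


def apply_mutation(
    reference: ReferenceModel,
    base_sequence: str,
    spec: MutationSpec,
    seed: int | np.random.Generator = 0,
) -> str:
    """Apply one mutation to ``base_sequence`` (reference coordinates).

    The caller is responsible for applying coordinate-shifting mutations
    (indels, truncation) after codon-level ones, or right-to-left.
    """
    rng = _as_rng(seed)
    seq = list(base_sequence)
    n = len(seq)

    if spec.kind == "substitution":
        if not 1 <= spec.position <= n:
            raise MutationSpecError(f"substitution position {spec.position} outside sequence")
        if not spec.payload or spec.payload.upper() not in "ACGT":
            raise MutationSpecError("substitution payload must be a single base")
        seq[spec.position - 1] = spec.payload.upper()

    elif spec.kind == "nonsense":
        codon = spec.payload.upper() if spec.payload else None
        if codon is None:
            codon = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
        if codon not in STOP_CODONS:
            raise MutationSpecError(f"nonsense payload {spec.payload!r} is not a stop codon")
        n_aa = reference.orf_aa_length(spec.orf)
        if not 1 <= spec.position <= n_aa:
            raise MutationSpecError(
                f"nonsense position {spec.position} outside ORF{spec.orf} (1..{n_aa})"
            )
        _replace_codon(seq, reference, spec.orf, spec.position, codon)

    elif spec.kind == "missense_at":
        if not spec.payload or spec.payload.upper() not in AA_TO_CODONS:
            raise MutationSpecError(f"missense payload {spec.payload!r} is not encodable")
        n_aa = reference.orf_aa_length(spec.orf)
        if not 1 <= spec.position <= n_aa:
            raise MutationSpecError(
                f"missense position {spec.position} outside ORF{spec.orf} (1..{n_aa})"
            )
        lo, hi = reference.codon_nt_span(spec.position, which_orf=spec.orf)
        current = "".join(seq[lo - 1 : hi])
        choices = AA_TO_CODONS[spec.payload.upper()]
        # minimal-change codon, alphabetical tie-break
        codon = min(choices, key=lambda c: (sum(a != b for a, b in zip(c, current)), c))
        _replace_codon(seq, reference, spec.orf, spec.position, codon)

    elif spec.kind in ("frameshift_indel", "inframe_indel"):
        if spec.length == 0:
            return base_sequence
        if spec.payload is not None:  # insertion after `position`
            if len(spec.payload) != spec.length:
                raise MutationSpecError("indel payload length != length field")
            if not 0 <= spec.position <= n:
                raise MutationSpecError(f"insertion position {spec.position} outside sequence")
            seq[spec.position : spec.position] = list(spec.payload.upper())
        else:  # deletion starting at `position`
            if not 1 <= spec.position <= n - spec.length + 1:
                raise MutationSpecError(f"deletion {spec.position}+{spec.length} outside sequence")
            del seq[spec.position - 1 : spec.position - 1 + spec.length]

    elif spec.kind == "five_prime_truncation":
        if not 0 <= spec.length < n:
            raise MutationSpecError(f"truncation length {spec.length} outside sequence")
        seq = seq[spec.length :]

    return "".join(seq)


# ---------------------------------------------------------------------------
# stop-position samplers

def uniform_stop_sampler(reference: ReferenceModel) -> Callable[[np.random.Generator], int]:
    """Uniform over ORF2 aa positions [2, orf2_aa_length]."""
    hi = reference.orf2_aa_length

    def sample(rng: np.random.Generator) -> int:
        return int(rng.integers(2, hi + 1))

    return sample


def figure2_like_stop_sampler(
    reference: ReferenceModel, scale_aa: float = 250.0
) -> Callable[[np.random.Generator], int]:
    """Early-ORF2-weighted sampler (truncated geometric-like decay).

    Provided for visual comparison with empirical first-stop histograms,
    which concentrate mass early in ORF2; not used for recovery testing.
    """
    hi = reference.orf2_aa_length

    def sample(rng: np.random.Generator) -> int:
        while True:
            pos = 2 + int(rng.exponential(scale_aa))
            if pos <= hi:
                return pos

    return sample


# ---------------------------------------------------------------------------
# background substitution process


def _orf_index(reference: ReferenceModel) -> dict[int, tuple[int, int, int]]:
    """Map 0-based nt index -> (orf, codon_start0, offset) for ORF positions."""
    out: dict[int, tuple[int, int, int]] = {}
    for which in (1, 2):
        s, e = reference.orf_span(which)
        for i in range(s - 1, e):
            off = (i - (s - 1)) % 3
            out[i] = (which, i - off, off)
    return out


def apply_background(
    sequence: str,
    reference: ReferenceModel,
    rate: float,
    rng: np.random.Generator,
    constrained: bool = True,
) -> str:
    """Apply i.i.d. per-site substitutions at ``rate`` (reference coordinates).

    In constrained mode a draw is re-proposed among the remaining bases if it
    would create a stop codon inside an ORF, and sites inside either ORF
    start codon are skipped, so labels derived from injected mutations stay
    exact.  Indels are never part of the background process.
    """
    if not 0.0 <= rate <= 0.1:
        raise ConfigurationError(f"background_rate must be in [0, 0.1], got {rate}")
    if rate == 0.0:
        return sequence
    seq = list(sequence)
    orf_idx = _orf_index(reference)
    start_codons = set()
    for which in (1, 2):
        s, _ = reference.orf_span(which)
        start_codons.update(range(s - 1, s + 2))
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        i = int(i)
        old = seq[i]
        alts = [b for b in "ACGT" if b != old]
        order = rng.permutation(3)
        if not constrained:
            seq[i] = alts[int(order[0])]
            continue
        if i in start_codons:
            continue
        info = orf_idx.get(i)
        for j in order:
            cand = alts[int(j)]
            if info is None:
                seq[i] = cand
                break
            _, cstart, off = info
            codon = seq[cstart : cstart + 3]
            codon[off] = cand
            if "".join(codon) not in STOP_CODONS:
                seq[i] = cand
                break
        # all three alternatives create a stop -> site left unchanged
    return "".join(seq)


# ---------------------------------------------------------------------------
# cohort generation


def _nt_anchor(spec: MutationSpec, reference: ReferenceModel) -> int:
    """Reference nt coordinate used to order right-to-left application."""
    if spec.kind in ("nonsense", "missense_at"):
        return reference.codon_nt_span(spec.position, which_orf=spec.orf)[0]
    if spec.kind == "five_prime_truncation":
        return 0
    return spec.position


def _draw_mutations(
    locus_class: str,
    reference: ReferenceModel,
    rng: np.random.Generator,
    stop_sampler: Callable[[np.random.Generator], int],
    truncation_range: tuple[int, int],
) -> list[MutationSpec]:
    o2s, o2e = reference.orf2_span
    o1s, o1e = reference.orf1_span
    muts: list[MutationSpec] = []

    def orf2_stops() -> list[MutationSpec]:
        k = 1 + int(rng.binomial(2, 0.3))
        positions = sorted({stop_sampler(rng) for _ in range(k)})
        return [MutationSpec("nonsense", pos, orf=2) for pos in positions]

    if locus_class == "screen_hit":
        muts += orf2_stops()
    elif locus_class == "intact_both_orfs":
        pass
    elif locus_class == "orf1_broken":
        if rng.random() < 0.5:
            pos = int(rng.integers(2, reference.orf1_aa_length + 1))
            muts.append(MutationSpec("nonsense", pos, orf=1))
        else:
            nt = int(rng.integers(o1s + 3, o1e - 6))
            length = int(rng.choice([1, 2]))
            if rng.random() < 0.5:
                payload = "".join(rng.choice(list("ACGT"), size=length))
                muts.append(MutationSpec("frameshift_indel", nt, payload, length))
            else:
                muts.append(MutationSpec("frameshift_indel", nt, None, length))
        if rng.random() < 0.5:
            muts += orf2_stops()
    elif locus_class == "orf2_frameshift":
        nt = int(rng.integers(o2s + 3, o2e - 12))
        length = int(rng.choice([1, 2]))
        if rng.random() < 0.5:
            payload = "".join(rng.choice(list("ACGT"), size=length))
            muts.append(MutationSpec("frameshift_indel", nt, payload, length))
        else:
            muts.append(MutationSpec("frameshift_indel", nt, None, length))
        if rng.random() < 0.5:
            muts += orf2_stops()
    elif locus_class == "orf2_gap":
        nt = int(rng.integers(o2s + 30, o2e - 60))
        length = 3 * int(rng.integers(1, 9))
        if rng.random() < 0.5:
            payload = "".join(rng.choice(list("ACGT"), size=length))
            muts.append(MutationSpec("inframe_indel", nt, payload, length))
        else:
            muts.append(MutationSpec("inframe_indel", nt, None, length))
    elif locus_class == "truncated_5p":
        lo, hi = truncation_range
        muts.append(MutationSpec("five_prime_truncation", 0, None, int(rng.integers(lo, hi + 1))))
    else:
        raise ConfigurationError(f"unknown locus class {locus_class!r}")
    return muts


def generate_cohort(
    reference: ReferenceModel,
    n: int,
    class_mix: dict[str, float] | None = None,
    background_rate: float = DEFAULT_BACKGROUND_RATE,
    stop_position_sampler: Callable[[np.random.Generator], int] | None = None,
    seed: int = 0,
    constrained_background: bool = True,
    truncation_range: tuple[int, int] | None = None,
) -> list[tuple[LocusRecord, GroundTruth]]:
    """Generate ``n`` synthetic loci with ground-truth labels.

    Classes are drawn i.i.d. from ``class_mix``; each locus then receives its
    class-defining mutations plus the background substitution process.
    Per-locus random streams are split from the master seed by locus index,
    so loci are reproducible independently of batch size.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    if any(v < 0 for v in mix.values()):
        raise ConfigurationError(f"negative class proportions: {mix}")
    unknown = set(mix) - set(LOCUS_CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown classes in mix: {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"class proportions sum to {total}, expected 1")
    classes = [c for c in LOCUS_CLASSES if mix.get(c, 0) > 0]
    probs = np.array([mix[c] for c in classes])

    sampler = stop_position_sampler or uniform_stop_sampler(reference)
    ref_len = len(reference.full_length_nt)
    if truncation_range is None:
        truncation_range = (int(0.12 * ref_len) + 1, reference.orf1_span[1])

    out: list[tuple[LocusRecord, GroundTruth]] = []
    width = len(str(n))
    for i in range(n):
        # one independent stream per locus: locus i is identical for any n
        rng = np.random.default_rng([seed, 1 + i])
        locus_class = classes[int(rng.choice(len(classes), p=probs))]
        muts = _draw_mutations(locus_class, reference, rng, sampler, truncation_range)
        seq = apply_background(
            reference.full_length_nt, reference, background_rate, rng,
            constrained=constrained_background,
        )
        for spec in sorted(muts, key=lambda m: -_nt_anchor(m, reference)):
            seq = apply_mutation(reference, seq, spec, rng)
        stops = [m.position for m in muts if m.kind == "nonsense" and m.orf == 2]
        truth = GroundTruth(
            locus_class=locus_class,
            true_first_stop_aa=min(stops) if stops else None,
            injected_mutations=tuple(muts),
            background_rate=background_rate,
        )
        record = LocusRecord(locus_id=f"syn{i:0{width}d}", sequence=seq)
        out.append((record, truth))
    return out


# ---------------------------------------------------------------------------
# output


def truth_table(pairs: Sequence[tuple[LocusRecord, GroundTruth]]) -> pd.DataFrame:
    rows = []
    for rec, truth in pairs:
        rows.append(
            {
                "locus_id": rec.locus_id,
                "locus_class": truth.locus_class,
                "true_first_stop_aa": (
                    "" if truth.true_first_stop_aa is None else truth.true_first_stop_aa
                ),
                "background_rate": truth.background_rate,
                "mutations": ";".join(m.describe() for m in truth.injected_mutations),
            }
        )
    return pd.DataFrame(rows)


def write_cohort(
    pairs: Sequence[tuple[LocusRecord, GroundTruth]],
    outdir: str | Path,
    prefix: str = "cohort",
    write_bed: bool = False,
) -> dict[str, Path]:
    """Write cohort FASTA + ground-truth TSV (+ optional BED). Byte-stable."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{prefix}.fa"
    with fasta.open("w") as fh:
        for rec, _ in pairs:
            fh.write(f">{rec.locus_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")
    tsv = outdir / f"{prefix}.truth.tsv"
    with tsv.open("w") as fh:
        fh.write("# coordinates: 1-based inclusive, reference amino-acid frame\n")
        truth_table(pairs).to_csv(fh, sep="\t", index=False)
    paths = {"fasta": fasta, "truth": tsv}
    if write_bed:
        bed = outdir / f"{prefix}.bed"
        with bed.open("w") as fh:
            pos = 0
            for rec, _ in pairs:
                end = pos + len(rec.sequence)
                fh.write(f"synthetic_contig\t{pos}\t{end}\t{rec.locus_id}\t0\t+\n")
                pos = end + 1000
        paths["bed"] = bed
    return paths
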