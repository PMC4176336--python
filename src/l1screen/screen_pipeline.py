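"""End-to-end screen: admission, ORF classification, truncation annotation.

The screen admits loci that cover the reference element from (near) its 5'
end, requires an intact ORF1 (no gaps, premature stops or frameshifts) and a
mostly intact ORF2 (no gaps or frameshifts) carrying at least one premature
stop codon, and predicts the truncated ORF2 protein implied by the first
stop.  A locus failing several criteria is attributed to the first failing
one in the order full-length -> ORF1 -> ORF2, mirroring the nested narrowing
of the original database query.

All output coordinates are 1-based inclusive, element-relative; every table
carries a header line saying so.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ConfigurationError, InputError
from .orf_integrity import (
    INTACT,
    PREMATURE_STOP,
    AlignmentParams,
    AlignmentResult,
    OrfStatus,
    align_to_reference,
    classify_orf,
    first_premature_stop,
    is_full_length,
)
from .reference_models import ReferenceModel, load_reference_model, translate_cds
from .synthetic_loci import LocusRecord
from .truncation_annotation import TruncationPrediction, predict_truncation

log = logging.getLogger("l1screen")

COORD_HEADER = "# coordinates: 1-based inclusive, element-relative"


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable parameters of the screen, loadable from YAML."""

    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    min_coverage: float = 0.90      # full-length admission: reference coverage
    max_5p_offset: int = 50         # full-length admission: 5' start slack, nt
    bin_width_aa: int = 100         # first-stop histogram bin width
    nls_mode: str = "exact"         # "exact" or "basic" (>=3 of 4 basic)
    missing_start_orfs: tuple[int, ...] = (1,)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        aln = AlignmentParams(**raw.pop("alignment", {}))
        known = {f for f in cls.__dataclass_fields__ if f != "alignment"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "missing_start_orfs" in raw:
            raw["missing_start_orfs"] = tuple(raw["missing_start_orfs"])
        return cls(alignment=aln, **raw)

    def describe(self) -> dict:
        d = asdict(self)
        d["coordinate_convention"] = "1-based inclusive, element-relative"
        return d


@dataclass(frozen=True)
class LocusClassification:
    """Full screen verdict for one locus."""

    locus_id: str
    full_length: bool
    orf1_status: OrfStatus
    orf2_status: OrfStatus
    passes_screen: bool
    truncation: TruncationPrediction | None
    rationale: str
    alignment: AlignmentResult | None = field(repr=False, default=None)


def screen_locus(
    locus: LocusRecord,
    reference: ReferenceModel,
    config: ScreenConfig | None = None,
) -> LocusClassification:
    """Run the whole screen on one locus.

    Input errors (bad alphabet, too-short sequence) are converted into a
    failing classification with a rationale, so batch runs never crash on a
    single record.
    """
    config = config or ScreenConfig()
    try:
        aln = align_to_reference(locus, reference, config.alignment)
    except InputError as exc:
        empty = OrfStatus(verdict="NOT_COVERED")
        return LocusClassification(
            locus_id=locus.locus_id,
            full_length=False,
            orf1_status=empty,
            orf2_status=empty,
            passes_screen=False,
            truncation=None,
            rationale=f"input error: {exc}",
        )
    full_length = is_full_length(
        aln, reference, config.min_coverage, config.max_5p_offset
    )
    orf1 = classify_orf(aln, locus, reference, 1, config.missing_start_orfs)
    orf2 = classify_orf(aln, locus, reference, 2, config.missing_start_orfs)

    if not full_length:
        rationale = (
            f"not full-length (coverage {aln.reference_coverage:.3f}, "
            f"5' offset {aln.five_prime_offset})"
        )
    elif orf1.verdict != INTACT:
        rationale = f"ORF1 not intact ({orf1.verdict})"
    elif orf2.verdict != PREMATURE_STOP:
        rationale = (
            "ORF2 has no premature stop"
            if orf2.verdict == INTACT
            else f"ORF2 not mostly intact ({orf2.verdict})"
        )
    else:
        rationale = "pass"

    passes = full_length and orf1.verdict == INTACT and orf2.verdict == PREMATURE_STOP
    truncation = None
    if passes:
        stop = first_premature_stop(orf2)
        o2s, o2e = reference.orf2_span
        bases = aln.locus_bases(o2s, o2e)
        protein = translate_cds(bases.replace("-", "N"))[: reference.orf2_aa_length]
        residues = {
            pos: protein[pos - 1] for pos in reference.catalytic_residues
        }
        truncation = predict_truncation(stop, reference, residues, protein)
    return LocusClassification(
        locus_id=locus.locus_id,
        full_length=full_length,
        orf1_status=orf1,
        orf2_status=orf2,
        passes_screen=passes,
        truncation=truncation,
        rationale=rationale,
        alignment=aln,
    )


# ---------------------------------------------------------------------------
# failure attribution & histogram


def failure_category(c: LocusClassification) -> str:
    """First failing criterion, in screen order; 'pass' if none."""
    if c.passes_screen:
        return "pass"
    if not c.full_length:
        return "not_full_length"
    if c.orf1_status.verdict != INTACT:
        return "orf1_defect"
    return "orf2_defect"


def predicted_class(c: LocusClassification) -> str:
    """Map a classification onto the synthetic generator's class labels."""
    if c.passes_screen:
        return "screen_hit"
    if not c.full_length:
        return "truncated_5p"
    if c.orf1_status.verdict != INTACT:
        return "orf1_broken"
    v = c.orf2_status.verdict
    if v == "FRAMESHIFT":
        return "orf2_frameshift"
    if v == "GAP":
        return "orf2_gap"
    return "intact_both_orfs"


def histogram_first_stops(
    classifications: list[LocusClassification],
    orf2_aa_length: int,
    bin_width_aa: int = 100,
) -> pd.DataFrame:
    """Bin first-stop positions of passing loci over [1, orf2_aa_length].

    Bins are left-closed ``[lo, hi]`` aa intervals of ``bin_width_aa``; the
    last bin may be short; empty bins are retained.
    """
    if bin_width_aa < 1:
        raise InputError("bin_width_aa must be >= 1")
    edges = list(range(1, orf2_aa_length + 1, bin_width_aa))
    rows = []
    for lo in edges:
        hi = min(lo + bin_width_aa - 1, orf2_aa_length)
        rows.append({"bin_start_aa": lo, "bin_end_aa": hi, "count": 0})
    df = pd.DataFrame(rows)
    for c in classifications:
        if c.passes_screen and c.truncation is not None:
            idx = (c.truncation.first_stop_aa - 1) // bin_width_aa
            df.loc[idx, "count"] += 1
    return df


# ---------------------------------------------------------------------------
# batch run


def classification_table(classifications: list[LocusClassification]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        t = c.truncation
        rows.append(
            {
                "locus_id": c.locus_id,
                "full_length": c.full_length,
                "orf1_verdict": c.orf1_status.verdict,
                "orf2_verdict": c.orf2_status.verdict,
                "orf2_first_stop_aa": (
                    "" if c.orf2_status.first_stop_aa is None
                    else c.orf2_status.first_stop_aa
                ),
                "orf2_all_stops_aa": ",".join(
                    str(s) for s in c.orf2_status.stop_positions_aa
                ),
                "orf2_frameshift_nt": ",".join(
                    str(p) for p in c.orf2_status.frameshift_positions
                ),
                "orf1_frameshift_nt": ",".join(
                    str(p) for p in c.orf1_status.frameshift_positions
                ),
                "passes_screen": c.passes_screen,
                "truncated_length_aa": "" if t is None else t.truncated_length_aa,
                "retained_domains": "" if t is None else "+".join(t.retained_domains),
                "partial_domain": "" if t is None or t.partial_domain is None else t.partial_domain,
                "en_status": "" if t is None else t.en_status,
                "nls_motif_present": "" if t is None else str(t.nls_motif_present),
                "rationale": c.rationale,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScreenReport:
    n_input: int
    n_full_length: int
    n_pass: int
    failure_counts: dict[str, int]
    histogram: pd.DataFrame
    per_locus: pd.DataFrame
    config: dict


def screen_records(
    records: list[LocusRecord],
    reference: ReferenceModel,
    config: ScreenConfig | None = None,
) -> list[LocusClassification]:
    config = config or ScreenConfig()
    return [screen_locus(rec, reference, config) for rec in records]


def run_screen(
    fasta_path: str | Path,
    species_id: str,
    config: ScreenConfig | None = None,
    outdir: str | Path | None = None,
    bed_path: str | Path | None = None,
    plot: bool = False,
    reference: ReferenceModel | None = None,
) -> ScreenReport:
    """Screen every locus in a FASTA file and (optionally) write reports.

    Loci are assumed element-sense; if ``bed_path`` (BED6) is given, records
    whose strand is '-' are reverse-complemented before alignment.
    """
    config = config or ScreenConfig()
    reference = reference or load_reference_model(species_id)
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise InputError(f"FASTA not found: {fasta_path}")

    strand_of: dict[str, str] = {}
    source_of: dict[str, tuple] = {}
    if bed_path is not None:
        bed = pd.read_csv(
            bed_path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        )
        for row in bed.itertuples(index=False):
            strand_of[str(row.name)] = str(row.strand)
            source_of[str(row.name)] = (
                str(row.chrom), int(row.start) + 1, int(row.end), str(row.strand)
            )

    records: list[LocusRecord] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if strand_of.get(rec.id) == "-":
            seq = str(Seq(seq).reverse_complement())
        records.append(LocusRecord(rec.id, seq, source=source_of.get(rec.id)))
    if not records:
        log.warning("empty FASTA %s: nothing to screen", fasta_path)

    log.info(
        "screening %d loci against %s reference; config=%s",
        len(records), species_id, json.dumps(config.describe(), default=str),
    )
    classifications = screen_records(records, reference, config)
    per_locus = classification_table(classifications)
    hist = histogram_first_stops(
        classifications, reference.orf2_aa_length, config.bin_width_aa
    )
    failures: dict[str, int] = {
        "not_full_length": 0, "orf1_defect": 0, "orf2_defect": 0, "pass": 0
    }
    for c in classifications:
        failures[failure_category(c)] += 1
    report = ScreenReport(
        n_input=len(records),
        n_full_length=sum(1 for c in classifications if c.full_length),
        n_pass=failures["pass"],
        failure_counts=failures,
        histogram=hist,
        per_locus=per_locus,
        config=config.describe(),
    )
    if outdir is not None:
        _write_report(report, Path(outdir), plot=plot)
    return report


def _write_report(report: ScreenReport, outdir: Path, plot: bool = False) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "per_locus.tsv").open("w") as fh:
        fh.write(COORD_HEADER + "\n")
        report.per_locus.to_csv(fh, sep="\t", index=False)
    with (outdir / "first_stop_histogram.tsv").open("w") as fh:
        fh.write(COORD_HEADER + "\n")
        report.histogram.to_csv(fh, sep="\t", index=False)
    summary = {
        "n_input": report.n_input,
        "n_full_length": report.n_full_length,
        "n_pass": report.n_pass,
        "failure_counts": report.failure_counts,
        "config": report.config,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        h = report.histogram
        ax.bar(h["bin_start_aa"], h["count"],
               width=(h["bin_end_aa"] - h["bin_start_aa"] + 1) * 0.9, align="edge")
        ax.set_xlabel("first premature stop position in ORF2 (aa)")
        ax.set_ylabel("loci")
        ax.set_title("First premature stop codon positions among passing loci")
        fig.tight_layout()
        fig.savefig(outdir / "first_stop_histogram.png", dpi=150)
        plt.close(fig)


# ---------------------------------------------------------------------------
# evaluation against synthetic ground truth


def evaluate_against_truth(
    classifications: list[LocusClassification],
    truth: pd.DataFrame | str | Path,
) -> dict:
    """Compare classifications with a generator ground-truth table.

    Returns a confusion matrix (true class x predicted class), the exact
    first-stop match rate among loci that are screen hits in both truth and
    prediction, and the distribution of (predicted - true) stop offsets.
    """
    if not isinstance(truth, pd.DataFrame):
        truth = pd.read_csv(truth, sep="\t", comment="#")
    truth = truth.copy()
    truth["locus_id"] = truth["locus_id"].astype(str)
    pred_ids = [c.locus_id for c in classifications]
    if sorted(pred_ids) != sorted(truth["locus_id"]):
        missing = sorted(set(truth["locus_id"]) ^ set(pred_ids))
        raise InputError(f"locus ids do not match 1:1; offenders: {missing[:10]}")

    by_id = {c.locus_id: c for c in classifications}
    rows = []
    for t in truth.itertuples(index=False):
        c = by_id[t.locus_id]
        pred = predicted_class(c)
        true_stop = getattr(t, "true_first_stop_aa", None)
        true_stop = None if pd.isna(true_stop) or true_stop == "" else int(true_stop)
        pred_stop = (
            c.truncation.first_stop_aa if c.truncation is not None else None
        )
        rows.append(
            {
                "locus_id": t.locus_id,
                "true_class": t.locus_class,
                "pred_class": pred,
                "true_first_stop_aa": true_stop,
                "pred_first_stop_aa": pred_stop,
            }
        )
    df = pd.DataFrame(rows)
    confusion = pd.crosstab(df["true_class"], df["pred_class"])
    both_hit = df[(df["true_class"] == "screen_hit") & (df["pred_class"] == "screen_hit")]
    if len(both_hit):
        offsets = both_hit["pred_first_stop_aa"] - both_hit["true_first_stop_aa"]
        exact = float((offsets == 0).mean())
        offset_counts = offsets.value_counts().sort_index().to_dict()
    else:
        exact, offset_counts = float("nan"), {}
    class_agreement = float((df["true_class"] == df["pred_class"]).mean())
    return {
        "confusion": confusion,
        "per_locus": df,
        "class_agreement": class_agreement,
        "first_stop_exact_match_rate": exact,
        "first_stop_offsets": offset_counts,
    }
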