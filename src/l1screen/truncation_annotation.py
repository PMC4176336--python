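"""Predicted truncated ORF2 proteins from first-stop coordinates.

A premature stop at reference aa position *k* predicts a truncated protein
of k-1 residues.  Which ORF2 domains (EN, z, RT, Cys) that protein retains
follows from the domain boundary table of the reference model; whether its
endonuclease is plausibly functional follows from conservation of the four
catalytic residues (N14, E43, D205, H230).  The EN flag is necessary, not
sufficient: it asserts only that no known inactivating substitution is
present in a complete EN domain.

The NLS check is a literal motif comparison at the model's z-motif
coordinates (KKKR at aa 382-385 by default), reported descriptively; it is
not a general NLS predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError
from .reference_models import DOMAIN_ORDER, ReferenceModel

EN_FUNCTIONAL = "functional"
EN_IMPAIRED = "impaired"
EN_INCOMPLETE = "incomplete"
EN_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class TruncationPrediction:
    """Predicted product of an ORF2 with a premature stop at ``first_stop_aa``."""

    first_stop_aa: int
    truncated_length_aa: int
    retained_domains: tuple[str, ...]  # complete domains only, 5'->3'
    partial_domain: str | None         # domain the stop falls inside, if any
    en_status: str
    nls_motif_present: bool | str      # True / False / "indeterminate"
    nls_start_aa: int | None


def predict_truncation(
    first_stop_aa: int,
    reference: ReferenceModel,
    locus_residues_at: dict[int, str] | None = None,
    protein: str | None = None,
) -> TruncationPrediction:
    """Predict the truncated protein for a first stop at ``first_stop_aa``.

    ``locus_residues_at`` (catalytic position -> observed residue) and
    ``protein`` (locus ORF2 protein in reference coordinates, gaps as '-')
    refine the EN and NLS calls; without them the EN status is
    ``indeterminate`` (or ``incomplete`` when the EN domain itself is cut)
    and the NLS status ``indeterminate``.
    """
    if not 1 <= first_stop_aa <= reference.orf2_aa_length:
        raise InputError(
            f"first_stop_aa {first_stop_aa} outside ORF2 (1..{reference.orf2_aa_length})"
        )
    length = first_stop_aa - 1
    retained = tuple(
        d for d in DOMAIN_ORDER if reference.domain_boundaries[d] <= length
    )
    # a truncation landing exactly on a domain boundary is not mid-domain
    partial = None
    if length not in reference.domain_boundaries.values():
        prev_end = 0
        for d in DOMAIN_ORDER:
            bound = reference.domain_boundaries[d]
            if prev_end < length + 1 <= bound:
                partial = d
                break
            prev_end = bound

    if locus_residues_at is not None:
        en = assess_en_functionality(locus_residues_at, length, reference)
    else:
        en = EN_INCOMPLETE if length < reference.en_boundary else EN_INDETERMINATE

    if protein is not None:
        present, start = scan_nls_motif(protein, reference, truncated_length_aa=length)
    else:
        present, start = "indeterminate", None
    return TruncationPrediction(
        first_stop_aa=first_stop_aa,
        truncated_length_aa=length,
        retained_domains=retained,
        partial_domain=partial,
        en_status=en,
        nls_motif_present=present,
        nls_start_aa=start,
    )


def assess_en_functionality(
    locus_residues_at: dict[int, str],
    truncated_length_aa: int,
    reference: ReferenceModel,
) -> str:
    """EN functionality flag from catalytic-residue conservation.

    ``incomplete`` when the truncation cuts the EN domain itself;
    ``impaired`` when any covered catalytic residue differs from the model
    expectation (a definite defect outranks missing data); ``indeterminate``
    when a catalytic position is unaligned ('-') or ambiguous ('X');
    ``functional`` otherwise.
    """
    if truncated_length_aa < reference.en_boundary:
        return EN_INCOMPLETE
    impaired = False
    unknown = False
    for pos, expect in reference.catalytic_residues.items():
        obs = locus_residues_at.get(pos)
        if obs is None or obs in ("-", "X"):
            unknown = True
        elif obs != expect:
            impaired = True
    if impaired:
        return EN_IMPAIRED
    if unknown:
        return EN_INDETERMINATE
    return EN_FUNCTIONAL


def scan_nls_motif(
    protein: str,
    reference: ReferenceModel,
    mode: str = "exact",
    truncated_length_aa: int | None = None,
) -> tuple[bool | str, int | None]:
    """Check the model NLS motif on a protein in reference aa coordinates.

    ``mode='exact'`` requires the motif residues verbatim; ``mode='basic'``
    accepts >=3 of 4 basic residues (K/R) across the region.  Returns
    ``("indeterminate", None)`` when the region is unaligned, ambiguous, or
    lies at/past the truncation point.
    """
    ns, ne = reference.nls_region
    if truncated_length_aa is not None and truncated_length_aa < ne:
        return "indeterminate", None
    if len(protein) < ne:
        return "indeterminate", None
    region = protein[ns - 1 : ne]
    if any(c in "-X*" for c in region):
        return "indeterminate", None
    if mode == "exact":
        present = region == reference.nls_motif
    elif mode == "basic":
        present = sum(c in "KR" for c in region) >= 3
    else:
        raise InputError(f"unknown NLS scan mode {mode!r}")
    return (True, ns) if present else (False, None)
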