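"""Reference L1 coordinate systems.

Every verdict the screen produces is expressed in the coordinates of a
reference L1 element: ORF1/ORF2 nucleotide spans, ORF2 protein-domain
boundaries (endonuclease EN, z-motif, reverse transcriptase RT and the
C-terminal cysteine-rich domain), the four catalytic endonuclease residues
(N14, E43, D205, H230) and the basic KKKR tetramer at ORF2 aa 382-385 that
acts as a putative nuclear localization signal.  This module defines that
coordinate system, loads the packaged reference models (one per species) and
validates any user-supplied replacement sequence against the same
assertions.

All coordinates are 1-based and inclusive, both at the nucleotide and the
amino-acid level.

The packaged sequences are *synthetic*: deterministic stand-ins generated by
:func:`build_synthetic_reference` that reproduce the published coordinate
geometry of the human L1.3 and mouse L1spa elements (ORF spans, domain
boundaries, catalytic residues, NLS motif) without redistributing the
archived accessions themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import ConfigurationError, InputError, ReferenceIntegrityError

# ---------------------------------------------------------------------------
# translation

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TO_AA[_stop] = "*"

#: codons that never terminate translation, used by the synthetic builder
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in _CODON_TO_AA.items() if aa != "*")
)
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

#: first (alphabetical) codon for each amino acid, for deterministic rewrites
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(_CODON_TO_AA[_codon], tuple())
    AA_TO_CODONS[_CODON_TO_AA[_codon]] += (_codon,)


def translate_cds(cds_nt: str, frame_offset: int = 0) -> str:
    """Translate a CDS with the standard genetic code.

    Stop codons are rendered ``*``.  Any codon containing a character
    outside ``ACGT`` is rendered ``X`` (a deliberately conservative rule: an
    ambiguous codon is never a stop).  A trailing partial codon is dropped.
    """
    if frame_offset not in (0, 1, 2):
        raise InputError(f"frame_offset must be 0, 1 or 2, got {frame_offset!r}")
    seq = cds_nt.upper()[frame_offset:]
    if len(seq) < 3:
        raise InputError("sequence shorter than one codon after frame offset")
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


# ---------------------------------------------------------------------------
# the model

DOMAIN_ORDER = ("EN", "z", "RT", "Cys")


@dataclass(frozen=True)
class ReferenceModel:
    """Coordinate system of one reference L1 element.

    ``domain_boundaries`` maps each ORF2 domain name to the 1-based aa
    coordinate of its *last* residue; the map is ordered 5'->3' and its last
    entry equals ``orf2_aa_length``.
    """

    species_id: str
    full_length_nt: str
    orf1_span: tuple[int, int]
    orf2_span: tuple[int, int]
    orf2_aa_length: int
    domain_boundaries: dict[str, int]
    catalytic_residues: dict[int, str]
    nls_region: tuple[int, int]
    nls_motif: str

    # -- derived views -----------------------------------------------------

    @property
    def orf1_cds(self) -> str:
        s, e = self.orf1_span
        return self.full_length_nt[s - 1 : e]

    @property
    def orf2_cds(self) -> str:
        s, e = self.orf2_span
        return self.full_length_nt[s - 1 : e]

    @property
    def orf1_aa_length(self) -> int:
        return len(self.orf1_cds) // 3 - 1  # excludes the terminal stop

    @property
    def orf2_protein(self) -> str:
        """ORF2 protein, terminal stop excluded."""
        return translate_cds(self.orf2_cds)[:-1]

    @property
    def en_boundary(self) -> int:
        return self.domain_boundaries["EN"]

    def orf_span(self, which_orf: int) -> tuple[int, int]:
        if which_orf == 1:
            return self.orf1_span
        if which_orf == 2:
            return self.orf2_span
        raise InputError(f"which_orf must be 1 or 2, got {which_orf!r}")

    def orf_aa_length(self, which_orf: int) -> int:
        return self.orf1_aa_length if which_orf == 1 else self.orf2_aa_length

    def codon_nt_span(self, aa_pos: int, which_orf: int = 2) -> tuple[int, int]:
        """1-based nt span on the full element of codon ``aa_pos`` of an ORF."""
        start, end = self.orf_span(which_orf)
        n_codons = (end - start + 1) // 3
        if not 1 <= aa_pos <= n_codons:
            raise InputError(
                f"aa position {aa_pos} outside ORF{which_orf} (1..{n_codons})"
            )
        lo = start + 3 * (aa_pos - 1)
        return lo, lo + 2

    def validate(self) -> None:
        """Assert every structural invariant; raise ReferenceIntegrityError."""
        n = len(self.full_length_nt)
        o1s, o1e = self.orf1_span
        o2s, o2e = self.orf2_span
        if not (1 <= o1s < o1e < o2s < o2e <= n):
            raise ReferenceIntegrityError(
                f"{self.species_id}: ORF spans out of order or outside sequence"
            )
        for which, cds in ((1, self.orf1_cds), (2, self.orf2_cds)):
            if len(cds) % 3:
                raise ReferenceIntegrityError(
                    f"{self.species_id}: ORF{which} span is not a whole number of codons"
                )
            prot = translate_cds(cds)
            if prot[0] != "M":
                raise ReferenceIntegrityError(
                    f"{self.species_id}: ORF{which} does not start with ATG"
                )
            if "*" in prot[:-1]:
                raise ReferenceIntegrityError(
                    f"{self.species_id}: ORF{which} contains internal stop codons "
                    "(corrupt reference)"
                )
            if prot[-1] != "*":
                raise ReferenceIntegrityError(
                    f"{self.species_id}: ORF{which} lacks a terminal stop codon"
                )
        bounds = list(self.domain_boundaries.values())
        if tuple(self.domain_boundaries) != DOMAIN_ORDER:
            raise ReferenceIntegrityError(
                f"{self.species_id}: domain order must be {DOMAIN_ORDER}"
            )
        if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise ReferenceIntegrityError(
                f"{self.species_id}: domain boundaries not strictly increasing"
            )
        if bounds[-1] != self.orf2_aa_length:
            raise ReferenceIntegrityError(
                f"{self.species_id}: last domain boundary {bounds[-1]} != "
                f"ORF2 length {self.orf2_aa_length}"
            )
        if self.orf2_aa_length != len(self.orf2_cds) // 3 - 1:
            raise ReferenceIntegrityError(
                f"{self.species_id}: orf2_aa_length inconsistent with ORF2 span"
            )
        prot2 = self.orf2_protein
        for pos, expect in self.catalytic_residues.items():
            if pos > self.en_boundary:
                raise ReferenceIntegrityError(
                    f"{self.species_id}: catalytic residue {pos} beyond EN boundary"
                )
            if prot2[pos - 1] != expect:
                raise ReferenceIntegrityError(
                    f"{self.species_id}: reference residue at ORF2 aa {pos} is "
                    f"{prot2[pos - 1]}, expected {expect}"
                )
        ns, ne = self.nls_region
        if not (self.en_boundary < ns <= ne <= self.domain_boundaries["z"]):
            raise ReferenceIntegrityError(
                f"{self.species_id}: NLS region {self.nls_region} not inside the z-motif"
            )
        if prot2[ns - 1 : ne] != self.nls_motif:
            raise ReferenceIntegrityError(
                f"{self.species_id}: NLS region reads {prot2[ns - 1:ne]!r}, "
                f"expected {self.nls_motif!r}"
            )


# ---------------------------------------------------------------------------
# packaged models

_BUILTIN = {
    "human": ("l1_human_synthetic.fa", "l1_human_synthetic.json"),
    "mouse": ("l1_mouse_synthetic.fa", "l1_mouse_synthetic.json"),
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("l1screen").joinpath("data", name)))


def load_reference_model(
    species_id: str,
    sequence_source: str | Path = "builtin",
    model_table: str | Path | None = None,
) -> ReferenceModel:
    """Load and validate a reference model.

    ``sequence_source`` is ``"builtin"`` for the packaged synthetic reference
    or a path to a single-record nucleotide FASTA overriding it; the override
    must pass the same load-time assertions (ORFs free of internal stops,
    catalytic residues and NLS motif at their model coordinates).
    ``model_table`` optionally overrides the packaged coordinate sidecar
    (JSON with ORF spans and domain boundaries).
    """
    if species_id not in _BUILTIN:
        raise ConfigurationError(
            f"unknown species {species_id!r}; supported: {sorted(_BUILTIN)}"
        )
    fa_name, js_name = _BUILTIN[species_id]
    sidecar = Path(model_table) if model_table is not None else _data_path(js_name)
    meta = json.loads(Path(sidecar).read_text())

    if isinstance(sequence_source, str) and sequence_source == "builtin":
        fasta = _data_path(fa_name)
    else:
        fasta = Path(sequence_source)
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if len(records) != 1:
        raise ReferenceIntegrityError(
            f"reference FASTA {fasta} must hold exactly one record, found {len(records)}"
        )
    seq = str(records[0].seq).upper()

    orf2_span = tuple(meta["orf2_span"])
    orf2_aa_length = (orf2_span[1] - orf2_span[0] + 1) // 3 - 1
    boundaries = {
        k: (orf2_aa_length if v is None else int(v))
        for k, v in meta["domain_boundaries"].items()
    }
    model = ReferenceModel(
        species_id=species_id,
        full_length_nt=seq,
        orf1_span=tuple(meta["orf1_span"]),
        orf2_span=orf2_span,
        orf2_aa_length=orf2_aa_length,
        domain_boundaries=boundaries,
        catalytic_residues={int(k): v for k, v in meta["catalytic_residues"].items()},
        nls_region=tuple(meta["nls_region"]),
        nls_motif=meta["nls_motif"],
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# deterministic synthetic reference builder

_GEOMETRY = {
    # total_nt, orf1_span, orf2_span, EN/z/RT boundaries, builder seed
    "human": (6050, (908, 1921), (1990, 5817), {"EN": 239, "z": 490, "RT": 773}, 20140820),
    "mouse": (7000, (1500, 2702), (2801, 6643), {"EN": 258, "z": 490, "RT": 773}, 20140821),
}
_CATALYTIC = {14: "N", 43: "E", 205: "D", 230: "H"}
_NLS_REGION = (382, 385)
_NLS_MOTIF = "KKKR"
# one codon per NLS residue, chosen once
_NLS_CODONS = ("AAA", "AAG", "AAA", "CGT")
_CATALYTIC_CODONS = {14: "AAC", 43: "GAA", 205: "GAT", 230: "CAC"}


def build_synthetic_reference(species_id: str) -> tuple[str, dict]:
    """Deterministically build a synthetic reference element for a species.

    The sequence is random at the codon level (sense codons only inside the
    ORFs) but pinned at every coordinate the screen depends on; repeated
    calls are byte-identical.  Returns ``(sequence, sidecar_dict)``.
    """
    if species_id not in _GEOMETRY:
        raise ConfigurationError(f"unknown species {species_id!r}")
    total, orf1_span, orf2_span, bounds, seed = _GEOMETRY[species_id]
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=total).tolist()

    def fill_orf(span: tuple[int, int], pinned: dict[int, str]) -> None:
        s, e = span
        n_codons = (e - s + 1) // 3
        codons = ["ATG"] + [
            SENSE_CODONS[i]
            for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
        ] + ["TAA"]
        for aa_pos, codon in pinned.items():
            codons[aa_pos - 1] = codon
        seq[s - 1 : e] = list("".join(codons))

    fill_orf(orf1_span, {})
    pinned = dict(_CATALYTIC_CODONS)
    for offset, codon in enumerate(_NLS_CODONS):
        pinned[_NLS_REGION[0] + offset] = codon
    fill_orf(orf2_span, pinned)

    sidecar = {
        "species_id": species_id,
        "coordinate_convention": "1-based inclusive",
        "synthetic": True,
        "orf1_span": list(orf1_span),
        "orf2_span": list(orf2_span),
        "domain_boundaries": {**bounds, "Cys": None},
        "catalytic_residues": {str(k): v for k, v in _CATALYTIC.items()},
        "nls_region": list(_NLS_REGION),
        "nls_motif": _NLS_MOTIF,
    }
    return "".join(seq), sidecar


def write_builtin_data(outdir: str | Path) -> None:
    """Regenerate the packaged synthetic reference FASTA + JSON sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for species, (fa_name, js_name) in _BUILTIN.items():
        seq, sidecar = build_synthetic_reference(species)
        header = (
            f">L1_{species}_synthetic deterministic synthetic reference L1 element "
            "(coordinate stand-in; 1-based inclusive spans in sidecar)"
        )
        lines = [header] + [seq[i : i + 70] for i in range(0, len(seq), 70)]
        (outdir / fa_name).write_text("\n".join(lines) + "\n")
        (outdir / js_name).write_text(json.dumps(sidecar, indent=2) + "\n")
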