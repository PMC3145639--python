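"""Catalytic-domain detection, kinase typing and SDR extraction.

A query sequence only yields predictions if a kinase catalytic domain can be
located in it, because the specificity-determining residues (SDRs) are read
at fixed positions relative to conserved domain motifs. Detection here is
anchored motif matching: the canonical glycine-rich loop, the beta-3 lysine
(VAIK-like) motif, the catalytic HRD loop and the activation-segment DFG/APE
motifs must occur in order with plausible spacing. A sequence in which the
anchors cannot all be placed is treated purely as a substrate — exactly as a
true kinase that fails to align would be.

The anchor set, kinase-type patterns and SDR offset table are configuration
data (``data/domain_model.yaml``), versioned so results are reproducible.
``detect_catalytic_domain`` accepts any object with the same fields, so an
external profile-HMM aligner can be plugged in by translating its alignment
into a :class:`KinaseAnnotation`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from Bio import SeqIO

from .alphabet import PHOSPHO_ALPHABET, SERINE_THREONINE
from .errors import KinspecError, SdrExtractionError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceRecord:
    """An identified protein sequence (1-based residue coordinates)."""

    id: str
    description: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise KinspecError("sequence id must be non-empty")
        if not self.residues:
            raise KinspecError(f"{self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: Path | str) -> list[SequenceRecord]:
    """Read a multi-record FASTA file; the first header token is the id."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise KinspecError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, rec.description, str(rec.seq).upper())
        )
    return records


def write_fasta(records: list[SequenceRecord], path: Path | str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


@dataclass(frozen=True)
class AnchorMotif:
    name: str
    pattern: str  # regular expression over residues
    min_gap: int  # residues between previous anchor end and this start
    max_gap: int


@dataclass(frozen=True)
class SdrPosition:
    anchor: str
    offset: int  # signed, relative to the anchor's first residue


@dataclass(frozen=True)
class DomainModel:
    """Versioned anchor/typing/SDR configuration."""

    version: str
    anchors: tuple[AnchorMotif, ...]
    type_patterns: tuple[tuple[str, str], ...]  # (kinase_type, regex)
    sdr_positions: tuple[SdrPosition, ...]

    @property
    def sdr_length(self) -> int:
        return len(self.sdr_positions)


def load_domain_model(path: Path | str | None = None) -> DomainModel:
    """Load a domain model from YAML; the bundled default when path is None."""
    if path is None:
        ref = resources.files("kinspec.data").joinpath("domain_model.yaml")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    return DomainModel(
        version=str(cfg["version"]),
        anchors=tuple(
            AnchorMotif(a["name"], a["pattern"], int(a["min_gap"]), int(a["max_gap"]))
            for a in cfg["anchors"]
        ),
        type_patterns=tuple(
            (p["kinase_type"], p["pattern"]) for p in cfg["type_patterns"]
        ),
        sdr_positions=tuple(
            SdrPosition(s["anchor"], int(s["offset"])) for s in cfg["sdr_positions"]
        ),
    )


_DEFAULT_MODEL: DomainModel | None = None


def default_domain_model() -> DomainModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_domain_model()
    return _DEFAULT_MODEL


@dataclass(frozen=True)
class KinaseAnnotation:
    """Detected catalytic domain for one sequence (1-based inclusive span)."""

    sequence_id: str
    domain_span: tuple[int, int]
    anchor_map: dict[str, int] = field(default_factory=dict)
    kinase_type: str | None = None
    sdr: str = ""

    @property
    def phospho_alphabet(self) -> str:
        if self.kinase_type is None:
            raise KinspecError("kinase type not yet classified")
        return PHOSPHO_ALPHABET[self.kinase_type]


def _chain_anchors(seq: str, anchors: tuple[AnchorMotif, ...], start: int) -> dict[str, int] | None:
    """Place anchors [1:] after a fixed first-anchor match; earliest-first."""
    first = re.compile(anchors[0].pattern).match(seq, start)
    if first is None:
        return None
    placed = {anchors[0].name: first.start()}
    prev_end = first.end()
    for a in anchors[1:]:
        lo = prev_end + a.min_gap
        hi = prev_end + a.max_gap
        m = re.compile(a.pattern).search(seq, lo, hi + len(seq))
        if m is None or m.start() > hi:
            return None
        placed[a.name] = m.start()
        prev_end = m.end()
    placed["_end"] = prev_end
    return placed


def detect_catalytic_domain(
    seq: SequenceRecord, model: DomainModel | None = None
) -> KinaseAnnotation | None:
    """Locate a kinase catalytic domain by ordered anchored motifs.

    Returns an annotation (kinase type and SDR string not yet filled in) when
    every anchor motif is found in order within its spacing bounds, scanning
    first-anchor matches left to right; ``None`` otherwise. Absence is a
    valid outcome — the sequence is then treated purely as a substrate.
    """
    model = model or default_domain_model()
    s = seq.residues
    first_pat = re.compile(model.anchors[0].pattern)
    pos = 0
    while True:
        m = first_pat.search(s, pos)
        if m is None:
            logger.info("%s: no catalytic domain detected", seq.id)
            return None
        placed = _chain_anchors(s, model.anchors, m.start())
        if placed is not None:
            end = placed.pop("_end")
            anchor_map = {k: v + 1 for k, v in placed.items()}  # 1-based
            return KinaseAnnotation(
                sequence_id=seq.id,
                domain_span=(m.start() + 1, end),
                anchor_map=anchor_map,
            )
        pos = m.start() + 1


def classify_kinase_type(
    annotation: KinaseAnnotation, seq: SequenceRecord, model: DomainModel | None = None
) -> str:
    """Classify the detected kinase via ordered residue patterns.

    The patterns are matched against the detected domain; the first match
    wins and serine/threonine is the default when none match (logged).
    """
    model = model or default_domain_model()
    lo, hi = annotation.domain_span
    domain = seq.residues[lo - 1 : hi]
    for kinase_type, pattern in model.type_patterns:
        if re.search(pattern, domain):
            return kinase_type
    logger.warning(
        "%s: no kinase-type pattern matched; defaulting to %s",
        annotation.sequence_id,
        SERINE_THREONINE,
    )
    return SERINE_THREONINE


def extract_sdrs(
    annotation: KinaseAnnotation, seq: SequenceRecord, model: DomainModel | None = None
) -> str:
    """Read the SDR string at the configured anchor-relative positions.

    Raises
    ------
    SdrExtractionError
        If any position falls outside the sequence; the kinase then yields
        no prediction.
    """
    model = model or default_domain_model()
    out = []
    for sp in model.sdr_positions:
        if sp.anchor not in annotation.anchor_map:
            raise SdrExtractionError(
                f"{annotation.sequence_id}: anchor {sp.anchor!r} not in annotation"
            )
        pos = annotation.anchor_map[sp.anchor] + sp.offset  # 1-based
        if not 1 <= pos <= len(seq.residues):
            raise SdrExtractionError(
                f"{annotation.sequence_id}: no valid SDR string "
                f"({sp.anchor}{sp.offset:+d} is outside the sequence)"
            )
        out.append(seq.residues[pos - 1])
    return "".join(out)


def annotate(
    seq: SequenceRecord, model: DomainModel | None = None
) -> KinaseAnnotation | None:
    """detect + classify + extract in one step; None if no domain."""
    model = model or default_domain_model()
    ann = detect_catalytic_domain(seq, model)
    if ann is None:
        return None
    kinase_type = classify_kinase_type(ann, seq, model)
    sdr = extract_sdrs(ann, seq, model)
    return KinaseAnnotation(
        sequence_id=ann.sequence_id,
        domain_span=ann.domain_span,
        anchor_map=ann.anchor_map,
        kinase_type=kinase_type,
        sdr=sdr,
    )
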