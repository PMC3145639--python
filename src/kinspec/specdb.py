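"""The phosphosite specificity database.

Each record links one experimentally observed phosphorylation site — stored
as the 7-residue substrate window from −3 to +3 around the phospho-residue —
to the kinase responsible, identified by its type and its SDR string. A
query kinase collects the heptamers of every database kinase of the same
type whose SDR string is similar under the active policy; those heptamers
are the raw material for its frequency matrix.

The on-disk format is a line-oriented TSV (one record per line, ``#``
comments, UTF-8) so a database can be assembled from UniProtKB or
Phospho.ELM exports with ordinary tools; harvesting those resources is out
of scope here and the bundled synthetic generator produces databases in the
same format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AA_INDEX, KINASE_TYPES, PHOSPHO_ALPHABET
from .errors import DatabaseFormatError, KinspecError
from .substitution import SimilarityPolicy, sdr_similar

#: Minimum matching sites for a frequency matrix to count as valid.
DEFAULT_MIN_SITES = 3

#: Probability floor for residues unseen in the background tally.
DEFAULT_BACKGROUND_FLOOR = 1e-4

_COLUMNS = ("kinase_id", "kinase_type", "kinase_sdr", "substrate_id",
            "site_position", "heptamer")


@dataclass(frozen=True)
class PhosphositeRecord:
    """One phosphosite linked to a kinase via its SDR string."""

    kinase_id: str
    kinase_type: str
    kinase_sdr: str
    substrate_id: str
    site_position: int  # 1-based position of the phospho-residue
    heptamer: str  # positions -3..+3; index 3 is the phospho-residue

    def __post_init__(self):
        if self.kinase_type not in KINASE_TYPES:
            raise KinspecError(
                f"unknown kinase type {self.kinase_type!r}; expected one of {KINASE_TYPES}"
            )
        if len(self.heptamer) != 7:
            raise KinspecError(
                f"heptamer must have length 7, got {len(self.heptamer)} ({self.heptamer!r})"
            )
        if any(a not in AA_INDEX for a in self.heptamer):
            raise KinspecError(
                f"heptamer {self.heptamer!r} contains non-standard residues"
            )
        allowed = PHOSPHO_ALPHABET[self.kinase_type]
        if self.heptamer[3] not in allowed:
            raise KinspecError(
                f"heptamer centre {self.heptamer[3]!r} not in phospho alphabet "
                f"{allowed!r} of {self.kinase_type} kinases"
            )
        if self.site_position < 1:
            raise KinspecError("site_position is 1-based and must be >= 1")


@dataclass(frozen=True)
class SpecificityDatabase:
    """An in-memory collection of phosphosite records with shared SDR length."""

    records: tuple[PhosphositeRecord, ...]
    sdr_length: int
    provenance: str = ""

    def __post_init__(self):
        for r in self.records:
            if len(r.kinase_sdr) != self.sdr_length:
                raise KinspecError(
                    f"record for {r.kinase_id} has SDR length {len(r.kinase_sdr)}, "
                    f"database declares {self.sdr_length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(
        cls, records, sdr_length: int | None = None, provenance: str = ""
    ) -> "SpecificityDatabase":
        records = tuple(records)
        if sdr_length is None:
            if not records:
                raise KinspecError("sdr_length required for an empty database")
            sdr_length = len(records[0].kinase_sdr)
        return cls(records, sdr_length, provenance)

    def kinase_types(self) -> set[str]:
        return {r.kinase_type for r in self.records}


def query_matching_sites(
    query_sdr: str,
    query_type: str,
    db: SpecificityDatabase,
    policy: SimilarityPolicy | None = None,
) -> list[PhosphositeRecord]:
    """All records of ``query_type`` whose SDR is similar to the query's.

    CMGC records match only CMGC queries (and likewise for the other types).
    The result order is deterministic: sorted by kinase id, substrate id,
    then site position.
    """
    policy = policy or SimilarityPolicy()
    if len(query_sdr) != db.sdr_length:
        raise KinspecError(
            f"query SDR length {len(query_sdr)} != database SDR length {db.sdr_length}"
        )
    hits = [
        r
        for r in db.records
        if r.kinase_type == query_type and sdr_similar(query_sdr, r.kinase_sdr, policy)
    ]
    hits.sort(key=lambda r: (r.kinase_id, r.substrate_id, r.site_position))
    return hits


def background_frequencies(
    db: SpecificityDatabase,
    kinase_type: str,
    floor: float = DEFAULT_BACKGROUND_FLOOR,
):
    """Residue background for one kinase type.

    The background of residue *a* is its frequency across all substrate
    heptamers of that kinase type in the database. Residues never observed
    receive ``floor`` and the vector is renormalised, so log-odds scores
    stay finite.
    """
    from .pwm import BackgroundFrequencies  # local import to avoid a cycle

    counts = np.zeros(20)
    n = 0
    for r in db.records:
        if r.kinase_type != kinase_type:
            continue
        n += 1
        for a in r.heptamer:
            counts[AA_INDEX[a]] += 1
    if n == 0:
        raise KinspecError(f"database has no records of type {kinase_type!r}")
    b = counts / counts.sum()
    b[b == 0] = floor
    b = b / b.sum()
    return BackgroundFrequencies(b=b, kinase_type=kinase_type)


def export_database(db: SpecificityDatabase, path: Path | str) -> None:
    """Write the documented TSV dialect (metadata in ``#`` comments)."""
    with open(path, "w") as fh:
        fh.write(f"# kinspec specificity database; sdr_length={db.sdr_length}\n")
        if db.provenance:
            for line in db.provenance.splitlines():
                fh.write(f"# provenance: {line}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in db.records:
            fh.write(
                f"{r.kinase_id}\t{r.kinase_type}\t{r.kinase_sdr}\t"
                f"{r.substrate_id}\t{r.site_position}\t{r.heptamer}\n"
            )


def import_database(path: Path | str) -> SpecificityDatabase:
    """Read the TSV dialect written by :func:`export_database`.

    Raises :class:`DatabaseFormatError` with the line number for malformed
    lines; a header-only file yields a valid empty database provided the
    metadata declares the SDR length.
    """
    sdr_length: int | None = None
    provenance: list[str] = []
    records: list[PhosphositeRecord] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "sdr_length=" in body:
                    try:
                        sdr_length = int(body.split("sdr_length=")[1].split()[0])
                    except ValueError:
                        raise DatabaseFormatError("bad sdr_length metadata", lineno)
                elif body.startswith("provenance:"):
                    provenance.append(body[len("provenance:"):].strip())
                continue
            parts = line.split("\t")
            if not header_seen:
                if tuple(parts) != _COLUMNS:
                    raise DatabaseFormatError(
                        f"expected header {_COLUMNS}, got {tuple(parts)}", lineno
                    )
                header_seen = True
                continue
            if len(parts) != len(_COLUMNS):
                raise DatabaseFormatError(
                    f"expected {len(_COLUMNS)} columns, got {len(parts)}", lineno
                )
            try:
                rec = PhosphositeRecord(
                    kinase_id=parts[0],
                    kinase_type=parts[1],
                    kinase_sdr=parts[2],
                    substrate_id=parts[3],
                    site_position=int(parts[4]),
                    heptamer=parts[5],
                )
            except (KinspecError, ValueError) as e:
                raise DatabaseFormatError(str(e), lineno) from e
            records.append(rec)
    if not header_seen:
        raise DatabaseFormatError(f"{path}: missing header line")
    if sdr_length is None:
        if not records:
            raise DatabaseFormatError(
                f"{path}: empty database with no sdr_length metadata"
            )
        sdr_length = len(records[0].kinase_sdr)
    return SpecificityDatabase(
        records=tuple(records),
        sdr_length=sdr_length,
        provenance="\n".join(provenance),
    )
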