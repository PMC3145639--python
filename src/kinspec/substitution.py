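"""BLOSUM substitution matrices and the SDR-similarity predicate.

Database matching hinges on whether a stored kinase's specificity-determining
residues (SDRs) are "similar" to the query kinase's. Similarity is judged
per position: residue pair (q, d) passes when its substitution score is at
least the policy cut-off, and the whole SDR string passes only when every
position does. With BLOSUM62 and the default cut-off of 1 this means every
substitution must have a positive score; dropping the cut-off to 0, or
switching to a shallower matrix such as BLOSUM30, relaxes matching and lets
more database kinases contribute sites.

Sixteen matrices of the BLOSUM series are bundled as plain-text tables
(see ``data/blosum``). The bundled BLOSUM95 is a synthetic stand-in
interpolated between BLOSUM90 and BLOSUM100 in bit units; its file header
says so. Users may drop additional tables in the same format and load them
with :func:`read_matrix_file`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .alphabet import AA20, AA_INDEX
from .errors import MatrixNotAvailableError

#: The bundled sweep, in ascending clustering order with 62 in series position.
BLOSUM_NAMES: tuple[str, ...] = tuple(
    f"BLOSUM{n}"
    for n in (30, 35, 40, 45, 50, 55, 60, 62, 65, 70, 75, 80, 85, 90, 95, 100)
)

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_CUTOFF = 1


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 integer substitution-score table."""

    name: str
    scores: np.ndarray  # (20, 20) int, rows/cols in AA20 order

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=int)
        if s.shape != (20, 20):
            raise ValueError(f"expected 20x20 scores, got {s.shape}")
        if not (s == s.T).all():
            raise ValueError(f"{self.name}: matrix is not symmetric")
        if not (np.diag(s) > 0).all():
            raise ValueError(f"{self.name}: diagonal entries must be positive")
        object.__setattr__(self, "scores", s)

    def score(self, a: str, b: str) -> int:
        """Substitution score for an ordered residue pair (symmetric)."""
        return int(self.scores[AA_INDEX[a], AA_INDEX[b]])

    @property
    def min(self) -> int:
        return int(self.scores.min())

    @property
    def max(self) -> int:
        return int(self.scores.max())


@dataclass(frozen=True)
class SimilarityPolicy:
    """How SDR strings are compared during database matching.

    Parameters
    ----------
    matrix:
        Substitution matrix; BLOSUM62 by default.
    cutoff:
        Minimum per-position score for a residue pair to count as similar.
        The default of 1 admits exactly the positive-score substitutions.
    nonstandard_score:
        Score assigned when either residue is outside the 20-letter
        alphabet. ``None`` (default) fails the position outright; setting
        it to ``cutoff - 1`` reproduces the optional lenient-looking but
        still-failing mapping some pipelines use.
    """

    matrix: SubstitutionMatrix = field(default=None)  # type: ignore[assignment]
    cutoff: int = DEFAULT_CUTOFF
    nonstandard_score: int | None = None

    def __post_init__(self):
        if self.matrix is None:
            object.__setattr__(self, "matrix", load_substitution_matrix(DEFAULT_MATRIX))
        if not isinstance(self.cutoff, (int, np.integer)):
            raise ValueError("cutoff must be an integer")


def read_matrix_file(path: Path | str, name: str | None = None) -> SubstitutionMatrix:
    """Read a whitespace-delimited square score table.

    Format: optional ``#`` comment lines; a header row of residue letters;
    then one row per residue, the row label first. All 20 standard residues
    must be present; extra residues are ignored.
    """
    path = Path(path)
    header: list[str] | None = None
    rows: dict[str, dict[str, int]] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if header is None:
            header = parts
        else:
            rows[parts[0]] = dict(zip(header, (int(v) for v in parts[1:])))
    if header is None:
        raise MatrixNotAvailableError(f"{path}: empty matrix file")
    missing = [a for a in AA20 if a not in rows or any(b not in rows[a] for b in AA20)]
    if missing:
        raise MatrixNotAvailableError(f"{path}: missing residues {missing}")
    scores = np.array([[rows[a][b] for b in AA20] for a in AA20], dtype=int)
    return SubstitutionMatrix(name or path.stem, scores)


_CACHE: dict[str, SubstitutionMatrix] = {}


def load_substitution_matrix(name: str) -> SubstitutionMatrix:
    """Load one of the bundled BLOSUM matrices by identifier.

    Raises
    ------
    MatrixNotAvailableError
        If ``name`` is not one of the sixteen bundled identifiers.
    """
    if name not in BLOSUM_NAMES:
        raise MatrixNotAvailableError(
            f"matrix not available: {name!r}; valid names: {', '.join(BLOSUM_NAMES)}"
        )
    if name not in _CACHE:
        ref = resources.files("kinspec.data.blosum").joinpath(f"{name}.txt")
        with resources.as_file(ref) as p:
            _CACHE[name] = read_matrix_file(p, name)
    return _CACHE[name]


def _pair_score(q: str, d: str, policy: SimilarityPolicy) -> int | None:
    if q in AA_INDEX and d in AA_INDEX:
        return policy.matrix.score(q, d)
    return policy.nonstandard_score


def sdr_similar(query_sdr: str, db_sdr: str, policy: SimilarityPolicy) -> bool:
    """True iff every SDR position scores at least ``policy.cutoff``.

    Non-standard residues are scored per ``policy.nonstandard_score``
    (by default the position simply fails); they are never skipped.
    """
    if len(query_sdr) != len(db_sdr):
        raise ValueError(
            f"SDR length mismatch: query has {len(query_sdr)}, database has {len(db_sdr)}"
        )
    for q, d in zip(query_sdr, db_sdr):
        s = _pair_score(q, d, policy)
        if s is None or s < policy.cutoff:
            return False
    return True
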