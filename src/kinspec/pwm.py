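"""Frequency matrices and position weight matrices.

A kinase's specificity model is a 20x7 position weight matrix (PWM): rows
are the twenty amino acids in alphabetical order, columns are substrate
positions −3..+3 around the phospho-residue, which sits in column 4
(0-based index 3). Matching database heptamers are tallied into a raw
frequency matrix; pseudo-counts proportional to the type background turn the
tallies into probabilities,

    f[a][j] = (c[a][j] + sqrt(N) * b[a]) / (N + sqrt(N)),

where N is the number of sites counted. Two PWM styles are built from f:

* **old** — per-position log-odds log2(f/b), negatives rectified to zero and
  each column renormalised to sum 1 (an all-zero column becomes uniform).
  This was the original, background-corrected construction.
* **new** — the pseudo-counted frequency matrix used directly as weights.
  Experimentally mapped matrices are typically not background-corrected, so
  this style tends to sit closer to them in Frobenius distance without
  changing predictive power much.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AA20, AA_INDEX
from .errors import KinspecError, NoPrediction, PwmFormatError

logger = logging.getLogger(__name__)

#: Substrate positions relative to the phospho-residue, in column order.
POSITIONS: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
N_POSITIONS = 7
#: 0-based column index of the phospho-residue ("column 4", 1-based).
PHOSPHO_COL = 3

PWM_STYLES = ("old", "new", "baseline", "external")

_COLUMN_HEADERS = ("-3", "-2", "-1", "0", "+1", "+2", "+3")


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Marginal residue distribution of substrate heptamers for one type."""

    b: np.ndarray  # (20,)
    kinase_type: str

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float)
        if b.shape != (20,):
            raise KinspecError(f"background must be a 20-vector, got {b.shape}")
        if abs(b.sum() - 1.0) > 1e-12:
            raise KinspecError(f"background sums to {b.sum()!r}, not 1")
        if (b <= 0).any():
            raise KinspecError("background entries must all be positive")
        object.__setattr__(self, "b", b)

    def of(self, residue: str) -> float:
        return float(self.b[AA_INDEX[residue]])


@dataclass(frozen=True)
class FrequencyMatrix:
    """Raw 20x7 residue counts over N heptamers; every column sums to N."""

    counts: np.ndarray  # (20, 7) non-negative int
    n_sites: int

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (20, N_POSITIONS):
            raise KinspecError(f"counts must be 20x7, got {c.shape}")
        if (c < 0).any():
            raise KinspecError("counts must be non-negative")
        if self.n_sites < 1:
            raise KinspecError("n_sites must be >= 1")
        if not (c.sum(axis=0) == self.n_sites).all():
            raise KinspecError("every column must sum to n_sites")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """A 20x7 weight matrix with a style tag and provenance metadata."""

    weights: np.ndarray  # (20, 7)
    style: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (20, N_POSITIONS):
            raise KinspecError(f"weights must be 20x7, got {w.shape}")
        if self.style not in PWM_STYLES:
            raise KinspecError(f"style must be one of {PWM_STYLES}, got {self.style!r}")
        object.__setattr__(self, "weights", w)

    def weight(self, residue: str, position: int) -> float:
        """Weight of a residue at a signed position (-3..+3)."""
        return float(self.weights[AA_INDEX[residue], POSITIONS.index(position)])

    def column_sums(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits, log2(20) + sum w log2 w.

        This is the column-height vector a sequence-logo renderer would use;
        image rendering itself is out of scope.
        """
        w = np.clip(self.weights, 1e-12, None)
        w = w / w.sum(axis=0, keepdims=True)
        return np.log2(20) + (w * np.log2(w)).sum(axis=0)


def build_frequency_matrix(
    sites: Sequence, min_sites: int = 3
) -> FrequencyMatrix:
    """Tally heptamers (or PhosphositeRecords) into a frequency matrix.

    Raises :class:`NoPrediction` carrying the count found when fewer than
    ``min_sites`` sites are available — the kinase then yields no prediction.
    """
    heptamers = [getattr(s, "heptamer", s) for s in sites]
    if len(heptamers) < min_sites:
        raise NoPrediction(
            f"too few matching sites (minimum {min_sites})", n_found=len(heptamers)
        )
    counts = np.zeros((20, N_POSITIONS), dtype=int)
    for h in heptamers:
        if len(h) != N_POSITIONS:
            raise KinspecError(f"heptamer {h!r} does not have length 7")
        for j, a in enumerate(h):
            try:
                counts[AA_INDEX[a], j] += 1
            except KeyError:
                raise KinspecError(f"non-standard residue {a!r} in heptamer {h!r}")
    return FrequencyMatrix(counts=counts, n_sites=len(heptamers))


def pseudo_count_frequencies(
    F: FrequencyMatrix, bg: BackgroundFrequencies
) -> np.ndarray:
    """Pseudo-counted probabilities, (c + sqrt(N) b) / (N + sqrt(N)).

    Every column sums to 1 because the background does.
    """
    n = F.n_sites
    root = np.sqrt(n)
    return (F.counts + root * bg.b[:, None]) / (n + root)


def new_style_pwm(
    F: FrequencyMatrix, bg: BackgroundFrequencies, metadata: dict | None = None
) -> PositionWeightMatrix:
    """The pseudo-counted frequency matrix used directly as weights."""
    meta = dict(metadata or {})
    meta.setdefault("n_sites", F.n_sites)
    return PositionWeightMatrix(
        weights=pseudo_count_frequencies(F, bg), style="new", metadata=meta
    )


def old_style_pwm(
    F: FrequencyMatrix, bg: BackgroundFrequencies, metadata: dict | None = None
) -> PositionWeightMatrix:
    """Rectified, column-normalised log-odds weights.

    Log-odds log2(f/b) are computed from the pseudo-counted frequencies,
    negatives are set to zero, and each column is renormalised to sum 1. A
    column with no positive log-odds (e.g. frequencies equal to background)
    becomes uniform 0.05 and is logged.
    """
    f = pseudo_count_frequencies(F, bg)
    s = np.log2(f / bg.b[:, None])
    s[s < 0] = 0.0
    sums = s.sum(axis=0)
    w = np.empty_like(s)
    for j in range(N_POSITIONS):
        if sums[j] <= 0:
            logger.info(
                "old-style PWM: column %+d has no positive log-odds; uniform",
                POSITIONS[j],
            )
            w[:, j] = 1.0 / 20.0
        else:
            w[:, j] = s[:, j] / sums[j]
    meta = dict(metadata or {})
    meta.setdefault("n_sites", F.n_sites)
    return PositionWeightMatrix(weights=w, style="old", metadata=meta)


def write_pwm(pwm: PositionWeightMatrix, path: Path | str) -> None:
    """Write the 20x7 TSV dialect: residue-labelled rows, headers -3..+3."""
    with open(path, "w") as fh:
        fh.write(f"# kinspec pwm; style={pwm.style}\n")
        for k in sorted(pwm.metadata):
            fh.write(f"# {k}={pwm.metadata[k]}\n")
        fh.write("\t" + "\t".join(_COLUMN_HEADERS) + "\n")
        for i, a in enumerate(AA20):
            row = "\t".join(f"{v:.17g}" for v in pwm.weights[i])
            fh.write(f"{a}\t{row}\n")


def read_pwm(path: Path | str) -> PositionWeightMatrix:
    """Read the TSV dialect written by :func:`write_pwm`.

    Row order (A..Y) and column-header order (−3..+3) are both enforced;
    files from other tools must be rearranged to match.
    """
    style = "external"
    metadata: dict = {}
    rows: list[list[float]] = []
    labels: list[str] = []
    header: list[str] | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                k = k.removeprefix("kinspec pwm;").strip()
                if k == "style" and v in PWM_STYLES:
                    style = v
                else:
                    metadata[k] = v
            continue
        parts = line.split("\t")
        if header is None:
            header = [p for p in parts if p]
            if tuple(header) != _COLUMN_HEADERS:
                raise PwmFormatError(
                    f"expected column headers {_COLUMN_HEADERS}, got {tuple(header)}"
                )
            continue
        labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as e:
            raise PwmFormatError(f"bad numeric value in row {parts[0]!r}") from e
    if header is None:
        raise PwmFormatError(f"{path}: missing column header line")
    if labels != list(AA20):
        raise PwmFormatError(
            f"expected 20 rows labelled {AA20!r} in order, got {''.join(labels)!r}"
        )
    w = np.array(rows, dtype=float)
    if w.shape != (20, N_POSITIONS):
        raise PwmFormatError(f"expected a 20x7 matrix, got {w.shape}")
    if "n_sites" in metadata:
        try:
            metadata["n_sites"] = int(metadata["n_sites"])
        except ValueError:
            pass
    return PositionWeightMatrix(weights=w, style=style, metadata=metadata)
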