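"""Candidate-site enumeration, heptamer scoring and the prediction driver.

A candidate phosphorylation site is any occurrence of an acceptor residue
(S/T for serine/threonine and CMGC kinases, Y for tyrosine kinases). Each
candidate contributes the −3..+3 heptamer around it; windows running past a
terminus are padded with ``X`` so position-1 serines remain scannable.

A heptamer h is scored against a PWM as a sum of per-position log-likelihood
ratios,

    score(h) = sum_j log2( max(w[h_j][j], 1e-4) / b[h_j] ),

with padding symbols contributing zero. Positive scores mean the window
looks more like the kinase's preferred context than like background.

:func:`run_prediction` drives the three analysis modes from a single
sequence collection: every sequence is tested for a catalytic domain;
sequences with one become query kinases while *all* sequences (kinases
included) remain candidate substrates, so autophosphorylation is scanned
automatically. Which mode you are in — kinase-to-substrates,
substrate-to-kinases, or whole-proteome — is determined purely by what the
input file contains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, PAD
from .errors import KinspecError, NoPrediction, SdrExtractionError
from .kinase_domain import (
    DomainModel,
    KinaseAnnotation,
    SequenceRecord,
    annotate,
    default_domain_model,
)
from .pwm import (
    BackgroundFrequencies,
    PositionWeightMatrix,
    build_frequency_matrix,
    new_style_pwm,
    old_style_pwm,
)
from .specdb import (
    DEFAULT_MIN_SITES,
    SpecificityDatabase,
    background_frequencies,
    query_matching_sites,
)
from .substitution import SimilarityPolicy

logger = logging.getLogger(__name__)

#: Floor applied to PWM weights before taking the log.
SCORE_FLOOR = 1e-4

# machine-readable no-prediction reasons
REASON_NO_SDR = "no valid SDR string"
REASON_TOO_FEW_SITES = "too few matching sites"
REASON_NO_TYPE_RECORDS = "no database records of kinase type"


@dataclass(frozen=True)
class ScoredSite:
    kinase_id: str
    substrate_id: str
    site_position: int  # 1-based
    heptamer: str
    score: float
    rank: int  # 1..K within the kinase's result set


def enumerate_candidate_sites(
    substrate: SequenceRecord, phospho_alphabet: str
) -> list[tuple[int, str]]:
    """All (1-based position, heptamer) pairs with an acceptor residue centre."""
    s = substrate.residues
    padded = PAD * 3 + s + PAD * 3
    return [
        (i + 1, padded[i : i + 7])
        for i, res in enumerate(s)
        if res in phospho_alphabet
    ]


def score_site(
    pwm: PositionWeightMatrix, heptamer: str, bg: BackgroundFrequencies
) -> float:
    """Sum of log2 likelihood ratios over the 7 positions (padding scores 0)."""
    if len(heptamer) != 7:
        raise KinspecError(f"heptamer {heptamer!r} does not have length 7")
    total = 0.0
    for j, a in enumerate(heptamer):
        if a == PAD:
            continue
        if a not in AA_INDEX:
            raise KinspecError(f"residue {a!r} outside alphabet in {heptamer!r}")
        w = max(float(pwm.weights[AA_INDEX[a], j]), SCORE_FLOOR)
        total += np.log2(w / bg.b[AA_INDEX[a]])
    return float(total)


@dataclass(frozen=True)
class KinaseOutcome:
    """Per-kinase outcome of a prediction run."""

    sequence_id: str
    annotation: KinaseAnnotation | None
    pwm: PositionWeightMatrix | None = None
    n_matching_sites: int = 0
    failure_reason: str | None = None  # None when a PWM was built


@dataclass
class PredictionResult:
    """Everything produced by one :func:`run_prediction` call."""

    scored_sites: dict[str, list[ScoredSite]] = field(default_factory=dict)
    kinase_outcomes: dict[str, KinaseOutcome] = field(default_factory=dict)
    substrate_ids: list[str] = field(default_factory=list)

    @property
    def kinase_ids(self) -> list[str]:
        return list(self.kinase_outcomes)

    @property
    def no_kinase_found(self) -> bool:
        return not self.kinase_outcomes

    def predicted_kinases(self) -> list[str]:
        return [k for k, o in self.kinase_outcomes.items() if o.pwm is not None]

    def coverage(self) -> float:
        """Valid-PWM kinases / detected kinases (0 when none detected)."""
        if not self.kinase_outcomes:
            return 0.0
        return len(self.predicted_kinases()) / len(self.kinase_outcomes)

    def failure_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for o in self.kinase_outcomes.values():
            if o.failure_reason is not None:
                out[o.failure_reason] = out.get(o.failure_reason, 0) + 1
        return out


def build_pwm_for_query(
    sdr: str,
    kinase_type: str,
    db: SpecificityDatabase,
    policy: SimilarityPolicy | None = None,
    style: str = "new",
    min_sites: int = DEFAULT_MIN_SITES,
    metadata: dict | None = None,
) -> tuple[PositionWeightMatrix, BackgroundFrequencies, int]:
    """Query the database and build a PWM for one (SDR, type) pair.

    Raises :class:`NoPrediction` when the type has no background data or
    fewer than ``min_sites`` records match.
    """
    policy = policy or SimilarityPolicy()
    if kinase_type not in db.kinase_types():
        raise NoPrediction(REASON_NO_TYPE_RECORDS, n_found=0)
    bg = background_frequencies(db, kinase_type)
    sites = query_matching_sites(sdr, kinase_type, db, policy)
    if len(sites) < min_sites:
        raise NoPrediction(REASON_TOO_FEW_SITES, n_found=len(sites))
    F = build_frequency_matrix(sites, min_sites=min_sites)
    meta = dict(metadata or {})
    meta.update(
        sdr=sdr,
        kinase_type=kinase_type,
        matrix=policy.matrix.name,
        cutoff=policy.cutoff,
    )
    builder = new_style_pwm if style == "new" else old_style_pwm
    return builder(F, bg, metadata=meta), bg, len(sites)


def run_prediction(
    sequences: list[SequenceRecord],
    db: SpecificityDatabase,
    policy: SimilarityPolicy | None = None,
    style: str = "new",
    top_k: int | None = None,
    min_sites: int = DEFAULT_MIN_SITES,
    model: DomainModel | None = None,
) -> PredictionResult:
    """Detect kinases, build their PWMs and score every candidate site.

    Sequences in which no catalytic domain is detected are substrates only.
    Detected kinases that yield no valid PWM are reported with a reason
    (no valid SDR string / too few matching sites / no records of the type).
    ``result.no_kinase_found`` is True when the whole file contains no
    detectable kinase; that is a reportable outcome, not an error.
    """
    if not sequences:
        raise KinspecError("no input sequences")
    policy = policy or SimilarityPolicy()
    model = model or default_domain_model()
    result = PredictionResult(substrate_ids=[s.id for s in sequences])

    backgrounds: dict[str, BackgroundFrequencies] = {}
    for seq in sequences:
        try:
            ann = annotate(seq, model)
        except SdrExtractionError as e:
            from .kinase_domain import detect_catalytic_domain

            bare = detect_catalytic_domain(seq, model)
            logger.info("%s: %s", seq.id, e)
            result.kinase_outcomes[seq.id] = KinaseOutcome(
                seq.id, bare, failure_reason=REASON_NO_SDR
            )
            continue
        if ann is None:
            continue  # substrate only
        try:
            pwm, bg, n_sites = build_pwm_for_query(
                ann.sdr,
                ann.kinase_type,
                db,
                policy,
                style=style,
                min_sites=min_sites,
                metadata={"kinase_id": seq.id},
            )
        except NoPrediction as e:
            logger.info("%s: %s", seq.id, e)
            result.kinase_outcomes[seq.id] = KinaseOutcome(
                seq.id, ann, n_matching_sites=e.n_found or 0, failure_reason=e.reason
            )
            continue
        backgrounds[seq.id] = bg
        result.kinase_outcomes[seq.id] = KinaseOutcome(
            seq.id, ann, pwm=pwm, n_matching_sites=n_sites
        )

    if result.no_kinase_found:
        logger.warning("no kinase found in the submitted sequences")
        return result

    for kid in result.predicted_kinases():
        outcome = result.kinase_outcomes[kid]
        pwm = outcome.pwm
        bg = backgrounds[kid]
        alphabet = outcome.annotation.phospho_alphabet
        scored: list[ScoredSite] = []
        for seq in sequences:
            for pos, hept in enumerate_candidate_sites(seq, alphabet):
                scored.append(
                    ScoredSite(kid, seq.id, pos, hept, score_site(pwm, hept, bg), 0)
                )
        scored.sort(key=lambda s: (-s.score, s.substrate_id, s.site_position))
        if top_k is not None:
            scored = scored[:top_k]
        result.scored_sites[kid] = [
            ScoredSite(s.kinase_id, s.substrate_id, s.site_position, s.heptamer, s.score, i + 1)
            for i, s in enumerate(scored)
        ]
    return result
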