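"""Seeded synthetic fixtures: kinases, specificity databases and proteomes.

Everything downstream of the database — matching, PWM construction, scoring,
evaluation — is testable without any external download by generating inputs
with planted ground truth:

* a planted PWM per kinase family (column 4 restricted to the family's
  acceptor residues, a configurable number of peaked flanking columns, the
  rest near-uniform — mirroring the observation that real kinases rarely
  show strong preferences at more than one or two flanking positions);
* a specificity database whose heptamers are sampled column-wise from those
  PWMs, with family SDR strings kept pairwise distant so similarity matching
  is discriminative;
* kinase sequences with the catalytic-domain anchors, a type marker and the
  SDR residues planted at exactly the positions the domain model reads;
* proteomes of background sequences with true sites inserted at recorded
  positions, plus the answer key.

All generators are pure functions of the spec (which carries the seed):
repeated calls give byte-identical output. The background residue
composition of substrates is uniform over the 20 amino acids — real
proteomes are not uniform, which is one reason these fixtures measure the
machinery rather than real-world accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import AA20, AA_INDEX, CMGC, PHOSPHO_ALPHABET, SERINE_THREONINE, TYROSINE
from .errors import KinspecError
from .kinase_domain import DomainModel, SequenceRecord, annotate, default_domain_model
from .pwm import N_POSITIONS, PHOSPHO_COL, PositionWeightMatrix
from .specdb import PhosphositeRecord, SpecificityDatabase

#: Catalytic-loop octamers planted as kinase-type markers (see domain model).
TYPE_MARKERS = {
    SERINE_THREONINE: "HRDIKPEN",
    CMGC: "HRDLKPQN",
    TYROSINE: "HRDLAARN",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for fixture generation.

    The defaults describe a moderately specific kinase family: two flanking
    positions with a strong preference (70% of the column mass on one
    residue), everything else close to uniform, and 50 sites per family —
    roughly the per-kinase evidence a well-covered database entry has.
    """

    seed: int = 0
    n_kinase_families: int = 5
    sdr_length: int = 5
    sites_per_kinase: int = 50
    #: flanking columns given a peaked preference (the rest stay near-uniform)
    n_peaked_columns: int = 2
    #: probability mass of the modal residue in a peaked column
    peak_mass: float = 0.7
    #: one shared modal residue across all peaked columns (consensus-motif
    #: style, e.g. poly-basic); used by the sharp low-entropy variant
    shared_modal_residue: bool = False
    #: residues the shared modal residue is drawn from
    modal_pool: str = "RPK"
    #: relative jitter of near-uniform columns around 0.05
    flank_jitter: float = 0.5
    #: substrate count and inclusive length range of the generated proteome
    n_substrates: int = 20
    substrate_length: tuple[int, int] = (100, 400)
    #: fraction of substrates carrying no planted site
    decoy_fraction: float = 0.3
    sites_per_substrate: int = 2
    #: sampling weights for (serine/threonine, CMGC, tyrosine) families
    type_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)
    #: fixed serine share of the phospho column for two-acceptor types;
    #: None draws it from Beta(5, 5) per kinase. 0.5 models kinases with no
    #: serine/threonine preference.
    phospho_split: float | None = None

    def __post_init__(self):
        if min(self.n_kinase_families, self.sdr_length, self.sites_per_kinase) < 1:
            raise KinspecError("counts in the synthetic spec must be positive")
        if not 0 < self.peak_mass < 1:
            raise KinspecError("peak_mass must be in (0, 1)")
        if not 0 <= self.n_peaked_columns <= 6:
            raise KinspecError("n_peaked_columns must be between 0 and 6")
        if not 0 <= self.decoy_fraction <= 1:
            raise KinspecError("decoy_fraction must be in [0, 1]")
        if self.n_substrates < 0:
            raise KinspecError("n_substrates must be >= 0")


def sharp_spec(**overrides) -> SyntheticSpec:
    """The low-entropy benchmark variant: every flanking column peaked at
    0.85 on one shared modal residue (a consensus motif such as R-R-R-S-R-R-R).
    Used by the PWM-recovery benchmark, where estimation error rather than
    motif entropy is the quantity under test."""
    base = dict(n_peaked_columns=6, peak_mass=0.85, shared_modal_residue=True)
    base.update(overrides)
    return SyntheticSpec(**base)


def style_benchmark_spec(**overrides) -> SyntheticSpec:
    """Conditions for comparing predictive power of the two PWM styles.

    A fully specific consensus kinase: every flanking column peaked at 0.95
    on its own modal residue and no serine/threonine preference. At
    *uninformative* positions the old (rectified log-odds) style has nothing
    to encode — half the column rectifies to zero and scoring then measures
    the weight floor rather than the matrix — so a fair predictive-power
    comparison plants information at every position both styles can model.
    """
    base = dict(n_peaked_columns=6, peak_mass=0.95, shared_modal_residue=False,
                phospho_split=0.5)
    base.update(overrides)
    return SyntheticSpec(**base)


def uniform_decoy_heptamers(
    kinase_type: str, n: int, rng: np.random.Generator
) -> list[str]:
    """Uniform-random candidate-site heptamers (acceptor residue at centre)."""
    alphabet = list(PHOSPHO_ALPHABET[kinase_type])
    out = []
    for _ in range(n):
        h = list(rng.choice(list(AA20), size=7))
        h[3] = str(rng.choice(alphabet))
        out.append("".join(h))
    return out


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def generate_planted_pwm(
    spec: SyntheticSpec, kinase_type: str, seed: int | np.random.Generator
) -> PositionWeightMatrix:
    """A planted truth PWM for one kinase family."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.zeros((20, N_POSITIONS))
    flank_cols = [c for c in range(N_POSITIONS) if c != PHOSPHO_COL]
    peaked = sorted(
        rng.choice(flank_cols, size=spec.n_peaked_columns, replace=False).tolist()
    )
    shared_modal = None
    if spec.shared_modal_residue:
        shared_modal = AA_INDEX[str(rng.choice(list(spec.modal_pool)))]
    for c in flank_cols:
        if c in peaked:
            m = shared_modal if shared_modal is not None else int(rng.integers(20))
            rest = rng.dirichlet(np.ones(19)) * (1 - spec.peak_mass)
            col = np.insert(rest, m, spec.peak_mass)
            w[:, c] = col
        else:
            u = 0.05 * (1 + spec.flank_jitter * (rng.random(20) - 0.5))
            w[:, c] = u / u.sum()
    acceptors = PHOSPHO_ALPHABET[kinase_type]
    if len(acceptors) == 1:
        w[AA_INDEX[acceptors], PHOSPHO_COL] = 1.0
    else:
        q = rng.beta(5, 5) if spec.phospho_split is None else spec.phospho_split
        w[AA_INDEX[acceptors[0]], PHOSPHO_COL] = q
        w[AA_INDEX[acceptors[1]], PHOSPHO_COL] = 1 - q
    return PositionWeightMatrix(
        weights=w, style="external", metadata={"planted": True, "kinase_type": kinase_type}
    )


def sample_heptamer(pwm: PositionWeightMatrix, rng: np.random.Generator) -> str:
    """Draw one heptamer column-wise from a PWM."""
    out = []
    for j in range(N_POSITIONS):
        p = pwm.weights[:, j] / pwm.weights[:, j].sum()
        out.append(AA20[int(rng.choice(20, p=p))])
    return "".join(out)


def _distant_sdrs(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """SDR strings pairwise different at >= ceil(length/2) positions."""
    min_diff = math.ceil(length / 2)
    out: list[str] = []
    while len(out) < n:
        cand = "".join(rng.choice(list(AA20), size=length))
        if all(sum(a != b for a, b in zip(cand, s)) >= min_diff for s in out):
            out.append(cand)
    return out


@dataclass(frozen=True)
class PlantedKinase:
    kinase_id: str
    kinase_type: str
    sdr: str
    pwm: PositionWeightMatrix


def generate_database(
    spec: SyntheticSpec,
) -> tuple[SpecificityDatabase, dict[str, PlantedKinase]]:
    """A synthetic specificity database plus its planted truth map."""
    rng = _rng(spec, stream=1)
    sdrs = _distant_sdrs(spec.n_kinase_families, spec.sdr_length, rng)
    types = (SERINE_THREONINE, CMGC, TYROSINE)
    records: list[PhosphositeRecord] = []
    truth: dict[str, PlantedKinase] = {}
    for i in range(spec.n_kinase_families):
        kid = f"KIN{i:03d}"
        ktype = str(rng.choice(types, p=spec.type_weights))
        pwm = generate_planted_pwm(spec, ktype, rng)
        truth[kid] = PlantedKinase(kid, ktype, sdrs[i], pwm)
        for j in range(spec.sites_per_kinase):
            records.append(
                PhosphositeRecord(
                    kinase_id=kid,
                    kinase_type=ktype,
                    kinase_sdr=sdrs[i],
                    substrate_id=f"{kid}_SUB{j:03d}",
                    site_position=int(rng.integers(10, 500)),
                    heptamer=sample_heptamer(pwm, rng),
                )
            )
    db = SpecificityDatabase(
        records=tuple(records),
        sdr_length=spec.sdr_length,
        provenance=f"kinspec synthetic generator, seed={spec.seed}",
    )
    return db, truth


def _random_residues(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=n)) if n > 0 else ""


def _build_kinase_residues(
    kinase_type: str, sdr: str, rng: np.random.Generator
) -> str:
    """One candidate kinase sequence with anchors, marker and SDRs planted."""
    if len(sdr) != 5:
        raise KinspecError(
            "the bundled domain model reads 5 SDR positions; "
            f"got an SDR string of length {len(sdr)}"
        )
    gly = "G" + _random_residues(1, rng) + "G" + _random_residues(2, rng) + "G"
    vaik = str(rng.choice(list("VAI"))) + _random_residues(1, rng) + "K"
    marker = TYPE_MARKERS[kinase_type]
    linker1 = _random_residues(int(rng.integers(10, 50)), rng)
    linker2 = list(_random_residues(int(rng.integers(50, 140)), rng))
    linker2[-2], linker2[-1] = sdr[0], sdr[1]  # hrd-2, hrd-1
    linker3 = _random_residues(int(rng.integers(4, 28)), rng)
    loop = list(_random_residues(int(rng.integers(14, 50)), rng))
    loop[0], loop[1] = sdr[2], sdr[3]  # dfg+3, dfg+4
    loop[-2] = sdr[4]  # ape-2
    nflank = _random_residues(int(rng.integers(10, 40)), rng)
    cflank = _random_residues(int(rng.integers(10, 40)), rng)
    return (
        nflank + gly + linker1 + vaik + "".join(linker2) + marker + linker3
        + "DFG" + "".join(loop) + "APE" + cflank
    )


def generate_kinase_sequence(
    kinase_id: str,
    kinase_type: str,
    sdr: str,
    rng: np.random.Generator,
    model: DomainModel | None = None,
    max_attempts: int = 100,
) -> SequenceRecord:
    """A kinase sequence whose annotation round-trips to the planted truth.

    Random linkers can occasionally create a spurious anchor chain; candidates
    are re-drawn (deterministically) until detect/classify/extract reproduces
    the planted type and SDR string exactly.
    """
    model = model or default_domain_model()
    for _ in range(max_attempts):
        residues = _build_kinase_residues(kinase_type, sdr, rng)
        seq = SequenceRecord(kinase_id, f"{kinase_id} synthetic kinase", residues)
        ann = annotate(seq, model)
        if ann is not None and ann.kinase_type == kinase_type and ann.sdr == sdr:
            return seq
    raise KinspecError(f"could not plant a consistent kinase sequence for {kinase_id}")


@dataclass(frozen=True)
class PlantedSite:
    kinase_id: str
    substrate_id: str
    site_position: int  # 1-based
    heptamer: str


def generate_proteome(
    spec: SyntheticSpec,
    truth: dict[str, PlantedKinase],
    model: DomainModel | None = None,
) -> tuple[list[SequenceRecord], list[PlantedSite]]:
    """Kinase sequences plus background substrates with planted true sites."""
    rng = _rng(spec, stream=2)
    model = model or default_domain_model()
    sequences = [
        generate_kinase_sequence(pk.kinase_id, pk.kinase_type, pk.sdr, rng, model)
        for pk in truth.values()
    ]
    answer_key: list[PlantedSite] = []
    n_decoys = round(spec.decoy_fraction * spec.n_substrates)
    decoy_idx = set(
        rng.choice(spec.n_substrates, size=n_decoys, replace=False).tolist()
    ) if spec.n_substrates else set()
    kinase_ids = sorted(truth)
    lo, hi = spec.substrate_length
    for i in range(spec.n_substrates):
        sid = f"SUB{i:03d}"
        length = int(rng.integers(lo, hi + 1))
        residues = list(_random_residues(length, rng))
        if i not in decoy_idx and kinase_ids:
            kid = str(rng.choice(kinase_ids))
            pwm = truth[kid].pwm
            used: list[tuple[int, int]] = []
            planted = 0
            attempts = 0
            while planted < spec.sites_per_substrate and attempts < 100:
                attempts += 1
                pos = int(rng.integers(4, length - 2))  # 1-based, full window inside
                if any(abs(pos - p) < 7 for p, _ in used):
                    continue
                hept = sample_heptamer(pwm, rng)
                residues[pos - 4 : pos + 3] = list(hept)
                used.append((pos, 0))
                answer_key.append(PlantedSite(kid, sid, pos, hept))
                planted += 1
        sequences.append(
            SequenceRecord(sid, f"{sid} synthetic substrate", "".join(residues))
        )
    return sequences, answer_key


def write_answer_key(key: list[PlantedSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("kinase_id\tsubstrate_id\tsite_position\theptamer\n")
        for s in key:
            fh.write(f"{s.kinase_id}\t{s.substrate_id}\t{s.site_position}\t{s.heptamer}\n")


def read_answer_key(path) -> list[PlantedSite]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            kid, sid, pos, hept = line.rstrip("\n").split("\t")
            out.append(PlantedSite(kid, sid, int(pos), hept))
    return out
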