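# Methods

## Model

A kinase's peptide specificity is represented as a 20×7 position weight
matrix (PWM): rows are the twenty standard amino acids in alphabetical
one-letter order, columns are substrate positions −3..+3 relative to the
phospho-residue, which occupies column 4. The method assumes that
specificity is carried by specificity-determining residues (SDRs) in the
catalytic domain: kinases whose SDR strings are similar are assumed to
prefer similar substrate contexts, so the known substrate heptamers of
SDR-similar database kinases are pooled to estimate the query's PWM. This is
a pure peptide-specificity model: substrate recruitment, co-localisation and
co-expression are outside its scope, and predictions should be read as
"sequence contexts this kinase could phosphorylate", not "substrates it does
phosphorylate in vivo".

### Domain detection and SDR extraction

Detection is anchored motif matching rather than profile-HMM alignment: the
glycine-rich loop (`G.G..G`), a β3-lysine motif (`[VAI].K`), the catalytic
loop (`HRD`), and the activation-segment `DFG` and `APE` motifs must occur
in order with bounded spacing (bounds in `data/domain_model.yaml`). The
algorithm scans first-anchor matches left to right and takes the earliest
chain that satisfies all spacing bounds, so results are deterministic and
the first detected domain wins in multi-domain sequences. A sequence in
which the chain cannot be completed yields no annotation and is treated
purely as a substrate — exactly the behaviour a true kinase that fails to
align would get, which is a known source of false negatives.

Kinase type (serine/threonine, CMGC, tyrosine) is assigned by three ordered
regular expressions over the detected domain, reading the catalytic-loop
octamer; the first match wins and serine/threonine is the logged default.
CMGC kinases are serine/threonine-directed but form a separate matching
class because their SDRs differ systematically. The SDR string is read at
anchor-relative offsets listed in the same config file. Both the type
patterns and the SDR offset table are *illustrative defaults with the
correct structure*: the original structural analysis that fixed the SDR
position list is not reproduced here, and the config file is versioned so
any alternative table gives reproducible, comparable results. Because every
database record stores the SDR string itself, the matching core is
independent of the extraction table. A profile-HMM aligner can be plugged in
by constructing `KinaseAnnotation` objects from its output.

### Matching policy

Database records match a query when record and query have the same kinase
type and, at **every** SDR position, the substitution score of the residue
pair is at least the cut-off (per-position AND, not a summed score). The
default is BLOSUM62 with cut-off 1, i.e. only positive-scoring substitutions
are allowed; cut-off 0 or a shallower matrix (BLOSUM30) relaxes matching
monotonically — the accepted set at a lower cut-off is always a superset.
Non-standard residues (B, Z, X, U, O, J) fail their position by default;
`SimilarityPolicy.nonstandard_score` can assign them a fixed score instead.
They are never silently skipped. Note the published BLOSUM series is not on
a single scale (1/5-bit units for BLOSUM30 up to half-bit units for
BLOSUM62/90), so a given cut-off is not equally stringent across matrices.
The bundled BLOSUM95 is a synthetic stand-in (mean of BLOSUM90 and BLOSUM100
in bit units, re-expressed in half-bit units); its data file and header say
so.

### Frequency estimation and the two PWM styles

Matching heptamers are tallied into raw counts `c_ij` (residue *i*, column
*j*) over `N` sites; a query with fewer than `min_sites` (default 3)
matching sites yields "no prediction possible" rather than an unreliable
matrix. Probabilities use square-root pseudo-counts:

    f_ij = (c_ij + sqrt(N) * b_i) / (N + sqrt(N))

where `b_i` is the background frequency of residue *i* across all substrate
heptamers of the kinase type in the database (zero counts floored at 1e-4,
then renormalised). Columns of `f` sum to 1 exactly because `Σ b_i = 1`. The
√N scheme is the standard choice that vanishes at rate 1/√N while dominating
the counts when data are scarce.

* **new style**: weights are `f` itself — no background transformation. This
  matches experimentally mapped PWMs, which are typically also plain
  frequency summaries, and is the default.
* **old style**: per-position log-odds `log2(f_ij / b_i)`, negatives
  rectified to zero, each column renormalised to sum 1; a column with no
  positive log-odds becomes uniform 0.05 (logged). Log base 2 only matters
  through the zero set, which any base preserves. Whether the historical
  construction rectified, shifted or exponentiated negative log-odds is not
  documented; rectification was chosen because it keeps the weights
  interpretable as probabilities concentrated on enriched residues.

### Scoring

Candidate sites are every S/T (or Y, for tyrosine kinases) in every
submitted sequence; terminal windows are padded with `X` so position-1
residues remain scannable. A heptamer scores

    score = Σ_j log2( max(w_ij, 1e-4) / b_i ),   X contributes 0.

The 1e-4 floor keeps old-style zeros finite (−8.97 bits against a uniform
background, a deliberate strong penalty). Scores are additive log-likelihood
ratios against the type background: 0 means background-like. Ranks are dense
1..K per kinase, ties broken by (substrate id, position), so output is
byte-identical across runs. No score threshold is applied by default;
`--top-k` truncates large scans.

### Evaluation

Frobenius distance `‖G − P‖_F = sqrt(Σ (g_ij − p_ij)²)`. Monte-Carlo
p-values use the add-one estimator `p = (1 + #{d_i ≤ d_obs}) / (n_random +
1)` (never zero, floor `1/(n_random+1)`), with `n_random` defaulting to
10 000 and the seed recorded in every result. Two null models are
implemented and always named in output: `uniform-simplex` (each column drawn
uniformly from the 20-simplex; the default) and `phospho-constrained`
(column 4 restricted to S/T/Y). The historical reference distribution behind
published challenge p-values is not documented, so p-values here are
internally consistent but not comparable to externally published absolute
values, and p-values under different nulls must not be compared to each
other. Baselines M1 (uniform 0.05), M2 (S/T = 0.5 at column 4) and M3
(S/T/Y = 1/3, with a flag for the rounded 0.33) quantify how well a
no-information matrix already does. Predictive power is measured separately
as ROC AUC of heptamer scores (rank-sum, ties 0.5) because Frobenius
distance rewards hedged matrices and is not a proxy for discrimination.

## Synthetic benchmark design

The generator (`kinspec.synthetic`) plants complete ground truth: per-family
PWMs, SDR strings pairwise different at ≥ ⌈L/2⌉ positions, heptamers sampled
column-wise from the planted PWMs, kinase sequences with the anchors, a
type-marker octamer and the SDR residues at exactly the positions the domain
model reads (candidates failing the detect→classify→extract round trip are
deterministically re-drawn), and substrate proteomes with planted sites and
an answer key. All generators are pure functions of the spec and seed.

Three named configurations are used:

* **Default** (`SyntheticSpec()`): 5 families, 50 sites per family, two
  peaked flanking columns with 70% of the mass on one residue, remaining
  columns jittered ±25% around uniform, S/T split drawn from Beta(5, 5),
  20 substrates of 100–400 residues, 30% decoys, 2 planted sites per
  non-decoy. This mirrors the common observation that a kinase has strong
  preferences at only one or two flanking positions.
* **Sharp** (`sharp_spec()`): all six flanking columns peaked at 0.85 on a
  single shared modal residue from a basic/proline pool (a consensus motif
  such as R-R-R-S-R-R-R). Used for PWM-recovery benchmarks, where the
  quantity under test is estimation error, not motif entropy: with the √N
  pseudo-count, both the sampling error and the shrinkage bias of `f` decay
  only as ~1/√N, and a motif with several near-uniform columns has an
  irreducible expected recovery distance of ≈ 0.17 at N = 200 — the shared
  consensus design brings the background close to every column and the
  expected distance to ≈ 0.12.
* **Style comparison** (`style_benchmark_spec()`): all six flanking columns
  peaked at 0.95 on distinct modal residues, S/T split fixed at 0.5. At
  uninformative positions the rectified old style has nothing to encode
  (half the column rectifies to zero and scoring then measures the weight
  floor, not the matrix), and an asymmetric S/T column is actively
  misranked by old-style scoring because log-odds-derived weights get
  divided by the background a second time. A fair predictive-power
  comparison therefore plants information at every position both styles can
  represent, and gives the phospho column no preference — consistent with
  the original submitted matrices, which weighted S and T equally.

What passing these benchmarks does **not** show: real proteomes are not
uniform in composition, real kinase families share SDR space much more
densely than the planted ⌈L/2⌉-separated strings, real databases carry
annotation errors, and the default SDR table is illustrative. The
benchmarks validate the machinery — matching, estimation, scoring,
evaluation — under controlled conditions, not real-world accuracy.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive everywhere; conversion happens only at
  file boundaries.
* PWM TSV files are written with 17 significant digits, so read∘write is
  exact to 1e-12; row order (A..Y) and column-header order (−3..+3) are
  enforced on read.
* Problem sizes in the test suite and acceptance script (20-seed sweeps,
  200 Monte-Carlo replicates of 1 000 null draws, 20-family databases) were
  chosen so the whole suite completes in well under a minute while keeping
  Monte-Carlo noise far from every asserted margin.
* Degenerate cases: an empty database is valid (queries return nothing); a
  whole input file without a detectable kinase is a reported outcome, not an
  error; an all-zero old-style column becomes uniform; background residues
  never observed get the 1e-4 floor.

## Known limitations

* Domain detection by anchor motifs is cruder than profile-HMM alignment;
  divergent kinases missing a literal anchor are not detected (the plug-in
  seam accepts external aligners).
* The shipped SDR position table and kinase-type patterns are structural
  placeholders; serious use requires substituting a curated table.
* Only the first catalytic domain of a multi-domain kinase is used.
* Atypical, lipid and pseudo-kinases are out of scope, as are PAM or
  user-supplied substitution matrices (the file format is documented, so
  they can be added).
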