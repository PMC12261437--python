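# Methods

## Generative model

Each sequenced read `r_n` is modelled as arising from one transcript `T_n`
drawn with probability `Pr(T_n = j | θ) = θ_j`, where `θ` lives on the
M-simplex. Because long-read protocols lack a fragmentation step, the
sampling rate is deliberately *not* proportional to transcript length; `θ_j`
is simultaneously the molar fraction and the expected read fraction, and the
output contains no TPM-style effective-length normalisation.

Conditional on the source transcript, an observed alignment contributes two
fixed factors:

1. **Score factor.** `Pr(A_n | T_n = j) = exp((AS_nj − AS_n^max) / c)` for
   transcripts in the read's alignment set `A(r_n)`, zero elsewhere, with
   `AS_n^max` the read's best score and `c = 10` score units by default. The
   best alignment always has probability exactly 1; an alignment 10 score
   units behind is down-weighted by `e^{-1}`; badly suboptimal alignments are
   effectively discarded by the exponential falloff, which is why no hard
   score filter is applied by default (an optional minimum score-fraction
   filter exists but is off). Mapping quality is never used: MAPQ estimates
   are unreliable across long-read aligners, while AS reflects the alignment
   itself.
2. **Coverage factor** (model `cov` only). Per transcript, coverage is
   summarised once, before inference, on segments of `bin_width = 100` nt
   (last segment truncated; its fractional-count denominator is its true
   length). Every retained alignment — including all hits of multimapping
   reads, each with weight 1 — adds to segment `i` the fraction of the
   segment it overlaps. After adding a pseudocount of 1% of the transcript's
   aligned reads to every segment (stabilising low-coverage transcripts),
   the relative deviation `δ_i = (E(c) − c_i) / E(c)` of each segment from
   the transcript mean `E(c)` is mapped through a logistic function
   `P_ij = 1/(1 + e^{−aδ_i})` with growth rate `a = 2`. Over-covered
   segments score below 1/2 and sparse segments above 1/2, with range
   bounded by `(1/(1+e^a), 1/(1+e^{a(1-K)}))` since `δ_i ≤ 1`. An
   alignment's start–end probability is the overlap-weighted *mean* of the
   `P_ij` over its span (weights normalised to sum to one), so it is a
   convex combination in (0, 1) and does not scale with read length.
   Transcripts with no coverage at all get a flat profile of 1/2.

The probability of the read sequence given its alignment is treated as the
constant 1: it carries no transcript-discriminating information beyond what
the alignment score already encodes, and any per-read constant cancels when
responsibilities are normalised. For the same reason the `cov` model with
`a = 0` (all coverage factors exactly 1/2) yields responsibilities — and
therefore EM trajectories — bit-identical to `nocov`; the test suite asserts
this equivalence.

## Inference

The marginal likelihood `L(θ) = Π_n Σ_{j∈A(r_n)} θ_j q_nj` is maximised by
EM on a sparse read × transcript matrix of the fixed conditionals `q_nj`:
E-step `r_nj = θ_j q_nj / Σ_{j'} θ_{j'} q_{nj'}`, M-step
`θ_j = Σ_n r_nj / N`. Numerical choices:

- **Initialisation**: uniform `θ_j = 1/M`. Inference contains no randomness;
  repeated runs are bit-identical.
- **Convergence**: stop when the largest absolute change in expected counts
  `θ_j·N` falls below `tol = 1e-3` reads, or after `max_iters = 1000`
  iterations. The per-iteration log-likelihood is recorded and is
  non-decreasing (a standard EM guarantee; asserted with 1e-9 slack in
  every EM test).
- **Degenerate rows**: a read whose entire posterior row is zero (θ zero on
  all its targets — impossible from the uniform start, but reachable with a
  custom initialisation) is assigned uniformly over its alignment set.
- **Ties**: exact symmetric instances sit at their symmetric fixed point
  from the uniform start (e.g. a read tied between two transcripts with no
  other evidence splits exactly 50/50).

Reads whose conditionals all underflow to zero are dropped with a logged
count and excluded from `N`.

## Input handling

Alignments must be collated by query name; a read name that reappears after
a different read raises a collation error rather than silently truncating a
group. Coordinates are converted to 0-based half-open on the transcript; the
aligned span is the CIGAR's reference-consumed length. Unmapped records are
dropped; reverse-strand alignments are dropped by default (transcriptome
references are sense-stranded) with a flag to retain them for
two-orientation cDNA libraries; duplicate hits of one read to one transcript
collapse to the max-score record; supplementary/secondary records are
otherwise eligible. A mapped record without an `AS` tag is a format error.

## Synthetic data

The generator emulates the data regime the quantifier targets, with all
randomness governed by a single seed (same seed ⇒ identical bytes):

- **Sampling law**: reads i.i.d. with `Pr(transcript = j) = θ_j` — no
  length weighting. Truth `θ` is either supplied or drawn from
  `Dirichlet(0.5)` over `n_transcripts = 50` transcripts of 500–3000 nt;
  `n_reads = 50 000`.
- **Truncation**: a read is full-length with probability 0.25; otherwise its
  aligned fraction is lognormal (median 0.65, σ = 0.35, floor 50 nt), so
  transcripts are typically ~1.5× longer than aligned reads. Truncated
  reads are 3'-anchored degradation/pore-exit products (end fixed at the
  transcript end) or, with probability 0.5, internal breakage fragments
  (both ends move). The internal class matters: if *every* read were
  end-anchored, each transcript's own coverage would be intrinsically
  3'-spiked and coverage uniformity would cease to be evidence of origin.
- **Ambiguity**: two classes, mirroring a real transcriptome. *Prefix pairs*
  (4% of transcripts are exact prefixes, 40–80% of the partner's length, as
  in the worked example) produce score-tied alignments that only coverage
  can arbitrate — kept rare, mirroring how uncommon exact proper-prefix
  transcripts are in real annotations. *Paralog pairs* (50% of transcripts have a same-length
  partner at 1–5% divergence) produce the bulk of multimapping; the
  cross-alignment pays a binomial per-mismatch penalty (match +2,
  mismatch −4, minimap2-like), so these are resolvable through the score
  model, matching the observation that most real multimapping is
  score-resolvable. Typical multimap rates land around 40–70% of reads.
- **Scores**: `AS = 2·span − 6·mismatches ± 2` integer jitter, so exact ties
  and near-ties both occur.
- **Output**: name-collated SAM written through pysam (primary record on the
  true transcript with the read sequence; partners as secondaries),
  transcript FASTA, and a truth TSV.

What the generator does **not** emulate: base-call errors and quality
strings, realistic indel/softclip structure, chimeras, strand flips,
positional bias within segments, and annotation incompleteness. Passing
recovery tests on this generator therefore demonstrates correctness of the
model and optimiser under the model's own assumptions plus controlled
ambiguity — not performance on any particular sequencing chemistry.

## Evaluation panel

Spearman and Kendall τ-b on raw counts; Pearson and Lin's CCC on
`log(1+x)` (raw-scale variants via a flag); `RMSE`; `NRMSE = RMSE /
mean(truth)`; `MARD` with `ARD = |x−y|/(x+y)`, defined as 0 at `(0,0)` —
bounded in [0, 1]. The ARD denominator is a convention choice (no single
standard exists); note it scores *any* positive estimate of a truly silent
transcript as a full error of 1. Expressed-transcript detection uses
precision–recall with the estimated abundance as the score (`truth > 0` as
the positive label); AP follows the step-wise definition
`Σ (R_k − R_{k−1}) P_k`. InfRV is
`max(σ² − μ, 0)/(μ + 5) + 0.01` with the additive 0.01 acting as a floor;
its inputs (mean and variance across inferential replicates) come from
external short-read quantifiers, not from this package.

Correlations on zero-variance input are reported as NaN rather than raised;
single-class PR input is an error from `precision_recall` and NaN inside the
aggregate report.

## Design choices that were genuinely open

- **Weight normalisation in the start–end probability**: a plain weighted
  sum over covered segments would grow with read length; normalising the
  overlap weights to one keeps the factor a probability-like score and
  length-invariant. This is the single most consequential reading choice in
  the coverage model.
- **Static profiles**: coverage profiles are computed once from all retained
  alignments and held fixed; re-estimating them from responsibilities
  during EM is attractive but raises convergence questions, and is out of
  scope here.
- **Profile weights**: multimapped alignments contribute to every target's
  profile with weight 1 (not split by alignment probability). This inflates
  coverage on heavily multimapped regions but requires no circular
  dependency on the inference result.
- **Convergence on counts, not log-likelihood**: a tolerance in read units
  (1e-3) is interpretable and matches common quantifier practice.

## Problem sizes used in the test suite

The suite exercises the full pipeline at 50 transcripts × 50 000 reads for
the recovery test, 20 simulations of 6 × 400 for the model-equivalence
test, 100 random transcripts (≤ 2 kb, ≤ 200 alignments) for the coverage
oracle, and exhaustive simplex grid search (resolution 1e-3, up to 3
transcripts × 6 reads) for EM optimality — sizes chosen so the oracles are
exact and the whole suite runs in well under a minute.

## Known limitations

- Exact-prefix pairs in which *both* partners are substantially expressed
  are only partially recoverable: the ambiguous reads' likelihood terms
  depend on `θ_short + θ_long` alone, so the unique reads of the long
  partner pull the MLE toward the boundary unless the coverage contrast is
  strong. The coverage term corrects the clean case (long partner silent —
  the worked example) and mitigates, but does not abolish, the mixed case.
- Strictly end-anchored protocols (pure direct-RNA truncation with no
  internal breakage) violate the model's uniform-coverage prior; under such
  data the coverage term can prefer the wrong partner and `nocov` may be
  the safer model.
- Coverage profiles ignore the possibility that observed non-uniformity is
  positional bias rather than mis-assignment evidence.
- The EM reports a point estimate only; no uncertainty quantification
  (Gibbs/bootstrap replicates) is provided.
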