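# Methods

This note records the model, the parameter choices that matter, what the
synthetic data does and does not emulate, and the numerical decisions —
in the spirit of the methods documentation of mature scientific
packages. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Profile HMM

**Architecture.** Match states `M_0..M_{L-1}` with position-specific
emission rows over the 20 amino acids; one shared insert emission vector;
delete states parallel to the match states. Allowed core transitions are
M→{M,I,D}, I→{M,I} and D→{M,D} (no I↔D moves, as in Plan7-style models).
Every stored transition row is a proper probability distribution.

**Construction.** Alignment columns with a gap fraction strictly above
0.5 are treated as insert columns (a Pfam-like occupancy heuristic);
the rest become match states. Match emissions use a single
background-weighted pseudocount: `(count + w·f_bg) / (n_obs + w)` with
default weight `w = 1`. Transitions are counted from each row's gap
structure, trimmed to its first and last aligned match residue (entry
and exit are local, so flanking gaps and flanking inserts carry no
information), with a uniform pseudocount of `w / n_targets` per allowed
move. Insert emissions are fixed at the background distribution so
inserted residues are score-neutral — the standard choice, and the one
that makes local scores independent of unaligned sequence.

**Local mode.** A path enters directly at any match state and exits from
any match state; the joint (entry, exit) pair is uniform over the
`L(L+1)/2` ordered pairs and enters the score once as
`log2(2/(L(L+1)))`. This mildly penalizes short model spans and reduces
to zero cost for `L = 1`. Residues outside the aligned region are
emitted by the background null and cancel exactly.

**Scoring.** All dynamic programming is in log2 space (bits); no
probability-space arithmetic is performed anywhere, so there is no
underflow regime. Viterbi returns the best path score with its realized
sequence and model spans (by backpointer traceback); forward returns the
log-sum over all paths. Both kernels are verified against exhaustive
path enumeration on random instances with `L ≤ 4` and sequences up to 6
residues. Unknown residues (X, B, Z, J, U, O) are emitted at background
frequency — log-odds zero — and are never an error in screening mode.

Two numerical facts worth knowing:

- *Forward flank neutrality is approximate.* Appending background-scored
  residues leaves the Viterbi score exactly unchanged, but forward gains
  a small amount of probability mass (observed ~1e-2 bits on a
  strong-scoring sequence) from near-null paths that shift part of the
  alignment into the flank. This is a property of any uniform-entry
  local model, not an implementation artifact.
- *E-values saturate in the deep left tail.* The Gumbel survival
  function is computed accurately via `expm1`, but for scores far below
  the location parameter it equals 1.0 in double precision, so E(S) is
  strictly decreasing only above that saturation region.

**Calibration.** Each profile is calibrated by scoring `n = 200` random
background sequences (lengths drawn log-normal, median 300, sigma 0.4 —
typical bacterial protein lengths — or from a caller-supplied sampler
matched to the target proteome) and fitting a Gumbel law by maximum
likelihood (`scipy.stats.gumbel_r.fit`). The E-value for a database of
`N` sequences is `N · P(S > s)` under the fit. The calibration seed is
stored in the profile JSON so builds are reproducible. A zero-variance
score distribution (possible only for degenerate profiles that emit the
background) raises a calibration error rather than producing a bogus
fit.

**Coverage.** The screening literature's "protein coverage" is ambiguous
between query and model. Here coverage defaults to **model coverage** —
the fraction of the profile's match states inside the reported alignment
span — because the failure mode the >90% filter plausibly targets is a
short fragment matching a small part of an enzyme model (e.g. an
isolated ATP-binding domain matching a kinase profile). Query-side
coverage is available via `coverage_mode="sequence"`.

## Pathway model and completeness calls

The pathway definition is declarative (YAML/JSON or the built-in
default): seven steps, each satisfiable by one or more canonical
variants, where a variant carries one or more profile identifiers (the
divergent DHQ synthase and shikimate kinase families carry two models
each; the best bit score across a variant's profiles represents it).
Fusion variants satisfy several steps at once — the pentafunctional AROM
protein (steps 2–6) and the bifunctional aroD/aroE protein (steps 3–4) —
and satisfy exactly their declared step set, never more.

Non-orthologous alternatives (KDPGal aldolase for step 1, GHMP-family
kinase for step 5) are deliberately excluded from the canonical
completeness call and recorded as per-step *rescues*: the headline
completeness statistics in the screen this package re-implements were
computed from the canonical enzyme set, and the GHMP model in particular
is known to be unspecific (it matches serine kinases broadly). A
sensitivity analysis that counts rescues can be run by editing the
variant roles in the pathway config.

Hit tie-breaking is fully deterministic: higher bit score, then smaller
E-value, then lexicographic protein id, then variant id. Step evaluation
is therefore idempotent and invariant to hit-list permutation. One
protein may satisfy any number of steps (fusions require this).

## Screening semantics

- E-value database size = number of proteins in the proteome being
  screened (per-proteome search semantics).
- All three thresholds are strict inequalities, read literally from the
  published cut-offs: score > 50, E < 1e-8, coverage > 90%.
- Proteins shorter than 10 residues are skipped with a logged warning;
  an empty proteome yields an all-missing call flagged with a warning
  rather than an error.
- Nucleotide mode translates all six reading frames (standard code),
  splits on stop codons, and screens ORF segments of ≥ 30 residues — a
  floor chosen below the shortest real pathway domain.

## Synthetic data: what it emulates, and what a green test establishes

Enzyme families are drawn from a fixed background amino-acid composition
(Robinson & Robinson frequencies, built in, so everything is
download-free). Members diverge from a consensus by per-site
substitution at rate `d` with replacements drawn from the background,
plus indels at rate `d/10` (one knob controls both). Family seed
alignments default to `d = 0.3` with 25 members — roughly Pfam-seed-like
diversity. Planted proteome copies diverge at `d_emit` (default 0.2);
decoy proteins are i.i.d. background with log-normal lengths (median
300, sigma 0.4). Default family lengths are typical bacterial enzyme
sizes (160–420 residues; the AROM fusion is the concatenation of its
five components).

The default cohort mirrors the structure of a 488-genome prokaryotic
screen: group fractions 147:250:45:46 (free-living Bacteria,
host-associated culturable, host-associated non-culturable, Archaea)
allocated by largest remainder (exact at n = 488); per-group
missing-step patterns reproduce the reported completeness rates
(131/147, 204/295, 1/46), the host-associated loss structure (most
incomplete genomes lost ≥ 5 genes; of single-loss genomes 16/20 lost
step 1) and the archaeal preference for losing steps 1 or 5. Fusions are
planted in 10% of eligible genomes; the KDPGal alternative appears in
14/108 of DAHP-missing genomes (and half of the rest), the GHMP family
in 90% of genomes, mirroring the near-universality of serine kinases.

What the generator does **not** emulate: real substitution matrices
(replacements are background draws, so synthetic divergence is "harder"
than BLOSUM-like divergence at the same d), compositional bias, paralog
interference between genuinely related families, multi-domain proteins
other than the declared fusions, and annotation noise in the proteome
itself. A green planted-truth test therefore establishes that the
pipeline machinery (scoring, calibration, thresholds, pathway logic) is
correct and well-calibrated — not that the shipped profiles would
reproduce any particular biological screen.

Every generator is a pure function of its parameters and seed; cohort
outputs are byte-identical across runs.

## Concordance

Agreement with a reference annotation is the per-genome binary
complete/incomplete call over the genomes present in both inputs, with
one-sided genomes listed separately. The published 84% BioCyc agreement
figure is treated as non-recomputable from its printed partial counts;
the package instead verifies the *property* that a reference flipped at
rate 0.16 over 500 genomes yields ≈ 84% agreement (within 3 points in
the mean over 10 seeds).

## Other numerical and design choices

- Integer percentages round to nearest with ties away from zero; this
  rule reproduces all seven printed percentages of the summary tables it
  mirrors (31, 24, 11, 31, 98, 28, 49) from their printed counts.
- The gene-clustering check formalizes "are the pathway genes clustered"
  as a sliding-window statistic: the maximum number of pathway gene
  starts in any 20 kb window per replicon, clustered iff ≥ 4 — the
  minimal reproducible version of a gene-map inspection. Both defaults
  are configurable; the statistic matches brute-force window enumeration.
- Genomes of unknown culturability form their own stratum, excluded from
  the culturable/non-culturable rows unless explicitly requested.
- The source material states both 486 and 488 analyzed proteomes in
  different places; the package is cohort-size-agnostic and the default
  synthetic mix uses the 488 figure.
- Profile JSON is versioned and includes build provenance (row/column
  counts, pseudocount, calibration seed).

## Known limitations

- Bit scores are not comparable to HMMER's (no Dirichlet mixture priors,
  no glocal/multi-hit mode, different local-entry parameterization);
  only the pipeline's own calibrated E-values should be thresholded.
- Gumbel calibration from 200 samples carries fit uncertainty of a few
  percent in tail probabilities; the acceptance test accounts for both
  Monte-Carlo and fit standard errors.
- The Viterbi kernel is O(L·n) per pair with no heuristic prefilter, so
  screening cost grows linearly in total profile length; a 60-genome
  cohort with ~107 proteins each against ~5300 total match states takes
  on the order of two minutes on one CPU.
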