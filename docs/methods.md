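# Methods

## Statistics and estimation conventions

All statistics are defined on the RNA alphabet {A, C, G, U}; DNA input is
normalized (case folded, T→U) and ambiguity codes are rejected rather
than skipped, because dropping a base would shift the codon frame and the
redundancy measures are defined on a strict 4-letter alphabet.

For a sequence of N bases with empirical base probabilities
p_i = count(i)/N:

- `D1 = 2 + Σ_i p_i log2 p_i` (bits). D1 ∈ [0, 2]; 0 iff the composition
  is exactly uniform, 2 iff a single base is present.
- `D2 = −2 Σ_i p_i log2 p_i + Σ_ij p_ij log2 p_ij` (bits), with p_ij the
  **overlapping** dinucleotide frequency on the **linear** sequence,
  denominator N−1.
- `C_GC = (N_G + N_C)/N`.

Estimation choices, made once and applied uniformly:

- plain frequency estimates, no pseudocounts;
- `0 · log2 0 := 0`;
- logarithms base 2 (the additive constant 2 in D1 confirms bits);
- p_i in D2 uses all N bases while p_ij uses the N−1 overlapping pairs.
  Because the marginals of the pair distribution then differ from p_i by
  one base at each end, D2 can be marginally **negative** for short
  sequences. This is the literal consequence of the defining equations and
  is documented rather than patched (circularizing or re-deriving p_i from
  the pairs would be a different estimator). For the i.i.d. null, D2 is
  the −2·log-likelihood-ratio mutual-information statistic up to scale and
  converges to 0 as N → ∞.

The defining equations are evaluated independently (dict-and-loop brute
force) in the test suite and the two routes are required to agree to
1e−12, exhaustively over all 64 length-6 two-letter sequences and on
random 4-letter sequences.

### Codon-position subsequences

A framed sequence (length a multiple of 3, ≥ 2 codons) is split into
three subsequences: position-k bases of successive codons, in order.
Adjacency within subsequence k therefore means "same codon position,
consecutive codons". All three statistics are recomputed per subsequence,
yielding the 12-parameter set in the fixed reporting order
`CGC, D1, D2, CGC1, D11, D21, CGC2, D12, D22, CGC3, D13, D23`.
The minimum accepted length for the full parameter set is 6 bases so each
subsequence supports a dinucleotide estimate; shorter inputs are an
error, never a silent NaN.

## Group-wise association

Each parameter x is paired with y = ln(k_f) within a group and summarized
by the sample Pearson correlation r, the least-squares slope and
intercept, and a two-sided p-value from t = r·sqrt((n−2)/(1−r²)) on n−2
degrees of freedom (via `scipy.stats.linregress`; the exhaustive
permutation null in the tests checks the t approximation at small n).
Four tables are built: all proteins pooled, then one per structural class
(all-α, all-β, α-β), each with rows all / two-state / multistate.

- Stars: `*` p<0.05, `**` p<0.01, `***` p<0.001 — the conventional
  levels, configurable via `--star-thresholds`.
- Cells whose group has n < 3 or a constant parameter are reported as the
  token `NC`, never dropped, so table shape is invariant.
- No multiple-testing correction is applied across the 12-parameter grid
  by default; `benjamini_hochberg` is provided as a clearly separate
  optional adjustment for users who want it.
- Formatted tables print r to two decimals with stars; a long-format CSV
  carries full precision, p, n, slope and intercept.

## Synthetic studies

The generator exists so that every pipeline stage has a closed-form or
construction-based oracle:

- **Sequences** come from a first-order Markov chain (stationary start),
  the exact dependence structure D2 measures. Theoretical values:
  D1 = 2 + Σ π_i log2 π_i and D2 = −2 Σ π_i log2 π_i + Σ π_i T_ij
  log2(π_i T_ij), the latter equal to the mutual information of the
  stationary adjacent pair and hence ≥ 0. Empirical d1/d2 of generated
  sequences are required to match these within 0.02 bits at length 1e5.
- **Rates** are ln k_f = β0 + β1·x + ε, ε ~ N(0, σ), with x one chosen
  parameter computed on the generated sequence. Given the realized spread
  σx of x, the implied correlation ρ = β1 σx / sqrt(β1² σx² + σ²) is
  written to the truth file, so recovery tests have an exact target; at
  σ = 0 the downstream |r| must equal 1 to 1e−12.

Defaults (chosen once, not tuned): 100 proteins of 100 codons (300
bases — typical of the small single-domain proteins with measured folding
rates); kinetic split 56/44 and structural split 21/39/40, apportioned
exactly by largest remainder and shuffled; coupling target `D12` with
β0 = 5, β1 = 40, σ = 1.5, giving an implied ρ ≈ 0.45 (moderate, i.e. in
the regime where both detection and calibration are non-trivial);
transition matrix T = 0.8·uniform + 0.2·I (uniform stationary
composition, theoretical D2 ≈ 0.078 bits). A single integer seed drives
one `numpy` generator for every draw, so outputs are byte-identical on
replay.

**What the generator does not emulate:** real codon-usage tables, amino
acid composition constraints, organism-specific GC regimes, mRNA
secondary structure, or any nonlinear rate dependence. Passing tests
therefore demonstrate that the statistics and the regression machinery
are computed correctly and are statistically calibrated — not that the
biological correlations themselves generalize.

## Numerical and design notes

- Sequences are used exactly as supplied: no automatic stop-codon
  stripping (an explicit `--strip-stop` flag removes one trailing
  UAA/UAG/UGA) and no automatic frame truncation (`--truncate-frame`
  opts in to dropping 1–2 trailing bases).
- Amino-acid segment extraction uses 1-based inclusive residue
  coordinates, the citation convention for protein segments.
- Annotation tables are CSV/TSV with auto-detected delimiter; class
  labels match case-insensitively against fixed vocabularies
  (`all_alpha|all_beta|alpha_beta`, `two_state|multi_state`, plus common
  variants like "multistate").
- Stationary vectors for user-supplied transition matrices are obtained
  from the eigendecomposition and polished by power iteration; models are
  validated to row-sum 1 within 1e−12 and stationarity within 1e−10.
- CSV round-trips are exact: ln(k_f) is written at full double precision
  and read back with pandas' round-trip float parser.
- Problem sizes in the test suite (length-1e5 convergence checks, 200
  replicate studies of 100 proteins for calibration) keep the whole suite
  around half a minute while leaving Monte-Carlo error well inside the
  asserted tolerances.

## Known limitations

- D2's slight negative bias at short lengths (end effects) is inherent to
  the chosen estimator; compare values only between sequences of similar
  length.
- The type-I error check over 200 replicates has binomial noise (SE ≈
  0.015 at the nominal 0.05), so its [0.03, 0.07] band is a calibration
  smoke test, not a precise size estimate.
- The association module reports marginal correlations only; no
  multivariate model or folding-rate predictor is built.
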