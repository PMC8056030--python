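# mrnalang

Information statistics of mRNA coding sequences and their correlation with
protein folding rates.

## The problem

Protein folding rates span microseconds to hours, and most predictors of
ln(k_f) use protein structure or amino-acid sequence alone. Treating the
coding mRNA as a *genetic language*, its **vocabulary** (base composition)
and **phraseology** (adjacent-base dependence) carry information that is
invisible at the protein level — in particular anything driven by
synonymous codon usage. `mrnalang` computes, for each coding sequence, a
set of language statistics and asks whether they correlate with the
experimental folding rate across groups of proteins (two-state vs
multistate folders; all-α, all-β and α-β structural classes).

The audience is anyone doing sequence-feature analyses of folding
kinetics, codon-usage or composition-bias studies who wants these
statistics and the group-wise regression scaffolding as a tested library
and CLI.

## The statistics

For a sequence over {A, C, G, U} with base probabilities p_i and
overlapping dinucleotide probabilities p_ij:

- **Single-base information redundancy**
  `D1 = 2 + Σ_i p_i log2 p_i` — 2 bits minus the Shannon entropy of the
  composition; 0 for uniform composition, 2 for a single-base sequence.
- **Adjacent-base related information redundancy**
  `D2 = −2 Σ_i p_i log2 p_i + Σ_ij p_ij log2 p_ij` — approximately the
  mutual information between a base and its successor.
- **GC content** `C_GC = (N_G + N_C) / N`.

Each is also computed on the three codon-position subsequences (all
first-position bases of successive codons, etc.), giving 12 parameters in
total: `CGC, D1, D2, CGC1, D11, D21, CGC2, D12, D22, CGC3, D13, D23`.
Every parameter is regressed against ln(k_f); the reported cell is the
signed Pearson r with significance stars (two-sided t-test;
`*` p<0.05, `**` p<0.01, `***` p<0.001).

A synthetic-study generator draws sequences from a first-order Markov
chain — whose theoretical D1/D2 are known in closed form — and couples
ln(k_f) linearly to a chosen parameter, so the entire pipeline is testable
without any external data.

## Worked example

Per-sequence statistics from Python:

```python
>>> from mrnalang import parameter_set
>>> ps = parameter_set("AUGGCUGAAGCUGCUAAAGAAUUCGGUCUG")  # 10 codons
>>> for name, value in ps.to_dict().items():
...     print(f"{name:5s} {value: .4f}")
CGC    0.4667
D1     0.0311
D2     0.4162
CGC1   0.7000
D11    0.4290
D21    0.7225
CGC2   0.4000
D12    0.1045
D22    0.8432
CGC3   0.3000
D13    0.1536
D23    0.7452
```

The sequence has near-uniform overall composition (`D1` ≈ 0.03 bits) but
strong position-wise bias: 70% GC at codon position 1 versus 30% at
position 3, and `D11` ≈ 0.43 bits of compositional redundancy at the
first position.

Full pipeline on a synthetic study (100 proteins, 100 codons each, ln k_f
coupled to `D12` with Gaussian noise):

```
$ mrnalang run-all --outdir demo --seed 1 --n-proteins 100 --length 300
$ head -3 demo/correlations_all_proteins.csv
group,CGC,D1,D2,CGC1,D11,D21,CGC2,D12,D22,CGC3,D13,D23
all,0.03,0.20*,-0.11,0.03,-0.05,0.06,-0.02,0.47***,0.07,0.04,0.23*,0.07
two_state,-0.06,0.23,0.14,-0.05,0.09,-0.03,-0.04,0.41**,-0.09,-0.03,0.04,0.08
```

The coupled parameter `D12` is recovered at r = 0.47 (p ≈ 1e-6, hence
`***`), matching the generator's implied correlation ρ = 0.469 recorded
in `demo/truth.json`; all uncoupled parameters hover near zero. Four
formatted tables (pooled + one per structural class) and a full-precision
long-format file are written alongside.

The stages are also available separately (`mrnalang simulate`,
`mrnalang compute`, `mrnalang correlate`) and exchange plain FASTA/CSV
files, so real sequence data with an annotation table
(`id, structural_class, kinetic_class, ln_kf`) drops into the same flow.

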