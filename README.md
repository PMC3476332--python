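# duplexscan

Fast search for near-complementary RNA–RNA duplexes using a dinucleotide
approximation of the Turner nearest-neighbor energy model.

Regulatory non-coding RNAs — bacterial sRNAs, microRNAs, antisense
transcripts — often act by base-pairing with other RNAs. Screening for
putative duplexes genome-wide needs something much faster than full
thermodynamic folding, but more faithful than pure complementarity
matching. `duplexscan` sits in between: a Smith–Waterman–Gotoh-like local
alignment in which *match* means *canonical base pair* (Watson–Crick or
G·U wobble) and all scores come from a 36×36 dinucleotide matrix, so that
consecutive matched columns score the tabulated stacking energy
S(q₍ᵢ₋₁₎qᵢ, t₍ⱼ₊₁₎tⱼ) of the two adjacent pairs, while bulges and interior
loops are charged through affine (opening + per-nucleotide extension)
approximations of the nearest-neighbor loop tables. The recursion keeps
three states — M (paired/mismatched columns), Bq and Bt (bulged
nucleotides in query or target) — and the scan phase stores only two rows
per state, so memory is linear in the sequence lengths. Reported free
energies are assembled as −score/100 + duplex initiation (4.1 kcal/mol in
the Turner 2004 set) + terminal A·U/G·U penalties, in kcal/mol.

The package contains:

* `duplexscan.params` — embedded Turner 1999 and 2004 nearest-neighbor
  constants and the affine bulge/interior-loop fits (the bulge fit is
  exact for bulge sizes 2–6; the asymmetric interior extension is
  0.6 kcal/mol in the 2004 set and 0.48 in the 1999 set),
* `duplexscan.matrix` — construction of the 36×36 scoring matrix over
  {A,C,G,U,−,N}, including an optional per-nucleotide penalty,
* `duplexscan.engine` — the two-phase scanner (linear-space scan, then
  windowed re-computation with traceback), plus quadratic-memory and
  exhaustive-enumeration oracles used by the tests,
* `duplexscan.oracle` — a full nearest-neighbor intermolecular duplex-MFE
  reference (exact loop tables, 1×1/1×2/2×2 lookups, Ninio asymmetry,
  loop terminal mismatches; no intramolecular pairs, no multiloops),
* `duplexscan.simbench` — simulated benchmark: random sequences, perfect
  complements, stepwise mutation (substitution 75%, deletion 17%,
  insertion 8%), Levenshtein-distance stratification,
* `duplexscan.metrics` — SEN/PPV/F/MCC over base pairs, rank product,
  relative hit score, correlation and top-k% overlap statistics.

## Worked example

```sh
$ cat q.fa
>mir-ex
UGAGGUAGUAGGUUGUAUAGUU
$ cat t.fa
>utr-ex
GGCUGAGGCAACCUACUACCUCAGGAGCC
$ duplexscan search -q q.fa -t t.fa -e -8 --merge
# duplexscan vintage=t04 threshold=-8.0 per_nt_penalty=0.0 window=40 n_subopt=1 merge=True seed=0
# query_id	q_start	q_end	target_id	t_start	t_end	energy_kcal	structure
mir-ex	1	22	utr-ex	1	23	-30.78	||||||||||||||||xq|||||
```

The query binds target positions 1–23 (both coordinates 1-based, 5'→3';
the strands run antiparallel, so query position 1 pairs target position
23). The structure string annotates alignment columns: `|` base pair,
`x` mismatch (interior loop), `q`/`t` gap in query/target (a bulged
nucleotide on the other strand). The free energy of −30.78 kcal/mol
includes the 4.1 kcal/mol duplex initiation. The full-model reference for
the same pair:

```sh
$ duplexscan oracle -q q.fa -t t.fa | tail -1
mir-ex	1	22	utr-ex	1	23	-30.50	||||||||||||||||xq|||||
```

Other subcommands: `simulate` (benchmark generation), `evaluate`
(correlation/top-k statistics from an energy table), `dump-matrix`
(the 36×36 matrix as TSV).

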