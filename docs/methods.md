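# Methods

## Model

`duplexscan` predicts intermolecular RNA–RNA duplexes only: stacked base
pairs, bulges and interior loops. Intramolecular structure, multiloops,
dangling ends and terminal mismatches at duplex ends are outside the
model. Two RNA strands pair antiparallel, so when the query index
advances 5'→3' the target index decreases; all coordinates are reported
1-based, 5'→3' on both strands, with `q_start` pairing `t_end`.

All energies are handled as integers in centi-kcal/mol (0.01 kcal/mol),
which makes the dynamic programming exact and reproducible bit-for-bit;
interfaces report kcal/mol rounded to two decimals.

### Scoring matrix

The elementary scoring unit is the dinucleotide: the score of an
alignment column depends on the previous column, giving a 36×36 integer
matrix over the ordered alphabet `A C G U - N`. Two adjacent pair columns
score the negated stacking energy of the quartet, indexed in the usual
nearest-neighbor convention (the second pair read from the opposite
strand); the stack table is symmetric under strand flip. Loop-related
entries are composed from two affine models fitted to the embedded loop
tables:

* **Bulges.** The tabulated bulge initiation is exactly affine over sizes
  2–6 (extension 0.4 kcal/mol in both parameter vintages); the fit
  reports `open = init(2) − 2·ext`. A run of k gap columns is charged
  `open + k·ext` — the opening matrix entry carries `open + ext`, each
  further gap column `ext` — so the model reproduces the table exactly
  for sizes 2–6, over-penalizes larger bulges, and charges a
  single-nucleotide bulge the affine opening (2.4 kcal/mol in T04)
  instead of the tabulated 3.8 with stack-through.
* **Interior loops.** `open` and the symmetric extension `ext_sym` are a
  least-squares fit of `open + (s/2)·ext_sym` to the tabulated symmetric
  interior-loop initiations over total sizes s = 4…14 (the region the
  affine model approximates well); loops above 14 nt are deliberately
  over-penalized. The asymmetric extension `ext_asym` is pinned to the
  parameter set's Ninio slope: 0.6 kcal/mol (T04), 0.48 (T99). The loop
  opening is split half at the transition entering the loop and half at
  the transition closing it, so a complete mismatch-bounded loop accrues
  exactly one opening regardless of length.

A gap column cannot tell a bulge from the asymmetric part of an interior
loop. Gap-after-gap entries take the (cheaper) bulge extension — the
genuinely ambiguous case — while gap-after-mismatch is necessarily inside
an interior loop and takes `ext_asym`. Terminal A·U/G·U penalties
(0.5 kcal/mol) are charged wherever a loop or bulge interrupts a helix,
and again at the two duplex termini during final energy assembly together
with the duplex initiation (4.1 kcal/mol in both embedded vintages; the
1999 exchange tables carry the same initiation constant as 2004).

The sixth symbol `N` is an unknown base: it never pairs, scores as a
mismatch, and no entry containing it is positive, so genomic FASTA with
Ns remains scannable. A user-chosen per-nucleotide penalty ≥ 0 is
subtracted once from every matrix entry and from the start entries
(every alignment column is charged exactly once); alignments start only
at canonical-pair columns.

### Scanner

Three states: `M` (both strands consumed: pair or mismatch), `Bq`
(bulged query nucleotide), `Bt` (bulged target nucleotide); `Bq`/`Bt`
open from `M` and extend themselves, never each other. Phase 1 sweeps
query × target keeping two rows per state (the `Bq` in-row affine
recursion is evaluated as a running maximum), recording per target
position the best interaction score ending there, its query end, and
optionally the 2nd/3rd best at distinct query ends — auxiliary memory is
linear in the query length. Because each target position keeps one query
end per layer, a weaker site overlapping a stronger one in the same rows
can be masked; this is the method's accepted ambiguity.

Phase 2 re-runs the DP with full matrices on a window of `window`
(default 40) target positions whose 5' edge is the candidate row, capped
to `window` query nucleotides ending at the candidate's query end, and
traces back from the best cell *in the candidate's row* (falling back to
the window optimum only if that row scores ≤ 0 after windowing — e.g.
when the true duplex exceeds the window, in which case the best duplex
fitting the window is returned, by design). Traceback prefers the start
over any predecessor at equal score (shorter duplex), then M over Bq
over Bt. Two slower oracles validate the scan: a quadratic-memory full
DP and an exhaustive enumeration of all co-linear alignments with
canonical first/last columns.

Swap symmetry (`search(q,t)` vs `search(t,q)`) deserves a caveat: it is
exact for helices, pure bulges and pure-mismatch interior loops, but
loops mixing gap and mismatch columns have order-dependent entry/exit
charges, so swapped optima can differ by up to about one bulge opening
per mixed loop (observed ≤ 1.6 kcal/mol on random pairs). An
order-independent entry composition would force bulges and interior
loops to share one opening constant, which the model intentionally does
not do.

## Parameter tables

The Turner 1999 and 2004 nearest-neighbor constants are embedded in the
package (`_nndb_t99.py`, `_nndb_t04.py`), transcribed from the standard
parameter-exchange files: stacks, bulge and interior-loop initiations
(sizes ≤ 30, Jacobson–Stockmayer logarithmic extrapolation beyond),
1×1/1×2/2×2 interior-loop lookups, interior terminal-mismatch tables,
Ninio asymmetry slope and cap, terminal A·U/G·U penalty, duplex
initiation. One deliberate correction: the 1999 asymmetry slope is
embedded as 0.48 kcal/mol (the value of the original 1999 rule set)
rather than the 0.50 the exchange file rounds it to. The scanner uses
only the stacks, the two 1-D loop tables and the scalar penalties; the
small-loop and mismatch lookups exist for the full-model oracle, since
per-loop lookups cannot be expressed in a dinucleotide matrix.

## Full-model oracle

`duplexscan.oracle.duplex_mfe` is a DuplexFold-style pair-based DP
(numba-compiled): transitions between consecutive pairs bounded by
`max_loop` = 30 unpaired nucleotides, exact loop energies (stacking
through 1-nt bulges, terminal penalties at multi-nucleotide bulges,
small-loop lookups, Ninio asymmetry capped at 3.0 kcal/mol, interior
terminal mismatches, log extrapolation), plus duplex initiation and
terminal penalties at both ends. It agrees exactly with RNAduplex
(Turner 2004) on duplexes whose MFE structure spans both sequences —
RNAduplex always adds exterior dangling ends, so flankless duplexes are
the clean comparison — and with an exhaustive structure enumeration on
short sequences. On ungapped helices the oracle and the scanner coincide
by construction.

## Simulated benchmark

The generator emulates degraded binding sites: random sequences (default
lengths 20–50 nt in steps of 5, GC 10–90%), each paired with its perfect
reverse complement, which is then mutated stepwise — substitution 0.75,
deletion 0.17, insertion 0.08 per round — keeping the mutant after every
cumulative round up to `floor(length/3)` rounds, so Levenshtein
distances from the optimal partner span 0 to about a third of the
length. All randomness flows through one seeded generator;
output is byte-reproducible.

The benchmark used by the tests and the acceptance script is the
50 nt / 50% GC class with 12 base sequences (204 duplexes), a size that
keeps the full run in seconds while the statistics are stable across
seeds. On it the scanner's energies track the full model closely
(Pearson r ≈ 0.994, Spearman ρ ≈ 0.993, top-5% overlap ≈ 94% averaged
over seeds; scanner energies are systematically slightly higher, median
relative deviation ≈ 3%). The comparison widens the traceback window to
the whole duplex so that it measures the energy model rather than the
windowing heuristic. What this does *not* show: behavior on real,
structured, accessibility-limited binding sites — the generator produces
isolated near-complementary duplexes with i.i.d. backgrounds, no
intramolecular structure and no conservation signal.

## Evaluation statistics

Base-pair-level sensitivity, PPV, F-measure, and the Matthews
coefficient in its geometric-mean form √(SEN·PPV), valid when true
negatives dominate; degenerate denominators report 0 with a flag. Method
comparison uses the rank product over fractional ranks (lowest hit count
ranks first) and a relative hit score: per interaction with maximum
count N, a method with count c scores (N−c)/N, averaged over
interactions with N > 0 — 0 for the worst method, scale-free by
construction (the defining property set; the exact averaging is this
package's choice). Energy agreement: Pearson and Spearman correlation
plus the overlap of the two methods' top-⌈k%⌉ most stable duplex sets
(ties broken by stable sort order).

## Numerical and interface choices

* Matrix entries are rounded to integer centi-kcal once, at composition;
  rebuilding from (vintage, penalty) is bit-exact.
* Candidate rows qualify at score ≥ −100·threshold (threshold in
  kcal/mol ≤ 0); the threshold applies to the raw score, i.e. before the
  initiation/terminal constants of the final energy assembly.
* Hit lists sort by energy, then target start, then query start;
  `--merge` collapses hits whose target intervals overlap ≥ 50% of the
  shorter interval, keeping the best energy.
* `n_subopt` ∈ {1,2,3} extends the per-row record to the 2nd/3rd best
  query ends.
* Degenerate inputs: empty sequences and non-`ACGUN` symbols are
  rejected at parse time with position-specific messages; sequences that
  cannot pair at all yield an empty hit list (CLI exit code 1).

## Known limitations

No accessibility or intramolecular structure; no P-value framework
(energies are not calibrated against a background model); per-row query
ambiguity as described above; mixed-loop swap asymmetry bounded as
described above; single-nucleotide bulges and long loops are
systematically over-penalized relative to the full model.
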