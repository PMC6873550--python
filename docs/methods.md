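# Methods

## Problem setting

A SMILES language model is trained on strings of molecules drawn from a
finite target chemical space and then sampled with replacement; the question
is how completely, uniformly and cleanly the sampled distribution covers the
target space, and how much the answer depends on the string representation
used for training (canonical, randomized, DeepSMILES).  Full-scale studies
of this question run on combinatorial databases of ~10^9 molecules; this
package reproduces the entire protocol at desk scale on a synthetic,
fully enumerable space, where every quantity of interest is exactly
computable.

## The toy chemical space

`enumerate_toy_space(max_heavy_atoms, elements, filters)` enumerates every
neutral, connected molecule over {C, N, O} up to a heavy-atom limit by
breadth-first molecular-graph growth (add one atom per level, then add
ring-closing bonds to a fixpoint within the level) with canonical-SMILES
deduplication; validity is delegated to RDKit sanitization.  Exclusion
filters then carve out the target space.  The defaults — no triple bonds, no
rings smaller than five atoms — are cheap, decidable analogs of the
strained-ring / unstable-group exclusions used by real fragment databases;
they make membership a canonical-string lookup and guarantee that valid
out-of-space molecules exist (anything with a triple bond or a small ring),
which the closedness metric needs.  Both filters are monotone (adding atoms
or bonds never removes the violating feature), so filter-violating
intermediates can be pruned during growth without changing the result; a
test verifies the enumeration against an independent exhaustive
bond-matrix search.  No claim is made that these filters mirror any real
database's rules, and the space's property distributions are not matched to
anything; what carries over to real data is the protocol, not the numbers.

Reference sizes: max 5 atoms gives 1,495 molecules, max 6 gives 9,877.

## SMILES variants

`canonicalize` is RDKit's canonical writer; canonical strings are used only
as internal keys and never compared across toolkits.

Both randomized variants are produced by a bespoke depth-first writer that
is a deterministic function of an explicit atom permutation: the traversal
starts at the rank-0 atom and picks neighbors in rank order.

* *Restricted* applies the traversal fix customary in canonical writers —
  sidechain (non-ring) bonds are visited before ring bonds — so a ring is
  always continued rather than entered through a parenthesized branch, and
  branches carry parentheses only when needed.
* *Unrestricted* follows the permutation literally and wraps the final
  branch of an atom in (redundant) parentheses whenever the child's rank is
  below its parent's.  This reproduces the convoluted ring entries
  (`c1cc(c(cc1))`-type strings on benzene) that restricted writing forbids.

Writing from the preorder ranking of any restricted traversal makes the
unrestricted writer reproduce that traversal with no redundant wrapping, so
restricted string sets are subsets of unrestricted ones by construction;
the suite verifies this exhaustively (all n! orderings) for every molecule
of the toy space.  Randomization is uniform over atom *permutations*, not
over distinct strings — several permutations can collapse onto one string —
which matters when counting distinct writings per molecule.  Ring-closure
digits are assigned in string order with reuse after closure; stereochemistry
is not written (the toy spaces are stereo-free).

DeepSMILES conversion (rings, branches, or both) is implemented from the
published grammar on an atom-stack simulation; decoding rebuilds the
molecular graph directly and returns an RDKit-written SMILES, so round trips
preserve the molecule, not the string.  Rings whose opening atom has left
the atom stack at closing time are not representable and raise a typed
conversion failure, counted as invalid downstream.

## Tokenization

Character-based with three multi-character exceptions: `Cl`/`Br`, bracket
atoms (`[nH]`, `[O-]`, ...), and `%NN` two-digit ring closures.  `^` begins
and `$` ends every sequence; `$` doubles as the padding symbol.  The
vocabulary is the lexicographically sorted distinct token set of the
corpus, so index assignments are reproducible regardless of corpus order.
Out-of-vocabulary tokens at encode time are hard errors: silently skipping
them would corrupt every NLL comparison.

## Model

Embedding (m dimensions, m <= w, default m = w since only the constraint is
prescribed) -> l stacked LSTM/GRU layers of width w with inter-layer
dropout only (none after the last layer, none between embedding and the
first layer) -> linear projection to the vocabulary -> softmax.  All weight
matrices are initialized i.i.d. uniform on (-sqrt(1/w), +sqrt(1/w));
biases start at zero.  The implementation is pure NumPy with hand-derived
backpropagation through time, validated against finite differences to
~1e-7 relative error; sampling is batched multinomial at temperature 1
(no temperature/top-k variants).

Two NLL conventions coexist deliberately:

* the *training loss* is the batch-mean NLL over every matrix position,
  unmasked past the first end token (padding is the end token, so the extra
  positions only reinforce end-predicts-end);
* *reporting NLLs* — everything fed to UC-JSD and the coverage metrics —
  truncate at the first end token, because they are whole-molecule
  log-probabilities.

Sampled sequences that hit `max_len` (default 128; 32–40 suffices for the
toy spaces) without emitting the end token are flagged non-terminated and
counted invalid downstream.

A molecule's NLL under a randomized-variant model is
`-ln sum_s exp(-NLL(s))` over its distinct strings: exact mode enumerates
all of them (guarded to <= 8 heavy atoms, n! writes), estimate mode sums
over the distinct strings seen in a fixed budget of randomized draws, which
lower-bounds the probability and so upper-bounds the molecule NLL.

## Training protocol

Per epoch: regenerate the epoch's strings (randomized variants rewrite
every molecule with a per-epoch child seed; the validation set is
regenerated the same way, since both sets receive fresh samples), shuffle,
batch with end-token padding, teacher-forced Adam steps with the global
gradient norm clipped to 1.0 (instrumented: the post-clip norm is asserted
at every step).  Epoch-file mode (pre-generated `.smi` files, one per
epoch) and on-the-fly regeneration produce identical statistics; on-the-fly
is the default to avoid the disk footprint.

After each epoch the UC-JSD is computed from equal-length NLL vectors of
the training, validation and freshly sampled sets (subsampled with a seeded
stream to `ucjsd_sample_size`, default 2048, reduced to 128–512 in the
desk-scale benchmarks).  The UC-JSD sum-normalizes each NLL vector
(element order preserved — the statistic is therefore invariant to scaling
any single vector, but it is not sorted; a sorted mode exists behind a flag
for sensitivity analysis) and takes the Jensen-Shannon divergence with
weights 1/3, so it lies in [0, ln 3].

The learning rate decays by `lr_decay_factor` (default 0.7) once per
`lr_patience` (default 5) consecutive epochs without improvement (tolerance
1e-4) of the trailing window-4 moving average of UC-JSD, and never
increases.  The exact published schedule for this family of experiments is
not public; these defaults are this package's own choice and are fully
configurable.  The optimizer is Adam with default moments for the same
reason.  The best epoch of a run is the argmin of the same smoothed UC-JSD
series, ties broken toward the earlier epoch.

## Coverage metrics

phi(k, N) = 1 - (1 - 1/N)^k is used exactly (log-space evaluation), not the
exp(-k/N) approximation, since exactness is free.  `evaluate_sample` counts
valid / in-space (with repeats) / unique in-space strings and reports
ratio_valid, closedness = ratio_in, ratio_unique = unique/N,
completeness = ratio_unique / phi(k, N), uniformity = ratio_unique /
phi(n_in, N) and UCC = completeness x uniformity x closedness.
Completeness and uniformity are not clamped at 1 — finite-sample
fluctuation above 1 is possible for a near-ideal generator and reports
flag it rather than hide it.  Invalid, non-terminated and
conversion-failed strings count against validity; duplicates count toward
every with-repeats quantity.

## Desk-scale benchmark conditions

The packaged benchmark (also exercised by the acceptance tests) uses the
max-6 C/N/O space (N = 9,877), a 500/250 train/validation split (a ~5%
training fraction, the regime where representation choice matters most),
an LSTM with l = 2, w = 96, batch 32, initial rate 3e-3, 80 epochs, and a
3N-draw sample of the best epoch, five seeded replicates per variant.
These sizes were chosen once as the smallest configuration that trains both
variants to >0.9 validity; with them the restricted-randomized arm beats
the canonical arm on UCC (~0.81 vs ~0.60) and on unique recovery (~0.89 vs
~0.77 of the space) in every replicate observed.  The UC-JSD/UCC
correlation check spans six hyperparameter configurations from clearly
undertrained to converged on the max-5 space and asserts only the sign of
the Spearman correlation.

## Known limitations

* The toy space has no charges, no stereochemistry, no elements beyond
  C/N/O and tops out near 10^4 molecules; absolute metric values do not
  transfer to 10^9-molecule spaces, only the orderings and the protocol.
* The bespoke writers do not reproduce any particular toolkit's randomized
  string distribution byte for byte; their contracts are the roundtrip and
  superset properties.
* The adaptive learning-rate recipe is a configurable stand-in, not a
  reproduction of any published schedule.
* NumPy training is single-threaded BLAS-bound; it is sized for ~10^3
  training molecules, not for million-molecule corpora.
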