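"""Coverage and divergence metrics for generative models of a finite space.

Everything is in natural-log units (nats).

Given a sample of size ``k`` drawn with replacement from a model targeting a
finite space of ``N`` molecules, the counted subsets are

* ``valid`` — strings that parse (with repeats),
* ``in``    — valid strings whose canonical form is in the space (with repeats),
* ``unique`` — distinct in-space canonical forms,

and the derived quantities

* ``ratio_valid = |valid|/k``, ``ratio_in = |in|/k``,
  ``ratio_unique = |unique|/N``,
* ``phi(k) = 1 - (1 - 1/N)^k`` — the expected unique fraction an *ideal*
  model (uniform over exactly the space) would recover in ``k`` draws,
* ``completeness = ratio_unique / phi(k)``,
* ``uniformity  = ratio_unique / phi(|in|)``,
* ``closedness  = ratio_in``,
* ``UCC = completeness * uniformity * closedness`` — a single score that
  heavily penalizes any weak component.

The UC-JSD is the Jensen-Shannon divergence (equal weights 1/3) of the
sum-normalized NLL vectors of the training, validation and sampled sets.
It approaches zero when the three NLL profiles are equal, which for a
randomly drawn sample indicates a near-uniform, complete generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chemspace import ChemicalSpace
from .variants import canonicalize


def shannon_entropy(p: Sequence[float]) -> float:
    """Shannon entropy of a probability vector, in nats (0·ln 0 = 0)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative probability entry")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def jsd(distributions: Sequence[Sequence[float]], weights: Sequence[float] | None = None) -> float:
    """Jensen-Shannon divergence of several distributions on a common support.

    ``H(sum_i a_i d_i) - sum_i a_i H(d_i)``; zero iff all distributions are
    identical, bounded above by the entropy of the weight vector.
    """
    ds = [np.asarray(d, dtype=float) for d in distributions]
    if len(ds) < 2:
        raise ValueError("need at least two distributions")
    dim = ds[0].shape[0]
    if any(d.shape != (dim,) for d in ds):
        raise ValueError("distribution dimension mismatch")
    if weights is None:
        weights = np.full(len(ds), 1.0 / len(ds))
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(ds),) or np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be positive and sum to 1")
    mixture = sum(wi * di for wi, di in zip(w, ds))
    value = shannon_entropy(mixture) - sum(
        wi * shannon_entropy(di) for wi, di in zip(w, ds)
    )
    return max(0.0, float(value))  # clip float negative-zero noise


@dataclass(frozen=True)
class NLLTriplet:
    """Equal-length NLL vectors of the training, validation and sampled sets."""

    training: np.ndarray
    validation: np.ndarray
    sampled: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.training, dtype=float)
        v = np.asarray(self.validation, dtype=float)
        s = np.asarray(self.sampled, dtype=float)
        if not (t.shape == v.shape == s.shape) or t.ndim != 1 or t.size == 0:
            raise ValueError("the three NLL vectors must be equal-length 1-D")
        object.__setattr__(self, "training", t)
        object.__setattr__(self, "validation", v)
        object.__setattr__(self, "sampled", s)


def uc_jsd(triplet: NLLTriplet, sort_vectors: bool = False) -> float:
    """Uniformity-completeness JSD of an NLL triplet, in [0, ln 3].

    Each NLL vector is divided by its sum (element order preserved; pass
    ``sort_vectors=True`` for the order-free sensitivity variant) and the
    three resulting distributions are compared with equal weights 1/3.
    """
    dists = []
    for vec in (triplet.training, triplet.validation, triplet.sampled):
        total = vec.sum()
        if total <= 0:
            raise ValueError("NLL vector with non-positive sum")
        d = vec / total
        if sort_vectors:
            d = np.sort(d)
        dists.append(d)
    return jsd(dists, [1 / 3, 1 / 3, 1 / 3])


def phi(k: int | float, N: int) -> float:
    """Expected unique fraction from ``k`` uniform draws with replacement on ``N``.

    Exact expectation ``1 - (1 - 1/N)^k``, evaluated in log space.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return 0.0
    if N == 1:
        return 1.0
    return float(-np.expm1(k * np.log1p(-1.0 / N)))


@dataclass(frozen=True)
class SampleEvaluation:
    """Counts and coverage ratios of a k-sample against a chemical space."""

    k: int
    space_size: int
    n_valid: int
    n_in: int
    n_unique: int
    ratio_valid: float
    ratio_in: float
    ratio_unique: float
    phi_k: float
    phi_in: float
    completeness: float
    uniformity: float
    closedness: float
    ucc: float

    def to_dict(self) -> dict:
        out = {}
        for key in (
            "k", "n_valid", "n_in", "n_unique", "ratio_valid", "ratio_in",
            "ratio_unique", "completeness", "uniformity", "closedness",
            "ucc", "space_size", "phi_k", "phi_in",
        ):
            val = getattr(self, key)
            out[key] = round(val, 6) if isinstance(val, float) else val
        return out


def evaluate_sample(
    sampled: Sequence[str],
    space: ChemicalSpace,
    precanonicalized: bool = False,
) -> SampleEvaluation:
    """Coverage evaluation of a with-replacement sample against a space.

    ``sampled`` may contain repeats and invalid strings; both are counted as
    the ratios require.  ``precanonicalized=True`` skips re-canonicalization
    when the caller guarantees every string is already a canonical form
    (e.g. the ideal sampler).
    """
    if len(sampled) == 0:
        raise ValueError("empty sample")
    if space.size == 0:
        raise ValueError("empty space")
    k = len(sampled)
    n_valid = 0
    n_in = 0
    uniques: set[str] = set()
    cache: dict[str, str | None] = {}
    for smi in sampled:
        if precanonicalized:
            can = smi
        else:
            if smi in cache:
                can = cache[smi]
            else:
                can = canonicalize(smi)
                cache[smi] = can
        if can is None:
            continue
        n_valid += 1
        if can in space.members:
            n_in += 1
            uniques.add(can)
    n_unique = len(uniques)
    N = space.size
    phi_k = phi(k, N)
    phi_in = phi(n_in, N)
    ratio_unique = n_unique / N
    completeness = ratio_unique / phi_k if phi_k > 0 else 0.0
    uniformity = ratio_unique / phi_in if phi_in > 0 else 0.0
    closedness = n_in / k
    return SampleEvaluation(
        k=k,
        space_size=N,
        n_valid=n_valid,
        n_in=n_in,
        n_unique=n_unique,
        ratio_valid=n_valid / k,
        ratio_in=n_in / k,
        ratio_unique=ratio_unique,
        phi_k=phi_k,
        phi_in=phi_in,
        completeness=completeness,
        uniformity=uniformity,
        closedness=closedness,
        ucc=completeness * uniformity * closedness,
    )


def ucc(completeness: float, uniformity: float, closedness: float) -> float:
    """The three-way product score."""
    return completeness * uniformity * closedness


def molecule_nll(
    model,
    canonical_smiles: str,
    variant: str,
    mode: str = "exact",
    budget: int = 1000,
    seed: int = 0,
    max_heavy_atoms: int = 8,
) -> float:
    """NLL of a *molecule* (not of one string) under a sequence model.

    For randomized variants a molecule's probability is the sum of the
    probabilities of all its strings; ``exact`` mode enumerates them
    (small molecules only), ``estimate`` mode sums over the distinct strings
    found in ``budget`` randomized draws — a lower bound on the probability,
    hence an upper bound on the molecule NLL.  For the canonical variant the
    molecule NLL is the single-string NLL.
    """
    from . import variants as V

    if variant == V.CANONICAL:
        return float(model.sequence_nlls([canonical_smiles])[0])
    V.check_variant(variant, V.RANDOMIZED_KINDS)
    if mode == "exact":
        strings = sorted(
            V.enumerate_random_smiles(canonical_smiles, variant, max_heavy_atoms)
        )
    elif mode == "estimate":
        if budget < 1:
            raise ValueError("budget must be >= 1")
        from .rngutil import child_seed

        strings = sorted(
            {
                V.randomize(canonical_smiles, variant, child_seed(seed, "mnll", i))
                for i in range(budget)
            }
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    nlls = np.asarray(model.sequence_nlls(strings), dtype=float)
    # -ln sum_i exp(-nll_i), computed stably
    m = nlls.min()
    return float(m - np.log(np.exp(m - nlls).sum()))
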