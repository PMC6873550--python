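import itertools

import numpy as np
import pytest

from smilesrnn.metrics import molecule_nll
from smilesrnn.model import GRU, LSTM, ModelHyperparams, SmilesRNN
from smilesrnn.tokenizer import build_vocabulary, encode_sequence, pad_batch
from smilesrnn.variants import RANDOMIZED_RESTRICTED, enumerate_random_smiles


@pytest.fixture(scope="module")
def vocab():
    return build_vocabulary(["C", "CC", "CCO", "OCO"])


def make_model(vocab, cell=LSTM, width=8, layers=2, seed=1, dropout=0.0):
    hp = ModelHyperparams(
        layers=layers, width=width, dropout=dropout, cell=cell, vocab_size=vocab.size
    )
    return SmilesRNN(hp, vocab, seed=seed, dtype=np.float64)


def zeroed(model):
    for k in model.params:
        model.params[k][:] = 0
    return model


def test_hyperparameter_validation():
    with pytest.raises(ValueError):
        ModelHyperparams(layers=2, width=8, embedding=16, vocab_size=5)
    with pytest.raises(ValueError):
        ModelHyperparams(layers=0, width=8, vocab_size=5)
    with pytest.raises(ValueError):
        ModelHyperparams(cell="rnn", vocab_size=5)
    assert ModelHyperparams(width=8, vocab_size=5).embedding_dim == 8  # m defaults to w


@pytest.mark.parametrize("cell", [LSTM, GRU])
def test_initialization_uniform_bounds_and_determinism(vocab, cell):
    """Weights are U(-sqrt(1/w), sqrt(1/w)); same seed gives identical params."""
    w = 4
    hp = ModelHyperparams(layers=2, width=w, cell=cell, vocab_size=vocab.size)
    m1 = SmilesRNN(hp, vocab, seed=9)
    bound = np.sqrt(1 / w)
    entries = []
    for name, p in m1.params.items():
        if name.startswith("b"):
            assert (p == 0).all()
        else:
            assert (np.abs(p) < bound).all()
            entries.append(p.ravel())
    m2 = SmilesRNN(hp, vocab, seed=9)
    for name in m1.params:
        assert (m1.params[name] == m2.params[name]).all()


def test_initialization_mean_near_zero(vocab):
    """Empirical mean of >=1e5 initial weights is 0 within 3 standard errors."""
    hp = ModelHyperparams(layers=2, width=128, cell=LSTM, vocab_size=vocab.size)
    m = SmilesRNN(hp, vocab, seed=5)
    entries = np.concatenate(
        [p.ravel() for k, p in m.params.items() if not k.startswith("b")]
    )
    assert len(entries) >= 1e5
    bound = np.sqrt(1 / 128)
    se = (2 * bound / np.sqrt(12)) / np.sqrt(len(entries))
    assert abs(entries.mean()) < 3 * se


@pytest.mark.parametrize("cell", [LSTM, GRU])
def test_forward_step_distribution(vocab, cell):
    m = make_model(vocab, cell)
    probs, state = m.forward_step([vocab.begin_index] * 3)
    assert probs.shape == (3, vocab.size)
    assert np.all(probs >= 0)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    # zero weights -> exactly uniform
    probs0, _ = zeroed(make_model(vocab, cell)).forward_step([0])
    assert np.allclose(probs0, 1 / vocab.size, atol=1e-12)
    # deterministic in evaluation mode
    p1, s1 = m.forward_step([1, 2], state=None)
    p2, s2 = m.forward_step([1, 2], state=None)
    assert (p1 == p2).all()
    with pytest.raises(ValueError):
        m.forward_step([vocab.size])
    with pytest.raises(ValueError):
        m.forward_step([0, 1], state=m.zero_state(3))


@pytest.mark.parametrize("cell", [LSTM, GRU])
def test_uniform_model_nll_closed_form(vocab, cell):
    """Zero-weight model: NLL = (L+1) ln v for payload length L, any L <= 20."""
    m = zeroed(make_model(vocab, cell))
    v = vocab.size
    for L in range(0, 21):
        s = "C" * L
        assert m.sequence_nll(s) == pytest.approx((L + 1) * np.log(v), rel=1e-12)


def test_sequence_nll_matches_stepwise_oracle(vocab):
    """Batch NLL equals -ln of the product of stepwise forward probabilities."""
    for cell in (LSTM, GRU):
        m = make_model(vocab, cell, seed=3)
        rng = np.random.default_rng(0)
        for _ in range(50):
            L = int(rng.integers(1, 8))
            s = "".join(rng.choice(["C", "O"], size=L))
            seq = encode_sequence(s, vocab)
            state, total = None, 0.0
            for t in range(len(seq) - 1):
                probs, state = m.forward_step([seq[t]], state)
                total -= np.log(probs[0, seq[t + 1]])
            assert m.sequence_nll(s) == pytest.approx(total, rel=1e-9)
            assert m.sequence_nll(s) >= 0


def test_nll_truncates_at_first_end_token(vocab):
    """Reporting NLL ignores padding; rows padded differently agree."""
    m = make_model(vocab, seed=4)
    alone = m.sequence_nlls(["C"])[0]
    padded = m.encoded_nlls(
        [encode_sequence("C", vocab), encode_sequence("CCO", vocab)]
    )[0]
    assert alone == pytest.approx(padded, rel=1e-12)


def test_batch_loss_unmasked_semantics(vocab):
    m = make_model(vocab, seed=5)
    row = encode_sequence("CC", vocab)
    X = pad_batch([row, row, row], vocab)
    # identical rows: batch loss equals one row's unmasked NLL
    single = m.batch_loss(row[None, :])
    assert m.batch_loss(X) == pytest.approx(single, rel=1e-12)
    # permutation invariance
    X2 = pad_batch([encode_sequence(s, vocab) for s in ["C", "CCO", "CC"]], vocab)
    X3 = X2[[2, 0, 1]]
    assert m.batch_loss(X2) == pytest.approx(m.batch_loss(X3), rel=1e-12)
    # no padding needed -> coincides with the truncated sequence NLL
    assert single == pytest.approx(m.sequence_nll("CC"), rel=1e-12)
    # with padding, the unmasked loss includes the end->end positions
    assert m.batch_loss(pad_batch([row, encode_sequence("CCO", vocab)], vocab)) != (
        pytest.approx((m.sequence_nll("CC") + m.sequence_nll("CCO")) / 2, rel=1e-9)
    )


@pytest.mark.parametrize("cell", [LSTM, GRU])
def test_gradients_match_finite_differences(vocab, cell):
    """Directional finite differences agree with backprop for every block."""
    m = make_model(vocab, cell, seed=2, dropout=0.0)
    X = pad_batch([encode_sequence(s, vocab) for s in ["CCO", "C", "OCO"]], vocab)
    _, grads = m.loss_and_grads(X)
    rng = np.random.default_rng(1)
    for name, P in m.params.items():
        d = rng.standard_normal(P.shape)
        eps = 1e-6
        P += eps * d
        lp = m.batch_loss(X)
        P -= 2 * eps * d
        lm = m.batch_loss(X)
        P += eps * d
        numeric = (lp - lm) / (2 * eps)
        analytic = float((grads[name] * d).sum())
        assert numeric == pytest.approx(analytic, rel=1e-5, abs=1e-10), name


def test_total_probability_sums_to_one(vocab):
    """Exhaustive enumeration of every token sequence a tiny model can emit:
    the autoregressive factorization is a proper distribution."""
    m = make_model(vocab, width=6, layers=1, seed=7)
    nonterm = [i for i in range(vocab.size) if i != vocab.end_index]
    max_len = 4

    def seq_prob(tokens):
        seq = [vocab.begin_index] + list(tokens)
        state, lp = None, 0.0
        for t in range(len(seq) - 1):
            probs, state = m.forward_step([seq[t]], state)
            lp += np.log(probs[0, seq[t + 1]])
        return np.exp(lp)

    total = 0.0
    for L in range(max_len):
        for combo in itertools.product(nonterm, repeat=L):
            total += seq_prob(list(combo) + [vocab.end_index])
    for combo in itertools.product(nonterm, repeat=max_len):
        total += seq_prob(combo)  # non-terminated mass
    assert total == pytest.approx(1.0, abs=1e-5)


def test_sampler_uniform_model_first_token(vocab3=None):
    """Zero-weight model emits the end token first with probability 1/v."""
    vocab3 = build_vocabulary(["C"])  # tokens {$, C, ^}, v=3
    m = zeroed(make_model(vocab3, width=4, layers=1))
    res = m.sample(10000, max_len=30, seed=11)
    frac_empty = np.mean([1.0 if (term and s == "") else 0.0 for s, _, term in res])
    p = 1 / 3
    se = np.sqrt(p * (1 - p) / 10000)
    assert abs(frac_empty - p) < 3 * se


def test_sampler_nll_self_consistency_and_determinism(vocab):
    m = make_model(vocab, seed=6)
    r1 = m.sample(200, max_len=15, seed=3)
    r2 = m.sample(200, max_len=15, seed=3)
    assert r1 == r2
    checked = 0
    for s, nll, term in r1:
        if term and "^" not in s and "$" not in s:
            assert m.sequence_nll(s) == pytest.approx(nll, rel=1e-9)
            checked += 1
    assert checked > 50
    assert any(not term for _, _, term in m.sample(200, max_len=2, seed=1))


def test_checkpoint_roundtrip(tmp_path, vocab):
    m = make_model(vocab, seed=8)
    p = tmp_path / "model.ckpt"
    m.save(p, epoch=3)
    m2 = SmilesRNN.load(p)
    assert m2.hparams == m.hparams
    assert m2.vocab.tokens == m.vocab.tokens
    assert m2.sequence_nll("CCO") == m.sequence_nll("CCO")  # bit-for-bit


def test_molecule_nll_exact_vs_estimate_and_oracle(vocab):
    """Exact molecule NLL = -ln sum of string probabilities; the sampled
    estimate never undershoots it (probability mass only grows)."""
    # vocabulary must cover every randomized writing (branches included)
    vocab = build_vocabulary(
        ["C", "CC", "OCO"] + sorted(enumerate_random_smiles("CCO", RANDOMIZED_RESTRICTED))
    )
    m = make_model(vocab, seed=9)
    # single-writing molecule: molecule NLL is the string NLL
    assert molecule_nll(m, "C", RANDOMIZED_RESTRICTED, "exact") == pytest.approx(
        m.sequence_nll("C"), rel=1e-12
    )
    exact = molecule_nll(m, "CCO", RANDOMIZED_RESTRICTED, "exact")
    # brute-force oracle: enumerate strings, sum probabilities directly
    strings = enumerate_random_smiles("CCO", RANDOMIZED_RESTRICTED)
    brute = -np.log(sum(np.exp(-m.sequence_nll(s)) for s in strings))
    assert exact == pytest.approx(brute, abs=1e-6)
    for budget in (1, 2, 20):
        est = molecule_nll(m, "CCO", RANDOMIZED_RESTRICTED, "estimate", budget=budget, seed=0)
        assert est >= exact - 1e-9
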