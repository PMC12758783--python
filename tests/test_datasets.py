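import numpy as np
import pytest

from dscahla import datasets
from dscahla.io import AA_INDEX, PairExample, PeptideRecord


def test_world_is_seed_deterministic():
    w1 = datasets.generate_world(6, 3, seed=9)
    w2 = datasets.generate_world(6, 3, seed=9)
    assert [a.alpha_chain for a in w1.alleles] == [a.alpha_chain for a in w2.alleles]
    for name in w1.core_pssms:
        assert np.array_equal(w1.core_pssms[name], w2.core_pssms[name])


def test_world_pssm_rows_normalized_and_anchored():
    w = datasets.generate_world(6, 3, seed=1)
    for pssm in w.core_pssms.values():
        assert np.allclose(pssm.sum(axis=1), 1.0, atol=1e-9)
        for pos in (0, 5, 8):  # P1, P6, P9
            top3 = np.sort(pssm[pos])[-3:].sum()
            assert top3 >= 0.6


def test_shared_pocket_codes_share_anchor_argmax():
    w = datasets.generate_world(6, 3, seed=2)
    by_code = {}
    for name, code in w.pocket_codes.items():
        by_code.setdefault(code, []).append(name)
    for names in by_code.values():
        ref = w.core_pssms[names[0]]
        for other in names[1:]:
            for pos in (0, 5, 8):
                assert ref[pos].argmax() == w.core_pssms[other][pos].argmax()


def test_world_rejects_degenerate_sizes():
    with pytest.raises(ValueError):
        datasets.generate_world(1, 1, seed=0)


def test_sample_dataset_invariants():
    w = datasets.generate_world(4, 2, seed=3)
    pairs = datasets.sample_dataset(w, 20, ratio=5, seed=4)
    for p in pairs:
        if p.label == 1:
            assert 0 <= p.core_start <= len(p.peptide) - 9
        else:
            assert p.core_start is None
        assert p.source == "synthetic"
    # 5:1 ratio per allele, exactly
    for allele in w.registry:
        sub = [p for p in pairs if p.allele == allele]
        n_pos = sum(p.label for p in sub)
        assert len(sub) - n_pos == 5 * n_pos
    # determinism
    again = datasets.sample_dataset(w, 20, ratio=5, seed=4)
    assert [p.peptide.sequence for p in again] == [p.peptide.sequence for p in pairs]


def test_planted_anchor_frequencies_match_generator():
    """Residues at planted P1 concentrate on the allele's anchor set."""
    w = datasets.generate_world(2, 1, seed=5)
    pairs = datasets.sample_dataset(w, 600, ratio=0, seed=6)
    allele = w.alleles[0].name
    pssm = w.core_pssms[allele]
    counts = np.zeros(21)
    n = 0
    for p in pairs:
        if p.allele != allele:
            continue
        aa = p.peptide.sequence[p.core_start]
        counts[AA_INDEX[aa]] += 1
        n += 1
    assert n >= 500
    freqs = counts / n
    anchors = np.argsort(pssm[0])[-2:]
    assert freqs[anchors].sum() >= 0.6


def _positives(world, n, seed):
    return [p for p in datasets.sample_dataset(world, n, ratio=0, seed=seed)]


def test_build_benchmark_ratio_and_length_matching():
    w = datasets.generate_world(2, 1, seed=7)
    positives = _positives(w, 100, seed=8)
    one_allele = [p for p in positives if p.allele == w.alleles[0].name]
    rng = np.random.default_rng(9)
    decoys = ["".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=l))
              for l in rng.integers(9, 33, size=5000)]
    out = datasets.build_benchmark(one_allele, decoys, ratio=5, seed=10)
    negs = [p for p in out if p.label == 0]
    assert len(negs) == 5 * len(one_allele)
    pos_hist = np.bincount([len(p.peptide) for p in one_allele], minlength=33)
    neg_hist = np.bincount([len(p.peptide) for p in negs], minlength=33)
    if not out.length_fallbacks:
        assert np.array_equal(neg_hist, 5 * pos_hist)


def test_build_benchmark_ratio_zero_and_determinism():
    w = datasets.generate_world(2, 1, seed=7)
    positives = _positives(w, 10, seed=8)
    decoys = ["ACDEFGHIKLMNP"] * 200
    out = datasets.build_benchmark(positives, decoys, ratio=0, seed=1)
    assert len(out) == len(positives)
    a = datasets.build_benchmark(positives, ["ACDEFGHIKLMNP" + "A" * i for i in range(20)],
                                 ratio=1, seed=2)
    b = datasets.build_benchmark(positives, ["ACDEFGHIKLMNP" + "A" * i for i in range(20)],
                                 ratio=1, seed=2)
    assert [p.peptide.sequence for p in a] == [p.peptide.sequence for p in b]


def test_build_benchmark_empty_pool():
    w = datasets.generate_world(2, 1, seed=7)
    with pytest.raises(ValueError, match="empty"):
        datasets.build_benchmark(_positives(w, 5, seed=8), [], ratio=5, seed=0)


def test_deduplicate_rules():
    pep = lambda s: PeptideRecord(id=s, sequence=s)
    train = [PairExample(pep("ACDEFGHIK"), "A", 1),
             PairExample(pep("KLMNPQRST"), "A", 0)]
    test = [PairExample(pep("KLMNPQRST"), "B", 1)]  # same peptide, other allele
    kept, removed = datasets.deduplicate(train, test)
    assert removed == 1
    assert [p.peptide.sequence for p in kept] == ["ACDEFGHIK"]
    # disjoint -> unchanged; idempotent
    kept2, removed2 = datasets.deduplicate(kept, test)
    assert removed2 == 0 and kept2 == kept


def test_split_warm_cold_contracts():
    w = datasets.generate_world(6, 3, seed=11)
    pairs = datasets.sample_dataset(w, 40, ratio=5, seed=12)
    cold = {w.alleles[-1].name, w.alleles[-2].name}
    split = datasets.split_warm_cold(pairs, cold, seed=13)
    train_alleles = {p.allele for p in split.train}
    assert not (train_alleles & cold)
    assert {p.allele for p in split.warm_test} <= train_alleles
    train_peps = {p.peptide.sequence for p in split.train}
    assert not (train_peps & {p.peptide.sequence for p in split.warm_test})
    assert not (train_peps & {p.peptide.sequence for p in split.cold_test})
    assert split.allele_partition[w.alleles[-1].name] == "cold-only"
    # every cold pair lands in cold_test
    assert len(split.cold_test) == sum(p.allele in cold for p in pairs)


def test_split_warm_cold_rejects_full_cold_cover():
    w = datasets.generate_world(3, 2, seed=14)
    pairs = datasets.sample_dataset(w, 10, ratio=1, seed=15)
    with pytest.raises(ValueError):
        datasets.split_warm_cold(pairs, {a.name for a in w.alleles}, seed=0)
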