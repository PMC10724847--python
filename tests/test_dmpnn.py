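"""Directed-edge message passing: oracle equivalence and symmetry properties."""

import numpy as np
import pytest

from graphtox import autodiff as ad
from graphtox.chemio import parse_smiles
from graphtox.dmpnn import (
    ClassifierHead,
    DMPNNParams,
    GraphBatch,
    encode,
    encode_batch,
    forward,
    init_edge_states,
    message_step,
    readout,
)
from graphtox.molgraph import FeatureVocab, MolGraph, featurize
from conftest import naive_edge_states, random_smiles_rewrite

VOCAB = FeatureVocab()


def make_params(seed=0, hidden=8, depth=3):
    return DMPNNParams.init(np.random.default_rng(seed), VOCAB, hidden=hidden, depth=depth)


class TestInitAndSteps:
    def test_zero_weights_give_zero_states(self):
        p = make_params()
        p.W_input.data[:] = 0.0
        g = featurize(parse_smiles("CCO"), VOCAB)
        assert np.all(init_edge_states(g, p) == 0.0)

    def test_identical_edge_inputs_give_identical_states(self):
        p = make_params()
        g = featurize(parse_smiles("c1ccccc1"), VOCAB)  # all edges equivalent
        h0 = init_edge_states(g, p)
        assert np.allclose(h0, h0[0])

    def test_selector_weight_hand_computation(self):
        """A weight matrix selecting one input coordinate reproduces the
        positive part of that coordinate."""
        p = make_params(hidden=1)
        g = featurize(parse_smiles("CO"), VOCAB)
        col = VOCAB.elements.index("O")  # element one-hot position for O
        p.W_input.data[:] = 0.0
        p.W_input.data[col, 0] = 1.0
        h0 = init_edge_states(g, p)
        # edge 0: C->O has source C (feature 0), edge 1: O->C has source O (feature 1)
        assert h0[0, 0] == 0.0 and h0[1, 0] == 1.0

    def test_two_atom_molecule_keeps_initial_states(self):
        """The only incoming edge is the excluded reverse twin, so states
        never change - the defining no-echo property."""
        p = make_params()
        g = featurize(parse_smiles("CO"), VOCAB)
        h0 = init_edge_states(g, p)
        h = h0
        for _ in range(5):
            h = message_step(h, g, h0, p)
            assert np.array_equal(h, np.maximum(h0, 0.0))

    def test_three_atom_path_message_is_upstream_state(self):
        """On A-B-C the message into edge (B->C) is exactly the state of
        (A->B), per brute-force enumeration of incoming edges."""
        p = make_params()
        g = featurize(parse_smiles("CCO"), VOCAB)
        h0 = init_edge_states(g, p)
        # find directed edges
        edges = {(int(s), int(d)): e for e, (s, d) in enumerate(zip(g.edge_src, g.edge_dst))}
        e_bc, e_ab = edges[(1, 2)], edges[(0, 1)]
        h1 = message_step(h0, g, h0, p)
        expected = np.maximum(h0[e_bc] + h0[e_ab] @ p.W_message.data, 0.0)
        assert np.allclose(h1[e_bc], expected)


class TestOracleEquivalence:
    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_vectorized_matches_bruteforce_loops(self, small_molecules, depth):
        p = make_params(seed=depth, depth=depth)
        for mol in small_molecules:
            g = featurize(mol, VOCAB)
            if g.n_dir_edges == 0:
                continue
            oracle = naive_edge_states(g, p, depth)
            h0 = init_edge_states(g, p)
            h = h0
            for _ in range(depth):
                h = message_step(h, g, h0, p)
            assert np.max(np.abs(h - oracle)) <= 1e-6

    def test_depth_zero_uses_initial_states(self):
        p = make_params(depth=0)
        g = featurize(parse_smiles("CCO"), VOCAB)
        emb_direct = readout(init_edge_states(g, p), g, p)
        assert np.allclose(encode(g, p), emb_direct)


class TestReadout:
    def test_single_atom_molecule(self):
        p = make_params()
        g = featurize(parse_smiles("O"), VOCAB)
        emb = encode(g, p)
        expected = np.maximum(
            np.concatenate([g.node_features[0], np.zeros(p.hidden)])
            @ p.readout_layer.weight.data
            + p.readout_layer.bias.data,
            0.0,
        )
        assert np.allclose(emb, expected)

    def test_disconnected_copies_double_the_embedding(self):
        p = make_params()
        g = featurize(parse_smiles("CCO"), VOCAB)
        doubled = MolGraph(
            node_features=np.vstack([g.node_features] * 2),
            edge_features=np.vstack([g.edge_features] * 2),
            edge_src=np.concatenate([g.edge_src, g.edge_src + g.n_atoms]),
            edge_dst=np.concatenate([g.edge_dst, g.edge_dst + g.n_atoms]),
            reverse_index=np.concatenate([g.reverse_index, g.reverse_index + g.n_dir_edges]),
            incoming=[list(e) for e in g.incoming]
            + [[e + g.n_dir_edges for e in inc] for inc in g.incoming],
        )
        assert np.allclose(encode(doubled, p), 2.0 * encode(g, p))

    def test_permutation_invariance_of_embeddings(self, fixture_molecules):
        p = make_params(hidden=16)
        rng = np.random.default_rng(9)
        for mol in fixture_molecules:
            ref = encode(featurize(mol, VOCAB), p)
            scale = np.linalg.norm(ref) + 1e-12
            for _ in range(5):
                g2 = featurize(parse_smiles(random_smiles_rewrite(mol, rng)), VOCAB)
                assert np.linalg.norm(encode(g2, p) - ref) / scale <= 1e-5


class TestForward:
    def test_zero_head_gives_half(self):
        p = make_params()
        head = ClassifierHead.init(np.random.default_rng(0), p.hidden, (4,))
        for layer in head.mlp.layers:
            layer.weight.data[:] = 0.0
            layer.bias.data[:] = 0.0
        assert forward(featurize(parse_smiles("CCO"), VOCAB), p, head) == pytest.approx(0.5)

    def test_probability_range_and_smiles_invariance(self, fixture_molecules):
        p = make_params(hidden=16)
        head = ClassifierHead.init(np.random.default_rng(1), p.hidden, (8,))
        rng = np.random.default_rng(2)
        for mol in fixture_molecules:
            prob = forward(featurize(mol, VOCAB), p, head)
            assert 0.0 < prob < 1.0
            prob2 = forward(featurize(parse_smiles(random_smiles_rewrite(mol, rng)), VOCAB), p, head)
            assert prob2 == pytest.approx(prob, rel=1e-6)


class TestBatching:
    def test_batched_encoder_matches_single_graph_path(self, fixture_molecules):
        p = make_params(hidden=12, depth=2)
        graphs = [featurize(m, VOCAB) for m in fixture_molecules]
        batch_emb = encode_batch(GraphBatch.from_graphs(graphs), p).data
        for i, g in enumerate(graphs):
            assert np.allclose(batch_emb[i], encode(g, p), atol=1e-10)

    def test_mean_aggregation_divides_by_atom_count(self):
        p = make_params(hidden=6, depth=1)
        p.aggregation = "mean"
        g = featurize(parse_smiles("CCO"), VOCAB)
        batch = GraphBatch.from_graphs([g])
        assert np.allclose(encode_batch(batch, p).data[0], encode(g, p))
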