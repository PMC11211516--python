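"""Graph attention encoders: attention math, pooling, readout, invariances."""

import numpy as np
import pytest

from combosyn.chem import build_drug_graph
from combosyn.gnn import (
    DrugEncoder,
    GATv2Layer,
    GnnConfig,
    elu,
    encode_drug,
    gatv2_attention,
    hierarchical_readout,
    layer_pool,
)
from combosyn.nn.autodiff import Tensor

MOLECULES = [
    "CCO",
    "c1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "CN1CCC[C@H]1c1cccnc1",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "Clc1ccccc1Cl",
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "CCCCc1ccccc1",
    "CC(C)(C)c1ccccc1",
    "OCC1OC(O)C(O)C(O)C1O",
    "c1ccc2ncccc2c1",
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",
    "O=C(Nc1ccccc1)c1ccccc1",
    "CC(C)NCC(O)c1ccc(O)c(O)c1",
    "Cc1ncc([N+]([O-])=O)n1CCO",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",
    "OC(=O)c1cc(O)c(O)c(O)c1",
    "CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1",
    "Fc1ccc(cc1)C(=O)CCCN1CCC(O)(CC1)c1ccc(Cl)cc1",
]


def permute_graph(graph, rng):
    perm = rng.permutation(graph.atom_count_R)
    from combosyn.chem import DrugGraph

    return perm, DrugGraph(
        drug_id=graph.drug_id,
        features_M=graph.features_M[perm],
        adjacency_A=graph.adjacency_A[np.ix_(perm, perm)],
    )


class TestElu:
    @pytest.mark.parametrize(
        "x,a,expected",
        [(0.0, 1.0, 0.0), (2.0, 1.0, 2.0), (-1.0, 1.0, np.exp(-1) - 1), (-2.0, 0.5, 0.5 * (np.exp(-2) - 1))],
    )
    def test_values(self, x, a, expected):
        assert elu(x, a) == pytest.approx(expected, abs=1e-12)

    def test_continuity_at_zero(self):
        assert abs(elu(1e-12) - elu(-1e-12)) < 1e-10


class TestAttention:
    def _layer(self, d=6, seed=0):
        return GATv2Layer(d, d, np.random.default_rng(seed))

    def test_rows_sum_to_one(self, rng):
        layer = self._layer()
        for _ in range(10):
            R = int(rng.integers(2, 8))
            A = (rng.random((R, R)) < 0.4).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            H = Tensor(rng.normal(size=(R, 6)))
            alpha = layer.attention(H, A).data
            np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(alpha >= 0)

    def test_identical_states_give_uniform_weights(self):
        layer = self._layer()
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        H = Tensor(np.tile(np.arange(6.0), (3, 1)))
        alpha = layer.attention(H, A).data
        # node 0 has 2 neighbors + self
        np.testing.assert_allclose(alpha[0], [1 / 3, 1 / 3, 1 / 3], atol=1e-12)
        # nodes 1,2 have 1 neighbor + self
        np.testing.assert_allclose(sorted(alpha[1], reverse=True)[:2], [0.5, 0.5], atol=1e-12)

    def test_isolated_node_attends_to_itself(self, rng):
        layer = self._layer()
        A = np.zeros((3, 3))
        H = Tensor(rng.normal(size=(3, 6)))
        alpha = layer.attention(H, A).data
        np.testing.assert_allclose(alpha, np.eye(3), atol=1e-12)

    def test_matches_hand_rolled_softmax(self, rng):
        """Direct evaluation of the attention definition on a 4-node graph."""
        layer = self._layer(d=5, seed=3)
        A = np.array(
            [[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 0], [0, 1, 0, 0]], dtype=float
        )
        H = rng.normal(size=(4, 5))
        W = layer.theta.weight.data  # (in, out)
        a = layer.attn_vector.data
        S = H @ W
        for i in range(4):
            nbrs = [j for j in range(4) if A[i, j] or j == i]
            logits = {}
            for j in nbrs:
                z = S[i] + S[j]
                z = np.where(z > 0, z, 0.2 * z)  # LeakyReLU, slope 0.2
                logits[j] = a @ z
            mx = max(logits.values())
            exps = {j: np.exp(v - mx) for j, v in logits.items()}
            Z = sum(exps.values())
            expected = {j: e / Z for j, e in exps.items()}
            got = gatv2_attention(i, H, A, layer)
            for j in range(4):
                assert got[j] == pytest.approx(expected.get(j, 0.0), abs=1e-10)


class TestLayer:
    def test_identical_states_reduce_to_elu_theta_h(self, rng):
        layer = GATv2Layer(4, 4, np.random.default_rng(1))
        h = rng.normal(size=4)
        H = Tensor(np.tile(h, (5, 1)))
        A = np.ones((5, 5)) - np.eye(5)
        out = layer(H, A).data
        expected = elu(h @ layer.theta.weight.data)
        for row in out:
            np.testing.assert_allclose(row, expected, atol=1e-10)

    def test_zero_states_give_zero(self):
        layer = GATv2Layer(4, 4, np.random.default_rng(1))
        A = np.array([[0, 1], [1, 0]], dtype=float)
        out = layer(Tensor(np.zeros((2, 4))), A).data
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        layer = GATv2Layer(6, 6, np.random.default_rng(2))
        R = 6
        A = (rng.random((R, R)) < 0.5).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        H = rng.normal(size=(R, 6))
        perm = rng.permutation(R)
        out1 = layer(Tensor(H), A).data
        out2 = layer(Tensor(H[perm]), A[np.ix_(perm, perm)]).data
        np.testing.assert_allclose(out2, out1[perm], atol=1e-10)

    def test_uniform_attention_limit_is_mean_aggregation(self, rng):
        """With a zero attention vector the layer is mean aggregation."""
        layer = GATv2Layer(4, 4, np.random.default_rng(5))
        layer.attn_vector.data = np.zeros(4)
        R = 5
        A = (rng.random((R, R)) < 0.6).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        H = rng.normal(size=(R, 4))
        out = layer(Tensor(H), A).data
        S = H @ layer.theta.weight.data
        for i in range(R):
            nbrs = [j for j in range(R) if A[i, j] or j == i]
            np.testing.assert_allclose(out[i], elu(S[nbrs].mean(axis=0)), atol=1e-10)


class TestPoolingAndReadout:
    def test_pool_examples(self):
        np.testing.assert_allclose(layer_pool(Tensor(np.array([[0.0, 2.0], [2.0, 0.0]]))).data, [1, 1])
        h = np.array([[3.0, -1.0]])
        np.testing.assert_allclose(layer_pool(Tensor(h)).data, h[0])

    def test_readout_identical_layers(self, rng):
        g = Tensor(rng.normal(size=8))
        c = Tensor(rng.normal(size=8))
        z, psi = hierarchical_readout([g, g, g], c)
        np.testing.assert_allclose(z.data, g.data, atol=1e-12)
        np.testing.assert_allclose(psi.data, [1 / 3] * 3, atol=1e-12)

    def test_readout_single_layer(self, rng):
        g = Tensor(rng.normal(size=8))
        z, psi = hierarchical_readout([g], Tensor(rng.normal(size=8)))
        np.testing.assert_allclose(z.data, g.data)
        assert psi.data[0] == pytest.approx(1.0)

    def test_readout_matches_hand_rolled_oracle(self, rng):
        d = 7
        gs = [rng.normal(size=d) for _ in range(3)]
        c = rng.normal(size=d)
        scores = np.array([c @ g for g in gs]) / np.sqrt(d)
        e = np.exp(scores - scores.max())
        psi_exp = e / e.sum()
        z_exp = sum(p * g for p, g in zip(psi_exp, gs))
        z, psi = hierarchical_readout([Tensor(g) for g in gs], Tensor(c))
        np.testing.assert_allclose(psi.data, psi_exp, atol=1e-10)
        np.testing.assert_allclose(z.data, z_exp, atol=1e-10)

    def test_psi_is_probability_vector(self, rng):
        for _ in range(10):
            gs = [Tensor(rng.normal(size=5)) for _ in range(4)]
            _, psi = hierarchical_readout(gs, Tensor(rng.normal(size=5)))
            assert psi.data.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(psi.data > 0)


@pytest.mark.parametrize("gnn_type", ["gatv2", "gat", "gcn"])
class TestEncoder:
    def test_embedding_length_and_determinism(self, gnn_type):
        enc = DrugEncoder(GnnConfig(gnn_type=gnn_type, emb_dim=100), np.random.default_rng(0))
        g = build_drug_graph("d", "CCO")
        z1, z2 = encode_drug(g, enc), encode_drug(g, enc)
        assert z1.shape == (100,)
        np.testing.assert_array_equal(z1, z2)

    def test_permutation_invariance(self, gnn_type, rng):
        enc = DrugEncoder(GnnConfig(gnn_type=gnn_type, emb_dim=16), np.random.default_rng(1))
        for smi in MOLECULES:
            g = build_drug_graph(smi, smi)
            _, gp = permute_graph(g, rng)
            np.testing.assert_allclose(encode_drug(gp, enc), encode_drug(g, enc), atol=1e-6)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        GnnConfig(gnn_type="sage")
    with pytest.raises(ValueError):
        GnnConfig(num_layer=0)
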