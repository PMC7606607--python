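"""Network data model: validation, topological order, joint probability,
serialization."""

import itertools

import numpy as np
import pytest

from sibbn.bn_core import (
    CPT,
    NetworkSpec,
    NetworkValidationError,
    NodeDef,
    build_network,
    joint_probability,
    topological_order,
)

from .conftest import enum_all_assignments, enum_joint, make_net, random_network


def _binary(name):
    return NodeDef(name, ("s0", "s1"))


def _cpt(child, parents, rows):
    return CPT(child=child, parents=tuple(parents),
               table={k: np.array(v, float) for k, v in rows.items()})


class TestValidation:
    def test_minimal_chain_is_valid(self):
        net = build_network(
            [_binary("A"), _binary("B")],
            [_cpt("A", (), {(): (0.5, 0.5)}),
             _cpt("B", ("A",), {("s0",): (1, 0), ("s1",): (0, 1)})],
        )
        assert set(net.nodes) == {"A", "B"}
        assert net.parents("B") == ("A",)

    def test_cycle_detected(self):
        with pytest.raises(NetworkValidationError, match="cycle"):
            build_network(
                [_binary("A"), _binary("B")],
                [_cpt("A", ("B",), {("s0",): (1, 0), ("s1",): (0, 1)}),
                 _cpt("B", ("A",), {("s0",): (1, 0), ("s1",): (0, 1)})],
            )

    def test_missing_row_counted(self):
        # binary child of 3 binary parents: 8 rows required, 7 given
        parents = ("P1", "P2", "P3")
        rows = {
            combo: (0.5, 0.5)
            for combo in itertools.product(("s0", "s1"), repeat=3)
        }
        rows.pop(("s1", "s1", "s1"))
        with pytest.raises(NetworkValidationError, match="8 required"):
            build_network(
                [_binary(p) for p in parents] + [_binary("C")],
                [_cpt(p, (), {(): (0.5, 0.5)}) for p in parents]
                + [_cpt("C", parents, rows)],
            )

    def test_row_not_summing_rejected(self):
        with pytest.raises(NetworkValidationError, match="not a distribution"):
            build_network([_binary("A")], [_cpt("A", (), {(): (0.6, 0.6)})])

    def test_duplicate_node_rejected(self):
        with pytest.raises(NetworkValidationError, match="duplicate"):
            build_network(
                [_binary("A"), _binary("A")],
                [_cpt("A", (), {(): (0.5, 0.5)})],
            )

    def test_node_without_cpt_rejected(self):
        with pytest.raises(NetworkValidationError, match="without CPT"):
            build_network(
                [_binary("A"), _binary("B")],
                [_cpt("A", (), {(): (0.5, 0.5)})],
            )

    def test_few_states_rejected(self):
        with pytest.raises(NetworkValidationError, match=">=2 states"):
            NodeDef("A", ("only",))


class TestTopologicalOrder:
    def test_chain(self, chain_net):
        assert topological_order(chain_net) == ["A", "B", "C"]

    def test_name_order_tie_break(self):
        net = make_net({
            "B": ((), {(): (0.5, 0.5)}),
            "A": ((), {(): (0.5, 0.5)}),
            "C": (("A", "B"), {
                (a, b): (0.5, 0.5)
                for a in ("s0", "s1") for b in ("s0", "s1")
            }),
        }, {"B": ("s0", "s1"), "A": ("s0", "s1"), "C": ("s0", "s1")})
        assert topological_order(net) == ["A", "B", "C"]

    def test_si_model_layering(self):
        from sibbn.si_model import (
            ECOLI_POU, ENV_NODE, ENV_PARENTS, STORAGE_NODE, build_model,
        )
        order = topological_order(build_model("1A"))
        for p in ENV_PARENTS:
            assert order.index(p) < order.index(ENV_NODE)
        assert order.index(ENV_NODE) < order.index(ECOLI_POU)
        assert order.index(STORAGE_NODE) < order.index(ECOLI_POU)
        assert order[-1] == ECOLI_POU


class TestJointProbability:
    def test_independent_fair_binaries(self):
        net = make_net({
            "A": ((), {(): (0.5, 0.5)}),
            "B": ((), {(): (0.5, 0.5)}),
        }, {"A": ("s0", "s1"), "B": ("s0", "s1")})
        for a in ("s0", "s1"):
            for b in ("s0", "s1"):
                assert joint_probability(net, {"A": a, "B": b}) == 0.25

    def test_zero_entry_gives_zero(self, chain_net):
        net = chain_net.copy()
        net.cpts["B"].table[("a0",)] = np.array([1.0, 0.0])
        assert joint_probability(net, {"A": "a0", "B": "b1", "C": "c0"}) == 0.0

    def test_matches_enumeration_oracle(self, collider_net):
        for a in enum_all_assignments(collider_net):
            assert joint_probability(collider_net, a) == pytest.approx(
                enum_joint(collider_net, a), abs=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_joint_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, n_nodes=int(rng.integers(3, 9)))
        total = sum(joint_probability(net, a)
                    for a in enum_all_assignments(net))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_partial_assignment_rejected(self, chain_net):
        with pytest.raises(NetworkValidationError, match="misses"):
            joint_probability(chain_net, {"A": "a0"})

    def test_unknown_state_rejected(self, chain_net):
        with pytest.raises(NetworkValidationError, match="unknown state"):
            joint_probability(chain_net, {"A": "zz", "B": "b0", "C": "c0"})


class TestSerialization:
    @pytest.mark.parametrize("seed", range(3))
    def test_round_trip_bit_for_bit(self, tmp_path, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_network(rng, n_nodes=6)
        path = tmp_path / "net.json"
        net.to_json(path)
        back = NetworkSpec.from_json(path)
        assert set(back.nodes) == set(net.nodes)
        for name, cpt in net.cpts.items():
            assert back.cpts[name].parents == cpt.parents
            assert back.cpts[name].locked == cpt.locked
            for key, vec in cpt.table.items():
                # repr-based JSON floats round-trip exactly
                assert np.array_equal(back.cpts[name].table[key], vec)

    def test_locked_flag_survives(self, tmp_path):
        from sibbn.si_model import ENV_NODE, build_model
        net = build_model("1B")
        path = tmp_path / "net.json"
        net.to_json(path)
        assert NetworkSpec.from_json(path).cpts[ENV_NODE].locked
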