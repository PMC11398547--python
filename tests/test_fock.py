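import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from polyfock import (
    apply_operator,
    apply_rule_instance,
    builtin_fixture,
    compile_model,
    derive_depletion,
    instantiate_rules,
    is_eligible,
)
from polyfock.fock import (
    field_operator_matrix,
    macrostate_vector,
    make_mode,
    mode_operator_matrix,
    product_operator_matrix,
)
from polyfock.model import ModelError


@pytest.fixture(scope="module")
def hd():
    return builtin_fixture("homodimer", 10)


def A(model, i):
    return make_mode(model, "A", (i,))


class TestApplyOperator:
    def test_create_on_excited_is_zero(self, hd):
        s = frozenset({A(hd, 3)})
        assert apply_operator("create", A(hd, 3), s) is None

    def test_create_on_vacuum(self, hd):
        assert apply_operator("create", A(hd, 3), frozenset()) == frozenset({A(hd, 3)})

    def test_annihilate_removes(self, hd):
        s = frozenset({A(hd, 2), A(hd, 5)})
        assert apply_operator("annihilate", A(hd, 2), s) == frozenset({A(hd, 5)})

    def test_annihilate_on_unexcited_is_zero(self, hd):
        assert apply_operator("annihilate", A(hd, 2), frozenset()) is None

    def test_presence_absence(self, hd):
        s = frozenset({A(hd, 1)})
        assert apply_operator("presence", A(hd, 1), s) == s
        assert apply_operator("presence", A(hd, 2), s) is None
        assert apply_operator("absence", A(hd, 2), s) == s
        assert apply_operator("absence", A(hd, 1), s) is None


class TestRuleInstances:
    def _bind_instance(self, hd, i, j):
        bind = next(r for r in hd.rules if r.name == "bind")
        for inst in instantiate_rules(bind, hd.N, hd):
            if dict(inst.binding) == {"i": i, "j": j}:
                return inst
        raise AssertionError

    def test_dimerization_product_state(self, hd):
        s = frozenset({A(hd, 2), A(hd, 3), A(hd, 5), A(hd, 7)})
        inst = self._bind_instance(hd, 3, 7)
        out = apply_rule_instance(inst, s)
        expected = s | {
            make_mode(hd, "a", (3,)),
            make_mode(hd, "a", (7,)),
            make_mode(hd, "I", (3, 7)),
        }
        assert out == expected

    def test_dimerization_on_vacuum_is_zero(self, hd):
        inst = self._bind_instance(hd, 3, 7)
        assert apply_rule_instance(inst, frozenset()) is None

    def test_bound_monomer_cannot_be_destroyed(self, hd):
        """Annihilation with an absence guard fails on an interacting monomer."""
        s = frozenset(
            {
                A(hd, 2),
                A(hd, 3),
                A(hd, 5),
                A(hd, 7),
                make_mode(hd, "a", (3,)),
                make_mode(hd, "a", (7,)),
                make_mode(hd, "I", (3, 7)),
            }
        )
        destroy = next(r for r in hd.rules if r.name == "destroy")
        inst3 = next(
            i for i in instantiate_rules(destroy, hd.N, hd) if dict(i.binding)["i"] == 3
        )
        assert apply_rule_instance(inst3, s) is None
        assert not is_eligible(inst3, s)

    def test_eligibility_monomer_pair(self, hd):
        s = frozenset({A(hd, 2), A(hd, 3), A(hd, 5), A(hd, 7)})
        assert is_eligible(self._bind_instance(hd, 3, 7), s)

    def test_eligibility_blocked_by_occupied_site(self, hd):
        s = frozenset(
            {
                A(hd, 2),
                A(hd, 3),
                A(hd, 5),
                A(hd, 7),
                make_mode(hd, "a", (3,)),
                make_mode(hd, "a", (7,)),
                make_mode(hd, "I", (3, 7)),
            }
        )
        assert not is_eligible(self._bind_instance(hd, 3, 5), s)

    def test_creation_rule_on_vacuum_eligible(self, hd):
        create = next(r for r in hd.rules if r.name == "create")
        for inst in instantiate_rules(create, hd.N, hd):
            assert is_eligible(inst, frozenset())

    def test_eligible_iff_apply_nonnull(self, hd):
        create = next(r for r in hd.rules if r.name == "create")
        s = frozenset({A(hd, 1)})
        for inst in instantiate_rules(create, hd.N, hd):
            assert is_eligible(inst, s) == (apply_rule_instance(inst, s) is not None)


class TestInstantiation:
    def test_homodimer_bind_count(self):
        hd = builtin_fixture("homodimer", 4)
        bind = next(r for r in hd.rules if r.name == "bind")
        assert len(instantiate_rules(bind, 4, hd)) == 6  # C(4,2)

    def test_homopolymer_bind_counts(self):
        hp = builtin_fixture("homopolymer", 3)
        bind = next(r for r in hp.rules if r.name == "bind")
        assert len(instantiate_rules(bind, 3, hp)) == 6  # ordered pairs, i != j
        hps = builtin_fixture("homopolymer", 3, allow_self=True)
        bind_s = next(r for r in hps.rules if r.name == "bind")
        assert len(instantiate_rules(bind_s, 3, hps)) == 9

    def test_monomer_create_count(self):
        m = builtin_fixture("monomer", 20)
        create = next(r for r in m.rules if r.name == "create")
        assert len(instantiate_rules(create, 20, m)) == 20

    def test_lexicographic_order(self):
        hp = builtin_fixture("homopolymer", 3)
        bind = next(r for r in hp.rules if r.name == "bind")
        bindings = [tuple(v for _, v in i.binding) for i in instantiate_rules(bind, 3, hp)]
        assert bindings == sorted(bindings)


class TestDepletion:
    def test_create_maps_to_absence(self):
        hp = builtin_fixture("homopolymer", 3)
        create = next(r for r in hp.rules if r.name == "create")
        dep = derive_depletion(create)
        assert [f.op for f in dep.factors] == ["absence", "absence", "absence"]

    def test_unbind_depletion(self):
        hp = builtin_fixture("homopolymer", 3)
        unbind = next(r for r in hp.rules if r.name == "unbind")
        dep = derive_depletion(unbind)
        # J-check a-check b-check A-bar A-bar -> J-bar a-bar b-bar A-bar A-bar
        assert [f.op for f in dep.factors] == [
            "presence",
            "presence",
            "presence",
            "presence",
            "presence",
        ]

    def test_presence_only_is_fixed_point(self):
        hp = builtin_fixture("homopolymer", 3)
        unbind = next(r for r in hp.rules if r.name == "unbind")
        dep = derive_depletion(unbind)
        dep2 = derive_depletion(dep)
        assert dep2.factors == dep.factors

    def test_rate_and_constraint_preserved(self):
        hp = builtin_fixture("homopolymer", 3, rates={"bind": 2.5})
        bind = next(r for r in hp.rules if r.name == "bind")
        dep = derive_depletion(bind)
        assert dep.rate == 2.5 and dep.constraint == bind.constraint


@pytest.fixture(scope="module")
def mono3():
    model = builtin_fixture("monomer", 3)
    return model, compile_model(model)


class TestMatrices:
    def test_nilpotency(self, mono3):
        model, cm = mono3
        for i in range(1, 4):
            C = mode_operator_matrix(cm, "create", make_mode(model, "A", (i,)))
            D = mode_operator_matrix(cm, "annihilate", make_mode(model, "A", (i,)))
            assert (C @ C).nnz == 0
            assert (D @ D).nnz == 0

    def test_absence_is_one_minus_presence(self, mono3):
        model, cm = mono3
        I = sp.identity(8, dtype=np.int64)
        for i in range(1, 4):
            P = mode_operator_matrix(cm, "presence", make_mode(model, "A", (i,)))
            Ab = mode_operator_matrix(cm, "absence", make_mode(model, "A", (i,)))
            assert (Ab - (I - P)).nnz == 0

    def test_mode_commutator_identity(self, mono3):
        """[check_i, hat_j] = delta_ij (1 - 2 presence_i)."""
        model, cm = mono3
        I = sp.identity(8, dtype=np.int64)
        for i, j in itertools.product(range(1, 4), repeat=2):
            C = mode_operator_matrix(cm, "create", make_mode(model, "A", (j,)))
            D = mode_operator_matrix(cm, "annihilate", make_mode(model, "A", (i,)))
            P = mode_operator_matrix(cm, "presence", make_mode(model, "A", (i,)))
            comm = D @ C - C @ D
            expected = (I - 2 * P) if i == j else sp.csr_matrix((8, 8), dtype=np.int64)
            assert (comm - expected).nnz == 0

    def test_presence_create_commutator(self, mono3):
        """[presence_i, hat_j] = delta_ij hat_j."""
        model, cm = mono3
        for i, j in itertools.product(range(1, 4), repeat=2):
            P = mode_operator_matrix(cm, "presence", make_mode(model, "A", (i,)))
            C = mode_operator_matrix(cm, "create", make_mode(model, "A", (j,)))
            comm = P @ C - C @ P
            expected = C if i == j else sp.csr_matrix((8, 8), dtype=np.int64)
            assert (comm - expected).nnz == 0

    def test_field_commutator(self, mono3):
        model, cm = mono3
        C = field_operator_matrix(cm, "create", "A")
        D = field_operator_matrix(cm, "annihilate", "A")
        P = field_operator_matrix(cm, "presence", "A")
        I = sp.identity(8, dtype=np.int64)
        assert ((D @ C - C @ D) - (3 * I - 2 * P)).nnz == 0
        assert ((P @ C - C @ P) - C).nnz == 0

    @pytest.mark.parametrize("N", [2, 3, 4])
    def test_macrostate_ladder_exact(self, N):
        """hat|n> = (n+1)|n+1>, check|n> = (N-n+1)|n-1>, exactly for all n <= N."""
        model = builtin_fixture("monomer", N)
        cm = compile_model(model)
        C = field_operator_matrix(cm, "create", "A")
        D = field_operator_matrix(cm, "annihilate", "A")
        P = field_operator_matrix(cm, "presence", "A")
        Ab = field_operator_matrix(cm, "absence", "A")
        vecs = [macrostate_vector(cm, C, n) for n in range(N + 2)]
        for n in range(N + 1):
            assert np.allclose(C @ vecs[n], (n + 1) * vecs[n + 1])
            if n >= 1:
                assert np.allclose(D @ vecs[n], (N - n + 1) * vecs[n - 1])
            assert np.allclose(P @ vecs[n], n * vecs[n])
            assert np.allclose(Ab @ vecs[n], (N - n) * vecs[n])

    def test_hat_on_n1_gives_2_n2_at_N3(self, mono3):
        model, cm = mono3
        C = field_operator_matrix(cm, "create", "A")
        assert np.allclose(C @ macrostate_vector(cm, C, 1), 2 * macrostate_vector(cm, C, 2))

    def test_check_on_n1_gives_3_vacuum_at_N3(self, mono3):
        model, cm = mono3
        C = field_operator_matrix(cm, "create", "A")
        D = field_operator_matrix(cm, "annihilate", "A")
        assert np.allclose(D @ macrostate_vector(cm, C, 1), 3 * macrostate_vector(cm, C, 0))

    def test_space_guard(self):
        model = builtin_fixture("homodimer", 6)  # 2*6 + 15 = 27 modes
        cm = compile_model(model)
        with pytest.raises(ModelError, match="guard"):
            mode_operator_matrix(cm, "create", make_mode(model, "A", (1,)))


@pytest.mark.parametrize("N", [2, 3])
def test_homodimer_monomer_dimer_fields_commute(N):
    model = builtin_fixture("homodimer", N)
    cm = compile_model(model)
    dim = 1 << cm.n_modes
    M = sp.csr_matrix((dim, dim), dtype=np.int64)
    for i in range(1, N + 1):
        M = M + product_operator_matrix(
            cm,
            [("create", make_mode(model, "A", (i,))), ("absence", make_mode(model, "a", (i,)))],
        )
    D = sp.csr_matrix((dim, dim), dtype=np.int64)
    for i in range(1, N + 1):
        for j in range(i + 1, N + 1):
            D = D + product_operator_matrix(
                cm,
                [
                    ("create", make_mode(model, "I", (i, j))),
                    ("create", make_mode(model, "a", (i,))),
                    ("create", make_mode(model, "a", (j,))),
                    ("create", make_mode(model, "A", (i,))),
                    ("create", make_mode(model, "A", (j,))),
                ],
            )
    assert (M @ D - D @ M).nnz == 0


@pytest.mark.parametrize("fixture_name", ["monomer", "homodimer", "homopolymer"])
def test_instance_application_matches_matrices(fixture_name):
    """Oracle equivalence: set-based application == matrix product on every basis state."""
    N = 3 if fixture_name == "monomer" else 2
    model = builtin_fixture(fixture_name, N)
    cm = compile_model(model)
    dim = 1 << cm.n_modes
    for template in model.rules:
        for inst in instantiate_rules(template, N, model):
            mat = product_operator_matrix(cm, inst.modes_touched)
            for mask in range(dim):
                s = cm.state_of(mask)
                out = apply_rule_instance(inst, s)
                col = mat.getcol(mask).toarray().ravel()
                if out is None:
                    assert not col.any()
                else:
                    expected = np.zeros(dim)
                    expected[cm.mask_of(out)] = 1
                    assert np.array_equal(col, expected)
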