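"""Microstates as excitation patterns over modes; mode operators and rule instances.

A *mode* is one hard-core boson degree of freedom: a (field, index-tuple) pair.
A *microstate* is the set of excited modes; the empty set is the vacuum.  Rule
templates are instantiated over the index range 1..N into concrete rule
instances, each a product of create/annihilate/presence/absence factors on
specific modes.

For identity testing on small systems, explicit sparse operator matrices are
built on the full 2^M Fock space in a fixed lexicographic basis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, FrozenSet, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .model import ModelSpec, RuleFactor, RuleTemplate, ModelError

__all__ = [
    "Mode",
    "Microstate",
    "RuleInstance",
    "CompiledModel",
    "compile_model",
    "apply_operator",
    "apply_rule_instance",
    "is_eligible",
    "instantiate_rules",
    "derive_depletion",
    "mode_operator_matrix",
    "field_operator_matrix",
    "product_operator_matrix",
    "template_operator_matrix",
    "macrostate_vector",
    "apply_factors_vec",
]

MAX_MATRIX_MODES = 20  # guard for explicit 2^M construction


class Mode(NamedTuple):
    field: str
    indices: Tuple[int, ...]

    def __repr__(self) -> str:  # A(3), I(2,5)
        return f"{self.field}({','.join(str(i) for i in self.indices)})"


Microstate = FrozenSet[Mode]

VACUUM: Microstate = frozenset()


def make_mode(model: ModelSpec, field: str, indices: Tuple[int, ...]) -> Mode:
    """Construct a mode, canonicalizing symmetric-bond index order."""
    spec = model.field(field)
    if len(indices) != spec.arity:
        raise ModelError(f"mode {field}{indices}: wrong arity")
    for i in indices:
        if not 1 <= i <= model.N:
            raise ModelError(f"mode {field}{indices}: index out of range 1..{model.N}")
    if spec.kind == "bond":
        i, j = indices
        if i == j and not spec.allow_self:
            raise ModelError(f"mode {field}{indices}: self pair not allowed")
        if spec.symmetric and i > j:
            indices = (j, i)
    return Mode(field, tuple(indices))


@dataclass(frozen=True)
class RuleInstance:
    """A rule template bound to concrete mode indices."""

    template: RuleTemplate
    binding: Tuple[Tuple[str, int], ...]  # (index var, value), template order
    modes_touched: Tuple[Tuple[str, Mode], ...]  # (op_kind, Mode) per factor

    @property
    def rate(self) -> float:
        return self.template.rate

    @property
    def name(self) -> str:
        args = ",".join(str(v) for _, v in self.binding)
        return f"{self.template.name}[{args}]"


def _binding_ok(template: RuleTemplate, values: Tuple[int, ...]) -> bool:
    if template.constraint == "ordered":
        return values[0] < values[1]
    if template.constraint == "distinct":
        return len(set(values)) == len(values)
    return True


def instantiate_rules(
    template: RuleTemplate, N: int, model: ModelSpec
) -> List[RuleInstance]:
    """All concrete instances of a template, in lexicographic binding order.

    Bindings whose factors would reference an invalid mode (e.g. a self bond
    pair on a field with ``allow_self=False``) are skipped.
    """
    ivars = template.index_vars
    out: List[RuleInstance] = []
    for values in itertools.product(range(1, N + 1), repeat=len(ivars)):
        if not _binding_ok(template, values):
            continue
        env = dict(zip(ivars, values))
        try:
            touched = tuple(
                (f.op, make_mode(model, f.field, tuple(env[v] for v in f.index_vars)))
                for f in template.factors
            )
        except ModelError:
            continue
        # duplicate identical factors (e.g. ?A(i) ?A(i) at i=j) are idempotent
        # and collapse to one; the same mode under different ops is a conflict
        seen: dict = {}
        deduped = []
        conflict = False
        for op, m in touched:
            if m in seen:
                if seen[m] != op:
                    conflict = True
                    break
                continue
            seen[m] = op
            deduped.append((op, m))
        if conflict:
            continue
        out.append(RuleInstance(template, tuple(zip(ivars, values)), tuple(deduped)))
    return out


def derive_depletion(template: RuleTemplate) -> RuleTemplate:
    """Depletion partner: create -> absence, annihilate -> presence, others fixed."""
    mapping = {
        "create": "absence",
        "annihilate": "presence",
        "presence": "presence",
        "absence": "absence",
    }
    factors = tuple(
        RuleFactor(mapping[f.op], f.field, f.index_vars) for f in template.factors
    )
    return RuleTemplate(template.name + "'", template.rate, factors, template.constraint)


# ---------------------------------------------------------------------------
# Operator application on microstates
# ---------------------------------------------------------------------------


def apply_operator(op_kind: str, mode: Mode, s: Microstate) -> Optional[Microstate]:
    """Apply one mode operator; ``None`` encodes the zero vector."""
    excited = mode in s
    if op_kind == "create":
        return None if excited else s | {mode}
    if op_kind == "annihilate":
        return s - {mode} if excited else None
    if op_kind == "presence":
        return s if excited else None
    if op_kind == "absence":
        return None if excited else s
    raise ValueError(f"unknown operator kind {op_kind!r}")


def is_eligible(instance: RuleInstance, s: Microstate) -> bool:
    """True iff every factor of the instance is eligible on microstate ``s``."""
    for op, mode in instance.modes_touched:
        excited = mode in s
        if op in ("create", "absence"):
            if excited:
                return False
        else:  # annihilate, presence
            if not excited:
                return False
    return True


def apply_rule_instance(instance: RuleInstance, s: Microstate) -> Optional[Microstate]:
    """Apply all factors of a rule instance; ``None`` if any factor kills the state."""
    if not is_eligible(instance, s):
        return None
    add = {m for op, m in instance.modes_touched if op == "create"}
    rem = {m for op, m in instance.modes_touched if op == "annihilate"}
    return (s | add) - rem


# ---------------------------------------------------------------------------
# Compiled model: enumerated mode universe and bitmask instances
# ---------------------------------------------------------------------------


class CompiledModel:
    """Mode universe plus bitmask-compiled rule instances for one ModelSpec.

    Modes are enumerated in lexicographic order: field declaration order, then
    indices.  Microstates are interchangeably frozensets of modes or integer
    bitmasks in this enumeration.
    """

    def __init__(self, model: ModelSpec):
        self.model = model
        self.modes: List[Mode] = []
        for f in model.fields:
            if f.kind == "bond":
                for i in range(1, model.N + 1):
                    for j in range(1, model.N + 1):
                        if f.symmetric and j < i:
                            continue
                        if i == j and not f.allow_self:
                            continue
                        self.modes.append(Mode(f.name, (i, j)))
            else:
                for i in range(1, model.N + 1):
                    self.modes.append(Mode(f.name, (i,)))
        self.bit: Dict[Mode, int] = {m: k for k, m in enumerate(self.modes)}
        self.n_modes = len(self.modes)

        self.instances: List[RuleInstance] = []
        self.instance_template_index: List[int] = []
        for ti, t in enumerate(model.rules):
            for inst in instantiate_rules(t, model.N, model):
                self.instances.append(inst)
                self.instance_template_index.append(ti)
        self.rates = np.array([inst.rate for inst in self.instances], dtype=float)
        # Bitmask compilation: need-set = modes that must be excited
        # (annihilate/presence), need-clear = modes that must be unexcited
        # (create/absence); flip = create ^ annihilate.
        self.need_set = np.zeros(len(self.instances), dtype=np.int64)
        self.need_clear = np.zeros(len(self.instances), dtype=np.int64)
        self.flip = np.zeros(len(self.instances), dtype=np.int64)
        self._need_set_py: List[int] = []
        self._need_clear_py: List[int] = []
        self._flip_py: List[int] = []
        small = self.n_modes <= 62
        for k, inst in enumerate(self.instances):
            ns = nc = fl = 0
            for op, mode in inst.modes_touched:
                b = 1 << self.bit[mode]
                if op in ("annihilate", "presence"):
                    ns |= b
                else:
                    nc |= b
                if op in ("create", "annihilate"):
                    fl |= b
            self._need_set_py.append(ns)
            self._need_clear_py.append(nc)
            self._flip_py.append(fl)
            if small:
                self.need_set[k] = ns
                self.need_clear[k] = nc
                self.flip[k] = fl

    # -- conversions -------------------------------------------------------

    def mask_of(self, s: Microstate) -> int:
        return sum(1 << self.bit[m] for m in s)

    def state_of(self, mask: int) -> Microstate:
        return frozenset(m for m in self.modes if mask >> self.bit[m] & 1)

    def init_mask(self) -> int:
        mask = 0
        for fname, idx in self.model.init:
            mask |= 1 << self.bit[make_mode(self.model, fname, idx)]
        return mask

    # -- bitmask semantics -------------------------------------------------

    def eligible_mask(self, mask: int, k: int) -> bool:
        return (mask & self._need_set_py[k]) == self._need_set_py[k] and (
            mask & self._need_clear_py[k]
        ) == 0

    def apply_mask(self, mask: int, k: int) -> int:
        return mask ^ self._flip_py[k]

    def hamiltonian_energy(self, mask: int) -> float:
        """Diagonal energy H(s) from the model's Hamiltonian terms."""
        e = 0.0
        for term in self.model.hamiltonian:
            bits = 0
            for m in self.modes:
                if m.field == term.field and (mask >> self.bit[m]) & 1:
                    bits += 1
            e += term.coeff * bits
        return e

    def field_bitmask(self, field: str) -> int:
        mask = 0
        for m in self.modes:
            if m.field == field:
                mask |= 1 << self.bit[m]
        return mask


def compile_model(model: ModelSpec) -> CompiledModel:
    return CompiledModel(model)


# ---------------------------------------------------------------------------
# Explicit matrices on the full 2^M space
# ---------------------------------------------------------------------------


def _check_space(cm: CompiledModel) -> int:
    if cm.n_modes > MAX_MATRIX_MODES:
        raise ModelError(
            f"explicit Fock space with {cm.n_modes} modes exceeds the "
            f"{MAX_MATRIX_MODES}-mode guard"
        )
    return 1 << cm.n_modes


def mode_operator_matrix(cm: CompiledModel, op_kind: str, mode: Mode) -> sp.csr_matrix:
    """Exact 0/1 matrix of one mode operator in the lexicographic basis."""
    dim = _check_space(cm)
    bit = 1 << cm.bit[mode]
    states = np.arange(dim, dtype=np.int64)
    excited = (states & bit) != 0
    if op_kind == "create":
        cols = states[~excited]
        rows = cols | bit
    elif op_kind == "annihilate":
        cols = states[excited]
        rows = cols & ~bit
    elif op_kind == "presence":
        cols = states[excited]
        rows = cols
    elif op_kind == "absence":
        cols = states[~excited]
        rows = cols
    else:
        raise ValueError(f"unknown operator kind {op_kind!r}")
    data = np.ones(len(cols), dtype=np.int64)
    return sp.csr_matrix((data, (rows, cols)), shape=(dim, dim))


def field_operator_matrix(cm: CompiledModel, op_kind: str, field: str) -> sp.csr_matrix:
    """Field operator: sum of the mode operators over all modes of ``field``."""
    dim = _check_space(cm)
    out = sp.csr_matrix((dim, dim), dtype=np.int64)
    for m in cm.modes:
        if m.field == field:
            out = out + mode_operator_matrix(cm, op_kind, m)
    return out


def product_operator_matrix(
    cm: CompiledModel, factors: Sequence[Tuple[str, Mode]]
) -> sp.csr_matrix:
    """Matrix of an operator product; factors apply right to left."""
    dim = _check_space(cm)
    out = sp.identity(dim, dtype=np.int64, format="csr")
    for op, mode in factors:  # product order: factors[0] is leftmost
        out = out @ mode_operator_matrix(cm, op, mode)
    return out


def template_operator_matrix(cm: CompiledModel, template: RuleTemplate) -> sp.csr_matrix:
    """Sum of instance product matrices over all bindings of the template."""
    dim = _check_space(cm)
    out = sp.csr_matrix((dim, dim), dtype=np.int64)
    for inst in instantiate_rules(template, cm.model.N, cm.model):
        out = out + product_operator_matrix(cm, inst.modes_touched)
    return out


def macrostate_vector(cm: CompiledModel, create_matrix: sp.spmatrix, n: int) -> np.ndarray:
    """|n> built literally as (create field operator)^n |0> / n! on the 2^M space."""
    dim = _check_space(cm)
    v = np.zeros(dim)
    v[0] = 1.0
    for k in range(1, n + 1):
        v = create_matrix @ v / k
    return v


# ---------------------------------------------------------------------------
# Exact rational state vectors (dicts mask -> Fraction), for Wick checks
# ---------------------------------------------------------------------------

VecF = Dict[int, Fraction]


def apply_factors_vec(
    cm: CompiledModel, factors: Sequence[Tuple[str, Mode]], vec: VecF
) -> VecF:
    """Apply an operator product (rightmost factor first) to an exact vector."""
    out: VecF = {}
    needs = 0
    clears = 0
    flips = 0
    for op, mode in factors:
        b = 1 << cm.bit[mode]
        if op in ("annihilate", "presence"):
            needs |= b
        else:
            clears |= b
        if op in ("create", "annihilate"):
            flips |= b
    for mask, coeff in vec.items():
        if (mask & needs) == needs and (mask & clears) == 0:
            tgt = mask ^ flips
            out[tgt] = out.get(tgt, Fraction(0)) + coeff
    return {k: v for k, v in out.items() if v != 0}


def add_vec(a: VecF, b: VecF, scale: Fraction = Fraction(1)) -> VecF:
    out = dict(a)
    for k, v in b.items():
        out[k] = out.get(k, Fraction(0)) + scale * v
        if out[k] == 0:
            del out[k]
    return out
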