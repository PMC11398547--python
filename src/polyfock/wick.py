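"""Brute-force contraction enumeration and factory/gallery equivalence checks.

A *productive-ordered* product has all compound presence operators to the left
of all creation operators; it equals the sum of all normally ordered
contractions.  This module enumerates contraction schemes of products of the
form (join factor)^p (monomer creation)^q for two systems:

* ``homodimer``: each join factor carries two equivalent presence slots linked
  by a symmetric bond; each creation slot may absorb at most one contraction.
* ``homopolymer``: each join factor carries one head-port and one tail-port
  presence slot linked by a directed bond; each creation slot may absorb at
  most one contraction per port side (zero, one, or two in total).

The matrix route (:func:`factory_gallery_check`) evaluates e^{F_L}...e^{F_1}|0>
exactly with rational arithmetic on the small-N Fock space and compares it
coordinatewise with the gallery sum over all complex species.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .fock import (
    CompiledModel,
    Mode,
    VecF,
    add_vec,
    apply_factors_vec,
    compile_model,
    make_mode,
)
from .model import ModelSpec

__all__ = [
    "LabeledProduct",
    "ContractionScheme",
    "make_product",
    "enumerate_contractions",
    "count_schemes_by_topology",
    "factory_apply_vacuum",
    "factory_state",
    "homodimer_gallery_state",
    "homopolymer_gallery_state",
    "factory_gallery_check",
]

GUARD_P = 4
GUARD_Q = 10

SYSTEMS = ("homodimer", "homopolymer")


@dataclass(frozen=True)
class PresenceSlot:
    factor: int  # which join factor
    port: str  # "a" or "b" (homodimer: both slots port "a")


@dataclass(frozen=True)
class LabeledProduct:
    """Productive-ordered product: p join factors left of q creation slots."""

    system: str
    p: int
    q: int

    @property
    def presence_slots(self) -> Tuple[PresenceSlot, ...]:
        if self.system == "homodimer":
            return tuple(
                PresenceSlot(f, port) for f in range(self.p) for port in ("a", "a2")
            )
        return tuple(
            PresenceSlot(f, port) for f in range(self.p) for port in ("a", "b")
        )

    @property
    def creation_slots(self) -> Tuple[int, ...]:
        return tuple(range(self.q))


ContractionScheme = FrozenSet[Tuple[PresenceSlot, int]]


def make_product(system: str, p: int, q: int) -> LabeledProduct:
    if system not in SYSTEMS:
        raise ValueError(f"system must be one of {SYSTEMS}")
    if p > GUARD_P or q > GUARD_Q:
        raise ValueError(f"guard exceeded: p <= {GUARD_P}, q <= {GUARD_Q}")
    return LabeledProduct(system, p, q)


def _creation_capacity_ok(system: str, pairs: Sequence[Tuple[PresenceSlot, int]]) -> bool:
    if system == "homodimer":
        used = [c for _, c in pairs]
        return len(used) == len(set(used))
    # homopolymer: at most one a-side and one b-side contraction per creation
    seen = set()
    for slot, c in pairs:
        key = (c, slot.port)
        if key in seen:
            return False
        seen.add(key)
    return True


def enumerate_contractions(
    prod: LabeledProduct, complete_only: bool = False
) -> List[Dict]:
    """Exhaustively enumerate contraction schemes of a productive-ordered product.

    Each result carries the scheme, the uncontracted presence/creation slots
    (the residual normally ordered term), and a per-factor contraction count.
    """
    pres = prod.presence_slots
    out: List[Dict] = []

    def emit(pairs: List[Tuple[PresenceSlot, int]]) -> None:
        scheme: ContractionScheme = frozenset(pairs)
        contracted_pres = {s for s, _ in pairs}
        per_factor = [0] * prod.p
        for s, _ in pairs:
            per_factor[s.factor] += 1
        used_creations: Dict[int, List[str]] = {}
        for s, c in pairs:
            used_creations.setdefault(c, []).append(s.port)
        out.append(
            {
                "scheme": scheme,
                "residual_presence": tuple(s for s in pres if s not in contracted_pres),
                "residual_creations": tuple(
                    c for c in prod.creation_slots if c not in used_creations
                ),
                "per_factor": tuple(per_factor),
                "creation_usage": used_creations,
            }
        )

    def rec(i: int, pairs: List[Tuple[PresenceSlot, int]]) -> None:
        if i == len(pres):
            emit(pairs)
            return
        slot = pres[i]
        if not complete_only:
            rec(i + 1, pairs)  # leave this presence slot uncontracted
        for c in prod.creation_slots:
            cand = pairs + [(slot, c)]
            if _creation_capacity_ok(prod.system, cand):
                rec(i + 1, cand)

    rec(0, [])
    return out


def count_schemes_by_topology(
    p: int, q: int, system: str = "homodimer", topology: str = "all"
) -> int:
    """Number of contraction schemes whose residual matches a topology class.

    Topology tags:
      ``all``              -- every scheme
      ``none``             -- no contractions
      ``same-factor-double`` -- exactly two contractions, both on one join factor
      ``cross-factor-double`` -- exactly two contractions on different factors
      ``single``           -- exactly one contraction
      ``fully-contracted`` -- every presence slot contracted
    """
    prod = make_product(system, p, q)
    n = 0
    for term in enumerate_contractions(prod):
        total = len(term["scheme"])
        pf = term["per_factor"]
        if topology == "all":
            match = True
        elif topology == "none":
            match = total == 0
        elif topology == "single":
            match = total == 1
        elif topology == "same-factor-double":
            match = total == 2 and max(pf, default=0) == 2
        elif topology == "cross-factor-double":
            match = total == 2 and max(pf, default=0) == 1
        elif topology == "fully-contracted":
            match = len(term["residual_presence"]) == 0
        else:
            raise ValueError(f"unknown topology tag {topology!r}")
        if match:
            n += 1
    return n


def factory_apply_vacuum(p: int, q: int, system: str = "homodimer") -> Dict:
    """Macrostate decomposition of (F2^p/p!) (F1^q/q!) |0> by contraction counting.

    Residual terms containing presence slots vanish on the vacuum, so only
    complete schemes survive.  For the homodimer every complete scheme leaves
    the same residual (p dimers, q-2p monomers); the returned coefficient is
    (#complete schemes) * p! (q-2p)! / (p! q!) as a Fraction.
    """
    if system != "homodimer":
        raise NotImplementedError("closed-form macrostates implemented for homodimer")
    prod = make_product(system, p, q)
    if q < 2 * p:
        return {}
    complete = enumerate_contractions(prod, complete_only=True)
    m = q - 2 * p
    coeff = Fraction(len(complete)) * Fraction(
        math.factorial(p) * math.factorial(m), math.factorial(p) * math.factorial(q)
    )
    if coeff == 0:
        return {}
    return {(m, p): coeff}


# ---------------------------------------------------------------------------
# Matrix route: exact factory and gallery states on the small-N Fock space
# ---------------------------------------------------------------------------


def _exp_apply(cm: CompiledModel, terms: List[List[Tuple[str, Mode]]], vec: VecF,
               scale: Fraction = Fraction(1)) -> VecF:
    """Apply e^{scale * sum(terms)} to an exact vector (nilpotent series)."""
    out = dict(vec)
    cur = dict(vec)
    k = 0
    while cur:
        k += 1
        nxt: VecF = {}
        for factors in terms:
            piece = apply_factors_vec(cm, factors, cur)
            nxt = add_vec(nxt, piece)
        cur = {m: c * scale / k for m, c in nxt.items() if c * scale != 0}
        out = add_vec(out, cur)
        if k > 200:  # pragma: no cover - nilpotency bound
            raise RuntimeError("exponential series failed to terminate")
    return out


def _factory_terms(cm: CompiledModel) -> List[Tuple[List[List[Tuple[str, Mode]]], Fraction]]:
    """Factory operators (ordered, rightmost applied first) with prefactors.

    Derived from the model's creation-direction rules: the monomer creation
    rule is F1; each bond formation rule is F2 (with prefactor 1/2 for a
    symmetric bond summed over ordered pairs).
    """
    model = cm.model
    factories: List[Tuple[List[List[Tuple[str, Mode]]], Fraction]] = []
    create_rules = [r for r in model.rules if r.name.startswith("create")]
    bind_rules = [r for r in model.rules if r.name.startswith("bind")]
    from .fock import instantiate_rules

    for r in create_rules:
        terms = [inst.modes_touched for inst in instantiate_rules(r, model.N, model)]
        factories.append(([list(t) for t in terms], Fraction(1)))
    for r in bind_rules:
        insts = instantiate_rules(r, model.N, model)
        # symmetric bonds instantiated with i<j: the paper's (1/2) sum over
        # ordered pairs equals the unordered sum, prefactor 1
        terms = [list(inst.modes_touched) for inst in insts]
        factories.append((terms, Fraction(1)))
    return factories


def factory_state(model: ModelSpec) -> VecF:
    """e^{F_L} ... e^{F_1} |0> computed exactly (F1 = creations first)."""
    cm = compile_model(model)
    vec: VecF = {0: Fraction(1)}
    for terms, scale in _factory_terms(cm):
        vec = _exp_apply(cm, terms, vec, scale)
    return vec


def homodimer_gallery_state(model: ModelSpec) -> VecF:
    """Sum over macrostates |m, d> with m + 2d <= N, built from gallery operators."""
    cm = compile_model(model)
    N = model.N
    mono = [
        [("create", make_mode(model, "A", (i,))), ("absence", make_mode(model, "a", (i,)))]
        for i in range(1, N + 1)
    ]
    dimer = []
    for i in range(1, N + 1):
        for j in range(i + 1, N + 1):
            dimer.append(
                [
                    ("create", make_mode(model, "I", (i, j))),
                    ("create", make_mode(model, "a", (i,))),
                    ("create", make_mode(model, "a", (j,))),
                    ("create", make_mode(model, "A", (i,))),
                    ("create", make_mode(model, "A", (j,))),
                ]
            )

    def apply_field(terms, vec):
        out: VecF = {}
        for factors in terms:
            out = add_vec(out, apply_factors_vec(cm, factors, vec))
        return out

    total: VecF = {}
    for d in range(N // 2 + 1):
        for m in range(N - 2 * d + 1):
            vec: VecF = {0: Fraction(1)}
            for k in range(1, d + 1):
                vec = apply_field(dimer, vec)
                vec = {s: c / k for s, c in vec.items()}
            for k in range(1, m + 1):
                vec = apply_field(mono, vec)
                vec = {s: c / k for s, c in vec.items()}
            total = add_vec(total, vec)
    return total


def _homopolymer_chain_terms(model: ModelSpec, x: int) -> List[List[Tuple[str, Mode]]]:
    """All labeled x-chain creation products (distinct particle index tuples)."""
    N = model.N
    out = []
    for tup in itertools.permutations(range(1, N + 1), x):
        factors: List[Tuple[str, Mode]] = []
        for i in tup:
            factors.append(("create", make_mode(model, "A", (i,))))
        for i in tup[:-1]:
            factors.append(("create", make_mode(model, "a", (i,))))
        for i in tup[1:]:
            factors.append(("create", make_mode(model, "b", (i,))))
        for u, v in zip(tup, tup[1:]):
            factors.append(("create", make_mode(model, "J", (u, v))))
        out.append(factors)
    return out


def _homopolymer_ring_terms(model: ModelSpec, x: int) -> List[List[Tuple[str, Mode]]]:
    N = model.N
    out = []
    for tup in itertools.permutations(range(1, N + 1), x):
        factors: List[Tuple[str, Mode]] = []
        for i in tup:
            factors.append(("create", make_mode(model, "A", (i,))))
            factors.append(("create", make_mode(model, "a", (i,))))
            factors.append(("create", make_mode(model, "b", (i,))))
        pairs = list(zip(tup, tup[1:])) + [(tup[-1], tup[0])]
        for u, v in pairs:
            factors.append(("create", make_mode(model, "J", (u, v))))
        out.append(factors)
    return out


def homopolymer_gallery_state(model: ModelSpec) -> VecF:
    """Sum over all chain/ring-product macrostates for the homopolymer at small N.

    Chain operators sum over distinct index tuples; ring operators carry the
    1/x rotational symmetry factor.  Rings of length 1 require the model's
    bond field to allow self pairs.
    """
    cm = compile_model(model)
    N = model.N
    allow_self = model.field("J").allow_self

    chain_ops = {x: _homopolymer_chain_terms(model, x) for x in range(1, N + 1)}
    ring_min = 1 if allow_self else 2
    ring_ops = {x: _homopolymer_ring_terms(model, x) for x in range(ring_min, N + 1)}

    def apply_field(terms, vec, scale=Fraction(1)):
        out: VecF = {}
        for factors in terms:
            out = add_vec(out, apply_factors_vec(cm, factors, vec))
        return {s: c * scale for s, c in out.items()}

    species = [("C", x) for x in chain_ops] + [("R", x) for x in ring_ops]
    weights = {("C", x): x for x in chain_ops} | {("R", x): x for x in ring_ops}

    total: VecF = {}

    def rec(i: int, budget: int, vec: VecF, counts: Dict) -> None:
        nonlocal total
        if i == len(species):
            total = add_vec(total, vec)
            return
        kind, x = species[i]
        w = weights[(kind, x)]
        cur = vec
        n = 0
        while True:
            rec(i + 1, budget - n * w, cur, counts)
            n += 1
            if n * w > budget:
                break
            terms = chain_ops[x] if kind == "C" else ring_ops[x]
            scale = Fraction(1, x) if kind == "R" else Fraction(1)
            cur = apply_field(terms, cur, scale)
            cur = {s: c / n for s, c in cur.items()}
            if not cur:
                break
    rec(0, N, {0: Fraction(1)}, {})
    return total


def factory_gallery_check(
    model: ModelSpec, gallery: Optional[VecF] = None
) -> Tuple[bool, Fraction]:
    """Compare the factory state with the gallery sum; exact integer equality.

    Returns (equal, max absolute coefficient deviation).
    """
    fac = factory_state(model)
    if gallery is None:
        n_sites = sum(1 for f in model.fields if f.kind == "site")
        if n_sites == 1:
            gallery = homodimer_gallery_state(model)
        else:
            gallery = homopolymer_gallery_state(model)
    keys = set(fac) | set(gallery)
    max_dev = Fraction(0)
    for k in keys:
        dev = abs(fac.get(k, Fraction(0)) - gallery.get(k, Fraction(0)))
        if dev > max_dev:
            max_dev = dev
    return max_dev == 0, max_dev
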