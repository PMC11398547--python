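"""Textual model format: fields, rules, rates, Hamiltonian coefficients, initial state.

A model is a plain-text, line-oriented description of a chemical system built
from three kinds of hard-core boson fields:

* ``particle`` fields -- one mode per internal particle index,
* ``site`` fields -- binding sites hosted on a particle field,
* ``bond`` fields -- pairwise interactions between two site fields, either
  symmetric (``a--a``) or directed (``a->b``).

Rules are ordered products of mode-operator factors, one of four kinds per
factor: create (``+``), annihilate (``-``), presence (``?``), absence (``~``).

Example::

    [params]
    N = 4

    [fields]
    A : particle
    a : site on A
    I : bond(a--a)

    [rules]
    create  : 1.0 : +A(i) ~a(i)
    destroy : 1.0 : -A(i) ~a(i)
    bind    : 1.0 : ?A(i) ?A(j) +a(i) +a(j) +I(i,j) | i<j
    unbind  : 1.0 : ?A(i) ?A(j) -a(i) -a(j) -I(i,j) | i<j

    [hamiltonian]
    A : -1.0
    I : 0.5

    [init]
    A(2) A(3) A(5) A(7)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence, Tuple

__all__ = [
    "FieldSpec",
    "RuleFactor",
    "RuleTemplate",
    "HamiltonianTerm",
    "ModelSpec",
    "ModelError",
    "parse_model",
    "render_model",
    "builtin_fixture",
    "conjugate_template",
    "FIXTURE_NAMES",
]

OP_KINDS = ("create", "annihilate", "presence", "absence")
_OP_SIGIL = {"+": "create", "-": "annihilate", "?": "presence", "~": "absence"}
_SIGIL_OP = {v: k for k, v in _OP_SIGIL.items()}

CONSTRAINTS = ("ordered", "distinct", None)  # "| i<j", "| i!=j", unconstrained


class ModelError(ValueError):
    """Raised for syntax or validation errors in a model definition."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class FieldSpec:
    """Declaration of one hard-core boson field."""

    name: str
    kind: str  # particle | site | bond
    host: Optional[str] = None  # for sites: host particle field
    endpoints: Optional[Tuple[str, str]] = None  # for bonds: site-field names
    symmetric: bool = False  # bonds only
    allow_self: bool = False  # bonds only: admit index pair (i, i)

    @property
    def arity(self) -> int:
        return 2 if self.kind == "bond" else 1


@dataclass(frozen=True)
class RuleFactor:
    """One mode-operator factor of a rule template."""

    op: str  # create | annihilate | presence | absence
    field: str
    index_vars: Tuple[str, ...]

    def __str__(self) -> str:
        return f"{_SIGIL_OP[self.op]}{self.field}({','.join(self.index_vars)})"


@dataclass(frozen=True)
class RuleTemplate:
    """An indexed product of mode operators with a per-instance rate."""

    name: str
    rate: float
    factors: Tuple[RuleFactor, ...]
    constraint: Optional[str] = None  # "ordered" (i<j), "distinct" (i!=j), None

    @property
    def index_vars(self) -> Tuple[str, ...]:
        seen: list[str] = []
        for f in self.factors:
            for v in f.index_vars:
                if v not in seen:
                    seen.append(v)
        return tuple(seen)


@dataclass(frozen=True)
class HamiltonianTerm:
    """Energy coefficient on the excitation count of one field.

    The Hamiltonian is diagonal: ``H(s) = sum_terms coeff * n_field(s)`` where
    ``n_field(s)`` is the number of excited modes of ``field`` in microstate s.
    """

    field: str
    coeff: float


@dataclass(frozen=True)
class ModelSpec:
    N: int
    fields: Tuple[FieldSpec, ...]
    rules: Tuple[RuleTemplate, ...] = ()
    hamiltonian: Tuple[HamiltonianTerm, ...] = ()
    init: Tuple[Tuple[str, Tuple[int, ...]], ...] = ()

    def field(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise ModelError(f"undeclared field {name!r}")

    @property
    def field_names(self) -> Tuple[str, ...]:
        return tuple(f.name for f in self.fields)

    def validate(self) -> "ModelSpec":
        if self.N < 1:
            raise ModelError(f"N must be positive, got {self.N}")
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise ModelError("duplicate field names")
        by_name = {f.name: f for f in self.fields}
        for f in self.fields:
            if f.kind == "site":
                if f.host not in by_name or by_name[f.host].kind != "particle":
                    raise ModelError(
                        f"site field {f.name!r} must reference a particle field, "
                        f"got host {f.host!r}"
                    )
            elif f.kind == "bond":
                if f.endpoints is None or len(f.endpoints) != 2:
                    raise ModelError(f"bond field {f.name!r} needs two endpoints")
                for e in f.endpoints:
                    if e not in by_name or by_name[e].kind not in ("site", "particle"):
                        raise ModelError(
                            f"bond field {f.name!r} endpoint {e!r} must be a "
                            "declared site or particle field"
                        )
                if f.symmetric and f.endpoints[0] != f.endpoints[1]:
                    raise ModelError(
                        f"symmetric bond {f.name!r} must join a site field to itself"
                    )
            elif f.kind != "particle":
                raise ModelError(f"unknown field kind {f.kind!r}")
        for rule in self.rules:
            if rule.rate < 0:
                raise ModelError(f"rule {rule.name!r} has negative rate {rule.rate}")
            seen: set[Tuple[str, Tuple[str, ...]]] = set()
            for fac in rule.factors:
                if fac.field not in by_name:
                    raise ModelError(
                        f"rule {rule.name!r} references undeclared field {fac.field!r}"
                    )
                if len(fac.index_vars) != by_name[fac.field].arity:
                    raise ModelError(
                        f"rule {rule.name!r}: factor {fac} has arity "
                        f"{len(fac.index_vars)}, field expects {by_name[fac.field].arity}"
                    )
                key = (fac.field, fac.index_vars)
                if key in seen:
                    raise ModelError(
                        f"rule {rule.name!r} touches mode {key} in two factors"
                    )
                seen.add(key)
            if rule.constraint == "ordered" and len(rule.index_vars) != 2:
                raise ModelError(
                    f"rule {rule.name!r}: 'i<j' constraint needs exactly two index "
                    "variables"
                )
        for term in self.hamiltonian:
            if term.field not in by_name:
                raise ModelError(f"Hamiltonian references undeclared field {term.field!r}")
        for fname, idx in self.init:
            if fname not in by_name:
                raise ModelError(f"init references undeclared field {fname!r}")
            spec = by_name[fname]
            if len(idx) != spec.arity:
                raise ModelError(f"init {fname}{idx}: wrong arity")
            for i in idx:
                if not 1 <= i <= self.N:
                    raise ModelError(f"init {fname}{idx}: index out of range 1..{self.N}")
        return self


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_FIELD_RE = re.compile(
    r"^(?P<name>\w+)\s*:\s*(?:"
    r"(?P<particle>particle)"
    r"|site\s+on\s+(?P<host>\w+)"
    r"|bond\(\s*(?P<e1>\w+)\s*(?P<dir>--|->)\s*(?P<e2>\w+)\s*\)(?P<self>\s*\[self\])?"
    r")\s*$"
)
_FACTOR_RE = re.compile(r"^(?P<op>[+\-?~])(?P<field>\w+)\((?P<vars>[\w,\s]+)\)$")
_INIT_RE = re.compile(r"^(?P<field>\w+)\((?P<idx>[\d,\s]+)\)$")


def _strip(line: str) -> str:
    return line.split("#", 1)[0].strip()


def parse_model(text: str) -> ModelSpec:
    """Parse the plain-text model format into a validated :class:`ModelSpec`."""
    section = None
    N: Optional[int] = None
    fields: list[FieldSpec] = []
    rules: list[RuleTemplate] = []
    ham: list[HamiltonianTerm] = []
    init: list[Tuple[str, Tuple[int, ...]]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip(raw)
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("params", "fields", "rules", "hamiltonian", "init"):
                raise ModelError(f"unknown section [{section}]", lineno)
            continue
        if section == "params":
            m = re.match(r"^N\s*=\s*(\d+)$", line)
            if not m:
                raise ModelError(f"bad params line {line!r}", lineno)
            N = int(m.group(1))
        elif section == "fields":
            m = _FIELD_RE.match(line)
            if not m:
                raise ModelError(f"bad field declaration {line!r}", lineno)
            if m.group("particle"):
                fields.append(FieldSpec(m.group("name"), "particle"))
            elif m.group("host"):
                fields.append(FieldSpec(m.group("name"), "site", host=m.group("host")))
            else:
                fields.append(
                    FieldSpec(
                        m.group("name"),
                        "bond",
                        endpoints=(m.group("e1"), m.group("e2")),
                        symmetric=m.group("dir") == "--",
                        allow_self=m.group("self") is not None,
                    )
                )
        elif section == "rules":
            rules.append(_parse_rule(line, lineno))
        elif section == "hamiltonian":
            m = re.match(r"^(\w+)\s*:\s*([-+0-9.eE]+)$", line)
            if not m:
                raise ModelError(f"bad hamiltonian line {line!r}", lineno)
            ham.append(HamiltonianTerm(m.group(1), float(m.group(2))))
        elif section == "init":
            for token in line.split():
                m = _INIT_RE.match(token)
                if not m:
                    raise ModelError(f"bad init token {token!r}", lineno)
                idx = tuple(int(x) for x in m.group("idx").replace(",", " ").split())
                init.append((m.group("field"), idx))
        else:
            raise ModelError(f"content outside any section: {line!r}", lineno)

    if N is None:
        raise ModelError("missing [params] N")
    return ModelSpec(
        N=N,
        fields=tuple(fields),
        rules=tuple(rules),
        hamiltonian=tuple(ham),
        init=tuple(init),
    ).validate()


def _parse_rule(line: str, lineno: int) -> RuleTemplate:
    constraint = None
    if "|" in line:
        line, tail = line.rsplit("|", 1)
        tail = tail.strip().replace(" ", "")
        if tail == "i<j":
            constraint = "ordered"
        elif tail == "i!=j":
            constraint = "distinct"
        else:
            raise ModelError(f"unknown constraint {tail!r}", lineno)
    parts = [p.strip() for p in line.split(":", 2)]
    if len(parts) != 3:
        raise ModelError(f"rule line must be 'name : rate : factors', got {line!r}", lineno)
    name, rate_s, factors_s = parts
    try:
        rate = float(rate_s)
    except ValueError:
        raise ModelError(f"bad rate {rate_s!r}", lineno) from None
    if rate < 0:
        raise ModelError(f"negative rate {rate}", lineno)
    factors = []
    for token in factors_s.split():
        m = _FACTOR_RE.match(token)
        if not m:
            raise ModelError(f"bad factor {token!r}", lineno)
        ivars = tuple(v.strip() for v in m.group("vars").split(","))
        factors.append(RuleFactor(_OP_SIGIL[m.group("op")], m.group("field"), ivars))
    return RuleTemplate(name, rate, tuple(factors), constraint)


def render_model(spec: ModelSpec) -> str:
    """Render a ModelSpec back to text. ``parse_model(render_model(s)) == s``."""
    out = ["[params]", f"N = {spec.N}", "", "[fields]"]
    for f in spec.fields:
        if f.kind == "particle":
            out.append(f"{f.name} : particle")
        elif f.kind == "site":
            out.append(f"{f.name} : site on {f.host}")
        else:
            arrow = "--" if f.symmetric else "->"
            suffix = " [self]" if f.allow_self else ""
            out.append(f"{f.name} : bond({f.endpoints[0]}{arrow}{f.endpoints[1]}){suffix}")
    if spec.rules:
        out += ["", "[rules]"]
        for r in spec.rules:
            factors = " ".join(str(f) for f in r.factors)
            tail = ""
            if r.constraint == "ordered":
                tail = " | i<j"
            elif r.constraint == "distinct":
                tail = " | i!=j"
            out.append(f"{r.name} : {r.rate!r} : {factors}{tail}")
    if spec.hamiltonian:
        out += ["", "[hamiltonian]"]
        for t in spec.hamiltonian:
            out.append(f"{t.field} : {t.coeff!r}")
    if spec.init:
        out += ["", "[init]"]
        out.append(
            " ".join(f"{f}({','.join(str(i) for i in idx)})" for f, idx in spec.init)
        )
    return "\n".join(out) + "\n"


def conjugate_template(t: RuleTemplate, name: Optional[str] = None) -> RuleTemplate:
    """Factor-wise conjugate: create <-> annihilate, presence/absence fixed."""
    swap = {"create": "annihilate", "annihilate": "create"}
    factors = tuple(
        replace(f, op=swap.get(f.op, f.op)) for f in t.factors
    )
    return RuleTemplate(name or t.name + "_conj", t.rate, factors, t.constraint)


# ---------------------------------------------------------------------------
# Built-in fixture systems
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "monomer",
    "homodimer",
    "homopolymer",
    "heterodimer",
    "occlusive",
    "cooperative",
    "heteropolymer",
    "branched_homopolymer",
    "isotropic_homopolymer",
)


def _rt(name, rate, spec, constraint=None):
    """Compact rule builder: spec like '+A(i) ~a(i)'."""
    factors = []
    for token in spec.split():
        m = _FACTOR_RE.match(token)
        if not m:  # pragma: no cover - fixture definitions are static
            raise ModelError(f"bad fixture factor {token!r}")
        ivars = tuple(v.strip() for v in m.group("vars").split(","))
        factors.append(RuleFactor(_OP_SIGIL[m.group("op")], m.group("field"), ivars))
    return RuleTemplate(name, rate, tuple(factors), constraint)


def builtin_fixture(
    name: str,
    N: int,
    rates: Optional[Mapping[str, float]] = None,
    mu: float = 0.0,
    eps: float = 0.0,
    allow_self: bool = False,
    init: Sequence[Tuple[str, Tuple[int, ...]]] = (),
) -> ModelSpec:
    """Return the ModelSpec for one of the built-in polymer/binding systems.

    ``rates`` overrides per-rule rates by rule name (default 1.0 each).
    ``mu``/``eps`` set the Hamiltonian coefficients for equilibrium use:
    every particle field carries energy -mu per particle and every bond field
    +eps per bond.
    """
    if name not in FIXTURE_NAMES:
        raise ModelError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    rates = dict(rates or {})

    def rate(rule_name: str) -> float:
        return float(rates.pop(rule_name, 1.0))

    fields: list[FieldSpec]
    rules: list[RuleTemplate]

    if name == "monomer":
        fields = [FieldSpec("A", "particle")]
        rules = [
            _rt("create", rate("create"), "+A(i)"),
            _rt("destroy", rate("destroy"), "-A(i)"),
        ]
    elif name == "homodimer":
        fields = [
            FieldSpec("A", "particle"),
            FieldSpec("a", "site", host="A"),
            FieldSpec("I", "bond", endpoints=("a", "a"), symmetric=True),
        ]
        rules = [
            _rt("create", rate("create"), "+A(i) ~a(i)"),
            _rt("destroy", rate("destroy"), "-A(i) ~a(i)"),
            _rt("bind", rate("bind"), "?A(i) ?A(j) +a(i) +a(j) +I(i,j)", "ordered"),
            _rt("unbind", rate("unbind"), "?A(i) ?A(j) -a(i) -a(j) -I(i,j)", "ordered"),
        ]
    elif name == "homopolymer":
        fields = [
            FieldSpec("A", "particle"),
            FieldSpec("a", "site", host="A"),
            FieldSpec("b", "site", host="A"),
            FieldSpec("J", "bond", endpoints=("a", "b"), allow_self=allow_self),
        ]
        constraint = None if allow_self else "distinct"
        rules = [
            _rt("create", rate("create"), "+A(i) ~a(i) ~b(i)"),
            _rt("destroy", rate("destroy"), "-A(i) ~a(i) ~b(i)"),
            _rt("bind", rate("bind"), "?A(i) ?A(j) +a(i) +b(j) +J(i,j)", constraint),
            _rt("unbind", rate("unbind"), "?A(i) ?A(j) -a(i) -b(j) -J(i,j)", constraint),
        ]
    elif name == "heterodimer":
        fields = [
            FieldSpec("A", "particle"),
            FieldSpec("B", "particle"),
            FieldSpec("a", "site", host="A"),
            FieldSpec("b", "site", host="B"),
            FieldSpec("I", "bond", endpoints=("a", "b")),
        ]
        rules = [
            _rt("createA", rate("createA"), "+A(i) ~a(i)"),
            _rt("destroyA", rate("destroyA"), "-A(i) ~a(i)"),
            _rt("createB", rate("createB"), "+B(i) ~b(i)"),
            _rt("destroyB", rate("destroyB"), "-B(i) ~b(i)"),
            _rt("bind", rate("bind"), "?A(i) ?B(j) +a(i) +b(j) +I(i,j)"),
            _rt("unbind", rate("unbind"), "?A(i) ?B(j) -a(i) -b(j) -I(i,j)"),
        ]
    elif name == "occlusive":
        # B and C compete for the single site a on A.
        fields = [
            FieldSpec("A", "particle"),
            FieldSpec("B", "particle"),
            FieldSpec("C", "particle"),
            FieldSpec("a", "site", host="A"),
            FieldSpec("b", "site", host="B"),
            FieldSpec("c", "site", host="C"),
            FieldSpec("I", "bond", endpoints=("a", "b")),
            FieldSpec("J", "bond", endpoints=("a", "c")),
        ]
        rules = [
            _rt("createA", rate("createA"), "+A(i) ~a(i)"),
            _rt("destroyA", rate("destroyA"), "-A(i) ~a(i)"),
            _rt("createB", rate("createB"), "+B(i) ~b(i)"),
            _rt("destroyB", rate("destroyB"), "-B(i) ~b(i)"),
            _rt("createC", rate("createC"), "+C(i) ~c(i)"),
            _rt("destroyC", rate("destroyC"), "-C(i) ~c(i)"),
            _rt("bindB", rate("bindB"), "?A(i) ?B(j) +a(i) +b(j) +I(i,j)"),
            _rt("unbindB", rate("unbindB"), "?A(i) ?B(j) -a(i) -b(j) -I(i,j)"),
            _rt("bindC", rate("bindC"), "?A(i) ?C(j) +a(i) +c(j) +J(i,j)"),
            _rt("unbindC", rate("unbindC"), "?A(i) ?C(j) -a(i) -c(j) -J(i,j)"),
        ]
    elif name == "cooperative":
        # C binds site v of A at different rates depending on whether B
        # occupies site u; the u-conditioned rule pairs are mutually exclusive.
        fields = [
            FieldSpec("A", "particle"),
            FieldSpec("B", "particle"),
            FieldSpec("C", "particle"),
            FieldSpec("u", "site", host="A"),
            FieldSpec("v", "site", host="A"),
            FieldSpec("b", "site", host="B"),
            FieldSpec("c", "site", host="C"),
            FieldSpec("I", "bond", endpoints=("u", "b")),
            FieldSpec("J", "bond", endpoints=("v", "c")),
        ]
        rules = [
            _rt("createA", rate("createA"), "+A(i) ~u(i) ~v(i)"),
            _rt("destroyA", rate("destroyA"), "-A(i) ~u(i) ~v(i)"),
            _rt("createB", rate("createB"), "+B(i) ~b(i)"),
            _rt("destroyB", rate("destroyB"), "-B(i) ~b(i)"),
            _rt("createC", rate("createC"), "+C(i) ~c(i)"),
            _rt("destroyC", rate("destroyC"), "-C(i) ~c(i)"),
            _rt("bindB", rate("bindB"), "?A(i) ?B(j) +u(i) +b(j) +I(i,j)"),
            _rt("unbindB", rate("unbindB"), "?A(i) ?B(j) -u(i) -b(j) -I(i,j)"),
            _rt("bindC_free", rate("bindC_free"), "?A(i) ?C(j) ~u(i) +v(i) +c(j) +J(i,j)"),
            _rt("unbindC_free", rate("unbindC_free"), "?A(i) ?C(j) ~u(i) -v(i) -c(j) -J(i,j)"),
            _rt("bindC_coop", rate("bindC_coop"), "?A(i) ?C(j) ?u(i) +v(i) +c(j) +J(i,j)"),
            _rt("unbindC_coop", rate("unbindC_coop"), "?A(i) ?C(j) ?u(i) -v(i) -c(j) -J(i,j)"),
        ]
    elif name == "heteropolymer":
        # Alternating A-B chains: I joins A.a to B.d, J joins B.c to A.b.
        fields = [
            FieldSpec("A", "particle"),
            FieldSpec("B", "particle"),
            FieldSpec("a", "site", host="A"),
            FieldSpec("b", "site", host="A"),
            FieldSpec("c", "site", host="B"),
            FieldSpec("d", "site", host="B"),
            FieldSpec("I", "bond", endpoints=("a", "d")),
            FieldSpec("J", "bond", endpoints=("c", "b")),
        ]
        rules = [
            _rt("createA", rate("createA"), "+A(i) ~a(i) ~b(i)"),
            _rt("destroyA", rate("destroyA"), "-A(i) ~a(i) ~b(i)"),
            _rt("createB", rate("createB"), "+B(i) ~c(i) ~d(i)"),
            _rt("destroyB", rate("destroyB"), "-B(i) ~c(i) ~d(i)"),
            _rt("bindI", rate("bindI"), "?A(i) ?B(j) +a(i) +d(j) +I(i,j)"),
            _rt("unbindI", rate("unbindI"), "?A(i) ?B(j) -a(i) -d(j) -I(i,j)"),
            _rt("bindJ", rate("bindJ"), "?B(i) ?A(j) +c(i) +b(j) +J(i,j)"),
            _rt("unbindJ", rate("unbindJ"), "?B(i) ?A(j) -c(i) -b(j) -J(i,j)"),
        ]
    elif name == "branched_homopolymer":
        # Each particle has two child slots (a via I, b via J) and one parent
        # slot (c); trees branch out from a particle whose c site is free.
        fields = [
            FieldSpec("A", "particle"),
            FieldSpec("a", "site", host="A"),
            FieldSpec("b", "site", host="A"),
            FieldSpec("c", "site", host="A"),
            FieldSpec("I", "bond", endpoints=("a", "c"), allow_self=allow_self),
            FieldSpec("J", "bond", endpoints=("b", "c"), allow_self=allow_self),
        ]
        constraint = None if allow_self else "distinct"
        rules = [
            _rt("create", rate("create"), "+A(i) ~a(i) ~b(i) ~c(i)"),
            _rt("destroy", rate("destroy"), "-A(i) ~a(i) ~b(i) ~c(i)"),
            _rt("bindI", rate("bindI"), "?A(i) ?A(j) +a(i) +c(j) +I(i,j)", constraint),
            _rt("unbindI", rate("unbindI"), "?A(i) ?A(j) -a(i) -c(j) -I(i,j)", constraint),
            _rt("bindJ", rate("bindJ"), "?A(i) ?A(j) +b(i) +c(j) +J(i,j)", constraint),
            _rt("unbindJ", rate("unbindJ"), "?A(i) ?A(j) -b(i) -c(j) -J(i,j)", constraint),
        ]
    else:  # isotropic_homopolymer
        # Two symmetric interaction classes: I joins a-sites, J joins b-sites,
        # so I and J alternate along every multimer and rings have even length.
        fields = [
            FieldSpec("A", "particle"),
            FieldSpec("a", "site", host="A"),
            FieldSpec("b", "site", host="A"),
            FieldSpec("I", "bond", endpoints=("a", "a"), symmetric=True),
            FieldSpec("J", "bond", endpoints=("b", "b"), symmetric=True),
        ]
        rules = [
            _rt("create", rate("create"), "+A(i) ~a(i) ~b(i)"),
            _rt("destroy", rate("destroy"), "-A(i) ~a(i) ~b(i)"),
            _rt("bindI", rate("bindI"), "?A(i) ?A(j) +a(i) +a(j) +I(i,j)", "ordered"),
            _rt("unbindI", rate("unbindI"), "?A(i) ?A(j) -a(i) -a(j) -I(i,j)", "ordered"),
            _rt("bindJ", rate("bindJ"), "?A(i) ?A(j) +b(i) +b(j) +J(i,j)", "ordered"),
            _rt("unbindJ", rate("unbindJ"), "?A(i) ?A(j) -b(i) -b(j) -J(i,j)", "ordered"),
        ]

    if rates:
        raise ModelError(f"unknown rate keys for fixture {name!r}: {sorted(rates)}")

    ham = []
    for f in fields:
        if f.kind == "particle" and mu != 0.0:
            ham.append(HamiltonianTerm(f.name, -mu))
        elif f.kind == "bond" and eps != 0.0:
            ham.append(HamiltonianTerm(f.name, eps))
    return ModelSpec(
        N=N,
        fields=tuple(fields),
        rules=tuple(rules),
        hamiltonian=tuple(ham),
        init=tuple(init),
    ).validate()
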