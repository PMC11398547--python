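"""Microstate transition generator, exact propagation, and macrostate dynamics.

The generator is built from rule instances on a reachable state space:
for every state and every eligible instance, the instance rate enters the
(target, source) off-diagonal entry and is subtracted from the source
diagonal, so every column sums to zero.  Propagation uses a sparse-aware
exponential-times-vector routine.

The macro level implements the combinatorial reaction coefficient
Omega(n, q, p) = prod_k C(n_k + q_k - p_k, q_k) * 1[n_k >= p_k],
a species-based flux projector with per-reaction multiplicities sigma,
and the truncated chain/ring count-vector master equation for the
directed homopolymer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .fock import CompiledModel, Microstate, compile_model
from .model import ModelSpec

__all__ = [
    "StateSpace",
    "StateSpaceCapError",
    "enumerate_reachable",
    "build_generator",
    "propagate",
    "macrostate_distribution",
    "omega_coefficient",
    "GalleryReaction",
    "species_flux_projector",
    "homopolymer_gallery_reactions",
    "homopolymer_macro_rhs",
    "macro_state_space",
    "build_macro_generator",
    "propagate_macro",
    "stationary_distribution",
]

DEFAULT_CAP = 200_000


class StateSpaceCapError(RuntimeError):
    def __init__(self, count: int, cap: int):
        super().__init__(
            f"reachable-state enumeration exceeded cap: reached {count} states "
            f"(cap {cap})"
        )
        self.count = count
        self.cap = cap


@dataclass
class StateSpace:
    """Ordered, reachable set of microstates for one compiled model.

    States are stored as integer bitmasks, sorted ascending; the ordering is
    therefore deterministic for a fixed model.
    """

    compiled: CompiledModel
    masks: np.ndarray  # sorted int64 masks (or object array of python ints)

    def __len__(self) -> int:
        return len(self.masks)

    def index_of(self, mask: int) -> int:
        i = int(np.searchsorted(self.masks, mask))
        if i >= len(self.masks) or int(self.masks[i]) != int(mask):
            raise KeyError(f"state {mask} not in space")
        return i

    def state(self, i: int) -> Microstate:
        return self.compiled.state_of(int(self.masks[i]))

    @property
    def states(self) -> List[Microstate]:
        return [self.state(i) for i in range(len(self))]

    def point_mass(self, mask: Optional[int] = None) -> np.ndarray:
        """Probability vector concentrated on one state (default: the init state)."""
        if mask is None:
            mask = self.compiled.init_mask()
        psi = np.zeros(len(self))
        psi[self.index_of(mask)] = 1.0
        return psi


def enumerate_reachable(
    model: ModelSpec | CompiledModel,
    cap: int = DEFAULT_CAP,
    init_mask: Optional[int] = None,
) -> StateSpace:
    """Breadth-first closure of the initial microstate under all rule instances."""
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    if init_mask is None:
        init_mask = cm.init_mask()
    if cm.n_modes <= 62:
        return _enumerate_reachable_vec(cm, cap, init_mask)
    return _enumerate_reachable_py(cm, cap, init_mask)


def _enumerate_reachable_vec(cm: CompiledModel, cap: int, init_mask: int) -> StateSpace:
    known = np.array([init_mask], dtype=np.int64)
    frontier = known
    while len(frontier):
        new_parts = []
        for k in range(len(cm.instances)):
            ns, nc, fl = int(cm.need_set[k]), int(cm.need_clear[k]), int(cm.flip[k])
            elig = ((frontier & ns) == ns) & ((frontier & nc) == 0)
            if elig.any():
                new_parts.append(frontier[elig] ^ fl)
        if not new_parts:
            break
        cand = np.unique(np.concatenate(new_parts))
        frontier = np.setdiff1d(cand, known, assume_unique=True)
        known = np.union1d(known, frontier)
        if len(known) > cap:
            raise StateSpaceCapError(len(known), cap)
    return StateSpace(cm, known)


def _enumerate_reachable_py(cm: CompiledModel, cap: int, init_mask: int) -> StateSpace:
    known = {init_mask}
    frontier = [init_mask]
    while frontier:
        nxt = []
        for mask in frontier:
            for k in range(len(cm.instances)):
                if cm.eligible_mask(mask, k):
                    tgt = cm.apply_mask(mask, k)
                    if tgt not in known:
                        known.add(tgt)
                        nxt.append(tgt)
                        if len(known) > cap:
                            raise StateSpaceCapError(len(known), cap)
        frontier = nxt
    masks = np.array(sorted(known), dtype=object)
    return StateSpace(cm, masks)


def build_generator(
    model: ModelSpec | CompiledModel,
    space: StateSpace,
    with_provenance: bool = False,
):
    """Sparse generator W over the state space; columns sum to zero exactly.

    With ``with_provenance`` also returns a list of (row, col, instance index)
    for every off-diagonal entry contribution.
    """
    cm = space.compiled
    masks = space.masks
    n = len(masks)
    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    data: List[np.ndarray] = []
    prov: List[Tuple[int, int, int]] = []
    vec = masks.dtype == np.int64
    for k in range(len(cm.instances)):
        rate = float(cm.rates[k])
        if rate == 0.0:
            continue
        if vec:
            ns, nc, fl = int(cm.need_set[k]), int(cm.need_clear[k]), int(cm.flip[k])
            elig = ((masks & ns) == ns) & ((masks & nc) == 0)
            src = np.nonzero(elig)[0]
            if not len(src):
                continue
            tgt_masks = masks[src] ^ fl
            tgt = np.searchsorted(masks, tgt_masks)
            ok = (tgt < n) & (masks[np.minimum(tgt, n - 1)] == tgt_masks)
            if not ok.all():
                raise RuntimeError(
                    "rule instance maps a state outside the space (closure violation)"
                )
        else:
            src_l, tgt_l = [], []
            for i, mask in enumerate(masks):
                if cm.eligible_mask(mask, k):
                    src_l.append(i)
                    tgt_l.append(space.index_of(cm.apply_mask(mask, k)))
            src = np.array(src_l, dtype=np.int64)
            tgt = np.array(tgt_l, dtype=np.int64)
            if not len(src):
                continue
        rows.append(tgt)
        cols.append(src)
        data.append(np.full(len(src), rate))
        rows.append(src)
        cols.append(src)
        data.append(np.full(len(src), -rate))
        if with_provenance:
            prov.extend((int(t), int(s), k) for t, s in zip(tgt, src))
    if rows:
        W = sp.csc_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
    else:
        W = sp.csc_matrix((n, n))
    if with_provenance:
        return W, prov
    return W


def propagate(
    W: sp.spmatrix,
    psi0: np.ndarray,
    times: Sequence[float],
    normalization_tol: float = 1e-9,
) -> np.ndarray:
    """psi(t) = exp(t W) psi(0) at each requested time, shape (len(times), n)."""
    psi0 = np.asarray(psi0, dtype=float)
    if abs(psi0.sum() - 1.0) > normalization_tol or (psi0 < -normalization_tol).any():
        raise ValueError("psi0 is not a normalized probability vector")
    times = np.asarray(times, dtype=float)
    if len(times) and times.min() < 0:
        raise ValueError("times must be nonnegative")
    uniform = (
        len(times) >= 3
        and times[0] == 0.0
        and np.allclose(np.diff(times), times[1] - times[0], rtol=1e-12, atol=0.0)
        and times[1] > times[0]
    )
    if uniform:
        out = expm_multiply(
            W, psi0, start=0.0, stop=float(times[-1]), num=len(times), endpoint=True
        )
    else:
        out = np.empty((len(times), len(psi0)))
        order = np.argsort(times)
        psi = psi0
        t_cur = 0.0
        for pos in order:
            t = float(times[pos])
            dt = t - t_cur
            if dt > 0:
                psi = expm_multiply(W * dt, psi)
            out[pos] = psi
            t_cur = t
    sums = out.sum(axis=1)
    if np.abs(sums - 1.0).max() > normalization_tol:
        raise RuntimeError(
            f"propagation lost probability: max |sum-1| = {np.abs(sums-1.0).max():.2e}"
        )
    return out


def macrostate_distribution(
    psi: np.ndarray,
    space: StateSpace,
    labeler: Callable[[int, CompiledModel], Hashable],
) -> Dict[Hashable, float]:
    """Sum probabilities over microstates sharing a label.

    ``labeler`` receives the integer bitmask and the compiled model and
    returns any hashable label (typically a frozen count vector).
    """
    out: Dict[Hashable, float] = {}
    cm = space.compiled
    for i, mask in enumerate(space.masks):
        lbl = labeler(int(mask), cm)
        out[lbl] = out.get(lbl, 0.0) + float(psi[i])
    return {k: v for k, v in out.items() if v != 0.0}


def stationary_distribution(W: sp.spmatrix) -> np.ndarray:
    """Normalized null vector of a (small) generator, by dense LU of W^T."""
    A = W.toarray()
    n = A.shape[0]
    # Replace one balance equation with normalization.
    M = np.vstack([A, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    x, *_ = np.linalg.lstsq(M, b, rcond=None)
    return x


# ---------------------------------------------------------------------------
# Species-based macro level
# ---------------------------------------------------------------------------

CountVector = Tuple[Tuple[Hashable, int], ...]  # sorted ((species, count), ...)


def freeze_counts(counts: Mapping[Hashable, int]) -> CountVector:
    return tuple(sorted((k, int(v)) for k, v in counts.items() if v))


def _thaw(n: CountVector) -> Dict[Hashable, int]:
    return dict(n)


def omega_coefficient(
    n: Mapping[Hashable, int] | CountVector,
    q: Mapping[Hashable, int] | CountVector,
    p: Mapping[Hashable, int] | CountVector,
) -> int:
    """Omega(n, q, p) = prod_k C(n_k + q_k - p_k, q_k) * 1[n_k >= p_k]."""
    nd = _thaw(n) if not isinstance(n, dict) else n
    qd = _thaw(q) if not isinstance(q, dict) else q
    pd = _thaw(p) if not isinstance(p, dict) else p
    out = 1
    for k in set(qd) | set(pd):
        nk = nd.get(k, 0)
        qk = qd.get(k, 0)
        pk = pd.get(k, 0)
        if qk < 0 or pk < 0:
            raise ValueError("q and p must be componentwise nonnegative")
        if nk < pk:
            return 0
        top = nk + qk - pk
        if top < qk:
            return 0
        out *= math.comb(top, qk)
    return out


@dataclass(frozen=True)
class GalleryReaction:
    """One species-level reaction: reactants q -> products p with multiplicity sigma."""

    rate: float
    q: CountVector
    p: CountVector
    sigma: int


def species_flux_projector(
    reactions: Sequence[GalleryReaction],
    n: Mapping[Hashable, int] | CountVector,
) -> List[Tuple[CountVector, float]]:
    """Terms of the flux projector at macrostate n.

    Returns (m, w) pairs meaning dP(n)/dt receives w * P(m): reaction terms
    sigma*Omega(n,q,p) at m = n+q-p and depletion terms -sigma*Omega(n,q,q)
    at m = n itself.  Depletion multiplicities use sigma (derived from the
    microstate-level depletion operators), not the species mode-count product.
    """
    nd = dict(_thaw(n) if not isinstance(n, dict) else n)
    out: List[Tuple[CountVector, float]] = []
    for rx in reactions:
        qd, pd = dict(rx.q), dict(rx.p)
        if any(k in pd and pd[k] and qd.get(k) for k in qd):
            raise ValueError("q and p must not overlap")
        w_in = rx.rate * rx.sigma * omega_coefficient(nd, qd, pd)
        if w_in:
            src = dict(nd)
            for k, v in qd.items():
                src[k] = src.get(k, 0) + v
            for k, v in pd.items():
                src[k] = src.get(k, 0) - v
            if all(v >= 0 for v in src.values()):
                out.append((freeze_counts(src), w_in))
        w_out = rx.rate * rx.sigma * omega_coefficient(nd, qd, qd)
        if w_out:
            out.append((freeze_counts(nd), -w_out))
    return out


# ---------------------------------------------------------------------------
# Directed homopolymer macro master equation
# ---------------------------------------------------------------------------
#
# Species keys: ("C", x) for x-chains, ("R", x) for x-rings.


def homopolymer_gallery_reactions(
    rates: Tuple[float, float, float, float], N: int, xmax: int
) -> List[GalleryReaction]:
    """All species-level homopolymer reactions with lengths <= xmax.

    Multiplicities: creation sigma=N; monomer annihilation sigma=1; joining of
    distinct or equal-length chains sigma=2; circularization sigma=1;
    splitting into unequal parts sigma=2; into equal halves sigma=1;
    ring opening sigma=x.
    """
    r1, r2, r3, r4 = rates
    F = freeze_counts
    out = [
        GalleryReaction(r1, F({}), F({("C", 1): 1}), N),
        GalleryReaction(r2, F({("C", 1): 1}), F({}), 1),
    ]
    # Joins act on any two chains of length <= xmax (the product may exceed
    # xmax; on a truncated space that flow is the reported truncation flux).
    # Splits act on any chain of length <= xmax.
    for x in range(1, xmax + 1):
        for y in range(x, xmax + 1):
            if x < y:
                q = F({("C", x): 1, ("C", y): 1})
                sigma_join, sigma_split = 2, 2
            else:
                q = F({("C", x): 2})
                sigma_join, sigma_split = 2, 1
            p = F({("C", x + y): 1})
            out.append(GalleryReaction(r3, q, p, sigma_join))
            if x + y <= xmax:
                out.append(GalleryReaction(r4, p, q, sigma_split))
    for x in range(1, xmax + 1):
        q = F({("C", x): 1})
        p = F({("R", x): 1})
        out.append(GalleryReaction(r3, q, p, 1))
        out.append(GalleryReaction(r4, p, q, x))
    return out


def homopolymer_macro_rhs(
    P: Mapping[CountVector, float],
    rates: Tuple[float, float, float, float],
    N: int,
    xmax: int,
) -> Dict[CountVector, float]:
    """dP/dt for the truncated chain/ring count-vector master equation.

    Implements, term by term: monomer creation at total rate N*r1, monomer
    annihilation at r2*c1, chain joining (factor 2 for unequal and equal-length
    pairs), circularization, and the reverse splittings (factor 2 unequal,
    1 equal halves, x for opening an x-ring), with the depletion coefficient
    N*r1 + r2*c1 + r3*nchain^2 + r4*nlink.
    """
    if xmax < 1:
        raise ValueError("xmax must be >= 1")
    r1, r2, r3, r4 = rates
    out: Dict[CountVector, float] = {key: 0.0 for key in P}

    def get(nd: Dict, key) -> int:
        return nd.get(key, 0)

    for n_key, prob in P.items():
        if prob == 0.0:
            continue
        nd = dict(n_key)
        c = {x: get(nd, ("C", x)) for x in range(1, xmax + 1)}
        r = {x: get(nd, ("R", x)) for x in range(1, xmax + 1)}
        nchain = sum(c.values())
        nlink = sum((x - 1) * c[x] for x in c) + sum(x * r[x] for x in r)

        def shift(**delta) -> CountVector:
            m = dict(nd)
            for spec, dv in delta.items():
                kind, x = spec[0], int(spec[1:])
                key = (kind, x)
                m[key] = m.get(key, 0) + dv
                if m[key] < 0:
                    return None  # type: ignore[return-value]
            return freeze_counts(m)

        def deposit(target: Optional[CountVector], w: float) -> None:
            if target is not None and w:
                out[target] = out.get(target, 0.0) + w * prob

        # outflow from this state
        depletion = N * r1 + r2 * c[1] + r3 * nchain**2 + r4 * nlink
        deposit(n_key, -depletion)
        # monomer creation / annihilation
        deposit(shift(C1=+1), N * r1)
        deposit(shift(C1=-1), r2 * c[1])
        # chain joining and circularization (r3); products beyond xmax are
        # deposited on out-of-range count vectors so total flux is conserved
        for x in range(1, xmax + 1):
            for y in range(x, xmax + 1):
                if x < y:
                    w = 2 * r3 * c[x] * c[y]
                    tgt = shift(**{f"C{x}": -1, f"C{y}": -1, f"C{x+y}": +1})
                else:
                    w = r3 * c[x] * (c[x] - 1)
                    tgt = shift(**{f"C{x}": -2, f"C{2*x}": +1})
                deposit(tgt, w)
            deposit(shift(**{f"C{x}": -1, f"R{x}": +1}), r3 * c[x])
        # splitting and ring opening (r4)
        for x in range(1, xmax + 1):
            for y in range(x, xmax + 1):
                if x + y > xmax:
                    break
                if x < y:
                    w = 2 * r4 * c[x + y]
                    tgt = shift(**{f"C{x+y}": -1, f"C{x}": +1, f"C{y}": +1})
                else:
                    w = r4 * c[2 * x]
                    tgt = shift(**{f"C{2*x}": -1, f"C{x}": +2})
                deposit(tgt, w)
            deposit(shift(**{f"R{x}": -1, f"C{x}": +1}), r4 * x * r[x])
    return out


def macro_state_space(xmax: int, nmax: int) -> List[CountVector]:
    """All chain/ring count vectors with total particle count <= nmax."""
    species = [("C", x) for x in range(1, xmax + 1)] + [
        ("R", x) for x in range(1, xmax + 1)
    ]
    weights = [x for _, x in species]
    states: List[CountVector] = []

    def rec(i: int, remaining: int, acc: Dict) -> None:
        if i == len(species):
            states.append(freeze_counts(acc))
            return
        w = weights[i]
        for cnt in range(remaining // w + 1):
            if cnt:
                acc[species[i]] = cnt
            rec(i + 1, remaining - cnt * w, acc)
            acc.pop(species[i], None)

    rec(0, nmax, {})
    return sorted(states)


def build_macro_generator(
    rates: Tuple[float, float, float, float],
    N: int,
    xmax: int,
    nmax: int,
) -> Tuple[List[CountVector], sp.csc_matrix, float]:
    """Generator of the truncated macro master equation on a bounded space.

    Creation events that would exceed the particle bound are dropped
    (reflecting boundary); the returned float is the summed rate of those
    dropped transitions maximized over source states, a truncation
    certificate.
    """
    states = macro_state_space(xmax, nmax)
    index = {s: i for i, s in enumerate(states)}
    reactions = homopolymer_gallery_reactions(rates, N, xmax)
    rows, cols, data = [], [], []
    max_trunc = 0.0
    for j, n_key in enumerate(states):
        nd = dict(n_key)
        trunc = 0.0
        for rx in reactions:
            w = rx.rate * rx.sigma * omega_coefficient(nd, dict(rx.q), dict(rx.q))
            if w == 0.0:
                continue
            tgt = dict(nd)
            for k, v in dict(rx.q).items():
                tgt[k] -= v
            for k, v in dict(rx.p).items():
                tgt[k] = tgt.get(k, 0) + v
            key = freeze_counts(tgt)
            i = index.get(key)
            if i is None:
                trunc += w
                continue
            rows.append(i)
            cols.append(j)
            data.append(w)
            rows.append(j)
            cols.append(j)
            data.append(-w)
        max_trunc = max(max_trunc, trunc)
    W = sp.csc_matrix((data, (rows, cols)), shape=(len(states), len(states)))
    return states, W, max_trunc


def propagate_macro(
    states: List[CountVector],
    W: sp.csc_matrix,
    p0: Mapping[CountVector, float],
    times: Sequence[float],
) -> np.ndarray:
    index = {s: i for i, s in enumerate(states)}
    psi0 = np.zeros(len(states))
    for key, v in p0.items():
        psi0[index[key]] = v
    return propagate(W, psi0, times)
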