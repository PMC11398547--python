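"""Closed-form equilibrium results and their exact small-N enumeration oracle.

Conventions: kB*T = 1 by default (beta carried explicitly throughout).

Effective parameters:
    mu' = mu + (1/beta) log(N/V)
    eps' (homodimer convention)   = eps - (1/beta) log V
    eps' (homopolymer convention) = eps + (1/beta) log V
    eta = exp(beta (mu' - eps'))   -- weight of one particle with a dangling bond

The two eps' sign conventions are stored per system because the closed forms
for the symmetric-bond homodimer and the directed-bond polymers renormalize
volume oppositely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Hashable, Optional, Tuple

from .census import StructuralIntegrityError, microstate_to_complexes
from .fock import CompiledModel, compile_model
from .model import ModelSpec

__all__ = [
    "DivergenceError",
    "EquilibriumParams",
    "monomer_equilibrium",
    "homodimer_effective_potentials",
    "homopolymer_species_potentials",
    "homopolymer_bulk",
    "isotropic_bulk",
    "branched_bulk",
    "exact_partition_oracle",
    "detailed_balance_rates",
]


class DivergenceError(ValueError):
    """The requested partition function diverges for these parameters."""


@dataclass(frozen=True)
class EquilibriumParams:
    mu: float
    eps: float = 0.0
    N: int = 1
    V: float = 1.0
    beta: float = 1.0

    @property
    def lam(self) -> float:
        """Per-mode fugacity e^{beta mu}."""
        return math.exp(self.beta * self.mu)

    @property
    def lam_prime(self) -> float:
        return self.N / self.V * self.lam

    @property
    def mu_prime(self) -> float:
        return self.mu + math.log(self.N / self.V) / self.beta

    def eps_prime(self, system: str = "homopolymer") -> float:
        if system == "homodimer":
            return self.eps - math.log(self.V) / self.beta
        return self.eps + math.log(self.V) / self.beta

    def eta(self, system: str = "homopolymer") -> float:
        return math.exp(self.beta * (self.mu_prime - self.eps_prime(system)))


# ---------------------------------------------------------------------------
# Monomer
# ---------------------------------------------------------------------------


def monomer_equilibrium(params: EquilibriumParams, large_N: bool = False) -> Dict:
    """Equilibrium macrostate law for independent monomer modes.

    Finite N: counts are Binomial(N, lam/(1+lam)) with Z = (1+lam)^N.
    Large N at fixed lam' = (N/V) lam: Poisson(V lam') with log Z = V lam'.
    """
    lam = params.lam
    N = params.N
    if large_N:
        mean = params.V * params.lam_prime
        from scipy.stats import poisson

        return {
            "Z": math.exp(mean),
            "logZ": mean,
            "mean": mean,
            "pmf": lambda n: poisson.pmf(n, mean),
        }
    from scipy.stats import binom

    p = lam / (1.0 + lam)
    return {
        "Z": (1.0 + lam) ** N,
        "logZ": N * math.log1p(lam),
        "mean": N * p,
        "pmf": lambda n: binom.pmf(n, N, p),
    }


# ---------------------------------------------------------------------------
# Homodimer
# ---------------------------------------------------------------------------


def homodimer_effective_potentials(params: EquilibriumParams) -> Dict[str, Dict[str, float]]:
    """Effective chemical potentials / fugacities for free monomers and dimers.

    mu'_M = mu'; mu'_D = 2 mu' - eps' - (1/beta) log 2 (symmetry of the dimer).
    Mode counts: N_M = N, N_D = N(N-1)/2 ~ N^2/2.
    """
    b = params.beta
    mu_p = params.mu_prime
    eps_p = params.eps_prime("homodimer")
    mu_D = 2.0 * mu_p - eps_p - math.log(2.0) / b
    return {
        "monomer": {
            "mu_prime": mu_p,
            "lam_prime": math.exp(b * mu_p),
            "modes": params.N,
        },
        "dimer": {
            "mu_prime": mu_D,
            "lam_prime": math.exp(b * mu_D),
            "modes": params.N * (params.N - 1) // 2,
        },
    }


# ---------------------------------------------------------------------------
# Directed homopolymer
# ---------------------------------------------------------------------------


def homopolymer_species_potentials(
    params: EquilibriumParams, x: int
) -> Tuple[float, float]:
    """(mu'_Cx, mu'_Rx) for x-chains and x-rings.

    mu'_Cx = x (mu' - eps') + eps'
    mu'_Rx = x (mu' - eps') - (1/beta) log x - (1/beta) log V
    so chain fugacity = e^{beta eps'} eta^x and ring fugacity = eta^x / (x V).
    """
    if x < 1:
        raise ValueError("x must be >= 1")
    b = params.beta
    mu_p = params.mu_prime
    eps_p = params.eps_prime("homopolymer")
    mu_C = x * (mu_p - eps_p) + eps_p
    mu_R = x * (mu_p - eps_p) - math.log(x) / b - math.log(params.V) / b
    return mu_C, mu_R


def homopolymer_bulk(
    params: Optional[EquilibriumParams] = None,
    *,
    eta: Optional[float] = None,
    eps_prime: float = 0.0,
    V: float = 1.0,
    beta: float = 1.0,
) -> Dict[str, float]:
    """Bulk equilibrium of the directed homopolymer for 0 < eta < 1.

    logZ/V  = e^{beta eps'} eta/(1-eta) - log(1-eta)/V   (chains + rings)
    <A>/V   = e^{beta eps'} eta/(1-eta)^2 + ring term/V  (diverges as 1/delta^2)
    Chain length statistics refer to the number of links per chain (length
    minus one) of the exponential length law P(x) ~ eta^x:
    mean = eta/(1-eta), variance = eta/(1-eta)^2.
    """
    if params is not None:
        eta = params.eta("homopolymer")
        eps_prime = params.eps_prime("homopolymer")
        V = params.V
        beta = params.beta
    if eta is None:
        raise ValueError("provide params or eta")
    if not 0.0 < eta < 1.0:
        raise DivergenceError(
            f"homopolymer partition function requires 0 < eta < 1, got eta={eta}"
        )
    w = math.exp(beta * eps_prime)
    chain_logZ = w * eta / (1.0 - eta)
    ring_logZ = -math.log1p(-eta) / V
    conc = w * eta / (1.0 - eta) ** 2 + eta / ((1.0 - eta) * V)
    return {
        "logZ_per_V": chain_logZ + ring_logZ,
        "concentration": conc,
        "chain_mean": eta / (1.0 - eta),
        "chain_var": eta / (1.0 - eta) ** 2,
        "divergence_coeff": w,  # coefficient of 1/delta^2 as delta = 1-eta -> 0
    }


def isotropic_bulk(
    params: Optional[EquilibriumParams] = None,
    *,
    eta: Optional[float] = None,
    eps_prime: float = 0.0,
    V: float = 1.0,
    beta: float = 1.0,
) -> Dict[str, float]:
    """Bulk equilibrium of the isotropic (two symmetric bond classes) homopolymer.

    Species families: odd chains (one species each), even chains (two species,
    I/J exchange), the 2-ring (symmetry order 2), and even rings >= 4
    (rotation + mirror, symmetry order 2x).  For 0 < eta < 1:

    logZ/V = e^{beta eps'} (eta + 2 eta^2)/(1 - eta^2)
             + eta^2/(4V) - log(1 - eta^2)/(4V)
    The chain contribution to <A>/V diverges as (3/2) e^{beta eps'} / delta^2.
    """
    if params is not None:
        eta = params.eta("homopolymer")
        eps_prime = params.eps_prime("homopolymer")
        V = params.V
        beta = params.beta
    if eta is None:
        raise ValueError("provide params or eta")
    if not 0.0 < eta < 1.0:
        raise DivergenceError(
            f"isotropic partition function requires 0 < eta < 1, got eta={eta}"
        )
    w = math.exp(beta * eps_prime)
    chains = w * (eta + 2.0 * eta**2) / (1.0 - eta**2)
    rings = eta**2 / (4.0 * V) - math.log1p(-(eta**2)) / (4.0 * V)
    # d(chains)/d(beta mu') = eta * d(chains)/d(eta)
    dchains = w * eta * (1.0 + 4.0 * eta + eta**2) / (1.0 - eta**2) ** 2
    drings = (eta**2 / 2.0 + eta**2 / (2.0 * (1.0 - eta**2))) / V
    return {
        "logZ_per_V": chains + rings,
        "concentration": dchains + drings,
        "divergence_coeff": 1.5 * w,  # coefficient of 1/delta^2
    }


def branched_bulk(
    params: Optional[EquilibriumParams] = None,
    *,
    eta: Optional[float] = None,
    eps_prime: float = 0.0,
    V: float = 1.0,
    beta: float = 1.0,
) -> Dict[str, float]:
    """Bulk equilibrium of the branched directed homopolymer, 0 < eta <= 1/4.

    xi solves xi = eta (1 + xi)^2, i.e. xi = (1 - 2 eta - sqrt(1-4 eta))/(2 eta);
    logZ/V = e^{beta eps'} xi - log(1-4 eta)/(2V).
    Near delta = 1/4 - eta -> 0 the concentration diverges as
    e^{beta eps'}/(2 sqrt(delta)) (trees) + 1/(8 V delta) (groves).
    """
    if params is not None:
        eta = params.eta("homopolymer")
        eps_prime = params.eps_prime("homopolymer")
        V = params.V
        beta = params.beta
    if eta is None:
        raise ValueError("provide params or eta")
    if not 0.0 < eta <= 0.25:
        raise DivergenceError(
            f"branched partition function is not defined for eta > 1/4 (eta={eta})"
        )
    w = math.exp(beta * eps_prime)
    s = math.sqrt(1.0 - 4.0 * eta)
    xi = (1.0 - 2.0 * eta - s) / (2.0 * eta)
    logZ = w * xi + (-math.log(1.0 - 4.0 * eta) / (2.0 * V) if eta < 0.25 else math.inf)
    # eta d(xi)/d(eta) = xi (1 + xi) / (1 - eta (1 + xi) ... ) via implicit diff:
    # xi' = (1+xi)^2 / (1 - 2 eta (1+xi)) = (1+xi)^2 / s
    dtree = w * eta * (1.0 + xi) ** 2 / s if eta < 0.25 else math.inf
    dgrove = (2.0 * eta / (1.0 - 4.0 * eta)) / V if eta < 0.25 else math.inf
    return {
        "xi": xi,
        "logZ_per_V": logZ,
        "concentration": dtree + dgrove,
        "tree_divergence": lambda delta: w / (2.0 * math.sqrt(delta)),
        "grove_divergence": lambda delta: 1.0 / (8.0 * V * delta),
    }


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------

ORACLE_MODE_CAP = 20


def exact_partition_oracle(
    model: ModelSpec | CompiledModel,
    beta: float = 1.0,
    cap_modes: int = ORACLE_MODE_CAP,
) -> Dict:
    """Exhaustive evaluation of e^{-beta H} over all structurally valid microstates.

    Uses the model's diagonal Hamiltonian terms; returns the exact partition
    function, per-microstate Gibbs probabilities, and macrostate (species
    count vector) marginals.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    if cm.n_modes > cap_modes:
        raise ValueError(
            f"oracle enumeration over 2^{cm.n_modes} microstates exceeds cap "
            f"2^{cap_modes}"
        )
    weights: Dict[int, float] = {}
    macro: Dict[Hashable, float] = {}
    Z = 0.0
    for mask in range(1 << cm.n_modes):
        try:
            counts = microstate_to_complexes(mask, cm)
        except StructuralIntegrityError:
            continue  # structurally invalid microstate
        w = math.exp(-beta * cm.hamiltonian_energy(mask))
        weights[mask] = w
        Z += w
        key = tuple(sorted((lbl.name, c) for lbl, c in counts.items()))
        macro[key] = macro.get(key, 0.0) + w
    probs = {m: w / Z for m, w in weights.items()}
    macro_probs = {k: v / Z for k, v in macro.items()}
    return {"Z": Z, "probabilities": probs, "macrostates": macro_probs}


def detailed_balance_rates(
    params: EquilibriumParams, model: Optional[ModelSpec] = None
) -> Dict[str, float]:
    """Per-instance rates whose stationary state is the Gibbs state.

    Creation/annihilation pairs satisfy r+/r- = e^{beta mu}; bond
    formation/dissolution pairs satisfy r+/r- = e^{-beta eps}.  Keys follow
    the fixture naming convention: any rule whose name starts with 'create'
    or 'bind' is a forward rule, 'destroy'/'unbind' its reverse.
    """
    create = math.exp(params.beta * params.mu)
    bind = math.exp(-params.beta * params.eps)
    if model is None:
        return {"create": create, "destroy": 1.0, "bind": bind, "unbind": 1.0}
    out = {}
    for rule in model.rules:
        if rule.name.startswith("create"):
            out[rule.name] = create
        elif rule.name.startswith("destroy"):
            out[rule.name] = 1.0
        elif rule.name.startswith("bind"):
            out[rule.name] = bind
        elif rule.name.startswith("unbind"):
            out[rule.name] = 1.0
    return out
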