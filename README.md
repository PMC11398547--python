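# polyfock

Rule-based modeling of multi-particle complexes on a classical Fock space of
hard-core boson modes.

A model declares three kinds of fields — particles, binding sites, and bonds —
each with `N` internal modes, and a set of rules. Every rule is a product of
mode operators (create `+`, annihilate `-`, presence `?`, absence `~`), so a
handful of rules implicitly defines an unbounded family of complexes (polymer
chains, rings, trees, ...) and every reaction among them. The package provides:

- **`polyfock.model`** — a plain-text model format (fields, rules, rates,
  Hamiltonian coefficients, initial state) with parser/renderer and built-in
  fixture systems: monomer, homodimer, homopolymer, heterodimer, occlusive
  binding, cooperative binding, heteropolymer, branched homopolymer, and
  isotropic homopolymer.
- **`polyfock.fock`** — microstates as excitation sets, rule instantiation
  over index ranges, depletion-operator derivation, and exact sparse operator
  matrices on small Fock spaces for identity testing.
- **`polyfock.master`** — breadth-first reachable state spaces, the sparse
  transition generator (reaction + depletion structure, columns sum to zero),
  matrix-exponential propagation, macrostate projection, the combinatorial
  reaction coefficient Ω(n, q, p), a species-level flux projector, and the
  truncated chain/ring count-vector master equation for the homopolymer.
- **`polyfock.ssa`** — an eligibility-driven Gillespie simulator over mode
  excitations with a state constructor, reproducible counter-based RNG, naive
  (full rescan) and incremental-index eligibility strategies producing
  bitwise-identical trajectories.
- **`polyfock.census`** — complexes as connected components of the
  particle-bond graph, canonical topology labels (monomer/dimer/chain-x/
  ring-x/tree/grove with relabeling invariance), trajectory censuses and
  ensemble statistics.
- **`polyfock.equilibrium`** — effective chemical potentials and fugacities,
  closed-form bulk partition-function densities for the directed, isotropic,
  and branched homopolymers (with critical-scaling coefficients), an exact
  enumeration oracle for small N, and detailed-balance rate construction.
- **`polyfock.wick`** — brute-force enumeration of contraction schemes of
  productive-ordered factory products, topology-classified scheme counts, and
  exact rational verification that the ordered factory exponentials reproduce
  the gallery sum over all complex species.

## Tests

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance criteria: worked-example
reaction-channel multiplicities, the contraction-coefficient check, exact
factory/gallery equality, the operator-identity suite, Gibbs/dynamics
stationary-state consistency, SSA-vs-exact-propagation ensembles (500 runs),
macro-ODE-vs-SSA consistency at N=60, and the analytics identities. The full
suite takes about two minutes on one CPU.

## CLI

```sh
polyfock fixtures --name homodimer --n 4 --rates bind=2.0 --out model.txt
polyfock validate model.txt
polyfock exact --model model.txt --tmax 5 --grid 50 --out probs.tsv
polyfock simulate --model model.txt --tmax 5 --runs 10 --seed 1 --out runs/
polyfock census --model model.txt --tmax 5 --runs 10 --times 0:5:0.5 --stats --out counts.tsv
polyfock macro-ode --rates 0.05,1,0.1,0.8 --n 60 --xmax 6 --tmax 6 --out macro.tsv
polyfock equilibrium --system branched --mu -6.0
polyfock wick --system homodimer --p 2 --q 5
```

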