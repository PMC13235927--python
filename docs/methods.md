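# Methods

## Model

The unit of state is the subpopulation `H[i,p]`: the number of individuals
of host population `i` (of `n_b`) carrying exactly the plasmid profile `p`,
a binary vector over `n_p` plasmids. Each plasmid exists in a single copy
per cell, so a community has at most `n_b * 2^n_p` subpopulations. Profiles
are indexed by the integer whose bit `a` is plasmid `a+1`'s presence; the
printed bitstring puts P1 leftmost, so `0011` is a cell carrying P3 and P4.

Two binary networks act as hard constraints. The infection network `I`
(hosts x plasmids) says which plasmid can infect which host; the
compatibility network `P` (plasmids x plasmids, symmetric, zero diagonal —
plasmids are self-incompatible) says which pairs can co-reside. A profile is
*feasible* for a host iff every carried plasmid can infect it and every
carried pair is compatible; infeasible subpopulations can never be created
and must have zero initial abundance.

Five stochastic events, with per-capita rates:

| event        | rate                                         | bookkeeping |
|--------------|----------------------------------------------|-------------|
| death        | `mu_i`                                       | actor −1 |
| growth       | `eta_{i,p} = eta_i * prod_{a in p}(1 − c_a)` | actor +1 |
| segregation  | `omega_{i,p} = e_i * eta_{i,p}`              | host's plasmid-free subpopulation +1 |
| competition  | `xi_{i,p} = eta_{i,p} (sum_j b_ij H_j)/K`    | actor −1 |
| infection    | `phi_{i,p} = gamma_i * sum_{(k,q) in L(i,p)} H_{k,q}` | recipient −1, transconjugant +1, donor unchanged |

Costs are multiplicative (a slight positive epistasis: the joint cost of
two plasmids, `1 − (1−c)^2`, is below the additive `2c`). Competition uses
a *community-wide* carrying capacity `K` with kernel `b_ii = 1`,
`b_ij = a_ij + 1` for `i ≠ j`, so all hosts draw on one resource pool and
interspecific pressure slightly exceeds intraspecific — strict competitive
exclusion in the long run. Segregation is modeled as a division in which the
daughter loses *all* plasmids; the parent subpopulation is unchanged and the
plasmid-free subpopulation gains one. The plasmid-free profile's segregation
rate is set to zero: the formal value `e_i * eta_i` would describe an event
indistinguishable from growth, and at `e ≈ 1e-8` the difference is far below
any observable.

Transfer feasibility from donor `(i,p)` to recipient `(k,q)` producing
`(k,r)` requires: (1) the donor carries plasmids; (2) the donor has plasmids
the recipient lacks; (3) every transferred plasmid can infect host `k`;
(4) all plasmids in `r` are pairwise compatible. A transfer set of size `nu`
gets raw propensity `1/2^(nu−1)` (larger batches are rarer); the
propensities of each (donor, recipient) column are normalized to 1.
Conjugation is donor-host-specific and profile-independent (`gamma_i`), and
occurs within and between hosts alike. The recipient-abundance sum in
`phi` runs over the donor's recipient list `L`; lists are built once over
the full feasible catalog, which stays valid as subpopulations appear and
disappear because absent subpopulations contribute zero weight.

## Simulation algorithm

Exact SSA (direct method): compute the five channel totals and their sum
`R`; draw `dt = X/R`, `X ~ Exp(1)`; choose a channel with probability
`R_c/R`; choose the actor with weight per-capita-rate x abundance (for
infection: donor by `phi*H`, then recipient by abundance within the donor's
list, then transconjugant by the normalized propensity column); execute;
repeat. Zero-rate channels and zero-abundance subpopulations are excluded
from sampling rather than sampled-and-rejected.

States are recorded on a fixed grid (default every 5 h): the state *after*
the first event whose time reaches or passes each grid point is stored at
that grid time, and the final state is always recorded. A run ends at
`t_max`, at community collapse (all abundances zero), or — optionally — at
one of two early-stopping conditions used by the experiment suite:
`single_host` (one host population left; its identity can no longer change)
and `absorbed_pairs` (no individual carries fewer than two plasmids, the
absorbing composition of the hub/modular compatibility cells).

Two backends implement identical semantics. The *fast* backend runs the
loop in a numba-compiled kernel that maintains host totals and each donor's
summed recipient abundance incrementally (only the one or two
subpopulations touched by an event are updated; the update rule is tested
against full recomputation) and resamples everything else per step in
`O(n_b * 2^n_p)`. The *reference* backend is a plain-Python loop over the
public per-event operations, recomputing all rates every step; it defines
the semantics and cross-checks the kernel statistically. Each replicate
uses one seeded generator; ensemble seeds are spawned from a base seed via
`numpy.random.SeedSequence` (documented, reproducible rule). Identical
(config, backend, seed) triples give bit-identical trajectories; the two
backends agree in distribution, not stream-for-stream.

## Parameters

Uniform defaults of the theoretical experiments (any community size):

| parameter | value | units |
|---|---|---|
| growth rate `eta_i` | 1 | 1/h |
| death rate `mu_i` | 0.12 | 1/h |
| conjugation rate `gamma_i` | 1e-5 | 1/(cell·h) |
| segregation probability `e_i` | 1e-8 | — |
| plasmid cost `c_a` | 0.3 | fraction of growth rate |
| carrying capacity `K` | 20000 | cells |
| interspecific competition `a_ij` | 0.01 | — |

The canonical motifs are 3 hosts x 4 plasmids. Infection structures: full
(all ones); nested stair-step (H1 susceptible to all four, H2 to
{P1,P2,P3}, specialist H3 only to the generalist P1 — only the generalist
and specialist rows are canonical, the intermediate row is our stair-step
choice); modular (H1 ← {P1,P2}, H2 ← {P2,P3} bridging, H3 ← {P3,P4}; any
consistent relabeling is isomorphic and leaves outcomes unchanged).
Compatibility structures: full; modular ({P1,P2} vs {P3,P4}); hub (one
plasmid compatible with all, non-hub pairs incompatible; results do not
depend on which plasmid is the hub, and the hub index is a parameter).

Experiments initialize each host with 2000 plasmid-free individuals plus 10
individuals for every single plasmid the host admits, so every plasmid
pre-exists in its focal hosts; horizon 20000 h, 300 replicates per cell.

## Scaled preset

Running nine cells x 300 replicates x 20000 h at `K = 20000` is a
cluster-scale job. The package ships a reduced preset used by the test
suite, the acceptance script, and the examples: `K = 2000`, initial
subpopulations 200 + 10 per host, horizons of a few thousand hours, tens to
a hundred replicates. Because conjugation is mass-action in absolute
numbers, the dimensionless infection pressure at capacity is `gamma * K`;
the preset therefore multiplies `gamma` by `K_ref/K` (giving `gamma*K =
0.2`, as in the full parameterization) so the smaller community sits in the
same dynamical regime — without this rescaling, infection would be ten
times weaker relative to growth, the plasmid-free subpopulation would be
self-sustaining, and the absorbing co-infected compositions would never be
reached. The checks run at this scale are structural (symmetries,
absorbing states, orderings of extinction times) and are insensitive to the
reduced size beyond faster drift; quantities that are *not*
scale-invariant, such as the ≈0.4 stable-coexistence probability of the
modular-infection cell at 20000 h, are checked only qualitatively
(nonzero, and above the full/full control) at desk scale.

## Mean-field oracle

`plasmidnet.diagnostics` integrates the deterministic expectation of the
model: the same per-capita rates, with infection as mass-action flow
`gamma_i H_donor H_recipient` split over transconjugants by the normalized
propensity column. For a single plasmid-free host it reduces to logistic
growth with equilibrium `H* = K(1 − mu/eta)` (17600 at the defaults),
which the integrator reproduces to 0.1% and the stochastic engine
fluctuates about. Ensemble means track the mean-field trajectory within
Monte-Carlo error through the demographic and early-infection phases; once
an infection sweep becomes quasi-exponential, the ensemble mean lags the
deterministic solution by a fixed few percent of `K` (donor–recipient
anticorrelation plus accumulated growth fluctuations), a standard
finite-size correction that shrinks with `K` but not with the number of
replicates. Tests therefore assert 3-SE agreement on the linear-noise
window and a 10%-of-`K` bound across the sweep. A brute-force propensity
tensor (naive loop over all transconjugant/donor/recipient triples,
checking the four transfer conditions directly) serves as an independent
oracle for the optimized constructor on all nine canonical cells.

## Heterogeneous lab-like scenario

`make_empirical_config()` mirrors a three-host, two-plasmid laboratory
community: modular infection (H1 ← {P1}, bridge H2 ← {P1,P2}, H3 ← {P2}),
full compatibility, `K = 1e5`, each host starting at `B0 = 3300` split
half plasmid-free / half carriers (link-balanced across the host's
plasmids), 240 h horizon. The exact trait values of that system are not
published; the shipped placeholders honor the reported orderings — growth
`H1 ≤ H2 < H3` (0.9, 0.98, 1.0; the bridge host's elevated growth is what
lets it outpace H1 despite double exposure), conjugation `H1 = H2 < H3`
(1e-7, 1e-7, 3e-7 at the `K = 1e5` reference, rescaled with `K`), costs
`P1 < P2` (0.05, 0.1), competitive effect `H1 < H2 < H3` (0.005, 0.01,
0.02) — with magnitudes chosen so growth-rate differences are a few percent
of `eta` and infection acts within the 240 h window without saturating
prevalence. All values are config-overridable; replacing them with measured
ones is a one-line change.

## What the synthetic experiments do and do not show

The generator *is* the study system: all inputs are parameter sets and
network motifs, not data. Passing tests show that the implementation
reproduces the mechanism-level consequences of network structure under the
stated idealizations — uniform traits (except where deliberately varied),
no spatial structure, no plasmid benefits, single-copy plasmids, fixed
networks, exact SSA. They do not show that real communities behave this
way: real systems have trait heterogeneity, evolving networks, multi-copy
plasmids and beneficial accessory genes, all outside scope here.

## Numerical choices and limitations

- Rates are float64; channel and actor sampling use a single cumulative
  walk with the final nonzero-weight candidate as a rounding guard, so
  weights summing to `R(1 − eps)` cannot select an invalid target.
- The snapshot comparator uses a 1e-9 h tolerance on grid arithmetic.
- An event falling beyond `t_max` is not executed; the state is frozen at
  the horizon (the run's last recorded state is the pre-event state).
- Mean-field integration uses LSODA with `rtol = atol = 1e-8` and clips
  negative excursions inside the derivative; stiffness failures raise.
- The propensity tensor is stored sparsely by (donor, recipient) column;
  dense storage is cubic in `n_b 2^n_p` and was rejected. Cost of building
  the tensor and lists still grows steeply with `n_p`; the engine is
  exact-SSA only (no tau-leaping), so runtime scales with total event rate,
  i.e. with `K` and with connectance.
- With `e = 1e-8`, segregation events are so rare that once the
  plasmid-free subpopulation of a host hits zero it is effectively gone;
  the absorbing pair-only compositions of the structured-compatibility
  cells rely on this.
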