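"""Mass-action kinetics of strand exchange between coiled-coil assemblies.

Three mechanisms are modelled, all label-blind (chains move without regard
to whether they carry the fluorophore), in units of micromolar and minutes:

``intermediate``
    Dimer exchange through a tetrameric steady-state species: any two dimers
    associate at ``k_assoc`` (with the factor-of-two symmetry correction for
    identical reactants) and the four-chain intermediate resolves at
    ``k_resolve`` into one of the three pairings of its chains into two
    dimers, chosen uniformly.  Uniform re-pairing makes the network satisfy
    detailed balance, so the long-time dimer composition is the binomial
    mixing distribution and the heterodimer equilibrium quotient
    ``[LU]^2 / ([LL][UU])`` equals the statistical factor 4.

``dissociation``
    Dimer exchange initiated by dissociation: ``D_xy <-> x + y`` with
    ``k_off`` per dimer and ``k_on`` per distinct monomer pair (``k_on / 2``
    flux for identical monomers), monomers recombining without label
    preference.

``swap``
    A generic chain-swap kernel for ``n``-mers: assemblies collide at
    ``k_swap`` and each partner hands over one uniformly chosen chain.  This
    is a minimal generative mechanism for the higher oligomers, whose true
    exchange kinetics are multi-step and not single-exponential.

A useful exact property of the intermediate mechanism under any mixing
ratio: the deviation of the dimer composition from equilibrium decays as a
single exponential with rate ``(2/3) k_assoc [total dimer]`` (the quadratic
mass-action flux has a concentration-independent derivative along the
conservation manifold).  The package therefore parameterizes CC-Di by the
apparent slope ``k_ref = (2/3) k_assoc`` so that ``k_obs = k_ref x [total
dimer]``.

The deterministic integrator is stiff-capable (``scipy`` LSODA, rtol 1e-8 /
atol 1e-10 uM); :func:`gillespie_oracle` runs an exact stochastic simulation
of the same reaction network for validation at small copy numbers.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, InputError, IntegrationError, SchemaError
from .species import QuenchModel, unquenched_labels_per_assembly

__all__ = [
    "DimerIntermediateParams",
    "DimerDissociationParams",
    "SwapKernelParams",
    "SpeciesDef",
    "Reaction",
    "ReactionNetwork",
    "ReactionState",
    "Trajectory",
    "dimer_intermediate_network",
    "dimer_dissociation_network",
    "swap_network",
    "network_for",
    "simulate_intermediate_mechanism",
    "simulate_dissociation_mechanism",
    "simulate_swap_kernel",
    "fluorescence_from_state",
    "gillespie_oracle",
]

RTOL = 1e-8
ATOL = 1e-10  # uM
CLIP = 1e-12  # concentrations below this are reported as zero


# ---------------------------------------------------------------------------
# mechanism parameters


@dataclass
class DimerIntermediateParams:
    """Rates for exchange via a tetrameric steady-state intermediate.

    k_assoc : per uM per minute, dimer-dimer association.
    k_resolve : per minute, resolution of the intermediate.
    resolution : "random" re-pairs the four chains uniformly (default);
        "mixed_only" resolves a 2-labelled intermediate exclusively to two
        mixed dimers, as the exchange scheme is usually drawn.
    """

    k_assoc: float
    k_resolve: float
    resolution: str = "random"

    def __post_init__(self) -> None:
        if self.k_assoc < 0 or self.k_resolve < 0:
            raise DomainError("rate constants must be >= 0")
        if self.resolution not in ("random", "mixed_only"):
            raise DomainError(f"unknown resolution rule {self.resolution!r}")


@dataclass
class DimerDissociationParams:
    """Rates for exchange initiated by dimer dissociation.

    k_off : per minute; k_on : per uM per minute.  ``K_D = k_off / k_on``.
    """

    k_off: float
    k_on: float

    def __post_init__(self) -> None:
        if self.k_off < 0 or self.k_on < 0:
            raise DomainError("rate constants must be >= 0")

    @property
    def K_D(self) -> float:
        return self.k_off / self.k_on

    @classmethod
    def from_kd(cls, k_off: float, K_D: float) -> "DimerDissociationParams":
        if K_D <= 0:
            raise DomainError("K_D must be positive")
        return cls(k_off=k_off, k_on=k_off / K_D)


@dataclass
class SwapKernelParams:
    """Chain-swap collision kernel for an ``n``-mer (k_swap per uM per min)."""

    n: int
    k_swap: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DomainError("oligomer state must be >= 2")
        if self.k_swap < 0:
            raise DomainError("k_swap must be >= 0")


def intermediate_params_from_slope(
    k_ref: float, k_resolve: float = 1000.0
) -> DimerIntermediateParams:
    """Intermediate-mechanism rates from the apparent slope ``k_ref``.

    ``k_obs = k_ref x [total dimer]`` exactly in the fast-resolution limit,
    with ``k_assoc = (3/2) k_ref``.
    """
    return DimerIntermediateParams(k_assoc=1.5 * k_ref, k_resolve=k_resolve)


# ---------------------------------------------------------------------------
# reaction-network core


@dataclass(frozen=True)
class SpeciesDef:
    """One chemical species with its labelled/unlabelled chain content."""

    id: str
    n_labelled: int
    n_unlabelled: int

    @property
    def size(self) -> int:
        return self.n_labelled + self.n_unlabelled


@dataclass(frozen=True)
class Reaction:
    """An elementary reaction with mass-action kinetics.

    Flux convention: ``rate * prod(c_i^s_i) / prod(s_i!)`` so that a
    reaction with reactants ``{A: 2}`` has flux ``(rate/2) [A]^2`` (the
    identical-reactant symmetry correction).
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: float


@dataclass
class ReactionState:
    """Concentrations (uM) keyed by species id, with chain bookkeeping."""

    concentrations: dict[str, float]
    species: dict[str, SpeciesDef]

    def __post_init__(self) -> None:
        for sid in self.concentrations:
            if sid not in self.species:
                raise SchemaError(f"unknown species id {sid!r}")

    def total_labelled(self) -> float:
        return sum(
            c * self.species[sid].n_labelled
            for sid, c in self.concentrations.items()
        )

    def total_unlabelled(self) -> float:
        return sum(
            c * self.species[sid].n_unlabelled
            for sid, c in self.concentrations.items()
        )


class ReactionNetwork:
    """A set of species and mass-action reactions over them."""

    def __init__(self, species: Sequence[SpeciesDef], reactions: Sequence[Reaction]):
        self.species = list(species)
        self.reactions = list(reactions)
        self.index = {sp.id: i for i, sp in enumerate(self.species)}
        ns, nr = len(self.species), len(self.reactions)
        self._R = np.zeros((nr, ns))  # reactant stoichiometry
        self._N = np.zeros((nr, ns))  # net stoichiometry
        self._rates = np.zeros(nr)
        self._sym = np.ones(nr)
        for j, rx in enumerate(self.reactions):
            for sid, s in rx.reactants:
                self._R[j, self.index[sid]] += s
            self._N[j] -= self._R[j]
            for sid, s in rx.products:
                self._N[j, self.index[sid]] += s
            self._rates[j] = rx.rate
            self._sym[j] = np.prod(
                [math.factorial(s) for _, s in rx.reactants] or [1.0]
            )
        # chain conservation is structural: every reaction must balance
        lab = np.array([sp.n_labelled for sp in self.species], float)
        unl = np.array([sp.n_unlabelled for sp in self.species], float)
        if np.any(np.abs(self._N @ lab) > 1e-12) or np.any(np.abs(self._N @ unl) > 1e-12):
            raise SchemaError("reaction network does not conserve chains")

    # -- state helpers ------------------------------------------------------

    def initial_vector(self, init: Mapping[str, float] | ReactionState) -> np.ndarray:
        conc = init.concentrations if isinstance(init, ReactionState) else init
        c0 = np.zeros(len(self.species))
        for sid, v in conc.items():
            if sid not in self.index:
                raise SchemaError(
                    f"unknown species id {sid!r}; expected one of "
                    f"{sorted(self.index)}"
                )
            if v < 0:
                raise DomainError(f"negative concentration for {sid!r}: {v}")
            c0[self.index[sid]] = v
        return c0

    def make_state(self, conc: Mapping[str, float]) -> ReactionState:
        vec = self.initial_vector(conc)  # validates ids and signs
        return ReactionState(
            concentrations={sp.id: float(vec[i]) for i, sp in enumerate(self.species)},
            species={sp.id: sp for sp in self.species},
        )

    # -- deterministic simulation ------------------------------------------

    def fluxes(self, c: np.ndarray) -> np.ndarray:
        cc = np.clip(c, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            powed = cc[None, :] ** self._R
        return self._rates * np.prod(powed, axis=1) / self._sym

    def rhs(self, t: float, c: np.ndarray) -> np.ndarray:
        return self._N.T @ self.fluxes(c)

    def simulate(
        self,
        init: Mapping[str, float] | ReactionState,
        times: Iterable[float],
        qm: QuenchModel | None = None,
    ) -> "Trajectory":
        t = np.asarray(list(times), dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise InputError("time grid must be a 1-D array with >= 2 points")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise InputError("time grid must be non-negative and strictly increasing")
        c0 = self.initial_vector(init)
        t0, t1 = float(t[0]), float(t[-1])
        sol = solve_ivp(
            self.rhs,
            (t0, t1),
            c0,
            method="LSODA",
            t_eval=t,
            rtol=RTOL,
            atol=ATOL,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed: {sol.message} "
                f"(nfev={sol.nfev}, final t={sol.t[-1] if sol.t.size else t0})"
            )
        conc = sol.y.T.copy()
        conc[np.abs(conc) < CLIP] = 0.0
        conc = np.clip(conc, 0.0, None)
        return Trajectory.from_concentrations(self, t, conc, qm)

    # -- exact stochastic simulation ---------------------------------------

    def gillespie(
        self,
        init: Mapping[str, float] | ReactionState,
        volume: float,
        seed: int,
        t_end: float,
        record_times: Iterable[float] | None = None,
        qm: QuenchModel | None = None,
    ) -> "Trajectory":
        """Exact SSA run; ``volume`` converts uM to copy numbers.

        If total propensity hits zero before ``t_end`` the state simply
        persists (absorbing state), which is the correct exact trajectory.
        """
        if volume <= 0:
            raise DomainError("volume must be positive")
        rng = np.random.default_rng(seed)
        counts = np.rint(self.initial_vector(init) * volume).astype(np.int64)
        if record_times is None:
            grid = np.linspace(0.0, t_end, 51)
        else:
            grid = np.asarray(list(record_times), dtype=float)
        rec = np.zeros((grid.size, counts.size), dtype=np.int64)
        order = self._R.sum(axis=1)
        t = 0.0
        gi = 0
        while True:
            props = self._propensities(counts, volume, order)
            a0 = props.sum()
            if a0 <= 0.0:
                t_next = np.inf
            else:
                t_next = t + rng.exponential(1.0 / a0)
            while gi < grid.size and grid[gi] <= min(t_next, t_end) + 1e-15:
                rec[gi] = counts
                gi += 1
            if t_next >= t_end or not np.isfinite(t_next):
                break
            t = t_next
            j = rng.choice(props.size, p=props / a0)
            counts += self._N[j].astype(np.int64)
        while gi < grid.size:
            rec[gi] = counts
            gi += 1
        conc = rec.astype(float) / volume
        return Trajectory.from_concentrations(self, grid, conc, qm)

    def _propensities(
        self, counts: np.ndarray, volume: float, order: np.ndarray
    ) -> np.ndarray:
        props = np.empty(len(self.reactions))
        for j, rx in enumerate(self.reactions):
            a = self._rates[j] / (volume ** (order[j] - 1.0)) / self._sym[j]
            for sid, s in rx.reactants:
                n = counts[self.index[sid]]
                for k in range(int(s)):
                    a *= max(n - k, 0)
            props[j] = a
        return props


@dataclass
class Trajectory:
    """Time-resolved species concentrations plus the fluorescence observable.

    The observable is the concentration of unquenched labels (uM) under the
    quench model, which is proportional to raw fluorescence in arbitrary
    units (the proportionality gauge is irrelevant downstream).
    """

    times: np.ndarray
    species_ids: list[str]
    concentrations: np.ndarray  # (n_times, n_species)
    observable: np.ndarray
    network: ReactionNetwork = field(repr=False)

    @classmethod
    def from_concentrations(
        cls,
        network: ReactionNetwork,
        times: np.ndarray,
        conc: np.ndarray,
        qm: QuenchModel | None = None,
    ) -> "Trajectory":
        qm = qm or QuenchModel()
        f = np.array(
            [
                unquenched_labels_per_assembly(sp.n_labelled, sp.size, qm)
                for sp in network.species
            ]
        )
        return cls(
            times=np.asarray(times, float),
            species_ids=[sp.id for sp in network.species],
            concentrations=conc,
            observable=conc @ f,
            network=network,
        )

    def state_at(self, i: int) -> ReactionState:
        return ReactionState(
            concentrations=dict(zip(self.species_ids, self.concentrations[i])),
            species={sp.id: sp for sp in self.network.species},
        )

    def final_state(self) -> ReactionState:
        return self.state_at(len(self.times) - 1)

    def total_labelled(self) -> np.ndarray:
        lab = np.array([sp.n_labelled for sp in self.network.species], float)
        return self.concentrations @ lab

    def total_unlabelled(self) -> np.ndarray:
        unl = np.array([sp.n_unlabelled for sp in self.network.species], float)
        return self.concentrations @ unl

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.concentrations, columns=self.species_ids)
        df.insert(0, "time_min", self.times)
        df["fluorescence_au"] = self.observable
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# network builders

_DIMERS = {"UU": 0, "LU": 1, "LL": 2}  # id -> labelled chains


def _dimer_id(l: int) -> str:
    return {0: "UU", 1: "LU", 2: "LL"}[l]


def _pairing_channels(l: int) -> list[tuple[Counter, float]]:
    """Resolution outcomes of a 4-chain intermediate with ``l`` labels.

    Enumerates the 3 perfect matchings of 4 distinguishable chains and
    aggregates the resulting dimer pairs with their probabilities.
    """
    chains = [1] * l + [0] * (4 - l)
    matchings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    out: Counter = Counter()
    for m in matchings:
        pair = tuple(
            sorted(_dimer_id(chains[i] + chains[j]) for i, j in m)
        )
        out[pair] += 1
    return [(Counter(pair), cnt / 3.0) for pair, cnt in out.items()]


def dimer_intermediate_network(params: DimerIntermediateParams) -> ReactionNetwork:
    species = [
        SpeciesDef("UU", 0, 2),
        SpeciesDef("LU", 1, 1),
        SpeciesDef("LL", 2, 0),
    ] + [SpeciesDef(f"I{l}", l, 4 - l) for l in range(5)]
    reactions: list[Reaction] = []
    for d1, d2 in itertools.combinations_with_replacement(_DIMERS, 2):
        l = _DIMERS[d1] + _DIMERS[d2]
        reactants = ((d1, 2),) if d1 == d2 else ((d1, 1), (d2, 1))
        reactions.append(Reaction(reactants, ((f"I{l}", 1),), params.k_assoc))
    for l in range(5):
        if params.resolution == "mixed_only" and l == 2:
            channels = [(Counter({"LU": 2}), 1.0)]
        else:
            channels = _pairing_channels(l)
        for prods, prob in channels:
            reactions.append(
                Reaction(
                    ((f"I{l}", 1),),
                    tuple((sid, cnt) for sid, cnt in sorted(prods.items())),
                    params.k_resolve * prob,
                )
            )
    return ReactionNetwork(species, reactions)


def dimer_dissociation_network(params: DimerDissociationParams) -> ReactionNetwork:
    species = [
        SpeciesDef("UU", 0, 2),
        SpeciesDef("LU", 1, 1),
        SpeciesDef("LL", 2, 0),
        SpeciesDef("L", 1, 0),
        SpeciesDef("U", 0, 1),
    ]
    reactions = [
        Reaction((("LL", 1),), (("L", 2),), params.k_off),
        Reaction((("LU", 1),), (("L", 1), ("U", 1)), params.k_off),
        Reaction((("UU", 1),), (("U", 2),), params.k_off),
        Reaction((("L", 2),), (("LL", 1),), params.k_on),
        Reaction((("L", 1), ("U", 1)), (("LU", 1),), params.k_on),
        Reaction((("U", 2),), (("UU", 1),), params.k_on),
    ]
    return ReactionNetwork(species, reactions)


def swap_network(params: SwapKernelParams) -> ReactionNetwork:
    """Composition-resolved chain-swap kernel over ``A0 .. An``.

    ``A{l}`` is the n-mer containing ``l`` labelled chains.  On a collision
    each partner donates one uniformly chosen chain to the other, so the
    outcome distribution of a ``(l, m)`` encounter is governed by two
    Bernoulli draws with success probabilities ``l/n`` and ``m/n``.
    """
    n = params.n
    species = [SpeciesDef(f"A{l}", l, n - l) for l in range(n + 1)]
    reactions: list[Reaction] = []
    for l, m in itertools.combinations_with_replacement(range(n + 1), 2):
        reactants = ((f"A{l}", 2),) if l == m else ((f"A{l}", 1), (f"A{m}", 1))
        outcome: Counter = Counter()
        for a1, a2 in itertools.product((0, 1), repeat=2):
            pl = l / n if a1 else 1 - l / n
            pm = m / n if a2 else 1 - m / n
            prob = pl * pm
            if prob == 0.0:
                continue
            l2, m2 = l - a1 + a2, m - a2 + a1
            if (l2, m2) == (l, m) or (l2, m2) == (m, l):
                continue  # identity swap: no state change
            outcome[tuple(sorted((l2, m2)))] += prob
        for (l2, m2), prob in outcome.items():
            prods = Counter([f"A{l2}", f"A{m2}"])
            reactions.append(
                Reaction(
                    reactants,
                    tuple((sid, cnt) for sid, cnt in sorted(prods.items())),
                    params.k_swap * prob,
                )
            )
    return ReactionNetwork(species, reactions)


def network_for(params) -> ReactionNetwork:
    """Dispatch a parameter object to its network builder."""
    if isinstance(params, DimerIntermediateParams):
        return dimer_intermediate_network(params)
    if isinstance(params, DimerDissociationParams):
        return dimer_dissociation_network(params)
    if isinstance(params, SwapKernelParams):
        return swap_network(params)
    raise DomainError(f"unknown mechanism parameters: {type(params).__name__}")


# ---------------------------------------------------------------------------
# public simulation entry points


def simulate_intermediate_mechanism(
    params: DimerIntermediateParams,
    init: Mapping[str, float] | ReactionState,
    times: Iterable[float],
    qm: QuenchModel | None = None,
) -> Trajectory:
    return dimer_intermediate_network(params).simulate(init, times, qm)


def simulate_dissociation_mechanism(
    params: DimerDissociationParams,
    init: Mapping[str, float] | ReactionState,
    times: Iterable[float],
    qm: QuenchModel | None = None,
) -> Trajectory:
    return dimer_dissociation_network(params).simulate(init, times, qm)


def simulate_swap_kernel(
    params: SwapKernelParams,
    init: Mapping[str, float] | ReactionState,
    times: Iterable[float],
    qm: QuenchModel | None = None,
) -> Trajectory:
    return swap_network(params).simulate(init, times, qm)


def fluorescence_from_state(state: ReactionState, qm: QuenchModel | None = None) -> float:
    """Unquenched-label concentration (uM) of one reaction state."""
    qm = qm or QuenchModel()
    total = 0.0
    for sid, c in state.concentrations.items():
        if sid not in state.species:
            raise SchemaError(f"unknown species id {sid!r}")
        sp = state.species[sid]
        total += c * unquenched_labels_per_assembly(sp.n_labelled, sp.size, qm)
    return total


def gillespie_oracle(
    params,
    init: Mapping[str, float] | ReactionState,
    volume: float,
    seed: int,
    t_end: float,
    record_times: Iterable[float] | None = None,
    qm: QuenchModel | None = None,
) -> Trajectory:
    """Exact stochastic trajectory of the mechanism given by ``params``.

    Intended as a validation oracle at small copy numbers (counts ~1e3-1e5);
    identical seeds reproduce the event sequence bit-for-bit.
    """
    return network_for(params).gillespie(init, volume, seed, t_end, record_times, qm)
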