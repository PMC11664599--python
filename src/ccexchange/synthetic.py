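"""Synthetic plate-reader data with the statistical structure the analysis assumes.

Ground truth is a :class:`PeptideModel` per peptide: oligomer state ``n``, an
apparent second-order homotypic exchange-rate constant ``k_ref`` at 25 C
(defined so that ``k_obs = k_ref x [total assemblies]`` under pseudo-first-
order conditions), an Arrhenius activation enthalpy ``Ea`` and a pairwise
``compatibility`` scalar ``c`` in [0, 1] giving the fraction of full random
mixing a heterotypic pair reaches at equilibrium.

Time courses are produced by running the mechanistic simulators
(:mod:`ccexchange.kinetics`) at temperature-scaled rates and mapping species
to fluorescence through the self-quenching rule; plates evaluate exchange
extents analytically (1 h and 24 h from the pair's pseudo-first-order
kinetics at 25 C, annealed = full equilibrium).  Plate-reader gain and
baseline defaults are arbitrary because every downstream analysis is
affine-invariant.  All randomness flows through a single integer seed, so a
fixed seed reproduces records bit-for-bit.

The CC-Di defaults are calibrated so that the standard condition (2 uM
labelled + 200 uM unlabelled chains, i.e. 101 uM total dimers, at 25 C)
yields a fitted exchange half-life of 4.2 min:
``k_ref = ln2 / (4.2 * 101)`` per uM per minute.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import kinetics
from .errors import ConfigError, DomainError
from .fitting import arrhenius_scale
from .species import OligomerSpec, QuenchModel, unquenched_labelled_fraction

__all__ = [
    "PeptideModel",
    "NoiseModel",
    "AssayCondition",
    "generate_timecourse",
    "generate_temperature_series",
    "generate_endpoint_plate",
    "builtin_panels",
    "CC_DI_K_REF",
]

log = logging.getLogger(__name__)

#: Calibrated CC-Di apparent slope: fitted t1/2 = 4.2 min at 101 uM total dimers.
CC_DI_K_REF = math.log(2.0) / (4.2 * 101.0)

#: Plate-reader gauge defaults (arbitrary units); downstream analysis is
#: affine-invariant so these are inert.
DEFAULT_GAIN = 1000.0
DEFAULT_BASELINE = 50.0

T_REF_C = 25.0
_TIMEPOINT_MINUTES = {"1h": 60.0, "24h": 1440.0}
BUFFER_ID = "buffer"  # reserved unlabelled_id for labelled-alone controls


@dataclass
class PeptideModel:
    """Ground-truth generator parameters for one peptide."""

    name: str
    n: int
    k_ref: float  # per uM (assemblies) per minute at 25 C
    Ea: float  # kcal/mol
    K_D: float | None = None  # uM, used by the dissociation mechanism
    compatibility: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        OligomerSpec(self.name, self.n)  # validates n and raises early
        if self.k_ref < 0:
            raise DomainError("k_ref must be >= 0")
        for partner, c in self.compatibility.items():
            if not 0.0 <= c <= 1.0:
                raise DomainError(
                    f"compatibility c({self.name},{partner})={c} outside [0, 1]"
                )

    def compat(self, partner: str, warn_missing: bool = False) -> float:
        """c(self, partner); self-compatibility is 1, unlisted pairs are 0."""
        if partner == self.name:
            return 1.0
        if partner not in self.compatibility:
            if warn_missing:
                log.warning(
                    "no compatibility entry for (%s, %s); defaulting to 0",
                    self.name, partner,
                )
            return 0.0
        return self.compatibility[partner]

    @property
    def spec(self) -> OligomerSpec:
        return OligomerSpec(self.name, self.n)


@dataclass
class NoiseModel:
    """Multiplicative CV + additive baseline noise, both Gaussian, seeded."""

    cv: float = 0.02
    baseline_sd: float = 5.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.baseline_sd < 0:
            raise DomainError("noise magnitudes must be >= 0")


@dataclass
class AssayCondition:
    """Chain concentrations (uM), temperature (C) and optional time grid."""

    conc_labelled: float = 2.0
    conc_unlabelled: float = 200.0
    temperature: float = 25.0
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.conc_labelled <= 0:
            raise DomainError("labelled chain concentration must be positive")
        if self.conc_unlabelled < 0:
            raise DomainError("unlabelled chain concentration must be >= 0")


def _mechanism_for(
    peptide: PeptideModel, mechanism: str, temperature: float
):
    """Mechanism parameters at the assay temperature."""
    k = arrhenius_scale(peptide.k_ref, peptide.Ea, temperature, T_REF_C)
    if mechanism == "auto":
        mechanism = "intermediate" if peptide.n == 2 else "swap"
    if mechanism == "intermediate":
        if peptide.n != 2:
            raise ConfigError("the intermediate mechanism is defined for dimers only")
        return kinetics.intermediate_params_from_slope(k)
    if mechanism == "dissociation":
        if peptide.n != 2:
            raise ConfigError("the dissociation mechanism is defined for dimers only")
        kd = peptide.K_D if peptide.K_D is not None else 1e-4  # 0.1 nM
        # k_off chosen so the dissociation-limited rate matches k_ref at the
        # standard 100 uM excess: exchange flux ~ 2 k_off [LL].
        return kinetics.DimerDissociationParams.from_kd(k_off=k * 100.0 / 2.0, K_D=kd)
    if mechanism == "swap":
        return kinetics.SwapKernelParams(n=peptide.n, k_swap=k)
    raise ConfigError(f"unknown mechanism tag {mechanism!r}")


def _initial_state(peptide: PeptideModel, cond: AssayCondition, params) -> dict:
    """Fully segregated start: labelled and unlabelled homo-assemblies."""
    a_l = cond.conc_labelled / peptide.n
    a_u = cond.conc_unlabelled / peptide.n
    if isinstance(params, kinetics.SwapKernelParams):
        return {f"A{peptide.n}": a_l, "A0": a_u}
    return {"LL": a_l, "UU": a_u}


def _auto_times(peptide: PeptideModel, cond: AssayCondition) -> np.ndarray:
    """Time grid spanning ~5 relaxation times, capped at 48 h."""
    k25 = peptide.k_ref * (cond.conc_labelled + cond.conc_unlabelled) / peptide.n
    k = arrhenius_scale(k25, peptide.Ea, cond.temperature, T_REF_C)
    t_max = min(max(5.0 / max(k, 1e-9), 20.0), 2880.0)
    return np.linspace(0.0, t_max, 121)


def generate_timecourse(
    peptide: PeptideModel,
    cond: AssayCondition,
    noise: NoiseModel | None = None,
    mechanism: str = "auto",
    n_replicates: int = 3,
    qm: QuenchModel | None = None,
    gain: float = DEFAULT_GAIN,
    baseline: float = DEFAULT_BASELINE,
) -> pd.DataFrame:
    """Simulated fluorescence time course, long format.

    Columns: ``time_min``, ``fluorescence_au``, ``replicate``.  The
    deterministic mechanistic trajectory is shared across replicates; each
    replicate draws its own noise from the seeded generator.
    """
    noise = noise or NoiseModel()
    params = _mechanism_for(peptide, mechanism, cond.temperature)
    times = cond.times if cond.times is not None else _auto_times(peptide, cond)
    traj = kinetics.network_for(params).simulate(
        _initial_state(peptide, cond, params), times, qm
    )
    clean = baseline + gain * traj.observable
    rng = np.random.default_rng(noise.seed)
    frames = []
    for rep in range(1, n_replicates + 1):
        noisy = clean * (1.0 + noise.cv * rng.standard_normal(clean.size))
        noisy = noisy + noise.baseline_sd * rng.standard_normal(clean.size)
        frames.append(
            pd.DataFrame(
                {
                    "time_min": traj.times,
                    "fluorescence_au": noisy,
                    "replicate": rep,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_temperature_series(
    peptide: PeptideModel,
    temps_celsius,
    cond: AssayCondition,
    noise: NoiseModel | None = None,
    **kwargs,
) -> dict[float, pd.DataFrame]:
    """One time course per temperature, same noise seed for every trace.

    Rates follow the Arrhenius law from (k_ref at 25 C, Ea); with Ea = 0 and
    a fixed seed every temperature reproduces the identical records.
    """
    temps = list(temps_celsius)
    if not temps:
        raise ConfigError("temperature list is empty")
    out: dict[float, pd.DataFrame] = {}
    for t_c in temps:
        cond_t = replace(cond, temperature=float(t_c))
        out[float(t_c)] = generate_timecourse(peptide, cond_t, noise, **kwargs)
    return out


def _pair_kobs(labelled: PeptideModel, unlabelled: PeptideModel, a_unlabelled: float) -> float:
    """Pseudo-first-order rate for a (labelled, unlabelled) pair at 25 C.

    The geometric mean of the two homotypic rate constants: a symmetric,
    label-free combination that reduces to the homotypic rate on the
    diagonal.
    """
    return math.sqrt(labelled.k_ref * unlabelled.k_ref) * a_unlabelled


def generate_endpoint_plate(
    panel: list[PeptideModel],
    ratio: float = 0.1,
    timepoints=("1h", "24h", "annealed"),
    noise: NoiseModel | None = None,
    conc_labelled: float = 2.0,
    n_replicates: int = 3,
    qm: QuenchModel | None = None,
    gain: float = DEFAULT_GAIN,
    baseline: float = DEFAULT_BASELINE,
) -> pd.DataFrame:
    """Full (labelled x unlabelled) endpoint plate in long format.

    ``ratio`` is labelled:unlabelled assembled species (default 1:10).  For
    each pair, the 1 h / 24 h exchange extents follow the pair's
    pseudo-first-order kinetics at 25 C and the annealed extent is 1 (the
    anneal drives the mixture to its thermodynamic equilibrium); the
    equilibrium dequench level combines the labelled peptide's oligomer
    state with the pair's compatibility scalar.  Buffer controls are emitted
    for every labelled peptide and timepoint.
    """
    if not panel:
        raise ConfigError("empty peptide panel")
    if ratio <= 0:
        raise DomainError("assembly ratio must be positive")
    bad_tp = sorted(set(timepoints) - {"1h", "24h", "annealed"})
    if bad_tp:
        raise ConfigError(f"unknown timepoints {bad_tp}")
    noise = noise or NoiseModel()
    qm = qm or QuenchModel()
    rng = np.random.default_rng(noise.seed)

    def emit(labelled_id, unlabelled_id, timepoint, clean, rows):
        for rep in range(1, n_replicates + 1):
            v = clean * (1.0 + noise.cv * rng.standard_normal())
            v += noise.baseline_sd * rng.standard_normal()
            rows.append((labelled_id, unlabelled_id, timepoint, rep, max(v, 0.0)))

    rows: list[tuple] = []
    for pep_l in panel:
        a_l = conc_labelled / pep_l.n  # labelled assemblies, uM
        a_u = a_l / ratio  # unlabelled assemblies, uM
        f_quenched = unquenched_labelled_fraction(pep_l.spec, 1.0, qm)
        for tp in timepoints:
            emit(pep_l.name, BUFFER_ID, tp, baseline + gain * conc_labelled * f_quenched, rows)
        for pep_u in panel:
            chains_u = a_u * pep_u.n
            p = conc_labelled / (conc_labelled + chains_u)
            f_full = unquenched_labelled_fraction(pep_l.spec, p, qm)
            c = pep_l.compat(pep_u.name, warn_missing=True)
            k_obs = _pair_kobs(pep_l, pep_u, a_u)
            for tp in timepoints:
                if tp == "annealed":
                    extent = 1.0
                else:
                    extent = 1.0 - math.exp(-k_obs * _TIMEPOINT_MINUTES[tp])
                f = f_quenched + c * extent * (f_full - f_quenched)
                emit(pep_l.name, pep_u.name, tp, baseline + gain * conc_labelled * f, rows)
    return pd.DataFrame(
        rows,
        columns=["labelled_id", "unlabelled_id", "timepoint", "replicate", "fluorescence_au"],
    )


# ---------------------------------------------------------------------------
# built-in panels


def _sym(compat: dict[tuple[str, str], float]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for (a, b), c in compat.items():
        out.setdefault(a, {})[b] = c
        out.setdefault(b, {})[a] = c
    return out


def builtin_panels() -> dict[str, list[PeptideModel]]:
    """Named ground-truth panels.

    ``basis_set``
        Dimer through heptamer with the qualitative exchange classes seen in
        the endpoint screens: the dimer exchanges only with itself, the
        trimer and tetramer cross-exchange (similar Type-I heptad repeats),
        and the three alpha-helical barrels (Type-II interfaces)
        cross-exchange with each other.
    ``orthogonal_set``
        The redesigned panel (salt-bridge repositioned tetramer, hendecad
        pentamer/heptamer): off-diagonal compatibilities are small, with a
        modest residual promiscuity among the tetramer, pentamer and
        hexamer.
    ``ideal``
        All off-diagonal compatibilities exactly zero.

    Numeric compatibility values are generator ground truth chosen to encode
    those classes; they are not measured quantities.
    """
    base_rates = {
        # (n, k_ref per uM assemblies per min at 25 C, Ea kcal/mol)
        "CC-Di": (2, CC_DI_K_REF, 37.9),
        "CC-Tri": (3, 2e-5, 33.0),
        "CC-Tet": (4, 8e-4, 35.0),
        "CC-Pent2": (5, 2e-5, 36.0),
        "CC-Hex2": (6, 6e-4, 34.0),
        "CC-Hept": (7, 3e-5, 38.0),
        "CC-Tet*": (4, 8e-4, 35.0),
        "CC-Pent2-hen3": (5, 2e-5, 36.0),
        "CC-Hept-IV-hen2": (7, 3e-5, 38.0),
    }

    def build(names, compat):
        table = _sym(compat)
        return [
            PeptideModel(
                name=nm,
                n=base_rates[nm][0],
                k_ref=base_rates[nm][1],
                Ea=base_rates[nm][2],
                K_D=1e-4 if nm == "CC-Di" else None,
                compatibility=table.get(nm, {}),
            )
            for nm in names
        ]

    basis_names = ["CC-Di", "CC-Tri", "CC-Tet", "CC-Pent2", "CC-Hex2", "CC-Hept"]
    basis_compat = {
        ("CC-Tri", "CC-Tet"): 0.80,
        ("CC-Pent2", "CC-Hex2"): 0.70,
        ("CC-Pent2", "CC-Hept"): 0.65,
        ("CC-Hex2", "CC-Hept"): 0.75,
        ("CC-Tet", "CC-Pent2"): 0.25,
        ("CC-Tet", "CC-Hex2"): 0.25,
        ("CC-Tet", "CC-Hept"): 0.30,
        ("CC-Tri", "CC-Pent2"): 0.10,
        ("CC-Tri", "CC-Hex2"): 0.10,
        ("CC-Tri", "CC-Hept"): 0.15,
        ("CC-Di", "CC-Tri"): 0.02,
        ("CC-Di", "CC-Tet"): 0.02,
        ("CC-Di", "CC-Pent2"): 0.02,
        ("CC-Di", "CC-Hex2"): 0.02,
        ("CC-Di", "CC-Hept"): 0.02,
    }

    ortho_names = [
        "CC-Di", "CC-Tri", "CC-Tet*", "CC-Pent2-hen3", "CC-Hex2", "CC-Hept-IV-hen2",
    ]
    ortho_compat = {
        ("CC-Tet*", "CC-Pent2-hen3"): 0.28,
        ("CC-Tet*", "CC-Hex2"): 0.22,
        ("CC-Pent2-hen3", "CC-Hex2"): 0.30,
        ("CC-Tri", "CC-Tet*"): 0.08,
        ("CC-Tri", "CC-Pent2-hen3"): 0.05,
        ("CC-Tri", "CC-Hex2"): 0.05,
        ("CC-Tri", "CC-Hept-IV-hen2"): 0.05,
        ("CC-Tet*", "CC-Hept-IV-hen2"): 0.08,
        ("CC-Pent2-hen3", "CC-Hept-IV-hen2"): 0.10,
        ("CC-Hex2", "CC-Hept-IV-hen2"): 0.10,
        ("CC-Di", "CC-Tri"): 0.02,
        ("CC-Di", "CC-Tet*"): 0.02,
        ("CC-Di", "CC-Pent2-hen3"): 0.02,
        ("CC-Di", "CC-Hex2"): 0.02,
        ("CC-Di", "CC-Hept-IV-hen2"): 0.02,
    }

    ideal_compat = {
        (a, b): 0.0
        for i, a in enumerate(basis_names)
        for b in basis_names[i + 1 :]
    }

    return {
        "basis_set": build(basis_names, basis_compat),
        "orthogonal_set": build(ortho_names, ortho_compat),
        "ideal": build(basis_names, ideal_compat),
    }
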