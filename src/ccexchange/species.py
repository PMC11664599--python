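"""Composition statistics of labelled/unlabelled coiled-coil oligomers.

A parallel coiled coil with oligomer state ``n`` is treated as an unordered
multiset of ``n`` chains, each chain either carrying an N-terminal
fluorophore (labelled, ``l``) or not (unlabelled, ``u``).  For a trimer the
assembled species are therefore u-u-u, u-u-l, u-l-l and l-l-l: exactly
``n + 1`` compositions for an ``n``-mer.

Under full, label-blind mixing the chains partition randomly, so at
equilibrium the number of labelled chains in an assembly is binomial:
``P(l) = C(n, l) p^l (1 - p)^(n - l)`` where ``p`` is the bulk fraction of
labelled chains.

Fluorescence follows a self-quenching rule: the fluorophore quenches when
two or more labelled chains are held in the same assembly (their effective
local concentration is far above the self-quenching threshold).  Under this
binary rule a labelled chain fluoresces iff all of its ``n - 1`` partners
are unlabelled, so the expected fluorescent fraction of labelled chains at
full mixing is ``(1 - p)^(n - 1)``.  A ``residual_quench`` parameter allows
quenched fluorophores to retain a fraction of their emission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError, InvalidOligomerError

__all__ = [
    "OligomerSpec",
    "Composition",
    "CompositionDistribution",
    "QuenchModel",
    "enumerate_compositions",
    "composition_distribution",
    "unquenched_labelled_fraction",
    "expected_endpoint_signal",
    "unquenched_labels_per_assembly",
]

#: Largest oligomer state supported by the package (dimer through nonamer).
MAX_OLIGOMER_STATE = 9


@dataclass(frozen=True)
class OligomerSpec:
    """A parallel homo-oligomer: ``n`` chains per assembly."""

    name: str
    n: int
    topology: str = "parallel"

    def __post_init__(self) -> None:
        if not isinstance(self.n, int) or self.n < 2:
            raise InvalidOligomerError(
                f"oligomer state must be an integer >= 2, got {self.n!r}"
            )
        if self.n > MAX_OLIGOMER_STATE:
            raise InvalidOligomerError(
                f"oligomer state {self.n} exceeds supported maximum "
                f"{MAX_OLIGOMER_STATE}"
            )
        if self.topology != "parallel":
            raise InvalidOligomerError(
                f"only parallel topologies are modelled, got {self.topology!r}"
            )


@dataclass(frozen=True, order=True)
class Composition:
    """Chain content of one assembly: ``n_labelled`` + ``n_unlabelled``."""

    n_labelled: int
    n_unlabelled: int

    def __post_init__(self) -> None:
        if self.n_labelled < 0 or self.n_unlabelled < 0:
            raise DomainError("chain counts must be non-negative")

    @property
    def size(self) -> int:
        return self.n_labelled + self.n_unlabelled


@dataclass
class QuenchModel:
    """Mapping from assembly composition to per-label fluorescence.

    rule
        Only ``"binary"`` is implemented: a labelled chain fluoresces iff it
        is the only labelled chain in its assembly.
    residual_quench
        Fraction of emission retained by a quenched fluorophore, in [0, 1).
        Zero (default) means complete self-quenching.
    """

    rule: str = "binary"
    residual_quench: float = 0.0

    def __post_init__(self) -> None:
        if self.rule != "binary":
            raise DomainError(f"unknown quench rule {self.rule!r}")
        if not 0.0 <= self.residual_quench < 1.0:
            raise DomainError(
                f"residual_quench must be in [0, 1), got {self.residual_quench}"
            )


@dataclass
class CompositionDistribution:
    """Probability over the ``n + 1`` compositions of one oligomer."""

    spec: OligomerSpec
    label_fraction: float
    probabilities: dict[Composition, float] = field(default_factory=dict)

    def as_array(self):
        """Probabilities ordered by ascending labelled-chain count."""
        import numpy as np

        return np.array(
            [self.probabilities[c] for c in enumerate_compositions(self.spec)]
        )


def enumerate_compositions(spec: OligomerSpec) -> list[Composition]:
    """All assembled species of a parallel ``n``-mer, ordered by labelled count.

    Parallel assemblies are unordered multisets of chains, so the species are
    fully determined by how many of the ``n`` chains are labelled: there are
    exactly ``n + 1`` of them.
    """
    return [Composition(l, spec.n - l) for l in range(spec.n + 1)]


def composition_distribution(spec: OligomerSpec, p: float) -> CompositionDistribution:
    """Equilibrium composition distribution under random chain mixing.

    ``p`` is the bulk labelled-chain fraction; the labelled count per
    assembly is Binomial(n, p).
    """
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"label fraction must be in [0, 1], got {p}")
    probs = {
        comp: math.comb(spec.n, comp.n_labelled)
        * p**comp.n_labelled
        * (1.0 - p) ** comp.n_unlabelled
        for comp in enumerate_compositions(spec)
    }
    return CompositionDistribution(spec=spec, label_fraction=p, probabilities=probs)


def unquenched_labels_per_assembly(
    n_labelled: int, assembly_size: int, qm: QuenchModel | None = None
) -> float:
    """Expected number of fluorescent labels in one assembly.

    Free labelled monomers (assembly_size 1) count as fully fluorescent: at
    micromolar bulk concentration an unassembled fluorophore cannot
    self-quench.  In larger assemblies the binary rule applies.
    """
    qm = qm or QuenchModel()
    if n_labelled == 0:
        return 0.0
    if assembly_size == 1:
        return float(n_labelled)
    unquenched = 1.0 if n_labelled == 1 else 0.0
    return unquenched + qm.residual_quench * (n_labelled - unquenched)


def unquenched_labelled_fraction(
    spec: OligomerSpec, p: float, qm: QuenchModel | None = None
) -> float:
    """Fluorescent fraction of labelled chains at full random mixing.

    A labelled chain fluoresces iff its ``n - 1`` partners are all
    unlabelled, which happens with probability ``(1 - p)^(n - 1)``; quenched
    labels retain ``residual_quench`` of their emission.
    """
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"label fraction must be in [0, 1], got {p}")
    qm = qm or QuenchModel()
    sole = (1.0 - p) ** (spec.n - 1)
    return sole + qm.residual_quench * (1.0 - sole)


def expected_endpoint_signal(
    spec: OligomerSpec,
    chain_ratio_labelled_to_unlabelled: float,
    qm: QuenchModel | None = None,
) -> float:
    """Theoretical normalized fluorescence plateau at full exchange.

    The assay mixes labelled and unlabelled material at a fixed chain ratio
    ``r`` (0.1 for the standard 1:10 mix of assembled species of the same
    oligomer).  That ratio fixes the label fraction ``p = r / (1 + r)`` and
    the plateau is the unquenched labelled fraction at that ``p``.
    ``math.inf`` is accepted and means fully labelled material (p = 1).
    """
    r = chain_ratio_labelled_to_unlabelled
    if not r > 0:
        raise DomainError(f"chain ratio must be positive, got {r}")
    p = 1.0 if math.isinf(r) else r / (1.0 + r)
    return unquenched_labelled_fraction(spec, p, qm)
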