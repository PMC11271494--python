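"""Force-extension models for folded bodies and unfolded peptide chains.

A stretched single-molecule tether is modelled as a mechanical series of
segments that all carry the same tension:

* a folded domain or a dimerized pair of rods is a rigid body of span ``b``
  whose orientational fluctuations follow the single-segment freely-jointed
  chain (FJC), so its mean extension is ``b * L(f b / kBT)`` with ``L`` the
  Langevin function;
* an unfolded peptide chain of ``N`` residues is a worm-like chain (WLC)
  with persistence length ``A`` and contour length ``N * l0``, following the
  Marko-Siggia interpolation formula.

The predicted bead-height step of a structural transition at force ``f`` is
the difference between the summed extensions of the "after" and "before"
series evaluated at that force.

Units are pN, nm, s and pN nm throughout; no conversions happen inside the
functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

from scipy.optimize import brentq

__all__ = [
    "KBT_22C",
    "PolymerEnvironment",
    "RigidSegment",
    "FlexibleChain",
    "FixedSpan",
    "Segment",
    "DEFAULT_ENV",
    "rigid_extension",
    "wlc_force",
    "wlc_extension",
    "loop_force",
    "segment_extension",
    "series_extension",
    "transition_step_size",
]

#: Thermal energy at 22 degC (295.15 K) in pN nm, the experimental temperature.
KBT_22C = 4.075

# Langevin-function argument below which the series expansion y/3 - y^3/45
# is used instead of coth(y) - 1/y (catastrophic cancellation region).
_LANGEVIN_SERIES_CUTOFF = 1e-4

# WLC inversion bracket: x in [0, L * (1 - eps)].
_WLC_BRACKET_EPS = 1e-9


@dataclass(frozen=True)
class PolymerEnvironment:
    """Physical constants shared by all polymer models.

    Parameters
    ----------
    kBT : float
        Thermal energy in pN nm. Default is the value at 22 degC.
    persistence_length : float
        WLC bending persistence length ``A`` of an unstructured peptide, nm.
    contour_per_residue : float
        Contour length per residue ``l0``, nm.
    """

    kBT: float = KBT_22C
    persistence_length: float = 0.8
    contour_per_residue: float = 0.38

    def __post_init__(self) -> None:
        for name in ("kBT", "persistence_length", "contour_per_residue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PolymerEnvironment.{name} must be > 0")


DEFAULT_ENV = PolymerEnvironment()


@dataclass(frozen=True)
class RigidSegment:
    """A folded body of span ``b`` (nm) between its force-attachment points."""

    span: float

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise ValueError(f"RigidSegment.span must be > 0, got {self.span}")


@dataclass(frozen=True)
class FlexibleChain:
    """An unstructured peptide chain of ``n_residues`` residues."""

    n_residues: int

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError(
                f"FlexibleChain.n_residues must be >= 1, got {self.n_residues}"
            )

    def contour_length(self, env: PolymerEnvironment = DEFAULT_ENV) -> float:
        """Contour length ``N * l0`` in nm."""
        return self.n_residues * env.contour_per_residue


@dataclass(frozen=True)
class FixedSpan:
    """A force-independent geometric offset (nm).

    Used for distances imposed by the tether geometry rather than by tension,
    e.g. the end-to-end distance of a looped linker held inside a dimer.
    ``span`` may be zero; it never responds to force.
    """

    span: float

    def __post_init__(self) -> None:
        if self.span < 0:
            raise ValueError(f"FixedSpan.span must be >= 0, got {self.span}")


Segment = Union[RigidSegment, FlexibleChain, FixedSpan]


def _langevin(y: float) -> float:
    if y < _LANGEVIN_SERIES_CUTOFF:
        return y / 3.0 - y**3 / 45.0
    return 1.0 / math.tanh(y) - 1.0 / y


def rigid_extension(
    force: float, segment: RigidSegment, env: PolymerEnvironment = DEFAULT_ENV
) -> float:
    """Mean extension (nm) of a rigid body under tension.

    Single-segment FJC: ``x(f) = b * (coth(fb/kBT) - kBT/(fb))``. The f -> 0
    limit is evaluated by series expansion and returns 0 exactly at f = 0.
    """
    if segment.span <= 0:
        raise ValueError("rigid body span must be positive")
    if force < 0:
        raise ValueError(f"force must be >= 0, got {force}")
    if force == 0:
        return 0.0
    return segment.span * _langevin(force * segment.span / env.kBT)


def wlc_force(
    extension: float, chain: FlexibleChain, env: PolymerEnvironment = DEFAULT_ENV
) -> float:
    """Tension (pN) of a worm-like chain at a given extension (nm).

    Marko-Siggia interpolation:
    ``f A / kBT = 1/(4 (1 - x/L)^2) - 1/4 + x/L`` with ``L = N * l0``.
    Diverges as x -> L; extensions at or beyond the contour length raise.
    """
    L = chain.contour_length(env)
    if extension < 0:
        raise ValueError(f"extension must be >= 0, got {extension}")
    if extension >= L:
        raise ValueError(
            f"extension {extension} nm is at or beyond contour length {L} nm"
        )
    z = extension / L
    return env.kBT / env.persistence_length * (0.25 / (1.0 - z) ** 2 - 0.25 + z)


def wlc_extension(
    force: float, chain: FlexibleChain, env: PolymerEnvironment = DEFAULT_ENV
) -> float:
    """Extension (nm) of a worm-like chain at a given tension (pN).

    Numerical inversion of the Marko-Siggia relation by bracketed root
    finding on ``[0, L (1 - 1e-9)]``; deterministic, no randomness.
    """
    if force < 0:
        raise ValueError(f"force must be >= 0, got {force}")
    if force == 0:
        return 0.0
    L = chain.contour_length(env)
    hi = L * (1.0 - _WLC_BRACKET_EPS)
    try:
        return brentq(
            lambda x: wlc_force(x, chain, env) - force,
            0.0,
            hi,
            xtol=1e-12,
            rtol=8.9e-16,
            maxiter=200,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"WLC inversion failed for force={force} pN, N={chain.n_residues} "
            f"(contour {L} nm): {exc}"
        ) from exc


def loop_force(
    chain: FlexibleChain, end_to_end: float, env: PolymerEnvironment = DEFAULT_ENV
) -> float:
    """Maximal force (pN) a looped flexible linker exerts across a dimer.

    The looped linker is a WLC whose end-to-end distance is imposed by the
    dimer geometry, so the force it applies is the WLC tension at that
    distance.
    """
    return wlc_force(end_to_end, chain, env)


def segment_extension(
    force: float, segment: Segment, env: PolymerEnvironment = DEFAULT_ENV
) -> float:
    """Extension (nm) of one segment at the given tension."""
    if isinstance(segment, RigidSegment):
        return rigid_extension(force, segment, env)
    if isinstance(segment, FlexibleChain):
        return wlc_extension(force, segment, env)
    if isinstance(segment, FixedSpan):
        return segment.span
    raise TypeError(f"unknown segment type: {type(segment).__name__}")


def series_extension(
    force: float, segments: Sequence[Segment], env: PolymerEnvironment = DEFAULT_ENV
) -> float:
    """Total extension (nm) of a mechanical series of segments.

    Segments in series share the same tension, so extensions add.
    """
    return sum(segment_extension(force, s, env) for s in segments)


def transition_step_size(
    force: float,
    before: Sequence[Segment],
    after: Sequence[Segment],
    env: PolymerEnvironment = DEFAULT_ENV,
) -> float:
    """Predicted bead-height step (nm) of a structural transition at ``force``.

    The step is the extension of the after-series minus the extension of the
    before-series at the same force. Positive values correspond to
    extension-gaining transitions (unfolding, rupture); refolding and
    re-dimerization steps come out negative when the series are swapped.
    """
    if force <= 0:
        raise ValueError(f"force must be > 0 for a transition step, got {force}")
    if not before or not after:
        raise ValueError("before and after series must be non-empty")
    return series_extension(force, after, env) - series_extension(force, before, env)
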