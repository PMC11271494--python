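"""Declarative single-molecule construct descriptions and step-size tables.

A construct is two spectrin-repeat (SR) rods dimerized anti-parallel, with a
long flexible linker looped inside the dimer, pulled either in shear
geometry (same-side termini, interfaces loaded in parallel) or unzip
geometry (peeling from one end). A conformational state of the tether maps
deterministically onto a mechanical series of rigid and flexible segments;
step-size predictions follow from the polymer models.

State bookkeeping, shear geometry:

* dimerized: the dimer contributes its rigid span; each un-paired boundary
  pair reroutes the force path through one domain, which contributes its
  folded span while folded and its residue chain once unfolded;
* ruptured: the force path runs through the whole tethered rod (rigid span
  if folded, one chain of ``total_residues`` if fully unfolded) and the
  released loop linker. In unzip geometry both rods end up on the path.

The looped linker is off the force path while the dimer is intact; its
geometrically imposed end-to-end distance can optionally be included as a
force-independent span so that a pure-release step equals the linker's WLC
extension minus that distance (``include_loop_geometry=True``). The default
leaves it out, which is the convention under which the composite
rupture-plus-unfolding steps reproduce the published predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .polymer import (
    DEFAULT_ENV,
    FixedSpan,
    FlexibleChain,
    PolymerEnvironment,
    RigidSegment,
    Segment,
    series_extension,
    transition_step_size,
    wlc_extension,
)

__all__ = [
    "DomainSpec",
    "RodSpec",
    "ConstructSpec",
    "TetherState",
    "state_to_series",
    "predicted_step_table",
    "loop_release_step",
    "get_preset",
    "list_presets",
]


@dataclass(frozen=True)
class DomainSpec:
    """One folded domain on the force-bearing path (SR defaults)."""

    name: str = "SR"
    n_residues: int = 110
    folded_span: float = 5.0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("DomainSpec.n_residues must be >= 1")
        if not (0 < self.folded_span < self.n_residues * 0.38):
            raise ValueError(
                "DomainSpec.folded_span must be positive and smaller than the "
                "chain contour length"
            )


@dataclass(frozen=True)
class RodSpec:
    """A tandem-SR rod: ordered domains plus total residue count and span.

    ``total_residues`` may exceed the sum over domains; the helical linkers
    between repeats account for the remainder.
    """

    domains: tuple[DomainSpec, ...]
    total_residues: int = 480
    folded_span: float = 24.0

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("RodSpec needs at least one domain")
        if self.total_residues < sum(d.n_residues for d in self.domains):
            raise ValueError(
                "RodSpec.total_residues must cover the residues of its domains"
            )
        if self.folded_span <= 0:
            raise ValueError("RodSpec.folded_span must be > 0")

    @property
    def n_domains(self) -> int:
        return len(self.domains)


def _sr_rod(n_domains: int, total_residues: int, folded_span: float) -> RodSpec:
    return RodSpec(
        domains=tuple(DomainSpec(name=f"SR{i + 1}") for i in range(n_domains)),
        total_residues=total_residues,
        folded_span=folded_span,
    )


@dataclass(frozen=True)
class ConstructSpec:
    """A complete tether: geometry, rods, loop linker and dimer spans."""

    name: str
    geometry: str  # "shear" | "unzip"
    rods: tuple[RodSpec, RodSpec]
    loop_linker: FlexibleChain
    dimer_span_before: float
    dimer_spans_after: tuple[float, ...]
    loop_end_to_end_in_dimer: float

    def __post_init__(self) -> None:
        if self.geometry not in ("shear", "unzip"):
            raise ValueError(
                f"geometry must be 'shear' or 'unzip', got {self.geometry!r}"
            )
        if self.dimer_span_before <= 0 or any(s <= 0 for s in self.dimer_spans_after):
            raise ValueError("all dimer spans must be positive")
        if self.loop_end_to_end_in_dimer < 0:
            raise ValueError("loop end-to-end distance must be >= 0")

    @property
    def path_rods(self) -> tuple[RodSpec, ...]:
        """Rods on the force path after rupture.

        In shear geometry only the surface-tethered rod stays on the path
        (the partner dangles from the bead); in unzip geometry the path runs
        through both rods in series.
        """
        return self.rods if self.geometry == "unzip" else self.rods[:1]

    @property
    def n_pairs(self) -> int:
        return self.rods[0].n_domains


@dataclass(frozen=True)
class TetherState:
    """Conformational state of the tether.

    ``open_pairs`` counts boundary domain pairs that are un-paired while the
    dimer as a whole is intact; each reroutes the force path through one
    domain. ``unfolded`` counts unfolded force-bearing domains (a subset of
    the open ones while dimerized; any of the path-rod domains once
    ruptured). ``loop_released`` defaults to the complement of ``dimerized``
    and must stay consistent with it.
    """

    dimerized: bool = True
    open_pairs: int = 0
    unfolded: int = 0
    loop_released: bool | None = None

    def __post_init__(self) -> None:
        released = (not self.dimerized) if self.loop_released is None else self.loop_released
        object.__setattr__(self, "loop_released", released)
        if self.loop_released == self.dimerized:
            raise ValueError(
                "inconsistent state: the loop is released if and only if the "
                "dimer is ruptured"
            )
        if self.open_pairs < 0 or self.unfolded < 0:
            raise ValueError("open_pairs and unfolded must be >= 0")
        if self.dimerized and self.unfolded > self.open_pairs:
            raise ValueError(
                "while dimerized only un-paired (open) domains can be unfolded"
            )

    def describe(self) -> str:
        if self.dimerized:
            tag = f"dimer+{self.open_pairs}open+{self.unfolded}unf"
        else:
            tag = f"ruptured+{self.unfolded}unf"
        return tag


def _rod_series(rod: RodSpec, n_unfolded: int) -> list[Segment]:
    """Series for one post-rupture rod with ``n_unfolded`` unfolded domains."""
    if n_unfolded == 0:
        return [RigidSegment(rod.folded_span)]
    if n_unfolded >= rod.n_domains:
        # Fully unfolded: one chain covering domains plus helical linkers.
        return [FlexibleChain(rod.total_residues)]
    segs: list[Segment] = [FlexibleChain(d.n_residues) for d in rod.domains[:n_unfolded]]
    segs += [RigidSegment(d.folded_span) for d in rod.domains[n_unfolded:]]
    return segs


def state_to_series(
    construct: ConstructSpec,
    state: TetherState,
    include_loop_geometry: bool = False,
) -> list[Segment]:
    """Map a tether state onto its mechanical series of segments.

    With ``include_loop_geometry=True`` the unreleased loop's imposed
    end-to-end distance enters the dimerized series as a fixed span, so that
    rupture steps subtract it (the linker extension-difference convention);
    by default the unreleased loop contributes nothing.
    """
    if state.dimerized:
        if state.open_pairs > construct.n_pairs:
            raise ValueError(
                f"state opens {state.open_pairs} pairs but the construct has "
                f"only {construct.n_pairs}"
            )
        segs: list[Segment] = [RigidSegment(construct.dimer_span_before)]
        domains = construct.rods[0].domains
        for i in range(state.open_pairs):
            d = domains[min(i, len(domains) - 1)]
            if i < state.unfolded:
                segs.append(FlexibleChain(d.n_residues))
            else:
                segs.append(RigidSegment(d.folded_span))
        if include_loop_geometry and construct.loop_end_to_end_in_dimer > 0:
            segs.append(FixedSpan(construct.loop_end_to_end_in_dimer))
        return segs

    # Ruptured: path rods plus the released loop linker.
    path = construct.path_rods
    max_unfolded = sum(r.n_domains for r in path)
    if state.unfolded > max_unfolded:
        raise ValueError(
            f"state unfolds {state.unfolded} domains but the force path has "
            f"only {max_unfolded}"
        )
    if state.unfolded == 0:
        segs = [RigidSegment(s) for s in construct.dimer_spans_after]
    else:
        segs = []
        remaining = state.unfolded
        for rod in path:
            take = min(remaining, rod.n_domains)
            segs.extend(_rod_series(rod, take))
            remaining -= take
    segs.append(FlexibleChain(construct.loop_linker.n_residues))
    return segs


def predicted_step_table(
    construct: ConstructSpec,
    transitions: Iterable[tuple[TetherState, TetherState]],
    forces: Sequence[float],
    env: PolymerEnvironment = DEFAULT_ENV,
    include_loop_geometry: bool = False,
) -> pd.DataFrame:
    """Step-size predictions for a set of transitions on a force grid.

    Returns a tidy table with columns ``transition``, ``force_pN`` and
    ``step_nm``; one row per (transition, force) cell. The force grid must
    be positive and ascending.
    """
    forces = list(forces)
    if any(f <= 0 for f in forces):
        raise ValueError("forces must be positive")
    if any(b >= a for b, a in zip(forces, forces[1:])):
        raise ValueError("forces must be strictly ascending")
    rows = []
    for before, after in transitions:
        label = f"{before.describe()}->{after.describe()}"
        b_series = state_to_series(construct, before, include_loop_geometry)
        a_series = state_to_series(construct, after, include_loop_geometry)
        for f in forces:
            rows.append(
                {
                    "transition": label,
                    "force_pN": f,
                    "step_nm": transition_step_size(f, b_series, a_series, env),
                }
            )
    return pd.DataFrame(rows, columns=["transition", "force_pN", "step_nm"])


def loop_release_step(
    construct: ConstructSpec,
    force: float,
    env: PolymerEnvironment = DEFAULT_ENV,
) -> float:
    """Step (nm) from releasing the looped linker alone at ``force``.

    The extension difference of the looped linker before and after rupture:
    its WLC extension at the transition force minus the end-to-end distance
    the dimer geometry imposed on it.
    """
    return (
        wlc_extension(force, construct.loop_linker, env)
        - construct.loop_end_to_end_in_dimer
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _load_preset_data() -> dict:
    text = resources.files("dimerforce").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def _construct_from_dict(name: str, d: dict) -> ConstructSpec:
    rod = _sr_rod(d["n_domains"], d["rod_residues"], d["rod_span"])
    return ConstructSpec(
        name=name,
        geometry=d["geometry"],
        rods=(rod, rod),
        loop_linker=FlexibleChain(d["loop_residues"]),
        dimer_span_before=d["dimer_span_before"],
        dimer_spans_after=tuple(d["dimer_spans_after"]),
        loop_end_to_end_in_dimer=d["loop_end_to_end_in_dimer"],
    )


def list_presets() -> list[str]:
    """Names of the built-in construct presets."""
    return sorted(_load_preset_data()["constructs"])


def get_preset(name: str) -> ConstructSpec:
    """Load a built-in construct preset by name."""
    data = _load_preset_data()["constructs"]
    if name not in data:
        raise KeyError(
            f"unknown construct preset {name!r}; available: {sorted(data)}"
        )
    return _construct_from_dict(name, data[name])
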