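"""Boolean-gate readouts of excitation dynamics.

A two-input gate is identified from how the network responds to the three
stimulated input pairs (x y) in {01, 10, 11} (the pair 00 leaves an
excitable medium at rest and needs no simulation). A 3-bit *response
vector* (b01, b10, b11) — did the readout fire under each pair — maps onto
the seven non-trivial gates:

    (1,1,1) or        x + y
    (1,0,1) select    y
    (1,1,0) xor       x ^ y
    (0,1,1) select    x
    (1,0,0) not-and   !x & y
    (0,1,0) and-not   x & !y
    (0,0,1) and       x & y
    (0,0,0) none

Four readout schemes are implemented: structural (which junction arms the
wavefronts reach), frequency-based (where high-frequency domains sit),
activity-level (intervals of mean network activity as logical True) and
spiking (aligned spike events at electrodes). The spiking scheme yields a
per-electrode gate census and a frequency-of-discovery hierarchy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import morphology

from . import fhn, probes
from .probes import INPUT_PAIRS, Domain, SpikeEvent
from .template import ConductiveMask

__all__ = [
    "GateLabel",
    "classify_response_vector",
    "StructuralResult",
    "structural_truth_table",
    "frequency_gate_placement",
    "ActivityGateRule",
    "activity_gates",
    "GateCensus",
    "spiking_gate_census",
    "compound_gate_report",
    "DEFAULT_ACTIVITY_RULES",
]


class GateLabel(str, Enum):
    OR = "or"                # x + y
    SELECT_Y = "select_y"    # y
    XOR = "xor"              # x ^ y
    SELECT_X = "select_x"    # x
    NOT_AND = "not_and"      # !x y
    AND_NOT = "and_not"      # x !y
    AND = "and"              # x y
    NONE = "none"


_VECTOR_TO_GATE = {
    (1, 1, 1): GateLabel.OR,
    (1, 0, 1): GateLabel.SELECT_Y,
    (1, 1, 0): GateLabel.XOR,
    (0, 1, 1): GateLabel.SELECT_X,
    (1, 0, 0): GateLabel.NOT_AND,
    (0, 1, 0): GateLabel.AND_NOT,
    (0, 0, 1): GateLabel.AND,
    (0, 0, 0): GateLabel.NONE,
}

#: the seven realisable gates, excluding NONE
GATES = tuple(g for g in GateLabel if g is not GateLabel.NONE)


def classify_response_vector(vector: Sequence[int]) -> GateLabel:
    """Map a (b01, b10, b11) response vector to its gate label."""
    v = tuple(int(b) for b in vector)
    if len(v) != 3 or any(b not in (0, 1) for b in v):
        raise ValueError(f"response vector must be three bits, got {vector!r}")
    return _VECTOR_TO_GATE[v]


# ---------------------------------------------------------------------------
# structural gates


@dataclass(frozen=True)
class StructuralResult:
    """Per-input-pair reachability of each output arm, and the Boolean
    function each arm therefore realises."""

    excited: Mapping[str, tuple[str, ...]]  # input pair -> excited outputs
    functions: Mapping[str, GateLabel]      # output arm -> gate
    non_functional: bool                    # no output reached for 11


def _pair_stimuli(h: str, spec, stim_kwargs):
    events = []
    if h[0] == "1":
        events.append(fhn.StimulusEvent(site=spec["x"], **stim_kwargs))
    if h[1] == "1":
        events.append(fhn.StimulusEvent(site=spec["y"], **stim_kwargs))
    return events


def structural_truth_table(
    mask: ConductiveMask,
    params: fhn.SimulationParams,
    output_labels: Sequence[str] | None = None,
    stim_kwargs: Mapping | None = None,
) -> StructuralResult:
    """Simulate the three input pairs on a junction fixture and read which
    output arms get excited.

    The mask's landmarks must contain input arms ``x`` and ``y``; outputs
    default to every other landmark except the hub. An output counts as
    excited when any node of its endpoint's 3x3 neighbourhood exceeds
    u > 0.1 at any step of the run. When both inputs together excite no
    output the geometry is flagged non-functional.
    """
    lm = mask.landmarks
    if "x" not in lm or "y" not in lm:
        raise ValueError("mask landmarks must include input arms 'x' and 'y'")
    if output_labels is None:
        output_labels = [k for k in lm if k not in ("x", "y", "hub")]
    stim_kwargs = dict(stim_kwargs or {})
    excited: dict[str, tuple[str, ...]] = {}
    for h in INPUT_PAIRS:
        rec = fhn.run(
            mask,
            params,
            stimuli=_pair_stimuli(h, lm, stim_kwargs),
            probes=fhn.ProbeSpec(track_frequency=False),
        )
        hit = []
        for out in output_labels:
            rr, cc = probes.neighborhood_indices(mask, lm[out])
            if rec.excited_ever[rr, cc].any():
                hit.append(out)
        excited[h] = tuple(hit)
    functions = {
        out: classify_response_vector(
            [int(out in excited[h]) for h in INPUT_PAIRS]
        )
        for out in output_labels
    }
    return StructuralResult(
        excited=excited,
        functions=functions,
        non_functional=len(excited["11"]) == 0,
    )


# ---------------------------------------------------------------------------
# frequency-based gates


@dataclass(frozen=True)
class GatePlacement:
    """A lattice region whose membership pattern across the three input
    pairs' high-frequency domains realises a gate."""

    gate: GateLabel
    nodes: tuple[tuple[int, int], ...]
    centroid: tuple[float, float]


def _presence_grid(domains: Iterable[Domain], shape) -> np.ndarray:
    grid = np.zeros(shape, dtype=bool)
    for d in domains:
        for r, c in d.nodes:
            grid[r, c] = True
    return grid


def frequency_gate_placement(
    domains_by_pair: Mapping[str, Sequence[Domain]],
    shape: tuple[int, int],
    colocate_radius: int = 10,
) -> dict[GateLabel, list[GatePlacement]]:
    """Electrode-placement regions for each gate from high-frequency
    domain maps.

    A lattice node is *near* an input pair's output domains when it lies
    within ``colocate_radius`` of any domain node for that pair. For each
    of the seven gates, the regions reported are the 8-connected components
    of nodes near exactly the pairs with a 1-bit in the gate's response
    vector (e.g. xor: near 01- and 10-domains but not near any 11-domain).
    """
    near = {}
    selem = morphology.disk(colocate_radius)
    for h in INPUT_PAIRS:
        g = _presence_grid(domains_by_pair.get(h, ()), shape)
        near[h] = morphology.dilation(g, selem) if g.any() else g
    out: dict[GateLabel, list[GatePlacement]] = {}
    from skimage import measure

    for vec, gate in _VECTOR_TO_GATE.items():
        if gate is GateLabel.NONE:
            continue
        match = np.ones(shape, dtype=bool)
        for h, bit in zip(INPUT_PAIRS, vec):
            match &= near[h] if bit else ~near[h]
        placements = []
        if match.any():
            labels = measure.label(match, connectivity=2)
            for region in measure.regionprops(labels):
                placements.append(
                    GatePlacement(
                        gate=gate,
                        nodes=tuple((int(r), int(c)) for r, c in region.coords),
                        centroid=tuple(float(x) for x in region.centroid),
                    )
                )
        out[gate] = placements
    return out


# ---------------------------------------------------------------------------
# activity-level gates


@dataclass(frozen=True)
class ActivityGateRule:
    """An interval of mean network activity read as logical True."""

    lo: float
    hi: float
    gate: GateLabel
    c2: float = 0.1

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("activity interval must satisfy lo <= hi")


#: reference interval-to-gate assignments for the two excitability modes
#: (intervals are specific to the network they were read off and serve as
#: worked examples / defaults, not universal constants)
DEFAULT_ACTIVITY_RULES = {
    0.1: (
        ActivityGateRule(0.075, 0.085, GateLabel.AND, 0.1),
        ActivityGateRule(0.045, 0.055, GateLabel.AND_NOT, 0.1),
        ActivityGateRule(0.063, 0.073, GateLabel.NOT_AND, 0.1),
        ActivityGateRule(0.045, 0.073, GateLabel.XOR, 0.1),
    ),
    0.107: (
        ActivityGateRule(0.005, 0.007, GateLabel.NOT_AND, 0.107),
        ActivityGateRule(0.015, 0.025, GateLabel.SELECT_X, 0.107),
    ),
}

#: limit-cycle onset (iterations) after which mean activity is measured
DEFAULT_SETTLE_STEPS = {0.1: 80_000, 0.107: 100_000}


@dataclass(frozen=True)
class ActivityRuleReport:
    rule: ActivityGateRule
    fired: tuple[int, int, int]  # response vector over (01, 10, 11)
    induced_gate: GateLabel
    matches: bool


@dataclass(frozen=True)
class ActivityReport:
    mean_activity: Mapping[str, float]
    rules: tuple[ActivityRuleReport, ...]


def activity_gates(
    traces_by_pair: Mapping[str, pd.DataFrame],
    rules: Sequence[ActivityGateRule],
    settle_step: int,
) -> ActivityReport:
    """Evaluate interval rules on the post-transient mean activity.

    ``traces_by_pair`` maps each input pair to a run trace frame with
    columns ``step`` and ``activity``. The mean of A over steps >=
    ``settle_step`` (after the system has settled onto its activity limit
    cycle) is compared with each rule's interval: the rule fires for a pair
    iff the mean lies inside it. The induced response vector is classified
    and checked against the rule's intended gate.
    """
    means: dict[str, float] = {}
    for h in INPUT_PAIRS:
        tr = traces_by_pair[h]
        tail = tr[tr["step"] >= settle_step]
        if tail.empty:
            raise ValueError(
                f"trace for input pair {h} is shorter than settle_step={settle_step}"
            )
        means[h] = float(tail["activity"].mean())
    reports = []
    for rule in rules:
        fired = tuple(
            int(rule.lo <= means[h] <= rule.hi) for h in INPUT_PAIRS
        )
        induced = classify_response_vector(fired)
        reports.append(
            ActivityRuleReport(
                rule=rule,
                fired=fired,
                induced_gate=induced,
                matches=induced is rule.gate,
            )
        )
    return ActivityReport(mean_activity=means, rules=tuple(reports))


# ---------------------------------------------------------------------------
# spiking gates


@dataclass
class GateCensus:
    """Per-electrode gate counts with summary statistics and hierarchy.

    ``table`` has one row per electrode, one column per gate plus a
    ``total`` column; ``summary`` holds mean, standard deviation (sample,
    ddof=1) and median of each column across electrodes. ``hierarchy``
    orders gates by descending total discovery count, grouping gates whose
    totals differ by less than 5% of the grand total into tie sets.
    """

    table: pd.DataFrame
    summary: pd.DataFrame
    hierarchy: tuple[tuple[str, ...], ...]
    events_by_electrode: dict[str, list[SpikeEvent]] = field(default_factory=dict)

    @property
    def totals(self) -> pd.Series:
        return self.table[[g.value for g in GATES]].sum(axis=0)

    @property
    def select_total(self) -> int:
        return int(
            self.totals[GateLabel.SELECT_X.value]
            + self.totals[GateLabel.SELECT_Y.value]
        )

    @property
    def xor_total(self) -> int:
        return int(self.totals[GateLabel.XOR.value])

    def hierarchy_string(self) -> str:
        def fmt(group):
            return group[0] if len(group) == 1 else "{" + ", ".join(group) + "}"

        return " > ".join(fmt(g) for g in self.hierarchy)


def _hierarchy(totals: pd.Series, tie_fraction: float = 0.05):
    grand = totals.sum()
    ordered = totals.sort_values(ascending=False, kind="stable")
    groups: list[list[str]] = []
    for name, count in ordered.items():
        if groups and abs(totals[groups[-1][-1]] - count) < tie_fraction * max(grand, 1):
            groups[-1].append(name)
        else:
            groups.append([name])
    return tuple(tuple(g) for g in groups)


def spiking_gate_census(
    events_by_electrode: Mapping[str, Sequence[SpikeEvent]],
    tie_fraction: float = 0.05,
) -> GateCensus:
    """Classify every aligned event at every electrode and tabulate.

    Each event contributes one gate to its electrode's row (events are
    already separated in time by the alignment's separation window). The
    summary statistics are recomputable from the count table: mean, sample
    standard deviation and median across electrodes.
    """
    gate_cols = [g.value for g in GATES]
    rows = {}
    for el, events in events_by_electrode.items():
        counts = dict.fromkeys(gate_cols, 0)
        for ev in events:
            gate = classify_response_vector(ev.vector)
            if gate is not GateLabel.NONE:
                counts[gate.value] += 1
        counts["total"] = sum(counts.values())
        rows[el] = counts
    table = pd.DataFrame.from_dict(rows, orient="index")[gate_cols + ["total"]]
    table.index.name = "electrode"
    summary = pd.DataFrame(
        {
            "mean": table.mean(),
            "std": table.std(ddof=1),
            "median": table.median(),
        }
    )
    hierarchy = _hierarchy(table[gate_cols].sum(axis=0), tie_fraction)
    return GateCensus(
        table=table,
        summary=summary,
        hierarchy=hierarchy,
        events_by_electrode={k: list(v) for k, v in events_by_electrode.items()},
    )


# ---------------------------------------------------------------------------
# compound (two-output) gates


@dataclass(frozen=True)
class CompoundFinding:
    kind: str  # 'half_adder' (and + xor) or 'toffoli' (select + xor)
    electrodes: tuple[str, str]
    times: tuple[int, int]


_SELECTS = (GateLabel.SELECT_X, GateLabel.SELECT_Y)


def compound_gate_report(
    events_by_electrode: Mapping[str, Sequence[SpikeEvent]],
    simultaneity_window: int = probes.SIMULTANEITY_WINDOW,
) -> list[CompoundFinding]:
    """Two-output circuits from co-timed gates at electrode pairs.

    Within the same event window (event times closer than the simultaneity
    window), one electrode realising AND while another realises XOR forms a
    one-bit half-adder; SELECT alongside XOR forms a Toffoli-style pair.
    Findings are symmetric in electrode order (pairs reported once, labels
    sorted).
    """
    classified = {
        el: [(ev.time, classify_response_vector(ev.vector)) for ev in evs]
        for el, evs in events_by_electrode.items()
    }
    findings = []
    for el_a, el_b in itertools.combinations(sorted(classified), 2):
        for (ta, ga), (tb, gb) in itertools.product(
            classified[el_a], classified[el_b]
        ):
            if abs(ta - tb) >= simultaneity_window:
                continue
            pair = {ga, gb}
            if GateLabel.XOR not in pair:
                continue
            other = (pair - {GateLabel.XOR}).pop() if len(pair) == 2 else None
            if other is GateLabel.AND:
                kind = "half_adder"
            elif other in _SELECTS:
                kind = "toffoli"
            else:
                continue
            findings.append(
                CompoundFinding(kind=kind, electrodes=(el_a, el_b), times=(ta, tb))
            )
    return findings
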